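"""Kinetic smoothing model of anaerobic batch glucose-xylose fermentation.

Measured extracellular time courses (substrates, products, cell dry weight)
are noisy; specific rates derived from them by direct differentiation are
noisier still.  The remedy is a small mechanistic ODE model fitted to the
data, from which rates at any time point are read off analytically:

* substrate uptake follows Monod kinetics gated by a first-order lag,
  ``dc_s/dt = -Y_s * c_x * c_s/(k_ms + c_s) * (1 - exp(-t/tau))``;
* biomass grows in proportion to substrate consumption,
  ``dc_x/dt = -mu_glu * dc_glu/dt - mu_xyl * dc_xyl/dt``;
* each product accumulates in proportion to substrate consumption through a
  substrate-specific yield, ``dc_p/dt = -sum_s Y_{s,p} * dc_s/dt``;
* measured ethanol additionally loses a first-order evaporation term
  ``e * c_eth`` with ``e = a - b*v`` a linear function of broth volume.

Fitting is maximum likelihood under independent Gaussian errors with
species-specific variances (so the optimizer sees a weighted least-squares
problem), in two steps: the substrate/biomass subsystem first, then the
product yields and the evaporation coefficient with step-1 estimates frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

SUBSTRATES = ("glucose", "xylose")
PRODUCTS = (
    "ethanol",
    "xylitol",
    "glycerol",
    "acetate",
    "lactate",
    "succinate",
    "malate",
    "co2",
)
BIOMASS = "cdw"

#: g/mol, for converting g/gCDW/h specific rates to mmol/gDW/h
MOLAR_MASS = {
    "glucose": 180.156,
    "xylose": 150.13,
    "xylitol": 152.15,
    "glycerol": 92.094,
    "acetate": 60.052,
    "ethanol": 46.069,
    "lactate": 90.078,
    "succinate": 118.088,
    "malate": 134.087,
    "co2": 44.009,
}


class FermentationError(ValueError):
    pass


@dataclass
class FermentationParams:
    """Parameters of the smoothing model.

    Units: Y_s in g substrate/g CDW/h; km in g/l; tau in h; mu in g CDW/g
    substrate; yields in g product/g substrate; evap_a in 1/h; evap_b in
    1/(h*l); volume in l.
    """

    Y: dict[str, float]
    km: dict[str, float]
    tau: float
    mu: dict[str, float]
    yields: dict[str, dict[str, float]] = field(default_factory=dict)
    evap_a: float = 0.0
    evap_b: float = 0.0
    volume: float = 1.5

    def __post_init__(self) -> None:
        for s in SUBSTRATES:
            if self.Y.get(s, 0.0) < 0:
                raise FermentationError(f"uptake rate Y[{s}] must be >= 0")
            if self.km.get(s, 1.0) <= 0:
                raise FermentationError(f"Monod constant km[{s}] must be > 0")
        if self.tau <= 0:
            raise FermentationError("lag constant tau must be > 0")
        for s, ys in self.yields.items():
            for p, y in ys.items():
                if y < 0:
                    raise FermentationError(f"yield Y[{s},{p}] must be >= 0")

    @property
    def evaporation(self) -> float:
        return evaporation_rate(self.evap_a, self.evap_b, self.volume)

    def yield_of(self, substrate: str, product: str) -> float:
        return self.yields.get(substrate, {}).get(product, 0.0)


def evaporation_rate(a: float, b: float, volume: float) -> float:
    """Ethanol evaporation coefficient ``e = a - b*v`` (1/h)."""
    e = a - b * volume
    if e < 0:
        warnings.warn(
            f"evaporation rate e = {e:.3g} 1/h is negative (a={a}, b={b}, v={volume})",
            stacklevel=2,
        )
    return e


@dataclass
class SpecificRates:
    """Specific rates at one time point, in g/gCDW/h (non-negative magnitudes).

    ``sign`` is -1 for consumed species (substrates), +1 for produced ones.
    Use :meth:`in_mmol` for mmol/gDW/h.
    """

    time: float
    q: dict[str, float]
    sign: dict[str, int]
    growth_rate: float  # 1/h

    def in_mmol(self, species: str) -> float:
        return self.q[species] * 1000.0 / MOLAR_MASS[species]


def _uptake_rates(params: FermentationParams, c_glu: float, c_xyl: float, t: float):
    lag = 1.0 - np.exp(-t / params.tau) if t > 0 else 0.0
    conc = {"glucose": max(c_glu, 0.0), "xylose": max(c_xyl, 0.0)}
    return {
        s: params.Y.get(s, 0.0) * conc[s] / (params.km.get(s, 1.0) + conc[s]) * lag
        for s in SUBSTRATES
    }


def _rhs(t, y, params: FermentationParams):
    # state: glu, xyl, cdw, products..., measured ethanol
    c_glu, c_xyl, c_x = y[0], y[1], y[2]
    per_x = _uptake_rates(params, c_glu, c_xyl, t)
    r = {s: per_x[s] * max(c_x, 0.0) for s in SUBSTRATES}  # g/l/h consumption
    dglu, dxyl = -r["glucose"], -r["xylose"]
    dx = params.mu.get("glucose", 0.0) * r["glucose"] + params.mu.get("xylose", 0.0) * r["xylose"]
    dy = [dglu, dxyl, dx]
    for p in PRODUCTS:
        dy.append(sum(params.yield_of(s, p) * r[s] for s in SUBSTRATES))
    c_eth = y[3 + PRODUCTS.index("ethanol")]
    e = params.evap_a - params.evap_b * params.volume
    dy.append(dy[3 + PRODUCTS.index("ethanol")] - e * c_eth)
    return dy


def simulate(
    params: FermentationParams,
    initial: dict[str, float],
    times: np.ndarray,
    rtol: float = 1e-8,
) -> pd.DataFrame:
    """Integrate the smoothing model; returns a frame indexed by ``time_h``.

    The ``ethanol`` column is the *measured* (evaporation-corrected) ethanol;
    the intrinsic cumulative production is in ``ethanol_produced``.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise FermentationError("times must be strictly increasing")
    for k, v in initial.items():
        if v < 0:
            raise FermentationError(f"negative initial concentration for {k}")
    y0 = [initial.get("glucose", 0.0), initial.get("xylose", 0.0), initial.get(BIOMASS, 0.0)]
    y0 += [initial.get(p, 0.0) for p in PRODUCTS]
    y0.append(initial.get("ethanol", 0.0))  # measured ethanol starts at observed value
    t0 = min(0.0, times[0])
    sol = solve_ivp(
        _rhs,
        (t0, times[-1]),
        y0,
        t_eval=times,
        args=(params,),
        method="LSODA",
        rtol=rtol,
        atol=1e-10,
    )
    if not sol.success:
        raise FermentationError(f"ODE integration failed: {sol.message}")
    Y = sol.y
    # clip tiny negative excursions from the integrator
    Y[(Y < 0) & (Y > -1e-12)] = 0.0
    cols = {"glucose": Y[0], "xylose": Y[1], BIOMASS: Y[2]}
    for i, p in enumerate(PRODUCTS):
        cols[p if p != "ethanol" else "ethanol_produced"] = Y[3 + i]
    cols["ethanol"] = Y[-1]
    df = pd.DataFrame(cols, index=pd.Index(times, name="time_h"))
    return df


def specific_rates(params: FermentationParams, state: dict[str, float], t: float) -> SpecificRates:
    """Specific consumption/production rates (g/gCDW/h) at time ``t``."""
    if state.get(BIOMASS, 0.0) <= 0:
        raise FermentationError("specific rates undefined at zero biomass")
    per_x = _uptake_rates(params, state.get("glucose", 0.0), state.get("xylose", 0.0), t)
    q = dict(per_x)
    sign = {s: -1 for s in SUBSTRATES}
    for p in PRODUCTS:
        q[p] = sum(params.yield_of(s, p) * per_x[s] for s in SUBSTRATES)
        sign[p] = +1
    growth = sum(params.mu.get(s, 0.0) * per_x[s] for s in SUBSTRATES)
    return SpecificRates(time=t, q=q, sign=sign, growth_rate=growth)


# ---------------------------------------------------------------------------
# two-step maximum-likelihood fit
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    params: FermentationParams
    nll: float
    sigma: dict[str, float]
    step1_cost: float
    step2_cost: float | None
    flags: list[str]


def _sigma_for(data: pd.DataFrame, noise_model: dict[str, float] | None) -> dict[str, float]:
    sigma = {}
    for col in data.columns:
        if noise_model and col in noise_model:
            sigma[col] = float(noise_model[col])
        else:
            scale = float(np.nanmax(np.abs(data[col].to_numpy()))) or 1.0
            sigma[col] = 0.02 * scale
    return sigma


def _nll(res_scaled: np.ndarray, sigma: np.ndarray) -> float:
    return 0.5 * float(np.sum(res_scaled**2)) + float(np.sum(np.log(sigma))) + 0.5 * len(
        res_scaled
    ) * np.log(2 * np.pi)


def fit_two_step(
    data: pd.DataFrame,
    init_guess: FermentationParams,
    noise_model: dict[str, float] | None = None,
    seed: int | None = None,
) -> FitResult:
    """Fit the smoothing model by two-step weighted maximum likelihood.

    Step 1 estimates ``{Y_s, km_s, tau, mu_s}`` against the glucose, xylose
    and cdw series; step 2 freezes them and estimates the product yields and
    the evaporation coefficient against the remaining series.  ``data`` is a
    frame indexed by time (h) with species columns in g/l; missing product
    columns are simply not fitted.  ``seed`` is accepted for interface
    symmetry (the optimizer itself is deterministic).
    """
    del seed
    for col in ("glucose", "xylose", BIOMASS):
        if col not in data.columns:
            raise FermentationError(f"fit requires a {col!r} series")
    times = data.index.to_numpy(dtype=float)
    initial = {c: float(data[c].iloc[0]) for c in data.columns}
    flags: list[str] = []
    sigma = _sigma_for(data, noise_model)

    # ---- step 1: substrate/biomass subsystem ----
    # the inoculation state is estimated alongside the kinetic parameters:
    # seeding the ODE with the noisy first observation (biomass especially)
    # propagates exponentially and biases every kinetic estimate
    step1_cols = ["glucose", "xylose", BIOMASS]
    init0 = [max(float(data[c].iloc[0]), 1e-3) for c in step1_cols]
    p0 = np.log(
        [
            max(init_guess.Y.get("glucose", 1.0), 1e-6),
            max(init_guess.Y.get("xylose", 1.0), 1e-6),
            init_guess.km["glucose"],
            init_guess.km["xylose"],
            init_guess.tau,
            max(init_guess.mu.get("glucose", 0.05), 1e-6),
            max(init_guess.mu.get("xylose", 0.05), 1e-6),
        ]
        + init0
    )

    def unpack1(theta: np.ndarray):
        v = np.exp(theta)
        params = replace(
            init_guess,
            Y={"glucose": v[0], "xylose": v[1]},
            km={"glucose": v[2], "xylose": v[3]},
            tau=v[4],
            mu={"glucose": v[5], "xylose": v[6]},
        )
        y0 = dict(initial)
        y0.update({"glucose": v[7], "xylose": v[8], BIOMASS: v[9]})
        return params, y0

    def resid1(theta: np.ndarray) -> np.ndarray:
        try:
            params, y0 = unpack1(theta)
            sim = simulate(params, y0, times)
        except FermentationError:
            return np.full(len(times) * len(step1_cols), 1e3)
        out = []
        for col in step1_cols:
            out.append((sim[col].to_numpy() - data[col].to_numpy()) / sigma[col])
        return np.concatenate(out)

    # wide box in log-space keeps the optimizer off the Y/km correlation ridge
    sol1 = least_squares(
        resid1, p0, method="trf", bounds=(p0 - 6.0, p0 + 6.0), xtol=1e-12, ftol=1e-12
    )
    if not sol1.success:
        raise FermentationError(f"step-1 optimizer did not converge: {sol1.message}")
    fitted, initial_fit = unpack1(sol1.x)
    initial = initial_fit
    for s in SUBSTRATES:
        if float(np.nanmin(data[s].to_numpy())) > fitted.km[s]:
            flags.append(
                f"flat-likelihood: {s} never falls below fitted km ({fitted.km[s]:.3g} g/l); "
                "km weakly identified"
            )
            warnings.warn(flags[-1], stacklevel=2)

    # ---- step 2: yields + evaporation, step-1 parameters frozen ----
    prod_cols = [p for p in PRODUCTS if p in data.columns]
    step2_cost = None
    if prod_cols:
        n_y = len(prod_cols)
        q0 = []
        for s in SUBSTRATES:
            for p in prod_cols:
                q0.append(init_guess.yield_of(s, p))
        fit_evap = "ethanol" in prod_cols
        if fit_evap:
            q0.append(max(init_guess.evaporation, 1e-4))
        q0 = np.array(q0)

        def unpack2(theta: np.ndarray) -> FermentationParams:
            yields = {s: {} for s in SUBSTRATES}
            k = 0
            for s in SUBSTRATES:
                for p in prod_cols:
                    yields[s][p] = abs(theta[k])
                    k += 1
            p = replace(fitted, yields=yields)
            if fit_evap:
                # one experiment at fixed broth volume identifies only the
                # effective rate e = a - b*v; b is kept from the guess
                e = abs(theta[-1])
                p = replace(p, evap_b=init_guess.evap_b, evap_a=e + init_guess.evap_b * p.volume)
            return p

        def resid2(theta: np.ndarray) -> np.ndarray:
            try:
                sim = simulate(unpack2(theta), initial, times)
            except FermentationError:
                return np.full(len(times) * n_y, 1e3)
            out = []
            for col in prod_cols:
                out.append((sim[col].to_numpy() - data[col].to_numpy()) / sigma[col])
            return np.concatenate(out)

        sol2 = least_squares(resid2, q0, method="lm", xtol=1e-12, ftol=1e-12)
        if not sol2.success:
            raise FermentationError(f"step-2 optimizer did not converge: {sol2.message}")
        fitted = unpack2(sol2.x)
        step2_cost = 2 * sol2.cost

    # achieved joint negative log-likelihood over all fitted series
    sim = simulate(fitted, initial, times)
    res_all, sig_all = [], []
    for col in step1_cols + prod_cols:
        res_all.append((sim[col].to_numpy() - data[col].to_numpy()) / sigma[col])
        sig_all.append(np.full(len(times), sigma[col]))
    nll = _nll(np.concatenate(res_all), np.concatenate(sig_all))
    return FitResult(
        params=fitted,
        nll=nll,
        sigma=sigma,
        step1_cost=2 * sol1.cost,
        step2_cost=step2_cost,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# time-course CSV I/O
# ---------------------------------------------------------------------------

def read_timecourse(path) -> pd.DataFrame:
    """Read a time-course CSV with a ``time_h`` column (g/l concentrations)."""
    df = pd.read_csv(path)
    if "time_h" not in df.columns:
        raise FermentationError("time-course CSV must have a time_h column")
    return df.set_index("time_h")


def write_timecourse(df: pd.DataFrame, path) -> None:
    df.reset_index().to_csv(path, index=False)
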