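"""Population-level orchestration: sampling pipeline, pruning, statistics.

Chains the workflow stages into populations of control-coefficient samples:
for each sampled thermodynamic displacement profile and each sampled
saturation state, build the elasticity matrix, compute control coefficients,
and retain the sample only if the linearized system is locally stable.
Populations can then be pruned on experimental sign information (e.g. reject
every sample where hexokinase has positive control over xylose transport),
summarized with the closest-to-the-mean 50% bands, correlated, and ranked.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import MechanismSpec, elasticity_matrix, sample_saturations
from .mca import ControlSample, DegenerateSampleError, control_coefficients
from .network import NetworkModel, reduce_structure
from .thermo import DisplacementProfile, FluxProfile, sample_concentrations


@dataclass
class PipelineConfig:
    n_conc: int = 10
    n_sat: int = 10
    seed: int = 0
    burn_in: int = 1000
    thin: int = 10
    conc_bounds: dict | None = None
    deltaG0: dict | None = None


@dataclass
class ModelPopulation:
    """An ordered collection of control samples with full audit counts."""

    reaction_ids: list[str]
    met_ids: list[str]
    samples: list[ControlSample]
    counts: dict[str, int]
    run_metadata: dict = field(default_factory=dict)

    @property
    def retained(self) -> list[ControlSample]:
        return self.samples

    def __len__(self) -> int:
        return len(self.samples)

    def coefficients(self, parameter: str, target: str, kind: str = "flux") -> np.ndarray:
        """Vector of one control coefficient across the retained samples."""
        if kind == "flux":
            return np.array([s.flux_cc(parameter, target) for s in self.samples])
        return np.array([s.conc_cc(parameter, target) for s in self.samples])


def _hash_model(model: NetworkModel) -> str:
    from .network import model_to_dict

    payload = json.dumps(model_to_dict(model), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(
    model: NetworkModel,
    flux: FluxProfile,
    config: PipelineConfig,
    mechanisms: dict[str, MechanismSpec],
) -> ModelPopulation:
    """Generate a population of stability-filtered control-coefficient samples.

    ``config.n_conc`` displacement profiles are drawn by the hit-and-run
    sampler; each is combined with ``config.n_sat`` saturation draws.
    Degenerate (singular) and unstable samples are excluded but counted, so
    population sizes stay auditable.  Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    conc_seed = int(rng.integers(2**31 - 1))
    sat_seed = int(rng.integers(2**31 - 1))
    reduced = reduce_structure(model)
    met_ids = [m.id for m in model.internal_metabolites]
    indep_ids = [met_ids[i] for i in reduced.independent_rows]
    try:
        profiles = sample_concentrations(
            model,
            flux,
            deltaG0=config.deltaG0,
            conc_bounds=config.conc_bounds,
            n=config.n_conc,
            seed=conc_seed,
            burn_in=config.burn_in,
            thin=config.thin,
        )
    except Exception as err:  # stage label per contract
        raise RuntimeError(f"concentration-sampling stage failed: {err}") from err
    saturations = sample_saturations(model, mechanisms, n=config.n_sat, seed=sat_seed)
    internal_index = [model.met_index[mid] for mid in met_ids]
    samples: list[ControlSample] = []
    n_unstable = n_degenerate = 0
    for i, prof in enumerate(profiles):
        x_int = np.exp(prof.ln_conc[internal_index])
        for j, sat in enumerate(saturations):
            try:
                E = elasticity_matrix(model, mechanisms, prof, sat, flux)
            except Exception as err:
                raise RuntimeError(
                    f"elasticity stage failed at displacement {i}, saturation {j}: {err}"
                ) from err
            try:
                cs = control_coefficients(
                    reduced,
                    flux.v,
                    E,
                    concentrations=x_int,
                    reaction_ids=flux.reaction_ids,
                    met_ids=indep_ids,
                    provenance=(i, j),
                )
            except DegenerateSampleError:
                n_degenerate += 1
                continue
            if not cs.stable:
                n_unstable += 1
                continue
            samples.append(cs)
    counts = {
        "generated": config.n_conc * config.n_sat,
        "degenerate": n_degenerate,
        "unstable": n_unstable,
        "stable": len(samples),
        "retained": len(samples),
    }
    meta = {
        "seed": config.seed,
        "conc_seed": conc_seed,
        "sat_seed": sat_seed,
        "n_conc": config.n_conc,
        "n_sat": config.n_sat,
        "burn_in": config.burn_in,
        "thin": config.thin,
        "model_hash": _hash_model(model),
        "flux_hash": hashlib.sha256(np.round(flux.v, 12).tobytes()).hexdigest()[:16],
    }
    return ModelPopulation(
        reaction_ids=list(flux.reaction_ids),
        met_ids=indep_ids,
        samples=samples,
        counts=counts,
        run_metadata=meta,
    )


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

_OPS = {
    "lt": np.less,
    "le": np.less_equal,
    "gt": np.greater,
    "ge": np.greater_equal,
}


def prune(
    population: ModelPopulation,
    parameter: str,
    target: str,
    op: str = "lt",
    threshold: float = 0.0,
    kind: str = "flux",
) -> ModelPopulation:
    """Non-destructively reject samples violating a sign/threshold constraint.

    ``prune(pop, 'HXK', 'XTR', 'lt', 0)`` keeps only samples where the
    control coefficient of HXK over the XTR flux is negative.  The original
    population is untouched; counts are updated on the returned copy.
    """
    if op not in _OPS:
        raise ValueError(f"unknown predicate op {op!r}")
    vals = population.coefficients(parameter, target, kind)
    keep = _OPS[op](vals, threshold)
    kept = [s for s, k in zip(population.samples, keep) if k]
    if not kept:
        raise ValueError(
            f"pruning on C_{parameter}^{target} {op} {threshold} removed every sample; "
            "inspect the population before pruning"
        )
    counts = dict(population.counts)
    counts["retained"] = len(kept)
    counts["pruned_away"] = int(len(population.samples) - len(kept))
    meta = dict(population.run_metadata)
    meta.setdefault("prunes", []).append(
        {"parameter": parameter, "target": target, "op": op, "threshold": threshold, "kind": kind}
    )
    return ModelPopulation(
        reaction_ids=population.reaction_ids,
        met_ids=population.met_ids,
        samples=kept,
        counts=counts,
        run_metadata=meta,
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def closest_band(values: np.ndarray, fraction: float = 0.5) -> tuple[float, float]:
    """Range of the ``ceil(n*fraction)`` samples closest to the mean.

    This is the error-bar convention used for the population bar charts: 50%
    of the samples closest to the mean value lie within the band.
    """
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    dist = np.abs(values - mean)
    k = int(np.ceil(len(values) * fraction))
    cutoff = np.sort(dist, kind="stable")[k - 1]
    sel = values[dist <= cutoff + 1e-15]  # ties at the cutoff are kept
    return float(sel.min()), float(sel.max())


def summarize(
    population: ModelPopulation,
    targets: list[tuple[str, str]],
    kind: str = "flux",
    band_fraction: float = 0.5,
) -> pd.DataFrame:
    """Mean, closest-50% band, and sign-consistency per (parameter, target).

    ``sign_fraction`` is the share of samples sharing the sign of the mean;
    ``indeterminate`` flags coefficients whose band straddles zero (the
    population cannot predict the response direction with confidence).
    """
    if len(population) == 0:
        raise ValueError("empty population")
    rows = []
    for parameter, target in targets:
        vals = population.coefficients(parameter, target, kind)
        mean = float(vals.mean())
        lo, hi = closest_band(vals, band_fraction)
        q1, q3 = np.percentile(vals, [25, 75])
        sf = float(np.mean(np.sign(vals) == np.sign(mean))) if mean != 0 else 0.0
        rows.append(
            {
                "parameter": parameter,
                "target": target,
                "mean": mean,
                "band_lo": lo,
                "band_hi": hi,
                "q1": float(q1),
                "q3": float(q3),
                "sign_fraction": sf,
                "indeterminate": bool(lo < 0 < hi),
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows)


def correlate(
    population: ModelPopulation,
    pairs: list[tuple[tuple[str, str], tuple[str, str]]],
    kind: str = "flux",
) -> dict:
    """Pearson correlation between control coefficients across the population."""
    if len(population) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    out = {}
    for (p1, t1), (p2, t2) in pairs:
        a = population.coefficients(p1, t1, kind)
        b = population.coefficients(p2, t2, kind)
        if np.std(a) == 0 or np.std(b) == 0:
            raise ValueError(f"zero variance in C_{p1}^{t1} or C_{p2}^{t2}")
        out[((p1, t1), (p2, t2))] = float(np.corrcoef(a, b)[0, 1])
    return out


def rank_controllers(summary: pd.DataFrame, target: str, k: int) -> list[str]:
    """Top-k parameters by |mean| control over ``target`` (ties lexicographic)."""
    sub = summary[summary["target"] == target].copy()
    sub = sub.sort_values(
        by=["mean", "parameter"],
        key=lambda col: -col.abs() if col.name == "mean" else col,
    )
    return sub["parameter"].head(max(k, 0)).tolist()
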