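"""Compartmentalized stoichiometric network model and I/O.

The in-memory model is deliberately small: metabolites, reactions with signed
stoichiometry, and the stoichiometric matrix derived from them.  Three on-disk
dialects are supported:

* ``native-json`` -- lossless, self-describing; metabolite ids carry an
  explicit compartment suffix (``_c`` cytosol, ``_m`` mitochondria,
  ``_e`` extracellular).
* ``tsv`` -- a reaction table (id, equation string, reversible, deltaG0,
  mechanism); metabolite attributes other than the compartment suffix are
  defaulted on load.
* ``sbml`` -- SBML Level 3 core, stoichiometry only.

Conserved-moiety reduction (:func:`reduce_structure`) produces the link-matrix
decomposition used by the control-analysis engine: the full stoichiometric
matrix restricted to internal metabolites factors as ``L @ N_R`` where the
rows of ``N_R`` are a maximal independent set of metabolite balances and the
left null space rows are the conservation relations (e.g. adenylate or
nicotinamide moiety totals).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

COMPARTMENTS = ("cytosol", "mitochondria", "extracellular")
_SUFFIX = {"c": "cytosol", "m": "mitochondria", "e": "extracellular"}
_SUFFIX_OF = {v: k for k, v in _SUFFIX.items()}

#: default concentration bounds (molar) for unmeasured intracellular species
DEFAULT_CONC_BOUNDS = (1e-8, 1e-1)


class ModelValidationError(ValueError):
    """Raised when a model file or object violates structural invariants."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    formula: dict[str, float] | None = None
    conc_lb: float = DEFAULT_CONC_BOUNDS[0]
    conc_ub: float = DEFAULT_CONC_BOUNDS[1]
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if not (0 < self.conc_lb < self.conc_ub):
            raise ModelValidationError(
                f"metabolite {self.id!r}: concentration bounds must satisfy "
                f"0 < lb < ub, got ({self.conc_lb}, {self.conc_ub})"
            )


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, Fraction | float]
    reversible: bool = True
    deltaG0: float | None = None
    mechanism: str | None = None
    is_transport: bool = False
    is_biomass: bool = False

    @property
    def substrates(self) -> dict[str, float]:
        return {m: -float(c) for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: float(c) for m, c in self.stoichiometry.items() if c > 0}

    @property
    def is_exchange(self) -> bool:
        """Single-species column: crosses the system boundary."""
        return len(self.stoichiometry) == 1


class NetworkModel:
    """Stoichiometric model: metabolites, reactions, and the derived matrix."""

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        name: str = "model",
    ) -> None:
        self.name = name
        self.metabolites = list(metabolites)
        self.reactions = list(reactions)
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        self.met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self.rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        for r in self.reactions:
            for mid in r.stoichiometry:
                if mid not in self.met_index:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references undeclared metabolite {mid!r}"
                    )
            if not r.is_exchange:
                if not r.substrates or not r.products:
                    raise ModelValidationError(
                        f"reaction {r.id!r} must have at least one substrate "
                        "and one product (or be an exchange)"
                    )
        self._stoich: np.ndarray | None = None

    # -- matrix views ------------------------------------------------------
    @property
    def stoich_matrix(self) -> np.ndarray:
        """Full m x n signed stoichiometric matrix (rows metabolites)."""
        if self._stoich is None:
            S = np.zeros((len(self.metabolites), len(self.reactions)))
            for j, r in enumerate(self.reactions):
                for mid, c in r.stoichiometry.items():
                    S[self.met_index[mid], j] = float(c)
            self._stoich = S
        return self._stoich

    @property
    def internal_rows(self) -> np.ndarray:
        return np.array(
            [i for i, m in enumerate(self.metabolites) if not m.boundary], dtype=int
        )

    @property
    def internal_stoich(self) -> np.ndarray:
        """Stoichiometric matrix restricted to non-boundary metabolites."""
        return self.stoich_matrix[self.internal_rows, :]

    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.boundary]

    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self.rxn_index[rid]]

    def metabolite(self, mid: str) -> Metabolite:
        return self.metabolites[self.met_index[mid]]

    def copy(self) -> "NetworkModel":
        return load_model_dict(model_to_dict(self))


@dataclass
class ReducedStructure:
    """Conserved-moiety decomposition of the internal stoichiometry.

    ``full = link_matrix @ reduced_matrix`` where ``reduced_matrix`` is the
    stoichiometry restricted to the independent metabolite rows and every row
    of ``conservation_relations`` annihilates the full internal matrix.
    """

    independent_rows: np.ndarray
    reduced_matrix: np.ndarray
    link_matrix: np.ndarray
    conservation_relations: np.ndarray


def reduce_structure(model: NetworkModel, tol: float = 1e-10) -> ReducedStructure:
    """Row-reduce the internal stoichiometric matrix (Reder decomposition)."""
    N = model.internal_stoich
    m = N.shape[0]
    # pivoted QR on N^T: pivot columns of N^T are the independent rows of N
    _, _, piv = linalg.qr(N.T, pivoting=True)
    rank = np.linalg.matrix_rank(N, tol=max(tol, 1e-12))
    indep = np.sort(piv[:rank])
    NR = N[indep, :]
    # L solves N = L @ NR  (least squares, exact when indep rows span)
    L = np.linalg.lstsq(NR.T, N.T, rcond=None)[0].T
    resid = np.max(np.abs(L @ NR - N)) if N.size else 0.0
    if resid > 1e-8:
        raise ModelValidationError(f"link-matrix reconstruction failed: {resid}")
    G = linalg.null_space(N.T).T if m else np.zeros((0, 0))
    return ReducedStructure(
        independent_rows=indep,
        reduced_matrix=NR,
        link_matrix=L,
        conservation_relations=G,
    )


# ---------------------------------------------------------------------------
# balance checking
# ---------------------------------------------------------------------------

def validate_balances(model: NetworkModel) -> pd.DataFrame:
    """Per-reaction elemental balance report.

    Returns a tidy frame with one row per reaction: status is ``balanced``,
    ``unbalanced``, ``skipped_missing_formula`` or ``exchange``; residuals is
    a dict element -> net atoms produced.
    """
    rows = []
    for r in model.reactions:
        if r.is_exchange:
            rows.append({"reaction": r.id, "status": "exchange", "residuals": {}})
            continue
        formulas = {mid: model.metabolite(mid).formula for mid in r.stoichiometry}
        if any(f is None for f in formulas.values()):
            rows.append(
                {
                    "reaction": r.id,
                    "status": "skipped_missing_formula",
                    "residuals": {},
                }
            )
            continue
        resid: dict[str, float] = {}
        for mid, coef in r.stoichiometry.items():
            for element, count in formulas[mid].items():  # type: ignore[union-attr]
                resid[element] = resid.get(element, 0.0) + float(coef) * count
        resid = {e: v for e, v in resid.items() if abs(v) > 1e-9}
        rows.append(
            {
                "reaction": r.id,
                "status": "balanced" if not resid else "unbalanced",
                "residuals": resid,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# native JSON dialect
# ---------------------------------------------------------------------------

def _coef_to_json(c: Fraction | float):
    if isinstance(c, Fraction):
        return [c.numerator, c.denominator]
    return float(c)


def _coef_from_json(c) -> Fraction | float:
    if isinstance(c, list):
        return Fraction(int(c[0]), int(c[1]))
    return float(c)


def model_to_dict(model: NetworkModel) -> dict:
    return {
        "name": model.name,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "conc_lb": m.conc_lb,
                "conc_ub": m.conc_ub,
                "boundary": m.boundary,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": {k: _coef_to_json(v) for k, v in r.stoichiometry.items()},
                "reversible": r.reversible,
                "deltaG0": r.deltaG0,
                "mechanism": r.mechanism,
                "is_transport": r.is_transport,
                "is_biomass": r.is_biomass,
            }
            for r in model.reactions
        ],
    }


def load_model_dict(d: Mapping) -> NetworkModel:
    mets = [
        Metabolite(
            id=m["id"],
            name=m.get("name", ""),
            compartment=m.get("compartment", "cytosol"),
            formula=m.get("formula"),
            conc_lb=m.get("conc_lb", DEFAULT_CONC_BOUNDS[0]),
            conc_ub=m.get("conc_ub", DEFAULT_CONC_BOUNDS[1]),
            boundary=m.get("boundary", False),
        )
        for m in d["metabolites"]
    ]
    rxns = [
        Reaction(
            id=r["id"],
            stoichiometry={k: _coef_from_json(v) for k, v in r["stoichiometry"].items()},
            reversible=r.get("reversible", True),
            deltaG0=r.get("deltaG0"),
            mechanism=r.get("mechanism"),
            is_transport=r.get("is_transport", False),
            is_biomass=r.get("is_biomass", False),
        )
        for r in d["reactions"]
    ]
    return NetworkModel(mets, rxns, name=d.get("name", "model"))


# ---------------------------------------------------------------------------
# TSV reaction-table dialect
# ---------------------------------------------------------------------------

def _format_equation(r: Reaction) -> str:
    def side(terms: dict[str, float]) -> str:
        parts = []
        for mid in sorted(terms):
            c = terms[mid]
            parts.append(mid if c == 1 else f"{c:g} {mid}")
        return " + ".join(parts)

    arrow = "<=>" if r.reversible else "-->"
    return f"{side(r.substrates)} {arrow} {side(r.products)}"


def _parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    if "<=>" in eq:
        lhs, rhs = eq.split("<=>")
        rev = True
    elif "-->" in eq:
        lhs, rhs = eq.split("-->")
        rev = False
    else:
        raise ModelValidationError(f"equation lacks an arrow: {eq!r}")
    stoich: dict[str, float] = {}

    def add(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            bits = term.split()
            if len(bits) == 2:
                coef, mid = float(bits[0]), bits[1]
            else:
                coef, mid = 1.0, bits[0]
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef

    add(lhs, -1.0)
    add(rhs, +1.0)
    return {k: v for k, v in stoich.items() if v != 0}, rev


def _compartment_from_suffix(mid: str) -> str:
    tail = mid.rsplit("_", 1)[-1]
    return _SUFFIX.get(tail, "cytosol")


def _model_from_tsv(path: Path) -> NetworkModel:
    df = pd.read_csv(path, sep="\t")
    met_ids: dict[str, None] = {}
    rxns = []
    for _, row in df.iterrows():
        stoich, rev = _parse_equation(row["equation"])
        for mid in stoich:
            met_ids.setdefault(mid)
        dg0 = row.get("deltaG0")
        mech = row.get("mechanism")
        rxns.append(
            Reaction(
                id=str(row["id"]),
                stoichiometry=stoich,
                reversible=bool(row["reversible"]) if not pd.isna(row["reversible"]) else rev,
                deltaG0=None if pd.isna(dg0) else float(dg0),
                mechanism=None if (mech is None or pd.isna(mech)) else str(mech),
            )
        )
    mets = [
        Metabolite(
            id=mid,
            compartment=_compartment_from_suffix(mid),
            boundary=_compartment_from_suffix(mid) == "extracellular",
        )
        for mid in met_ids
    ]
    return NetworkModel(mets, rxns, name=path.stem)


def _model_to_tsv(model: NetworkModel, path: Path) -> None:
    rows = [
        {
            "id": r.id,
            "equation": _format_equation(r),
            "reversible": r.reversible,
            "deltaG0": r.deltaG0,
            "mechanism": r.mechanism,
        }
        for r in model.reactions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SBML dialect (Level 3 core, stoichiometry only)
# ---------------------------------------------------------------------------

def _model_to_sbml(model: NetworkModel, path: Path) -> None:
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    sm = doc.createModel()
    sm.setId(_sanitize_sbml_id(model.name))
    for comp in COMPARTMENTS:
        c = sm.createCompartment()
        c.setId(_SUFFIX_OF[comp])
        c.setConstant(True)
    for m in model.metabolites:
        s = sm.createSpecies()
        s.setId(_sanitize_sbml_id(m.id))
        s.setName(m.name or m.id)
        s.setCompartment(_SUFFIX_OF[m.compartment])
        s.setBoundaryCondition(m.boundary)
        s.setHasOnlySubstanceUnits(False)
        s.setConstant(False)
    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(_sanitize_sbml_id(r.id))
        rx.setReversible(r.reversible)
        for mid, c in r.substrates.items():
            ref = rx.createReactant()
            ref.setSpecies(_sanitize_sbml_id(mid))
            ref.setStoichiometry(float(c))
            ref.setConstant(True)
        for mid, c in r.products.items():
            ref = rx.createProduct()
            ref.setSpecies(_sanitize_sbml_id(mid))
            ref.setStoichiometry(float(c))
            ref.setConstant(True)
    libsbml.writeSBMLToFile(doc, str(path))


def _sanitize_sbml_id(raw: str) -> str:
    out = "".join(ch if (ch.isalnum() or ch == "_") else "_" for ch in raw)
    return out if (out and not out[0].isdigit()) else f"r_{out}"


def _model_from_sbml(path: Path) -> NetworkModel:
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ModelValidationError(
            f"SBML parse error in {path}: {doc.getErrorLog().toString()}"
        )
    sm = doc.getModel()
    comp_map = {c.getId(): _SUFFIX.get(c.getId(), "cytosol") for c in sm.getListOfCompartments()}
    mets = [
        Metabolite(
            id=s.getId(),
            name=s.getName() or "",
            compartment=comp_map.get(s.getCompartment(), "cytosol"),
            boundary=s.getBoundaryCondition(),
        )
        for s in sm.getListOfSpecies()
    ]
    rxns = []
    for rx in sm.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rx.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in rx.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        rxns.append(Reaction(id=rx.getId(), stoichiometry=stoich, reversible=rx.getReversible()))
    return NetworkModel(mets, rxns, name=sm.getId() or path.stem)


# ---------------------------------------------------------------------------
# front doors
# ---------------------------------------------------------------------------

_FORMATS = ("native-json", "tsv", "sbml")


def _guess_format(path: Path) -> str:
    ext = path.suffix.lower()
    return {".json": "native-json", ".tsv": "tsv", ".xml": "sbml", ".sbml": "sbml"}.get(
        ext, "native-json"
    )


def load_model(path: str | Path, format: str | None = None) -> NetworkModel:
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "native-json":
        with open(path) as fh:
            return load_model_dict(json.load(fh))
    if fmt == "tsv":
        return _model_from_tsv(path)
    return _model_from_sbml(path)


def write_model(model: NetworkModel, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or _guess_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "native-json":
        with open(path, "w") as fh:
            json.dump(model_to_dict(model), fh, indent=1)
    elif fmt == "tsv":
        _model_to_tsv(model, path)
    else:
        _model_to_sbml(model, path)
    return path
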