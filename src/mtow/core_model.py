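"""Data model for metabolic networks, growth media and thermodynamic parameters.

Conventions used throughout the package:

* Concentrations are in mM; log-concentration variables are natural logs of
  the concentration in mM, so standard reaction Gibbs energies are referenced
  to a 1 mM standard state.
* The stoichiometric matrix ``S`` has one row per metabolite and one column
  per reaction; exchange reactions carry stoichiometry on a single boundary
  metabolite and open the system (``S v = 0`` still holds row-wise).
* Exchange reactions are exempt from thermodynamic constraints: the
  second-law constraint applies to reactions with a standard Gibbs energy
  (the set ``R_G``), and transport energetics are not modelled here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ModelFormatError, ModelValidationError

#: Gas constant in kJ/(mol*K).
R_GAS_KJ = 8.314e-3


@dataclass
class ThermoParams:
    """Global thermodynamic and trade-off parameters.

    Attributes
    ----------
    T : float
        Temperature in K.
    R : float
        Gas constant in kJ/(mol*K).  ``R`` is configurable so that the
        rounded value RT = 2.5 kJ/mol can be reproduced exactly.
    alpha : float
        Dimensionless driving force (-ΔG'/RT) above which extra driving
        force no longer reduces the enzyme demand per unit flux.
    beta : float
        Minimal dimensionless driving force at which a reaction can carry
        forward flux (the hard second-law floor).
    w_plus : float
        Kinetic capacity bound, mmol/(gDW*h) per unit enzyme mass fraction.
    delta : float
        Trade-off weight between metabolite load and enzyme cost.
    c_lower, c_upper : float
        Default global concentration bounds in mM.
    """

    T: float = 298.15
    R: float = R_GAS_KJ
    alpha: float = 4.0
    beta: float = 0.02
    w_plus: float = 1000.0
    delta: float = 1.0
    c_lower: float = 1e-5
    c_upper: float = 100.0

    def __post_init__(self) -> None:
        if not (0 < self.beta < self.alpha):
            raise ValueError("require 0 < beta < alpha")
        if self.w_plus <= 0 or self.T <= 0:
            raise ValueError("w_plus and T must be positive")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")

    @property
    def RT(self) -> float:
        """RT in kJ/mol (~2.479 at 298.15 K with the exact gas constant)."""
        return self.R * self.T


@dataclass
class Dg0Estimate:
    """A standard reaction Gibbs energy with uncertainty and provenance.

    ``category`` records how the estimate was obtained: "I" from the span of
    measured reactions, "II" from group contributions alone, "III" from a
    combination of the two half-reactions, and "undetermined" when neither
    route applies (in which case ``value`` is meaningless and the reaction
    is simply left outside R_G).
    """

    value: float
    stderr: float = 0.0
    category: str = "I"

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be non-negative")
        if self.category not in ("I", "II", "III", "undetermined"):
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    conc_lower: float = 1e-5
    conc_upper: float = 100.0
    fixed_conc: Optional[float] = None
    is_extracellular: bool = False
    is_currency: bool = False


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    flux_lower: float = 0.0
    flux_upper: float = 1000.0
    dg0: Optional[Dg0Estimate] = None
    in_rg: Optional[bool] = None
    is_exchange: bool = False

    def __post_init__(self) -> None:
        # drop explicitly-zero coefficients rather than storing them
        self.stoichiometry = {m: c for m, c in self.stoichiometry.items() if c != 0.0}
        if self.in_rg is None:
            self.in_rg = self.dg0 is not None


@dataclass
class MediumSpec:
    """Growth-medium constraints applied on top of a model.

    ``exchange_bounds`` are net-flux bounds on exchange reactions (referenced
    by original reaction id, valid also after reversible splitting);
    ``extracellular_concs`` and ``currency_concs`` pin metabolite
    concentrations (mM); ``measured_fluxes`` are (value, tolerance) pairs on
    net fluxes, and ``growth_rate`` optionally constrains the biomass flux.
    """

    exchange_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    extracellular_concs: dict[str, float] = field(default_factory=dict)
    currency_concs: dict[str, float] = field(default_factory=dict)
    measured_fluxes: dict[str, tuple[float, float]] = field(default_factory=dict)
    growth_rate: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        for name, concs in (("extracellular_concs", self.extracellular_concs),
                            ("currency_concs", self.currency_concs)):
            for mid, c in concs.items():
                if c <= 0:
                    raise ValueError(f"{name}[{mid}] must be positive")
        for rid, (_, tol) in self.measured_fluxes.items():
            if tol < 0:
                raise ValueError(f"measured_fluxes[{rid}] tolerance must be >= 0")
        if self.growth_rate is not None and self.growth_rate[1] < 0:
            raise ValueError("growth_rate tolerance must be >= 0")


@dataclass
class NetworkModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction: Optional[str] = None
    params: ThermoParams = field(default_factory=ThermoParams)
    #: split reaction id -> original reaction id (populated by split_reversible)
    split_map: dict[str, str] = field(default_factory=dict)
    #: (forward id, reverse id) pairs created by split_reversible
    split_pairs: list[tuple[str, str]] = field(default_factory=list)

    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r.id: j for j, r in enumerate(self.reactions)}

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def stoichiometric_matrix(self, sparse: bool = True):
        """n x m stoichiometric matrix over all metabolites."""
        midx = self.metabolite_index()
        rows, cols, data = [], [], []
        for j, rxn in enumerate(self.reactions):
            for mid, coeff in rxn.stoichiometry.items():
                rows.append(midx[mid])
                cols.append(j)
                data.append(coeff)
        S = sp.coo_matrix(
            (data, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        ).tocsc()
        return S if sparse else S.toarray()

    @property
    def rg_reactions(self) -> list[str]:
        """Ids of reactions subject to thermodynamic constraints."""
        return [r.id for r in self.reactions if r.in_rg and not r.is_exchange]


# ---------------------------------------------------------------------------
# validation


def validate_model(model: NetworkModel) -> list[str]:
    """Return a list of human-readable diagnostics; empty iff the model is valid."""
    diags: list[str] = []
    seen_m: set[str] = set()
    for m in model.metabolites:
        if m.id in seen_m:
            diags.append(f"metabolite {m.id}: duplicate id")
        seen_m.add(m.id)
        if not (0 < m.conc_lower <= m.conc_upper):
            diags.append(f"metabolite {m.id}: requires 0 < conc_lower <= conc_upper")
        if m.fixed_conc is not None and not (m.conc_lower <= m.fixed_conc <= m.conc_upper):
            diags.append(f"metabolite {m.id}: fixed_conc outside [conc_lower, conc_upper]")
    seen_r: set[str] = set()
    for r in model.reactions:
        if r.id in seen_r:
            diags.append(f"reaction {r.id}: duplicate id")
        seen_r.add(r.id)
        if not r.stoichiometry:
            diags.append(f"reaction {r.id}: empty stoichiometry")
        for mid in r.stoichiometry:
            if mid not in seen_m:
                diags.append(f"reaction {r.id}: references unknown metabolite {mid}")
        if r.flux_lower > r.flux_upper:
            diags.append(f"reaction {r.id}: flux_lower > flux_upper")
        if r.in_rg and r.dg0 is None:
            diags.append(f"reaction {r.id}: in_rg is set but no dg0 is present")
        if not r.in_rg and r.dg0 is not None:
            diags.append(f"reaction {r.id}: dg0 present but in_rg is false")
    if model.biomass_reaction is not None and model.biomass_reaction not in seen_r:
        diags.append(f"model: biomass_reaction {model.biomass_reaction} not found")
    return diags


def _require_valid(model: NetworkModel, source: str) -> NetworkModel:
    diags = validate_model(model)
    if diags:
        raise ModelValidationError(f"{source}: " + "; ".join(diags))
    return model


# ---------------------------------------------------------------------------
# reversible splitting


def split_reversible(model: NetworkModel) -> NetworkModel:
    """Replace every reversible reaction with an irreversible forward/reverse pair.

    The reverse copy carries the negated stoichiometry and the negated
    standard Gibbs energy; both copies get flux bounds [0, |original bound|].
    Idempotent on already-irreversible models.  A mapping from split ids to
    original ids and the list of (forward, reverse) pairs are retained on the
    returned model.
    """
    new_reactions: list[Reaction] = []
    split_map = dict(model.split_map)
    split_pairs = list(model.split_pairs)
    for r in model.reactions:
        if not r.reversible:
            clamped = replace(r, flux_lower=max(0.0, r.flux_lower))
            new_reactions.append(clamped)
            continue
        fwd_id, rev_id = f"{r.id}__fwd", f"{r.id}__rev"
        fwd = Reaction(
            id=fwd_id,
            stoichiometry=dict(r.stoichiometry),
            reversible=False,
            flux_lower=0.0,
            flux_upper=max(0.0, r.flux_upper),
            dg0=None if r.dg0 is None else replace(r.dg0),
            is_exchange=r.is_exchange,
        )
        rev = Reaction(
            id=rev_id,
            stoichiometry={m: -c for m, c in r.stoichiometry.items()},
            reversible=False,
            flux_lower=0.0,
            flux_upper=max(0.0, -r.flux_lower),
            dg0=None if r.dg0 is None else replace(r.dg0, value=-r.dg0.value),
            is_exchange=r.is_exchange,
        )
        new_reactions.extend([fwd, rev])
        split_map[fwd_id] = r.id
        split_map[rev_id] = r.id
        split_pairs.append((fwd_id, rev_id))
    return NetworkModel(
        metabolites=[replace(m) for m in model.metabolites],
        reactions=new_reactions,
        biomass_reaction=model.biomass_reaction,
        params=replace(model.params),
        split_map=split_map,
        split_pairs=split_pairs,
    )


def net_flux_rows(model: NetworkModel, original_id: str) -> dict[str, float]:
    """Coefficients expressing the net flux of ``original_id`` in split variables."""
    ridx = model.reaction_index()
    if original_id in ridx:
        return {original_id: 1.0}
    coeffs: dict[str, float] = {}
    for fwd, rev in model.split_pairs:
        if model.split_map.get(fwd) == original_id:
            coeffs[fwd] = 1.0
            coeffs[rev] = -1.0
    if not coeffs:
        raise KeyError(f"reaction {original_id} not found in model (or its split map)")
    return coeffs


def fixed_ln_conc(model: NetworkModel, medium: Optional[MediumSpec] = None) -> dict[str, float]:
    """Map metabolite id -> pinned ln(concentration in mM).

    Medium-level pins (currency and extracellular concentrations) take
    precedence over per-metabolite ``fixed_conc`` values.
    """
    fixed: dict[str, float] = {}
    for m in model.metabolites:
        if m.fixed_conc is not None:
            fixed[m.id] = math.log(m.fixed_conc)
    if medium is not None:
        for mid, c in {**medium.extracellular_concs, **medium.currency_concs}.items():
            fixed[mid] = math.log(c)
    return fixed


# ---------------------------------------------------------------------------
# JSON dialect (canonical round-trip format)


def _metabolite_to_dict(m: Metabolite) -> dict:
    return {
        "id": m.id,
        "name": m.name,
        "compartment": m.compartment,
        "conc_lower": m.conc_lower,
        "conc_upper": m.conc_upper,
        "fixed_conc": m.fixed_conc,
        "is_extracellular": m.is_extracellular,
        "is_currency": m.is_currency,
    }


def _reaction_to_dict(r: Reaction) -> dict:
    return {
        "id": r.id,
        "stoichiometry": dict(r.stoichiometry),
        "reversible": r.reversible,
        "flux_lower": r.flux_lower,
        "flux_upper": r.flux_upper,
        "dg0": None
        if r.dg0 is None
        else {"value": r.dg0.value, "stderr": r.dg0.stderr, "category": r.dg0.category},
        "is_exchange": r.is_exchange,
    }


def write_model(model: NetworkModel, path: str | Path) -> None:
    """Write the model in the JSON dialect (bit-exact round trip)."""
    doc = {
        "metabolites": [_metabolite_to_dict(m) for m in model.metabolites],
        "reactions": [_reaction_to_dict(r) for r in model.reactions],
        "params": {
            "T": model.params.T,
            "R": model.params.R,
            "alpha": model.params.alpha,
            "beta": model.params.beta,
            "w_plus": model.params.w_plus,
            "delta": model.params.delta,
            "c_lower": model.params.c_lower,
            "c_upper": model.params.c_upper,
        },
        "biomass_reaction": model.biomass_reaction,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def _model_from_json_doc(doc: dict, source: str) -> NetworkModel:
    try:
        mets = [
            Metabolite(
                id=d["id"],
                name=d.get("name", ""),
                compartment=d.get("compartment", "c"),
                conc_lower=float(d.get("conc_lower", 1e-5)),
                conc_upper=float(d.get("conc_upper", 100.0)),
                fixed_conc=None if d.get("fixed_conc") is None else float(d["fixed_conc"]),
                is_extracellular=bool(d.get("is_extracellular", False)),
                is_currency=bool(d.get("is_currency", False)),
            )
            for d in doc["metabolites"]
        ]
        rxns = []
        for d in doc["reactions"]:
            dg0 = d.get("dg0")
            rxns.append(
                Reaction(
                    id=d["id"],
                    stoichiometry={k: float(v) for k, v in d["stoichiometry"].items()},
                    reversible=bool(d.get("reversible", False)),
                    flux_lower=float(d.get("flux_lower", 0.0)),
                    flux_upper=float(d.get("flux_upper", 1000.0)),
                    dg0=None
                    if dg0 is None
                    else Dg0Estimate(
                        value=float(dg0["value"]),
                        stderr=float(dg0.get("stderr", 0.0)),
                        category=dg0.get("category", "I"),
                    ),
                    is_exchange=bool(d.get("is_exchange", False)),
                )
            )
        pd_ = doc.get("params", {})
        params = ThermoParams(
            T=float(pd_.get("T", 298.15)),
            R=float(pd_.get("R", R_GAS_KJ)),
            alpha=float(pd_.get("alpha", 4.0)),
            beta=float(pd_.get("beta", 0.02)),
            w_plus=float(pd_.get("w_plus", 1000.0)),
            delta=float(pd_.get("delta", 1.0)),
            c_lower=float(pd_.get("c_lower", 1e-5)),
            c_upper=float(pd_.get("c_upper", 100.0)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"{source}: malformed model record ({exc})") from exc
    model = NetworkModel(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction=doc.get("biomass_reaction"),
        params=params,
    )
    return _require_valid(model, source)


# ---------------------------------------------------------------------------
# TSV dialect


def _model_from_tsv(path: Path, reactions_path: Optional[Path]) -> NetworkModel:
    try:
        stoich = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error wrapping
        raise ModelFormatError(f"{path}: cannot parse TSV ({exc})") from exc
    required = {"reaction_id", "metabolite_id", "coefficient"}
    if not required.issubset(stoich.columns):
        raise ModelFormatError(f"{path}: missing columns {sorted(required - set(stoich.columns))}")
    if reactions_path is None:
        candidate = path.with_suffix(".reactions.tsv")
        reactions_path = candidate if candidate.exists() else None
    attrs = None
    if reactions_path is not None:
        attrs = pd.read_csv(reactions_path, sep="\t").set_index("reaction_id")
    met_ids = list(dict.fromkeys(stoich["metabolite_id"]))
    mets = [Metabolite(id=m) for m in met_ids]
    rxns: list[Reaction] = []
    for rid, grp in stoich.groupby("reaction_id", sort=False):
        st = dict(zip(grp["metabolite_id"], grp["coefficient"].astype(float)))
        kw: dict = {}
        if attrs is not None and rid in attrs.index:
            row = attrs.loc[rid]
            kw["reversible"] = bool(row.get("reversible", False))
            kw["flux_lower"] = float(row.get("flux_lower", 0.0))
            kw["flux_upper"] = float(row.get("flux_upper", 1000.0))
            kw["is_exchange"] = bool(row.get("is_exchange", False))
            if "dg0" in attrs.columns and pd.notna(row.get("dg0")):
                kw["dg0"] = Dg0Estimate(
                    value=float(row["dg0"]),
                    stderr=float(row.get("dg0_stderr", 0.0) if pd.notna(row.get("dg0_stderr")) else 0.0),
                )
        rxns.append(Reaction(id=str(rid), stoichiometry=st, **kw))
    return _require_valid(NetworkModel(metabolites=mets, reactions=rxns), str(path))


# ---------------------------------------------------------------------------
# SBML (read-only, level 3 + FBC via cobrapy)


def _model_from_sbml(path: Path) -> NetworkModel:
    import cobra.io

    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise ModelFormatError(f"{path}: SBML parse failure ({exc})") from exc
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or "c",
            is_extracellular=(m.compartment or "").startswith("e"),
        )
        for m in cmodel.metabolites
    ]
    biomass = None
    rxns = []
    for r in cmodel.reactions:
        if "biomass" in r.id.lower() and biomass is None:
            biomass = r.id
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: c for m, c in r.metabolites.items()},
                reversible=r.lower_bound < 0,
                flux_lower=r.lower_bound,
                flux_upper=r.upper_bound,
                is_exchange=r.boundary,
            )
        )
    return _require_valid(
        NetworkModel(metabolites=mets, reactions=rxns, biomass_reaction=biomass), str(path)
    )


def load_model(
    path: str | Path,
    format: str = "json",
    reactions_path: Optional[str | Path] = None,
) -> NetworkModel:
    """Load and validate a NetworkModel from ``path``.

    ``format`` is one of "json" (the canonical dialect), "tsv" (a
    stoichiometry table with an optional companion reaction-attribute table)
    or "sbml" (read-only, bounds taken from the FBC package).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"{path}: invalid JSON ({exc})") from exc
        return _model_from_json_doc(doc, str(path))
    if format == "tsv":
        return _model_from_tsv(path, None if reactions_path is None else Path(reactions_path))
    if format == "sbml":
        return _model_from_sbml(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# medium I/O (JSON or YAML mapping)


def load_medium(path: str | Path) -> MediumSpec:
    import yaml

    doc = yaml.safe_load(Path(path).read_text()) or {}
    return MediumSpec(
        exchange_bounds={k: (float(v[0]), float(v[1])) for k, v in doc.get("exchange_bounds", {}).items()},
        extracellular_concs={k: float(v) for k, v in doc.get("extracellular_concs", {}).items()},
        currency_concs={k: float(v) for k, v in doc.get("currency_concs", {}).items()},
        measured_fluxes={k: (float(v[0]), float(v[1])) for k, v in doc.get("measured_fluxes", {}).items()},
        growth_rate=None
        if doc.get("growth_rate") is None
        else (float(doc["growth_rate"][0]), float(doc["growth_rate"][1])),
    )


def write_medium(medium: MediumSpec, path: str | Path) -> None:
    doc = {
        "exchange_bounds": {k: list(v) for k, v in medium.exchange_bounds.items()},
        "extracellular_concs": dict(medium.extracellular_concs),
        "currency_concs": dict(medium.currency_concs),
        "measured_fluxes": {k: list(v) for k, v in medium.measured_fluxes.items()},
        "growth_rate": None if medium.growth_rate is None else list(medium.growth_rate),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
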