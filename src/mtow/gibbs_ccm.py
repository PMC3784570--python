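"""Component-contribution estimation of standard reaction Gibbs energies.

A hybrid estimator: reactions (as signed vectors over a compound index) are
decomposed orthogonally against the span of a training set of measured
reactions.  The in-span half is priced by a least-squares fit to the
measured Gibbs energies ("reactant contribution"); the orthogonal remainder
is priced by group contributions fit on the same training data.  Because
both halves reduce to a single per-compound formation-energy vector, every
estimate is first-law consistent by construction: estimates are linear in
the reaction vector, so sums of reactions get sums of estimates and reverse
reactions get negated estimates.

Reactions are assigned to categories:

* ``I``   -- entirely within the span of measured reactions,
* ``II``  -- no span component at all; group contributions price everything,
* ``III`` -- a non-trivial span half plus a group-decomposable remainder,
* ``undetermined`` -- the remainder touches a compound that cannot be
  decomposed into groups; no estimate is produced and the reaction is left
  outside the thermodynamically-constrained set downstream.

Category I is preferred over III (the span fit does not rely on the group
independence assumption and is more accurate); this falls out of the
orthogonal decomposition, which puts as much of the reaction as possible in
the span half.

A biochemical (pH / ionic-strength conditioned) value is obtained from
species-level formation energies by a Legendre transform over pseudoisomers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core_model import Dg0Estimate, ThermoParams
from .errors import EstimationError

#: relative residual-norm tolerance deciding span membership and support
SPAN_TOL = 1e-8

#: Debye-Hueckel parameters for aqueous solutions at 25 degC (kJ/mol units)
_DH_A = 2.91482
_DH_B = 1.6


@dataclass
class MeasuredReactionSet:
    """Training data: measured reactions over a shared compound index."""

    S_train: np.ndarray  # (n_compounds, k) signed stoichiometries
    dg0_obs: np.ndarray  # (k,) observed standard Gibbs energies, kJ/mol
    reaction_ids: list[str]
    compound_ids: list[str]

    def __post_init__(self) -> None:
        self.S_train = np.asarray(self.S_train, dtype=float)
        self.dg0_obs = np.asarray(self.dg0_obs, dtype=float)
        n_c, k = self.S_train.shape
        if k < 1:
            raise ValueError("need at least one measured reaction")
        if np.any(np.all(self.S_train == 0, axis=0)):
            raise ValueError("training columns must be non-zero")
        if len(self.reaction_ids) != k or len(self.compound_ids) != n_c:
            raise ValueError("id lists must match matrix dimensions")


@dataclass
class GroupDecomposition:
    """Compound-by-group incidence counts plus a decomposability flag."""

    G: np.ndarray  # (n_compounds, n_groups) non-negative counts
    group_ids: list[str]
    compound_ids: list[str]
    decomposable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.decomposable is None:
            self.decomposable = np.ones(self.G.shape[0], dtype=bool)
        self.decomposable = np.asarray(self.decomposable, dtype=bool)
        if self.G.shape != (len(self.compound_ids), len(self.group_ids)):
            raise ValueError("G shape must match id lists")


@dataclass
class PseudoisomerSet:
    """Protonation species of one compound: (formation dG°, n_H, charge)."""

    compound_id: str
    species: list[tuple[float, int, int]]
    pH: Optional[float] = None
    ionic_strength: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError(f"{self.compound_id}: at least one species required")


class ComponentContribution:
    """Fitted component-contribution estimator.

    Parameters
    ----------
    train : MeasuredReactionSet
    groups : GroupDecomposition
        Must share the training compound index (same order).
    group_energies : array, optional
        Known per-group energies (kJ/mol).  When omitted they are fit by
        least squares of the group model against the measured reaction
        energies.
    """

    def __init__(
        self,
        train: MeasuredReactionSet,
        groups: GroupDecomposition,
        group_energies: Optional[np.ndarray] = None,
    ):
        if groups.compound_ids != train.compound_ids:
            raise ValueError("train and groups must share the compound index")
        self.train = train
        self.groups = groups
        S = train.S_train
        y = train.dg0_obs
        n_c, k = S.shape

        # orthogonal projector onto the span of measured reactions
        U, sv, _ = np.linalg.svd(S, full_matrices=False)
        rank = int(np.sum(sv > SPAN_TOL * (sv[0] if sv.size else 1.0)))
        self._rank = rank
        Ur = U[:, :rank]
        self.P = Ur @ Ur.T  # (n_c, n_c)

        # reactant-contribution fit: formation-energy vector from S'^T g ~ y
        A = S.T  # (k, n_c)
        self._A_pinv = np.linalg.pinv(A, rcond=SPAN_TOL)
        self.g_rc = self._A_pinv @ y
        resid_rc = A @ self.g_rc - y
        dof_rc = max(k - rank, 1)
        self.sigma2_rc = float(resid_rc @ resid_rc) / dof_rc

        # group-contribution fit (or supplied energies)
        B = A @ groups.G  # (k, n_groups)
        if group_energies is not None:
            self.group_energies = np.asarray(group_energies, dtype=float)
            self._B_pinv = None
            self.sigma2_gc = 0.0
        else:
            self._B_pinv = np.linalg.pinv(B, rcond=SPAN_TOL)
            self.group_energies = self._B_pinv @ y
            resid_gc = B @ self.group_energies - y
            rank_b = np.linalg.matrix_rank(B, tol=None)
            dof_gc = max(k - rank_b, 1)
            self.sigma2_gc = float(resid_gc @ resid_gc) / dof_gc

        # the whole estimator collapses to one formation-energy vector
        g_group = groups.G @ self.group_energies
        self.formation = self.P @ self.g_rc + (np.eye(n_c) - self.P) @ g_group

    # -- categorisation ----------------------------------------------------

    def categorize(self, reaction_vector: np.ndarray) -> str:
        r = np.asarray(reaction_vector, dtype=float)
        if r.shape != (len(self.train.compound_ids),):
            raise ValueError("reaction vector must live on the training compound index")
        norm = np.linalg.norm(r)
        if norm == 0:
            return "I"  # the empty reaction is trivially in the span
        r_span = self.P @ r
        r_perp = r - r_span
        if np.linalg.norm(r_perp) < SPAN_TOL * norm:
            return "I"
        support_perp = np.abs(r_perp) > SPAN_TOL * norm
        if np.any(support_perp & ~self.groups.decomposable):
            return "undetermined"
        if np.linalg.norm(r_span) < SPAN_TOL * norm:
            return "II"
        return "III"

    # -- estimation --------------------------------------------------------

    def estimate(self, reaction_vector: np.ndarray) -> Dg0Estimate:
        r = np.asarray(reaction_vector, dtype=float)
        category = self.categorize(r)
        if category == "undetermined":
            raise EstimationError(
                "reaction has a non-decomposable compound outside the measured span"
            )
        value = float(r @ self.formation)
        stderr = self._stderr(r)
        return Dg0Estimate(value=value, stderr=stderr, category=category)

    def half_reaction_values(self, reaction_vector: np.ndarray) -> tuple[float, float]:
        """(span half, group half) energies whose sum is the estimate."""
        r = np.asarray(reaction_vector, dtype=float)
        r_span = self.P @ r
        r_perp = r - r_span
        g_group = self.groups.G @ self.group_energies
        return float(r_span @ self.g_rc), float(r_perp @ g_group)

    def _stderr(self, r: np.ndarray) -> float:
        r_span = self.P @ r
        r_perp = r - r_span
        var = self.sigma2_rc * float(np.sum((self._A_pinv.T @ r_span) ** 2))
        if self._B_pinv is not None:
            c = self.groups.G.T @ r_perp
            var += self.sigma2_gc * float(np.sum((self._B_pinv.T @ c) ** 2))
        return math.sqrt(max(var, 0.0))


# ---------------------------------------------------------------------------
# functional façade


def categorize(
    reaction_vector: np.ndarray,
    train: MeasuredReactionSet,
    groups: GroupDecomposition,
) -> str:
    return ComponentContribution(train, groups).categorize(reaction_vector)


def estimate_dg0(
    reaction_vector: np.ndarray,
    train: MeasuredReactionSet,
    groups: GroupDecomposition,
    group_energies: Optional[np.ndarray] = None,
) -> Dg0Estimate:
    return ComponentContribution(train, groups, group_energies).estimate(reaction_vector)


# ---------------------------------------------------------------------------
# Legendre transform over pseudoisomers


def transformed_formation_energy(
    pseudo: PseudoisomerSet,
    pH: float,
    ionic_strength: float,
    params: ThermoParams,
) -> float:
    """pH/ionic-strength conditioned formation energy of one compound.

    Each species energy is corrected for proton binding
    (+ n_H·RT·ln(10)·pH) and for ionic-strength screening (extended
    Debye-Hueckel on z² - n_H), then the species are pooled:
    ΔfG'° = -RT · ln Σ exp(-ΔfG'°_species / RT).
    """
    RT = params.RT
    sqrt_i = math.sqrt(max(ionic_strength, 0.0))
    dh = _DH_A * sqrt_i / (1.0 + _DH_B * sqrt_i)
    corrected = [
        dgf + n_h * RT * math.log(10.0) * pH - dh * (charge**2 - n_h)
        for dgf, n_h, charge in pseudo.species
    ]
    return float(-RT * logsumexp(-np.asarray(corrected) / RT))


def legendre_transform(
    raw_dg0: float,
    participants: Sequence[tuple[float, Optional[PseudoisomerSet]]],
    pH: float,
    ionic_strength: float,
    params: ThermoParams,
) -> float:
    """Transformed reaction Gibbs energy at the given pH and ionic strength.

    ``participants`` pairs each stoichiometric coefficient with the
    compound's pseudoisomer table.  When every participant has species
    data, the reaction energy is recomposed from the transformed
    per-compound formation energies; if any table is missing the raw value
    is passed through unchanged with a warning (no partial transforms).
    """
    if any(ps is None for _, ps in participants):
        warnings.warn(
            "pseudoisomer data missing for some participants; "
            "returning the untransformed value",
            stacklevel=2,
        )
        return raw_dg0
    return float(
        sum(
            coeff * transformed_formation_energy(ps, pH, ionic_strength, params)
            for coeff, ps in participants
        )
    )


# ---------------------------------------------------------------------------
# leave-one-out cross-validation


@dataclass
class LooResult:
    table: pd.DataFrame  # reaction_id, category, abs_err_cc, abs_err_gcm, included
    median_cc: float
    median_gcm: float


def loo_crossvalidate(
    train: MeasuredReactionSet,
    groups: GroupDecomposition,
) -> LooResult:
    """Leave-one-out comparison of span-augmented vs group-only estimation.

    Each training reaction is held out in turn and re-estimated from the
    remainder, once with the full component-contribution estimator and once
    with the group-contribution fit alone.  Held-out reactions that become
    undetermined without their own measurement are flagged and excluded
    from the medians.
    """
    S, y = train.S_train, train.dg0_obs
    k = S.shape[1]
    if k < 2:
        raise ValueError("leave-one-out needs at least two training reactions")
    rows = []
    for i in range(k):
        keep = [j for j in range(k) if j != i]
        sub = MeasuredReactionSet(
            S_train=S[:, keep],
            dg0_obs=y[keep],
            reaction_ids=[train.reaction_ids[j] for j in keep],
            compound_ids=train.compound_ids,
        )
        cc = ComponentContribution(sub, groups)
        r = S[:, i]
        category = cc.categorize(r)
        if category == "undetermined":
            rows.append((train.reaction_ids[i], category, np.nan, np.nan, False))
            continue
        est_cc = float(r @ cc.formation)
        est_gcm = float(r @ (groups.G @ cc.group_energies))
        rows.append(
            (
                train.reaction_ids[i],
                category,
                abs(est_cc - y[i]),
                abs(est_gcm - y[i]),
                True,
            )
        )
    table = pd.DataFrame(
        rows, columns=["reaction_id", "category", "abs_err_cc", "abs_err_gcm", "included"]
    )
    used = table[table["included"]]
    return LooResult(
        table=table,
        median_cc=float(used["abs_err_cc"].median()) if len(used) else math.nan,
        median_gcm=float(used["abs_err_gcm"].median()) if len(used) else math.nan,
    )


# ---------------------------------------------------------------------------
# tabular I/O


def load_measured_reactions(stoich_path: str | Path, dg0_path: str | Path) -> MeasuredReactionSet:
    """Read the TSV training tables.

    ``stoich_path``: columns reaction_id, compound_id, coefficient.
    ``dg0_path``: columns reaction_id, dg0_obs.
    """
    stoich = pd.read_csv(stoich_path, sep="\t")
    obs = pd.read_csv(dg0_path, sep="\t").set_index("reaction_id")
    reaction_ids = list(dict.fromkeys(stoich["reaction_id"]))
    compound_ids = sorted(set(stoich["compound_id"]))
    cidx = {c: i for i, c in enumerate(compound_ids)}
    S = np.zeros((len(compound_ids), len(reaction_ids)))
    for j, rid in enumerate(reaction_ids):
        grp = stoich[stoich["reaction_id"] == rid]
        for _, row in grp.iterrows():
            S[cidx[row["compound_id"]], j] += float(row["coefficient"])
    y = np.array([float(obs.loc[rid, "dg0_obs"]) for rid in reaction_ids])
    return MeasuredReactionSet(S, y, [str(r) for r in reaction_ids], compound_ids)


def load_group_decomposition(
    path: str | Path, compound_ids: list[str], non_decomposable: Sequence[str] = ()
) -> GroupDecomposition:
    """Read the TSV group incidence table (compound_id, group_id, count)."""
    tab = pd.read_csv(path, sep="\t")
    group_ids = sorted(set(tab["group_id"]))
    gidx = {g: i for i, g in enumerate(group_ids)}
    cidx = {c: i for i, c in enumerate(compound_ids)}
    G = np.zeros((len(compound_ids), len(group_ids)))
    for _, row in tab.iterrows():
        if row["compound_id"] in cidx:
            G[cidx[row["compound_id"]], gidx[row["group_id"]]] += float(row["count"])
    decomposable = np.array([c not in set(non_decomposable) for c in compound_ids])
    return GroupDecomposition(G, group_ids, list(compound_ids), decomposable)


def load_pseudoisomers(path: str | Path) -> dict[str, PseudoisomerSet]:
    """Read a JSON pseudoisomer table keyed by compound id."""
    import json

    doc = json.loads(Path(path).read_text())
    out = {}
    for cid, entry in doc.items():
        out[cid] = PseudoisomerSet(
            compound_id=cid,
            species=[(float(s["dg0_f"]), int(s["n_H"]), int(s["charge"])) for s in entry["species"]],
            pH=entry.get("pH"),
            ionic_strength=entry.get("ionic_strength"),
        )
    return out
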