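"""Step (i): thermodynamically feasible flux via mixed-integer programming.

Finds a mass-balanced flux distribution on the split-irreversible network
such that every flux-carrying reaction with a known standard Gibbs energy
admits log concentrations (within the global box, fixed metabolites pinned)
giving it at least the minimal driving force β.  Measurement error in the
standard energies is absorbed by per-reaction corrections ε_j bounded by
``correction_bound``; the objective minimises Σ|ε_j| (L1, via positive /
negative splitting), so corrections are only spent where the uncorrected
energies admit no feasible solution.

Indicator (big-M) constraints tie the second-law requirement to binary
activity variables; forward/reverse copies of a split reversible reaction
are never active together.  The backend is HiGHS through
``scipy.optimize.milp``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .core_model import (
    MediumSpec,
    NetworkModel,
    ThermoParams,
    fixed_ln_conc,
    net_flux_rows,
)
from .errors import SolverError

#: fluxes below this (mmol/gDW/h) count as inactive and are thermodynamically
#: unconstrained; a strict v > 0 is not MILP-representable
FLUX_EPSILON = 1e-6

#: default correction bound fallback (kJ/mol): the typical accuracy of
#: component-contribution estimates on measured reaction sets
DEFAULT_CORRECTION_FLOOR = 2.9

#: tie-break weight steering HiGHS to sparse low-flux solutions among
#: correction-equivalent optima (reported objectives exclude it)
_FLUX_TIEBREAK = 1e-6


@dataclass
class FluxSolution:
    """Output of the MILP step on a split-irreversible model."""

    reaction_ids: list[str]
    v: np.ndarray  # fluxes, mmol/gDW/h, >= 0
    active: np.ndarray  # booleans, v > FLUX_EPSILON
    corrections: dict[str, float]  # reaction id -> epsilon, kJ/mol (R_G only)
    objective: float  # total |correction|, kJ/mol
    status: str  # optimal | feasible | infeasible
    ln_conc_witness: dict[str, float] = field(default_factory=dict)

    def flux(self, rid: str) -> float:
        return float(self.v[self.reaction_ids.index(rid)])

    def corrected_dg0(self, model: NetworkModel) -> dict[str, float]:
        """Standard energies with the MILP corrections folded in."""
        out = {}
        for r in model.reactions:
            if r.dg0 is not None:
                out[r.id] = r.dg0.value + self.corrections.get(r.id, 0.0)
        return out

    def active_rg(self, model: NetworkModel) -> list[str]:
        rg = set(model.rg_reactions)
        return [
            rid
            for rid, a in zip(self.reaction_ids, self.active)
            if a and rid in rg
        ]


def _correction_bounds(model: NetworkModel, correction_bound: Optional[float]) -> dict[str, float]:
    out = {}
    for r in model.reactions:
        if r.in_rg and not r.is_exchange:
            if correction_bound is not None:
                out[r.id] = correction_bound
            else:
                out[r.id] = max(2.0 * r.dg0.stderr, DEFAULT_CORRECTION_FLOOR)
    return out


def _conc_bounds(model: NetworkModel, medium: Optional[MediumSpec], params: ThermoParams):
    """Per-metabolite ln-concentration bounds with fixed values pinned."""
    fixed = fixed_ln_conc(model, medium)
    lo, hi = [], []
    for m in model.metabolites:
        if m.id in fixed:
            lo.append(fixed[m.id])
            hi.append(fixed[m.id])
        else:
            lo.append(math.log(max(m.conc_lower, params.c_lower)))
            hi.append(math.log(min(m.conc_upper, params.c_upper)))
    return np.array(lo), np.array(hi)


def solve_feasible_flux(
    model: NetworkModel,
    medium: Optional[MediumSpec] = None,
    params: Optional[ThermoParams] = None,
    correction_bound: Optional[float] = None,
    extra_constraints: Sequence[LinearConstraint] = (),
    mip_rel_gap: float = 0.0,
) -> FluxSolution:
    """Solve the feasibility MILP; see the module docstring for the model.

    ``correction_bound`` overrides the per-reaction default
    max(2·stderr, 2.9) kJ/mol.  ``extra_constraints`` (over the full MILP
    variable vector) is used internally for integer cuts.
    """
    params = params or model.params
    if any(r.reversible for r in model.reactions):
        raise ValueError("model must be split to irreversible reactions first")
    m = len(model.reactions)
    n = len(model.metabolites)
    ridx = model.reaction_index()
    rg_ids = model.rg_reactions
    eps_bound = _correction_bounds(model, correction_bound)

    # binary indicators for R_G members and both halves of split pairs
    bin_ids = list(dict.fromkeys(rg_ids + [x for pair in model.split_pairs for x in pair]))
    bidx = {rid: i for i, rid in enumerate(bin_ids)}
    nb = len(bin_ids)
    nrg = len(rg_ids)

    lo_ln, hi_ln = _conc_bounds(model, medium, params)
    RT, beta = params.RT, params.beta

    # variable layout: v (m) | a (nb) | ln_c (n) | eps+ (nrg) | eps- (nrg)
    off_a, off_ln, off_ep, off_em = m, m + nb, m + nb + n, m + nb + n + nrg
    nvar = m + nb + n + 2 * nrg

    v_lo = np.array([max(0.0, r.flux_lower) for r in model.reactions])
    v_hi = np.minimum(np.array([r.flux_upper for r in model.reactions]), 1e6)
    lb = np.concatenate([v_lo, np.zeros(nb), lo_ln, np.zeros(2 * nrg)])
    ub = np.concatenate(
        [v_hi, np.ones(nb), hi_ln, *[np.array([eps_bound[r] for r in rg_ids])] * 2]
    )

    constraints: list[LinearConstraint] = []
    S = model.stoichiometric_matrix()

    # (1) steady-state mass balance
    A_mb = sp.hstack([S, sp.csr_matrix((n, nvar - m))])
    constraints.append(LinearConstraint(A_mb, 0.0, 0.0))

    # (2) indicator/flux coupling: ub_j * a_j >= v_j >= 2*FLUX_EPSILON * a_j,
    #     so a_j == 1 exactly when reaction j carries (non-negligible) flux
    rows = []
    for rid in bin_ids:
        j = ridx[rid]
        row = np.zeros(nvar)
        row[j] = 1.0
        row[off_a + bidx[rid]] = -max(v_hi[j], FLUX_EPSILON)
        rows.append(row)
    constraints.append(LinearConstraint(np.array(rows), -np.inf, 0.0))
    rows = []
    for rid in bin_ids:
        j = ridx[rid]
        row = np.zeros(nvar)
        row[j] = 1.0
        row[off_a + bidx[rid]] = -2.0 * FLUX_EPSILON
        rows.append(row)
    constraints.append(LinearConstraint(np.array(rows), 0.0, np.inf))

    # (3) second law with corrections, relaxed by big-M when inactive:
    #     dg0 + eps + RT * S_j . ln c <= -beta*RT + M_j (1 - a_j)
    midx = model.metabolite_index()
    rows, rhs = [], []
    for jj, rid in enumerate(rg_ids):
        rxn = model.get_reaction(rid)
        dg0 = rxn.dg0.value
        # tightest big-M valid over the concentration box
        worst = dg0 + eps_bound[rid] + beta * RT
        for mid, coeff in rxn.stoichiometry.items():
            i = midx[mid]
            worst += RT * (coeff * (hi_ln[i] if coeff > 0 else lo_ln[i]))
        M = max(worst, 0.0) + 1.0
        row = np.zeros(nvar)
        for mid, coeff in rxn.stoichiometry.items():
            row[off_ln + midx[mid]] = RT * coeff
        row[off_ep + jj] = 1.0
        row[off_em + jj] = -1.0
        row[off_a + bidx[rid]] = M
        rows.append(row)
        rhs.append(M - beta * RT - dg0)
    if rows:
        constraints.append(LinearConstraint(np.array(rows), -np.inf, np.array(rhs)))

    # (4) a forward/reverse split pair is never active together
    rows = []
    for fwd, rev in model.split_pairs:
        row = np.zeros(nvar)
        row[off_a + bidx[fwd]] = 1.0
        row[off_a + bidx[rev]] = 1.0
        rows.append(row)
    if rows:
        constraints.append(LinearConstraint(np.array(rows), -np.inf, 1.0))

    # (5) medium: exchange bounds, measured net fluxes, growth rate
    def _net_constraint(orig_id: str, lo: float, hi: float):
        row = np.zeros(nvar)
        for rid, coeff in net_flux_rows(model, orig_id).items():
            row[ridx[rid]] = coeff
        constraints.append(LinearConstraint(row[None, :], lo, hi))

    if medium is not None:
        for orig_id, (lo, hi) in medium.exchange_bounds.items():
            _net_constraint(orig_id, lo, hi)
        for orig_id, (val, tol) in medium.measured_fluxes.items():
            _net_constraint(orig_id, val - tol, val + tol)
        if medium.growth_rate is not None and model.biomass_reaction is not None:
            val, tol = medium.growth_rate
            _net_constraint(model.biomass_reaction, val - tol, val + tol)

    constraints.extend(extra_constraints)

    c = np.zeros(nvar)
    c[:m] = _FLUX_TIEBREAK
    c[off_ep:] = 1.0
    integrality = np.zeros(nvar)
    integrality[off_a : off_a + nb] = 1

    res = milp(
        c=c,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"mip_rel_gap": mip_rel_gap},
    )
    if res.status != 0 or res.x is None:
        status = "infeasible" if res.status == 2 else "infeasible"
        return FluxSolution(
            reaction_ids=[r.id for r in model.reactions],
            v=np.zeros(m),
            active=np.zeros(m, dtype=bool),
            corrections={},
            objective=math.inf,
            status=status,
        )
    x = res.x
    v = np.where(np.abs(x[:m]) < FLUX_EPSILON, 0.0, x[:m])
    corrections = {
        rid: float(x[off_ep + jj] - x[off_em + jj]) for jj, rid in enumerate(rg_ids)
    }
    # zero out numerically-insignificant corrections on inactive reactions
    for jj, rid in enumerate(rg_ids):
        if v[ridx[rid]] <= FLUX_EPSILON:
            corrections[rid] = 0.0
    witness = {mid: float(x[off_ln + i]) for mid, i in midx.items()}
    return FluxSolution(
        reaction_ids=[r.id for r in model.reactions],
        v=v,
        active=v > FLUX_EPSILON,
        corrections=corrections,
        objective=float(sum(abs(e) for e in corrections.values())),
        status="optimal",
        ln_conc_witness=witness,
    )


def enumerate_alternative_fluxes(
    model: NetworkModel,
    medium: Optional[MediumSpec] = None,
    params: Optional[ThermoParams] = None,
    n_alternatives: int = 5,
    seed: int = 0,
    correction_bound: Optional[float] = None,
    objective_gap: float = 1e-6,
) -> list[FluxSolution]:
    """Activity-distinct near-optimal flux distributions via integer cuts.

    Repeatedly re-solves the MILP, each time excluding the binary activity
    pattern of all previous solutions and capping the correction objective
    at optimum + ``objective_gap``.  Deterministic for a fixed solver
    build; ``seed`` is accepted for interface stability.
    """
    del seed  # HiGHS is deterministic; kept for a stable call signature
    params = params or model.params
    base = solve_feasible_flux(model, medium, params, correction_bound)
    if base.status == "infeasible":
        return []
    solutions = [base]
    m = len(model.reactions)
    rg_ids = model.rg_reactions
    bin_ids = list(dict.fromkeys(rg_ids + [x for pair in model.split_pairs for x in pair]))
    ridx = model.reaction_index()
    nb, nrg = len(bin_ids), len(rg_ids)
    n = len(model.metabolites)
    nvar = m + nb + n + 2 * nrg
    off_a, off_ep = m, m + nb + n

    cuts: list[LinearConstraint] = []
    # cap total corrections near the optimum
    cap = np.zeros(nvar)
    cap[off_ep:] = 1.0
    cuts.append(LinearConstraint(cap[None, :], -np.inf, base.objective + objective_gap))

    while len(solutions) < n_alternatives:
        prev = solutions[-1]
        pattern = {rid: prev.flux(rid) > FLUX_EPSILON for rid in bin_ids}
        row = np.zeros(nvar)
        ones = 0
        for i, rid in enumerate(bin_ids):
            if pattern[rid]:
                row[off_a + i] = -1.0
                ones += 1
            else:
                row[off_a + i] = 1.0
        # Hamming distance to the previous activity pattern >= 1
        cuts.append(LinearConstraint(row[None, :], 1 - ones, np.inf))
        sol = solve_feasible_flux(
            model, medium, params, correction_bound, extra_constraints=cuts
        )
        if sol.status == "infeasible":
            break
        solutions.append(sol)
    return solutions


def validate_flux_solution(
    model: NetworkModel,
    solution: FluxSolution,
    medium: Optional[MediumSpec] = None,
    params: Optional[ThermoParams] = None,
    mass_balance_tol: float = 1e-6,
) -> list[str]:
    """Independent post-hoc checks; returns a list of violations (empty = ok).

    Checks mass balance, forward/reverse exclusivity, and — via a small
    feasibility LP — that concentrations within the box give every active
    constrained reaction a driving force of at least β under the corrected
    standard energies.
    """
    params = params or model.params
    issues: list[str] = []
    S = model.stoichiometric_matrix()
    resid = np.abs(S @ solution.v)
    if resid.size and resid.max() > mass_balance_tol:
        issues.append(f"mass-balance residual {resid.max():.3g} exceeds {mass_balance_tol}")
    ridx = model.reaction_index()
    for fwd, rev in model.split_pairs:
        if solution.v[ridx[fwd]] > FLUX_EPSILON and solution.v[ridx[rev]] > FLUX_EPSILON:
            issues.append(f"forward/reverse pair {fwd}/{rev} simultaneously active")

    active_rg = solution.active_rg(model)
    if active_rg:
        lo_ln, hi_ln = _conc_bounds(model, medium, params)
        midx = model.metabolite_index()
        dg0c = solution.corrected_dg0(model)
        A, bub = [], []
        for rid in active_rg:
            rxn = model.get_reaction(rid)
            row = np.zeros(len(model.metabolites))
            for mid, coeff in rxn.stoichiometry.items():
                row[midx[mid]] = params.RT * coeff
            A.append(row)
            bub.append(-dg0c[rid] - params.beta * params.RT)
        res = linprog(
            c=np.zeros(len(model.metabolites)),
            A_ub=np.array(A),
            b_ub=np.array(bub),
            bounds=list(zip(lo_ln, hi_ln)),
            method="highs",
        )
        if res.status != 0:
            issues.append("no feasible concentration witness for the active reactions")
    return issues


def write_flux_tsv(model: NetworkModel, solution: FluxSolution, path) -> None:
    """TSV report: reaction_id, flux, active, correction."""
    import pandas as pd

    pd.DataFrame(
        {
            "reaction_id": solution.reaction_ids,
            "flux": solution.v,
            "active": solution.active.astype(int),
            "correction": [
                solution.corrections.get(rid, 0.0) for rid in solution.reaction_ids
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def read_flux_tsv(model: NetworkModel, path) -> FluxSolution:
    """Rehydrate a FluxSolution from the TSV report."""
    import pandas as pd

    tab = pd.read_csv(path, sep="\t").set_index("reaction_id")
    ids = [r.id for r in model.reactions]
    v = np.array([float(tab.loc[rid, "flux"]) for rid in ids])
    rg = set(model.rg_reactions)
    corrections = {
        rid: float(tab.loc[rid, "correction"]) for rid in ids if rid in rg
    }
    return FluxSolution(
        reaction_ids=ids,
        v=v,
        active=v > FLUX_EPSILON,
        corrections=corrections,
        objective=float(sum(abs(e) for e in corrections.values())),
        status="feasible",
    )
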