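"""Step (ii): optimal log concentrations for a fixed flux distribution.

Given the MILP flux solution (and its corrected standard Gibbs energies),
minimise

    Σ_i (ln(c_i / c_L))²  +  δ · Σ_{j active ∩ R_G} Ẽ_j(c, v_j)

over log concentrations within the global box, with fixed extracellular and
currency metabolites pinned.  The piecewise enzyme surrogate Ẽ_j is encoded
exactly with one slack per reaction, s_j = max(0, α - f_j), contributing
v_j·s_j²; the infinite branch below the driving-force floor β becomes the
hard second-law constraint f_j ≥ β.  The resulting program is a convex QP
in (ln c, s) with affine constraints, solved with ``trust-constr``.

The metabolite-load sum runs over all intracellular metabolites; pinned
metabolites contribute a constant.  Metabolites untouched by any active
constrained reaction relax to the concentration floor c_L and are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .core_model import MediumSpec, NetworkModel, ThermoParams, fixed_ln_conc
from .errors import SolverError
from .flux_milp import FLUX_EPSILON, FluxSolution
from .thermo import enzyme_cost_term

#: allowed slack on the hard driving-force floor at reported solutions
SECOND_LAW_TOL = 1e-6


@dataclass
class ConcentrationSolution:
    """Log-concentration optimum with per-reaction driving forces."""

    metabolite_ids: list[str]
    ln_c: np.ndarray  # ln(mM), full metabolite vector
    conc: np.ndarray  # mM
    dg_prime: dict[str, float]  # active R_G reaction -> ΔG' (corrected), kJ/mol
    load_objective: float
    enzyme_objective: float  # Σ v_j (α - f_j)_+² over active R_G (exact piecewise)
    delta: float
    status: str  # optimal | infeasible
    fixed_metabolites: list[str] = field(default_factory=list)
    unconstrained_metabolites: list[str] = field(default_factory=list)

    def ln_conc_map(self) -> dict[str, float]:
        return dict(zip(self.metabolite_ids, self.ln_c))

    def conc_map(self) -> dict[str, float]:
        return dict(zip(self.metabolite_ids, self.conc))


def _problem_data(
    model: NetworkModel,
    flux: FluxSolution,
    medium: Optional[MediumSpec],
    params: ThermoParams,
):
    """Shared assembly: intracellular index, fixed pins, active R_G rows."""
    intracellular = [m for m in model.metabolites if not m.is_extracellular]
    fixed = fixed_ln_conc(model, medium)
    dg0c = flux.corrected_dg0(model)
    active = [
        model.get_reaction(rid)
        for rid in flux.active_rg(model)
    ]
    return intracellular, fixed, dg0c, active


def solve_concentrations(
    model: NetworkModel,
    flux: FluxSolution,
    medium: Optional[MediumSpec] = None,
    params: Optional[ThermoParams] = None,
    delta: Optional[float] = None,
    total_conc_cap: Optional[float] = None,
) -> ConcentrationSolution:
    """Solve the concentration QP for one trade-off weight δ.

    Uses the corrected standard Gibbs energies carried by ``flux``.  Returns
    a solution with ``status='infeasible'`` when the pinned metabolite
    concentrations contradict the flux step's feasibility witness (no log
    concentrations give all active reactions the minimal driving force).

    ``total_conc_cap`` optionally bounds the summed intracellular
    concentration (mM); Σ exp(ln c) is convex, so the program stays convex,
    but the constraint is off by default — the quadratic load term already
    penalises large pools.
    """
    params = params or model.params
    delta = params.delta if delta is None else float(delta)
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if flux.status not in ("optimal", "feasible"):
        raise ValueError("flux solution must be optimal or feasible")

    intracellular, fixed, dg0c, active = _problem_data(model, flux, medium, params)
    RT, alpha, beta = params.RT, params.alpha, params.beta
    ln_l_global = math.log(params.c_lower)

    # free variables: intracellular metabolites that are not pinned
    free_ids = [m.id for m in intracellular if m.id not in fixed]
    fidx = {mid: i for i, mid in enumerate(free_ids)}
    n_f = len(free_ids)
    lo = np.array(
        [math.log(max(m.conc_lower, params.c_lower)) for m in intracellular if m.id not in fixed]
    )
    hi = np.array(
        [math.log(min(m.conc_upper, params.c_upper)) for m in intracellular if m.id not in fixed]
    )

    # per-active-reaction affine rows: f_j = f_const_j - row_j . x  (x = free ln c)
    rows, f_consts, v_active, act_ids = [], [], [], []
    touched: set[str] = set()
    for rxn in active:
        row = np.zeros(n_f)
        const = -dg0c[rxn.id] / RT
        for mid, coeff in rxn.stoichiometry.items():
            if mid in fidx:
                row[fidx[mid]] = coeff
                touched.add(mid)
            elif mid in fixed:
                const -= coeff * fixed[mid]
            # extracellular metabolites without a pin keep ln c = 0 (1 mM)
        rows.append(row)
        f_consts.append(const)
        v_active.append(flux.flux(rxn.id))
        act_ids.append(rxn.id)
    A_f = np.array(rows) if rows else np.zeros((0, n_f))
    f_consts = np.array(f_consts)
    v_active = np.array(v_active)
    n_a = len(act_ids)

    def full_solution(x: np.ndarray, status: str) -> ConcentrationSolution:
        ln_full, conc_full, load = _assemble(model, intracellular, fixed, free_ids, x, params)
        f_vals = f_consts - A_f @ x if n_a else np.zeros(0)
        dg_prime = {rid: float(-f * RT) for rid, f in zip(act_ids, f_vals)}
        enzyme = float(
            sum(
                v * max(0.0, alpha - f) ** 2 if f < alpha else 0.0
                for v, f in zip(v_active, f_vals)
            )
        )
        return ConcentrationSolution(
            metabolite_ids=[m.id for m in model.metabolites],
            ln_c=ln_full,
            conc=conc_full,
            dg_prime=dg_prime,
            load_objective=load,
            enzyme_objective=enzyme,
            delta=delta,
            status=status,
            fixed_metabolites=sorted(set(fixed) & {m.id for m in intracellular}),
            unconstrained_metabolites=[mid for mid in free_ids if mid not in touched],
        )

    if n_f == 0 and n_a == 0:
        return full_solution(np.zeros(0), "optimal")

    # strictly-interior start via a Chebyshev-style margin LP
    x0, feasible = _feasible_start(A_f, f_consts, beta, lo, hi)
    if not feasible:
        sol = full_solution(np.clip(x0, lo, hi), "infeasible")
        return sol

    use_slack = delta > 0 and n_a > 0
    n_s = n_a if use_slack else 0
    w_s = 2.0 * delta * v_active if use_slack else np.zeros(0)

    def objective(z):
        x, s = z[:n_f], z[n_f:]
        val = float(np.sum((x - ln_l_global) ** 2))
        if use_slack:
            val += float(np.sum(delta * v_active * s**2))
        return val

    def gradient(z):
        x, s = z[:n_f], z[n_f:]
        g = np.concatenate([2.0 * (x - ln_l_global), w_s * s])
        return g

    hess_diag = np.concatenate([np.full(n_f, 2.0), w_s])

    def hessian(z):
        return np.diag(hess_diag)

    constraints = []
    if n_a:
        # second law: f_j >= beta  <=>  A_f x <= f_const - beta
        constraints.append(
            LinearConstraint(
                np.hstack([A_f, np.zeros((n_a, n_s))]), -np.inf, f_consts - beta
            )
        )
    if use_slack:
        # s_j >= alpha - f_j  <=>  s_j - A_f x >= alpha - f_const
        C = np.hstack([-A_f, np.eye(n_a)])
        constraints.append(LinearConstraint(C, alpha - f_consts, np.inf))
    if total_conc_cap is not None:
        from scipy.optimize import NonlinearConstraint

        fixed_sum = sum(
            math.exp(fixed[m.id]) for m in intracellular if m.id in fixed
        )
        if fixed_sum > total_conc_cap:
            return full_solution(np.clip(x0, lo, hi), "infeasible")
        constraints.append(
            NonlinearConstraint(
                lambda z: float(np.sum(np.exp(z[:n_f]))),
                -np.inf,
                total_conc_cap - fixed_sum,
                jac=lambda z: np.concatenate([np.exp(z[:n_f]), np.zeros(n_s)])[None, :],
            )
        )

    z0 = np.concatenate(
        [x0, np.maximum(0.0, alpha - (f_consts - A_f @ x0))] if use_slack else [x0]
    )
    bounds = Bounds(
        np.concatenate([lo, np.zeros(n_s)]),
        np.concatenate([hi, np.full(n_s, np.inf)]),
    )
    res = minimize(
        objective,
        z0,
        jac=gradient,
        hess=hessian,
        bounds=bounds,
        constraints=constraints,
        method="trust-constr",
        options={"gtol": 1e-12, "xtol": 1e-14, "barrier_tol": 1e-14, "maxiter": 3000},
    )
    if res.status not in (1, 2) or res.constr_violation > 1e-7:
        raise SolverError(
            f"QP did not certify optimality (status {res.status}, "
            f"violation {res.constr_violation:.3g})"
        )

    if total_conc_cap is not None:
        # the cap constraint is non-affine; skip the affine active-set polish
        return full_solution(np.clip(res.x[:n_f], lo, hi), "optimal")

    # polish the interior-point solution to machine precision: the problem
    # is a diagonal QP with affine constraints, so an active-set refinement
    # (KKT solves on the guessed active set) removes the barrier bias
    w_q = np.concatenate([np.full(n_f, 1.0), 0.5 * w_s])  # f(z) = Σ w (z-t)²
    t_q = np.concatenate([np.full(n_f, ln_l_global), np.zeros(n_s)])
    A_rows, b_rows = [], []
    nz = n_f + n_s
    if n_a:
        A_rows.append(np.hstack([A_f, np.zeros((n_a, n_s))]))
        b_rows.append(f_consts - beta)
    if use_slack:
        A_rows.append(np.hstack([A_f, -np.eye(n_a)]))  # -(s - A_f x) <= f_const - alpha
        b_rows.append(f_consts - alpha)
    eye = np.eye(nz)
    A_rows.extend([eye, -eye])
    b_rows.extend(
        [
            np.concatenate([hi, np.full(n_s, np.inf)]),
            -np.concatenate([lo, np.zeros(n_s)]),
        ]
    )
    A_all = np.vstack(A_rows)
    b_all = np.concatenate(b_rows)
    finite = np.isfinite(b_all)
    z_opt = _active_set_polish(w_q, t_q, A_all[finite], b_all[finite], res.x)
    x_opt = np.clip(z_opt[:n_f], lo, hi)
    return full_solution(x_opt, "optimal")


def _active_set_polish(w, t, A, b, z_ip, act_tol=1e-3, max_iter=60):
    """Refine a nearly-optimal point of min Σ w(z-t)² s.t. A z <= b.

    Starting from the active set guessed at ``z_ip``, alternately solves the
    equality-constrained KKT system, adds violated constraints and drops
    constraints with negative multipliers.  Falls back to ``z_ip`` if the
    loop does not settle or does not improve the objective.
    """

    def obj(z):
        return float(w @ (z - t) ** 2)

    def feasible(z, tol=1e-9):
        return not len(b) or float(np.max(A @ z - b)) <= tol

    best_z, best_f = z_ip, obj(z_ip)
    active = list(np.flatnonzero(b - A @ z_ip < act_tol))
    nz = len(z_ip)
    for _ in range(max_iter):
        A_act = A[active] if active else np.zeros((0, nz))
        kkt = np.block(
            [[np.diag(2.0 * w), A_act.T], [A_act, np.zeros((len(active), len(active)))]]
        )
        rhs = np.concatenate([2.0 * w * t, b[active] if active else np.zeros(0)])
        sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
        z, lam = sol[:nz], sol[nz:]
        viol = A @ z - b
        inactive = np.setdiff1d(np.arange(len(b)), active)
        if inactive.size and viol[inactive].max() > 1e-10:
            active.append(int(inactive[np.argmax(viol[inactive])]))
            continue
        if len(lam) and lam.min() < -1e-10:
            active.pop(int(np.argmin(lam)))
            continue
        if feasible(z) and obj(z) <= best_f + 1e-12:
            return z
        break
    return best_z


def _feasible_start(A_f, f_consts, beta, lo, hi):
    """Maximise the margin to all constraints; returns (x0, feasible)."""
    n_f = lo.size
    n_a = A_f.shape[0]
    if n_a == 0:
        return lo.copy(), True
    # variables (x, t): maximise t s.t. A_f x + t <= f_const - beta, lo <= x <= hi
    c = np.zeros(n_f + 1)
    c[-1] = -1.0
    A_ub = np.hstack([A_f, np.ones((n_a, 1))])
    b_ub = f_consts - beta
    bounds = [(l, h) for l, h in zip(lo, hi)] + [(0.0, 1.0)]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if res.status != 0:
        return (lo + hi) / 2.0, False
    return res.x[:n_f], True


def _assemble(model, intracellular, fixed, free_ids, x, params):
    """Full ln-c vector over all model metabolites + the load objective."""
    ln_l_global = math.log(params.c_lower)
    fidx = {mid: i for i, mid in enumerate(free_ids)}
    ln_full = np.zeros(len(model.metabolites))
    load = 0.0
    for i, m in enumerate(model.metabolites):
        if m.id in fixed:
            ln_full[i] = fixed[m.id]
        elif m.id in fidx:
            ln_full[i] = x[fidx[m.id]]
        else:
            # extracellular and unpinned: reference 1 mM, outside the load sum
            ln_full[i] = 0.0
        if not m.is_extracellular:
            load += (ln_full[i] - ln_l_global) ** 2
    return ln_full, np.exp(ln_full), float(load)


def objective_components(
    solution: ConcentrationSolution,
    model: NetworkModel,
    flux: FluxSolution,
    params: Optional[ThermoParams] = None,
) -> tuple[float, float]:
    """Recompute (metabolite load, enzyme cost) from ln_c, solver-independently.

    The load term is Σ (ln(c_i/c_L))² over intracellular metabolites; the
    enzyme term is Σ v_j·Ẽ over active constrained reactions, evaluated with
    the exact piecewise surrogate (not the slack encoding).
    """
    params = params or model.params
    ln_l = math.log(params.c_lower)
    lnc = solution.ln_conc_map()
    load = sum(
        (lnc[m.id] - ln_l) ** 2 for m in model.metabolites if not m.is_extracellular
    )
    dg0c = flux.corrected_dg0(model)
    enzyme = 0.0
    for rid in flux.active_rg(model):
        rxn = model.get_reaction(rid)
        dg = dg0c[rid] + params.RT * sum(
            coeff * lnc[mid] for mid, coeff in rxn.stoichiometry.items()
        )
        f = -dg / params.RT
        if f >= params.beta - SECOND_LAW_TOL:
            # clamp round-off at the hard floor so boundary solutions do
            # not spuriously read as infinite
            dg = min(dg, -params.beta * params.RT)
        enzyme += enzyme_cost_term(flux.flux(rid), dg, params)
    return float(load), float(enzyme)


def write_conc_tsv(model: NetworkModel, solution: ConcentrationSolution, path) -> None:
    """TSV report: metabolite_id, conc_mM, ln_conc, fixed_flag, unconstrained_flag."""
    import pandas as pd

    fixed = set(solution.fixed_metabolites)
    uncon = set(solution.unconstrained_metabolites)
    pd.DataFrame(
        {
            "metabolite_id": solution.metabolite_ids,
            "conc_mM": solution.conc,
            "ln_conc": solution.ln_c,
            "fixed_flag": [int(mid in fixed) for mid in solution.metabolite_ids],
            "unconstrained_flag": [int(mid in uncon) for mid in solution.metabolite_ids],
        }
    ).to_csv(path, sep="\t", index=False)


def write_reaction_report(
    model: NetworkModel,
    flux: FluxSolution,
    solution: ConcentrationSolution,
    path,
    params: Optional[ThermoParams] = None,
) -> None:
    """Per-active-reaction TSV: flux, ΔG', driving force, enzyme term."""
    import pandas as pd

    params = params or model.params
    rows = []
    for rid, dg in solution.dg_prime.items():
        v = flux.flux(rid)
        rows.append(
            {
                "reaction_id": rid,
                "flux": v,
                "dg_prime": dg,
                "driving_force": -dg / params.RT,
                "enzyme_term": enzyme_cost_term(v, dg, params),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
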