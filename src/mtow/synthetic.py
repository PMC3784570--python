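"""Synthetic fixture generators and brute-force oracles.

Toy networks (linear chain, diamond, cycle) with prescribed standard Gibbs
energies and a unit-demand medium; an exhaustive grid-search oracle for the
concentration problem on small networks; and a generator of synthetic
component-contribution training data with known ground truth.  All
generators are pure functions of (spec, seed).

A generated toy admits a thermodynamically feasible flux whenever some
source→sink route satisfies  Σ ΔG'° along the route < -n·β·RT + RT·(log
span slack available from the concentration box) — each of the n route
reactions needs a driving force of at least β, and the total chemical
potential drop the box can supply is bounded by the log-concentration span.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core_model import (
    Dg0Estimate,
    MediumSpec,
    Metabolite,
    NetworkModel,
    Reaction,
    ThermoParams,
)
from .errors import GridTooLargeError
from .flux_milp import FluxSolution
from .gibbs_ccm import GroupDecomposition, MeasuredReactionSet

#: refuse exhaustive grids beyond this many points
MAX_GRID_POINTS = int(1e8)


@dataclass
class ToySpec:
    """Specification of a toy network.

    ``n_steps`` is the number of internal metabolites along the main route
    (linear: M1..Mn with n-1 conversions; diamond and cycle have fixed /
    n-step shapes, see ``make_toy_model``).  ``dg0s`` supplies one standard
    Gibbs energy per internal reaction, in kJ/mol.  ``boundary_concs``
    optionally pins the source and sink metabolite concentrations (mM).
    """

    n_steps: int
    dg0s: Sequence[float]
    boundary_concs: Optional[tuple[float, float]] = None
    branch_topology: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.branch_topology not in ("linear", "diamond", "cycle"):
            raise ValueError(f"unknown topology {self.branch_topology!r}")
        expected = _edge_count(self)
        if len(self.dg0s) != expected:
            raise ValueError(
                f"{self.branch_topology} with n_steps={self.n_steps} needs "
                f"{expected} dg0 values, got {len(self.dg0s)}"
            )


def _edge_count(spec: ToySpec) -> int:
    if spec.branch_topology == "linear":
        return spec.n_steps - 1
    if spec.branch_topology == "diamond":
        return 4
    return max(spec.n_steps, 3)  # cycle


def make_toy_model(spec: ToySpec) -> tuple[NetworkModel, MediumSpec]:
    """Build the toy network and its unit-demand medium.

    * linear: M1 → M2 → ... → Mn, import into M1, export of Mn.
    * diamond: A → B1 → C and A → B2 → C (two parallel 2-step routes),
      import into A, export of C.
    * cycle: M1 → M2 → ... → Mn → M1 (n >= 3 edges), import into M1,
      export of Mn.

    Every internal reaction is in R_G with the prescribed dg0.  The medium
    demands one unit of export flux and allows up to 10 units of import.
    """
    dg0s = list(spec.dg0s)
    if spec.branch_topology == "linear":
        met_ids = [f"M{i+1}" for i in range(spec.n_steps)]
        edges = [(met_ids[i], met_ids[i + 1]) for i in range(spec.n_steps - 1)]
        source, sink = met_ids[0], met_ids[-1]
    elif spec.branch_topology == "diamond":
        met_ids = ["A", "B1", "B2", "C"]
        edges = [("A", "B1"), ("B1", "C"), ("A", "B2"), ("B2", "C")]
        source, sink = "A", "C"
    else:  # cycle
        n = max(spec.n_steps, 3)
        met_ids = [f"M{i+1}" for i in range(n)]
        edges = [(met_ids[i], met_ids[(i + 1) % n]) for i in range(n)]
        source, sink = met_ids[0], met_ids[-1]

    metabolites = [Metabolite(id=mid) for mid in met_ids]
    if spec.boundary_concs is not None:
        src_c, snk_c = spec.boundary_concs
        for m in metabolites:
            if m.id == source:
                m.fixed_conc = src_c
            if m.id == sink:
                m.fixed_conc = snk_c

    reactions = [
        Reaction(
            id=f"R_{a}_{b}",
            stoichiometry={a: -1.0, b: 1.0},
            dg0=Dg0Estimate(value=float(dg0s[k]), stderr=0.0, category="I"),
        )
        for k, (a, b) in enumerate(edges)
    ]
    reactions.append(
        Reaction(id="EX_src", stoichiometry={source: 1.0}, is_exchange=True, flux_upper=10.0)
    )
    reactions.append(
        Reaction(id="EX_snk", stoichiometry={sink: -1.0}, is_exchange=True, flux_upper=10.0)
    )
    model = NetworkModel(metabolites=metabolites, reactions=reactions)
    medium = MediumSpec(exchange_bounds={"EX_snk": (1.0, 1.0), "EX_src": (0.0, 10.0)})
    return model, medium


# ---------------------------------------------------------------------------
# grid-search oracle for the concentration problem


def brute_force_concentrations(
    model: NetworkModel,
    flux: FluxSolution,
    medium: Optional[MediumSpec] = None,
    params: Optional[ThermoParams] = None,
    grid_step: float = 0.01,
    delta: Optional[float] = None,
) -> tuple[dict[str, float], float]:
    """Exhaustive grid search over free ln-concentrations.

    Evaluates the exact objective Σ(ln(c/c_L))² + δ·Σ Ẽ on a regular
    ln-space grid (step ``grid_step``) subject to the same hard
    driving-force floor f ≥ β as the QP, so both optimise the identical
    feasible set.  Returns (best ln-concentration map over free
    metabolites, objective value including the fixed-metabolite load
    constant).  Refuses grids above 1e8 points.
    """
    from .conc_qp import _problem_data  # shared assembly keeps the two aligned

    params = params or model.params
    delta = params.delta if delta is None else float(delta)
    intracellular, fixed, dg0c, active = _problem_data(model, flux, medium, params)
    free = [m for m in intracellular if m.id not in fixed]
    ln_l_global = math.log(params.c_lower)
    RT, alpha, beta = params.RT, params.alpha, params.beta

    axes = []
    for m in free:
        lo = math.log(max(m.conc_lower, params.c_lower))
        hi = math.log(min(m.conc_upper, params.c_upper))
        axes.append(np.arange(lo, hi + grid_step / 2, grid_step))
    n_points = math.prod(len(a) for a in axes) if axes else 1
    if n_points > MAX_GRID_POINTS:
        suggested = grid_step * (n_points / MAX_GRID_POINTS) ** (1.0 / max(len(axes), 1))
        raise GridTooLargeError(
            f"{n_points:.3g} grid points exceed {MAX_GRID_POINTS:.0g}; "
            f"try grid_step >= {suggested:.3g}"
        )

    fidx = {m.id: i for i, m in enumerate(free)}
    grids = np.meshgrid(*axes, indexing="ij") if axes else []
    flat = [g.ravel() for g in grids]
    total = np.zeros(n_points)
    # load over free metabolites
    for g in flat:
        total += (g - ln_l_global) ** 2
    # constant load of pinned intracellular metabolites
    const = sum(
        (fixed[m.id] - ln_l_global) ** 2 for m in intracellular if m.id in fixed
    )
    total += const

    feasible = np.ones(n_points, dtype=bool)
    for rxn in active:
        f_val = np.full(n_points, -dg0c[rxn.id] / RT)
        for mid, coeff in rxn.stoichiometry.items():
            if mid in fidx:
                f_val -= coeff * flat[fidx[mid]]
            elif mid in fixed:
                f_val -= coeff * fixed[mid]
        feasible &= f_val >= beta - 1e-12
        if delta > 0:
            v = flux.flux(rxn.id)
            shortfall = np.maximum(0.0, alpha - f_val)
            total += delta * v * shortfall**2
    total = np.where(feasible, total, np.inf)
    best = int(np.argmin(total))
    if not np.isfinite(total[best]):
        raise ValueError("no feasible grid point (grid too coarse or problem infeasible)")
    best_point = {m.id: float(flat[fidx[m.id]][best]) for m in free} if free else {}
    return best_point, float(total[best])


def grid_objective_bound(
    model: NetworkModel,
    flux: FluxSolution,
    params: Optional[ThermoParams] = None,
    delta: Optional[float] = None,
    grid_step: float = 0.01,
    medium: Optional[MediumSpec] = None,
) -> float:
    """Upper bound on (grid optimum − true optimum) for one grid step.

    A Lipschitz bound on the objective over the box: moving every free
    coordinate by at most one grid step changes the load term by at most
    2·span per coordinate and each enzyme term by at most 2·α·δ·v·‖S_j‖₁
    per unit step.  Constraint snapping can cost one extra step in each
    coordinate, hence the factor 2.
    """
    from .conc_qp import _problem_data

    params = params or model.params
    delta = params.delta if delta is None else float(delta)
    intracellular, fixed, dg0c, active = _problem_data(model, flux, medium, params)
    free = [m for m in intracellular if m.id not in fixed]
    span = sum(
        math.log(min(m.conc_upper, params.c_upper))
        - math.log(max(m.conc_lower, params.c_lower))
        for m in free
    )
    lipschitz = 2.0 * span
    for rxn in active:
        s_norm = sum(abs(c) for c in rxn.stoichiometry.values())
        lipschitz += 2.0 * params.alpha * delta * flux.flux(rxn.id) * s_norm
    return 2.0 * grid_step * lipschitz


def benchmark_specs() -> list[ToySpec]:
    """The standard battery of small toys used to cross-check the QP.

    Twenty-one specs spanning the three topologies, favourable and uphill
    energetics, and pinned or free boundaries; every network keeps at most
    two free metabolites so the exhaustive ln-space grid at step 0.01 stays
    tractable for the oracle.
    """
    specs = [
        # two free metabolites, open boundaries
        ToySpec(n_steps=2, dg0s=[0.0]),
        ToySpec(n_steps=2, dg0s=[-5.0]),
        ToySpec(n_steps=2, dg0s=[-12.0]),
        ToySpec(n_steps=2, dg0s=[5.0]),
        # one free metabolite, boundaries pinned
        ToySpec(n_steps=3, dg0s=[0.0, 0.0], boundary_concs=(1.0, 0.01)),
        ToySpec(n_steps=3, dg0s=[-5.0, -5.0], boundary_concs=(1.0, 0.01)),
        ToySpec(n_steps=3, dg0s=[-10.0, 2.0], boundary_concs=(1.0, 0.01)),
        ToySpec(n_steps=3, dg0s=[4.0, -8.0], boundary_concs=(1.0, 0.1)),
        ToySpec(n_steps=3, dg0s=[-2.0, -2.0], boundary_concs=(1.0, 0.1)),
        ToySpec(n_steps=3, dg0s=[-15.0, -15.0], boundary_concs=(10.0, 0.001)),
        # two free metabolites, boundaries pinned (tight spans trade off)
        ToySpec(n_steps=4, dg0s=[-5.0, -5.0, -5.0], boundary_concs=(1.0, 0.01)),
        ToySpec(n_steps=4, dg0s=[0.0, 0.0, 0.0], boundary_concs=(10.0, 0.01)),
        ToySpec(n_steps=4, dg0s=[-8.0, 3.0, -8.0], boundary_concs=(1.0, 0.1)),
        ToySpec(n_steps=4, dg0s=[-3.0, -3.0, -3.0], boundary_concs=(0.05, 0.05)),
        # diamond: parallel routes, endpoints pinned -> two free branches
        ToySpec(n_steps=2, dg0s=[-5.0, -5.0, -5.0, -5.0], branch_topology="diamond",
                boundary_concs=(1.0, 0.01)),
        ToySpec(n_steps=2, dg0s=[-2.0, -8.0, -8.0, -2.0], branch_topology="diamond",
                boundary_concs=(1.0, 0.01)),
        ToySpec(n_steps=2, dg0s=[0.0, -6.0, -6.0, 0.0], branch_topology="diamond",
                boundary_concs=(0.5, 0.05)),
        # cycles with the closing edge idle
        ToySpec(n_steps=3, dg0s=[-5.0, -5.0, -5.0], branch_topology="cycle",
                boundary_concs=(1.0, 0.01)),
        ToySpec(n_steps=3, dg0s=[0.0, -4.0, -4.0], branch_topology="cycle",
                boundary_concs=(1.0, 0.1)),
        ToySpec(n_steps=4, dg0s=[-6.0, -6.0, -6.0, -6.0], branch_topology="cycle",
                boundary_concs=(1.0, 0.01)),
        ToySpec(n_steps=4, dg0s=[-2.0, 1.0, -9.0, -2.0], branch_topology="cycle",
                boundary_concs=(1.0, 0.05)),
    ]
    return specs


def make_category_iii_example(
    span_energy: float, group_energy: float
) -> tuple[MeasuredReactionSet, GroupDecomposition, np.ndarray, np.ndarray]:
    """Minimal category-III estimation problem with known half-reaction energies.

    Four compounds: C1→C2 is the single measured reaction (energy
    ``span_energy``); C3 and C4 are absent from all measurements but carry
    one group each, with group energies fixed so the group half-reaction
    C3→C4 costs exactly ``group_energy``.  The target reaction
    C1 + C3 → C2 + C4 then decomposes into those two halves, and its
    estimate must equal their sum.  Returns (train, groups,
    group_energies, target_vector).
    """
    compound_ids = ["C1", "C2", "C3", "C4"]
    train = MeasuredReactionSet(
        S_train=np.array([[-1.0], [1.0], [0.0], [0.0]]),
        dg0_obs=np.array([span_energy]),
        reaction_ids=["T1"],
        compound_ids=compound_ids,
    )
    groups = GroupDecomposition(
        G=np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
        group_ids=["g1", "g2"],
        compound_ids=compound_ids,
    )
    group_energies = np.array([0.0, group_energy])
    target = np.array([-1.0, 1.0, -1.0, 1.0])
    return train, groups, group_energies, target


# ---------------------------------------------------------------------------
# synthetic component-contribution training data


def make_synthetic_ccm_data(
    n_compounds: int = 30,
    n_groups: int = 8,
    n_train_reactions: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
    frac_non_decomposable: float = 0.0,
    dependency_frac: float = 0.25,
) -> tuple[MeasuredReactionSet, GroupDecomposition, dict]:
    """Draw a group model and a consistent measured-reaction training set.

    Compounds get integer group counts; true group energies are drawn
    N(0, 50 kJ/mol); formation energies follow the group model exactly, so
    with ``noise_sd = 0`` the training energies are first-law consistent
    and fully explained by groups.  Training reactions are sparse signed
    combinations of 2–5 compounds; a fraction ``dependency_frac`` of them
    are sums/differences of earlier reactions, mimicking the linear
    dependencies (pathway sums) found in real measured-reaction
    collections — these make held-out reactions recoverable from the span
    alone.  Returns (training set, group decomposition, ground truth with
    ``group_energies`` and ``formation_energies``).  Deterministic per
    seed.
    """
    if min(n_compounds, n_groups, n_train_reactions) < 1:
        raise ValueError("all sizes must be >= 1")
    rng = np.random.default_rng(seed)
    G = rng.integers(0, 4, size=(n_compounds, n_groups)).astype(float)
    # avoid all-zero compounds (they would have no groups at all)
    for i in range(n_compounds):
        if not G[i].any():
            G[i, rng.integers(n_groups)] = 1.0
    group_energies = rng.normal(0.0, 50.0, size=n_groups)
    formation = G @ group_energies

    S = np.zeros((n_compounds, n_train_reactions))
    n_dep = int(round(dependency_frac * n_train_reactions)) if n_train_reactions > 2 else 0
    for j in range(n_train_reactions):
        if j >= n_train_reactions - n_dep:
            # linear combination of two earlier reactions (pathway sum)
            while True:
                a, b = rng.choice(j, size=2, replace=False)
                col = S[:, a] + rng.choice([-1.0, 1.0]) * S[:, b]
                if col.any():
                    break
            S[:, j] = col
            continue
        k = int(rng.integers(2, 6))
        members = rng.choice(n_compounds, size=min(k, n_compounds), replace=False)
        coeffs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=len(members))
        S[members, j] = coeffs
    dg0_obs = S.T @ formation + rng.normal(0.0, noise_sd, size=n_train_reactions)

    decomposable = np.ones(n_compounds, dtype=bool)
    if frac_non_decomposable > 0:
        n_bad = int(round(frac_non_decomposable * n_compounds))
        bad = rng.choice(n_compounds, size=n_bad, replace=False)
        decomposable[bad] = False

    compound_ids = [f"C{i+1:03d}" for i in range(n_compounds)]
    train = MeasuredReactionSet(
        S_train=S,
        dg0_obs=dg0_obs,
        reaction_ids=[f"T{j+1:03d}" for j in range(n_train_reactions)],
        compound_ids=compound_ids,
    )
    groups = GroupDecomposition(
        G=G,
        group_ids=[f"g{k+1}" for k in range(n_groups)],
        compound_ids=compound_ids,
        decomposable=decomposable,
    )
    truth = {"group_energies": group_energies, "formation_energies": formation}
    return train, groups, truth
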