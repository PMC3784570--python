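"""Trade-off sweep, Pareto-front extraction, compromise selection, robustness.

The trade-off weight δ scalarises the two objectives (metabolite load,
enzyme cost).  Sweeping δ from 0 towards infinity traces the Pareto front;
a single compromise solution is then selected as the point minimising the
sum of min–max-normalised objectives (a scale-free version of "high in
both"; max-normalisation is available as an alternative).  A robustness
scan reports how much the agreement with reference concentrations changes
across front points near the selected one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .conc_qp import ConcentrationSolution, objective_components, solve_concentrations
from .core_model import MediumSpec, NetworkModel, ThermoParams
from .errors import SolverError
from .flux_milp import FluxSolution

#: default geometric δ grid; anchors δ=0 (pure load) and a large δ
#: (pure-enzyme limit) are appended by sweep()
DEFAULT_DELTAS = tuple(np.geomspace(1e-4, 1e4, 25))
DELTA_LARGE = 1e8


@dataclass
class ParetoPoint:
    delta: float
    load: float
    enzyme: float
    solution: ConcentrationSolution


@dataclass
class ParetoFront:
    points: list[ParetoPoint]
    normalized: list[tuple[float, float]] = field(default_factory=list)
    selected_index: int = -1

    @property
    def selected(self) -> ParetoPoint:
        if self.selected_index < 0:
            raise ValueError("no solution selected yet")
        return self.points[self.selected_index]


def _dominates(a: tuple[float, float], b: tuple[float, float], tol: float = 1e-9) -> bool:
    """a dominates b: <= in both objectives, strictly < in at least one."""
    return (
        a[0] <= b[0] + tol
        and a[1] <= b[1] + tol
        and (a[0] < b[0] - tol or a[1] < b[1] - tol)
    )


def filter_dominated(pairs: Sequence[tuple[float, float]], tol: float = 1e-9) -> list[int]:
    """Indices of mutually non-dominated points (stable order).

    Points coinciding within ``tol`` on both axes count as duplicates and
    only the first occurrence is kept.
    """
    keep = []
    for i, p in enumerate(pairs):
        dominated = any(
            _dominates(q, p, tol) for j, q in enumerate(pairs) if j != i
        ) or any(
            abs(q[0] - p[0]) <= tol and abs(q[1] - p[1]) <= tol for q in pairs[:i]
        )
        if not dominated:
            keep.append(i)
    return keep


def sweep(
    model: NetworkModel,
    flux: FluxSolution,
    medium: Optional[MediumSpec] = None,
    params: Optional[ThermoParams] = None,
    deltas: Optional[Sequence[float]] = None,
    select: bool = True,
    normalization: str = "minmax",
) -> ParetoFront:
    """Solve the concentration QP over a δ grid and keep the Pareto front.

    The grid defaults to 25 geometric points on [1e-4, 1e4] plus the anchors
    δ = 0 and δ = 1e8.  Points are de-dominated and ordered by increasing
    metabolite load.  Any QP infeasibility aborts the sweep, naming the
    offending δ.
    """
    params = params or model.params
    if deltas is None:
        deltas = [0.0, *DEFAULT_DELTAS, DELTA_LARGE]
    raw: list[ParetoPoint] = []
    for d in deltas:
        sol = solve_concentrations(model, flux, medium, params, delta=d)
        if sol.status != "optimal":
            raise SolverError(f"concentration QP infeasible at delta={d}")
        load, enzyme = objective_components(sol, model, flux, params)
        raw.append(ParetoPoint(delta=d, load=load, enzyme=enzyme, solution=sol))
    pairs = [(p.load, p.enzyme) for p in raw]
    keep = filter_dominated(pairs)
    points = sorted((raw[i] for i in keep), key=lambda p: (p.load, p.enzyme))
    front = ParetoFront(points=points)
    front.normalized = _normalize_to_min(points)
    if select and points:
        select_solution(front, normalization=normalization)
    return front


def _normalize_to_min(points: Sequence[ParetoPoint]) -> list[tuple[float, float]]:
    """Fold-change from the per-axis minimum (1 = the minimum).

    A zero minimum is handled by an additive floor so ratios stay finite.
    """
    if not points:
        return []
    loads = np.array([p.load for p in points])
    enzymes = np.array([p.enzyme for p in points])

    def norm(v: np.ndarray) -> np.ndarray:
        floor = 1e-9 * (v.max() if v.max() > 0 else 1.0) + 1e-12
        return (v + floor) / (v.min() + floor)

    return list(zip(norm(loads).tolist(), norm(enzymes).tolist()))


def select_solution(front: ParetoFront, normalization: str = "minmax") -> ConcentrationSolution:
    """Pick the compromise point scoring best on both normalised objectives.

    ``minmax`` (default): per-axis (x - min) / (max - min), degenerate axes
    contribute 0; ``max``: per-axis x / max.  The point with the smallest
    score sum wins; ties break first towards the more balanced point (the
    smaller worst-axis score), then towards the smaller metabolite load.
    Sets ``front.selected_index`` and returns the winning solution.
    """
    if not front.points:
        raise ValueError("empty Pareto front")
    loads = np.array([p.load for p in front.points])
    enzymes = np.array([p.enzyme for p in front.points])

    def scores(v: np.ndarray) -> np.ndarray:
        if normalization == "minmax":
            span = v.max() - v.min()
            return np.zeros_like(v) if span <= 0 else (v - v.min()) / span
        if normalization == "max":
            return np.zeros_like(v) if v.max() <= 0 else v / v.max()
        raise ValueError(f"unknown normalization {normalization!r}")

    s_load, s_enz = scores(loads), scores(enzymes)
    total = s_load + s_enz
    worst = np.maximum(s_load, s_enz)
    order = sorted(range(len(total)), key=lambda i: (total[i], worst[i], loads[i]))
    front.selected_index = order[0]
    return front.points[order[0]].solution


@dataclass
class RobustnessSummary:
    selected_correlation: float
    mean_neighborhood_correlation: float
    correlation_drop: float
    n_neighbors: int


def _log_pearson(solution: ConcentrationSolution, reference: Mapping[str, float]) -> float:
    """Pearson correlation of log10 predicted vs log10 reference, pairwise-complete."""
    from scipy.stats import pearsonr

    pred = solution.conc_map()
    shared = [mid for mid in reference if mid in pred and pred[mid] > 0 and reference[mid] > 0]
    if len(shared) < 2:
        return math.nan
    x = np.log10([pred[mid] for mid in shared])
    y = np.log10([reference[mid] for mid in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 1.0 if np.allclose(x - x.mean(), y - y.mean()) else math.nan
    return float(pearsonr(x, y).statistic)


def robustness_scan(
    front: ParetoFront,
    tolerance: float,
    reference: Mapping[str, float],
) -> RobustnessSummary:
    """Correlation change across front points near the selected compromise.

    The neighbourhood contains front points whose objectives both lie
    within ±``tolerance`` (fractional) of the selected point's.  Reports the
    mean log-log Pearson correlation against ``reference`` over the
    neighbourhood and the drop relative to the selected point; an empty
    neighbourhood degenerates to the selected point alone.
    """
    sel = front.selected
    r_sel = _log_pearson(sel.solution, reference)

    def close(x: float, x0: float) -> bool:
        return abs(x - x0) <= tolerance * abs(x0) if x0 != 0 else x == x0

    neighbors = [
        p
        for p in front.points
        if close(p.load, sel.load) and close(p.enzyme, sel.enzyme)
    ]
    if not neighbors:
        neighbors = [sel]
    corrs = [_log_pearson(p.solution, reference) for p in neighbors]
    mean_corr = float(np.nanmean(corrs))
    return RobustnessSummary(
        selected_correlation=r_sel,
        mean_neighborhood_correlation=mean_corr,
        correlation_drop=float(r_sel - mean_corr),
        n_neighbors=len(neighbors),
    )


def write_front_tsv(front: ParetoFront, path) -> None:
    """TSV report: delta, load, enzyme, normalized columns, selected flag."""
    import pandas as pd

    pd.DataFrame(
        {
            "delta": [p.delta for p in front.points],
            "load": [p.load for p in front.points],
            "enzyme": [p.enzyme for p in front.points],
            "load_norm": [n[0] for n in front.normalized],
            "enzyme_norm": [n[1] for n in front.normalized],
            "selected": [
                int(i == front.selected_index) for i in range(len(front.points))
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def plot_front(front: ParetoFront, path) -> None:
    """Optional SVG/PNG scatter of the normalised front."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    xs = [n[0] for n in front.normalized]
    ys = [n[1] for n in front.normalized]
    ax.plot(xs, ys, "o-", color="tab:blue", label="Pareto front")
    if front.selected_index >= 0:
        ax.plot(
            xs[front.selected_index],
            ys[front.selected_index],
            "s",
            color="tab:red",
            markersize=9,
            label="selected",
        )
    ax.set_xlabel("metabolite load (fold over minimum)")
    ax.set_ylabel("enzyme cost (fold over minimum)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
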