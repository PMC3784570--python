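"""Pure thermodynamic functions.

Reaction Gibbs energy from concentrations (ΔG' = ΔG'° + RT ln Q), the
minimal enzyme level needed to sustain a net flux at a given driving force,
the two quadratic surrogate objective terms used by the concentration QP,
adjusted Gibbs energies at a reference concentration, and detection of
distributed thermodynamic bottlenecks along a pathway.

The canonical internal variable is the dimensionless driving force
``f = -ΔG'/RT``; kJ/mol values are derived views.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_model import Reaction, ThermoParams
from .errors import ConcentrationLookupError, ThermodynamicInfeasibleError


@dataclass
class GibbsProfile:
    """Thermodynamic state of one reaction at given log concentrations."""

    reaction_id: str
    dg0: float  # kJ/mol
    dg_prime: float  # kJ/mol
    driving_force: float  # dimensionless, -dg_prime / RT
    ln_q: float  # dimensionless reaction quotient log


def reaction_gibbs(
    reaction: Reaction,
    ln_conc: Mapping[str, float],
    params: ThermoParams,
) -> GibbsProfile:
    """Evaluate ΔG' = ΔG'° + RT · (S'_j · ln c) for one reaction.

    ``ln_conc`` maps metabolite ids to natural logs of concentrations in mM
    (the standard state matching the 1 mM reference of ``dg0``).
    """
    if reaction.dg0 is None:
        raise ValueError(f"reaction {reaction.id} has no standard Gibbs energy")
    ln_q = 0.0
    for mid, coeff in reaction.stoichiometry.items():
        if mid not in ln_conc:
            raise ConcentrationLookupError(
                f"no concentration for metabolite {mid} (reaction {reaction.id})"
            )
        ln_q += coeff * ln_conc[mid]
    dg_prime = reaction.dg0.value + params.RT * ln_q
    return GibbsProfile(
        reaction_id=reaction.id,
        dg0=reaction.dg0.value,
        dg_prime=dg_prime,
        driving_force=-dg_prime / params.RT,
        ln_q=ln_q,
    )


def enzyme_level(v: float, dg_prime: float, params: ThermoParams) -> float:
    """Minimal enzyme mass fraction sustaining net flux ``v`` at ``dg_prime``.

    E = v / (w⁺ · (1 - exp(ΔG'/RT))).  The denominator vanishes as the
    driving force approaches zero, so the required enzyme level diverges;
    a non-negative ΔG' with positive flux is thermodynamically infeasible.
    """
    if v < 0:
        raise ValueError("flux must be non-negative")
    if v == 0:
        return 0.0
    if dg_prime >= 0:
        raise ThermodynamicInfeasibleError(
            f"dg_prime = {dg_prime:.6g} kJ/mol >= 0: infinite enzyme demand"
        )
    return v / (params.w_plus * (1.0 - math.exp(dg_prime / params.RT)))


def metabolite_load_term(ln_c, params: ThermoParams):
    """Quadratic surrogate for the concentration of one metabolite.

    ``ln_c`` is ln(concentration in mM); returns (ln(c / c_L))², the
    squared log-distance from the global concentration floor.  Accepts
    scalars or arrays.  Concentrations below c_L are a domain error.
    """
    ln_c = np.asarray(ln_c, dtype=float)
    ln_l = math.log(params.c_lower)
    if np.any(ln_c < ln_l - 1e-12):
        raise ValueError("concentration below the global floor c_L")
    out = (ln_c - ln_l) ** 2
    return out.item() if out.ndim == 0 else out


def enzyme_cost_term(v: float, dg_prime: float, params: ThermoParams) -> float:
    """Quadratic surrogate for the enzyme demand of one reaction.

    With f = -ΔG'/RT: +inf below the hard floor β, v·(α - f)² on [β, α]
    (the boundary f = β takes the finite branch value) and 0 beyond the
    saturation threshold α.
    """
    if v < 0:
        raise ValueError("flux must be non-negative")
    f = -dg_prime / params.RT
    if f < params.beta:
        return math.inf
    if f >= params.alpha:
        return 0.0
    return v * (params.alpha - f) ** 2


def adjusted_gibbs(
    reaction: Reaction,
    cofactor_concs: Mapping[str, float],
    params: ThermoParams,
    reference_conc: float = 1.0,
) -> float:
    """ΔG' with cofactors at measured concentrations, all else at a reference.

    ``cofactor_concs`` is in mM; every participant not listed there is held
    at ``reference_conc`` (default 1 mM, i.e. the standard state).
    """
    ln_ref = math.log(reference_conc)
    ln_conc = {mid: ln_ref for mid in reaction.stoichiometry}
    for mid, c in cofactor_concs.items():
        if mid in ln_conc:
            ln_conc[mid] = math.log(c)
    return reaction_gibbs(reaction, ln_conc, params).dg_prime


def find_distributed_bottlenecks(
    pathway: Sequence[Reaction | str],
    adjusted_dgs: Sequence[float],
    threshold: float,
) -> list[tuple[int, int, float]]:
    """Maximal contiguous runs of reactions with summed adjusted ΔG' > threshold.

    A distributed thermodynamic bottleneck is a stretch of consecutive
    pathway reactions whose summed adjusted Gibbs energy is so unfavourable
    that a concentration gradient must be spread across the whole stretch.
    Returns (start index, end index inclusive, summed adjusted ΔG') for every
    qualifying window not strictly contained in another qualifying window.
    """
    if len(pathway) != len(adjusted_dgs):
        raise ValueError("pathway and adjusted_dgs must be aligned")
    n = len(adjusted_dgs)
    if n == 0:
        return []
    dgs = [float(x) for x in adjusted_dgs]
    # direct left-to-right window sums: exact agreement with naive
    # enumeration, including pathological float inputs
    sums = {}
    for i in range(n):
        acc = 0.0
        for j in range(i, n):
            acc = sum(dgs[i : j + 1])
            sums[(i, j)] = acc
    qualifying = [(i, j, s) for (i, j), s in sums.items() if s > threshold]
    maximal = [
        (i, j, s)
        for (i, j, s) in qualifying
        if not any(
            (i2 <= i and j <= j2 and (i2, j2) != (i, j)) for (i2, j2, _) in qualifying
        )
    ]
    maximal.sort(key=lambda w: (w[0], w[1]))
    return maximal


def write_gibbs_profiles(profiles: Sequence[GibbsProfile], path: str | Path) -> None:
    """TSV report: reaction_id, dg0, dg_prime, driving_force, ln_q."""
    import pandas as pd

    pd.DataFrame(
        {
            "reaction_id": [p.reaction_id for p in profiles],
            "dg0": [p.dg0 for p in profiles],
            "dg_prime": [p.dg_prime for p in profiles],
            "driving_force": [p.driving_force for p in profiles],
            "ln_q": [p.ln_q for p in profiles],
        }
    ).to_csv(path, sep="\t", index=False)
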