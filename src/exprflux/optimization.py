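"""Weighted flux-minimization LP and flux variability analysis.

The objective is min sum_j c_j * |v_j| subject to S v = 0 and bounds,
where c_j >= 1 are per-reaction penalty coefficients.  With all c_j = 1
this is exactly parsimonious FBA.  The absolute value is linearized by
splitting every reaction (exchanges included) into two nonnegative
half-reactions v = v+ - v- that share the reaction's c_j; at an optimum
with c_j > 0 at most one half carries flux unless bounds force otherwise.

Solved with scipy's HiGHS interface (sparse); deterministic for a fixed
reaction/metabolite ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core_model import MultiTissueModel

__all__ = [
    "FluxSolution",
    "FvaRanges",
    "InfeasibleError",
    "UnboundedError",
    "minimize_weighted_flux",
    "run_fva",
    "assert_feasible",
]

FEAS_TOL = 1e-9


class InfeasibleError(RuntimeError):
    """The LP admits no feasible flux vector."""


class UnboundedError(RuntimeError):
    """The LP objective is unbounded below (should not happen with c_j > 0)."""


@dataclass
class FluxSolution:
    """Net fluxes at a weighted-minimum optimum."""

    fluxes: Dict[str, float]
    objective: float
    status: str = "optimal"
    method: str = "highs"

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass
class FvaRanges:
    """Per-reaction (min, max) net flux over the near-optimal face."""

    ranges: Dict[str, Tuple[float, float]]
    objective: float
    objective_tolerance: float

    def __getitem__(self, rid: str) -> Tuple[float, float]:
        return self.ranges[rid]


class _Lp:
    """Split-variable LP data for one model: columns (v+_j, v-_j) per reaction."""

    def __init__(self, model: MultiTissueModel):
        self.reaction_ids = [r.id for r in model.reactions]
        met_index = {m.id: i for i, m in enumerate(model.metabolites)}
        n_rxn = len(model.reactions)
        rows, cols, vals = [], [], []
        lo = np.zeros(2 * n_rxn)
        hi = np.zeros(2 * n_rxn)
        for j, rxn in enumerate(model.reactions):
            for met, coef in rxn.stoichiometry.items():
                i = met_index[met]
                rows.extend((i, i))
                cols.extend((2 * j, 2 * j + 1))
                vals.extend((coef, -coef))
            # v+ in [max(lb,0), max(ub,0)], v- in [max(-ub,0), max(-lb,0)]
            lo[2 * j] = max(rxn.lower_bound, 0.0)
            hi[2 * j] = max(rxn.upper_bound, 0.0)
            lo[2 * j + 1] = max(-rxn.upper_bound, 0.0)
            hi[2 * j + 1] = max(-rxn.lower_bound, 0.0)
        self.A_eq = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_index), 2 * n_rxn)
        )
        self.b_eq = np.zeros(len(met_index))
        self.bounds = np.column_stack([lo, hi])

    def cost(self, weights: Mapping[str, float]) -> np.ndarray:
        c = np.empty(2 * len(self.reaction_ids))
        for j, rid in enumerate(self.reaction_ids):
            c[2 * j] = c[2 * j + 1] = weights[rid]
        return c


def _coerce_weights(model: MultiTissueModel, weights) -> Mapping[str, float]:
    if weights is None:
        return {rid: 1.0 for rid in (r.id for r in model.reactions)}
    coeffs = getattr(weights, "coefficients", weights)
    missing = [r.id for r in model.reactions if r.id not in coeffs]
    if missing:
        raise KeyError(f"weight vector missing reactions, e.g. {missing[:3]}")
    return coeffs


def _solve(lp: _Lp, c: np.ndarray, A_ub=None, b_ub=None, method: str = "highs"):
    res = linprog(
        c,
        A_eq=lp.A_eq,
        b_eq=lp.b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=lp.bounds,
        method=method,
    )
    if res.status == 2:
        raise InfeasibleError(res.message)
    if res.status == 3:
        raise UnboundedError(res.message)
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    return res


def minimize_weighted_flux(
    model: MultiTissueModel,
    weights=None,
    method: str = "highs",
) -> FluxSolution:
    """Solve min sum_j c_j |v_j| over the model's feasible set.

    ``weights`` is a WeightVector or a mapping reaction id -> c_j; ``None``
    means all ones (plain pFBA).  ``method`` is any scipy-linprog HiGHS
    method ("highs", "highs-ds", "highs-ipm").
    """
    coeffs = _coerce_weights(model, weights)
    lp = _Lp(model)
    res = _solve(lp, lp.cost(coeffs), method=method)
    x = res.x
    fluxes = {
        rid: float(x[2 * j] - x[2 * j + 1]) for j, rid in enumerate(lp.reaction_ids)
    }
    return FluxSolution(
        fluxes=fluxes, objective=float(res.fun), status="optimal", method=method
    )


def assert_feasible(model: MultiTissueModel) -> None:
    """Raise :class:`InfeasibleError` if the model has no feasible flux vector."""
    lp = _Lp(model)
    _solve(lp, np.zeros(lp.bounds.shape[0]))


def run_fva(
    model: MultiTissueModel,
    weights=None,
    reactions: Optional[Sequence[str]] = None,
    objective_tolerance: float = 1e-6,
    incumbent: Optional[FluxSolution] = None,
    method: str = "highs",
) -> FvaRanges:
    """Flux variability analysis over the near-optimal face.

    For each reaction in ``reactions`` (default: all), minimize and
    maximize its net flux subject to the model constraints plus
    sum c_j |v_j| <= (1 + objective_tolerance) * optimum.  The returned
    ranges bracket the incumbent optimal fluxes.
    """
    if objective_tolerance < 0:
        raise ValueError("objective_tolerance must be >= 0")
    coeffs = _coerce_weights(model, weights)
    lp = _Lp(model)
    cost = lp.cost(coeffs)
    if incumbent is None:
        res = _solve(lp, cost, method=method)
        optimum = float(res.fun)
    else:
        optimum = incumbent.objective
    # absolute slack floor keeps the face nonempty when the optimum is ~0
    cap = optimum * (1.0 + objective_tolerance) + max(abs(optimum), 1.0) * FEAS_TOL
    A_ub = sparse.csr_matrix(cost.reshape(1, -1))
    b_ub = np.array([cap])

    if reactions is None:
        targets = list(lp.reaction_ids)
    else:
        known = set(lp.reaction_ids)
        unknown = [rid for rid in reactions if rid not in known]
        if unknown:
            raise KeyError(f"unknown reactions in FVA subset: {unknown[:3]}")
        targets = list(reactions)

    index = {rid: j for j, rid in enumerate(lp.reaction_ids)}
    ranges: Dict[str, Tuple[float, float]] = {}
    n = lp.bounds.shape[0]
    for rid in targets:
        j = index[rid]
        obj = np.zeros(n)
        obj[2 * j], obj[2 * j + 1] = 1.0, -1.0
        lo = _solve(lp, obj, A_ub=A_ub, b_ub=b_ub, method=method)
        hi = _solve(lp, -obj, A_ub=A_ub, b_ub=b_ub, method=method)
        vmin = float(lo.x[2 * j] - lo.x[2 * j + 1])
        vmax = float(hi.x[2 * j] - hi.x[2 * j + 1])
        if vmin > vmax:  # numerical jitter on a point face
            vmin, vmax = vmax, vmin
        ranges[rid] = (vmin, vmax)
    return FvaRanges(ranges=ranges, objective=optimum, objective_tolerance=objective_tolerance)
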