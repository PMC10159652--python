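"""Scoring FBA flux maps against 13C-MFA flux estimates.

MFA studies report fluxes for lumped biochemical steps, so each measured
flux is paired with a signed linear combination of model reactions.  FBA
fluxes are first rescaled by a single normalization factor

    A = (measured net CO2 uptake) / (model net CO2 uptake)

which absorbs the arbitrary biomass anchor of the FBA scenario.  Agreement
is summarized by the weighted-average percent error

    100 * sum_j |A*v_j^p - v_j^m| / sum_j |v_j^m|

(equivalently: per-flux % errors averaged with |v_m| weights), which keeps
tiny measured fluxes from dominating.  Because the LP optimum is usually a
face rather than a point, the error is bracketed by min/max values derived
from FVA ranges via interval arithmetic.  Physiology summaries (RuBisCO
carboxylation/net assimilation, photorespiratory CO2 loss, CEF/LEF, carbon
conversion efficiency) are computed from configurable reaction sets.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .expression_weights import build_weight_vector
from .optimization import FluxSolution, FvaRanges, minimize_weighted_flux, run_fva

__all__ = [
    "MfaEntry",
    "MfaComparison",
    "ErrorReport",
    "PhysiologyMetrics",
    "normalization_factor",
    "weighted_average_error",
    "error_bounds",
    "per_flux_errors",
    "physiology_metrics",
    "sweep_scaling_factor",
    "parse_combo",
    "combo_to_string",
]

Combo = List[Tuple[str, float]]


@dataclass
class MfaEntry:
    mfa_id: str
    measured: float  # v_m, in the MFA study's units
    combo: Combo  # signed combination of model reaction ids


@dataclass
class MfaComparison:
    """Measured fluxes paired to signed combinations of model reactions."""

    entries: List[MfaEntry]
    measured_co2_uptake: float
    co2_combo: Combo

    def __post_init__(self):
        if not self.entries:
            raise ValueError("MFA comparison needs at least one entry")
        for e in self.entries:
            if not math.isfinite(e.measured):
                raise ValueError(f"entry {e.mfa_id!r}: non-finite measured flux")

    def validate_against(self, model) -> None:
        known = set(r.id for r in model.reactions)
        for e in self.entries:
            for rid, _ in e.combo:
                if rid not in known:
                    raise ValueError(
                        f"MFA entry {e.mfa_id!r} references unknown reaction {rid!r}"
                    )
        for rid, _ in self.co2_combo:
            if rid not in known:
                raise ValueError(f"CO2 combo references unknown reaction {rid!r}")

    @classmethod
    def from_tsv(cls, path, measured_co2_uptake: float, co2_combo) -> "MfaComparison":
        df = pd.read_csv(path, sep="\t", dtype={"mfa_id": str})
        entries = [
            MfaEntry(row["mfa_id"], float(row["measured_value"]), parse_combo(row["combo"]))
            for _, row in df.iterrows()
        ]
        if isinstance(co2_combo, str):
            co2_combo = parse_combo(co2_combo)
        return cls(entries, measured_co2_uptake, co2_combo)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "mfa_id": e.mfa_id,
                    "measured_value": e.measured,
                    "combo": combo_to_string(e.combo),
                }
                for e in self.entries
            ]
        ).to_csv(path, sep="\t", index=False)


_COMBO_TERM = re.compile(r"^\s*(?:([0-9.eE]+)\s*\*\s*)?(\S+)\s*$")


def parse_combo(text: str) -> Combo:
    """Parse "1.0*R1 - 2*R2 + R3" into [(R1, 1.0), (R2, -2.0), (R3, 1.0)]."""
    combo: Combo = []
    # split on +/- that separate terms (not inside exponents: ids have no spaces)
    for sign, term in re.findall(r"([+-]?)\s*([^+-]+)", text):
        term = term.strip()
        if not term:
            continue
        m = _COMBO_TERM.match(term)
        if m is None:
            raise ValueError(f"bad combo term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        if sign == "-":
            coef = -coef
        combo.append((m.group(2), coef))
    if not combo:
        raise ValueError(f"empty combo {text!r}")
    return combo


def combo_to_string(combo: Combo) -> str:
    parts = []
    for i, (rid, coef) in enumerate(combo):
        sign = "-" if coef < 0 else ("+" if i else "")
        parts.append(f"{sign} {abs(coef):g}*{rid}".strip())
    return " ".join(parts)


def evaluate_combo(combo: Combo, fluxes: Mapping[str, float]) -> float:
    return sum(coef * fluxes[rid] for rid, coef in combo)


def normalization_factor(sol: FluxSolution, mfa: MfaComparison) -> float:
    """A = measured net CO2 uptake / model net CO2 uptake."""
    model_co2 = evaluate_combo(mfa.co2_combo, sol.fluxes)
    if abs(model_co2) < 1e-12:
        raise ZeroDivisionError(
            "model net CO2 uptake is zero; normalization factor undefined"
        )
    return mfa.measured_co2_uptake / model_co2


def weighted_average_error(sol: FluxSolution, mfa: MfaComparison, A: float) -> float:
    """Weighted-average percent error of a flux map against the MFA set."""
    if not math.isfinite(A):
        raise ValueError("normalization factor must be finite")
    num = sum(abs(A * evaluate_combo(e.combo, sol.fluxes) - e.measured) for e in mfa.entries)
    den = sum(abs(e.measured) for e in mfa.entries)
    if den == 0:
        raise ZeroDivisionError("all measured fluxes are zero; error undefined")
    return 100.0 * num / den


def per_flux_errors(sol: FluxSolution, mfa: MfaComparison, A: float) -> pd.DataFrame:
    """Per-entry % errors; entries with v_m = 0 are flagged, not divided."""
    rows = []
    for e in mfa.entries:
        pred = A * evaluate_combo(e.combo, sol.fluxes)
        if e.measured == 0:
            rows.append(
                {
                    "mfa_id": e.mfa_id,
                    "measured": 0.0,
                    "predicted": pred,
                    "pct_error": np.nan,
                    "zero_measured": True,
                }
            )
        else:
            rows.append(
                {
                    "mfa_id": e.mfa_id,
                    "measured": e.measured,
                    "predicted": pred,
                    "pct_error": 100.0 * abs(pred - e.measured) / abs(e.measured),
                    "zero_measured": False,
                }
            )
    return pd.DataFrame(rows)


def _combo_interval(combo: Combo, fva: FvaRanges) -> Tuple[float, float]:
    lo = hi = 0.0
    for rid, coef in combo:
        rmin, rmax = fva.ranges[rid]
        if coef >= 0:
            lo += coef * rmin
            hi += coef * rmax
        else:
            lo += coef * rmax
            hi += coef * rmin
    return lo, hi


def error_bounds(fva: FvaRanges, mfa: MfaComparison, A: float) -> Tuple[float, float]:
    """(min%, max%) weighted-average error over the near-optimal face.

    Each entry's predicted value ranges over [A*lo, A*hi] (interval
    arithmetic over FVA ranges; conservative when combo reactions
    co-vary).  The minimum uses the in-interval point nearest v_m, the
    maximum the farthest endpoint; aggregation is |v_m|-weighted as for
    the point error.
    """
    missing = [
        rid
        for e in mfa.entries
        for rid, _ in e.combo
        if rid not in fva.ranges
    ]
    if missing:
        raise KeyError(f"FVA ranges missing combo reactions: {sorted(set(missing))[:3]}")
    num_min = num_max = 0.0
    den = sum(abs(e.measured) for e in mfa.entries)
    if den == 0:
        raise ZeroDivisionError("all measured fluxes are zero; error undefined")
    for e in mfa.entries:
        lo, hi = _combo_interval(e.combo, fva)
        plo, phi = sorted((A * lo, A * hi))
        if e.measured < plo:
            nearest = plo
        elif e.measured > phi:
            nearest = phi
        else:
            nearest = e.measured
        num_min += abs(nearest - e.measured)
        num_max += max(abs(plo - e.measured), abs(phi - e.measured))
    return 100.0 * num_min / den, 100.0 * num_max / den


@dataclass
class ErrorReport:
    """Point weighted-average error with FVA bounds and per-entry detail."""

    A: float
    point_pct: float
    min_pct: Optional[float]
    max_pct: Optional[float]
    per_flux: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "normalization_factor": self.A,
            "weighted_avg_error_pct": self.point_pct,
            "min_error_pct": self.min_pct,
            "max_error_pct": self.max_pct,
        }


def evaluate_solution(
    sol: FluxSolution,
    mfa: MfaComparison,
    fva: Optional[FvaRanges] = None,
) -> ErrorReport:
    """Normalize, score, and (optionally) FVA-bound one flux map."""
    A = normalization_factor(sol, mfa)
    point = weighted_average_error(sol, mfa, A)
    lo = hi = None
    if fva is not None:
        lo, hi = error_bounds(fva, mfa, A)
    return ErrorReport(
        A=A, point_pct=point, min_pct=lo, max_pct=hi, per_flux=per_flux_errors(sol, mfa, A)
    )


# ---------------------------------------------------------------------------
# physiology summary metrics


@dataclass
class PhysiologyMetrics:
    """Carbon/energy economy diagnostics of one flux map.

    Ratios are computed from summed signed fluxes over configured reaction
    sets; any metric with a zero denominator is left ``None`` and named in
    ``undefined``.
    """

    rubisco_ratio: Optional[float]
    photorespiratory_loss_pct: Optional[float]
    cef_lef_pct: Optional[float]
    biomass_carbon_pct: Optional[float]
    undefined: List[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "rubisco_ratio": self.rubisco_ratio,
            "photorespiratory_loss_pct": self.photorespiratory_loss_pct,
            "cef_lef_pct": self.cef_lef_pct,
            "biomass_carbon_pct": self.biomass_carbon_pct,
            "undefined": list(self.undefined),
        }


def _set_flux(entries, fluxes: Mapping[str, float]) -> float:
    """Sum signed fluxes over a set given as rids or "coef*rid" strings."""
    total = 0.0
    for entry in entries:
        if isinstance(entry, str) and "*" in entry:
            combo = parse_combo(entry)
            total += evaluate_combo(combo, fluxes)
        else:
            total += fluxes[entry]
    return total


def load_physiology_sets(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def physiology_metrics(sol: FluxSolution, sets: Mapping) -> PhysiologyMetrics:
    """Compute the four physiology summaries from named reaction sets.

    ``sets`` keys: ``rubisco_carboxylase``, ``co2_net``,
    ``photorespiratory_decarboxylation``, ``cef``, ``lef`` (each a list of
    reaction ids or "coef*rid" strings), and ``biomass_carbon`` (a mapping
    reaction id -> carbon atoms per unit flux).  Daytime-only metrics are
    expressed by listing daytime reaction replicas in the config.
    """
    undefined: List[str] = []
    co2_net = _set_flux(sets.get("co2_net", []), sol.fluxes)

    def ratio(num: float, den: float, name: str) -> Optional[float]:
        if abs(den) < 1e-12:
            undefined.append(name)
            return None
        return num / den

    rubisco = _set_flux(sets.get("rubisco_carboxylase", []), sol.fluxes)
    prd = _set_flux(sets.get("photorespiratory_decarboxylation", []), sol.fluxes)
    cef = _set_flux(sets.get("cef", []), sol.fluxes)
    lef = _set_flux(sets.get("lef", []), sol.fluxes)
    bc = sets.get("biomass_carbon", {}) or {}
    biomass_c = sum(float(carbon) * sol.fluxes[rid] for rid, carbon in bc.items())

    rr = ratio(rubisco, co2_net, "rubisco_ratio")
    pr = ratio(prd, co2_net, "photorespiratory_loss_pct")
    cl = ratio(cef, lef, "cef_lef_pct")
    bcp = ratio(biomass_c, co2_net, "biomass_carbon_pct")
    return PhysiologyMetrics(
        rubisco_ratio=rr,
        photorespiratory_loss_pct=None if pr is None else 100.0 * pr,
        cef_lef_pct=None if cl is None else 100.0 * cl,
        biomass_carbon_pct=None if bcp is None else 100.0 * bcp,
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# scaling-factor sweep


def sweep_scaling_factor(
    model,
    expr,
    sf_grid: Sequence[float],
    policies: Sequence[str],
    mfa: MfaComparison,
    fva_tolerance: float = 1e-6,
    with_fva: bool = True,
    solver_method: str = "highs",
) -> pd.DataFrame:
    """One build/solve/FVA/evaluate cycle per (SF, policy) grid point.

    FVA is restricted to the reactions appearing in MFA combos.  Solver
    failures are recorded in the ``status`` column and the sweep continues.
    Returns columns: sf, policy, objective, A, min_pct, point_pct, max_pct,
    status.
    """
    if len(sf_grid) == 0:
        raise ValueError("SF grid must be non-empty")
    combo_rids = sorted(
        {rid for e in mfa.entries for rid, _ in e.combo}
        | {rid for rid, _ in mfa.co2_combo}
    )
    rows = []
    for policy in policies:
        for sf in sf_grid:
            row = {"sf": sf, "policy": policy, "status": "ok"}
            try:
                wv = build_weight_vector(model, expr, sf=sf, gprless_policy=policy)
                sol = minimize_weighted_flux(model, wv, method=solver_method)
                fva = (
                    run_fva(
                        model,
                        wv,
                        reactions=combo_rids,
                        objective_tolerance=fva_tolerance,
                        incumbent=sol,
                        method=solver_method,
                    )
                    if with_fva
                    else None
                )
                report = evaluate_solution(sol, mfa, fva)
                row.update(
                    objective=sol.objective,
                    A=report.A,
                    min_pct=report.min_pct,
                    point_pct=report.point_pct,
                    max_pct=report.max_pct,
                )
            except Exception as exc:  # record and continue (long sweeps)
                row.update(
                    objective=np.nan,
                    A=np.nan,
                    min_pct=np.nan,
                    point_pct=np.nan,
                    max_pct=np.nan,
                    status=f"error: {exc}",
                )
            rows.append(row)
    return pd.DataFrame(rows)
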