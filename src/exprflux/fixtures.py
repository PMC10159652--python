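"""Synthetic multi-tissue fixtures with planted ground-truth flux maps.

:func:`make_toy_plant` builds a small diel plant: a leaf fixes CO2 with
photon-driven ATP during the day, exports sucrose to sink tissues in both
phases, and buffers night metabolism through a starch day->night
carry-over.  Biomass precursor synthesis runs through a chain of segments
offering parallel routes:

* *isozyme segments* — two routes of equal stoichiometric cost whose OR
  GPRs are co-expressed everywhere; the planted truth splits flux 50/50,
  so the pFBA optimum is a nontrivial face and every LP vertex pays the
  same irreducible error against the planted split;
* *resolved segments* — the true route in one "carrier" tissue is two
  reactions long (AND-form complex GPRs peaking in that tissue) while the
  alternative is a single reaction (an OR isozyme pair peaking in the
  other tissues).  Plain flux minimization always takes the short route
  and is therefore deterministically wrong in the carrier tissue; the
  inter-tissue expression signal corrects it once the scaling factor is
  large enough.

The planted flux map satisfies steady state and all bounds by
construction, and the MFA comparison derived from it (which also covers
photon uptake and linear electron flow, so rerouted energy metabolism is
penalized) scores 0% error at A = 1 when noise is zero.  Recovering the
planted map from the expression table is what the rest of the package is
tested against.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .core_model import (
    CoreNetwork,
    LinkSpec,
    Metabolite,
    MultiTissueModel,
    RatioConstraint,
    Reaction,
    ScenarioSpec,
    apply_scenario,
    build_multi_tissue,
    namespaced_id,
    write_tabular,
)
from .evaluation import MfaComparison, MfaEntry, combo_to_string
from .expression_weights import ExpressionTable
from .optimization import FluxSolution

__all__ = ["FixtureBundle", "make_toy_plant", "perturb_mfa", "write_bundle"]

PHASES = ("day", "night")
_TISSUE_NAMES = ["leaf", "stem", "root"]


@dataclass
class FixtureBundle:
    """Everything needed to run and score the pipeline on synthetic data."""

    core: CoreNetwork
    model: MultiTissueModel  # scenario already applied
    expression: ExpressionTable
    true_fluxes: FluxSolution  # planted ground truth
    mfa: MfaComparison  # derived from the planted fluxes
    scenario: ScenarioSpec
    link_specs: List[LinkSpec]
    physiology_sets: dict
    seed: int
    params: dict = field(default_factory=dict)
    truth_routes: Dict[Tuple[int, str], str] = field(default_factory=dict)

    def steady_state_residual(self) -> float:
        """max_i |sum_j S_ij * v_j| of the planted flux map."""
        balance: Dict[str, float] = {m.id: 0.0 for m in self.model.metabolites}
        for rxn in self.model.reactions:
            v = self.true_fluxes.fluxes[rxn.id]
            for met, coef in rxn.stoichiometry.items():
                balance[met] += coef * v
        # boundary metabolites do not exist in this model: every reaction is
        # balanced or an explicit one-sided exchange, which is fine because
        # exchanged metabolites are only the namespaced internal ones.
        internal = {
            m.id
            for m in self.model.metabolites
        }
        return max(abs(balance[m]) for m in internal) if internal else 0.0


def _tissue_labels(n_tissues: int) -> List[str]:
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues (one source, one sink)")
    labels = list(_TISSUE_NAMES[:n_tissues])
    for k in range(len(labels) + 1, n_tissues + 1):
        labels.append(f"tissue{k}")
    return labels


def _build_core(n_isozyme_pairs: int, n_resolved: int) -> Tuple[CoreNetwork, dict]:
    """Core single-tissue network with parallel-route chain segments.

    ``n_isozyme_pairs`` equal-cost segments (OR GPRs, planted 50/50 use)
    followed by ``n_resolved`` unequal segments (2-step complex route vs
    1-step isozyme route), in series from hexose-phosphate to the biomass
    precursor.
    """
    n_seg = n_isozyme_pairs + n_resolved
    chain_nodes = ["hp"] + [f"c{i}" for i in range(1, n_seg)] + ["bm"]
    mets = (
        ["co2", "ph", "atp", "hp", "suc", "starch", "bm"]
        + [f"c{i}" for i in range(1, n_seg)]
        + [f"x{j}" for j in range(1, n_resolved + 1)]  # long-route intermediates
    )
    reactions = [
        Reaction("CUP", {"co2": 1.0}, 0.0, 1000.0, "", "exchange"),
        Reaction("LGT", {"ph": 1.0}, 0.0, 1000.0, "", "exchange"),
        Reaction("LEF", {"ph": -1.0, "atp": 1.0}, 0.0, 1000.0, "LEF1 and LEF2", "light"),
        Reaction("CEF", {"ph": -2.0, "atp": 1.0}, 0.0, 1000.0, "CEF1", "light"),
        Reaction("RBC", {"co2": -1.0, "atp": -1.0, "hp": 1.0}, 0.0, 1000.0, "RBC1 or RBC2", "calvin"),
        Reaction("PRD", {"hp": -1.0, "co2": 1.0}, 0.0, 1000.0, "PRD1", "photorespiration"),
        Reaction("SUC_SYN", {"hp": -1.0, "suc": 1.0}, 0.0, 1000.0, "SPS1 or SPS2", "sucrose"),
        Reaction("SUC_CAT", {"suc": -1.0, "hp": 1.0}, 0.0, 1000.0, "INV1", "sucrose"),
        Reaction("STS", {"hp": -1.0, "starch": 1.0}, 0.0, 1000.0, "STS1 and STS2", "starch"),
        Reaction("STD", {"starch": -1.0, "hp": 1.0}, 0.0, 1000.0, "STD1", "starch"),
    ]
    segments = []
    for i in range(1, n_isozyme_pairs + 1):
        src, dst = chain_nodes[i - 1], chain_nodes[i]
        rid_a, rid_b = f"ISO{i}A", f"ISO{i}B"
        reactions.append(
            Reaction(rid_a, {src: -1.0, dst: 1.0}, 0.0, 1000.0, f"IA{i}1 or IA{i}2", "chain")
        )
        reactions.append(
            Reaction(rid_b, {src: -1.0, dst: 1.0}, 0.0, 1000.0, f"IB{i}1 or IB{i}2", "chain")
        )
        segments.append(
            {"index": i, "kind": "isozyme", "routes": {"a": [rid_a], "b": [rid_b]}}
        )
    for j in range(1, n_resolved + 1):
        i = n_isozyme_pairs + j
        src, dst = chain_nodes[i - 1], chain_nodes[i]
        mid = f"x{j}"
        long1, long2, short = f"CPX{j}A1", f"CPX{j}A2", f"CPX{j}B"
        reactions.append(
            Reaction(long1, {src: -1.0, mid: 1.0}, 0.0, 1000.0, f"CA{j}1 and CA{j}2", "chain")
        )
        reactions.append(
            Reaction(long2, {mid: -1.0, dst: 1.0}, 0.0, 1000.0, f"CA{j}3", "chain")
        )
        reactions.append(
            Reaction(short, {src: -1.0, dst: 1.0}, 0.0, 1000.0, f"CB{j}1 or CB{j}2", "chain")
        )
        segments.append(
            {"index": i, "kind": "resolved", "routes": {"a": [long1, long2], "b": [short]}}
        )
    reactions.append(Reaction("BIO", {"bm": -1.0}, 0.0, 1000.0, "", "biomass"))

    core = CoreNetwork(metabolites=[Metabolite(m) for m in mets], reactions=reactions)
    core.validate()
    from .gpr import gpr_genes, parse_gpr

    route_genes = {}
    for seg in segments:
        for route, rids in seg["routes"].items():
            genes = set()
            for rid in rids:
                genes |= gpr_genes(parse_gpr(core.get_reaction(rid).gpr))
            route_genes[(seg["index"], route)] = sorted(genes)
    return core, {"segments": segments, "route_genes": route_genes}


def make_toy_plant(
    seed: int = 0,
    n_tissues: int = 3,
    n_isozyme_pairs: int = 2,
    n_complexes: int = 2,
    biomass_flux: float = 0.01,
    light_level: float = 1000.0,
    n_distractor_genes: int = 3,
    max_core_reactions: int = 100,
    max_retries: int = 5,
) -> FixtureBundle:
    """Generate a feasible multi-tissue fixture with planted true fluxes.

    ``n_isozyme_pairs`` equal-cost chain segments carry OR-form GPRs,
    ``n_complexes`` carry AND-form GPRs; one additional segment has an
    unequal-length route pair (the leaf's true route is the long one).
    The biomass anchor defaults to 0.01 per tissue and phase.
    """
    last_err: Optional[Exception] = None
    for attempt in range(max_retries):
        try:
            return _make_toy_plant_once(
                seed + 7919 * attempt,
                n_tissues,
                n_isozyme_pairs,
                n_complexes,
                biomass_flux,
                light_level,
                n_distractor_genes,
                max_core_reactions,
            )
        except _ConstructionError as exc:  # pragma: no cover - by design unreachable
            last_err = exc
    raise RuntimeError(f"fixture construction failed after {max_retries} tries: {last_err}")


class _ConstructionError(RuntimeError):
    pass


def _make_toy_plant_once(
    seed: int,
    n_tissues: int,
    n_isozyme_pairs: int,
    n_complexes: int,
    biomass_flux: float,
    light_level: float,
    n_distractor_genes: int,
    max_core_reactions: int,
) -> FixtureBundle:
    if n_complexes < 1:
        raise ValueError("need at least one resolved (complex) segment")
    rng = np.random.default_rng(seed)
    tissues = _tissue_labels(n_tissues)
    leaf, sinks = tissues[0], tissues[1:]
    core, topo = _build_core(n_isozyme_pairs, n_complexes)
    if len(core.reactions) > max_core_reactions:
        raise ValueError(
            f"core has {len(core.reactions)} reactions > max_core_reactions={max_core_reactions}"
        )
    segments = topo["segments"]

    # --- plant the true route per (segment, tissue) -----------------------
    # isozyme segments: both routes co-active everywhere ("ab");
    # resolved segments: a seeded carrier tissue runs the long route.
    truth: Dict[Tuple[int, str], str] = {}
    carriers: Dict[int, str] = {}
    for seg in segments:
        if seg["kind"] == "isozyme":
            for t in tissues:
                truth[(seg["index"], t)] = "ab"
        else:
            carrier = tissues[int(rng.integers(n_tissues))]
            carriers[seg["index"]] = carrier
            for t in tissues:
                truth[(seg["index"], t)] = "a" if t == carrier else "b"

    # --- expression table -------------------------------------------------
    carrying: Dict[str, List[str]] = {}
    for (idx, route), genes in topo["route_genes"].items():
        carriers_of_route = [t for t in tissues if route in truth[(idx, t)]]
        for g in genes:
            carrying[g] = carriers_of_route
    for g in ("RBC1", "RBC2", "LEF1", "LEF2", "PRD1", "SPS1", "SPS2", "STS1", "STS2", "STD1"):
        carrying[g] = [leaf]
    carrying["INV1"] = list(sinks)
    carrying["CEF1"] = [sinks[0]]
    genes = sorted(carrying) + [f"XTRA{k}" for k in range(1, n_distractor_genes + 1)]

    values = np.exp(rng.uniform(np.log(1.0), np.log(1000.0), size=(len(genes), n_tissues)))
    import pandas as pd

    df = pd.DataFrame(values, index=genes, columns=tissues)
    for g, peak_tissues in carrying.items():
        if peak_tissues:
            df.loc[g, peak_tissues] = 10.0 * df.loc[g].max()
    df = df.round(3)
    expression = ExpressionTable(df)

    # --- multi-tissue model ----------------------------------------------
    link_specs: List[LinkSpec] = []
    for t in sinks:
        for p in PHASES:
            link_specs.append(LinkSpec("suc", leaf, p, t, p))
    link_specs.append(LinkSpec("starch", leaf, "day", leaf, "night"))
    model = build_multi_tissue(
        core,
        tissues,
        list(PHASES),
        link_specs,
        biomass_reaction="BIO",
        shareable=["suc", "starch"],
    )

    exchanges: Dict[str, Tuple[float, float]] = {}
    for t in tissues:
        for p in PHASES:
            is_leaf_day = t == leaf and p == "day"
            exchanges[namespaced_id("CUP", t, p)] = (0.0, 1000.0 if is_leaf_day else 0.0)
            exchanges[namespaced_id("LGT", t, p)] = (
                0.0,
                light_level if is_leaf_day else 0.0,
            )
    starch_sucrose_ratio = n_tissues / (n_tissues - 1)
    scenario = ScenarioSpec(
        biomass={(t, p): biomass_flux for t in tissues for p in PHASES},
        exchanges=exchanges,
        ratios=[
            RatioConstraint(
                namespaced_id("STS", leaf, "day"),
                namespaced_id("SUC_SYN", leaf, "day"),
                starch_sucrose_ratio,
            )
        ],
        variants={
            "open_root_proton": {}  # placeholder variant slot; fixture has no protons
        },
    )
    try:
        constrained = apply_scenario(model, scenario, check_feasible=True)
    except Exception as exc:
        raise _ConstructionError(str(exc)) from exc

    # --- planted flux map -------------------------------------------------
    bf = biomass_flux
    fluxes = {rid: 0.0 for rid in constrained.reaction_ids}
    for t in tissues:
        for p in PHASES:
            fluxes[namespaced_id("BIO", t, p)] = bf
            for seg in segments:
                chosen = truth[(seg["index"], t)]
                share = bf / len(chosen)  # "ab" = 50/50 isozyme split
                for route in chosen:
                    for rid in seg["routes"][route]:
                        fluxes[namespaced_id(rid, t, p)] = share
    n_sink = len(sinks)
    fluxes[namespaced_id("SUC_SYN", leaf, "day")] = bf * n_sink
    fluxes[namespaced_id("SUC_SYN", leaf, "night")] = bf * n_sink
    fluxes[namespaced_id("STS", leaf, "day")] = bf * n_tissues
    fluxes[namespaced_id("STD", leaf, "night")] = bf * n_tissues
    assim = bf * 2 * n_tissues
    for rid in ("RBC", "LEF", "LGT", "CUP"):
        fluxes[namespaced_id(rid, leaf, "day")] = assim
    for t in sinks:
        for p in PHASES:
            fluxes[LinkSpec("suc", leaf, p, t, p).linker_id()] = bf
            fluxes[namespaced_id("SUC_CAT", t, p)] = bf
    fluxes[LinkSpec("starch", leaf, "day", leaf, "night").linker_id()] = bf * n_tissues
    true_sol = FluxSolution(
        fluxes=fluxes,
        objective=float(sum(abs(v) for v in fluxes.values())),
        status="planted",
        method="construction",
    )

    # --- MFA comparison from the planted map ------------------------------
    entries: List[MfaEntry] = []

    def add(mfa_id: str, rid: str):
        entries.append(MfaEntry(mfa_id, fluxes[rid], [(rid, 1.0)]))

    add("rbc_leaf", namespaced_id("RBC", leaf, "day"))
    add("lef_leaf", namespaced_id("LEF", leaf, "day"))
    add("cef_leaf", namespaced_id("CEF", leaf, "day"))
    add("photon_uptake_leaf", namespaced_id("LGT", leaf, "day"))
    add("photoresp_leaf", namespaced_id("PRD", leaf, "day"))
    add("suc_syn_leaf", namespaced_id("SUC_SYN", leaf, "day"))
    add("starch_syn_leaf", namespaced_id("STS", leaf, "day"))
    add("starch_deg_leaf_night", namespaced_id("STD", leaf, "night"))
    for t in sinks:
        add(f"suc_export_{t}", LinkSpec("suc", leaf, "day", t, "day").linker_id())
    for seg in segments:
        for route, rids in seg["routes"].items():
            for rid in rids:
                for t in tissues:
                    add(f"seg{seg['index']}{route}_{rid}_{t}", namespaced_id(rid, t, "day"))
    mfa = MfaComparison(
        entries=entries,
        measured_co2_uptake=assim,
        co2_combo=[(namespaced_id("CUP", leaf, "day"), 1.0)],
    )
    mfa.validate_against(constrained)

    physiology_sets = {
        "rubisco_carboxylase": [namespaced_id("RBC", leaf, "day")],
        "co2_net": [namespaced_id("CUP", leaf, "day")],
        "photorespiratory_decarboxylation": [namespaced_id("PRD", leaf, "day")],
        "cef": [namespaced_id("CEF", leaf, "day")],
        "lef": [namespaced_id("LEF", leaf, "day")],
        "biomass_carbon": {namespaced_id("BIO", t, "day"): 1 for t in [leaf]},
    }

    bundle = FixtureBundle(
        core=core,
        model=constrained,
        expression=expression,
        true_fluxes=true_sol,
        mfa=mfa,
        scenario=scenario,
        link_specs=link_specs,
        physiology_sets=physiology_sets,
        seed=seed,
        params={
            "n_tissues": n_tissues,
            "n_isozyme_pairs": n_isozyme_pairs,
            "n_complexes": n_complexes,
            "biomass_flux": biomass_flux,
            "light_level": light_level,
            "starch_sucrose_ratio": starch_sucrose_ratio,
            "carriers": carriers,
        },
        truth_routes=truth,
    )
    residual = bundle.steady_state_residual()
    if residual > 1e-9:
        raise _ConstructionError(f"planted fluxes violate steady state ({residual})")
    return bundle


def perturb_mfa(bundle_or_mfa, relative_noise: float, seed: int) -> MfaComparison:
    """Multiply measured values by independent (1 + eps), eps ~ U(-noise, +noise)."""
    if relative_noise < 0:
        raise ValueError("relative_noise must be >= 0")
    mfa = getattr(bundle_or_mfa, "mfa", bundle_or_mfa)
    rng = np.random.default_rng(seed)
    eps = rng.uniform(-relative_noise, relative_noise, size=len(mfa.entries))
    entries = [
        MfaEntry(e.mfa_id, e.measured * (1.0 + float(eps[i])), list(e.combo))
        for i, e in enumerate(mfa.entries)
    ]
    return MfaComparison(
        entries=entries,
        measured_co2_uptake=mfa.measured_co2_uptake,
        co2_combo=list(mfa.co2_combo),
    )


def write_bundle(bundle: FixtureBundle, directory) -> None:
    """Write the bundle in the same formats the other modules read."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_tabular(bundle.core, directory)
    bundle.expression.to_tsv(directory / "expression.tsv")
    bundle.mfa.to_tsv(directory / "mfa_comparison.tsv")
    with open(directory / "physiology_sets.yaml", "w") as fh:
        yaml.safe_dump(bundle.physiology_sets, fh, sort_keys=False)

    config = {
        "tissues": bundle.model.tissues,
        "phases": bundle.model.phases,
        "biomass_reaction": "BIO",
        "shareable": ["suc", "starch"],
        "linkers": [
            {
                "metabolite": ls.metabolite,
                "from_tissue": ls.from_tissue,
                "from_phase": ls.from_phase,
                "to_tissue": ls.to_tissue,
                "to_phase": ls.to_phase,
                "reversible": ls.reversible,
            }
            for ls in bundle.link_specs
        ],
        "biomass": {f"{t}/{p}": v for (t, p), v in bundle.scenario.biomass.items()},
        "exchanges": {rid: list(b) for rid, b in bundle.scenario.exchanges.items()},
        "ratios": [
            {"a": rc.reaction_a, "b": rc.reaction_b, "ratio": rc.ratio}
            for rc in bundle.scenario.ratios
        ],
        "mfa": {
            "measured_co2_uptake": bundle.mfa.measured_co2_uptake,
            "co2_combo": combo_to_string(bundle.mfa.co2_combo),
        },
        "seed": bundle.seed,
        "params": bundle.params,
    }
    with open(directory / "scenario.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    import pandas as pd

    pd.DataFrame(
        {"reaction_id": list(bundle.true_fluxes.fluxes),
         "flux": list(bundle.true_fluxes.fluxes.values())}
    ).to_csv(directory / "true_fluxes.tsv", sep="\t", index=False)
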