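"""Metabolic network containers, multi-tissue replication, and scenarios.

A :class:`CoreNetwork` is a single-tissue stoichiometric model (metabolites,
bounded reactions, GPR strings).  :func:`build_multi_tissue` replicates it
once per (tissue, phase) pair — e.g. leaf/stem/root x day/night — and wires
the copies together with *linker* reactions: inter-tissue transporters
(phloem-style metabolite movement) and diel carry-over reactions (e.g.
starch accumulated in the light and consumed in the dark).  Scenario
constraints (fixed biomass rates, exchange bounds such as light level, and
flux-ratio constraints such as starch:sucrose synthesis or vo/vc through
RuBisCO) are applied afterwards by :func:`apply_scenario`.

File formats: SBML Level 3 with the fbc package (delegated to cobrapy) or a
plain tabular dialect (``reactions.tsv`` + ``metabolites.tsv``); build and
scenario configuration is YAML (keys: tissues, phases, linkers, biomass,
ratios, exchanges, variants).
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .gpr import GprParseError, gpr_genes, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "CoreNetwork",
    "LinkSpec",
    "MultiTissueModel",
    "RatioConstraint",
    "ScenarioSpec",
    "ModelFormatError",
    "BuildError",
    "InfeasibleScenarioError",
    "read_core_network",
    "write_tabular",
    "write_sbml",
    "build_multi_tissue",
    "apply_scenario",
    "to_cobra",
    "load_config",
    "namespaced_id",
    "split_namespaced_id",
]

NS_SEP = "__"
RATIO_COMPARTMENT = "constraint"
DEFAULT_BOUND = 1000.0


class ModelFormatError(ValueError):
    """A model file violates the format or a network invariant."""


class BuildError(ValueError):
    """Multi-tissue assembly failed (bad link spec, unknown ids, ...)."""


class InfeasibleScenarioError(RuntimeError):
    """Scenario constraints admit no steady-state flux vector."""

    def __init__(self, message: str, binding: Optional[List[str]] = None):
        super().__init__(message)
        self.binding = binding or []


# ---------------------------------------------------------------------------
# containers


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass
class Reaction:
    """A reaction with stoichiometry, flux bounds (mmol gDW^-1 h^-1) and GPR."""

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    subsystem: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def equation_string(self) -> str:
        lhs, rhs = [], []
        for met, coef in self.stoichiometry.items():
            side = rhs if coef > 0 else lhs
            c = abs(coef)
            side.append(met if c == 1 else f"{c:g} {met}")
        arrow = "<=>" if self.reversible else "-->"
        return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


def _parse_equation(eq: str, rid: str) -> Tuple[Dict[str, float], bool]:
    if "<=>" in eq:
        parts, reversible = eq.split("<=>"), True
    elif "-->" in eq:
        parts, reversible = eq.split("-->"), False
    else:
        raise ModelFormatError(f"reaction {rid!r}: equation needs '-->' or '<=>': {eq!r}")
    if len(parts) != 2:
        raise ModelFormatError(f"reaction {rid!r}: malformed equation {eq!r}")
    left, right = parts
    stoich: Dict[str, float] = {}

    def add_side(side: str, sign: float):
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            m = re.match(r"^(?:([0-9.eE+\-]+)\s+)?(\S+)$", term)
            if m is None:
                raise ModelFormatError(f"reaction {rid!r}: bad term {term!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    return stoich, reversible


@dataclass
class CoreNetwork:
    """A validated single-tissue metabolic network."""

    metabolites: List[Metabolite]
    reactions: List[Reaction]
    genes: List[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.genes:
            seen: Dict[str, None] = {}
            for rxn in self.reactions:
                for g in sorted(gpr_genes(parse_gpr(rxn.gpr))):
                    seen.setdefault(g, None)
            self.genes = list(seen)

    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def validate(self) -> None:
        met_ids = set(self.metabolite_ids)
        if len(met_ids) != len(self.metabolites):
            raise ModelFormatError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != len(self.reactions):
            raise ModelFormatError("duplicate reaction ids")
        gene_set = set(self.genes)
        for rxn in self.reactions:
            for met in rxn.stoichiometry:
                if met not in met_ids:
                    raise ModelFormatError(
                        f"reaction {rxn.id!r} references undeclared metabolite {met!r}"
                    )
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelFormatError(
                    f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                    f"upper bound {rxn.upper_bound}"
                )
            try:
                tree = parse_gpr(rxn.gpr)
            except GprParseError as exc:
                raise ModelFormatError(f"reaction {rxn.id!r}: GPR error: {exc}") from exc
            missing = gpr_genes(tree) - gene_set
            if missing:
                raise ModelFormatError(
                    f"reaction {rxn.id!r}: GPR genes {sorted(missing)} not in gene list"
                )


# ---------------------------------------------------------------------------
# reading / writing


def read_core_network(path) -> CoreNetwork:
    """Read a core network from SBML (.xml/.sbml) or the tabular dialect.

    The tabular dialect is a directory (or the ``reactions.tsv`` file inside
    one) with ``reactions.tsv`` columns id, equation, lb, ub, gpr, subsystem
    and an optional ``metabolites.tsv`` (id, name, compartment).  GPR strings
    from the tabular path are preserved verbatim.
    """
    path = Path(path)
    if path.suffix.lower() in (".xml", ".sbml"):
        return _core_from_sbml(path)
    if path.is_dir():
        rxn_path = path / "reactions.tsv"
    else:
        rxn_path = path
    if not rxn_path.exists():
        raise ModelFormatError(f"no such model file: {rxn_path}")
    return _core_from_tabular(rxn_path)


def _core_from_tabular(rxn_path: Path) -> CoreNetwork:
    df = pd.read_csv(rxn_path, sep="\t", dtype=str).fillna("")
    required = {"id", "equation", "lb", "ub"}
    if not required <= set(df.columns):
        raise ModelFormatError(
            f"{rxn_path}: reactions.tsv needs columns {sorted(required)}"
        )
    met_path = rxn_path.parent / "metabolites.tsv"
    metabolites: List[Metabolite] = []
    declared = None
    if met_path.exists():
        mdf = pd.read_csv(met_path, sep="\t", dtype=str).fillna("")
        metabolites = [
            Metabolite(row["id"], row.get("name", ""), row.get("compartment", ""))
            for _, row in mdf.iterrows()
        ]
        declared = {m.id for m in metabolites}
    reactions = []
    seen_mets: Dict[str, None] = {}
    for _, row in df.iterrows():
        stoich, reversible = _parse_equation(row["equation"], row["id"])
        lb, ub = float(row["lb"]), float(row["ub"])
        for met in stoich:
            seen_mets.setdefault(met, None)
            if declared is not None and met not in declared:
                raise ModelFormatError(
                    f"reaction {row['id']!r} references undeclared metabolite {met!r}"
                )
        reactions.append(
            Reaction(
                id=row["id"],
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=row.get("gpr", ""),
                subsystem=row.get("subsystem", ""),
            )
        )
    if not metabolites:
        metabolites = [Metabolite(m) for m in seen_mets]
    core = CoreNetwork(metabolites=metabolites, reactions=reactions)
    core.validate()
    return core


def _core_from_sbml(path: Path) -> CoreNetwork:
    import cobra.io

    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # libsbml raises a zoo of types
        raise ModelFormatError(f"cannot parse SBML file {path}: {exc}") from exc
    metabolites = [
        Metabolite(m.id, m.name or "", m.compartment or "") for m in cmodel.metabolites
    ]
    reactions = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: c for m, c in r.metabolites.items()},
            lower_bound=r.lower_bound,
            upper_bound=r.upper_bound,
            gpr=r.gene_reaction_rule or "",
            subsystem=r.subsystem or "",
        )
        for r in cmodel.reactions
    ]
    core = CoreNetwork(metabolites=metabolites, reactions=reactions)
    core.validate()
    return core


def write_tabular(network, directory) -> None:
    """Write a CoreNetwork or MultiTissueModel to reactions/metabolites.tsv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "id": r.id,
                "equation": r.equation_string(),
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": r.gpr,
                "subsystem": r.subsystem,
            }
            for r in network.reactions
        ]
    ).to_csv(directory / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"id": m.id, "name": m.name, "compartment": m.compartment} for m in network.metabolites]
    ).to_csv(directory / "metabolites.tsv", sep="\t", index=False)


def to_cobra(network, model_id: str = "exprflux"):
    """Convert a CoreNetwork or MultiTissueModel to a ``cobra.Model``."""
    import cobra

    cmodel = cobra.Model(model_id)
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        for m in network.metabolites
    }
    cmodel.add_metabolites(list(mets.values()))
    rxns = []
    for r in network.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        rxns.append(cr)
    cmodel.add_reactions(rxns)
    for r in network.reactions:
        cr = cmodel.reactions.get_by_id(r.id)
        cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        if r.gpr:
            cr.gene_reaction_rule = r.gpr
    return cmodel


def write_sbml(network, path) -> None:
    import cobra.io

    cobra.io.write_sbml_model(to_cobra(network), str(path))


# ---------------------------------------------------------------------------
# multi-tissue replication


def namespaced_id(core_id: str, tissue: str, phase: str) -> str:
    return f"{core_id}{NS_SEP}{tissue}{NS_SEP}{phase}"


def split_namespaced_id(rid: str) -> Tuple[str, str, str]:
    parts = rid.rsplit(NS_SEP, 2)
    if len(parts) != 3:
        raise ValueError(f"{rid!r} is not a namespaced id")
    return parts[0], parts[1], parts[2]


@dataclass
class LinkSpec:
    """One linker reaction: moves a shareable metabolite between copies.

    Inter-tissue transport keeps the phase fixed; a diel carry-over keeps
    the tissue fixed and moves day -> night.  ``home_tissue`` is the tissue
    whose expression weights the linker inherits under the tissue-median
    GPR-less policy (defaults to the source tissue); ``None`` marks a
    whole-plant reaction that always gets weight 1.
    """

    metabolite: str
    from_tissue: str
    from_phase: str
    to_tissue: str
    to_phase: str
    reversible: bool = False
    id: Optional[str] = None
    home_tissue: Optional[str] = "__from__"  # sentinel: default to from_tissue

    def linker_id(self) -> str:
        if self.id:
            return self.id
        return (
            f"LNK_{self.metabolite}_{self.from_tissue}.{self.from_phase}"
            f"_to_{self.to_tissue}.{self.to_phase}"
        )


@dataclass
class MultiTissueModel:
    """Tissue x phase replicated network plus linkers.

    ``provenance`` maps every replicated reaction id back to its
    (core_id, tissue, phase); ``linker_home`` maps linker/exchange reaction
    ids to their home tissue (``None`` = whole-plant); ``biomass_ids`` maps
    (tissue, phase) to the replicated biomass reaction id.
    """

    tissues: List[str]
    phases: List[str]
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    provenance: Dict[str, Tuple[str, str, str]]
    linker_home: Dict[str, Optional[str]] = field(default_factory=dict)
    biomass_ids: Dict[Tuple[str, str], str] = field(default_factory=dict)

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        idx = getattr(self, "_rxn_index", None)
        if idx is None or len(idx) != len(self.reactions):
            idx = {r.id: r for r in self.reactions}
            object.__setattr__(self, "_rxn_index", idx)
        return idx[rid]

    def tissue_of(self, rid: str) -> Optional[str]:
        """Home tissue of a reaction, or None for whole-plant reactions."""
        if rid in self.provenance:
            return self.provenance[rid][1]
        return self.linker_home.get(rid)

    def copy(self) -> "MultiTissueModel":
        model = MultiTissueModel(
            tissues=list(self.tissues),
            phases=list(self.phases),
            metabolites=_copy.deepcopy(self.metabolites),
            reactions=_copy.deepcopy(self.reactions),
            provenance=dict(self.provenance),
            linker_home=dict(self.linker_home),
            biomass_ids=dict(self.biomass_ids),
        )
        return model

    def validate(self) -> None:
        met_ids = {m.id for m in self.metabolites}
        for r in self.reactions:
            for m in r.stoichiometry:
                if m not in met_ids:
                    raise ModelFormatError(
                        f"reaction {r.id!r} references undeclared metabolite {m!r}"
                    )
            if r.lower_bound > r.upper_bound:
                raise ModelFormatError(f"reaction {r.id!r}: inverted bounds")


def build_multi_tissue(
    core: CoreNetwork,
    tissues: Sequence[str],
    phases: Sequence[str],
    link_spec: Sequence[LinkSpec] = (),
    biomass_reaction: Optional[str] = None,
    shareable: Optional[Iterable[str]] = None,
) -> MultiTissueModel:
    """Replicate ``core`` per (tissue, phase) and add linker reactions.

    Every replicated reaction id is ``<core_id>__<tissue>__<phase>``; GPR
    strings are copied verbatim to every replica.  ``shareable``, when
    given, restricts which core metabolites linkers may move.
    """
    if not tissues or not phases:
        raise BuildError("tissues and phases must be non-empty")
    if len(set(tissues)) != len(tissues) or len(set(phases)) != len(phases):
        raise BuildError("tissue/phase labels must be unique")
    core.validate()
    core_mets = set(core.metabolite_ids)
    shareable_set = set(shareable) if shareable is not None else None

    metabolites: List[Metabolite] = []
    reactions: List[Reaction] = []
    provenance: Dict[str, Tuple[str, str, str]] = {}
    biomass_ids: Dict[Tuple[str, str], str] = {}

    for tissue in tissues:
        for phase in phases:
            for m in core.metabolites:
                metabolites.append(
                    Metabolite(namespaced_id(m.id, tissue, phase), m.name, m.compartment)
                )
            for r in core.reactions:
                rid = namespaced_id(r.id, tissue, phase)
                reactions.append(
                    Reaction(
                        id=rid,
                        stoichiometry={
                            namespaced_id(m, tissue, phase): c
                            for m, c in r.stoichiometry.items()
                        },
                        lower_bound=r.lower_bound,
                        upper_bound=r.upper_bound,
                        gpr=r.gpr,
                        subsystem=r.subsystem,
                    )
                )
                provenance[rid] = (r.id, tissue, phase)
                if biomass_reaction is not None and r.id == biomass_reaction:
                    biomass_ids[(tissue, phase)] = rid

    linker_home: Dict[str, Optional[str]] = {}
    for spec in link_spec:
        if spec.metabolite not in core_mets:
            raise BuildError(f"link spec names unknown metabolite {spec.metabolite!r}")
        if shareable_set is not None and spec.metabolite not in shareable_set:
            raise BuildError(
                f"metabolite {spec.metabolite!r} is not declared shareable"
            )
        for label, pool in ((spec.from_tissue, tissues), (spec.to_tissue, tissues)):
            if label not in pool:
                raise BuildError(f"link spec names unknown tissue {label!r}")
        for label in (spec.from_phase, spec.to_phase):
            if label not in phases:
                raise BuildError(f"link spec names unknown phase {label!r}")
        rid = spec.linker_id()
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry={
                    namespaced_id(spec.metabolite, spec.from_tissue, spec.from_phase): -1.0,
                    namespaced_id(spec.metabolite, spec.to_tissue, spec.to_phase): +1.0,
                },
                lower_bound=-DEFAULT_BOUND if spec.reversible else 0.0,
                upper_bound=DEFAULT_BOUND,
                subsystem="linker",
            )
        )
        home = spec.from_tissue if spec.home_tissue == "__from__" else spec.home_tissue
        linker_home[rid] = home

    model = MultiTissueModel(
        tissues=list(tissues),
        phases=list(phases),
        metabolites=metabolites,
        reactions=reactions,
        provenance=provenance,
        linker_home=linker_home,
        biomass_ids=biomass_ids,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class RatioConstraint:
    """Enforce v_a = ratio * v_b exactly (an added steady-state row)."""

    reaction_a: str
    reaction_b: str
    ratio: float


@dataclass
class ScenarioSpec:
    """Constraints defining one growth scenario.

    ``biomass`` maps (tissue, phase) pairs — or a tissue label, meaning all
    phases — to a fixed biomass flux (the model's dimensionless growth
    anchor; a value like 0.01 is typical and is later absorbed by the
    error-evaluation normalization factor).  ``exchanges`` maps reaction
    ids to (lb, ub) bounds, e.g. a photon-uptake light level.  ``variants``
    are named optional bound overlays (e.g. unconstrained root proton
    exchange); only those listed in ``enabled_variants`` are applied.
    """

    biomass: Dict[object, float] = field(default_factory=dict)
    exchanges: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    ratios: List[RatioConstraint] = field(default_factory=list)
    variants: Dict[str, Dict[str, Tuple[float, float]]] = field(default_factory=dict)
    enabled_variants: List[str] = field(default_factory=list)

    def validate(self) -> None:
        for rc in self.ratios:
            if not (rc.ratio > 0 and rc.ratio < float("inf")):
                raise ValueError(f"ratio for {rc.reaction_a}/{rc.reaction_b} must be finite and positive")
        for name in self.enabled_variants:
            if name not in self.variants:
                raise ValueError(f"unknown variant {name!r}")


def _ratio_metabolite_id(rc: RatioConstraint) -> str:
    return f"RATIO{NS_SEP}{rc.reaction_a}{NS_SEP}{rc.reaction_b}"


def apply_scenario(
    model: MultiTissueModel,
    spec: ScenarioSpec,
    check_feasible: bool = True,
) -> MultiTissueModel:
    """Return a copy of ``model`` with scenario constraints materialized.

    Biomass reactions get LB = UB = fixed value; exchange bounds are set;
    each ratio constraint v_a = r * v_b becomes an auxiliary balance row
    (a pseudo-metabolite produced by a with +1 and consumed by b with -r),
    which is exact regardless of flux magnitude.  Re-applying the same
    spec is a no-op (deterministic row ids, bounds overwritten).
    """
    spec.validate()
    out = model.copy()
    rxn_by_id = {r.id: r for r in out.reactions}

    # biomass fixing
    for key, value in spec.biomass.items():
        if isinstance(key, str) and key in rxn_by_id:
            targets = [key]
        elif isinstance(key, str):
            targets = [
                rid for (t, p), rid in out.biomass_ids.items() if t == key
            ]
            if not targets:
                raise ValueError(f"biomass key {key!r} matches no tissue or reaction")
        else:
            tissue, phase = key
            try:
                targets = [out.biomass_ids[(tissue, phase)]]
            except KeyError:
                raise ValueError(f"no biomass reaction for tissue/phase {key!r}")
        for rid in targets:
            rxn_by_id[rid].lower_bound = value
            rxn_by_id[rid].upper_bound = value

    bound_sets = [spec.exchanges] + [spec.variants[v] for v in spec.enabled_variants]
    for bounds in bound_sets:
        for rid, (lb, ub) in bounds.items():
            if rid not in rxn_by_id:
                raise ValueError(f"exchange bound names unknown reaction {rid!r}")
            rxn_by_id[rid].lower_bound = float(lb)
            rxn_by_id[rid].upper_bound = float(ub)

    existing_mets = {m.id for m in out.metabolites}
    for rc in spec.ratios:
        for rid in (rc.reaction_a, rc.reaction_b):
            if rid not in rxn_by_id:
                raise ValueError(f"ratio constraint names unknown reaction {rid!r}")
        pm = _ratio_metabolite_id(rc)
        if pm not in existing_mets:
            out.metabolites.append(Metabolite(pm, compartment=RATIO_COMPARTMENT))
            existing_mets.add(pm)
        rxn_by_id[rc.reaction_a].stoichiometry[pm] = 1.0
        rxn_by_id[rc.reaction_b].stoichiometry[pm] = -rc.ratio

    if check_feasible:
        from .optimization import assert_feasible, InfeasibleError

        try:
            assert_feasible(out)
        except InfeasibleError as exc:
            fixed = sorted(
                rid for rid, r in rxn_by_id.items() if r.lower_bound == r.upper_bound != 0
            )
            raise InfeasibleScenarioError(
                f"scenario makes the model infeasible: {exc}", binding=fixed
            ) from exc
    return out


# ---------------------------------------------------------------------------
# config files


def load_config(path) -> dict:
    """Load a YAML build/scenario config.

    Recognized keys: ``tissues``, ``phases``, ``linkers`` (list of linker
    mappings), ``biomass_reaction``, ``biomass`` (mapping tissue or
    "tissue/phase" to value), ``ratios`` (list of {a, b, ratio}),
    ``exchanges`` (mapping rid to [lb, ub]), ``variants`` and
    ``enabled_variants``, ``shareable``.
    Returns a dict with parsed ``link_specs`` and ``scenario`` objects.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    link_specs = [
        LinkSpec(
            metabolite=entry["metabolite"],
            from_tissue=entry["from_tissue"],
            from_phase=entry["from_phase"],
            to_tissue=entry["to_tissue"],
            to_phase=entry["to_phase"],
            reversible=bool(entry.get("reversible", False)),
            id=entry.get("id"),
            home_tissue=entry.get("home_tissue", "__from__"),
        )
        for entry in raw.get("linkers", [])
    ]
    biomass: Dict[object, float] = {}
    for key, value in (raw.get("biomass") or {}).items():
        if isinstance(key, str) and "/" in key:
            tissue, phase = key.split("/", 1)
            biomass[(tissue, phase)] = float(value)
        else:
            biomass[key] = float(value)
    scenario = ScenarioSpec(
        biomass=biomass,
        exchanges={
            rid: (float(b[0]), float(b[1])) for rid, b in (raw.get("exchanges") or {}).items()
        },
        ratios=[
            RatioConstraint(entry["a"], entry["b"], float(entry["ratio"]))
            for entry in raw.get("ratios", [])
        ],
        variants={
            name: {rid: (float(b[0]), float(b[1])) for rid, b in overlay.items()}
            for name, overlay in (raw.get("variants") or {}).items()
        },
        enabled_variants=list(raw.get("enabled_variants", [])),
    )
    return {
        "tissues": raw.get("tissues", []),
        "phases": raw.get("phases", []),
        "link_specs": link_specs,
        "biomass_reaction": raw.get("biomass_reaction"),
        "shareable": raw.get("shareable"),
        "scenario": scenario,
        "raw": raw,
    }


def dump_config(config: Mapping, path) -> None:
    """Write a build/scenario config dict (inverse of :func:`load_config`)."""
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=False)
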