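"""Per-reaction penalty weights from inter-tissue relative expression.

The weight of gene *i* in tissue *t* is the fold-difference between the
gene's most-expressing tissue and tissue *t*::

    W_it = max(E_i) / E_it        (>= 1; == 1 in the peak tissue)

so only *relative* abundances across tissues matter — TPM-like transcript
values and IBAQ-like protein intensities are equally usable.  Gene weights
are folded through the reaction's GPR tree: isozymes (OR) contribute the
arithmetic mean of their weights, complex subunits (AND) the maximum
("worst") weight.  A single scaling factor SF >= 0 then interpolates
between plain pFBA and full expression weighting::

    c_R = SF * (w_R - 1) + 1      (c_R = 1 for every R when SF = 0)

Reactions with no GPR (transporters, linkers, biomass, exchanges) get
either c = 1 (``unit`` policy) or the SF-scaled median base weight of the
GPR-weighted reactions in their home tissue (``tissue_median`` policy);
whole-plant reactions always get 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .core_model import MultiTissueModel
from .gpr import GprLeaf, GprOp, GprTree, parse_gpr

__all__ = [
    "ExpressionTable",
    "ZeroPolicy",
    "WeightVector",
    "ConfigError",
    "gene_weight",
    "combine_gpr_weights",
    "apply_scaling",
    "build_weight_vector",
    "randomize_weights",
    "swap_tissue_expression",
]

GPRLESS_POLICIES = ("unit", "tissue_median")


class ConfigError(ValueError):
    pass


@dataclass
class ZeroPolicy:
    """How to weight a tissue with zero abundance for an expressed gene.

    Eq. W_it = max/E_it diverges at E_it = 0; the weight is capped at
    ``w_max`` instead, keeping "strongly penalized, never forbidden"
    semantics.  Genes with all-zero rows carry no relative evidence and
    are treated as absent.
    """

    w_max: float = 1000.0


@dataclass
class ExpressionTable:
    """Gene x tissue nonnegative abundance matrix (relative units)."""

    data: pd.DataFrame  # index: gene ids, columns: tissue labels

    def __post_init__(self):
        if self.data.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression table")
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate tissue labels in expression table")
        if (self.data.values < 0).any():
            raise ValueError("expression table contains negative abundances")

    @property
    def genes(self):
        return list(self.data.index)

    @property
    def tissues(self):
        return list(self.data.columns)

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(float))

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def gene_weight(
    expr_row: Mapping[str, float],
    tissue: str,
    zero_policy: ZeroPolicy = ZeroPolicy(),
) -> Optional[float]:
    """W_it = max(E_i) / E_it, or ``None`` if the gene is absent (all zero)."""
    if tissue not in expr_row:
        raise KeyError(f"tissue {tissue!r} not in expression row")
    values = np.asarray([expr_row[t] for t in expr_row], dtype=float)
    if (values < 0).any():
        raise ValueError("negative abundance")
    peak = values.max()
    if peak <= 0:
        return None
    e_it = float(expr_row[tissue])
    if e_it <= 0:
        return zero_policy.w_max
    return min(peak / e_it, zero_policy.w_max)


def combine_gpr_weights(
    tree: GprTree, weights: Mapping[str, Optional[float]]
) -> Optional[float]:
    """Fold gene weights through a GPR tree: OR -> mean, AND -> max.

    Genes absent from ``weights`` or mapped to ``None`` are dropped from
    their parent's argument list; a node whose children are all absent is
    itself absent.  Returns ``None`` when the whole tree carries no
    evidence (caller falls back to the GPR-less policy).
    """
    if isinstance(tree, GprLeaf):
        return weights.get(tree.gene)
    vals = [combine_gpr_weights(child, weights) for child in tree.children]
    vals = [v for v in vals if v is not None]
    if not vals:
        return None
    if tree.op == "or":
        return float(np.mean(vals))
    return float(max(vals))


def apply_scaling(w: float, sf: float) -> float:
    """c = SF * (w - 1) + 1; affine in SF with intercept 1 (pFBA at SF=0)."""
    if sf < 0:
        raise ValueError("scaling factor must be >= 0")
    return sf * (w - 1.0) + 1.0


@dataclass
class WeightVector:
    """Per-reaction penalty coefficients c_j plus provenance metadata."""

    coefficients: Dict[str, float]
    base_weights: Dict[str, float]
    sf: float
    gprless_policy: str
    zero_policy: ZeroPolicy = field(default_factory=ZeroPolicy)
    flags: Dict[str, str] = field(default_factory=dict)

    def to_frame(self, model: Optional[MultiTissueModel] = None) -> pd.DataFrame:
        rows = []
        for rid in self.coefficients:
            tissue = phase = ""
            if model is not None:
                if rid in model.provenance:
                    _, tissue, phase = model.provenance[rid]
                else:
                    tissue = model.linker_home.get(rid) or ""
            rows.append(
                {
                    "reaction_id": rid,
                    "tissue": tissue,
                    "phase": phase,
                    "base_weight": self.base_weights.get(rid, 1.0),
                    "c_j": self.coefficients[rid],
                    "policy_flag": self.flags.get(rid, ""),
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path, model: Optional[MultiTissueModel] = None) -> None:
        self.to_frame(model).to_csv(path, sep="\t", index=False)


def build_weight_vector(
    model: MultiTissueModel,
    expr: ExpressionTable,
    sf: float = 1.0,
    gprless_policy: str = "unit",
    zero_policy: ZeroPolicy = ZeroPolicy(),
) -> WeightVector:
    """Compute c_j for every reaction of a multi-tissue model.

    Expression datasets are tissue atlases without diel resolution, so the
    same tissue weight is applied to the day and the night replica of a
    reaction.  Reactions with an empty GPR, or whose genes are all absent
    from the dataset, follow ``gprless_policy``; whole-plant reactions
    (no home tissue) always get 1.
    """
    if gprless_policy not in GPRLESS_POLICIES:
        raise ConfigError(f"unknown GPR-less policy {gprless_policy!r}")
    if sf < 0:
        raise ConfigError("scaling factor must be >= 0")
    table_tissues = set(expr.tissues)
    missing = [t for t in model.tissues if t not in table_tissues]
    if missing:
        raise ConfigError(f"expression table lacks model tissues {missing}")

    # per-gene per-tissue weights, computed once
    gene_w: Dict[str, Dict[str, Optional[float]]] = {}
    for gene in expr.genes:
        row = expr.data.loc[gene]
        row_map = row.to_dict()
        gene_w[gene] = {t: gene_weight(row_map, t, zero_policy) for t in model.tissues}

    base: Dict[str, float] = {}
    flags: Dict[str, str] = {}
    pending_gprless: Dict[str, Optional[str]] = {}  # rid -> home tissue (None = whole plant)
    tissue_bases: Dict[str, list] = {t: [] for t in model.tissues}

    gpr_cache: Dict[str, object] = {}
    for rxn in model.reactions:
        tissue = model.tissue_of(rxn.id)
        gpr = rxn.gpr
        tree = None
        if gpr:
            if gpr not in gpr_cache:
                gpr_cache[gpr] = parse_gpr(gpr)
            tree = gpr_cache[gpr]
        if tree is None or tissue is None:
            pending_gprless[rxn.id] = tissue
            continue
        weights_t = {g: w[tissue] for g, w in gene_w.items()}
        w = combine_gpr_weights(tree, weights_t)
        if w is None:
            pending_gprless[rxn.id] = tissue
            flags[rxn.id] = "no_evidence"
            continue
        base[rxn.id] = w
        flags[rxn.id] = "gpr"
        tissue_bases[tissue].append(w)

    medians = {
        t: (float(np.median(vals)) if vals else 1.0) for t, vals in tissue_bases.items()
    }
    for rid, tissue in pending_gprless.items():
        if tissue is None:
            base[rid] = 1.0
            flags[rid] = "whole_plant"
        elif gprless_policy == "tissue_median":
            base[rid] = medians[tissue]
            flags[rid] = flags.get(rid, "") and flags[rid] + "+median" or "gprless_median"
        else:
            base[rid] = 1.0
            flags[rid] = flags.get(rid, "") and flags[rid] + "+unit" or "gprless_unit"

    coefficients = {rid: apply_scaling(w, sf) for rid, w in base.items()}
    return WeightVector(
        coefficients=coefficients,
        base_weights=base,
        sf=sf,
        gprless_policy=gprless_policy,
        zero_policy=zero_policy,
        flags=flags,
    )


def randomize_weights(wv: WeightVector, seed: int) -> WeightVector:
    """Uniform random permutation of the c_j values over reaction ids.

    The multiset of coefficients is preserved exactly (a negative-control
    transformation: same weight distribution, no tissue signal).
    """
    rng = np.random.default_rng(seed)
    rids = sorted(wv.coefficients)
    perm = rng.permutation(len(rids))
    coeffs = {rids[i]: wv.coefficients[rids[perm[i]]] for i in range(len(rids))}
    bases = {rids[i]: wv.base_weights.get(rids[perm[i]], 1.0) for i in range(len(rids))}
    return WeightVector(
        coefficients=coeffs,
        base_weights=bases,
        sf=wv.sf,
        gprless_policy=wv.gprless_policy,
        zero_policy=wv.zero_policy,
        flags={rid: "permuted" for rid in rids},
    )


def swap_tissue_expression(expr: ExpressionTable, a: str, b: str) -> ExpressionTable:
    """Exchange the abundance columns of tissues ``a`` and ``b``.

    A negative control: a gene peaking in ``a`` afterwards peaks in ``b``,
    so its weight-1 tissue moves with the swap.
    """
    for t in (a, b):
        if t not in expr.data.columns:
            raise KeyError(f"unknown tissue {t!r}")
    df = expr.data.copy()
    df[a], df[b] = expr.data[b].copy(), expr.data[a].copy()
    return ExpressionTable(df)
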