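"""Methylation-expression integration.

Joins DMR-gene links with differential expression to identify
"co-different" genes: genes that are simultaneously differentially expressed
(fold change > 2 or < 0.5 at FDR < 0.05, myogenic relative to adipogenic)
and linked to at least one DMR. Each such gene receives a quadrant label
combining its expression direction with the methylation direction of its
linked DMRs (hyper-up, hypo-up, hyper-down, hypo-down).

Also provides the per-category fold-change comparison between hyper- and
hypo-linked genes, the transcription-factor subset tables, a generic
hypergeometric over-representation analysis against user-supplied gene sets,
and the 2^-ddCt relative-expression utility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import bh_adjust
from .errors import ConfigError

__all__ = [
    "deg_table",
    "call_degs",
    "co_different",
    "fold_change_by_category",
    "tf_subset",
    "ora_enrichment",
    "ddct",
]

logger = logging.getLogger(__name__)


def deg_table(
    expression: pd.DataFrame,
    groups: tuple[str, str] = ("adipogenic", "myogenic"),
) -> pd.DataFrame:
    """Fold change and FDR per gene from replicate expression values.

    Fold change is the ratio of group means (case over reference); the FDR
    comes from a two-sided Welch t-test on log2-transformed values followed
    by Benjamini-Hochberg adjustment. Tables that already carry ``fc`` and
    ``fdr`` columns are passed through (precomputed-statistics dialect).
    """
    if {"fc", "fdr"}.issubset(expression.columns):
        out = expression[["gene_id", "fc", "fdr"]].copy()
        missing = out["fdr"].isna()
        if missing.any():
            logger.info("excluding %d genes without FDR", int(missing.sum()))
            out = out[~missing]
        return out.reset_index(drop=True)
    ref, case = groups
    ref_cols = [c for c in expression.columns if c.startswith(f"{ref}_")]
    case_cols = [c for c in expression.columns if c.startswith(f"{case}_")]
    if len(ref_cols) < 2 or len(case_cols) < 2:
        raise ConfigError("need >= 2 replicates per group (or fc/fdr columns)")
    a = expression[ref_cols].to_numpy(dtype=float)
    b = expression[case_cols].to_numpy(dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ConfigError("expression values must be non-negative")
    fc = b.mean(axis=1) / a.mean(axis=1)
    la, lb = np.log2(np.maximum(a, 1e-12)), np.log2(np.maximum(b, 1e-12))
    t, p = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    return pd.DataFrame({
        "gene_id": expression["gene_id"],
        "fc": fc,
        "fdr": bh_adjust(np.nan_to_num(p, nan=1.0)),
    })


def call_degs(
    expression: pd.DataFrame,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    fdr_max: float = 0.05,
    groups: tuple[str, str] = ("adipogenic", "myogenic"),
) -> pd.DataFrame:
    """Differentially expressed genes: FDR < fdr_max and FC > fc_up (up) or
    FC < fc_down (down), strict inequalities. Returns gene_id, fc, fdr and
    direction ("up"/"down", case group relative to reference)."""
    table = deg_table(expression, groups=groups)
    sig = table["fdr"] < fdr_max
    up = sig & (table["fc"] > fc_up)
    down = sig & (table["fc"] < fc_down)
    out = table[up | down].copy()
    out["direction"] = np.where(out["fc"] > fc_up, "up", "down")
    return out.reset_index(drop=True)


@dataclass
class CoDifferentResult:
    """Gene-level co-different table plus DMR-level quadrant counts."""

    genes: pd.DataFrame        # gene_id, expr_direction, meth_direction, quadrant, ...
    quadrant_counts: dict      # gene-level quadrant tally
    dmr_quadrant_counts: dict  # DMR-link-level tally (a gene's every link counts)


def co_different(degs: pd.DataFrame, dmr_links: pd.DataFrame) -> CoDifferentResult:
    """Intersect DEGs with DMR-linked genes.

    ``dmr_links`` needs one row per DMR with columns gene_id, direction
    (hyper/hypo) and delta (and optionally category). A gene linked to DMRs
    of both directions takes the direction of its largest-|delta| DMR for
    the gene-level quadrant; every link is retained in the DMR-level tally.
    """
    linked = dmr_links.dropna(subset=["gene_id"])
    deg_dirs = dict(zip(degs["gene_id"], degs["direction"]))
    rows = []
    dmr_quad: dict[str, int] = {q: 0 for q in
                                ("hyper-up", "hypo-up", "hyper-down", "hypo-down")}
    for gene_id, sub in linked.groupby("gene_id", sort=True):
        if gene_id not in deg_dirs:
            continue
        expr_dir = deg_dirs[gene_id]
        for d in sub["direction"]:
            dmr_quad[f"{d}-{expr_dir}"] += 1
        top = sub.loc[sub["delta"].abs().idxmax()]
        meth_dir = top["direction"]
        rows.append({
            "gene_id": gene_id,
            "expr_direction": expr_dir,
            "meth_direction": meth_dir,
            "quadrant": f"{meth_dir}-{expr_dir}",
            "n_linked_dmrs": len(sub),
            "categories": ",".join(sorted(set(sub["category"])))
            if "category" in sub else "",
        })
    genes = pd.DataFrame(
        rows, columns=["gene_id", "expr_direction", "meth_direction",
                       "quadrant", "n_linked_dmrs", "categories"],
    )
    quad = {q: 0 for q in ("hyper-up", "hypo-up", "hyper-down", "hypo-down")}
    for q in genes["quadrant"]:
        quad[q] += 1
    return CoDifferentResult(genes=genes, quadrant_counts=quad,
                             dmr_quadrant_counts=dmr_quad)


def fold_change_by_category(
    dmr_links: pd.DataFrame,
    expression: pd.DataFrame,
    categories: list[str] | None = None,
    min_genes: int = 3,
    groups: tuple[str, str] = ("adipogenic", "myogenic"),
) -> pd.DataFrame:
    """Compare expression fold changes of hyper- vs hypo-linked genes per
    feature category.

    For each category, genes linked to hyper-methylated DMRs form one arm and
    genes linked to hypo-methylated DMRs the other; arms are compared on
    log2 fold change with a two-sided Mann-Whitney rank-sum test (exact for
    small samples). Categories with fewer than ``min_genes`` genes in either
    arm are flagged not testable.
    """
    table = deg_table(expression, groups=groups)
    log2fc = dict(zip(table["gene_id"], np.log2(table["fc"])))
    links = dmr_links.dropna(subset=["gene_id"])
    if "category" not in links.columns:
        raise ConfigError("dmr_links must carry a 'category' column")
    cats = categories or sorted(links["category"].unique())
    rows = []
    for cat in cats:
        sub = links[links["category"] == cat]
        arms = {}
        for direction in ("hyper", "hypo"):
            genes = set(sub.loc[sub["direction"] == direction, "gene_id"])
            arms[direction] = np.array(
                [log2fc[g] for g in sorted(genes) if g in log2fc])
        testable = all(len(v) >= min_genes for v in arms.values())
        if testable:
            res = stats.mannwhitneyu(
                arms["hypo"], arms["hyper"], alternative="two-sided",
                method="exact" if max(map(len, arms.values())) <= 25 else "auto",
            )
            p = float(res.pvalue)
        else:
            p = np.nan
        rows.append({
            "category": cat,
            "n_hyper": len(arms["hyper"]),
            "n_hypo": len(arms["hypo"]),
            "median_log2fc_hyper": float(np.median(arms["hyper"]))
            if len(arms["hyper"]) else np.nan,
            "median_log2fc_hypo": float(np.median(arms["hypo"]))
            if len(arms["hypo"]) else np.nan,
            "p_value": p,
            "testable": testable,
            "significant": bool(testable and p < 0.05),
        })
    return pd.DataFrame(rows)


def tf_subset(
    expression: pd.DataFrame,
    tf_names: list[str],
    degs: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transcription-factor tables: expressed TFs (TF list intersected with
    detected genes) and differentially expressed TFs partitioned by
    direction."""
    if not tf_names:
        logger.warning("empty TF list; returning empty tables")
    tfs = set(tf_names)
    expressed = expression[expression["gene_id"].isin(tfs)].reset_index(drop=True)
    de_tfs = degs[degs["gene_id"].isin(tfs)].reset_index(drop=True)
    return expressed, de_tfs


def ora_enrichment(
    query: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    universe: set[str] | list[str],
    p_max: float = 0.05,
    use_q: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation analysis against gene sets.

    For each pathway with members in the universe, the one-sided upper-tail
    probability P(X >= overlap) of drawing the observed overlap when
    sampling |query| genes from the universe is computed, then BH-adjusted
    across pathways. ``significant`` thresholds p (or q with ``use_q``)
    at ``p_max``.
    """
    query = set(query)
    universe = set(universe)
    strays = sorted(query - universe)
    if strays:
        raise ValueError(f"query genes missing from universe: {strays}")
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe
        if not in_universe:
            logger.info("gene set %s has no universe members; skipped", name)
            continue
        overlap = len(query & in_universe)
        # P(X >= overlap), X ~ Hypergeom(M=|U|, n=|set|, N=|query|)
        p = float(stats.hypergeom.sf(
            overlap - 1, len(universe), len(in_universe), len(query)))
        rows.append({"gene_set": name, "set_size": len(in_universe),
                     "overlap": overlap, "p_value": p})
    out = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p_value"])
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        crit = out["q_value"] if use_q else out["p_value"]
        out["significant"] = crit < p_max
    else:
        out["q_value"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) in the case condition minus the same
    difference in the control condition; the result is 2**(-ddCt).
    """
    ddct_value = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct_value))
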