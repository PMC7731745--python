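"""Per-CpG count handling: report I/O, strand collapse, filters, size factors.

The count container collapses the two strands of each CpG dyad into a single
record (both strands report the same methylation unit) and keys sites by the
0-based forward-strand position of the dyad's C.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd

from .errors import EstimationError, ReportParseError
from .simulate import NonCpGControls

__all__ = [
    "CpGCountMatrix",
    "PIG_AUTOSOMES",
    "read_cpg_report",
    "read_noncpg_controls",
    "write_cpg_report",
    "merge_samples",
    "estimate_conversion_rate",
    "filter_sites",
    "size_factors",
    "methylation_level",
]

#: default autosome set (pig assembly naming); override for other genomes
PIG_AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 19))

_CPG_CONTEXTS = {"CpG", "CG"}


@dataclass
class CpGCountMatrix:
    """Methylated/total read counts at strand-collapsed CpG dyads.

    ``sites`` has columns (chrom, pos) with pos the 0-based dyad position;
    ``samples`` has columns (name, animal, group); ``meth`` and ``total`` are
    (n_sites, n_samples) integer arrays with 0 <= meth <= total.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth)
        self.total = np.asarray(self.total)
        if self.meth.shape != self.total.shape:
            raise ValueError("meth and total shapes differ")
        if self.meth.shape != (len(self.sites), len(self.samples)):
            raise ValueError("count arrays do not match sites x samples")
        if self.meth.size and ((self.meth < 0).any() or (self.meth > self.total).any()):
            raise ValueError("counts must satisfy 0 <= meth <= total")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def levels(self) -> np.ndarray:
        """Per-site per-sample methylation level meth/total (NaN where total=0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / np.maximum(self.total, 1), np.nan)

    def subset(self, mask: np.ndarray) -> "CpGCountMatrix":
        return CpGCountMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            samples=self.samples.copy(),
            meth=self.meth[mask],
            total=self.total[mask],
        )

    def group_columns(self, group: str) -> np.ndarray:
        return np.flatnonzero((self.samples["group"] == group).to_numpy())


def _parse_report_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str,
            names=["chrom", "pos", "strand", "meth", "unmeth", "context"],
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "meth", "unmeth", "context"]
        )
    for col in ("pos", "meth", "unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.astype("Int64").astype(float))
        if bad.any():
            line = int(df.index[bad][0]) + 1
            raise ReportParseError(f"{path}:{line}: non-integer value in column {col}")
        df[col] = vals.astype(np.int64)
    if ((df["meth"] < 0) | (df["unmeth"] < 0)).any():
        line = int(df.index[(df["meth"] < 0) | (df["unmeth"] < 0)][0]) + 1
        raise ReportParseError(f"{path}:{line}: negative count")
    if (df["pos"] < 1).any():
        line = int(df.index[df["pos"] < 1][0]) + 1
        raise ReportParseError(f"{path}:{line}: position must be >= 1 (1-based)")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = int(df.index[bad_strand][0]) + 1
        raise ReportParseError(
            f"{path}:{line}: unknown strand {df['strand'][bad_strand].iloc[0]!r}"
        )
    return df


def read_cpg_report(
    path: str | Path,
    sample: str | None = None,
    animal: int | str | None = None,
    group: str | None = None,
    collapse_strands: bool = True,
) -> CpGCountMatrix:
    """Read a Bismark-style cytosine report into a one-sample count matrix.

    Expected TSV columns (no header): chrom, 1-based position, strand (+/-),
    methylated count, unmethylated count, context. Only CpG-context rows are
    used. With ``collapse_strands`` (default), the minus-strand record at
    position p+1 is merged with the plus-strand record at p into one dyad
    keyed by 0-based position p-1; totals are summed. Dialects that are
    already destranded can pass ``collapse_strands=False`` (positions are
    then only shifted to 0-based).
    """
    df = _parse_report_frame(path)
    df = df[df["context"].isin(_CPG_CONTEXTS)]
    name = sample if sample is not None else Path(path).stem
    samples = pd.DataFrame(
        [{"name": name, "animal": animal, "group": group}]
    )
    if df.empty:
        return CpGCountMatrix(
            sites=pd.DataFrame({"chrom": pd.Series(dtype=str),
                                "pos": pd.Series(dtype=np.int64)}),
            samples=samples,
            meth=np.zeros((0, 1), dtype=np.int64),
            total=np.zeros((0, 1), dtype=np.int64),
        )
    pos0 = df["pos"].to_numpy() - 1
    if collapse_strands:
        pos0 = np.where(df["strand"].to_numpy() == "-", pos0 - 1, pos0)
    agg = (
        pd.DataFrame({
            "chrom": df["chrom"].to_numpy(),
            "pos": pos0,
            "meth": df["meth"].to_numpy(),
            "total": (df["meth"] + df["unmeth"]).to_numpy(),
        })
        .groupby(["chrom", "pos"], as_index=False, sort=True)
        .sum()
    )
    return CpGCountMatrix(
        sites=agg[["chrom", "pos"]].reset_index(drop=True),
        samples=samples,
        meth=agg[["meth"]].to_numpy(),
        total=agg[["total"]].to_numpy(),
    )


def read_noncpg_controls(path: str | Path, sample: str | None = None) -> NonCpGControls:
    """Read the non-CpG-context rows of a cytosine report for conversion QC."""
    df = _parse_report_frame(path)
    df = df[~df["context"].isin(_CPG_CONTEXTS)]
    name = sample if sample is not None else Path(path).stem
    return NonCpGControls(
        sites=df[["chrom", "pos"]].reset_index(drop=True),
        samples=[name],
        meth=df[["meth"]].to_numpy(dtype=np.int64),
        total=(df["meth"] + df["unmeth"]).to_numpy(dtype=np.int64).reshape(-1, 1),
    )


def write_cpg_report(
    matrix: CpGCountMatrix,
    path: str | Path,
    sample: str,
    controls: NonCpGControls | None = None,
) -> None:
    """Write one sample of a count matrix as a cytosine-report TSV.

    Dyad counts are split across the two strands (plus-strand row at the C,
    minus-strand row at the G) so that re-reading with strand collapse
    reproduces the dyad counts exactly.
    """
    j = list(matrix.samples["name"]).index(sample)
    meth = matrix.meth[:, j]
    unmeth = matrix.total[:, j] - meth
    pos1 = matrix.sites["pos"].to_numpy() + 1  # 1-based C of the dyad
    mp, up = meth // 2, unmeth // 2
    rows = pd.concat([
        pd.DataFrame({
            "chrom": matrix.sites["chrom"], "pos": pos1, "strand": "+",
            "meth": meth - mp, "unmeth": unmeth - up, "context": "CpG",
        }),
        pd.DataFrame({
            "chrom": matrix.sites["chrom"], "pos": pos1 + 1, "strand": "-",
            "meth": mp, "unmeth": up, "context": "CpG",
        }),
    ])
    if controls is not None and len(controls.sites):
        k = controls.samples.index(sample)
        rows = pd.concat([rows, pd.DataFrame({
            "chrom": controls.sites["chrom"],
            "pos": controls.sites["pos"].to_numpy() + 1,
            "strand": "+",
            "meth": controls.meth[:, k],
            "unmeth": controls.total[:, k] - controls.meth[:, k],
            "context": "CHH",
        })])
    rows = rows.sort_values(["chrom", "pos"], kind="stable")
    rows.to_csv(path, sep="\t", header=False, index=False)


def merge_samples(matrices: Sequence[CpGCountMatrix]) -> CpGCountMatrix:
    """Outer-join one-sample matrices on sites (missing counts become 0)."""
    if not matrices:
        raise ValueError("no matrices to merge")
    frames = []
    for i, m in enumerate(matrices):
        f = m.sites.copy()
        f[f"meth_{i}"] = m.meth[:, 0]
        f[f"total_{i}"] = m.total[:, 0]
        frames.append(f.set_index(["chrom", "pos"]))
    joined = pd.concat(frames, axis=1).fillna(0).sort_index()
    sites = joined.index.to_frame(index=False)
    meth = joined[[f"meth_{i}" for i in range(len(matrices))]].to_numpy(np.int64)
    total = joined[[f"total_{i}" for i in range(len(matrices))]].to_numpy(np.int64)
    samples = pd.concat([m.samples for m in matrices], ignore_index=True)
    return CpGCountMatrix(sites=sites, samples=samples, meth=meth, total=total)


def estimate_conversion_rate(controls: NonCpGControls) -> pd.Series:
    """Bisulfite conversion rate from non-CpG cytosines.

    Non-CpG cytosines are (assumed) unmethylated, so reads that survived
    conversion appear unmethylated; the rate is unmethylated/total. Returns
    one value per sample plus a read-pooled ``pooled`` entry; samples with
    zero total are reported as NaN.
    """
    meth_sum = controls.meth.sum(axis=0).astype(float)
    tot_sum = controls.total.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_sample = np.where(tot_sum > 0, 1.0 - meth_sum / np.maximum(tot_sum, 1), np.nan)
    pooled = (
        1.0 - meth_sum.sum() / tot_sum.sum() if tot_sum.sum() > 0 else np.nan
    )
    return pd.Series(
        np.append(per_sample, pooled), index=[*controls.samples, "pooled"]
    )


def filter_sites(
    matrix: CpGCountMatrix,
    min_depth: int = 10,
    autosomes: Iterable[str] = PIG_AUTOSOMES,
) -> CpGCountMatrix:
    """Keep autosomal CpGs with depth strictly greater than ``min_depth`` in
    every sample (the common-to-all-samples depth filter). Site order is
    preserved; chromosomes outside the autosome set are excluded with a
    warning when present."""
    autosomes = set(autosomes)
    if matrix.n_sites == 0:
        return matrix.subset(np.zeros(0, dtype=bool))
    chroms = matrix.sites["chrom"].to_numpy()
    on_autosome = np.isin(chroms, list(autosomes))
    dropped = set(np.unique(chroms[~on_autosome]))
    if dropped:
        warnings.warn(
            f"excluding non-autosome chromosomes: {sorted(dropped)}", stacklevel=2
        )
    deep = (matrix.total > min_depth).all(axis=1)
    return matrix.subset(on_autosome & deep)


def size_factors(matrix: CpGCountMatrix) -> pd.Series:
    """Median-of-ratios size factors on per-site total counts.

    Per site, each sample's total is divided by the geometric mean of the
    site's totals across samples; a sample's factor is the median of its
    ratios over sites with all-positive totals.
    """
    totals = matrix.total.astype(float)
    positive = (totals > 0).all(axis=1)
    if not positive.any():
        raise EstimationError("no site has positive totals in every sample")
    t = totals[positive]
    log_geo = np.log(t).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(t) - log_geo)
    return pd.Series(np.median(ratios, axis=0), index=list(matrix.samples["name"]))


def methylation_level(meth: float, total: float) -> float:
    """Coverage-ratio methylation level meth/total; NaN when total is 0."""
    if total == 0:
        return float("nan")
    return meth / total
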