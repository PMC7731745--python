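"""Windowed paired differential-methylation testing.

The genome is tiled into fixed-width windows; each window's per-sample
methylation level is the pooled coverage ratio (sum of methylated reads over
sum of total reads across the window's CpGs). A two-sided paired t-test on
per-animal differences (each animal contributes one pair: its two cell
types) is run per window, p-values are Benjamini-Hochberg adjusted in one
genome-wide family, and a window is called a DMR when the group mean
difference is at least ``delta_min`` (absolute methylation fraction, default
3 percentage points) and q < ``q_max`` (default 0.05). Direction is "hyper"
when the case group (myogenic by convention) is more methylated.

An alternative test mode operating on size-factor-normalized methylated read
counts is provided (``mode="normalized_counts"``); the level mode is the
default because an absolute percentage difference is only well defined on
methylation levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from statsmodels.stats.multitest import multipletests

from .core import CpGCountMatrix
from .errors import ConfigError

__all__ = [
    "WindowSpec",
    "MethylWindowTable",
    "DMRSet",
    "tile_windows",
    "paired_t_test",
    "test_windows",
    "bh_adjust",
    "call_dmrs",
    "merge_adjacent_dmrs",
    "cluster_samples",
    "metagene_profile",
    "cgi_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class WindowSpec:
    """Window geometry: width (bp), step (default non-overlapping), and the
    minimum number of covered CpGs a window must hold to be tested."""

    width: int = 100
    step: int | None = None
    min_cpgs: int = 3

    def __post_init__(self) -> None:
        if self.step is None:
            self.step = self.width
        if self.width < 1:
            raise ConfigError("width must be >= 1")
        if not 1 <= self.step <= self.width:
            raise ConfigError("step must satisfy 1 <= step <= width")
        if self.width % self.step != 0:
            raise ConfigError("width must be a multiple of step")
        if self.min_cpgs < 1:
            raise ConfigError("min_cpgs must be >= 1")


@dataclass
class MethylWindowTable:
    """Tiled windows with per-sample pooled counts and levels."""

    windows: pd.DataFrame  # chrom, start, end, n_cpgs
    samples: pd.DataFrame  # name, animal, group
    meth: np.ndarray       # (n_windows, n_samples) pooled methylated counts
    total: np.ndarray      # pooled total counts

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def levels(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.meth / np.maximum(self.total, 1), np.nan)


def tile_windows(matrix: CpGCountMatrix, spec: WindowSpec | None = None
                 ) -> MethylWindowTable:
    """Pool the filtered count matrix into fixed-width genomic windows.

    Windows are tiled per chromosome from position 0; windows holding fewer
    than ``spec.min_cpgs`` covered CpGs are discarded. With ``step < width``
    the tiling is repeated on each shifted grid, so windows overlap.
    """
    spec = spec or WindowSpec()
    pieces = []
    pos = matrix.sites["pos"].to_numpy()
    chroms = matrix.sites["chrom"].to_numpy()
    for offset in range(0, spec.width, spec.step):
        widx = (pos - offset) // spec.width
        valid = pos >= offset
        key = pd.DataFrame({"chrom": chroms[valid], "widx": widx[valid]})
        grouped = key.groupby(["chrom", "widx"], sort=True)
        n_cpgs = grouped.size()
        sums_m = pd.DataFrame(matrix.meth[valid]).groupby(
            [key["chrom"].to_numpy(), key["widx"].to_numpy()]).sum()
        sums_t = pd.DataFrame(matrix.total[valid]).groupby(
            [key["chrom"].to_numpy(), key["widx"].to_numpy()]).sum()
        win = n_cpgs.rename("n_cpgs").to_frame().reset_index()
        win["start"] = win["widx"] * spec.width + offset
        win["end"] = win["start"] + spec.width
        keep = win["n_cpgs"].to_numpy() >= spec.min_cpgs
        pieces.append((
            win.loc[keep, ["chrom", "start", "end", "n_cpgs"]],
            sums_m.to_numpy()[keep],
            sums_t.to_numpy()[keep],
        ))
    windows = pd.concat([p[0] for p in pieces], ignore_index=True)
    meth = np.concatenate([p[1] for p in pieces]) if pieces else np.zeros((0, matrix.n_samples))
    total = np.concatenate([p[2] for p in pieces]) if pieces else np.zeros((0, matrix.n_samples))
    order = np.lexsort((windows["start"].to_numpy(), windows["chrom"].to_numpy()))
    return MethylWindowTable(
        windows=windows.iloc[order].reset_index(drop=True),
        samples=matrix.samples.copy(),
        meth=meth[order].astype(np.int64),
        total=total[order].astype(np.int64),
    )


def _paired_t_from_diffs(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided paired t on per-animal differences, df = n - 1, with the
    zero-variance conventions: sd=0 & mean!=0 -> p=0; sd=0 & mean=0 -> p=1."""
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n = diffs.shape[1]
    if n < 2:
        raise ConfigError("paired t-test needs at least 2 pairs")
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    # exact ties, not sd == 0: float cancellation never reaches exactly zero
    zero_var = (diffs == diffs[:, :1]).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
        t = np.where(zero_var & (mean != 0), np.sign(mean) * np.inf, t)
    t = np.where(zero_var & (mean == 0), 0.0, t)
    p = np.where(zero_var, np.where(mean == 0, 1.0, 0.0), p)
    return t, p


def paired_t_test(x, y=None) -> tuple[float, float]:
    """Two-sided paired t-test.

    ``paired_t_test(x, y)`` tests paired observations; ``paired_t_test(d)``
    tests precomputed per-pair differences against zero. Returns (t, p) with
    df = n_pairs - 1. Zero-variance differences follow the continuity
    convention: p = 0 for a nonzero mean difference, p = 1 otherwise.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    t, p = _paired_t_from_diffs(d[None, :])
    return float(t[0]), float(p[0])


def _pair_columns(samples: pd.DataFrame, groups: tuple[str, str]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Column indices pairing each animal's reference- and case-group sample."""
    ref, case = groups
    by = {(g, a): i for i, (g, a) in enumerate(zip(samples["group"], samples["animal"]))}
    animals = sorted({a for g, a in by if g == ref} & {a for g, a in by if g == case})
    if len(animals) < 2:
        raise ConfigError("need >= 2 animals with both group members present")
    return (np.array([by[(ref, a)] for a in animals]),
            np.array([by[(case, a)] for a in animals]))


def test_windows(
    table: MethylWindowTable,
    groups: tuple[str, str] = ("adipogenic", "myogenic"),
    mode: str = "level",
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Run the paired t-test on every window and BH-adjust genome-wide.

    ``groups`` is (reference, case); delta and direction are case relative
    to reference. ``mode="level"`` (default) tests pooled methylation levels;
    ``mode="normalized_counts"`` tests methylated counts divided by the
    supplied per-sample size factors.
    """
    ref_cols, case_cols = _pair_columns(table.samples, groups)
    if mode == "level":
        values = table.levels()
    elif mode == "normalized_counts":
        if size_factors is None:
            raise ConfigError("normalized_counts mode requires size_factors")
        sf = np.array([size_factors[n] for n in table.samples["name"]])
        values = table.meth / sf
    else:
        raise ConfigError(f"unknown test mode {mode!r}")
    diffs = values[:, case_cols] - values[:, ref_cols]
    complete = ~np.isnan(diffs).any(axis=1)
    if not complete.all():
        logger.info("excluding %d windows with missing pair members",
                    int((~complete).sum()))
    out = table.windows.copy()
    levels = table.levels()
    out["delta"] = np.nanmean(levels[:, case_cols], axis=1) - \
        np.nanmean(levels[:, ref_cols], axis=1)
    t = np.full(table.n_windows, np.nan)
    p = np.full(table.n_windows, np.nan)
    if complete.any():
        t[complete], p[complete] = _paired_t_from_diffs(diffs[complete])
    out["t_stat"] = t
    out["p_value"] = p
    out = out[complete].reset_index(drop=True)
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, alpha=0.05, method="fdr_bh")[1]


@dataclass
class DMRSet:
    """Called DMRs plus the full tested-window table they came from."""

    records: pd.DataFrame  # called windows: coords, n_cpgs, delta, t, p, q, direction
    tested: pd.DataFrame   # every tested window
    levels: np.ndarray     # per-sample levels at called windows
    samples: pd.DataFrame

    @property
    def n_dmrs(self) -> int:
        return len(self.records)

    def summary(self) -> dict:
        n = self.n_dmrs
        n_hyper = int((self.records["direction"] == "hyper").sum())
        n_hypo = n - n_hyper
        return {
            "n_tested": len(self.tested),
            "n_dmrs": n,
            "n_hyper": n_hyper,
            "n_hypo": n_hypo,
            "pct_hyper": 100.0 * n_hyper / n if n else 0.0,
            "pct_hypo": 100.0 * n_hypo / n if n else 0.0,
        }


def call_dmrs(
    tested: pd.DataFrame,
    table: MethylWindowTable,
    delta_min: float = 0.03,
    q_max: float = 0.05,
) -> DMRSet:
    """Call windows with |delta| >= delta_min and q < q_max as DMRs.

    Direction is "hyper" when delta > 0 (case group more methylated than
    reference), "hypo" otherwise.
    """
    called = (tested["delta"].abs() >= delta_min) & (tested["q_value"] < q_max)
    records = tested[called].reset_index(drop=True)
    records["direction"] = np.where(records["delta"] > 0, "hyper", "hypo")
    # align levels of called windows from the table by coordinates
    key = pd.MultiIndex.from_frame(table.windows[["chrom", "start"]])
    want = pd.MultiIndex.from_frame(records[["chrom", "start"]])
    idx = key.get_indexer(want)
    levels = table.levels()[idx] if len(records) else np.zeros((0, len(table.samples)))
    return DMRSet(records=records, tested=tested, levels=levels,
                  samples=table.samples.copy())


def merge_adjacent_dmrs(dmrset: DMRSet) -> pd.DataFrame:
    """Optional convenience: merge book-ended called windows that share a
    direction into wider regions (off by default in the pipeline)."""
    rec = dmrset.records.sort_values(["chrom", "start"]).reset_index(drop=True)
    merged = []
    for _, row in rec.iterrows():
        if merged and merged[-1]["chrom"] == row["chrom"] \
                and merged[-1]["end"] == row["start"] \
                and merged[-1]["direction"] == row["direction"]:
            merged[-1]["end"] = row["end"]
            merged[-1]["n_windows"] += 1
        else:
            merged.append({"chrom": row["chrom"], "start": row["start"],
                           "end": row["end"], "direction": row["direction"],
                           "n_windows": 1})
    return pd.DataFrame(merged,
                        columns=["chrom", "start", "end", "direction", "n_windows"])


def cluster_samples(levels: np.ndarray, method: str = "average",
                    metric: str = "euclidean") -> np.ndarray:
    """Agglomerative clustering of samples on their DMR methylation levels.

    ``levels`` is (n_dmrs, n_samples); returns the scipy linkage matrix
    (merge order and heights). Requires at least two samples.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.ndim != 2 or levels.shape[1] < 2:
        raise ValueError("need a (n_dmrs, n_samples) matrix with >= 2 samples")
    return linkage(levels.T, method=method, metric=metric)


def _bin_means(positions: np.ndarray, values: np.ndarray, start: int, end: int,
               n_bins: int) -> np.ndarray:
    """Mean of values per equal-width bin over [start, end); NaN where empty."""
    out = np.full((n_bins, values.shape[1]), np.nan)
    if end <= start:
        return out
    sel = (positions >= start) & (positions < end)
    if not sel.any():
        return out
    b = ((positions[sel] - start) * n_bins // (end - start)).astype(int)
    v = values[sel]
    for k in np.unique(b):
        sub = v[b == k]
        cnt = (~np.isnan(sub)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            out[k] = np.where(cnt > 0, np.nansum(sub, axis=0) / np.maximum(cnt, 1),
                              np.nan)
    return out


def _scaled_profile(
    matrix: CpGCountMatrix,
    regions: list[tuple[str, int, int, str]],
    flank: int,
    body_bins: int,
    flank_bins: int,
    what: str,
) -> pd.DataFrame:
    levels = matrix.levels()
    pos_all = matrix.sites["pos"].to_numpy()
    chrom_all = matrix.sites["chrom"].to_numpy()
    n_bins = body_bins + 2 * flank_bins
    acc = np.zeros((n_bins, matrix.n_samples))
    cnt = np.zeros((n_bins, matrix.n_samples))
    used = 0
    for chrom, start, end, strand in regions:
        if end - start < body_bins:
            logger.info("%s %s:%d-%d shorter than body_bins, skipped",
                        what, chrom, start, end)
            continue
        sel = chrom_all == chrom
        if not sel.any():
            continue
        pos, val = pos_all[sel], levels[sel]
        up = _bin_means(pos, val, start - flank, start, flank_bins)
        body = _bin_means(pos, val, start, end, body_bins)
        down = _bin_means(pos, val, end, end + flank, flank_bins)
        prof = np.vstack([up, body, down])
        if strand == "-":
            prof = prof[::-1]
        ok = ~np.isnan(prof)
        acc[ok] += prof[ok]
        cnt[ok] += 1
        used += 1
    if used == 0:
        logger.warning("no covered %s regions; profile is empty", what)
        return pd.DataFrame(columns=["bin", "segment",
                                     *matrix.samples["name"]])
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    segment = (["upstream"] * flank_bins + ["body"] * body_bins
               + ["downstream"] * flank_bins)
    out = pd.DataFrame(mean, columns=list(matrix.samples["name"]))
    out.insert(0, "segment", segment)
    out.insert(0, "bin", np.arange(n_bins) - flank_bins)
    return out


def metagene_profile(
    matrix: CpGCountMatrix,
    gene_models: pd.DataFrame,
    flank: int = 2000,
    body_bins: int = 40,
    flank_bins: int = 20,
) -> pd.DataFrame:
    """Strand-aware mean methylation around genes: fixed-width flank bins and
    a gene body scaled to ``body_bins``, averaged over genes, per sample.
    Bin 0 is the TSS boundary; minus-strand genes are reversed so upstream
    always comes first."""
    regions = [
        (r.chrom, int(r.start), int(r.end), r.strand)
        for r in gene_models.itertuples()
    ]
    return _scaled_profile(matrix, regions, flank, body_bins, flank_bins, "gene")


def cgi_profile(
    matrix: CpGCountMatrix,
    cgis: list[tuple[str, int, int]],
    flank: int = 2000,
    body_bins: int = 20,
    flank_bins: int = 20,
) -> pd.DataFrame:
    """Mean methylation across CpG islands scaled to ``body_bins``, with the
    2-kb shores as flanks; the curve's shape is entirely data-dependent."""
    regions = [(c, int(s), int(e), "+") for c, s, e in cgis]
    return _scaled_profile(matrix, regions, flank, body_bins, flank_bins, "CGI")
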