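"""CpG-island detection, genomic feature model, and DMR-gene linkage.

CpG islands follow the classical sequence criteria: length > 200 bp, GC
fraction >= 0.5, and observed/expected CpG ratio >= 0.6, where
obs/exp = (N_CpG * L) / (N_C * N_G). Detection is a two-phase scan in the
Takai-Jones style: flag every 200-bp window (1-bp step) passing the GC and
obs/exp criteria, merge overlapping flagged windows, and trim each merged
region to its maximal sub-interval that still passes all three criteria.

The feature model assigns every genomic position at least one category.
DMRs are placed by their midpoint with the precedence
promoter (P1 > P2 > P3) > 5'UTR > 3'UTR > first exon > other exon >
first intron > other intron > distal intergenic, which guarantees the
category counts partition the DMR set. Promoter bins are TSS to -200 (P1),
-200 to -1500 (P2) and -1500 to -2000 (P3), strand-aware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "CGIRecord",
    "FeatureModel",
    "CATEGORIES",
    "find_cgis",
    "define_shores",
    "build_feature_model",
    "annotate_dmr",
    "annotate_dmrs",
    "closest_gene",
    "closest_genes",
    "feature_distribution",
    "export_dmr_fasta",
]

logger = logging.getLogger(__name__)

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")

#: category precedence, highest first; the last is the complement category
CATEGORIES: tuple[str, ...] = (
    "promoter_p1", "promoter_p2", "promoter_p3",
    "utr5", "utr3",
    "first_exon", "other_exon",
    "first_intron", "other_intron",
    "distal_intergenic",
)

_WIN = 200  # scan window, also the minimum island length (strictly greater)


@dataclass
class CGIRecord:
    """A detected CpG island with its verified composition statistics."""

    chrom: str
    start: int
    end: int
    gc_fraction: float
    obs_exp_cpg: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _seq_cumsums(seq: str):
    a = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    is_c = (a == _C).astype(np.int64)
    is_g = (a == _G).astype(np.int64)
    is_n = (~np.isin(a, [_A, _C, _G, _T])).astype(np.int64)
    cpg = np.zeros(len(a), dtype=np.int64)
    if len(a) > 1:
        cpg[:-1] = (a[:-1] == _C) & (a[1:] == _G)
    z = np.zeros(1, dtype=np.int64)
    return (np.concatenate([z, np.cumsum(is_c)]),
            np.concatenate([z, np.cumsum(is_g)]),
            np.concatenate([z, np.cumsum(is_n)]),
            np.concatenate([z, np.cumsum(cpg)]))


def _region_stats(cums, start: int, end: int) -> tuple[float, float, int]:
    c_c, c_g, c_n, c_cpg = cums
    n_c = int(c_c[end] - c_c[start])
    n_g = int(c_g[end] - c_g[start])
    n_n = int(c_n[end] - c_n[start])
    # a CpG is counted when both bases lie inside the region
    n_cpg = int(c_cpg[end - 1] - c_cpg[start]) if end - start >= 2 else 0
    length = (end - start) - n_n  # N bases excluded from counts
    gc = (n_c + n_g) / length if length else 0.0
    oe = n_cpg * length / (n_c * n_g) if n_c and n_g else 0.0
    return gc, oe, length


def _passing_window_starts(cums, seq_len: int) -> np.ndarray:
    if seq_len < _WIN:
        return np.array([], dtype=np.int64)
    c_c, c_g, c_n, c_cpg = cums
    s = np.arange(seq_len - _WIN + 1)
    n_c = c_c[s + _WIN] - c_c[s]
    n_g = c_g[s + _WIN] - c_g[s]
    n_n = c_n[s + _WIN] - c_n[s]
    n_cpg = c_cpg[s + _WIN - 1] - c_cpg[s]
    length = _WIN - n_n
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = np.where(length > 0, (n_c + n_g) / np.maximum(length, 1), 0.0)
        oe = np.where((n_c > 0) & (n_g > 0),
                      n_cpg * length / np.maximum(n_c * n_g, 1), 0.0)
    return s[(gc >= 0.5) & (oe >= 0.6)]


def _merge_windows(starts: np.ndarray) -> list[tuple[int, int]]:
    if starts.size == 0:
        return []
    regions = []
    a = int(starts[0])
    prev_end = a + _WIN
    for s in starts[1:]:
        if s <= prev_end:  # overlapping or book-ended windows merge
            prev_end = int(s) + _WIN
        else:
            regions.append((a, prev_end))
            a = int(s)
            prev_end = a + _WIN
    regions.append((a, prev_end))
    return regions


def _max_passing_subinterval(cums, a: int, b: int) -> tuple[int, int] | None:
    """Longest (leftmost on ties) sub-interval of [a, b) with length > 200
    passing the GC and obs/exp criteria; None when no such interval exists."""
    c_c, c_g, c_n, c_cpg = cums
    for length in range(b - a, _WIN, -1):
        s = np.arange(a, b - length + 1)
        n_c = c_c[s + length] - c_c[s]
        n_g = c_g[s + length] - c_g[s]
        n_n = c_n[s + length] - c_n[s]
        n_cpg = c_cpg[s + length - 1] - c_cpg[s]
        eff = length - n_n
        with np.errstate(divide="ignore", invalid="ignore"):
            gc = np.where(eff > 0, (n_c + n_g) / np.maximum(eff, 1), 0.0)
            oe = np.where((n_c > 0) & (n_g > 0),
                          n_cpg * eff / np.maximum(n_c * n_g, 1), 0.0)
        ok = np.flatnonzero((gc >= 0.5) & (oe >= 0.6) & (eff > 0))
        if ok.size:
            start = int(s[ok[0]])
            return start, start + length
    return None


def find_cgis(genome: dict[str, str] | str | Path) -> list[CGIRecord]:
    """Detect CpG islands on every chromosome.

    ``genome`` is a mapping of chromosome name to sequence, or a FASTA path.
    Every emitted record satisfies length > 200, GC >= 0.5 and
    obs/exp CpG >= 0.6 when re-verified by direct counting.
    """
    if not isinstance(genome, dict):
        import pyfaidx

        fa = pyfaidx.Fasta(str(genome))
        genome = {name: str(fa[name][:]) for name in fa.keys()}
    records: list[CGIRecord] = []
    for chrom, seq in genome.items():
        cums = _seq_cumsums(seq)
        starts = _passing_window_starts(cums, len(seq))
        for a, b in _merge_windows(starts):
            gc, oe, eff = _region_stats(cums, a, b)
            if b - a > _WIN and gc >= 0.5 and oe >= 0.6:
                records.append(CGIRecord(chrom, a, b, gc, oe))
                continue
            trimmed = _max_passing_subinterval(cums, a, b)
            if trimmed is not None:
                s, e = trimmed
                gc, oe, _ = _region_stats(cums, s, e)
                records.append(CGIRecord(chrom, s, e, gc, oe))
    return records


def _subtract_intervals(
    interval: tuple[int, int], blockers: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    parts = [interval]
    for bs, be in blockers:
        nxt = []
        for s, e in parts:
            if be <= s or bs >= e:
                nxt.append((s, e))
                continue
            if s < bs:
                nxt.append((s, bs))
            if be < e:
                nxt.append((be, e))
        parts = nxt
    return parts


def define_shores(
    cgis: list[CGIRecord] | list[tuple[str, int, int]],
    width: int = 2000,
    chrom_lengths: dict[str, int] | None = None,
) -> list[tuple[str, int, int]]:
    """CpG-island shores: the ``width``-bp flanks of each island, clipped to
    chromosome bounds, with island-overlapping portions removed and
    overlapping shores merged."""
    triples = [
        (r.chrom, r.start, r.end) if isinstance(r, CGIRecord) else tuple(r)
        for r in cgis
    ]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in triples:
        by_chrom.setdefault(chrom, []).append((s, e))
    shores: list[tuple[str, int, int]] = []
    for chrom, islands in by_chrom.items():
        islands.sort()
        limit = chrom_lengths.get(chrom) if chrom_lengths else None
        candidates = []
        for s, e in islands:
            up = (max(0, s - width), s)
            down = (e, min(limit, e + width) if limit is not None else e + width)
            for c in (up, down):
                if c[1] > c[0]:
                    candidates.extend(_subtract_intervals(c, islands))
        candidates.sort()
        merged: list[list[int]] = []
        for s, e in candidates:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        shores.extend((chrom, s, e) for s, e in merged)
    return shores


class FeatureModel:
    """Interval index of strand-aware gene features plus CGI/shore tracks."""

    def __init__(self) -> None:
        self._trees: dict[str, dict[str, IntervalTree]] = {
            cat: {} for cat in CATEGORIES if cat != "distal_intergenic"
        }
        self.genes = pd.DataFrame(
            columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
        )
        self.cgis: list[tuple[str, int, int]] = []
        self.shores: list[tuple[str, int, int]] = []

    def _add(self, category: str, chrom: str, start: int, end: int,
             gene_id: str) -> None:
        if end <= start:
            return
        tree = self._trees[category].setdefault(chrom, IntervalTree())
        tree.addi(start, end, gene_id)

    def category_at(self, chrom: str, pos: int) -> str:
        known = any(chrom in t for t in self._trees.values()) or \
            (self.genes["chrom"] == chrom).any()
        if not known:
            logger.warning("chromosome %s absent from the feature model", chrom)
            return "distal_intergenic"
        for cat in CATEGORIES[:-1]:
            tree = self._trees[cat].get(chrom)
            if tree is not None and tree.overlaps_point(pos):
                return cat
        return "distal_intergenic"


def _exonic_overlap(ex_starts, ex_ends, lo: int, hi: int):
    """Exon pieces intersected with [lo, hi)."""
    for s, e in zip(ex_starts, ex_ends):
        a, b = max(s, lo), min(e, hi)
        if b > a:
            yield a, b


def build_feature_model(
    gene_models: pd.DataFrame,
    cgis: list[CGIRecord] | list[tuple[str, int, int]] | None = None,
    shores: list[tuple[str, int, int]] | None = None,
) -> FeatureModel:
    """Build the interval index from collapsed gene models.

    ``gene_models`` must have one row per gene (the I/O readers collapse
    transcripts to the longest one) with columns gene_id, chrom, start, end,
    strand, exon_starts, exon_ends, cds_start, cds_end. Promoter bins are
    laid out upstream of the TSS on the coding strand: for a minus-strand
    gene the promoter occupies genomic coordinates greater than the TSS and
    the transcription-order first exon is the genomically rightmost.
    """
    model = FeatureModel()
    rows = []
    for row in gene_models.itertuples():
        if row.end <= row.start:
            logger.warning("rejecting gene %s with end <= start", row.gene_id)
            continue
        gid, chrom, strand = row.gene_id, row.chrom, row.strand
        tss = row.start if strand == "+" else row.end
        rows.append({"gene_id": gid, "chrom": chrom, "start": row.start,
                     "end": row.end, "strand": strand, "tss": tss})
        # promoter bins: P1 = TSS..-200, P2 = -200..-1500, P3 = -1500..-2000
        if strand == "+":
            bins = [(tss - 200, tss), (tss - 1500, tss - 200),
                    (tss - 2000, tss - 1500)]
        else:
            bins = [(tss, tss + 200), (tss + 200, tss + 1500),
                    (tss + 1500, tss + 2000)]
        for cat, (s, e) in zip(("promoter_p1", "promoter_p2", "promoter_p3"), bins):
            model._add(cat, chrom, max(0, s), max(0, e), gid)

        ex_starts = list(row.exon_starts)
        ex_ends = list(row.exon_ends)
        cds_start = getattr(row, "cds_start", None)
        cds_end = getattr(row, "cds_end", None)
        has_cds = (
            cds_start is not None and cds_end is not None
            and not (pd.isna(cds_start) or pd.isna(cds_end))
            and cds_end > cds_start
        )
        if has_cds:
            left = list(_exonic_overlap(ex_starts, ex_ends, row.start, int(cds_start)))
            right = list(_exonic_overlap(ex_starts, ex_ends, int(cds_end), row.end))
            utr5, utr3 = (left, right) if strand == "+" else (right, left)
            for s, e in utr5:
                model._add("utr5", chrom, s, e, gid)
            for s, e in utr3:
                model._add("utr3", chrom, s, e, gid)

        # transcription order decides "first"
        order = range(len(ex_starts)) if strand == "+" \
            else range(len(ex_starts) - 1, -1, -1)
        for rank, i in enumerate(order):
            cat = "first_exon" if rank == 0 else "other_exon"
            model._add(cat, chrom, ex_starts[i], ex_ends[i], gid)
        intron_bounds = [
            (ex_ends[i], ex_starts[i + 1]) for i in range(len(ex_starts) - 1)
        ]
        order_i = range(len(intron_bounds)) if strand == "+" \
            else range(len(intron_bounds) - 1, -1, -1)
        for rank, i in enumerate(order_i):
            cat = "first_intron" if rank == 0 else "other_intron"
            model._add(cat, chrom, intron_bounds[i][0], intron_bounds[i][1], gid)

    model.genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "tss"]
    )
    if cgis is not None:
        model.cgis = [
            (r.chrom, r.start, r.end) if isinstance(r, CGIRecord) else tuple(r)
            for r in cgis
        ]
    if shores is not None:
        model.shores = list(shores)
    return model


def annotate_dmr(dmr: tuple[str, int, int], model: FeatureModel) -> str:
    """Category of a DMR by its midpoint, first match in precedence order."""
    chrom, start, end = dmr
    return model.category_at(chrom, (int(start) + int(end)) // 2)


def annotate_dmrs(records: pd.DataFrame, model: FeatureModel) -> pd.Series:
    """Vector version of :func:`annotate_dmr` over a DMR record frame."""
    return pd.Series(
        [annotate_dmr((r.chrom, r.start, r.end), model) for r in records.itertuples()],
        index=records.index, name="category",
    )


def closest_gene(
    dmr: tuple[str, int, int], genes: pd.DataFrame
) -> tuple[str | None, float]:
    """Closest gene by span distance (0 if the DMR overlaps TSS..TTS).

    Ties are broken by smaller midpoint-to-TSS distance, then lexicographic
    gene id. Linking never crosses chromosomes: a chromosome without genes
    yields (None, nan).
    """
    chrom, start, end = dmr
    g = genes[genes["chrom"] == chrom]
    if g.empty:
        return None, float("nan")
    gs = g["start"].to_numpy()
    ge = g["end"].to_numpy()
    tss = g["tss"].to_numpy() if "tss" in g else np.where(
        g["strand"].to_numpy() == "+", gs, ge)
    dist = np.maximum(0, np.maximum(gs - end, start - ge))
    mid = (start + end) // 2
    tss_dist = np.abs(mid - tss)
    ids = g["gene_id"].to_numpy()
    order = np.lexsort((ids, tss_dist, dist))
    best = order[0]
    return str(ids[best]), float(dist[best])


def closest_genes(records: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Closest-gene link for every DMR record; columns gene_id, distance."""
    out = [closest_gene((r.chrom, r.start, r.end), genes)
           for r in records.itertuples()]
    return pd.DataFrame(out, columns=["gene_id", "distance"], index=records.index)


def feature_distribution(categories: pd.Series) -> pd.DataFrame:
    """Count and percentage per category; the counts partition the DMR set
    (every DMR has exactly one category) so percentages sum to 100."""
    counts = categories.value_counts()
    total = int(counts.sum())
    rows = []
    for cat in CATEGORIES:
        n = int(counts.get(cat, 0))
        rows.append({
            "category": cat,
            "count": n,
            "percent": 100.0 * n / total if total else 0.0,
        })
    return pd.DataFrame(rows)


def export_dmr_fasta(
    records: pd.DataFrame, genome: dict[str, str], path: str | Path
) -> None:
    """Write DMR sequences as multi-FASTA (motif-discovery input).

    Headers encode coordinates and direction as ``chrom:start-end|direction``;
    the sequence is the genome slice at the DMR's 0-based half-open coords.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out = []
    for r in records.itertuples():
        seq = genome.get(r.chrom)
        if seq is None or r.start < 0 or r.end > len(seq):
            raise ValueError(f"DMR {r.chrom}:{r.start}-{r.end} out of genome bounds")
        direction = getattr(r, "direction", ".")
        out.append(SeqRecord(
            Seq(seq[r.start:r.end]),
            id=f"{r.chrom}:{r.start}-{r.end}|{direction}",
            description="",
        ))
    with open(path, "w") as fh:
        SeqIO.write(out, fh, "fasta")
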