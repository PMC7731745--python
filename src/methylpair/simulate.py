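"""Synthetic paired RRBS study generator.

Emulates the design of a paired two-group reduced-representation bisulfite
study: two precursor cell types (adipogenic, myogenic) sampled from the same
animals (default three), sequenced after in-silico MspI digestion and
225-290 bp size selection. The generator plants ground truth at every level
-- CpG islands in the genome sequence, differentially methylated windows in
the methylation surface, and differentially expressed genes in the
expression table -- so downstream callers can be benchmarked for sensitivity
and false discovery rate without any external data.

Scale is deliberately reduced relative to a mammalian genome (a few hundred
kilobases per chromosome instead of gigabases); all layout knobs live on
:class:`SimConfig`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, PlacementError, SizingError

__all__ = [
    "SimConfig",
    "SimTruth",
    "MethylationSurface",
    "NonCpGControls",
    "SimulatedDataset",
    "generate_genome",
    "generate_gene_models",
    "digest_mspi",
    "size_select",
    "simulate_methylomes",
    "simulate_counts",
    "simulate_expression",
    "simulate_dataset",
]

# ASCII codes used in the uint8 sequence buffers
_A, _C, _G, _T = (ord(b) for b in "ACGT")

# independent substream tags, one per stage
_STAGE_GENOME = 11
_STAGE_GENES = 12
_STAGE_METH = 13
_STAGE_COUNTS = 14
_STAGE_EXPR = 15

# geometry of the CGI building block: 25 bp holding two CG dinucleotides,
# seven C and seven G in total (GC = 0.56, obs/exp CpG = 2*25/(7*7) ~ 1.02)
_CGI_BLOCK = ["CG", "CG", "C", "C", "C", "C", "C", "G", "G", "G", "G", "G",
              "A", "A", "A", "A", "A", "A", "T", "T", "T", "T", "T"]
_CGI_FLANK = 250  # bp of CpG-free AT-rich buffer on each side of a planted CGI


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic paired RRBS experiment.

    The statistical defaults mirror the emulated study: three animals, two
    cell types per animal (paired), per-CpG depth averaging 50 reads,
    bisulfite conversion 99.5 %, a hypermethylated genome baseline (0.75)
    with hypomethylation at transcription start sites and CpG islands, and
    planted differential windows of +/-0.40 methylation difference.
    """

    seed: int = 0
    # genome layout
    n_chrom: int = 3
    chrom_length: int = 700_000
    n_genes: int = 120
    n_cgi: int = 60
    cgi_length_range: tuple[int, int] = (800, 1600)
    background_gc: float = 0.42
    cpg_depletion: float = 0.45  # keep-probability for background CpG dinucleotides
    # sampling design
    n_animals: int = 3
    groups: tuple[str, str] = ("adipogenic", "myogenic")
    mean_depth: float = 50.0
    depth_dispersion: float = 0.15
    conversion_rate: float = 0.995
    # methylation surface
    baseline_methylation: float = 0.75
    tss_dip_depth: float = 0.8
    tss_dip_halfwidth: int = 500
    n_dmr: int = 250
    dmr_delta: float = 0.40
    animal_sd: float = 0.05  # per-animal random effect, logit scale
    # expression
    n_deg: int = 30
    deg_log2fc: float = 2.0
    expr_noise_sd: float = 0.25  # log2 scale
    n_expr_reps: int = 3
    # simulator layout internals
    dmr_window: int = 100         # planted DMRs occupy whole analysis windows
    dmr_min_cpgs: int = 8         # observable CpGs required in a planted window
    n_control_sites: int = 2000   # non-CpG cytosines emitted for conversion QC
    frag_in_range_prob: float = 0.45  # background MspI spacing in the 225-290 band

    def __post_init__(self) -> None:
        fracs = {
            "background_gc": self.background_gc,
            "conversion_rate": self.conversion_rate,
            "baseline_methylation": self.baseline_methylation,
            "tss_dip_depth": self.tss_dip_depth,
            "dmr_delta": self.dmr_delta,
            "frag_in_range_prob": self.frag_in_range_prob,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 < self.cpg_depletion <= 1.0:
            raise ConfigError("cpg_depletion must be in (0, 1]")
        if self.n_animals < 2:
            raise ConfigError("n_animals must be >= 2")
        if len(self.groups) != 2 or self.groups[0] == self.groups[1]:
            raise ConfigError("groups must be two distinct labels")
        lo, hi = self.cgi_length_range
        if not 200 < lo <= hi:
            raise ConfigError("cgi_length_range must satisfy 200 < low <= high")
        if self.n_cgi > 0 and self.chrom_length < 10 * hi:
            raise SizingError(
                f"chrom_length {self.chrom_length} < 10x max CGI length {hi}"
            )
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if self.depth_dispersion < 0 or self.animal_sd < 0 or self.expr_noise_sd < 0:
            raise ConfigError("dispersion/sd parameters must be non-negative")
        if self.n_expr_reps < 2:
            raise ConfigError("n_expr_reps must be >= 2")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def sample_names(self) -> list[str]:
        return [f"{g}_{a + 1}" for g in self.groups for a in range(self.n_animals)]

    def _rng(self, stage: int) -> np.random.Generator:
        # per-stage independent substream derived from the top-level seed
        return np.random.default_rng(np.random.SeedSequence((int(self.seed), stage)))


@dataclass
class SimTruth:
    """Planted ground truth: CGIs, DMR windows (signed), and DEG genes."""

    cgi_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    dmr_intervals: list[tuple[str, int, int, float]] = field(default_factory=list)
    deg_genes: list[tuple[str, float]] = field(default_factory=list)

    def dmr_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dmr_intervals, columns=["chrom", "start", "end", "delta"]
        )


@dataclass
class MethylationSurface:
    """True per-CpG methylation fractions for every sample.

    ``sites`` holds one row per CpG dyad (chrom, 0-based position of the
    forward-strand C); ``level`` is (n_sites, n_samples) with the noiseless
    methylation fraction each sample would show at infinite depth.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame  # columns: name, animal, group
    level: np.ndarray

    def group_mean(self, group: str) -> np.ndarray:
        cols = np.flatnonzero((self.samples["group"] == group).to_numpy())
        return self.level[:, cols].mean(axis=1)


@dataclass
class NonCpGControls:
    """Counts at non-CpG cytosines (true methylation 0) for conversion QC."""

    sites: pd.DataFrame
    samples: list[str]
    meth: np.ndarray
    total: np.ndarray


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    config: SimConfig
    genome: dict[str, str]
    gene_models: pd.DataFrame
    rrbs_intervals: dict[str, list[tuple[int, int]]]
    truth: SimTruth
    surface: MethylationSurface
    counts: "object"  # CpGCountMatrix; annotated loosely to avoid import cycle
    controls: NonCpGControls
    expression: pd.DataFrame


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _iid_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.array([_A, _C, _G, _T], dtype=np.uint8), size=n, p=probs)


def _thin_cpgs(seq: np.ndarray, rng: np.random.Generator, keep_prob: float) -> None:
    """Replace the C of CpG dinucleotides with T, keeping each with keep_prob."""
    idx = np.flatnonzero((seq[:-1] == _C) & (seq[1:] == _G))
    if idx.size == 0:
        return
    kill = rng.random(idx.size) >= keep_prob
    seq[idx[kill]] = _T


def _suppress_ccgg(seq: np.ndarray, start: int, end: int) -> None:
    """Destroy CCGG occurrences in seq[start:end] by mutating the first C to A."""
    view = seq[start:end]
    hit = np.flatnonzero(
        (view[:-3] == _C) & (view[1:-2] == _C) & (view[2:-1] == _G) & (view[3:] == _G)
    )
    view[hit] = _A


def _write_ccgg_grid(
    seq: np.ndarray, start: int, end: int, rng: np.random.Generator,
    low: int, high: int,
) -> None:
    pos = start + int(rng.integers(low, high + 1))
    while pos + 4 <= end:
        seq[pos:pos + 4] = [_C, _C, _G, _G]
        pos += int(rng.integers(low, high + 1))


def _cgi_body(rng: np.random.Generator, length: int) -> np.ndarray:
    n_blocks = length // 25 + 1
    parts: list[str] = []
    for _ in range(n_blocks):
        units = list(_CGI_BLOCK)
        rng.shuffle(units)
        parts.append("".join(units))
    body = np.frombuffer("".join(parts).encode(), dtype=np.uint8)[:length].copy()
    _suppress_ccgg(body, 0, length)
    return body


def _place_disjoint(
    rng: np.random.Generator, chrom_length: int, lengths: Sequence[int],
    margin: int, gap: int,
) -> list[tuple[int, int]]:
    """Random disjoint intervals with pairwise gap >= gap, away from ends."""
    k = len(lengths)
    if k == 0:
        return []
    occupied = sum(lengths) + gap * (k - 1) + 2 * margin
    free = chrom_length - occupied
    if free < 0:
        raise SizingError(
            f"chromosome of {chrom_length} bp cannot host {k} intervals "
            f"totalling {sum(lengths)} bp with {gap} bp gaps"
        )
    cuts = np.sort(rng.random(k)) * free
    starts, acc = [], margin
    for i, ln in enumerate(lengths):
        s = int(acc + cuts[i])
        starts.append(s)
        acc += ln + gap
    return [(s, s + ln) for s, ln in zip(starts, lengths)]


def _verify_cgi(seq: np.ndarray, start: int, end: int) -> tuple[float, float]:
    region = seq[start:end]
    n_c = int((region == _C).sum())
    n_g = int((region == _G).sum())
    n_cpg = int(((region[:-1] == _C) & (region[1:] == _G)).sum())
    length = end - start
    gc = (n_c + n_g) / length
    oe = n_cpg * length / (n_c * n_g) if n_c and n_g else 0.0
    return gc, oe


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(cfg: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Generate chromosome sequences with planted CpG islands.

    The background is i.i.d. sequence at ``background_gc`` GC content with
    CpG dinucleotides thinned to ``cpg_depletion`` of their random-expectation
    frequency. MspI sites (CCGG) are laid down on a randomized grid whose
    spacing puts a realistic share of fragments inside the RRBS size-selection
    band. Planted CGIs are CpG- and GC-rich segments (flanked by short
    CpG-free AT-rich buffers so island boundaries are crisp) that satisfy the
    classical island criteria (length > 200 bp, GC >= 0.5, obs/exp >= 0.6)
    by construction; each one is re-verified by direct counting before the
    genome is returned.
    """
    rng = cfg._rng(_STAGE_GENOME)
    truth = SimTruth()
    genome: dict[str, str] = {}

    # distribute CGIs across chromosomes as evenly as possible
    per_chrom = [cfg.n_cgi // cfg.n_chrom] * cfg.n_chrom
    for i in range(cfg.n_cgi % cfg.n_chrom):
        per_chrom[i] += 1

    for ci, chrom in enumerate(cfg.chrom_names):
        seq = _iid_bases(rng, cfg.chrom_length, cfg.background_gc)
        _thin_cpgs(seq, rng, cfg.cpg_depletion)

        # background MspI grid: mixture spacing, ~frag_in_range_prob of
        # fragments land in the 225-290 bp selection band
        pos = 0
        while True:
            u = rng.random()
            if u < cfg.frag_in_range_prob:
                step = int(rng.integers(225, 291))
            elif u < cfg.frag_in_range_prob + 0.25:
                step = int(rng.integers(60, 201))
            else:
                step = int(rng.integers(320, 1501))
            pos += step
            if pos + 4 > cfg.chrom_length:
                break
            seq[pos:pos + 4] = [_C, _C, _G, _G]

        n_here = per_chrom[ci]
        if n_here:
            lengths = rng.integers(
                cfg.cgi_length_range[0], cfg.cgi_length_range[1] + 1, size=n_here
            )
            intervals = _place_disjoint(
                rng, cfg.chrom_length, list(lengths),
                margin=5000, gap=3000,
            )
            for start, end in intervals:
                # AT-rich CpG-free flanks make the island edge detectable
                for fs, fe in ((start - _CGI_FLANK, start), (end, end + _CGI_FLANK)):
                    flank = _iid_bases(rng, fe - fs, 0.30)
                    _thin_cpgs(flank, rng, 1e-12)  # remove essentially all CpGs
                    seq[fs:fe] = flank
                for _attempt in range(5):
                    seq[start:end] = _cgi_body(rng, end - start)
                    _write_ccgg_grid(seq, start, end, rng, 225, 290)
                    gc, oe = _verify_cgi(seq, start, end)
                    if gc >= 0.5 and oe >= 0.6 and end - start > 200:
                        break
                else:  # pragma: no cover - construction guarantees success
                    raise PlacementError(
                        f"could not build a valid CGI at {chrom}:{start}-{end}"
                    )
                truth.cgi_intervals.append((chrom, start, end))

        genome[chrom] = seq.tobytes().decode("ascii")

    return genome, truth


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def generate_gene_models(cfg: SimConfig) -> pd.DataFrame:
    """Random non-overlapping gene models with exon/intron structure and UTRs.

    Returns a frame with one row per gene: gene_id, chrom, start, end,
    strand, exon_starts/exon_ends (tuples of absolute coordinates, 0-based
    half-open, in genomic order) and cds_start/cds_end delimiting the coding
    span (UTRs are the exonic sequence outside it).
    """
    rng = cfg._rng(_STAGE_GENES)
    per_chrom = [cfg.n_genes // cfg.n_chrom] * cfg.n_chrom
    for i in range(cfg.n_genes % cfg.n_chrom):
        per_chrom[i] += 1

    rows = []
    gid = 0
    for ci, chrom in enumerate(cfg.chrom_names):
        n_here = per_chrom[ci]
        if n_here == 0:
            continue
        lengths = rng.integers(2000, 8001, size=n_here)
        spans = _place_disjoint(
            rng, cfg.chrom_length, list(lengths), margin=4000, gap=4500
        )
        for start, end in spans:
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            length = end - start
            max_exons = max(1, min(6, (length - 200) // 700))
            n_ex = int(rng.integers(1, max_exons + 1))
            if n_ex == 1:
                ex_starts, ex_ends = [start], [end]
            else:
                # alternate exon/intron segments with floors of 150/200 bp
                n_seg = 2 * n_ex - 1
                floors = np.where(np.arange(n_seg) % 2 == 0, 150, 200)
                slack = length - floors.sum()
                w = rng.dirichlet(np.ones(n_seg))
                sizes = floors + np.floor(w * slack).astype(int)
                sizes[-1] += length - sizes.sum()
                bounds = start + np.concatenate([[0], np.cumsum(sizes)])
                ex_starts = [int(bounds[i]) for i in range(0, n_seg, 2)]
                ex_ends = [int(bounds[i + 1]) for i in range(0, n_seg, 2)]
            first_len = ex_ends[0] - ex_starts[0]
            last_len = ex_ends[-1] - ex_starts[-1]
            if strand == "+":
                utr5 = int(rng.integers(50, max(51, min(250, first_len - 50))))
                utr3 = int(rng.integers(80, max(81, min(400, last_len - 50))))
                cds_start, cds_end = ex_starts[0] + utr5, ex_ends[-1] - utr3
            else:
                utr5 = int(rng.integers(50, max(51, min(250, last_len - 50))))
                utr3 = int(rng.integers(80, max(81, min(400, first_len - 50))))
                cds_start, cds_end = ex_starts[0] + utr3, ex_ends[-1] - utr5
            if cds_end <= cds_start:  # degenerate tiny single exon: no UTRs
                cds_start, cds_end = start, end
            rows.append({
                "gene_id": f"gene{gid:04d}",
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "strand": strand,
                "exon_starts": tuple(int(x) for x in ex_starts),
                "exon_ends": tuple(int(x) for x in ex_ends),
                "cds_start": int(cds_start),
                "cds_end": int(cds_end),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RRBS restriction
# ---------------------------------------------------------------------------

_CCGG = re.compile("CCGG")


def digest_mspi(sequence: str) -> list[tuple[int, int]]:
    """In-silico MspI digestion: cut at C^CGG, scanning left to right.

    Returns 0-based half-open fragment intervals whose concatenation is the
    input sequence. An empty sequence yields an empty list; a sequence
    without CCGG yields a single full-length fragment.
    """
    if not sequence:
        return []
    cuts = [m.start() + 1 for m in _CCGG.finditer(sequence)]
    bounds = [0, *cuts, len(sequence)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def size_select(
    fragments: Sequence[tuple[int, int]], low: int = 225, high: int = 290
) -> list[tuple[int, int]]:
    """Keep fragments whose length is in [low, high] (the gel selection band)."""
    if low > high:
        raise ConfigError(f"size_select: low {low} > high {high}")
    return [(s, e) for s, e in fragments if low <= e - s <= high]


def rrbs_intervals(genome: dict[str, str], low: int = 225, high: int = 290
                   ) -> dict[str, list[tuple[int, int]]]:
    """Digest every chromosome and size-select; the kept intervals define
    which CpGs are observable."""
    return {c: size_select(digest_mspi(s), low, high) for c, s in genome.items()}


# ---------------------------------------------------------------------------
# methylation surface
# ---------------------------------------------------------------------------

def _cpg_positions(seq: str) -> np.ndarray:
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    return np.flatnonzero((a[:-1] == _C) & (a[1:] == _G))


def _in_intervals(pos: np.ndarray, intervals: Sequence[tuple[int, int]]) -> np.ndarray:
    """Boolean mask: which positions fall inside any of the sorted intervals."""
    if len(intervals) == 0:
        return np.zeros(pos.shape, dtype=bool)
    iv = np.asarray(sorted(intervals))
    starts, ends = iv[:, 0], iv[:, 1]
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(pos.shape, dtype=bool)
    out[ok] = pos[ok] < ends[idx[ok]]
    return out


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylomes(
    genome: dict[str, str],
    gene_models: pd.DataFrame,
    cfg: SimConfig,
    cgi_intervals: Sequence[tuple[str, int, int]] = (),
    kept_fragments: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[MethylationSurface, list[tuple[str, int, int, float]]]:
    """Build the true methylation surface and plant DMR windows.

    The surface is hypermethylated at ``baseline_methylation`` genome-wide,
    dips towards TSSs (linear ramp inside ``tss_dip_halfwidth``) and inside
    CGIs, carries a per-animal logit-scale random effect shared by both cell
    types of the same animal (the paired structure), and differs between
    groups by +/- ``dmr_delta`` inside ``n_dmr`` planted analysis windows.
    Planted windows are whole ``dmr_window``-bp tiles holding at least
    ``dmr_min_cpgs`` observable CpGs, so truth aligns with the tested units.
    """
    rng = cfg._rng(_STAGE_METH)
    if kept_fragments is None:
        kept_fragments = rrbs_intervals(genome)

    site_chrom: list[str] = []
    site_pos: list[np.ndarray] = []
    base_level: list[np.ndarray] = []
    observable: list[np.ndarray] = []

    cgi_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in cgi_intervals:
        cgi_by_chrom.setdefault(c, []).append((s, e))

    for chrom, seq in genome.items():
        pos = _cpg_positions(seq)
        level = np.full(pos.shape, cfg.baseline_methylation)

        # TSS dip: linear ramp from full depth at the TSS to zero at halfwidth
        genes_here = gene_models[gene_models["chrom"] == chrom]
        if len(genes_here) and len(pos):
            tss = np.where(
                genes_here["strand"].to_numpy() == "+",
                genes_here["start"].to_numpy(),
                genes_here["end"].to_numpy(),
            )
            tss = np.sort(tss)
            j = np.searchsorted(tss, pos)
            d_right = np.where(j < len(tss), tss[np.minimum(j, len(tss) - 1)] - pos,
                               np.iinfo(np.int64).max)
            d_left = np.where(j > 0, pos - tss[np.maximum(j - 1, 0)],
                              np.iinfo(np.int64).max)
            dist = np.minimum(np.abs(d_right), np.abs(d_left)).astype(float)
            ramp = np.clip(1.0 - dist / cfg.tss_dip_halfwidth, 0.0, 1.0)
            level = np.minimum(level, cfg.baseline_methylation * (1 - cfg.tss_dip_depth * ramp))

        # CGI interior: full dip
        in_cgi = _in_intervals(pos, cgi_by_chrom.get(chrom, []))
        level[in_cgi] = np.minimum(
            level[in_cgi], cfg.baseline_methylation * (1 - cfg.tss_dip_depth)
        )

        site_chrom.append(chrom)
        site_pos.append(pos)
        base_level.append(level)
        observable.append(_in_intervals(pos, kept_fragments.get(chrom, [])))

    # plant DMRs on analysis windows with enough observable CpGs
    eligible: list[tuple[int, int]] = []  # (chrom index, window index)
    for k, chrom in enumerate(genome):
        obs_pos = site_pos[k][observable[k]]
        if obs_pos.size == 0:
            continue
        win, counts = np.unique(obs_pos // cfg.dmr_window, return_counts=True)
        for w in win[counts >= cfg.dmr_min_cpgs]:
            eligible.append((k, int(w)))
    if cfg.n_dmr > len(eligible):
        raise PlacementError(
            f"cannot place {cfg.n_dmr} disjoint DMR windows: only "
            f"{len(eligible)} windows hold >= {cfg.dmr_min_cpgs} observable CpGs"
        )
    chosen = [eligible[i] for i in rng.choice(len(eligible), cfg.n_dmr, replace=False)] \
        if cfg.n_dmr else []
    signs = np.ones(cfg.n_dmr)
    signs[: cfg.n_dmr // 2] = -1.0
    rng.shuffle(signs)

    chrom_names = list(genome)
    dmr_truth: list[tuple[str, int, int, float]] = []
    # per-group base level (group 0 = adipogenic reference, group 1 = myogenic)
    group_level = [
        [lv.copy() for lv in base_level],
        [lv.copy() for lv in base_level],
    ]
    for (k, w), sign in zip(chosen, signs):
        start, end = w * cfg.dmr_window, (w + 1) * cfg.dmr_window
        mask = (site_pos[k] >= start) & (site_pos[k] < end)
        # centre the window so +/- delta/2 keeps both groups inside (0, 1)
        group_level[0][k][mask] = 0.5 - sign * cfg.dmr_delta / 2
        group_level[1][k][mask] = 0.5 + sign * cfg.dmr_delta / 2
        dmr_truth.append(
            (chrom_names[k], int(start), int(end), float(sign * cfg.dmr_delta))
        )

    # assemble per-sample surface with the shared animal effect
    animal_eff = rng.normal(0.0, cfg.animal_sd, size=cfg.n_animals)
    sample_rows = []
    cols = []
    for gi, group in enumerate(cfg.groups):
        glev = np.concatenate(group_level[gi])
        for a in range(cfg.n_animals):
            sample_rows.append(
                {"name": f"{group}_{a + 1}", "animal": a + 1, "group": group}
            )
            cols.append(_expit(_logit(glev) + animal_eff[a]))
    sites = pd.DataFrame({
        "chrom": np.repeat(site_chrom, [len(p) for p in site_pos]),
        "pos": np.concatenate(site_pos).astype(np.int64),
    })
    surface = MethylationSurface(
        sites=sites,
        samples=pd.DataFrame(sample_rows),
        level=np.column_stack(cols),
    )
    return surface, dmr_truth


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------

def _draw_depth(rng: np.random.Generator, shape: tuple[int, ...], cfg: SimConfig
                ) -> np.ndarray:
    """Overdispersed totals: gamma-Poisson with Var = mu(1 + disp*mu);
    dispersion 0 degenerates to Poisson."""
    if cfg.depth_dispersion > 0:
        lam = rng.gamma(1.0 / cfg.depth_dispersion,
                        cfg.mean_depth * cfg.depth_dispersion, size=shape)
        return rng.poisson(lam)
    return rng.poisson(cfg.mean_depth, size=shape)


def simulate_counts(
    surface: MethylationSurface,
    kept_fragments: dict[str, list[tuple[int, int]]],
    cfg: SimConfig,
    genome: dict[str, str] | None = None,
):
    """Draw per-CpG read counts at observable sites, plus non-CpG controls.

    The methylated-read probability is ``m + (1 - m) * (1 - conversion_rate)``:
    an unmethylated cytosine escapes conversion (and therefore reads as
    methylated) with probability ``1 - conversion_rate``. Non-CpG cytosine
    control sites have true methylation 0, so their pooled methylated
    fraction estimates the conversion failure rate.

    Returns ``(CpGCountMatrix, NonCpGControls)``; the control block is empty
    when ``genome`` is not supplied.
    """
    from .core import CpGCountMatrix  # deferred to avoid import cycle

    if cfg.mean_depth <= 0:  # defensive; SimConfig already validates
        raise ConfigError("mean_depth must be positive")
    rng = cfg._rng(_STAGE_COUNTS)

    obs_mask = np.zeros(len(surface.sites), dtype=bool)
    for chrom, ivs in kept_fragments.items():
        sel = (surface.sites["chrom"] == chrom).to_numpy()
        obs_mask[sel] = _in_intervals(surface.sites["pos"].to_numpy()[sel], ivs)

    sites = surface.sites.loc[obs_mask].reset_index(drop=True)
    m = surface.level[obs_mask]
    total = _draw_depth(rng, m.shape, cfg)
    p = np.clip(m + (1 - m) * (1 - cfg.conversion_rate), 0.0, 1.0)
    meth = rng.binomial(total, p)
    matrix = CpGCountMatrix(
        sites=sites, samples=surface.samples.copy(), meth=meth, total=total
    )

    if genome is None or cfg.n_control_sites == 0:
        controls = NonCpGControls(
            sites=pd.DataFrame(columns=["chrom", "pos"]),
            samples=list(surface.samples["name"]),
            meth=np.zeros((0, len(surface.samples)), dtype=int),
            total=np.zeros((0, len(surface.samples)), dtype=int),
        )
        return matrix, controls

    ctrl_chrom, ctrl_pos = [], []
    per_chrom = max(1, cfg.n_control_sites // max(len(genome), 1))
    for chrom, seq in genome.items():
        a = np.frombuffer(seq.encode(), dtype=np.uint8)
        non_cpg_c = np.flatnonzero((a[:-1] == _C) & (a[1:] != _G))
        keep = non_cpg_c[_in_intervals(non_cpg_c, kept_fragments.get(chrom, []))]
        if keep.size == 0:
            continue
        take = min(per_chrom, keep.size)
        sel = np.sort(rng.choice(keep, size=take, replace=False))
        ctrl_chrom.extend([chrom] * take)
        ctrl_pos.append(sel)
    cpos = np.concatenate(ctrl_pos) if ctrl_pos else np.array([], dtype=np.int64)
    ctot = _draw_depth(rng, (len(cpos), len(surface.samples)), cfg)
    cmeth = rng.binomial(ctot, 1 - cfg.conversion_rate)
    controls = NonCpGControls(
        sites=pd.DataFrame({"chrom": ctrl_chrom, "pos": cpos}),
        samples=list(surface.samples["name"]),
        meth=cmeth,
        total=ctot,
    )
    return matrix, controls


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    gene_models: pd.DataFrame, cfg: SimConfig
) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """Log-normal replicate expression with planted DEGs.

    Returns a table with one row per gene and one column per replicate
    (named ``<group>_rep<k>``), plus the planted (gene_id, signed log2 fold
    change) truth list. Fold changes are myogenic relative to adipogenic.
    """
    rng = cfg._rng(_STAGE_EXPR)
    genes = list(gene_models["gene_id"])
    n = len(genes)
    if cfg.n_deg > n:
        raise ConfigError(f"n_deg {cfg.n_deg} exceeds n_genes {n}")
    base = rng.uniform(3.0, 10.0, size=n)  # log2 abundance
    lfc = np.zeros(n)
    if cfg.n_deg:
        idx = rng.choice(n, cfg.n_deg, replace=False)
        signs = np.ones(cfg.n_deg)
        signs[: cfg.n_deg // 2] = -1.0
        rng.shuffle(signs)
        lfc[idx] = signs * cfg.deg_log2fc

    data = {"gene_id": genes}
    for group in cfg.groups:
        offset = lfc if group == cfg.groups[1] else 0.0
        for rep in range(1, cfg.n_expr_reps + 1):
            noise = rng.normal(0.0, cfg.expr_noise_sd, size=n)
            data[f"{group}_rep{rep}"] = 2.0 ** (base + offset + noise)
    truth = [(genes[i], float(lfc[i])) for i in np.flatnonzero(lfc)]
    return pd.DataFrame(data), truth


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Run every simulation stage and return the full bundle with truth."""
    genome, truth = generate_genome(cfg)
    gene_models = generate_gene_models(cfg)
    kept = rrbs_intervals(genome)
    surface, dmrs = simulate_methylomes(
        genome, gene_models, cfg, truth.cgi_intervals, kept
    )
    truth.dmr_intervals = dmrs
    counts, controls = simulate_counts(surface, kept, cfg, genome)
    expression, degs = simulate_expression(gene_models, cfg)
    truth.deg_genes = degs
    return SimulatedDataset(
        config=cfg, genome=genome, gene_models=gene_models,
        rrbs_intervals=kept, truth=truth, surface=surface,
        counts=counts, controls=controls, expression=expression,
    )
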