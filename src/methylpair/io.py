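"""Readers and writers for the standard formats around the pipeline.

Coordinates are 0-based half-open internally; GTF is read as 1-based
inclusive, BED is read and written 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "load_genome",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "read_bed12",
    "read_gene_models",
    "read_gmt",
    "read_tf_list",
    "write_bed6",
    "read_bed6",
    "read_expression",
]


def load_genome(path: str | Path) -> dict[str, str]:
    """Read a FASTA into a chrom -> sequence mapping (pyfaidx-backed)."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def _longest_transcript(transcripts: dict) -> dict:
    def span(tr):
        return max(e for _, e in tr["exons"]) - min(s for s, _ in tr["exons"])

    return max(transcripts.values(), key=span)


def read_gtf(path: str | Path) -> pd.DataFrame:
    """Collapse a GTF (1-based, inclusive) to one model per gene.

    Exon and CDS features are grouped per transcript; each gene keeps its
    longest transcript. Returns the internal gene-model frame (0-based
    half-open coordinates).
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    genes: dict[str, dict[str, dict]] = {}
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            gid = feat.attributes.get("gene_id", [feat.id])[0]
            tid = feat.attributes.get("transcript_id", [gid])[0]
            tr = genes.setdefault(gid, {}).setdefault(
                tid, {"chrom": feat.seqid, "strand": feat.strand,
                      "exons": [], "cds": []},
            )
            # GTF is 1-based inclusive; convert here
            iv = (feat.start - 1, feat.end)
            tr["exons" if ftype == "exon" else "cds"].append(iv)
    rows = []
    for gid, transcripts in genes.items():
        tr = _longest_transcript(transcripts)
        exons = sorted(tr["exons"])
        if not exons:
            continue
        start, end = exons[0][0], exons[-1][1]
        if end <= start:
            logger.warning("rejecting gene %s with end <= start", gid)
            continue
        cds = sorted(tr["cds"])
        rows.append({
            "gene_id": gid, "chrom": tr["chrom"], "start": start, "end": end,
            "strand": tr["strand"],
            "exon_starts": tuple(s for s, _ in exons),
            "exon_ends": tuple(e for _, e in exons),
            "cds_start": cds[0][0] if cds else None,
            "cds_end": cds[-1][1] if cds else None,
        })
    return pd.DataFrame(rows).sort_values(
        ["chrom", "start"]).reset_index(drop=True)


def write_gtf(gene_models: pd.DataFrame, path: str | Path,
              source: str = "methylpair") -> None:
    """Write the internal gene-model frame as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for r in gene_models.itertuples():
            attrs = f'gene_id "{r.gene_id}"; transcript_id "{r.gene_id}.t1";'
            fh.write("\t".join([
                r.chrom, source, "transcript", str(r.start + 1), str(r.end),
                ".", r.strand, ".", attrs]) + "\n")
            for s, e in zip(r.exon_starts, r.exon_ends):
                fh.write("\t".join([
                    r.chrom, source, "exon", str(s + 1), str(e),
                    ".", r.strand, ".", attrs]) + "\n")
            if r.cds_start is not None and not pd.isna(r.cds_start):
                cs, ce = int(r.cds_start), int(r.cds_end)
                for s, e in zip(r.exon_starts, r.exon_ends):
                    a, b = max(s, cs), min(e, ce)
                    if b > a:
                        fh.write("\t".join([
                            r.chrom, source, "CDS", str(a + 1), str(b),
                            ".", r.strand, ".", attrs]) + "\n")


_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "rgb", "block_count", "block_sizes",
    "block_starts",
]


def read_bed12(path: str | Path) -> pd.DataFrame:
    """Read gene models from BED12 (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, names=_BED12_COLS, comment="#")
    rows = []
    for r in df.itertuples():
        sizes = [int(x) for x in str(r.block_sizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(r.block_starts).rstrip(",").split(",")]
        ex_starts = tuple(r.start + o for o in offsets)
        ex_ends = tuple(s + sz for s, sz in zip(ex_starts, sizes))
        has_cds = r.thick_end > r.thick_start
        rows.append({
            "gene_id": r.name, "chrom": r.chrom, "start": int(r.start),
            "end": int(r.end), "strand": r.strand,
            "exon_starts": ex_starts, "exon_ends": ex_ends,
            "cds_start": int(r.thick_start) if has_cds else None,
            "cds_end": int(r.thick_end) if has_cds else None,
        })
    return pd.DataFrame(rows)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Dispatch on extension: .gtf/.gff -> GTF reader, .bed -> BED12 reader."""
    suffix = Path(path).suffix.lower()
    if suffix in {".gtf", ".gff", ".gff3"}:
        return read_gtf(path)
    if suffix == ".bed":
        return read_bed12(path)
    raise ValueError(f"unrecognised gene annotation extension: {suffix}")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def read_tf_list(path: str | Path) -> list[str]:
    """Plain-text transcription-factor names, one per line."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_bed6(df: pd.DataFrame, path: str | Path,
               name_col: str = "name", score_col: str = "score") -> None:
    """Write 6-column BED: chrom, start, end, name, score, strand '.'."""
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(int),
        "end": df["end"].astype(int),
        "name": df[name_col] if name_col in df else ".",
        "score": df[score_col] if score_col in df else 0,
        "strand": ".",
    })
    out.to_csv(path, sep="\t", header=False, index=False,
               float_format="%.6g")


def read_bed6(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "name", "score", "strand"])


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV: gene_id plus either per-replicate value columns
    (named <group>_rep<k>) or precomputed fc/fdr columns."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("expression table must have a gene_id column")
    return df


def dmr_score(q_values: np.ndarray) -> np.ndarray:
    """BED score: -log10(q) clipped to [0, 1000]."""
    with np.errstate(divide="ignore"):
        s = -np.log10(np.maximum(np.asarray(q_values, dtype=float), 1e-300))
    return np.clip(s, 0.0, 1000.0)
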