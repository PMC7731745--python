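"""CGI detection, shores, feature model, DMR annotation, closest genes."""

import numpy as np
import pandas as pd
import pytest

import methylpair as mp
from methylpair.annotation import CATEGORIES, CGIRecord, _region_stats, _seq_cumsums


def direct_stats(seq: str) -> tuple[float, float]:
    """Straightforward counting oracle for GC fraction and obs/exp CpG."""
    eff = sum(seq.count(b) for b in "ACGT")
    n_c, n_g = seq.count("C"), seq.count("G")
    n_cpg = sum(1 for i in range(len(seq) - 1) if seq[i:i + 2] == "CG")
    gc = (n_c + n_g) / eff if eff else 0.0
    oe = n_cpg * eff / (n_c * n_g) if n_c and n_g else 0.0
    return gc, oe


def passes(seq: str) -> bool:
    gc, oe = direct_stats(seq)
    return gc >= 0.5 and oe >= 0.6


def naive_find_cgis(seq: str) -> list[tuple[int, int]]:
    """Independent oracle: flag every 200-bp window by direct counting, merge,
    then exhaustively search each merged region for its longest (leftmost)
    sub-interval of length > 200 passing all criteria."""
    flagged = [s for s in range(len(seq) - 199) if passes(seq[s:s + 200])]
    regions = []
    for s in flagged:
        if regions and s <= regions[-1][1]:
            regions[-1][1] = s + 200
        else:
            regions.append([s, s + 200])
    out = []
    for a, b in regions:
        found = None
        for length in range(b - a, 200, -1):
            for s in range(a, b - length + 1):
                if passes(seq[s:s + length]):
                    found = (s, s + length)
                    break
            if found:
                break
        if found:
            out.append(found)
    return out


def random_cgi_like_seq(rng, n=700) -> str:
    """Background with an embedded GC/CpG-rich run, CGI-detection fodder."""
    bases = rng.choice(list("ACGT"), size=n, p=[0.3, 0.2, 0.2, 0.3])
    s = max(0, int(rng.integers(0, n - 300)))
    width = int(rng.integers(150, 400))
    rich = []
    while len(rich) < width:
        rich.append("CG" if rng.random() < 0.12 else
                    rng.choice(list("ACGT"), p=[0.22, 0.28, 0.28, 0.22]))
    bases[s:s + width] = list("".join(rich))[: min(width, n - s)]
    return "".join(bases)


class TestFindCgis:
    def test_cg_run_detected_and_stats_verified(self):
        seq = "AT" * 300 + "CG" * 200 + "TA" * 300
        records = mp.find_cgis({"c": seq})
        assert len(records) == 1
        r = records[0]
        assert r.length > 200
        sub = seq[r.start:r.end]
        gc, oe = direct_stats(sub)
        assert gc == pytest.approx(r.gc_fraction)
        assert oe == pytest.approx(r.obs_exp_cpg)
        # the island stays confined to the CG-rich run plus < one window
        assert r.start >= 400 and r.end <= 600 + 400 + 200

    def test_all_at_chromosome_empty(self):
        assert mp.find_cgis({"c": "AT" * 1000}) == []

    def test_obs_exp_ratio_hand_example(self):
        # CGCGCGCG: N_CpG=4, N_C=4, N_G=4 -> oe = 4*8/(4*4) = 2.0
        gc, oe, _ = _region_stats(_seq_cumsums("CGCGCGCG"), 0, 8)
        assert oe == pytest.approx(2.0)
        assert gc == pytest.approx(1.0)

    def test_emitted_islands_reverify_on_fuzz(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            seq = random_cgi_like_seq(rng)
            for r in mp.find_cgis({"c": seq}):
                gc, oe = direct_stats(seq[r.start:r.end])
                assert r.length > 200
                assert gc >= 0.5
                assert oe >= 0.6

    def test_matches_exhaustive_oracle_on_short_sequences(self):
        rng = np.random.default_rng(2)
        for _ in range(12):
            seq = random_cgi_like_seq(rng, n=600)
            got = [(r.start, r.end) for r in mp.find_cgis({"c": seq})]
            assert got == naive_find_cgis(seq)

    def test_matches_oracle_on_two_kb_sequence(self):
        rng = np.random.default_rng(3)
        seq = random_cgi_like_seq(rng, n=2000)
        got = [(r.start, r.end) for r in mp.find_cgis({"c": seq})]
        assert got == naive_find_cgis(seq)

    def test_n_bases_excluded(self):
        assert mp.find_cgis({"c": "N" * 1000}) == []

    def test_planted_cgis_recovered_with_high_jaccard(self):
        """Averaged over 10 seeds, planted islands are recovered with
        interval Jaccard >= 0.9."""
        jacc = []
        for seed in range(10):
            cfg = mp.SimConfig(seed=seed, n_chrom=1, chrom_length=200_000,
                               n_cgi=10, n_genes=10, n_dmr=0)
            genome, truth = mp.generate_genome(cfg)
            detected = [(r.start, r.end) for r in mp.find_cgis(genome)]
            for _, s, e in truth.cgi_intervals:
                best = 0.0
                for ds_, de_ in detected:
                    inter = max(0, min(e, de_) - max(s, ds_))
                    if inter:
                        best = max(best, inter / (max(e, de_) - min(s, ds_)))
                jacc.append(best)
        assert np.mean(jacc) >= 0.9


class TestDefineShores:
    def test_plain_flanks(self):
        shores = mp.define_shores([("chr1", 5000, 6000)],
                                  chrom_lengths={"chr1": 20000})
        assert shores == [("chr1", 3000, 5000), ("chr1", 6000, 8000)]

    def test_clipped_at_chromosome_start(self):
        shores = mp.define_shores([("chr1", 500, 900)],
                                  chrom_lengths={"chr1": 20000})
        assert ("chr1", 0, 500) in shores

    def test_inter_cgi_gap_not_double_counted(self):
        shores = mp.define_shores(
            [("chr1", 5000, 6000), ("chr1", 7000, 8000)],
            chrom_lengths={"chr1": 30000})
        # the 1-kb gap appears once; no shore overlaps an island
        assert ("chr1", 6000, 7000) in shores
        covered = sum(e - s for _, s, e in shores)
        assert covered == 2000 + 1000 + 2000


def make_gene(gene_id="gA", chrom="chr1", start=8000, end=14000, strand="+",
              exons=None, cds=(8200, 13500)):
    exons = exons or [(start, end)]
    return {
        "gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
        "strand": strand,
        "exon_starts": tuple(s for s, _ in exons),
        "exon_ends": tuple(e for _, e in exons),
        "cds_start": cds[0] if cds else None,
        "cds_end": cds[1] if cds else None,
    }


class TestFeatureModel:
    def test_plus_strand_promoter_bins(self):
        gene = make_gene(start=10_000, end=16_000)
        model = mp.build_feature_model(pd.DataFrame([gene]))
        assert mp.annotate_dmr(("chr1", 9850, 9950), model) == "promoter_p1"
        assert mp.annotate_dmr(("chr1", 9000, 9100), model) == "promoter_p2"
        assert mp.annotate_dmr(("chr1", 8100, 8200), model) == "promoter_p3"

    def test_minus_strand_promoter_beyond_tss(self):
        gene = make_gene(start=4000, end=10_000, strand="-",
                         exons=[(4000, 5000), (6000, 10_000)],
                         cds=(4500, 9500))
        model = mp.build_feature_model(pd.DataFrame([gene]))
        assert mp.annotate_dmr(("chr1", 10_050, 10_150), model) == "promoter_p1"
        assert mp.annotate_dmr(("chr1", 11_800, 11_900), model) == "promoter_p3"
        # transcription-order first exon is the genomically rightmost
        assert mp.annotate_dmr(("chr1", 9000, 9100), model) == "first_exon"
        # 5'UTR sits at the high-coordinate end for a minus-strand gene
        assert mp.annotate_dmr(("chr1", 9700, 9900), model) == "utr5"
        assert mp.annotate_dmr(("chr1", 4100, 4300), model) == "utr3"

    def test_single_exon_gene_has_no_introns(self):
        gene = make_gene()
        model = mp.build_feature_model(pd.DataFrame([gene]))
        assert not model._trees["first_intron"]
        assert not model._trees["other_intron"]

    def test_intron_ranks(self):
        gene = make_gene(exons=[(8000, 9000), (10_000, 11_000), (12_000, 14_000)],
                         cds=(8200, 13500))
        model = mp.build_feature_model(pd.DataFrame([gene]))
        assert mp.annotate_dmr(("chr1", 9400, 9500), model) == "first_intron"
        assert mp.annotate_dmr(("chr1", 11_400, 11_500), model) == "other_intron"

    def test_promoter_precedence_over_intron(self):
        gene_a = make_gene("gA", start=10_000, end=16_000)
        gene_b = make_gene("gB", start=2000, end=12_000,
                           exons=[(2000, 3000), (11_000, 12_000)],
                           cds=(2200, 11_800))
        model = mp.build_feature_model(pd.DataFrame([gene_a, gene_b]))
        # midpoint 9900: promoter P1 of gA and intron of gB -> promoter wins
        assert mp.annotate_dmr(("chr1", 9850, 9950), model) == "promoter_p1"

    def test_unknown_chromosome_is_distal_intergenic(self):
        model = mp.build_feature_model(pd.DataFrame([make_gene()]))
        assert mp.annotate_dmr(("chr9", 100, 200), model) == "distal_intergenic"

    def test_rejects_inverted_gene(self):
        bad = make_gene(start=5000, end=5000)
        model = mp.build_feature_model(pd.DataFrame([bad, make_gene("ok")]))
        assert list(model.genes["gene_id"]) == ["ok"]


class TestClosestGene:
    def _genes(self):
        return pd.DataFrame([
            {"gene_id": "gA", "chrom": "chr1", "start": 5000, "end": 8000,
             "strand": "+", "tss": 5000},
            {"gene_id": "gB", "chrom": "chr1", "start": 13_300, "end": 20_000,
             "strand": "+", "tss": 13_300},
        ])

    def test_overlap_gives_zero_distance(self):
        gid, dist = mp.closest_gene(("chr1", 6000, 6100), self._genes())
        assert (gid, dist) == ("gA", 0.0)

    def test_nearer_span_wins(self):
        gid, dist = mp.closest_gene(("chr1", 8200, 8300), self._genes())
        assert gid == "gA"
        assert dist == 200.0

    def test_chromosome_without_genes_unlinked(self):
        gid, dist = mp.closest_gene(("chr7", 0, 100), self._genes())
        assert gid is None and np.isnan(dist)

    def test_fuzz_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(5)
        genes = pd.DataFrame([
            {"gene_id": f"g{i:02d}", "chrom": f"chr{rng.integers(1, 3)}",
             "start": (s := int(rng.integers(0, 90_000))),
             "end": s + int(rng.integers(500, 5000)),
             "strand": "+", "tss": s}
            for i in range(20)
        ])
        for _ in range(200):
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(0, 95_000))
            dmr = (chrom, start, start + 100)
            got = mp.closest_gene(dmr, genes)
            # brute force over all genes with the documented tie-breaks
            best = None
            for g in genes.itertuples():
                if g.chrom != chrom:
                    continue
                dist = max(0, g.start - dmr[2], dmr[1] - g.end)
                tss_dist = abs((dmr[1] + dmr[2]) // 2 - g.tss)
                key = (dist, tss_dist, g.gene_id)
                if best is None or key < best:
                    best = key
            assert got == (best[2], float(best[0]))


class TestFeatureDistribution:
    def test_manual_tally(self):
        cats = pd.Series(["first_exon"] * 3 + ["distal_intergenic"] * 5
                         + ["promoter_p1"] * 2)
        dist = mp.feature_distribution(cats)
        d = dict(zip(dist["category"], dist["count"]))
        assert d["first_exon"] == 3
        assert d["distal_intergenic"] == 5
        assert d["promoter_p1"] == 2
        assert dist["percent"].sum() == pytest.approx(100.0)
        pct = dict(zip(dist["category"], dist["percent"]))
        assert pct["distal_intergenic"] == pytest.approx(50.0)

    def test_single_category(self):
        dist = mp.feature_distribution(pd.Series(["distal_intergenic"] * 4))
        assert dist.loc[dist["category"] == "distal_intergenic",
                        "percent"].iloc[0] == 100.0

    def test_empty_set_all_zero(self):
        dist = mp.feature_distribution(pd.Series([], dtype=str))
        assert (dist["count"] == 0).all()

    def test_annotation_is_total_on_simulated_dmrs(self, dataset, called):
        *_, dmrset = called
        model = mp.build_feature_model(dataset.gene_models)
        cats = mp.annotate_dmrs(dmrset.records, model)
        assert cats.isin(CATEGORIES).all()
        dist = mp.feature_distribution(cats)
        assert dist["count"].sum() == dmrset.n_dmrs
        assert dist["percent"].sum() == pytest.approx(100.0)


class TestExportFasta:
    def test_roundtrip(self, tmp_path):
        genome = {"chr1": "ACGT" * 100}
        records = pd.DataFrame({
            "chrom": ["chr1"], "start": [100], "end": [200],
            "direction": ["hyper"],
        })
        path = tmp_path / "dmrs.fa"
        mp.export_dmr_fasta(records, genome, path)
        from Bio import SeqIO
        recs = list(SeqIO.parse(str(path), "fasta"))
        assert len(recs) == 1
        assert len(recs[0].seq) == 100
        assert str(recs[0].seq) == genome["chr1"][100:200]
        assert recs[0].id == "chr1:100-200|hyper"

    def test_empty_set(self, tmp_path):
        path = tmp_path / "empty.fa"
        mp.export_dmr_fasta(pd.DataFrame(columns=["chrom", "start", "end"]),
                            {"chr1": "ACGT"}, path)
        assert path.read_text() == ""

    def test_out_of_bounds(self, tmp_path):
        records = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [999]})
        with pytest.raises(ValueError):
            mp.export_dmr_fasta(records, {"chr1": "ACGT"}, tmp_path / "x.fa")
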