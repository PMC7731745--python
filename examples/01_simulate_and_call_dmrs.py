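"""Simulate a paired RRBS study and call DMRs with the paired t-test.

Generates a small two-cell-type, three-animal study with 250 planted
differential windows (+/-0.40 methylation), then runs the depth filter,
100-bp window tiling, the paired test with BH adjustment, and the
|delta| >= 3% & q < 0.05 call rule.
"""

import methylpair as mp
from methylpair.pipeline import _truth_confusion

cfg = mp.SimConfig(seed=1)
ds = mp.simulate_dataset(cfg)
print(f"simulated {cfg.n_chrom} chromosomes x {cfg.chrom_length:,} bp; "
      f"{ds.counts.n_sites:,} CpG dyads observable after MspI digestion "
      f"and 225-290 bp size selection")

matrix = mp.filter_sites(ds.counts)          # autosomes, depth > 10 everywhere
table = mp.tile_windows(matrix)              # 100-bp windows, >= 3 CpGs
tested = mp.test_windows(table)              # paired t per window + BH
dmrset = mp.call_dmrs(tested, table)         # |delta| >= 0.03 and q < 0.05

s = dmrset.summary()
print(f"windows tested: {s['n_tested']:,}; DMRs called: {s['n_dmrs']} "
      f"({s['pct_hyper']:.1f}% hyper-, {s['pct_hypo']:.1f}% hypo-methylated "
      f"in myogenic precursors)")

conf = _truth_confusion(tested, dmrset.records, ds.truth)
print(f"against planted truth: sensitivity {conf['sensitivity']:.3f}, "
      f"empirical FDR {conf['empirical_fdr']:.3f}")
print("a sensitivity near 1 and FDR near 0 mean the paired design recovers "
      "the planted 0.40 methylation differences almost perfectly")
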