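"""In-vivo style preprocessing on a synthetic genome and peak sets.

Simulates a genome with annotated TSSs and two overlapping ChIP-Seq peak
sets, then runs the peak pipeline: 50-bp summit windows, strand-aware
promoters (500 bp upstream of the TSS), two-set Venn counts and
promoter-peak classification.
"""

import numpy as np

from nfymatrix import (
    PeakSimConfig,
    classify_promoter_peaks,
    implant_peaks,
    promoter_intervals,
    simulate_genome,
    summit_window,
    venn_counts,
)
from nfymatrix.peaks import GenomicInterval, Peak, PeakSet
from nfymatrix.synthetic_reference import synthetic_ccaat_pwm

config = PeakSimConfig(genome_length=400_000, n_genes=200, n_peaks=120, seed=5)
genome, annotations = simulate_genome(config)
genome, set_a, truth = implant_peaks(genome, synthetic_ccaat_pwm(), config,
                                     label="repA")

# a second replicate re-detects 70% of the peaks with some summit drift
rng = np.random.default_rng(6)
peaks_b = []
for p in set_a.peaks:
    if rng.random() < 0.7:
        shift = int(rng.integers(-30, 31))
        iv = p.interval
        start = max(0, iv.start + shift)
        peaks_b.append(Peak(GenomicInterval(iv.chrom, start, start + iv.length),
                            summit_offset=p.summit_offset, name=p.name + "B"))
set_b = PeakSet(label="repB", peaks=peaks_b)

windows = [summit_window(p) for p in set_a.peaks]
print(f"{len(set_a)} peaks -> {len(windows)} summit windows of "
      f"{windows[0].length} bp")

counts = venn_counts(set_a, set_b)
print(f"Venn: only A {counts.only_a}, shared (A side) {counts.shared_a}, "
      f"shared (B side) {counts.shared_b}, only B {counts.only_b}")

promoters = promoter_intervals(annotations, upstream=500)
in_promoters = classify_promoter_peaks(set_a, promoters)
print(f"{len(in_promoters)}/{len(set_a)} peaks overlap a promoter "
      f"({100 * len(in_promoters) / len(set_a):.0f}%)")

# Shared counts are reported per set because peak overlap is many-to-many;
# the promoter fraction reflects how much of the genome the 500-bp
# upstream windows of the simulated genes cover.
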