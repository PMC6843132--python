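"""Synthetic data with the statistical structure the analysis assumes.

Two generators are provided:

* competition EMSA gels — dose curves with known true relative affinities,
  Gaussian densitometry noise on percent bound, and lane intensities with a
  random per-lane scale factor;
* genomes with annotated TSSs and narrowPeak peak sets in which a stated
  fraction of summit windows carries a motif sampled from a PWM.

The default binding model is an off-rate *exchange* model: during the
competition incubation a fraction kappa of the preformed complexes
re-equilibrate, and the competitor captures a share proportional to its
relative affinity a times its mole fraction x = r/(1+r) (r = competitor /
probe fold ratio), so the noiseless percent bound is
``100 * beta * (1 - a * kappa * x)`` clipped to [0, 100].  Inside the
operating range (a * kappa * x <= 1) percent bound is affine in a, which
makes the slope/WT statistic exactly proportional to the true relative
affinity — the property the quantification procedure relies on.  A
saturating equilibrium-partition alternative
(``100 * beta * (1-x) / ((1-x) + a*x)``) is available as
``model="partition"``.

All generators are bit-reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .emsa import DoseCurve, DosePoint
from .matrix import BASES, PWM, AffinityTable
from .oligos import CAB2_PROBE, Oligo
from .peaks import Annotation, GenomicInterval, Peak, PeakSet
from .scan import reverse_complement

__all__ = [
    "EmsaSimConfig",
    "PeakSimConfig",
    "expected_percent_bound",
    "simulate_competition_curve",
    "simulate_saturation_experiment",
    "simulate_genome",
    "implant_peaks",
    "sample_pwm_site",
    "write_fasta",
    "write_gff3",
    "write_narrowpeak",
]


@dataclass(frozen=True)
class EmsaSimConfig:
    """Conditions of a simulated competition EMSA series.

    ``ratios`` are competitor/probe fold ratios and must include the
    no-competitor reference 0; ``beta`` is the bound fraction of probe in
    the reference lane; ``exchange_fraction`` (kappa) is the fraction of
    complexes that re-equilibrate during the competitor incubation;
    ``noise_sd`` is Gaussian noise in percent-bound units.
    """

    probe_conc: float = 20.0          # nM, the labeled-probe concentration
    ratios: tuple[float, ...] = (0.0, 1.0, 5.0)
    beta: float = 0.6
    exchange_fraction: float = 0.5
    noise_sd: float = 0.0
    replicates: int = 1
    seed: int = 0
    model: str = "exchange"           # "exchange" | "partition"

    def __post_init__(self) -> None:
        if 0.0 not in self.ratios:
            raise ValueError("dose ratios must include the no-competitor 0")
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.model not in ("exchange", "partition"):
            raise ValueError(f"unknown binding model {self.model!r}")


def expected_percent_bound(
    affinity: float, x: float, beta: float = 0.6, model: str = "exchange"
) -> float:
    """Noiseless percent bound at effective competitor exposure ``x``.

    ``x`` is the competitor's effective mole fraction in [0, 1).  The
    exchange model is affine in affinity and clipped to [0, 100]; the
    partition model is the saturating two-species equilibrium split.
    """
    if affinity < 0:
        raise ValueError("relative affinity must be >= 0")
    if not 0.0 <= x < 1.0:
        raise ValueError("competitor fraction x must lie in [0, 1)")
    if model == "exchange":
        return float(np.clip(100.0 * beta * (1.0 - affinity * x), 0.0, 100.0))
    if model == "partition":
        return 100.0 * beta * (1.0 - x) / ((1.0 - x) + affinity * x)
    raise ValueError(f"unknown binding model {model!r}")


def _effective_x(ratio: float, config: EmsaSimConfig) -> float:
    x = ratio / (1.0 + ratio)
    if config.model == "exchange":
        x *= config.exchange_fraction
    return x


def simulate_competition_curve(
    affinity: float,
    config: EmsaSimConfig,
    rng: np.random.Generator | None = None,
    oligo_id: str = "oligo",
) -> tuple[DoseCurve, list[tuple[float, float, float]]]:
    """One noisy dose curve plus its emitted lane intensities.

    Returns ``(curve, lanes)`` where lanes holds (ratio, bound, free)
    tuples; lane intensities are the percent split scaled by a random
    per-lane total factor, so downstream percent-bound computation must be
    scale invariant.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    points = []
    lanes = []
    for ratio in config.ratios:
        percent = expected_percent_bound(
            affinity, _effective_x(ratio, config), config.beta, config.model
        )
        if config.noise_sd > 0:
            percent += rng.normal(0.0, config.noise_sd)
        percent = float(np.clip(percent, 0.0, 100.0))
        total = float(rng.uniform(0.5, 2.0)) if config.noise_sd > 0 else 1.0
        points.append(DosePoint(ratio=float(ratio), percent_bound=percent))
        lanes.append((float(ratio), percent * total, (100.0 - percent) * total))
    return DoseCurve(oligo_id=oligo_id, points=tuple(points)), lanes


def _mutant_oligo(wt: Oligo, position: int, base: str) -> Oligo:
    seq_pos = wt.position_of(position)  # 1-based
    seq = wt.sequence[: seq_pos - 1] + base + wt.sequence[seq_pos:]
    return Oligo(
        id=f"N{position}{base}",
        sequence=seq,
        role="competitor",
        numbering_offset=wt.numbering_offset,
    )


def simulate_saturation_experiment(
    truth: AffinityTable,
    config: EmsaSimConfig,
    wt_oligo: Oligo | None = None,
) -> tuple[pd.DataFrame, dict[str, Oligo], dict[str, tuple[int, str]], pd.DataFrame]:
    """Simulate a full saturation-mutagenesis competition series.

    One WT dose curve and one curve per measured (position, mutant base)
    cell of the truth table, per replicate.  Returns ``(lanes, oligos,
    mutant_annotations, truth_table)`` in exactly the shapes the
    quantification layer consumes; the truth table records each oligo's
    true relative affinity.
    """
    if wt_oligo is None:
        wt_oligo = Oligo.from_ccaat_anchor("CAB2", CAB2_PROBE, role="probe")
    rng = np.random.default_rng(config.seed)
    mutants: list[tuple[str, int, str, float]] = []
    for pos in truth.positions:
        wt_base = truth.wt_context[pos]
        for base in BASES:
            if base == wt_base:
                continue
            a = truth.affinity(pos, base)
            if a is None:
                continue
            mutants.append((f"N{pos}{base}", pos, base, float(a)))
    oligos = {wt_oligo.id: wt_oligo}
    annotations: dict[str, tuple[int, str]] = {}
    for oligo_id, pos, base, _a in mutants:
        oligos[oligo_id] = _mutant_oligo(wt_oligo, pos, base)
        annotations[oligo_id] = (pos, base)
    rows = []
    for rep in range(1, config.replicates + 1):
        series = [(wt_oligo.id, 1.0)] + [(oid, a) for oid, _p, _b, a in mutants]
        for oligo_id, affinity in series:
            _curve, lanes = simulate_competition_curve(
                affinity, config, rng=rng, oligo_id=oligo_id
            )
            for ratio, bound, free in lanes:
                rows.append(
                    {
                        "experiment_id": "saturation",
                        "replicate": rep,
                        "oligo_id": oligo_id,
                        "ratio": ratio,
                        "bound": bound,
                        "free": free,
                    }
                )
    truth_rows = [{"oligo_id": wt_oligo.id, "position": pd.NA, "base": pd.NA,
                   "true_affinity": 1.0}]
    truth_rows += [
        {"oligo_id": oid, "position": pos, "base": base, "true_affinity": a}
        for oid, pos, base, a in mutants
    ]
    return (
        pd.DataFrame(rows),
        oligos,
        annotations,
        pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# genomes and peak sets


@dataclass(frozen=True)
class PeakSimConfig:
    """Conditions of a simulated genome + ChIP-Seq peak set."""

    genome_length: int = 200_000
    gc: float = 0.36               # A. thaliana-like genomic GC
    n_genes: int = 100
    n_peaks: int = 60
    motif_fraction: float = 0.6
    summit_jitter_sd: float = 5.0
    peak_width: int = 200
    min_gene_spacing: int = 400
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.motif_fraction <= 1.0:
            raise ValueError("motif_fraction must lie in [0, 1]")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must lie in (0, 1)")


def simulate_genome(
    config: PeakSimConfig,
) -> tuple[dict[str, str], list[Annotation]]:
    """I.i.d. genome at the stated GC plus uniformly spaced gene TSSs."""
    rng = np.random.default_rng(config.seed)
    p = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2,
                  (1 - config.gc) / 2])
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, config.genome_length, p=p)])
    genome = {config.chrom: seq}
    annotations: list[Annotation] = []
    if config.n_genes > 0:
        s = config.min_gene_spacing
        slack = config.genome_length - config.n_genes * s
        if slack <= 0:
            raise ValueError("gene spacing infeasible for this genome length")
        offsets = np.sort(rng.integers(0, slack, config.n_genes))
        positions = offsets + s * np.arange(config.n_genes)
        strands = rng.choice(["+", "-"], config.n_genes)
        for i, (pos, strand) in enumerate(zip(positions, strands)):
            annotations.append(
                Annotation(gene_id=f"gene{i + 1:04d}", chrom=config.chrom,
                           strand=str(strand), tss=int(pos))
            )
    return genome, annotations


def sample_pwm_site(pwm: PWM, rng: np.random.Generator) -> str:
    """Draw one site from the per-position base probabilities of a PWM."""
    return "".join(BASES[rng.choice(4, p=row)] for row in pwm.matrix)


def implant_peaks(
    genome: dict[str, str],
    pwm: PWM,
    config: PeakSimConfig,
    label: str = "sim",
) -> tuple[dict[str, str], PeakSet, pd.DataFrame]:
    """Place peaks on the genome, implanting PWM sites in a stated fraction.

    Summits are sampled without overlap (minimum separation one peak
    width); for ``round(motif_fraction * n_peaks)`` randomly chosen peaks a
    PWM-sampled site is written into the genome centered at the summit
    plus Gaussian jitter, on a random strand.  Returns the modified genome,
    the narrowPeak-shaped peak set, and a truth table with per-peak
    motif-present flags and implant offsets.
    """
    if pwm.width > config.peak_width:
        raise ValueError("PWM wider than the peak width")
    if config.n_peaks * config.peak_width * 4 > config.genome_length:
        raise ValueError("peaks would tile too much of the genome; "
                         "increase genome_length or reduce n_peaks")
    rng = np.random.default_rng(config.seed + 1)
    chrom = config.chrom
    seq = list(genome[chrom])
    length = len(seq)
    half = config.peak_width // 2
    summits: list[int] = []
    tries = 0
    while len(summits) < config.n_peaks:
        tries += 1
        if tries > 1000 * config.n_peaks:
            raise RuntimeError("peak placement collision; genome too crowded")
        cand = int(rng.integers(half + 50, length - half - 50))
        if all(abs(cand - s) >= config.peak_width for s in summits):
            summits.append(cand)
    summits.sort()
    n_implant = int(round(config.motif_fraction * config.n_peaks))
    implant_idx = set(rng.choice(config.n_peaks, size=n_implant, replace=False).tolist())
    peaks: list[Peak] = []
    truth_rows = []
    for i, summit in enumerate(summits):
        has_motif = i in implant_idx
        implant_start = -1
        strand = "."
        if has_motif:
            site = sample_pwm_site(pwm, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                site = reverse_complement(site)
            jitter = (
                int(round(rng.normal(0.0, config.summit_jitter_sd)))
                if config.summit_jitter_sd > 0
                else 0
            )
            implant_start = summit - pwm.width // 2 + jitter
            implant_start = max(0, min(length - pwm.width, implant_start))
            seq[implant_start: implant_start + pwm.width] = list(site)
        interval = GenomicInterval(chrom, summit - half, summit + half, ".")
        peaks.append(
            Peak(
                interval=interval,
                summit_offset=half,
                score=float(rng.integers(100, 1000)),
                name=f"{label}_peak{i + 1:04d}",
            )
        )
        truth_rows.append(
            {
                "name": f"{label}_peak{i + 1:04d}",
                "summit": summit,
                "motif_present": has_motif,
                "implant_start": implant_start,
                "implant_strand": strand,
            }
        )
    new_genome = dict(genome)
    new_genome[chrom] = "".join(seq)
    return new_genome, PeakSet(label=label, peaks=peaks), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# file emission (exactly the formats the analysis layer consumes)


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def write_gff3(
    annotations: Sequence[Annotation], path, chrom_sizes: dict[str, int],
    gene_length: int = 200,
) -> None:
    """Emit gene features whose strand-aware 5' end is the stored TSS."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, size in chrom_sizes.items():
            fh.write(f"##sequence-region {chrom} 1 {size}\n")
        for ann in annotations:
            size = chrom_sizes[ann.chrom]
            if ann.strand == "+":
                start1 = ann.tss + 1
                end1 = min(size, ann.tss + gene_length)
            else:
                end1 = ann.tss + 1
                start1 = max(1, end1 - gene_length + 1)
            fh.write(
                f"{ann.chrom}\tsim\tgene\t{start1}\t{end1}\t.\t{ann.strand}\t.\t"
                f"ID={ann.gene_id}\n"
            )


def write_narrowpeak(peak_set: PeakSet, path) -> None:
    with open(path, "w") as fh:
        for p in peak_set.peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t{int(p.score)}\t"
                f"{iv.strand}\t{p.score:.2f}\t-1\t-1\t{p.summit_offset}\n"
            )
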