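"""End-to-end benchmark experiments on synthetic data.

These drive the full pipeline — generator, quantification, matrix building,
scanning, enrichment — under fixed study conditions and report summary
statistics: affinity-recovery quality, enrichment power at the in-vivo
significance bar (p < 1e-30), and null calibration of the hypergeometric
test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .emsa import quantify_lanes
from .enrich import enrich, make_background
from .matrix import PWM, affinity_to_pwm, build_affinity_table
from .peaks import summit_window
from .scan import log_odds, relative_threshold
from .simulate import (
    EmsaSimConfig,
    PeakSimConfig,
    implant_peaks,
    simulate_genome,
    simulate_saturation_experiment,
)
from .synthetic_reference import cab2_wt_oligo

__all__ = [
    "RecoveryResult",
    "recovery_benchmark",
    "power_benchmark",
    "null_calibration",
]

#: in-vivo significance bar on log10 p
LOG10_ALPHA = -30.0


@dataclass(frozen=True)
class RecoveryResult:
    spearman_by_seed: tuple[float, ...]
    noiseless_max_abs_error: float
    n_oligos: int

    @property
    def mean_spearman(self) -> float:
        return float(np.mean(self.spearman_by_seed))


def _affinity_grid_table(affinities):
    from .matrix import AffinityTable
    from .oligos import base_at

    wt = cab2_wt_oligo()
    positions = tuple(range(5, 5 + len(affinities)))
    wt_ctx = {p: base_at(wt, p) for p in positions}
    cells = {}
    for pos, a in zip(positions, affinities):
        base = next(b for b in "ACGT" if b != wt_ctx[pos])
        cells[(pos, base)] = float(a)
    return AffinityTable(positions=positions, wt_context=wt_ctx, cells=cells)


def recovery_benchmark(
    n_seeds: int = 20,
    noise_sd: float = 3.0,
    replicates: int = 3,
    affinities=None,
    seed0: int = 0,
) -> RecoveryResult:
    """Truth-vs-estimate agreement of the saturation-mutagenesis pipeline.

    Simulates a 12-oligo saturation experiment with true relative
    affinities spanning 0.2-2.0, runs the quantification (dose regression,
    slope/WT, replicate averaging) and reports the per-seed Spearman rank
    correlation between truth and estimate, plus the worst-case absolute
    error of a noiseless single-replicate run.
    """
    if affinities is None:
        affinities = np.linspace(0.2, 2.0, 12)
    truth = _affinity_grid_table(affinities)

    def estimates(config):
        lanes, _oligos, _ann, truth_df = simulate_saturation_experiment(
            truth, config
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = {r.oligo_id: r.efficiency for r in quantify_lanes(lanes, "CAB2")}
        rows = truth_df[truth_df.oligo_id != "CAB2"]
        return (
            rows.true_affinity.to_numpy(dtype=float),
            np.array([results[o] for o in rows.oligo_id]),
        )

    true0, est0 = estimates(EmsaSimConfig(noise_sd=0.0, replicates=1, seed=seed0))
    noiseless_err = float(np.abs(true0 - est0).max())
    rhos = []
    for seed in range(seed0, seed0 + n_seeds):
        tr, est = estimates(
            EmsaSimConfig(noise_sd=noise_sd, replicates=replicates, seed=seed)
        )
        rhos.append(float(spearmanr(tr, est).statistic))
    return RecoveryResult(
        spearman_by_seed=tuple(rhos),
        noiseless_max_abs_error=noiseless_err,
        n_oligos=len(affinities),
    )


def power_benchmark(
    pwm: PWM,
    seeds,
    n_windows: int = 500,
    implant_fraction: float = 0.6,
    threshold_fraction: float = 0.9,
) -> list[float]:
    """log10 enrichment p-values of implanted summit windows, per seed.

    For each seed: simulate a genome, implant PWM-sampled sites into the
    stated fraction of peaks, take the 50-bp summit windows, build a
    dinucleotide-shuffled background (one shuffle per window) and run the
    ZOOPS hypergeometric enrichment.
    """
    sm = log_odds(pwm)
    threshold = relative_threshold(sm, threshold_fraction)
    logs = []
    for seed in seeds:
        config = PeakSimConfig(
            genome_length=max(500_000, n_windows * 200 * 4),
            n_genes=0,
            n_peaks=n_windows,
            motif_fraction=implant_fraction,
            seed=int(seed),
        )
        genome, _ = simulate_genome(config)
        genome, peak_set, _truth = implant_peaks(genome, pwm, config)
        seq = genome[config.chrom]
        windows = [
            seq[w.start: w.end]
            for w in (summit_window(p) for p in peak_set.peaks)
        ]
        background = make_background(windows, "dinuc-shuffle", seed=int(seed))
        result = enrich(sm, windows, background, threshold)
        logs.append(result.log10_p)
    return logs


def null_calibration(
    pwm: PWM,
    n_sims: int = 1000,
    n_target: int = 100,
    n_bg: int = 100,
    alpha: float = 0.05,
    threshold_fraction: float = 0.9,
    gc: float = 0.36,
    seed0: int = 0,
) -> float:
    """Rejection rate of the enrichment test when no motif is implanted.

    Both target and background sets are motif-free random sequences of the
    stated composition; returns the fraction of simulations with
    p <= alpha (the test is discrete, hence conservative: the rate should
    sit at or below alpha).
    """
    sm = log_odds(pwm)
    threshold = relative_threshold(sm, threshold_fraction)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    fires = 0
    for i in range(n_sims):
        rng = np.random.default_rng(seed0 + 100_000 + i)
        targets = ["".join(alphabet[rng.choice(4, 50, p=p)]) for _ in range(n_target)]
        bg = ["".join(alphabet[rng.choice(4, 50, p=p)]) for _ in range(n_bg)]
        fires += enrich(sm, targets, bg, threshold).p_value <= alpha
    return fires / n_sims
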