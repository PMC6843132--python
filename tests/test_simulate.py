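import warnings

import numpy as np
import pytest

from nfymatrix.emsa import quantify_lanes
from nfymatrix.peaks import extract_sequences, summit_window
from nfymatrix.scan import best_hit, log_odds
from nfymatrix.simulate import (
    EmsaSimConfig,
    PeakSimConfig,
    expected_percent_bound,
    implant_peaks,
    sample_pwm_site,
    simulate_competition_curve,
    simulate_genome,
    simulate_saturation_experiment,
    write_fasta,
    write_gff3,
    write_narrowpeak,
)

from conftest import make_affinity_grid


class TestBindingModel:
    def test_equal_affinity_halves_exchangeable_binding(self):
        # a=1, x=0.5, beta=0.6: competitor takes half the exchanging complexes
        assert expected_percent_bound(1.0, 0.5, 0.6) == pytest.approx(30.0)

    def test_non_competitor_leaves_binding_at_beta(self):
        for x in (0.1, 0.5, 0.9):
            assert expected_percent_bound(0.0, x, 0.6) == pytest.approx(60.0)

    def test_infinitely_strong_competitor_strips_probe(self):
        assert expected_percent_bound(1e9, 0.5, 0.6) == 0.0
        assert expected_percent_bound(1e9, 0.5, 0.6, model="partition") == pytest.approx(
            0.0, abs=1e-6
        )

    def test_partition_model_matches_closed_form(self):
        a, x, beta = 2.0, 0.4, 0.6
        expected = 100 * beta * (1 - x) / ((1 - x) + a * x)
        assert expected_percent_bound(a, x, beta, model="partition") == pytest.approx(
            expected
        )


class TestCompetitionCurves:
    def test_noiseless_curve_is_deterministic_and_clean(self):
        config = EmsaSimConfig(noise_sd=0.0, seed=1)
        c1, lanes1 = simulate_competition_curve(1.0, config)
        c2, lanes2 = simulate_competition_curve(1.0, config)
        assert c1 == c2 and lanes1 == lanes2
        assert c1.points[0].percent_bound == pytest.approx(60.0)

    def test_noise_changes_with_seed(self):
        c1, _ = simulate_competition_curve(1.0, EmsaSimConfig(noise_sd=3.0, seed=1))
        c2, _ = simulate_competition_curve(1.0, EmsaSimConfig(noise_sd=3.0, seed=2))
        assert c1.points != c2.points

    def test_ratio_zero_required(self):
        with pytest.raises(ValueError):
            EmsaSimConfig(ratios=(1.0, 5.0))


class TestSaturationExperiment:
    def test_all_wt_truth_recovers_unity(self, wt_oligo):
        truth = make_affinity_grid(wt_oligo, [1.0, 1.0, 1.0])
        lanes, _, _, _ = simulate_saturation_experiment(
            truth, EmsaSimConfig(noise_sd=0.0, replicates=1, seed=0)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = quantify_lanes(lanes, "CAB2")
        assert all(abs(r.efficiency - 1.0) < 1e-9 for r in results)

    def test_noiseless_recovery_of_strong_binder(self, wt_oligo):
        # a 2.0-affinity mutant at N7 must be estimated at 2.0 exactly
        truth = make_affinity_grid(wt_oligo, [2.0], positions=(7,))
        lanes, _, _, _ = simulate_saturation_experiment(
            truth, EmsaSimConfig(noise_sd=0.0, replicates=1, seed=0)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = {r.oligo_id: r for r in quantify_lanes(lanes, "CAB2")}
        mutant = next(r for oid, r in results.items() if oid != "CAB2")
        assert mutant.efficiency == pytest.approx(2.0, abs=1e-6)

    def test_replicates_populate_sd_column(self, wt_oligo):
        truth = make_affinity_grid(wt_oligo, [0.5])
        lanes, _, _, _ = simulate_saturation_experiment(
            truth, EmsaSimConfig(noise_sd=3.0, replicates=3, seed=0)
        )
        results = {r.oligo_id: r for r in quantify_lanes(lanes, "CAB2")}
        mutant = next(r for oid, r in results.items() if oid != "CAB2")
        assert mutant.n_replicates == 3
        assert mutant.sd > 0

    def test_mutant_oligos_carry_the_annotated_change(self, wt_oligo):
        truth = make_affinity_grid(wt_oligo, [0.5, 1.5], positions=(8, 13))
        _, oligos, annotations, _ = simulate_saturation_experiment(
            truth, EmsaSimConfig(seed=0)
        )
        for oligo_id, (pos, base) in annotations.items():
            oligo = oligos[oligo_id]
            assert oligo.sequence[oligo.position_of(pos) - 1] == base
            diffs = sum(
                a != b for a, b in zip(oligo.sequence, wt_oligo.sequence)
            )
            assert diffs == 1


class TestGenomeSimulation:
    def test_gc_content_concentrates_at_target(self):
        genome, _ = simulate_genome(
            PeakSimConfig(genome_length=100_000, gc=0.5, n_genes=0, seed=0)
        )
        seq = genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.49 <= gc <= 0.51

    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        config = PeakSimConfig(genome_length=20_000, n_genes=10, seed=7)
        for name in ("a.fa", "b.fa"):
            genome, _ = simulate_genome(config)
            write_fasta(genome, tmp_path / name)
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_different_seed_changes_genome(self):
        g1, _ = simulate_genome(PeakSimConfig(genome_length=5_000, n_genes=0, seed=1))
        g2, _ = simulate_genome(PeakSimConfig(genome_length=5_000, n_genes=0, seed=2))
        assert g1 != g2

    def test_no_genes_gives_empty_annotation(self, tmp_path):
        genome, annotations = simulate_genome(
            PeakSimConfig(genome_length=10_000, n_genes=0, seed=0)
        )
        assert annotations == []
        write_gff3(annotations, tmp_path / "empty.gff3", {"chr1": 10_000})
        body = [
            line
            for line in (tmp_path / "empty.gff3").read_text().splitlines()
            if not line.startswith("#")
        ]
        assert body == []

    def test_gene_spacing_enforced(self):
        genome, annotations = simulate_genome(
            PeakSimConfig(genome_length=100_000, n_genes=50, seed=3)
        )
        positions = sorted(a.tss for a in annotations)
        spacing = min(b - a for a, b in zip(positions, positions[1:]))
        assert spacing >= PeakSimConfig().min_gene_spacing

    def test_infeasible_spacing_rejected(self):
        with pytest.raises(ValueError):
            simulate_genome(
                PeakSimConfig(genome_length=20_000, n_genes=60,
                              n_peaks=1, seed=0)
            )


class TestImplantPeaks:
    def test_full_fraction_no_jitter_marks_every_window(self, ccaat_point_pwm):
        config = PeakSimConfig(
            genome_length=100_000, n_genes=0, n_peaks=40,
            motif_fraction=1.0, summit_jitter_sd=0.0, seed=5,
        )
        genome, _ = simulate_genome(config)
        genome, peak_set, truth = implant_peaks(genome, ccaat_point_pwm, config)
        assert truth.motif_present.all()
        seq = genome["chr1"]
        sm = log_odds(ccaat_point_pwm)
        for p in peak_set.peaks:
            window = summit_window(p)
            window_seq = seq[window.start: window.end]
            hit = best_hit(sm, window_seq)
            assert hit.score == pytest.approx(sm.max_score)

    def test_truth_flags_agree_with_scanner(self, plant_pwm):
        # fraction 1, zero jitter: scanner detections at the implant offset
        # must agree 100% with the truth table
        config = PeakSimConfig(
            genome_length=120_000, n_genes=0, n_peaks=50,
            motif_fraction=1.0, summit_jitter_sd=0.0, seed=11,
        )
        genome, _ = simulate_genome(config)
        genome, peak_set, truth = implant_peaks(genome, plant_pwm, config)
        seq = genome["chr1"]
        for row, p in zip(truth.itertuples(index=False), peak_set.peaks):
            implanted = seq[row.implant_start: row.implant_start + plant_pwm.width]
            site = implanted
            if row.implant_strand == "-":
                from nfymatrix.scan import reverse_complement

                site = reverse_complement(implanted)
            # the written site is drawable from the matrix (no zero-probability base)
            probs = [
                plant_pwm.matrix[j]["ACGT".index(b)] for j, b in enumerate(site)
            ]
            assert min(probs) > 0

    def test_zero_fraction_background_rate_matches_expectation(self, ccaat_point_pwm):
        config = PeakSimConfig(
            genome_length=400_000, gc=0.5, n_genes=0, n_peaks=200,
            motif_fraction=0.0, seed=13,
        )
        genome, _ = simulate_genome(config)
        genome, peak_set, truth = implant_peaks(genome, ccaat_point_pwm, config)
        assert not truth.motif_present.any()
        sm = log_odds(ccaat_point_pwm)
        seq = genome["chr1"]
        hits = 0
        for p in peak_set.peaks:
            w = summit_window(p)
            if best_hit(sm, seq[w.start: w.end]).score >= sm.max_score:
                hits += 1
        # exact-CCAAT chance per 50-bp window at GC 0.5:
        # ~ 1 - (1 - 4^-5)^(2*46) ~ 8.6%; allow 4 binomial sds
        p_window = 1 - (1 - 0.25 ** 5) ** (2 * 46)
        sd = np.sqrt(p_window * (1 - p_window) / len(peak_set))
        assert abs(hits / len(peak_set) - p_window) < 4 * sd

    def test_narrowpeak_bytes_reproducible(self, tmp_path, ccaat_point_pwm):
        config = PeakSimConfig(genome_length=50_000, n_genes=0, n_peaks=10, seed=2)
        for name in ("a.np", "b.np"):
            genome, _ = simulate_genome(config)
            _, peak_set, _ = implant_peaks(genome, ccaat_point_pwm, config)
            write_narrowpeak(peak_set, tmp_path / name)
        assert (tmp_path / "a.np").read_bytes() == (tmp_path / "b.np").read_bytes()

    def test_emitted_files_round_trip_through_readers(self, tmp_path, plant_pwm):
        from nfymatrix.peaks import read_gff3_tss, read_narrowpeak

        config = PeakSimConfig(genome_length=60_000, n_genes=20, n_peaks=12, seed=4)
        genome, annotations = simulate_genome(config)
        genome, peak_set, _ = implant_peaks(genome, plant_pwm, config)
        write_fasta(genome, tmp_path / "g.fa")
        write_gff3(annotations, tmp_path / "g.gff3", {"chr1": 60_000})
        write_narrowpeak(peak_set, tmp_path / "g.narrowPeak")
        ps = read_narrowpeak(tmp_path / "g.narrowPeak")
        assert len(ps) == 12 and ps.n_malformed == 0
        tss = read_gff3_tss(tmp_path / "g.gff3")
        assert {a.gene_id for a in tss} == {a.gene_id for a in annotations}
        assert {a.tss for a in tss} == {a.tss for a in annotations}
        windows = [summit_window(p) for p in ps.peaks]
        seqs = extract_sequences(windows, tmp_path / "g.fa")
        assert len(seqs) == 12 and all(len(s) == 50 for _n, s in seqs)

    def test_pwm_wider_than_peak_rejected(self, plant_pwm):
        config = PeakSimConfig(peak_width=10, n_peaks=2, genome_length=10_000,
                               n_genes=0, seed=0)
        genome, _ = simulate_genome(config)
        with pytest.raises(ValueError):
            implant_peaks(genome, plant_pwm, config)
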