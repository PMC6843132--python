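import warnings

import numpy as np
import pytest

from nfymatrix.emsa import CompetitionResult, quantify_lanes
from nfymatrix.matrix import (
    PWM,
    AffinityTable,
    AnnotationConflictError,
    affinity_to_pwm,
    build_affinity_table,
    compare_pwms,
    information_content,
    pwm_to_logo,
    read_jaspar,
    relative_label,
    write_jaspar,
)
from nfymatrix.simulate import EmsaSimConfig, simulate_saturation_experiment

from conftest import make_affinity_grid


def res(oligo_id, eff, n=3):
    return CompetitionResult(oligo_id=oligo_id, slope=-1.0, efficiency=eff,
                             n_replicates=n, sd=0.0)


class TestBuildAffinityTable:
    def test_wt_only_input_gives_wt_cells_only(self, wt_oligo):
        table = build_affinity_table([], wt_oligo, {})
        for pos in table.positions:
            wt = table.wt_context[pos]
            assert table.affinity(pos, wt) == 1.0
            assert table.measured_bases(pos) == [wt]

    def test_single_mutant_fills_its_cell(self, wt_oligo):
        table = build_affinity_table(
            [res("C8A", 0.1)], wt_oligo, {"C8A": (8, "A")}
        )
        assert table.affinity(8, "A") == pytest.approx(0.1)

    def test_negative_efficiency_clamped_with_warning(self, wt_oligo):
        with pytest.warns(UserWarning):
            table = build_affinity_table(
                [res("N5G", -0.02)], wt_oligo, {"N5G": (5, "G")}
            )
        assert table.affinity(5, "G") == 0.0

    def test_conflicting_annotations_rejected(self, wt_oligo):
        with pytest.raises(AnnotationConflictError):
            build_affinity_table(
                [res("a", 0.1), res("b", 0.2)],
                wt_oligo,
                {"a": (8, "A"), "b": (8, "A")},
            )


class TestAffinityToPwm:
    def make_table(self, cells, wt="A"):
        return AffinityTable(positions=(5,), wt_context={5: wt},
                             cells={(5, b): v for b, v in cells.items()})

    def test_symmetric_affinities_give_uniform_column(self):
        table = self.make_table({"A": 1, "C": 1, "G": 1, "T": 1})
        pwm = affinity_to_pwm(table)
        assert np.allclose(pwm.matrix[0], 0.25)

    def test_epsilon_floored_normalization(self):
        table = self.make_table({"A": 1.0, "C": 0.0, "G": 0.0, "T": 0.0})
        pwm = affinity_to_pwm(table, epsilon=0.01)
        assert np.allclose(pwm.matrix[0], [1 / 1.03, 0.01 / 1.03, 0.01 / 1.03,
                                           0.01 / 1.03])

    def test_plain_normalization(self):
        table = self.make_table({"A": 2, "T": 2, "C": 0.5, "G": 0.5})
        pwm = affinity_to_pwm(table, epsilon=1e-9)
        assert np.allclose(pwm.matrix[0], [0.4, 0.1, 0.1, 0.4])

    def test_rescaling_affinities_leaves_pwm_unchanged(self):
        base = {"A": 1.0, "C": 0.4, "G": 0.7, "T": 0.05}
        p1 = affinity_to_pwm(self.make_table(base), epsilon=1e-12)
        scaled = {b: 3.7 * v for b, v in base.items()}
        p2 = affinity_to_pwm(self.make_table(scaled), epsilon=1e-12)
        assert np.allclose(p1.matrix, p2.matrix)

    def test_missing_policy_floor_vs_wt_share(self, wt_oligo):
        table = build_affinity_table([res("C8A", 0.1)], wt_oligo, {"C8A": (8, "A")})
        floor = affinity_to_pwm(table, missing_policy="floor")
        share = affinity_to_pwm(table, missing_policy="wt-share")
        i = floor.crystal_positions.index(8)
        # untested G/T negligible under floor, as strong as WT under wt-share
        assert floor.matrix[i, 2] < 0.02
        assert share.matrix[i, 2] == pytest.approx(share.matrix[i, 1])

    def test_drop_position_removes_unmeasured_columns(self, wt_oligo):
        table = build_affinity_table([res("C8A", 0.1)], wt_oligo, {"C8A": (8, "A")})
        with pytest.warns(UserWarning):
            pwm = affinity_to_pwm(table, missing_policy="drop-position")
        assert pwm.crystal_positions == (8,)

    def test_columns_always_normalized(self, plant_pwm):
        assert np.allclose(plant_pwm.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(plant_pwm.matrix >= 0)


class TestInformationContent:
    @pytest.mark.parametrize(
        "column, bits",
        [
            ((0.25, 0.25, 0.25, 0.25), 0.0),
            ((1, 0, 0, 0), 2.0),
            ((0.5, 0.5, 0, 0), 1.0),
        ],
    )
    def test_schneider_entropy(self, column, bits):
        assert information_content(column) == pytest.approx(bits, abs=1e-12)

    def test_logo_heights_scale_probabilities_by_ic(self):
        pwm = PWM(matrix=np.array([[0.5, 0.5, 0, 0], [1, 0, 0, 0],
                                   [0.25, 0.25, 0.25, 0.25]]),
                  crystal_positions=(8, 9, 10))
        cols = pwm_to_logo(pwm)
        assert cols[0].letter_heights["A"] == pytest.approx(0.5)
        assert cols[0].letter_heights["C"] == pytest.approx(0.5)
        assert cols[1].letter_heights["A"] == pytest.approx(2.0)
        assert all(h == 0 for h in cols[2].letter_heights.values())
        for col in cols:
            assert sum(col.letter_heights.values()) == pytest.approx(
                col.ic_bits, abs=1e-9
            )


class TestComparePwms:
    def test_identical_matrices_have_zero_divergence(self, plant_pwm):
        assert all(d == pytest.approx(0.0, abs=1e-12)
                   for _, d in compare_pwms(plant_pwm, plant_pwm))

    def test_disjoint_point_masses_diverge_one_bit(self):
        a = PWM(matrix=np.array([[1.0, 0, 0, 0]]), crystal_positions=(8,))
        b = PWM(matrix=np.array([[0, 1.0, 0, 0]]), crystal_positions=(8,))
        [(pos, d)] = compare_pwms(a, b)
        assert (pos, d) == (8, pytest.approx(1.0))

    def test_no_overlap_raises(self):
        a = PWM(matrix=np.array([[1.0, 0, 0, 0]]), crystal_positions=(5,))
        b = PWM(matrix=np.array([[1.0, 0, 0, 0]]), crystal_positions=(9,))
        with pytest.raises(ValueError):
            compare_pwms(a, b)


class TestRelativeLabels:
    def test_core_and_flank_labels(self):
        labels = [relative_label(n) for n in range(5, 17)]
        assert labels == ["-3", "-2", "-1", "C", "C", "A", "A", "T",
                          "+1", "+2", "+3", "+4"]


def test_jaspar_round_trip(tmp_path, plant_pwm):
    path = tmp_path / "pwm.jaspar"
    write_jaspar(plant_pwm, path)
    back = read_jaspar(path, crystal_start=5)
    assert np.allclose(back.matrix, plant_pwm.matrix, atol=1e-6)
    assert back.id == plant_pwm.id


class TestEndToEndRecovery:
    def test_noiseless_pipeline_reproduces_normalized_affinities(self, wt_oligo):
        # the derived PWM must equal the epsilon-floored normalization of
        # the generator's truth at every position, to 1e-6
        grid = [0.2, 0.5, 0.8, 1.1, 1.4, 1.7, 2.0, 0.3, 0.6, 0.9, 1.2, 1.5]
        truth = make_affinity_grid(wt_oligo, grid)
        lanes, _oligos, annotations, _ = simulate_saturation_experiment(
            truth, EmsaSimConfig(noise_sd=0.0, replicates=1, seed=3)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = quantify_lanes(lanes, "CAB2")
            table = build_affinity_table(results, wt_oligo, annotations)
            estimated = affinity_to_pwm(table)
            expected = affinity_to_pwm(truth)
        assert estimated.crystal_positions == expected.crystal_positions
        assert np.abs(estimated.matrix - expected.matrix).max() < 1e-6

    def test_total_logo_information_decreases_with_noise(self, wt_oligo):
        from nfymatrix.synthetic_reference import synthetic_affinity_table

        truth = synthetic_affinity_table()

        def mean_total_ic(noise_sd):
            totals = []
            for seed in range(20):
                lanes, _o, ann, _t = simulate_saturation_experiment(
                    truth,
                    EmsaSimConfig(noise_sd=noise_sd, replicates=3, seed=seed),
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    results = quantify_lanes(lanes, "CAB2")
                    table = build_affinity_table(results, wt_oligo, ann)
                    pwm = affinity_to_pwm(table)
                totals.append(sum(c.ic_bits for c in pwm_to_logo(pwm)))
            return np.mean(totals)

        ics = [mean_total_ic(sd) for sd in (0.0, 4.0, 8.0)]
        assert ics[0] >= ics[1] >= ics[2]
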