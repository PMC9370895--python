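"""Spinal maps: chart validation, subsegment projection, P2 indicators."""

import numpy as np
import pytest
import yaml

from pepato.errors import (
    ParameterError,
    PreconditionError,
    SchemaError,
    UndefinedMetricError,
)
from pepato.spinalmap import (
    N_SUBSEGMENTS,
    SEGMENTS,
    SLICES_PER_SEGMENT,
    InnervationChart,
    coactivation_index,
    compute_spinal_map,
    load_innervation_chart,
    map_similarity,
    timing_of_max,
)
from pepato.synthgen import gaussian_burst

MUSCLES = ["R_Sol", "R_GaLa", "R_TiAn", "R_ReFe", "R_VaLa", "R_VaMe", "R_SeTe", "R_BiFe"]


@pytest.fixture(scope="module")
def fixture_chart():
    """Test chart independent of the shipped default values."""
    per_segment = {
        "L2": ["ReFe", "VaLa", "VaMe"],
        "L3": ["ReFe", "VaLa", "VaMe"],
        "L4": ["ReFe", "TiAn"],
        "L5": ["TiAn", "Sol", "SeTe", "BiFe"],
        "S1": ["Sol", "GaLa", "SeTe", "BiFe"],
        "S2": ["Sol", "GaLa"],
    }
    muscles_per = [
        frozenset(per_segment[seg]) for seg in SEGMENTS for _ in range(SLICES_PER_SEGMENT)
    ]
    return InnervationChart(muscles_per)


class TestChart:
    def test_default_chart_has_36_subsegments(self):
        chart = load_innervation_chart()
        assert len(chart.muscles_per_subsegment) == N_SUBSEGMENTS
        covered = set().union(*chart.muscles_per_subsegment)
        assert covered == set(chart.known_muscles)

    def test_wrong_subsegment_count_rejected(self):
        with pytest.raises(SchemaError, match="36"):
            InnervationChart([frozenset({"Sol"})] * 30)

    def test_unknown_muscle_rejected(self, tmp_path):
        chart = {
            "subsegments": [
                {"segment": seg, "slice": sl, "muscles": ["XYZ"]}
                for seg in SEGMENTS
                for sl in range(1, 7)
            ]
        }
        path = tmp_path / "chart.yaml"
        path.write_text(yaml.safe_dump(chart))
        with pytest.raises(SchemaError, match="XYZ"):
            load_innervation_chart(path)

    def test_chart_yaml_order_enforced(self, tmp_path):
        chart = {
            "subsegments": [
                {"segment": seg, "slice": sl, "muscles": ["Sol"]}
                for sl in range(1, 7)
                for seg in SEGMENTS  # transposed order
            ]
        }
        path = tmp_path / "chart.yaml"
        path.write_text(yaml.safe_dump(chart))
        with pytest.raises(SchemaError):
            load_innervation_chart(path)


class TestSpinalMapProjection:
    def test_identical_envelopes_give_identical_subsegments(self, fixture_chart):
        e = gaussian_burst(40, 15)
        env = np.tile(e[:, None], (1, 8))
        smap = compute_spinal_map(env, MUSCLES, fixture_chart)
        assert smap.activation.shape == (36, 200)
        assert np.allclose(smap.activation, e[None, :])

    def test_single_active_muscle_lights_its_subsegments(self, fixture_chart):
        env = np.zeros((200, 8))
        env[:, MUSCLES.index("R_Sol")] = 1.0
        smap = compute_spinal_map(env, MUSCLES, fixture_chart)
        nonzero_rows = set(np.nonzero(smap.activation.sum(axis=1))[0])
        expected = {
            j
            for j, muscles in enumerate(fixture_chart.muscles_per_subsegment)
            if "Sol" in muscles
        }
        assert nonzero_rows == expected

    def test_missing_muscle_reduces_divisor_with_warning(self, fixture_chart):
        env = np.ones((200, 7))
        smap = compute_spinal_map(env, MUSCLES[:7], fixture_chart)
        assert any("BiFe" in w for w in smap.warnings)
        assert np.allclose(smap.activation, 1.0)  # mean over available muscles

    def test_segment_waveform_is_slice_mean_and_groups_sum(self, fixture_chart):
        rng = np.random.default_rng(0)
        env = np.abs(rng.standard_normal((200, 8)))
        smap = compute_spinal_map(env, MUSCLES, fixture_chart)
        for i, seg in enumerate(SEGMENTS):
            rows = smap.activation[i * 6 : (i + 1) * 6]
            assert np.allclose(smap.segment_waveforms[seg], rows.mean(axis=0))
        assert np.allclose(
            smap.lumbar, smap.segment_waveforms["L3"] + smap.segment_waveforms["L4"]
        )
        assert np.allclose(
            smap.sacral, smap.segment_waveforms["S1"] + smap.segment_waveforms["S2"]
        )

    def test_brute_force_loop_agreement(self, fixture_chart):
        """Naive per-sample loop over the projection formula matches."""
        rng = np.random.default_rng(1)
        env = np.abs(rng.standard_normal((200, 8)))
        smap = compute_spinal_map(env, MUSCLES, fixture_chart)
        codes = [m.split("_")[1] for m in MUSCLES]
        for j in range(36):
            muscles = fixture_chart.muscles_per_subsegment[j]
            idx = [codes.index(c) for c in muscles]
            for t in range(0, 200, 17):
                expected = sum(env[t, i] for i in idx) / len(idx)
                assert smap.activation[j, t] == pytest.approx(expected, abs=1e-12)

    def test_conservation_under_scaling(self, fixture_chart):
        rng = np.random.default_rng(2)
        env = np.abs(rng.standard_normal((200, 8)))
        a = compute_spinal_map(env, MUSCLES, fixture_chart)
        b = compute_spinal_map(3.7 * env, MUSCLES, fixture_chart)
        assert np.allclose(b.activation, 3.7 * a.activation)
        assert coactivation_index(a.lumbar, a.sacral) == pytest.approx(
            coactivation_index(b.lumbar, b.sacral)
        )


class TestTimingOfMax:
    def test_peak_index_to_percent(self):
        w = np.zeros(200)
        w[60] = 1.0  # sample 61 one-based
        assert timing_of_max(w) == 30.0

    def test_constant_waveform_ties_break_earliest(self):
        assert timing_of_max(np.ones(200)) == 0.0

    def test_cyclic_shift_equivariance(self):
        w = gaussian_burst(25, 10)
        shifted = np.roll(w, 40)  # +20% of cycle
        assert (timing_of_max(shifted) - timing_of_max(w)) % 100 == pytest.approx(20.0)

    def test_all_zero_undefined(self):
        with pytest.raises(UndefinedMetricError):
            timing_of_max(np.zeros(200))


class TestCoactivationIndex:
    def test_identical_waveforms_give_mean(self):
        x = gaussian_burst(30, 20)
        x = x / x.max()
        assert coactivation_index(x, x) == pytest.approx(float(x.mean()))

    def test_disjoint_supports_give_zero(self):
        a = np.zeros(200)
        b = np.zeros(200)
        a[:100] = 1.0
        b[100:] = 1.0
        assert coactivation_index(a, b) == 0.0

    def test_both_constant_give_one(self):
        assert coactivation_index(np.full(200, 2.0), np.full(200, 5.0)) == pytest.approx(1.0)

    def test_brute_force_loop_agreement(self):
        rng = np.random.default_rng(3)
        a = np.abs(rng.standard_normal(200))
        b = np.abs(rng.standard_normal(200))
        an, bn = a / a.max(), b / b.max()
        expected = 0.0
        for j in range(200):
            high, low = max(an[j], bn[j]), min(an[j], bn[j])
            if high > 0:
                expected += ((high + low) / 2) * (low / high)
        expected /= 200
        assert coactivation_index(a, b) == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = np.abs(rng.standard_normal(200))
            b = np.abs(rng.standard_normal(200))
            ci = coactivation_index(a, b)
            assert 0.0 <= ci <= 1.0

    def test_negative_input_rejected(self):
        with pytest.raises(PreconditionError):
            coactivation_index(-np.ones(200), np.ones(200))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            coactivation_index(np.ones(100), np.ones(200))


class TestMapSimilarity:
    def test_identity_and_offset_invariance(self):
        w = gaussian_burst(45, 18)
        assert map_similarity(w, w) == pytest.approx(1.0)
        assert map_similarity(w + 5.0, w) == pytest.approx(1.0)

    def test_antiphase_sinusoids(self):
        t = np.arange(200)
        a = 1 + np.sin(2 * np.pi * t / 200)
        b = 1 - np.sin(2 * np.pi * t / 200)
        assert map_similarity(a, b) == pytest.approx(-1.0)

    def test_constant_undefined(self):
        with pytest.raises(UndefinedMetricError):
            map_similarity(np.ones(200), gaussian_burst(30, 10))
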