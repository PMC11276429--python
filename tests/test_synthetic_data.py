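"""Generator contracts: population structure, trace physics, reproducibility,
and the on-disk CSV round trip."""

import numpy as np
import pytest

import fruitrelax as fr
from fruitrelax.synthetic_data import ConfigurationError, FormatError, GeneratorError

from conftest import NOISELESS


class TestPopulation:
    def test_group_counts(self):
        pop = fr.sample_population(35, noise=NOISELESS)
        assert len(pop) == 210
        for size in ("large", "medium", "small"):
            for pos in ("locule", "septum"):
                assert sum(s.size_class == size and s.position == pos for s in pop) == 35

    def test_param_scale_zero_collapses_to_means(self):
        pop = fr.sample_population(3, noise=fr.NoiseSpec(param_scale=0.0), family="maxwell")
        for s in pop:
            expected = fr.TOMATO_MAXWELL_MEAN
            if s.position == "septum":
                expected = expected.scale_moduli(1.3)
            assert np.allclose(s.true_params.as_array(), expected.as_array(), rtol=1e-12)

    def test_septum_moduli_scaled_not_times(self):
        pop = fr.sample_population(1, noise=fr.NoiseSpec(param_scale=0.0),
                                   family="maxwell", position_effect=1.3)
        locule = next(s for s in pop if s.position == "locule").true_params
        septum = next(s for s in pop if s.position == "septum").true_params
        assert septum.E0 == pytest.approx(1.3 * locule.E0)
        assert septum.T1 == locule.T1 and septum.T2 == locule.T2

    def test_seed_reproducibility(self):
        a = fr.sample_population(4, noise=fr.NoiseSpec(seed=11))
        b = fr.sample_population(4, noise=fr.NoiseSpec(seed=11))
        c = fr.sample_population(4, noise=fr.NoiseSpec(seed=12))
        assert all(x.true_params == y.true_params and x.radius_mm == y.radius_mm
                   for x, y in zip(a, b))
        assert any(x.true_params != y.true_params for x, y in zip(a, c))

    def test_radius_within_configured_band(self):
        bands = {"large": (40.0, 45.0), "medium": (33.0, 40.0), "small": (25.0, 33.0)}
        for s in fr.sample_population(5, size_bands=bands, noise=NOISELESS):
            lo, hi = bands[s.size_class]
            assert lo <= s.radius_mm <= hi

    @pytest.mark.parametrize("kwargs", [
        {"size_bands": {"large": (30.0, 36.0), "medium": (32.0, 38.0), "small": (26.0, 32.0)}},
        {"size_bands": {"large": (44.0, 38.0), "medium": (32.0, 38.0), "small": (26.0, 32.0)}},
        {"position_effect": 0.0},
        {"family": "kelvin"},
    ])
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            fr.sample_population(2, noise=NOISELESS, **kwargs)


class TestForceTrace:
    def test_relaxation_sample_count(self, maxwell_fruit):
        # 60 s hold sampled at 20 Hz -> 1200 relaxation points
        trace = fr.generate_force_trace(maxwell_fruit, fr.CompressionProtocol(), NOISELESS)
        assert int((trace.stages == "relaxation").sum()) == 1200
        assert np.all(np.diff(trace.times) > 0)

    def test_stage_blocks_ordered(self, maxwell_fruit):
        trace = fr.generate_force_trace(maxwell_fruit, noise=NOISELESS)
        stages = list(trace.stages)
        first_relax = stages.index("relaxation")
        first_unload = stages.index("unloading")
        assert set(stages[:first_relax]) == {"loading"}
        assert set(stages[first_relax:first_unload]) == {"relaxation"}
        assert set(stages[first_unload:]) == {"unloading"}

    def test_loading_starts_at_contact_trigger(self, maxwell_fruit):
        trace = fr.generate_force_trace(maxwell_fruit, noise=NOISELESS)
        assert trace.forces[0] == pytest.approx(0.49)

    def test_initial_relaxation_stress_matches_hand_value(self, maxwell_curve):
        # (E0+E1+E2) * eps0 = 0.3717 / 70 at the hold start, R = 35 mm
        sigma0 = fr.maxwell_stress(fr.TOMATO_MAXWELL_MEAN, 0.0, 1.0 / 70.0)
        assert sigma0 == pytest.approx(5.310e-3, rel=1e-3)
        # the first generated sample sits one interval (0.05 s) into the hold
        assert maxwell_curve.stress[0] == pytest.approx(
            fr.maxwell_stress(fr.TOMATO_MAXWELL_MEAN, 0.05, 1.0 / 70.0), rel=1e-12)

    @pytest.mark.parametrize("family", ["maxwell", "caputo"])
    def test_noiseless_relaxation_force_non_increasing(self, family):
        s = fr.sample_population(1, noise=NOISELESS, family=family)[0]
        trace = fr.generate_force_trace(s, noise=NOISELESS)
        relax = trace.forces[trace.stages == "relaxation"]
        assert np.all(np.diff(relax) <= 0)

    def test_roundtrip_force_to_stress_is_exact(self, maxwell_fruit, maxwell_curve):
        # generator's inverse Hertz composed with the forward conversion
        expected = fr.maxwell_stress(maxwell_fruit.true_params, maxwell_curve.times,
                                     maxwell_curve.strain0)
        assert np.allclose(maxwell_curve.stress, expected, rtol=1e-12)

    def test_septum_stress_dominates_locule(self):
        noise = fr.NoiseSpec(force_sd=1e-4, param_scale=0.2, seed=5)
        pop = fr.sample_population(6, noise=noise, family="maxwell", position_effect=1.3)
        maxima = {"locule": [], "septum": []}
        for s in pop:
            trace = fr.generate_force_trace(s, noise=noise)
            curve = fr.force_to_stress(fr.trim_relaxation(trace), s)
            maxima[s.position].append(curve.stress.max())
        assert np.median(maxima["septum"]) > np.median(maxima["locule"])

    def test_same_seed_bit_identical_traces(self, maxwell_fruit):
        noise = fr.NoiseSpec(force_sd=0.01, seed=3)
        a = fr.generate_force_trace(maxwell_fruit, noise=noise)
        b = fr.generate_force_trace(maxwell_fruit, noise=noise)
        assert np.array_equal(a.forces, b.forces)

    def test_missing_ground_truth_rejected(self):
        bare = fr.FruitSample(id="x", radius_mm=35.0, size_class="medium", position="locule")
        with pytest.raises(GeneratorError):
            fr.generate_force_trace(bare, noise=NOISELESS)


class TestDatasetIO:
    def _tiny(self):
        pop = fr.sample_population(1, noise=fr.NoiseSpec(seed=2), family="mixed")[:3]
        protocol = fr.CompressionProtocol(hold_duration_s=2.0)
        traces = [fr.generate_force_trace(s, protocol, fr.NoiseSpec(seed=2)) for s in pop]
        return pop, traces

    def test_write_read_roundtrip(self, tmp_path):
        pop, traces = self._tiny()
        fr.write_dataset(pop, traces, tmp_path)
        pop2, traces2 = fr.read_dataset(tmp_path)
        assert [s.id for s in pop2] == [s.id for s in pop]
        for s, s2 in zip(pop, pop2):
            assert np.allclose(s.true_params.as_array(), s2.true_params.as_array(), rtol=1e-12)
            assert s2.radius_mm == pytest.approx(s.radius_mm, rel=1e-12)
        for t, t2 in zip(traces, traces2):
            assert np.allclose(t.forces, t2.forces, rtol=1e-12)
            assert list(t.stages) == list(t2.stages)

    def test_missing_force_column_named_in_error(self, tmp_path):
        pop, traces = self._tiny()
        fr.write_dataset(pop, traces, tmp_path)
        trace_file = tmp_path / "traces" / f"{pop[0].id}.csv"
        import pandas as pd
        df = pd.read_csv(trace_file).drop(columns=["force_N"])
        df.to_csv(trace_file, index=False)
        with pytest.raises(FormatError, match="force_N"):
            fr.read_dataset(tmp_path)

    def test_unknown_size_class_rejected(self, tmp_path):
        pop, traces = self._tiny()
        fr.write_dataset(pop, traces, tmp_path)
        meta = (tmp_path / "metadata.csv").read_text().replace("large", "giant")
        (tmp_path / "metadata.csv").write_text(meta)
        with pytest.raises(FormatError, match="size_class"):
            fr.read_dataset(tmp_path)
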