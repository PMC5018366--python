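"""Synergy distributions and their scalar summaries."""

import numpy as np
import pytest

import combokit as ck


def _dist_from(values, doses=None, exp_mean=None):
    """Build a distribution (and matching experiment) from a raw matrix."""
    values = np.asarray(values, dtype=float)
    n_b, n_a = values.shape
    if doses is None:
        doses_a = np.arange(n_a, dtype=float)
        doses_b = np.arange(n_b, dtype=float)
    else:
        doses_a, doses_b = doses
    mean = np.full(values.shape, 50.0) if exp_mean is None else exp_mean
    exp = ck.CombinationExperiment.build(
        "synthetic", doses_a, doses_b, [mean])
    dist = ck.SynergyDistribution(
        model=ck.Model.BLISS, doses_a=np.asarray(doses_a, float),
        doses_b=np.asarray(doses_b, float), values=values,
        per_cell_sd=None, n_replicates=1)
    return dist, exp


class TestDistribution:
    def test_sign_convention(self, curves, tiny_experiment):
        ref = ck.ReferenceSurface(
            ck.Model.BLISS, tiny_experiment.doses_a, tiny_experiment.doses_b,
            np.array([[100.0, 60.0], [70.0, 60.0]]),
            np.zeros((2, 2), dtype=np.int8))
        dist = ck.synergy_distribution(tiny_experiment, ref)
        # data 50 below reference 60 -> +10 synergy
        assert dist.values[1, 1] == pytest.approx(10.0)
        flipped = ck.synergy_distribution(tiny_experiment, ref,
                                          sign="data_minus_reference")
        assert flipped.values[1, 1] == pytest.approx(-10.0)

    def test_identical_data_gives_zero(self, clean_bliss_experiment):
        exp = clean_bliss_experiment
        ref = ck.ReferenceSurface(ck.Model.BLISS, exp.doses_a, exp.doses_b,
                                  exp.mean_response.copy(),
                                  np.zeros(exp.mean_response.shape, np.int8))
        dist = ck.synergy_distribution(exp, ref)
        np.testing.assert_allclose(dist.values, 0.0, atol=1e-12)

    def test_shape_mismatch_rejected(self, tiny_experiment, curves):
        ref = ck.bliss_surface(*curves, [0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="mismatch|grids"):
            ck.synergy_distribution(tiny_experiment, ref)

    def test_replicate_sd_propagated(self):
        reps = [np.array([[100.0, 60.0], [70.0, 40.0]]),
                np.array([[100.0, 60.0], [70.0, 60.0]])]
        exp = ck.CombinationExperiment.build("r", [0, 1], [0, 1], reps)
        ref = ck.ReferenceSurface(ck.Model.HSA, exp.doses_a, exp.doses_b,
                                  np.full((2, 2), 50.0),
                                  np.zeros((2, 2), np.int8))
        dist = ck.synergy_distribution(exp, ref)
        assert dist.per_cell_sd[1, 1] == pytest.approx(np.std([40, 60], ddof=1))

    def test_noise_calibration(self):
        """Under the generating model, synergy is zero-mean noise with
        per-cell SD ~ sigma/sqrt(n_replicates)."""
        sigma, n_rep, n_sim = 3.0, 4, 60
        vals = []
        for s in range(n_sim):
            spec = ck.SimulationSpec(seed=1000 + s, model="hsa",
                                     noise_sd=sigma, n_replicates=n_rep)
            exp = ck.simulate_experiment(spec)
            ref = ck.reference_surface("hsa", spec.curve_a, spec.curve_b,
                                       spec.doses_a, spec.doses_b)
            vals.append(ck.synergy_distribution(exp, ref).interior_values)
        vals = np.array(vals)
        assert abs(vals.mean()) < 3 * sigma / np.sqrt(n_rep * vals[0].size * n_sim)
        assert vals.std() == pytest.approx(sigma / np.sqrt(n_rep), rel=0.1)


class TestSignificance:
    def test_mask_flags_planted_cell_only(self):
        field = np.zeros((8, 8))
        field[4, 4] = 25.0
        spec = ck.SimulationSpec(seed=9, model="bliss", noise_sd=1.0,
                                 n_replicates=6, synergy_field=field)
        exp = ck.simulate_experiment(spec)
        ref = ck.reference_surface("bliss", spec.curve_a, spec.curve_b,
                                   spec.doses_a, spec.doses_b)
        mask = ck.significance_mask(exp, ref, alpha=0.05)
        assert mask[4, 4]
        assert mask.sum() <= 3  # essentially only the planted cell
        assert not mask[0, :].any() and not mask[:, 0].any()

    def test_requires_three_replicates(self, tiny_experiment, curves):
        ref = ck.bliss_surface(*curves, tiny_experiment.doses_a,
                               tiny_experiment.doses_b)
        with pytest.raises(ValueError, match="replicates"):
            ck.significance_mask(tiny_experiment, ref)


class TestMetrics:
    def test_zero_distribution(self):
        dist, exp = _dist_from(np.zeros((4, 4)))
        rec = ck.compute_metrics(dist, exp)
        for f in ("max_synergy", "max_antagonism", "sum_synergy",
                  "sum_antagonism", "integrated_total", "weighted_integrated"):
            assert getattr(rec, f) == 0.0
        # peak defaults to the lowest interior dose pair
        assert (rec.peak_dose_a, rec.peak_dose_b) == (1.0, 1.0)
        assert rec.n_cells == 9

    def test_single_spike_arithmetic(self):
        v = np.zeros((4, 4))
        v[2, 2] = 10.0  # one interior cell of the 3x3 interior
        dist, exp = _dist_from(v)
        rec = ck.compute_metrics(dist, exp)
        assert rec.max_synergy == pytest.approx(10.0)
        assert rec.integrated_total == pytest.approx(10.0 / 9.0)
        assert rec.sum_antagonism == 0.0
        assert (rec.peak_dose_a, rec.peak_dose_b) == (2.0, 2.0)

    def test_constant_field_invariant_to_weighting(self):
        v = np.full((4, 4), 5.0)
        mean = np.linspace(20, 90, 16).reshape(4, 4)  # non-trivial weights
        dist, exp = _dist_from(v, exp_mean=mean)
        rec = ck.compute_metrics(dist, exp)
        assert rec.weighted_integrated == pytest.approx(5.0)

    def test_sum_decomposition_and_bounds(self):
        rng = np.random.default_rng(2)
        v = rng.normal(0, 5, (6, 6))
        dist, exp = _dist_from(v)
        rec = ck.compute_metrics(dist, exp)
        interior = v[1:, 1:]
        assert rec.integrated_total == pytest.approx(
            rec.sum_synergy + rec.sum_antagonism)
        assert rec.max_synergy >= interior.max() - 1e-12
        assert rec.max_antagonism <= interior.min() + 1e-12
        assert interior.min() - 1e-12 <= rec.weighted_integrated <= interior.max() + 1e-12

    def test_scaling_property(self):
        rng = np.random.default_rng(4)
        v = rng.normal(0, 3, (5, 5))
        dist, exp = _dist_from(v)
        r1 = ck.compute_metrics(dist, exp)
        dist2, _ = _dist_from(2.5 * v)
        r2 = ck.compute_metrics(dist2, exp)
        for f in ("max_synergy", "max_antagonism", "sum_synergy",
                  "sum_antagonism", "integrated_total", "weighted_integrated"):
            assert getattr(r2, f) == pytest.approx(2.5 * getattr(r1, f))
        assert (r2.peak_dose_a, r2.peak_dose_b) == (r1.peak_dose_a, r1.peak_dose_b)

    def test_peak_follows_density_not_lone_cell(self):
        """A 2x2 block of moderate synergy outweighs one isolated spike."""
        v = np.zeros((6, 6))
        v[1, 1] = 12.0                    # lone spike
        v[3:5, 3:5] = 10.0                # dense block
        dist, exp = _dist_from(v)
        rec = ck.compute_metrics(dist, exp)
        assert rec.peak_dose_a >= 3.0 and rec.peak_dose_b >= 3.0

    def test_no_interior_cells_rejected(self):
        dist, exp = _dist_from(np.full((1, 1), 0.0),
                               doses=([0.0], [0.0]))
        with pytest.raises(ValueError, match="interior"):
            ck.compute_metrics(dist, exp)
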