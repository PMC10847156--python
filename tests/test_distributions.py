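"""Mixture fitting, KDE scoring and modality-transition calls."""

import numpy as np
import pytest

from fibrilmorph import fit_mixture, kde, mfd_range, modality_transition, r_squared
from fibrilmorph.distributions import MixtureParams
from fibrilmorph.synthetic import sample_mfd, timepoint_mixture

TRIMODAL = MixtureParams([60, 120, 200], [64, 144, 400], [1 / 3, 1 / 3, 1 / 3])
BIMODAL = MixtureParams([50, 150], [25, 25], [0.5, 0.5])


class TestFitMixture:
    def test_k1_closed_form_mle(self):
        fit = fit_mixture([40.0, 50.0, 60.0] * 4, k=1)
        assert fit.params.means[0] == pytest.approx(50.0)
        assert fit.params.variances[0] == pytest.approx(200.0 / 3)

    def test_k2_parameter_recovery(self):
        x = sample_mfd(BIMODAL, 2000, seed=4)
        fit = fit_mixture(x, k=2, seed=0)
        assert fit.converged
        assert np.allclose(fit.params.means, [50, 150], atol=2.0)
        assert np.allclose(fit.params.weights, 0.5, atol=0.05)

    def test_identical_components_degenerate_mixture(self):
        # all generating components identical: the fitted means cannot
        # separate beyond the bulk of the single population (the likelihood
        # is nearly flat in the component means inside +- 2 sd)
        m = MixtureParams([100, 100, 100], [100, 100, 100], [1 / 3, 1 / 3, 1 / 3])
        x = sample_mfd(m, 3000, seed=5)
        fit = fit_mixture(x, k=3, seed=0)
        assert np.all(np.abs(fit.params.means - 100.0) < 2 * 10.0)
        assert fit.params.mean() == pytest.approx(100.0, abs=1.0)

    def test_log_likelihood_nondecreasing_in_k(self):
        x = sample_mfd(TRIMODAL, 1500, seed=6)
        lls = [fit_mixture(x, k, seed=1).log_likelihood for k in (1, 2, 3)]
        assert lls[0] <= lls[1] + 1e-6 <= lls[2] + 2e-6

    def test_sample_size_guard(self):
        with pytest.raises(ValueError, match="at least"):
            fit_mixture(np.arange(15.0) + 1, k=2)

    def test_deterministic_for_fixed_seed(self):
        x = sample_mfd(TRIMODAL, 800, seed=7)
        f1 = fit_mixture(x, 3, seed=42)
        f2 = fit_mixture(x, 3, seed=42)
        assert np.array_equal(f1.params.means, f2.params.means)

    def test_matches_sklearn_gaussian_mixture(self):
        """Independent EM implementation agrees with sklearn on the same data."""
        from sklearn.mixture import GaussianMixture
        x = sample_mfd(TRIMODAL, 2000, seed=8)
        ours = fit_mixture(x, 3, seed=0)
        ref = GaussianMixture(3, n_init=5, random_state=0,
                              covariance_type="full").fit(x[:, None])
        ref_means = np.sort(ref.means_.ravel())
        assert np.allclose(ours.params.means, ref_means, atol=2.0)
        # average log-likelihood per point should agree closely
        assert ours.log_likelihood / x.size == pytest.approx(
            ref.score(x[:, None]), abs=5e-3)


class TestKde:
    def test_mode_near_true_mean(self):
        x = sample_mfd(MixtureParams([80.0], [100.0], [1.0]), 5000, seed=9)
        prof = kde(x)
        assert prof.grid[np.argmax(prof.density)] == pytest.approx(80.0, abs=2.0)

    def test_integrates_to_one(self):
        x = sample_mfd(TRIMODAL, 1000, seed=10)
        assert kde(x).integral() == pytest.approx(1.0, abs=0.01)

    def test_duplicated_sample_identical_density_at_fixed_bandwidth(self):
        # densities are normalised, so duplicating every observation changes
        # nothing once the bandwidth factor is held fixed
        x = sample_mfd(BIMODAL, 500, seed=11)
        p1 = kde(x, bw_method=0.2)
        p2 = kde(np.repeat(x, 2), bw_method=0.2)
        # identical up to the ddof=1 variance factor inside gaussian_kde
        assert np.allclose(p1.density, p2.density, rtol=5e-3)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError):
            kde([1.0, 2.0, 3.0])


class TestRSquared:
    def test_perfect_agreement_is_one(self):
        x = sample_mfd(MixtureParams([100.0], [64.0], [1.0]), 4000, seed=12)
        prof = kde(x)
        fit = fit_mixture(x, 1)
        # replace the KDE by the smoothed fitted pdf: residuals vanish
        prof.density = fit.params.pdf(prof.grid, extra_var=prof.bandwidth**2)
        assert r_squared(fit, prof) == pytest.approx(1.0)

    def test_trimodal_beats_unimodal_on_trimodal_sample(self):
        x = sample_mfd(TRIMODAL, 5000, seed=13)
        prof = kde(x)
        r2 = {k: r_squared(fit_mixture(x, k, seed=k), prof) for k in (1, 3)}
        assert r2[3] > 0.98
        assert r2[1] < r2[3]

    def test_constant_kde_rejected(self):
        x = sample_mfd(BIMODAL, 100, seed=14)
        prof = kde(x)
        prof.density = np.ones_like(prof.density)
        with pytest.raises(ValueError, match="SS_tot"):
            r_squared(fit_mixture(x, 1), prof)


def _series_fits(n_per_day=1500, days=range(1, 22), seed0=200):
    fits, kdes = {}, {}
    for day in days:
        x = sample_mfd(timepoint_mixture(day), n_per_day, seed=seed0 + day)
        kdes[day] = kde(x)
        fits[day] = {k: fit_mixture(x, k, seed=seed0 + 10 * day + k, n_restarts=6)
                     for k in (1, 2, 3)}
    return fits, kdes


class TestModalityTransition:
    def test_transitions_called_at_days_8_and_14(self):
        fits, kdes = _series_fits()
        series = modality_transition(fits, kdes, r2_threshold=0.98)
        assert series.transition_day(2) == 8
        assert series.transition_day(3) == 14
        assert np.all(series.modality[series.days < 8] == 1)
        assert np.all(series.modality[(series.days >= 8) & (series.days < 14)] == 2)
        assert np.all(series.modality[series.days >= 14] == 3)

    def test_unimodal_series_stays_unimodal(self):
        fits, kdes = _series_fits(days=[1, 2, 3, 4], n_per_day=800)
        series = modality_transition(fits, kdes)
        assert np.all(series.modality == 1)
        assert series.transition_day(2) is None

    def test_degenerate_threshold_gives_modality_one(self):
        fits, kdes = _series_fits(days=[14, 16], n_per_day=800)
        series = modality_transition(fits, kdes, r2_threshold=-np.inf)
        assert np.all(series.modality == 1)

    def test_missing_k_rejected(self):
        fits, kdes = _series_fits(days=[1, 2], n_per_day=800)
        del fits[1][2]
        with pytest.raises(ValueError, match="missing"):
            modality_transition(fits, kdes)


class TestMfdRange:
    def test_arithmetic(self):
        assert mfd_range([35.0, 120.0, 400.0]) == (35.0, 400.0, 365.0)
        assert mfd_range([42.0])[2] == 0.0
        with pytest.raises(ValueError):
            mfd_range([])

    def test_widening_generator_gives_positive_trend(self):
        rng_widths = []
        for i, sd in enumerate([5.0, 15.0, 25.0, 35.0]):
            x = sample_mfd(MixtureParams([150.0], [sd**2], [1.0]), 2000, seed=40 + i)
            rng_widths.append(mfd_range(x)[2])
        assert np.all(np.diff(rng_widths) > 0)


def test_parameter_recovery_twenty_replicates():
    """Median absolute error of recovered trimodal means stays below 5 nm."""
    errors = []
    for rep in range(20):
        x = sample_mfd(TRIMODAL, 2000, seed=1000 + rep)
        fit = fit_mixture(x, 3, seed=rep)
        errors.append(np.abs(fit.params.means - np.array([60, 120, 200])))
    assert np.median(np.concatenate(errors)) < 5.0
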