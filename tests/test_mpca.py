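"""The normal-operation MPCA model: fitting, projection, SPE statistics,
chi-square limits, contribution diagnostics and score-space outliers."""

import numpy as np
import pytest

import ischemix as ix
from ischemix.exceptions import DegenerateDataError, ModelError, ValidationError
from ischemix.mpca import spe_limit
from ischemix.preprocess import apply_scaler, invert_scaler, unfold, unfold_batch


@pytest.fixture(scope="module")
def random_dataset(panel):
    rng = np.random.default_rng(77)
    return ix.BatchDataset(panel, rng.normal(size=(8, 25, 6)))


class TestFit:
    def test_identical_batches_rejected(self, panel):
        values = np.broadcast_to(np.arange(150.0).reshape(25, 6), (5, 25, 6)).copy()
        with pytest.raises(DegenerateDataError):
            ix.fit_mpca(ix.BatchDataset(panel, values), R=1)

    def test_r_beyond_rank_rejected(self, random_dataset):
        with pytest.raises(ModelError):
            ix.fit_mpca(random_dataset, R=8)  # rank of centred 8-batch data is 7

    def test_loadings_match_eigenvectors_of_column_covariance(self, random_dataset):
        """Independent cross-check against scikit-learn's PCA."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        model = ix.fit_mpca(random_dataset, R=3)
        X = unfold(apply_scaler(random_dataset, model.scaler)).matrix
        ref = sklearn.PCA(n_components=3, svd_solver="full").fit(X)
        for r in range(3):
            v = ref.components_[r]
            sign = np.sign(v[np.argmax(np.abs(v))])
            np.testing.assert_allclose(model.loadings[:, r], sign * v, atol=1e-8)

    def test_shapes_and_invariants(self, mpca_model):
        P = mpca_model.loadings
        assert P.shape == (150, 3)
        assert mpca_model.scores.shape == (10, 3)
        np.testing.assert_allclose(P.T @ P, np.eye(3), atol=1e-8)
        ev = mpca_model.explained_variance
        assert (np.diff(ev) <= 1e-12).all()  # non-increasing
        for mode in ("instantaneous", "cumulative"):
            lim = mpca_model.limits_online[mode]
            assert (lim[0.01] >= lim[0.05]).all()
        assert mpca_model.limits_offline[0.01] >= mpca_model.limits_offline[0.05]

    def test_full_rank_model_has_zero_training_spe(self, random_dataset):
        model = ix.fit_mpca(random_dataset, R=7)
        assert model.spe_train_offline.max() <= 1e-10


class TestProjection:
    def test_training_mean_surface_projects_to_origin(self, mpca_model):
        t, e = mpca_model.project(mpca_model.scaler.means)
        np.testing.assert_allclose(t, 0.0, atol=1e-10)
        np.testing.assert_allclose(e, 0.0, atol=1e-10)

    def test_in_plane_batch_has_zero_residual(self, mpca_model, rng):
        t = rng.normal(size=3) * 5
        x = t @ mpca_model.loadings.T
        batch = invert_scaler(x.reshape(6, 25).T, mpca_model.scaler)
        _, e = mpca_model.project(batch)
        assert np.abs(e).max() < 1e-10
        assert mpca_model.spe_offline(batch).spe < 1e-10

    def test_residual_matches_dense_projector(self, mpca_model, rng):
        batch = rng.normal(size=(25, 6)) + mpca_model.scaler.means
        _, e = mpca_model.project(batch)
        x = unfold_batch(apply_scaler(batch, mpca_model.scaler))
        P = mpca_model.loadings
        dense = (np.eye(150) - P @ P.T) @ x
        np.testing.assert_allclose(e, dense, atol=1e-10)
        spe = mpca_model.spe_offline(batch).spe
        assert spe == pytest.approx(dense @ dense, rel=1e-10)

    def test_wrong_shape_rejected(self, mpca_model):
        with pytest.raises(ValidationError):
            mpca_model.project(np.zeros((25, 5)))


class TestOnline:
    def test_full_horizon_equals_offline_scores(self, mpca_model, rng):
        batch = rng.normal(size=(25, 6)) + mpca_model.scaler.means
        t_full, _ = mpca_model.project(batch)
        t_online, _ = mpca_model.online_scores(batch, k=6)
        np.testing.assert_allclose(t_online, t_full, atol=1e-8)

    def test_mean_surface_scores_zero_every_hour(self, mpca_model):
        for k in (1, 3, 6):
            t, e = mpca_model.online_scores(mpca_model.scaler.means[:, :k], k)
            np.testing.assert_allclose(t, 0.0, atol=1e-10)
            assert mpca_model.spe_online(mpca_model.scaler.means[:, :k], k).spe < 1e-12

    def test_truncated_least_squares_oracle(self, mpca_model, rng):
        k = 3
        partial = rng.normal(size=(25, k)) + mpca_model.scaler.means[:, :k]
        t, e = mpca_model.online_scores(partial, k)
        x = unfold_batch(apply_scaler(partial, mpca_model.scaler))
        Pk = mpca_model.loadings[: 25 * k]
        t_ref = np.linalg.pinv(Pk) @ x
        np.testing.assert_allclose(t, t_ref, atol=1e-8)
        # both online SPE modes against brute force
        e_ref = x - Pk @ t_ref
        inst = mpca_model.spe_online(partial, k, "instantaneous").spe
        cum = mpca_model.spe_online(partial, k, "cumulative").spe
        assert inst == pytest.approx(e_ref[25 * (k - 1):] @ e_ref[25 * (k - 1):], rel=1e-8)
        assert cum == pytest.approx(e_ref @ e_ref, rel=1e-8)

    def test_k_out_of_range_rejected(self, mpca_model):
        with pytest.raises(ValidationError):
            mpca_model.online_scores(np.zeros((25, 6)), k=7)

    def test_wi_batches_alarm_at_every_hour(self, mpca_model, study):
        """Warm-ischemic batches stay above the 99% online limit and above
        the log-SPE ischemia threshold from hour 1 to the end."""
        for batch in study.select_label("wi").iter_batches():
            trace = mpca_model.online_trace(batch)
            assert trace.flags.all()
            assert trace.index_flag.all()
            assert (trace.log_index > 1.35).all()

    def test_fresh_offline_spe_mostly_under_limit(self, mpca_model, default_config):
        held = ix.generate_fresh(default_config.with_(seed=321), n=100)
        spe = np.array([mpca_model.spe_offline(b).spe for b in held.iter_batches()])
        assert (spe < mpca_model.limits_offline[0.01]).mean() > 0.9

    def test_wi_offline_spe_exceeds_99_limit(self, mpca_model, study):
        for b in study.select_label("wi").iter_batches():
            trace = mpca_model.spe_offline(b)
            assert bool(trace.flags)
            assert trace.spe > mpca_model.limits_offline[0.01]


class TestSPELimit:
    def test_exact_moments_give_chi2_quantile(self):
        # sample with mean 2 and variance 4 -> g = 1, h = 2; the chi-square
        # quantile with 2 df has the closed form -2 ln(alpha)
        sample = np.array([0.0, 2.0, 4.0])
        assert spe_limit(sample, 0.05) == pytest.approx(-2.0 * np.log(0.05), rel=1e-12)

    def test_chi2_self_consistency(self, rng):
        h = 6.0
        sample = rng.chisquare(h, size=200_000)
        from scipy.stats import chi2
        assert spe_limit(sample, 0.05) == pytest.approx(chi2.ppf(0.95, h), rel=0.02)

    def test_alpha_monotonicity(self, rng):
        sample = rng.chisquare(4, size=50)
        assert spe_limit(sample, 0.01) > spe_limit(sample, 0.05)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(DegenerateDataError):
            spe_limit(np.ones(10), 0.05)
        with pytest.raises(DegenerateDataError):
            spe_limit(np.array([1.0, 2.0]), 0.05)


class TestContributions:
    def test_in_plane_batch_contributes_nothing(self, mpca_model, rng):
        t = rng.normal(size=3)
        x = t @ mpca_model.loadings.T
        batch = invert_scaler(x.reshape(6, 25).T, mpca_model.scaler)
        table = mpca_model.contributions(batch)
        assert np.abs(table.squared).max() < 1e-18

    def test_contributions_conserve_spe(self, mpca_model, rng):
        batch = rng.normal(size=(25, 6)) + mpca_model.scaler.means
        table = mpca_model.contributions(batch)
        spe = mpca_model.spe_offline(batch).spe
        assert table.squared.sum() == pytest.approx(spe, rel=1e-8)
        assert (table.squared >= 0).all()
        np.testing.assert_allclose(table.squared, table.normalized ** 2)

    def test_wi_albumin_normalized_error_negative_every_hour(self, mpca_model, study, panel):
        for b in study.select_label("wi").iter_batches():
            table = mpca_model.contributions(b)
            assert (table.normalized[panel.index_of("Albumin")] < 0).all()


class TestContributorFlags:
    def test_fresh_batch_rarely_flags(self, default_config):
        """Null behaviour of the 3-sigma screen: a healthy batch judged
        against a well-estimated fresh reference flags at most ~1 of its
        150 metabolite-hours on average."""
        model = ix.fit_mpca(ix.generate_fresh(default_config, n=100), R=3)
        held = ix.generate_fresh(default_config.with_(seed=555), n=60)
        reference = model.training_reference()
        counts = [
            ix.flag_contributors(model.contributions(b), reference).n_flagged
            for b in held.iter_batches()
        ]
        assert np.mean(counts) <= 1.0  # out of 150 metabolite-hours

    def test_single_fault_names_the_metabolite(self, panel):
        cfg = ix.GeneratorConfig(seed=31, noise_sd=0.1,
                                 wi_perturbation=np.zeros((25, 6)))
        model = ix.fit_mpca(ix.generate_fresh(cfg, n=100), R=3)
        delta = np.zeros((25, 6))
        delta[panel.index_of("Ornithine"), 1] = 6.0  # fault at k = 2 hr only
        faulty = ix.generate_wi(cfg.with_(seed=99, wi_perturbation=delta), n=1)
        flags = ix.flag_contributors(model.contributions(faulty.batches[0]),
                                     model.training_reference())
        assert flags.flagged_at(2) == ["Ornithine"]
        assert flags.n_flagged == 1

    def test_default_wi_flags_ornithine_at_two_hours(self, mpca_model, study):
        for b in study.select_label("wi").iter_batches():
            flags = ix.flag_contributors(mpca_model.contributions(b),
                                         mpca_model.training_reference())
            assert "Ornithine" in flags.flagged_at(2)

    def test_empty_reference_rejected(self, mpca_model, study):
        table = mpca_model.contributions(study.batches[0])
        with pytest.raises(ValidationError):
            ix.flag_contributors(table, [])


class TestScoreEllipseAndOutliers:
    def test_origin_inside_any_ellipse(self, mpca_model):
        ellipse = mpca_model.score_ellipse()
        assert ellipse.contains((0.0, 0.0), 0.05)
        assert ellipse.contains((0.0, 0.0), 0.01)

    def test_99_ellipse_contains_95_ellipse(self, mpca_model):
        ellipse = mpca_model.score_ellipse()
        a95 = ellipse.semi_axes(0.05)
        a99 = ellipse.semi_axes(0.01)
        assert a99[0] > a95[0] and a99[1] > a95[1]

    def test_constructed_outlier_is_flagged_exactly(self, default_config):
        data = ix.generate_fresh(default_config.with_(seed=44), n=20)
        shifted = ix.inject_anomalies(data, ix.AnomalySpec(batch_shifts={7: 10.0}))
        model = ix.fit_mpca(shifted, R=3)
        out99 = ix.detect_outlier_batches(model, shifted, alpha=0.01)
        assert out99 == [shifted.batch_ids[7]]
        out95 = ix.detect_outlier_batches(model, shifted, alpha=0.05)
        assert set(out99) <= set(out95)

    def test_r1_model_has_no_ellipse(self, fresh10):
        model = ix.fit_mpca(fresh10, R=1)
        with pytest.raises(ModelError):
            model.score_ellipse()


class TestSeverityAndSerialization:
    def test_spe_grows_with_perturbation_severity(self, mpca_model, default_config):
        """Scaling the injury surface by c >= 1 never lowers mean SPE_k."""
        base = default_config.wi_perturbation
        prev = np.zeros(6)
        for c in (1.0, 2.0, 4.0):
            cfg = default_config.with_(seed=202, wi_perturbation=c * base)
            wi = ix.generate_wi(cfg, n=6)
            mean_spe = np.mean(
                [mpca_model.online_trace(b).spe for b in wi.iter_batches()], axis=0)
            assert (mean_spe >= prev - 1e-9).all()
            prev = mean_spe

    def test_model_round_trips_through_json(self, mpca_model, study, tmp_path):
        path = tmp_path / "model.json"
        ix.save_model(mpca_model, path)
        loaded = ix.load_model(path)
        b = study.batches[12]
        np.testing.assert_allclose(loaded.spe_offline(b).spe, mpca_model.spe_offline(b).spe)
        np.testing.assert_allclose(loaded.online_trace(b).spe, mpca_model.online_trace(b).spe)
        np.testing.assert_array_equal(loaded.loadings, mpca_model.loadings)
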