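import numpy as np
import pytest
import statsmodels.api as sm

from persistlsd import (
    CovariateBundle,
    PersistenceLabels,
    fit_lsd,
    lsd_score,
    lsd_scores,
    prepare_covariates,
    screen_collinearity,
)
from persistlsd.errors import EstimationError
from persistlsd.lsd import back_transform
from persistlsd.selection import aicc


def _bundle(**covs):
    n = len(next(iter(covs.values())))
    ids = tuple(f"S{i}" for i in range(n))
    return ids, CovariateBundle(ids, {k: np.asarray(v, dtype=float) for k, v in covs.items()})


class TestPrepareCovariates:
    def test_offset_is_half_min_positive(self):
        e = np.e
        _, b = _bundle(x=[1.0, e - 0.5, e**2 - 0.5])
        out = prepare_covariates(b, ["x"])
        assert out.transforms["x"] == 0.5
        np.testing.assert_allclose(out.site_covs["x"], [np.log(1.5), 1.0, 2.0])

    def test_all_zero_uses_unit_offset(self):
        _, b = _bundle(x=[0.0, 0.0, 0.0])
        out = prepare_covariates(b, ["x"])
        assert out.transforms["x"] == 1.0
        np.testing.assert_allclose(out.site_covs["x"], 0.0)

    def test_back_transform_recovers_input(self):
        _, b = _bundle(x=[0.2, 1.7, 3.0, 0.05])
        out = prepare_covariates(b, ["x"])
        np.testing.assert_allclose(back_transform(out, "x"), b.site_covs["x"])

    def test_negative_values_rejected(self):
        _, b = _bundle(x=[-1.0, 2.0])
        with pytest.raises(ValueError, match="negative"):
            prepare_covariates(b, ["x"])

    def test_other_covariates_untouched(self):
        _, b = _bundle(x=[1.0, 2.0], y=[5.0, 6.0])
        out = prepare_covariates(b, ["x"])
        np.testing.assert_array_equal(out.site_covs["y"], [5.0, 6.0])


class TestFitLsd:
    def test_two_by_two_closed_form(self):
        # persisted 8/10 when x=1, 2/10 when x=0: beta-hat = log odds ratio
        x = np.r_[np.ones(10), np.zeros(10)]
        z = np.r_[np.ones(8), np.zeros(2), np.ones(2), np.zeros(8)].astype(np.int8)
        ids, bundle = _bundle(x=x)
        fit = fit_lsd(PersistenceLabels(ids, z), bundle, ["x"])
        assert fit.converged
        assert fit.betas["x"] == pytest.approx(np.log(16.0), abs=1e-4)
        assert fit.intercept == pytest.approx(np.log(2 / 8), abs=1e-4)

    def test_matches_statsmodels_logit(self, lsd_fixture_20):
        labels, bundle = lsd_fixture_20
        fit = fit_lsd(labels, bundle, ["x"])
        X = sm.add_constant(bundle.site_covs["x"])
        ref = sm.Logit(labels.z, X).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-5)
        assert fit.betas["x"] == pytest.approx(ref.params[1], abs=1e-5)
        assert fit.intercept_se == pytest.approx(ref.bse[0], rel=1e-3)
        assert fit.ses["x"] == pytest.approx(ref.bse[1], rel=1e-3)
        assert fit.logL == pytest.approx(ref.llf, abs=1e-6)

    def test_matches_dense_grid_search(self, lsd_fixture_20):
        """Brute-force oracle: best (b0, b1) on a 0.01 grid over [-10, 10]."""
        labels, bundle = lsd_fixture_20
        fit = fit_lsd(labels, bundle, ["x"])
        x = bundle.site_covs["x"]
        z = labels.z.astype(float)
        grid = np.arange(-10.0, 10.0 + 1e-9, 0.01)
        best = (np.inf, None, None)
        for b0_chunk in np.array_split(grid, 40):
            eta = b0_chunk[:, None, None] + grid[None, :, None] * x[None, None, :]
            nll = (np.logaddexp(0.0, eta) - z * eta).sum(axis=2)
            i, j = np.unravel_index(np.argmin(nll), nll.shape)
            if nll[i, j] < best[0]:
                best = (nll[i, j], b0_chunk[i], grid[j])
        assert fit.intercept == pytest.approx(best[1], abs=0.02)
        assert fit.betas["x"] == pytest.approx(best[2], abs=0.02)

    def test_all_identical_labels_is_error(self):
        ids, bundle = _bundle(x=[1.0, 2.0, 3.0])
        labels = PersistenceLabels(ids, np.ones(3, dtype=np.int8))
        with pytest.raises(EstimationError):
            fit_lsd(labels, bundle, ["x"])

    def test_separation_flagged_not_raised(self):
        x = np.r_[np.zeros(5), np.ones(5)]
        z = x.astype(np.int8)  # perfect separation
        ids, bundle = _bundle(x=x)
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_lsd(PersistenceLabels(ids, z), bundle, ["x"])
        assert fit.separation_flag and not fit.converged

    def test_covariate_shift_moves_only_intercept(self, lsd_fixture_20):
        labels, bundle = lsd_fixture_20
        fit = fit_lsd(labels, bundle, ["x"])
        shifted = CovariateBundle(bundle.site_ids, {"x": bundle.site_covs["x"] + 7.5})
        fit2 = fit_lsd(labels, shifted, ["x"])
        assert fit2.betas["x"] == pytest.approx(fit.betas["x"], abs=1e-6)
        assert fit2.intercept != pytest.approx(fit.intercept, abs=0.1)
        # score ratios between sites are unchanged by the shift
        s1 = lsd_scores(fit, bundle)
        s2 = lsd_scores(fit2, shifted)
        np.testing.assert_allclose(s1 / s1[0], s2 / s2[0], rtol=1e-6)

    def test_recovers_truth_at_large_n(self):
        rng = np.random.default_rng(555)
        n = 2000
        x = rng.normal(size=n)
        from scipy.special import expit

        z = (rng.random(n) < expit(-0.5 + 0.9 * x)).astype(np.int8)
        ids = tuple(f"S{i}" for i in range(n))
        fit = fit_lsd(PersistenceLabels(ids, z), CovariateBundle(ids, {"x": x}), ["x"])
        assert abs(fit.betas["x"] - 0.9) < 0.1
        assert abs(fit.intercept + 0.5) < 0.1


class TestLsdScore:
    def test_zero_betas_score_one(self, lsd_fixture_20):
        labels, bundle = lsd_fixture_20
        fit = fit_lsd(labels, bundle, ["x"])
        zero = fit.__class__(**{**fit.__dict__, "betas": {"x": 0.0}})
        assert lsd_score(zero, {"x": 123.0}) == 1.0

    def test_intercept_excluded(self):
        from persistlsd import LsdFit

        fit = LsdFit("m", intercept=5.0, intercept_se=1.0, betas={"a": 2.0, "b": -1.0},
                     ses={"a": 0.1, "b": 0.1}, logL=-1.0, n_used=4, converged=True,
                     separation_flag=False)
        assert lsd_score(fit, {"a": 1.0, "b": 2.0}) == pytest.approx(1.0)

    def test_doubling_covariates_doubles_log_score(self):
        from persistlsd import LsdFit

        fit = LsdFit("m", 0.0, 0.0, {"a": 0.7, "b": -0.3}, {"a": 0.1, "b": 0.1},
                     -1.0, 4, True, False)
        x = {"a": 1.3, "b": 2.1}
        x2 = {k: 2 * v for k, v in x.items()}
        assert np.log(lsd_score(fit, x2)) == pytest.approx(2 * np.log(lsd_score(fit, x)))

    def test_missing_term_raises(self):
        from persistlsd import LsdFit

        fit = LsdFit("m", 0.0, 0.0, {"a": 1.0}, {"a": 0.1}, -1.0, 4, True, False)
        with pytest.raises(KeyError):
            lsd_score(fit, {"b": 1.0})


class TestScreening:
    @pytest.fixture
    def triad(self):
        """10 sites; A and B strongly correlated, C moderately with B,
        nearly orthogonal to A; labels track A."""
        rng = np.random.default_rng(99)
        a = np.linspace(-1.5, 1.5, 10)
        b = a + rng.normal(scale=0.35, size=10)
        c_raw = rng.normal(size=10)
        # project out A so corr(A, C) ~ 0, then blend in B
        c = 0.8 * (c_raw - np.polyval(np.polyfit(a, c_raw, 1), a)) + 0.9 * (b - a)
        z = np.array([0, 0, 0, 1, 0, 1, 1, 1, 1, 1], dtype=np.int8)
        ids = tuple(f"S{i}" for i in range(10))
        bundle = CovariateBundle(ids, {"A": a, "B": b, "C": c})
        return PersistenceLabels(ids, z), bundle

    def test_greedy_trace_matches_hand_rule(self, triad):
        """Independent oracle: univariate AICc from statsmodels, pairwise r
        from numpy, greedy rule applied by hand in the test."""
        labels, bundle = triad
        report = screen_collinearity(bundle, ["A", "B", "C"], labels, threshold=0.65)

        corr = np.corrcoef([bundle.site_covs[k] for k in ("A", "B", "C")])
        scores = {}
        for name in ("A", "B", "C"):
            X = sm.add_constant(bundle.site_covs[name])
            scores[name] = aicc(sm.Logit(labels.z, X).fit(disp=0).llf, K=2, n=10)
        # independent greedy trace: largest |r| first, drop the member
        # with the worse univariate AICc, skip pairs touching a drop
        names = ("A", "B", "C")
        assert abs(corr[0, 1]) > 0.65  # the fixture's only guaranteed hot pair
        pairs = sorted(
            ((abs(corr[i, j]), names[i], names[j]) for i in range(3) for j in range(i + 1, 3)),
            key=lambda t: -t[0],
        )
        dropped: list[tuple[str, str]] = []
        gone: set[str] = set()
        for r_abs, u, v in pairs:
            if r_abs <= 0.65 or u in gone or v in gone:
                continue
            worse = u if scores[u] > scores[v] else v
            gone.add(worse)
            dropped.append((worse, u if worse == v else v))
        assert set(report.retained) == set(names) - gone
        assert [(d, k) for d, k, _ in report.dropped] == dropped
        for name in ("A", "B", "C"):
            assert report.univariate_scores[name] == pytest.approx(scores[name], abs=1e-4)

    def test_proportional_pair_keeps_better_univariate(self, triad):
        labels, bundle = triad
        b2 = CovariateBundle(
            bundle.site_ids,
            {"A": bundle.site_covs["A"], "A2": 2.0 * bundle.site_covs["A"] + 1.0},
        )
        report = screen_collinearity(b2, ["A", "A2"], labels)
        assert len(report.retained) == 1
        # identical predictive ability (affine copy): tie broken alphabetically
        assert report.retained == ("A",)

    def test_orthogonal_pair_both_kept(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        b -= np.polyval(np.polyfit(a, b, 1), a)  # exact sample orthogonality
        ids = tuple(f"S{i}" for i in range(30))
        z = (a + rng.normal(size=30) > 0).astype(np.int8)
        report = screen_collinearity(
            CovariateBundle(ids, {"a": a, "b": b}), ["a", "b"], PersistenceLabels(ids, z)
        )
        assert set(report.retained) == {"a", "b"}

    def test_threshold_is_strict_inequality(self):
        # engineer |r| exactly at the threshold via a 2-point structure
        a = np.array([0.0, 1.0, 2.0, 3.0])
        ids = ("a", "b", "c", "d")
        z = np.array([0, 1, 0, 1], dtype=np.int8)
        bundle = CovariateBundle(ids, {"A": a, "B": a.copy()})
        report = screen_collinearity(
            bundle, ["A", "B"], PersistenceLabels(ids, z), threshold=1.0
        )
        assert set(report.retained) == {"A", "B"}  # r == threshold: both kept

    def test_constant_covariate_excluded_with_warning(self, triad):
        labels, bundle = triad
        b2 = CovariateBundle(
            bundle.site_ids,
            {**{k: v for k, v in bundle.site_covs.items()}, "flat": np.ones(10)},
        )
        with pytest.warns(UserWarning, match="constant"):
            report = screen_collinearity(b2, ["A", "B", "C", "flat"], labels)
        assert report.excluded_constant == ("flat",)
        assert "flat" not in report.retained
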