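import numpy as np
import pandas as pd
import pytest

from lncpair.pairs import PairMatrix
from lncpair.published import LUAD_SIGNATURE_ROWS
from lncpair.signature import (
    RiskProfile,
    SignatureModel,
    Z95,
    build_signature,
    compute_risk_scores,
    efron_log_partial_likelihood,
    fit_cox,
    fit_lasso_cox,
    univariate_screen,
)


# ---------------------------------------------------------------------------
# Independent oracle: direct Efron partial likelihood + dense grid search
# ---------------------------------------------------------------------------


def efron_lpl_oracle(beta, x, times, events):
    """Straight-from-the-definition Efron log partial likelihood (1 covariate)."""
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        tied = np.flatnonzero((times == t) & (events == 1))
        risk = np.flatnonzero(times >= t)
        d = len(tied)
        s_risk = sum(np.exp(beta * x[i]) for i in risk)
        s_tied = sum(np.exp(beta * x[i]) for i in tied)
        ll += sum(beta * x[i] for i in tied)
        for ell in range(d):
            ll -= np.log(s_risk - ell / d * s_tied)
    return ll


def grid_mle(x, times, events, lo=-5.0, hi=5.0, step=1e-3):
    grid = np.arange(lo, hi + step, step)
    lls = [efron_lpl_oracle(b, x, times, events) for b in grid]
    return grid[int(np.argmax(lls))]


TOY_FIXTURES = [
    # (times, events, x) — small datasets with ties and censoring
    ([1, 1, 2, 3, 4, 4, 5, 6], [1, 0, 1, 1, 1, 0, 1, 0], [1, 0, 1, 1, 0, 0, 1, 0]),
    ([2, 2, 2, 5, 6, 7], [1, 1, 0, 1, 1, 1], [0, 1, 1, 0, 1, 0]),
    ([1, 2, 3, 4, 5, 6, 7, 8, 9, 10], [1, 1, 1, 0, 1, 0, 1, 1, 0, 1], [1, 1, 0, 1, 0, 0, 1, 0, 1, 0]),
]


class TestFitCox:
    @pytest.mark.parametrize("times,events,x", TOY_FIXTURES)
    def test_matches_brute_force_partial_likelihood(self, times, events, x):
        times = np.array(times, dtype=float)
        events = np.array(events)
        x = np.array(x, dtype=float)
        res = fit_cox(pd.DataFrame({"x": x}), times, events)[0]
        beta_grid = grid_mle(x, times, events)
        assert res.beta == pytest.approx(beta_grid, abs=1.5e-3)
        # and the package's own Efron evaluation agrees with the oracle
        ll_pkg = efron_log_partial_likelihood(np.array([res.beta]), x[:, None], times, events)
        assert ll_pkg == pytest.approx(efron_lpl_oracle(res.beta, x, times, events), abs=1e-10)

    def test_hr_and_ci_identities(self):
        times, events, x = (np.array(v, dtype=float) for v in TOY_FIXTURES[0])
        res = fit_cox(pd.DataFrame({"x": x}), times, events.astype(int))[0]
        assert res.hr == pytest.approx(np.exp(res.beta), rel=1e-15)
        assert np.sqrt(res.ci_low * res.ci_high) == pytest.approx(res.hr, rel=1e-12)
        assert res.ci_low <= res.hr <= res.ci_high

    def test_null_covariate_beta_near_zero(self):
        rng = np.random.default_rng(21)
        n = 300
        times = rng.exponential(100, n)
        events = rng.integers(0, 2, n)
        x = rng.integers(0, 2, n).astype(float)  # independent of survival
        res = fit_cox(pd.DataFrame({"x": x}), times, events)[0]
        assert abs(res.beta) < 0.5
        assert res.p > 1e-4

    def test_zero_events_and_constant_covariate_errors(self):
        df = pd.DataFrame({"x": [0.0, 1.0, 0.0, 1.0]})
        with pytest.raises(ValueError, match="no events"):
            fit_cox(df, np.arange(1.0, 5.0), np.zeros(4, dtype=int))
        with pytest.raises(ValueError, match="constant"):
            fit_cox(pd.DataFrame({"x": [1.0] * 4}), np.arange(1.0, 5.0), np.array([1, 0, 1, 0]))

    def test_collinear_covariates_flagged(self):
        rng = np.random.default_rng(22)
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        times = rng.exponential(50, n)
        events = np.ones(n, dtype=int)
        res = fit_cox(pd.DataFrame({"a": x, "b": x}), times, events)
        assert not all(r.converged for r in res)


def _pm_from_matrix(ind, samples=None):
    k = ind.shape[0]
    genes = [f"G{i}" for i in range(2 * k)]
    pairs = [(genes[2 * i], genes[2 * i + 1]) for i in range(k)]
    samples = samples or [f"S{i}" for i in range(ind.shape[1])]
    return PairMatrix(pairs=pairs, samples=samples, indicator=ind.astype(np.int8))


def _ph_cohort(rng, X, betas, lam=0.01, censor=0.005):
    eta = X @ betas
    t_event = rng.exponential(1.0, len(eta)) / (lam * np.exp(eta - eta.mean()))
    t_cens = rng.exponential(1.0 / censor, len(eta))
    return np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int)


class TestUnivariateScreen:
    def test_alpha_zero_empty_and_null_calibration(self):
        rng = np.random.default_rng(23)
        ind = rng.integers(0, 2, size=(40, 200))
        pm = _pm_from_matrix(ind)
        times = rng.exponential(100, 200)
        events = rng.integers(0, 2, 200)
        names, results = univariate_screen(pm, times, events, alpha=0.0)
        assert names == []
        names05, _ = univariate_screen(pm, times, events, alpha=0.05)
        assert len(names05) <= 8  # ~5% of 40 null pairs, generous bound

    def test_planted_pair_retained(self):
        rng = np.random.default_rng(24)
        ind = rng.integers(0, 2, size=(10, 300))
        times, events = _ph_cohort(rng, ind.T.astype(float), np.array([0.9] + [0.0] * 9))
        pm = _pm_from_matrix(ind)
        names, _ = univariate_screen(pm, times, events, alpha=0.05)
        assert pm.pair_names[0] in names


class TestLassoCox:
    def test_path_endpoints_and_selection(self):
        rng = np.random.default_rng(25)
        n, p = 300, 30
        ind = rng.integers(0, 2, size=(n, p)).astype(float)
        betas = np.zeros(p)
        betas[0] = 1.0  # one strong planted pair among noise
        times, events = _ph_cohort(rng, ind, betas)
        X = pd.DataFrame(ind, columns=[f"P{i}" for i in range(p)])
        res = fit_lasso_cox(X, times, events, n_folds=5, seed=0)
        # definition of lambda_max: the largest penalty zeroes everything
        assert not np.any(res.coef_path[:, 0])
        # active set grows from the lambda_max end of the path
        nnz = (res.coef_path != 0).sum(axis=0)
        assert nnz[0] <= nnz[-1]
        assert "P0" in res.selected
        assert res.coefs["P0"] > 0

    def test_penalty_free_limit_matches_unpenalized_fit(self):
        rng = np.random.default_rng(26)
        n = 400
        ind = rng.integers(0, 2, size=(n, 3)).astype(float)
        times, events = _ph_cohort(rng, ind, np.array([0.8, -0.5, 0.3]))
        X = pd.DataFrame(ind, columns=["a", "b", "c"])
        res = fit_lasso_cox(X, times, events, n_folds=5, seed=1, alphas=[0.01, 1e-4, 1e-9])
        full = {r.covariate: r.beta for r in fit_cox(X, times, events)}
        final = res.coef_path[:, -1]
        for j, c in enumerate(X.columns):
            assert final[j] == pytest.approx(full[c], abs=1e-3)

    def test_too_few_candidates_error(self):
        with pytest.raises(ValueError, match=">= 2 candidate"):
            fit_lasso_cox(pd.DataFrame({"a": [0.0, 1.0]}), np.array([1.0, 2.0]), np.array([1, 1]))


class TestSignatureAndRiskScore:
    def test_single_pair_signature_support(self):
        rng = np.random.default_rng(27)
        ind = rng.integers(0, 2, size=(2, 200))
        pm = _pm_from_matrix(ind)
        times, events = _ph_cohort(rng, ind.T.astype(float), np.array([0.8, 0.0]))
        model, results = build_signature([pm.pair_names[0]], pm, times, events)
        assert len(model.terms) == 1
        profile = compute_risk_scores(pm, model)
        beta = model.terms[0][1]
        assert set(np.round(profile.scores.unique(), 12)) <= {0.0, round(beta, 12)}

    def test_collinear_pair_dropped_with_first_kept(self, caplog):
        rng = np.random.default_rng(28)
        row = rng.integers(0, 2, size=200)
        ind = np.vstack([row, row, rng.integers(0, 2, size=200)])
        pm = _pm_from_matrix(ind)
        times, events = _ph_cohort(rng, ind.T.astype(float), np.array([0.5, 0.0, 0.0]))
        with caplog.at_level("WARNING"):
            model, _ = build_signature(pm.pair_names, pm, times, events)
        assert model.pair_names == [pm.pair_names[0], pm.pair_names[2]]
        assert "collinear" in caplog.text

    def test_risk_score_formula_and_linearity(self):
        ind = np.array([[1, 0, 1], [1, 1, 0]], dtype=np.int8)
        pm = _pm_from_matrix(ind)
        model = SignatureModel(terms=[(pm.pair_names[0], 0.5), (pm.pair_names[1], -0.25)])
        profile = compute_risk_scores(pm, model)
        assert profile.scores.tolist() == pytest.approx([0.25, -0.25, 0.5])
        doubled = SignatureModel(terms=[(n, 2 * b) for n, b in model.terms])
        assert compute_risk_scores(pm, doubled).scores.tolist() == pytest.approx(
            [0.5, -0.5, 1.0]
        )
        # all-zero indicators -> score 0
        pm0 = _pm_from_matrix(np.zeros((2, 3), dtype=np.int8))
        model0 = SignatureModel(terms=[(pm0.pair_names[0], 0.5), (pm0.pair_names[1], -0.25)])
        assert compute_risk_scores(pm0, model0).scores.tolist() == [0.0, 0.0, 0.0]

    def test_missing_pair_error_names_it(self):
        pm = _pm_from_matrix(np.array([[1, 0]], dtype=np.int8))
        model = SignatureModel(terms=[("X|Y", 1.0)])
        with pytest.raises(KeyError, match="X\\|Y"):
            compute_risk_scores(pm, model)

    def test_published_signature_all_indicators_one(self):
        # a patient ranking every pair's first gene above the second scores the
        # coefficient sum of the published eight-pair model
        total = sum(row[1] for row in LUAD_SIGNATURE_ROWS)
        ind = np.ones((8, 1), dtype=np.int8)
        genes = [r[0] for r in LUAD_SIGNATURE_ROWS]
        pairs = [tuple(g.split("|")) for g in genes]
        pm = PairMatrix(pairs=pairs, samples=["P1"], indicator=ind)
        model = SignatureModel(terms=[(r[0], r[1]) for r in LUAD_SIGNATURE_ROWS])
        score = compute_risk_scores(pm, model).scores["P1"]
        assert score == pytest.approx(total)
        assert score == pytest.approx(-0.2006424, abs=1e-6)
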