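"""Composite quality index: eigen-oracle equivalence and scoring."""

import math

import numpy as np
import pytest

from astraqc import (
    PUBLISHED_COMPOSITE_WEIGHTS,
    CompositeModel,
    composite_report,
    fit_composite,
    score_composite,
)
from astraqc.composite import load_model, save_model
from astraqc.records import IndicatorPanel


def brute_force_reference(X, preprocessing="correlation"):
    """Independent oracle: eigendecomposition via SVD of the centred
    (and scaled) data matrix, no shared code with fit_composite."""
    X = np.asarray(X, float)
    n = X.shape[0]
    Z = X - X.mean(axis=0)
    if preprocessing == "correlation":
        Z = Z / X.std(axis=0, ddof=1)
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (n - 1)
    return eigvals / eigvals.sum(), Vt


def fix_sign(v):
    return -v if v[np.argmax(np.abs(v))] < 0 else v


@pytest.mark.parametrize("preprocessing", ["correlation", "covariance"])
def test_fit_matches_svd_oracle_on_random_matrices(rng, preprocessing):
    """Contributions, retained eigenvectors and combined weights agree
    with an independent SVD-based reference to 1e-9 on 100 random
    48 x 4 matrices."""
    for _ in range(100):
        X = rng.uniform(0, 1, size=(48, 4)) * np.array([3.0, 2.0, 0.3, 0.05])
        model = fit_composite(X, preprocessing=preprocessing)
        contrib, Vt = brute_force_reference(X, preprocessing)
        assert np.allclose(model.contributions, contrib, atol=1e-9)
        expected_w = np.zeros(4)
        for k in range(model.retained_k):
            v = fix_sign(Vt[k])
            assert np.allclose(model.eigenvectors[k], v, atol=1e-9)
            expected_w += contrib[k] * v
        assert np.allclose(model.weights, expected_w, atol=1e-9)
        assert model.cumulative_contribution == pytest.approx(
            contrib[: model.retained_k].sum(), abs=1e-9
        )
        assert model.cumulative_contribution >= 0.85


def test_contribution_identities(rng):
    X = rng.normal(size=(48, 4))
    model = fit_composite(X)
    assert sum(model.contributions) == pytest.approx(1.0, abs=1e-9)
    assert list(model.contributions) == sorted(model.contributions, reverse=True)
    for v in model.eigenvectors:
        assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)


def test_two_variable_closed_form_eigenstructure():
    """Data with sample covariance [[2,1],[1,2]] has eigenvalues 3 and 1,
    hence contributions 0.75 / 0.25."""
    base = np.array([[1.0, 1.0 / math.sqrt(3)],
                     [0.0, -2.0 / math.sqrt(3)],
                     [-1.0, 1.0 / math.sqrt(3)]])  # orthogonal columns, unit sample variance
    L = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 2.0]]))
    X = base @ L.T
    assert np.allclose(np.cov(X, rowvar=False), [[2, 1], [1, 2]], atol=1e-12)
    model = fit_composite(X, preprocessing="covariance", threshold=1.0,
                          indicator_names=("u", "v"))
    assert model.contributions == pytest.approx((0.75, 0.25), abs=1e-12)


def test_rank_one_limit_retains_single_pc(rng):
    """Perfectly collinear positive columns: k = 1, cumulative 1.0,
    weights proportional to the first eigenvector."""
    t = rng.uniform(1, 2, size=12)
    X = np.outer(t, [1.0, 2.0, 3.0, 4.0])
    model = fit_composite(X, preprocessing="covariance")
    assert model.retained_k == 1
    assert model.cumulative_contribution == pytest.approx(1.0, abs=1e-9)
    v = np.asarray(model.eigenvectors[0])
    assert np.allclose(model.weights, model.contributions[0] * v, atol=1e-12)


def test_zero_variance_column_named():
    X = np.ones((10, 4))
    X[:, [0, 1, 3]] = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(ValueError, match="polysaccharides"):
        fit_composite(X)


def test_too_few_samples_rejected(rng):
    with pytest.raises(ValueError, match="samples"):
        fit_composite(rng.normal(size=(3, 4)))


def test_sample_order_invariance(rng):
    X = rng.normal(size=(48, 4))
    a = fit_composite(X)
    b = fit_composite(X[rng.permutation(48)])
    assert np.allclose(a.weights, b.weights, atol=1e-9)
    assert np.allclose(a.contributions, b.contributions, atol=1e-9)


def test_correlation_preprocessing_is_scale_invariant(rng):
    X = rng.normal(size=(48, 4)) + 5
    scaled = X * np.array([1.0, 1000.0, 0.01, 1.0])
    a = fit_composite(X, preprocessing="correlation")
    b = fit_composite(scaled, preprocessing="correlation")
    assert np.allclose(a.weights, b.weights, atol=1e-9)
    za = [score_composite(a, row) for row in X]
    zb = [score_composite(b, row) for row in scaled]
    assert np.allclose(za, zb, atol=1e-9)


# --- scoring ---------------------------------------------------------------


def test_published_weights_on_unit_panel():
    model = CompositeModel.from_weights(PUBLISHED_COMPOSITE_WEIGHTS)
    assert score_composite(model, [1.0, 1.0, 1.0, 1.0]) == pytest.approx(75.055)
    assert score_composite(model, [0.0, 0.0, 0.0, 0.0]) == 0.0


def test_explicit_weight_scoring_is_linear(rng):
    model = CompositeModel.from_weights(PUBLISHED_COMPOSITE_WEIGHTS)
    x, y = rng.uniform(0, 2, 4), rng.uniform(0, 2, 4)
    assert score_composite(model, x + y) == pytest.approx(
        score_composite(model, x) + score_composite(model, y), rel=1e-12
    )


def test_fitted_model_scores_zero_at_column_means(rng):
    X = rng.uniform(1, 3, size=(20, 4))
    model = fit_composite(X)
    assert score_composite(model, X.mean(axis=0)) == pytest.approx(0.0, abs=1e-9)


def test_model_save_load_round_trip(tmp_path, rng):
    X = rng.normal(size=(20, 4))
    model = fit_composite(X)
    save_model(model, tmp_path / "model.txt")
    back = load_model(tmp_path / "model.txt")
    assert back == model


# --- cohort report ---------------------------------------------------------


def panel(sid, values):
    names = ("calycosin_glucoside", "astragaloside_iv", "polysaccharides", "extracts")
    return IndicatorPanel(sample_id=sid, **dict(zip(names, values)))


def test_report_ranks_descending_with_stable_ties():
    model = CompositeModel.from_weights([1.0, 0.0, 0.0, 0.0])
    panels = [panel("b", [2, 0, 0, 0]), panel("c", [5, 0, 0, 0]), panel("a", [2, 0, 0, 0])]
    report = composite_report(model, panels)
    assert list(report.scores["sample_id"]) == ["c", "a", "b"]


def test_report_empty_panel_list():
    model = CompositeModel.from_weights(PUBLISHED_COMPOSITE_WEIGHTS)
    report = composite_report(model, [])
    assert len(report.scores) == 0


def test_dominating_group_scores_higher(study_cohort):
    """With positive weights, panels that dominate component-wise score
    higher on average; the perennial group dominates by construction."""
    samples, panels = study_cohort
    model = CompositeModel.from_weights([43.563, 27.067, 6.978, 0.0])
    report = composite_report(model, panels, samples)
    joined = dict(zip(report.scores["sample_id"], report.scores["F"]))
    pa = np.mean([joined[s.sample_id] for s in samples if s.cultivation == "PA"])
    fa = np.mean([joined[s.sample_id] for s in samples if s.cultivation == "FA"])
    assert pa > fa


def test_samples_without_panels_are_skipped_with_reason(study_cohort, caplog):
    samples, panels = study_cohort
    model = CompositeModel.from_weights(PUBLISHED_COMPOSITE_WEIGHTS)
    with caplog.at_level("WARNING", logger="astraqc.composite"):
        report = composite_report(model, panels[:-2], samples)
    assert set(report.skipped) == {samples[-2].sample_id, samples[-1].sample_id}
    assert len(report.scores) == len(samples) - 2
    assert any("missing_indicator_panel" in m for m in caplog.messages)
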