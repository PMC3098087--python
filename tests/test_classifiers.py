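import numpy as np
import pytest
from scipy import optimize, stats
from scipy.special import expit

from imbsim.core import CLASS1, CLASS2
from imbsim.classifiers import (
    DLDA,
    DQDA,
    KNN,
    PAM,
    PLR,
    LinearSVM,
    RandomForest,
    make_classifier,
)


def two_class_data(rng, n1=8, n2=8, p=5, shift=0.0):
    X = rng.standard_normal((n1 + n2, p))
    X[n1:] += shift
    y = np.concatenate([np.full(n1, CLASS1), np.full(n2, CLASS2)])
    return X, y


# ---------------------------------------------------------------- k-NN


def test_knn_rejects_even_k():
    with pytest.raises(ValueError, match="odd"):
        KNN(k=2)


def test_knn_memorizes_training_points(rng):
    X, y = two_class_data(rng, shift=0.5)
    model = KNN(k=1).fit(X, y)
    np.testing.assert_array_equal(model.predict(X), y)


def test_knn_majority_vote_and_score():
    X = np.array([[0.0], [0.1], [2.0]])
    y = np.array([CLASS1, CLASS1, CLASS2])
    model = KNN(k=3).fit(X, y)
    assert model.predict([[0.05]])[0] == CLASS1
    assert model.score([[0.05]])[0] == pytest.approx(2 / 3)


def test_knn_matches_bruteforce_scan(rng):
    """Predictions equal an exhaustive O(n^2) nearest-neighbour scan."""
    Xtr, ytr = two_class_data(rng, n1=5, n2=5, p=5)
    Xte = rng.standard_normal((12, 5))
    for k in (1, 3, 5):
        model = KNN(k=k).fit(Xtr, ytr)
        expected = []
        for x in Xte:
            d = [(np.sum((x - xt) ** 2), i) for i, xt in enumerate(Xtr)]
            d.sort()  # ties fall to the lowest index
            votes = [ytr[i] for _, i in d[:k]]
            expected.append(CLASS1 if votes.count(CLASS1) > k / 2 else CLASS2)
        np.testing.assert_array_equal(model.predict(Xte), expected)


# ---------------------------------------------------------------- DLDA / DQDA


def gaussian_density_scores(X, Xtr, ytr, pooled):
    """Independent oracle: diagonal-Gaussian log densities, equal priors."""
    x1, x2 = Xtr[ytr == CLASS1], Xtr[ytr == CLASS2]
    m1, m2 = x1.mean(0), x2.mean(0)
    if pooled:
        n1, n2 = len(x1), len(x2)
        v = ((n1 - 1) * x1.var(0, ddof=1) + (n2 - 1) * x2.var(0, ddof=1)) / (n1 + n2 - 2)
        v1 = v2 = v
    else:
        v1, v2 = x1.var(0, ddof=1), x2.var(0, ddof=1)
    ll1 = stats.norm.logpdf(X, m1, np.sqrt(v1)).sum(axis=1)
    ll2 = stats.norm.logpdf(X, m2, np.sqrt(v2)).sum(axis=1)
    return ll1 - ll2


def test_dlda_single_variable_and_midpoint_tie():
    X = np.array([[-0.5], [0.5], [1.5], [2.5]])
    y = np.array([CLASS1, CLASS1, CLASS2, CLASS2])
    model = DLDA().fit(X, y)
    assert model.predict([[0.5]])[0] == CLASS1  # nearer standardized centroid
    assert model.predict([[1.0]])[0] == CLASS1  # exact midpoint: "<=" tie rule


@pytest.mark.parametrize("cls, pooled", [(DLDA, True), (DQDA, False)])
def test_diagonal_da_agree_with_density_oracle(rng, cls, pooled):
    Xtr, ytr = two_class_data(rng, n1=6, n2=6, p=4, shift=1.0)
    Xte = rng.standard_normal((30, 4)) + 0.5
    model = cls().fit(Xtr, ytr)
    oracle = gaussian_density_scores(Xte, Xtr, ytr, pooled)
    np.testing.assert_array_equal(model.predict(Xte), np.where(oracle >= 0, CLASS1, CLASS2))
    # score orientation agrees in sign with the log-density difference
    assert (np.sign(model.score(Xte)) == np.sign(oracle)).all()


def test_dqda_prefers_high_variance_class_in_tails():
    # means 0/0, variances ~1 vs ~100: x*=3 gives 9 vs 0.09 + log 100 -> Class 2
    x1 = np.array([[-1.0], [1.0]])        # var 2 -> scaled below
    x1 = np.array([[-1.0], [1.0]]) / np.sqrt(2)   # var exactly 1
    x2 = np.array([[-10.0], [10.0]]) / np.sqrt(2)  # var exactly 100
    X = np.vstack([x1, x2])
    y = np.array([CLASS1, CLASS1, CLASS2, CLASS2])
    model = DQDA().fit(X, y)
    assert model.predict([[3.0]])[0] == CLASS2


def test_dqda_reduces_to_dlda_with_equal_class_variances(rng):
    x1 = rng.standard_normal((5, 3))
    x2 = x1 + 1.0  # identical within-class variances by construction
    X, y = np.vstack([x1, x2]), np.array([CLASS1] * 5 + [CLASS2] * 5)
    Xte = rng.standard_normal((20, 3)) + 0.5
    np.testing.assert_array_equal(
        DLDA().fit(X, y).predict(Xte), DQDA().fit(X, y).predict(Xte)
    )


def test_dlda_drops_zero_variance_variable_with_warning(rng):
    Xtr, ytr = two_class_data(rng, p=3, shift=1.0)
    Xtr[:, 1] = 7.0
    with pytest.warns(RuntimeWarning, match="zero-variance"):
        model = DLDA().fit(Xtr, ytr)
    assert model.keep.sum() == 2
    assert np.isfinite(model.score(Xtr)).all()


# ---------------------------------------------------------------- PAM


def test_pam_hand_computed_soft_thresholding(rng):
    """Shrunken centroids match the soft-threshold algebra d' = sign(d)(|d|-D)+."""
    Xtr, ytr = two_class_data(rng, n1=3, n2=3, p=3, shift=2.0)
    model = PAM().fit(Xtr, ytr)
    x1, x2 = Xtr[ytr == CLASS1], Xtr[ytr == CLASS2]
    overall = Xtr.mean(0)
    cent = np.vstack([x1.mean(0), x2.mean(0)])
    s = np.sqrt((((x1 - cent[0]) ** 2).sum(0) + ((x2 - cent[1]) ** 2).sum(0)) / 4)
    s0 = np.median(s)
    mk = np.sqrt(np.array([1 / 3 - 1 / 6, 1 / 3 - 1 / 6]))[:, None]
    d = (cent - overall) / (mk * (s + s0))
    dshr = np.sign(d) * np.maximum(np.abs(d) - model.delta, 0.0)
    expected = overall + mk * (s + s0) * dshr
    np.testing.assert_allclose(model.centroids, expected, rtol=1e-10)


def test_pam_zero_threshold_is_nearest_centroid_with_priors(rng):
    Xtr, ytr = two_class_data(rng, n1=5, n2=5, p=4, shift=3.0)
    model = PAM(n_thresholds=1).fit(Xtr, ytr)  # grid = {0}: no shrinkage
    assert model.delta == 0.0
    Xte = rng.standard_normal((10, 4)) + 1.5
    x1, x2 = Xtr[ytr == CLASS1], Xtr[ytr == CLASS2]
    s = np.sqrt((((x1 - x1.mean(0)) ** 2).sum(0) + ((x2 - x2.mean(0)) ** 2).sum(0)) / 8)
    s0 = np.median(s)
    d1 = (((Xte - x1.mean(0)) / (s + s0)) ** 2).sum(1)
    d2 = (((Xte - x2.mean(0)) / (s + s0)) ** 2).sum(1)
    np.testing.assert_array_equal(model.predict(Xte), np.where(d1 <= d2, CLASS1, CLASS2))


def test_pam_full_shrinkage_classifies_to_larger_prior(rng):
    # under the null, full shrinkage leaves only the -2 log(pi_k) terms
    X = rng.standard_normal((10, 3))
    y = np.array([CLASS1] * 3 + [CLASS2] * 7)
    model = PAM().fit(X, y)
    cents = model._shrunken_centroids(np.abs(model._d).max() + 1.0)
    pred = model._classify(rng.standard_normal((50, 3)), cents)
    assert (pred == CLASS2).all()


# ---------------------------------------------------------------- PLR


def plr_objective(theta, X, y01, lam):
    eta = theta[0] + X @ theta[1:]
    return float(np.sum(np.logaddexp(0, eta) - y01 * eta) + lam / 2 * np.sum(theta[1:] ** 2))


def test_plr_matches_blackbox_optimizer(rng):
    """Newton-Raphson coefficients agree with a generic optimizer to 1e-6."""
    X, y = two_class_data(rng, n1=5, n2=5, p=3, shift=1.0)
    model = PLR(lam=1.0).fit(X, y)
    y01 = (y == CLASS1).astype(float)
    res = optimize.minimize(
        plr_objective, np.zeros(4), args=(X, y01, 1.0), method="BFGS",
        options={"gtol": 1e-10, "maxiter": 1000},
    )
    np.testing.assert_allclose(model.coef_, res.x, atol=1e-6)


def test_plr_heavy_penalty_shrinks_to_intercept(rng):
    X, y = two_class_data(rng, n1=3, n2=7, p=4, shift=1.0)
    model = PLR(lam=1e8).fit(X, y)
    assert np.abs(model.coef_[1:]).max() < 1e-5
    np.testing.assert_allclose(model.score(X), 0.3, atol=1e-3)  # training proportion


def test_plr_symmetric_two_point_problem():
    X = np.array([[1.0], [-1.0]])
    y = np.array([CLASS1, CLASS2])
    model = PLR(lam=1.0).fit(X, y)
    assert model.score([[0.0]])[0] == pytest.approx(0.5, abs=1e-10)


def test_plr_threshold_variant_uses_k1train(rng):
    X, y = two_class_data(rng, n1=4, n2=16, p=3, shift=1.0)
    base = make_classifier("plr").fit(X, y)
    thr = make_classifier("plr_thr", k1train=0.2).fit(X, y)
    np.testing.assert_allclose(base.coef_, thr.coef_)  # same fit, different cutoffs
    p_hat = base.score(X)
    np.testing.assert_array_equal(thr.predict(X), np.where(p_hat > 0.2, CLASS1, CLASS2))
    assert (thr.predict(X) == CLASS1).sum() >= (base.predict(X) == CLASS1).sum()


# ---------------------------------------------------------------- RF / SVM adapters


def test_rf_requires_two_classes(rng):
    X = rng.standard_normal((6, 3))
    with pytest.raises(ValueError):
        RandomForest(n_trees=10).fit(X, np.full(6, CLASS1))


def test_rf_cutoff_contract_and_separable_blobs(rng):
    X, y = two_class_data(rng, n1=10, n2=10, p=4, shift=6.0)
    model = RandomForest(n_trees=50, cutoff=0.5, seed=0).fit(X, y)
    assert (model.predict(X) == y).all()
    scores = model.score(X)
    assert ((scores >= 0) & (scores <= 1)).all()
    strict = RandomForest(n_trees=50, cutoff=0.99, seed=0).fit(X, y)
    # raising the cutoff can only move predictions toward Class 2
    assert ((strict.predict(X) == CLASS1) <= (model.predict(X) == CLASS1)).all()


def test_svm_midpoint_boundary_and_label_flip(rng):
    X = np.array([[1.0], [-1.0], [2.0], [-2.0]])
    y = np.array([CLASS1, CLASS2, CLASS1, CLASS2])
    model = LinearSVM().fit(X, y)
    assert abs(model.score([[0.0]])[0]) < 1e-6  # boundary near 0 by symmetry
    Xr, yr = two_class_data(rng, n1=8, n2=8, p=3, shift=4.0)
    assert (LinearSVM().fit(Xr, yr).predict(Xr) == yr).all()
    flipped = np.where(yr == CLASS1, CLASS2, CLASS1)
    np.testing.assert_array_equal(
        LinearSVM().fit(Xr, flipped).predict(Xr),
        np.where(LinearSVM().fit(Xr, yr).predict(Xr) == CLASS1, CLASS2, CLASS1),
    )


def test_make_classifier_names_and_thresholds():
    for name in ("knn1", "knn3", "knn5", "dlda", "dqda", "pam", "plr", "svm", "rf"):
        assert make_classifier(name, k1train=0.3) is not None
    with pytest.raises(ValueError, match="k1train"):
        make_classifier("rf_thr")
    with pytest.raises(ValueError, match="unknown"):
        make_classifier("lda")
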