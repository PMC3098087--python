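"""Two-class classifiers behind one fit / predict / score contract.

From scratch (closed-form or Newton-Raphson): k-NN, diagonal linear and
quadratic discriminant analysis (DLDA, DQDA), nearest shrunken centroids
(PAM) with training-error threshold selection, and ridge-penalized logistic
regression (PLR).  Random forest and linear SVM are thin adapters over
scikit-learn with the study's options (class priors / weights equal to
training class proportions, no internal feature scaling, vote-fraction
scores, optional classification cutoff at the training Class-1 proportion).

Conventions shared by every classifier here:

* labels are 1 (Class 1) and 2 (Class 2);
* ``score(X)`` is continuous and oriented so that larger means Class 1
  (used for ROC/AUC);
* discriminant ties are assigned to Class 1 (the "<=" rule), except PLR
  whose ties at the probability threshold are broken at random.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from .core import CLASS1, CLASS2


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge; carries diagnostics."""

    def __init__(self, message: str, iterations: int, grad_norm: float):
        super().__init__(f"{message} (iterations={iterations}, |grad|={grad_norm:.3e})")
        self.iterations = iterations
        self.grad_norm = grad_norm


def _check_two_classes(y: np.ndarray, min_per_class: int = 1) -> tuple[int, int]:
    n1 = int((y == CLASS1).sum())
    n2 = int((y == CLASS2).sum())
    if n1 < min_per_class or n2 < min_per_class:
        raise ValueError(
            f"both classes need >= {min_per_class} training samples (got {n1} vs {n2})"
        )
    return n1, n2


class FittedClassifier:
    """Base contract: ``predict`` returns labels in {1, 2}; ``score`` returns
    a finite continuous value per sample, larger meaning Class 1."""

    name: str = "base"

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FittedClassifier":
        raise NotImplementedError

    def score(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict(self, X: np.ndarray) -> np.ndarray:
        # default: sign rule on the Class-1-oriented score, ties to Class 1
        return np.where(self.score(X) >= 0, CLASS1, CLASS2)


class KNN(FittedClassifier):
    """k-nearest neighbours with Euclidean distance and majority vote.

    ``k`` must be odd so a two-class vote cannot tie.  Exact distance ties
    are broken in favour of the lowest training index (stable sort).
    """

    def __init__(self, k: int = 1):
        if k % 2 == 0:
            raise ValueError("k must be odd (even k allows vote ties)")
        self.k = k
        self.name = f"knn{k}"

    def fit(self, X, y):
        _check_two_classes(y)
        if self.k > len(y):
            raise ValueError("k cannot exceed the number of training samples")
        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y, dtype=int)
        return self

    def _neighbor_labels(self, X) -> np.ndarray:
        d = cdist(np.asarray(X, dtype=float), self._X)
        order = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        return self._y[order]

    def score(self, X):
        return (self._neighbor_labels(X) == CLASS1).mean(axis=1)

    def predict(self, X):
        return np.where(self.score(X) > 0.5, CLASS1, CLASS2)


class DLDA(FittedClassifier):
    """Diagonal linear discriminant analysis.

    Assigns x* to Class 1 iff
    ``sum_g (x*_g - m1_g)^2 / s_g^2 <= sum_g (x*_g - m2_g)^2 / s_g^2``
    with ``s_g^2`` the pooled within-class variance.  Equivalent to a Gaussian
    classifier with shared diagonal covariance and equal priors.  Variables
    with zero pooled variance are dropped with a warning.
    """

    name = "dlda"

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        n1, n2 = _check_two_classes(y, min_per_class=2)
        x1, x2 = X[y == CLASS1], X[y == CLASS2]
        self.mean1 = x1.mean(axis=0)
        self.mean2 = x2.mean(axis=0)
        self.var = (
            (n1 - 1) * x1.var(axis=0, ddof=1) + (n2 - 1) * x2.var(axis=0, ddof=1)
        ) / (n1 + n2 - 2)
        self.keep = self.var > 0
        if not self.keep.all():
            warnings.warn(
                f"DLDA: dropping {int((~self.keep).sum())} zero-variance variable(s)",
                RuntimeWarning,
                stacklevel=2,
            )
        return self

    def score(self, X):
        X = np.asarray(X, dtype=float)[:, self.keep]
        m1, m2, v = self.mean1[self.keep], self.mean2[self.keep], self.var[self.keep]
        d1 = ((X - m1) ** 2 / v).sum(axis=1)
        d2 = ((X - m2) ** 2 / v).sum(axis=1)
        return d2 - d1


class DQDA(FittedClassifier):
    """Diagonal quadratic discriminant analysis (per-class variances with
    ``log(s_kg^2)`` terms); reduces to DLDA when the class variances agree."""

    name = "dqda"

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        _check_two_classes(y, min_per_class=2)
        x1, x2 = X[y == CLASS1], X[y == CLASS2]
        self.mean1, self.mean2 = x1.mean(axis=0), x2.mean(axis=0)
        self.var1 = x1.var(axis=0, ddof=1)
        self.var2 = x2.var(axis=0, ddof=1)
        self.keep = (self.var1 > 0) & (self.var2 > 0)
        if not self.keep.all():
            warnings.warn(
                f"DQDA: dropping {int((~self.keep).sum())} zero-variance variable(s)",
                RuntimeWarning,
                stacklevel=2,
            )
        return self

    def score(self, X):
        X = np.asarray(X, dtype=float)[:, self.keep]
        m1, m2 = self.mean1[self.keep], self.mean2[self.keep]
        v1, v2 = self.var1[self.keep], self.var2[self.keep]
        d1 = ((X - m1) ** 2 / v1 + np.log(v1)).sum(axis=1)
        d2 = ((X - m2) ** 2 / v2 + np.log(v2)).sum(axis=1)
        return d2 - d1


class PAM(FittedClassifier):
    """Nearest shrunken centroids with a prior-probability correction.

    Class centroids are standardized by ``m_k (s_g + s0)`` — with ``s_g`` the
    pooled within-class standard deviation, ``s0`` its median over variables
    and ``m_k = sqrt(1/n_k - 1/n)`` — and soft-thresholded toward the overall
    centroid by an amount ``Delta``:  ``d' = sign(d) (|d| - Delta)_+``.
    A sample is assigned to Class 1 iff

    ``sum_g (x*_g - c1_g)^2/(s_g+s0)^2 - 2 log pi_1 <=  (same for Class 2)``

    with ``pi_k`` the training class proportions.  ``Delta`` is chosen by
    scanning ``n_thresholds`` evenly spaced values from 0 to the smallest
    threshold that shrinks every centroid difference to zero, and taking the
    largest value attaining the minimum training misclassification count.
    """

    name = "pam"

    def __init__(self, n_thresholds: int = 30):
        self.n_thresholds = n_thresholds

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        n1, n2 = _check_two_classes(y, min_per_class=2)
        n = n1 + n2
        x1, x2 = X[y == CLASS1], X[y == CLASS2]
        overall = X.mean(axis=0)
        cent = np.vstack([x1.mean(axis=0), x2.mean(axis=0)])  # (2, p)
        within_ss = ((x1 - cent[0]) ** 2).sum(axis=0) + ((x2 - cent[1]) ** 2).sum(axis=0)
        s = np.sqrt(within_ss / (n - 2))
        s0 = float(np.median(s))
        self.keep = (s + s0) > 0
        if not self.keep.all():
            warnings.warn(
                f"PAM: dropping {int((~self.keep).sum())} zero-scale variable(s)",
                RuntimeWarning,
                stacklevel=2,
            )
        denom = (s + s0)[self.keep]
        overall = overall[self.keep]
        cent = cent[:, self.keep]
        mk = np.array([np.sqrt(1.0 / n1 - 1.0 / n), np.sqrt(1.0 / n2 - 1.0 / n)])
        d = (cent - overall) / (mk[:, None] * denom)  # standardized differences
        self.priors = np.array([n1 / n, n2 / n])
        self._overall, self._denom, self._mk, self._d = overall, denom, mk, d

        dmax = float(np.abs(d).max()) if d.size else 0.0
        grid = np.linspace(0.0, dmax, self.n_thresholds)
        best_err, best_delta = None, 0.0
        for delta in grid:  # largest delta with minimal training error
            cents = self._shrunken_centroids(delta)
            pred = self._classify(X[:, self.keep], cents)
            err = int((pred != y).sum())
            if best_err is None or err <= best_err:
                best_err, best_delta = err, float(delta)
        self.delta = best_delta
        self.centroids = self._shrunken_centroids(self.delta)
        return self

    def _shrunken_centroids(self, delta: float) -> np.ndarray:
        dshr = np.sign(self._d) * np.maximum(np.abs(self._d) - delta, 0.0)
        return self._overall + self._mk[:, None] * self._denom * dshr

    def _discriminants(self, X: np.ndarray, cents: np.ndarray) -> np.ndarray:
        # rows: samples; cols: class-1 and class-2 discriminant values
        d1 = ((X - cents[0]) ** 2 / self._denom**2).sum(axis=1) - 2 * np.log(self.priors[0])
        d2 = ((X - cents[1]) ** 2 / self._denom**2).sum(axis=1) - 2 * np.log(self.priors[1])
        return np.column_stack([d1, d2])

    def _classify(self, X: np.ndarray, cents: np.ndarray) -> np.ndarray:
        disc = self._discriminants(X, cents)
        return np.where(disc[:, 0] <= disc[:, 1], CLASS1, CLASS2)

    def score(self, X):
        disc = self._discriminants(np.asarray(X, dtype=float)[:, self.keep], self.centroids)
        return disc[:, 1] - disc[:, 0]


class PLR(FittedClassifier):
    """Ridge-penalized logistic regression fit by damped Newton-Raphson.

    Minimizes the penalized negative log-likelihood
    ``-sum_i [y_i log p_i + (1-y_i) log(1-p_i)] + (lambda/2) sum_g beta_g^2``
    with the intercept unpenalized, to gradient norm < ``tol`` (default 1e-8,
    at most ``max_iter`` iterations; non-convergence raises
    :class:`ConvergenceError`).  Classifies to Class 1 iff ``p_hat > tau``
    where ``tau`` is 0.5 (default) or the training Class-1 proportion
    (thresholded variant); a sample landing exactly on ``tau`` is assigned at
    random.
    """

    def __init__(
        self,
        lam: float = 1.0,
        threshold: float = 0.5,
        max_iter: int = 100,
        tol: float = 1e-8,
        seed: Optional[int] = None,
    ):
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        self.lam = lam
        self.threshold = threshold
        self.max_iter = max_iter
        self.tol = tol
        self._rng = np.random.default_rng(seed)
        self.name = "plr" if threshold == 0.5 else "plr_thr"

    @staticmethod
    def _objective(beta, Xd, yb, lam):
        eta = Xd @ beta
        # log(1 + e^eta) - y*eta, numerically stable
        nll = np.sum(np.logaddexp(0.0, eta) - yb * eta)
        return nll + 0.5 * lam * np.sum(beta[1:] ** 2)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        _check_two_classes(y)
        yb = (np.asarray(y) == CLASS1).astype(float)
        n, p = X.shape
        Xd = np.column_stack([np.ones(n), X])
        pen = np.full(p + 1, self.lam)
        pen[0] = 0.0
        beta = np.zeros(p + 1)
        grad_norm = np.inf
        for it in range(self.max_iter):
            prob = expit(Xd @ beta)
            grad = Xd.T @ (prob - yb) + pen * beta
            grad_norm = float(np.linalg.norm(grad))
            if grad_norm < self.tol:
                self.coef_ = beta
                self.n_iter_ = it
                return self
            w = np.maximum(prob * (1 - prob), 1e-12)
            H = (Xd.T * w) @ Xd + np.diag(pen)
            step = np.linalg.solve(H, grad)
            # damped update: halve the step until the objective stops increasing
            obj = self._objective(beta, Xd, yb, self.lam)
            t = 1.0
            for _ in range(30):
                cand = beta - t * step
                if self._objective(cand, Xd, yb, self.lam) <= obj + 1e-12 * (1 + abs(obj)):
                    break
                t /= 2.0
            beta = beta - t * step
            # objective changes below floating resolution: accept the optimum
            if np.max(np.abs(t * step)) < 1e-12 * (1.0 + np.max(np.abs(beta))):
                break
        prob = expit(Xd @ beta)
        grad = Xd.T @ (prob - yb) + pen * beta
        grad_norm = float(np.linalg.norm(grad))
        if grad_norm < max(self.tol, 1e-6):
            self.coef_ = beta
            self.n_iter_ = self.max_iter
            return self
        raise ConvergenceError("PLR Newton-Raphson did not converge", self.max_iter, grad_norm)

    def score(self, X):
        X = np.asarray(X, dtype=float)
        return expit(self.coef_[0] + X @ self.coef_[1:])

    def predict(self, X):
        p_hat = self.score(X)
        pred = np.where(p_hat > self.threshold, CLASS1, CLASS2)
        ties = p_hat == self.threshold
        if ties.any():
            pred[ties] = self._rng.choice([CLASS1, CLASS2], size=int(ties.sum()))
        return pred


class RandomForest(FittedClassifier):
    """Adapter over :class:`sklearn.ensemble.RandomForestClassifier`.

    ``T`` unpruned trees, ``floor(sqrt(p))`` candidate variables per split by
    default (``mtry='all'`` uses every variable), class priors (sample
    weights) equal to the training class proportions.  The continuous score
    is the fraction of trees voting Class 1; classification compares it to
    ``cutoff`` (0.5, or the training Class-1 proportion for the thresholded
    variant).
    """

    def __init__(self, n_trees: int = 500, mtry: str = "sqrt", cutoff: float = 0.5,
                 seed: Optional[int] = None):
        if mtry not in ("sqrt", "all"):
            raise ValueError("mtry must be 'sqrt' or 'all'")
        self.n_trees = n_trees
        self.mtry = mtry
        self.cutoff = cutoff
        self.seed = seed
        self.name = "rf" if cutoff == 0.5 else "rf_thr"

    def fit(self, X, y):
        n1, n2 = _check_two_classes(y)
        n = n1 + n2
        max_features = "sqrt" if self.mtry == "sqrt" else None
        try:
            self._model = RandomForestClassifier(
                n_estimators=self.n_trees,
                max_features=max_features,
                class_weight={CLASS1: n1 / n, CLASS2: n2 / n},
                random_state=None if self.seed is None else int(self.seed),
            ).fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        except Exception as exc:  # pragma: no cover - backend failure context
            raise RuntimeError(f"random-forest backend failed: {exc}") from exc
        return self

    def score(self, X):
        X = np.asarray(X, dtype=float)
        # sub-estimators predict encoded class indices; map back to labels
        classes = self._model.classes_
        votes = np.stack(
            [classes[t.predict(X).astype(int)] for t in self._model.estimators_]
        )
        return (votes == CLASS1).mean(axis=0)

    def predict(self, X):
        return np.where(self.score(X) > self.cutoff, CLASS1, CLASS2)


class LinearSVM(FittedClassifier):
    """Adapter over :class:`sklearn.svm.SVC` with a linear kernel, per-class
    weights equal to the training class proportions, and no feature scaling."""

    name = "svm"

    def fit(self, X, y):
        n1, n2 = _check_two_classes(y)
        n = n1 + n2
        try:
            self._model = SVC(
                kernel="linear",
                class_weight={CLASS1: n1 / n, CLASS2: n2 / n},
            ).fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        except Exception as exc:  # pragma: no cover
            raise RuntimeError(f"SVM backend failed: {exc}") from exc
        return self

    def score(self, X):
        # sklearn's decision_function is positive toward classes_[1] (Class 2)
        dec = self._model.decision_function(np.asarray(X, dtype=float))
        return -dec if self._model.classes_[1] == CLASS2 else dec

    def predict(self, X):
        return self._model.predict(np.asarray(X, dtype=float)).astype(int)


def make_classifier(
    name: str,
    k1train: Optional[float] = None,
    seed: Optional[int] = None,
    rf_trees: int = 500,
    rf_mtry: str = "sqrt",
    plr_lambda: float = 1.0,
) -> FittedClassifier:
    """Instantiate a classifier by config identifier.

    ``k1train`` (training Class-1 proportion) is required for the
    thresholded variants ``plr_thr`` and ``rf_thr``.
    """
    if name in ("knn1", "knn3", "knn5"):
        return KNN(k=int(name[3:]))
    if name == "dlda":
        return DLDA()
    if name == "dqda":
        return DQDA()
    if name == "pam":
        return PAM()
    if name == "plr":
        return PLR(lam=plr_lambda, threshold=0.5, seed=seed)
    if name == "plr_thr":
        if k1train is None:
            raise ValueError("plr_thr needs k1train as its threshold")
        return PLR(lam=plr_lambda, threshold=k1train, seed=seed)
    if name == "rf":
        return RandomForest(n_trees=rf_trees, mtry=rf_mtry, cutoff=0.5, seed=seed)
    if name == "rf_thr":
        if k1train is None:
            raise ValueError("rf_thr needs k1train as its cutoff")
        return RandomForest(n_trees=rf_trees, mtry=rf_mtry, cutoff=k1train, seed=seed)
    if name == "svm":
        return LinearSVM()
    raise ValueError(f"unknown classifier {name!r}")
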