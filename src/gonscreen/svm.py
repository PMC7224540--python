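"""SVM branch: RBF-kernel classifier over the (cdr, rdr_sup, rdr_inf)
features with grid-searched hyperparameters.

Features are standardized on training statistics (RBF kernels are
scale-sensitive) and probability outputs are enabled so this branch emits the
same calibrated decision record as the CNN branch.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .decision import ClassifierDecision
from .features import FEATURE_ORDER
from .synthetic import GLAUCOMA

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.01, 0.1, 1.0, 10.0)


class CdrSvmClassifier(BaseEstimator, ClassifierMixin):
    """RBF SVM over the three CDR/rim ratios.

    Grid search is exhaustive over ``c_grid`` x ``gamma_grid`` by stratified
    cross-validated accuracy; the best pair is refit on all data with
    probability calibration enabled.

    Fitted attributes: ``pipeline_`` (scaler + SVC), ``best_params_``
    (chosen C and gamma, always members of the supplied grid), ``classes_``.
    """

    feature_order = FEATURE_ORDER

    def __init__(self, c_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                 cv_folds=3, seed=0):
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.cv_folds = cv_folds
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(f"expected (n, 3) feature matrix, got {X.shape}")
        if np.isnan(X).any():
            raise ValueError("NaN features")
        if len(np.unique(y)) < 2:
            raise ValueError("need both classes to train")
        n_splits = min(self.cv_folds, *np.bincount(np.unique(y, return_inverse=True)[1]))
        cv = StratifiedKFold(max(2, n_splits), shuffle=True, random_state=self.seed)
        # grid search on the plain SVC (fast); probability calibration only on
        # the refit winner
        search = GridSearchCV(
            Pipeline([
                ("scale", StandardScaler()),
                ("svc", SVC(kernel="rbf", random_state=self.seed)),
            ]),
            {"svc__C": list(self.c_grid), "svc__gamma": list(self.gamma_grid)},
            scoring="accuracy",
            cv=cv,
        )
        search.fit(X, y)
        # break accuracy ties toward the largest (C, gamma): on cleanly
        # separable data every grid point scores 1.0, but an underfit SVM's
        # near-zero decision function leaves Platt calibration uninformative
        res = search.cv_results_
        order = sorted(
            range(len(res["mean_test_score"])),
            key=lambda i: (
                res["mean_test_score"][i],
                res["param_svc__C"][i],
                res["param_svc__gamma"][i],
            ),
            reverse=True,
        )
        best = order[0]
        self.best_params_ = {
            "C": float(res["param_svc__C"][best]),
            "gamma": float(res["param_svc__gamma"][best]),
        }
        self.pipeline_ = Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", probability=True, random_state=self.seed,
                        **{"C": self.best_params_["C"],
                           "gamma": self.best_params_["gamma"]})),
        ])
        import warnings as _warnings

        with _warnings.catch_warnings():
            # internal Platt-scaling calibration of SVC is the behavior we
            # want; silence the upstream deprecation chatter
            _warnings.simplefilter("ignore", FutureWarning)
            self.pipeline_.fit(X, y)
        self.classes_ = self.pipeline_.classes_
        return self

    def _check_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None]
        if X.shape[1] != 3:
            raise ValueError(f"feature vector must have arity 3, got {X.shape[1]}")
        return X

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(self._check_X(X))

    def predict_proba(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict_proba(self._check_X(X))

    def p_glaucoma(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        col = int(np.searchsorted(self.classes_, GLAUCOMA))
        return proba[:, col]

    def decide(self, features) -> ClassifierDecision:
        """Decision record for one (cdr, rdr_sup, rdr_inf) vector."""
        p = float(self.p_glaucoma(features)[0])
        return ClassifierDecision.from_p_glaucoma(p, source="svm")


def train_svm(features, labels, grid=None, cv_folds=3, seed=0) -> CdrSvmClassifier:
    c_grid, gamma_grid = grid if grid else (DEFAULT_C_GRID, DEFAULT_GAMMA_GRID)
    return CdrSvmClassifier(c_grid, gamma_grid, cv_folds, seed).fit(features, labels)


def predict_svm(model: CdrSvmClassifier, features) -> ClassifierDecision:
    return model.decide(features)
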