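"""scikit-learn style estimators wrapping the pipeline.

:class:`ECGFeatureExtractor` turns a list of :class:`~ecgmi.records.ECGRecord`
objects into the assembled feature matrix (median filtering included), and
:class:`SSSDRNClassifier` trains the compact residual network with the SSS
metaheuristic.  Both follow sklearn conventions (``get_params`` /
``set_params``, fitted attributes with a trailing underscore) and compose
with sklearn pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin

from .network import ParamVector, forward, make_preset
from .optim import SSSConfig, train_drn
from .preprocessing import MedianFilterConfig, denoise_record
from .staticfeat import AssembleConfig, assemble


class ECGFeatureExtractor(BaseEstimator, TransformerMixin):
    """Median filter + full feature-vector assembly per record.

    ``transform`` accepts an iterable of ECGRecord and returns an
    (n_records, n_features) array; the block layout is exposed as
    ``layout_`` after the first call to :meth:`fit`/:meth:`transform`.
    """

    def __init__(self, median_window: int = 5, assemble_config: AssembleConfig | None = None):
        self.median_window = median_window
        self.assemble_config = assemble_config

    def _config(self) -> AssembleConfig:
        return self.assemble_config or AssembleConfig()

    def fit(self, X, y=None):
        self.layout_ = self._config().layout()
        return self

    def transform(self, X):
        config = self._config()
        self.layout_ = config.layout()
        rows = []
        for record in X:
            filtered = denoise_record(record, MedianFilterConfig(self.median_window))
            rows.append(assemble(filtered, config).values)
        return np.vstack(rows)


class SSSDRNClassifier(BaseEstimator, ClassifierMixin):
    """Residual-network classifier whose weights are found by the SSS
    metaheuristic (no gradients anywhere).

    Parameters mirror the optimizer configuration; ``preset`` selects the
    network size ('tiny' is the default and the only preset practical for
    population search budgets).  Features are z-scored with training-set
    statistics before entering the network.

    Attributes (after ``fit``)
    --------------------------
    classes_ : ndarray of class labels (sklearn order)
    spec_ : NetworkSpec, params_ : ParamVector — the trained network
    convergence_ : list of best fitness per iteration
    best_fitness_ : final training MSE
    """

    def __init__(self, preset: str = "tiny", pop_size: int = 30, n_iter: int = 100,
                 lb: float = -0.7, ub: float = 0.7, l_start: float = 2.0,
                 l_end: float = 0.0, tol: float = 0.0, patience: int = 25,
                 standardize: bool = True, random_state: int = 0):
        self.preset = preset
        self.pop_size = pop_size
        self.n_iter = n_iter
        self.lb = lb
        self.ub = ub
        self.l_start = l_start
        self.l_end = l_end
        self.tol = tol
        self.patience = patience
        self.standardize = standardize
        self.random_state = random_state

    def _sss_config(self) -> SSSConfig:
        return SSSConfig(y=self.pop_size, K=self.n_iter, lb=self.lb, ub=self.ub,
                         l_start=self.l_start, l_end=self.l_end, tol=self.tol,
                         patience=self.patience, seed=self.random_state)

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.standardize:
            X = (X - self.mean_) / self.scale_
        return X

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("fit needs at least two classes")
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xs = self._prepare(X)
        self.spec_ = make_preset(self.preset, X.shape[1])
        params, best, trace, classes = train_drn(
            Xs, y, self.spec_, self._sss_config(), classes=self.classes_.tolist()
        )
        self.params_ = params
        self.best_fitness_ = best
        self.convergence_ = trace
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        if not hasattr(self, "params_"):
            raise AttributeError("this SSSDRNClassifier instance is not fitted yet")
        Xs = self._prepare(X)
        return forward(self.spec_, self.params_, Xs)

    def predict(self, X):
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]

    def decision_scores(self, X, positive="MI"):
        """Probability of the positive class (for ROC curves)."""
        probs = self.predict_proba(X)
        idx = list(self.classes_).index(positive)
        return probs[:, idx]
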