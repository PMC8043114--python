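"""Self-organizing map for expression-profile clustering.

A small rectangular Kohonen map trained online: at each step the
best-matching unit (BMU) of one sample is found and every unit moves
toward the sample, weighted by a Gaussian neighborhood kernel on the
grid.  Learning rate and neighborhood radius decay linearly to (near)
zero over training.  With the default 5 x 1 grid the map quantizes
protein z-profiles into five ordered clusters.

The estimator follows scikit-learn conventions (``fit`` / ``predict``,
``get_params`` / ``set_params``, trailing-underscore fitted attributes)
so it composes with sklearn tooling.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = ["SelfOrganizingMap"]


class SelfOrganizingMap(ClusterMixin, BaseEstimator):
    """Rectangular SOM with Gaussian neighborhood and linear decay.

    Parameters
    ----------
    rows, cols : int
        Grid dimensions; ``rows * cols`` is the number of prototype
        units (= clusters).
    epochs : int
        Full passes over the data.
    learning_rate : float
        Initial learning rate; decays linearly to 0 over training.
    sigma : float or None
        Initial neighborhood radius in grid units; default
        ``max(rows, cols) / 2``.  Decays linearly to a minimum of 0.1.
    random_state : int
        Seeds prototype initialization and the sample presentation
        order; identical seeds give identical maps.

    Attributes
    ----------
    prototypes_ : ndarray of shape (rows * cols, n_features)
        Unit weight vectors, row-major over the grid.
    labels_ : ndarray of shape (n_samples,)
        BMU (flat unit index) of each training sample.
    """

    def __init__(
        self,
        rows: int = 5,
        cols: int = 1,
        epochs: int = 500,
        learning_rate: float = 0.5,
        sigma: float | None = None,
        random_state: int = 0,
    ):
        self.rows = rows
        self.cols = cols
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.sigma = sigma
        self.random_state = random_state

    def _grid_sq_dists(self) -> np.ndarray:
        coords = np.array([(r, c) for r in range(self.rows) for c in range(self.cols)], dtype=float)
        diff = coords[:, None, :] - coords[None, :, :]
        return (diff**2).sum(axis=2)

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        n, d = X.shape
        n_units = self.rows * self.cols
        if n_units > n:
            raise ValueError(f"SOM grid has {n_units} units but only {n} samples")
        if self.rows < 1 or self.cols < 1 or self.epochs < 1:
            raise ValueError("rows, cols and epochs must be positive")
        rng = np.random.default_rng(self.random_state)
        # init prototypes from distinct data points
        init_idx = rng.choice(n, size=n_units, replace=False)
        w = X[init_idx].copy()
        grid_sq = self._grid_sq_dists()
        sigma0 = self.sigma if self.sigma is not None else max(self.rows, self.cols) / 2.0
        total = self.epochs * n
        t = 0
        for _ in range(self.epochs):
            for i in rng.permutation(n):
                frac = t / total
                lr = self.learning_rate * (1.0 - frac)
                sig = max(sigma0 * (1.0 - frac), 0.1)
                x = X[i]
                bmu = int(np.argmin(((w - x) ** 2).sum(axis=1)))
                h = np.exp(-grid_sq[bmu] / (2.0 * sig * sig))
                w += (lr * h)[:, None] * (x - w)
                t += 1
        self.prototypes_ = w
        self.n_features_in_ = d
        self.labels_ = self.predict(X)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "prototypes_")
        X = check_array(X, dtype=float)
        d2 = ((X[:, None, :] - self.prototypes_[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)
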