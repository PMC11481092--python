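"""Gaussian-process surrogate with a Matérn-5/2 ARD kernel.

The campaign surrogate is a standard GP regression on unit-scaled inputs and
standardized objective values,

    k(x, x') = sigma_f^2 (1 + sqrt(5) r + 5 r^2 / 3) exp(-sqrt(5) r),
    r^2 = sum_i ((x_i - x'_i) / l_i)^2,

with an additive white-noise term whose variance is fitted subject to a
floor.  Hyperparameters maximize the log marginal likelihood by seeded
multistart L-BFGS (delegated to scikit-learn's GaussianProcessRegressor);
prediction uses this module's own dense Cholesky linear algebra at the
fitted hyperparameters, which is fast for the small campaign datasets
(7-30 points) and is cross-checked against the scikit-learn posterior in
the test suite.

Per-variable length scales double as an importance diagnostic: the smaller
the ARD length scale, the faster the objective varies along that variable,
hence the more it mattered to the optimization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .design_space import DesignSpace

__all__ = ["FitError", "GPSurrogate", "ImportanceRanking", "matern52"]

SQRT5 = np.sqrt(5.0)


class FitError(ValueError):
    """Surrogate fitting failed (e.g. duplicate-only data)."""


def matern52(A: np.ndarray, B: np.ndarray, length_scales: np.ndarray,
             amplitude: float = 1.0) -> np.ndarray:
    """Matérn-5/2 ARD kernel matrix between row sets A and B."""
    A = np.atleast_2d(A) / length_scales
    B = np.atleast_2d(B) / length_scales
    d2 = np.maximum(
        np.sum(A**2, axis=1)[:, None] + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T, 0.0)
    r = np.sqrt(d2)
    return amplitude * (1.0 + SQRT5 * r + 5.0 * d2 / 3.0) * np.exp(-SQRT5 * r)


@dataclass(frozen=True)
class ImportanceRanking:
    """Per-variable ARD length scales, ranked ascending (1 = most important).

    ``ties`` lists groups of variable names whose length scales agree within
    5 % relative, where the rank order is not meaningful.
    """

    names: tuple[str, ...]
    length_scales: tuple[float, ...]
    ranks: tuple[int, ...]
    ties: tuple[tuple[str, ...], ...] = ()

    def most_important(self) -> str:
        return self.names[self.ranks.index(1)]

    def least_important(self) -> str:
        return self.names[self.ranks.index(len(self.names))]


class GPSurrogate:
    """Fitted GP posterior over the unit hypercube.

    Attributes of interest: ``length_scales`` (per-variable, unit-scaled
    space), ``amplitude`` (signal variance, standardized units),
    ``noise_variance`` (fitted, floored), ``y_mean``/``y_std`` (the
    de-standardization constants).
    """

    #: length-scale search bounds in unit-scaled space
    LS_BOUNDS = (0.01, 100.0)
    NOISE_FLOOR = 1e-8

    def __init__(self, X: np.ndarray, y: np.ndarray, amplitude: float,
                 length_scales: np.ndarray, noise_variance: float,
                 y_mean: float, y_std: float, lml: float,
                 sk_model: GaussianProcessRegressor | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)  # standardized targets
        self.amplitude = float(amplitude)
        self.length_scales = np.asarray(length_scales, dtype=float)
        self.noise_variance = float(noise_variance)
        self.y_mean = float(y_mean)
        self.y_std = float(y_std)
        self.lml = float(lml)
        self._sk = sk_model
        K = matern52(self.X, self.X, self.length_scales, self.amplitude)
        K[np.diag_indices_from(K)] += self.noise_variance
        # PSD by construction; jitter escalation guards rounding only.
        jitter = 0.0
        while True:
            try:
                self._chol = cho_factor(K + jitter * np.eye(len(K)), lower=True)
                break
            except np.linalg.LinAlgError:  # pragma: no cover - defensive
                jitter = 1e-10 if jitter == 0.0 else jitter * 10.0
                if jitter > 1e-8:
                    raise FitError("kernel matrix not positive definite")
        self._alpha = cho_solve(self._chol, self.y)

    # -- fitting ----------------------------------------------------------

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray, n_restarts: int = 5,
            seed: int = 0) -> "GPSurrogate":
        """Maximize the log marginal likelihood with seeded multistart.

        ``X`` must be unit-scaled points (>= 2 distinct); ``y`` finite
        objective values in their natural units (standardized internally).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] < 2 or X.shape[0] != y.size:
            raise FitError("need at least two (x, y) observations")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise FitError("non-finite training data")
        if np.unique(X, axis=0).shape[0] < 2:
            raise FitError(
                "all training inputs coincide; add jitter to the duplicate "
                "points or collect a distinct condition before fitting")
        y_mean = float(y.mean())
        y_std = float(y.std())
        if y_std < 1e-12:
            y_std = 1.0  # constant objective: posterior mean = that constant
        ys = (y - y_mean) / y_std
        n = X.shape[1]
        kernel = (
            ConstantKernel(1.0, (1e-3, 1e3))
            * Matern(length_scale=np.full(n, 0.3),
                     length_scale_bounds=cls.LS_BOUNDS, nu=2.5)
            + WhiteKernel(noise_level=1e-4,
                          noise_level_bounds=(cls.NOISE_FLOOR, 1.0))
        )
        gpr = GaussianProcessRegressor(kernel=kernel, optimizer="fmin_l_bfgs_b",
                                       n_restarts_optimizer=n_restarts,
                                       normalize_y=False,
                                       random_state=int(seed) % (2**32))
        import warnings
        from sklearn.exceptions import ConvergenceWarning
        with warnings.catch_warnings():
            # hitting the noise floor on near-noiseless data is expected
            warnings.simplefilter("ignore", ConvergenceWarning)
            gpr.fit(X, ys)
        k = gpr.kernel_
        amplitude = float(k.k1.k1.constant_value)
        length_scales = np.atleast_1d(np.asarray(k.k1.k2.length_scale,
                                                 dtype=float))
        if length_scales.size == 1 and n > 1:  # pragma: no cover - defensive
            length_scales = np.full(n, float(length_scales[0]))
        noise = max(float(k.k2.noise_level), cls.NOISE_FLOOR)
        return cls(X, ys, amplitude, length_scales, noise, y_mean, y_std,
                   lml=float(gpr.log_marginal_likelihood_value_), sk_model=gpr)

    # -- prediction -------------------------------------------------------

    def predict(self, X: np.ndarray, standardized: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
        """GP posterior mean and standard deviation at unit-scaled points.

        The predictive variance includes the fitted observation-noise term
        (matching the scikit-learn convention for a kernel with an additive
        white component).  With ``standardized=True`` the outputs stay in
        standardized objective units.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Ks = matern52(X, self.X, self.length_scales, self.amplitude)
        mean_s = Ks @ self._alpha
        v = cho_solve(self._chol, Ks.T)
        var = self.amplitude + self.noise_variance - np.sum(Ks * v.T, axis=1)
        sd_s = np.sqrt(np.maximum(var, 0.0))
        if standardized:
            return mean_s, sd_s
        return self.y_mean + self.y_std * mean_s, self.y_std * sd_s

    def log_marginal_likelihood(self, theta: np.ndarray | None = None) -> float:
        """LML of the fitted model, or at another log-hyperparameter vector."""
        if self._sk is None:
            raise FitError("log marginal likelihood requires a fitted model")
        if theta is None:
            return self.lml
        return float(self._sk.log_marginal_likelihood(theta))

    def incumbent(self) -> tuple[np.ndarray, float]:
        """Training point with the best (largest) observed objective."""
        i = int(np.argmax(self.y))
        return self.X[i], self.y_mean + self.y_std * float(self.y[i])

    # -- importance -------------------------------------------------------

    def importance(self, space: DesignSpace) -> ImportanceRanking:
        """Rank variables by ARD length scale (ascending; smallest = rank 1).

        Ties (length scales within 5 % relative) are broken by variable
        order and reported in ``ties``.
        """
        ls = self.length_scales
        if ls.size != space.n:
            raise ValueError("model dimensionality does not match the space")
        order = list(np.argsort(ls, kind="stable"))
        # group near-equal length scales; within a group, variable order wins
        groups: list[list[int]] = [[int(order[0])]]
        for a, b in zip(order[:-1], order[1:]):
            if abs(ls[b] - ls[a]) <= 0.05 * max(ls[a], ls[b]):
                groups[-1].append(int(b))
            else:
                groups.append([int(b)])
        order = [i for g in groups for i in sorted(g)]
        ranks = np.empty(space.n, dtype=int)
        ranks[order] = np.arange(1, space.n + 1)
        ties = [tuple(space.names[i] for i in sorted(g))
                for g in groups if len(g) > 1]
        return ImportanceRanking(names=space.names,
                                 length_scales=tuple(float(v) for v in ls),
                                 ranks=tuple(int(r) for r in ranks),
                                 ties=tuple(ties))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "X": self.X.tolist(),
            "y_standardized": self.y.tolist(),
            "amplitude": self.amplitude,
            "length_scales": self.length_scales.tolist(),
            "noise_variance": self.noise_variance,
            "y_mean": self.y_mean,
            "y_std": self.y_std,
            "log_marginal_likelihood": self.lml,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "GPSurrogate":
        return cls(np.asarray(d["X"]), np.asarray(d["y_standardized"]),
                   d["amplitude"], np.asarray(d["length_scales"]),
                   d["noise_variance"], d["y_mean"], d["y_std"],
                   d["log_marginal_likelihood"])
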