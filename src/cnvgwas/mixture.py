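"""One-dimensional Gaussian mixture model for copy-number class calling.

Each copy-number-variable region (CNVR) is summarised to one intensity value
per sample (mean Log R Ratio of the in-region probes).  Samples are then
clustered by fitting a univariate Gaussian mixture with EM; each mixture
component is one copy-number class.  Model selection over the number of
classes K uses BIC.  The fitted posterior class probabilities feed the
continuous copy-number "dose" used downstream in association testing.

The interface follows the statsmodels Model/Results convention:
``IntensityMixture`` holds the data, ``fit``/``select`` return an
``IntensityMixtureResults`` carrying parameters, posteriors, doses and a
``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["IntensityMixture", "IntensityMixtureResults"]

# Numerical guards for the EM iterations.
VARIANCE_FLOOR = 1e-6
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 500
DEFAULT_N_INIT = 10


@dataclass
class IntensityMixtureResults:
    """Fitted per-CNVR mixture: parameters, posteriors and derived calls.

    Components are always relabelled by ascending mean, so class ``k`` is the
    k-th lowest-intensity cluster; class labels are relative copy states, not
    absolute copy numbers.
    """

    model: "IntensityMixture"
    k: int
    weights: np.ndarray          # (k,) mixing proportions, sum to 1
    means: np.ndarray            # (k,) ascending
    variances: np.ndarray        # (k,) >= VARIANCE_FLOOR
    posteriors: np.ndarray       # (n, k) responsibilities, rows sum to 1
    loglike: float
    loglike_path: np.ndarray = field(repr=False, default=None)
    converged: bool = True
    degenerate: bool = False
    low_quality: bool = False

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def n_params(self) -> int:
        # k-1 free weights, k means, k variances
        return 3 * self.k - 1

    @property
    def bic(self) -> float:
        return -2.0 * self.loglike + self.n_params * math.log(self.nobs)

    @property
    def map_classes(self) -> np.ndarray:
        """Maximum-a-posteriori class per sample, 0..k-1 by ascending mean."""
        return np.argmax(self.posteriors, axis=1)

    @property
    def doses(self) -> np.ndarray:
        """Posterior-expected class, d_i = sum_k k * gamma_ik, in [0, k-1]."""
        return self.posteriors @ np.arange(self.k, dtype=float)

    @property
    def confidences(self) -> np.ndarray:
        return np.max(self.posteriors, axis=1)

    def class_counts(self) -> np.ndarray:
        """MAP-class tallies, length k (zeros kept for empty classes)."""
        return np.bincount(self.map_classes, minlength=self.k)

    def class_frequencies(self) -> np.ndarray:
        c = self.class_counts()
        return c / c.sum()

    def expected_counts(self) -> np.ndarray:
        return self.weights * self.nobs

    def is_polymorphic(self, min_expected: float = 3.0) -> bool:
        """Polymorphic iff K >= 2 and every class expects >= min_expected samples."""
        if self.degenerate or self.k < 2:
            return False
        return bool(np.all(self.expected_counts() >= min_expected))

    def summary(self) -> str:
        lines = [
            "Intensity mixture model (EM Gaussian mixture)",
            f"  n = {self.nobs}, K = {self.k}, logL = {self.loglike:.4f}, "
            f"BIC = {self.bic:.4f}",
            f"  converged = {self.converged}, degenerate = {self.degenerate}, "
            f"low_quality = {self.low_quality}",
            "  class    weight       mean   variance   map_count",
        ]
        counts = self.class_counts()
        for j in range(self.k):
            lines.append(
                f"  {j:5d}  {self.weights[j]:8.4f}  {self.means[j]:9.4f}"
                f"  {self.variances[j]:9.6f}  {counts[j]:9d}"
            )
        return "\n".join(lines)


class IntensityMixture:
    """Univariate Gaussian mixture model of per-sample CNVR intensity summaries.

    Parameters
    ----------
    endog : array-like
        One intensity summary value per sample (LRR units).  Must be finite.
    """

    def __init__(self, endog) -> None:
        x = np.asarray(endog, dtype=float).ravel()
        if x.size == 0:
            raise ValueError("empty intensity summary")
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite intensity summary values")
        self.endog = x

    @property
    def nobs(self) -> int:
        return self.endog.size

    # ------------------------------------------------------------------
    def _initial_params(self, k: int, rng: np.random.Generator, perturb: bool):
        x = self.endog
        spread = max(x.std(), math.sqrt(VARIANCE_FLOOR))
        if not perturb:
            # first restart: deterministic K-quantile means
            means = np.quantile(x, (np.arange(k) + 0.5) / k)
            var = np.full(k, max((spread / k) ** 2, VARIANCE_FLOOR))
            return np.full(k, 1.0 / k), np.sort(means), var
        # remaining restarts: distance-weighted seeding from the data points
        # (k-means++ style) — quantile starts cannot reach rare classes that
        # sit far from the bulk, e.g. a handful of homozygous deletions
        means = [x[rng.integers(x.size)]]
        for _ in range(1, k):
            d2 = np.min((x[:, None] - np.asarray(means)[None, :]) ** 2, axis=1)
            tot = d2.sum()
            if tot <= 0:
                means.append(x[rng.integers(x.size)])
            else:
                means.append(x[rng.choice(x.size, p=d2 / tot)])
        means = np.sort(np.asarray(means))
        # moment-match each component from its nearest-mean assignment
        assign = np.argmin(np.abs(x[:, None] - means[None, :]), axis=1)
        weights = np.maximum(np.bincount(assign, minlength=k), 0.5)
        weights = weights / weights.sum()
        var = np.empty(k)
        for j in range(k):
            sel = x[assign == j]
            var[j] = sel.var() if sel.size > 1 else (spread / k) ** 2
        var = np.maximum(var, VARIANCE_FLOOR)
        return weights, means, var

    @staticmethod
    def _e_step(x, weights, means, var):
        # inline logsumexp: this loop dominates pipeline runtime
        lp = np.log(weights)[None, :] - 0.5 * (
            np.log(2.0 * np.pi * var)[None, :]
            + (x[:, None] - means[None, :]) ** 2 / var[None, :]
        )
        m = lp.max(axis=1)
        log_norm = m + np.log(np.exp(lp - m[:, None]).sum(axis=1))
        resp = np.exp(lp - log_norm[:, None])
        return resp, float(log_norm.sum())

    def _em(self, k: int, weights, means, var, max_iter: int, tol: float):
        x = self.endog
        n = x.size
        ll_path = []
        ll_old = -np.inf
        converged = False
        for _ in range(max_iter):
            resp, ll = self._e_step(x, weights, means, var)
            ll_path.append(ll)
            # M-step
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-300)
            weights = nk / n
            means = (resp * x[:, None]).sum(axis=0) / nk
            d = x[:, None] - means[None, :]
            var = (resp * d * d).sum(axis=0) / nk
            var = np.maximum(var, VARIANCE_FLOOR)
            if ll - ll_old <= tol * max(abs(ll), 1.0) and len(ll_path) > 1:
                converged = True
                break
            ll_old = ll
        # final E-step so posteriors/loglike match the returned parameters
        resp, ll = self._e_step(x, weights, means, var)
        ll_path.append(ll)
        return weights, means, var, resp, ll, np.asarray(ll_path), converged

    # ------------------------------------------------------------------
    def fit(
        self,
        k: int,
        seed: int = 0,
        n_init: int = DEFAULT_N_INIT,
        max_iter: int = DEFAULT_MAX_ITER,
        tol: float = DEFAULT_TOL,
    ) -> IntensityMixtureResults:
        """Fit a K-component mixture by EM, best of ``n_init`` restarts.

        Restart 0 uses plain K-quantile means; the remaining restarts perturb
        them with seeded Gaussian noise.  Components are relabelled by
        ascending mean.  Data with zero spread and k > 1 return the exact
        single-component fit flagged ``degenerate``.
        """
        if k < 1:
            raise ValueError(f"k must be >= 1, got {k}")
        x = self.endog
        if x.size < max(1, k):
            raise ValueError(f"need at least {k} observations for k={k}")
        if np.ptp(x) == 0.0 and k > 1:
            res = self.fit(1, seed=seed, n_init=1, max_iter=max_iter, tol=tol)
            res.degenerate = True
            return res

        ss = np.random.SeedSequence(entropy=seed)
        child_seeds = ss.spawn(max(n_init, 1))
        best = None
        for i in range(max(n_init, 1)):
            rng = np.random.default_rng(child_seeds[i])
            w0, m0, v0 = self._initial_params(k, rng, perturb=(i > 0))
            fitted = self._em(k, w0, m0, v0, max_iter, tol)
            if best is None or fitted[4] > best[4]:
                best = fitted
        weights, means, var, resp, ll, ll_path, converged = best

        order = np.argsort(means, kind="stable")
        return IntensityMixtureResults(
            model=self,
            k=k,
            weights=weights[order],
            means=means[order],
            variances=var[order],
            posteriors=resp[:, order],
            loglike=ll,
            loglike_path=ll_path,
            converged=converged,
        )

    def select(
        self,
        k_max: int = 6,
        seed: int = 0,
        n_init: int = DEFAULT_N_INIT,
        max_iter: int = DEFAULT_MAX_ITER,
        tol: float = DEFAULT_TOL,
    ) -> IntensityMixtureResults:
        """Choose K in 1..k_max by minimum BIC (ties favour the smaller K)."""
        best = None
        for k in range(1, k_max + 1):
            if self.nobs < k:
                break
            res = self.fit(k, seed=seed, n_init=n_init, max_iter=max_iter, tol=tol)
            if best is None or res.bic < best.bic:
                best = res
            if res.degenerate:
                break
        return best
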