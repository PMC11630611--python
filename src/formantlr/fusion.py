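"""Logistic-regression calibration and fusion of parallel log-LR scores.

Raw MVKD scores are well-ordered but not necessarily well-calibrated, and
one score is produced per vowel; both problems are solved by a single
binary logistic regression of the hypothesis label on the per-vowel score
vector, fitted on development comparisons. The calibrated-and-fused log10 LR
of a score vector ``x`` is

    ( w . x + b - log(Nss/Nds) ) / ln 10,

i.e. the model's log posterior odds with the development-set prior log-odds
subtracted, so the output is an equal-prior likelihood ratio. With a single
input dimension this reduces to plain calibration.

Perfectly separable development sets (common with strong features and small
folds) make the unpenalised MLE diverge; in that case the fit falls back to
an L2-ridge logistic regression (lambda = 1e-3) and records a warning.
Missing score dimensions (a vowel absent from one sample) are imputed with
the development-set column mean, a documented bias that keeps the fold
usable.
"""

from __future__ import annotations

import warnings

from math import comb

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2
from sklearn.base import BaseEstimator, TransformerMixin

_CHIBAR_CACHE: dict[tuple[int, float], float] = {}

__all__ = ["ScoreFusion", "fit_fusion"]

_LOG10 = np.log(10.0)

#: |weight| beyond which an unpenalised fit on bounded log10-LR inputs is
#: taken as diverging towards separation (a well-calibrated input needs
#: w = ln 10 ~ 2.3; an order of magnitude above that is divergence).
_SEPARATION_COEF = 25.0
_MLE_MAX_ITER = 150


class ScoreFusion(BaseEstimator, TransformerMixin):
    """Fuse/calibrate per-vowel log10 LR vectors into one log10 LR.

    Parameters
    ----------
    ridge_lambda
        L2 penalty used by the fallback fit when the unpenalised logistic
        regression diverges (perfect separation).

    Attributes (after :meth:`fit`)
    ------------------------------
    weights_ : (k,) fused coefficient per input score dimension
    intercept_ : scalar intercept (natural-log-odds scale)
    prior_logodds_ : development-set log(Nss/Nds), subtracted at transform
    column_means_ : (k,) development column means used for imputation
    used_ridge_ : whether the ridge fallback was taken
    """

    def __init__(self, ridge_lambda: float = 1e-3):
        self.ridge_lambda = ridge_lambda

    def fit(self, X, y) -> "ScoreFusion":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        n_ss = int((y == 1).sum())
        n_ds = int((y == 0).sum())
        if n_ss < 2 or n_ds < 2:
            raise ValueError("need at least 2 development comparisons per hypothesis")

        self.column_means_ = np.nanmean(X, axis=0)
        if not np.isfinite(self.column_means_).all():
            raise ValueError("a score column is entirely missing in the development set")
        Xf = np.where(np.isnan(X), self.column_means_, X)

        # constant columns carry no information and break the unpenalised fit
        keep = Xf.std(axis=0) > 0
        if not keep.any():
            raise ValueError("all score columns are constant")
        Xk = Xf[:, keep]

        coef, intercept, used_ridge = self._solve(Xk, y)
        self.prior_logodds_ = float(np.log(n_ss / n_ds))
        # Evidential-value gate: unless the fitted model beats the
        # intercept-only model in a likelihood-ratio test, the development
        # data cannot support any discrimination claim and the calibrated
        # system collapses to LR = 1 for every comparison. Because the
        # weights are constrained to the nonnegative cone, the null
        # distribution of the deviance improvement is the chi-bar-square
        # mixture sum_j C(d,j) 2^-d chi2(j), not chi2(d).
        if self._gate_supported(Xk, y, coef, intercept):
            self.weights_ = np.zeros(X.shape[1])
            self.weights_[keep] = coef
            self.intercept_ = float(intercept)
            self.collapsed_ = False
        else:
            warnings.warn(
                "development scores carry no significant speaker information; "
                "calibrated LRs collapse to 1",
                RuntimeWarning,
                stacklevel=2,
            )
            self.weights_ = np.zeros(X.shape[1])
            self.intercept_ = self.prior_logodds_
            self.collapsed_ = True
        self.used_ridge_ = used_ridge
        self.n_features_in_ = X.shape[1]
        return self

    @classmethod
    def _gate_supported(cls, X, y, coef, intercept, alpha: float = 0.05) -> bool:
        z = X @ coef + intercept
        ll_model = -np.logaddexp(0.0, -z)[y == 1].sum() - np.logaddexp(0.0, z)[y == 0].sum()
        p = y.mean()
        ll_null = len(y) * (p * np.log(p) + (1.0 - p) * np.log(1.0 - p))
        return 2.0 * (ll_model - ll_null) > cls._chi_bar_square_ppf(X.shape[1], alpha)

    @staticmethod
    def _chi_bar_square_ppf(d: int, alpha: float) -> float:
        """Upper alpha point of the chi-bar-square mixture for d bound
        constraints: sum_j C(d,j) 2^-d chi2(j) (j = 0 term is a point mass
        at zero)."""
        key = (d, alpha)
        cached = _CHIBAR_CACHE.get(key)
        if cached is not None:
            return cached
        w = np.array([comb(d, j) for j in range(d + 1)], dtype=float) / 2.0**d

        def sf(t: float) -> float:
            return float(sum(w[j] * chi2.sf(t, j) for j in range(1, d + 1)))

        lo, hi = 0.0, chi2.ppf(1.0 - alpha, d) + 1.0
        for _ in range(100):
            mid = 0.5 * (lo + hi)
            if sf(mid) > alpha:
                lo = mid
            else:
                hi = mid
        _CHIBAR_CACHE[key] = hi
        return hi

    @staticmethod
    def _fit_nonneg_logistic(X, y, lam: float) -> tuple[np.ndarray, float, bool]:
        """Sign-constrained penalised logistic regression.

        Minimises the mean log-loss plus ``lam/2 * ||w||^2`` subject to
        ``w >= 0``: every input is itself a log LR for the same-speaker
        proposition, so a fused model in which more same-speaker support in
        one vowel *lowers* the overall LR is rejected as unphysical. The
        intercept is unconstrained and unpenalised.
        """
        n, k = X.shape
        sign = np.where(y == 1, 1.0, -1.0)

        def objective(theta):
            z = sign * (X @ theta[:k] + theta[k])
            loss = np.logaddexp(0.0, -z)
            p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
            grad_z = -p * sign
            grad = np.empty(k + 1)
            grad[:k] = X.T @ grad_z / n + lam * theta[:k]
            grad[k] = grad_z.mean()
            return loss.mean() + 0.5 * lam * theta[:k] @ theta[:k], grad

        res = minimize(
            objective,
            np.zeros(k + 1),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * k + [(None, None)],
            options={"maxiter": _MLE_MAX_ITER, "ftol": 1e-14, "gtol": 1e-9},
        )
        return res.x[:k], float(res.x[k]), bool(res.success)

    def _solve(self, X, y):
        coef, intercept, converged = self._fit_nonneg_logistic(X, y, lam=0.0)
        # perfect separation leaves the MLE unbounded even when the
        # optimiser halts; detect it on the fitted scores
        s = X @ coef + intercept
        separated = s[y == 1].min() > s[y == 0].max()
        if converged and not separated and np.abs(coef).max() < _SEPARATION_COEF:
            return coef, intercept, False
        warnings.warn(
            "separable development scores: falling back to ridge logistic regression",
            RuntimeWarning,
            stacklevel=3,
        )
        coef, intercept, _ = self._fit_nonneg_logistic(X, y, lam=self.ridge_lambda)
        return coef, intercept, True

    def transform(self, X) -> np.ndarray:
        """Calibrated log10 LR for each row of per-vowel scores."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("score vector dimensionality mismatch")
        Xf = np.where(np.isnan(X), self.column_means_, X)
        return (Xf @ self.weights_ + self.intercept_ - self.prior_logodds_) / _LOG10


def fit_fusion(dev_scores, labels, ridge_lambda: float = 1e-3) -> ScoreFusion:
    """Fit a :class:`ScoreFusion` on development score vectors and Hs/Hd labels."""
    return ScoreFusion(ridge_lambda=ridge_lambda).fit(dev_scores, labels)
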