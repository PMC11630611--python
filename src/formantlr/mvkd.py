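"""Two-level multivariate kernel-density (MVKD) likelihood-ratio scoring.

The forensic question for a pair of vowel samples is

    LR = p(evidence | same speaker) / p(evidence | different speakers),

evaluated against a background population that calibrates how *typical* the
observed formant values are. The model is two-level: token-level
(within-speaker) variation is normal with a pooled covariance ``W``, while
the speaker-level (between-speaker) distribution of mean vectors is a
kernel-density mixture over the ``m`` background speakers' means with kernel
covariance ``h^2 B``, where ``B`` is the between-speaker covariance of the
means and ``h`` the normal-reference bandwidth

    h = (4 / ((2 d + 1) m)) ** (1 / (d + 4)),

``d`` being the number of formants scored jointly.

For a questioned sample with mean ``yq`` over ``nq`` tokens and a reference
sample with mean ``yr`` over ``nr`` tokens (and writing ``C = h^2 B``):

* numerator (same origin): the joint density of the two means under one
  unknown source mean drawn from the kernel density,

    p(yq, yr | Hs) = N(yq - yr; 0, W/nq + W/nr)
                     * (1/m) sum_j N(w; mu_j, C + W/(nq + nr)),

  with ``w = (nq yq + nr yr) / (nq + nr)`` the pooled mean — the product of
  a *similarity* term and a *typicality* term;

* denominator (different origins): the product of the two marginal kernel
  mixtures ``(1/m) sum_j N(y; mu_j, C + W/n)``.

Scores are returned as log10 LR, clamped to [-10, 10] (bounded penalties,
as is common practice with density-underflow-prone forensic LR systems).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cholesky
from sklearn.base import BaseEstimator

__all__ = [
    "MVKDScorer",
    "ComparisonSample",
    "fit_background",
    "reference_bandwidth",
    "SingularCovarianceError",
]

_LOG10 = np.log(10.0)
_LOG_2PI = np.log(2.0 * np.pi)


class SingularCovarianceError(ValueError):
    """The pooled within-speaker covariance is not positive definite.

    Typically means too few tokens for the number of formants scored
    jointly; use more tokens per speaker or a smaller formant subset.
    """


def reference_bandwidth(d: int, m: int) -> float:
    """Normal-reference kernel bandwidth for d dimensions and m speakers."""
    return float((4.0 / ((2 * d + 1) * m)) ** (1.0 / (d + 4)))


@dataclass(frozen=True)
class ComparisonSample:
    """One side of a comparison: the selected-formant token matrix of one
    speaker's vowel tokens (n_tokens x d, Hz) plus provenance labels."""

    speaker: str
    vowel: str
    matrix: np.ndarray
    subset: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if m.shape[0] < 2:
            raise ValueError("a comparison sample needs at least 2 tokens")
        if not np.isfinite(m).all():
            raise ValueError("comparison sample rows must be complete and finite")
        object.__setattr__(self, "matrix", m)


def _scaled_whiteners(base: np.ndarray, add: np.ndarray, scales: np.ndarray):
    """Whitening transforms for the covariance family ``base + add / s``.

    Returns per-scale inverse Cholesky factors (s, d, d) and log-determinants,
    batched so each unique scale costs one stacked decomposition.
    """
    d = base.shape[0]
    covs = base[None, :, :] + add[None, :, :] / scales[:, None, None]
    Ls = np.linalg.cholesky(covs)  # raises LinAlgError if not PD
    logdets = 2.0 * np.log(np.diagonal(Ls, axis1=1, axis2=2)).sum(axis=1)
    inv = np.linalg.solve(Ls, np.broadcast_to(np.eye(d), (len(scales), d, d)))
    return inv, logdets


def _logsumexp_rows(a: np.ndarray) -> np.ndarray:
    hi = a.max(axis=1)
    return hi + np.log(np.exp(a - hi[:, None]).sum(axis=1))


class MVKDScorer(BaseEstimator):
    """Two-level kernel-density likelihood-ratio model for one vowel.

    Parameters
    ----------
    clamp
        Symmetric bound on the returned log10 LR.

    Attributes (after :meth:`fit`)
    ------------------------------
    speaker_means_ : (m, d) background speaker mean vectors
    within_covariance_ : (d, d) pooled within-speaker covariance ``W``
    between_covariance_ : (d, d) covariance of the speaker means ``B``
    bandwidth_ : normal-reference kernel bandwidth ``h``
    n_speakers_ : number of background speakers ``m``
    n_features_in_ : number of formants ``d``
    """

    def __init__(self, clamp: float = 10.0):
        self.clamp = clamp

    # -- fitting -----------------------------------------------------------
    def fit(self, samples_by_speaker, y=None) -> "MVKDScorer":
        """Fit background statistics from per-speaker token matrices.

        ``samples_by_speaker`` is a mapping speaker -> (n_i x d) array or a
        plain sequence of such arrays; every speaker needs >= 2 tokens and
        there must be >= 3 speakers.
        """
        if isinstance(samples_by_speaker, dict):
            arrays = [np.atleast_2d(np.asarray(a, dtype=float)) for _, a in sorted(samples_by_speaker.items())]
        else:
            arrays = [np.atleast_2d(np.asarray(a, dtype=float)) for a in samples_by_speaker]
        m = len(arrays)
        if m < 3:
            raise ValueError("need at least 3 background speakers")
        d = arrays[0].shape[1]
        if any(a.shape[1] != d for a in arrays):
            raise ValueError("all speakers must share the same formant subset")
        if any(a.shape[0] < 2 for a in arrays):
            raise ValueError("every background speaker needs at least 2 tokens")

        means = np.vstack([a.mean(axis=0) for a in arrays])
        n_total = sum(a.shape[0] for a in arrays)
        scatter = np.zeros((d, d))
        for a, mu in zip(arrays, means):
            c = a - mu
            scatter += c.T @ c
        W = scatter / (n_total - m)
        try:
            cholesky(W, lower=True)
        except LinAlgError as err:
            raise SingularCovarianceError(
                "pooled within-speaker covariance is singular; "
                "use more tokens per speaker or fewer formants"
            ) from err
        B = np.atleast_2d(np.cov(means.T, ddof=1))

        self.speaker_means_ = means
        self.within_covariance_ = W
        self.between_covariance_ = B
        self.n_speakers_ = m
        self.n_features_in_ = d
        self.bandwidth_ = reference_bandwidth(d, m)
        return self

    def subset_model(self, indices) -> "MVKDScorer":
        """The fitted model restricted to a subset of its formant dimensions.

        Valid because all fitted statistics are moments: the sub-model's
        ``W``/``B``/means are the corresponding sub-blocks, and only the
        bandwidth is recomputed for the new dimensionality.
        """
        idx = np.asarray(indices, dtype=int)
        sub = MVKDScorer(clamp=self.clamp)
        sub.speaker_means_ = self.speaker_means_[:, idx]
        sub.within_covariance_ = self.within_covariance_[np.ix_(idx, idx)]
        sub.between_covariance_ = self.between_covariance_[np.ix_(idx, idx)]
        sub.n_speakers_ = self.n_speakers_
        sub.n_features_in_ = len(idx)
        sub.bandwidth_ = reference_bandwidth(len(idx), self.n_speakers_)
        return sub

    # -- scoring -----------------------------------------------------------
    def _mixture_logpdf(self, Y: np.ndarray, scale: np.ndarray) -> np.ndarray:
        """log[(1/m) sum_j N(Y_i; mu_j, C + W/scale_i)] vectorised by scale."""
        C = self.bandwidth_**2 * self.between_covariance_
        W = self.within_covariance_
        d = self.n_features_in_
        uniq, inv = np.unique(scale, return_inverse=True)
        whiten, logdets = _scaled_whiteners(C, W, uniq)
        diff = Y[:, None, :] - self.speaker_means_[None, :, :]  # (k, m, d)
        z = np.einsum("kij,kmj->kmi", whiten[inv], diff)
        quad = (z**2).sum(axis=-1)
        lp = -0.5 * (d * _LOG_2PI + logdets[inv][:, None] + quad)
        return _logsumexp_rows(lp) - np.log(self.n_speakers_)

    def score_means(self, yq, yr, nq, nr) -> np.ndarray:
        """Vectorised log10 LR for rows of (questioned mean, reference mean).

        ``yq``/``yr`` are (k, d) mean vectors; ``nq``/``nr`` the token counts
        behind each mean.
        """
        yq = np.atleast_2d(np.asarray(yq, dtype=float))
        yr = np.atleast_2d(np.asarray(yr, dtype=float))
        k = yq.shape[0]
        nq = np.broadcast_to(np.asarray(nq, dtype=float), (k,)).copy()
        nr = np.broadcast_to(np.asarray(nr, dtype=float), (k,)).copy()
        if yq.shape != yr.shape or yq.shape[1] != self.n_features_in_:
            raise ValueError("questioned/reference means must match the fitted dimension")
        W = self.within_covariance_

        # similarity: N(yq - yr; 0, W (1/nq + 1/nr)), grouped by the scalar factor
        diff = yq - yr
        factor = 1.0 / nq + 1.0 / nr
        d = self.n_features_in_
        uniq, inv = np.unique(factor, return_inverse=True)
        whiten, logdets = _scaled_whiteners(np.zeros((d, d)), W, 1.0 / uniq)
        z = np.einsum("kij,kj->ki", whiten[inv], diff)
        log_sim = -0.5 * (d * _LOG_2PI + logdets[inv] + (z**2).sum(axis=-1))

        pooled = (nq[:, None] * yq + nr[:, None] * yr) / (nq + nr)[:, None]
        log_num = log_sim + self._mixture_logpdf(pooled, nq + nr)
        log_den = self._mixture_logpdf(yq, nq) + self._mixture_logpdf(yr, nr)
        llr = (log_num - log_den) / _LOG10
        if not np.isfinite(llr).all():
            warnings.warn("non-finite MVKD log-LR clamped", RuntimeWarning, stacklevel=2)
            llr = np.nan_to_num(llr, nan=0.0, posinf=self.clamp, neginf=-self.clamp)
        return np.clip(llr, -self.clamp, self.clamp)

    def score_pair(self, questioned, reference) -> float:
        """log10 LR for one questioned-vs-reference token-matrix pair."""
        q = questioned.matrix if isinstance(questioned, ComparisonSample) else np.atleast_2d(
            np.asarray(questioned, dtype=float)
        )
        r = reference.matrix if isinstance(reference, ComparisonSample) else np.atleast_2d(
            np.asarray(reference, dtype=float)
        )
        if q.shape[1] != self.n_features_in_ or r.shape[1] != self.n_features_in_:
            raise ValueError("sample dimensionality does not match the fitted model")
        return float(
            self.score_means(q.mean(axis=0), r.mean(axis=0), q.shape[0], r.shape[0])[0]
        )


def fit_background(
    samples_by_speaker, vowel: str | None = None, subset: tuple[str, ...] = (), clamp: float = 10.0
) -> MVKDScorer:
    """Convenience wrapper: fit an :class:`MVKDScorer` and tag its provenance."""
    model = MVKDScorer(clamp=clamp).fit(samples_by_speaker)
    model.vowel = vowel
    model.subset = tuple(subset)
    return model
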