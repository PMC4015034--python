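"""Maximum-likelihood estimation of the sample SFS from SAF vectors.

Treating the allele-frequency category of each site as drawn i.i.d. from
an unknown probability vector ``p`` over 0..2n, the log-likelihood of the
data is ``sum_s log sum_j p_j Pr(D_s | x = j)`` and the EM update is

    p_j <- (1/M) sum_s  p_j K_sj / sum_k p_k K_sk

with ``K_sj = Pr(D_s | x = j)`` and ``M`` the number of sites.  The total
log-likelihood is non-decreasing across iterations.  Expected category
counts are ``M * p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectrum import FrequencySpectrum

__all__ = ["PriorSFS", "EMResult", "estimate_sfs_em", "sfs_log_likelihood"]

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 500


@dataclass
class PriorSFS:
    """A probability vector over allele-frequency categories 0..2n."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or len(self.probs) < 2:
            raise ValueError("prior must be a vector of length 2n + 1 >= 2")
        if np.any(self.probs < 0):
            raise ValueError("prior probabilities must be non-negative")
        tot = self.probs.sum()
        if not np.isclose(tot, 1.0, atol=1e-12, rtol=1e-9):
            raise ValueError(f"prior must sum to 1 (got {tot})")

    @property
    def n_chrom(self) -> int:
        return len(self.probs) - 1


@dataclass
class EMResult:
    probs: PriorSFS
    counts: FrequencySpectrum
    log_likelihoods: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def _lin_saf(saf: np.ndarray, scale: str) -> np.ndarray:
    saf = np.asarray(saf)
    if saf.ndim != 2:
        raise ValueError("expected a (n_sites, 2n+1) SAF matrix")
    if saf.shape[0] == 0:
        raise ValueError("no sites to estimate an SFS from")
    mx = saf.max(axis=1)
    if not np.all(np.isfinite(mx)):
        bad = int(np.flatnonzero(~np.isfinite(mx))[0])
        raise ValueError(f"non-finite SAF likelihood at site index {bad}")
    if scale == "log":
        return np.exp(saf - mx[:, None])
    if scale == "linear":
        if np.any(mx <= 0):
            bad = int(np.flatnonzero(mx <= 0)[0])
            raise ValueError(f"all-zero SAF likelihood at site index {bad}")
        return saf
    raise ValueError("scale must be 'log' or 'linear'")


def sfs_log_likelihood(probs, saf_loglik: np.ndarray, scale: str = "log") -> float:
    """Total log-likelihood ``sum_s log sum_j p_j Pr(D_s | x = j)``.

    Computed with each site's SAF vector on its stored normalization,
    i.e. up to a data-dependent additive constant.
    """
    p = probs.probs if isinstance(probs, PriorSFS) else np.asarray(probs, float)
    K = _lin_saf(saf_loglik, scale)
    if K.shape[1] != len(p):
        raise ValueError(
            f"prior length {len(p)} does not match SAF width {K.shape[1]}"
        )
    return float(np.log(K @ p.astype(K.dtype, copy=False)).sum(dtype=np.float64))


def estimate_sfs_em(
    saf_loglik: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    init: np.ndarray | None = None,
    scale: str = "log",
) -> EMResult:
    """EM maximum-likelihood estimate of the SFS from SAF vectors.

    Parameters
    ----------
    saf_loglik:
        (n_sites, 2n+1) matrix of per-site SAF likelihoods; log scale by
        default, ``scale="linear"`` accepts linear-scale rows (e.g. from
        :func:`~ngstheta.saf.saf_matrix_linear`).
    tol:
        Relative change in total log-likelihood below which iteration
        stops.
    max_iter:
        Iteration cap.
    init:
        Starting probability vector; defaults to uniform over 0..2n (a
        deliberately non-neutral start).

    Returns
    -------
    :class:`EMResult` with the probability-scale estimate, expected
    category counts (``M * p``), and the log-likelihood trace.
    """
    K = _lin_saf(saf_loglik, scale)
    M, ncat = K.shape
    if init is None:
        p = np.full(ncat, 1.0 / ncat)
    else:
        p = np.asarray(init, dtype=float).copy()
        p /= p.sum()
        if len(p) != ncat:
            raise ValueError("init length does not match SAF width")
    trace: list[float] = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = K @ p.astype(K.dtype, copy=False)  # (M,)
        ll = float(np.log(denom).sum(dtype=np.float64))
        trace.append(ll)
        # E+M step: p_j <- p_j/M * sum_s K_sj / denom_s
        p = p * (K.T @ (1.0 / denom)).astype(np.float64) / M
        p /= p.sum()  # guard drift
        if np.isfinite(prev) and abs(ll - prev) <= tol * max(abs(ll), 1.0):
            converged = True
            break
        prev = ll
    counts = FrequencySpectrum(M * p, ncat - 1)
    return EMResult(
        probs=PriorSFS(p),
        counts=counts,
        log_likelihoods=trace,
        n_iter=it,
        converged=converged,
    )
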