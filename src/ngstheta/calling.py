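"""Genotype-calling comparators: per-site allele frequency ML, LRT SNP
inclusion, and the two hard-call rules (highest-GL and HWE-prior).

These are the baseline methods that the likelihood-based SFS machinery is
compared against.  They treat every site as di-allelic, estimate the
minor-allele frequency f by EM across individuals, test H0: f = 0 by a
likelihood ratio test (chi-square, 1 df), and only let sites that pass
the test contribute polymorphic genotypes to the spectrum; everything
else is counted as monomorphic (category 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .spectrum import FrequencySpectrum

__all__ = [
    "AlleleFrequencyEstimate",
    "estimate_f_em",
    "estimate_f_em_sites",
    "call_genotype_mlike",
    "call_genotype_hwe",
    "sfs_from_called_genotypes",
]

F_INIT = 0.05
F_TOL = 1e-8
F_MAX_ITER = 200


@dataclass
class AlleleFrequencyEstimate:
    """ML minor-allele frequency with its LRT against f = 0."""

    f_hat: float
    log_lik_at_f: float
    log_lik_at_0: float
    lrt_stat: float
    p_value: float
    uninformative: bool = False


def _hwe_weights(f: np.ndarray) -> np.ndarray:
    """(..., 3) HWE genotype priors (1-f)^2, 2f(1-f), f^2."""
    f = np.asarray(f, dtype=float)
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)


def estimate_f_em_sites(
    gls: np.ndarray,
    tol: float = F_TOL,
    max_iter: int = F_MAX_ITER,
    init: float = F_INIT,
    scale: str = "log",
):
    """Vectorized per-site EM for the minor allele frequency.

    Parameters
    ----------
    gls:
        (n_sites, n_ind, 3) genotype likelihoods; log scale by default,
        ``scale="linear"`` accepts linear-scale values (any
    per-individual normalization — likelihood ratios are scale-free).

    Returns
    -------
    ``(f_hat, lrt, p_value, uninformative)`` arrays of length n_sites.
    The LRT statistic is ``2 (l(f_hat) - l(0))`` clamped at 0 and its
    p-value comes from a chi-square with 1 df.
    """
    gls = np.asarray(gls, dtype=float)
    if gls.ndim == 2:
        gls = gls[None]
    n_sites, n_ind, _ = gls.shape
    mx = gls.max(axis=2, keepdims=True)
    if scale == "log":
        lin = np.exp(gls - mx)  # (S, I, 3), per-individual max = 1
    elif scale == "linear":
        if np.any(mx <= 0):
            raise ValueError("linear-scale likelihoods must be positive somewhere")
        lin = gls / mx
    else:
        raise ValueError("scale must be 'log' or 'linear'")
    flat = np.all(np.ptp(lin, axis=2) < 1e-12, axis=1)
    # contiguous per-genotype slabs: the EM update touches (S, I) arrays
    L0 = np.ascontiguousarray(lin[:, :, 0])
    L1 = np.ascontiguousarray(lin[:, :, 1])
    L2 = np.ascontiguousarray(lin[:, :, 2])
    f = np.full(n_sites, float(init))
    active = np.arange(n_sites)
    for _ in range(max_iter):
        fa = f[active][:, None]
        a0 = (1 - fa) ** 2 * L0[active]
        a1 = 2 * fa * (1 - fa) * L1[active]
        a2 = fa * fa * L2[active]
        # E[g] per individual = (a1 + 2 a2) / (a0 + a1 + a2)
        f_new = ((a1 + 2 * a2) / (a0 + a1 + a2)).sum(axis=1) / (2.0 * n_ind)
        delta = np.abs(f_new - f[active])
        f[active] = f_new
        active = active[delta >= tol]
        if len(active) == 0:
            break
    fa = f[:, None]
    ll_f = np.log(
        (1 - fa) ** 2 * L0 + 2 * fa * (1 - fa) * L1 + fa * fa * L2
    ).sum(axis=1)
    with np.errstate(divide="ignore"):
        ll_0 = np.log(L0).sum(axis=1)
    lrt = np.maximum(2.0 * (ll_f - ll_0), 0.0)
    lrt[flat] = 0.0
    f = np.where(flat, float(init), f)
    p = chi2.sf(lrt, df=1)
    p[flat] = 1.0
    return f, lrt, p, flat


def estimate_f_em(
    log_gls: np.ndarray,
    tol: float = F_TOL,
    max_iter: int = F_MAX_ITER,
    init: float = F_INIT,
) -> AlleleFrequencyEstimate:
    """EM estimate of the minor allele frequency at one site.

    With all-flat genotype likelihoods the likelihood is constant in f:
    the estimate is flagged uninformative, the LRT statistic is 0 and the
    p-value 1.
    """
    log_gls = np.atleast_2d(np.asarray(log_gls, dtype=float))
    f, lrt, p, flat = estimate_f_em_sites(log_gls[None], tol, max_iter, init)
    lin = np.exp(log_gls - log_gls.max(axis=1, keepdims=True))
    w = _hwe_weights(np.array([f[0]]))[0]
    ll_f = float(np.log(lin @ w).sum())
    with np.errstate(divide="ignore"):
        ll_0 = float(np.log(lin[:, 0]).sum())
    return AlleleFrequencyEstimate(
        f_hat=float(f[0]),
        log_lik_at_f=ll_f,
        log_lik_at_0=ll_0,
        lrt_stat=float(lrt[0]),
        p_value=float(p[0]),
        uninformative=bool(flat[0]),
    )


def call_genotype_mlike(log_gl: np.ndarray) -> int:
    """Highest-genotype-likelihood call; ties go to the smaller dosage."""
    return int(np.argmax(np.asarray(log_gl, dtype=float)))


def call_genotype_hwe(log_gl: np.ndarray, f: float) -> int:
    """Maximum a posteriori call with an HWE prior at frequency f."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must be in [0, 1]")
    gl = np.asarray(log_gl, dtype=float)
    lin = np.exp(gl - gl.max())
    return int(np.argmax(_hwe_weights(np.array(f)) * lin))


def _call_matrix(lin: np.ndarray, prior: np.ndarray | None) -> np.ndarray:
    """Argmax calls for (S, I, 3) linear GLs, optional (S, 3) priors."""
    scored = lin if prior is None else lin * prior[:, None, :]
    return scored.argmax(axis=2)  # argmax takes the first (smallest) on ties


def sfs_from_called_genotypes(
    log_gls: np.ndarray,
    method: str = "mlike",
    snp_p_cutoff: float = 1e-6,
    n_invariant_extra: int = 0,
) -> FrequencySpectrum:
    """Spectrum of called genotypes with LRT-based SNP inclusion.

    Sites whose LRT p-value is >= ``snp_p_cutoff`` are deemed invariable
    and counted in category 0; at the remaining sites each individual's
    genotype is hard-called (``method``: "mlike" or "hwe") and the site
    contributes at the summed dosage.  ``n_invariant_extra`` adds
    read-free/omitted monomorphic sites to category 0 so that total
    spectrum mass stays accountable.
    """
    if method not in ("mlike", "hwe"):
        raise ValueError("method must be 'mlike' or 'hwe'")
    log_gls = np.asarray(log_gls, dtype=float)
    n_sites, n_ind, _ = log_gls.shape
    K = 2 * n_ind
    counts = np.zeros(K + 1)
    counts[0] += n_invariant_extra
    f, lrt, p, flat = estimate_f_em_sites(log_gls)
    variable = p < snp_p_cutoff
    counts[0] += int((~variable).sum())
    if variable.any():
        lin = np.exp(log_gls[variable] - log_gls[variable].max(axis=2, keepdims=True))
        prior = _hwe_weights(f[variable]) if method == "hwe" else None
        dosage = _call_matrix(lin, prior).sum(axis=1)
        np.add.at(counts, dosage, 1.0)
    return FrequencySpectrum(counts, K)
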