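"""Per-site sample-allele-frequency (SAF) likelihoods.

For n diploid individuals with per-genotype likelihoods ``L_i(g)``, the
likelihood of the data given that ``j`` of the ``2n`` sampled chromosomes
carry the derived allele is

    Pr(D | x = j) = C(2n, j)^-1 *
        sum_{g_1..g_n : sum g_i = j} prod_i C(2, g_i) L_i(g_i),

i.e. the genotype configuration probabilities are hypergeometric given j.
With this convention a site where every individual is data-free (flat GLs)
has a flat SAF vector, and for a single individual Pr(D | x = j) = L(j).

The sum is computed by a dynamic program over individuals in O(n^2) per
site, vectorized across sites; a brute-force enumerator over all 3^n
configurations is provided as an independent oracle for small n.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "SiteAFLikelihood",
    "SafTable",
    "site_af_likelihood",
    "saf_matrix",
    "saf_matrix_linear",
    "brute_force_af_likelihood",
    "read_saf",
    "write_saf",
]

_BINOM2 = np.array([1.0, 2.0, 1.0])  # C(2, g)


def _log_binom(n: int, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@dataclass
class SiteAFLikelihood:
    """Log Pr(D | x = j), j = 0..2n, for one site; max-normalized to 0."""

    loglik: np.ndarray
    n_chrom: int
    chrom: str = "chr"
    position: int = 1

    def __post_init__(self):
        self.loglik = np.asarray(self.loglik, dtype=float)
        if len(self.loglik) != self.n_chrom + 1:
            raise ValueError("SAF vector must have length 2n + 1")


@dataclass
class SafTable:
    """SAF vectors for many sites of one chromosome, sorted by position."""

    chrom: str
    positions: np.ndarray  # 1-based, strictly increasing
    loglik: np.ndarray  # (n_sites, 2n + 1)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.loglik = np.asarray(self.loglik)
        if self.loglik.ndim != 2 or len(self.positions) != self.loglik.shape[0]:
            raise ValueError("positions and loglik rows must align")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_chrom(self) -> int:
        return self.loglik.shape[1] - 1

    @property
    def n_sites(self) -> int:
        return self.loglik.shape[0]

    def informative_mask(self, tol: float = 1e-9) -> np.ndarray:
        """True for sites whose SAF vector is not flat (some read data)."""
        return np.ptp(self.loglik, axis=1) > tol


def _dp_block(lin: np.ndarray, dtype=np.float64):
    """Band DP over individuals for one block of sites.

    ``lin``: (m, n_ind, 3) linear-scale genotype likelihoods (any
    per-individual scale).  Returns ``(w, log_scale)`` where ``w`` is
    (2n+1, m) with per-site max 1 and ``log_scale`` holds the per-site
    log of the running rescaling factors, so that the unnormalized
    configuration sum is ``w * exp(log_scale)``.
    """
    m, n_ind, _ = lin.shape
    K = 2 * n_ind + 1
    w = np.zeros((K, m), dtype=dtype)
    new = np.zeros((K, m), dtype=dtype)
    tmp = np.empty((K, m), dtype=dtype)
    w[0] = 1.0
    log_scale = np.zeros(m)
    width = 1
    for i in range(n_ind):
        new[: width + 2] = 0.0
        for g in range(3):
            coef = (_BINOM2[g] * lin[:, i, g]).astype(dtype)
            np.multiply(w[:width], coef[None, :], out=tmp[:width])
            new[g : g + width] += tmp[:width]
        width += 2
        w, new = new, w
        mx = w[:width].max(axis=0)
        mx[mx == 0] = 1.0  # degenerate all-zero column; leave as is
        w[:width] /= mx[None, :]
        log_scale += np.log(mx)
    return w, log_scale


def saf_matrix_linear(
    lin_gls: np.ndarray, chunk: int = 100_000, dtype=np.float32
) -> np.ndarray:
    """Linear-scale SAF matrix for many sites.

    Like :func:`saf_matrix` but takes (n_sites, n_ind, 3) linear-scale
    genotype likelihoods and returns each site's SAF vector on linear
    scale, normalized to max 1.  Single precision by default: relative
    magnitudes below ~1e-38 flush to 0, which is irrelevant for EM and
    posterior computations.  This is the fast path for whole regions.
    """
    lin_gls = np.asarray(lin_gls)
    if lin_gls.ndim == 2:
        lin_gls = lin_gls[None, :, :]
    n_sites, n_ind, _ = lin_gls.shape
    K = 2 * n_ind + 1
    inv_choose = np.exp(-_log_binom(2 * n_ind, np.arange(K, dtype=float))).astype(dtype)
    out = np.empty((n_sites, K), dtype=dtype)
    for start in range(0, n_sites, chunk):
        w, _ = _dp_block(lin_gls[start : start + chunk], dtype=dtype)
        block = w.T * inv_choose[None, :]
        block /= block.max(axis=1, keepdims=True)
        out[start : start + chunk] = block
    return out


def saf_matrix(log_gls: np.ndarray, chunk: int = 100_000) -> np.ndarray:
    """SAF log-likelihood vectors for many sites at once.

    Parameters
    ----------
    log_gls:
        Array (n_sites, n_ind, 3) of per-individual genotype
        log-likelihoods (any normalization).
    chunk:
        Number of sites processed per block, bounding peak memory.

    Returns
    -------
    Array (n_sites, 2n + 1) of log Pr(D | x = j), max-normalized to 0
    per site.
    """
    log_gls = np.asarray(log_gls, dtype=float)
    if log_gls.ndim == 2:
        log_gls = log_gls[None, :, :]
    n_sites, n_ind, _ = log_gls.shape
    K = 2 * n_ind + 1
    out = np.empty((n_sites, K))
    log_choose = _log_binom(2 * n_ind, np.arange(K, dtype=float))
    for start in range(0, n_sites, chunk):
        block = log_gls[start : start + chunk]
        lin = np.exp(block - block.max(axis=2, keepdims=True))
        w, _ = _dp_block(lin, dtype=np.float64)
        with np.errstate(divide="ignore"):
            ll = np.log(w.T) - log_choose[None, :]
        ll -= ll.max(axis=1, keepdims=True)
        out[start : start + chunk] = ll
    return out


def site_af_likelihood(
    log_gls: np.ndarray, chrom: str = "chr", position: int = 1
) -> SiteAFLikelihood:
    """SAF vector for a single site from (n_ind, 3) genotype log-likelihoods."""
    log_gls = np.asarray(log_gls, dtype=float)
    ll = saf_matrix(log_gls[None, :, :])[0]
    return SiteAFLikelihood(ll, 2 * log_gls.shape[0], chrom, position)


def brute_force_af_likelihood(
    log_gls: np.ndarray, chrom: str = "chr", position: int = 1
) -> SiteAFLikelihood:
    """Direct enumeration over all 3^n genotype configurations (n <= 5).

    Test oracle for the dynamic program; refuses larger n.
    """
    log_gls = np.asarray(log_gls, dtype=float)
    n_ind = log_gls.shape[0]
    if n_ind > 5:
        raise ValueError("brute force limited to n <= 5 individuals")
    lin = np.exp(log_gls - log_gls.max(axis=1, keepdims=True))
    K = 2 * n_ind + 1
    acc = np.zeros(K)
    for config in itertools.product(range(3), repeat=n_ind):
        j = sum(config)
        term = 1.0
        for i, g in enumerate(config):
            term *= _BINOM2[g] * lin[i, g]
        acc[j] += term
    choose = np.exp(_log_binom(2 * n_ind, np.arange(K, dtype=float)))
    with np.errstate(divide="ignore"):
        ll = np.log(acc / choose)
    ll -= ll.max()
    return SiteAFLikelihood(ll, 2 * n_ind, chrom, position)


def write_saf(path, table: SafTable) -> None:
    """Write a SAF table as TSV: chrom, position, then 2n+1 log-likelihoods.

    Gzip-transparent: a ``.gz`` suffix compresses.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for pos, row in zip(table.positions, table.loglik):
            fh.write(
                table.chrom
                + "\t"
                + str(int(pos))
                + "\t"
                + "\t".join(f"{x:.12g}" for x in row)
                + "\n"
            )


def read_saf(path) -> list[SafTable]:
    """Read a SAF TSV (gzip-transparent); one table per chromosome."""
    opener = gzip.open if str(path).endswith(".gz") else open
    chroms: dict[str, tuple[list, list]] = {}
    order: list[str] = []
    with opener(path, "rt") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: too few columns")
            chrom = parts[0]
            if chrom not in chroms:
                chroms[chrom] = ([], [])
                order.append(chrom)
            try:
                chroms[chrom][0].append(int(parts[1]))
                chroms[chrom][1].append([float(x) for x in parts[2:]])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    return [
        SafTable(c, np.array(chroms[c][0]), np.array(chroms[c][1])) for c in order
    ]
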