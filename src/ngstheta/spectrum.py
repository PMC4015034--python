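"""Site frequency spectra, theta estimators and neutrality test statistics.

The site frequency spectrum (SFS) of a sample of ``2n`` chromosomes is the
vector ``eta`` of length ``2n + 1`` whose ``k``-th entry counts the sites at
which exactly ``k`` chromosomes carry the derived allele.  Entries may be
fractional: posterior-expected spectra produced by the empirical Bayes
machinery are real-valued.

All classical theta estimators used here are linear functions of the
spectrum, ``theta_hat = sum_i alpha_i * eta_i``:

* Watterson's ``theta_w`` weights every segregating category equally.
* The pairwise-difference estimator ``theta_pi`` up-weights intermediate
  frequencies.
* Fu & Li's ``theta_FL`` counts derived singletons only.
* Fay & Wu's ``theta_H`` up-weights high-frequency derived alleles.

Neutrality tests (Tajima's D, Fu & Li's D and F) are standardized contrasts
between two such estimators; their variance constants under the standard
neutral model are collected in :class:`NeutralityConstants`.

Statistics that are undefined (no segregating sites, or a non-positive
variance on a fractional spectrum) are returned as ``nan`` — an explicit
missing marker, never coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FrequencySpectrum",
    "NeutralityConstants",
    "ThetaSet",
    "compute_constants",
    "estimator_weights",
    "theta_estimators",
    "tajimas_d",
    "fuli_d",
    "fuli_f",
    "fold",
    "standardize_scores",
    "read_sfs",
    "write_sfs",
]


@dataclass
class FrequencySpectrum:
    """A (possibly fractional) site frequency spectrum for 2n chromosomes.

    Parameters
    ----------
    counts:
        Vector of length ``n_chrom + 1``; index ``k`` holds the number of
        sites with ``k`` derived alleles.  Non-negative reals.
    n_chrom:
        Number of sampled chromosomes (2 x diploid individuals).
    """

    counts: np.ndarray
    n_chrom: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.n_chrom < 1:
            raise ValueError("n_chrom must be positive")
        if self.counts.ndim != 1 or len(self.counts) != self.n_chrom + 1:
            raise ValueError(
                f"spectrum length {len(self.counts)} != n_chrom + 1 = {self.n_chrom + 1}"
            )
        if np.any(self.counts < 0):
            raise ValueError("spectrum entries must be non-negative")

    @property
    def segregating_sites(self) -> float:
        """Total mass in the polymorphic categories 1 .. 2n-1."""
        return float(self.counts[1:-1].sum())

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class NeutralityConstants:
    """Standardization constants for Tajima's D and Fu & Li's D and F.

    ``a1 = sum_{i=1}^{n-1} 1/i`` and ``a2 = sum 1/i^2``; the remaining
    fields are the variance multipliers of the classical unfolded test
    statistics for ``n`` sequences under the standard neutral model.
    """

    n_chrom: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float
    cn: float
    uD: float
    vD: float
    uF: float
    vF: float


def _harmonic(n: int, power: int = 1) -> float:
    return float(np.sum(1.0 / np.arange(1, n, dtype=float) ** power))


def compute_constants(n_chrom: int) -> NeutralityConstants:
    """Compute all Tajima and Fu & Li standardization constants.

    Parameters
    ----------
    n_chrom:
        Number of sequences; must be at least 3 (the Fu & Li constants
        divide by ``(n - 1)(n - 2)``).
    """
    n = int(n_chrom)
    if n < 3:
        raise ValueError(f"variance constants undefined for n_chrom={n} < 3")
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    # Tajima (1989) chain
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    # Fu & Li (1993) unfolded constants, with the later F-statistic correction
    cn = 2.0 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    vD = 1.0 + (a1**2 / (a2 + a1**2)) * (cn - (n + 1) / (n - 1))
    uD = a1 - 1.0 - vD
    an1 = a1 + 1.0 / n  # harmonic number over n terms
    vF = (cn + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1)) - 2.0 / (n - 1)) / (a1**2 + a2)
    uF = (
        1.0
        + (n + 1) / (3.0 * (n - 1))
        - 4.0 * ((n + 1) / (n - 1) ** 2) * (an1 - 2.0 * n / (n + 1))
    ) / a1 - vF
    return NeutralityConstants(
        n_chrom=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2,
        e1=e1, e2=e2, cn=cn, uD=uD, vD=vD, uF=uF, vF=vF,
    )


@dataclass(frozen=True)
class ThetaSet:
    """Linear theta estimates computed from one spectrum."""

    tW: float
    tP: float
    tFL: float
    tH: float
    S: float


def estimator_weights(n_chrom: int) -> dict[str, np.ndarray]:
    """Weight vectors ``alpha`` such that ``theta_hat = alpha . eta``.

    The invariant and fixed categories (0 and 2n) carry zero weight for
    all four estimators.
    """
    n = int(n_chrom)
    if n < 2:
        raise ValueError("need at least 2 chromosomes")
    i = np.arange(n + 1, dtype=float)
    a1 = _harmonic(n)
    pairs = n * (n - 1) / 2.0
    w = {}
    w["tW"] = np.where((i > 0) & (i < n), 1.0 / a1, 0.0)
    w["tP"] = np.where((i > 0) & (i < n), i * (n - i) / pairs, 0.0)
    alpha_fl = np.zeros(n + 1)
    alpha_fl[1] = 1.0
    w["tFL"] = alpha_fl
    w["tH"] = np.where((i > 0) & (i < n), i * i / pairs, 0.0)
    return w


def theta_estimators(sfs: FrequencySpectrum) -> ThetaSet:
    """Compute Watterson, pi, Fu & Li singleton and Fay & Wu H estimates."""
    w = estimator_weights(sfs.n_chrom)
    eta = sfs.counts
    return ThetaSet(
        tW=float(eta @ w["tW"]),
        tP=float(eta @ w["tP"]),
        tFL=float(eta @ w["tFL"]),
        tH=float(eta @ w["tH"]),
        S=sfs.segregating_sites,
    )


def tajimas_d(sfs: FrequencySpectrum) -> float:
    """Tajima's D: standardized theta_pi - theta_w.

    Returns ``nan`` when no sites segregate (variance 0) or when the
    variance expression is non-positive on a fractional spectrum.
    """
    c = compute_constants(sfs.n_chrom)
    t = theta_estimators(sfs)
    S = t.S
    if S <= 0:
        return math.nan
    var = c.e1 * S + c.e2 * S * (S - 1.0)
    if var <= 0:
        return math.nan
    return (t.tP - t.tW) / math.sqrt(var)


def fuli_d(sfs: FrequencySpectrum) -> float:
    """Fu & Li's D: standardized contrast of S against derived singletons."""
    c = compute_constants(sfs.n_chrom)
    S = sfs.segregating_sites
    if S <= 0:
        return math.nan
    var = c.uD * S + c.vD * S * S
    if var <= 0:
        return math.nan
    return (S - c.a1 * float(sfs.counts[1])) / math.sqrt(var)


def fuli_f(sfs: FrequencySpectrum) -> float:
    """Fu & Li's F: standardized contrast of theta_pi against singletons."""
    c = compute_constants(sfs.n_chrom)
    t = theta_estimators(sfs)
    S = t.S
    if S <= 0:
        return math.nan
    var = c.uF * S + c.vF * S * S
    if var <= 0:
        return math.nan
    return (t.tP - float(sfs.counts[1])) / math.sqrt(var)


def fold(sfs: FrequencySpectrum) -> FrequencySpectrum:
    """Fold a spectrum: minor-allele counts, ancestral state forgotten.

    ``eta*_k = eta_k + eta_{2n-k}`` for ``k < n``; the middle category of
    an even spectrum is kept as is; categories above ``n`` are zeroed.
    Total mass is conserved, and folding is idempotent.
    """
    m = sfs.n_chrom
    eta = sfs.counts
    out = np.zeros_like(eta)
    half = m // 2
    for k in range(half + 1):
        if k < m - k:
            out[k] = eta[k] + eta[m - k]
        else:  # middle category of an even spectrum
            out[k] = eta[k]
    return FrequencySpectrum(out, m)


def standardize_scores(values, reference_values) -> np.ndarray:
    """Standardize ``values`` by the mean/sd of a reference distribution.

    Used to put genotype-calling scans on a common scale with a neutral
    reference set.  ``nan`` entries in the reference are ignored; ``nan``
    values propagate.  Uses the sample (n-1) standard deviation.
    """
    v = np.asarray(values, dtype=float)
    ref = np.asarray(reference_values, dtype=float)
    ref = ref[np.isfinite(ref)]
    if len(ref) < 2:
        raise ValueError("reference needs at least 2 finite entries")
    sd = ref.std(ddof=1)
    if sd == 0:
        raise ValueError("reference standard deviation is 0")
    return (v - ref.mean()) / sd


def write_sfs(path, sfs: FrequencySpectrum) -> None:
    """Write a spectrum as one line of whitespace-separated reals."""
    with open(path, "w") as fh:
        fh.write(" ".join(f"{x:.12g}" for x in sfs.counts) + "\n")


def read_sfs(path) -> FrequencySpectrum:
    """Read a spectrum file (single line, length 2n+1)."""
    with open(path) as fh:
        vals = [float(x) for x in fh.read().split()]
    if len(vals) < 2:
        raise ValueError(f"{path}: expected at least 2 values")
    return FrequencySpectrum(np.array(vals), len(vals) - 1)
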