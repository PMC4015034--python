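"""Genotype likelihoods under the simplified GATK base-quality model.

For a diploid genotype ``G = {A1, A2}`` and a pileup of ``M`` bases
``b_1..b_M`` with per-base error probabilities ``e_i``, the likelihood is

    Pr(D | G) = prod_i [ 1/2 p(b_i|A1) + 1/2 p(b_i|A2) ],
    p(b|A) = 1 - e   if b == A
           = e / 3   otherwise.

Only base identity and quality enter the model; read position, cycle and
mapping effects are not modelled.  Likelihoods are defined up to a
constant, so all routines work in log space renormalized to max = 0, and
an individual with no reads gets a flat (all-zero) log-likelihood vector.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

NUCLEOTIDES = "ACGT"

#: The 10 unordered diploid genotypes in lexicographic order.
GENOTYPE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations_with_replacement(NUCLEOTIDES, 2)
)

#: The 6 unordered allele pairs (candidate di-allelic site configurations).
ALLELE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    itertools.combinations(NUCLEOTIDES, 2)
)

ERROR_FLOOR = 1e-6
ERROR_CEIL = 0.75

__all__ = [
    "AllelePair",
    "SitePileup",
    "phred_to_error",
    "genotype_likelihood",
    "genotype_likelihood_all_pairs",
    "restrict_to_pair",
    "infer_major_minor",
    "read_beagle",
    "write_beagle",
    "GENOTYPE_PAIRS",
    "ALLELE_PAIRS",
    "NUCLEOTIDES",
]


@dataclass(frozen=True)
class AllelePair:
    """An ordered (major-or-ancestral, minor-or-derived) nucleotide pair."""

    first: str
    second: str

    def __post_init__(self):
        if self.first not in NUCLEOTIDES or self.second not in NUCLEOTIDES:
            raise ValueError(f"alleles must be in {NUCLEOTIDES}")
        if self.first == self.second:
            raise ValueError("allele pair must be two distinct nucleotides")


@dataclass
class SitePileup:
    """Observed bases and error probabilities for the individuals at a site."""

    bases: list[str]  # per individual: string of observed bases
    error_probs: list[np.ndarray]  # per individual: matching error probs

    def __post_init__(self):
        if len(self.bases) != len(self.error_probs):
            raise ValueError("bases and error_probs must align per individual")
        for b, e in zip(self.bases, self.error_probs):
            if len(b) != len(e):
                raise ValueError("per-individual bases and error probs differ in length")

    @property
    def n_individuals(self) -> int:
        return len(self.bases)


def phred_to_error(q) -> float:
    """Convert a phred quality to an error probability, clamped to
    ``(1e-6, 0.75)`` to avoid log(0) and pathological q=0 bases."""
    e = 10.0 ** (-np.asarray(q, dtype=float) / 10.0)
    return np.clip(e, ERROR_FLOOR, ERROR_CEIL) if np.ndim(q) else float(
        min(max(float(e), ERROR_FLOOR), ERROR_CEIL)
    )


def _base_given_allele(base: str, allele: str, e: float) -> float:
    return 1.0 - e if base == allele else e / 3.0


def genotype_likelihood(
    bases: Sequence[str], error_probs: Sequence[float], pair: AllelePair
) -> np.ndarray:
    """Log-likelihoods of carrying 0/1/2 copies of ``pair.second``.

    Index g counts copies of the second (minor/derived) allele; the output
    is renormalized so the maximum is 0.  An empty pileup yields a flat
    vector of zeros.
    """
    out = np.zeros(3)
    a1, a2 = pair.first, pair.second
    for b, e in zip(bases, error_probs):
        e = float(e)
        pa = _base_given_allele(b, a1, e)
        pd = _base_given_allele(b, a2, e)
        out[0] += math.log(pa)
        out[1] += math.log(0.5 * pa + 0.5 * pd)
        out[2] += math.log(pd)
    return out - out.max()


def genotype_likelihood_all_pairs(
    bases: Sequence[str], error_probs: Sequence[float]
) -> np.ndarray:
    """Log-likelihoods of the 10 unordered genotypes (``GENOTYPE_PAIRS``
    order), renormalized so the maximum is 0."""
    out = np.zeros(10)
    for b, e in zip(bases, error_probs):
        e = float(e)
        p = np.array([_base_given_allele(b, a, e) for a in NUCLEOTIDES])
        for gi, (x, y) in enumerate(GENOTYPE_PAIRS):
            px = p[NUCLEOTIDES.index(x)]
            py = p[NUCLEOTIDES.index(y)]
            out[gi] += math.log(0.5 * px + 0.5 * py)
    return out - out.max()


def _pair_indices(pair: AllelePair) -> list[int]:
    return [
        GENOTYPE_PAIRS.index(tuple(sorted((pair.first, pair.first)))),
        GENOTYPE_PAIRS.index(tuple(sorted((pair.first, pair.second)))),
        GENOTYPE_PAIRS.index(tuple(sorted((pair.second, pair.second)))),
    ]


def restrict_to_pair(gl10: np.ndarray, pair: AllelePair) -> np.ndarray:
    """Slice a 10-genotype log-likelihood vector down to the three genotypes
    of one allele pair (0/1/2 copies of ``pair.second``), renormalized."""
    out = gl10[_pair_indices(pair)].astype(float)
    return out - out.max()


def _pair_loglik_at_f(gl3_lin: np.ndarray, f: float) -> float:
    """Site log-likelihood of minor-allele frequency f under HWE, summed
    over individuals.  gl3_lin: (n_ind, 3) linear-scale likelihoods."""
    w = np.array([(1 - f) ** 2, 2 * f * (1 - f), f * f])
    per_ind = gl3_lin @ w
    if np.any(per_ind <= 0):
        return -math.inf
    return float(np.log(per_ind).sum())


def _maximize_f(gl3_lin: np.ndarray, lo: float = 1e-6, hi: float = 0.5) -> tuple[float, float]:
    """Golden-section maximization of the HWE site likelihood over f."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc = _pair_loglik_at_f(gl3_lin, c)
    fd = _pair_loglik_at_f(gl3_lin, d)
    for _ in range(60):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _pair_loglik_at_f(gl3_lin, c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _pair_loglik_at_f(gl3_lin, d)
    f_opt = (a + b) / 2.0
    return f_opt, _pair_loglik_at_f(gl3_lin, f_opt)


def infer_major_minor(gl10_matrix: np.ndarray) -> AllelePair | None:
    """Infer the di-allelic (major, minor) pair from per-individual
    10-genotype log-likelihoods.

    For each of the 6 candidate pairs the site likelihood is maximized
    over the minor allele frequency f under HWE, and the best pair wins;
    ties break lexicographically.  Returns ``None`` when every individual
    is data-free (flat 10-vector).
    """
    gl10_matrix = np.atleast_2d(np.asarray(gl10_matrix, dtype=float))
    if np.all(np.ptp(gl10_matrix, axis=1) < 1e-12):
        return None
    best: tuple[float, tuple[str, str], float] | None = None
    for a, b in ALLELE_PAIRS:
        # raw slices: cross-pair comparability requires a common scale
        gl3 = gl10_matrix[:, _pair_indices(AllelePair(a, b))]
        f_opt, ll = _maximize_f(np.exp(gl3))
        if best is None or ll > best[0] + 1e-12:
            best = (ll, (a, b), f_opt)
    ll, (a, b), f_opt = best
    # orient: major = the more frequent allele at the optimum
    if f_opt > 0.5:
        a, b = b, a
    return AllelePair(a, b)


def write_beagle(path, markers, allele_pairs, log_gls) -> None:
    """Write Beagle-style genotype likelihoods.

    ``markers``: list of "chrom_position" strings; ``allele_pairs``: list
    of (major, minor) nucleotide pairs coded 0..3 = A,C,G,T in the file;
    ``log_gls``: array (n_sites, n_ind, 3) of log likelihoods.  Each
    individual's 3 likelihoods are normalized to sum to 1 in the file.
    """
    log_gls = np.asarray(log_gls, dtype=float)
    n_ind = log_gls.shape[1]
    with open(path, "w") as fh:
        cols = ["marker", "allele1", "allele2"]
        for i in range(n_ind):
            cols += [f"Ind{i}"] * 3
        fh.write("\t".join(cols) + "\n")
        for m, (a1, a2), site in zip(markers, allele_pairs, log_gls):
            lin = np.exp(site - site.max(axis=1, keepdims=True))
            lin /= lin.sum(axis=1, keepdims=True)
            row = [m, str(NUCLEOTIDES.index(a1)), str(NUCLEOTIDES.index(a2))]
            row += [f"{x:.6g}" for x in lin.ravel()]
            fh.write("\t".join(row) + "\n")


def read_beagle(path):
    """Read a Beagle genotype-likelihood file.

    Returns ``(markers, allele_pairs, log_gls)`` with log-likelihoods
    renormalized so each individual's max is 0.
    """
    markers, pairs, rows = [], [], []
    with open(path) as fh:
        header = fh.readline().split()
        n_ind = (len(header) - 3) // 3
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3 + 3 * n_ind:
                raise ValueError(f"{path}:{ln}: expected {3 + 3 * n_ind} columns")
            markers.append(parts[0])
            pairs.append((NUCLEOTIDES[int(parts[1])], NUCLEOTIDES[int(parts[2])]))
            rows.append([float(x) for x in parts[3:]])
    lik = np.array(rows).reshape(len(rows), n_ind, 3)
    with np.errstate(divide="ignore"):
        log_gls = np.log(lik)
    log_gls -= log_gls.max(axis=2, keepdims=True)
    return markers, pairs, log_gls
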