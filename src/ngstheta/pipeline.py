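"""High-level helpers chaining simulation, SAF computation and estimation.

These functions glue the modules into the workflows used by the command
line interface and the reproduction scripts: simulate a region, compute
genotype likelihoods and SAF vectors, then estimate the SFS by EM or the
expected SFS by empirical Bayes, and derive theta estimates and
neutrality statistics.

Whole-region work runs on a linear-scale fast path: with a fixed error
rate the genotype likelihood at a site depends on the pileup only
through the (ancestral, derived, other) read counts, so linear GLs are
assembled from small power lookup tables and fed straight into the band
dynamic program — no per-base bookkeeping and no large log/exp round
trips.
"""

from __future__ import annotations

import numpy as np

from .calling import estimate_f_em_sites, sfs_from_called_genotypes
from .emsfs import EMResult, PriorSFS, estimate_sfs_em
from .saf import SafTable, saf_matrix, saf_matrix_linear
from .scan import expected_window_sfs, posterior_af
from .simulate import (
    GenotypeMatrix,
    SimulationParams,
    simulate_neutral_genotypes,
    simulate_read_counts,
    simulate_region_gls,
)
from .spectrum import FrequencySpectrum, fuli_d, fuli_f, tajimas_d, theta_estimators

__all__ = [
    "counts_to_linear_gls",
    "region_saf",
    "region_saf_linear_from_counts",
    "simulate_region_saf",
    "ml_region_sfs",
    "ml_sfs_linear",
    "eb_expected_sfs_linear",
    "eb_region_sfs",
    "called_sfs_from_counts",
    "called_spectra_from_counts",
    "region_summary",
    "simulate_region_counts",
]


def _emission_probs(e: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-read emission probabilities for genotypes g = 0, 1, 2 copies of
    the derived allele: (p(ancestral base | g), p(derived base | g))."""
    pa = np.array([1 - e, 0.5 * (1 - e) + 0.5 * e / 3.0, e / 3.0])
    return pa, pa[::-1].copy()


def counts_to_linear_gls(k_anc, k_der, error_rate: float) -> np.ndarray:
    """Linear-scale genotype likelihoods from read counts, via lookup
    tables of the emission-probability powers.

    Reads of off-pair nucleotides contribute the same factor e/3 to all
    genotypes and are dropped (likelihoods are defined up to scale).
    Output: (n_sites, n_ind, 3) float64, unnormalized.
    """
    ka = np.asarray(k_anc)
    kd = np.asarray(k_der)
    pa, pd = _emission_probs(float(error_rate))
    top = int(max(ka.max(initial=0), kd.max(initial=0))) + 1
    powers = np.arange(top, dtype=float)
    pow_a = pa[None, :] ** powers[:, None]  # (top, 3)
    pow_d = pd[None, :] ** powers[:, None]
    return pow_a[ka] * pow_d[kd]


def region_saf(log_gls: np.ndarray, chrom: str = "chr", positions=None) -> SafTable:
    """SAF table for a region from (n_sites, n_ind, 3) genotype log-GLs."""
    ll = saf_matrix(log_gls)
    if positions is None:
        positions = np.arange(1, ll.shape[0] + 1)
    return SafTable(chrom, positions, ll)


def region_saf_linear_from_counts(
    k_anc, k_der, error_rate: float, chunk: int = 100_000
) -> np.ndarray:
    """Linear-scale SAF matrix for a whole region from read counts.

    Chunks the count -> GL -> DP pipeline to bound peak memory; returns
    (n_sites, 2n+1) float32 with per-site max 1.
    """
    ka = np.asarray(k_anc)
    n_sites, n_ind = ka.shape
    out = np.empty((n_sites, 2 * n_ind + 1), dtype=np.float32)
    for s in range(0, n_sites, chunk):
        lin = counts_to_linear_gls(ka[s : s + chunk], k_der[s : s + chunk], error_rate)
        out[s : s + chunk] = saf_matrix_linear(lin.astype(np.float32), chunk=chunk)
    return out


def simulate_region_counts(params: SimulationParams, seed: int | None = None):
    """Simulate a region down to read counts.

    Returns ``(genotypes, k_anc, k_der, k_o1, k_o2)`` — the sufficient
    statistics of the fixed-error read model for every position 1..L.
    """
    seed = params.seed if seed is None else seed
    gm = simulate_neutral_genotypes(params, seed=seed)
    ka, kd, ko1, ko2 = simulate_read_counts(
        gm, params.mean_depth, params.error_rate, seed=seed + 104_729
    )
    return gm, ka, kd, ko1, ko2


def simulate_region_saf(
    params: SimulationParams, seed: int | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate a region end to end: coalescent -> reads -> linear SAF.

    Returns ``(genotypes, saf_linear)`` with the SAF matrix on linear
    scale (float32, per-site max 1), sites without reads included.
    """
    gm, ka, kd, _, _ = simulate_region_counts(params, seed)
    return gm, region_saf_linear_from_counts(ka, kd, params.error_rate)


def _informative_linear(saf_lin: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    return np.ptp(saf_lin, axis=1) > tol


def ml_sfs_linear(
    saf_lin: np.ndarray,
    drop_uninformative: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> EMResult:
    """EM ML SFS from a linear-scale SAF matrix (fast path)."""
    keep = _informative_linear(saf_lin) if drop_uninformative else slice(None)
    return estimate_sfs_em(saf_lin[keep], tol=tol, max_iter=max_iter, scale="linear")


def ml_region_sfs(
    table: SafTable,
    drop_uninformative: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> EMResult:
    """EM maximum-likelihood SFS for all (informative) sites of a region."""
    keep = table.informative_mask() if drop_uninformative else slice(None)
    return estimate_sfs_em(table.loglik[keep], tol=tol, max_iter=max_iter)


def eb_expected_sfs_linear(
    saf_lin: np.ndarray,
    prior: PriorSFS,
    drop_uninformative: bool = True,
    chunk: int = 200_000,
) -> FrequencySpectrum:
    """Posterior-expected SFS from a linear-scale SAF matrix.

    Sums per-site posteriors Pr(x = j | D) chunk by chunk.
    """
    keep = _informative_linear(saf_lin) if drop_uninformative else np.ones(len(saf_lin), bool)
    K = saf_lin[keep]
    n_cat = saf_lin.shape[1]
    p32 = prior.probs.astype(saf_lin.dtype)
    acc = np.zeros(n_cat)
    for s in range(0, len(K), chunk):
        num = K[s : s + chunk] * p32[None, :]
        num /= num.sum(axis=1, keepdims=True)
        acc += num.sum(axis=0, dtype=np.float64)
    return FrequencySpectrum(acc, n_cat - 1)


def eb_region_sfs(
    table: SafTable, prior: PriorSFS, drop_uninformative: bool = True
) -> FrequencySpectrum:
    """Posterior-expected SFS of a region from a log-scale SAF table."""
    keep = table.informative_mask() if drop_uninformative else np.ones(table.n_sites, bool)
    post = posterior_af(table.loglik[keep], prior)
    return expected_window_sfs(post, table.n_chrom)


def called_sfs_from_counts(
    k_anc,
    k_der,
    k_o1,
    k_o2,
    error_rate: float,
    method: str = "mlike",
    snp_p_cutoff: float = 1e-6,
) -> FrequencySpectrum:
    """Genotype-calling spectrum for a whole region from read counts.

    The minor allele at each site is chosen from the data, as callers
    must do: the non-ancestral nucleotide with the most reads across
    individuals (ties favour the true derived allele, then the first
    alternative).  Sites with no non-ancestral read at all cannot reject
    f = 0 (their LRT statistic is 0) and are counted as monomorphic
    directly; the likelihood-ratio machinery runs on the remaining
    candidate sites only.
    """
    return called_spectra_from_counts(
        k_anc, k_der, k_o1, k_o2, error_rate, (method,), (snp_p_cutoff,)
    )[method, snp_p_cutoff]


def called_spectra_from_counts(
    k_anc,
    k_der,
    k_o1,
    k_o2,
    error_rate: float,
    methods: tuple[str, ...] = ("mlike", "hwe"),
    cutoffs: tuple[float, ...] = (1e-6, 5e-3),
) -> dict[tuple[str, float], FrequencySpectrum]:
    """Genotype-calling spectra for several method/cutoff combinations.

    The per-site frequency EM and LRT p-values do not depend on the
    caller or the inclusion cutoff, so they are computed once and shared.
    Returns a dict keyed by ``(method, cutoff)``.
    """
    ka = np.asarray(k_anc)
    n_sites, n_ind = ka.shape
    K = 2 * n_ind
    alts = [np.asarray(k_der), np.asarray(k_o1), np.asarray(k_o2)]
    totals = np.stack([a.sum(axis=1) for a in alts])  # (3, n_sites)
    candidates = np.flatnonzero(totals.sum(axis=0) > 0)
    choice = totals[:, candidates].argmax(axis=0)
    km = alts[0][candidates].copy()
    for alt_idx in (1, 2):
        rows = choice == alt_idx
        km[rows] = alts[alt_idx][candidates[rows]]
    lin = counts_to_linear_gls(ka[candidates], km, error_rate)
    f, lrt, p, flat = estimate_f_em_sites(lin, scale="linear")
    union = p < max(cutoffs)
    lin_u = lin[union]
    f_u = f[union]
    calls = {}
    if "mlike" in methods:
        calls["mlike"] = lin_u.argmax(axis=2)
    if "hwe" in methods:
        w = np.stack([(1 - f_u) ** 2, 2 * f_u * (1 - f_u), f_u**2], axis=-1)
        calls["hwe"] = (lin_u * w[:, None, :]).argmax(axis=2)
    out: dict[tuple[str, float], FrequencySpectrum] = {}
    p_u = p[union]
    n_mono_base = n_sites - len(candidates)
    for method in methods:
        dosage = calls[method].sum(axis=1)
        for cutoff in cutoffs:
            counts = np.zeros(K + 1)
            passing = p_u < cutoff
            counts[0] = n_mono_base + (len(candidates) - int(passing.sum()))
            np.add.at(counts, dosage[passing], 1.0)
            out[method, cutoff] = FrequencySpectrum(counts, K)
    return out


def region_summary(sfs: FrequencySpectrum) -> dict:
    """Theta estimates and neutrality statistics for a region spectrum."""
    t = theta_estimators(sfs)
    return {
        "tW": t.tW,
        "tP": t.tP,
        "tFL": t.tFL,
        "tH": t.tH,
        "S": t.S,
        "TajimaD": tajimas_d(sfs),
        "FuLiD": fuli_d(sfs),
        "FuLiF": fuli_f(sfs),
    }
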