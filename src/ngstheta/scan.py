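"""Empirical Bayes posteriors and sliding-window neutrality scans.

The empirical Bayes route combines each site's sample-allele-frequency
likelihood with a prior SFS (typically the genome-wide or region-wide ML
estimate) into a posterior over allele-frequency categories:

    Pr(x = j | D) = Pr(D | x = j) Pr(x = j) / sum_i Pr(D | x = i) Pr(x = i).

Summing posteriors over the sites of a window gives a fractional expected
spectrum E[eta | D], and because every theta estimator is linear in eta,
plugging the expected spectrum into the estimators yields genuine
posterior expectations E[theta_hat | D].  The full-ML alternative
re-estimates the SFS by EM within each window instead.

Windows are half-open ``[start, start + window_size)`` on 1-based
coordinates, advanced by ``step_size``; only windows fully inside the
region are emitted.  Statistics of windows with no segregating mass are
``nan`` and serialized as "NA".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .emsfs import PriorSFS, estimate_sfs_em
from .saf import SafTable
from .spectrum import (
    FrequencySpectrum,
    ThetaSet,
    fuli_d,
    fuli_f,
    tajimas_d,
    theta_estimators,
)

__all__ = [
    "WindowResult",
    "posterior_af",
    "expected_window_sfs",
    "scan",
    "ml_window_scan",
    "window_statistics",
    "write_windows",
    "read_windows",
]

WINDOW_COLUMNS = [
    "chrom", "winStart", "winEnd", "winCenter", "nSites",
    "tW", "tP", "tFL", "tH", "S", "TajimaD", "FuLiD", "FuLiF",
]


@dataclass
class WindowResult:
    """Expected spectrum and neutrality statistics for one genomic window."""

    chrom: str
    win_start: int  # 1-based inclusive
    win_end: int  # exclusive
    win_center: int
    n_sites_used: int
    expected_sfs: FrequencySpectrum
    thetas: ThetaSet
    tajima_d: float
    fuli_d: float
    fuli_f: float


def posterior_af(saf_loglik: np.ndarray, prior: PriorSFS) -> np.ndarray:
    """Posterior Pr(x = j | D) per site.

    Accepts a single SAF log-likelihood vector or a (n_sites, 2n+1)
    matrix; returns probabilities of the same shape, each row summing
    to 1.
    """
    ll = np.asarray(saf_loglik, dtype=float)
    single = ll.ndim == 1
    ll = np.atleast_2d(ll)
    if ll.shape[1] != len(prior.probs):
        raise ValueError("prior and SAF dimensions disagree")
    num = np.exp(ll - ll.max(axis=1, keepdims=True)) * prior.probs
    tot = num.sum(axis=1)
    if np.any(tot <= 0):
        bad = int(np.flatnonzero(tot <= 0)[0])
        raise ValueError(
            f"prior and likelihood have disjoint support at site index {bad}"
        )
    post = num / tot[:, None]
    return post[0] if single else post


def expected_window_sfs(posteriors: np.ndarray, n_chrom: int | None = None) -> FrequencySpectrum:
    """Sum site posteriors into a fractional expected spectrum.

    Total mass equals the number of sites summed; an empty input yields a
    zero spectrum (``n_chrom`` must then be given).
    """
    post = np.atleast_2d(np.asarray(posteriors, dtype=float))
    if post.size == 0:
        if n_chrom is None:
            raise ValueError("n_chrom required for an empty window")
        return FrequencySpectrum(np.zeros(n_chrom + 1), n_chrom)
    return FrequencySpectrum(post.sum(axis=0), post.shape[1] - 1)


def window_statistics(
    sfs: FrequencySpectrum,
    chrom: str,
    win_start: int,
    win_end: int,
    n_sites_used: int,
    window_size: int,
) -> WindowResult:
    """Assemble a WindowResult from a (possibly fractional) spectrum."""
    return WindowResult(
        chrom=chrom,
        win_start=win_start,
        win_end=win_end,
        win_center=win_start + window_size // 2,
        n_sites_used=n_sites_used,
        expected_sfs=sfs,
        thetas=theta_estimators(sfs),
        tajima_d=tajimas_d(sfs),
        fuli_d=fuli_d(sfs),
        fuli_f=fuli_f(sfs),
    )


def _window_starts(region_end: int, window_size: int, step_size: int) -> list[int]:
    if window_size <= 0 or step_size <= 0:
        raise ValueError("window and step sizes must be positive")
    if step_size > window_size:
        raise ValueError("step size must not exceed window size")
    starts = []
    s = 1
    while s + window_size - 1 <= region_end:
        starts.append(s)
        s += step_size
    return starts or [1]


def _check_sorted(table: SafTable) -> None:
    if len(table.positions) > 1 and np.any(np.diff(table.positions) <= 0):
        raise ValueError("SAF sites must be sorted by position")


def scan(
    table: SafTable,
    prior: PriorSFS,
    window_size: int,
    step_size: int,
    region_end: int | None = None,
    drop_uninformative: bool = True,
) -> list[WindowResult]:
    """Empirical Bayes sliding-window scan over one chromosome.

    Sites whose SAF vector is flat (no reads in any individual) are
    excluded by default: their posterior is exactly the prior and would
    drag every window toward the prior's statistics.
    """
    _check_sorted(table)
    n_chrom = table.n_chrom
    if n_chrom != prior.n_chrom:
        raise ValueError("prior and SAF table disagree on 2n")
    keep = table.informative_mask() if drop_uninformative else np.ones(table.n_sites, bool)
    pos = table.positions[keep]
    post = posterior_af(table.loglik[keep], prior) if keep.any() else np.zeros((0, n_chrom + 1))
    end = int(region_end if region_end is not None else (pos.max() if len(pos) else window_size))
    results = []
    for s in _window_starts(end, window_size, step_size):
        lo = np.searchsorted(pos, s, side="left")
        hi = np.searchsorted(pos, s + window_size, side="left")
        sfs = expected_window_sfs(post[lo:hi], n_chrom)
        results.append(
            window_statistics(sfs, table.chrom, s, s + window_size, hi - lo, window_size)
        )
    return results


def ml_window_scan(
    table: SafTable,
    window_size: int,
    step_size: int,
    region_end: int | None = None,
    drop_uninformative: bool = True,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> list[WindowResult]:
    """Full-ML sliding-window scan: an EM SFS estimate per window."""
    _check_sorted(table)
    n_chrom = table.n_chrom
    keep = table.informative_mask() if drop_uninformative else np.ones(table.n_sites, bool)
    pos = table.positions[keep]
    ll = table.loglik[keep]
    end = int(region_end if region_end is not None else (pos.max() if len(pos) else window_size))
    results = []
    for s in _window_starts(end, window_size, step_size):
        lo = np.searchsorted(pos, s, side="left")
        hi = np.searchsorted(pos, s + window_size, side="left")
        if hi > lo:
            em = estimate_sfs_em(ll[lo:hi], tol=tol, max_iter=max_iter)
            sfs = em.counts
        else:
            sfs = FrequencySpectrum(np.zeros(n_chrom + 1), n_chrom)
        results.append(
            window_statistics(sfs, table.chrom, s, s + window_size, hi - lo, window_size)
        )
    return results


def _fmt(x: float) -> str:
    return "NA" if (x is None or (isinstance(x, float) and math.isnan(x))) else f"{x:.6f}"


def write_windows(path, results: list[WindowResult]) -> None:
    """Write window results as TSV with a fixed, documented column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(WINDOW_COLUMNS) + "\n")
        for r in results:
            t = r.thetas
            row = [
                r.chrom, str(r.win_start), str(r.win_end), str(r.win_center),
                str(r.n_sites_used),
                _fmt(t.tW), _fmt(t.tP), _fmt(t.tFL), _fmt(t.tH), _fmt(t.S),
                _fmt(r.tajima_d), _fmt(r.fuli_d), _fmt(r.fuli_f),
            ]
            fh.write("\t".join(row) + "\n")


def read_windows(path) -> list[dict]:
    """Read a window TSV back into a list of dicts (floats, NA -> nan)."""
    out = []
    with open(path) as fh:
        header = fh.readline().split()
        if header != WINDOW_COLUMNS:
            raise ValueError(f"{path}: unexpected header")
        for ln, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != len(WINDOW_COLUMNS):
                raise ValueError(f"{path}:{ln}: wrong column count")
            rec: dict = {"chrom": parts[0]}
            for key, val in zip(WINDOW_COLUMNS[1:5], parts[1:5]):
                rec[key] = int(val)
            for key, val in zip(WINDOW_COLUMNS[5:], parts[5:]):
                rec[key] = math.nan if val == "NA" else float(val)
            out.append(rec)
    return out
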