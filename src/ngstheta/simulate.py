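"""Coalescent genotype simulation and NGS read/GL simulation.

The simulation protocol mirrors how low-depth resequencing studies are
benchmarked:

1. Haplotypes for a region of length L are drawn under the standard
   neutral coalescent with human-like parameters (N = 10,000,
   mu = 2.35e-8 per bp per generation, r = 1e-8) and paired into
   diploid genotypes.  msprime backs the coalescent; externally
   simulated haplotypes (e.g. selective sweeps from msms) enter through
   the ms-format reader.
2. Invariant sites are inserted so every position 1..L exists; each site
   gets an ancestral nucleotide drawn uniformly from {A,C,G,T} and a
   derived nucleotide drawn uniformly from the remaining three.  The
   ancestral state is treated as known.
3. Per site and individual, a sequencing depth is drawn from
   Poisson(mean_depth) (or an empirical depth table), bases are sampled
   uniformly from the individual's two alleles, and each base is flipped
   to one of the three other nucleotides with probability e (fixed, or
   phred-derived from an empirical quality table).  Sites are
   independent: no read-length or mapping structure is modelled.

Two read-simulation surfaces are provided: :func:`simulate_reads`
materializes per-site pileups (bases + error probabilities) for the
full genotype-likelihood machinery, while :func:`simulate_region_gls`
exploits the fixed-error model to draw sufficient read counts directly
and emit genotype likelihoods for whole regions at once.
"""

from __future__ import annotations


import math
from dataclasses import dataclass

import msprime
import numpy as np

from .likelihoods import AllelePair, SitePileup, phred_to_error
from .spectrum import FrequencySpectrum

__all__ = [
    "SimulationParams",
    "GenotypeMatrix",
    "EmpiricalErrorModel",
    "simulate_neutral_genotypes",
    "simulate_genotypes_from_sfs",
    "read_ms",
    "simulate_reads",
    "simulate_read_counts",
    "counts_to_gls",
    "simulate_region_gls",
    "load_empirical_tables",
    "write_genotypes",
    "neutral_prior",
    "sweep_like_prior",
]


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulated region.

    Defaults are the human-like benchmark settings: 25 diploids, 1 Mb,
    N = 10,000, mu = 2.35e-8, r = 1e-8, mean depth 2x, error rate 0.5%.
    """

    n_diploid: int = 25
    L: int = 1_000_000
    N_e: float = 10_000.0
    mu: float = 2.35e-8
    rec: float = 1e-8
    mean_depth: float = 2.0
    error_rate: float = 0.005
    seed: int = 1

    def __post_init__(self):
        if self.n_diploid < 1 or self.L < 1:
            raise ValueError("need at least 1 diploid and 1 bp")
        if not (0 < self.error_rate < 1):
            raise ValueError("error_rate must be in (0, 1)")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")
        theta = 4 * self.N_e * self.mu
        if not (theta > 0 and math.isfinite(theta)):
            raise ValueError("theta = 4*N*mu must be positive and finite")

    @property
    def theta_per_site(self) -> float:
        return 4 * self.N_e * self.mu


@dataclass
class GenotypeMatrix:
    """Derived-allele dosages at the segregating sites of one region."""

    dosages: np.ndarray  # (n_sites, n_ind) ints in {0,1,2}
    positions: np.ndarray  # 1-based bp, strictly increasing
    L: int
    chrom: str = "chr"

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.dosages.ndim != 2 or len(self.positions) != self.dosages.shape[0]:
            raise ValueError("positions and dosage rows must align")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must be in {0, 1, 2}")
        if len(self.positions) and (
            self.positions.min() < 1 or self.positions.max() > self.L
        ):
            raise ValueError("positions must lie in [1, L]")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_ind(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_chrom(self) -> int:
        return 2 * self.n_ind

    def true_sfs(self) -> FrequencySpectrum:
        """Sample SFS over all L positions (invariant sites in category 0)."""
        counts = np.zeros(self.n_chrom + 1)
        if self.dosages.size:
            js = self.dosages.sum(axis=1)
            np.add.at(counts, js, 1.0)
        counts[0] += self.L - len(self.positions)
        return FrequencySpectrum(counts, self.n_chrom)


def _positions_to_bp(rel_positions: np.ndarray, L: int) -> np.ndarray:
    """Map relative positions in [0, 1) to distinct 1-based bp.

    floor(pos * L) + 1; collisions shift to the next free bp (infinite
    sites emulation).
    """
    bp = np.floor(np.asarray(rel_positions, dtype=float) * L).astype(np.int64) + 1
    bp = np.clip(bp, 1, L)
    used: set[int] = set()
    out = np.empty_like(bp)
    for i, p in enumerate(bp):
        while p in used:
            p += 1
        if p > L:
            raise ValueError("could not place all sites within [1, L]")
        used.add(int(p))
        out[i] = p
    if np.any(np.diff(out) <= 0):
        order = np.argsort(out, kind="stable")
        if len(set(out.tolist())) != len(out):
            raise ValueError("position collision could not be resolved")
        return out[order], order
    return out, np.arange(len(out))


def _haplotypes_to_genotypes(hap: np.ndarray) -> np.ndarray:
    """Collapse a (n_sites, 2n) 0/1 haplotype matrix into dosages by
    pairing consecutive haplotype columns."""
    if hap.shape[1] % 2:
        raise ValueError("odd number of haplotypes cannot form diploids")
    return (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8)


def simulate_neutral_genotypes(
    params: SimulationParams, seed: int | None = None
) -> GenotypeMatrix:
    """Simulate one region of diploid genotypes under the neutral coalescent.

    Haplotypes are drawn with mutation rate mu and recombination rate r
    over L bp (msprime, infinite-sites mutations) and paired into
    diploids; the derived allele is the mutant.
    """
    seed = params.seed if seed is None else seed
    ts = msprime.sim_ancestry(
        samples=params.n_diploid,
        ploidy=2,
        sequence_length=params.L,
        recombination_rate=params.rec,
        population_size=params.N_e,
        random_seed=max(1, seed % (2**31 - 1)),
    )
    mts = msprime.sim_mutations(
        ts,
        rate=params.mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=max(1, (seed + 7_654_321) % (2**31 - 1)),
    )
    hap = mts.genotype_matrix()  # (n_sites, 2n), 0/1
    rel = np.array([s.position for s in mts.sites()]) / params.L
    if len(rel) == 0:
        return GenotypeMatrix(
            np.zeros((0, params.n_diploid), dtype=np.int8),
            np.zeros(0, dtype=np.int64),
            params.L,
        )
    bp, order = _positions_to_bp(rel, params.L)
    return GenotypeMatrix(_haplotypes_to_genotypes(hap)[order], bp, params.L)


def simulate_genotypes_from_sfs(
    probs: np.ndarray, L: int, n_diploid: int, seed: int
) -> GenotypeMatrix:
    """Draw genotypes whose sample allele counts follow a given SFS.

    Each position's derived-allele count j is drawn from ``probs`` (a
    probability vector over 0..2n); at segregating positions the j
    derived copies are assigned to chromosomes uniformly at random and
    collapsed into diploid dosages.  Used to emulate regions with skewed
    (e.g. post-sweep) spectra without a structured coalescent.
    """
    rng = np.random.default_rng(seed)
    probs = np.asarray(probs, dtype=float)
    n_chrom = len(probs) - 1
    if n_chrom != 2 * n_diploid:
        raise ValueError("probs length must be 2*n_diploid + 1")
    js = rng.choice(n_chrom + 1, size=L, p=probs / probs.sum())
    seg = np.flatnonzero(js > 0)
    positions = seg + 1
    dosages = np.zeros((len(seg), n_diploid), dtype=np.int8)
    for row, j in enumerate(js[seg]):
        chroms = rng.choice(n_chrom, size=j, replace=False)
        np.add.at(dosages[row], chroms // 2, 1)
    return GenotypeMatrix(dosages, positions, L)


def read_ms(source, L: int, n_diploid: int | None = None) -> list[GenotypeMatrix]:
    """Parse ms/msms-format text into genotype matrices.

    ``source`` may be a path or a file-like object.  Relative positions
    are mapped to bp via floor(pos*L)+1 with collision shifting;
    consecutive haplotypes are paired into diploids.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    replicates: list[GenotypeMatrix] = []
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        if i >= n or not lines[i].startswith("segsites:"):
            raise ValueError(f"line {i + 1}: expected 'segsites:' after '//'")
        try:
            segsites = int(lines[i].split(":")[1])
        except (IndexError, ValueError):
            raise ValueError(f"line {i + 1}: malformed segsites") from None
        i += 1
        if segsites == 0:
            n_ind = n_diploid or 0
            replicates.append(
                GenotypeMatrix(
                    np.zeros((0, n_ind), dtype=np.int8), np.zeros(0, np.int64), L
                )
            )
            continue
        if i >= n or not lines[i].startswith("positions:"):
            raise ValueError(f"line {i + 1}: expected 'positions:'")
        rel = np.array([float(x) for x in lines[i].split()[1:]])
        if len(rel) != segsites:
            raise ValueError(f"line {i + 1}: {len(rel)} positions != segsites {segsites}")
        i += 1
        haps = []
        while i < n and lines[i].strip() and set(lines[i].strip()) <= {"0", "1"}:
            row = lines[i].strip()
            if len(row) != segsites:
                raise ValueError(f"line {i + 1}: haplotype length != segsites")
            haps.append([int(c) for c in row])
            i += 1
        if not haps:
            raise ValueError(f"line {i + 1}: no haplotype rows in block")
        hap = np.array(haps, dtype=np.int8).T  # (sites, n_hap)
        if hap.shape[1] % 2:
            raise ValueError(f"line {i + 1}: odd haplotype count {hap.shape[1]}")
        bp, order = _positions_to_bp(rel, L)
        replicates.append(GenotypeMatrix(_haplotypes_to_genotypes(hap)[order], bp, L))
    return replicates


class EmpiricalErrorModel:
    """Samplers for depth and per-base error drawn from observed tables."""

    def __init__(self, depth_values, depth_weights, q_values, q_weights):
        self.depth_values = np.asarray(depth_values, dtype=np.int64)
        self.depth_probs = np.asarray(depth_weights, dtype=float)
        self.q_values = np.asarray(q_values, dtype=np.int64)
        self.q_probs = np.asarray(q_weights, dtype=float)
        if len(self.depth_values) == 0 or len(self.q_values) == 0:
            raise ValueError("empirical tables must be non-empty")
        if np.any(self.depth_probs <= 0) or np.any(self.q_probs <= 0):
            raise ValueError("table counts must be positive")
        self.depth_probs = self.depth_probs / self.depth_probs.sum()
        self.q_probs = self.q_probs / self.q_probs.sum()

    def sample_depth(self, rng: np.random.Generator, size) -> np.ndarray:
        return rng.choice(self.depth_values, size=size, p=self.depth_probs)

    def sample_error(self, rng: np.random.Generator, size) -> np.ndarray:
        q = rng.choice(self.q_values, size=size, p=self.q_probs)
        return phred_to_error(q)

    @property
    def mean_error(self) -> float:
        return float(self.q_probs @ phred_to_error(self.q_values))


def load_empirical_tables(depth_table, qscore_table) -> EmpiricalErrorModel:
    """Build an error model from (value, count) tables.

    Each table is an iterable of (value, count) pairs — e.g. tabulated
    sequencing depths and phred quality scores from real alignments.
    """
    depth_table = list(depth_table)
    qscore_table = list(qscore_table)
    if not depth_table or not qscore_table:
        raise ValueError("empirical tables must be non-empty")
    dv, dw = zip(*depth_table)
    qv, qw = zip(*qscore_table)
    return EmpiricalErrorModel(dv, dw, qv, qw)


_OTHER = {  # the three alternatives to each nucleotide
    "A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG",
}


def _site_alleles(rng: np.random.Generator, n_sites: int) -> list[AllelePair]:
    anc_idx = rng.integers(0, 4, size=n_sites)
    der_off = rng.integers(0, 3, size=n_sites)
    pairs = []
    for a, d in zip(anc_idx, der_off):
        anc = "ACGT"[a]
        pairs.append(AllelePair(anc, _OTHER[anc][d]))
    return pairs


def simulate_reads(
    gm: GenotypeMatrix,
    mean_depth: float | None = None,
    error_rate: float | None = None,
    error_model: EmpiricalErrorModel | None = None,
    seed: int = 1,
    include_invariant: bool = True,
):
    """Simulate per-site pileups (bases + error probabilities).

    Every position 1..L is emitted when ``include_invariant``; each
    individual's depth is Poisson(mean_depth) or drawn from the
    empirical depth table, bases are sampled uniformly from the
    individual's two alleles, and each base is flipped to one of the
    three other nucleotides with probability e (uniformly among them).

    Returns ``(positions, allele_pairs, pileups)`` with one
    :class:`~ngstheta.likelihoods.SitePileup` per emitted site.
    """
    if (mean_depth is None) == (error_model is None) and error_model is None:
        raise ValueError("provide mean_depth/error_rate or an error_model")
    rng = np.random.default_rng(seed)
    if include_invariant:
        positions = np.arange(1, gm.L + 1, dtype=np.int64)
    else:
        positions = gm.positions.copy()
    pos_to_row = {int(p): r for r, p in enumerate(gm.positions)}
    pairs = _site_alleles(rng, len(positions))
    pileups: list[SitePileup] = []
    for si, pos in enumerate(positions):
        anc, der = pairs[si].first, pairs[si].second
        row = pos_to_row.get(int(pos))
        bases_per_ind: list[str] = []
        errs_per_ind: list[np.ndarray] = []
        for ind in range(gm.n_ind):
            g = int(gm.dosages[row, ind]) if row is not None else 0
            if error_model is not None:
                M = int(error_model.sample_depth(rng, ()))
                errs = np.atleast_1d(error_model.sample_error(rng, M))
            else:
                M = int(rng.poisson(mean_depth))
                errs = np.full(M, float(error_rate))
            picks = rng.random(M) < g / 2.0  # True -> derived chromosome
            bases = []
            for k in range(M):
                b = der if picks[k] else anc
                if rng.random() < errs[k]:
                    b = _OTHER[b][rng.integers(0, 3)]
                bases.append(b)
            bases_per_ind.append("".join(bases))
            errs_per_ind.append(errs)
        pileups.append(SitePileup(bases_per_ind, errs_per_ind))
    return positions, pairs, pileups


def simulate_read_counts(
    gm: GenotypeMatrix,
    mean_depth: float,
    error_rate: float,
    seed: int = 1,
):
    """Draw per-(site, individual) read counts by nucleotide class.

    With a fixed error rate the genotype likelihood depends on the
    pileup only through the per-nucleotide read counts, so whole regions
    (all L positions, invariant sites included) can be simulated without
    materializing bases.  Returns ``(k_anc, k_der, k_o1, k_o2)`` as
    (L, n_ind) int16 arrays: reads matching the ancestral allele, the
    derived allele, and each of the two remaining nucleotides.
    """
    rng = np.random.default_rng(seed)
    e = float(error_rate)
    d = float(mean_depth)
    L, n_ind = gm.L, gm.n_ind
    shape = (L, n_ind)
    # Poisson thinning: depth ~ Poisson(d) and a per-read base category
    # (ancestral / derived / other) drawn multinomially is equivalent to
    # independent Poisson counts with rates d * p_category(g).  A read is
    # the derived base when drawn from a derived chromosome and not
    # flipped, or drawn from an ancestral chromosome and flipped onto the
    # derived nucleotide (prob e/3 of the three alternatives).
    def rates(g: float) -> tuple[float, float, float]:
        p_der = (g / 2.0) * (1 - e) + (1 - g / 2.0) * (e / 3.0)
        p_anc = (1 - g / 2.0) * (1 - e) + (g / 2.0) * (e / 3.0)
        # each of the two off-pair nucleotides is hit equally often
        return d * p_anc, d * p_der, d * (1.0 - p_anc - p_der) / 2.0

    # scalar-rate draws for the invariant-site majority (g = 0)
    la, ld, lo = rates(0.0)
    k_anc = rng.poisson(la, size=shape).astype(np.int16)
    k_der = rng.poisson(ld, size=shape).astype(np.int16)
    k_o1 = rng.poisson(lo, size=shape).astype(np.int16)
    k_o2 = rng.poisson(lo, size=shape).astype(np.int16)
    # overwrite the (few) segregating-site entries per genotype value
    if len(gm.positions):
        rows = gm.positions - 1
        for g in (1, 2):
            mask = gm.dosages == g
            cnt = int(mask.sum())
            if cnt == 0:
                continue
            la, ld, lo = rates(float(g))
            r, c = np.nonzero(mask)
            k_anc[rows[r], c] = rng.poisson(la, size=cnt)
            k_der[rows[r], c] = rng.poisson(ld, size=cnt)
            k_o1[rows[r], c] = rng.poisson(lo, size=cnt)
            k_o2[rows[r], c] = rng.poisson(lo, size=cnt)
    return k_anc, k_der, k_o1, k_o2


def counts_to_gls(k_anc, k_der, error_rate: float) -> np.ndarray:
    """Genotype log-likelihoods from (ancestral, derived) read counts.

    Index g = copies of the derived allele.  Reads of the two off-pair
    nucleotides contribute a factor e/3 to every genotype, which cancels
    in the max-0 normalization, so their counts do not enter.
    Output: (n_sites, n_ind, 3) float32.
    """
    e = float(error_rate)
    # per-read emission probs for genotypes g = 0, 1, 2
    pa = np.array([1 - e, 0.5 * (1 - e) + 0.5 * e / 3.0, e / 3.0])
    pd = pa[::-1].copy()
    ka = np.asarray(k_anc, dtype=np.float32)
    kd = np.asarray(k_der, dtype=np.float32)
    gl = ka[..., None] * np.log(pa, dtype=np.float32) + kd[..., None] * np.log(
        pd, dtype=np.float32
    )
    gl -= gl.max(axis=-1, keepdims=True)
    return gl


def simulate_region_gls(
    params: SimulationParams, seed: int | None = None
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Genotypes plus genotype likelihoods for a whole region.

    Runs the coalescent, draws read counts at every position 1..L under
    Poisson depth and fixed error rate, and converts them to GLs.
    Returns ``(genotypes, log_gls)`` with log_gls shaped (L, n_ind, 3).
    """
    seed = params.seed if seed is None else seed
    gm = simulate_neutral_genotypes(params, seed=seed)
    ka, kd, _, _ = simulate_read_counts(
        gm, params.mean_depth, params.error_rate, seed=seed + 104_729
    )
    return gm, counts_to_gls(ka, kd, params.error_rate)


def neutral_prior(n_chrom: int, theta_per_site: float, fixed_mass: float = 0.0) -> np.ndarray:
    """Standard-neutral prior over allele-frequency categories.

    Under the standard neutral model E[eta_i] = theta/i for the
    polymorphic categories; category 0 absorbs the remaining per-site
    probability and ``fixed_mass`` (default 0) goes to category 2n.
    """
    p = np.zeros(n_chrom + 1)
    i = np.arange(1, n_chrom)
    p[1:n_chrom] = theta_per_site / i
    p[n_chrom] = fixed_mass
    if p.sum() >= 1.0:
        raise ValueError("theta too large for a per-site prior")
    p[0] = 1.0 - p.sum()
    return p


def sweep_like_prior(
    n_chrom: int,
    theta_w: float,
    theta_pi: float,
    theta_fl: float,
    L: int,
) -> np.ndarray:
    """Per-site allele-frequency probabilities with sweep-like moments.

    A selective sweep reduces overall variability, leaves an excess of
    derived singletons and piles derived alleles at high frequency.
    This builds the simplest spectrum with those features — a scaled
    neutral 1/i background plus extra mass in the singleton and
    highest-frequency polymorphic categories — whose Watterson, pi and
    singleton theta estimates (per L sites) equal the given values.
    """
    n = int(n_chrom)
    a1 = _harmonic_sum(n)
    alpha = (theta_pi - (2.0 / n) * a1 * theta_w) / (1.0 - (2.0 / n) * a1)
    s1 = theta_fl - alpha
    h = a1 * (theta_w - alpha) - s1
    if alpha < 0 or s1 < 0 or h < 0:
        raise ValueError("theta moments are not representable by this shape")
    eta = np.zeros(n + 1)
    eta[1:n] = alpha / np.arange(1, n)
    eta[1] += s1
    eta[n - 1] += h
    p = eta / L
    if p.sum() >= 1.0:
        raise ValueError("thetas too large for region length L")
    p[0] = 1.0 - p.sum()
    return p


def _harmonic_sum(n: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n)))


def write_genotypes(path, gm: GenotypeMatrix) -> None:
    """Write true genotypes as TSV: chrom, position, then one dosage per
    individual (segregating sites only)."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tposition\t"
            + "\t".join(f"Ind{i}" for i in range(gm.n_ind))
            + "\n"
        )
        for pos, row in zip(gm.positions, gm.dosages):
            fh.write(gm.chrom + "\t" + str(int(pos)) + "\t" + "\t".join(map(str, row)) + "\n")
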