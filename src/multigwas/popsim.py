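"""Multi-population genotype/phenotype simulator.

Generates several related aquaculture-style breeding populations with the
statistical features that matter for cross-population association studies:

* allele-frequency drift between populations (Balding-Nichols model around a
  shared ancestral frequency),
* cryptic relatedness and admixture, produced by copying haplotype blocks
  from small population-specific founder haplotype pools according to an
  admixture matrix (shared pool ancestry across populations creates
  non-zero cross-population genomic relationships),
* population-specific LD phase, a by-product of block copying from distinct
  pools,
* full-sib family structure within populations (paired parents, offspring by
  recombination with on average one crossover per chromosome per meiosis),
* an ordinal 0-5 phenotype obtained by thresholding a Gaussian liability
  composed of a population shift, optional major-QTL effects, a polygenic
  term and residual noise.

All randomness flows through a single integer seed; the same configuration
and seed reproduce bit-identical panels and phenotypes.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PhenotypeTable


@dataclasses.dataclass
class SimConfig:
    """Parameters of the multi-population simulator.

    Parameters
    ----------
    pop_sizes : list of int
        Number of phenotyped samples per population.
    n_snps, n_chroms, chrom_length_bp : int
        Marker panel geometry; SNPs are evenly spread over chromosomes.
    fst : float or list of float
        Balding-Nichols drift parameter per population (0 = no drift).
    admixture : array (n_pops, n_pops)
        Row j gives the ancestry proportions of population j's founders over
        the population-specific haplotype pools; rows sum to 1.
    n_families_per_pop : int or list of int
        Full-sib families per population; 0 means founders are used directly
        as samples (no family structure).
    qtl : list of (chrom, bp, effect)
        Major QTL: allele-substitution effect of the counted allele on the
        liability scale, at an existing marker position.
    h2_poly : float
        Proportion of the residual (non-QTL) liability variance that is
        polygenic, spread over all markers.
    pop_liability_shift : list of float
        Additive liability offset per population (severity differences).
    score_thresholds : 5 increasing floats
        Liability cut-points mapping to ordinal scores 0-5.
    ld_block_bp : int
        Haplotype-block length for founder block copying.
    n_pool_haplotypes : int
        Size of each population's founder haplotype pool; smaller pools give
        stronger relatedness and LD.
    missing_rate : float
        Uniform sporadic missingness injected into the delivered genotypes.
    """

    pop_sizes: list
    n_snps: int = 1000
    n_chroms: int = 5
    chrom_length_bp: int = 30_000_000
    fst: float | list = 0.03
    admixture: np.ndarray | None = None
    n_families_per_pop: int | list = 0
    qtl: list = dataclasses.field(default_factory=list)
    h2_poly: float = 0.3
    n_causal: int | None = None
    pop_liability_shift: list | None = None
    score_thresholds: tuple = (-0.7, 0.15, 0.45, 2.15, 2.45)
    ld_block_bp: int = 500_000
    n_pool_haplotypes: int = 40
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.pop_sizes = [int(s) for s in self.pop_sizes]
        n_pops = self.n_pops
        if np.isscalar(self.fst):
            self.fst = [float(self.fst)] * n_pops
        self.fst = [float(f) for f in self.fst]
        if any(not np.isfinite(f) or f < 0 or f > 1 for f in self.fst):
            raise ValueError("fst must be finite and within [0, 1]")
        if self.admixture is None:
            self.admixture = np.eye(n_pops)
        self.admixture = np.asarray(self.admixture, dtype=float)
        if self.admixture.shape != (n_pops, n_pops):
            raise ValueError("admixture matrix must be n_pops x n_pops")
        if np.abs(self.admixture.sum(axis=1) - 1).max() > 1e-12:
            raise ValueError("admixture rows must sum to 1")
        if np.isscalar(self.n_families_per_pop):
            self.n_families_per_pop = [int(self.n_families_per_pop)] * n_pops
        if self.pop_liability_shift is None:
            self.pop_liability_shift = [0.0] * n_pops
        if len(self.pop_liability_shift) != n_pops:
            raise ValueError("pop_liability_shift length mismatch")
        th = np.asarray(self.score_thresholds, dtype=float)
        if len(th) != 5 or np.any(np.diff(th) <= 0):
            raise ValueError("score_thresholds must be 5 strictly increasing values")
        if not 0 <= self.h2_poly <= 1:
            raise ValueError("h2_poly must lie in [0, 1]")

    @property
    def n_pops(self) -> int:
        return len(self.pop_sizes)

    @property
    def pop_names(self) -> list:
        return [f"POP{j + 1}" for j in range(self.n_pops)]


@dataclasses.dataclass
class Founders:
    """Founder haplotypes plus the frequency tables that generated them."""

    ancestral_freq: np.ndarray           # (n_snps,)
    pop_freq: np.ndarray                 # (n_pops, n_snps)
    haplotypes: list                     # per pop: (2*n_founders, n_snps) uint8
    snp_chrom: np.ndarray
    snp_bp: np.ndarray
    config: SimConfig


def _marker_map(config: SimConfig):
    """Evenly spaced marker positions over n_chroms chromosomes."""
    m = config.n_snps
    per = np.full(config.n_chroms, m // config.n_chroms)
    per[: m % config.n_chroms] += 1
    chrom = np.repeat(np.arange(1, config.n_chroms + 1), per)
    spacing = config.chrom_length_bp // (per.max() + 1)
    bp = np.concatenate([spacing * (np.arange(k) + 1) for k in per])
    return chrom.astype(np.int64), bp.astype(np.int64)


def _n_founders(config: SimConfig) -> list:
    return [
        2 * nf if nf > 0 else size
        for nf, size in zip(config.n_families_per_pop, config.pop_sizes)
    ]


def simulate_founders(config: SimConfig, rng: np.random.Generator | None = None) -> Founders:
    """Draw per-population allele frequencies and admixed founder haplotypes.

    Ancestral frequencies are uniform on [0.05, 0.95]; each population's
    frequencies follow the Balding-Nichols Beta distribution with its drift
    parameter.  Founder haplotypes are mosaics of blocks copied from small
    population-specific haplotype pools, with the source pool of each block
    drawn from the founder population's admixture row.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom, bp = _marker_map(config)
    m = config.n_snps
    anc = rng.uniform(0.05, 0.95, size=m)
    pop_freq = np.empty((config.n_pops, m))
    for j, f in enumerate(config.fst):
        if f == 0:
            pop_freq[j] = anc
        else:
            a = anc * (1 - f) / f
            b = (1 - anc) * (1 - f) / f
            pop_freq[j] = rng.beta(a, b)
    # haplotype pools: the ancestral gene pool of each population
    H = config.n_pool_haplotypes
    pools = (rng.random((config.n_pops, H, m)) < pop_freq[:, None, :]).astype(np.uint8)
    flat_pools = pools.reshape(config.n_pops * H, m)

    # block index per SNP (blocks never span chromosomes)
    block = np.zeros(m, dtype=np.int64)
    b0 = 0
    for c in range(1, config.n_chroms + 1):
        mask = chrom == c
        block[mask] = b0 + bp[mask] // config.ld_block_bp
        b0 = block[mask].max() + 1 if mask.any() else b0
    n_blocks = int(block.max()) + 1

    haplotypes = []
    col = np.arange(m)
    for j, n_f in enumerate(_n_founders(config)):
        n_h = 2 * n_f
        src = rng.choice(config.n_pops, size=(n_h, n_blocks), p=config.admixture[j])
        pool_idx = rng.integers(0, H, size=(n_h, n_blocks))
        key = src * H + pool_idx              # row in flat_pools per (hap, block)
        haplotypes.append(flat_pools[key[:, block], col])
    return Founders(anc, pop_freq, haplotypes, chrom, bp, config)


def _meiosis(hap_pair: np.ndarray, chrom: np.ndarray, bp: np.ndarray,
             chrom_ids: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a (2, n_snps) haplotype pair: Poisson(1) crossovers
    per chromosome at uniform positions, random starting phase."""
    phase = np.empty(len(chrom), dtype=np.int64)
    for c in chrom_ids:
        mask = chrom == c
        pos = bp[mask]
        k = rng.poisson(1)
        start = rng.integers(0, 2)
        if k == 0:
            phase[mask] = start
        else:
            xovers = rng.uniform(0, pos[-1] + 1, size=k)
            phase[mask] = (start + np.searchsorted(xovers, pos).astype(np.int64)) % 2
    return hap_pair[phase, np.arange(len(chrom))]


def simulate_families(founders: Founders, config: SimConfig | None = None,
                      rng: np.random.Generator | None = None) -> GenotypePanel:
    """Turn founder haplotypes into the delivered sample panel.

    With ``n_families_per_pop == 0`` founders themselves are the samples.
    Otherwise consecutive founder pairs (0,1), (2,3), ... become full-sib
    families whose offspring are produced by recombination; the population's
    sample budget is split as evenly as possible over its families.
    """
    if config is None:
        config = founders.config
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chrom, bp = founders.snp_chrom, founders.snp_bp
    chrom_ids = np.unique(chrom)
    genos, sids, pops = [], [], []
    for j, name in enumerate(config.pop_names):
        size = config.pop_sizes[j]
        n_fam = config.n_families_per_pop[j]
        haps = founders.haplotypes[j]
        if n_fam == 0:
            g = (haps[0::2] + haps[1::2]).astype(np.int8)
        else:
            per_fam = np.full(n_fam, size // n_fam)
            per_fam[: size % n_fam] += 1
            if size < n_fam:
                warnings.warn(
                    f"population {name}: {n_fam} families requested for "
                    f"{size} samples; empty families dropped")
            g = np.empty((size, len(chrom)), dtype=np.int8)
            row = 0
            for fam in range(n_fam):
                sire = haps[4 * fam: 4 * fam + 2]
                dam = haps[4 * fam + 2: 4 * fam + 4]
                for _ in range(per_fam[fam]):
                    g[row] = (_meiosis(sire, chrom, bp, chrom_ids, rng)
                              + _meiosis(dam, chrom, bp, chrom_ids, rng))
                    row += 1
        genos.append(g)
        sids.extend(f"{name}_{i:05d}" for i in range(size))
        pops.extend([name] * size)

    return GenotypePanel(
        genotypes=np.vstack(genos),
        snp_ids=np.array([f"snp{c}_{p}" for c, p in zip(chrom, bp)]),
        chromosomes=chrom,
        positions_bp=bp,
        a1=np.full(len(chrom), "G"),
        a2=np.full(len(chrom), "A"),
        sample_ids=np.array(sids),
        populations=np.array(pops),
    )


def simulate_phenotype(panel: GenotypePanel, config: SimConfig,
                       rng: np.random.Generator | None = None) -> PhenotypeTable:
    """Ordinal score from a thresholded Gaussian liability.

    liability = population shift + sum_q x_q * b_q + polygenic + noise,
    where the polygenic term is built from all markers and standardised to
    variance ``h2_poly`` and the noise has variance ``1 - h2_poly``; the
    non-QTL liability therefore has unit variance by construction.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n, m = panel.genotypes.shape
    if np.any(panel.genotypes == MISSING):
        raise ValueError("phenotypes must be simulated on complete genotypes")
    g = panel.genotypes.astype(float)

    pop_index = pd.Index(config.pop_names)
    pop_of = pop_index.get_indexer(panel.populations)
    liability = np.asarray(config.pop_liability_shift, dtype=float)[pop_of]

    genetic = np.zeros(n)
    for chrom_q, bp_q, beta_q in config.qtl:
        hit = np.flatnonzero((panel.chromosomes == chrom_q)
                             & (panel.positions_bp == bp_q))
        if hit.size == 0:
            raise ValueError(f"QTL position {chrom_q}:{bp_q} absent from marker map")
        genetic += g[:, hit[0]] * beta_q

    if config.h2_poly > 0:
        # finite polygenicity: effects on a random causal subset of markers,
        # so the per-locus signal does not dilute with panel density
        n_causal = m if config.n_causal is None else min(config.n_causal, m)
        effects = np.zeros(m)
        causal = rng.choice(m, size=n_causal, replace=False)
        effects[causal] = rng.normal(size=n_causal)
        poly = (g - g.mean(axis=0)) @ effects
        sd = poly.std()
        if sd > 0:
            poly = poly / sd * np.sqrt(config.h2_poly)
        genetic += poly
    # centre genetic terms within population: severity differences between
    # populations are governed by pop_liability_shift alone, while all
    # within-population genetic signal (what association models test after
    # fitting an intercept / population effect) is preserved
    for j in range(config.n_pops):
        mask = pop_of == j
        if mask.any():
            genetic[mask] -= genetic[mask].mean()
    liability += genetic
    noise_sd = np.sqrt(1.0 - config.h2_poly)
    liability += rng.normal(scale=noise_sd, size=n) if noise_sd > 0 else 0.0

    score = np.searchsorted(np.asarray(config.score_thresholds), liability)
    return PhenotypeTable(pd.DataFrame({
        "sample_id": panel.sample_ids,
        "population": panel.populations,
        "score": score.astype(np.int64),
        "liability": liability,
    }))


def inject_missing(panel: GenotypePanel, rate: float,
                   rng: np.random.Generator) -> GenotypePanel:
    """Uniform sporadic missingness at the given per-call rate."""
    g = panel.genotypes.copy()
    g[rng.random(g.shape) < rate] = MISSING
    return dataclasses.replace(panel, genotypes=g)


def simulate_panel(config: SimConfig):
    """Full pipeline: founders -> families -> phenotype -> missingness.

    Returns ``(panel, phenotypes)``; phenotypes are simulated on the
    complete genotypes, missingness is injected afterwards.
    """
    founders = simulate_founders(config)
    panel = simulate_families(founders, config)
    phen = simulate_phenotype(panel, config)
    if config.missing_rate > 0:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
        panel = inject_missing(panel, config.missing_rate, rng)
    return panel, phen


# ----------------------------------------------------------------------
# The "salmon" preset: four breeding populations with the geometry of a
# medium-density gill-score study -- sizes 2006/640/2911/2949 (scalable),
# per-population score means ~1.5-2.35 and SDs ~1.2-1.35, small genetic
# distances with admixture-driven cryptic relatedness, family structure,
# and one major QTL.

SALMON_SIZES = (2006, 640, 2911, 2949)
SALMON_ADMIXTURE = np.array([
    [0.55, 0.15, 0.15, 0.15],
    [0.15, 0.55, 0.15, 0.15],
    [0.20, 0.10, 0.55, 0.15],
    [0.20, 0.10, 0.15, 0.55],
])
SALMON_SHIFTS = (0.62, 0.3, 0.0, 0.0)


def salmon_preset(scale: float = 1.0, *, n_snps: int = 5000, seed: int = 0,
                  qtl: bool = True, admixed: bool = True,
                  missing_rate: float = 0.01) -> SimConfig:
    """Four-population preset; ``scale`` shrinks sample sizes for desk runs.

    ``admixed=False`` switches to identity admixture (no cryptic
    relatedness); ``qtl=False`` removes the major QTL for null runs.
    """
    sizes = [max(8, int(round(scale * s))) for s in SALMON_SIZES]
    n_chroms = 10
    chrom_len = 30_000_000
    qtl_list = []
    if qtl:
        # place the QTL on the middle marker of chromosome 5 of the map grid
        probe = SimConfig(pop_sizes=[8], n_snps=n_snps, n_chroms=n_chroms,
                          chrom_length_bp=chrom_len)
        chrom, bp = _marker_map(probe)
        on5 = bp[chrom == 5]
        qtl_list = [(5, int(on5[len(on5) // 2]), 0.55)]
    admix = SALMON_ADMIXTURE if admixed else np.eye(4)
    return SimConfig(
        pop_sizes=sizes,
        n_snps=n_snps,
        n_chroms=n_chroms,
        chrom_length_bp=chrom_len,
        fst=0.03,
        admixture=admix,
        n_families_per_pop=[max(4, s // 10) for s in sizes],
        qtl=qtl_list,
        h2_poly=0.40,
        n_causal=600,
        pop_liability_shift=list(SALMON_SHIFTS),
        ld_block_bp=500_000,
        n_pool_haplotypes=12,
        missing_rate=missing_rate,
        seed=seed,
    )
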