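"""Synthetic founder genomes, genetic maps, meiosis and trait architecture.

The simulated genome stands in for a real genotyped founder panel: a set of
biallelic loci laid out on a multi-chromosome genetic map, with segregating
allele frequencies and within-chromosome linkage disequilibrium created by a
few generations of random mating.  Traits are fully controlled by a random
subset of loci (the QTL); the remaining loci serve as markers for genomic
prediction.

Recombination follows the Haldane model (no crossover interference): the
number of crossovers on a chromosome of length L cM is Poisson with mean
L/100 and positions are uniform.  Gametes are sampled in the equivalent
interval form -- independent recombination events between adjacent loci with
probability (1 - exp(-2d/100))/2 for spacing d cM -- which has an identical
joint distribution over locus phases and vectorizes over whole cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeMap",
    "TraitArchitecture",
    "build_genetic_map",
    "generate_founder_population",
    "assign_trait_architecture",
    "true_breeding_values",
    "meiosis",
    "sample_gametes",
    "simulate_phenotypes",
]


@dataclass(frozen=True)
class GenomeMap:
    """Per-locus genetic positions grouped by chromosome.

    Attributes
    ----------
    chrom
        Chromosome index (0-based) of every locus, non-decreasing.
    pos_cM
        Genetic position of every locus within its chromosome, in cM,
        non-decreasing within a chromosome.
    chrom_length_cM
        Allotted genetic length of each chromosome; the sum is the total
        map length.
    """

    chrom: np.ndarray
    pos_cM: np.ndarray
    chrom_length_cM: np.ndarray

    def __post_init__(self) -> None:
        if self.chrom.shape != self.pos_cM.shape:
            raise ValueError("chrom and pos_cM must have equal length")
        if np.any(np.diff(self.chrom) < 0):
            raise ValueError("loci must be ordered by chromosome")
        for c in range(self.n_chromosomes):
            p = self.pos_cM[self.chrom == c]
            if p.size and (np.any(np.diff(p) < 0) or p.min() < 0 or p.max() > self.chrom_length_cM[c]):
                raise ValueError(f"positions on chromosome {c} out of order or out of range")

    @property
    def n_loci(self) -> int:
        return int(self.chrom.size)

    @property
    def n_chromosomes(self) -> int:
        return int(self.chrom_length_cM.size)

    @property
    def total_length_cM(self) -> float:
        return float(self.chrom_length_cM.sum())

    def chromosome_slices(self) -> list[slice]:
        """Contiguous locus slice for each chromosome."""
        bounds = np.searchsorted(self.chrom, np.arange(self.n_chromosomes + 1))
        return [slice(bounds[c], bounds[c + 1]) for c in range(self.n_chromosomes)]

    def recombination_fractions(self) -> np.ndarray:
        """Per-locus phase-switch probability under the Haldane map.

        Entry ``i`` is the probability that the gamete phase changes between
        locus ``i-1`` and locus ``i``; at the first locus of each chromosome
        it is 0.5 (fresh random phase).
        """
        d = np.diff(self.pos_cM, prepend=self.pos_cM[0])
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        first = np.r_[True, np.diff(self.chrom) > 0]
        r[first] = 0.5
        return r

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": self.chrom + 1,
                "locus": np.arange(self.n_loci),
                "position_cM": self.pos_cM,
            }
        )


def build_genetic_map(
    n_chromosomes: int, total_length_cM: float, n_loci: int, seed: int | np.random.Generator
) -> GenomeMap:
    """Lay ``n_loci`` loci on ``n_chromosomes`` equal-length chromosomes.

    Locus counts per chromosome are as equal as possible and positions are
    uniform within each chromosome (sorted).  Deterministic given ``seed``.
    """
    if n_chromosomes <= 0 or n_loci <= 0 or total_length_cM <= 0:
        raise ValueError("chromosome count, locus count and map length must be positive")
    if n_loci < n_chromosomes:
        raise ValueError("need at least one locus per chromosome")
    rng = np.random.default_rng(seed)
    counts = np.full(n_chromosomes, n_loci // n_chromosomes, dtype=np.int64)
    counts[: n_loci % n_chromosomes] += 1
    clen = np.full(n_chromosomes, total_length_cM / n_chromosomes)
    chrom = np.repeat(np.arange(n_chromosomes), counts)
    pos = np.concatenate(
        [np.sort(rng.uniform(0.0, clen[c], size=counts[c])) for c in range(n_chromosomes)]
    )
    return GenomeMap(chrom=chrom, pos_cM=pos, chrom_length_cM=clen)


def sample_gametes(
    parent_haplotypes: np.ndarray, gmap: GenomeMap, rng: np.random.Generator
) -> np.ndarray:
    """Draw one gamete from each parent haplotype pair.

    Parameters
    ----------
    parent_haplotypes
        Array of shape ``(k, 2, L)`` (or ``(2, L)`` for a single parent)
        holding 0/1 alleles for the two haplotypes of each of ``k`` meioses.
        The same parent may appear on several rows to produce several
        gametes.
    """
    single = parent_haplotypes.ndim == 2
    h = parent_haplotypes[None] if single else parent_haplotypes
    k, two, L = h.shape
    if two != 2 or L != gmap.n_loci:
        raise ValueError("haplotypes must have shape (k, 2, n_loci)")
    r = gmap.recombination_fractions()
    switches = (rng.random((k, L)) < r).astype(np.uint8)
    # parity of the switch count selects the haplotype; uint8 overflow keeps
    # the low bit intact, so the cheap cumsum is exact
    phase = np.cumsum(switches, axis=1, dtype=np.uint8) & 1
    gam = np.where(phase.astype(bool), h[:, 1, :], h[:, 0, :])
    return gam[0] if single else gam


def meiosis(parent_haplotypes: np.ndarray, gmap: GenomeMap, rng: np.random.Generator) -> np.ndarray:
    """Single meiosis: one gamete ``(L,)`` from a ``(2, L)`` haplotype pair."""
    return sample_gametes(parent_haplotypes, gmap, rng)


def generate_founder_population(
    n_founders: int,
    gmap: GenomeMap,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    n_mixing_generations: int = 10,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Create founder haplotypes with segregating loci and within-chromosome LD.

    Per-locus allele-1 frequencies are drawn uniformly from
    ``[maf_low, maf_high]``; haplotypes start in linkage equilibrium and
    ``n_mixing_generations`` rounds of random mating with recombination build
    up LD between nearby loci.  Loci that drift to fixation during mixing are
    re-seeded from their initial frequency so that every locus segregates.

    Returns
    -------
    ndarray of shape ``(n_founders, 2, n_loci)``, dtype uint8.
    """
    if n_founders < 2:
        raise ValueError("need at least two founders")
    if not (0.0 < maf_low <= maf_high <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    rng = np.random.default_rng(seed)
    L = gmap.n_loci
    p = rng.uniform(maf_low, maf_high, size=L)
    haplos = (rng.random((n_founders, 2, L)) < p).astype(np.uint8)
    for _ in range(n_mixing_generations):
        sires = rng.integers(0, n_founders, size=n_founders)
        dams = (sires + 1 + rng.integers(0, n_founders - 1, size=n_founders)) % n_founders
        g1 = sample_gametes(haplos[sires], gmap, rng)
        g2 = sample_gametes(haplos[dams], gmap, rng)
        haplos = np.stack([g1, g2], axis=1)
    # re-seed loci lost to drift so the panel stays fully polymorphic
    for _ in range(20):
        counts = haplos.sum(axis=(0, 1))
        mono = (counts == 0) | (counts == 2 * n_founders)
        if not mono.any():
            break
        haplos[:, :, mono] = (rng.random((n_founders, 2, int(mono.sum()))) < p[mono]).astype(np.uint8)
    return haplos


@dataclass(frozen=True)
class TraitArchitecture:
    """QTL set and additive effects realizing two correlated traits.

    Both traits (performance measured in the breeding environment B and in
    the commercial environment C) are fully controlled by the same QTL with
    per-QTL effect pairs drawn from a bivariate normal with correlation
    ``r_g``, rescaled so each trait has founder genetic variance 1.
    ``sigma_e2`` is the residual variance ``(1 - h2)/h2`` implied by the
    heritability on the founder scale.
    """

    qtl_indices: np.ndarray
    marker_indices: np.ndarray
    effects: np.ndarray  # (n_qtl, 2): columns are the B and C traits
    r_g: float
    h2: float
    sigma_e2: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def n_qtl(self) -> int:
        return int(self.qtl_indices.size)

    @property
    def n_markers(self) -> int:
        return int(self.marker_indices.size)


def assign_trait_architecture(
    gmap: GenomeMap,
    founder_haplotypes: np.ndarray,
    n_qtl: int,
    r_g: float,
    h2: float,
    seed: int | np.random.Generator,
) -> TraitArchitecture:
    """Pick QTL, draw correlated effects and scale to unit founder variance."""
    L = gmap.n_loci
    if not (0 < n_qtl < L):
        raise ValueError("n_qtl must lie strictly between 0 and the locus count")
    if abs(r_g) > 1:
        raise ValueError("|r_g| must not exceed 1")
    if not (0 < h2 < 1):
        raise ValueError("h2 must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(L, size=n_qtl, replace=False))
    markers = np.setdiff1d(np.arange(L), qtl, assume_unique=True)
    cov = np.array([[1.0, r_g], [r_g, 1.0]])
    eff = rng.multivariate_normal(np.zeros(2), cov, size=n_qtl, method="svd")
    dosage = founder_haplotypes[:, :, qtl].sum(axis=1).astype(np.float64)
    raw = dosage @ eff
    sd = raw.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("founder QTL dosages carry no variance; increase founders or QTL")
    eff = eff / sd
    tbv = dosage @ eff
    return TraitArchitecture(
        qtl_indices=qtl,
        marker_indices=markers,
        effects=eff,
        r_g=float(r_g),
        h2=float(h2),
        sigma_e2=(1.0 - h2) / h2,
        center=tbv.mean(axis=0),
    )


def true_breeding_values(haplotypes: np.ndarray, arch: TraitArchitecture) -> np.ndarray:
    """Sum of QTL allele effects, centered on the founder mean.

    ``haplotypes`` may be ``(2, L)`` for one individual or ``(k, 2, L)`` for
    a cohort; returns ``(2,)`` or ``(k, 2)`` with columns (B trait, C trait).
    """
    single = haplotypes.ndim == 2
    h = haplotypes[None] if single else haplotypes
    dosage = h[:, :, arch.qtl_indices].sum(axis=1).astype(np.float64)
    tbv = dosage @ arch.effects - arch.center
    return tbv[0] if single else tbv


def simulate_phenotypes(
    tbv_own_env: np.ndarray, sigma_e2: float, rng: np.random.Generator
) -> np.ndarray:
    """Phenotype = TBV of the trait matching the fish's environment + noise.

    The simulated fixed year effect is zero; the evaluation model still fits
    year effects.
    """
    tbv_own_env = np.asarray(tbv_own_env, dtype=np.float64)
    if sigma_e2 < 0:
        raise ValueError("residual variance must be non-negative")
    return tbv_own_env + rng.normal(0.0, np.sqrt(sigma_e2), size=tbv_own_env.shape)
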