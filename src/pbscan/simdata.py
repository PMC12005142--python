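"""Synthetic low-coverage sequencing data under a Balding-Nichols model.

Generates a three-population study design: an ancestral allele frequency per
site, population frequencies drifted away from it with per-population drift
coefficients, optional admixed individuals, an optional implanted selection
region (a localized displacement of the focal population's frequencies), and
short-read pileups at a configurable mean depth and error rate.

Sites are independent (no linkage); positions are uniform without replacement
on ``[1, chrom_length]``, 1-based. Under the Balding-Nichols model a
population with drift ``c`` has frequencies ``p_i ~ Beta(p(1-c)/c,
(1-p)(1-c)/c)`` around the ancestral ``p``, so that
``E[(p_i - p)^2] = c * p(1-p)`` — the drift coefficient is the population's
FST to the ancestor, which makes the generator's differentiation level
analytically checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

BASES = np.array(["A", "C", "G", "T"])
BASE_CODE = {b: i for i, b in enumerate(BASES)}

# Default design: one focal population at ~2x coverage plus two related
# reference panels; Hudson FST between pops i and j is ~ (c_i + c_j)/2, and
# these drifts put the three pairwise FSTs at 0.044 / 0.040 / 0.016 — the
# 0.01-0.05 range typical of closely related human populations.
DEFAULT_N_INDIVIDUALS = (33, 25, 25)
DEFAULT_DRIFT = (0.068, 0.020, 0.012)


@dataclass
class Sweep:
    """A localized allele-frequency displacement in one population.

    Inside ``[start, end]`` (1-based, inclusive) the focal population's minor
    allele frequency is moved toward fixation (or loss) by a fraction
    ``delta``: ``p' = p + delta * (1 - p)`` (toward 1) or ``p' = p * (1 -
    delta)`` (toward 0).
    """

    population: int
    start: int
    end: int
    delta: float
    toward: int = 1  # 1: favored allele is the minor allele; 0: the major

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError(f"sweep delta must be in [0, 1], got {self.delta}")
        if self.start > self.end:
            raise ValueError("sweep interval start must be <= end")
        if self.toward not in (0, 1):
            raise ValueError("sweep 'toward' must be 0 or 1")


@dataclass
class SimulationConfig:
    n_sites: int = 10_000
    chrom_length: int = 10_000_000
    n_individuals: Sequence[int] = DEFAULT_N_INDIVIDUALS
    drift: Sequence[float] = DEFAULT_DRIFT
    mean_depth: float = 2.0
    error_rate: float = 0.01
    maf_floor: float = 0.05
    sweep: Optional[Sweep] = None
    admixture: Optional[np.ndarray] = None  # individuals x K true Q matrix
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_individuals = tuple(int(n) for n in self.n_individuals)
        self.drift = tuple(float(c) for c in self.drift)
        if len(self.n_individuals) != len(self.drift):
            raise ValueError("n_individuals and drift must have equal length")
        if any(c < 0 or c >= 1 for c in self.drift):
            raise ValueError("drift coefficients must lie in [0, 1)")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be >= 0")
        if not (0 <= self.error_rate < 0.25):
            raise ValueError("error_rate must lie in [0, 0.25)")
        if not (0 <= self.maf_floor < 0.5):
            raise ValueError("maf_floor must lie in [0, 0.5)")
        if self.n_sites > self.chrom_length:
            raise ValueError("more sites than positions on the chromosome")
        if self.sweep is not None:
            if not (1 <= self.sweep.start and self.sweep.end <= self.chrom_length):
                raise ValueError("sweep interval outside [1, chrom_length]")
            if not (0 <= self.sweep.population < len(self.n_individuals)):
                raise ValueError("sweep population index out of range")
        if self.admixture is not None:
            q = np.asarray(self.admixture, dtype=float)
            if q.ndim != 2 or q.shape[0] != sum(self.n_individuals):
                raise ValueError("admixture Q must be (total individuals) x K")
            if q.shape[1] != len(self.n_individuals):
                raise ValueError("admixture Q needs one column per population")
            if not np.allclose(q.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("admixture Q rows must sum to 1")
            self.admixture = q

    @property
    def n_pops(self) -> int:
        return len(self.n_individuals)

    @property
    def n_total(self) -> int:
        return sum(self.n_individuals)


@dataclass
class PileupTable:
    """Flat per-read observations: one entry per read.

    ``site_idx`` indexes into ``sites`` (a DataFrame with chrom, pos, major,
    minor); ``base`` is a 0-3 code into A,C,G,T; ``strand`` is 0 (forward) or
    1 (reverse); ``qual`` is a Phred base quality.
    """

    sites: pd.DataFrame
    n_individuals: int
    site_idx: np.ndarray
    indiv: np.ndarray
    base: np.ndarray
    qual: np.ndarray
    strand: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def depths(self) -> np.ndarray:
        """(sites x individuals) read-depth matrix."""
        d = np.zeros((self.n_sites, self.n_individuals), dtype=np.int32)
        np.add.at(d, (self.site_idx, self.indiv), 1)
        return d

    def subset_individuals(self, idx: Sequence[int]) -> "PileupTable":
        idx = np.asarray(idx, dtype=int)
        remap = -np.ones(self.n_individuals, dtype=int)
        remap[idx] = np.arange(len(idx))
        keep = remap[self.indiv] >= 0
        return PileupTable(
            sites=self.sites,
            n_individuals=len(idx),
            site_idx=self.site_idx[keep],
            indiv=remap[self.indiv[keep]],
            base=self.base[keep],
            qual=self.qual[keep],
            strand=self.strand[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        """One row per read: chrom, pos, indiv, base, qual, strand."""
        return pd.DataFrame(
            {
                "chrom": self.sites["chrom"].to_numpy()[self.site_idx],
                "pos": self.sites["pos"].to_numpy()[self.site_idx],
                "indiv": self.indiv,
                "base": BASES[self.base],
                "qual": self.qual,
                "strand": np.where(self.strand == 0, "+", "-"),
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SimulationTruth:
    config: SimulationConfig
    positions: np.ndarray  # 1-based, strictly increasing
    major: np.ndarray  # base codes
    minor: np.ndarray
    ancestral_freqs: np.ndarray  # minor-allele frequency per site
    pop_freqs: np.ndarray  # pops x sites
    genotypes: np.ndarray  # individuals x sites, minor-allele counts {0,1,2}
    true_Q: np.ndarray  # individuals x K, rows sum to 1
    pop_of_individual: np.ndarray  # label per individual (argmax ancestry)
    sweep_interval: Optional[tuple] = None

    def pop_slice(self, pop: int) -> slice:
        starts = np.concatenate([[0], np.cumsum(self.config.n_individuals)])
        return slice(int(starts[pop]), int(starts[pop + 1]))

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.config.chrom,
                "pos": self.positions,
                "major": BASES[self.major],
                "minor": BASES[self.minor],
            }
        )


def simulate_frequencies(config: SimulationConfig, rng=None):
    """Draw ancestral and per-population minor-allele frequencies.

    Ancestral frequencies are uniform on ``[maf_floor, 1 - maf_floor]``
    (emulating SNP ascertainment); populations drift by the Balding-Nichols
    Beta draw, with ``c=0`` meaning no drift (frequencies copied exactly).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    p = rng.uniform(config.maf_floor, 1.0 - config.maf_floor, size=config.n_sites)
    pop_freqs = np.empty((config.n_pops, config.n_sites))
    for i, c in enumerate(config.drift):
        if c == 0.0:
            pop_freqs[i] = p
        else:
            a = p * (1.0 - c) / c
            b = (1.0 - p) * (1.0 - c) / c
            pop_freqs[i] = rng.beta(a, b)
    return p, pop_freqs


def implant_sweep(pop_freqs: np.ndarray, positions: np.ndarray, sweep: Sweep) -> np.ndarray:
    """Displace the focal population's frequencies inside the sweep interval.

    Returns a copy; all other populations and sites are untouched.
    """
    out = pop_freqs.copy()
    in_region = (positions >= sweep.start) & (positions <= sweep.end)
    p = out[sweep.population, in_region]
    if sweep.toward == 1:
        out[sweep.population, in_region] = p + sweep.delta * (1.0 - p)
    else:
        out[sweep.population, in_region] = p * (1.0 - sweep.delta)
    return out


def simulate_admixed_genotypes(pop_freqs: np.ndarray, true_Q: np.ndarray, rng) -> np.ndarray:
    """Genotypes for admixed individuals: ``g ~ Binomial(2, h)``, ``h = QF``.

    ``pop_freqs`` is (K x sites), ``true_Q`` (individuals x K). An unadmixed
    individual (a one-hot Q row) reduces to Binomial(2, F_ks).
    """
    true_Q = np.asarray(true_Q, dtype=float)
    if not np.allclose(true_Q.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("Q rows must sum to 1")
    h = true_Q @ pop_freqs  # individuals x sites
    return rng.binomial(2, h).astype(np.int8)


def simulate_reads(
    genotypes: np.ndarray,
    mean_depth: float,
    error_rate: float,
    rng,
    sites: Optional[pd.DataFrame] = None,
    major: Optional[np.ndarray] = None,
    minor: Optional[np.ndarray] = None,
) -> PileupTable:
    """Poisson-depth reads with uniform sequencing error.

    Per individual per site the read count is Poisson(mean_depth); each read
    samples one of the two chromosomes (the minor allele with probability
    g/2), is miscalled with probability ``error_rate`` (uniformly to one of
    the three other bases), and lands on either strand with probability 1/2.
    Base quality is the Phred-scaled error rate, rounded.
    """
    n_ind, n_sites = genotypes.shape
    if major is None:
        major = np.zeros(n_sites, dtype=np.int8)  # all-A majors
    if minor is None:
        minor = np.ones(n_sites, dtype=np.int8)  # all-C minors
    if sites is None:
        sites = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, n_sites + 1),
                "major": BASES[major],
                "minor": BASES[minor],
            }
        )
    depth = rng.poisson(mean_depth, size=(n_sites, n_ind))
    total = int(depth.sum())
    site_idx = np.repeat(
        np.tile(np.arange(n_sites), n_ind), depth.T.reshape(-1)
    )
    indiv = np.repeat(np.arange(n_ind), depth.sum(axis=0))
    g = genotypes[indiv, site_idx]
    true_is_minor = rng.random(total) < g / 2.0
    true_base = np.where(true_is_minor, minor[site_idx], major[site_idx])
    is_err = rng.random(total) < error_rate
    # a miscall lands uniformly on one of the 3 other bases
    shift = rng.integers(1, 4, size=total)
    base = np.where(is_err, (true_base + shift) % 4, true_base).astype(np.int8)
    qual_val = int(round(-10.0 * np.log10(error_rate))) if error_rate > 0 else 60
    return PileupTable(
        sites=sites,
        n_individuals=n_ind,
        site_idx=site_idx.astype(np.int32),
        indiv=indiv.astype(np.int32),
        base=base,
        qual=np.full(total, qual_val, dtype=np.int16),
        strand=(rng.random(total) < 0.5).astype(np.int8),
    )


def simulate_dataset(config: SimulationConfig):
    """Run the full generator: frequencies -> sweep -> genotypes -> reads.

    Returns ``(truth, pileup)``. Individuals are ordered by population; with
    an admixture Q supplied, individual ``i``'s genotype law is
    ``Binomial(2, sum_k Q_ik F_ks)`` instead of the pure population draw.
    Fully deterministic under ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_freq, rng_geno, rng_reads, rng_sites = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    positions = np.sort(
        rng_sites.choice(config.chrom_length, size=config.n_sites, replace=False) + 1
    )
    # major/minor base labels per site; major is the ancestral majority allele
    pair = rng_sites.integers(0, 4, size=(config.n_sites, 2))
    clash = pair[:, 0] == pair[:, 1]
    pair[clash, 1] = (pair[clash, 0] + 1 + rng_sites.integers(0, 3, clash.sum())) % 4

    p_anc, pop_freqs = simulate_frequencies(config, rng_freq)

    # Fold so the tracked allele is the ancestral-minor allele everywhere:
    # truth frequencies, genotypes and downstream GL triples all count copies
    # of the same (minor) allele.
    flip = p_anc > 0.5
    p_anc = np.where(flip, 1.0 - p_anc, p_anc)
    pop_freqs[:, flip] = 1.0 - pop_freqs[:, flip]
    minor = np.where(flip, pair[:, 1], pair[:, 0]).astype(np.int8)
    major = np.where(flip, pair[:, 0], pair[:, 1]).astype(np.int8)
    # ties (p == 0.5): lexicographically smaller base label is the major;
    # swapping labels also flips the tracked orientation, so flip freqs too
    swap = (p_anc == 0.5) & (major > minor)
    if swap.any():
        major[swap], minor[swap] = minor[swap], major[swap].copy()
        pop_freqs[:, swap] = 1.0 - pop_freqs[:, swap]

    sweep_interval = None
    if config.sweep is not None:
        pop_freqs = implant_sweep(pop_freqs, positions, config.sweep)
        sweep_interval = (config.sweep.start, config.sweep.end)

    if config.admixture is not None:
        true_Q = config.admixture
    else:
        true_Q = np.zeros((config.n_total, config.n_pops))
        start = 0
        for k, n in enumerate(config.n_individuals):
            true_Q[start : start + n, k] = 1.0
            start += n
    genotypes = simulate_admixed_genotypes(pop_freqs, true_Q, rng_geno)

    truth = SimulationTruth(
        config=config,
        positions=positions,
        major=major,
        minor=minor,
        ancestral_freqs=p_anc,
        pop_freqs=pop_freqs,
        genotypes=genotypes,
        true_Q=true_Q,
        pop_of_individual=np.argmax(true_Q, axis=1),
        sweep_interval=sweep_interval,
    )
    pileup = simulate_reads(
        genotypes,
        config.mean_depth,
        config.error_rate,
        rng_reads,
        sites=truth.sites_frame(),
        major=major,
        minor=minor,
    )
    return truth, pileup
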