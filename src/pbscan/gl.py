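"""Genotype likelihoods from pileups, per-site MAF by EM, and Beagle/VCF IO.

The likelihood model is the standard independent-error allele-sampling
mixture: for an individual with genotype ``g`` copies of the minor allele,
each read's base ``b`` contributes

    P(b | g) = (1 - g/2) * e(b | major) + (g/2) * e(b | minor)

with ``e(b | a) = 1 - eps`` when ``b == a`` and ``eps / 3`` otherwise, where
``eps`` is the read's Phred-scaled base error probability. Reads carrying
bases other than the site's two alleles, or below the base-quality cutoff,
are discarded. Likelihood triples are stored max-rescaled (Beagle
convention); a missing individual is the uninformative triple ``(1, 1, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simdata import BASES, BASE_CODE, PileupTable

MISSING_MAF = np.nan


@dataclass(frozen=True)
class SiteRecord:
    chrom: str
    pos: int
    major: str
    minor: str

    def __post_init__(self):
        if self.major == self.minor:
            raise ValueError("major and minor allele must differ")
        if self.pos < 1:
            raise ValueError("positions are 1-based")


@dataclass
class GenotypeLikelihoodTable:
    """Sites x individuals x 3 genotype likelihoods plus site metadata.

    ``gl[s, i, g]`` is the (max-rescaled) likelihood of ``g`` copies of the
    minor allele. ``sites`` has columns chrom, pos, major, minor and is
    sorted by (chrom, pos).
    """

    sites: pd.DataFrame
    gl: np.ndarray

    def __post_init__(self):
        if self.gl.ndim != 3 or self.gl.shape[2] != 3:
            raise ValueError("gl must be sites x individuals x 3")
        if len(self.sites) != self.gl.shape[0]:
            raise ValueError("site metadata and gl length mismatch")

    @property
    def n_sites(self) -> int:
        return self.gl.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.gl.shape[1]

    def subset_sites(self, mask) -> "GenotypeLikelihoodTable":
        return GenotypeLikelihoodTable(
            sites=self.sites.loc[np.asarray(mask)].reset_index(drop=True),
            gl=self.gl[np.asarray(mask)],
        )

    def subset_individuals(self, idx: Sequence[int]) -> "GenotypeLikelihoodTable":
        return GenotypeLikelihoodTable(sites=self.sites, gl=self.gl[:, list(idx), :])

    def is_missing(self) -> np.ndarray:
        """sites x individuals mask of uninformative (1,1,1) triples."""
        return np.all(self.gl == self.gl[:, :, :1], axis=2)


def _phred_to_eps(qual: np.ndarray) -> np.ndarray:
    return np.power(10.0, -np.asarray(qual, dtype=float) / 10.0)


def compute_gl(
    bases: Sequence[str],
    quals: Sequence[float],
    major: str,
    minor: str,
    min_base_quality: int = 20,
) -> np.ndarray:
    """GL triple for one individual at one site from its reads.

    Returns the max-rescaled ``(L(0), L(1), L(2))``; with no surviving reads
    the uninformative ``(1, 1, 1)``.
    """
    bases = np.asarray([BASE_CODE[b] if isinstance(b, str) else b for b in bases])
    quals = np.asarray(quals, dtype=float)
    maj, mnr = BASE_CODE[major], BASE_CODE[minor]
    keep = (quals >= min_base_quality) & ((bases == maj) | (bases == mnr))
    bases, quals = bases[keep], quals[keep]
    if len(bases) == 0:
        return np.ones(3)
    eps = _phred_to_eps(quals)
    e_major = np.where(bases == maj, 1.0 - eps, eps / 3.0)
    e_minor = np.where(bases == mnr, 1.0 - eps, eps / 3.0)
    g = np.array([0.0, 0.5, 1.0])  # g/2 for g = 0, 1, 2
    loglik = np.log(
        (1.0 - g[:, None]) * e_major[None, :] + g[:, None] * e_minor[None, :]
    ).sum(axis=1)
    lik = np.exp(loglik - loglik.max())
    return lik


def compute_gl_table(pileup: PileupTable, min_base_quality: int = 20) -> GenotypeLikelihoodTable:
    """Vectorized GL computation for a whole pileup table.

    Identical model to :func:`compute_gl`, applied to every (site,
    individual) cell at once.
    """
    maj_code = np.array([BASE_CODE[b] for b in pileup.sites["major"]], dtype=np.int8)
    mnr_code = np.array([BASE_CODE[b] for b in pileup.sites["minor"]], dtype=np.int8)
    site_maj = maj_code[pileup.site_idx]
    site_mnr = mnr_code[pileup.site_idx]
    keep = (pileup.qual >= min_base_quality) & (
        (pileup.base == site_maj) | (pileup.base == site_mnr)
    )
    s, i = pileup.site_idx[keep], pileup.indiv[keep]
    eps = _phred_to_eps(pileup.qual[keep])
    is_major = pileup.base[keep] == site_maj[keep]
    e_major = np.where(is_major, 1.0 - eps, eps / 3.0)
    e_minor = np.where(is_major, eps / 3.0, 1.0 - eps)

    loglik = np.zeros((pileup.n_sites, pileup.n_individuals, 3))
    for g_idx, w in enumerate((0.0, 0.5, 1.0)):
        np.add.at(loglik[:, :, g_idx], (s, i), np.log((1.0 - w) * e_major + w * e_minor))
    loglik -= loglik.max(axis=2, keepdims=True)
    gl = np.exp(loglik)  # cells with no reads end up exactly (1,1,1)
    return GenotypeLikelihoodTable(sites=pileup.sites.copy(), gl=gl)


@dataclass
class MafEstimate:
    freq: float
    n_iter: int
    loglik: float


def _hwe_prior(f: np.ndarray) -> np.ndarray:
    """(sites x 1 x 3) HWE genotype prior for per-site frequencies f."""
    return np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=1)[:, None, :]


def _maf_em_array(
    gl: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
    f0: float = 0.1,
    record_loglik: bool = False,
):
    """EM for per-site minor allele frequency under an HWE prior.

    ``gl`` is (sites x individuals x 3). Returns (freq, n_iter, loglik[,
    history]) arrays; fully uninformative sites get NaN frequency.
    """
    S, N, _ = gl.shape
    informative = ~np.all(gl == gl[:, :, :1], axis=2)  # per site x individual
    any_info = informative.any(axis=1)
    f = np.full(S, f0)
    n_iter = np.zeros(S, dtype=int)
    active = any_info.copy()
    g = np.arange(3)
    history = []
    for _ in range(max_iter):
        if not active.any():
            break
        w = gl[active] * _hwe_prior(f[active])
        post = w / w.sum(axis=2, keepdims=True)
        f_new = (post * g).sum(axis=2).mean(axis=1) / 2.0
        idx = np.flatnonzero(active)
        converged = np.abs(f_new - f[idx]) < tol
        f[idx] = f_new
        n_iter[idx] += 1
        active[idx[converged]] = False
        if record_loglik:
            history.append(np.log((gl * _hwe_prior(f)).sum(axis=2)).sum(axis=1))
    loglik = np.log((gl * _hwe_prior(f)).sum(axis=2)).sum(axis=1)
    f[~any_info] = MISSING_MAF
    loglik[~any_info] = np.nan
    if record_loglik:
        return f, n_iter, loglik, np.array(history)
    return f, n_iter, loglik


def estimate_maf_em(
    gl_site: np.ndarray, tol: float = 1e-6, max_iter: int = 100
) -> MafEstimate:
    """MAF EM for a single site (individuals x 3 GL matrix)."""
    f, n, ll = _maf_em_array(np.asarray(gl_site, dtype=float)[None], tol, max_iter)
    return MafEstimate(freq=float(f[0]), n_iter=int(n[0]), loglik=float(ll[0]))


def estimate_maf_table(
    table: GenotypeLikelihoodTable, tol: float = 1e-6, max_iter: int = 100
) -> np.ndarray:
    """Per-site MAF estimates for a whole table."""
    f, _, _ = _maf_em_array(table.gl, tol, max_iter)
    return f


def filter_maf(
    table: GenotypeLikelihoodTable, maf_threshold: float = 0.05, maf: Optional[np.ndarray] = None
) -> GenotypeLikelihoodTable:
    """Keep sites whose estimated MAF is strictly above the threshold.

    Sites with missing (NaN) MAF are dropped.
    """
    if maf is None:
        maf = estimate_maf_table(table)
    keep = maf > maf_threshold  # NaN compares False
    return table.subset_sites(keep)


def table_from_genotypes(genotypes: np.ndarray, sites: Optional[pd.DataFrame] = None) -> GenotypeLikelihoodTable:
    """One-hot GL table from known genotypes (the infinite-depth limit).

    ``genotypes`` is (individuals x sites) minor-allele counts in {0, 1, 2};
    -1 marks a missing individual (uninformative triple).
    """
    genotypes = np.asarray(genotypes)
    n_ind, n_sites = genotypes.shape
    gl = np.zeros((n_sites, n_ind, 3))
    g = genotypes.T
    missing = g < 0
    for k in range(3):
        gl[:, :, k] = (g == k).astype(float)
    gl[missing] = 1.0
    if sites is None:
        sites = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, n_sites + 1), "major": "A", "minor": "C"}
        )
    return GenotypeLikelihoodTable(sites=sites, gl=gl)


# ---------------------------------------------------------------------------
# Beagle genotype-likelihood format
# ---------------------------------------------------------------------------

def write_beagle(table: GenotypeLikelihoodTable, path, sample_names=None) -> None:
    """Beagle GL text format: marker, allele1, allele2, then 3 cols/individual."""
    n = table.n_individuals
    if sample_names is None:
        sample_names = [f"Ind{i}" for i in range(n)]
    header = ["marker", "allele1", "allele2"] + [s for s in sample_names for _ in range(3)]
    marker = table.sites["chrom"].astype(str) + "_" + table.sites["pos"].astype(str)
    a1 = table.sites["major"].map(BASE_CODE)
    a2 = table.sites["minor"].map(BASE_CODE)
    flat = table.gl.reshape(table.n_sites, 3 * n)
    out = pd.DataFrame(flat)
    out.insert(0, "allele2", a2.to_numpy())
    out.insert(0, "allele1", a1.to_numpy())
    out.insert(0, "marker", marker.to_numpy())
    out.columns = header
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_beagle(path) -> GenotypeLikelihoodTable:
    df = pd.read_csv(path, sep="\t", header=0, dtype={"marker": str})
    ncol = df.shape[1]
    if (ncol - 3) % 3 != 0 or ncol < 6:
        raise ValueError(f"malformed Beagle file: {ncol} columns")
    split = df["marker"].str.rsplit("_", n=1)
    chrom = split.str[0]
    pos = split.str[1].astype(int)
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "major": BASES[df.iloc[:, 1].astype(int)],
            "minor": BASES[df.iloc[:, 2].astype(int)],
        }
    )
    gl = df.iloc[:, 3:].to_numpy(dtype=float).reshape(len(df), -1, 3)
    mx = gl.max(axis=2, keepdims=True)
    bad = ~np.isfinite(mx) | (mx <= 0)
    mx = np.where(bad, 1.0, mx)
    gl = gl / mx
    return GenotypeLikelihoodTable(sites=sites, gl=gl)


# ---------------------------------------------------------------------------
# VCF with GL FORMAT field
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GL,Number=G,Type=Float,Description="Genotype likelihoods, log10-scaled">
"""


def write_vcf_gl(table: GenotypeLikelihoodTable, path, sample_names=None) -> None:
    """VCF 4.2 with a GL FORMAT field (log10-scaled, REF=major, ALT=minor)."""
    n = table.n_individuals
    if sample_names is None:
        sample_names = [f"Ind{i}" for i in range(n)]
    with np.errstate(divide="ignore"):
        log_gl = np.log10(table.gl)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        chroms = table.sites["chrom"].to_numpy()
        poss = table.sites["pos"].to_numpy()
        majors = table.sites["major"].to_numpy()
        minors = table.sites["minor"].to_numpy()
        for s in range(table.n_sites):
            cells = []
            for i in range(n):
                trip = log_gl[s, i]
                cells.append(",".join("%.6g" % v if np.isfinite(v) else "-999" for v in trip))
            fh.write(
                f"{chroms[s]}\t{poss[s]}\t.\t{majors[s]}\t{minors[s]}\t.\tPASS\t.\tGL\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf_gl(path) -> GenotypeLikelihoodTable:
    """Read a VCF with GL FORMAT triples; multiallelic records are rejected."""
    from cyvcf2 import VCF

    chroms, poss, majors, minors, gls = [], [], [], [], []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            if len(rec.ALT) != 1:
                raise ValueError(
                    f"non-biallelic record at {rec.CHROM}:{rec.POS} "
                    f"(ALT={rec.ALT}); only biallelic SNPs are supported"
                )
            gl_field = rec.format("GL")
            if gl_field is None or gl_field.shape[1] != 3:
                raise ValueError(f"missing/malformed GL field at {rec.CHROM}:{rec.POS}")
            chroms.append(rec.CHROM)
            poss.append(rec.POS)
            majors.append(rec.REF)
            minors.append(rec.ALT[0])
            gls.append(np.asarray(gl_field, dtype=float))
    finally:
        vcf.close()
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "major": majors, "minor": minors})
    log_gl = np.stack(gls, axis=0)
    log_gl[log_gl <= -999] = -np.inf
    gl = np.power(10.0, log_gl - log_gl.max(axis=2, keepdims=True))
    return GenotypeLikelihoodTable(sites=sites, gl=gl)
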