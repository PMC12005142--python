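"""Pre-analysis site filters for low-coverage data.

Three predicates, applied independently per site:

* coverage — at least ``k`` individuals covered by at least ``u`` reads;
* excess heterozygosity — one-sided exact Hardy-Weinberg test (Levene/
  Haldane conditional distribution of the heterozygote count given the
  sample size and minor-allele count), rejecting sites with a surplus of
  heterozygotes (a classic signature of mapping collapse / paralogy);
* strand bias — two-sided Fisher exact test on the 2x2 allele-by-strand
  table.

Genotype counts for the heterozygosity test come from GL-based hard calls:
an individual is called when its genotype posterior under the site's
MAF-HWE prior reaches 0.95, and uncalled individuals are excluded, which
keeps the filter self-contained at ~2x coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact

from .gl import GenotypeLikelihoodTable, estimate_maf_table, _hwe_prior
from .simdata import BASE_CODE, PileupTable


@dataclass
class FilterConfig:
    min_individuals: int = 10  # k
    min_depth: int = 1  # u
    het_p: float = 1e-6  # H
    strand_p: float = 1e-4  # S
    min_base_quality: int = 20
    call_posterior: float = 0.95
    enable_coverage: bool = True
    enable_het: bool = True
    enable_strand: bool = True


def coverage_filter(depths: np.ndarray, k: int = 10, u: int = 1) -> bool:
    """Pass iff at least ``k`` individuals have depth >= ``u``."""
    return int(np.sum(np.asarray(depths) >= u)) >= k


def _het_pmf_log(n: int, n_minor: int, h: np.ndarray) -> np.ndarray:
    """Log pmf of the heterozygote count under the exact conditional HWE law.

    ``n`` diploid individuals, ``n_minor`` minor-allele copies; support is
    ``h`` in {n_minor mod 2, ..., min(n_minor, 2n - n_minor)} stepping by 2.
    """
    n_major = 2 * n - n_minor
    return (
        h * np.log(2.0)
        + gammaln(n + 1)
        - gammaln((n_minor - h) / 2 + 1)
        - gammaln(h + 1)
        - gammaln((n_major - h) / 2 + 1)
        - (gammaln(2 * n + 1) - gammaln(n_minor + 1) - gammaln(n_major + 1))
    )


def excess_het_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-sided exact test for heterozygote excess.

    Returns P(het count >= observed | n, minor allele count) under the exact
    conditional Hardy-Weinberg distribution. Degenerate sites (no minor
    alleles) return 1.
    """
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one called genotype")
    n_minor = n_Aa + 2 * n_aa
    if n_minor > n:  # fold: work with the rarer allele
        n_minor = 2 * n - n_minor
    if n_minor == 0:
        return 1.0
    h_support = np.arange(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    logpmf = _het_pmf_log(n, n_minor, h_support)
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    return float(pmf[h_support >= n_Aa].sum())


def strand_bias_test(table: np.ndarray) -> float:
    """Two-sided Fisher exact test on a 2x2 allele-by-strand count table."""
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected a 2x2 nonnegative count table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    return float(fisher_exact(table, alternative="two-sided")[1])


def hard_calls(table: GenotypeLikelihoodTable, maf: np.ndarray, call_posterior: float = 0.95):
    """Genotype hard calls from the GL posterior under the MAF-HWE prior.

    Returns (sites x individuals) genotype array with -1 for uncalled.
    """
    f = np.nan_to_num(maf, nan=0.0)
    post = table.gl * _hwe_prior(f)
    post /= post.sum(axis=2, keepdims=True)
    best = post.argmax(axis=2)
    called = post.max(axis=2) >= call_posterior
    return np.where(called, best, -1)


def strand_tables(pileup: PileupTable, min_base_quality: int = 20) -> np.ndarray:
    """Per-site 2x2 tables: (major, minor) x (forward, reverse) read counts."""
    maj = np.array([BASE_CODE[b] for b in pileup.sites["major"]], dtype=np.int8)
    mnr = np.array([BASE_CODE[b] for b in pileup.sites["minor"]], dtype=np.int8)
    site_maj = maj[pileup.site_idx]
    site_mnr = mnr[pileup.site_idx]
    keep = (pileup.qual >= min_base_quality) & (
        (pileup.base == site_maj) | (pileup.base == site_mnr)
    )
    s = pileup.site_idx[keep]
    allele = (pileup.base[keep] == site_mnr[keep]).astype(int)  # 0 major, 1 minor
    strand = pileup.strand[keep].astype(int)
    out = np.zeros((pileup.n_sites, 2, 2), dtype=np.int64)
    np.add.at(out, (s, allele, strand), 1)
    return out


def apply_filters(
    pileup: PileupTable,
    gl_table: GenotypeLikelihoodTable,
    config: FilterConfig = FilterConfig(),
    maf: np.ndarray | None = None,
) -> pd.DataFrame:
    """Evaluate all enabled filters per site and return the report.

    The report has one row per site: chrom, pos, n_covered, het_p, strand_p,
    per-filter pass flags and the overall conjunction. Filters are
    independent predicates, so their order is irrelevant.
    """
    S = pileup.n_sites
    depths = pileup.depths()
    n_covered = (depths >= config.min_depth).sum(axis=1)

    het_p = np.ones(S)
    if config.enable_het:
        if maf is None:
            maf = estimate_maf_table(gl_table)
        calls = hard_calls(gl_table, maf, config.call_posterior)
        for s_idx in range(S):
            c = calls[s_idx]
            c = c[c >= 0]
            if len(c) == 0:
                het_p[s_idx] = 1.0
            else:
                het_p[s_idx] = excess_het_test(
                    int((c == 0).sum()), int((c == 1).sum()), int((c == 2).sum())
                )

    strand_p = np.ones(S)
    if config.enable_strand:
        tables = strand_tables(pileup, config.min_base_quality)
        for s_idx in range(S):
            strand_p[s_idx] = strand_bias_test(tables[s_idx])

    pass_cov = (
        n_covered >= config.min_individuals if config.enable_coverage else np.ones(S, bool)
    )
    pass_het = het_p >= config.het_p if config.enable_het else np.ones(S, bool)
    pass_strand = strand_p >= config.strand_p if config.enable_strand else np.ones(S, bool)

    return pd.DataFrame(
        {
            "chrom": gl_table.sites["chrom"],
            "pos": gl_table.sites["pos"],
            "n_covered": n_covered,
            "het_p": het_p,
            "strand_p": strand_p,
            "pass_coverage": pass_cov,
            "pass_het": pass_het,
            "pass_strand": pass_strand,
            "pass": pass_cov & pass_het & pass_strand,
        }
    )


def passing_bed(report: pd.DataFrame) -> pd.DataFrame:
    """BED (0-based half-open) intervals of passing sites, merged when adjacent."""
    ok = report.loc[report["pass"], ["chrom", "pos"]].sort_values(["chrom", "pos"])
    rows = []
    for chrom, grp in ok.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if len(pos) == 0:
            continue
        start = pos[0]
        prev = pos[0]
        for p in pos[1:]:
            if p == prev + 1:
                prev = p
                continue
            rows.append((chrom, start - 1, prev))
            start = prev = p
        rows.append((chrom, start - 1, prev))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
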