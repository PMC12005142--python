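"""GL-aware FST components, the PBS transform, sliding windows, peak calling.

Per-site FST uses Hudson-style moment components evaluated as posterior
expectations over the joint allele-count pair (j, k) under the 2D-SFS prior:

    N(j,k) = (p1 - p2)^2 - p1(1-p1)/(2n1 - 1) - p2(1-p2)/(2n2 - 1)
    D(j,k) = p1(1-p2) + p2(1-p1),         p1 = j/2n1, p2 = k/2n2

Window FST is the ratio of sums (sum a / sum d) over the window's sites —
never the mean of per-site ratios. The population branch statistic for focal
population i against j and k is

    PBS_i = (T_ij + T_ik - T_jk) / 2,   T = -log(1 - FST)

computed per sliding window; candidate selection peaks are clusters of
windows in the extreme upper tail of the genome-wide PBS distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


def fst_component_grids(n1: int, n2: int):
    """Hudson numerator/denominator grids over all (j, k) count pairs."""
    if n1 < 1 or n2 < 1:
        raise ValueError("need at least one diploid individual per population")
    p1 = np.arange(2 * n1 + 1) / (2 * n1)
    p2 = np.arange(2 * n2 + 1) / (2 * n2)
    P1, P2 = np.meshgrid(p1, p2, indexing="ij")
    num = (
        (P1 - P2) ** 2
        - P1 * (1 - P1) / (2 * n1 - 1)
        - P2 * (1 - P2) / (2 * n2 - 1)
    )
    den = P1 * (1 - P2) + P2 * (1 - P1)
    return num, den


def fst_site_components(
    saf1: np.ndarray, saf2: np.ndarray, eta: np.ndarray, n1: int, n2: int
):
    """Posterior-expected (a, d) per site under P(j,k) ~ eta * L1(j) * L2(k).

    ``saf1``/``saf2`` are (sites x 2n+1) SAF tables; returns two length-S
    arrays. ``a`` is the expected numerator, ``d`` the expected denominator
    of the Hudson estimator.
    """
    num, den = fst_component_grids(n1, n2)
    w = eta  # prior over (j, k)
    z = np.einsum("sj,jk,sk->s", saf1, w, saf2)
    a = np.einsum("sj,jk,sk->s", saf1, w * num, saf2) / z
    d = np.einsum("sj,jk,sk->s", saf1, w * den, saf2) / z
    return a, d


def window_fst(a: np.ndarray, d: np.ndarray) -> float:
    """Ratio-of-sums FST for one window; NaN when the denominator is zero."""
    ds = float(np.sum(d))
    if ds == 0.0:
        return float("nan")
    return float(np.sum(a) / ds)


def branch_length(fst: float) -> float:
    """Branch-length transform T = -log(1 - FST), clamping negatives to 0.

    FST of exactly 1 maps to +inf (flagged upstream).
    """
    if np.isnan(fst):
        return float("nan")
    f = max(fst, 0.0)
    if f >= 1.0:
        return float("inf")
    return -math.log(1.0 - f)


def pbs(fst_ij: float, fst_ik: float, fst_jk: float) -> float:
    """Population branch statistic for focal population i."""
    if any(np.isnan(x) for x in (fst_ij, fst_ik, fst_jk)):
        return float("nan")
    return (branch_length(fst_ij) + branch_length(fst_ik) - branch_length(fst_jk)) / 2.0


def genome_fst(a: np.ndarray, d: np.ndarray) -> float:
    """Genome-wide ratio-of-sums FST over all sites."""
    return window_fst(a, d)


def sliding_scan(
    positions: np.ndarray,
    components: dict,
    window: int = 50_000,
    step: int = 10_000,
    chrom: str = "1",
    chrom_length: Optional[int] = None,
    min_sites: int = 10,
) -> pd.DataFrame:
    """Sliding-window FST for three population pairs plus focal-population PBS.

    ``components`` maps pair names ``"ij"``, ``"ik"``, ``"jk"`` to (a, d)
    tuples of per-site arrays aligned with ``positions`` (sorted, 1-based).
    Windows are [start, start + window), starting at 1, 1+step, ...; windows
    with fewer than ``min_sites`` sites get NaN statistics and are excluded
    from any percentile ranking downstream.
    """
    if window % step != 0:
        warnings.warn(f"window {window} is not a multiple of step {step}")
    positions = np.asarray(positions)
    if len(positions) and np.any(np.diff(positions) < 0):
        raise ValueError("positions must be sorted")
    last = int(chrom_length if chrom_length is not None else (positions[-1] if len(positions) else 0))
    if last == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_sites", "fst_ij", "fst_ik", "fst_jk", "pbs"]
        )
    starts = np.arange(1, last + 1, step)
    ends = starts + window
    lo = np.searchsorted(positions, starts, side="left")
    hi = np.searchsorted(positions, ends, side="left")
    n_sites = hi - lo

    sums = {}
    for pair, (a, d) in components.items():
        ca = np.concatenate([[0.0], np.cumsum(a)])
        cd = np.concatenate([[0.0], np.cumsum(d)])
        sa = ca[hi] - ca[lo]
        sd = cd[hi] - cd[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            fst = np.where(sd > 0, sa / np.maximum(sd, 1e-300), np.nan)
        sums[pair] = fst

    ok = n_sites >= min_sites
    out = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "n_sites": n_sites,
            "fst_ij": np.where(ok, sums["ij"], np.nan),
            "fst_ik": np.where(ok, sums["ik"], np.nan),
            "fst_jk": np.where(ok, sums["jk"], np.nan),
        }
    )
    t = {
        k: -np.log(1.0 - np.clip(out[f"fst_{k}"].to_numpy(), 0.0, None))
        for k in ("ij", "ik", "jk")
    }
    out["pbs"] = (t["ij"] + t["ik"] - t["jk"]) / 2.0
    return out


@dataclass
class PeakCall:
    chrom: str
    start: int
    best_pbs: float
    n_top_windows: int


def pbs_threshold(pbs_values: np.ndarray, top_fraction: float = 0.001) -> float:
    """Empirical (1 - top_fraction) quantile of non-missing window PBS.

    Top windows are those strictly above the threshold; tied values at the
    threshold are excluded (strict inequality).
    """
    v = np.asarray(pbs_values)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("no non-missing PBS values")
    if len(v) < 1.0 / top_fraction:
        warnings.warn(
            f"only {len(v)} windows for a top fraction of {top_fraction}; "
            "threshold is still the empirical quantile"
        )
    return float(np.quantile(v, 1.0 - top_fraction))


def call_peaks(
    windows: pd.DataFrame,
    top_fraction: float = 0.001,
    min_windows: int = 6,
    merge_distance: int = 1_000_000,
) -> list[PeakCall]:
    """Cluster extreme-tail windows into candidate selection peaks.

    The highest-PBS window above the genome-wide threshold seeds a peak and
    absorbs every remaining top window on the same chromosome within
    ``merge_distance`` (center to center); clusters with at least
    ``min_windows`` top windows are reported, sorted by best PBS.
    """
    w = windows.dropna(subset=["pbs"])
    if len(w) == 0:
        return []
    thr = pbs_threshold(w["pbs"].to_numpy(), top_fraction)
    top = w.loc[w["pbs"] > thr].sort_values("pbs", ascending=False)
    peaks = []
    remaining = top.copy()
    remaining["center"] = (remaining["start"] + remaining["end"]) / 2.0
    while len(remaining):
        seed = remaining.iloc[0]
        close = (remaining["chrom"] == seed["chrom"]) & (
            np.abs(remaining["center"] - seed["center"]) <= merge_distance
        )
        cluster = remaining.loc[close]
        if len(cluster) >= min_windows:
            peaks.append(
                PeakCall(
                    chrom=str(seed["chrom"]),
                    start=int(seed["start"]),
                    best_pbs=float(seed["pbs"]),
                    n_top_windows=int(len(cluster)),
                )
            )
        remaining = remaining.loc[~close]
    peaks.sort(key=lambda p: -p.best_pbs)
    return peaks


def peaks_frame(peaks: list[PeakCall]) -> pd.DataFrame:
    """Peak table in the style of a selection-scan summary (position in kb)."""
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in peaks],
            "position_kb": [p.start / 1000.0 for p in peaks],
            "pbs": [p.best_pbs for p in peaks],
            "windows": [p.n_top_windows for p in peaks],
        }
    )


def manhattan_plot(windows: pd.DataFrame, top_fraction: float = 0.001, path=None):
    """PBS along the genome with the top-quantile threshold as a dashed line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    w = windows.dropna(subset=["pbs"])
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.scatter(w["start"] / 1e6, w["pbs"], s=2, c="steelblue")
    try:
        thr = pbs_threshold(w["pbs"].to_numpy(), top_fraction)
        ax.axhline(thr, ls="--", c="black", lw=0.8)
    except ValueError:
        pass
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("PBS")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
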