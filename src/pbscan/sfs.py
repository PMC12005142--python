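"""Sample-allele-frequency likelihoods and site-frequency-spectrum EM.

For a population of N diploids, the SAF vector at a site is the likelihood
L(j) of observing the data given that the 2N sampled chromosomes carry j
copies of the minor allele, j = 0..2N. It is built by a dynamic program over
individuals: each individual's genotype contributes its GL weighted by the
number of chromosome arrangements, and the final convolution is divided by
C(2N, j) to convert arrangement counts into the conditional likelihood of an
unordered allele count. Values are max-rescaled per site (relative
likelihoods are what the downstream EM consumes).

The (2D-)SFS eta is then estimated by EM over sites assumed independent:
the posterior of the allele-count pair (j, k) at a site is proportional to
eta(j,k) * L1(j) * L2(k), and the M-step sets eta to the mean posterior.
This is the prior required for genotype-likelihood-aware FST.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln


def _log_binom(n, k):
    n, k = np.asarray(n, float), np.asarray(k, float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def saf_site(gl_site: np.ndarray) -> np.ndarray:
    """SAF vector L(0..2N) for one site from an (N x 3) GL matrix."""
    return saf_table(np.asarray(gl_site, dtype=float)[None])[0]


def saf_table(gl: np.ndarray) -> np.ndarray:
    """Vectorized SAF dynamic program for (sites x N x 3) GLs.

    Returns (sites x 2N+1), max-rescaled per site. The recursion is
    q_i(j) = sum_g q_{i-1}(j - g) * GL_i(g) * C(2, g), finishing with
    L(j) = q_N(j) / C(2N, j).
    """
    S, N, _ = gl.shape
    w = np.array([1.0, 2.0, 1.0])  # C(2, g)
    q = np.zeros((S, 2 * N + 1))
    q[:, 0] = 1.0
    width = 0
    for i in range(N):
        new = np.zeros_like(q)
        for g in range(3):
            new[:, g : width + g + 1] += q[:, : width + 1] * (gl[:, i, g] * w[g])[:, None]
        width += 2
        # per-site rescale to dodge underflow; relative likelihoods exact
        new /= new.max(axis=1, keepdims=True)
        q = new
    j = np.arange(2 * N + 1)
    L = q * np.exp(-_log_binom(2 * N, j))[None, :]
    return L / L.max(axis=1, keepdims=True)


@dataclass
class JointSFS:
    """SFS probability array (1D vector or 2D matrix) with EM diagnostics."""

    eta: np.ndarray
    n_sites: int
    loglik: float
    n_iter: int
    loglik_history: np.ndarray = field(default_factory=lambda: np.array([]))


def estimate_sfs_em(
    saf1: np.ndarray,
    saf2: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> JointSFS:
    """EM estimate of the 1D or pairwise 2D site-frequency spectrum.

    ``saf1`` (and optionally ``saf2``) are (sites x 2N+1) SAF tables for the
    same sites. Starts from a uniform spectrum; stops when max|delta eta| <
    tol. Sites whose SAF product is identically zero are excluded. The
    log-likelihood sum_s log sum_jk eta L1 L2 is non-decreasing (EM).
    """
    if saf2 is None:
        return _sfs_em_1d(saf1, tol, max_iter)
    ok = (saf1.max(axis=1) > 0) & (saf2.max(axis=1) > 0)
    if not ok.all():
        import warnings

        warnings.warn(f"excluding {np.sum(~ok)} sites with all-zero SAF")
    L1, L2 = saf1[ok], saf2[ok]
    S = L1.shape[0]
    if S == 0:
        raise ValueError("no usable sites for SFS estimation")
    J, K = L1.shape[1], L2.shape[1]
    eta = np.full((J, K), 1.0 / (J * K))
    history = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        z = np.einsum("sj,jk,sk->s", L1, eta, L2)
        history.append(float(np.log(z).sum()))
        m = np.einsum("sj,sk,s->jk", L1, L2, 1.0 / z)
        eta_new = eta * m / S
        eta_new /= eta_new.sum()  # guard drift; analytically already 1
        delta = np.abs(eta_new - eta).max()
        eta = eta_new
        if delta < tol:
            break
    loglik = float(np.log(np.einsum("sj,jk,sk->s", L1, eta, L2)).sum())
    history.append(loglik)
    return JointSFS(eta=eta, n_sites=S, loglik=loglik, n_iter=n_iter,
                    loglik_history=np.array(history))


def _sfs_em_1d(saf: np.ndarray, tol: float, max_iter: int) -> JointSFS:
    ok = saf.max(axis=1) > 0
    L = saf[ok]
    S, J = L.shape
    eta = np.full(J, 1.0 / J)
    history = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        z = L @ eta
        history.append(float(np.log(z).sum()))
        eta_new = eta * (L / z[:, None]).sum(axis=0) / S
        eta_new /= eta_new.sum()
        delta = np.abs(eta_new - eta).max()
        eta = eta_new
        if delta < tol:
            break
    loglik = float(np.log(L @ eta).sum())
    history.append(loglik)
    return JointSFS(eta=eta, n_sites=S, loglik=loglik, n_iter=n_iter,
                    loglik_history=np.array(history))
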