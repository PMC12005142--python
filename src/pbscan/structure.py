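"""Admixture proportions and PCA from genotype likelihoods.

The admixture model: individual i's allele frequency at site s is
``h_is = sum_k Q_ik F_ks`` and its genotype is Binomial(2, h_is); observed
data enter only through the genotype likelihoods, so the likelihood is

    L(Q, F) = prod_i prod_s sum_g GL_isg * Binom(g; 2, h_is).

Q and F are fit by EM with multiplicative updates (each allele copy carries
a latent ancestry component; the E-step also marginalizes the unknown
genotype through the GLs), run from several random restarts with the best
final likelihood reported — mirroring the common 3-restart / 1000-iteration
protocol for structure inference on low-coverage data.

PCA follows the iterated individual-allele-frequency scheme: expected
genotype dosages under per-individual frequency priors are standardized and
their covariance eigendecomposed; the top principal components refine the
individual frequencies, and the procedure repeats a small fixed number of
times. This keeps low-coverage noise from inflating the diagonal as it would
with naive hard-call PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .gl import GenotypeLikelihoodTable, estimate_maf_table

_F_CLAMP = 1e-6


@dataclass
class AncestryModel:
    Q: np.ndarray  # individuals x K
    F: np.ndarray  # K x sites
    loglik: float
    n_iter: int
    restart_id: int
    loglik_history: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class CovarianceResult:
    C: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    variance_fractions: np.ndarray


def _genotype_prior(h: np.ndarray) -> np.ndarray:
    """(..., 3) HWE genotype probabilities for allele frequencies h."""
    return np.stack([(1 - h) ** 2, 2 * h * (1 - h), h**2], axis=-1)


def admixture_loglik(gl: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    """Log-likelihood of (Q, F) for a (sites x individuals x 3) GL array."""
    h = np.clip(Q @ F, _F_CLAMP, 1 - _F_CLAMP)  # individuals x sites
    lik = (gl.transpose(1, 0, 2) * _genotype_prior(h)).sum(axis=2)
    return float(np.log(lik).sum())


def _admixture_em_single(
    gl: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    record_history: bool = False,
):
    """One EM run. ``gl`` is (sites x individuals x 3)."""
    S, N, _ = gl.shape
    glT = gl.transpose(1, 0, 2)  # individuals x sites x 3
    Q = rng.dirichlet(np.ones(K), size=N)
    F = rng.uniform(0.05, 0.95, size=(K, S))
    history = []
    prev_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        h = np.clip(Q @ F, _F_CLAMP, 1 - _F_CLAMP)  # N x S
        prior = _genotype_prior(h)
        w = glT * prior
        lik = w.sum(axis=2)
        ll = float(np.log(lik).sum())
        if record_history:
            history.append(ll)
        # expected minor-allele dosage per individual/site given GL and h
        e = (w[:, :, 1] + 2.0 * w[:, :, 2]) / lik  # N x S
        # split each expected allele copy across components
        r_min = Q[:, :, None] * F[None, :, :] / h[:, None, :]  # N x K x S
        r_maj = Q[:, :, None] * (1 - F[None, :, :]) / (1 - h[:, None, :])
        a_min = e[:, None, :] * r_min  # expected minor copies from component k
        a_maj = (2.0 - e)[:, None, :] * r_maj
        Q = (a_min + a_maj).sum(axis=2) / (2.0 * S)
        Q /= Q.sum(axis=1, keepdims=True)
        F = np.clip(
            a_min.sum(axis=0) / np.maximum((a_min + a_maj).sum(axis=0), 1e-300),
            _F_CLAMP,
            1 - _F_CLAMP,
        )
        if ll - prev_ll < tol and n_iter > 1:
            break
        prev_ll = ll
    h = np.clip(Q @ F, _F_CLAMP, 1 - _F_CLAMP)
    final_ll = float(np.log((glT * _genotype_prior(h)).sum(axis=2)).sum())
    if record_history:
        history.append(final_ll)
    return Q, F, final_ll, n_iter, np.array(history)


def admixture_em(
    table: GenotypeLikelihoodTable,
    K: int,
    max_iter: int = 1000,
    tol: float = 1e-6,
    n_restarts: int = 3,
    seed: int = 0,
    record_history: bool = False,
) -> AncestryModel:
    """Fit the K-component admixture model; best of ``n_restarts`` by loglik."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > table.n_individuals:
        raise ValueError("K cannot exceed the number of individuals")
    ss = np.random.SeedSequence(seed)
    best = None
    for r, child in enumerate(ss.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        Q, F, ll, n_iter, hist = _admixture_em_single(
            table.gl, K, rng, max_iter, tol, record_history
        )
        if not np.isfinite(ll):
            continue
        if best is None or ll > best.loglik:
            best = AncestryModel(
                Q=Q, F=F, loglik=ll, n_iter=n_iter, restart_id=r, loglik_history=hist
            )
    if best is None:
        raise RuntimeError("all restarts produced non-finite likelihoods")
    return best


def align_labels(model: AncestryModel, reference_Q: np.ndarray) -> AncestryModel:
    """Permute components to best match a reference Q (label switching fix).

    Uses the assignment maximizing sum_k Q[:, perm(k)] . ref[:, k]; fully
    deterministic.
    """
    ref = np.asarray(reference_Q, dtype=float)
    if ref.shape != model.Q.shape:
        raise ValueError("reference Q must match the model's shape")
    cost = -(model.Q.T @ ref)  # K x K
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty_like(rows)
    perm[cols] = rows
    return AncestryModel(
        Q=model.Q[:, perm],
        F=model.F[perm, :],
        loglik=model.loglik,
        n_iter=model.n_iter,
        restart_id=model.restart_id,
        loglik_history=model.loglik_history,
    )


def mean_ancestry_report(model: AncestryModel, population_labels) -> pd.DataFrame:
    """Per-population mean ancestry percentages (rows sum to 100)."""
    labels = np.asarray(population_labels)
    if len(labels) != model.Q.shape[0]:
        raise ValueError("one label per individual required")
    rows = {}
    for lab in pd.unique(labels):
        rows[lab] = model.Q[labels == lab].mean(axis=0) * 100.0
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=[f"component_{k}" for k in range(model.Q.shape[1])])
    out.index.name = "population"
    return out


def pca_covariance(
    table: GenotypeLikelihoodTable,
    maf: np.ndarray | None = None,
    n_iter_indf: int = 2,
    n_pcs: int = 2,
) -> CovarianceResult:
    """GL-aware covariance with iterated individual allele frequencies.

    Iteration 0 uses the site MAF as every individual's frequency prior;
    each refinement projects the standardized expected dosages onto the top
    ``n_pcs`` eigenvectors to form per-individual frequencies. Monomorphic
    sites must have been filtered out beforehand.
    """
    if maf is None:
        maf = estimate_maf_table(table)
    maf = np.asarray(maf, dtype=float)
    if np.any(~np.isfinite(maf)) or np.any(maf <= 0) or np.any(maf >= 1):
        raise ValueError("monomorphic or missing-MAF sites must be filtered before PCA")
    glT = table.gl.transpose(1, 0, 2)  # N x S x 3
    N, S, _ = glT.shape
    g = np.arange(3)
    denom = np.sqrt(2.0 * maf * (1.0 - maf))  # per site

    h = np.broadcast_to(maf, (N, S)).copy()
    C = None
    X = None
    for it in range(n_iter_indf + 1):
        w = glT * _genotype_prior(np.clip(h, 1e-4, 1 - 1e-4))
        e = (w * g).sum(axis=2) / w.sum(axis=2)  # expected dosage, N x S
        X = (e - 2.0 * maf) / denom
        C = (X @ X.T) / S
        if it < n_iter_indf:
            vals, vecs = np.linalg.eigh(C)
            V = vecs[:, ::-1][:, :n_pcs]  # top eigenvectors
            X_hat = V @ (V.T @ X)
            h = np.clip((X_hat * denom + 2.0 * maf) / 2.0, 1e-4, 1 - 1e-4)
    vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    return CovarianceResult(
        C=C,
        eigenvalues=vals,
        eigenvectors=vecs,
        variance_fractions=vals / vals.sum(),
    )
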