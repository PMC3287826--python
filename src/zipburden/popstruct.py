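"""Population structure: genotype PCA, outlier removal, ancestry grouping.

A single PCA on the standardized genotype matrix serves both roles the
field usually splits between MDS (grouping subjects into ancestry
clusters) and Eigenstrat-style PCA (eigenvector covariates for the
regression): each SNP column is centered at twice its allele frequency
and scaled by the binomial standard deviation sqrt(2 f (1 - f)), and
the top-K left singular vectors are the subject scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import MISSING, GenotypeMatrix


@dataclass
class EigenDecomposition:
    """Top-K eigenvectors of the standardized genotype covariance."""

    subjects: list[str]
    vectors: np.ndarray          # N x K, orthonormal columns
    eigenvalues: np.ndarray      # length K, descending
    snps_used: list[str]

    def __post_init__(self) -> None:
        gram = self.vectors.T @ self.vectors
        if not np.allclose(gram, np.eye(self.vectors.shape[1]), atol=1e-8):
            raise ValueError("eigenvectors are not orthonormal")
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(ev < -1e-12) or np.any(np.diff(ev) > 1e-12):
            raise ValueError("eigenvalues must be non-negative and descending")
        self.eigenvalues = np.maximum(ev, 0.0)

    @property
    def k(self) -> int:
        return self.vectors.shape[1]

    def subset(self, subjects: list[str]) -> np.ndarray:
        """Rows of the eigenvector matrix for a subject subset (no
        re-orthonormalisation; used as regression covariates)."""
        index = {s: i for i, s in enumerate(self.subjects)}
        return self.vectors[[index[s] for s in subjects]]


def compute_eigenvectors(geno: GenotypeMatrix, k: int = 10,
                         subset: list[str] | None = None) -> EigenDecomposition:
    """Top-k principal components of the standardized genotype matrix.

    Missing calls are imputed at the column mean (2 f-hat) before
    standardization; monomorphic SNPs are dropped.  Each eigenvector's
    sign is fixed so its largest-magnitude entry is positive, making the
    decomposition fully deterministic.
    """
    rows = geno.subject_indices(subset)
    n = rows.size
    if n < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} subjects, got {n}")
    calls = geno.calls[rows].astype(float)
    calls[geno.calls[rows] == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        f = np.nanmean(calls, axis=0) / 2.0
    poly = np.isfinite(f) & (f > 0.0) & (f < 1.0)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; no structure to estimate")
    calls = calls[:, poly]
    f = f[poly]
    # mean-impute missing, then Eigenstrat standardization
    idx = np.where(np.isnan(calls))
    calls[idx] = (2.0 * f)[idx[1]]
    Z = (calls - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    U, s = U[:, :k], s[:k]
    # sign convention: largest-|entry| positive
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    eigenvalues = s ** 2 / Z.shape[1]
    snps_used = [snp for snp, keep in zip(geno.snps, poly) if keep]
    subjects = [geno.subjects[i] for i in rows]
    return EigenDecomposition(subjects=subjects, vectors=U,
                              eigenvalues=eigenvalues, snps_used=snps_used)


def detect_outliers(eig: EigenDecomposition, sd_threshold: float = 6.0,
                    n_iterations: int = 5, geno: GenotypeMatrix | None = None,
                    k: int | None = None) -> list[str]:
    """Subjects lying beyond ``sd_threshold`` standard deviations from the
    mean on any top principal component.

    With ``geno`` supplied, removal is iterative: flagged subjects are
    dropped and the decomposition recomputed, up to ``n_iterations``
    rounds (the usual convention for genotype-PCA outlier pruning).
    Without it, a single pass on the given decomposition is performed.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be positive")
    k = k if k is not None else eig.k
    outliers: list[str] = []
    current = eig
    remaining = list(eig.subjects)
    for _ in range(max(1, n_iterations)):
        V = current.vectors[:, :k]
        sd = V.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        dev = np.abs(V - V.mean(axis=0)) / sd
        flagged = np.where((dev > sd_threshold).any(axis=1))[0]
        if flagged.size == 0:
            break
        newly = [current.subjects[i] for i in flagged]
        outliers.extend(newly)
        remaining = [s for s in remaining if s not in set(newly)]
        if not remaining:
            raise ValueError("outlier removal would empty the sample")
        if geno is None:
            break
        if len(remaining) < current.k + 1:
            break
        current = compute_eigenvectors(geno, current.k, subset=remaining)
    return outliers


def assign_groups(eig: EigenDecomposition, n_groups: int | None = None,
                  labels: dict[str, str] | None = None,
                  seed: int = 0) -> dict[str, str]:
    """Partition subjects into ancestry groups.

    Either pass through user-provided ``labels`` verbatim, or run
    k-means (fixed seed, 10 restarts) on the top-2 principal
    components.  Group labels are "G0", "G1", ... ordered by mean PC1
    so the labelling is deterministic.
    """
    if labels is not None:
        missing = set(eig.subjects) - set(labels)
        if missing:
            raise ValueError(f"labels missing for subjects: {sorted(missing)[:5]}")
        return {s: labels[s] for s in eig.subjects}
    if n_groups is None or n_groups < 1:
        raise ValueError("n_groups must be >= 1 when labels are not given")
    n = len(eig.subjects)
    if n_groups > n:
        raise ValueError(f"n_groups = {n_groups} exceeds N = {n}")
    if n_groups == 1:
        return {s: "G0" for s in eig.subjects}
    coords = eig.vectors[:, : min(2, eig.k)]
    km = KMeans(n_clusters=n_groups, n_init=10, random_state=seed)
    raw = km.fit_predict(coords)
    # relabel clusters by ascending mean PC1 for determinism
    order = np.argsort([coords[raw == c, 0].mean() for c in range(n_groups)])
    relabel = {int(c): f"G{rank}" for rank, c in enumerate(order)}
    return {s: relabel[int(c)] for s, c in zip(eig.subjects, raw)}


def write_eigenvectors(eig: EigenDecomposition, path: str | Path) -> None:
    cols = {f"PC{j + 1}": eig.vectors[:, j] for j in range(eig.k)}
    df = pd.DataFrame(cols, index=pd.Index(eig.subjects, name="subject"))
    df.to_csv(path, sep="\t")


def read_eigenvectors(path: str | Path) -> EigenDecomposition:
    """Read subject scores written by :func:`write_eigenvectors` (or any
    external tool emitting the same subject + PC1..PCK TSV layout).

    Re-orthonormalises via QR so externally computed covariates satisfy
    the container's invariant; test p-values are unaffected because the
    covariate column space is preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    V = df.to_numpy(dtype=float)
    Q, R = np.linalg.qr(V)
    Q = Q * np.sign(np.diag(R))[None, :]
    for j in range(Q.shape[1]):
        i = int(np.argmax(np.abs(Q[:, j])))
        if Q[i, j] < 0:
            Q[:, j] = -Q[:, j]
    ev = np.sort((V ** 2).sum(axis=0))[::-1]
    return EigenDecomposition(subjects=[str(s) for s in df.index], vectors=Q,
                              eigenvalues=ev, snps_used=[])
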