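"""Genomic relationship matrix, its Cholesky factor, and covariate blocks.

The GRM is the VanRaden-style cross-product G = Wc Wc' / p of the
(column-centered) J x p marker matrix.  Its Cholesky factor L gives J
genomic covariates per line: ridge regression on the rows of L is exactly
GBLUP with covariance G, which is why both the mixed model and the neural
network can share one covariate construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg


@dataclass
class MarkerMatrix:
    """J x p numeric marker codes with line and marker labels (no missing entries)."""

    values: np.ndarray
    line_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("marker matrix must be 2-D")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 lines")
        if self.values.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("marker matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("marker matrix contains missing or non-finite entries")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass
class GenomicRelationship:
    """J x J symmetric PSD relationship matrix with line labels."""

    values: np.ndarray
    line_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        J = len(self.line_ids)
        if self.values.shape != (J, J):
            raise ValueError("GRM shape does not match line labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM is not symmetric (tolerance 1e-10)")

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]

    def mean_diag(self) -> float:
        return float(np.mean(np.diag(self.values)))


@dataclass
class CholeskyFactor:
    """Lower-triangular L with L L' = G + jitter * I; jitter_used records the repair."""

    values: np.ndarray
    line_ids: list[str]
    jitter_used: float = 0.0

    @property
    def n_lines(self) -> int:
        return self.values.shape[0]


@dataclass
class DesignMatrices:
    """Covariate blocks shared by GBLUP and the network, one row per phenotype cell.

    env_block:  one-hot environment indicators (no intercept column).
    geno_block: row j of L for a cell of line j.
    gxe_block:  environment-wise copies of geno_block, zero outside the
                cell's own environment block (absent when G*E is excluded).
    """

    env_block: np.ndarray
    geno_block: np.ndarray
    gxe_block: np.ndarray | None
    cell_index: list[tuple[str, str]]
    env_labels: list[str]
    line_labels: list[str]

    def full_matrix(self) -> np.ndarray:
        blocks = [self.env_block, self.geno_block]
        if self.gxe_block is not None:
            blocks.append(self.gxe_block)
        return np.hstack(blocks)

    @property
    def n_features(self) -> int:
        n = self.env_block.shape[1] + self.geno_block.shape[1]
        if self.gxe_block is not None:
            n += self.gxe_block.shape[1]
        return n


def compute_grm(W: MarkerMatrix, center: bool = True, vanraden_scale: bool = False) -> GenomicRelationship:
    """Genomic relationship matrix G = Wc Wc' / p from marker codes.

    Parameters
    ----------
    W
        J x p marker matrix (codes 0/1/2 or real-valued).
    center
        Column-center markers before the cross-product (default).  With
        ``center=False`` the raw codes are used, which conflates allele
        coding with relatedness but replicates the literal W W' / p.
    vanraden_scale
        Divide by 2 * sum_k p_k (1 - p_k) instead of the marker count p,
        where p_k is the allele frequency of marker k estimated from the
        codes.  Only meaningful for 0/1/2 coding.
    """
    if W.n_markers == 0:
        raise ValueError("marker matrix has no markers")
    X = W.values.astype(float)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if vanraden_scale:
        freq = W.values.mean(axis=0) / 2.0
        denom = 2.0 * float(np.sum(freq * (1.0 - freq)))
        if denom == 0.0:
            warnings.warn("all markers monomorphic; zero GRM returned", stacklevel=2)
            return GenomicRelationship(values=np.zeros((W.n_lines, W.n_lines)), line_ids=list(W.line_ids))
    else:
        denom = float(W.n_markers)
    G = (X @ X.T) / denom
    G = 0.5 * (G + G.T)  # exact symmetry against rounding
    if np.allclose(G, 0.0):
        warnings.warn("constant marker matrix yields a zero GRM", stacklevel=2)
    return GenomicRelationship(values=G, line_ids=list(W.line_ids))


def cholesky_factor(G: GenomicRelationship, max_jitter_scale: float = 1e-6) -> CholeskyFactor:
    """Lower Cholesky factor of G, with escalating diagonal jitter for PSD repair.

    A plain factorization is attempted first.  On failure, jitter
    eps * mean(diag(G)) * I is added with eps escalating from 1e-10 to
    ``max_jitter_scale`` in decade steps.  The jitter actually used is
    recorded so callers can see how far G was from numerically PD.
    """
    A = G.values
    scale = G.mean_diag()
    if scale <= 0:
        scale = 1.0
    try:
        L = np.linalg.cholesky(A)
        return CholeskyFactor(values=L, line_ids=list(G.line_ids), jitter_used=0.0)
    except np.linalg.LinAlgError:
        pass
    eps = 1e-10
    while eps <= max_jitter_scale * (1 + 1e-12):
        jitter = eps * scale
        try:
            L = np.linalg.cholesky(A + jitter * np.eye(A.shape[0]))
            return CholeskyFactor(values=L, line_ids=list(G.line_ids), jitter_used=jitter)
        except np.linalg.LinAlgError:
            eps *= 10.0
    min_eig = float(scipy.linalg.eigvalsh(A, subset_by_index=[0, 0])[0])
    raise np.linalg.LinAlgError(
        f"GRM is not positive semi-definite even after jitter up to {max_jitter_scale * scale:.3g} "
        f"(minimum eigenvalue {min_eig:.3g})"
    )


def build_design(
    cells: list[tuple[str, str]],
    L: CholeskyFactor,
    env_labels: list[str],
    include_gxe: bool = True,
) -> DesignMatrices:
    """Assemble environment / genomic / G*E covariate blocks for a list of cells.

    Cell (line j, env i) gets a one-hot row for env i, row j of L as the
    genomic covariates, and — with ``include_gxe`` — a copy of that L row in
    the i-th of I column blocks of width J, zero elsewhere.  Total width is
    I + J (+ I*J).
    """
    line_pos = {lid: k for k, lid in enumerate(L.line_ids)}
    env_pos = {env: k for k, env in enumerate(env_labels)}
    n = len(cells)
    I, J = len(env_labels), L.n_lines
    env_block = np.zeros((n, I))
    geno_block = np.zeros((n, J))
    gxe_block = np.zeros((n, I * J)) if include_gxe else None
    for r, (line, env) in enumerate(cells):
        if line not in line_pos:
            raise KeyError(f"line {line!r} has no row in the Cholesky factor")
        if env not in env_pos:
            raise KeyError(f"environment {env!r} not in the environment list {env_labels}")
        j, i = line_pos[line], env_pos[env]
        env_block[r, i] = 1.0
        geno_block[r, :] = L.values[j, :]
        if gxe_block is not None:
            gxe_block[r, i * J : (i + 1) * J] = L.values[j, :]
    return DesignMatrices(
        env_block=env_block,
        geno_block=geno_block,
        gxe_block=gxe_block,
        cell_index=list(cells),
        env_labels=list(env_labels),
        line_labels=list(L.line_ids),
    )
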