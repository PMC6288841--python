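"""Synthetic marker and multi-environment phenotype generator.

Phenotypes follow the same generative model the estimators assume:

    y_ij = E_i + g_j + gE_ij + e_ij

with g ~ N(0, var_g * G), gE ~ N(0, var_ge * I_I (x) G) and i.i.d. residuals
e_ij ~ N(0, var_e), where G is the genomic relationship matrix computed from
the simulated markers.  Markers are independent biallelic SNPs with allele
frequencies drawn uniformly from a configurable MAF range — no linkage
disequilibrium, pedigree, or selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gxepred.io import PhenotypeTable
from gxepred.kinship import GenomicRelationship, MarkerMatrix, cholesky_factor, compute_grm


@dataclass
class SimConfig:
    """Generative parameters for one simulated multi-environment trial.

    env_means are the fixed per-environment means E_i (trait units);
    var_g, var_ge, var_e are the genomic, interaction and residual variance
    components (trait units squared).
    """

    n_lines: int
    n_envs: int
    n_markers: int
    env_means: np.ndarray | list[float] | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    var_g: float = 1.0
    var_ge: float = 0.5
    var_e: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("need at least 2 lines")
        if self.n_envs < 1:
            raise ValueError("need at least 1 environment")
        if self.n_markers < 1:
            raise ValueError("need at least 1 marker")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} must lie within (0, 0.5]")
        for name in ("var_g", "var_ge", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.env_means is None:
            self.env_means = np.zeros(self.n_envs)
        self.env_means = np.asarray(self.env_means, dtype=float)
        if self.env_means.shape != (self.n_envs,):
            raise ValueError(f"env_means must have length n_envs={self.n_envs}")


@dataclass
class SimulatedDataset:
    """Markers, phenotypes, and the latent truth behind them."""

    markers: MarkerMatrix
    phenotypes: PhenotypeTable
    grm: GenomicRelationship
    true_g: np.ndarray  # length J
    true_ge: np.ndarray  # I x J
    true_h2: np.ndarray  # length I, in [0, 1]


def simulate_markers(
    J: int, p: int, maf_range: tuple[float, float] = (0.05, 0.5), seed: int = 0
) -> MarkerMatrix:
    """Simulate a J x p matrix of 0/1/2 SNP codes.

    Marker k has an allele frequency f_k ~ Uniform(maf_range) and codes
    Binomial(2, f_k) across lines.  Monomorphic columns are redrawn (new
    frequency and new codes) so the returned matrix has exactly p
    polymorphic markers.
    """
    if J < 2 or p < 1:
        raise ValueError("need J >= 2 lines and p >= 1 markers")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range {maf_range} must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)
    W = np.empty((J, p), dtype=float)
    for k in range(p):
        while True:
            f = rng.uniform(lo, hi)
            col = rng.binomial(2, f, size=J).astype(float)
            if col.min() != col.max():
                W[:, k] = col
                break
    line_ids = [f"L{j + 1:04d}" for j in range(J)]
    marker_ids = [f"M{k + 1:05d}" for k in range(p)]
    return MarkerMatrix(values=W, line_ids=line_ids, marker_ids=marker_ids)


def true_heritability(cfg: SimConfig, Gg: GenomicRelationship) -> np.ndarray:
    """Per-environment broad-sense heritability implied by the generative model.

    With mean GRM diagonal d, each environment has genetic variance
    (var_g + var_ge) * d and total variance (var_g + var_ge) * d + var_e, so

        h2_i = ((var_g + var_ge) * d) / ((var_g + var_ge) * d + var_e)

    identical across environments because the variance components are shared.
    """
    if cfg.var_g == 0 and cfg.var_ge == 0 and cfg.var_e == 0:
        raise ValueError("heritability undefined: all variance components are zero")
    d = Gg.mean_diag()
    genetic = (cfg.var_g + cfg.var_ge) * d
    if genetic == 0:
        raise ValueError("heritability undefined: no genetic variance (var_g = var_ge = 0)")
    h2 = genetic / (genetic + cfg.var_e)
    return np.full(cfg.n_envs, h2)


def simulate_phenotypes(markers: MarkerMatrix, cfg: SimConfig) -> SimulatedDataset:
    """Draw phenotypes for every (line, environment) cell under the mixed model.

    The genomic effects use the (jitter-repaired) Cholesky factor of the GRM
    computed from ``markers``; the I blocks of the interaction effect are
    drawn as independent N(0, var_ge * G) vectors, which is the same
    distribution as the block-diagonal I (x) G covariance without ever
    materialising an (I*J) x (I*J) matrix.
    """
    if markers.n_lines != cfg.n_lines:
        raise ValueError(f"marker matrix has {markers.n_lines} lines but config says {cfg.n_lines}")
    rng = np.random.default_rng(cfg.seed)
    G = compute_grm(markers)
    L = cholesky_factor(G)
    J, I = cfg.n_lines, cfg.n_envs
    g = np.sqrt(cfg.var_g) * (L.values @ rng.standard_normal(J))
    gE = np.empty((I, J))
    for i in range(I):
        gE[i] = np.sqrt(cfg.var_ge) * (L.values @ rng.standard_normal(J))
    e = np.sqrt(cfg.var_e) * rng.standard_normal((I, J))
    env_ids = [f"E{i + 1}" for i in range(I)]
    rows = []
    for i in range(I):
        for j in range(J):
            rows.append(
                (markers.line_ids[j], env_ids[i], cfg.env_means[i] + g[j] + gE[i, j] + e[i, j])
            )
    records = pd.DataFrame(rows, columns=["line", "env", "value"])
    phenotypes = PhenotypeTable(lines=list(markers.line_ids), envs=env_ids, records=records)
    if cfg.var_g + cfg.var_ge > 0:
        h2 = true_heritability(cfg, G)
    else:
        h2 = np.zeros(I)  # no genetic signal: h2 = 0 by convention inside the simulator
    return SimulatedDataset(
        markers=markers, phenotypes=phenotypes, grm=G, true_g=g, true_ge=gE, true_h2=h2
    )


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Markers plus phenotypes in one call, both driven by cfg.seed."""
    markers = simulate_markers(cfg.n_lines, cfg.n_markers, cfg.maf_range, seed=cfg.seed)
    return simulate_phenotypes(markers, cfg)
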