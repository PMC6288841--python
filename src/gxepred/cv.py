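"""Nested random cross-validation over (line, environment) cells.

The outer loop mimics incomplete field trials: a fixed fraction of cells is
held out by sampling lines (without replacement when there are enough
distinct lines, with replacement otherwise) and picking one environment per
sampled line, so a line may be tested in some environments while training in
others.  The inner loop carves 20% off each outer training set to select
the network's units/epochs/layers by full-factorial grid search; GBLUP has
no tuned hyperparameters and uses the full outer training set directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from gxepred.densenet import NetConfig, init_network, predict_net, train_network
from gxepred.gblup import fit_gblup, predict_gblup
from gxepred.io import PhenotypeTable
from gxepred.kinship import GenomicRelationship, build_design, cholesky_factor
from gxepred.metrics import AccuracyTable, adjust_by_heritability, aggregate_accuracy, pearson

logger = logging.getLogger(__name__)

Cell = tuple[str, str]


@dataclass
class CVPartition:
    """One outer train/test split of the N = J*I cells."""

    trn_cells: list[Cell]
    tst_cells: list[Cell]
    seed: int
    replicate_index: int = 1

    def __post_init__(self) -> None:
        trn, tst = set(self.trn_cells), set(self.tst_cells)
        if trn & tst:
            raise ValueError("training and testing cells overlap")


@dataclass
class HyperGrid:
    """Full-factorial levels for units, epochs and layers.

    The default levels span the ranges that matter for small breeding data
    sets: 6 unit levels x 5 epoch levels x 3 layer levels = 90
    configurations.
    """

    unit_levels: list[int] = field(default_factory=lambda: [50, 60, 70, 80, 90, 100])
    epoch_levels: list[int] = field(default_factory=lambda: [20, 40, 60, 80, 100])
    layer_levels: list[int] = field(default_factory=lambda: [1, 2, 3])

    def __post_init__(self) -> None:
        for name in ("unit_levels", "epoch_levels", "layer_levels"):
            levels = getattr(self, name)
            if not levels:
                raise ValueError(f"{name} must be non-empty")
            if any((not isinstance(v, (int, np.integer))) or v < 1 for v in levels):
                raise ValueError(f"{name} must contain positive integers")

    @property
    def n_configs(self) -> int:
        return len(self.unit_levels) * len(self.epoch_levels) * len(self.layer_levels)


def outer_partition(lines: list[str], envs: list[str], p_test: float, seed: int) -> CVPartition:
    """Random cell partition holding out round(p_test * N) cells.

    Lines are drawn without replacement when J >= p_test * N and with
    replacement otherwise; each drawn line contributes one uniformly chosen
    environment.  Duplicate cells under with-replacement sampling are
    redrawn so the test set has exactly its nominal size.
    """
    if not (0.0 <= p_test < 1.0):
        raise ValueError(f"p_test must lie in [0, 1), got {p_test}")
    J, I = len(lines), len(envs)
    N = J * I
    n_tst = int(round(p_test * N))
    rng = np.random.default_rng(seed)
    tst: list[Cell] = []
    if n_tst > 0:
        if J >= p_test * N:  # enough distinct lines: sample without replacement
            picked = rng.choice(J, size=n_tst, replace=False)
            for j in picked:
                tst.append((lines[j], envs[rng.integers(I)]))
        else:
            chosen: set[Cell] = set()
            while len(chosen) < n_tst:
                cell = (lines[rng.integers(J)], envs[rng.integers(I)])
                if cell not in chosen:  # duplicate draws are discarded and redrawn
                    chosen.add(cell)
                    tst.append(cell)
    tst_set = set(tst)
    trn = [(l, e) for l in lines for e in envs if (l, e) not in tst_set]
    return CVPartition(trn_cells=trn, tst_cells=tst, seed=seed)


def inner_split(trn: list, val_fraction: float, seed: int) -> tuple[list, list]:
    """Random disjoint (training-inner, testing-inner) split of the outer training set."""
    if not (0.0 < val_fraction < 1.0):
        raise ValueError(f"val_fraction must lie in (0, 1), got {val_fraction}")
    if len(trn) < 5:
        raise ValueError(f"outer training set too small to split ({len(trn)} cells)")
    n_val = int(round(val_fraction * len(trn)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trn))
    test_inner = [trn[i] for i in order[:n_val]]
    train_inner = [trn[i] for i in order[n_val:]]
    return train_inner, test_inner


def enumerate_grid(grid: HyperGrid, **config_overrides) -> list[NetConfig]:
    """Full factorial NetConfig list, units varying slowest, layers fastest."""
    configs = []
    for u, e, l in product(grid.unit_levels, grid.epoch_levels, grid.layer_levels):
        configs.append(NetConfig(n_units=int(u), n_epochs=int(e), n_layers=int(l), **config_overrides))
    return configs


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: HyperGrid,
    seed: int,
    val_fraction: float = 0.2,
    scorer=None,
    **config_overrides,
):
    """Select the network configuration with minimal validation MSE.

    Each candidate trains on the training-inner rows and is scored on the
    testing-inner rows; ties go to the earlier configuration in enumeration
    order.  ``scorer(cfg) -> float`` replaces the train-and-score step when
    supplied (used for deterministic testing of the selection logic).
    Returns (best config, per-config scores, the model trained under the
    best config on training-inner, the inner row split).
    """
    configs = enumerate_grid(grid, **{"seed": seed, **config_overrides})
    rows = list(range(len(y)))
    train_rows, val_rows = inner_split(rows, val_fraction, seed)
    scores: list[float] = []
    models: list = []
    for cfg in configs:
        if scorer is not None:
            scores.append(float(scorer(cfg)))
            models.append(None)
            continue
        state = init_network(X.shape[1], cfg)
        trained, _ = train_network(state, X[train_rows], y[train_rows], cfg)
        pred = predict_net(trained, X[val_rows])
        scores.append(float(np.mean((pred - y[val_rows]) ** 2)))
        models.append(trained)
    finite = np.isfinite(scores)
    if not finite.any():
        raise RuntimeError("every grid configuration produced a non-finite validation loss")
    best_idx = int(np.argmin(np.where(finite, scores, np.inf)))
    return configs[best_idx], scores, models[best_idx], (train_rows, val_rows)


def _as_h2_map(h2, envs: list[str]) -> dict[str, float]:
    if isinstance(h2, dict):
        mapping = {str(k): float(v) for k, v in h2.items()}
    else:
        vals = np.asarray(h2, dtype=float)
        if vals.shape != (len(envs),):
            raise ValueError(f"h2 vector must have one entry per environment ({len(envs)})")
        mapping = dict(zip(envs, vals.tolist()))
    for env in envs:
        if env not in mapping:
            raise ValueError(f"no heritability supplied for environment {env!r}")
        if not (0.0 < mapping[env] <= 1.0):
            raise ValueError(f"h2 for {env!r} must lie in (0, 1], got {mapping[env]}")
    return mapping


def run_nested_cv(
    data: PhenotypeTable,
    G: GenomicRelationship,
    models: list[tuple[str, bool]],
    n_outer: int = 10,
    p_test: float = 0.35,
    grid: HyperGrid | None = None,
    h2=None,
    base_seed: int = 0,
    val_fraction: float = 0.2,
    refit: bool = False,
    net_defaults: dict | None = None,
) -> tuple[AccuracyTable, AccuracyTable]:
    """Full nested cross-validation driver for any mix of GBLUP and network models.

    ``models`` holds (kind, include_gxe) pairs with kind in {"gblup", "dnn"}.
    For each of ``n_outer`` outer replicates (seeded base_seed + r) the
    network's hyperparameters are tuned by grid search on an inner split of
    the training cells; the tuned network trained on training-inner predicts
    the outer test set (set ``refit=True`` to refit it on the full outer
    training set first).  GBLUP is fit by REML on the full outer training
    set.  Per-environment Pearson correlations on the test cells are divided
    by sqrt(h2) and averaged over replicates.

    Returns (adjusted accuracy table, raw accuracy table).
    """
    if grid is None:
        grid = HyperGrid()
    if h2 is None:
        raise ValueError("per-environment heritabilities are required to adjust accuracies")
    h2_map = _as_h2_map(h2, data.envs)
    net_defaults = net_defaults or {}
    for kind, _ in models:
        if kind not in ("gblup", "dnn"):
            raise ValueError(f"unknown model kind {kind!r}")

    L = cholesky_factor(G)
    adjusted: list[tuple[str, str, float]] = []
    raw: list[tuple[str, str, float]] = []
    for r in range(1, n_outer + 1):
        seed_r = base_seed + r
        part = outer_partition(data.lines, data.envs, p_test, seed_r)
        part.replicate_index = r
        trn = data.subset(part.trn_cells)
        tst = data.subset(part.tst_cells)
        y_tst = tst.values()
        for kind, include_gxe in models:
            label = kind + ("+gxe" if include_gxe else "")
            if kind == "gblup":
                model = fit_gblup(trn, G, include_gxe=include_gxe)
                preds = predict_gblup(model, part.tst_cells)
            else:
                design_trn = build_design(part.trn_cells, L, data.envs, include_gxe=include_gxe)
                design_tst = build_design(part.tst_cells, L, data.envs, include_gxe=include_gxe)
                X_trn, y_trn = design_trn.full_matrix(), trn.values()
                best_cfg, _scores, best_model, _split = grid_search(
                    X_trn, y_trn, grid, seed_r, val_fraction, **net_defaults
                )
                if refit:
                    state = init_network(X_trn.shape[1], best_cfg)
                    best_model, _ = train_network(state, X_trn, y_trn, best_cfg)
                preds = predict_net(best_model, design_tst.full_matrix())
            for i, env in enumerate(data.envs):
                mask = (tst.records["env"] == env).to_numpy()
                if mask.sum() < 3:
                    logger.warning(
                        "replicate %d: environment %s has %d test cells; correlation skipped",
                        r, env, int(mask.sum()),
                    )
                    continue
                try:
                    r_env = pearson(y_tst[mask], preds[mask])
                except ValueError as exc:
                    logger.warning("replicate %d: environment %s skipped (%s)", r, env, exc)
                    continue
                raw.append((label, env, r_env))
                adjusted.append((label, env, adjust_by_heritability(r_env, h2_map[env])))
    return aggregate_accuracy(adjusted), aggregate_accuracy(raw)
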