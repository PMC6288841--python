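"""GBLUP mixed model for multi-environment phenotypes.

The model is y_ij = E_i + g_j (+ gE_ij) + e_ij with g ~ N(0, var_g * G),
gE ~ N(0, var_ge * I (x) G) and i.i.d. residuals.  Variance components are
estimated by REML: the residual variance is profiled out analytically and
the restricted likelihood is maximised over the variance ratios
gamma_k = var_k / var_e in log space.  Fixed effects are re-solved by
generalised least squares at every likelihood evaluation, and BLUPs follow
from the standard conditional-expectation formulas, so predictions are
available for any line with a GRM row — including lines never phenotyped,
through their relatedness to the training lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from gxepred.io import PhenotypeTable
from gxepred.kinship import GenomicRelationship

# search space for variance ratios gamma = var_component / var_residual
_LOG10_GAMMA_MIN = -6.0
_LOG10_GAMMA_MAX = 6.0


@dataclass
class VarianceComponents:
    var_g: float
    var_e: float
    var_ge: float | None = None

    def __post_init__(self) -> None:
        if self.var_g < 0 or (self.var_ge is not None and self.var_ge < 0):
            raise ValueError("variance components must be non-negative")
        if self.var_e <= 0:
            raise ValueError("residual variance must be strictly positive")


@dataclass
class GBLUPModel:
    """Fitted model: environment means, BLUPs, and variance components."""

    beta: np.ndarray  # length I, fixed environment effects
    u_g: np.ndarray  # length J, genomic BLUPs (all GRM lines)
    u_ge: np.ndarray | None  # I x J interaction BLUPs, or None
    vc: VarianceComponents
    include_gxe: bool
    env_labels: list[str]
    line_ids: list[str]
    reml_info: dict | None = None

    def _env_pos(self, env: str) -> int:
        try:
            return self.env_labels.index(env)
        except ValueError:
            raise KeyError(f"environment {env!r} was not in the training environments") from None

    def _line_pos(self, line: str) -> int:
        try:
            return self.line_ids.index(line)
        except ValueError:
            raise KeyError(f"line {line!r} has no GRM row in this model") from None


def _training_arrays(train: PhenotypeTable, G: GenomicRelationship):
    """Index training cells against the GRM and build the kernel matrices."""
    line_pos = {lid: k for k, lid in enumerate(G.line_ids)}
    cells = train.cells()
    for line, _ in cells:
        if line not in line_pos:
            raise KeyError(f"training line {line!r} has no GRM row")
    env_labels = list(train.envs)
    counts = train.records["env"].value_counts()
    for env in env_labels:
        if counts.get(env, 0) == 0:
            raise ValueError(f"environment {env!r} has no training records; cannot estimate its mean")
        if counts.get(env, 0) < 2:
            raise ValueError(f"environment {env!r} has fewer than 2 training records")
    jidx = np.array([line_pos[line] for line, _ in cells])
    eidx = np.array([env_labels.index(env) for _, env in cells])
    y = train.values()
    n, I = len(y), len(env_labels)
    X = np.zeros((n, I))
    X[np.arange(n), eidx] = 1.0
    K1 = G.values[np.ix_(jidx, jidx)]
    K2 = K1 * (eidx[:, None] == eidx[None, :])
    return y, X, K1, K2, jidx, eidx, env_labels


def _reml_neg2ll(log10_gamma: np.ndarray, y: np.ndarray, X: np.ndarray, kernels: list[np.ndarray]) -> float:
    """-2 x restricted log-likelihood with the residual variance profiled out.

    H = I + sum_k gamma_k K_k;  -2 REML ll (up to a constant) is
    (n - q) log(y' P y) + log|H| + log|X' H^-1 X|.
    """
    n, q = X.shape
    gamma = 10.0 ** np.asarray(log10_gamma, dtype=float)
    H = np.eye(n)
    for g, K in zip(gamma, kernels):
        H = H + g * K
    try:
        cho = scipy.linalg.cho_factor(H, lower=True, check_finite=False)
    except scipy.linalg.LinAlgError:
        return np.inf
    logdet_H = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    Hinv_y = scipy.linalg.cho_solve(cho, y, check_finite=False)
    Hinv_X = scipy.linalg.cho_solve(cho, X, check_finite=False)
    XtHiX = X.T @ Hinv_X
    sign, logdet_XtHiX = np.linalg.slogdet(XtHiX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtHiX, X.T @ Hinv_y)
    ypy = float(y @ Hinv_y - (X.T @ Hinv_y) @ beta)
    if ypy <= 0:
        return np.inf
    return (n - q) * np.log(ypy / (n - q)) + logdet_H + logdet_XtHiX


def _optimize_reml(y, X, kernels):
    """Maximise the restricted likelihood over log10 variance ratios."""
    d = len(kernels)
    bounds = [(_LOG10_GAMMA_MIN, _LOG10_GAMMA_MAX)] * d
    starts = [np.zeros(d), np.full(d, -3.0)]
    best = None
    for x0 in starts:
        res = scipy.optimize.minimize(
            _reml_neg2ll,
            x0,
            args=(y, X, kernels),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_gblup(
    train: PhenotypeTable,
    G: GenomicRelationship,
    include_gxe: bool = True,
    fixed_vc: VarianceComponents | None = None,
) -> GBLUPModel:
    """Fit environment means plus genomic (and optional G*E) random effects.

    With ``fixed_vc`` the variance components are taken as given and only
    the GLS fixed effects and BLUPs are computed; otherwise the variance
    ratios are estimated by REML first.
    """
    if train.n_records == 0:
        raise ValueError("empty training set")
    y, X, K1, K2, jidx, eidx, env_labels = _training_arrays(train, G)
    kernels = [K1, K2] if include_gxe else [K1]
    n = len(y)
    reml_info = None
    if fixed_vc is not None:
        if include_gxe and fixed_vc.var_ge is None:
            raise ValueError("include_gxe=True requires var_ge in fixed_vc")
        gamma = [fixed_vc.var_g / fixed_vc.var_e]
        if include_gxe:
            gamma.append(fixed_vc.var_ge / fixed_vc.var_e)
        gamma = np.asarray(gamma)
        vc = fixed_vc
    else:
        res = _optimize_reml(y, X, kernels)
        if not np.isfinite(res.fun):
            raise RuntimeError("REML optimisation failed: restricted likelihood not finite")
        gamma = 10.0 ** res.x
        # profile residual variance at the optimum
        H = np.eye(n)
        for g, K in zip(gamma, kernels):
            H = H + g * K
        cho = scipy.linalg.cho_factor(H, lower=True, check_finite=False)
        Hinv_y = scipy.linalg.cho_solve(cho, y, check_finite=False)
        Hinv_X = scipy.linalg.cho_solve(cho, X, check_finite=False)
        XtHiX = X.T @ Hinv_X
        beta_tmp = np.linalg.solve(XtHiX, X.T @ Hinv_y)
        var_e = float(y @ Hinv_y - (X.T @ Hinv_y) @ beta_tmp) / (n - X.shape[1])
        vc = VarianceComponents(
            var_g=float(gamma[0] * var_e),
            var_e=var_e,
            var_ge=float(gamma[1] * var_e) if include_gxe else None,
        )
        reml_info = {
            "neg2ll": float(res.fun),
            "log10_gamma": [float(v) for v in res.x],
            "converged": bool(res.success),
            "n_evals": int(res.nfev),
        }

    H = np.eye(n)
    for g, K in zip(gamma, kernels):
        H = H + g * K
    cho = scipy.linalg.cho_factor(H, lower=True, check_finite=False)
    Hinv_y = scipy.linalg.cho_solve(cho, y, check_finite=False)
    Hinv_X = scipy.linalg.cho_solve(cho, X, check_finite=False)
    XtHiX = X.T @ Hinv_X
    try:
        beta = np.linalg.solve(XtHiX, X.T @ Hinv_y)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular fixed-effects block (an environment lacks training data)") from exc
    resid = y - X @ beta
    w = scipy.linalg.cho_solve(cho, resid, check_finite=False)  # H^-1 (y - X beta)

    # BLUPs: u_g = gamma_1 * G Z' w over all GRM lines
    J = G.n_lines
    Zt_w = np.zeros(J)
    np.add.at(Zt_w, jidx, w)
    u_g = gamma[0] * (G.values @ Zt_w)
    u_ge = None
    if include_gxe:
        I = len(env_labels)
        u_ge = np.zeros((I, J))
        for i in range(I):
            mask = eidx == i
            Zt_wi = np.zeros(J)
            np.add.at(Zt_wi, jidx[mask], w[mask])
            u_ge[i] = gamma[1] * (G.values @ Zt_wi)
    return GBLUPModel(
        beta=beta,
        u_g=u_g,
        u_ge=u_ge,
        vc=vc,
        include_gxe=include_gxe,
        env_labels=env_labels,
        line_ids=list(G.line_ids),
        reml_info=reml_info,
    )


def predict_gblup(model: GBLUPModel, cells: list[tuple[str, str]]) -> np.ndarray:
    """Point predictions beta_i + u_g[j] (+ u_ge[i, j]) for the given cells."""
    preds = np.empty(len(cells))
    for r, (line, env) in enumerate(cells):
        i = model._env_pos(env)
        j = model._line_pos(line)
        val = model.beta[i] + model.u_g[j]
        if model.include_gxe and model.u_ge is not None:
            val += model.u_ge[i, j]
        preds[r] = val
    return preds
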