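"""Discretized generalized Lotka-Volterra (gLV) inference and prediction.

The gLV equations are discretized per consecutive sample pair as

    (ln x_i(t+dt) - ln x_i(t)) / dt = beta_i + sum_j alpha_ij x_j(t)

which in matrix form reads ``F = (A B) Y`` with ``F`` the per-interval
log-abundance rates (already normalized by the time difference, since
longitudinal microbiome sampling is irregular), ``A`` the interaction
matrix, ``B`` the intrinsic growth rates, and ``Y`` the abundances at the
interval starts topped with an all-ones row.

Three estimators for ``(A B)`` are provided: ordinary least squares
(``fit_glv_mse``), maximum-likelihood unconstrained ridge regression
(``fit_glv_mlrr``, with leave-one-pair-out cross-validated shrinkage), and
the sparse bootstrap-stepwise LIMITS estimator (``fit_glv_limits``).
Prediction is a single forward Euler step from the nearest preceding sample.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .profiles import CompositionVector, LongitudinalProfile, normalize

__all__ = [
    "GLVRegressionMatrices",
    "GLVParameters",
    "build_glv_regression",
    "fit_glv_mse",
    "fit_glv_mlrr",
    "fit_glv_limits",
    "predict_glv",
    "GLVModel",
    "GLVResults",
]

DEFAULT_EPS = 1e-6
LOG_RATE_BOUND = 50.0


@dataclasses.dataclass(frozen=True)
class GLVRegressionMatrices:
    """The regression system ``F = (A B) Y`` built from one profile."""

    F: np.ndarray            # (n_taxa, n_pairs) log-abundance rates
    Y: np.ndarray            # (n_taxa + 1, n_pairs), last row all ones
    pair_deltas: np.ndarray  # (n_pairs,) time differences, days
    taxa: tuple[str, ...]

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        d = np.asarray(self.pair_deltas, dtype=float)
        if F.shape[1] != Y.shape[1] or Y.shape[0] != F.shape[0] + 1:
            raise ValueError("inconsistent F/Y shapes")
        if not np.allclose(Y[-1], 1.0):
            raise ValueError("last row of Y must be all ones")
        if np.any(d <= 0):
            raise ValueError("pair time differences must be positive")
        object.__setattr__(self, "F", F)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "pair_deltas", d)

    @property
    def n_taxa(self) -> int:
        return self.F.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.F.shape[1]


@dataclasses.dataclass(frozen=True)
class GLVParameters:
    """Interaction matrix ``A`` (per day per unit abundance) and growth
    vector ``B`` (per day)."""

    A: np.ndarray
    B: np.ndarray
    taxa: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1] or B.shape != (A.shape[0],):
            raise ValueError("A must be square and B a matching vector")
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
            raise ValueError("gLV parameters must be finite")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)

    def to_frame(self):
        """Taxa-labeled DataFrame of A with B as a final ``growth_rate`` column."""
        import pandas as pd

        taxa = list(self.taxa) if self.taxa else [
            f"taxon_{i}" for i in range(self.B.size)
        ]
        df = pd.DataFrame(self.A, index=taxa, columns=taxa)
        df["growth_rate"] = self.B
        return df


def build_glv_regression(
    profile: LongitudinalProfile, eps: float = DEFAULT_EPS
) -> GLVRegressionMatrices:
    """Assemble ``F`` and ``Y`` from consecutive sample pairs.

    Zero abundances are replaced by the pseudocount ``eps`` before taking
    logs; each ``F`` column is divided by the pair's time difference.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if profile.n_samples < 2:
        raise ValueError("need at least 2 samples to form a pair")
    x = np.clip(profile.abundances, eps, None)
    logx = np.log(x)
    deltas = np.diff(profile.times)
    F = (logx[1:] - logx[:-1]).T / deltas
    Y = np.vstack([x[:-1].T, np.ones(deltas.size)])
    return GLVRegressionMatrices(F=F, Y=Y, pair_deltas=deltas, taxa=profile.taxa)


def _coef_to_params(coef: np.ndarray, taxa) -> GLVParameters:
    # coef has shape (n_taxa + 1, n_taxa): rows = regressors, cols = children
    return GLVParameters(A=coef[:-1].T.copy(), B=coef[-1].copy(), taxa=taxa)


def fit_glv_mse(mats: GLVRegressionMatrices) -> GLVParameters:
    """Ordinary least-squares estimator of ``(A B)``, row by row.

    When the system is underdetermined (fewer pairs than taxa + 1) the
    minimum-norm solution is returned.
    """
    coef, *_ = np.linalg.lstsq(mats.Y.T, mats.F.T, rcond=None)
    return _coef_to_params(coef, mats.taxa)


def _ridge_coef(X: np.ndarray, T: np.ndarray, lam: float,
                svd=None) -> np.ndarray:
    if svd is None:
        svd = np.linalg.svd(X, full_matrices=False)
    U, s, Vt = svd
    if lam > 0:
        shrink = s / (s**2 + lam)
    else:  # pseudoinverse limit
        shrink = np.where(s > 1e-12, 1.0 / np.maximum(s, 1e-12), 0.0)
    return Vt.T @ (shrink[:, None] * (U.T @ T))


def fit_glv_mlrr(
    mats: GLVRegressionMatrices,
    lambda_ridge: float | None = None,
    grid: np.ndarray | None = None,
) -> GLVParameters:
    """Ridge-regression (MLRR) estimator of the gLV parameters.

    With ``lambda_ridge=None`` the shrinkage is selected by leave-one-pair-
    out cross-validation over a log-spaced grid, computed in closed form
    from the SVD of the design.  ``lambda_ridge=0`` reproduces the
    least-squares estimator.
    """
    X = mats.Y.T                      # (n_pairs, n_taxa + 1)
    T = mats.F.T                      # (n_pairs, n_taxa)
    svd = np.linalg.svd(X, full_matrices=False)
    if lambda_ridge is None:
        if grid is None:
            grid = np.logspace(-6, 2, 9)
        U, s, _ = svd
        best, best_score = grid[0], np.inf
        for lam in grid:
            f = s**2 / (s**2 + lam)
            H = (U * f) @ U.T
            h = np.clip(np.diag(H), None, 1 - 1e-8)
            resid = (T - H @ T) / (1.0 - h)[:, None]
            score = float(np.mean(resid**2))
            if score < best_score:
                best, best_score = lam, score
        lambda_ridge = float(best)
    if lambda_ridge < 0:
        raise ValueError("lambda_ridge must be >= 0")
    if lambda_ridge == 0:
        return fit_glv_mse(mats)
    coef = _ridge_coef(X, T, lambda_ridge, svd=svd)
    return _coef_to_params(coef, mats.taxa)


def _ols_batched(Xtr, ytr, base_cols, cand_cols):
    """Coefficients for base + one candidate column, batched over candidates.

    Returns an array of shape (n_candidates, k + 1) where k = len(base_cols).
    """
    B = Xtr[:, base_cols]                     # (n, k)
    C = Xtr[:, cand_cols]                     # (n, c)
    k = B.shape[1]
    c = C.shape[1]
    G = np.empty((c, k + 1, k + 1))
    G[:, :k, :k] = B.T @ B
    cross = B.T @ C                           # (k, c)
    G[:, :k, k] = cross.T
    G[:, k, :k] = cross.T
    G[:, k, k] = np.einsum("ij,ij->j", C, C)
    G += 1e-12 * np.eye(k + 1)
    rhs = np.empty((c, k + 1))
    rhs[:, :k] = (B.T @ ytr)[None, :]
    rhs[:, k] = C.T @ ytr
    return np.linalg.solve(G, rhs[:, :, None])[:, :, 0]


def fit_glv_limits(
    mats: GLVRegressionMatrices,
    n_bootstrap: int = 100,
    improvement_threshold: float = 1e-3,
    seed: int | None = 0,
    max_terms: int | None = None,
) -> GLVParameters:
    """Sparse LIMITS estimator: bootstrap-aggregated forward stepwise
    regression.

    For each taxon and each bootstrap repetition, the sample pairs are split
    50/50 into train and test halves; the regression starts from the taxon's
    self-interaction term (plus growth rate) and greedily adds the covariate
    that most reduces test-half prediction error, stopping when the relative
    improvement drops below ``improvement_threshold``.  The final coefficient
    for every entry is the median over repetitions, with unselected entries
    contributing zeros.
    """
    if mats.n_pairs < 3:
        raise ValueError("LIMITS needs at least 3 sample pairs")
    rng = np.random.default_rng(seed)
    m = mats.n_taxa
    X = mats.Y.T                               # (p, m + 1); column m = intercept
    p = X.shape[0]
    n_train = p // 2 if p // 2 >= 2 else p - 1
    coefs = np.zeros((n_bootstrap, m, m + 1))  # per child: m interactions + growth

    for b in range(n_bootstrap):
        perm = rng.permutation(p)
        tr, te = perm[:n_train], perm[n_train:]
        Xtr, Xte = X[tr], X[te]
        for i in range(m):
            y_tr, y_te = mats.F[i, tr], mats.F[i, te]
            active = [i, m]                    # self-interaction + intercept
            w = _ols_batched(Xtr, y_tr, [i], [m])[0]
            err = float(np.mean((Xte[:, active] @ w - y_te) ** 2))
            cap = max_terms if max_terms is not None else m
            cap = min(cap, max(n_train - 2, 1))
            while len(active) - 1 < cap:
                cands = [j for j in range(m) if j not in active]
                if not cands:
                    break
                W = _ols_batched(Xtr, y_tr, active, cands)
                preds = Xte[:, active] @ W[:, :-1].T + Xte[:, cands] * W[:, -1]
                errs = np.mean((preds - y_te[:, None]) ** 2, axis=0)
                best = int(np.argmin(errs))
                if err <= 0 or (err - errs[best]) / err < improvement_threshold:
                    break
                active.append(cands[best])
                w = np.append(W[best, :-1], W[best, -1])
                err = float(errs[best])
            coefs[b, i, active] = w
    med = np.median(coefs, axis=0)             # (m, m + 1)
    return GLVParameters(A=med[:, :m], B=med[:, m], taxa=mats.taxa)


def predict_glv(
    params: GLVParameters,
    previous_sample,
    delta_t: float,
    eps: float = DEFAULT_EPS,
    rate_bound: float = LOG_RATE_BOUND,
) -> CompositionVector:
    """One forward Euler step from the preceding sample, then closure.

    ``ln x_i(t+dt) = ln x_i(t) + dt * (beta_i + sum_j alpha_ij x_j(t))``,
    exponentiated and renormalized.  ``previous_sample`` may be a
    :class:`CompositionVector` or a raw positive vector (absolute-abundance
    validation mode).  Log-rate magnitudes are clamped at ``rate_bound`` to
    keep the exponent finite (a warning is emitted).
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    x = np.asarray(
        previous_sample.values
        if isinstance(previous_sample, CompositionVector)
        else previous_sample,
        dtype=float,
    )
    if x.size != params.B.size:
        raise ValueError("dimension mismatch between parameters and sample")
    rate = delta_t * (params.B + params.A @ x)
    if np.any(np.abs(rate) > rate_bound):
        warnings.warn(
            "gLV log-rate clamped; the fitted dynamics are explosive at this step",
            RuntimeWarning,
            stacklevel=2,
        )
        rate = np.clip(rate, -rate_bound, rate_bound)
    logx = np.log(np.clip(x, eps, None)) + rate
    logx -= logx.max()
    return normalize(np.exp(logx))


# -- model/results surface ------------------------------------------------


class GLVModel:
    """Generalized Lotka-Volterra model of one individual's time series.

    ``GLVModel(profile).fit(method=...)`` returns a :class:`GLVResults`
    holding the estimated interaction matrix and growth rates.
    """

    def __init__(self, profile: LongitudinalProfile, eps: float = DEFAULT_EPS):
        self.profile = profile
        self.matrices = build_glv_regression(profile, eps=eps)

    def fit(self, method: str = "mse", **kwargs) -> "GLVResults":
        if method == "mse":
            params = fit_glv_mse(self.matrices)
        elif method == "mlrr":
            params = fit_glv_mlrr(self.matrices, **kwargs)
        elif method == "limits":
            params = fit_glv_limits(self.matrices, **kwargs)
        else:
            raise ValueError(f"unknown gLV estimator {method!r}")
        resid = self.matrices.F - (
            np.column_stack([params.A, params.B]) @ self.matrices.Y
        )
        return GLVResults(
            params=params,
            method=method,
            residual_mse=float(np.mean(resid**2)),
            matrices=self.matrices,
        )


@dataclasses.dataclass(frozen=True)
class GLVResults:
    params: GLVParameters
    method: str
    residual_mse: float
    matrices: GLVRegressionMatrices

    def predict(self, previous_sample: CompositionVector, delta_t: float,
                **kwargs) -> CompositionVector:
        return predict_glv(self.params, previous_sample, delta_t, **kwargs)

    def summary(self) -> str:
        m = self.params.B.size
        nz = int(np.count_nonzero(self.params.A))
        lines = [
            "Generalized Lotka-Volterra fit",
            f"  estimator:        {self.method}",
            f"  taxa:             {m}",
            f"  sample pairs:     {self.matrices.n_pairs}",
            f"  residual MSE:     {self.residual_mse:.6g}",
            f"  nonzero alpha_ij: {nz}/{m * m}",
            f"  growth-rate range: [{self.params.B.min():.4g}, "
            f"{self.params.B.max():.4g}] per day",
        ]
        return "\n".join(lines)
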