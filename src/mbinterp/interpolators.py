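"""Interpolation methods for compositional time series.

Twelve methods are registered, spanning four families:

* naive: per-taxon ``mean`` / ``median`` across all samples, ``last``
  (carry the preceding sample forward), and the ``equal`` null that assigns
  every taxon the same abundance;
* general-purpose: ``weighted_average`` between the bracketing samples,
  ``knn`` (K nearest samples in time, Epanechnikov-kernel weighted, K=5 by
  default), and per-taxon not-a-knot cubic ``spline`` with clipping;
* population dynamics: discretized generalized Lotka-Volterra with three
  estimators (``glv_mse``, ``mlrr``, ``limits``);
* temporal machine learning: a linear-Gaussian dynamic Bayesian network in
  ``dbn_dense`` and ``dbn_sparse`` configurations.

All methods return a :class:`~mbinterp.profiles.CompositionVector`; outputs
are renormalized to the simplex where the estimator does not already
guarantee it.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping

import numpy as np
from scipy.interpolate import CubicSpline

from .profiles import CompositionVector, LongitudinalProfile, normalize

__all__ = [
    "InterpolatorSpec",
    "METHOD_NAMES",
    "interpolate",
    "interpolate_naive",
    "interpolate_equal",
    "interpolate_weighted_average",
    "interpolate_knn",
    "interpolate_spline",
]


@dataclasses.dataclass(frozen=True)
class InterpolatorSpec:
    """A method name plus its parameter map (e.g. ``K`` for KNN)."""

    method_name: str
    parameters: Mapping[str, object] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method_name not in METHOD_NAMES:
            raise ValueError(
                f"unknown method {self.method_name!r}; "
                f"registered: {sorted(METHOD_NAMES)}"
            )
        object.__setattr__(self, "parameters", dict(self.parameters))


def interpolate_naive(
    profile: LongitudinalProfile, target_time: float, mode: str
) -> CompositionVector:
    """Per-taxon mean/median across all samples, or the preceding sample.

    Mean and median vectors need not sum to one, so they are renormalized.
    ``mode='last'`` requires at least one sample strictly before
    ``target_time`` (extrapolation backwards is not supported).
    """
    if mode == "mean":
        return normalize(profile.abundances.mean(axis=0))
    if mode == "median":
        return normalize(np.median(profile.abundances, axis=0))
    if mode == "last":
        idx = profile.nearest_preceding(target_time)
        return normalize(profile.abundances[idx])
    raise ValueError(f"unknown naive mode {mode!r}")


def interpolate_equal(n_taxa: int) -> CompositionVector:
    """The null prediction: every taxon gets abundance ``1/n_taxa``."""
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    return CompositionVector(np.full(n_taxa, 1.0 / n_taxa))


def interpolate_weighted_average(
    profile: LongitudinalProfile, target_time: float
) -> CompositionVector:
    """Convex combination of the bracketing samples.

    With the closest preceding sample ``x1`` at ``t1`` and the closest
    subsequent sample ``x2`` at ``t2``, predicts
    ``((t2-t)*x1 + (t-t1)*x2) / (t2-t1)``.  Convexity keeps the result on
    the simplex without renormalization.
    """
    t = float(target_time)
    before = np.flatnonzero(profile.times < t)
    after = np.flatnonzero(profile.times > t)
    if before.size == 0 or after.size == 0:
        raise ValueError(
            "weighted average needs samples on both sides of the target time"
        )
    i1, i2 = before[-1], after[0]
    t1, t2 = profile.times[i1], profile.times[i2]
    w = (t2 - t) / (t2 - t1)
    values = w * profile.abundances[i1] + (1.0 - w) * profile.abundances[i2]
    return CompositionVector(values, taxa=profile.taxa)


def _knn_neighbors(times: np.ndarray, t: float, k: int) -> np.ndarray:
    dist = np.abs(times - t)
    # ties for the K-th slot resolved toward the earlier sample
    order = np.lexsort((times, dist))
    return order[: min(k, times.size)]


def interpolate_knn(
    profile: LongitudinalProfile, target_time: float, k: int = 5
) -> CompositionVector:
    """Epanechnikov-kernel weighted K nearest neighbors in time.

    The K samples minimizing ``|t_i - t|`` (on either side of ``t``) are
    combined with weights ``3/4 * (1 - u_i^2)`` where
    ``u_i = |t_i - t| / max_j |t_j - t|`` over the selected neighbors; the
    result is renormalized.  The farthest selected neighbor always has
    ``u = 1`` and hence exactly zero weight; in the degenerate case where
    all selected distances are equal (every weight zero) the neighbors are
    averaged uniformly, the kernel's limit as the spread vanishes.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if profile.n_samples == 0:
        raise ValueError("empty profile")
    sel = _knn_neighbors(profile.times, float(target_time), k)
    dist = np.abs(profile.times[sel] - float(target_time))
    dmax = dist.max()
    if dmax == 0:
        # target coincides with the (unique) nearest sample
        weights = np.ones_like(dist)
    else:
        u = dist / dmax
        weights = 0.75 * (1.0 - u**2)
        if weights.sum() <= 0:
            weights = np.ones_like(weights)
    values = weights @ profile.abundances[sel]
    return normalize(values)


def interpolate_spline(
    profile: LongitudinalProfile, target_time: float
) -> CompositionVector:
    """Per-taxon cubic-spline value at the target, clipped and renormalized.

    Uses a not-a-knot cubic spline on each taxon's abundance series;
    negative spline values are set to 0 before closure.  With only 2 or 3
    samples the spline degenerates to the unique linear/quadratic
    interpolant.  Raises if every taxon is clipped to zero.
    """
    t = float(target_time)
    if t < profile.times[0] or t > profile.times[-1]:
        raise ValueError("spline interpolation requires an interior target time")
    n = profile.n_samples
    if n >= 4:
        values = CubicSpline(profile.times, profile.abundances, axis=0,
                             bc_type="not-a-knot")(t)
    else:
        # unique polynomial through 2 or 3 points, per taxon
        values = np.array([
            np.polyval(np.polyfit(profile.times, col, deg=n - 1), t)
            for col in profile.abundances.T
        ])
    values = np.clip(values, 0.0, None)
    if values.sum() <= 0:
        raise ValueError(
            "degenerate spline: every taxon clipped to zero at the target"
        )
    return normalize(values)


def _glv_predict(profile, target_time, fit):
    from . import glv

    mats = glv.build_glv_regression(profile)
    params = fit(mats)
    idx = profile.nearest_preceding(target_time)
    prev = profile.sample(idx)
    delta_t = float(target_time) - float(profile.times[idx])
    return glv.predict_glv(params, prev, delta_t)


def _dbn_predict(profile, target_time, mode, **params):
    from . import dbn

    model = dbn.fit_dbn(profile, mode=mode, **params)
    idx = profile.nearest_preceding(target_time)
    prev = profile.sample(idx)
    delta_t = float(target_time) - float(profile.times[idx])
    return dbn.predict_dbn(model, prev, delta_t)


def _make_registry() -> dict[str, Callable]:
    from . import glv

    return {
        "mean": lambda p, t, **kw: interpolate_naive(p, t, "mean"),
        "median": lambda p, t, **kw: interpolate_naive(p, t, "median"),
        "last": lambda p, t, **kw: interpolate_naive(p, t, "last"),
        "equal": lambda p, t, **kw: interpolate_equal(p.n_taxa),
        "weighted_average": lambda p, t, **kw: interpolate_weighted_average(p, t),
        "knn": lambda p, t, K=5, **kw: interpolate_knn(p, t, k=int(K)),
        "spline": lambda p, t, **kw: interpolate_spline(p, t),
        "glv_mse": lambda p, t, **kw: _glv_predict(p, t, glv.fit_glv_mse),
        "mlrr": lambda p, t, lambda_ridge=None, **kw: _glv_predict(
            p, t, lambda m: glv.fit_glv_mlrr(m, lambda_ridge=lambda_ridge)
        ),
        "limits": lambda p, t, n_bootstrap=100, improvement_threshold=1e-3,
        seed=0, **kw: _glv_predict(
            p,
            t,
            lambda m: glv.fit_glv_limits(
                m,
                n_bootstrap=int(n_bootstrap),
                improvement_threshold=float(improvement_threshold),
                seed=int(seed),
            ),
        ),
        "dbn_dense": lambda p, t, **kw: _dbn_predict(p, t, "dense", **kw),
        "dbn_sparse": lambda p, t, **kw: _dbn_predict(p, t, "sparse", **kw),
    }


_REGISTRY: dict[str, Callable] | None = None
METHOD_NAMES = (
    "mean", "median", "last", "equal", "weighted_average", "knn", "spline",
    "glv_mse", "mlrr", "limits", "dbn_dense", "dbn_sparse",
)


def interpolate(
    profile: LongitudinalProfile,
    target_time: float,
    spec: InterpolatorSpec | str,
    **params,
) -> CompositionVector:
    """Predict the composition at ``target_time`` with the named method.

    Trainable methods (gLV family, DBN) are fit on ``profile`` as given;
    leave-one-out callers pass the profile with the target removed.
    """
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _make_registry()
    if isinstance(spec, InterpolatorSpec):
        name = spec.method_name
        merged = {**spec.parameters, **params}
    else:
        name, merged = spec, params
    if name not in _REGISTRY:
        raise ValueError(f"unknown method {name!r}")
    return _REGISTRY[name](profile, float(target_time), **merged)
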