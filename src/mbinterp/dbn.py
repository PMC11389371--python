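"""Linear-Gaussian dynamic Bayesian network for next-sample prediction.

The network is a bipartite directed graph: one node layer holds the taxa
abundances at a sample plus a node for the time difference to the subsequent
sample; the second layer holds the taxa at that subsequent sample.  Each
child taxon is a linear-Gaussian function of its parents.  Two
configurations are supported:

* ``dense`` — every child has all taxa plus the time-difference node as
  parents; coefficients estimated by ridge regression (the intercept is not
  penalized);
* ``sparse`` — parents chosen per child by greedy forward selection under
  the Bayesian information criterion, capped at ``max_parents``.

Training pairs are all consecutive pairs among the available (non-missing)
samples, so after a leave-one-out deletion the flanking samples form a pair
with their actual time difference.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .profiles import CompositionVector, LongitudinalProfile, normalize

__all__ = ["DBNModel", "fit_dbn", "predict_dbn", "DBN"]


@dataclasses.dataclass(frozen=True)
class DBNModel:
    """Fitted bipartite network.

    ``parent_sets[c]`` holds feature indices into the parent layer
    ``[taxon_0 .. taxon_{m-1}, delta_t]`` for child ``c``; ``weights[c]`` the
    matching coefficients with the intercept appended last;
    ``noise_variances[c]`` the residual variance of child ``c``.
    """

    parent_sets: tuple[tuple[int, ...], ...]
    weights: tuple[np.ndarray, ...]
    noise_variances: np.ndarray
    taxa: tuple[str, ...]
    mode: str

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


def _training_pairs(profile: LongitudinalProfile):
    x = profile.abundances
    prev = x[:-1]
    nxt = x[1:]
    dt = np.diff(profile.times)
    return prev, nxt, dt


def fit_dbn(
    profile: LongitudinalProfile,
    mode: str = "dense",
    max_parents: int = 3,
    ridge: float = 1e-6,
) -> DBNModel:
    """Fit the network on all consecutive sample pairs of ``profile``.

    Requires at least 3 samples (2 pairs).  ``ridge`` regularizes the dense
    fit; set it to 0 for a plain (minimum-norm) least-squares fit.
    """
    if profile.n_samples < 3:
        raise ValueError("DBN fitting needs at least 3 samples (2 pairs)")
    prev, nxt, dt = _training_pairs(profile)
    p, m = prev.shape
    features = np.column_stack([prev, dt])          # (p, m + 1)
    design = np.column_stack([features, np.ones(p)])

    parent_sets: list[tuple[int, ...]] = []
    weights: list[np.ndarray] = []
    variances = np.empty(m)

    if mode == "dense":
        if ridge > 0:
            penalty = ridge * np.eye(m + 2)
            penalty[-1, -1] = 0.0                   # free intercept
            G = design.T @ design + penalty
            coef = np.linalg.solve(G, design.T @ nxt)   # (m+2, m)
        else:
            coef, *_ = np.linalg.lstsq(design, nxt, rcond=None)
        resid = nxt - design @ coef
        for c in range(m):
            parent_sets.append(tuple(range(m + 1)))
            weights.append(coef[:, c].copy())
            variances[c] = max(float(np.mean(resid[:, c] ** 2)), 1e-12)
    elif mode == "sparse":
        for c in range(m):
            sel = _greedy_bic(features, nxt[:, c], max_parents)
            cols = np.column_stack([features[:, sel], np.ones(p)]) if sel else \
                np.ones((p, 1))
            w, *_ = np.linalg.lstsq(cols, nxt[:, c], rcond=None)
            resid = nxt[:, c] - cols @ w
            parent_sets.append(tuple(sel))
            weights.append(w)
            variances[c] = max(float(np.mean(resid**2)), 1e-12)
    else:
        raise ValueError(f"unknown DBN mode {mode!r}")

    return DBNModel(
        parent_sets=tuple(parent_sets),
        weights=tuple(weights),
        noise_variances=variances,
        taxa=profile.taxa,
        mode=mode,
    )


def _greedy_bic(features: np.ndarray, y: np.ndarray, max_parents: int) -> list[int]:
    """Forward selection of parent columns minimizing BIC.

    Candidate regressions at each step are scored in one batched
    normal-equations solve.
    """
    from .glv import _ols_batched

    p, q = features.shape
    X = np.column_stack([features, np.ones(p)])     # intercept = column q
    sel: list[int] = []
    rss = float(np.sum((y - y.mean()) ** 2))
    bic = p * np.log(max(rss / p, 1e-300)) + np.log(p)  # intercept only
    while len(sel) < min(max_parents, q, max(p - 2, 1)):
        cands = [j for j in range(q) if j not in sel]
        if not cands:
            break
        base = sel + [q]
        W = _ols_batched(X, y, base, cands)          # (c, len(base) + 1)
        preds = X[:, base] @ W[:, :-1].T + X[:, cands] * W[:, -1]
        rss_c = np.sum((y[:, None] - preds) ** 2, axis=0)
        k = len(sel) + 2
        bics = p * np.log(np.maximum(rss_c / p, 1e-300)) + k * np.log(p)
        best = int(np.argmin(bics))
        if bics[best] >= bic - 1e-12:
            break
        sel.append(cands[best])
        bic, rss = float(bics[best]), float(rss_c[best])
    return sel


def predict_dbn(
    model: DBNModel, previous_sample: CompositionVector, delta_t: float
) -> CompositionVector:
    """Predict the next composition from the previous sample and the gap.

    Each child's linear prediction is computed from its parents; negatives
    are clipped to zero and the result renormalized.  Raises when every
    child is non-positive (nothing to normalize).
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    x = np.asarray(previous_sample.values, dtype=float)
    if x.size != model.n_taxa:
        raise ValueError("dimension mismatch between model and sample")
    feat = np.append(x, delta_t)
    out = np.empty(model.n_taxa)
    for c, (sel, w) in enumerate(zip(model.parent_sets, model.weights)):
        out[c] = float(np.dot(w[:-1], feat[list(sel)]) + w[-1])
    out = np.clip(out, 0.0, None)
    if out.sum() <= 0:
        raise ValueError("all DBN child predictions non-positive; cannot normalize")
    return normalize(out)


class DBN:
    """Model/results convenience wrapper around :func:`fit_dbn`."""

    def __init__(self, profile: LongitudinalProfile):
        self.profile = profile

    def fit(self, mode: str = "dense", **kwargs) -> DBNModel:
        return fit_dbn(self.profile, mode=mode, **kwargs)
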