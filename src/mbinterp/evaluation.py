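"""Leave-one-out evaluation of interpolation accuracy and related analyses.

Accuracy is the Bray-Curtis similarity between the predicted and true
compositions.  The leave-one-out protocol omits every interior sample in
turn (first and last time points are never targets), refits trainable
methods on the remaining samples, and scores the prediction at the omitted
time.  Monte-Carlo subsampling experiments probe the effect of sample size
and sampling gap, and a set of correlation analyses quantifies how accuracy
varies in time, across individuals, and with community diversity.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .interpolators import InterpolatorSpec, interpolate
from .profiles import CompositionVector, LongitudinalProfile

__all__ = [
    "EvaluationRecord",
    "SubsampleResult",
    "bray_curtis_similarity",
    "relative_error",
    "loo_evaluate",
    "records_to_frame",
    "summarize_accuracy",
    "subsample_experiment",
    "stratified_effects",
    "accuracy_autocorrelation",
    "neighbor_context_correlation",
    "diversity_accuracy_correlation",
    "method_agreement",
]


def bray_curtis_similarity(x, y) -> float:
    """``1 - sum|x_i - y_i| / sum(x_i + y_i)``; equals ``sum min(x_i, y_i)``
    for two simplex vectors."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("vectors must be aligned to the same taxa")
    denom = float(np.sum(xv + yv))
    if denom == 0:
        return 1.0
    return 1.0 - float(np.sum(np.abs(xv - yv))) / denom


def relative_error(real_comp, predicted) -> np.ndarray:
    """Per-taxon ``|real - predicted| / real``; NaN where the true abundance
    is zero (those entries are excluded from aggregates)."""
    r = np.asarray(real_comp, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if r.shape != p.shape:
        raise ValueError("vectors must be aligned to the same taxa")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.abs(r - p) / r
    out[r == 0] = np.nan
    return out


@dataclasses.dataclass(frozen=True)
class EvaluationRecord:
    """One leave-one-out trial for one (method, target sample)."""

    individual_id: str
    dataset: str
    target_index: int
    target_time: float
    method_name: str
    predicted: np.ndarray | None
    bc_similarity: float
    relative_errors: np.ndarray | None
    gap_prev: float
    gap_next: float
    n_samples_available: int
    failed: bool = False
    message: str = ""


def loo_evaluate(
    profile: LongitudinalProfile,
    spec: InterpolatorSpec | str,
    **params,
) -> list[EvaluationRecord]:
    """Leave-one-out evaluation of one method on one profile.

    Every interior sample is omitted in turn; trainable methods are refit on
    the remaining samples; returns ``n_samples - 2`` records in time order.
    A method failure at a target yields a flagged record (``failed=True``)
    rather than a silent drop.
    """
    if profile.n_samples < 3:
        raise ValueError("leave-one-out needs at least 3 samples")
    if not isinstance(spec, InterpolatorSpec):
        spec = InterpolatorSpec(spec, params)
    records: list[EvaluationRecord] = []
    for i in range(1, profile.n_samples - 1):
        reduced = profile.without_sample(i)
        t = float(profile.times[i])
        truth = profile.sample(i).values
        gap_prev = t - float(profile.times[i - 1])
        gap_next = float(profile.times[i + 1]) - t
        common = dict(
            individual_id=profile.individual_id,
            dataset=profile.dataset,
            target_index=i,
            target_time=t,
            method_name=spec.method_name,
            gap_prev=gap_prev,
            gap_next=gap_next,
            n_samples_available=reduced.n_samples,
        )
        try:
            pred = interpolate(reduced, t, spec)
        except Exception as exc:  # isolate per-target failures
            records.append(
                EvaluationRecord(
                    predicted=None,
                    bc_similarity=float("nan"),
                    relative_errors=None,
                    failed=True,
                    message=f"{type(exc).__name__}: {exc}",
                    **common,
                )
            )
            continue
        records.append(
            EvaluationRecord(
                predicted=pred.values,
                bc_similarity=bray_curtis_similarity(truth, pred.values),
                relative_errors=relative_error(truth, pred.values),
                **common,
            )
        )
    return records


def records_to_frame(records: Iterable[EvaluationRecord]) -> pd.DataFrame:
    """Tidy DataFrame, one row per (method, target)."""
    rows = []
    for r in records:
        rows.append(
            {
                "individual_id": r.individual_id,
                "dataset": r.dataset,
                "method": r.method_name,
                "target_index": r.target_index,
                "target_time": r.target_time,
                "bc_similarity": r.bc_similarity,
                "mean_relative_error": (
                    float(np.nanmean(r.relative_errors))
                    if r.relative_errors is not None
                    and not np.all(np.isnan(r.relative_errors))
                    else float("nan")
                ),
                "gap_prev": r.gap_prev,
                "gap_next": r.gap_next,
                "n_samples_available": r.n_samples_available,
                "failed": r.failed,
            }
        )
    return pd.DataFrame(rows)


def summarize_accuracy(
    records: Iterable[EvaluationRecord], group_by: str = "method"
) -> pd.DataFrame:
    """Grouped accuracy summary with method ranking.

    ``group_by`` is one of ``method``, ``individual``, ``dataset``.  Failed
    records are excluded from the means and counted separately.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValueError("no records to summarize")
    key = {"method": "method", "individual": "individual_id",
           "dataset": "dataset"}[group_by]
    ok = df[~df["failed"]]
    agg = ok.groupby(key).agg(
        n=("bc_similarity", "size"),
        mean_bc=("bc_similarity", "mean"),
        median_bc=("bc_similarity", "median"),
        mean_relative_error=("mean_relative_error", lambda s: float(np.nanmean(s))),
    )
    agg["n_failed"] = df[df["failed"]].groupby(key).size().reindex(agg.index).fillna(0).astype(int)
    agg["rank"] = agg["mean_bc"].rank(ascending=False, method="min").astype(int)
    return agg.sort_values("rank")


@dataclasses.dataclass(frozen=True)
class SubsampleResult:
    """One Monte-Carlo subsampling trial."""

    individual_id: str
    method_name: str
    sample_size: int
    replicate: int
    seed: int
    target_time: float
    gap_prev: float
    bc_similarity: float


def subsample_experiment(
    profile: LongitudinalProfile,
    spec: InterpolatorSpec | str,
    sizes: Sequence[int],
    replicates: int,
    seed: int = 0,
) -> list[SubsampleResult]:
    """Monte-Carlo sample-size experiment.

    Per (size, replicate): the first and last samples are always retained
    (so every target is an interpolation problem); interior samples are
    subsampled uniformly without replacement down to ``size``; one retained
    interior sample is chosen at random as the target and predicted from the
    remaining retained samples.  Sizes exceeding the available sample count
    are skipped with a warning.
    """
    import warnings

    if not isinstance(spec, InterpolatorSpec):
        spec = InterpolatorSpec(spec)
    rng = np.random.default_rng(seed)
    n = profile.n_samples
    results: list[SubsampleResult] = []
    for size in sizes:
        if size < 3:
            raise ValueError("subsample size must be >= 3")
        if size > n:
            warnings.warn(f"size {size} exceeds {n} samples; skipped")
            continue
        for rep in range(replicates):
            interior = rng.choice(np.arange(1, n - 1), size=size - 2, replace=False)
            retained = np.sort(np.concatenate([[0], interior, [n - 1]]))
            target_pos = int(rng.integers(1, retained.size - 1))
            target_idx = int(retained[target_pos])
            sub = profile.subset(retained)
            t = float(profile.times[target_idx])
            truth = profile.sample(target_idx).values
            reduced = sub.without_sample(target_pos)
            pred = interpolate(reduced, t, spec)
            gap_prev = t - float(profile.times[retained[target_pos - 1]])
            results.append(
                SubsampleResult(
                    individual_id=profile.individual_id,
                    method_name=spec.method_name,
                    sample_size=int(size),
                    replicate=rep,
                    seed=seed,
                    target_time=t,
                    gap_prev=gap_prev,
                    bc_similarity=bray_curtis_similarity(truth, pred.values),
                )
            )
    return results


def stratified_effects(
    results: Sequence[SubsampleResult],
    fix: str = "sample_size",
    bins: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Mean accuracy across bins of one variable with the other held fixed.

    ``fix='sample_size'`` strata are the distinct sizes and the free
    variable is the preceding gap (binned by ``bins`` edges);
    ``fix='gap_prev'`` reverses the roles.  Empty strata yield NaN rows.
    """
    if not results:
        raise ValueError("no subsample results")
    df = pd.DataFrame(
        {
            "sample_size": [r.sample_size for r in results],
            "gap_prev": [r.gap_prev for r in results],
            "bc_similarity": [r.bc_similarity for r in results],
        }
    )
    if fix == "sample_size":
        fixed, free = "sample_size", "gap_prev"
    elif fix == "gap_prev":
        fixed, free = "gap_prev", "sample_size"
    else:
        raise ValueError("fix must be 'sample_size' or 'gap_prev'")
    if bins is not None:
        df["free_bin"] = pd.cut(df[free], bins=np.asarray(bins, dtype=float))
    else:
        df["free_bin"] = df[free]
    if fixed == "gap_prev":
        edges = np.quantile(df[fixed], [0, 1 / 3, 2 / 3, 1])
        df["fixed_bin"] = pd.cut(df[fixed], bins=np.unique(edges),
                                 include_lowest=True)
    else:
        df["fixed_bin"] = df[fixed]
    out = (
        df.groupby(["fixed_bin", "free_bin"], observed=False)["bc_similarity"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_bc", "count": "n"})
    )
    return out


def accuracy_autocorrelation(
    records: Sequence[EvaluationRecord], lag_bins: Sequence[float]
) -> pd.DataFrame:
    """Pearson correlation of accuracy across sample pairs, by time lag.

    All record pairs of one individual/method are assigned to ``lag_bins``
    by their time difference; per bin, the correlation is computed between
    the paired accuracies.  Bins with fewer than 3 pairs (or zero variance)
    yield NaN.
    """
    recs = [r for r in records if not r.failed]
    if len(recs) < 10:
        raise ValueError("need at least 10 records")
    times = np.array([r.target_time for r in recs])
    acc = np.array([r.bc_similarity for r in recs])
    i, j = np.triu_indices(len(recs), k=1)
    lags = np.abs(times[i] - times[j])
    edges = np.asarray(lag_bins, dtype=float)
    which = np.digitize(lags, edges[1:-1], right=False)
    rows = []
    for b in range(edges.size - 1):
        mask = which == b
        n_pairs = int(mask.sum())
        if n_pairs < 3 or np.std(acc[i[mask]]) == 0 or np.std(acc[j[mask]]) == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(acc[i[mask]], acc[j[mask]])[0])
        rows.append({"lag_low": edges[b], "lag_high": edges[b + 1],
                     "n_pairs": n_pairs, "pearson_r": r})
    return pd.DataFrame(rows)


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


def neighbor_context_correlation(
    records: Sequence[EvaluationRecord],
    seed: int = 0,
    n_draws: int = 1,
) -> dict[str, float]:
    """Correlation of a sample's accuracy with four reference contexts.

    For every record the accuracy is paired with (a) the mean accuracy of
    its two temporally adjacent records (one-sided at boundaries), (b) a
    random record of the same individual, (c) a random record of the same
    dataset, and (d) a random record of another dataset.  Returns the four
    Pearson coefficients (random pairings averaged over ``n_draws`` seeded
    draws); contexts that do not exist (e.g. a single dataset) are NaN.
    """
    recs = [r for r in records if not r.failed]
    rng = np.random.default_rng(seed)
    by_ind: dict[str, list[int]] = {}
    by_ds: dict[str, list[int]] = {}
    for idx, r in enumerate(recs):
        by_ind.setdefault(r.individual_id, []).append(idx)
        by_ds.setdefault(r.dataset, []).append(idx)
    acc = np.array([r.bc_similarity for r in recs])

    # adjacent within individual (records are in time order per individual)
    adj = np.full(len(recs), np.nan)
    for ind, idxs in by_ind.items():
        order = sorted(idxs, key=lambda k: recs[k].target_time)
        for pos, k in enumerate(order):
            neigh = []
            if pos > 0:
                neigh.append(acc[order[pos - 1]])
            if pos < len(order) - 1:
                neigh.append(acc[order[pos + 1]])
            adj[k] = float(np.mean(neigh)) if neigh else np.nan
    ok = ~np.isnan(adj)
    out = {"adjacent": _safe_pearson(acc[ok], adj[ok])}

    def _random_r(pool_of):
        rs = []
        for _ in range(n_draws):
            partner = np.full(len(recs), np.nan)
            for k in range(len(recs)):
                pool = pool_of(k)
                if pool:
                    partner[k] = acc[pool[int(rng.integers(len(pool)))]]
            m = ~np.isnan(partner)
            rs.append(_safe_pearson(acc[m], partner[m]))
        return float(np.nanmean(rs)) if rs else float("nan")

    out["random_same_individual"] = _random_r(
        lambda k: [j for j in by_ind[recs[k].individual_id] if j != k]
    )
    out["random_same_dataset"] = _random_r(
        lambda k: [j for j in by_ds[recs[k].dataset] if j != k]
    )
    other = {
        ds: [j for d2, idxs in by_ds.items() if d2 != ds for j in idxs]
        for ds in by_ds
    }
    out["random_other_dataset"] = _random_r(lambda k: other[recs[k].dataset])
    return out


def diversity_accuracy_correlation(
    records: Sequence[EvaluationRecord],
    profiles: Sequence[LongitudinalProfile],
) -> pd.DataFrame:
    """Per-individual Pearson correlation between the true sample's Shannon
    diversity and its interpolation accuracy."""
    from .stability import shannon_diversity

    prof_by_id = {p.individual_id: p for p in profiles}
    rows = []
    by_ind: dict[str, list[EvaluationRecord]] = {}
    for r in records:
        if not r.failed:
            by_ind.setdefault(r.individual_id, []).append(r)
    for ind, recs in by_ind.items():
        if len(recs) < 5 or ind not in prof_by_id:
            continue
        prof = prof_by_id[ind]
        div = np.array(
            [shannon_diversity(prof.sample(r.target_index)) for r in recs]
        )
        acc = np.array([r.bc_similarity for r in recs])
        if np.std(div) == 0 or np.std(acc) == 0:
            rows.append({"individual_id": ind, "pearson_r": float("nan"),
                         "p_value": float("nan"), "n": len(recs)})
            continue
        r_val, p_val = stats.pearsonr(div, acc)
        rows.append({"individual_id": ind, "pearson_r": float(r_val),
                     "p_value": float(p_val), "n": len(recs)})
    return pd.DataFrame(rows)


def method_agreement(records: Sequence[EvaluationRecord]) -> pd.DataFrame:
    """Pairwise Pearson matrix of per-individual mean accuracies across
    methods (pairwise-complete over shared individuals)."""
    df = records_to_frame(records)
    df = df[~df["failed"]]
    table = df.pivot_table(
        index="individual_id", columns="method", values="bc_similarity",
        aggfunc="mean"
    )
    if table.shape[0] < 3:
        raise ValueError("method agreement needs >= 3 individuals")
    return table.corr(method="pearson", min_periods=3)
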