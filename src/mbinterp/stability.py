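"""Community- and taxon-level stability statistics.

Community stability around a time point is the mean Bray-Curtis similarity
among its surrounding samples; taxon stability is quantified by the
bimodality coefficient

    beta = (gamma^2 + 1) / (kappa + 3 (n-1)^2 / ((n-2)(n-3)))

with ``gamma`` the sample skewness and ``kappa`` the sample excess kurtosis
(moment estimators; the finite-n correction term in the denominator plays
the role of a bias adjustment).  High beta marks bimodal, conditionally-rare
or otherwise non-stable behavior; the conventional cutoff is 0.7.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import EvaluationRecord, bray_curtis_similarity
from .profiles import CompositionVector, LongitudinalProfile

__all__ = [
    "BimodalityStats",
    "shannon_diversity",
    "timepoint_stability",
    "stability_series",
    "bimodality_coefficient",
    "classify_taxon_stability",
    "taxon_bimodality_table",
    "stability_accuracy_correlation",
    "bimodality_abundance_correlation",
]


def shannon_diversity(x) -> float:
    """Shannon diversity ``-sum x_i ln x_i`` in nats (zeros contribute 0)."""
    v = np.asarray(x, dtype=float)
    pos = v[v > 0]
    return float(-np.sum(pos * np.log(pos)))


def timepoint_stability(profile: LongitudinalProfile, index: int) -> float:
    """Local community stability around the sample at ``index``.

    Mean of three Bray-Curtis similarities: between the two preceding
    samples, between the two succeeding samples, and between the nearest
    preceding and succeeding samples.  Requires two samples on each side;
    returns NaN otherwise.
    """
    if index < 2 or index > profile.n_samples - 3:
        return float("nan")
    ab = profile.abundances
    pairs = [
        (ab[index - 2], ab[index - 1]),
        (ab[index + 1], ab[index + 2]),
        (ab[index - 1], ab[index + 1]),
    ]
    return float(np.mean([bray_curtis_similarity(a, b) for a, b in pairs]))


def stability_series(profile: LongitudinalProfile) -> pd.DataFrame:
    """Per-interior-sample stability table (NaN where context is missing)."""
    rows = [
        {
            "individual_id": profile.individual_id,
            "target_index": i,
            "target_time": float(profile.times[i]),
            "stability": timepoint_stability(profile, i),
        }
        for i in range(1, profile.n_samples - 1)
    ]
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class BimodalityStats:
    beta: float
    skewness: float
    kurtosis_excess: float
    n: int


def bimodality_coefficient(values: Sequence[float]) -> BimodalityStats:
    """Bimodality coefficient of a sample of abundances.

    Benchmarks: uniform -> 5/9, normal -> 1/3, symmetric two-point mass -> 1
    (in the large-n limit).  Requires ``n >= 4`` and nonzero variance.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 4:
        raise ValueError("bimodality coefficient needs n >= 4")
    if np.var(v) == 0:
        raise ValueError("bimodality coefficient undefined at zero variance")
    gamma = float(stats.skew(v, bias=True))
    kappa = float(stats.kurtosis(v, fisher=True, bias=True))
    correction = 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    beta = (gamma**2 + 1.0) / (kappa + correction)
    return BimodalityStats(beta=beta, skewness=gamma, kurtosis_excess=kappa, n=n)


def classify_taxon_stability(
    beta: float, threshold: float = 0.7, high_is_stable: bool = False
) -> str:
    """Classify a taxon by its bimodality coefficient.

    Default orientation: ``beta > threshold`` marks non-stable behavior
    (conditionally rare / strongly fluctuating taxa).  The opposite
    orientation is selectable via ``high_is_stable`` for comparability with
    sources that use the reversed convention.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    high = beta > threshold
    if high_is_stable:
        return "stable" if high else "non_stable"
    return "non_stable" if high else "stable"


def taxon_bimodality_table(
    profiles: Sequence[LongitudinalProfile], threshold: float = 0.7
) -> pd.DataFrame:
    """Per (individual, taxon) bimodality, mean abundance, and class."""
    rows = []
    for prof in profiles:
        for t_idx, taxon in enumerate(prof.taxa):
            series = prof.abundances[:, t_idx]
            if series.size < 4 or np.var(series) == 0:
                continue
            bs = bimodality_coefficient(series)
            rows.append(
                {
                    "individual_id": prof.individual_id,
                    "dataset": prof.dataset,
                    "taxon": taxon,
                    "beta": bs.beta,
                    "mean_abundance": float(series.mean()),
                    "stability_class": classify_taxon_stability(bs.beta, threshold),
                }
            )
    return pd.DataFrame(rows)


def stability_accuracy_correlation(
    records: Sequence[EvaluationRecord],
    profiles: Sequence[LongitudinalProfile],
    level: str = "sample",
    threshold: float = 0.7,
) -> dict:
    """Correlation between stability measures and interpolation accuracy.

    * ``level='sample'`` — Spearman rho between the local time-point
      stability and the record's Bray-Curtis accuracy, pooled over records.
    * ``level='taxon'`` — contrast of mean per-taxon relative error between
      stable and non-stable taxa (by bimodality class), plus the Spearman
      correlation between beta and the taxon's mean relative error.
    * ``level='individual'`` — Spearman rho between an individual's mean
      taxon bimodality and its mean accuracy.

    Returns a dict with ``rho``, ``p_value``, ``n`` (and group means at the
    taxon level).  NaN when fewer than 5 paired observations exist.
    """
    prof_by_id = {p.individual_id: p for p in profiles}
    recs = [r for r in records if not r.failed]

    def _spearman(a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        if a.size < 5 or np.std(a) == 0 or np.std(b) == 0:
            return {"rho": float("nan"), "p_value": float("nan"), "n": int(a.size)}
        rho, p = stats.spearmanr(a, b)
        return {"rho": float(rho), "p_value": float(p), "n": int(a.size)}

    if level == "sample":
        st, acc = [], []
        for r in recs:
            prof = prof_by_id.get(r.individual_id)
            if prof is None:
                continue
            s = timepoint_stability(prof, r.target_index)
            if np.isfinite(s):
                st.append(s)
                acc.append(r.bc_similarity)
        return _spearman(st, acc)

    if level == "taxon":
        table = taxon_bimodality_table(profiles, threshold=threshold)
        err: dict[tuple[str, str], list[float]] = {}
        for r in recs:
            if r.relative_errors is None:
                continue
            prof = prof_by_id.get(r.individual_id)
            if prof is None:
                continue
            for t_idx, taxon in enumerate(prof.taxa):
                e = r.relative_errors[t_idx]
                if np.isfinite(e):
                    err.setdefault((r.individual_id, taxon), []).append(float(e))
        table = table.assign(
            mean_relative_error=[
                float(np.mean(err.get((row.individual_id, row.taxon), [np.nan])))
                for row in table.itertuples()
            ]
        ).dropna(subset=["mean_relative_error"])
        out = _spearman(table["beta"], table["mean_relative_error"])
        groups = table.groupby("stability_class")["mean_relative_error"].mean()
        out["group_mean_error"] = groups.to_dict()
        return out

    if level == "individual":
        table = taxon_bimodality_table(profiles, threshold=threshold)
        mean_beta = table.groupby("individual_id")["beta"].mean()
        acc = (
            pd.DataFrame(
                {
                    "individual_id": [r.individual_id for r in recs],
                    "bc": [r.bc_similarity for r in recs],
                }
            )
            .groupby("individual_id")["bc"]
            .mean()
        )
        joined = pd.concat([mean_beta, acc], axis=1).dropna()
        return _spearman(joined["beta"], joined["bc"])

    raise ValueError("level must be 'sample', 'taxon', or 'individual'")


def bimodality_abundance_correlation(
    profiles: Sequence[LongitudinalProfile],
) -> dict:
    """Spearman correlation between taxon bimodality and mean abundance
    across all (taxon, individual) pairs."""
    table = taxon_bimodality_table(profiles)
    if len(table) < 10:
        raise ValueError("need at least 10 (taxon, individual) pairs")
    rho, p = stats.spearmanr(table["beta"], table["mean_abundance"])
    return {"rho": float(rho), "p_value": float(p), "n": int(len(table))}
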