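"""Mixed-effects prediction of per-sample interpolation accuracy.

A linear mixed model with a per-individual random intercept predicts the
logit-transformed Bray-Curtis accuracy of a leave-one-out record from the
sampling gaps to its neighbors and the (logit) accuracies observed at those
neighboring records:

    logit(BC) ~ 1 + gap_prev + gap_next + logit_bc_prev + logit_bc_next
                [+ n_samples]  +  (1 | individual)

Accuracies are clipped into ``[eps, 1 - eps]`` before the logit.  Fixed
effects are tested with Wald z statistics; out-of-sample performance is
reported as the mean absolute error on the Bray-Curtis scale and the
Spearman correlation between predicted and observed accuracy, under a
grouped (leave-individuals-out) split to avoid leakage through the random
intercepts.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import EvaluationRecord

__all__ = [
    "DEFAULT_COVARIATES",
    "build_features",
    "InterpolationAccuracyModel",
    "AccuracyModelResults",
    "fit_lmm",
    "wald_tests",
    "predict_accuracy",
    "evaluate_predictor",
    "logit",
    "inv_logit",
]

DEFAULT_COVARIATES = ("gap_prev", "gap_next", "logit_bc_prev", "logit_bc_next")


def logit(p, eps: float = 0.0):
    p = np.clip(np.asarray(p, dtype=float), eps, 1.0 - eps) if eps else np.asarray(p, float)
    return np.log(p / (1.0 - p))


def inv_logit(z):
    z = np.asarray(z, dtype=float)
    return 1.0 / (1.0 + np.exp(-z))


def build_features(
    records: Sequence[EvaluationRecord], clip_epsilon: float = 1e-3
) -> pd.DataFrame:
    """Feature table for the accuracy model from one method's LOO records.

    Per record: the response is ``logit(BC)`` with BC clipped into
    ``[eps, 1-eps]``; the neighbor accuracies are the same method's LOO
    accuracies at the temporally adjacent records of the same individual.
    Boundary records (missing a neighbor) are dropped, as are individuals
    with fewer than 3 usable records.
    """
    if not 0 < clip_epsilon < 0.5:
        raise ValueError("clip_epsilon must be in (0, 0.5)")
    by_ind: dict[str, list[EvaluationRecord]] = {}
    for r in records:
        if not r.failed and np.isfinite(r.bc_similarity):
            by_ind.setdefault(r.individual_id, []).append(r)
    rows = []
    for ind, recs in by_ind.items():
        if len(recs) < 3:
            warnings.warn(f"individual {ind!r} has <3 records; excluded")
            continue
        recs = sorted(recs, key=lambda r: r.target_time)
        lg = logit([r.bc_similarity for r in recs], eps=clip_epsilon)
        for pos in range(1, len(recs) - 1):
            r = recs[pos]
            rows.append(
                {
                    "individual_id": ind,
                    "n_samples": r.n_samples_available + 1,
                    "gap_prev": r.gap_prev,
                    "gap_next": r.gap_next,
                    "logit_bc_prev": lg[pos - 1],
                    "logit_bc_next": lg[pos + 1],
                    "logit_bc": lg[pos],
                    "bc_similarity": r.bc_similarity,
                }
            )
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class AccuracyModelResults:
    """Fitted accuracy predictor.

    ``fixed_effects`` has one row per coefficient (including the intercept)
    with columns ``coef``, ``se``, ``z``, ``p``.
    """

    fixed_effects: pd.DataFrame
    random_intercept_variance: float
    residual_variance: float
    converged: bool
    covariates: tuple[str, ...]
    random_effects: dict[str, float]
    clip_epsilon: float

    def predict(self, features: pd.DataFrame, include_random: bool = False) -> np.ndarray:
        return predict_accuracy(self, features, include_random=include_random)

    def evaluate(self, features: pd.DataFrame) -> tuple[float, float]:
        return evaluate_predictor(self, features)

    def wald_tests(self) -> pd.DataFrame:
        return wald_tests(self)

    def summary(self) -> str:
        lines = [
            "Interpolation-accuracy mixed model (logit Bray-Curtis response)",
            f"  converged: {self.converged}",
            f"  random intercept variance: {self.random_intercept_variance:.6g}",
            f"  residual variance:         {self.residual_variance:.6g}",
            "",
            self.fixed_effects.to_string(float_format=lambda v: f"{v: .4g}"),
        ]
        return "\n".join(lines)


class InterpolationAccuracyModel:
    """statsmodels-style model: construct from a feature table, then
    :meth:`fit` by REML to obtain :class:`AccuracyModelResults`."""

    def __init__(
        self,
        features: pd.DataFrame,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        clip_epsilon: float = 1e-3,
    ):
        required = set(covariates) | {"logit_bc", "individual_id"}
        missing = required - set(features.columns)
        if missing:
            raise ValueError(f"feature table missing columns: {sorted(missing)}")
        if features["individual_id"].nunique() < 2:
            raise ValueError("need at least 2 individuals for a random intercept")
        if len(features) < 10:
            raise ValueError("need at least 10 feature rows")
        self.features = features.reset_index(drop=True)
        self.covariates = tuple(covariates)
        self.clip_epsilon = clip_epsilon

    @classmethod
    def from_records(
        cls,
        records: Sequence[EvaluationRecord],
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        clip_epsilon: float = 1e-3,
    ) -> "InterpolationAccuracyModel":
        feats = build_features(records, clip_epsilon=clip_epsilon)
        return cls(feats, covariates=covariates, clip_epsilon=clip_epsilon)

    def fit(self, reml: bool = True) -> AccuracyModelResults:
        import statsmodels.api as sm
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        df = self.features
        exog = sm.add_constant(df[list(self.covariates)].to_numpy(),
                               has_constant="add")
        endog = df["logit_bc"].to_numpy()
        groups = df["individual_id"].to_numpy()
        names = ["intercept", *self.covariates]

        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            try:
                model = sm.MixedLM(endog, exog, groups=groups)
                res = model.fit(reml=reml)
                converged = bool(res.converged)
                coefs = np.asarray(res.fe_params)
                ses = np.asarray(res.bse_fe)
                re_var = float(np.asarray(res.cov_re).ravel()[0])
                resid_var = float(res.scale)
                re_blups = {
                    str(g): float(np.asarray(v).ravel()[0])
                    for g, v in res.random_effects.items()
                }
            except Exception:
                res = None
                converged = False
            if res is None or not np.all(np.isfinite(ses)):
                # singular mixed fit: fall back to zero random-effect variance
                warnings.warn(
                    "mixed model singular; falling back to OLS with zero "
                    "random-intercept variance"
                )
                ols = sm.OLS(endog, exog).fit(method="pinv")
                coefs = np.asarray(ols.params)
                ses = np.asarray(ols.bse)
                re_var, resid_var = 0.0, float(ols.scale)
                re_blups = {str(g): 0.0 for g in np.unique(groups)}
                converged = True

        z = np.divide(coefs, ses, out=np.full_like(coefs, np.nan), where=ses > 0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        fixed = pd.DataFrame({"coef": coefs, "se": ses, "z": z, "p": p}, index=names)
        return AccuracyModelResults(
            fixed_effects=fixed,
            random_intercept_variance=max(re_var, 0.0),
            residual_variance=resid_var,
            converged=converged,
            covariates=self.covariates,
            random_effects=re_blups,
            clip_epsilon=self.clip_epsilon,
        )


def fit_lmm(
    features: pd.DataFrame,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    reml: bool = True,
) -> AccuracyModelResults:
    """Convenience wrapper: build and REML-fit the accuracy model."""
    return InterpolationAccuracyModel(features, covariates=covariates).fit(reml=reml)


def wald_tests(fit: AccuracyModelResults) -> pd.DataFrame:
    """Per-coefficient Wald z and two-sided normal p (NaN where SE = 0)."""
    fe = fit.fixed_effects
    return fe[["z", "p"]].copy()


def predict_accuracy(
    fit: AccuracyModelResults,
    features: pd.DataFrame,
    include_random: bool = False,
) -> np.ndarray:
    """Predicted Bray-Curtis accuracy in [0, 1] for the given features.

    With ``include_random``, known individuals get their estimated random
    intercept; unseen individuals fall back to the fixed effects only.
    """
    X = features[list(fit.covariates)].to_numpy(dtype=float)
    coefs = fit.fixed_effects["coef"].to_numpy()
    lin = coefs[0] + X @ coefs[1:]
    if include_random:
        offs = np.array(
            [fit.random_effects.get(str(g), 0.0) for g in features["individual_id"]]
        )
        lin = lin + offs
    return inv_logit(lin)


def evaluate_predictor(
    fit: AccuracyModelResults, features: pd.DataFrame
) -> tuple[float, float]:
    """MAE (Bray-Curtis scale) and Spearman rho on held-out features.

    Predictions use fixed effects only, as appropriate for individuals not
    seen in training.  Spearman is NaN under zero variance.
    """
    if len(features) < 10:
        raise ValueError("need at least 10 held-out rows")
    pred = predict_accuracy(fit, features, include_random=False)
    obs = features["bc_similarity"].to_numpy(dtype=float)
    mae = float(np.mean(np.abs(pred - obs)))
    if np.std(pred) == 0 or np.std(obs) == 0:
        return mae, float("nan")
    rho = float(stats.spearmanr(pred, obs)[0])
    return mae, rho
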