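"""Group-level statistical models.

Contracts used by the analysis:

* robust pairwise group contrasts — iteratively reweighted least squares
  with a bisquare (Tukey biweight) weight function, Bonferroni-corrected
  over the six pairwise contrasts of four groups (alpha 0.05/6);
* linear mixed-effects models with a participant random intercept, for the
  time-interval, velocity-quantile and repetition analyses;
* one-sample and paired location tests (e.g. AUC against chance 0.5);
* product-moment correlations and the Fisher-z comparison of two
  correlations;
* the binomial-logit recognition model: per-image naming correctness
  regressed on participant visual acuity (logMAR) and AUC, compared across
  predictor subsets by AIC and Tjur's discrimination index.

Denominator degrees of freedom for mixed models use a residual-df t
reference (recorded as ``df_method='residual'`` in the result metadata);
the Satterthwaite approximation is not available in the backend used here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "ContrastResult",
    "MixedModelResult",
    "LocationTestResult",
    "CorrelationComparison",
    "RecognitionModelResult",
    "robust_group_contrasts",
    "mixed_model",
    "one_sample_test",
    "paired_test",
    "pearson_correlation",
    "compare_correlations",
    "recognition_model",
]

#: Tuning constant of the bisquare weight function (95% Gaussian efficiency).
BISQUARE_C = 4.685


@dataclass
class ContrastResult:
    contrast: str          # "A-B"
    estimate: float
    se: float
    statistic: float
    pvalue: float
    corrected_alpha: float

    @property
    def significant(self) -> bool:
        return self.pvalue < self.corrected_alpha


def robust_group_contrasts(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
) -> list[ContrastResult]:
    """All pairwise robust group contrasts with Bonferroni correction.

    Fits value ~ group by IRLS with the bisquare weight function (tuning
    constant 4.685) and tests every pairwise difference of group locations
    at the family alpha divided by the number of pairs (0.05/6 for four
    groups).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    levels = sorted(set(groups))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    for lev in levels:
        if np.sum(groups == lev) < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 members")

    # dummy design, first level as baseline
    X = np.column_stack(
        [np.ones(len(values))] + [(groups == lev).astype(float) for lev in levels[1:]]
    )
    res = sm.RLM(values, X, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C)).fit()
    if not np.isfinite(res.scale) or res.scale < 1e-8 * (np.std(values) + 1e-12):
        # an exact fit leaves the robust scale degenerate; IRLS and OLS then
        # coincide, so report the OLS solution
        res = sm.OLS(values, X).fit()

    def coef_vector(level: str) -> np.ndarray:
        vec = np.zeros(X.shape[1])
        if level != levels[0]:
            vec[1 + levels[1:].index(level)] = 1.0
        return vec

    pairs = list(combinations(levels, 2))
    corrected = alpha / len(pairs)
    out = []
    for a, b in pairs:
        L = coef_vector(a) - coef_vector(b)
        tt = res.t_test(L)
        out.append(ContrastResult(
            contrast=f"{a}-{b}",
            estimate=float(np.squeeze(tt.effect)),
            se=float(np.squeeze(tt.sd)),
            statistic=float(np.squeeze(tt.tvalue)),
            pvalue=float(np.squeeze(tt.pvalue)),
            corrected_alpha=corrected,
        ))
    return out


@dataclass
class MixedModelResult:
    formula: str
    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    df_resid: float
    random_intercept_var: float
    df_method: str = "residual"
    singular: bool = False
    fallback_fixed_only: bool = False

    def __getitem__(self, name: str) -> float:
        return float(self.params[name])


def mixed_model(
    frame: pd.DataFrame,
    formula: str,
    group_col: str = "participant",
) -> MixedModelResult:
    """Fit a linear mixed model with a participant random intercept (REML).

    ``formula`` describes the fixed effects (patsy syntax; group x covariate
    interactions permitted).  p-values use a t reference with residual
    degrees of freedom.  A singular random-effect fit (zero intercept
    variance, or failed optimization) is flagged and reported from a
    fixed-effects-only OLS refit.
    """
    counts = frame[group_col].value_counts()
    if (counts < 2).any():
        raise ValueError("every participant needs at least 2 rows")
    singular = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = smf.mixedlm(formula, frame, groups=frame[group_col])
            res = md.fit(reml=True)
        re_var = float(np.squeeze(np.asarray(res.cov_re))) if res.cov_re.size else 0.0
        if not res.converged or re_var < 1e-10:
            singular = True
    except (np.linalg.LinAlgError, ValueError):
        singular = True
        res = None

    if singular:
        ols = smf.ols(formula, frame).fit()
        df = float(ols.df_resid)
        t = ols.params / ols.bse
        pv = 2 * sps.t.sf(np.abs(t), df)
        return MixedModelResult(
            formula=formula, params=ols.params, se=ols.bse,
            pvalues=pd.Series(pv, index=ols.params.index),
            df_resid=df, random_intercept_var=0.0,
            singular=True, fallback_fixed_only=True,
        )

    fe = res.fe_params
    se = res.bse_fe
    df = float(len(frame) - len(fe) - frame[group_col].nunique())
    df = max(df, 1.0)
    t = fe / se
    pv = 2 * sps.t.sf(np.abs(t), df)
    return MixedModelResult(
        formula=formula, params=fe, se=se,
        pvalues=pd.Series(pv, index=fe.index),
        df_resid=df, random_intercept_var=re_var,
    )


@dataclass
class LocationTestResult:
    mean: float
    statistic: float | None
    pvalue: float | None
    df: int
    exact_equality: bool = False


def one_sample_test(values: Sequence[float], reference: float = 0.5) -> LocationTestResult:
    """One-sample t test of the mean against a reference (default chance 0.5).

    Zero-variance input yields an exact-equality report with no statistic.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(values) == 0:
        return LocationTestResult(
            mean=float(values[0]), statistic=None, pvalue=None,
            df=values.size - 1, exact_equality=bool(values[0] == reference),
        )
    t, p = sps.ttest_1samp(values, reference)
    return LocationTestResult(mean=float(values.mean()), statistic=float(t),
                              pvalue=float(p), df=values.size - 1)


def paired_test(x: Sequence[float], y: Sequence[float]) -> LocationTestResult:
    """Paired t test on element-wise differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(d) == 0:
        return LocationTestResult(
            mean=float(d[0]), statistic=None, pvalue=None,
            df=d.size - 1, exact_equality=bool(d[0] == 0),
        )
    t, p = sps.ttest_rel(x, y)
    return LocationTestResult(mean=float(d.mean()), statistic=float(t),
                              pvalue=float(p), df=d.size - 1)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class CorrelationComparison:
    r1: float
    r2: float
    z: float
    pvalue: float


def compare_correlations(r1: float, n1: int, r2: float, n2: int) -> CorrelationComparison:
    """Compare two independent correlations via the Fisher z transform.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p-value.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("need at least 4 observations per correlation")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * sps.norm.sf(abs(z))
    return CorrelationComparison(r1=float(r1), r2=float(r2), z=float(z), pvalue=float(p))


@dataclass
class RecognitionModelResult:
    predictors: tuple[str, ...]
    params: pd.Series
    pvalues: pd.Series
    aic: float
    tjur_r2: float
    separation: bool = False


def _binomial_aic(y: np.ndarray, p: np.ndarray, k: int) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return -2 * llf + 2 * k


def _tjur(y: np.ndarray, p: np.ndarray) -> float:
    if not (y == 1).any() or not (y == 0).any():
        return float("nan")
    return float(p[y == 1].mean() - p[y == 0].mean())


def recognition_model(
    correct: Sequence[int],
    participant: Sequence[str],
    acuity_logmar: Mapping[str, float],
    auc: Mapping[str, float],
) -> dict[str, RecognitionModelResult]:
    """Binomial-logit models of per-image recognition correctness.

    Outcomes are modeled at the image level with participant-level
    predictors (visual acuity in logMAR and the participant's AUC).  Three
    fits are returned under keys ``acuity``, ``auc`` and ``both``, each with
    AIC and Tjur's R^2 for model comparison.  Perfect separation (or a
    degenerate all-equal outcome) is flagged and reported from a weakly
    L2-penalized refit.
    """
    y = np.asarray(correct, dtype=float)
    pid = np.asarray(participant, dtype=object)
    if y.size != pid.size:
        raise ValueError("correct and participant must align")
    if len(set(pid)) < 2:
        raise ValueError("need at least 2 participants")
    frame = pd.DataFrame({
        "y": y,
        "acuity": [acuity_logmar[p] for p in pid],
        "auc": [auc[p] for p in pid],
    })
    if np.ptp(y) == 0:
        variants = {"acuity": ("acuity",), "auc": ("auc",), "both": ("acuity", "auc")}
        out = {}
        for name, preds in variants.items():
            k = len(preds) + 1
            p_hat = np.full(y.size, y[0])
            out[name] = RecognitionModelResult(
                predictors=preds,
                params=pd.Series(dtype=float), pvalues=pd.Series(dtype=float),
                aic=_binomial_aic(y, p_hat, k), tjur_r2=float("nan"),
                separation=True,
            )
        return out

    results = {}
    for name, preds in (
        ("acuity", ("acuity",)), ("auc", ("auc",)), ("both", ("acuity", "auc"))
    ):
        X = sm.add_constant(frame[list(preds)])
        separation = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.GLM(frame["y"], X, family=sm.families.Binomial()).fit()
            if not np.all(np.isfinite(fit.bse)) or np.max(np.abs(fit.params)) > 30:
                separation = True
        except Exception:
            separation = True
        if separation:
            reg = sm.GLM(frame["y"], X, family=sm.families.Binomial()).fit_regularized(
                alpha=1e-3, L1_wt=0.0)
            params = pd.Series(np.asarray(reg.params), index=X.columns)
            p_hat = np.asarray(
                sm.families.Binomial().link.inverse(X.to_numpy() @ params.to_numpy())
            )
            results[name] = RecognitionModelResult(
                predictors=preds, params=params,
                pvalues=pd.Series(np.nan, index=X.columns),
                aic=_binomial_aic(y, p_hat, X.shape[1]),
                tjur_r2=_tjur(y, p_hat), separation=True,
            )
        else:
            p_hat = np.asarray(fit.fittedvalues)
            results[name] = RecognitionModelResult(
                predictors=preds, params=fit.params, pvalues=fit.pvalues,
                aic=float(fit.aic), tjur_r2=_tjur(y, p_hat),
            )
    return results


def best_recognition_model(results: Mapping[str, RecognitionModelResult]) -> str:
    """Name of the model with the lowest AIC."""
    return min(results, key=lambda k: results[k].aic)
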