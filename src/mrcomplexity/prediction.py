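"""Logistic outcome classifiers evaluated by leave-one-out cross-validation.

Seven fixed variable sets (no variable selection) are fitted per outcome;
every set includes the demographic block.  SAPS II stands in for admission
severity in the combined models because APACHE II is nearly collinear with
it (the Pearson screen below reports such pairs).  Out-of-fold
probabilities from deterministic LOOCV yield the point AUC via the
Mann-Whitney rank identity; medians and 95% CIs come from bootstrap
resampling of the (probability, outcome) pairs.  Sensitivity and
specificity are reported at the Youden-optimal threshold by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import LinAlgWarning
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .association import CLASS_COLUMNS, DEMOGRAPHICS, OUTCOMES


def _unpenalized_logit() -> LogisticRegression:
    # C=1e12 gives the maximum-likelihood fit without a penalty argument;
    # newton-cholesky is exact and fast for n >> p
    return LogisticRegression(C=1e12, solver="newton-cholesky", max_iter=200)

#: the seven classifier variable sets (demographics included in each)
CLASSIFIER_SETS: dict[str, tuple[str, ...]] = {
    "admission": ("saps2", "cci", "gcs"),
    "mrci": ("mrci_24h", "mrci_48h"),
    "mrci_saps2": ("mrci_24h", "mrci_48h", "saps2"),
    "mrc_icu": ("mrc_icu_24h", "mrc_icu_48h"),
    "mrc_icu_saps2": ("mrc_icu_24h", "mrc_icu_48h", "saps2"),
    "medication": CLASS_COLUMNS,
    "full": ("saps2", "cci", "gcs", "mrci_24h", "mrci_48h",
             "mrc_icu_24h", "mrc_icu_48h") + CLASS_COLUMNS,
}


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    outcome: str
    variables: tuple[str, ...]

    def __post_init__(self):
        if self.name not in CLASSIFIER_SETS:
            raise ValueError(f"unknown classifier {self.name!r}; "
                             f"choose from {sorted(CLASSIFIER_SETS)}")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")


def classifier_spec(name: str, outcome: str) -> ClassifierSpec:
    return ClassifierSpec(
        name=name, outcome=outcome,
        variables=DEMOGRAPHICS + tuple(CLASSIFIER_SETS[name]),
    )


@dataclass
class PredictionResult:
    spec: ClassifierSpec
    aic: float
    auc_point: float
    auc_median: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    threshold: float
    importance: pd.Series  # descending
    oof_probs: np.ndarray
    ridge_fallback_folds: int = 0

    @property
    def acceptable(self) -> bool:
        """AUC of at least 0.7 is regarded as acceptable discrimination."""
        return self.auc_median >= 0.7


def _design(spec: ClassifierSpec, analysis_table: pd.DataFrame):
    """Complete-case standardised design matrix and outcome vector.

    Predictors are standardised (the logistic MLE is equivariant under
    affine maps, so fitted probabilities are unchanged) for numerical
    conditioning; a coefficient on this scale is already per-SD.
    """
    frame = analysis_table[list(spec.variables) + [spec.outcome]].dropna()
    X = frame[list(spec.variables)].astype(float)
    X = X.loc[:, X.nunique() > 1]  # constant columns carry no information
    X = (X - X.mean()) / X.std(ddof=0)
    y = frame[spec.outcome].astype(float)
    return X, y


def loocv_predict(
    spec: ClassifierSpec,
    analysis_table: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Out-of-fold probability for each patient from a fit on all others.

    Deterministic given the data.  A fold whose unpenalised fit fails to
    converge falls back to a ridge-stabilised fit; the count of such folds
    is returned alongside.
    """
    X, y = _design(spec, analysis_table)
    n = len(y)
    if n < 20:
        raise ValueError(f"LOOCV needs at least 20 complete cases, got {n}")
    Xv = X.to_numpy()
    yv = y.to_numpy()
    probs = np.empty(n)
    fallbacks = 0
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                warnings.simplefilter("error", LinAlgWarning)
                clf = _unpenalized_logit()
                clf.fit(Xv[mask], yv[mask])
        except Exception:
            clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
            clf.fit(Xv[mask], yv[mask])
            fallbacks += 1
        probs[i] = clf.predict_proba(Xv[i][None, :])[:, 1][0]
        mask[i] = True
    return probs, yv, fallbacks


def auc_rank(probs: np.ndarray, outcomes: np.ndarray) -> float:
    """Point AUC via the Mann-Whitney rank identity.

    Equals the probability that a random positive outranks a random
    negative, with ties counting one half.
    """
    probs = np.asarray(probs, float)
    outcomes = np.asarray(outcomes, float)
    pos = probs[outcomes == 1]
    neg = probs[outcomes == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC undefined: a single outcome class present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def auc_with_ci(
    probs: np.ndarray,
    outcomes: np.ndarray,
    repetitions: int = 10_000,
    seed: int = 0,
) -> tuple[float, float, tuple[float, float]]:
    """Point AUC plus bootstrap median and 95% CI.

    ``repetitions`` bootstrap draws resample (probability, outcome) pairs
    with replacement; single-class resamples are discarded and redrawn.
    Bit-reproducible for a fixed (seed, repetitions).
    """
    probs = np.asarray(probs, float)
    outcomes = np.asarray(outcomes, float)
    point = auc_rank(probs, outcomes)
    rng = np.random.default_rng(seed)
    n = len(probs)
    boot = np.empty(repetitions)
    for r in range(repetitions):
        while True:
            idx = rng.integers(0, n, size=n)
            ys = outcomes[idx]
            if 0.0 < ys.mean() < 1.0:
                break
        boot[r] = auc_rank(probs[idx], ys)
    lo, med, hi = np.percentile(boot, [2.5, 50.0, 97.5])
    return point, float(med), (float(lo), float(hi))


def threshold_metrics(
    probs: np.ndarray,
    outcomes: np.ndarray,
    rule: Literal["youden", "fixed"] = "youden",
    fixed_threshold: float = 0.5,
) -> tuple[float, float, float]:
    """(sensitivity, specificity, threshold) at the configured rule.

    ``youden`` maximises sensitivity + specificity - 1 over the observed
    out-of-fold probabilities (smallest qualifying threshold on ties);
    ``fixed`` classifies at ``fixed_threshold``.
    """
    probs = np.asarray(probs, float)
    outcomes = np.asarray(outcomes, float)
    n_pos = outcomes.sum()
    n_neg = (1 - outcomes).sum()
    if n_pos == 0 or n_neg == 0:
        raise ValueError("metrics undefined: a single outcome class present")
    if rule == "fixed":
        thresholds = np.array([fixed_threshold])
    elif rule == "youden":
        thresholds = np.unique(probs)
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    best = (-np.inf, fixed_threshold, 0.0, 0.0)
    for t in thresholds:
        pred = probs >= t
        sens = float((pred & (outcomes == 1)).sum() / n_pos)
        spec = float((~pred & (outcomes == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        if j > best[0]:
            best = (j, float(t), sens, spec)
    _, threshold, sens, spec = best
    return sens, spec, threshold


def rank_importance(values: Mapping[str, float] | pd.Series) -> pd.Series:
    """Sort importances descending; exact ties break alphabetically."""
    series = pd.Series(values, dtype=float)
    return series.sort_index().sort_values(ascending=False, kind="stable")


def variable_importance(
    spec: ClassifierSpec,
    analysis_table: pd.DataFrame,
    top: int | None = None,
) -> pd.Series:
    """Absolute standardised coefficients of the full-data fit, descending.

    Importance of a predictor is |coefficient| x its standard deviation (the
    effect of a one-SD move on the log-odds); ties break alphabetically.
    A permutation alternative is available via :func:`permutation_importance`.
    """
    X, y = _design(spec, analysis_table)
    clf = _unpenalized_logit()
    clf.fit(X.to_numpy(), y.to_numpy())
    raw = np.abs(clf.coef_[0]) * X.std(ddof=0).to_numpy()
    series = rank_importance(pd.Series(raw, index=X.columns))
    return series.head(top) if top else series


def permutation_importance(
    spec: ClassifierSpec,
    analysis_table: pd.DataFrame,
    n_permutations: int = 20,
    seed: int = 0,
    top: int | None = None,
) -> pd.Series:
    """Mean AUC drop when one predictor is permuted (full-data fit)."""
    X, y = _design(spec, analysis_table)
    clf = _unpenalized_logit()
    clf.fit(X.to_numpy(), y.to_numpy())
    base = auc_rank(clf.predict_proba(X.to_numpy())[:, 1], y.to_numpy())
    rng = np.random.default_rng(seed)
    drops = {}
    for col in X.columns:
        vals = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            vals.append(base - auc_rank(clf.predict_proba(Xp.to_numpy())[:, 1],
                                        y.to_numpy()))
        drops[col] = float(np.mean(vals))
    series = rank_importance(drops)
    return series.head(top) if top else series


def model_aic(spec: ClassifierSpec, analysis_table: pd.DataFrame) -> float:
    """AIC = deviance + 2 x parameter count of the full-data fit."""
    X, y = _design(spec, analysis_table)
    clf = _unpenalized_logit()
    clf.fit(X.to_numpy(), y.to_numpy())
    p = np.clip(clf.predict_proba(X.to_numpy())[:, 1], 1e-12, 1 - 1e-12)
    yv = y.to_numpy()
    deviance = -2.0 * np.sum(yv * np.log(p) + (1 - yv) * np.log(1 - p))
    k = X.shape[1] + 1  # coefficients + intercept
    return float(deviance + 2 * k)


def evaluate_classifier(
    spec: ClassifierSpec,
    analysis_table: pd.DataFrame,
    repetitions: int = 10_000,
    seed: int = 0,
    threshold_rule: Literal["youden", "fixed"] = "youden",
) -> PredictionResult:
    probs, yv, fallbacks = loocv_predict(spec, analysis_table)
    point, med, ci = auc_with_ci(probs, yv, repetitions=repetitions, seed=seed)
    sens, spec_, threshold = threshold_metrics(probs, yv, rule=threshold_rule)
    return PredictionResult(
        spec=spec,
        aic=model_aic(spec, analysis_table),
        auc_point=point,
        auc_median=med,
        auc_ci=ci,
        sensitivity=sens,
        specificity=spec_,
        threshold=threshold,
        importance=variable_importance(spec, analysis_table, top=10),
        oof_probs=probs,
        ridge_fallback_folds=fallbacks,
    )


def compare_classifiers(
    results: Sequence[PredictionResult],
) -> pd.DataFrame:
    """Comparison table per outcome: AIC, AUC (median, 95% CI), sens, spec.

    The best three models per outcome are flagged, ranked by AUC median with
    AIC as tie-breaker (lower better).
    """
    rows = []
    for res in results:
        rows.append({
            "outcome": res.spec.outcome,
            "model": res.spec.name,
            "aic": res.aic,
            "auc": res.auc_point,
            "auc_median": res.auc_median,
            "auc_ci_low": res.auc_ci[0],
            "auc_ci_high": res.auc_ci[1],
            "sensitivity": res.sensitivity,
            "specificity": res.specificity,
            "acceptable": res.acceptable,
        })
    frame = pd.DataFrame(rows)
    frame["best3"] = False
    for outcome, group in frame.groupby("outcome"):
        ranked = group.sort_values(["auc_median", "aic"],
                                   ascending=[False, True]).head(3)
        frame.loc[ranked.index, "best3"] = True
    return frame


def pearson_screen(
    analysis_table: pd.DataFrame,
    columns: Sequence[str],
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Report predictor pairs whose |Pearson r| exceeds the threshold.

    Nothing is dropped silently; the report documents exclusions such as
    APACHE II from the combined severity classifiers.
    """
    corr = analysis_table[list(columns)].corr(method="pearson")
    pairs = []
    for i, a in enumerate(columns):
        for b in columns[i + 1:]:
            r = corr.loc[a, b]
            if abs(r) > threshold:
                pairs.append({"var_a": a, "var_b": b, "pearson_r": float(r)})
    return pd.DataFrame(pairs, columns=["var_a", "var_b", "pearson_r"])
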