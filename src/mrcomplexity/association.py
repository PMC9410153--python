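"""Multivariable logistic association models with forward selection.

Four candidate sets (Models I-IV) are fitted per binary outcome: severity
scores only, each complexity instrument with its 24 h / 48 h values, and
the union.  Predictors enter by stepwise forward selection at p < 0.05
(add-one Wald test, ties broken lexicographically); the final model is
refitted jointly and reported as OR (95% CI).  An L1-penalised (LASSO)
fit with cross-validated penalty confirms the selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .records import DRUG_CLASSES

OUTCOMES = ("mortality", "los_gt_48", "mv")

DEMOGRAPHICS = ("age", "sex_male", "height", "weight", "bmi",
                "race_white", "race_black", "race_hispanic", "race_asian")

CLASS_COLUMNS = tuple(f"class_{name}" for name in DRUG_CLASSES)


@dataclass(frozen=True)
class ModelSpec:
    """Candidate-variable set for one association model and outcome."""

    model_id: Literal["I", "II", "III", "IV"]
    outcome: str
    candidates: tuple[str, ...]

    def __post_init__(self):
        if self.outcome == "los_gt_48":
            offenders = [c for c in self.candidates if c.endswith("_48h")]
            if offenders:
                raise ValueError(
                    f"48 h scores {offenders} are not admissible candidates for "
                    "the LOS outcome (the outcome is defined at the same 48 h "
                    "threshold)"
                )


def model_candidates(model_id: str, outcome: str) -> ModelSpec:
    """Build the Model I-IV candidate list for an outcome.

    Model I: demographics, APACHE II, SAPS II, CCI and the 15 medication
    classes.  Model II: demographics, MRCI at 24 h and 48 h, CCI, classes.
    Model III: demographics, MRC-ICU at 24 h and 48 h, CCI, classes.
    Model IV: the union.  For the prolonged-LOS outcome the 48 h scores are
    dropped from every set, since the outcome itself is defined at 48 h.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    base = DEMOGRAPHICS + ("cci",) + CLASS_COLUMNS
    if model_id == "I":
        extra = ("apache2", "saps2")
    elif model_id == "II":
        extra = ("mrci_24h", "mrci_48h")
    elif model_id == "III":
        extra = ("mrc_icu_24h", "mrc_icu_48h")
    elif model_id == "IV":
        extra = ("apache2", "saps2", "mrci_24h", "mrci_48h",
                 "mrc_icu_24h", "mrc_icu_48h")
    else:
        raise ValueError(f"unknown model id {model_id!r}")
    if outcome == "los_gt_48":
        extra = tuple(c for c in extra if not c.endswith("_48h"))
    return ModelSpec(model_id=model_id, outcome=outcome, candidates=base + extra)


@dataclass
class AssociationFit:
    """Final stepwise-selected logistic fit for one model/outcome cell."""

    model_id: str
    outcome: str
    selected: tuple[str, ...]
    table: pd.DataFrame  # coef, se, or_, ci_low, ci_high, p per selected variable
    converged: bool
    selection_path: tuple[tuple[str, float], ...] = ()
    notes: tuple[str, ...] = ()


def build_design_matrix(
    spec: ModelSpec,
    analysis_table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Complete-case design matrix and outcome vector for one model.

    Race/ethnicity is already expanded to indicator columns against the
    composite non-White/non-Hispanic reference; drug classes are binary
    exposure indicators.  Constant columns are dropped with a warning (they
    cannot enter a logistic fit).  Returns (X, y, dropped).
    """
    missing = [c for c in spec.candidates + (spec.outcome,)
               if c not in analysis_table.columns]
    if missing:
        raise KeyError(f"analysis table lacks columns {missing}")
    frame = analysis_table[list(spec.candidates) + [spec.outcome]].dropna()
    y = frame[spec.outcome].astype(float)
    X = frame[list(spec.candidates)].astype(float)
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant candidate columns {dropped}")
        X = X.drop(columns=dropped)
    return X, y, dropped


def _fit_logit(X: pd.DataFrame, y: pd.Series):
    """MLE logistic fit with an intercept; returns (result, columns, converged).

    Fits on internally standardised predictors (the logistic MLE is
    equivariant under affine predictor maps, so Wald statistics are
    unchanged) and returns coefficients mapped back to the original scale.
    A fit that raises (e.g. perfect separation) returns ``(None, cols,
    False)`` so callers can skip or flag it.
    """
    design = sm.add_constant(X, has_constant="add")
    cols = list(design.columns)
    Z = np.asarray(design, float).copy()
    scale = np.ones(Z.shape[1])
    for j in range(1, Z.shape[1]):
        mu, sd = Z[:, j].mean(), Z[:, j].std()
        if sd > 0:
            Z[:, j] = (Z[:, j] - mu) / sd
            scale[j] = sd
    model = sm.Logit(np.asarray(y, float), Z)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(disp=0, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            return None, cols, False
    # undo the standardisation (intercept is reported as-is and unused)
    res._params_orig = np.asarray(res.params, float) / scale
    res._bse_orig = np.asarray(res.bse, float) / scale
    return res, cols, converged


def _wald_p_for(res, columns: list[str], name: str) -> float:
    idx = columns.index(name)
    return float(res.pvalues[idx])


def stepwise_forward_logistic(
    X: pd.DataFrame,
    y: pd.Series,
    alpha: float = 0.05,
    model_id: str = "",
    outcome: str = "",
    min_events: int = 10,
) -> AssociationFit:
    """Forward selection: add the smallest-p candidate while p < alpha.

    At each step every remaining candidate is tested by the Wald p-value of
    its coefficient when added to the current model; the smallest-p candidate
    (lexicographic tie-break) enters if p < alpha, otherwise selection stops.
    The final model is refitted jointly on the selected set.  With no
    qualifying candidate the fit is intercept-only.
    """
    notes: list[str] = []
    events = int(min(y.sum(), (1 - y).sum()))
    if events < min_events:
        notes.append(f"only {events} events in the rarer outcome class")
        warnings.warn(notes[-1])

    selected: list[str] = []
    path: list[tuple[str, float]] = []
    remaining = sorted(X.columns)
    while remaining:
        best_name, best_p = None, np.inf
        for name in remaining:  # lexicographic order breaks exact ties
            trial = X[selected + [name]]
            res, cols, conv = _fit_logit(trial, y)
            if res is None or not conv:
                continue  # separation or non-convergence: candidate not addable
            p = _wald_p_for(res, cols, cols[-1])
            if np.isnan(p):
                continue
            if p < best_p:
                best_name, best_p = name, p
        if best_name is None or best_p >= alpha:
            break
        selected.append(best_name)
        path.append((best_name, float(best_p)))
        remaining.remove(best_name)

    res, cols, converged = _fit_logit(X[selected], y)
    if res is None:
        raise RuntimeError(
            f"joint refit of selected variables {selected} failed to converge"
        )
    params = res._params_orig
    bse = res._bse_orig
    pvals = np.asarray(res.pvalues, float)
    z = stats.norm.ppf(0.975)
    rows = []
    for i, name in enumerate(cols):
        if name == "const":
            continue
        coef, se = params[i], bse[i]
        rows.append({
            "variable": name,
            "coef": coef,
            "se": se,
            "or_": float(np.exp(coef)),
            "ci_low": float(np.exp(coef - z * se)),
            "ci_high": float(np.exp(coef + z * se)),
            "p": float(pvals[i]),
        })
    table = pd.DataFrame(rows, columns=["variable", "coef", "se", "or_",
                                        "ci_low", "ci_high", "p"])
    return AssociationFit(
        model_id=model_id,
        outcome=outcome,
        selected=tuple(selected),
        table=table,
        converged=converged,
        selection_path=tuple(path),
        notes=tuple(notes),
    )


def lasso_logistic(
    X: pd.DataFrame,
    y: pd.Series,
    lambda_rule: Literal["min", "1se"] = "min",
    n_folds: int = 10,
    n_lambdas: int = 30,
    seed: int = 0,
) -> tuple[tuple[str, ...], pd.Series]:
    """L1-penalised logistic fit with cross-validated penalty strength.

    Predictors are standardised internally; the penalty is chosen over a
    log-spaced grid by minimum mean CV deviance (or the one-standard-error
    rule).  Returns the nonzero-coefficient variable set and the penalised
    coefficients on the original predictor scale.
    """
    y_arr = np.asarray(y, float)
    if len(np.unique(y_arr)) < 2:
        raise ValueError("degenerate outcome: only one class present")
    mu = X.mean()
    sd = X.std(ddof=0).replace(0.0, 1.0)
    Z = (X - mu) / sd

    n = len(y_arr)
    lambdas = np.logspace(-3, 1.2, n_lambdas)  # per-observation penalty scale
    n_folds = min(n_folds, int(min(y_arr.sum(), n - y_arr.sum())))
    if n_folds < 2:
        raise ValueError("too few events for cross-validated penalty selection")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    deviances = np.zeros((n_lambdas, n_folds))
    for j, (train, test) in enumerate(cv.split(Z, y_arr)):
        for i, lam in enumerate(lambdas):
            clf = LogisticRegression(l1_ratio=1, solver="liblinear",
                                     C=1.0 / (lam * len(train)), max_iter=2000)
            clf.fit(Z.iloc[train], y_arr[train])
            p = np.clip(clf.predict_proba(Z.iloc[test])[:, 1], 1e-12, 1 - 1e-12)
            yt = y_arr[test]
            deviances[i, j] = -2.0 * np.mean(yt * np.log(p) + (1 - yt) * np.log(1 - p))
    mean_dev = deviances.mean(axis=1)
    if lambda_rule == "min":
        pick = int(np.argmin(mean_dev))
    elif lambda_rule == "1se":
        se_dev = deviances.std(axis=1, ddof=1) / np.sqrt(n_folds)
        best = int(np.argmin(mean_dev))
        within = np.where(mean_dev <= mean_dev[best] + se_dev[best])[0]
        pick = int(within.max())  # sparsest penalty within one SE
    else:
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")

    lam = lambdas[pick]
    clf = LogisticRegression(l1_ratio=1, solver="liblinear",
                             C=1.0 / (lam * n), max_iter=5000)
    clf.fit(Z, y_arr)
    coef_std = pd.Series(clf.coef_[0], index=X.columns)
    coef = coef_std / sd
    selected = tuple(sorted(coef.index[coef_std != 0.0]))
    return selected, coef


def report_associations(
    fits: Mapping[tuple[str, str], AssociationFit],
    digits: int = 2,
) -> pd.DataFrame:
    """Wide report: one row per (model, variable), OR (95% CI) and p per outcome.

    Variables not selected in a cell are dashed.
    """
    by_model: dict[str, list[str]] = {}
    for (model_id, _), fit in sorted(fits.items()):
        seen = by_model.setdefault(model_id, [])
        for name in fit.selected:
            if name not in seen:
                seen.append(name)
    outcomes = sorted({outcome for _, outcome in fits})
    rows = []
    for model_id, variables in by_model.items():
        for name in variables:
            row: dict[str, object] = {"model": model_id, "variable": name}
            for outcome in outcomes:
                fit = fits.get((model_id, outcome))
                cell, pcell = "-", "-"
                if fit is not None and name in fit.selected:
                    rec = fit.table.set_index("variable").loc[name]
                    cell = (f"{rec['or_']:.{digits}f} "
                            f"({rec['ci_low']:.{digits}f}-{rec['ci_high']:.{digits}f})")
                    pcell = f"{rec['p']:.3f}" if rec["p"] >= 0.001 else "<0.001"
                row[f"{outcome}_or"] = cell
                row[f"{outcome}_p"] = pcell
            rows.append(row)
    return pd.DataFrame(rows)
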