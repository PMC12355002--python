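"""Prediction of sinus-rhythm maintenance: LASSO-logistic feature selection
and evaluation.

The modelling stage follows a fixed protocol on a patient-by-feature table
with a binary outcome (1 = sinus rhythm maintained at 3 months):

1. rows with missing features are dropped;
2. the data are split 60/40 into training and testing parts (stratified by
   outcome);
3. continuous features are standardized on the training part and the
   training parameters are applied to the test part (no leakage);
4. L1-penalized (LASSO) logistic regressions are fitted along a
   log-spaced penalty grid with stratified 5-fold cross-validation; the
   features with nonzero coefficients at the CV-optimal penalty are the
   selected set, and the distinct supports along the path are the candidate
   models;
5. each candidate is refitted without penalty, and the final model is the
   one with minimal AIC (ties within 2 AIC points broken by higher training
   AUC, then smaller support);
6. the test part is used only to evaluate the AUC of that final model.

`SinusRhythmModel` wraps the protocol; `fit()` returns a
`SinusRhythmResults` carrying coefficients, their standard errors, the
penalty path, train/test AUC and a `summary()` table.  Univariate per-SD
odds ratios and baseline group comparisons are available on the model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "SinusRhythmModel", "SinusRhythmResults", "UnivariateResult",
    "standardize", "apply_standardization", "inverse_standardization",
    "split_train_test", "lasso_path", "lasso_select", "select_model",
    "mann_whitney_auc", "evaluate_auc", "univariate_or",
    "baseline_comparison", "UndefinedAucError", "ZeroVarianceError",
]


class UndefinedAucError(ValueError):
    """AUC is undefined when one outcome class is absent."""


class ZeroVarianceError(ValueError):
    """A continuous column has zero variance and cannot be standardized."""


# --------------------------------------------------------------------------
# standardization and splitting
# --------------------------------------------------------------------------

def _is_binary(col: pd.Series) -> bool:
    vals = pd.unique(col.dropna())
    return set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def standardize(table: pd.DataFrame, columns=None
                ) -> tuple[pd.DataFrame, dict]:
    """Center/scale continuous columns to mean 0, SD 1; binary (0/1)
    columns pass through.  Returns the standardized frame and the
    per-column (mean, sd) parameters for reuse on a test set."""
    out = table.copy()
    params: dict = {}
    for c in (columns if columns is not None else table.columns):
        col = table[c]
        if not pd.api.types.is_numeric_dtype(col) or _is_binary(col):
            continue
        sd = float(col.std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ZeroVarianceError(f"column {c!r} has zero variance")
        mu = float(col.mean())
        out[c] = (col - mu) / sd
        params[c] = (mu, sd)
    return out, params


def apply_standardization(table: pd.DataFrame, params: dict) -> pd.DataFrame:
    out = table.copy()
    for c, (mu, sd) in params.items():
        if c in out:
            out[c] = (out[c] - mu) / sd
    return out


def inverse_standardization(table: pd.DataFrame, params: dict) -> pd.DataFrame:
    out = table.copy()
    for c, (mu, sd) in params.items():
        if c in out:
            out[c] = out[c] * sd + mu
    return out


def split_train_test(table: pd.DataFrame, train_frac: float = 0.6,
                     seed: int = 0, stratify: bool = True,
                     outcome: str = "outcome"
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test split with train size
    round(train_frac * n); stratified by outcome by default.  If a split
    leaves one partition single-class it is retried with a fresh internal
    seed (at most 100 times)."""
    n = len(table)
    if n < 10:
        raise ValueError("need at least 10 rows to split")
    n_train = round(train_frac * n)
    rng = np.random.default_rng(seed)
    y = table[outcome].to_numpy()
    for _ in range(100):
        if stratify:
            idx_train: list = []
            # largest-remainder apportionment of the train size over classes
            classes = [np.flatnonzero(y == v) for v in np.unique(y)]
            quotas = [len(c) * train_frac for c in classes]
            takes = [int(np.floor(q)) for q in quotas]
            rema = np.argsort([t - q for t, q in zip(takes, quotas)])
            for i in rema:
                if sum(takes) >= n_train:
                    break
                takes[i] += 1
            for cls, take in zip(classes, takes):
                idx_train.extend(rng.permutation(cls)[:take])
            idx_train = np.sort(np.asarray(idx_train))
        else:
            idx_train = np.sort(rng.permutation(n)[:n_train])
        mask = np.zeros(n, dtype=bool)
        mask[idx_train] = True
        train, test = table.iloc[mask], table.iloc[~mask]
        if train[outcome].nunique() > 1 and test[outcome].nunique() > 1:
            return train, test
    raise RuntimeError("could not produce a two-class split in 100 tries")


# --------------------------------------------------------------------------
# AUC (Mann-Whitney, ties counted 1/2)
# --------------------------------------------------------------------------

def mann_whitney_auc(scores, y) -> float:
    """AUC as the Mann-Whitney U statistic of scores vs outcome, with tied
    scores counted 1/2.  Invariant to any strictly monotone transform of
    the scores."""
    scores = np.asarray(scores, float)
    y = np.asarray(y)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise UndefinedAucError("both outcome classes required for an AUC")
    r = stats.rankdata(scores)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


# --------------------------------------------------------------------------
# LASSO path and selection
# --------------------------------------------------------------------------

@dataclass
class LassoSelection:
    """CV outcome of the L1 path: selected features at the CV-optimal
    penalty plus the whole path for candidate construction."""

    selected: list
    lambda_opt: float
    lambdas: np.ndarray
    cv_deviance: np.ndarray          # mean validation deviance per lambda
    cv_deviance_se: np.ndarray       # between-fold standard error
    supports: list                   # support (tuple of names) per lambda
    coefs: np.ndarray                # full-train coefficients per lambda
    rule: str = "1se"


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_points: int = 40,
                 ratio: float = 1e-3) -> np.ndarray:
    n = len(y)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max * 1.05, lam_max * ratio, n_points)


def _l1_fit(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Coefficients of the L1-penalized logistic fit at penalty lam (glmnet
    scale: (1/n) * deviance/2 + lam * |coef|_1, i.e. C = 1/(n*lam))."""
    clf = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                             C=1.0 / (len(y) * lam), max_iter=2000,
                             tol=1e-7)
    clf.fit(X, y)
    return clf.coef_.ravel(), float(clf.intercept_[0])


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lasso_path(train: pd.DataFrame, features, outcome: str = "outcome",
               n_folds: int = 5, lambda_grid=None, seed: int = 0,
               rule: str = "1se") -> LassoSelection:
    """L1 logistic path with stratified, seeded K-fold CV.

    The CV criterion is the mean validation binomial deviance.  With the
    default ``rule='1se'`` the chosen penalty is the largest (sparsest)
    whose mean deviance is within one between-fold standard error of the
    minimum — the standard parsimonious choice for feature *selection*;
    ``rule='min'`` takes the deviance-minimising penalty instead.  The
    selected set is the support of the full-training-set fit at that
    penalty."""
    if rule not in ("1se", "min"):
        raise ValueError("rule must be '1se' or 'min'")
    features = list(features)
    X = train[features].to_numpy(float)
    y = train[outcome].to_numpy(float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    # perfectly collinear duplicates carry no information and make the L1
    # solution non-unique; keep only the first of each identical pair
    keep = []
    for j in range(X.shape[1]):
        if not any(np.array_equal(X[:, j], X[:, k]) for k in keep):
            keep.append(j)
    if len(keep) < len(features):
        dropped = [features[j] for j in range(len(features))
                   if j not in keep]
        warnings.warn(f"dropping duplicated column(s) {dropped} from the "
                      f"penalized path", stacklevel=2)
        features = [features[j] for j in keep]
        X = X[:, keep]
    lambdas = (np.asarray(lambda_grid, float) if lambda_grid is not None
               else _lambda_grid(X, y))

    n_min = int(min(np.bincount(y.astype(int))))
    if n_min < n_folds:
        warnings.warn(f"reducing CV folds from {n_folds} to {n_min} "
                      f"(minority class size)", stacklevel=2)
        n_folds = max(2, n_min)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    fold_dev = np.zeros((len(lambdas), len(folds)))
    for il, lam in enumerate(lambdas):
        for ifold, (tr, va) in enumerate(folds):
            coef, icpt = _l1_fit(X[tr], y[tr], lam)
            eta = X[va] @ coef + icpt
            fold_dev[il, ifold] = _deviance(
                y[va], 1.0 / (1.0 + np.exp(-eta))) / len(va)
    cv_dev = fold_dev.mean(axis=1)
    cv_se = fold_dev.std(axis=1, ddof=1) / np.sqrt(len(folds))

    coefs = np.zeros((len(lambdas), len(features)))
    supports = []
    for il, lam in enumerate(lambdas):
        coef, _ = _l1_fit(X, y, lam)
        coefs[il] = coef
        supports.append(tuple(f for f, c in zip(features, coef) if c != 0.0))

    imin = int(np.argmin(cv_dev))
    if rule == "1se":
        # grid is ordered from largest (sparsest) lambda downward
        within = np.flatnonzero(cv_dev <= cv_dev[imin] + cv_se[imin])
        iopt = int(within[0])
    else:
        iopt = imin
    return LassoSelection(
        selected=list(supports[iopt]), lambda_opt=float(lambdas[iopt]),
        lambdas=lambdas, cv_deviance=cv_dev, cv_deviance_se=cv_se,
        supports=supports, coefs=coefs, rule=rule)


def lasso_select(train: pd.DataFrame, features, outcome: str = "outcome",
                 n_folds: int = 5, lambda_grid=None, seed: int = 0,
                 rule: str = "1se") -> list:
    """Feature names with nonzero coefficients at the CV-chosen penalty."""
    return lasso_path(train, features, outcome, n_folds, lambda_grid,
                      seed, rule).selected


# --------------------------------------------------------------------------
# candidate refits, AIC + training-AUC choice, evaluation
# --------------------------------------------------------------------------

@dataclass
class _Candidate:
    support: tuple
    params: pd.Series
    bse: pd.Series
    aic: float
    auc_train: float
    separation_flag: bool = False


def _refit(train: pd.DataFrame, support, outcome: str) -> _Candidate:
    """Unpenalized logistic refit of one support; AIC is only well defined
    for maximum-likelihood fits.  Perfect separation falls back to a
    ridge-stabilized fit, flagged."""
    y = train[outcome].to_numpy(float)
    names = list(support)
    X = sm.add_constant(train[names].to_numpy(float), has_constant="add")
    cols = ["const"] + names
    flag = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = pd.Series(res.params, index=cols)
        bse = pd.Series(res.bse, index=cols)
        aic = float(res.aic)
    except Exception:
        flag = True
        if names:
            clf = LogisticRegression(C=1e3, max_iter=5000)
            clf.fit(train[names].to_numpy(float), y)
            beta = np.concatenate(([clf.intercept_[0]], clf.coef_.ravel()))
        else:
            p = np.clip(y.mean(), 1e-9, 1 - 1e-9)
            beta = np.array([np.log(p / (1 - p))])
        params = pd.Series(beta, index=cols)
        bse = pd.Series(np.full(len(cols), np.nan), index=cols)
        eta = X @ beta
        aic = _deviance(y, 1 / (1 + np.exp(-eta))) + 2 * len(cols)
    eta = X @ params.to_numpy()
    try:
        auc = mann_whitney_auc(eta, y)
    except UndefinedAucError:
        auc = np.nan
    return _Candidate(tuple(names), params, bse, aic, auc, flag)


def select_model(train: pd.DataFrame, candidate_sets, outcome: str = "outcome",
                 auc_tol: float = 0.01) -> _Candidate:
    """Refit every candidate support without penalty and pick the minimum-
    AIC model; candidates within 2 AIC points of the best are tie-broken by
    higher training AUC, then by smaller support.

    A nested superset's training AUC is almost surely (trivially) higher,
    so AUC differences below ``auc_tol`` are treated as ties and resolved
    toward the smaller support — otherwise the AIC parsimony penalty could
    never act inside the near-tie band."""
    seen, cands = set(), []
    for s in candidate_sets:
        key = tuple(s)
        if key not in seen:
            seen.add(key)
            cands.append(_refit(train, key, outcome))
    if not cands:
        raise ValueError("no candidate feature sets")
    best_aic = min(c.aic for c in cands)
    near = [c for c in cands if c.aic < best_aic + 2.0]
    best_auc = max((c.auc_train for c in near
                    if np.isfinite(c.auc_train)), default=np.nan)
    if np.isfinite(best_auc):
        near = [c for c in near if np.isfinite(c.auc_train)
                and c.auc_train >= best_auc - auc_tol]
    near.sort(key=lambda c: (len(c.support), c.aic,
                             -(c.auc_train if np.isfinite(c.auc_train)
                               else -np.inf)))
    return near[0]


def evaluate_auc(params: pd.Series, test: pd.DataFrame,
                 outcome: str = "outcome") -> tuple[float, pd.DataFrame]:
    """Test-set AUC of the linear score plus ROC points (threshold sweep)."""
    names = [c for c in params.index if c != "const"]
    eta = (test[names].to_numpy(float) @ params[names].to_numpy()
           + params.get("const", 0.0))
    y = test[outcome].to_numpy()
    auc = mann_whitney_auc(eta, y)
    fpr, tpr, thr = roc_curve(y, eta)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, roc


# --------------------------------------------------------------------------
# univariate odds ratios and baseline comparisons
# --------------------------------------------------------------------------

@dataclass
class UnivariateResult:
    feature: str
    odds_ratio: float          # per SD of the (standardized) feature
    ci95: tuple
    p_value: float
    separation_flag: bool = False

    def __post_init__(self):
        if not (self.ci95[0] <= self.odds_ratio <= self.ci95[1]):
            raise ValueError("CI must bracket the odds ratio")


def univariate_or(table: pd.DataFrame, feature: str,
                  outcome: str = "outcome") -> UnivariateResult:
    """Single-feature logistic fit on a standardized column: odds ratio per
    SD with Wald 95% CI and Wald p-value."""
    y = table[outcome].to_numpy(float)
    X = sm.add_constant(table[[feature]].to_numpy(float))
    flag = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        b, se = res.params[1], res.bse[1]
        p = res.pvalues[1]
    except Exception:
        flag = True
        clf = LogisticRegression(C=1e3, max_iter=5000)
        clf.fit(table[[feature]].to_numpy(float), y)
        b = float(clf.coef_[0, 0])
        se, p = np.nan, np.nan
    lo = np.exp(b - 1.96 * se) if np.isfinite(se) else np.exp(b)
    hi = np.exp(b + 1.96 * se) if np.isfinite(se) else np.exp(b)
    return UnivariateResult(feature, float(np.exp(b)),
                            (float(lo), float(hi)), float(p), flag)


def baseline_comparison(table: pd.DataFrame, group_col: str = "outcome",
                        variables=None) -> pd.DataFrame:
    """Per-variable two-group comparison, test chosen as appropriate:
    continuous variables use Student's t when both groups pass a
    Shapiro-Wilk normality screen (p > 0.05), otherwise Mann-Whitney U;
    binary variables use the chi-square test when all expected cell counts
    are >= 5, otherwise Fisher's exact test."""
    groups = [g for _, g in table.groupby(group_col)]
    if len(groups) != 2 or any(len(g) == 0 for g in groups):
        raise ValueError("group column must define two non-empty groups")
    g0, g1 = groups
    rows = []
    for var in (variables if variables is not None
                else [c for c in table.columns if c != group_col]):
        a, b = g0[var].dropna(), g1[var].dropna()
        if _is_binary(table[var]):
            tab = np.array([[(a == 0).sum(), (a == 1).sum()],
                            [(b == 0).sum(), (b == 1).sum()]], float)
            expected = stats.contingency.expected_freq(tab)
            if (expected >= 5).all():
                stat, p, *_ = stats.chi2_contingency(tab)
                test = "chi2"
            else:
                stat, p = stats.fisher_exact(tab)
                test = "fisher"
        else:
            normal = (len(a) >= 3 and len(b) >= 3
                      and stats.shapiro(a).pvalue > 0.05
                      and stats.shapiro(b).pvalue > 0.05)
            if normal:
                stat, p = stats.ttest_ind(a, b)
                test = "t"
            else:
                stat, p = stats.mannwhitneyu(a, b)
                test = "mannwhitney"
        rows.append({"variable": var, "test": test,
                     "statistic": float(stat), "p_value": float(p)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Model / Results objects
# --------------------------------------------------------------------------

class SinusRhythmModel:
    """Logistic prediction of sinus-rhythm maintenance from a cohort table.

    Parameters
    ----------
    table : DataFrame
        One row per patient; feature columns plus a binary outcome column.
        Rows with missing feature values are dropped (mirroring exclusion
        of incomplete cases before modelling).
    features : sequence of str, optional
        Candidate predictor columns; defaults to every column except the
        outcome.
    outcome : str
        Name of the 0/1 outcome column (1 = sinus-rhythm maintenance).
    """

    def __init__(self, table: pd.DataFrame, features=None,
                 outcome: str = "outcome"):
        if outcome not in table.columns:
            raise ValueError(f"outcome column {outcome!r} missing")
        self.outcome = outcome
        self.features = list(features) if features is not None else \
            [c for c in table.columns if c != outcome]
        cols = self.features + [outcome]
        self.table = table[cols].dropna().reset_index(drop=True)
        self.n_dropped = len(table) - len(self.table)
        if not set(np.unique(self.table[outcome])) <= {0, 1}:
            raise ValueError("outcome must be binary 0/1")

    @classmethod
    def from_csv(cls, path, features=None, outcome: str = "outcome"
                 ) -> "SinusRhythmModel":
        return cls(pd.read_csv(path), features=features, outcome=outcome)

    # -- protocol ----------------------------------------------------------

    def fit(self, train_frac: float = 0.6, n_folds: int = 5, seed: int = 0,
            lambda_grid=None, stratify: bool = True, rule: str = "1se"
            ) -> "SinusRhythmResults":
        """Run the full selection/evaluation protocol; see module docstring."""
        train_raw, test_raw = split_train_test(
            self.table, train_frac=train_frac, seed=seed,
            stratify=stratify, outcome=self.outcome)
        train, params = standardize(train_raw, self.features)
        test = apply_standardization(test_raw, params)

        sel = lasso_path(train, self.features, self.outcome,
                         n_folds=n_folds, lambda_grid=lambda_grid, seed=seed,
                         rule=rule)
        candidates = [s for s in sel.supports if s]
        if tuple(sel.selected) not in candidates and sel.selected:
            candidates.append(tuple(sel.selected))
        if not candidates:
            candidates = [()]          # intercept-only: nothing selected
        best = select_model(train, candidates, self.outcome)

        if best.support:
            auc_test, roc = evaluate_auc(best.params, test, self.outcome)
        else:
            auc_test, roc = np.nan, pd.DataFrame(
                columns=["fpr", "tpr", "threshold"])
        return SinusRhythmResults(
            model=self, selected_features=list(best.support),
            params=best.params, bse=best.bse, lambda_=sel.lambda_opt,
            aic_train=best.aic, auc_train=best.auc_train, auc_test=auc_test,
            roc_test=roc, lasso=sel, standardization=params,
            n_train=len(train), n_test=len(test), seed=seed,
            separation_flag=best.separation_flag,
        )

    # -- descriptive analyses (whole dataset) ------------------------------

    def univariate(self, features=None) -> pd.DataFrame:
        """Per-SD univariate odds ratios on the whole (standardized)
        dataset."""
        std, _ = standardize(self.table, self.features)
        rows = []
        for f in (features if features is not None else self.features):
            r = univariate_or(std, f, self.outcome)
            rows.append({"feature": r.feature, "odds_ratio": r.odds_ratio,
                         "ci_lo": r.ci95[0], "ci_hi": r.ci95[1],
                         "p_value": r.p_value})
        return pd.DataFrame(rows)

    def baseline_table(self, variables=None) -> pd.DataFrame:
        """Group comparison of every variable between outcome classes."""
        return baseline_comparison(self.table, self.outcome, variables)


@dataclass
class SinusRhythmResults:
    """Fitted protocol: selected features, ML coefficients (log-odds per SD
    for continuous features), penalty path, and train/test performance."""

    model: SinusRhythmModel
    selected_features: list
    params: pd.Series
    bse: pd.Series
    lambda_: float
    aic_train: float
    auc_train: float
    auc_test: float
    roc_test: pd.DataFrame
    lasso: LassoSelection
    standardization: dict
    n_train: int
    n_test: int
    seed: int
    separation_flag: bool = False

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Probability of sinus-rhythm maintenance for new (raw-scale)
        rows; the stored training standardization is applied first."""
        std = apply_standardization(table, self.standardization)
        names = [c for c in self.params.index if c != "const"]
        eta = (std[names].to_numpy(float) @ self.params[names].to_numpy()
               + self.params.get("const", 0.0))
        return 1.0 / (1.0 + np.exp(-eta))

    def odds_ratios(self) -> pd.DataFrame:
        rows = []
        for name in self.params.index:
            if name == "const":
                continue
            b, se = self.params[name], self.bse[name]
            rows.append({
                "feature": name, "odds_ratio": float(np.exp(b)),
                "ci_lo": float(np.exp(b - 1.96 * se)),
                "ci_hi": float(np.exp(b + 1.96 * se)),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Sinus-rhythm maintenance model (LASSO-selected, ML refit)",
            "=" * 58,
            f"n train / test:      {self.n_train} / {self.n_test} "
            f"(seed {self.seed})",
            f"penalty (CV-opt):    lambda = {self.lambda_:.5f}",
            f"selected features:   "
            f"{', '.join(self.selected_features) or '(none)'}",
            f"AIC (train):         {self.aic_train:.2f}",
            f"AUC train / test:    {self.auc_train:.3f} / "
            f"{self.auc_test:.3f}",
        ]
        if self.separation_flag:
            lines.append("note: ridge-stabilized refit (separation)")
        lines.append("-" * 58)
        lines.append(f"{'term':<14}{'coef':>10}{'se':>10}{'OR':>10}")
        for name in self.params.index:
            b = self.params[name]
            se = self.bse[name]
            orr = np.exp(b) if name != "const" else np.nan
            lines.append(f"{name:<14}{b:>10.3f}{se:>10.3f}"
                         f"{orr:>10.3f}" if np.isfinite(orr) else
                         f"{name:<14}{b:>10.3f}{se:>10.3f}{'':>10}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC curve of the test set (matplotlib axes returned)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc_test["fpr"], self.roc_test["tpr"],
                label=f"test AUC = {self.auc_test:.2f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        return ax

    def to_report(self) -> dict:
        return {
            "selected_features": self.selected_features,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "lambda": self.lambda_,
            "aic_train": float(self.aic_train),
            "auc_train": float(self.auc_train),
            "auc_test": (float(self.auc_test)
                         if np.isfinite(self.auc_test) else None),
            "n_train": self.n_train,
            "n_test": self.n_test,
            "seed": self.seed,
            "separation_flag": self.separation_flag,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_report(), fh, indent=2)
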