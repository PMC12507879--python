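"""Statistical protocol: split, screening, stepwise logistic regression,
ROC/Youden evaluation, cross-validation, and inter-rater ICC.

The protocol mirrors a standard clinical-prediction workflow:

1. stratified 6:4 split into training and validation sets;
2. group comparison of candidate features (Welch t / Mann-Whitney for
   continuous data after a Kolmogorov-Smirnov normality screen; chi-square
   with Fisher fallback for categorical data);
3. univariate logistic screening (p < 0.05), then multivariate logistic
   regression with backward stepwise elimination on Wald p-values;
4. ROC analysis: AUC by the Mann-Whitney statistic with DeLong 95% CI,
   operating point by the Youden index, with
   sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
   accuracy = (TP+TN)/(TP+TN+FP+FN);
5. stratified five-fold cross-validation refitting the whole recipe per
   fold;
6. ICC(2,1) — two-way random effects, single measure, absolute agreement —
   for intra-/inter-rater reliability.

Logistic fits are maximum likelihood via statsmodels; everything reported
(odds ratios, Wald CIs and p-values) comes from the fitted model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import DegenerateInputError, InputError, RankDeficiencyError

ALPHA = 0.05
Z_95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# Cohort split

def split_cohort(labels: Sequence[int], train_fraction: float = 0.6,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/validation split of subject indices.

    Each class contributes ``round(train_fraction * n_class)`` subjects to
    the training set; the partition is disjoint, exhaustive and
    reproducible under the seed.
    """
    labels = np.asarray(labels)
    if not 0 < train_fraction < 1:
        raise InputError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, val = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise InputError(f"class {cls} has fewer than 2 members")
        rng.shuffle(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train.append(idx[:n_train])
        val.append(idx[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(val))


# ---------------------------------------------------------------------------
# Group comparison

@dataclass
class GroupComparison:
    test: str          # "welch_t" | "mann_whitney" | "chi_square" | "fisher"
    statistic: float
    p_value: float


def _is_normal(x: np.ndarray, alpha: float = ALPHA) -> bool:
    if x.size < 3 or np.std(x, ddof=1) == 0:
        return False
    z = (x - x.mean()) / np.std(x, ddof=1)
    return stats.kstest(z, "norm").pvalue > alpha


def group_compare(values: Sequence, labels: Sequence[int],
                  categorical: bool = False) -> GroupComparison:
    """Compare one feature between the two groups.

    Continuous features: Kolmogorov-Smirnov normality screen on each group,
    then Welch's t-test if both pass, Mann-Whitney U otherwise.
    Categorical features: chi-square on the contingency table without
    continuity correction, falling back to Fisher's exact test when any
    expected cell of a 2x2 table is below 5.
    """
    labels = np.asarray(labels)
    if categorical:
        table = pd.crosstab(pd.Series(values, name="value"),
                            pd.Series(labels, name="group")).to_numpy()
        if table.shape[1] < 2 or table.shape[0] < 2:
            raise DegenerateInputError("feature or grouping is constant")
        chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
        if table.shape == (2, 2) and (expected < 5).any():
            odds, p = stats.fisher_exact(table)
            return GroupComparison("fisher", float(odds), float(p))
        return GroupComparison("chi_square", float(chi2), float(p))

    values = np.asarray(values, dtype=np.float64)
    g0, g1 = values[labels == 0], values[labels == 1]
    if g0.size == 0 or g1.size == 0:
        raise InputError("both groups must be non-empty")
    if np.all(values == values[0]):
        raise DegenerateInputError("feature is constant")
    if _is_normal(g0) and _is_normal(g1):
        t, p = stats.ttest_ind(g0, g1, equal_var=False)
        return GroupComparison("welch_t", float(t), float(p))
    # tie-corrected asymptotic p without continuity correction, so that
    # identical groups score exactly p = 1
    u, p = stats.mannwhitneyu(g0, g1, alternative="two-sided",
                              use_continuity=False, method="asymptotic")
    return GroupComparison("mann_whitney", float(u), float(p))


# ---------------------------------------------------------------------------
# Logistic regression

@dataclass
class LogisticModel:
    predictor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    std_errors: np.ndarray
    odds_ratios: np.ndarray
    or_ci_low: np.ndarray
    or_ci_high: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_obs: int
    llf: float = math.nan       # fitted log-likelihood
    llnull: float = math.nan    # intercept-only log-likelihood

    @property
    def lr_p_value(self) -> float:
        """Likelihood-ratio test p-value of the whole model against the
        intercept-only fit; usable when Wald inference degenerates
        (quasi-separation)."""
        lr = 2.0 * (self.llf - self.llnull)
        return float(stats.chi2.sf(max(lr, 0.0), df=len(self.predictor_names)))

    def predict(self, data: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predicted probability of the positive class."""
        if isinstance(data, pd.DataFrame):
            x = data[self.predictor_names].to_numpy(dtype=np.float64)
        else:
            x = np.asarray(data, dtype=np.float64)
        eta = self.intercept + x @ self.coefficients
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-eta))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "predictor": self.predictor_names,
            "coef": self.coefficients,
            "OR": self.odds_ratios,
            "OR_CI_low": self.or_ci_low,
            "OR_CI_high": self.or_ci_high,
            "p": self.p_values,
        })


def fit_logistic(design: pd.DataFrame, labels: Sequence[int],
                 maxiter: int = 100) -> LogisticModel:
    """Maximum-likelihood logistic regression with Wald inference.

    ``design`` holds one column per predictor (no constant; one is added).
    Raises :class:`RankDeficiencyError` on collinear designs; perfect
    separation is flagged by ``converged = False`` rather than raised.
    """
    if not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(np.asarray(design))
        design.columns = [f"x{i}" for i in range(design.shape[1])]
    y = np.asarray(labels, dtype=np.float64)
    x = design.to_numpy(dtype=np.float64)
    if x.shape[0] != y.size:
        raise InputError("design and labels differ in length")
    if not np.all(np.isfinite(x)):
        raise InputError("design matrix contains missing values; drop them "
                         "listwise before fitting")
    if np.linalg.matrix_rank(sm.add_constant(x, has_constant="add")) \
            < x.shape[1] + 1:
        raise RankDeficiencyError("design matrix is rank deficient")

    # fit on standardised predictors for numerical stability, then map the
    # estimates back to per-original-unit scale (Wald p-values are invariant)
    loc = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    z = sm.add_constant((x - loc) / scale, has_constant="add")

    separation = False
    with warnings.catch_warnings(), np.errstate(over="ignore"):
        warnings.simplefilter("ignore")
        try:
            result = sm.Logit(y, z).fit(disp=0, maxiter=maxiter,
                                        tol=1e-8, warn_convergence=False)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
            result = sm.Logit(y, z).fit(method="bfgs", disp=0,
                                        maxiter=2 * maxiter)
    params_z = np.asarray(result.params, dtype=np.float64)
    try:
        bse_z = np.asarray(result.bse, dtype=np.float64)
        pvals = np.asarray(result.pvalues, dtype=np.float64)
    except np.linalg.LinAlgError:
        bse_z = np.full(params_z.size, np.nan)
        pvals = np.full(params_z.size, np.nan)
    if separation:
        pvals = np.full(params_z.size, np.nan)

    coef = params_z[1:] / scale
    intercept = float(params_z[0] - np.sum(params_z[1:] * loc / scale))
    bse = bse_z[1:] / scale
    # a (quasi-)separated fit drives the likelihood to ~0 with runaway
    # coefficients; Wald inference is meaningless there
    if result.llf > -1e-4 or np.max(np.abs(params_z)) > 25:
        separation = True
        pvals = np.full(params_z.size, np.nan)
    converged = (not separation
                 and bool(getattr(result, "mle_retvals",
                                  {}).get("converged", True))
                 and np.all(np.isfinite(bse)))
    with np.errstate(over="ignore"):
        return LogisticModel(
            predictor_names=list(design.columns),
            coefficients=coef,
            intercept=intercept,
            std_errors=bse,
            odds_ratios=np.exp(coef),
            or_ci_low=np.exp(coef - Z_95 * bse),
            or_ci_high=np.exp(coef + Z_95 * bse),
            p_values=pvals[1:],
            converged=converged,
            n_obs=int(y.size),
            llf=float(result.llf),
            llnull=float(result.llnull),
        )


def univariate_screen(data: pd.DataFrame, label_col: str,
                      candidate_cols: Sequence[str],
                      alpha: float = ALPHA
                      ) -> tuple[list[str], dict[str, LogisticModel]]:
    """Single-predictor logistic fits; keep predictors with Wald p < alpha.

    Rows with a missing value of the candidate are dropped for that
    candidate only; constant or unfittable candidates are screened out.
    """
    kept: list[str] = []
    fits: dict[str, LogisticModel] = {}
    for col in candidate_cols:
        sub = data[[col, label_col]].dropna()
        if sub[col].nunique() < 2 or sub[label_col].nunique() < 2:
            continue
        try:
            model = fit_logistic(sub[[col]], sub[label_col])
        except (RankDeficiencyError, InputError, np.linalg.LinAlgError):
            continue
        fits[col] = model
        p = model.p_values[0]
        if not np.isfinite(p):
            # Wald inference degenerates under (quasi-)separation even
            # though the predictor is maximally informative; fall back to
            # the likelihood-ratio test
            p = model.lr_p_value
        if np.isfinite(p) and p < alpha:
            kept.append(col)
    return kept, fits


def backward_stepwise(data: pd.DataFrame, label_col: str,
                      candidate_cols: Sequence[str], alpha: float = ALPHA
                      ) -> tuple[LogisticModel, list[str]]:
    """Backward elimination on Wald p-values.

    Starts from the full multivariate model and repeatedly removes the
    predictor with the largest p while that p exceeds ``alpha``, stopping
    when all remaining predictors are significant or only one is left.
    Returns the final model and the removal order.
    """
    cols = list(candidate_cols)
    if not cols:
        raise InputError("no candidate predictors to select from")
    sub = data[list(cols) + [label_col]].dropna()
    removed: list[str] = []
    while True:
        model = fit_logistic(sub[cols], sub[label_col])
        if len(cols) == 1:
            return model, removed
        pvals = np.where(np.isfinite(model.p_values), model.p_values, 1.0)
        worst = int(np.argmax(pvals))
        if pvals[worst] <= alpha:
            return model, removed
        removed.append(cols.pop(worst))


# ---------------------------------------------------------------------------
# ROC / AUC / Youden

@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else math.nan


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J statistic: sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


@dataclass
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> AucResult:
    """AUC via the Mann-Whitney statistic (ties count 1/2) with a DeLong
    95% confidence interval."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise InputError("both classes must be present")
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(np.float64) + 0.5 * (diff == 0)
    auc = float(psi.mean())
    v10 = psi.mean(axis=1)   # per-positive placements
    v01 = psi.mean(axis=0)   # per-negative placements
    s10 = float(np.var(v10, ddof=1)) if pos.size > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if neg.size > 1 else 0.0
    se = math.sqrt(s10 / pos.size + s01 / neg.size)
    return AucResult(auc=auc,
                     ci_low=max(0.0, auc - Z_95 * se),
                     ci_high=min(1.0, auc + Z_95 * se),
                     n_pos=int(pos.size), n_neg=int(neg.size))


@dataclass
class RocSummary:
    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    accuracy: float
    youden: float
    counts: ConfusionCounts


def confusion_at(scores: np.ndarray, labels: np.ndarray,
                 cutoff: float) -> ConfusionCounts:
    """Counts when ``score >= cutoff`` predicts the positive class."""
    pred = np.asarray(scores) >= cutoff
    labels = np.asarray(labels).astype(bool)
    return ConfusionCounts(tp=int(np.sum(pred & labels)),
                           fp=int(np.sum(pred & ~labels)),
                           fn=int(np.sum(~pred & labels)),
                           tn=int(np.sum(~pred & ~labels)))


def candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct sorted scores, plus sentinels
    below and above the score range."""
    uniq = np.unique(scores)
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    return np.concatenate(([-np.inf], mids, [np.inf]))


def youden_cutoff(scores: Sequence[float], labels: Sequence[int]) -> RocSummary:
    """Operating-point selection by the Youden index.

    Scans every candidate cutoff (``score >= cutoff`` = positive call) and
    keeps the one maximising sensitivity + specificity - 1; ties break to
    higher sensitivity, then to the lower cutoff.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    auc = roc_auc(scores, labels)
    best: tuple[float, float, float, ConfusionCounts] | None = None
    for cut in candidate_cutoffs(scores):
        c = confusion_at(scores, labels, cut)
        j = youden_index(c.sensitivity, c.specificity)
        key = (j, c.sensitivity, -cut)
        if best is None or key > (best[0], best[1], -best[2]):
            best = (j, c.sensitivity, cut, c)
    j, _, cut, counts = best  # type: ignore[misc]
    return RocSummary(auc=auc.auc, auc_ci=(auc.ci_low, auc.ci_high),
                      cutoff=float(cut),
                      sensitivity=counts.sensitivity,
                      specificity=counts.specificity,
                      accuracy=counts.accuracy,
                      youden=j, counts=counts)


# ---------------------------------------------------------------------------
# Full model recipe (screen -> stepwise -> final fit)

@dataclass
class RecipeResult:
    candidates: list[str]
    screened: list[str]
    univariate_fits: dict[str, LogisticModel]
    full_model: LogisticModel | None      # all screened predictors together
    final_model: LogisticModel | None     # after backward elimination
    removal_order: list[str] = field(default_factory=list)


def fit_recipe(train: pd.DataFrame, label_col: str,
               candidate_cols: Sequence[str],
               alpha: float = ALPHA) -> RecipeResult:
    """Univariate screen, multivariate fit, backward stepwise selection.

    Returns both the full pre-selection multivariate model and the final
    selected model; either may be ``None`` when no predictor survives the
    screen.  Collinear screened sets are pruned greedily before the
    multivariate fit.
    """
    screened, fits = univariate_screen(train, label_col, candidate_cols, alpha)
    result = RecipeResult(candidates=list(candidate_cols), screened=screened,
                          univariate_fits=fits, full_model=None,
                          final_model=None)
    if not screened:
        return result
    sub = train[screened + [label_col]].dropna()
    usable = list(screened)
    # drop collinear columns (keep first occurrence) so Wald tests exist
    while len(usable) > 1:
        x = sm.add_constant(sub[usable].to_numpy(dtype=np.float64),
                            has_constant="add")
        if np.linalg.matrix_rank(x) == x.shape[1]:
            break
        usable.pop()
    try:
        result.full_model = fit_logistic(sub[usable], sub[label_col])
        result.final_model, result.removal_order = backward_stepwise(
            sub, label_col, usable, alpha)
    except (RankDeficiencyError, InputError, np.linalg.LinAlgError):
        result.full_model = None
        result.final_model = None
    return result


def score_with_model(model: LogisticModel, data: pd.DataFrame,
                     label_col: str) -> tuple[np.ndarray, np.ndarray]:
    """Predicted probabilities and aligned labels, after listwise removal
    of rows missing any model predictor."""
    sub = data[model.predictor_names + [label_col]].dropna()
    return model.predict(sub), sub[label_col].to_numpy()


# ---------------------------------------------------------------------------
# Cross-validation

@dataclass
class CvResult:
    fold_aucs: list[float]
    mean_auc: float
    seed: int


def five_fold_cv(train: pd.DataFrame, label_col: str,
                 candidate_cols: Sequence[str], seed: int = 0,
                 n_splits: int = 5, alpha: float = ALPHA) -> CvResult:
    """Stratified k-fold refit of the entire recipe.

    Each fold re-runs screening, stepwise selection and the final fit on
    the remaining folds and scores the held-out fold; a fold whose recipe
    yields no model scores at chance (constant score, AUC 0.5).
    """
    from sklearn.model_selection import StratifiedKFold

    y = train[label_col].to_numpy()
    counts = np.bincount(y.astype(int))
    if counts.min() < n_splits:
        raise InputError(f"need >= {n_splits} subjects per class")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    fold_aucs: list[float] = []
    for fit_idx, hold_idx in skf.split(np.zeros(len(y)), y):
        fit_df = train.iloc[fit_idx]
        hold_df = train.iloc[hold_idx]
        recipe = fit_recipe(fit_df, label_col, candidate_cols, alpha)
        if recipe.final_model is None:
            fold_aucs.append(0.5)
            continue
        scores, labels = score_with_model(recipe.final_model, hold_df,
                                          label_col)
        fold_aucs.append(roc_auc(scores, labels).auc)
    return CvResult(fold_aucs=fold_aucs,
                    mean_auc=float(np.mean(fold_aucs)), seed=seed)


# ---------------------------------------------------------------------------
# Intraclass correlation

def icc_two_way_random(ratings: np.ndarray | pd.DataFrame) -> float:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    ``ratings`` is a complete subjects x raters matrix.  Computed from the
    two-way ANOVA mean squares as
    ``(MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)``.
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise InputError("need a 2-D matrix with >= 2 subjects and raters")
    if not np.all(np.isfinite(x)):
        raise InputError("ratings matrix must be complete")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r <= 0:
        raise DegenerateInputError("no between-subject variance")
    return float((ms_r - ms_e)
                 / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n))
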