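"""Grade-association statistics: screening, logistic modelling, ROC.

This module implements the cohort-level workflow that links the 54
image features and clinical covariates to pathologic grade:

* grade grouping of histologic subtypes (IASLC/ATS/ERS predominant
  pattern: low = AIS/MIA, intermediate = lepidic/acinar/papillary,
  high = solid/micropapillary/colloid/invasive mucinous);
* inter-rater agreement (Cohen's kappa with qualitative bands);
* 2×2 association (Pearson chi-square, or Fisher's exact test when any
  expected cell is below 5);
* a per-feature univariate screen (Welch t-test when both groups pass
  Shapiro–Wilk normality, otherwise Mann–Whitney U);
* maximum-likelihood logistic regression (IRLS) with Wald inference,
  backward elimination, ROC/Youden analysis and the DeLong test for
  correlated AUCs.

The statsmodels-style entry point is :class:`GradeModel`: build it from
a cohort DataFrame, call :meth:`GradeModel.fit`, and read the
:class:`GradeModelResults` (univariate table, clinical and texture
logistic models, ROC summaries, DeLong comparison, ``summary()``).

Outcome coding follows the convention needed to reproduce standard
clinical-model reporting: model coefficients are for the probability of
*intermediate* grade (so a smoker OR < 1 means smokers are less likely
intermediate), while ROC sensitivity/specificity take *high* grade as
the positive class.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from .errors import (
    ClassificationError,
    DesignError,
    ParameterError,
    SeparationError,
)
from .features import FEATURE_IDS, FEATURE_NAMES

# --------------------------------------------------------------------------
# grade grouping


_GRADE_RULES = [
    ("low", ("in situ", "ais", "minimally invasive", "mia")),
    ("high", ("micropapillary", "solid", "colloid", "invasive mucinous", "mucinous")),
    ("intermediate", ("lepidic", "acinar", "papillary")),
]


def assign_grade(subtype: str) -> str:
    """Map a histologic subtype label to pathologic grade.

    Accepts labels with or without the word "predominant" (e.g.
    "acinar predominant", "invasive mucinous adenocarcinoma").
    """
    s = str(subtype).strip().lower()
    for grade, keys in _GRADE_RULES:
        if any(k in s for k in keys):
            return grade
    raise ClassificationError(f"unknown histologic subtype: {subtype!r}")


# --------------------------------------------------------------------------
# agreement and 2x2 association


@dataclass
class KappaResult:
    kappa: float
    band: str
    po: float
    pe: float


_KAPPA_BANDS = [
    (0.81, "excellent"),
    (0.61, "substantial"),
    (0.41, "moderate"),
    (0.21, "fair"),
    (-np.inf, "poor"),
]


def cohen_kappa(table) -> KappaResult:
    """Cohen's kappa for a square rater-agreement count table."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1] or (t < 0).any() or t.sum() <= 0:
        raise ParameterError("need a square non-negative count table with total > 0")
    n = t.sum()
    po = np.trace(t) / n
    pe = float((t.sum(axis=1) * t.sum(axis=0)).sum()) / n**2
    if pe >= 1.0:
        kappa = 1.0 if po >= 1.0 else float("nan")
    else:
        kappa = (po - pe) / (1.0 - pe)
    band = "undefined" if np.isnan(kappa) else next(b for lo, b in _KAPPA_BANDS if kappa >= lo)
    return KappaResult(float(kappa), band, float(po), float(pe))


@dataclass
class Assoc2x2Result:
    p: float
    method: str  # "chi-square" | "fisher" | "degenerate"
    statistic: float


def compare_2x2(table) -> Assoc2x2Result:
    """Association test for a 2×2 count table.

    Pearson chi-square without continuity correction when every expected
    cell is at least 5, otherwise Fisher's exact test (two-sided).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ParameterError("need a 2x2 non-negative count table")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        return Assoc2x2Result(float("nan"), "degenerate", float("nan"))
    expected = np.outer(rows, cols) / t.sum()
    if (expected >= 5).all():
        chi2 = float((((t - expected) ** 2) / expected).sum())
        p = float(sps.chi2.sf(chi2, df=1))
        return Assoc2x2Result(p, "chi-square", chi2)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return Assoc2x2Result(float(p), "fisher", float(odds))


# --------------------------------------------------------------------------
# univariate screen


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


def univariate_screen(
    data: pd.DataFrame,
    feature_cols: list[str],
    grade_col: str = "grade",
    normality_alpha: float = 0.05,
    adjust: str = "none",
) -> pd.DataFrame:
    """Per-feature two-group comparison, mirroring the usual reporting.

    Each feature goes to a two-sided Welch t-test (reporting group
    mean ± SD) when Shapiro–Wilk accepts normality in *both* grade
    groups at ``normality_alpha``, otherwise to a Mann–Whitney U test
    (reporting per-group mean ranks of the pooled ranking).  Zero- or
    tie-degenerate features are flagged and never significant.
    """
    g = data[grade_col].astype(str)
    mask_int, mask_high = (g == "intermediate").values, (g == "high").values
    if mask_int.sum() == 0 or mask_high.sum() == 0:
        raise ParameterError("both grade groups must be non-empty")
    rows = []
    for f in feature_cols:
        x = data[f].astype(float).values
        if not np.isfinite(x).all():
            raise ParameterError(f"feature {f} contains non-finite values")
        a, b = x[mask_int], x[mask_high]
        ranks = sps.rankdata(x)
        row = {
            "feature": f,
            "name": FEATURE_NAMES.get(f, f),
            "mean_intermediate": a.mean(),
            "sd_intermediate": a.std(ddof=1) if a.size > 1 else 0.0,
            "mean_high": b.mean(),
            "sd_high": b.std(ddof=1) if b.size > 1 else 0.0,
            "mean_rank_intermediate": ranks[mask_int].mean(),
            "mean_rank_high": ranks[mask_high].mean(),
            "degenerate": False,
        }
        if np.ptp(x) == 0:
            row.update(test="mann-whitney", p=1.0, degenerate=True)
        else:
            normal = False
            if min(a.size, b.size) >= 3 and np.ptp(a) > 0 and np.ptp(b) > 0:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    normal = (
                        sps.shapiro(a).pvalue > normality_alpha
                        and sps.shapiro(b).pvalue > normality_alpha
                    )
            if normal:
                res = sps.ttest_ind(a, b, equal_var=False)
                row.update(test="t", p=float(res.pvalue))
            else:
                res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
                row.update(test="mann-whitney", p=float(res.pvalue))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature")
    if adjust == "bh":
        out["q"] = _benjamini_hochberg(out["p"].values)
        out["significant"] = out["q"] < 0.05
    elif adjust == "none":
        out["significant"] = out["p"] < 0.05
    else:
        raise ParameterError(f"unknown adjust mode {adjust!r}")
    out.loc[out["degenerate"], "significant"] = False
    return out


# --------------------------------------------------------------------------
# logistic regression (IRLS)


@dataclass
class LogisticModel:
    """A fitted binary logistic model with Wald inference."""

    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    pvalues: np.ndarray
    fitted: np.ndarray
    converged: bool
    n_iter: int
    llf: float
    removed: list[tuple[str, float]] = field(default_factory=list)

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    @property
    def or_ci(self) -> np.ndarray:
        """(k, 2) Wald 95% CI for the odds ratios."""
        half = 1.959963984540054 * self.bse
        return np.exp(np.column_stack([self.params - half, self.params + half]))

    @property
    def predictor_names(self) -> list[str]:
        return [n for n in self.names if n != "intercept"]

    def summary_frame(self) -> pd.DataFrame:
        ci = self.or_ci
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "p": self.pvalues,
                "odds_ratio": self.odds_ratios,
                "or_ci_low": ci[:, 0],
                "or_ci_high": ci[:, 1],
            },
            index=self.names,
        )


def fit_logistic(
    X,
    y,
    names: list[str] | None = None,
    add_intercept: bool = True,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    beta_bound: float = 20.0,
) -> LogisticModel:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    Convergence when the max absolute score component drops below
    ``score_tol`` (or after ``max_iter`` iterations).  Standard errors
    come from the inverse observed information.  Diverging coefficients
    (max |β| above ``beta_bound``) raise
    :class:`~tumortex.errors.SeparationError`; a rank-deficient design
    raises :class:`~tumortex.errors.DesignError`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(y)) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    if X.size == 0:
        X = np.empty((y.size, 0))
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ParameterError("outcome must be coded 0/1")
    if y.min() == y.max():
        raise ParameterError("outcome must contain both classes")
    if names is None:
        names = [f"x{i + 1}" for i in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(y.size), X])
        names = ["intercept"] + names
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError("design matrix is rank deficient")
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.abs(score).max() < score_tol:
            converged = True
            break
        w = mu * (1.0 - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        beta = beta + step
        if np.abs(beta).max() > beta_bound:
            raise SeparationError(
                "coefficients diverging: outcome is (quasi-)separated"
            )
    eta = np.clip(X @ beta, -30, 30)
    mu = expit(eta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.pinv(H)
    bse = np.sqrt(np.diag(cov))
    z = np.divide(beta, bse, out=np.zeros_like(beta), where=bse > 0)
    pvalues = 2.0 * sps.norm.sf(np.abs(z))
    llf = float(np.sum(y * np.log(np.clip(mu, 1e-300, 1)) +
                       (1 - y) * np.log(np.clip(1 - mu, 1e-300, 1))))
    return LogisticModel(names, beta, bse, pvalues, mu, converged, it, llf)


def _ridge_logistic_coefs(X: np.ndarray, y: np.ndarray, lam: float = 1e-3) -> np.ndarray:
    """Weakly penalized fit used only to rank offenders under separation."""
    X = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(X.shape[1])
    for _ in range(200):
        mu = expit(np.clip(X @ beta, -30, 30))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = (X * w[:, None]).T @ X + lam * np.eye(X.shape[1])
        step = np.linalg.solve(H, X.T @ (y - mu) - lam * beta)
        beta = beta + step
        if np.abs(step).max() < 1e-6:
            break
    return beta[1:]


def _feature_order(name: str) -> tuple:
    m = re.fullmatch(r"F(\d+)", str(name))
    return (0, int(m.group(1)), "") if m else (1, 0, str(name))


def backward_eliminate(
    X: pd.DataFrame,
    y,
    p_remove: float = 0.05,
    **fit_kwargs,
) -> LogisticModel:
    """Backward elimination of logistic predictors.

    Starting from all candidate columns of ``X``, iteratively refit and
    drop the predictor with the largest Wald p among those above
    ``p_remove`` (one per step; ties broken toward the higher feature
    index) until every retained predictor satisfies p ≤ ``p_remove``.
    Candidates are canonically ordered first, so the final model does
    not depend on input column order.  If a refit hits separation, the
    predictor with the largest |coefficient| in a weakly penalized fit
    is dropped instead (recorded in ``removed`` with p = nan).
    """
    y = np.asarray(y, dtype=float).ravel()
    cols = sorted(X.columns, key=_feature_order)
    removed: list[tuple[str, float]] = []
    while True:
        try:
            model = fit_logistic(X[cols].values, y, names=cols, **fit_kwargs)
        except SeparationError:
            if not cols:
                raise
            coefs = _ridge_logistic_coefs(X[cols].values, y)
            worst = int(np.argmax(np.abs(coefs)))
            warnings.warn(
                f"separation while refitting; dropping {cols[worst]} by |coef|",
                stacklevel=2,
            )
            removed.append((cols.pop(worst), float("nan")))
            continue
        if not cols:
            break
        pv = model.pvalues[1:]  # skip intercept
        over = [k for k in range(len(cols)) if pv[k] > p_remove]
        if not over:
            break
        worst = max(over, key=lambda k: (pv[k], _feature_order(cols[k])))
        removed.append((cols[worst], float(pv[worst])))
        cols.pop(worst)
    model.removed = removed
    return model


# --------------------------------------------------------------------------
# ROC / AUC


@dataclass
class ROCResult:
    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    specificity: float
    threshold: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray
    scores: np.ndarray
    labels: np.ndarray


def _placement_values(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), 1.0 - cmp.mean(axis=0)


def roc_analysis(scores, labels, positive=1) -> ROCResult:
    """ROC curve, tie-corrected AUC with DeLong CI, and the Youden cutoff.

    AUC is the concordance probability (#concordant + 0.5·#ties)/(n1·n0),
    identical to the Mann–Whitney U statistic divided by n1·n0.  The
    operating point maximizes Youden's J = sensitivity + specificity − 1
    (ties resolved toward higher sensitivity) with prediction rule
    "score ≥ threshold ⇒ positive".
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    pos_mask = labels == positive
    n1, n0 = int(pos_mask.sum()), int((~pos_mask).sum())
    if n1 == 0 or n0 == 0:
        raise ParameterError("both classes must be present")
    pos, neg = scores[pos_mask], scores[~pos_mask]
    v10, v01 = _placement_values(pos, neg)
    auc = float(v10.mean())
    var = 0.0
    if n1 > 1:
        var += v10.var(ddof=1) / n1
    if n0 > 1:
        var += (1.0 - v01).var(ddof=1) / n0
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = np.array([(pos >= t).mean() for t in thresholds])
    fpr = np.array([(neg >= t).mean() for t in thresholds])
    j = tpr - fpr
    best = max(range(len(thresholds)), key=lambda k: (j[k], tpr[k]))
    return ROCResult(
        auc=auc,
        auc_ci=ci,
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        threshold=float(thresholds[best]),
        n_pos=n1,
        n_neg=n0,
        fpr=fpr,
        tpr=tpr,
        scores=scores,
        labels=pos_mask.astype(int),
    )


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p: float


def delong_compare(scores_a, scores_b, labels, positive=1) -> DeLongResult:
    """DeLong test for two correlated (same-subject) AUCs.

    Uses placement-value covariances; two-sided normal p.  Identical
    scores give ΔAUC = 0 with p = 1.
    """
    sa = np.asarray(scores_a, dtype=float).ravel()
    sb = np.asarray(scores_b, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if not (len(sa) == len(sb) == len(labels)):
        raise ParameterError("scores and labels must have equal length")
    pos = labels == positive
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ParameterError("both classes must be present")
    v10 = np.empty((2, n1))
    v01 = np.empty((2, n0))
    for k, s in enumerate((sa, sb)):
        v10[k], v01[k] = _placement_values(s[pos], s[~pos])
    aucs = v10.mean(axis=1)
    delta = float(aucs[0] - aucs[1])
    s10 = np.cov(v10) if n1 > 1 else np.zeros((2, 2))
    s01 = np.cov(1.0 - v01) if n0 > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n0
    if var <= 0:
        if delta == 0.0:
            return DeLongResult(float(aucs[0]), float(aucs[1]), 0.0, 0.0, 1.0)
        z = np.inf * np.sign(delta)
        return DeLongResult(float(aucs[0]), float(aucs[1]), delta, float(z), 0.0)
    z = delta / np.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return DeLongResult(float(aucs[0]), float(aucs[1]), delta, float(z), p)


# --------------------------------------------------------------------------
# 2x2-derived clinical model (counts-only entry point)


def expand_2x2(table) -> tuple[np.ndarray, np.ndarray]:
    """Expand {never/smoker × intermediate/high} counts into per-patient
    (smoker indicator, intermediate indicator) arrays.

    ``table`` rows are exposure (never, smoker), columns are grade
    (intermediate, high).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ParameterError("need a 2x2 non-negative count table")
    smoker, y_int = [], []
    for r, exp_flag in enumerate((0, 1)):
        for c, int_flag in enumerate((1, 0)):
            smoker.extend([exp_flag] * t[r, c])
            y_int.extend([int_flag] * t[r, c])
    return np.array(smoker, dtype=float), np.array(y_int, dtype=float)


def clinical_model_from_counts(table) -> tuple[LogisticModel, ROCResult, Assoc2x2Result]:
    """Fit the smoking-only clinical model directly from a 2×2 table.

    Returns the logistic model (outcome: intermediate grade), the ROC
    result with high grade as positive class (scores are the predicted
    probability of high grade), and the 2×2 association test.
    """
    smoker, y_int = expand_2x2(table)
    model = fit_logistic(smoker[:, None], y_int, names=["smoking"])
    roc = roc_analysis(1.0 - model.fitted, 1.0 - y_int, positive=1)
    assoc = compare_2x2(table)
    return model, roc, assoc


# --------------------------------------------------------------------------
# GradeModel / GradeModelResults


_CLINICAL_ENCODING = {
    "smoking": ("smoking", lambda s: (s.astype(str) == "smoker").astype(float)),
    "sex": ("male", lambda s: (s.astype(str) == "male").astype(float)),
    "age": ("age", lambda s: s.astype(float)),
    "stage": ("advanced_stage", lambda s: s.astype(str).isin(["III", "IV"]).astype(float)),
}


class GradeModel:
    """Two-grade cohort model: univariate screen + logistic models + ROC.

    Parameters
    ----------
    data : DataFrame
        One row per patient with a ``grade`` column ("intermediate" /
        "high"), any of the clinical columns (age, sex, smoking, stage)
        and any of the feature columns F1..F54.
    entry_p : float
        Univariable logistic p-value below which a predictor enters the
        initial multivariable model (default 0.15).
    removal_p : float
        Backward-elimination retention threshold (default 0.05).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        grade_col: str = "grade",
        feature_cols: list[str] | None = None,
        entry_p: float = 0.15,
        removal_p: float = 0.05,
        normality_alpha: float = 0.05,
        adjust: str = "none",
        collinearity_r: float = 0.98,
    ) -> None:
        if not (0 < removal_p < 1 and 0 < entry_p < 1):
            raise ParameterError("thresholds must lie in (0,1)")
        if entry_p < removal_p:
            raise ParameterError("entry_p must be >= removal_p")
        self.data = data.reset_index(drop=True)
        self.grade_col = grade_col
        grades = set(self.data[grade_col].astype(str))
        if not grades <= {"intermediate", "high"}:
            raise ParameterError(f"unexpected grade labels: {grades}")
        if len(grades) < 2:
            raise ParameterError("cohort must contain both grade groups")
        if feature_cols is None:
            feature_cols = [c for c in FEATURE_IDS if c in self.data.columns]
        self.feature_cols = feature_cols
        self.entry_p = entry_p
        self.removal_p = removal_p
        self.normality_alpha = normality_alpha
        self.adjust = adjust
        self.collinearity_r = collinearity_r
        # outcome: 1 = intermediate (coefficient convention), ROC positive = high
        self.y_intermediate = (
            self.data[grade_col].astype(str) == "intermediate"
        ).astype(float).values

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "GradeModel":
        return cls(data, **kwargs)

    # -- internal helpers ---------------------------------------------------

    def _clinical_design(self) -> pd.DataFrame:
        cols = {}
        for raw, (name, enc) in _CLINICAL_ENCODING.items():
            if raw in self.data.columns:
                cols[name] = enc(self.data[raw])
        return pd.DataFrame(cols, index=self.data.index)

    def _texture_design(self) -> pd.DataFrame:
        """Z-scored feature columns (constant features dropped)."""
        out = {}
        for f in self.feature_cols:
            x = self.data[f].astype(float).values
            sd = x.std()
            if sd > 0:
                out[f] = (x - x.mean()) / sd
        return pd.DataFrame(out, index=self.data.index)

    def _screen_candidates(self, design: pd.DataFrame) -> tuple[list[str], dict]:
        """Univariable logistic screen at entry_p."""
        pvals = {}
        for c in design.columns:
            try:
                m = fit_logistic(design[[c]].values, self.y_intermediate, names=[c])
                pvals[c] = float(m.pvalues[1])
            except SeparationError:
                pvals[c] = 0.0  # perfectly predictive on its own: enters
        keep = [c for c in design.columns if pvals[c] < self.entry_p]
        return keep, pvals

    def _prune_collinear(self, design: pd.DataFrame, cand: list[str], pvals: dict) -> list[str]:
        """Greedy pruning of redundant candidates before the initial model.

        In priority order (smaller univariable p first) a candidate is
        dropped if it nearly duplicates a kept one (|r| >= threshold) or
        is linearly dependent on the kept set (features such as Range =
        Max − Min are exact combinations); the initial design is then
        guaranteed full rank."""
        ordered = sorted(cand, key=lambda c: (pvals[c], _feature_order(c)))
        kept: list[str] = []
        for c in ordered:
            x = design[c].values
            dup = any(
                abs(np.corrcoef(x, design[k].values)[0, 1]) >= self.collinearity_r
                for k in kept
            )
            if dup:
                continue
            block = design[kept + [c]].values
            if np.linalg.matrix_rank(np.column_stack([np.ones(len(block)), block])) < (
                len(kept) + 2
            ):
                continue
            kept.append(c)
        return sorted(kept, key=_feature_order)

    def _model_branch(self, design: pd.DataFrame):
        cand, pvals = self._screen_candidates(design)
        cand = self._prune_collinear(design, cand, pvals)
        if not cand:
            model = fit_logistic(
                np.empty((len(self.y_intermediate), 0)), self.y_intermediate, names=[]
            )
        else:
            model = backward_eliminate(design[cand], self.y_intermediate, self.removal_p)
        scores_high = 1.0 - model.fitted
        roc = roc_analysis(scores_high, 1.0 - self.y_intermediate, positive=1)
        return model, roc, pvals

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "GradeModelResults":
        univariate = None
        if self.feature_cols:
            univariate = univariate_screen(
                self.data,
                self.feature_cols,
                self.grade_col,
                normality_alpha=self.normality_alpha,
                adjust=self.adjust,
            )
        clinical_model = clinical_roc = None
        clin_design = self._clinical_design()
        if not clin_design.empty:
            clinical_model, clinical_roc, _ = self._model_branch(clin_design)
        texture_model = texture_roc = None
        if self.feature_cols:
            texture_model, texture_roc, _ = self._model_branch(self._texture_design())
        delong = None
        if clinical_roc is not None and texture_roc is not None:
            delong = delong_compare(
                texture_roc.scores, clinical_roc.scores, texture_roc.labels, positive=1
            )
        return GradeModelResults(
            model=self,
            univariate=univariate,
            clinical_model=clinical_model,
            clinical_roc=clinical_roc,
            texture_model=texture_model,
            texture_roc=texture_roc,
            delong=delong,
        )


@dataclass
class GradeModelResults:
    """Fitted cohort analysis: tables, models, ROC and AUC comparison."""

    model: GradeModel
    univariate: pd.DataFrame | None
    clinical_model: LogisticModel | None
    clinical_roc: ROCResult | None
    texture_model: LogisticModel | None
    texture_roc: ROCResult | None
    delong: DeLongResult | None

    def _summary_block(self, title: str, m: LogisticModel, roc: ROCResult) -> list[str]:
        lines = [title, "-" * len(title)]
        if not m.predictor_names:
            lines.append("  (intercept only: no predictor retained)")
        else:
            sf = m.summary_frame().drop(index="intercept")
            for name, r in sf.iterrows():
                lines.append(
                    f"  {name:<16s} OR {r['odds_ratio']:.3f} "
                    f"(95% CI {r['or_ci_low']:.3f}-{r['or_ci_high']:.3f}), p={r['p']:.4g}"
                )
        lines.append(
            f"  AUC {roc.auc:.3f} (95% CI {roc.auc_ci[0]:.3f}-{roc.auc_ci[1]:.3f}); "
            f"sens {100 * roc.sensitivity:.1f}%, spec {100 * roc.specificity:.1f}% at Youden cutoff"
        )
        return lines

    def summary(self) -> str:
        n_int = int(self.model.y_intermediate.sum())
        n_high = len(self.model.y_intermediate) - n_int
        lines = [
            "Pathologic-grade association analysis",
            "=====================================",
            f"cohort: {n_int} intermediate, {n_high} high grade",
            "outcome coding: model ORs for intermediate grade; ROC positive class: high grade",
            "",
        ]
        if self.univariate is not None:
            nsig = int(self.univariate["significant"].sum())
            lines += [
                f"univariate screen: {nsig}/{len(self.univariate)} features with p < 0.05",
                "",
            ]
        if self.clinical_model is not None:
            lines += self._summary_block(
                "Clinical model", self.clinical_model, self.clinical_roc
            ) + [""]
        if self.texture_model is not None:
            lines += self._summary_block(
                "Texture model (per-SD odds ratios)", self.texture_model, self.texture_roc
            ) + [""]
        if self.delong is not None:
            lines.append(
                f"DeLong texture vs clinical: ΔAUC = {self.delong.delta:+.3f}, "
                f"z = {self.delong.z:.3f}, p = {self.delong.p:.4g}"
            )
        return "\n".join(lines)

    def plot_roc(self, path=None):
        """Plot both ROC curves; save to ``path`` if given."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for label, roc in (("clinical", self.clinical_roc), ("texture", self.texture_roc)):
            if roc is None:
                continue
            ax.plot(roc.fpr, roc.tpr, label=f"{label} (AUC {roc.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
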