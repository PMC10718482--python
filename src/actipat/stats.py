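"""Group-difference tests and logistic association models.

Categorical cohort characteristics are compared between the stable and
shifting pattern groups with the chi-square test, switching to the Fisher
exact test when any observed cell count is below 5; numerical variables use
the two-tailed t test (pooled variance by default, Welch by flag).  The
association between the shifting pattern and covariates (sex, age group,
number of metabolic risk factors — all binary) is estimated by maximum
likelihood logistic regression with Wald 95% confidence intervals, plus the
usual small-cohort diagnostics: McFadden pseudo-R^2, classification accuracy
at 0.5, the Hosmer–Lemeshow goodness-of-fit statistic and the ROC curve.  A
companion reverse-direction model (risk-factor count as outcome, pattern
group as predictor) guards against reverse causality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    p_value: float
    method: str
    statistic: float | None = None
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        self.p_value = min(self.p_value, 1.0)


def _as_table(table) -> np.ndarray:
    t = np.asarray(table)
    if (t < 0).any() or not np.issubdtype(t.dtype, np.number):
        raise ValueError("contingency table must hold non-negative counts")
    return t.astype(int)


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test for a 2x2 table.

    p is the total hypergeometric probability of all tables with the
    observed margins at most as likely as the observed one.  A table with an
    empty margin carries no information: p = 1 by convention.
    """
    t = _as_table(table)
    if t.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return TestResult(p_value=1.0, method="fisher")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(p_value=float(p), method="fisher")


def chi_square(table) -> TestResult:
    """Pearson chi-square test of independence (no continuity correction)."""
    t = _as_table(table)
    expected = sps.contingency.expected_freq(t)
    if (expected == 0).any():
        raise ValueError("zero expected cell count; use the Fisher exact test")
    stat, p, df, _ = sps.chi2_contingency(t, correction=False)
    return TestResult(p_value=float(p), method="chi_square", statistic=float(stat), df=df)


def categorical_test(table) -> TestResult:
    """Dispatch: Fisher exact when any observed cell < 5, chi-square otherwise."""
    t = _as_table(table)
    if (t < 5).any():
        if t.shape != (2, 2):
            raise ValueError("small-count table is not 2x2; collapse categories first")
        return fisher_exact(t)
    return chi_square(t)


def t_test(group_a, group_b, variant: str = "pooled") -> TestResult:
    """Two-tailed t test on raw samples (pooled Student or Welch)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return TestResult(p_value=1.0, method=f"t_{variant}", statistic=0.0)
    stat, p = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    df = (
        a.size + b.size - 2
        if variant == "pooled"
        else _welch_df(a.var(ddof=1), a.size, b.var(ddof=1), b.size)
    )
    return TestResult(p_value=float(p), method=f"t_{variant}", statistic=float(stat), df=df)


def t_test_from_stats(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    variant: str = "pooled",
) -> TestResult:
    """Two-tailed t test from published summary statistics."""
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a == 0 and sd_b == 0 and mean_a == mean_b:
        return TestResult(p_value=1.0, method=f"t_{variant}", statistic=0.0)
    stat, p = sps.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(variant == "pooled")
    )
    df = n_a + n_b - 2 if variant == "pooled" else _welch_df(sd_a**2, n_a, sd_b**2, n_b)
    return TestResult(p_value=float(p), method=f"t_{variant}", statistic=float(stat), df=df)


def _welch_df(va: float, na: int, vb: float, nb: int) -> float:
    num = (va / na + vb / nb) ** 2
    den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    return num / den


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

#: |coefficient| beyond which quasi-separation is flagged
SEPARATION_BOUND = 15.0


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    odds_ratio: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    converged: bool
    separation: bool
    fitted: np.ndarray = field(repr=False)
    outcome: np.ndarray = field(repr=False)

    def table(self) -> pd.DataFrame:
        """OR table (intercept excluded), one row per predictor."""
        df = pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "or": self.odds_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            }
        )
        return df[df["term"] != "intercept"].reset_index(drop=True)


def logistic_fit(X: pd.DataFrame, y, tol: float = 1e-8, maxiter: int = 100) -> LogisticFit:
    """Fit P(y=1) = logistic(b0 + X b) by Newton/IRLS maximum likelihood.

    Wald 95% CIs are exp(coef +/- 1.96 * SE).  Non-convergence or diverging
    coefficients (quasi-separation) are flagged on the result rather than
    raised, so small-cohort pathologies stay visible.
    """
    y = np.asarray(y, dtype=float)
    if y.min() < 0 or y.max() > 1:
        raise ValueError("outcome must be binary 0/1")
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("outcome needs at least one event and one non-event")
    Xd = sm.add_constant(pd.DataFrame(X).astype(float), has_constant="add")
    terms = ["intercept"] + [c for c in Xd.columns if c != "const"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, Xd)
        try:
            res = model.fit(
                method="newton", tol=tol, maxiter=maxiter, disp=0, warn_convergence=False
            )
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
            # Newton's Hessian degenerates under (quasi-)separation; a
            # gradient method still yields the diverging MLE path, which we
            # report flagged rather than hide.
            res = model.fit(method="lbfgs", maxiter=500, disp=0)
    coef = np.asarray(res.params)
    se = np.asarray(res.bse)
    separation = bool(np.any(np.abs(coef) > SEPARATION_BOUND))
    if separation:
        logger.warning("quasi-separation suspected: |coef| > %s", SEPARATION_BOUND)
    z = 1.959963984540054  # standard normal 97.5% point
    with np.errstate(over="ignore"):  # separated fits have infinite CI bounds
        ci_low, ci_high = np.exp(coef - z * se), np.exp(coef + z * se)
    return LogisticFit(
        terms=terms,
        coef=coef,
        se=se,
        odds_ratio=np.exp(coef),
        ci_low=ci_low,
        ci_high=ci_high,
        p_values=np.asarray(res.pvalues),
        log_likelihood=float(res.llf),
        null_log_likelihood=float(res.llnull),
        converged=bool(res.mle_retvals.get("converged", True)),
        separation=separation,
        fitted=np.asarray(res.predict()),
        outcome=y,
    )


def hosmer_lemeshow(probs, y, groups: int = 10) -> TestResult:
    """Hosmer–Lemeshow goodness of fit over deciles of fitted risk.

    Risk-tied deciles are merged (with a warning), and the statistic is
    referred to chi-square with (g - 2) degrees of freedom.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=float)
    edges = np.unique(np.quantile(probs, np.linspace(0, 1, groups + 1)))
    if edges.size - 1 < groups:
        logger.warning(
            "tied fitted risks: merged to %d Hosmer-Lemeshow groups", edges.size - 1
        )
    g = edges.size - 1
    if g < 3:
        raise ValueError("too few distinct risk groups for the Hosmer-Lemeshow test")
    which = np.clip(np.searchsorted(edges, probs, side="right") - 1, 0, g - 1)
    stat = 0.0
    for b in range(g):
        mask = which == b
        n = mask.sum()
        if n == 0:
            continue
        obs = y[mask].sum()
        exp = probs[mask].sum()
        if 0 < exp < n:
            stat += (obs - exp) ** 2 / exp + ((n - obs) - (n - exp)) ** 2 / (n - exp)
    df = g - 2
    p = float(sps.chi2.sf(stat, df))
    return TestResult(p_value=p, method="hosmer_lemeshow", statistic=float(stat), df=df)


def diagnostics(fit: LogisticFit, groups: int = 10) -> dict:
    """Model diagnostics: pseudo-R^2, accuracy, Hosmer–Lemeshow, ROC/AUC."""
    mcfadden = 1.0 - fit.log_likelihood / fit.null_log_likelihood
    accuracy = float(np.mean((fit.fitted >= 0.5) == (fit.outcome == 1)))
    try:
        hl = hosmer_lemeshow(fit.fitted, fit.outcome, groups=groups)
    except ValueError as exc:  # e.g. intercept-only fit: one fitted risk
        logger.warning("Hosmer-Lemeshow not computable: %s", exc)
        hl = TestResult(p_value=1.0, method="hosmer_lemeshow_undefined", statistic=None)
    fpr, tpr, _ = _roc_curve(fit.outcome, fit.fitted)
    return {
        "pseudo_r2": float(mcfadden),
        "accuracy": accuracy,
        "hosmer_lemeshow_stat": hl.statistic,
        "hosmer_lemeshow_p": hl.p_value,
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist()},
        "auc": float(_trapezoid_auc(fpr, tpr)),
    }


def pattern_association_model(data: pd.DataFrame) -> LogisticFit:
    """Shifting-pattern outcome vs sex, age group and risk-factor count.

    ``data`` needs binary columns ``female``, ``age_ge40``, ``multi_risk``
    and a ``group`` column with values stable/shifting.
    """
    y = (data["group"] == "shifting").astype(int)
    return logistic_fit(data[["female", "age_ge40", "multi_risk"]], y)


def reverse_model(data: pd.DataFrame) -> LogisticFit:
    """Reverse-direction check: >1 risk factors as outcome, pattern group in.

    If pattern groups merely reflected pre-existing risk burden, the group
    indicator would predict the risk-factor count here.
    """
    y = data["multi_risk"].astype(int)
    X = pd.DataFrame(
        {
            "shifting": (data["group"] == "shifting").astype(int),
            "female": data["female"].astype(int),
            "age_ge40": data["age_ge40"].astype(int),
        }
    )
    return logistic_fit(X, y)


def group_comparison_table(data: pd.DataFrame, ee: pd.DataFrame | None = None) -> pd.DataFrame:
    """Stable-vs-shifting comparison of cohort characteristics.

    Categorical rows get counts per group and a Fisher/chi-square p; EE rows
    (if ``ee`` has weekday/weekend mean daily kcal per participant) get
    means, SDs and a pooled t-test p.
    """
    rows = []
    groups = data["group"]
    stable, shifting = groups == "stable", groups == "shifting"
    for var, level_one in (
        ("female", "female"),
        ("age_ge40", ">=40y"),
        ("sitting", "sitting"),
        ("multi_risk", ">1 risk factors"),
    ):
        if var not in data.columns:
            continue
        x = data[var].astype(int)
        tab = np.array(
            [
                [int(((x == 1) & stable).sum()), int(((x == 1) & shifting).sum())],
                [int(((x == 0) & stable).sum()), int(((x == 0) & shifting).sum())],
            ]
        )
        res = categorical_test(tab)
        rows.append(
            {
                "variable": var,
                "level": level_one,
                "stable_n": tab[0, 0] + tab[1, 0],
                "shifting_n": tab[0, 1] + tab[1, 1],
                "stable_level_n": tab[0, 0],
                "shifting_level_n": tab[0, 1],
                "p": res.p_value,
                "method": res.method,
            }
        )
    if ee is not None:
        merged = data.merge(ee, left_on="participant_id", right_index=True, how="inner")
        for seg in ("weekday", "weekend"):
            if seg not in merged.columns:
                continue
            a = merged.loc[merged["group"] == "stable", seg].dropna()
            b = merged.loc[merged["group"] == "shifting", seg].dropna()
            if len(a) < 2 or len(b) < 2:
                logger.warning("daily EE %s: a group has n < 2, t test skipped", seg)
                rows.append(
                    {
                        "variable": f"daily_ee_{seg}",
                        "level": "mean_kcal",
                        "stable_n": len(a),
                        "shifting_n": len(b),
                        "p": np.nan,
                        "method": "t_skipped_small_group",
                    }
                )
                continue
            res = t_test(a, b)
            rows.append(
                {
                    "variable": f"daily_ee_{seg}",
                    "level": "mean_kcal",
                    "stable_n": len(a),
                    "shifting_n": len(b),
                    "stable_mean": float(a.mean()),
                    "shifting_mean": float(b.mean()),
                    "stable_sd": float(a.std(ddof=1)),
                    "shifting_sd": float(b.std(ddof=1)),
                    "p": res.p_value,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)
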