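"""Inferential statistics used around the pipeline outputs.

Balanced-design repeated-measures and mixed (split-plot) two-way ANOVA with
classical effect sizes, Greenhouse–Geisser sphericity correction, Pearson
correlation, and Holm–Bonferroni step-down adjustment.

Conventions: η² is the *classical* effect size SS_effect / SS_total (not
partial); designs must be complete and balanced (unbalanced inputs are
rejected, no imputation); p-values are reported to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._exceptions import ValidationError


@dataclass
class AnovaResult:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    eta_sq: float
    gg_epsilon: float | None = None
    p_gg: float | None = None


@dataclass
class CorrelationResult:
    r: float
    df: int
    p: float


def _as_wide(data, index_cols=("subject",), column="condition", value="value"):
    """Accept an (n_subjects, k_conditions) array or a long DataFrame."""
    if isinstance(data, pd.DataFrame) and value in data.columns:
        wide = data.pivot_table(index=list(index_cols), columns=column,
                                values=value, aggfunc="first")
        if wide.isna().any().any():
            raise ValidationError("missing cells in design (no imputation)")
        return wide
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D subject x condition table")
    if np.isnan(arr).any():
        raise ValidationError("missing cells in design (no imputation)")
    return arr


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse–Geisser ε from the covariance of within-subject conditions.

    ε = tr(S̃)² / ((k−1) tr(S̃²)) with S̃ the double-centered covariance.
    Equals 1 under compound symmetry (and always when k = 2); bounded below
    by 1/(k−1).
    """
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1] or S.shape[0] < 2:
        raise ValidationError("covariance must be square with k >= 2")
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValidationError("covariance must be symmetric")
    if np.linalg.eigvalsh(S).min() < -1e-8 * max(1.0, abs(S).max()):
        raise ValidationError("covariance is not positive semi-definite")
    k = S.shape[0]
    row = S.mean(axis=0)
    Sc = S - row[None, :] - row[:, None] + S.mean()
    denom = (k - 1) * float((Sc * Sc).sum())
    if denom == 0:
        return 1.0
    eps = float(np.trace(Sc)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_oneway(data) -> AnovaResult:
    """One-way repeated-measures ANOVA on a complete subject x condition table.

    F = MS_condition / MS_error with df (k−1, (k−1)(n−1)); η² =
    SS_condition / SS_total; the Greenhouse–Geisser corrected p-value is
    attached (``p_gg``).
    """
    wide = _as_wide(data)
    arr = wide.to_numpy(float) if isinstance(wide, pd.DataFrame) else wide
    n, k = arr.shape
    if n < 2 or k < 2:
        raise ValidationError("need >= 2 subjects and >= 2 conditions")
    grand = arr.mean()
    ss_total = float(((arr - grand) ** 2).sum())
    ss_cond = float(n * ((arr.mean(axis=0) - grand) ** 2).sum())
    ss_subj = float(k * ((arr.mean(axis=1) - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond, ms_err = ss_cond / df1, ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else (0.0 if ms_cond == 0 else np.inf)
    p = float(sps.f.sf(F, df1, df2))
    eps = gg_epsilon(np.cov(arr, rowvar=False))
    p_gg = float(sps.f.sf(F, eps * df1, eps * df2))
    eta = ss_cond / ss_total if ss_total > 0 else 0.0
    return AnovaResult("condition", float(F), df1, df2, p, eta,
                       gg_epsilon=eps, p_gg=p_gg)


def mixed_anova_twoway(data: pd.DataFrame, subject="subject", group="group",
                       condition="condition", value="value") -> dict[str, AnovaResult]:
    """Mixed two-way (split-plot) ANOVA: between-subject group x
    within-subject condition.

    Requires a balanced design (equal group sizes, complete conditions).
    Returns the ``group`` and ``condition`` main effects and their
    ``interaction``, each with classical η² = SS_effect / SS_total.
    """
    need = {subject, group, condition, value}
    if need - set(data.columns):
        raise ValidationError(f"need columns {sorted(need)}")
    wide = data.pivot_table(index=[group, subject], columns=condition,
                            values=value, aggfunc="first")
    if wide.isna().any().any():
        raise ValidationError("missing cells in design (no imputation)")
    groups = wide.index.get_level_values(0)
    sizes = pd.Series(groups).value_counts()
    if len(sizes) < 2:
        raise ValidationError("need >= 2 groups")
    if sizes.min() < 2:
        raise ValidationError("singleton group (cannot estimate subject error)")
    if sizes.nunique() != 1:
        raise ValidationError("unbalanced group sizes are not supported")
    g, n = len(sizes), int(sizes.iloc[0])
    arr = wide.to_numpy(float).reshape(g, n, -1)
    k = arr.shape[2]
    if k < 2:
        raise ValidationError("need >= 2 within-subject conditions")

    grand = arr.mean()
    ss_total = float(((arr - grand) ** 2).sum())
    gmean = arr.mean(axis=(1, 2))  # per group
    cmean = arr.mean(axis=(0, 1))  # per condition
    smean = arr.mean(axis=2)  # per subject
    cell = arr.mean(axis=1)  # group x condition means
    ss_group = float(n * k * ((gmean - grand) ** 2).sum())
    ss_subj_within = float(k * ((smean - gmean[:, None]) ** 2).sum())
    ss_cond = float(g * n * ((cmean - grand) ** 2).sum())
    ss_inter = float(n * ((cell - gmean[:, None] - cmean[None, :] + grand) ** 2).sum())
    ss_err = ss_total - ss_group - ss_subj_within - ss_cond - ss_inter

    df_group, df_subj = g - 1, g * (n - 1)
    df_cond, df_inter = k - 1, (g - 1) * (k - 1)
    df_err = (k - 1) * g * (n - 1)

    def _res(name, ss, df1, df2, ms_err):
        ms = ss / df1
        F = ms / ms_err if ms_err > 0 else (0.0 if ms == 0 else np.inf)
        return AnovaResult(name, float(F), df1, df2, float(sps.f.sf(F, df1, df2)),
                           ss / ss_total if ss_total > 0 else 0.0)

    ms_subj = ss_subj_within / df_subj
    ms_err = ss_err / df_err
    return {
        "group": _res("group", ss_group, df_group, df_subj, ms_subj),
        "condition": _res("condition", ss_cond, df_cond, df_err, ms_err),
        "interaction": _res("interaction", ss_inter, df_inter, df_err, ms_err),
    }


def pearson_corr(x, y) -> CorrelationResult:
    """Product-moment correlation with df = n − 2 and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValidationError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), len(x) - 2, float(p))


def holm_bonferroni(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone after sorting, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
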