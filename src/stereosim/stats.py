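"""Behavioral and brain-behavior statistics.

Repeated-measures ANOVA (one-way and general fully-within factorials),
Bonferroni-corrected paired t tests with Cohen's d, per-subject behavioral
indices (threshold differences between stimulus conditions), and Pearson
brain-behavior correlations with a per-family Bonferroni correction.

The ANOVA is computed from the classic sum-of-squares decomposition for a
complete balanced within-subject design: the error term for every effect
is that effect's interaction with subject, and sphericity is assumed
(uncorrected degrees of freedom).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PostHocResult",
    "BrainBehaviorResult",
    "rm_anova_oneway",
    "rm_anova_factorial",
    "posthoc_bonferroni",
    "behavioral_index",
    "correlate",
    "threshold_table_to_wide",
]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


@dataclass(frozen=True)
class PostHocResult:
    pair: tuple[str, str]
    t: float
    df: int
    p_raw: float
    p_bonferroni: float
    cohens_d: float


@dataclass(frozen=True)
class BrainBehaviorResult:
    roi: str
    comparison: str
    r: float
    p: float
    p_bonferroni: float
    n: int


def threshold_table_to_wide(table: pd.DataFrame, value: str = "threshold",
                            subject: str = "subject",
                            condition: str = "condition") -> pd.DataFrame:
    """Pivot a long (subject, condition, threshold) table to subjects x conditions.

    Raises if the within-subject design is incomplete.
    """
    wide = table.pivot_table(index=subject, columns=condition, values=value,
                             aggfunc="mean")
    if wide.isna().any().any():
        missing = wide.isna().stack()
        raise ValueError(f"incomplete design: missing cells "
                         f"{list(missing[missing].index)}")
    return wide


def _anova_from_array(data: np.ndarray, factor_names: list[str]) -> list[AnovaResult]:
    """Fully-within RM-ANOVA on an array shaped (subjects, l1, ..., lk).

    Effects are decomposed by inclusion-exclusion over marginal means; the
    error term for effect E is the E x subject interaction.
    """
    n_subj = data.shape[0]
    k = data.ndim - 1
    if n_subj < 2:
        raise ValueError("need >= 2 subjects")
    axes_all = tuple(range(data.ndim))
    total_cells = data.size

    def marginal(axes_kept: tuple[int, ...]) -> np.ndarray:
        other = tuple(a for a in axes_all if a not in axes_kept)
        return data.mean(axis=other, keepdims=True)

    # subset of axes (0 = subject, 1..k = factors) -> effect array and SS
    ss: dict[frozenset, float] = {}
    effects: dict[frozenset, np.ndarray] = {}
    for size in range(0, data.ndim + 1):
        for axes in itertools.combinations(axes_all, size):
            key = frozenset(axes)
            eff = np.zeros((1,) * data.ndim)
            for sub_size in range(0, len(axes) + 1):
                for sub in itertools.combinations(axes, sub_size):
                    sign = (-1) ** (len(axes) - len(sub))
                    eff = eff + sign * marginal(sub)
            effects[key] = eff
            n_cells = int(np.prod([data.shape[a] for a in axes])) if axes else 1
            # each cell of T averages total/n_cells raw observations
            ss[key] = float((eff ** 2).sum() * (total_cells // n_cells))

    results = []
    for size in range(1, k + 1):
        for factor_axes in itertools.combinations(range(1, k + 1), size):
            key = frozenset(factor_axes)
            err_key = frozenset((0,) + factor_axes)
            df_num = int(np.prod([data.shape[a] - 1 for a in factor_axes]))
            df_den = df_num * (n_subj - 1)
            ms_eff = ss[key] / df_num
            ms_err = ss[err_key] / df_den
            if ms_err > 0:
                f = ms_eff / ms_err
            else:
                f = 0.0 if ms_eff == 0 else math.inf  # degenerate error term
            p = float(sps.f.sf(f, df_num, df_den)) if math.isfinite(f) else 0.0
            eta = ss[key] / (ss[key] + ss[err_key]) if ss[key] + ss[err_key] > 0 else 0.0
            name = " x ".join(factor_names[a - 1] for a in factor_axes)
            results.append(AnovaResult(effect=name, F=float(f), df_num=df_num,
                                       df_den=df_den, p=p,
                                       partial_eta_sq=float(eta),
                                       ss_effect=ss[key], ss_error=ss[err_key]))
    return results


def rm_anova_oneway(table: pd.DataFrame | np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA across stimulus conditions.

    Accepts a long table (subject, condition, threshold) or a wide
    subjects x conditions array.  F = MS_condition / MS_(condition x
    subject); partial eta^2 = SS_cond / (SS_cond + SS_error).
    """
    if isinstance(table, pd.DataFrame) and {"subject", "condition"} <= set(table.columns):
        wide = threshold_table_to_wide(table).to_numpy()
    else:
        wide = np.asarray(table, dtype=float)
    if wide.ndim != 2 or wide.shape[1] < 2:
        raise ValueError("need a subjects x conditions layout with >= 2 conditions")
    return _anova_from_array(wide, ["condition"])[0]


def rm_anova_factorial(table: pd.DataFrame, dv: str, subject: str,
                       within: list[str]) -> pd.DataFrame:
    """General fully-within-subject factorial RM-ANOVA (e.g. hemisphere x
    condition x ROI), returning one row per main effect and interaction."""
    levels = [sorted(table[f].unique()) for f in within]
    wide = table.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if wide.isna().any().any():
        raise ValueError("incomplete design")
    full_index = pd.MultiIndex.from_product(levels, names=within) if len(within) > 1 \
        else pd.Index(levels[0], name=within[0])
    wide = wide.reindex(columns=full_index)
    data = wide.to_numpy().reshape(wide.shape[0], *[len(l) for l in levels])
    results = _anova_from_array(data, within)
    return pd.DataFrame([r.__dict__ for r in results])


def posthoc_bonferroni(table: pd.DataFrame, pair: tuple[str, str],
                       n_comparisons: int = 3) -> PostHocResult:
    """Bonferroni-corrected paired t test between two conditions.

    Cohen's d for the paired contrast is t / sqrt(n) (the mean difference
    over the SD of the differences).
    """
    wide = threshold_table_to_wide(table)
    a, b = wide[pair[0]].to_numpy(), wide[pair[1]].to_numpy()
    n = a.size
    if n < 2:
        raise ValueError("need >= 2 paired observations")
    if np.allclose(a, b):
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_rel(a, b)
    d = float(t) / math.sqrt(n)
    return PostHocResult(pair=pair, t=float(t), df=n - 1, p_raw=float(p),
                         p_bonferroni=min(1.0, n_comparisons * float(p)),
                         cohens_d=d)


def behavioral_index(table: pd.DataFrame, condition_a: str,
                     condition_b: str | list[str]) -> pd.Series:
    """Per-subject threshold difference between two conditions.

    ``condition_b`` may be a list, in which case its conditions are
    averaged per subject first (the non-upright-face concatenation:
    upright minus the mean of the inverted and random thresholds).
    """
    wide = threshold_table_to_wide(table)
    if isinstance(condition_b, str):
        b = wide[condition_b]
    else:
        b = wide[list(condition_b)].mean(axis=1)
    return wide[condition_a] - b


def correlate(index: pd.Series | np.ndarray, accuracy: pd.Series | np.ndarray,
              roi: str = "", comparison: str = "",
              family_size: int = 10) -> BrainBehaviorResult:
    """Pearson correlation between a behavioral index and decoding accuracy.

    Vectors must be aligned by subject (pass pandas Series to have the
    alignment enforced on the index).  The two-sided p uses the t
    transform with df = n - 2; the Bonferroni-corrected p multiplies by
    the ROI family size (10 by default).
    """
    if isinstance(index, pd.Series) and isinstance(accuracy, pd.Series):
        joined = pd.concat([index.rename("x"), accuracy.rename("y")], axis=1)
        if joined.isna().any().any():
            raise ValueError("index and accuracy subjects do not align")
        x, y = joined["x"].to_numpy(), joined["y"].to_numpy()
    else:
        x, y = np.asarray(index, dtype=float), np.asarray(accuracy, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return BrainBehaviorResult(roi=roi, comparison=comparison, r=float(r),
                               p=float(p),
                               p_bonferroni=min(1.0, family_size * float(p)),
                               n=int(x.size))
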