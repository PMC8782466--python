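"""Paired within-subject statistics on cohort feature tables.

Each subject contributes one recording per mood state (manic, euthymic);
features are compared state-vs-state with the paired-samples t-test, except
triangle (3-clique) counts, whose skewed distribution calls for the related
samples Wilcoxon signed-rank test.  A Bonferroni-corrected threshold is used
for the morning-vs-evening within-state family; a feature-by-feature Pearson
correlation matrix describes how the variability, complexity and graph
estimates relate to each other.

A *cohort table* is a tidy pandas DataFrame with one row per
(subject_id, state, epoch) and one column per feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "CorrelationMatrix",
    "DegenerateContrastError",
    "paired_comparison",
    "bonferroni_alpha",
    "pearson_matrix",
    "state_comparison_report",
    "ID_COLUMNS",
]

ID_COLUMNS = ("subject_id", "state", "epoch")


class DegenerateContrastError(ValueError):
    """The paired differences carry no usable signal (all equal / all zero)."""


@dataclass(frozen=True)
class TestResult:
    method: str  # "paired_t" | "wilcoxon_signed_rank"
    statistic: float
    p_value: float
    n_pairs: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


@dataclass(frozen=True)
class CorrelationMatrix:
    features: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame


def paired_comparison(a, b, method: str = "paired_t") -> TestResult:
    """Two-sided paired comparison of per-subject values a vs b.

    ``paired_t`` tests the mean of the differences a - b against zero with
    n - 1 degrees of freedom.  ``wilcoxon_signed_rank`` drops zero
    differences and uses the exact signed-rank null for small tie-free
    samples, a normal approximation with midranks otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    n = len(a)
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    diff = a - b
    if method == "paired_t":
        if np.ptp(diff) == 0:
            raise DegenerateContrastError("paired differences have zero variance")
        stat, p = stats.ttest_rel(a, b)
    elif method == "wilcoxon_signed_rank":
        if np.all(diff == 0):
            raise DegenerateContrastError("all paired differences are zero")
        stat, p = stats.wilcoxon(
            a, b, zero_method="wilcox", correction=False, alternative="two-sided"
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(
        method=method,
        statistic=float(stat),
        p_value=float(p),
        n_pairs=n,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
    )


def bonferroni_alpha(alpha: float, m_tests: int) -> float:
    """Per-test significance threshold alpha / m (0.05 / 4 = 0.0125)."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m_tests < 1:
        raise ValueError(f"m_tests must be >= 1, got {m_tests}")
    return alpha / m_tests


def pearson_matrix(table: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson r with two-sided p (t transform, n - 2 df).

    ``table`` holds one row per subject and one numeric column per feature;
    zero-variance columns yield NaN rows/columns with a warning.
    """
    feats = [c for c in table.columns if c not in ID_COLUMNS]
    x = table[feats].to_numpy(dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if np.isnan(x).any():
        raise ValueError("missing feature values; drop or impute first")
    m = len(feats)
    r = np.eye(m)
    p = np.zeros((m, m))
    degenerate = [feats[j] for j in range(m) if np.ptp(x[:, j]) == 0]
    if degenerate:
        warnings.warn(f"zero-variance features flagged undefined: {degenerate}")
    for i in range(m):
        for j in range(i + 1, m):
            if feats[i] in degenerate or feats[j] in degenerate:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(x[:, i], x[:, j])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    for name in degenerate:
        idx = feats.index(name)
        r[idx, idx] = np.nan
    return CorrelationMatrix(
        features=tuple(feats),
        r=pd.DataFrame(r, index=feats, columns=feats),
        p=pd.DataFrame(p, index=feats, columns=feats),
    )


def _is_triangle_feature(name: str) -> bool:
    return name.startswith("triangles")


def state_comparison_report(
    cohort: pd.DataFrame,
    epoch: str,
    state_a: str = "manic",
    state_b: str = "euthymic",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Feature-by-feature paired comparison of two mood states in one epoch.

    Returns one row per feature: mean (SD) per state, test method, statistic,
    two-sided p and a significance flag at ``alpha``.  Triangle counts use
    the Wilcoxon signed-rank test, everything else the paired t-test.
    Subjects lacking either state are excluded with a warning.  Degenerate
    contrasts are reported with NaN statistics and ``degenerate=True``.
    """
    sub = cohort[cohort["epoch"] == epoch]
    if sub.empty:
        raise ValueError(f"no rows for epoch {epoch!r}")
    feats = [c for c in sub.columns if c not in ID_COLUMNS and not sub[c].isna().all()]
    wide_a = sub[sub["state"] == state_a].set_index("subject_id")[feats]
    wide_b = sub[sub["state"] == state_b].set_index("subject_id")[feats]
    paired = wide_a.index.intersection(wide_b.index)
    unpaired = wide_a.index.symmetric_difference(wide_b.index)
    if len(unpaired):
        warnings.warn(f"excluding unpaired subjects: {sorted(unpaired)}")
    if len(paired) < 2:
        raise ValueError("fewer than 2 paired subjects")
    wide_a, wide_b = wide_a.loc[paired], wide_b.loc[paired]

    rows = []
    for feat in feats:
        method = "wilcoxon_signed_rank" if _is_triangle_feature(feat) else "paired_t"
        a, b = wide_a[feat].to_numpy(float), wide_b[feat].to_numpy(float)
        row = {
            "feature": feat,
            f"mean_{state_a}": a.mean(),
            f"sd_{state_a}": a.std(ddof=1),
            f"mean_{state_b}": b.mean(),
            f"sd_{state_b}": b.std(ddof=1),
            "method": method,
            "n_pairs": len(paired),
        }
        try:
            res = paired_comparison(a, b, method=method)
            row.update(statistic=res.statistic, p_value=res.p_value,
                       significant=res.p_value < alpha, degenerate=False)
        except DegenerateContrastError:
            row.update(statistic=np.nan, p_value=np.nan,
                       significant=False, degenerate=True)
        rows.append(row)
    return pd.DataFrame(rows)


def format_report_text(report: pd.DataFrame, state_a: str = "manic",
                       state_b: str = "euthymic") -> str:
    """Aligned text rendering of a state-comparison report."""
    lines = []
    header = f"{'feature':<22} {state_a:>18} {state_b:>18} {'p':>8}  method"
    lines.append(header)
    lines.append("-" * len(header))
    for _, r in report.iterrows():
        cell_a = f"{r[f'mean_{state_a}']:.2f} ({r[f'sd_{state_a}']:.2f})"
        cell_b = f"{r[f'mean_{state_b}']:.2f} ({r[f'sd_{state_b}']:.2f})"
        p = "degen." if r["degenerate"] else f"{r['p_value']:.4f}"
        star = " *" if r.get("significant", False) else ""
        lines.append(
            f"{r['feature']:<22} {cell_a:>18} {cell_b:>18} {p:>8}  {r['method']}{star}"
        )
    return "\n".join(lines) + "\n"
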