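"""Native significance engine: Student's t-test, Bonferroni correction, and a
per-protein fixed-effects linear-model contrast.

The two-sample test is the classical equal-variance Student's t-test (pooled
variance, df = n_a + n_b - 2, two-sided). Multiple testing is controlled by
Bonferroni only — p_adj = min(1, m p) — matching the workflow's conservative
convention. For proteins quantified by several peptide features, an ordinary
least-squares two-factor model (log2 intensity ~ feature + group) provides an
MSstats-flavoured contrast between two stage points; for a single-feature
protein it reduces exactly to the t-test on log2 values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

__all__ = [
    "TestResult",
    "students_t",
    "students_t_matrix",
    "bonferroni",
    "linear_contrast",
]


@dataclass
class TestResult:
    """Outcome of one two-group comparison.

    ``estimate`` is mean(a) - mean(b) on the analysis scale (log2 scale for
    the linear contrast), matching the classical t-statistic's sign.
    ``p_adj``/``significant`` are filled in once a multiple-testing family is
    applied.
    """

    estimate: float
    t: float
    df: float
    p: float
    p_adj: float | None = None
    significant: bool | None = None

    def adjust(self, m: int, alpha: float) -> "TestResult":
        self.p_adj = float(bonferroni(np.array([self.p]), m)[0])
        self.significant = bool(self.p_adj < alpha)
        return self


def students_t(group_a, group_b) -> TestResult:
    """Equal-variance two-sided Student's t-test.

    Each group needs n >= 2. With zero pooled variance the statistic is
    degenerate: equal means give t = 0, p = 1; unequal means give t = ±inf
    with p = 0 (a zero-variance separation is reported as the 0-limit).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p, df, est = _pooled_t(a[None, :], b[None, :])
    return TestResult(estimate=float(est[0]), t=float(t[0]), df=float(df), p=float(p[0]))


def _pooled_t(A: np.ndarray, B: np.ndarray):
    """Row-wise pooled t-test for matrices (rows = tests, cols = replicates)."""
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    ssa = ((A - ma[:, None]) ** 2).sum(axis=1)
    ssb = ((B - mb[:, None]) ** 2).sum(axis=1)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), 0.0)
    t = np.where((se == 0) & (diff != 0), np.where(diff > 0, np.inf, -np.inf), t)
    p = 2.0 * t_dist.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where((se == 0) & (diff == 0), 1.0, p)
    return t, p, df, diff


def students_t_matrix(A: np.ndarray, B: np.ndarray) -> pd.DataFrame:
    """Vectorized row-wise Student's t-tests.

    ``A`` and ``B`` are (tests × replicates) matrices sharing rows. Returns a
    frame with columns estimate, t, df, p — one row per test.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise ValueError("A and B must have the same number of rows")
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("each group needs at least 2 replicates")
    t, p, df, est = _pooled_t(A, B)
    return pd.DataFrame({"estimate": est, "t": t, "df": df, "p": p})


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment p_adj = min(1, m p).

    ``m`` defaults to the number of p-values and must be at least that many
    (the family may be larger than the tests actually computed, never
    smaller).
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than number of tests {p.size}")
    return np.minimum(1.0, m * p)


def linear_contrast(
    data: pd.DataFrame,
    group_a: str,
    group_b: str,
    feature_col: str = "feature_id",
    group_col: str = "group",
    value_col: str = "log2_intensity",
) -> TestResult:
    """OLS two-factor contrast: log2 intensity ~ feature + group.

    ``data`` holds the (already log2-transformed) intensities of one
    protein's features across the two groups. The returned estimate is the
    group contrast (a minus b) on the log2 scale, with a t-statistic on the
    residual degrees of freedom; its magnitude is the model-based log2 fold
    change between the two stage points. Each
    group needs >= 2 observations and the design must be full rank; for a
    single-feature protein the result equals :func:`students_t` on the log2
    values exactly.
    """
    d = data[data[group_col].isin([group_a, group_b])]
    counts = d[group_col].value_counts()
    if counts.get(group_a, 0) < 2 or counts.get(group_b, 0) < 2:
        raise ValueError("each group needs at least 2 observations")
    y = d[value_col].to_numpy(dtype=float)
    feats = pd.Categorical(d[feature_col])
    n = len(y)
    # design: intercept + (k-1) feature dummies + group indicator
    F = pd.get_dummies(feats, drop_first=True).to_numpy(dtype=float)
    g = (d[group_col] == group_b).to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), F, g])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design (confounded feature/group structure)")
    df_resid = n - rank
    if df_resid < 1:
        raise ValueError("not enough residual degrees of freedom")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = resid @ resid / df_resid
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(s2 * XtX_inv[-1, -1])
    est = -beta[-1]  # group_a minus group_b, same sign convention as students_t
    if se == 0:
        t = 0.0 if est == 0 else np.sign(est) * np.inf
        p = 1.0 if est == 0 else 0.0
    else:
        t = est / se
        p = float(2.0 * t_dist.sf(abs(t), df_resid))
    return TestResult(estimate=float(est), t=float(t), df=float(df_resid), p=float(p))
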