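"""Two-arm nonparametric cohort statistics.

Small preclinical cohorts (7–14 animals per arm) call for rank-based
testing: intergroup comparisons use the Mann–Whitney U-test, intragroup
baseline-vs-follow-up comparisons use the Wilcoxon signed-rank test after
pairwise deletion of incomplete pairs, and the parameter correlation
matrix uses Spearman's rho.  Raw two-sided p-values are reported
throughout — by design there is no multiplicity adjustment, matching the
exploratory character of such studies — with significance flagged at
alpha = 0.05.

Exact small-sample p-values are used where they are well defined
(tie-free data with min(n1, n2) <= 8 for Mann–Whitney, n <= 15 for
Wilcoxon); larger or tied samples switch to the normal approximation with
tie and continuity corrections.  The switch is recorded in each result's
``method`` note.  The computations are delegated to scipy.stats behind
this module's conventions.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InputError
from .io import GROUPS, TIMEPOINTS, CohortTable

__all__ = [
    "ALPHA",
    "StatResult",
    "CorrelationMatrix",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "spearman_matrix",
    "group_summary",
    "run_study_statistics",
]

ALPHA = 0.05

MANN_WHITNEY_EXACT_MAX_N = 8
WILCOXON_EXACT_MAX_N = 15


@dataclasses.dataclass
class StatResult:
    """One hypothesis test: statistic, two-sided p, sample sizes, method."""

    test: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < ALPHA)

    @property
    def n_pairs(self) -> int:
        """Alias for paired tests, where n1 == n2 == number of pairs."""
        return self.n1


def _clean(sample) -> np.ndarray:
    arr = np.asarray(sample, dtype=float).ravel()
    return arr[np.isfinite(arr)]


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(x, y) -> StatResult:
    """Two-sided Mann–Whitney U-test between independent samples.

    Missing values are dropped per sample.  The exact null distribution is
    used for tie-free data with min(n1, n2) <= 8; otherwise the normal
    approximation with tie correction and continuity correction.  The
    reported statistic is ``min(U1, U2)``.
    """
    x, y = _clean(x), _clean(y)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise InputError("empty sample after dropping missing values")
    exact = min(n1, n2) <= MANN_WHITNEY_EXACT_MAX_N and not _has_ties(
        np.concatenate([x, y])
    )
    method = "exact" if exact else "normal approximation (tie/continuity corrected)"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=not exact,
    )
    u1 = float(res.statistic)
    u = min(u1, n1 * n2 - u1)
    return StatResult("mann_whitney_u", u, min(float(res.pvalue), 1.0),
                      n1, n2, method)


def wilcoxon_signed_rank(before, after, zero_method: str = "wilcox"
                         ) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Pairs where either value is missing are deleted first (pairwise
    deletion); ``n_pairs`` in the result counts the complete pairs.  Zero
    differences are then dropped (classic Wilcoxon convention; pass
    ``zero_method='pratt'`` to rank them instead).  Exact p for tie-free
    differences with n <= 15, else the continuity-corrected normal
    approximation.  All-zero differences give a degenerate p = 1 with a
    warning.
    """
    before = np.asarray(before, dtype=float).ravel()
    after = np.asarray(after, dtype=float).ravel()
    if before.shape != after.shape:
        raise InputError("paired samples must have equal length")
    complete = np.isfinite(before) & np.isfinite(after)
    b, a = before[complete], after[complete]
    n_pairs = int(b.size)
    if n_pairs == 0:
        raise InputError("no complete pairs after pairwise deletion")
    d = a - b
    nonzero = d != 0
    if not nonzero.any():
        warnings.warn("all paired differences are zero; p-value undefined, "
                      "reporting p = 1")
        return StatResult("wilcoxon_signed_rank", 0.0, 1.0, n_pairs, n_pairs,
                          "degenerate (all differences zero)")
    d_used = d[nonzero] if zero_method == "wilcox" else d
    n_used = d_used.size if zero_method == "wilcox" else np.count_nonzero(d)
    exact = (d[nonzero].size <= WILCOXON_EXACT_MAX_N
             and not _has_ties(np.abs(d[nonzero])))
    method = "exact" if exact else "normal approximation (continuity corrected)"
    res = sps.wilcoxon(
        a[d != 0] if zero_method == "wilcox" else a,
        b[d != 0] if zero_method == "wilcox" else b,
        zero_method=zero_method, alternative="two-sided",
        correction=not exact,
        method="exact" if exact else "approx",
    )
    return StatResult("wilcoxon_signed_rank", float(res.statistic),
                      min(float(res.pvalue), 1.0), n_pairs, n_pairs, method)


@dataclasses.dataclass
class CorrelationMatrix:
    """Spearman correlation matrix with p-values and significance flags."""

    parameters: list[str]
    rho: np.ndarray
    p: np.ndarray
    n: np.ndarray

    @property
    def significant(self) -> np.ndarray:
        """True where p < alpha (diagonal excluded)."""
        sig = self.p < ALPHA
        np.fill_diagonal(sig, False)
        return sig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.parameters,
                            columns=self.parameters)

    def to_csv(self, path) -> None:
        rows = []
        k = len(self.parameters)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append({
                    "parameter_1": self.parameters[i],
                    "parameter_2": self.parameters[j],
                    "rho": self.rho[i, j],
                    "p_value": self.p[i, j],
                    "n": self.n[i, j],
                    "significant": bool(self.p[i, j] < ALPHA),
                })
        pd.DataFrame(rows).to_csv(path, index=False)


def spearman_matrix(table: CohortTable, parameters: list[str] | None = None
                    ) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlations between image parameters.

    Observations are (subject, timepoint) measurements; each parameter
    pair uses its pairwise-complete rows (>= 3 required, else NaN).  rho
    is the Pearson correlation of average-ranked values; p comes from the
    t-distribution with n - 2 degrees of freedom.  Constant columns give
    NaN for all their pairs.
    """
    parameters = parameters or table.parameters()
    wide = table.df.pivot_table(
        index=["subject_id", "timepoint"], columns="parameter",
        values="value", aggfunc="first",
    )
    k = len(parameters)
    rho = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(k):
        for j in range(i + 1, k):
            if parameters[i] not in wide.columns or parameters[j] not in wide.columns:
                continue
            xi = wide[parameters[i]].to_numpy(float)
            xj = wide[parameters[j]].to_numpy(float)
            keep = np.isfinite(xi) & np.isfinite(xj)
            n[i, j] = n[j, i] = int(keep.sum())
            if keep.sum() < 3:
                continue
            a, b = xi[keep], xj[keep]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue  # rho undefined for a constant column
            r = sps.spearmanr(a, b)
            rho[i, j] = rho[j, i] = float(r.statistic)
            p[i, j] = p[j, i] = float(r.pvalue)
    np.fill_diagonal(n, int(wide.shape[0]))
    return CorrelationMatrix(list(parameters), rho, p, n)


def plot_correlation_heatmap(matrix: CorrelationMatrix, path) -> None:
    """Render the correlation matrix: rho color-coded, nonsignificant
    entries overlaid with a cross."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    k = len(matrix.parameters)
    fig, ax = plt.subplots(figsize=(1.0 + 0.7 * k, 1.0 + 0.7 * k))
    im = ax.imshow(matrix.rho, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(k), matrix.parameters, rotation=45, ha="right")
    ax.set_yticks(range(k), matrix.parameters)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            val = matrix.rho[i, j]
            if np.isfinite(val):
                ax.text(j, i, f"{val:.2f}", ha="center", va="center",
                        fontsize=8)
            if not matrix.significant[i, j]:
                ax.plot(j, i, marker="x", color="black", markersize=14,
                        alpha=0.5)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def group_summary(table: CohortTable) -> pd.DataFrame:
    """Mean ± sample SD (n - 1 denominator) per group x timepoint x
    parameter, with the per-cell n of non-missing values."""
    rows = []
    for param in table.parameters():
        for group in GROUPS:
            for tp in TIMEPOINTS:
                vals = table.values_for(group, tp, param)
                rows.append({
                    "parameter": param,
                    "group": group,
                    "timepoint": tp,
                    "n": int(vals.size),
                    "mean": float(vals.mean()) if vals.size else np.nan,
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                })
    return pd.DataFrame(rows)


def run_study_statistics(table: CohortTable, zero_method: str = "wilcox"
                         ) -> pd.DataFrame:
    """The full two-arm testing scheme as one tidy report.

    Per parameter: Mann–Whitney therapy-vs-control at each timepoint and
    Wilcoxon baseline-vs-follow-up within each group (pairwise deletion).
    One row per comparison with raw (unadjusted) p-values.
    """
    rows = []
    for param in table.parameters():
        for tp in TIMEPOINTS:
            x = table.values_for("control", tp, param)
            y = table.values_for("therapy", tp, param)
            if x.size == 0 or y.size == 0:
                continue
            r = mann_whitney_u(x, y)
            rows.append({
                "parameter": param, "comparison": f"control_vs_therapy@{tp}",
                "test": r.test, "n1": r.n1, "n2": r.n2,
                "statistic": r.statistic, "p_value": r.p_value,
                "method": r.method,
            })
        for group in GROUPS:
            pairs = table.paired_values(group, param)
            if pairs.empty:
                continue
            try:
                r = wilcoxon_signed_rank(pairs["baseline"], pairs["follow_up"],
                                         zero_method=zero_method)
            except InputError:
                continue
            rows.append({
                "parameter": param,
                "comparison": f"baseline_vs_follow_up@{group}",
                "test": r.test, "n1": r.n_pairs, "n2": r.n_pairs,
                "statistic": r.statistic, "p_value": r.p_value,
                "method": r.method,
            })
    return pd.DataFrame(rows)
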