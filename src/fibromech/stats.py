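"""Statistical layer: normalizations, ROUT outliers, group tests, exact Spearman.

Mirrors a conventional biomechanics analysis stack: per-sample median
centering, control-mean normalization and z-scores; robust outlier removal at
an FDR level Q (default 1%); Shapiro-gated two-group (t / Mann-Whitney) and
multi-group (ANOVA+Bonferroni / Kruskal-Wallis+Dunn) testing with significance
stars at 0.05 / 0.01 / 0.001 / 0.0001; Spearman rank correlation with an exact
permutation p-value at small n; and ddCt relative expression.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RoutResult",
    "CorrelationResult",
    "median_center",
    "normalize_to_control",
    "zscore",
    "rout_outliers",
    "significance_stars",
    "group_tests",
    "dunn_posthoc",
    "spearman_exact",
    "ddct_fold_change",
    "stage_correlation",
]


# ---------------------------------------------------------------------------
# Normalizations (all invertible given the stored reference parameters)
# ---------------------------------------------------------------------------

def median_center(values: np.ndarray, mode: str = "divide") -> np.ndarray:
    """Normalize a sample by its median.

    ``divide`` (default) returns fold-of-median values, appropriate for
    positive moduli (equivalent to subtraction on the log scale); ``subtract``
    returns values minus the median.  The output median is exactly 1 (or 0).
    """
    v = np.asarray(values, dtype=float)
    med = float(np.median(v))
    if mode == "divide":
        if med == 0:
            raise ValueError("sample median is zero; cannot divide")
        return v / med
    if mode == "subtract":
        return v - med
    raise ValueError(f"unknown mode {mode!r}")


def normalize_to_control(values: np.ndarray, control_mean: float) -> np.ndarray:
    """Express values as fold of the control-group mean."""
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    return np.asarray(values, dtype=float) / control_mean


def zscore(values: np.ndarray, ref_mean: float, ref_sd: float) -> np.ndarray:
    if ref_sd <= 0:
        raise ValueError("ref_sd must be positive")
    return (np.asarray(values, dtype=float) - ref_mean) / ref_sd


# ---------------------------------------------------------------------------
# ROUT outlier removal (univariate constant-model restriction)
# ---------------------------------------------------------------------------

@dataclass
class RoutResult:
    inlier_mask: np.ndarray
    outlier_indices: np.ndarray
    rsdr: float
    q: float
    warning: str | None = None

    @property
    def n_outliers(self) -> int:
        return int(len(self.outlier_indices))


def rout_outliers(values: np.ndarray, q: float = 0.01) -> RoutResult:
    """Robust outlier detection for a univariate sample at FDR level ``q``.

    The constant model is fitted robustly (median); the robust residual scale
    (RSDR) is the 68.27th percentile of absolute residuals with the n/(n-1)
    small-sample degrees-of-freedom correction.  Residual t-ratios are then
    screened by a Benjamini-Hochberg step-up schedule at rate ``q``; points
    passing the sweep are flagged as outliers.  With fewer than 10 points no
    removal is attempted.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 10:
        return RoutResult(
            inlier_mask=np.ones(n, dtype=bool),
            outlier_indices=np.array([], dtype=int),
            rsdr=float("nan"),
            q=q,
            warning="n < 10: outlier removal skipped",
        )
    resid = v - np.median(v)
    abs_resid = np.abs(resid)
    rsdr = float(np.percentile(abs_resid, 68.27)) * n / (n - 1)
    # degenerate scale (over half the sample identical): any non-zero residual
    # is then unambiguous; use a relative floor to stay affine-equivariant
    if rsdr <= 0:
        rsdr = 1e-12 * max(float(abs_resid.max()), 1.0)
    t_ratio = abs_resid / rsdr
    p = 2.0 * sps.t.sf(t_ratio, df=n - 1)

    order = np.argsort(p)
    thresholds = q * (np.arange(1, n + 1)) / n
    passed = p[order] <= thresholds
    k = int(np.max(np.nonzero(passed)[0])) + 1 if passed.any() else 0
    outliers = np.sort(order[:k])
    mask = np.ones(n, dtype=bool)
    mask[outliers] = False
    return RoutResult(inlier_mask=mask, outlier_indices=outliers, rsdr=rsdr, q=q)


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


def _groups_normal(groups: dict[str, np.ndarray], alpha: float = 0.05) -> bool:
    for g in groups.values():
        if len(g) < 3:
            return False
        if sps.shapiro(g).pvalue <= alpha:
            return False
    return True


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "none") -> pd.DataFrame:
    """Dunn's rank-sum post hoc test after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt(S * (1/n_i + 1/n_j)) with
    S = N(N+1)/12 - tie correction; two-sided normal p, optionally Bonferroni
    adjusted (unadjusted is the default).
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = [len(groups[g]) for g in names]
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, size in zip(names, sizes):
        mean_ranks[name] = ranks[start:start + size].mean()
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    s = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    pairs = list(itertools.combinations(range(len(names)), 2))
    for i, j in pairs:
        se = math.sqrt(s * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[names[i]] - mean_ranks[names[j]]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * len(pairs))
        rows.append({
            "comparison": f"{names[i]} vs {names[j]}",
            "statistic": z,
            "p": p,
            "stars": significance_stars(p),
            "method": f"dunn ({adjust})",
            "n": sizes[i] + sizes[j],
        })
    return pd.DataFrame(rows)


def group_tests(
    groups: dict[str, np.ndarray],
    parametric: bool | None = None,
    dunn_adjust: str = "none",
) -> pd.DataFrame:
    """Two- or multi-group comparison following the normality-gated scheme.

    Two groups: unpaired t-test if every group passes Shapiro-Wilk, otherwise
    Mann-Whitney U.  More groups: one-way ANOVA with Bonferroni-adjusted
    pairwise t-tests, or Kruskal-Wallis followed by Dunn's post hoc.  Groups
    with n < 3 are skipped with a reason.  Returns a tidy report.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    usable = {k: v for k, v in groups.items() if len(v) >= 3}
    for name in set(groups) - set(usable):
        rows.append({
            "comparison": name, "statistic": float("nan"), "p": float("nan"),
            "stars": "skipped", "method": "skipped: n < 3", "n": len(groups[name]),
        })
    if len(usable) < 2:
        return pd.DataFrame(rows)

    if parametric is None:
        parametric = _groups_normal(usable)

    names = list(usable)
    arrays = [usable[n] for n in names]
    if len(usable) == 2:
        if parametric:
            stat, p = sps.ttest_ind(*arrays)
            method = "t-test (unpaired)"
        else:
            stat, p = sps.mannwhitneyu(*arrays, alternative="two-sided")
            method = "mann-whitney"
        rows.append({
            "comparison": f"{names[0]} vs {names[1]}",
            "statistic": float(stat), "p": float(p),
            "stars": significance_stars(float(p)), "method": method,
            "n": sum(map(len, arrays)),
        })
    else:
        if parametric:
            stat, p = sps.f_oneway(*arrays)
            method = "one-way anova"
        else:
            stat, p = sps.kruskal(*arrays)
            method = "kruskal-wallis"
        rows.append({
            "comparison": " vs ".join(names), "statistic": float(stat),
            "p": float(p), "stars": significance_stars(float(p)),
            "method": method, "n": sum(map(len, arrays)),
        })
        if parametric:
            n_pairs = len(names) * (len(names) - 1) // 2
            for a, b in itertools.combinations(names, 2):
                stat, p = sps.ttest_ind(usable[a], usable[b])
                p = min(1.0, float(p) * n_pairs)
                rows.append({
                    "comparison": f"{a} vs {b}", "statistic": float(stat),
                    "p": p, "stars": significance_stars(p),
                    "method": "t-test (bonferroni)",
                    "n": len(usable[a]) + len(usable[b]),
                })
        else:
            rows.extend(dunn_posthoc(usable, adjust=dunn_adjust).to_dict("records"))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-n permutation p
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    rho: float
    p_two_sided: float
    n: int
    method: str
    note: str | None = None


def _sum_d2_distribution(n: int):
    """Iterate the permutation distribution of sum(d^2) against identity ranks."""
    base = np.arange(n)
    chunk = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            yield np.sum((np.array(chunk) - base) ** 2, axis=1)
            chunk = []
    if chunk:
        yield np.sum((np.array(chunk) - base) ** 2, axis=1)


def spearman_exact(x, y, exact_max_n: int = 10) -> CorrelationResult:
    """Spearman rho with an exact two-sided permutation p-value for n <= 10.

    With no ties: rho = 1 - 6 sum(d^2) / (n (n^2 - 1)); the exact tail counts
    permutations at least as extreme in the direction of the observed rho
    (sum(d^2) at most / at least the observed value), then doubles, capped at
    1.  With ties, midrank rho and the asymptotic p are used, with a note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, "undefined",
                                 note="constant input: correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    has_ties = (np.unique(rx).size < n) or (np.unique(ry).size < n)
    if has_ties or n > exact_max_n:
        rho, p = sps.spearmanr(x, y)
        note = "ties present: midrank rho, asymptotic p" if has_ties else None
        return CorrelationResult(float(rho), float(p), n, "asymptotic", note)

    d2 = int(np.sum((rx - ry) ** 2))
    rho = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    mean_d2 = n * (n**2 - 1) / 6.0  # sum(d^2) at rho = 0
    total = math.factorial(n)
    count = 0
    for block in _sum_d2_distribution(n):
        if d2 <= mean_d2:
            count += int(np.sum(block <= d2))
        else:
            count += int(np.sum(block >= d2))
    p = min(1.0, 2.0 * count / total)
    return CorrelationResult(float(rho), float(p), n, "exact-permutation")


# ---------------------------------------------------------------------------
# ddCt and stage-wise correlation
# ---------------------------------------------------------------------------

def ddct_fold_change(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression 2^-ddCt.

    ddCt = (Ct_target - Ct_reference)_treated - (Ct_target - Ct_reference)_control.
    """
    for ct in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if ct <= 0:
            raise ValueError("Ct values must be positive")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return float(2.0 ** (-ddct))


def stage_correlation(table: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint Spearman correlation of collagen content vs mean modulus.

    ``table`` needs columns specimen_id, timepoint_days, collagen_fraction,
    mean_e_kpa.  Timepoints with fewer than 4 specimens, or with a constant
    variable, are reported as skipped/undefined rather than dropped.
    """
    required = {"specimen_id", "timepoint_days", "collagen_fraction", "mean_e_kpa"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for tp, sub in table.groupby("timepoint_days"):
        if len(sub) < 4:
            rows.append({"timepoint_days": tp, "rho": float("nan"),
                         "p": float("nan"), "n": len(sub),
                         "method": "skipped: n < 4"})
            continue
        res = spearman_exact(sub["collagen_fraction"].to_numpy(),
                             sub["mean_e_kpa"].to_numpy())
        rows.append({"timepoint_days": tp, "rho": res.rho, "p": res.p_two_sided,
                     "n": res.n,
                     "method": res.method if res.note is None
                     else f"{res.method} ({res.note})"})
    return pd.DataFrame(rows)
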