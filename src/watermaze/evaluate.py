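"""Statistical evaluation of water-maze measures.

Implements the protocol used to compare the deviation indices against
escape latency:

* a Lilliefors-corrected one-sample Kolmogorov-Smirnov normality gate that
  selects a two-sample t test (both groups normal) or a Mann-Whitney U test
  (otherwise);
* Monte Carlo estimation of true-positive (rejection) and false-positive
  rates of the t and U tests over a range of sample sizes and significance
  levels, resampling from pooled per-trial databases;
* empirical ROC curves with trapezoidal AUC, DeLong standard errors, and
  the DeLong paired Z test for two correlated AUCs measured on the same
  animals;
* counting of consecutive trainings without improvement, a stability
  measure of learning curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupTable",
    "ComparisonResult",
    "MonteCarloResult",
    "RocResult",
    "AucComparison",
    "normality_test",
    "format_normality_p",
    "compare_groups",
    "monte_carlo_evaluation",
    "roc_curve",
    "compare_auc",
    "non_improvement_count",
    "non_improvement_table",
    "paired_count_test",
]


@dataclass(frozen=True)
class GroupTable:
    """Values of one measure for one group (one training, or a pooled database)."""

    index_name: str
    group: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)


def _values(x) -> np.ndarray:
    if isinstance(x, GroupTable):
        return x.values
    return np.asarray(x, dtype=float)


# ---------------------------------------------------------------------------
# Normality gate and two-group comparison


def normality_test(values) -> float:
    """Lilliefors-corrected one-sample K-S test of normality; returns the p value.

    The reference normal has mean and SD estimated from the sample
    (Lilliefors correction).  The exact p value is returned; statistical
    packages conventionally display values above 0.2 as "0.200" in tables —
    use :func:`format_normality_p` for that.
    """
    v = _values(values)
    if v.size < 4:
        raise ValueError("normality test needs at least 4 observations")
    if np.std(v) == 0:
        raise ValueError("normality test is undefined for a constant sample")
    _, p = lilliefors(v, dist="norm")
    return float(p)


def format_normality_p(p: float) -> float:
    """Table display convention: p values above 0.2 are reported as 0.200."""
    return min(float(p), 0.200)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of the normality-gated two-group comparison."""

    index_name: str
    test_used: str  # "t" or "U"
    p_value: float
    statistic: float
    normal_model: bool
    normal_control: bool
    normality_p_model: float
    normality_p_control: float


def compare_groups(
    model: GroupTable,
    control: GroupTable,
    alpha_norm: float = 0.05,
    equal_var: bool = False,
) -> ComparisonResult:
    """Normality-gated two-group test on one measure.

    If both groups pass the normality gate (Lilliefors p > ``alpha_norm``)
    an independent two-sample t test is used (Welch by default); otherwise a
    two-sided Mann-Whitney U test.
    """
    if model.index_name != control.index_name:
        raise ValueError(
            f"mismatched measures: {model.index_name!r} vs {control.index_name!r}"
        )
    if model.n < 3 or control.n < 3:
        raise ValueError("each group needs at least 3 observations")
    p_norm_m = normality_test(model)
    p_norm_c = normality_test(control)
    normal_m = p_norm_m > alpha_norm
    normal_c = p_norm_c > alpha_norm
    if normal_m and normal_c:
        res = stats.ttest_ind(model.values, control.values, equal_var=equal_var)
        test = "t"
    else:
        res = stats.mannwhitneyu(model.values, control.values, alternative="two-sided")
        test = "U"
    return ComparisonResult(
        index_name=model.index_name,
        test_used=test,
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        normal_model=normal_m,
        normal_control=normal_c,
        normality_p_model=p_norm_m,
        normality_p_control=p_norm_c,
    )


# ---------------------------------------------------------------------------
# Monte Carlo sensitivity / specificity


@dataclass(frozen=True)
class MonteCarloResult:
    """Rejection-rate grid from the resampling experiment.

    ``grid`` is a long-format table with columns
    ``index,test,alpha,n,rejection_rate,false_positive_rate``: the rejection
    rate comes from model-vs-control draws (true positives), the
    false-positive rate from control-vs-control draws (null run).
    """

    grid: pd.DataFrame
    n_replicates: int
    seed: int
    index_name: str = ""


@lru_cache(maxsize=None)
def _u_null_distribution(m: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null pmf and cdf of the Mann-Whitney U statistic (no ties).

    Classic counting recursion c(m, n, u) = c(m-1, n, u-n) + c(m, n-1, u),
    evaluated iteratively as arrays over u.
    """
    size = m * n + 1
    # table[nn] holds counts for (mm, nn) as mm grows
    table = [np.zeros(size) for _ in range(n + 1)]
    for nn in range(n + 1):
        table[nn][0] = 1.0
    for _mm in range(1, m + 1):
        prev = [row.copy() for row in table]
        for nn in range(1, n + 1):
            shifted = np.zeros(size)
            shifted[nn:] = prev[nn][: size - nn]
            table[nn] = shifted + table[nn - 1]
    pmf = table[n] / table[n].sum()
    return pmf, np.cumsum(pmf)


#: largest m*n for which the U test uses the exact mid-p null in Monte Carlo
_EXACT_U_LIMIT = 10_000


def _u_midp_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided mid-p values of the U test from its exact null distribution.

    Plain p values of a discrete statistic make the test conservative at
    small samples (the attainable size sits well below alpha); the mid-p
    convention — half weight on the observed value — keeps the realised
    rejection rate tracking alpha, which is what the Monte Carlo calibration
    requires.  Tied observations yield half-integer U, which falls between
    lattice points and is handled by the floor of the statistic.
    """
    m, n = a.shape[1], b.shape[1]
    u = np.atleast_1d(stats.mannwhitneyu(a, b, axis=1).statistic)
    pmf, cdf = _u_null_distribution(m, n)
    lo = np.clip(np.floor(u).astype(int), 0, m * n)
    half_integer = u != lo
    f_mid = np.where(half_integer, cdf[lo], cdf[lo] - 0.5 * pmf[lo])
    return np.minimum(2.0 * np.minimum(f_mid, 1.0 - f_mid), 1.0)


def _batch_pvalues(a: np.ndarray, b: np.ndarray, test: str) -> np.ndarray:
    """Two-sided p values of a batch of two-sample tests (rows are replicates)."""
    if test == "t":
        return stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    if test == "U":
        if a.shape[1] * b.shape[1] <= _EXACT_U_LIMIT:
            return _u_midp_pvalues(a, b)
        return stats.mannwhitneyu(a, b, axis=1, alternative="two-sided").pvalue
    raise ValueError(f"unknown test {test!r}")


def monte_carlo_evaluation(
    database_model,
    database_control,
    sample_sizes=range(10, 41),
    alphas=(0.05, 0.01, 0.005),
    n_replicates: int = 10_000,
    seed: int = 0,
    tests: tuple[str, ...] = ("t", "U"),
    parametric: bool = False,
) -> MonteCarloResult:
    """Estimate true- and false-positive rates of the t and U tests.

    For every sample size n, ``n_replicates`` pairs of samples are drawn
    with replacement: model-pool vs control-pool for the true-positive run
    and control-pool vs control-pool for the null (false-positive) run.
    Both tests are applied unconditionally (no normality gate) and the
    fraction of p values at or below each alpha is recorded.  With
    ``parametric=True`` draws come from normal distributions fitted to each
    pool instead of from the empirical values.

    All randomness derives from ``seed`` through a keyed seed-sequence
    scheme, so results do not depend on the order of the requested grid.
    """
    model = _values(database_model)
    control = _values(database_control)
    if model.size == 0 or control.size == 0:
        raise ValueError("empty resampling pool")
    if n_replicates < 100:
        raise ValueError("n_replicates must be at least 100")
    index_name = (
        database_model.index_name if isinstance(database_model, GroupTable) else ""
    )

    pools = {"tp": (model, control), "null": (control, control)}
    fits = {
        id(p): (float(np.mean(p)), float(np.std(p, ddof=1))) for p in (model, control)
    }
    rows = []
    for n in sample_sizes:
        n = int(n)
        for run_idx, (run, (pool_a, pool_b)) in enumerate(pools.items()):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(run_idx, n))
            )
            if parametric:
                ma, sa = fits[id(pool_a)]
                mb, sb = fits[id(pool_b)]
                a = rng.normal(ma, sa, size=(n_replicates, n))
                b = rng.normal(mb, sb, size=(n_replicates, n))
            else:
                a = rng.choice(pool_a, size=(n_replicates, n), replace=True)
                b = rng.choice(pool_b, size=(n_replicates, n), replace=True)
            for test in tests:
                p = _batch_pvalues(a, b, test)
                for alpha in alphas:
                    rows.append(
                        {
                            "run": run,
                            "test": test,
                            "alpha": float(alpha),
                            "n": n,
                            "rate": float(np.mean(p <= alpha)),
                        }
                    )
    long = pd.DataFrame(rows)
    grid = (
        long.pivot_table(
            index=["test", "alpha", "n"], columns="run", values="rate"
        )
        .rename(columns={"tp": "rejection_rate", "null": "false_positive_rate"})
        .reset_index()
    )
    grid.columns.name = None
    grid.insert(0, "index", index_name)
    return MonteCarloResult(
        grid=grid[
            ["index", "test", "alpha", "n", "rejection_rate", "false_positive_rate"]
        ],
        n_replicates=n_replicates,
        seed=seed,
        index_name=index_name,
    )


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong errors


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values via mid-ranks (ties count one half)."""
    m, n = pos.size, neg.size
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - stats.rankdata(neg)) / m
    auc = float(v10.mean())
    return auc, v10, v01


def _auc_mannwhitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """Tie-corrected U / (n_pos * n_neg); the rank-sum route to the AUC."""
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u) / (pos.size * neg.size)


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve of one measure (model group = positive class)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_se: float
    auc_ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    index_name: str = ""


def roc_curve(model_values, control_values, index_name: str = "") -> RocResult:
    """Empirical ROC and AUC, with DeLong standard error and 95% CI.

    Higher values are scored as more model-like (all five measures are
    larger in impaired animals).  Ties contribute one half; the trapezoidal
    AUC is cross-checked against the tie-corrected Mann-Whitney statistic
    U/(n_pos * n_neg), which it must equal to numerical precision.
    """
    pos = _values(model_values)
    neg = _values(control_values)
    if isinstance(model_values, GroupTable) and not index_name:
        index_name = model_values.index_name
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    scores = np.concatenate([pos, neg])
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    auc_rank, v10, v01 = _placements(pos, neg)
    if abs(auc - auc_rank) > 1e-10:
        raise AssertionError(
            f"trapezoidal AUC {auc!r} disagrees with rank-based AUC {auc_rank!r}"
        )
    var = 0.0
    if pos.size > 1:
        var += np.var(v10, ddof=1) / pos.size
    if neg.size > 1:
        var += np.var(v01, ddof=1) / neg.size
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    ci = (max(auc - z * se, 0.0), min(auc + z * se, 1.0))
    return RocResult(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=auc_rank,
        auc_se=se,
        auc_ci95=ci,
        n_pos=pos.size,
        n_neg=neg.size,
        index_name=index_name,
    )


@dataclass(frozen=True)
class AucComparison:
    """DeLong paired comparison of two correlated AUCs."""

    auc_a: float
    auc_b: float
    auc_difference: float
    se_difference: float
    ci95: tuple[float, float]
    z: float
    p_value: float


def compare_auc(scores_a, scores_b, labels) -> AucComparison:
    """DeLong Z test for two AUCs measured on the same animals.

    ``labels`` marks the positive (model) class; both score vectors must be
    aligned with it element-wise.  The variance of the AUC difference uses
    the covariance of the paired placement values, so the correlation
    induced by scoring the same animals twice is accounted for.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores_a, scores_b and labels must be aligned 1-D arrays")
    if y.all() or not y.any():
        raise ValueError("need both classes among the labels")
    m, n = int(y.sum()), int((~y).sum())
    auc_a, v10_a, v01_a = _placements(a[y], a[~y])
    auc_b, v10_b, v01_b = _placements(b[y], b[~y])
    s10 = np.cov(v10_a, v10_b, ddof=1) / m if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01_a, v01_b, ddof=1) / n if n > 1 else np.zeros((2, 2))
    s = s10 + s01
    var_diff = float(s[0, 0] + s[1, 1] - 2.0 * s[0, 1])
    diff = auc_a - auc_b
    se = float(np.sqrt(max(var_diff, 0.0)))
    if se == 0.0:
        z_stat = 0.0
        p = 1.0
    else:
        z_stat = diff / se
        p = float(2.0 * stats.norm.sf(abs(z_stat)))
    z975 = stats.norm.ppf(0.975)
    return AucComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        auc_difference=diff,
        se_difference=se,
        ci95=(diff - z975 * se, diff + z975 * se),
        z=z_stat,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# Learning-curve stability


def non_improvement_count(series) -> int:
    """Number of consecutive-training pairs where the value did not decrease.

    The measures all shrink with learning, so a pair (k, k+1) with
    value_{k+1} >= value_k (ties included) counts as a failure to improve.
    """
    v = np.asarray(series, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two trainings")
    return int(np.sum(np.diff(v) >= 0))


def non_improvement_table(
    indices: pd.DataFrame,
    measures,
    animal_col: str = "animal_id",
    training_col: str = "training",
) -> pd.DataFrame:
    """Per-animal non-improvement counts for each measure.

    ``indices`` is a long table with one row per animal and training.
    Returns one row per animal with a count column per measure.
    """
    out = {}
    grouped = indices.sort_values(training_col).groupby(animal_col, sort=True)
    for measure in measures:
        out[measure] = grouped[measure].apply(non_improvement_count)
    return pd.DataFrame(out)


def paired_count_test(counts_a, counts_b) -> tuple[float, float]:
    """Paired t test between two per-animal count vectors; returns (t, p)."""
    res = stats.ttest_rel(np.asarray(counts_a, float), np.asarray(counts_b, float))
    return float(res.statistic), float(res.pvalue)
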