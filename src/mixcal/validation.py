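"""Figures of merit and the model-validation battery.

Error metrics (RMSE / recovery / regression diagnostics), nested K-fold
cross-validation with bootstrap confidence intervals, Y-randomization,
applicability-domain (Williams plot) analysis, pooled t / variance-ratio F
method-comparison statistics and the Friedman rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricsReport",
    "ADReport",
    "ComparisonReport",
    "NestedCVResult",
    "error_metrics",
    "rmse_reduction",
    "nested_cv",
    "y_randomization",
    "applicability_domain",
    "pooled_t_test",
    "variance_ratio_f",
    "friedman_test",
]


@dataclass(frozen=True)
class MetricsReport:
    context: str                 # calibration | cv | prediction
    rmse: float
    recovery_percent: np.ndarray  # per sample
    mean_recovery: float
    sd_recovery: float
    rsd_percent: float
    slope: float
    intercept: float
    r: float
    r_squared: float

    def to_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "recovery_percent"}
        d["recovery_percent"] = self.recovery_percent.tolist()
        return d


def error_metrics(actual: np.ndarray, predicted: np.ndarray, context: str = "prediction") -> MetricsReport:
    """RMSE, per-sample %R, SD, %RSD and the predicted-vs-actual regression line.

    RMSE uses the plain 1/n denominator in every context so RMSEC, RMSECV
    and RMSEP share one formula.
    """
    actual = np.asarray(actual, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if actual.size != predicted.size:
        raise ValueError("actual and predicted must be aligned")
    if actual.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(actual == 0):
        raise ValueError("recovery undefined: actual contains zero")
    rmse = float(np.sqrt(np.mean((predicted - actual) ** 2)))
    rec = 100.0 * predicted / actual
    sd = float(rec.std(ddof=1))
    mean_rec = float(rec.mean())
    reg = stats.linregress(actual, predicted)
    return MetricsReport(
        context=context,
        rmse=rmse,
        recovery_percent=rec,
        mean_recovery=mean_rec,
        sd_recovery=sd,
        rsd_percent=100.0 * sd / mean_rec,
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r=float(reg.rvalue),
        r_squared=float(reg.rvalue**2),
    )


def rmse_reduction(base: float, improved: float) -> float:
    """Percent reduction 100 * (base - improved) / base."""
    if base <= 0:
        raise ValueError("base RMSE must be > 0")
    return 100.0 * (base - improved) / base


# ---------------------------------------------------------------------------
# Nested cross-validation

@dataclass
class NestedCVResult:
    fold_rmse: np.ndarray
    pooled_rmsecv: float
    ci_low: float
    ci_high: float
    predictions: np.ndarray
    fold_assignment: np.ndarray
    train_indices: list = field(default_factory=list)
    test_indices: list = field(default_factory=list)


def nested_cv(
    x: np.ndarray,
    y: np.ndarray,
    model_factory,
    outer_folds: int = 5,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> NestedCVResult:
    """Outer K-fold loop; all tuning happens inside ``model_factory``.

    ``model_factory(x_train, y_train)`` must return a fitted object with a
    ``predict`` method and may only use the data it is given — that is what
    confines hyperparameter search to the inner folds.  The pooled outer
    residuals feed a seeded percentile bootstrap for the RMSECV 95% CI.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = x.shape[0]
    if outer_folds > n:
        raise ValueError("outer_folds exceeds the number of samples")
    rng = np.random.default_rng(seed)
    assign = rng.permutation(np.tile(np.arange(outer_folds), n // outer_folds + 1)[:n])

    preds = np.zeros_like(y)
    fold_rmse = np.zeros(outer_folds)
    train_idx_rec, test_idx_rec = [], []
    for f in range(outer_folds):
        te = np.nonzero(assign == f)[0]
        tr = np.nonzero(assign != f)[0]
        model = model_factory(x[tr], y[tr])
        preds[te] = np.atleast_2d(model.predict(x[te]))
        fold_rmse[f] = np.sqrt(np.mean((preds[te] - y[te]) ** 2))
        train_idx_rec.append(tr)
        test_idx_rec.append(te)

    sq = ((preds - y) ** 2).mean(axis=1)  # per-sample squared error
    pooled = float(np.sqrt(sq.mean()))
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        boot[b] = np.sqrt(sq[rng.integers(0, n, size=n)].mean())
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return NestedCVResult(
        fold_rmse=fold_rmse, pooled_rmsecv=pooled,
        ci_low=float(lo), ci_high=float(hi),
        predictions=preds, fold_assignment=assign,
        train_indices=train_idx_rec, test_indices=test_idx_rec,
    )


# ---------------------------------------------------------------------------
# Y-randomization

def y_randomization(
    x: np.ndarray,
    y: np.ndarray,
    model_factory,
    n_permutations: int = 20,
    seed: int | None = None,
) -> dict:
    """Refit on shuffled responses to rule out chance correlation.

    The verdict passes when the original model's calibration r beats every
    permuted model's r and the mean permuted r is below 0.5.  The identity
    permutation is excluded from the draw.
    """
    if n_permutations < 10:
        raise ValueError("use at least 10 permutations")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if np.allclose(y.std(axis=0), 0):
        raise ValueError("constant response: correlation undefined")
    n = x.shape[0]
    rng = np.random.default_rng(seed)

    def _mean_r(y_true, y_pred):
        rs = []
        for j in range(y_true.shape[1]):
            if y_true[:, j].std() == 0 or y_pred[:, j].std() == 0:
                raise ValueError("degenerate column: correlation undefined")
            rs.append(np.corrcoef(y_true[:, j], y_pred[:, j])[0, 1])
        return float(np.mean(rs))

    model = model_factory(x, y)
    r_orig = _mean_r(y, np.atleast_2d(model.predict(x)))
    rmse_orig = float(np.sqrt(np.mean((model.predict(x) - y) ** 2)))

    perm_r = np.empty(n_permutations)
    perm_rmse = np.empty(n_permutations)
    for i in range(n_permutations):
        while True:
            perm = rng.permutation(n)
            if not np.array_equal(perm, np.arange(n)):
                break
        yp = y[perm]
        m = model_factory(x, yp)
        pred = np.atleast_2d(m.predict(x))
        perm_r[i] = _mean_r(yp, pred)
        perm_rmse[i] = np.sqrt(np.mean((pred - yp) ** 2))

    return {
        "r_original": r_orig,
        "rmse_original": rmse_orig,
        "r_permuted": perm_r,
        "rmse_permuted": perm_rmse,
        "mean_permuted_r": float(perm_r.mean()),
        "passed": bool(r_orig > perm_r.max() and perm_r.mean() < 0.5),
    }


# ---------------------------------------------------------------------------
# Applicability domain (Williams plot)

@dataclass
class ADReport:
    leverage: np.ndarray
    std_residual: np.ndarray
    h_star: float
    in_domain: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "leverage": self.leverage,
            "std_residual": self.std_residual,
            "in_domain": self.in_domain,
        })


def applicability_domain(
    train_scores: np.ndarray,
    residuals: np.ndarray,
    eval_scores: np.ndarray | None = None,
    eval_residuals: np.ndarray | None = None,
) -> ADReport:
    """Leverage / standardized-residual table for a Williams plot.

    Leverage h_i = 1/n + t_i' (T'T)^-1 t_i in latent-score space; the
    critical limit is h* = 3(p+1)/n with p latent variables.  A sample is in
    the applicability domain iff |standardized residual| < 3 and h < h*.
    When ``eval_scores`` is given the report covers those samples instead,
    with leverage still referenced to the training scores.
    """
    t = np.atleast_2d(np.asarray(train_scores, dtype=float))
    n, p = t.shape
    gram = t.T @ t
    try:
        ginv = np.linalg.inv(gram)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError("singular score covariance") from e

    if eval_scores is None:
        scores = t
        resid = np.asarray(residuals, dtype=float)
    else:
        scores = np.atleast_2d(np.asarray(eval_scores, dtype=float))
        resid = np.asarray(eval_residuals, dtype=float)
    if resid.ndim > 1:
        resid = resid.mean(axis=1) if resid.shape[1] > 1 else resid.ravel()
    leverage = 1.0 / n + np.einsum("ij,jk,ik->i", scores, ginv, scores)
    sd = resid.std(ddof=0)
    std_resid = resid / sd if sd > 0 else np.zeros_like(resid)
    h_star = 3.0 * (p + 1) / n
    in_dom = (np.abs(std_resid) < 3.0) & (leverage < h_star)
    return ADReport(leverage=leverage, std_residual=std_resid,
                    h_star=float(h_star), in_domain=in_dom)


# ---------------------------------------------------------------------------
# Method-comparison statistics

@dataclass(frozen=True)
class ComparisonReport:
    statistic: float
    df: tuple
    critical_value: float
    passed: bool    # no significant difference at p = 0.05


def pooled_t_test(mean1, sd1, n1, mean2, sd2, n2) -> ComparisonReport:
    """Two-sample pooled-variance t statistic from summary data.

    t = |m1 - m2| / sqrt(sp^2 (1/n1 + 1/n2)), sp^2 the pooled variance,
    df = n1 + n2 - 2, compared against the two-tailed 5% critical value.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("invalid SDs (negative, or both zero)")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = abs(mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    crit = float(stats.t.ppf(0.975, df))
    return ComparisonReport(statistic=float(t), df=(df,), critical_value=crit,
                            passed=bool(t < crit))


def variance_ratio_f(sd_num, n_num, sd_den, n_den) -> ComparisonReport:
    """F = sd_num^2 / sd_den^2 with caller-chosen numerator.

    The numerator is explicit because published comparison tables are not
    always consistent about which variance goes on top.
    """
    if sd_den <= 0:
        raise ValueError("denominator SD must be > 0")
    if n_num < 2 or n_den < 2:
        raise ValueError("need n >= 2 per group")
    f = (sd_num / sd_den) ** 2
    dfn, dfd = n_num - 1, n_den - 1
    crit = float(stats.f.ppf(0.95, dfn, dfd))
    return ComparisonReport(statistic=float(f), df=(dfn, dfd), critical_value=crit,
                            passed=bool(f < crit))


# ---------------------------------------------------------------------------
# Friedman rank test

def friedman_test(scores: np.ndarray) -> dict:
    """Friedman chi-square over a blocks x treatments score matrix.

    Average ranks on ties with the standard tie correction; the statistic is
    referred to a chi-square distribution with (treatments - 1) df.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    b, k = scores.shape
    if b < 2 or k < 2:
        raise ValueError("need >= 2 blocks and >= 2 treatments")
    ranks = np.empty_like(scores)
    tie_sum = 0.0
    for i in range(b):
        ranks[i] = stats.rankdata(scores[i])
        _, counts = np.unique(scores[i], return_counts=True)
        if counts.max() == k:
            warnings.warn(f"block {i} entirely tied; ranks averaged", stacklevel=2)
        tie_sum += float(np.sum(counts**3 - counts))
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (b * k * (k + 1)) * float(rj @ rj) - 3.0 * b * (k + 1)
    correction = 1.0 - tie_sum / (b * k * (k**2 - 1))
    if correction > 0:
        chi2 /= correction
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return {"chi2": float(chi2), "df": df, "p_value": p}
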