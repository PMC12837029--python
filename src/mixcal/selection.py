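"""Genetic-algorithm wavelength selection for PLS.

A binary chromosome marks which wavelengths enter the PLS regression.  Two
fitness functions are available (both minimized):

* ``cv_rmse`` — K-fold cross-validated RMSE of a PLS fit on the selected
  columns (conventional GA-PLS);
* ``icomp``  — an information-complexity score combining the Gaussian
  -2 log-likelihood of the residuals with a covariance-complexity penalty
  C(Sigma) = 0.5 * [(tr Sigma)^2 - tr(Sigma^2)] of the residual covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibration import PLSModel, fit_pls, select_lv_loocv

__all__ = [
    "GAConfig",
    "SelectionResult",
    "icomp_score",
    "complexity_penalty",
    "ga_select",
    "compare_selection",
]

ICOMP_PERFECT_FIT = -np.inf


def complexity_penalty(residual_cov: np.ndarray) -> float:
    """C(Sigma) = 0.5 * [(tr Sigma)^2 - tr(Sigma^2)].

    Zero for any scalar (1x1) Sigma and, more generally, small when the
    residual covariance is close to spherical.
    """
    sigma = np.atleast_2d(np.asarray(residual_cov, dtype=float))
    if sigma.shape[0] != sigma.shape[1]:
        raise ValueError("residual covariance must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-8):
        raise ValueError("residual covariance must be symmetric")
    tr = np.trace(sigma)
    tr_sq = np.trace(sigma @ sigma)
    return 0.5 * (tr**2 - tr_sq)


def icomp_score(y: np.ndarray, y_hat: np.ndarray, residual_cov: np.ndarray) -> float:
    """ICOMP = -2 log L + 2 C(Sigma), lower is better.

    With the ML variance sigma^2 = RSS/n the likelihood term reduces to
    n*ln(2*pi*sigma^2) + n.  A perfect fit (RSS == 0) has no finite ML
    likelihood; a -inf sentinel is returned with a warning.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have the same shape")
    resid = (y - y_hat).ravel()
    n = resid.size
    if n < 2:
        raise ValueError("need at least 2 residuals")
    rss = float(resid @ resid)
    c = complexity_penalty(residual_cov)
    if rss <= 0.0:
        warnings.warn("perfect fit: ICOMP reported as -inf sentinel", stacklevel=2)
        return ICOMP_PERFECT_FIT
    sigma2 = rss / n
    neg2logl = n * np.log(2 * np.pi * sigma2) + n
    return float(neg2logl + 2 * c)


@dataclass
class GAConfig:
    population: int = 30
    generations: int = 50
    crossover_rate: float = 0.8
    mutation_rate: float = 0.01     # per bit
    elitism: int = 1
    fitness: str = "cv_rmse"        # or "icomp"
    cv_folds: int = 5
    min_selected: int = 5
    max_selected: int | None = None
    max_lv: int = 5                 # LV cap for per-chromosome LOO selection
    full_loo_lv: bool = False       # lift the cap to the rank bound
    tournament: int = 2
    seed: int | None = None

    def __post_init__(self):
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 <= self.crossover_rate <= 1 or not 0 <= self.mutation_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.fitness not in ("cv_rmse", "icomp"):
            raise ValueError("fitness must be 'cv_rmse' or 'icomp'")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass
class SelectionResult:
    mask: np.ndarray                   # (p,) bool, best chromosome
    best_fitness: float
    trace_best: np.ndarray             # (generations + 1,)
    trace_median: np.ndarray
    selection_frequency: np.ndarray    # per-wavelength freq in final population
    model: PLSModel                    # PLS refit on the selected columns
    config: GAConfig = field(repr=False, default=None)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def _repair(chrom: np.ndarray, cfg: GAConfig, rng: np.random.Generator) -> np.ndarray:
    """Enforce the min/max selected-bit constraints in place."""
    n_on = int(chrom.sum())
    if n_on < cfg.min_selected:
        off = np.nonzero(~chrom)[0]
        turn_on = rng.choice(off, size=cfg.min_selected - n_on, replace=False)
        chrom[turn_on] = True
    if cfg.max_selected is not None and chrom.sum() > cfg.max_selected:
        on = np.nonzero(chrom)[0]
        turn_off = rng.choice(on, size=int(chrom.sum()) - cfg.max_selected, replace=False)
        chrom[turn_off] = False
    return chrom


def _chromosome_lv(x_sub: np.ndarray, y: np.ndarray, cfg: GAConfig) -> int:
    from .calibration import effective_rank

    n = x_sub.shape[0]
    bound = min(n - 2, x_sub.shape[1], effective_rank(x_sub))
    cap = bound if cfg.full_loo_lv else min(cfg.max_lv, bound)
    if cap < 1:
        return 1
    best, _ = select_lv_loocv(x_sub, y, cap)
    return best


def _fold_assignment(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    if folds > n:
        raise ValueError("cv_folds exceeds the number of samples")
    assign = np.tile(np.arange(folds), n // folds + 1)[:n]
    return rng.permutation(assign)


def _fitness_cv_rmse(x_sub, y, n_lv, folds_assign) -> float:
    preds = np.zeros_like(y, dtype=float)
    for f in np.unique(folds_assign):
        tr = folds_assign != f
        te = ~tr
        lv = min(n_lv, int(tr.sum()) - 1, x_sub.shape[1])
        m = fit_pls(x_sub[tr], y[tr], max(1, lv))
        preds[te] = m.predict(x_sub[te])
    return float(np.sqrt(np.mean((preds - y) ** 2)))


def _fitness_icomp(x_sub, y, n_lv) -> float:
    m = fit_pls(x_sub, y, n_lv)
    y_hat = m.predict(x_sub)
    resid = y - y_hat
    cov = np.atleast_2d(np.cov(resid, rowvar=False))
    return icomp_score(y, y_hat, cov)


def ga_select(x: np.ndarray, y: np.ndarray, config: GAConfig | None = None) -> SelectionResult:
    """Evolve a wavelength mask minimizing the configured fitness.

    Tournament selection, uniform crossover, per-bit mutation and elitism;
    fitness evaluations are memoized by chromosome so revisited masks are
    free.  Every cv_rmse evaluation reuses one fixed seeded fold assignment.
    """
    cfg = config or GAConfig()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, p = x.shape
    rng = np.random.default_rng(cfg.seed)
    folds_assign = _fold_assignment(n, cfg.cv_folds, rng) if cfg.fitness == "cv_rmse" else None

    cache: dict[bytes, float] = {}

    def evaluate(chrom: np.ndarray) -> float:
        key = np.packbits(chrom).tobytes()
        if key in cache:
            return cache[key]
        if not chrom.any():
            raise ValueError("all-zero chromosome survived repair")
        x_sub = x[:, chrom]
        n_lv = _chromosome_lv(x_sub, y, cfg)
        if cfg.fitness == "cv_rmse":
            fit = _fitness_cv_rmse(x_sub, y, n_lv, folds_assign)
        else:
            fit = _fitness_icomp(x_sub, y, n_lv)
        cache[key] = fit
        return fit

    pop = rng.random((cfg.population, p)) < 0.5
    pop = np.array([_repair(c, cfg, rng) for c in pop])
    fits = np.array([evaluate(c) for c in pop])

    trace_best = [float(fits.min())]
    trace_median = [float(np.median(fits))]

    for _ in range(cfg.generations):
        order = np.argsort(fits)
        new_pop = [pop[i].copy() for i in order[:cfg.elitism]]
        while len(new_pop) < cfg.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population, size=cfg.tournament)
                parents.append(pop[contenders[np.argmin(fits[contenders])]])
            p1, p2 = parents
            if rng.random() < cfg.crossover_rate:
                take = rng.random(p) < 0.5  # uniform crossover
                child = np.where(take, p1, p2)
            else:
                child = p1.copy()
            flip = rng.random(p) < cfg.mutation_rate
            child = child ^ flip
            new_pop.append(_repair(child, cfg, rng))
        pop = np.array(new_pop[: cfg.population])
        fits = np.array([evaluate(c) for c in pop])
        trace_best.append(float(min(fits.min(), trace_best[-1])))
        trace_median.append(float(np.median(fits)))

    best_idx = int(np.argmin(fits))
    # elitism guarantees the all-time best is in the final population
    best = pop[best_idx]
    x_sub = x[:, best]
    model = fit_pls(x_sub, y, _chromosome_lv(x_sub, y, cfg))
    return SelectionResult(
        mask=best.copy(),
        best_fitness=float(fits[best_idx]),
        trace_best=np.array(trace_best),
        trace_median=np.array(trace_median),
        selection_frequency=pop.mean(axis=0),
        model=model,
        config=cfg,
    )


def compare_selection(
    x: np.ndarray,
    y: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    configs: list[GAConfig] | None = None,
    max_lv: int = 5,
    seed: int | None = None,
) -> "pd.DataFrame":
    """Benchmark full-spectrum PLS against GA variants on identical folds.

    Returns one row per candidate with the selected-variable count, RMSECV
    (shared fold assignment, recorded as a hash) and RMSEP on the supplied
    validation set.
    """
    import pandas as pd

    if x_val is None or y_val is None:
        raise ValueError("a validation set is required")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    y_val = np.asarray(y_val, dtype=float)
    if y_val.ndim == 1:
        y_val = y_val[:, None]
    if configs is None:
        configs = [
            GAConfig(fitness="cv_rmse", seed=seed),
            GAConfig(fitness="icomp", seed=seed),
        ]
    if not configs:
        raise ValueError("need at least one GA config")

    rng = np.random.default_rng(seed)
    folds = min(5, x.shape[0])
    assign = _fold_assignment(x.shape[0], folds, rng)
    fold_hash = hash(assign.tobytes())

    def row(name, mask):
        x_sub = x[:, mask]
        bound = min(x.shape[0] - 2, x_sub.shape[1])
        lv, _ = select_lv_loocv(x_sub, y, min(max_lv, bound))
        rmsecv = _fitness_cv_rmse(x_sub, y, lv, assign)
        m = fit_pls(x_sub, y, lv)
        rmsep = float(np.sqrt(np.mean((m.predict(x_val[:, mask]) - y_val) ** 2)))
        return {
            "candidate": name,
            "n_selected": int(mask.sum()),
            "n_lv": lv,
            "rmsecv": rmsecv,
            "rmsep": rmsep,
            "fold_hash": fold_hash,
        }

    rows = [row("full_spectrum_pls", np.ones(x.shape[1], dtype=bool))]
    for cfg in configs:
        res = ga_select(x, y, cfg)
        rows.append(row(f"ga_{cfg.fitness}", res.mask))
    return pd.DataFrame(rows)
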