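"""Diagnostic-accuracy evaluation: confusion matrices, binomial confidence
intervals, pooled cross-validation, and bootstrap hyper-parameter tuning.

Sensitivity, specificity, PPV, NPV and accuracy are each a binomial
proportion with its own denominator, so each carries its own 95% interval.
Two interval methods are provided: the Wilson score interval with continuity
correction (the default for reporting; this is what R's ``prop.test``
computes) and the exact Clopper-Pearson interval from beta quantiles (which
guarantees >= nominal coverage).

Cross-validated performance pools the out-of-fold predictions of stratified
k-fold CV into a single confusion matrix before computing metrics, so the
intervals use the full class denominators.  Hyper-parameter tuning draws
bootstrap resamples, fits on each resample and scores on its out-of-bag
records, and selects the grid point with the best mean Youden index
(sensitivity + specificity - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as _beta_dist
from scipy.stats import norm as _norm
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .chaid import ChaidClassifier

__all__ = [
    "ConfusionMatrix",
    "MetricEstimate",
    "DiagnosticReport",
    "TuningResult",
    "confusion",
    "metrics",
    "exact_binomial_ci",
    "wilson_cc_ci",
    "kfold_cv",
    "bootstrap_tune",
    "default_grid",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts against the reference standard; frail is the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn


def confusion(predictions, labels) -> ConfusionMatrix:
    """Tally a binary prediction vector against binary reference labels."""
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if len(pred) != len(lab):
        raise ValueError(f"length mismatch: {len(pred)} predictions, {len(lab)} labels")
    for name, v in (("predictions", pred), ("labels", lab)):
        u = set(np.unique(v).tolist())
        if not u <= {0, 1, 0.0, 1.0, True, False}:
            raise ValueError(f"{name} must be binary 0/1, got values {sorted(map(str, u))}")
    pred = pred.astype(int)
    lab = lab.astype(int)
    return ConfusionMatrix(
        tp=int(((pred == 1) & (lab == 1)).sum()),
        fp=int(((pred == 1) & (lab == 0)).sum()),
        fn=int(((pred == 0) & (lab == 1)).sum()),
        tn=int(((pred == 0) & (lab == 0)).sum()),
    )


def exact_binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial interval via beta quantiles."""
    if n <= 0 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    a = (1.0 - level) / 2.0
    lo = 0.0 if successes == 0 else float(_beta_dist.ppf(a, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(_beta_dist.ppf(1 - a, successes + 1, n - successes))
    return lo, hi


def wilson_cc_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval with continuity correction, as computed by R's
    ``prop.test``: the sample proportion is shifted by the 0.5/n correction
    and the score interval solved on the shifted value."""
    if n <= 0 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: {successes}/{n}")
    p = successes / n
    z = float(_norm.ppf(1 - (1 - level) / 2))
    z22n = z * z / (2 * n)
    yates = min(0.5, abs(successes - n * 0.5))  # correction capped as in prop.test

    def _bound(p_c: float, sign: float) -> float:
        return ((p_c + z22n + sign * z * np.sqrt(p_c * (1 - p_c) / n + z22n / (2 * n)))
                / (1 + 2 * z22n))

    p_hi = p + yates / n
    hi = 1.0 if p_hi >= 1 else _bound(p_hi, +1.0)
    p_lo = p - yates / n
    lo = 0.0 if p_lo <= 0 else _bound(p_lo, -1.0)
    return max(lo, 0.0), min(hi, 1.0)


_CI_METHODS = {"wilson-cc": wilson_cc_ci, "clopper-pearson": exact_binomial_ci}


@dataclass(frozen=True)
class MetricEstimate:
    """A binomial proportion with its confidence interval and raw counts."""

    estimate: float
    lower: float
    upper: float
    successes: int
    denominator: int

    def as_percent(self, decimals: int = 2) -> tuple[float, float, float]:
        r = lambda v: float(round(v * 100, decimals))
        return r(self.estimate), r(self.lower), r(self.upper)


@dataclass(frozen=True)
class DiagnosticReport:
    """Point estimates and 95% CIs of the five diagnostic-accuracy metrics.

    Metrics with a zero denominator are ``None`` (undefined, not 0).
    """

    cm: ConfusionMatrix
    sensitivity: MetricEstimate | None
    specificity: MetricEstimate | None
    ppv: MetricEstimate | None
    npv: MetricEstimate | None
    accuracy: MetricEstimate
    prevalence: float
    n: int
    level: float = 0.95
    ci_method: str = "wilson-cc"

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "prevalence": self.prevalence,
            "level": self.level,
            "ci_method": self.ci_method,
            "confusion": {"tp": self.cm.tp, "fp": self.cm.fp,
                          "fn": self.cm.fn, "tn": self.cm.tn},
        }
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            m: MetricEstimate | None = getattr(self, name)
            out[name] = None if m is None else {
                "estimate": m.estimate, "lower": m.lower, "upper": m.upper,
                "successes": m.successes, "denominator": m.denominator,
            }
        return out

    def to_percent_frame(self, decimals: int = 2) -> pd.DataFrame:
        rows = []
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            m = getattr(self, name)
            if m is None:
                rows.append((name, np.nan, np.nan, np.nan))
            else:
                rows.append((name, *m.as_percent(decimals)))
        return pd.DataFrame(rows, columns=["metric", "estimate", "lower", "upper"])


def _estimate(successes: int, denom: int, level: float,
              ci) -> MetricEstimate | None:
    if denom == 0:
        return None
    lo, hi = ci(successes, denom, level)
    return MetricEstimate(successes / denom, lo, hi, successes, denom)


def metrics(cm: ConfusionMatrix, level: float = 0.95,
            ci_method: str = "wilson-cc") -> DiagnosticReport:
    """Diagnostic-accuracy report from a confusion matrix."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    try:
        ci = _CI_METHODS[ci_method]
    except KeyError:
        raise ValueError(f"unknown ci_method {ci_method!r}; "
                         f"known: {sorted(_CI_METHODS)}") from None
    return DiagnosticReport(
        cm=cm,
        sensitivity=_estimate(cm.tp, cm.tp + cm.fn, level, ci),
        specificity=_estimate(cm.tn, cm.tn + cm.fp, level, ci),
        ppv=_estimate(cm.tp, cm.tp + cm.fp, level, ci),
        npv=_estimate(cm.tn, cm.tn + cm.fn, level, ci),
        accuracy=_estimate(cm.tp + cm.tn, cm.n, level, ci),
        prevalence=cm.positives / cm.n,
        n=cm.n,
        level=level,
        ci_method=ci_method,
    )


def kfold_cv(estimator, X: pd.DataFrame, y, k: int = 10, seed: int = 0,
             level: float = 0.95, ci_method: str = "wilson-cc",
             ) -> tuple[DiagnosticReport, np.ndarray]:
    """Pooled stratified k-fold cross-validation.

    Each record is predicted exactly once by a model not trained on it; the
    pooled out-of-fold predictions form one confusion matrix so the CIs use
    the full class denominators.  Returns the report and the out-of-fold
    prediction vector (aligned with ``y``).
    """
    y = np.asarray(y).astype(int)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"minority class has {counts.min()} members; cannot stratify into {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof = np.full(n, -1, dtype=int)
    Xv = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    for tr, te in skf.split(Xv, y):
        est = clone(estimator)
        est.fit(Xv.iloc[tr], y[tr])
        oof[te] = np.asarray(est.predict(Xv.iloc[te])).astype(int)
    assert (oof >= 0).all()
    cm = confusion(oof, y)
    return metrics(cm, level=level, ci_method=ci_method), oof


def default_grid() -> list[tuple[float, int]]:
    """The tuning grid: alpha 0.01 to 0.3 in steps of 0.03, heights 2..6."""
    alphas = [round(0.01 + 0.03 * i, 2) for i in range(10)]
    return [(a, h) for a in alphas for h in range(2, 7)]


@dataclass(frozen=True)
class TuningResult:
    """Bootstrap out-of-bag metric means per grid point, and the selection."""

    table: pd.DataFrame          # alpha, height, <metric>_mean, <metric>_sd, youden_mean
    best_alpha: float
    best_height: int

    def curves(self) -> pd.DataFrame:
        """Long-format (alpha, height, metric, mean, sd) for plotting."""
        rows = []
        for _, r in self.table.iterrows():
            for m in ("sensitivity", "specificity", "ppv", "npv", "youden"):
                rows.append({
                    "alpha": r["alpha"], "height": int(r["height"]), "metric": m,
                    "mean": r[f"{m}_mean"],
                    "sd": r.get(f"{m}_sd", np.nan),
                })
        return pd.DataFrame(rows)


def _oob_metrics(est, X: pd.DataFrame, y: np.ndarray,
                 rng: np.random.Generator) -> dict[str, float]:
    n = len(y)
    while True:
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) > 0:
            break
    est.fit(X.iloc[idx], y[idx])
    pred = np.asarray(est.predict(X.iloc[oob])).astype(int)
    cm = confusion(pred, y[oob])
    out: dict[str, float] = {}
    out["sensitivity"] = cm.tp / cm.positives if cm.positives else np.nan
    out["specificity"] = cm.tn / cm.negatives if cm.negatives else np.nan
    out["ppv"] = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else np.nan
    out["npv"] = cm.tn / (cm.tn + cm.fn) if cm.tn + cm.fn else np.nan
    out["youden"] = out["sensitivity"] + out["specificity"] - 1.0
    return out


def bootstrap_tune(X: pd.DataFrame, y, grid: Sequence[tuple[float, int]] | None = None,
                   B: int = 200, seed: int = 0, min_node_size: int = 10,
                   leaf_rule: float = 0.5) -> TuningResult:
    """Bootstrap-with-replacement hyper-parameter search for the CHAID tree.

    For each (alpha, height) grid point, ``B`` bootstrap resamples are fit
    and scored on their out-of-bag records; the point with the highest mean
    Youden index wins (ties toward smaller height, then smaller alpha).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    grid = list(grid) if grid is not None else default_grid()
    y = np.asarray(y).astype(int)
    Xv = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    rows = []
    root = np.random.SeedSequence(seed)
    seeds = root.spawn(len(grid))
    metric_names = ("sensitivity", "specificity", "ppv", "npv", "youden")
    for (alpha, height), ss in zip(grid, seeds):
        rng = np.random.default_rng(ss)
        est = ChaidClassifier(alpha=alpha, max_height=int(height),
                              min_node_size=min_node_size, leaf_rule=leaf_rule)
        reps = {m: [] for m in metric_names}
        for _ in range(B):
            vals = _oob_metrics(clone(est), Xv, y, rng)
            for m in metric_names:
                reps[m].append(vals[m])
        row = {"alpha": float(alpha), "height": int(height)}
        for m in metric_names:
            arr = np.asarray(reps[m], dtype=float)
            row[f"{m}_mean"] = float(np.nanmean(arr)) if not np.isnan(arr).all() else np.nan
            row[f"{m}_sd"] = float(np.nanstd(arr, ddof=1)) if np.sum(~np.isnan(arr)) > 1 else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    ranked = table.copy()
    ranked["youden_rank"] = ranked["youden_mean"].fillna(-np.inf)
    ranked = ranked.sort_values(
        by=["youden_rank", "height", "alpha"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    best = ranked.iloc[0]
    return TuningResult(table=table, best_alpha=float(best["alpha"]),
                        best_height=int(best["height"]))
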