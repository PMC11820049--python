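"""Goodness-of-fit metrics and cross-model comparison statistics.

Metrics per held-out series: R^2 (about the mean of the measured series;
negative values are reported, not clipped), RMSE in degrees, and NRMSE
(RMSE divided by the measured range). Model comparison is a one-way ANOVA
across the per-fold metric samples followed by Tukey's HSD at alpha=0.05,
with significance binned into the three conventional star levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "MetricsTriple",
    "ComparisonResult",
    "metrics",
    "aggregate",
    "aggregate_report",
    "compare_models",
    "stars",
    "evaluate_folds",
]


@dataclass(frozen=True)
class MetricsTriple:
    r2: float
    rmse: float
    nrmse: float
    n: int
    joint: str = ""
    model: str = ""
    fold: int = -1


def metrics(
    y: np.ndarray, yhat: np.ndarray, *, joint: str = "", model: str = "", fold: int = -1
) -> MetricsTriple:
    """R^2, RMSE and range-normalized RMSE of a prediction against truth."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if len(y) != len(yhat):
        raise ValueError("series lengths differ")
    if len(y) < 2:
        raise ValueError("need at least two samples")
    rng = float(np.max(y) - np.min(y))
    if rng == 0.0:
        raise ValueError("measured series is constant: NRMSE and R^2 are undefined")
    ss_res = float(np.sum((yhat - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rmse = float(np.sqrt(ss_res / len(y)))
    return MetricsTriple(
        r2=1.0 - ss_res / ss_tot,
        rmse=rmse,
        nrmse=rmse / rng,
        n=len(y),
        joint=joint,
        model=model,
        fold=fold,
    )


def aggregate(folds: list[MetricsTriple]) -> dict[str, tuple[float, float]]:
    """Mean and (ddof=1) sd of each metric across folds of one model/joint."""
    if not folds:
        raise ValueError("no metric triples to aggregate")
    joints = {f.joint for f in folds}
    if len(joints) > 1:
        raise ValueError(f"mixed joint labels {sorted(joints)}: aggregate per joint")
    out = {}
    for name in ("r2", "rmse", "nrmse"):
        vals = np.array([getattr(f, name) for f in folds], dtype=float)
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[name] = (float(vals.mean()), sd)
    return out


def aggregate_report(triples: list[MetricsTriple]) -> pd.DataFrame:
    """Tidy per-(model, joint) summary table over folds."""
    rows = []
    keys = sorted({(t.model, t.joint) for t in triples})
    for model, joint in keys:
        sub = [t for t in triples if t.model == model and t.joint == joint]
        agg = aggregate(sub)
        rows.append(
            {
                "model": model,
                "joint": joint,
                "n_folds": len(sub),
                **{f"{m}_mean": agg[m][0] for m in agg},
                **{f"{m}_sd": agg[m][1] for m in agg},
            }
        )
    return pd.DataFrame(rows)


def stars(p: float) -> str:
    """Significance bins: * for 0.05 >= p > 0.001, ** to 0.0001, *** below."""
    if p < 0.0001:
        return "***"
    if p <= 0.001:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    """One-way ANOVA plus all-pairs Tukey HSD over per-model metric samples."""

    f_stat: float
    p_value: float
    tukey: pd.DataFrame
    degenerate: bool = False
    unit: str = "fold"

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value <= 0.05


def compare_models(
    groups: dict[str, np.ndarray], *, alpha: float = 0.05, tukey: bool = True
) -> ComparisonResult:
    """Compare >= 2 models from their per-fold metric samples.

    Zero-variance ties (all samples of all groups identical) leave the F
    statistic undefined; that case is flagged ``degenerate`` and reported
    as no significant difference rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs at least two samples")

    allvals = np.concatenate(list(arrays.values()))
    if np.ptp(allvals) == 0.0:
        pairs = pd.DataFrame(
            [
                {"group1": a, "group2": b, "p_adj": 1.0, "significant": False, "stars": "ns"}
                for i, a in enumerate(arrays)
                for b in list(arrays)[i + 1:]
            ]
        )
        return ComparisonResult(f_stat=float("nan"), p_value=1.0, tukey=pairs, degenerate=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p_value = stats.f_oneway(*arrays.values())

    if tukey:
        labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
        res = pairwise_tukeyhsd(allvals, labels, alpha=alpha)
        tk = pd.DataFrame(
            res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
        )
        pairs = pd.DataFrame(
            {
                "group1": tk["group1"],
                "group2": tk["group2"],
                "p_adj": res.pvalues,
                "significant": res.reject,
                "stars": [stars(p) for p in res.pvalues],
            }
        )
    else:
        pairs = pd.DataFrame(columns=["group1", "group2", "p_adj", "significant", "stars"])
    return ComparisonResult(
        f_stat=float(f_stat), p_value=float(p_value), tukey=pairs,
        degenerate=not np.isfinite(f_stat),
    )


def evaluate_folds(fold_results, joint_names: list[str], model: str) -> list[MetricsTriple]:
    """Per-joint metric triples for every cross-validation fold."""
    out = []
    for fr in fold_results:
        for j, joint in enumerate(joint_names):
            out.append(
                metrics(fr.targets[:, j], fr.predictions[:, j],
                        joint=joint, model=model, fold=fr.fold)
            )
    return out


def results_table(triples: list[MetricsTriple], pattern: str = "") -> pd.DataFrame:
    """Tidy (model, joint, movement, fold, r2, rmse, nrmse) rows."""
    return pd.DataFrame(
        [
            {
                "model": t.model,
                "joint": t.joint,
                "movement": pattern,
                "fold": t.fold,
                "r2": t.r2,
                "rmse": t.rmse,
                "nrmse": t.nrmse,
            }
            for t in triples
        ]
    )
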