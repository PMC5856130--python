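"""Evaluation procedures for parametric lab summaries.

Two evaluations, mirroring how such summaries are validated in practice:

1. **Physiologic-relation preservation** — for variables like glucose whose
   per-patient mean and standard deviation are known to be linearly related,
   check whether the fitted summary parameters reproduce the relation.  The
   empirical mean/SD baseline typically needs a by-hand truncation (dropping
   summaries whose SD exceeds ~2000, i.e. unit-error casualties) before the
   relation appears; model-based summaries should reveal it automatically.

2. **Extreme-group purity** — order patients by parameter deciles, take the
   groups whose parameters are *all* in the bottom or all in the top decile
   (for the GEV, additionally split by the sign of the tail-shape
   parameter), subsample a review-sized group, and measure cluster purity
   against binary disease labels.

A maximum-entropy lookup is included as an independent reference: knowing
only a mean the maxent model is uniform, mean+SD gives the Gaussian, and
mean+SD with a linear mean–SD constraint gives the gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .summaries import STATUS_INCLUDED

__all__ = [
    "RelationReport",
    "PurityResult",
    "maxent_model",
    "relation",
    "extreme_groups",
    "cluster_purity",
]

SD_TRUNCATION_DEFAULT = 2000.0

_MAXENT_TABLE = {
    frozenset({"mean"}): "uniform",
    frozenset({"mean", "sd"}): "normal",
    frozenset({"mean", "sd", "linear_mean_sd"}): "gamma",
}


def maxent_model(constraints) -> str:
    """Maximum-entropy family for a set of moment constraints.

    ``{mean} -> uniform``, ``{mean, sd} -> normal``,
    ``{mean, sd, linear_mean_sd} -> gamma``.
    """
    key = frozenset(constraints)
    if not key:
        raise ValueError("constraints must be non-empty")
    try:
        return _MAXENT_TABLE[key]
    except KeyError:
        raise ValueError(
            f"unsupported constraint set {sorted(key)}; supported: "
            f"{[sorted(k) for k in _MAXENT_TABLE]}"
        ) from None


@dataclass(frozen=True)
class RelationReport:
    """Linear relation between two summary parameters across patients."""

    x_param: str
    y_param: str
    pearson_r: float
    spearman_rho: float
    slope: float
    intercept: float
    n: int
    truncation_applied: tuple[str, float] | None = None

    def to_dict(self) -> dict:
        return {
            "x_param": self.x_param,
            "y_param": self.y_param,
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "slope": self.slope,
            "intercept": self.intercept,
            "n": self.n,
            "truncation_applied": list(self.truncation_applied)
            if self.truncation_applied else None,
        }


def relation(summaries: pd.DataFrame, x_param: str, y_param: str,
             truncation: tuple[str, float] | None = None) -> RelationReport:
    """Correlations and least-squares line between two parameter columns.

    Only included summaries enter.  ``truncation=(column, max)`` first drops
    rows where ``column`` exceeds ``max`` — the by-hand outlier removal that
    empirical mean/SD summaries need (conventional threshold
    ``SD_TRUNCATION_DEFAULT = 2000``); it exists for evaluation parity only
    and is never part of the summarization pipeline itself.
    """
    df = summaries
    if "status" in df.columns:
        df = df[df["status"] == STATUS_INCLUDED]
    cols = [x_param, y_param]
    if truncation is not None and truncation[0] not in cols:
        cols.append(truncation[0])
    df = df[cols].dropna()
    applied = None
    if truncation is not None:
        col, cap = truncation
        df = df[df[col] <= cap]
        applied = (col, float(cap))
    if len(df) < 3:
        raise ValueError(f"need at least 3 rows for a relation, got {len(df)}")
    x = df[x_param].to_numpy(dtype=float)
    y = df[y_param].to_numpy(dtype=float)
    pear = stats.pearsonr(x, y).statistic
    spear = stats.spearmanr(x, y).statistic
    ls = stats.linregress(x, y)
    return RelationReport(
        x_param=x_param, y_param=y_param,
        pearson_r=float(pear), spearman_rho=float(spear),
        slope=float(ls.slope), intercept=float(ls.intercept),
        n=int(len(df)), truncation_applied=applied,
    )


def extreme_groups(categorical: pd.DataFrame, summaries: pd.DataFrame,
                   n_bins: int = 10, shape_param: str | None = None,
                   k: int | None = 15, seed: int | None = 0) -> dict[str, list[str]]:
    """Patients whose parameters are *all* bottom-bin or *all* top-bin.

    Parameters
    ----------
    categorical : DataFrame
        Output of the discretizer (``patient_id`` plus ``bin_*`` columns).
    summaries : DataFrame
        Continuous summaries; needed when splitting by a shape parameter.
    n_bins : int
        The top bin index.
    shape_param : str, optional
        If given (e.g. ``"shape"`` for the GEV), each extreme group is split
        by the sign of that fitted parameter into ``*_shape_pos`` /
        ``*_shape_neg`` subgroups.
    k : int, optional
        Subsample size per group (review-sized, default 15); ``None`` keeps
        whole groups.  Subsampling is seeded and without replacement.

    Returns
    -------
    dict mapping group name (``"bottom"``/``"top"`` or shape-split variants)
    to a list of patient ids.  Empty groups are allowed.
    """
    bin_cols = [c for c in categorical.columns if c.startswith("bin_")]
    if not bin_cols:
        raise ValueError("categorical frame has no bin_* columns")
    bins = categorical[bin_cols].to_numpy()
    ids = categorical["patient_id"].to_numpy()
    groups = {
        "bottom": list(ids[np.all(bins == 1, axis=1)]),
        "top": list(ids[np.all(bins == n_bins, axis=1)]),
    }
    if shape_param is not None:
        shp = summaries.set_index("patient_id")[shape_param]
        split: dict[str, list[str]] = {}
        for name, members in groups.items():
            vals = shp.reindex(members)
            split[f"{name}_shape_pos"] = [m for m, v in vals.items() if v > 0]
            split[f"{name}_shape_neg"] = [m for m, v in vals.items() if v <= 0]
        groups = split
    if k is not None:
        rng = np.random.default_rng(seed)
        groups = {
            name: sorted(rng.choice(members, size=min(k, len(members)),
                                    replace=False).tolist())
            if members else []
            for name, members in groups.items()
        }
    return groups


@dataclass(frozen=True)
class PurityResult:
    """Cluster purity of one patient group against binary labels.

    ``purity`` is the strict majority-class fraction (always ≥ 0.5);
    ``target_class_fraction`` is the fraction carrying the label of
    interest (label 1), which is what clinical tables usually print — the
    two coincide when the group is majority-positive.
    """

    group_id: str
    group_size: int
    majority_count: int
    purity: float
    target_count: int
    target_class_fraction: float

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "group_size": self.group_size,
            "majority_count": self.majority_count,
            "purity": round(self.purity, 2),
            "target_count": self.target_count,
            "target_class_fraction": round(self.target_class_fraction, 2),
        }


def cluster_purity(labels: pd.Series | dict, group, group_id: str = "group") -> PurityResult:
    """Purity of ``group`` (patient ids) under binary ``labels``.

    Every member must be labeled; an empty group is an error.
    """
    members = list(group)
    if not members:
        raise ValueError("cannot compute purity of an empty group")
    if isinstance(labels, dict):
        missing = [m for m in members if m not in labels]
        if missing:
            raise ValueError(f"unlabeled group members: {missing[:5]}")
        arr = np.fromiter((labels[m] for m in members), dtype=int,
                          count=len(members))
    else:
        vals = labels.reindex(members)
        if vals.isna().any():
            missing = [m for m, v in zip(members, vals) if pd.isna(v)]
            raise ValueError(f"unlabeled group members: {missing[:5]}")
        arr = vals.to_numpy(dtype=int)
    n = arr.size
    pos = int(arr.sum())
    majority = max(pos, n - pos)
    return PurityResult(
        group_id=group_id,
        group_size=n,
        majority_count=majority,
        purity=majority / n,
        target_count=pos,
        target_class_fraction=pos / n,
    )
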