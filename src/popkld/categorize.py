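"""Discretization of continuous summaries into ordinal category tuples.

The categorical companion of the parametric summary: each fitted parameter
is binned into population quantiles (deciles by default), so a patient whose
mean sits in the 1st decile and whose spread sits in the 8th becomes the
tuple ``(1, 8)``.  Bin boundaries are computed only from *included* patients,
frozen in a :class:`BinningScheme`, and serialized, so new patients can later
be categorized against the same scheme.

Conventions: bins are 1-indexed; bin *k* covers ``[b_{k-1}, b_k)`` with the
top bin closed above.  Increasing a parameter value can therefore never
decrease its bin.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from dataclasses import dataclass, field
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .families import get_family
from .summaries import STATUS_INCLUDED, IndividualSummary

__all__ = [
    "BinningScheme",
    "CategoricalSummary",
    "PopKLDCat",
    "compute_binning",
    "assign_bins",
    "categorize_frame",
]


@dataclass(frozen=True)
class BinningScheme:
    """Frozen per-parameter quantile boundaries.

    ``boundaries[p]`` holds the interior quantile cut points for parameter
    ``p`` (``n_bins - 1`` values when all quantiles are distinct; fewer if
    duplicates collapsed, in which case the effective number of bins for
    that parameter is smaller).
    """

    family_name: str
    n_bins: int
    boundaries: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def effective_bins(self, param: str) -> int:
        return len(self.boundaries[param]) + 1

    def to_dict(self) -> dict:
        return {
            "family_name": self.family_name,
            "n_bins": self.n_bins,
            "boundaries": {p: list(b) for p, b in self.boundaries.items()},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "BinningScheme":
        return cls(
            family_name=d["family_name"],
            n_bins=int(d["n_bins"]),
            boundaries={p: tuple(map(float, b))
                        for p, b in d["boundaries"].items()},
        )


@dataclass(frozen=True)
class CategoricalSummary:
    """A patient's ordinal bin tuple, one entry per model parameter."""

    patient_id: str
    family_name: str
    bins: tuple[int, ...]

    @property
    def token(self) -> str:
        """Joined form, e.g. ``"gev:1-8-3"`` for topic-modeling consumers."""
        return f"{self.family_name}:" + "-".join(map(str, self.bins))


def _bin_value(value: float, bounds: tuple[float, ...]) -> int:
    # [b_{k-1}, b_k) half-open; values beyond the last boundary land in the
    # top bin (closed above)
    return int(np.searchsorted(bounds, value, side="right")) + 1


class PopKLDCat(BaseEstimator, TransformerMixin):
    """Quantile discretizer for summary parameter frames.

    ``fit`` learns per-parameter quantile boundaries from the *included*
    rows of a summaries frame (as produced by
    :class:`~popkld.summaries.PopKLDSummarizer`); ``transform`` maps each
    included row to its ordinal bin tuple.

    Parameters
    ----------
    n_bins : int
        Number of ordinal categories per parameter (default 10, deciles).
    params : sequence of str, optional
        Which columns to bin; defaults to the family's parameter names.

    Attributes
    ----------
    scheme_ : BinningScheme
        The frozen boundaries (serializable; reusable on new patients).
    """

    def __init__(self, n_bins: int = 10, params=None):
        self.n_bins = n_bins
        self.params = params

    def _param_columns(self, frame: pd.DataFrame) -> list[str]:
        if self.params is not None:
            return list(self.params)
        family = frame["family"].iloc[0]
        return list(get_family(family).param_names)

    def fit(self, X: pd.DataFrame, y=None):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        included = X[X["status"] == STATUS_INCLUDED]
        if len(included) < self.n_bins:
            raise ValueError(
                f"need at least n_bins={self.n_bins} included summaries, "
                f"got {len(included)}"
            )
        cols = self._param_columns(included)
        qs = np.arange(1, self.n_bins) / self.n_bins
        boundaries: dict[str, tuple[float, ...]] = {}
        for col in cols:
            values = included[col].to_numpy(dtype=float)
            cuts = np.quantile(values, qs)
            uniq = np.unique(cuts)
            if uniq.size < cuts.size:
                warnings.warn(
                    f"parameter '{col}': duplicate quantile boundaries "
                    f"collapsed ({cuts.size} -> {uniq.size}); fewer than "
                    f"{self.n_bins} effective bins",
                    UserWarning, stacklevel=2,
                )
            boundaries[col] = tuple(float(v) for v in uniq)
        family = included["family"].iloc[0] if "family" in included else "unknown"
        self.scheme_ = BinningScheme(family, self.n_bins, boundaries)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "scheme_")
        included = X[X["status"] == STATUS_INCLUDED]
        cols = list(self.scheme_.boundaries)
        out = included[["patient_id"]].copy()
        for col in cols:
            bounds = self.scheme_.boundaries[col]
            out[f"bin_{col}"] = [
                _bin_value(v, bounds)
                for v in included[col].to_numpy(dtype=float)
            ]
        fam = self.scheme_.family_name
        bin_cols = [f"bin_{c}" for c in cols]
        out["token"] = [
            f"{fam}:" + "-".join(str(b) for b in row)
            for row in out[bin_cols].to_numpy()
        ]
        return out.reset_index(drop=True)


def compute_binning(summaries, n_bins: int = 10) -> BinningScheme:
    """Quantile bin boundaries from included summaries (thin wrapper)."""
    frame = _as_frame(summaries)
    return PopKLDCat(n_bins=n_bins).fit(frame).scheme_


def assign_bins(summary: IndividualSummary,
                scheme: BinningScheme) -> CategoricalSummary:
    """Map one included patient summary to its ordinal bin tuple."""
    if summary.status != STATUS_INCLUDED or summary.params is None:
        raise ValueError(
            f"cannot categorize excluded patient {summary.patient_id} "
            f"(status={summary.status})"
        )
    values = summary.params.as_dict()
    missing = [p for p in scheme.boundaries if p not in values]
    if missing:
        raise ValueError(f"scheme parameters not in summary: {missing}")
    bins = tuple(_bin_value(values[p], scheme.boundaries[p])
                 for p in scheme.boundaries)
    return CategoricalSummary(summary.patient_id, summary.family_name, bins)


def categorize_frame(summaries, n_bins: int = 10,
                     scheme: BinningScheme | None = None) -> pd.DataFrame:
    """Fit boundaries (unless given) and categorize in one call."""
    frame = _as_frame(summaries)
    cat = PopKLDCat(n_bins=n_bins)
    if scheme is not None:
        cat.scheme_ = scheme
        return cat.transform(frame)
    return cat.fit_transform(frame)


def _as_frame(summaries) -> pd.DataFrame:
    if isinstance(summaries, pd.DataFrame):
        return summaries
    from .summaries import summaries_to_frame
    return summaries_to_frame(list(summaries))
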