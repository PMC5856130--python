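"""Per-patient parametric summaries (the continuous PopKLD output).

Once a family has been selected at the population level, every patient's own
values are fitted by maximum likelihood under that family and the fitted
parameter vector becomes the patient's summary.  Patients with too few
observations or whose fits fail to converge are *emitted with a status*
rather than silently dropped, so downstream counts always reconcile.

Input tables are long-format: one row per measurement with columns
``patient_id``, ``lab_name``, ``value`` and optionally ``context`` and
``timestamp``.  Timestamps are carried but never used — the summary is
deliberately time-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .families import DistributionFamily, ParamVector, get_family
from .selection import PopKLDSelector

__all__ = [
    "IndividualSummary",
    "PopKLDSummarizer",
    "summarize_individuals",
    "summaries_to_frame",
    "empirical_summaries",
    "exclusion_rate",
    "validate_table",
]

STATUS_INCLUDED = "included"
STATUS_INSUFFICIENT = "excluded_insufficient_obs"
STATUS_NONCONVERGENCE = "excluded_nonconvergence"

REQUIRED_COLUMNS = ("patient_id", "lab_name", "value")


@dataclass(frozen=True)
class IndividualSummary:
    """One patient's fitted summary for one laboratory variable."""

    patient_id: str
    lab_name: str
    family_name: str
    params: ParamVector | None
    n_obs: int
    status: str

    @property
    def included(self) -> bool:
        return self.status == STATUS_INCLUDED


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format measurement table contract."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    values = pd.to_numeric(table["value"], errors="coerce")
    bad = ~np.isfinite(values)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} non-numeric or non-finite values in table "
            f"(first bad row index: {table.index[bad][0]})"
        )
    out = table.copy()
    out["value"] = values.astype(float)
    return out


def _fit_patients(table: pd.DataFrame, lab_name: str,
                  family: DistributionFamily, min_obs: int,
                  context: str | None = None) -> list[IndividualSummary]:
    if min_obs < 2:
        raise ValueError("min_obs must be >= 2")
    sub = table[table["lab_name"] == lab_name]
    if sub.empty:
        raise ValueError(f"lab '{lab_name}' not present in table")
    if context is not None:
        if "context" not in sub.columns:
            raise ValueError("table has no 'context' column to filter on")
        sub = sub[sub["context"] == context]

    out: list[IndividualSummary] = []
    for pid, grp in sub.groupby("patient_id", sort=True):
        vals = grp["value"].to_numpy()
        n = vals.size
        if n < min_obs:
            out.append(IndividualSummary(str(pid), lab_name, family.name,
                                         None, n, STATUS_INSUFFICIENT))
            continue
        fit = family.fit(vals)
        if not fit.converged:
            out.append(IndividualSummary(str(pid), lab_name, family.name,
                                         None, n, STATUS_NONCONVERGENCE))
        else:
            out.append(IndividualSummary(str(pid), lab_name, family.name,
                                         fit.params, n, STATUS_INCLUDED))
    return out


def summaries_to_frame(summaries: list[IndividualSummary]) -> pd.DataFrame:
    """Tabulate summaries: one row per patient, named parameter columns.

    Included rows additionally carry the model-implied ``mean_like`` and
    ``sd_like`` quantities (the model mean and standard deviation), which
    are what physiologic-relation evaluations compare.
    """
    if not summaries:
        return pd.DataFrame(columns=["patient_id", "lab_name", "family",
                                     "n_obs", "status"])
    fam = get_family(summaries[0].family_name)
    rows = []
    for s in summaries:
        row = {
            "patient_id": s.patient_id,
            "lab_name": s.lab_name,
            "family": s.family_name,
            "n_obs": s.n_obs,
            "status": s.status,
        }
        if s.params is not None:
            row.update(s.params.as_dict())
            try:
                row["mean_like"] = fam.mean(s.params.values)
                row["sd_like"] = fam.sd(s.params.values)
            except ValueError:
                row["mean_like"] = np.nan
                row["sd_like"] = np.nan
        rows.append(row)
    frame = pd.DataFrame(rows)
    for p in fam.param_names:
        if p not in frame.columns:
            frame[p] = np.nan
    return frame


class PopKLDSummarizer(BaseEstimator, TransformerMixin):
    """Population model selection plus per-patient summarization.

    ``fit`` pools all values of one laboratory variable and selects the
    summary family by KL divergence against the population KDE (or accepts a
    fixed family).  ``transform`` fits that family to each patient and
    returns one row per patient with the fitted parameters.

    Parameters
    ----------
    lab_name : str
        Which laboratory variable of the table to summarize.
    family : str, optional
        Skip selection and use this family directly.
    min_obs : int
        Minimum number of observations for a patient to be fitted
        (default 5; sparser patients are excluded with a status).
    context : str, optional
        If given, restrict to rows with this collection context before
        pooling and fitting (explicit single-context runs).
    families, bandwidth_rule, bandwidth, grid_size, tie_ratio, kl_cap
        Passed to :class:`~popkld.selection.PopKLDSelector`.

    Attributes
    ----------
    selected_family_ : str
    selection_report_ : PopulationSelectionReport or None
        ``None`` when ``family`` was fixed by the caller.
    """

    def __init__(self, lab_name="lab", family=None, min_obs=5, context=None,
                 families=None, bandwidth_rule="silverman", bandwidth=None,
                 grid_size=512, tie_ratio=10.0, kl_cap=1e3):
        self.lab_name = lab_name
        self.family = family
        self.min_obs = min_obs
        self.context = context
        self.families = families
        self.bandwidth_rule = bandwidth_rule
        self.bandwidth = bandwidth
        self.grid_size = grid_size
        self.tie_ratio = tie_ratio
        self.kl_cap = kl_cap

    def _pooled(self, table: pd.DataFrame) -> np.ndarray:
        sub = table[table["lab_name"] == self.lab_name]
        if self.context is not None and "context" in sub.columns:
            sub = sub[sub["context"] == self.context]
        return sub["value"].to_numpy()

    def fit(self, X: pd.DataFrame, y=None):
        table = validate_table(X)
        if self.family is not None:
            get_family(self.family)  # fail fast on unknown names
            self.selected_family_ = self.family
            self.selection_report_ = None
        else:
            selector = PopKLDSelector(
                families=self.families,
                bandwidth_rule=self.bandwidth_rule,
                bandwidth=self.bandwidth,
                grid_size=self.grid_size,
                tie_ratio=self.tie_ratio,
                kl_cap=self.kl_cap,
                lab_name=self.lab_name,
            ).fit(self._pooled(table))
            self.selected_family_ = selector.selected_family_
            self.selection_report_ = selector.report_
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "selected_family_")
        table = validate_table(X)
        summaries = _fit_patients(table, self.lab_name,
                                  get_family(self.selected_family_),
                                  self.min_obs, self.context)
        self.summaries_ = summaries
        return summaries_to_frame(summaries)


def summarize_individuals(table: pd.DataFrame, lab_name: str,
                          family, min_obs: int = 5,
                          context: str | None = None) -> list[IndividualSummary]:
    """Fit ``family`` to each patient's values of ``lab_name``.

    Thin wrapper over the summarizer; returns the summary records themselves
    (use :func:`summaries_to_frame` to tabulate them).
    """
    return _fit_patients(validate_table(table), lab_name,
                         get_family(family), min_obs, context)


def empirical_summaries(table: pd.DataFrame, lab_name: str,
                        min_obs: int = 5,
                        context: str | None = None) -> pd.DataFrame:
    """Plain mean/standard-deviation summaries, for comparison baselines.

    Same exclusion rules and output shape as the model-based summaries, with
    ``mean_like`` = sample mean and ``sd_like`` = sample standard deviation.
    """
    if min_obs < 2:
        raise ValueError("min_obs must be >= 2")
    tab = validate_table(table)
    sub = tab[tab["lab_name"] == lab_name]
    if sub.empty:
        raise ValueError(f"lab '{lab_name}' not present in table")
    if context is not None and "context" in sub.columns:
        sub = sub[sub["context"] == context]
    grp = sub.groupby("patient_id", sort=True)["value"]
    frame = grp.agg(n_obs="size", mean_like="mean",
                    sd_like=lambda v: float(np.std(v))).reset_index()
    frame["patient_id"] = frame["patient_id"].astype(str)
    frame["lab_name"] = lab_name
    frame["family"] = "empirical"
    frame["status"] = np.where(frame["n_obs"] >= min_obs,
                               STATUS_INCLUDED, STATUS_INSUFFICIENT)
    frame.loc[frame["status"] != STATUS_INCLUDED,
              ["mean_like", "sd_like"]] = np.nan
    return frame


def exclusion_rate(summaries) -> float:
    """Fraction of patients excluded (any status other than included)."""
    if isinstance(summaries, pd.DataFrame):
        statuses = summaries["status"]
        n = len(statuses)
        if n == 0:
            raise ValueError("no summaries")
        return float((statuses != STATUS_INCLUDED).mean())
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries")
    return sum(1 for s in summaries if not s.included) / len(summaries)
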