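"""Per-patient summarization and exclusion accounting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

from popkld.summaries import (STATUS_INCLUDED, STATUS_INSUFFICIENT,
                              STATUS_NONCONVERGENCE, PopKLDSummarizer,
                              empirical_summaries, exclusion_rate,
                              summaries_to_frame, summarize_individuals)

from conftest import make_patient_table


def small_table():
    rows = []
    rows += [("a", "glu", v) for v in (1.0, 2.0, 3.0, 4.0)]          # 4 obs
    rows += [("b", "glu", float(v)) for v in range(10, 35)]          # 25 obs
    rows += [("c", "glu", 5.0)] * 25                                 # constant
    return pd.DataFrame(rows, columns=["patient_id", "lab_name", "value"])


def test_min_obs_threshold_excludes_sparse_patients():
    out = summarize_individuals(small_table(), "glu", "normal", min_obs=5)
    by_id = {s.patient_id: s for s in out}
    assert by_id["a"].status == STATUS_INSUFFICIENT
    assert by_id["a"].n_obs == 4 and by_id["a"].params is None
    assert by_id["b"].status == STATUS_INCLUDED


def test_degenerate_patient_is_excluded_not_fatal():
    out = summarize_individuals(small_table(), "glu", "gamma", min_obs=5)
    by_id = {s.patient_id: s for s in out}
    assert by_id["c"].status == STATUS_NONCONVERGENCE


def test_unknown_lab_raises():
    with pytest.raises(ValueError, match="not present"):
        summarize_individuals(small_table(), "missing", "normal")


def test_latent_recovery_across_patients(normal_patient_table):
    table, mus, sigmas = normal_patient_table
    out = summarize_individuals(table, "lab", "normal", min_obs=5)
    frame = summaries_to_frame(out).sort_values("patient_id")
    assert (frame["status"] == STATUS_INCLUDED).all()
    r = pearsonr(frame["loc"], mus).statistic
    assert r > 0.95
    # ranking by fitted location == ranking by sample mean (outlier-free)
    means = table.groupby("patient_id")["value"].mean().sort_index()
    assert spearmanr(frame["loc"], means).statistic > 0.99


def test_patients_are_processed_independently():
    table = small_table()
    full = summarize_individuals(table, "glu", "normal", min_obs=5)
    sub = summarize_individuals(table[table.patient_id != "c"], "glu",
                                "normal", min_obs=5)
    assert [s for s in full if s.patient_id != "c"] == sub


def test_exclusion_rate_arithmetic():
    out = summarize_individuals(small_table(), "glu", "normal", min_obs=5)
    # "a" is too sparse, "c" is constant-valued (degenerate MLE)
    assert exclusion_rate(out) == pytest.approx(2 / 3)
    frame = pd.DataFrame({"status": [STATUS_INCLUDED] * 19
                          + [STATUS_NONCONVERGENCE]})
    assert exclusion_rate(frame) == pytest.approx(0.05)
    with pytest.raises(ValueError):
        exclusion_rate([])


def test_exclusion_is_rare_on_well_conditioned_data(normal_patient_table):
    table, _, _ = normal_patient_table
    out = summarize_individuals(table, "lab", "normal", min_obs=5)
    assert exclusion_rate(out) < 0.05


def test_context_filter_is_explicit():
    table = small_table()
    table["context"] = ["icu"] * 4 + ["outpatient"] * 25 + ["icu"] * 25
    out = summarize_individuals(table, "glu", "normal", min_obs=2,
                                context="outpatient")
    assert [s.patient_id for s in out] == ["b"]


def test_min_obs_lower_bound():
    with pytest.raises(ValueError):
        summarize_individuals(small_table(), "glu", "normal", min_obs=1)


def test_empirical_summaries_match_numpy():
    table = small_table()
    emp = empirical_summaries(table, "glu", min_obs=5).set_index("patient_id")
    b = table.loc[table.patient_id == "b", "value"]
    assert emp.loc["b", "mean_like"] == pytest.approx(b.mean())
    assert emp.loc["b", "sd_like"] == pytest.approx(np.std(b))
    assert emp.loc["a", "status"] == STATUS_INSUFFICIENT
    assert np.isnan(emp.loc["a", "mean_like"])


class TestPopKLDSummarizer:
    def test_fixed_family_fit_transform(self, normal_patient_table):
        table, _, _ = normal_patient_table
        est = PopKLDSummarizer(lab_name="lab", family="normal", min_obs=5)
        frame = est.fit(table).transform(table)
        assert est.selected_family_ == "normal"
        assert est.selection_report_ is None
        assert {"loc", "scale", "mean_like", "sd_like"} <= set(frame.columns)
        assert len(frame) == 200

    def test_selection_happens_when_family_not_fixed(self):
        latents = [(100.0 + d, 15.0) for d in np.linspace(-5, 5, 40)]
        table = make_patient_table("normal", latents, n_obs=50, seed=3)
        est = PopKLDSummarizer(lab_name="lab", min_obs=5)
        est.fit(table)
        assert est.selection_report_ is not None
        assert "normal" in est.selection_report_.near_minimum_set

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone
        est = PopKLDSummarizer(lab_name="glu", family="gev", min_obs=7)
        params = clone(est).get_params()
        assert params["min_obs"] == 7 and params["family"] == "gev"

    def test_unknown_family_fails_fast(self, normal_patient_table):
        table, _, _ = normal_patient_table
        with pytest.raises(KeyError):
            PopKLDSummarizer(lab_name="lab", family="cauchyish").fit(table)
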