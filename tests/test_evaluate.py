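"""Evaluation: maxent lookup, relations, extreme groups, purity."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from popkld.categorize import PopKLDCat
from popkld.evaluate import (cluster_purity, extreme_groups, maxent_model,
                             relation)
from popkld.simulate import (glucose_coupled_spec, label_by_latent,
                             simulate_cohort)
from popkld.summaries import (STATUS_INCLUDED, empirical_summaries,
                              summaries_to_frame, summarize_individuals)


@pytest.mark.parametrize("constraints,expected", [
    ({"mean"}, "uniform"),
    ({"mean", "sd"}, "normal"),
    ({"mean", "sd", "linear_mean_sd"}, "gamma"),
])
def test_maximum_entropy_lookup(constraints, expected):
    assert maxent_model(constraints) == expected


def test_maxent_rejects_unknown_constraint_sets():
    with pytest.raises(ValueError):
        maxent_model({"sd"})
    with pytest.raises(ValueError):
        maxent_model(set())


def params_frame(x, y, xname="mean_like", yname="sd_like"):
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(len(x))],
        "status": STATUS_INCLUDED, xname: x, yname: y,
    })


class TestRelation:
    def test_exact_line(self):
        x = np.linspace(1, 10, 50)
        rep = relation(params_frame(x, 2 * x), "mean_like", "sd_like")
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.slope == pytest.approx(2.0)
        assert rep.intercept == pytest.approx(0.0, abs=1e-9)
        assert rep.n == 50

    def test_independent_parameters_show_no_relation(self):
        rng = np.random.default_rng(0)
        rep = relation(params_frame(rng.normal(size=1000),
                                    rng.normal(size=1000)),
                       "mean_like", "sd_like")
        assert abs(rep.pearson_r) < 0.1

    def test_truncation_is_applied_and_recorded(self):
        x = np.linspace(1, 10, 30)
        y = 2 * x
        y[-1] = 5000.0  # unit-error casualty
        rep = relation(params_frame(x, y), "mean_like", "sd_like",
                       truncation=("sd_like", 2000.0))
        assert rep.truncation_applied == ("sd_like", 2000.0)
        assert rep.n == 29
        assert rep.pearson_r == pytest.approx(1.0)

    def test_insufficient_rows_raise(self):
        with pytest.raises(ValueError):
            relation(params_frame([1.0, 2.0], [1.0, 2.0]),
                     "mean_like", "sd_like")

    def test_coupled_gamma_cohort_preserves_the_relation(self):
        cohort = simulate_cohort(glucose_coupled_spec("gamma", seed=0))
        frame = summaries_to_frame(
            summarize_individuals(cohort.table, "glucose", "gamma", 5))
        rep = relation(frame, "mean_like", "sd_like")
        assert rep.pearson_r > 0.8
        assert rep.slope == pytest.approx(0.3, abs=0.1)


def cats_frame(rows):
    frame = pd.DataFrame(rows, columns=["patient_id", "bin_loc", "bin_scale"])
    return frame


class TestExtremeGroups:
    def test_membership_rules(self):
        cats = cats_frame([("a", 10, 10), ("b", 1, 10), ("c", 1, 1),
                           ("d", 5, 5)])
        groups = extreme_groups(cats, None, n_bins=10, k=None)
        assert groups["top"] == ["a"]
        assert groups["bottom"] == ["c"]  # "b" mixes deciles: in neither

    def test_shape_sign_split(self):
        cats = cats_frame([("a", 10, 10), ("b", 10, 10)])
        summaries = pd.DataFrame({"patient_id": ["a", "b"],
                                  "shape": [0.4, -0.2]})
        groups = extreme_groups(cats, summaries, n_bins=10,
                                shape_param="shape", k=None)
        assert groups["top_shape_pos"] == ["a"]
        assert groups["top_shape_neg"] == ["b"]
        assert groups["bottom_shape_pos"] == []

    def test_subsampling_is_seeded_and_sized(self):
        cats = cats_frame([(f"p{i}", 10, 10) for i in range(40)])
        g1 = extreme_groups(cats, None, n_bins=10, k=15, seed=3)
        g2 = extreme_groups(cats, None, n_bins=10, k=15, seed=3)
        assert g1 == g2
        assert len(g1["top"]) == 15
        assert len(g1["bottom"]) == 0


class TestClusterPurity:
    def test_worked_examples(self):
        labels = {f"p{i}": int(i < 14) for i in range(15)}
        res = cluster_purity(labels, list(labels), "g")
        assert res.target_class_fraction == pytest.approx(14 / 15)
        assert round(res.target_class_fraction, 2) == 0.93
        assert res.purity == res.target_class_fraction

    def test_minority_target_class(self):
        labels = {f"p{i}": int(i < 4) for i in range(15)}
        res = cluster_purity(labels, list(labels))
        assert res.purity == pytest.approx(11 / 15)      # max-class
        assert round(res.purity, 2) == 0.73
        assert res.target_class_fraction == pytest.approx(4 / 15)  # printed

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            cluster_purity({"a": 1}, [])

    def test_unlabeled_member_raises(self):
        with pytest.raises(ValueError, match="unlabeled"):
            cluster_purity({"a": 1}, ["a", "b"])

    def test_permutation_invariance_and_brute_force_small(self):
        # exhaustive over all label patterns of a size-10 group
        members = [f"p{i}" for i in range(10)]
        for bits in itertools.product((0, 1), repeat=10):
            labels = dict(zip(members, bits))
            res = cluster_purity(labels, members)
            brute = max(sum(bits), 10 - sum(bits)) / 10
            assert res.purity == pytest.approx(brute)
            rev = cluster_purity(labels, members[::-1])
            assert rev.purity == res.purity


def test_phenotyping_top_group_is_enriched_and_location_ranks_survive_outliers():
    """End-to-end: on a coupled glucose cohort with 2% x1000 unit errors,
    (a) the all-top-decile group carries more positives than the bottom
    group, and (b) the model location summary preserves the true latent
    ordering far better than the raw empirical mean."""
    for seed in (0, 1):
        cohort = simulate_cohort(
            glucose_coupled_spec("lognormal", outlier_rate=0.02, seed=seed))
        labels = label_by_latent(cohort, 0.9)
        frame = summaries_to_frame(
            summarize_individuals(cohort.table, "glucose", "lognormal", 5))
        cats = PopKLDCat(10).fit_transform(frame)
        groups = extreme_groups(cats, frame, k=15, seed=seed)
        top = cluster_purity(labels, groups["top"]).target_class_fraction
        bottom = (cluster_purity(labels, groups["bottom"]).target_class_fraction
                  if groups["bottom"] else 0.0)
        assert top > bottom

        latent = cohort.latents.set_index("patient_id")["location_like"]
        fr = frame.set_index("patient_id")
        emp = empirical_summaries(cohort.table, "glucose", 5) \
            .set_index("patient_id")
        rho_model = spearmanr(fr["mu"], latent.reindex(fr.index)).statistic
        rho_emp = spearmanr(emp["mean_like"],
                            latent.reindex(emp.index)).statistic
        assert rho_model > rho_emp + 0.2
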