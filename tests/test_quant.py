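"""Enrichment accounting, site filters, imputation, t-test and iBAQ."""

import numpy as np
import pandas as pd
import pytest

from phosid.quant import (QuantParams, build_site_table, compare_conditions,
                          enrichment_summary, ibaq_prioritize,
                          impute_missing, normality_report)
from phosid.synthetic import (make_enrichment_intensities, make_proteome,
                              plant_labels, site_intensity_matrix)


class TestEnrichmentSummary:
    def test_single_class_takes_all(self):
        df = pd.DataFrame({"run": ["r1"] * 3, "class": ["probe"] * 3,
                           "intensity": [10.0, 20.0, 30.0]})
        out = enrichment_summary(df)
        assert out.fraction.tolist() == [1.0]

    def test_equal_classes_split_evenly(self):
        df = pd.DataFrame({"run": ["r1"] * 3,
                           "class": ["probe", "phospho", "unmodified"],
                           "intensity": [5.0, 5.0, 5.0]})
        out = enrichment_summary(df).set_index("class").fraction
        assert out["probe"] == pytest.approx(1 / 3)

    def test_fractions_sum_to_one_per_run(self, rng):
        df = pd.DataFrame({
            "run": rng.choice(["input", "elution"], 200),
            "class": rng.choice(["probe", "phospho", "unmodified"], 200),
            "intensity": rng.uniform(1, 100, 200)})
        out = enrichment_summary(df)
        for _run, group in out.groupby("run"):
            assert group.fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_generator_planted_fractions_recovered(self):
        df = make_enrichment_intensities(labeled_fraction_post=0.23,
                                         phospho_fraction_post=0.14, seed=3)
        out = enrichment_summary(df).set_index(["run", "class"]).fraction
        assert out[("elution", "probe")] == pytest.approx(0.23, abs=1e-6)
        assert out[("elution", "phospho")] == pytest.approx(0.14, abs=1e-6)
        assert out[("input", "probe")] == pytest.approx(1e-5, rel=1e-3)

    def test_zero_total_intensity_errors(self):
        df = pd.DataFrame({"run": ["r"], "class": ["probe"],
                           "intensity": [0.0]})
        with pytest.raises(ValueError, match="zero total"):
            enrichment_summary(df)


def site_rows(protein, position, presence, intensity=100.0):
    """presence: {condition: [replicates present]}"""
    rows = []
    for condition, reps in presence.items():
        for rep in reps:
            rows.append({"protein": protein, "position": position,
                         "condition": condition, "replicate": rep,
                         "intensity": intensity})
    return rows


class TestSiteTable:
    def test_two_of_three_rule_keeps(self):
        df = pd.DataFrame(site_rows("P1", 10, {"lysate": [1, 2]}))
        out = build_site_table(df, QuantParams(), "tryptic")
        assert len(out) == 2

    def test_one_of_three_in_each_condition_drops(self):
        df = pd.DataFrame(site_rows("P1", 10, {"lysate": [1],
                                               "intact": [2]}))
        out = build_site_table(df, QuantParams(), "tryptic")
        assert out.empty

    def test_pepsin_psm_rule(self):
        one = pd.DataFrame(site_rows("P1", 5, {"intact": [1]}))
        two = pd.DataFrame(site_rows("P1", 5, {"intact": [1]}) * 2)
        assert build_site_table(one, QuantParams(), "pepsin").empty
        assert not build_site_table(two, QuantParams(), "pepsin").empty

    def test_site_intensity_sums_peptide_evidence(self):
        rows = site_rows("P1", 10, {"lysate": [1, 2, 3]}, 40.0) * 2
        out = build_site_table(pd.DataFrame(rows), QuantParams(), "tryptic")
        assert (out.intensity == 80.0).all()

    def test_filter_idempotent(self):
        df = pd.DataFrame(
            site_rows("P1", 10, {"lysate": [1, 2, 3]})
            + site_rows("P2", 4, {"lysate": [2]}))
        once = build_site_table(df, QuantParams(), "tryptic")
        twice = build_site_table(once, QuantParams(), "tryptic")
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True))


class TestImputation:
    def matrix(self, rng, n=60, missing=0.25):
        values = rng.normal(24, 1.2, size=(n, 4))
        mask = rng.random((n, 4)) < missing
        values[mask] = np.nan
        return pd.DataFrame(values, columns=list("ABCD"))

    def test_complete_matrix_unchanged(self, rng):
        m = pd.DataFrame(rng.normal(24, 1, (30, 3)), columns=list("XYZ"))
        pd.testing.assert_frame_equal(impute_missing(m, seed=1), m)

    def test_observed_entries_untouched(self, rng):
        m = self.matrix(rng)
        out = impute_missing(m, seed=2)
        observed = ~m.isna()
        assert (out[observed] == m[observed]).all().all() or \
            np.allclose(out.values[observed.values], m.values[observed.values])

    def test_downshift_mean_recovered_at_large_n(self, rng):
        """Mean of imputed draws converges to mean - 1.8 SD (3 SE)."""
        n = 20000
        col = rng.normal(24.0, 1.0, n)
        m = pd.DataFrame({"A": col.copy()})
        missing_idx = rng.choice(n, size=10000, replace=False)
        m.loc[missing_idx, "A"] = np.nan
        observed = m["A"].dropna()
        params = QuantParams()
        out = impute_missing(m, params, seed=3)
        imputed = out.loc[m["A"].isna(), "A"]
        expected = observed.mean() - 1.8 * observed.std(ddof=1)
        width = params.impute_width_sd * observed.std(ddof=1)
        se = width / np.sqrt(len(imputed))
        assert abs(imputed.mean() - expected) < 3 * se

    def test_deterministic_per_seed(self, rng):
        m = self.matrix(rng)
        a = impute_missing(m, seed=7)
        b = impute_missing(m, seed=7)
        c = impute_missing(m, seed=8)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_fully_missing_column_names_column(self):
        m = pd.DataFrame({"good": [1.0, 2.0], "bad": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="bad"):
            impute_missing(m)


class TestNormalityReport:
    def test_reports_every_column_never_blocks(self, rng):
        m = pd.DataFrame({"A": rng.normal(0, 1, 50),
                          "B": rng.exponential(1, 50),
                          "C": [1.0] + [np.nan] * 49})
        out = normality_report(m)
        assert list(out.column) == ["A", "B", "C"]
        assert np.isnan(out.loc[2, "p_value"])  # too few observations


def two_group_matrix(values_a, values_b):
    cols = [f"lysate_{i}" for i in range(1, len(values_a) + 1)] + \
           [f"intact_{i}" for i in range(1, len(values_b) + 1)]
    m = pd.DataFrame([list(values_a) + list(values_b)], columns=cols)
    cond = {c: c.rsplit("_", 1)[0] for c in cols}
    return m, cond


class TestCompareConditions:
    def test_identical_groups_ns_and_zero_fc(self):
        m, cond = two_group_matrix([24.0, 24.1, 23.9], [24.0, 24.1, 23.9])
        out = compare_conditions(m, cond)
        assert out.log2fc.iloc[0] == pytest.approx(0.0)
        assert out["class"].iloc[0] == "ns"

    def test_label_swap_mirrors_volcano(self):
        m, cond = two_group_matrix([20.0, 20.2, 19.8], [24.0, 24.1, 23.9])
        forward = compare_conditions(m, cond)
        swapped = {c: ("intact" if v == "lysate" else "lysate")
                   for c, v in cond.items()}
        backward = compare_conditions(m, swapped)
        assert forward.log2fc.iloc[0] == pytest.approx(
            -backward.log2fc.iloc[0])
        assert forward["class"].iloc[0] == "intact-enriched"
        assert backward["class"].iloc[0] == "lysate-enriched"

    def test_zero_variance_everywhere_flagged(self):
        m, cond = two_group_matrix([24.0, 24.0, 24.0], [25.0, 25.0, 25.0])
        out = compare_conditions(m, cond)
        assert out["class"].iloc[0] == "flagged"
        assert np.isnan(out.p_value.iloc[0])

    def test_planted_fourfold_effect_recovered(self, rng):
        """4-fold planted effects classify to the correct side in >= 95%
        of 200 simulated sites at n=3 per condition."""
        hits = 0
        for _ in range(200):
            a = rng.normal(24.0, 0.4, 3)
            b = rng.normal(26.0, 0.4, 3)
            m, cond = two_group_matrix(a, b)
            if compare_conditions(m, cond)["class"].iloc[0] == \
                    "intact-enriched":
                hits += 1
        assert hits >= 0.95 * 200

    def test_bh_adjustment_is_monotone_and_bounded(self, rng):
        m = pd.DataFrame(rng.normal(24, 0.5, (40, 6)),
                         columns=[f"lysate_{i}" for i in range(3)]
                         + [f"intact_{i}" for i in range(3)])
        cond = {c: c.rsplit("_", 1)[0] for c in m.columns}
        out = compare_conditions(m, cond, QuantParams(bh_correction=True))
        assert (out.p_adjusted >= out.p_value - 1e-12).all()
        assert (out.p_adjusted <= 1.0).all()


class TestIbaq:
    def test_ibaq_definition(self):
        sites = pd.DataFrame([{"protein": "P1", "position": 3,
                               "intensity": 50.0}])
        out = ibaq_prioritize({"P1": 100.0}, {"P1": 4}, sites)
        assert out.ibaq.iloc[0] == pytest.approx(25.0)
        assert out.log2_ratio.iloc[0] == pytest.approx(np.log2(50.0 / 25.0))

    def test_ranking_invariant_to_global_scaling(self):
        sites = pd.DataFrame([
            {"protein": "P1", "position": 1, "intensity": 50.0},
            {"protein": "P2", "position": 2, "intensity": 500.0},
        ])
        protein = {"P1": 100.0, "P2": 100000.0}
        peptides = {"P1": 4, "P2": 4}
        base = ibaq_prioritize(protein, peptides, sites)
        scaled = ibaq_prioritize(
            {k: v * 1000 for k, v in protein.items()}, peptides,
            sites.assign(intensity=sites.intensity * 1000))
        assert base.protein.tolist() == scaled.protein.tolist()
        np.testing.assert_allclose(base.log2_ratio, scaled.log2_ratio)

    def test_low_abundance_protein_with_intense_site_ranks_first(self):
        """An earnest low-abundance target with a bright probe peptide
        outranks an abundant protein with weak labeling."""
        sites = pd.DataFrame([
            {"protein": "SCARCE", "position": 1101, "intensity": 4e8},
            {"protein": "ABUNDANT", "position": 20, "intensity": 1e8},
        ])
        protein = {"SCARCE": 4e7 * 30, "ABUNDANT": 1e10 * 30}
        peptides = {"SCARCE": 30, "ABUNDANT": 30}
        out = ibaq_prioritize(protein, peptides, sites)
        assert out.protein.iloc[0] == "SCARCE"

    def test_zero_theoretical_peptides_excluded(self):
        sites = pd.DataFrame([{"protein": "P1", "position": 1,
                               "intensity": 10.0}])
        out = ibaq_prioritize({"P1": 100.0}, {"P1": 0}, sites)
        assert out.empty


class TestEndToEndSiteRecovery:
    def test_planted_sites_recovered_and_no_spurious_sites(self):
        """>= 90% of planted sites with 2-replicate presence survive the
        filter; sites never planted never appear."""
        proteome = make_proteome(25, seed=21)
        truth = plant_labels(proteome, seed=21)
        observed = truth.dropna(subset=["intensity"])
        table = build_site_table(observed, QuantParams(), "tryptic")
        kept = set(map(tuple, table[["protein", "position"]]
                       .drop_duplicates().itertuples(index=False)))
        planted = set(map(tuple, truth[["protein", "position"]]
                          .drop_duplicates().itertuples(index=False)))
        # qualifying: present in >=2 replicates of at least one condition
        qualifying = set()
        for (protein, position), group in observed.groupby(
                ["protein", "position"]):
            if (group.groupby("condition")["replicate"].nunique() >= 2).any():
                qualifying.add((protein, position))
        assert kept <= planted          # nothing fabricated
        assert len(kept & qualifying) >= 0.9 * len(qualifying)
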