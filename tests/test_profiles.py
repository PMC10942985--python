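"""Label-engineering rules checked against brute-force counting oracles."""

import numpy as np
import pandas as pd
import pytest

from histomark.profiles import (
    DEFAULT_FILTER_RULES,
    BiomarkerProfile,
    FilterRule,
    OmicType,
    PROTEOME_THRESHOLDS,
    TRANSCRIPTOME_THRESHOLDS,
    ZScoreThresholds,
    apply_filter,
    clinical_outcome_profiles,
    expression_profiles,
    mean_binarize,
    msi_profile,
    one_hot_profiles,
    snv_profile,
)
from histomark.synthetic import generate_mutation_table, generate_zscore_table


class TestSnvProfile:
    def test_single_snv_is_positive(self):
        muts = pd.DataFrame(
            [("S1", "G", "SNP")],
            columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Type"],
        )
        (prof,) = snv_profile(muts, ["G"], ["S1", "S2"])
        assert prof.labels == {"S1": 1, "S2": 0}

    def test_unlisted_sequenced_sample_is_wild_type(self):
        muts = pd.DataFrame(
            columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Type"]
        )
        (prof,) = snv_profile(muts, ["G"], ["S1", "S2", "S3"])
        assert prof.n_positive == 0 and prof.n_total == 3

    def test_counts_match_brute_force_tally(self):
        genes = [f"g{i}" for i in range(10)]
        muts = generate_mutation_table(50, {g: 0.3 for g in genes}, seed=3)
        samples = [f"S{i:04d}" for i in range(50)]
        profs = snv_profile(muts, genes, samples)
        for prof, gene in zip(profs, genes):
            expected = {
                s: int(((muts["Tumor_Sample_Barcode"] == s)
                        & (muts["Hugo_Symbol"] == gene)).sum() >= 1)
                for s in samples
            }
            assert prof.labels == expected

    def test_empty_driver_list_rejected(self):
        with pytest.raises(ValueError):
            snv_profile(pd.DataFrame(columns=["Tumor_Sample_Barcode",
                                              "Hugo_Symbol", "Variant_Type"]),
                        [], ["S1"])


class TestExpressionProfiles:
    def test_boundary_inclusive_at_t_under(self):
        z = pd.DataFrame({"S1": [-2.0], "S2": [0.0]}, index=["G"])
        under, over = expression_profiles(z, TRANSCRIPTOME_THRESHOLDS, ["G"])
        assert under.labels == {"S1": 1, "S2": 0}
        assert over.labels == {"S1": 0, "S2": 0}

    def test_boundary_inclusive_at_t_over_proteomic(self):
        z = pd.DataFrame({"S1": [1.5]}, index=["G"])
        under, over = expression_profiles(z, PROTEOME_THRESHOLDS, ["G"],
                                          omic="protein")
        assert over.labels["S1"] == 1
        assert over.omic_type is OmicType.PROTEIN_OVER

    def test_all_zero_scores_all_negative(self):
        z = pd.DataFrame(np.zeros((1, 5)), index=["G"],
                         columns=[f"S{i}" for i in range(5)])
        under, over = expression_profiles(z, TRANSCRIPTOME_THRESHOLDS, ["G"])
        assert under.n_positive == 0 and over.n_positive == 0

    def test_counts_match_threshold_counting_oracle(self):
        z = generate_zscore_table(80, ["a", "b", "c"], seed=5)
        profs = expression_profiles(z, TRANSCRIPTOME_THRESHOLDS, ["a", "b", "c"])
        for prof in profs:
            gene = prof.biomarker_id.rsplit("_", 1)[0]
            if prof.omic_type is OmicType.TRANSCRIPTOME_UNDER:
                expected = int((z.loc[gene] <= -2).sum())
            else:
                expected = int((z.loc[gene] >= 2).sum())
            assert prof.n_positive == expected

    def test_under_over_never_both_positive(self):
        z = generate_zscore_table(200, ["g"], seed=6)
        under, over = expression_profiles(z, TRANSCRIPTOME_THRESHOLDS, ["g"])
        both = [s for s in under.labels
                if under.labels[s] == 1 and over.labels[s] == 1]
        assert both == []

    def test_missing_gene_skipped_with_warning(self):
        z = generate_zscore_table(10, ["g"], seed=1)
        with pytest.warns(UserWarning):
            profs = expression_profiles(z, TRANSCRIPTOME_THRESHOLDS,
                                        ["g", "absent"])
        assert len(profs) == 2  # only g's pair

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ZScoreThresholds(2.0, -2.0)


class TestApplyFilter:
    def _profile(self, n_pos, n_total, omic=OmicType.SNV):
        labels = {f"P{i}": int(i < n_pos) for i in range(n_total)}
        return BiomarkerProfile("b", omic, labels)

    def test_nine_positives_dropped_general_rule(self):
        keep, reason = apply_filter(self._profile(9, 100))
        assert not keep and "9 positives" in reason

    def test_ten_positives_kept_general_rule(self):
        keep, _ = apply_filter(self._profile(10, 100))
        assert keep

    def test_protein_nineteen_positives_dropped(self):
        keep, _ = apply_filter(self._profile(19, 100, OmicType.PROTEIN_OVER))
        assert not keep
        keep, _ = apply_filter(self._profile(20, 100, OmicType.PROTEIN_OVER))
        assert keep

    def test_transcriptome_ratio_rule(self):
        # 15/200 = 7.5% < 10% -> drop despite >= 10 positives
        keep, reason = apply_filter(
            self._profile(15, 200, OmicType.TRANSCRIPTOME_OVER))
        assert not keep and "ratio" in reason
        keep, _ = apply_filter(
            self._profile(20, 200, OmicType.TRANSCRIPTOME_OVER))
        assert keep

    def test_emitted_profiles_satisfy_their_rule(self):
        """Post-filter re-check: every kept profile passes its rule again."""
        rng = np.random.default_rng(0)
        for omic in OmicType:
            for _ in range(5):
                prof = self._profile(int(rng.integers(0, 40)), 120, omic)
                keep, _ = apply_filter(prof)
                if keep:
                    rule = DEFAULT_FILTER_RULES[omic]
                    assert prof.n_positive >= rule.min_positive
                    if rule.min_positive_ratio:
                        assert prof.positive_ratio >= rule.min_positive_ratio


class TestOneHot:
    def test_three_categories_row_sums_one(self):
        cats = {f"P{i}": "ABC"[i % 3] for i in range(9)}
        profs = one_hot_profiles(cats)
        assert len(profs) == 3
        for p in cats:
            assert sum(prof.labels[p] for prof in profs) == 1

    def test_two_categories_complementary(self):
        cats = {"P1": "x", "P2": "y", "P3": "x"}
        a, b = one_hot_profiles(cats)
        assert all(a.labels[p] + b.labels[p] == 1 for p in cats)

    def test_counts_match_brute_force(self, rng):
        cats = {f"P{i}": "WXYZ"[rng.integers(4)] for i in range(50)}
        for prof in one_hot_profiles(cats):
            cat = prof.biomarker_id.rsplit("_", 1)[1]
            assert prof.n_positive == sum(v == cat for v in cats.values())

    def test_single_category_rejected(self):
        with pytest.raises(ValueError):
            one_hot_profiles({"P1": "a", "P2": "a"})


class TestMeanBinarize:
    def test_simple_rule_with_tie_at_mean_negative(self):
        prof = mean_binarize({"a": 2.0, "b": 4.0, "c": 6.0})
        assert prof.labels == {"a": 0, "b": 0, "c": 1}

    def test_constant_values_all_negative(self):
        prof = mean_binarize({"a": 5.0, "b": 5.0})
        assert prof.n_positive == 0

    def test_nan_excluded_mean_over_nonmissing(self, rng):
        vals = {f"P{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 30))}
        vals["PX"] = float("nan")
        prof = mean_binarize(vals)
        clean = {k: v for k, v in vals.items() if k != "PX"}
        mu = np.mean(list(clean.values()))
        assert "PX" not in prof.labels
        assert prof.labels == {k: int(v > mu) for k, v in clean.items()}

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            mean_binarize({"a": float("nan")})


class TestClinicalOutcomes:
    def test_residual_tumor_r2_positive(self):
        t = pd.DataFrame({"patient_id": ["P1", "P2"],
                          "residual_tumor": ["R2", "R0"]})
        (prof,) = clinical_outcome_profiles(t)
        assert prof.labels == {"P1": 1, "P2": 0}

    def test_partial_response_negative(self):
        t = pd.DataFrame({"patient_id": ["P1"],
                          "treatment_best_response": ["Partial Response"]})
        (prof,) = clinical_outcome_profiles(t)
        assert prof.labels["P1"] == 0

    def test_unknown_string_excluded_with_warning(self):
        t = pd.DataFrame({"patient_id": ["P1", "P2"],
                          "residual_tumor": ["RX", "R1"]})
        with pytest.warns(UserWarning):
            (prof,) = clinical_outcome_profiles(t)
        assert prof.labels == {"P2": 1}

    def test_no_recognized_columns_rejected(self):
        with pytest.raises(ValueError):
            clinical_outcome_profiles(pd.DataFrame({"patient_id": ["P1"],
                                                    "shoe_size": [42]}))

    def test_binary_survival_endpoints_passed_through(self):
        t = pd.DataFrame({"patient_id": ["P1", "P2"], "OS": [1, 0]})
        (prof,) = clinical_outcome_profiles(t)
        assert prof.labels == {"P1": 1, "P2": 0}


class TestMsiProfile:
    @pytest.mark.parametrize("level,expected",
                             [("MSI-H", 1), ("MSS", 0), ("MSI-L", 0)])
    def test_levels(self, level, expected):
        prof = msi_profile({"P1": level})
        assert prof.labels["P1"] == expected

    def test_positive_count_equals_msih_count(self, rng):
        levels = ["MSI-H", "MSI-L", "MSS"]
        status = {f"P{i}": levels[rng.integers(3)] for i in range(60)}
        prof = msi_profile(status)
        assert prof.n_positive == sum(v == "MSI-H" for v in status.values())


def test_profile_construction_order_independent(rng):
    """Shuffling mutation-record rows leaves profiles unchanged."""
    muts = generate_mutation_table(30, {"a": 0.4, "b": 0.3}, seed=9)
    samples = [f"S{i:04d}" for i in range(30)]
    shuffled = muts.sample(frac=1.0, random_state=1).reset_index(drop=True)
    for p1, p2 in zip(snv_profile(muts, ["a", "b"], samples),
                      snv_profile(shuffled, ["a", "b"], samples)):
        assert p1.labels == p2.labels
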