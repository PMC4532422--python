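"""Cohort analysis: classification, dynamics, spectra, profile splitting."""

import math

import pytest

from mitohet import (
    HeteroplasmyCall,
    VariantLabel,
    classify_variant,
    expansion_summary,
    high_level_fraction,
    level_distribution_test,
    load_shared_mutation_tables,
    nonsyn_enrichment,
    parse_variant_label,
    region_spectrum,
    shared_somatic_summary,
    spectrum_correlations,
    split_profiles,
)
from mitohet.cohort import (
    NA,
    ND,
    TissueVariantRecord,
    classify_records,
    level_distribution_test_from_counts,
    records_from_level_table,
)
from mitohet.errors import InsufficientDataError, UndefinedCorrelationError


def record(patient, label, **levels):
    full = {cls: levels.get(cls, NA) for cls in (
        "benign_margin", "blood", "primary_tumor", "recurrence",
        "lymph_node_metastasis",
    )}
    return TissueVariantRecord(
        patient_id=patient, variant=parse_variant_label(label), levels=full,
    )


@pytest.fixture(scope="module")
def published_records():
    t1, t2 = load_shared_mutation_tables()
    return classify_records(records_from_level_table(t1) +
                            records_from_level_table(t2))


class TestClassifyVariant:
    def test_benign_blood_and_tumor_heteroplasmy_is_germline(self):
        r = record("MKG04", "m.T5789Y",
                   benign_margin=16.91, blood=45.62, primary_tumor=8.21)
        assert classify_variant(r) == "germline_heteroplasmy"

    def test_absent_in_benign_present_in_two_cancerous_is_somatic_shared(self):
        r = record("MKG05", "m.A5894R", benign_margin=ND, blood=ND,
                   primary_tumor=15.54, recurrence=71.6)
        assert classify_variant(r) == "somatic_shared"

    def test_homoplasmic_everywhere_is_germline_homoplasmic(self):
        r = record("P", "m.G15498A", benign_margin=100.0, blood=100.0,
                   primary_tumor=100.0)
        assert classify_variant(r) == "germline_homoplasmic"

    def test_benign_and_blood_only_counts_as_germline(self):
        # heteroplasmic in two benign-side tissues, cancer tissue unavailable
        r = record("MKG11", "m.T146Y", benign_margin=98.73, blood=45.16)
        assert classify_variant(r) == "germline_heteroplasmy"

    def test_single_tissue_heteroplasmy_is_private(self):
        r = record("P", "m.T146Y", primary_tumor=12.0, benign_margin=ND)
        assert classify_variant(r) == "somatic_private"

    def test_all_unavailable_raises(self):
        r = record("P", "m.T146Y")
        with pytest.raises(InsufficientDataError):
            classify_variant(r)

    def test_statuses_are_exclusive_and_total(self, published_records):
        assert all(r.status in (
            "germline_homoplasmic", "germline_heteroplasmy",
            "somatic_shared", "somatic_private",
        ) for r in published_records)


class TestSharedSomaticSummary:
    def test_published_tissue_means(self, published_records):
        summary = shared_somatic_summary(published_records)
        assert summary["primary_tumor"]["mean"] == pytest.approx(17.9, abs=0.05)
        assert summary["primary_tumor"]["n"] == 12
        assert summary["recurrence"]["mean"] == pytest.approx(39.6, abs=0.05)
        assert summary["recurrence"]["n"] == 5
        assert summary["lymph_node_metastasis"]["mean"] == pytest.approx(49.8, abs=0.05)
        assert summary["lymph_node_metastasis"]["n"] == 7

    def test_mean_is_permutation_invariant(self, published_records):
        reversed_summary = shared_somatic_summary(list(reversed(published_records)))
        forward_summary = shared_somatic_summary(published_records)
        assert reversed_summary["primary_tumor"] == forward_summary["primary_tumor"]

    def test_single_record_mean_is_its_level(self):
        r = record("P", "m.T146Y", benign_margin=ND, primary_tumor=5.0,
                   recurrence=7.0)
        summary = shared_somatic_summary([r])
        assert summary["primary_tumor"]["mean"] == 5.0


class TestHighLevelFraction:
    def test_published_primary_levels_give_75_percent(self, published_records):
        shared = [r for r in published_records if r.status == "somatic_shared"]
        levels = [r.detected()["primary_tumor"] for r in shared
                  if "primary_tumor" in r.detected()]
        assert high_level_fraction(levels) == pytest.approx(75.0)

    def test_all_below_boundary_gives_zero(self):
        assert high_level_fraction([1.0, 5.0, 9.9]) == 0.0

    def test_matches_brute_force_count(self, rng):
        levels = rng.uniform(0, 100, size=200)
        expected = 100 * sum(1 for v in levels if v > 10) / len(levels)
        assert high_level_fraction(levels) == pytest.approx(expected)


class TestExpansion:
    def test_mkg05_decreasing_sites_average_nine_percent(self, published_records):
        summary = expansion_summary(published_records, "MKG05",
                                    "primary_tumor", "recurrence")
        assert summary["n_decrease"] == 2
        assert summary["mean_decrease"] == pytest.approx(9.0, abs=0.5)

    def test_mkg20_lymph_node_ratio_rounds_to_1_4(self, published_records):
        summary = expansion_summary(published_records, "MKG20",
                                    "primary_tumor", "lymph_node_metastasis")
        assert round(summary["ratio_of_means"], 1) == 1.4

    def test_no_overlapping_sites_raises(self, published_records):
        with pytest.raises(InsufficientDataError):
            expansion_summary(published_records, "MKG01",
                              "recurrence", "lymph_node_metastasis")


class TestLevelDistribution:
    def test_published_counts_reproduce_p_value(self):
        result = level_distribution_test_from_counts(65, 82, 62, 97)
        assert result.p == pytest.approx(0.024, abs=5e-4)
        assert result.chi2 == pytest.approx(5.08, abs=5e-3)
        assert result.prop_low_a == pytest.approx(79.3, abs=0.05)
        assert result.prop_low_b == pytest.approx(63.9, abs=0.05)

    def test_counts_are_conserved(self):
        result = level_distribution_test_from_counts(65, 82, 62, 97)
        (la, ha), (lb, hb) = result.counts
        assert la + ha == 82 and lb + hb == 97

    def test_identical_groups_give_p_near_one(self):
        result = level_distribution_test_from_counts(50, 100, 50, 100)
        assert result.p == pytest.approx(1.0)

    def test_raw_levels_are_binned_percent_wide(self, rng):
        benign = rng.uniform(1, 30, size=60)
        tumor = rng.uniform(1, 60, size=70)
        result = level_distribution_test(benign, tumor)
        assert result.bins_a.sum() == 60 and result.bins_b.sum() == 70
        assert result.bin_edges[1] - result.bin_edges[0] == 1.0

    def test_empty_group_raises(self):
        with pytest.raises(InsufficientDataError):
            level_distribution_test([], [1.0])


class TestRegionSpectrum:
    def test_single_gene_concentration(self, annotation):
        spectrum = region_spectrum([13000, 13001, 13002, 13003], [13000],
                                   annotation)
        assert spectrum.loc["MT-ND5", "somatic_prop"] == pytest.approx(1.0)
        assert spectrum.drop("MT-ND5")["somatic_count"].sum() == 0

    def test_proportions_sum_to_one(self, annotation, rng):
        positions = rng.integers(1, 16570, size=80)
        spectrum = region_spectrum(positions[:50], positions[50:], annotation)
        assert spectrum["somatic_prop"].sum() == pytest.approx(1.0)
        assert spectrum["inherited_prop"].sum() == pytest.approx(1.0)

    def test_counts_match_brute_force_tally(self, annotation, rng):
        positions = [int(p) for p in rng.integers(1, 16570, size=60)]
        spectrum = region_spectrum(positions, [], annotation)
        tally = {}
        for pos in positions:
            region = annotation.locate(pos)
            key = ("tRNA" if region.region_class == "tRNA"
                   else "control" if region.region_class == "control"
                   else region.name)
            tally[key] = tally.get(key, 0) + 1
        for key, count in tally.items():
            assert spectrum.loc[key, "somatic_count"] == count

    def test_class_split_reproduces_published_proportions(self, annotation):
        """A fixture placing 1000 somatic variants as 6.9% tRNA / 18.3% rRNA /
        52.2% protein / 22.6% control reproduces those percentages."""
        from mitohet.cohort import class_spectrum

        targets = {"tRNA": 69, "rRNA": 183, "protein": 522, "control": 226}
        pools = {"tRNA": 577, "rRNA": 700, "protein": 13000, "control": 300}
        positions = []
        for cls, n in targets.items():
            anchor = pools[cls]
            assert annotation.locate(anchor).region_class == cls
            positions += [anchor] * n
        spectrum = class_spectrum(positions, annotation)
        assert spectrum.loc["tRNA", "proportion_pct"] == pytest.approx(6.9)
        assert spectrum.loc["rRNA", "proportion_pct"] == pytest.approx(18.3)
        assert spectrum.loc["protein", "proportion_pct"] == pytest.approx(52.2)
        assert spectrum.loc["control", "proportion_pct"] == pytest.approx(22.6)


class TestSpectrumCorrelations:
    def test_identical_sets_correlate_perfectly(self, annotation, rng):
        positions = [int(p) for p in rng.integers(1, 16570, size=60)]
        spectrum = region_spectrum(positions, positions, annotation)
        result = spectrum_correlations(spectrum)
        assert result.r_somatic_vs_inherited == pytest.approx(1.0)

    def test_length_proportional_burden_gives_r_one(self, annotation):
        proteins = [r for r in annotation if r.region_class == "protein"]
        positions = []
        for region in proteins:
            positions += [region.start] * round(region.length / 100)
        spectrum = region_spectrum(positions, positions, annotation)
        result = spectrum_correlations(spectrum)
        assert result.r_somatic_vs_length == pytest.approx(1.0, abs=0.02)

    def test_constant_proportions_raise(self, annotation):
        spectrum = region_spectrum([13000], [13000], annotation)
        spectrum["somatic_prop"] = 0.5
        spectrum["inherited_prop"] = 0.5
        with pytest.raises(UndefinedCorrelationError):
            spectrum_correlations(spectrum)


class TestNonsynEnrichment:
    def test_maximal_separation_is_highly_significant(self):
        result = nonsyn_enrichment(["nonsynonymous"] * 20, ["synonymous"] * 20)
        assert result["p"] < 0.001

    def test_identical_distributions_not_significant(self):
        effects = ["nonsynonymous"] * 10 + ["synonymous"] * 10
        result = nonsyn_enrichment(effects, effects)
        assert result["p"] == pytest.approx(1.0)

    def test_small_tables_fall_back_to_fisher_matching_hypergeometric(self):
        result = nonsyn_enrichment(["nonsynonymous"] * 4 + ["synonymous"],
                                   ["nonsynonymous"] + ["synonymous"] * 4)
        assert result["method"] == "fisher"
        # brute-force two-sided Fisher p over all tables with fixed margins
        a, b = 4, 1
        c, d = 1, 4
        n = a + b + c + d
        row1, col1 = a + b, a + c

        def table_p(x):
            return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                    / math.comb(n, row1))

        observed = table_p(a)
        p_expected = sum(table_p(x) for x in
                         range(max(0, row1 - (n - col1)), min(row1, col1) + 1)
                         if table_p(x) <= observed + 1e-12)
        assert result["p"] == pytest.approx(p_expected)

    def test_chi2_used_for_large_tables_matches_formula(self, rng):
        result = nonsyn_enrichment(
            ["nonsynonymous"] * 30 + ["synonymous"] * 20,
            ["nonsynonymous"] * 15 + ["synonymous"] * 35,
        )
        assert result["method"] == "chi2"
        a, b, c, d = 30, 20, 15, 35
        n = a + b + c + d
        chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert result["statistic"] == pytest.approx(chi2)


class TestSplitProfiles:
    def _call(self, pos, major, minor, level=30.0):
        return HeteroplasmyCall(
            position=pos, ref_base=major, major_allele=major, minor_allele=minor,
            level_pct=level, minor_pct=min(level, 100 - level),
            minor_fwd_pct=level, minor_rev_pct=level,
            depth_fwd=1000, depth_rev=1000,
        )

    def test_no_heteroplasmies_gives_identical_profiles(self):
        homs = [VariantLabel(100, "A", "G"), VariantLabel(200, "C", "T")]
        major, minor = split_profiles([], homs)
        assert major == minor == [(100, "G"), (200, "T")]

    def test_heteroplasmy_splits_into_major_and_minor_alleles(self):
        homs = [VariantLabel(p, "A", "G") for p in (10, 20, 30, 40, 50)]
        call = self._call(500, major="A", minor="G", level=30.0)
        major, minor = split_profiles([call], homs)
        assert (500, "A") in major
        assert (500, "G") in minor
        assert len(major) == len(minor) == 6

    def test_union_reconstructs_variant_set(self):
        homs = [VariantLabel(p, "A", "G") for p in (10, 20)]
        calls = [self._call(100, "A", "C"), self._call(200, "G", "T")]
        major, minor = split_profiles(calls, homs)
        union = set(major) | set(minor)
        expected = {(10, "G"), (20, "G"), (100, "A"), (100, "C"),
                    (200, "G"), (200, "T")}
        assert union == expected
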