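"""Artifact filters: recurrence/context, strand drop, satellites, zones."""

import numpy as np
import pytest

from mitohet import (
    FilterConfig,
    HeteroplasmyCall,
    apply_filters,
    correlated_neighbors,
    flag_recurrent_context,
    strand_coverage_drop,
    zone_exclusion,
)
from mitohet.errors import ConfigError
from mitohet.pileup import BASE_INDEX, Pileup


def make_call(pos, level, sample="s", ref="A", minor="G"):
    minor_pct = min(level, 100 - level)
    return HeteroplasmyCall(
        position=pos, ref_base=ref, major_allele=ref if level < 50 else minor,
        minor_allele=minor if level < 50 else ref,
        level_pct=level, minor_pct=minor_pct,
        minor_fwd_pct=minor_pct, minor_rev_pct=minor_pct,
        depth_fwd=17500, depth_rev=17500, sample=sample,
    )


class TestRecurrentContext:
    def test_low_level_recurrence_is_flagged(self, genome):
        cohort = {f"s{i}": [make_call(414, 1.5, f"s{i}")] for i in range(12)}
        cohort.update({f"t{i}": [] for i in range(8)})
        flags = flag_recurrent_context(cohort, genome)
        assert len(flags) == 1
        assert flags[0].position == 414
        assert flags[0].evidence["recurrence"] == 12
        assert flags[0].evidence["mean_minor_pct"] == pytest.approx(1.5)

    def test_single_sample_position_not_flagged(self, genome):
        cohort = {"s0": [make_call(5000, 1.5, "s0")],
                  "s1": [make_call(6000, 1.5, "s1")]}
        assert flag_recurrent_context(cohort, genome) == []

    def test_high_level_calls_do_not_count_toward_recurrence(self, genome):
        cohort = {f"s{i}": [make_call(414, 60.0, f"s{i}")] for i in range(12)}
        assert flag_recurrent_context(cohort, genome) == []

    def test_identical_context_positions_grouped(self):
        """Two flagged positions with a planted identical 9-mer end up in one
        context group; verified against a brute-force pairwise comparison."""
        from mitohet.reference import GENOME_LENGTH, MitoGenome

        seq = list("A" * GENOME_LENGTH)
        motif = "GGTTATGCA"  # 9-mer planted around two positions
        for centre in (1000, 9000):
            seq[centre - 5:centre + 4] = motif
        genome = MitoGenome("".join(seq))
        cohort = {
            f"s{i}": [make_call(1000, 1.5, f"s{i}"), make_call(9000, 1.4, f"s{i}")]
            for i in range(10)
        }
        flags = flag_recurrent_context(cohort, genome)
        assert len(flags) == 2
        # brute-force oracle: compare context strings of all flagged pairs
        same = flags[0].evidence["context"] == flags[1].evidence["context"]
        assert same
        assert flags[0].evidence["context_group"] == flags[1].evidence["context_group"]
        assert flags[0].evidence["context_group_size"] == 2

    def test_context_window_wraps_origin(self, genome):
        cohort = {f"s{i}": [make_call(2, 1.0, f"s{i}")] for i in range(8)}
        flags = flag_recurrent_context(cohort, genome)
        context = flags[0].evidence["context"]
        assert len(context) == 11  # 9-mer plus brackets
        assert context == genome.context(2, 9)


def _flat_pileup(length=60, fwd=35000, rev=35000):
    ref = "A" * length
    pile = Pileup(ref)
    pile.counts[:, 0, BASE_INDEX["A"]] = fwd
    pile.counts[:, 1, BASE_INDEX["A"]] = rev
    return pile


class TestStrandDrop:
    def test_forward_drop_with_stable_reverse_is_flagged(self):
        pile = _flat_pileup()
        pile.counts[29, 0, BASE_INDEX["A"]] = 18_200  # ratio ~0.52 at pos 30
        flag = strand_coverage_drop(pile, 30)
        assert flag is not None
        assert flag.evidence["ratio_forward"] == pytest.approx(0.52)
        assert flag.evidence["dropped_strand"] == "+"

    def test_uniform_coverage_is_not_flagged(self):
        assert strand_coverage_drop(_flat_pileup(), 30) is None

    def test_both_strands_dropping_is_not_flagged(self):
        pile = _flat_pileup()
        pile.counts[29, :, BASE_INDEX["A"]] = 10_000
        assert strand_coverage_drop(pile, 30) is None

    def test_ratios_match_direct_recomputation(self, rng):
        pile = _flat_pileup()
        noise = rng.integers(30_000, 40_000, size=(60, 2))
        pile.counts[:, 0, BASE_INDEX["A"]] = noise[:, 0]
        pile.counts[:, 1, BASE_INDEX["A"]] = noise[:, 1]
        pos = 30
        flag = strand_coverage_drop(pile, pos, drop_ratio_max=2.0,
                                    stable_ratio_min=0.0)
        flank = [i for i in range(pos - 5, pos + 6) if i != pos]
        exp_f = noise[pos - 1, 0] / np.median([noise[i - 1, 0] for i in flank])
        exp_r = noise[pos - 1, 1] / np.median([noise[i - 1, 1] for i in flank])
        assert flag is not None
        assert flag.evidence["ratio_forward"] == pytest.approx(exp_f)
        assert flag.evidence["ratio_reverse"] == pytest.approx(exp_r)


class TestCorrelatedNeighbors:
    ANCHOR_LEVELS = {"mkg04": 60.18, "mkg08": 16.62, "mkg20": 27.41}

    def _cohort(self, neighbor_scale=0.5, extra=None):
        cohort = {}
        for sample, level in self.ANCHOR_LEVELS.items():
            cohort[sample] = [
                make_call(72, level, sample),
                make_call(73, level * neighbor_scale, sample),
            ]
        if extra:
            cohort.update(extra)
        return cohort

    def test_proportional_neighbor_is_flagged(self):
        flags, _ = correlated_neighbors(self._cohort(), anchor=72)
        assert [f.position for f in flags] == [73]
        assert flags[0].evidence["pearson_r"] == pytest.approx(1.0)

    def test_correlation_matches_closed_form_pearson(self, rng):
        cohort = {}
        x, y = [], []
        for i in range(6):
            xi, yi = float(rng.uniform(5, 60)), float(rng.uniform(5, 60))
            x.append(xi), y.append(yi)
            cohort[f"s{i}"] = [make_call(72, xi, f"s{i}"),
                               make_call(74, yi, f"s{i}")]
        flags, _ = correlated_neighbors(cohort, anchor=72, correlation_min=-1.1)
        x, y = np.array(x), np.array(y)
        expected = float(((x - x.mean()) * (y - y.mean())).sum()
                         / np.sqrt(((x - x.mean())**2).sum()
                                   * ((y - y.mean())**2).sum()))
        assert flags[0].evidence["pearson_r"] == pytest.approx(expected)

    def test_neighbor_in_anchor_negative_sample_not_flagged(self):
        extra = {"other": [make_call(73, 12.0, "other")]}  # no anchor call
        flags, notes = correlated_neighbors(self._cohort(extra=extra), anchor=72)
        assert flags == []
        assert any("anchor-negative" in n for n in notes)

    def test_fewer_than_three_pairs_is_indeterminate(self):
        cohort = {s: calls for s, calls in list(self._cohort().items())[:2]}
        flags, notes = correlated_neighbors(cohort, anchor=72)
        assert flags == []
        assert notes


class TestZones:
    def test_primer_zone_and_circular_edge(self):
        cohort = {"s": [make_call(2600, 3.0, "s"), make_call(3, 2.0, "s"),
                        make_call(5000, 3.0, "s")]}
        flags = zone_exclusion(cohort)
        kinds = {(f.position, f.flag_kind) for f in flags}
        assert (2600, "primer_zone") in kinds
        assert (3, "circular_edge") in kinds
        assert not any(f.position == 5000 for f in flags)


class TestApplyFilters:
    def _cohort_with_anchor(self, genome):
        """8 low-level and 3 high-level calls at one recurrent position."""
        cohort = {}
        for i in range(8):
            cohort[f"low{i}"] = [make_call(72, 1.5, f"low{i}")]
        for i, level in enumerate((60.18, 16.62, 27.41)):
            cohort[f"high{i}"] = [make_call(72, level, f"high{i}")]
        return cohort

    def test_low_level_excluded_high_level_retained(self, genome):
        cohort = self._cohort_with_anchor(genome)
        result = apply_filters(cohort, genome=genome)
        n_excluded = sum(len(v) for v in result.excluded.values())
        n_passed = sum(len(v) for v in result.passed.values())
        assert n_excluded == 8
        assert n_passed == 3
        for calls in result.excluded.values():
            for call in calls:
                assert call.filter_flags

    def test_pass_and_excluded_partition_the_input(self, genome):
        cohort = self._cohort_with_anchor(genome)
        cohort["z"] = [make_call(2600, 3.0, "z"), make_call(8000, 2.0, "z")]
        result = apply_filters(cohort, genome=genome)
        for sample, calls in cohort.items():
            merged = result.passed[sample] + result.excluded[sample]
            assert sorted(c.position for c in merged) == \
                   sorted(c.position for c in calls)
            assert not (set(map(id, result.passed[sample]))
                        & set(map(id, result.excluded[sample])))

    def test_idempotence_on_the_pass_set(self, genome):
        cohort = self._cohort_with_anchor(genome)
        first = apply_filters(cohort, genome=genome)
        second = apply_filters(first.passed, genome=genome)
        assert second.audit["n_excluded"] == 0
        assert second.audit["n_pass"] == first.audit["n_pass"]

    def test_audit_counts_match_independent_tally(self, genome):
        cohort = self._cohort_with_anchor(genome)
        cohort["z"] = [make_call(2600, 3.0, "z")]
        result = apply_filters(cohort, genome=genome)
        tally = {}
        for calls in result.excluded.values():
            for call in calls:
                for kind in call.filter_flags:
                    tally[kind] = tally.get(kind, 0) + 1
        assert result.audit["excluded_by_kind"] == tally

    def test_empty_call_set_yields_empty_outputs(self, genome):
        result = apply_filters({}, genome=genome)
        assert result.audit["n_pass"] == 0
        assert result.audit["n_excluded"] == 0
        assert result.flags == []

    def test_unknown_config_key_raises(self, tmp_path):
        path = tmp_path / "filters.yaml"
        path.write_text("min_samples: 8\nnot_a_filter: 1\n")
        with pytest.raises(ConfigError):
            FilterConfig.from_yaml(path)

    def test_config_round_trip_from_yaml(self, tmp_path):
        path = tmp_path / "filters.yaml"
        path.write_text("min_samples: 5\nzones: [[100, 200]]\n")
        config = FilterConfig.from_yaml(path)
        assert config.min_samples == 5
        assert config.zones == ((100, 200),)
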