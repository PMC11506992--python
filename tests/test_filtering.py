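"""Threshold filtering, chromosome lengths, display windows."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genotracks import (
    ChromosomeLengths,
    ChromosomeLimits,
    GenotracksError,
    Thresholds,
    apply_chrom_limits,
    apply_threshold,
    compute_chrom_length,
    filter_tables,
    remove_empty_chromosomes,
    validate_table,
)
from genotracks.filtering import read_chrom_lengths_csv, read_chrom_limits


def _gwas(scores, chrom="1"):
    return validate_table(
        pd.DataFrame(
            {
                "chromosome": [chrom] * len(scores),
                "position": range(10, 10 + len(scores)),
                "score": scores,
            }
        ),
        "gwas",
    )


class TestApplyThreshold:
    def test_keeps_at_and_above_threshold_drops_missing(self):
        out = apply_threshold(_gwas([0.5, 1.3, 2.0, None, 4.0]), 1.3)
        assert list(out.data["score"]) == [1.3, 2.0, 4.0]

    def test_zero_thresholds_keep_everything_non_missing(self, de_table):
        out = apply_threshold(de_table, 0.0, 0.0)
        # the row with missing padj (hence missing score) is excluded
        assert len(out) == 2

    def test_empty_table_stays_empty(self):
        out = apply_threshold(_gwas([]), 1.3)
        assert len(out) == 0

    def test_de_missing_log2fc_excluded_even_with_good_score(self):
        ft = validate_table(
            pd.DataFrame(
                {
                    "chromosome": ["1", "1"],
                    "start": [1, 5],
                    "end": [2, 6],
                    "score": [5.0, 5.0],
                    "log2FoldChange": [None, 1.0],
                }
            ),
            "de",
        )
        out = apply_threshold(ft, 1.0, 0.0)
        assert len(out) == 1

    def test_log2fc_threshold_is_two_sided(self, de_table):
        out = apply_threshold(de_table, 0.0, 1.6)
        assert list(out.data["log2fc"]) == [-2.0]  # |−2| ≥ 1.6, |1.5| < 1.6

    def test_candidate_tables_pass_through(self, candidate_table):
        assert apply_threshold(candidate_table, 100.0) is candidate_table

    def test_infinite_score_always_passes(self):
        ft = validate_table(
            pd.DataFrame({"chromosome": ["1"], "position": [1], "padj": [0.0]}), "gwas"
        )
        assert len(apply_threshold(ft, 1e9)) == 1

    @given(
        scores=st.lists(
            st.one_of(st.floats(min_value=0, max_value=10), st.just(float("nan"))),
            max_size=30,
        ),
        t1=st.floats(min_value=0, max_value=10),
        t2=st.floats(min_value=0, max_value=10),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_idempotent_subset(self, scores, t1, t2):
        table = _gwas(scores)
        lo, hi = sorted((t1, t2))
        a, b = apply_threshold(table, lo), apply_threshold(table, hi)
        # raising the threshold never retains more
        assert len(b) <= len(a)
        # idempotence at a fixed threshold
        pd.testing.assert_frame_equal(apply_threshold(a, lo).data, a.data)
        # subset of the input, original order
        assert a.data.index.isin(table.data.index).all()
        assert list(a.data.index) == sorted(a.data.index)


class TestThresholds:
    def test_negative_log2fc_threshold_rejected(self):
        with pytest.raises(ValueError):
            Thresholds(log2fc_thr=-1)

    def test_per_track_override(self):
        tables = [_gwas([1.0, 3.0]), _gwas([1.0, 3.0])]
        out = filter_tables(tables, Thresholds(score_thr_gwas=2.0), per_track_thr={1: 0.5})
        assert [len(t) for t in out] == [1, 2]


class TestChromLength:
    def test_max_over_positions_and_ends(self, gwas_table, de_table):
        lengths = compute_chrom_length([gwas_table, de_table])
        assert lengths["1"] == 700  # DE end 700 beats GWAS position 500
        assert lengths["2"] == 90
        assert lengths["10"] == 7

    def test_singleton(self):
        assert compute_chrom_length([_gwas([1.0])])["1"] == 10

    def test_all_empty_raises(self):
        with pytest.raises(GenotracksError, match="no features"):
            compute_chrom_length([_gwas([])])

    def test_user_lengths_override_listed_chromosomes(self, gwas_table):
        lengths = compute_chrom_length([gwas_table]).with_user_lengths({"1": 1_000_000})
        assert lengths["1"] == 1_000_000
        assert lengths["2"] == 90  # untouched

    def test_natural_order(self, gwas_table):
        assert compute_chrom_length([gwas_table]).chromosomes == ["1", "2", "10"]

    @given(
        data=st.lists(
            st.tuples(st.sampled_from(["1", "2", "3"]), st.integers(0, 10**6)),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_max(self, data):
        df = pd.DataFrame(data, columns=["chromosome", "position"])
        df["score"] = 1.0
        lengths = compute_chrom_length([validate_table(df, "gwas")])
        brute = {}
        for c, p in data:
            brute[c] = max(brute.get(c, 0), p)
        assert lengths.entries == {c: float(v) for c, v in brute.items()}


class TestChromLimits:
    def test_window_is_closed_and_per_chromosome(self):
        t = validate_table(
            pd.DataFrame(
                {
                    "chromosome": ["5", "5", "5", "7"],
                    "position": [2.1e6, 3e6, 2.5e6, 9e6],
                    "score": [1, 1, 1, 1],
                }
            ),
            "gwas",
        )
        limits = ChromosomeLimits({"5": (2e6, 2.5e6)})
        (out,) = apply_chrom_limits([t], limits)
        assert list(out.data["position"]) == [2.1e6, 2.5e6, 9e6]  # boundary kept, chr7 untouched

    def test_empty_limits_is_identity(self, gwas_table):
        (out,) = apply_chrom_limits([gwas_table], ChromosomeLimits({}))
        pd.testing.assert_frame_equal(out.data, gwas_table.data)

    def test_full_length_window_is_identity(self, gwas_table):
        lengths = compute_chrom_length([gwas_table])
        limits = ChromosomeLimits({"1": (0, lengths["1"])})
        (out,) = apply_chrom_limits([gwas_table], limits)
        pd.testing.assert_frame_equal(out.data, gwas_table.data)

    def test_unknown_chromosome_warns_and_is_ignored(self, gwas_table):
        with pytest.warns(UserWarning, match="unknown chromosome"):
            (out,) = apply_chrom_limits([gwas_table], ChromosomeLimits({"99": (0, 10)}))
        pd.testing.assert_frame_equal(out.data, gwas_table.data)

    @pytest.mark.parametrize("window", [(-1, 5), (10, 10), (10, 5)])
    def test_invalid_windows_rejected(self, window):
        with pytest.raises(ValueError):
            ChromosomeLimits({"1": window})

    def test_limited_positions_all_inside_window(self, sim_small):
        limits = ChromosomeLimits({"3": (14e6, 16e6), "10": (48e6, 49.5e6)})
        out = apply_chrom_limits([sim_small.gwas, sim_small.de], limits)
        for t in out:
            for c, (lo, hi) in limits.entries.items():
                pos = t.data.loc[t.data["chromosome"] == c, "position"]
                assert ((pos >= lo) & (pos <= hi)).all()


class TestRemoveEmptyChromosomes:
    def test_only_occupied_chromosomes_survive(self):
        t5, t10 = _gwas([5.0], chrom="5"), _gwas([5.0], chrom="10")
        lengths = ChromosomeLengths({str(i): 100.0 for i in range(1, 13)})
        _, out = remove_empty_chromosomes([t5, t10], lengths)
        assert out.chromosomes == ["5", "10"]

    def test_identity_when_every_chromosome_occupied(self, gwas_table):
        lengths = compute_chrom_length([gwas_table])
        _, out = remove_empty_chromosomes([gwas_table], lengths)
        assert out.chromosomes == lengths.chromosomes

    def test_no_records_removes_all_facets(self):
        lengths = ChromosomeLengths({"1": 100.0})
        _, out = remove_empty_chromosomes([_gwas([])], lengths)
        assert len(out) == 0


class TestConfigFiles:
    def test_lengths_csv(self, tmp_path):
        p = tmp_path / "len.csv"
        p.write_text("chromosome,length\n1,1000\n2,2000\n")
        assert read_chrom_lengths_csv(p) == {"1": 1000.0, "2": 2000.0}

    def test_limits_json_and_csv_agree(self, tmp_path):
        j = tmp_path / "lim.json"
        j.write_text('{"5": [2e6, 2.5e6], "8": [53e6, 53.5e6]}')
        c = tmp_path / "lim.csv"
        c.write_text("chromosome,min,max\n5,2e6,2.5e6\n8,53e6,53.5e6\n")
        assert read_chrom_limits(j).entries == read_chrom_limits(c).entries
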