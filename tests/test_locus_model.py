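"""Domain types, table I/O, diploid filtering and count summaries."""

import numpy as np
import pytest

from xescape import locus_model as lm
from xescape.locus_model import (
    CountSummary,
    NucleusScore,
    Sex,
    filter_diploid,
    load_fixture,
    load_locus_map,
    percentages_to_counts,
    read_nucleus_table,
    summarize_counts,
    table2_female_summaries,
    write_nucleus_table,
)
from xescape.synthetic import LocusSim, SimConfig, simulate_single_locus


def _score(nid=0, test=1, control=2, sex=Sex.FEMALE, locus="LRCH2"):
    return NucleusScore(nid, "ind1", sex, locus, test, control)


class TestValidation:
    def test_signal_counts_outside_0_2_rejected(self):
        with pytest.raises(ValueError, match="test_signals=3"):
            _score(test=3)

    def test_locus_meta_requires_genes_and_positive_position(self):
        with pytest.raises(ValueError):
            lm.LocusMeta("L1", genes=())
        with pytest.raises(ValueError):
            lm.LocusMeta("L1", genes=("G",), x_position=0)

    def test_count_summary_partition_enforced(self):
        with pytest.raises(ValueError):
            CountSummary("L", n_scored=10, n2=5, n1=4, n0=2)


class TestNucleusTableIO:
    def test_round_trip_preserves_records(self, tmp_path):
        cfg = SimConfig(
            loci=(LocusSim("LRCH2", 0.05, 0.96),), n_nuclei=100, seed=1
        )
        records = simulate_single_locus(cfg)
        path = tmp_path / "nuclei.tsv"
        write_nucleus_table(records, path)
        back = read_nucleus_table(path)
        assert back == records
        assert len(back) == 100

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("nucleus_id\tsex\n1\tmale\n")
        with pytest.raises(lm.TableFormatError, match="missing column"):
            read_nucleus_table(path)

    def test_out_of_range_row_is_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "nucleus_id\tindividual_id\tsex\tlocus_id\ttest_signals\tcontrol_signals\n"
            "1\ta\tfemale\tL\t1\t2\n"
            "2\ta\tfemale\tL\t3\t2\n"
        )
        with pytest.raises(lm.TableValidationError, match="row 2"):
            read_nucleus_table(path)
        with pytest.warns(UserWarning, match="dropped 1"):
            kept = read_nucleus_table(path, permissive=True)
        assert len(kept) == 1


class TestDiploidFilter:
    def test_keeps_exactly_control_two(self):
        scores = [_score(i, control=c) for i, c in enumerate([2] * 97 + [1, 0, 0])]
        assert len(filter_diploid(scores)) == 97

    def test_empty_when_no_diploid_nuclei(self):
        assert filter_diploid([_score(i, control=0) for i in range(5)]) == []

    def test_idempotent(self):
        scores = [_score(i, control=c) for i, c in enumerate([2, 1, 2, 0])]
        once = filter_diploid(scores)
        assert filter_diploid(once) == once

    def test_retained_fraction_matches_control_detection_squared(self):
        cfg = SimConfig(
            loci=(LocusSim("L", 0.2, 0.95),),
            n_nuclei=1000,
            control_detection=0.97,
            seed=7,
        )
        scores = simulate_single_locus(cfg)
        frac = len(filter_diploid(scores)) / len(scores)
        p = 0.97**2
        se = np.sqrt(p * (1 - p) / 1000)
        assert abs(frac - p) < 3 * se

    def test_male_two_signal_nuclei_flagged_not_dropped(self):
        scores = [_score(0, test=2, sex=Sex.MALE), _score(1, test=1, sex=Sex.MALE)]
        with pytest.warns(UserWarning, match="two test signals"):
            kept = filter_diploid(scores)
        assert len(kept) == 2


class TestSummaries:
    def test_lrch2_like_counts_round_to_published_percentages(self):
        s = CountSummary("LRCH2", n_scored=97, n2=5, n1=90, n0=2)
        f2, f1, f0 = s.fractions
        assert (round(100 * f2, 1), round(100 * f1, 1), round(100 * f0, 1)) == (
            5.2, 92.8, 2.1,
        )

    def test_single_two_signal_nucleus(self):
        s = summarize_counts([_score(test=2)], "LRCH2")
        assert (s.n2, s.n1, s.n0) == (1, 0, 0)

    def test_no_escape_perfect_detection_gives_all_single(self):
        cfg = SimConfig(
            loci=(LocusSim("L", 0.0, 1.0),), n_nuclei=50,
            control_detection=1.0, seed=3,
        )
        s = summarize_counts(filter_diploid(simulate_single_locus(cfg)), "L")
        assert s.n1 == s.n_scored

    def test_unknown_locus_raises_no_data(self):
        with pytest.raises(lm.NoDataError):
            summarize_counts([_score()], "ATRX")

    @pytest.mark.parametrize("summary", table2_female_summaries())
    def test_fixture_percentages_sum_to_100_within_rounding(self, summary):
        f2, f1, f0 = summary.fractions
        assert abs(100 * (f2 + f1 + f0) - 100) <= 0.2


class TestPercentApportionment:
    @pytest.mark.parametrize(
        "pcts, expected",
        [
            ((5.2, 92.8, 2.1), (5, 93, 2)),
            ((67.8, 32.2, 0.0), (68, 32, 0)),
            ((59.8, 39.2, 1.0), (60, 39, 1)),
            ((23.5, 73.5, 3.1), (24, 73, 3)),
        ],
    )
    def test_largest_remainder_counts(self, pcts, expected):
        assert percentages_to_counts(pcts, n=100) == expected

    def test_counts_always_sum_to_n(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            raw = rng.dirichlet([1, 1, 1]) * 100
            pcts = np.round(raw, 1)
            if pcts.sum() > 100.2:
                continue
            assert sum(percentages_to_counts(pcts, n=100)) == 100


class TestFixtures:
    def test_fixture_shapes(self):
        assert len(load_fixture("table2")) == 23
        assert len(load_fixture("table1")) == 25
        assert len(load_fixture("table4")) == 4
        assert len(load_locus_map()) == 25

    def test_unexpressed_probes_carry_zero_percent(self):
        t1 = load_fixture("table1").set_index("locus_id")
        assert t1.loc["F9", "pct_one_signal"] == 0
        assert t1.loc["PLP1", "pct_one_signal"] == 0

    def test_unknown_fixture_name(self):
        with pytest.raises(KeyError):
            load_fixture("table9")

    def test_locus_map_positions_strictly_increasing(self):
        pos = [m.x_position for m in load_locus_map()]
        assert all(a < b for a, b in zip(pos, pos[1:]))
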