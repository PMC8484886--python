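"""Cohort I/O, score recoding and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twinlate as tl
from twinlate.errors import DomainError, IntegrityError, SchemaError

from conftest import make_cohort

CSV_HEADER = (
    "person_id,wave,age_at_wave,score,family_id,zygosity,study,sex,"
    "birth_year,education,isei,illness,apoe_e4,dementia,event_age"
)


def _toy_csv(tmp_path, rows, name="cohort.csv", header=CSV_HEADER):
    path = tmp_path / name
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


def _standard_rows():
    rows = []
    for f, zyg in [(1, "MZ"), (2, "DZ")]:
        for i in range(2):
            pid = f"P{f}{i}"
            for w in range(1, 4):
                rows.append(
                    f"{pid},{w},{70 + 3 * w},{(w + i) % 4},F{f},{zyg},SATSA,F,"
                    f"1920,2,45.0,2.0,1,0,85.0"
                )
    return rows


class TestLoadCohort:
    def test_counts_from_fixture(self, tmp_path):
        cohort = tl.load_cohort(_toy_csv(tmp_path, _standard_rows()))
        assert cohort.n_individuals == 4
        assert len(cohort.observations) == 12
        assert cohort.n_pairs == 2

    def test_missing_column_names_it(self, tmp_path):
        header = CSV_HEADER.replace("zygosity,", "")
        rows = [r.replace(",MZ", "").replace(",DZ", "") for r in _standard_rows()]
        with pytest.raises(SchemaError, match="zygosity"):
            tl.load_cohort(_toy_csv(tmp_path, rows, header=header))

    def test_duplicate_person_wave_rejected(self, tmp_path):
        rows = _standard_rows()
        rows.append(rows[0])
        with pytest.raises(IntegrityError, match="duplicate"):
            tl.load_cohort(_toy_csv(tmp_path, rows))

    def test_unparseable_ids_reported_with_line_numbers(self, tmp_path):
        rows = _standard_rows()
        rows.insert(2, rows[0].replace("P10", "", 1))
        cohort = tl.load_cohort(_toy_csv(tmp_path, rows))
        assert cohort.rejected_lines == [4]  # header is line 1
        assert cohort.n_individuals == 4

    def test_round_trip_is_exact(self, tmp_path):
        path = _toy_csv(tmp_path, _standard_rows())
        cohort = tl.load_cohort(path)
        out = tmp_path / "again.csv"
        tl.write_cohort(cohort, out)
        again = tl.load_cohort(out)
        pd.testing.assert_frame_equal(cohort.individuals, again.individuals)
        pd.testing.assert_frame_equal(cohort.observations, again.observations)

    def test_schema_mapping_renames_columns(self, tmp_path):
        header = CSV_HEADER.replace("score", "lonely")
        path = _toy_csv(tmp_path, _standard_rows(), header=header)
        cohort = tl.load_cohort(path, schema={"score": "lonely"})
        assert cohort.n_individuals == 4


class TestReverseScore:
    @pytest.mark.parametrize("raw,expected", [(4, 0), (1, 3), (2, 2), (3, 1)])
    def test_reversal(self, raw, expected):
        assert tl.reverse_score_loneliness(raw) == expected

    @pytest.mark.parametrize("raw", [0, 5, -1, 2.5])
    def test_out_of_range(self, raw):
        with pytest.raises(DomainError):
            tl.reverse_score_loneliness(raw)

    @given(st.integers(min_value=0, max_value=3))
    @settings(deadline=None)
    def test_involution_through_relabeling(self, s):
        # analysis score -> raw response -> analysis score is the identity
        assert tl.reverse_score_loneliness(4 - s) == s

    def test_vectorised(self):
        out = tl.reverse_score_loneliness(np.array([1, 2, 3, 4]))
        assert list(out) == [3, 2, 1, 0]


class TestSummarize:
    def test_constant_scores_degenerate_t(self):
        ind, obs = [], []
        for f in (1, 2):
            for i in range(2):
                pid = f"P{f}{i}"
                ind.append((pid, f"F{f}", "MZ", "SATSA", "F", 1920, 2, 45.0,
                            2.0, 0, 0, 85.0))
                obs += [(pid, w, 70 + 3 * w, 1) for w in (1, 2, 3)]
        s = tl.summarize_cohort(make_cohort(ind, obs))
        assert s.paired_t_statistic == 0.0
        assert s.t_degenerate

    def test_two_person_means(self):
        ind = [
            ("A", "F1", "MZ", "SATSA", "F", 1920, 2, 45.0, 2.0, 0, 0, 85.0),
            ("B", "F2", "DZ", "OCTO", "M", 1921, 2, 45.0, 2.0, 0, 1, 88.0),
        ]
        obs = [("A", 1, 70.0, 0), ("A", 2, 73.0, 1),
               ("B", 1, 71.0, 1), ("B", 2, 74.0, 2)]
        s = tl.summarize_cohort(make_cohort(ind, obs))
        assert s.mean_baseline_loneliness == pytest.approx(0.5)
        assert s.mean_last_loneliness == pytest.approx(1.5)

    def test_paired_t_matches_direct_formula(self):
        # 10-person fixture; oracle is mean(d) / (sd(d) / sqrt(n))
        rng = np.random.default_rng(17)
        ind, obs, diffs = [], [], []
        for i in range(10):
            pid = f"P{i}"
            ind.append((pid, f"F{i}", "MZ", "SATSA", "F", 1920, 2, 45.0, 2.0,
                        0, 0, 85.0))
            b, l = int(rng.integers(0, 4)), int(rng.integers(0, 4))
            obs += [(pid, 1, 70.0, b), (pid, 2, 75.0, l)]
            diffs.append(l - b)
        d = np.array(diffs, dtype=float)
        oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        s = tl.summarize_cohort(make_cohort(ind, obs))
        assert s.paired_t_statistic == pytest.approx(oracle, abs=1e-12)

    def test_no_missing_baseline_counts_everyone(self, toy_cohort):
        s = tl.summarize_cohort(toy_cohort)
        assert s.n_individuals == 4
        base = toy_cohort.baseline_table()
        assert len(base) == 4

    def test_empty_cohort_errors(self):
        with pytest.raises(Exception):
            tl.summarize_cohort(make_cohort([], []))


class TestValidation:
    def test_bad_zygosity(self):
        ind = [("A", "F1", "XX", "SATSA", "F", 1920, 2, 45.0, 2.0, 0, 0, 85.0)]
        with pytest.raises(IntegrityError, match="zygosity"):
            make_cohort(ind, [("A", 1, 70.0, 1)])

    def test_pair_zygosity_mismatch(self):
        ind = [
            ("A", "F1", "MZ", "SATSA", "F", 1920, 2, 45.0, 2.0, 0, 0, 85.0),
            ("B", "F1", "DZ", "SATSA", "F", 1920, 2, 45.0, 2.0, 0, 0, 85.0),
        ]
        with pytest.raises(IntegrityError, match="zygosity"):
            make_cohort(ind, [("A", 1, 70.0, 1), ("B", 1, 70.0, 1)])

    def test_score_out_of_range(self):
        ind = [("A", "F1", "MZ", "SATSA", "F", 1920, 2, 45.0, 2.0, 0, 0, 85.0)]
        with pytest.raises(IntegrityError, match="score"):
            make_cohort(ind, [("A", 1, 70.0, 7)])
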