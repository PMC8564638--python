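import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ctscreen as cs
from ctscreen.errors import (
    InputFormatError,
    ReferentialIntegrityError,
    ValidationError,
)


def matrix_from(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return cs.ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples))


class TestExpressionMatrixIO:
    def test_read_well_formed(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text("probeset_id\ts1\ts2\np1\t1.0\t2.0\np2\t3.0\t4.0\np3\t5.5\t6.5\n")
        m = cs.read_expression_matrix(f)
        assert list(m.probeset_ids) == ["p1", "p2", "p3"]
        assert list(m.sample_ids) == ["s1", "s2"]
        assert m.data.loc["p3", "s2"] == 6.5

    def test_duplicate_sample_header_is_named(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text("probeset_id\ts1\ts1\np1\t1\t2\np2\t3\t4\n")
        with pytest.raises(InputFormatError, match="s1"):
            cs.read_expression_matrix(f)

    def test_non_numeric_cell_rejected(self, tmp_path):
        f = tmp_path / "m.tsv"
        f.write_text("probeset_id\ts1\ts2\np1\t1.0\tabc\np2\t3\t4\n")
        with pytest.raises(InputFormatError):
            cs.read_expression_matrix(f)

    def test_round_trip_is_byte_stable(self, tmp_path, default_dataset):
        f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        cs.write_expression_matrix(default_dataset.matrix, f1)
        cs.write_expression_matrix(cs.read_expression_matrix(f1), f2)
        assert f1.read_bytes() == f2.read_bytes()

    @pytest.mark.parametrize(
        "bad",
        [
            [[np.nan, 1.0], [2.0, 3.0]],
            [[np.inf, 1.0], [2.0, 3.0]],
        ],
    )
    def test_non_finite_values_rejected(self, bad):
        with pytest.raises(ValidationError):
            matrix_from(bad)

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValidationError):
            matrix_from([[1.0, 2.0]])


class TestSampleAnnotationIO:
    def test_valid_annotation_parses(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text(
            "sample_id\tgroup_id\tcategory\tmatched_normal\tlabel\n"
            "t1\ttestis\tTARGET\t\ttestis\n"
            "n1\tliver\tNORMAL\t\tliver\n"
            "n2\tbrain\tNORMAL\t\tbrain\n"
            "c1\thcc\tCANCER\tliver\tliver cancer\n"
        )
        a = cs.read_sample_annotation(f)
        assert a.groups_of("NORMAL") == ["liver", "brain"]
        assert a.matched_normal("hcc") == "liver"

    def test_cancer_matched_to_target_rejected(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text(
            "sample_id\tgroup_id\tcategory\tmatched_normal\tlabel\n"
            "t1\ttestis\tTARGET\t\t\n"
            "n1\tliver\tNORMAL\t\t\n"
            "c1\thcc\tCANCER\ttestis\t\n"
        )
        with pytest.raises(ReferentialIntegrityError):
            cs.read_sample_annotation(f)

    def test_unknown_category_rejected(self, tmp_path):
        f = tmp_path / "s.tsv"
        f.write_text(
            "sample_id\tgroup_id\tcategory\tmatched_normal\tlabel\n"
            "t1\ttestis\tGERM\t\t\n"
            "n1\tliver\tNORMAL\t\t\n"
        )
        with pytest.raises(ValidationError):
            cs.read_sample_annotation(f)

    def test_simulator_annotation_round_trips(self, tmp_path, default_dataset):
        f = tmp_path / "s.tsv"
        cs.write_sample_annotation(default_dataset.samples, f)
        a = cs.read_sample_annotation(f)
        assert set(a.samples.index) == set(default_dataset.samples.samples.index)
        pd.testing.assert_frame_equal(
            a.groups.sort_index(), default_dataset.samples.groups.sort_index()
        )


class TestGlobalThresholds:
    def test_constant_matrix_degenerates(self):
        m = matrix_from(np.full((3, 4), 5.0))
        t = cs.compute_global_thresholds(m)
        assert (t.bec, t.q_low, t.q_high) == (5.0, 5.0, 5.0)

    def test_two_by_four_matrix_matches_rank_interpolation(self):
        # brute-force linear interpolation between closest ranks of {1..8}
        def pct(sorted_vals, p):
            h = (len(sorted_vals) - 1) * p
            lo = int(np.floor(h))
            hi = int(np.ceil(h))
            return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

        vals = list(range(1, 9))
        m = matrix_from(np.array(vals, dtype=float).reshape(2, 4))
        t = cs.compute_global_thresholds(m)
        assert t.q_low == pct(vals, 0.25)
        assert t.bec == pct(vals, 0.50)
        assert t.q_high == pct(vals, 0.75)

    def test_invariant_violating_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            cs.GlobalThresholds(bec=4.0, q_low=5.0, q_high=6.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_ordering_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = matrix_from(rng.normal(5, 2, size=(4, 5)))
        t = cs.compute_global_thresholds(m)
        assert t.q_low <= t.bec <= t.q_high
        perm = matrix_from(
            m.values[rng.permutation(4)][:, rng.permutation(5)]
        )
        assert cs.compute_global_thresholds(perm) == t


class TestGroupSummaries:
    def test_median_of_known_group(self):
        m = matrix_from([[4.0, 6.0, 8.0, 1.0], [2.0, 2.0, 2.0, 9.0]],
                        samples=["g1_a", "g1_b", "g1_c", "g2_a"])
        samples = pd.DataFrame(
            {"group_id": ["g1", "g1", "g1", "g2"]},
            index=["g1_a", "g1_b", "g1_c", "g2_a"],
        )
        groups = pd.DataFrame(
            {"category": ["NORMAL", "TARGET"], "matched_normal": ["", ""], "label": ["", ""]},
            index=["g1", "g2"],
        )
        annot = cs.SampleAnnotation(samples=samples, groups=groups)
        s = cs.group_summaries(m, annot)
        assert s.loc["p0", "g1"] == 6.0       # median of {4, 6, 8}
        assert s.loc["p0", "g2"] == 1.0       # single-sample group
        assert s.loc["p1", "g1"] == 2.0

    def test_matches_per_cell_brute_force(self, default_dataset):
        ds = default_dataset
        sub = ds.matrix.data.iloc[:20]
        s = cs.group_summaries(ds.matrix, ds.samples)
        for p in sub.index:
            for g in ds.samples.groups.index[:12]:
                cells = sorted(
                    ds.matrix.data.loc[p, ds.samples.samples_in_group(g)].tolist()
                )
                n = len(cells)
                med = cells[n // 2] if n % 2 else (cells[n // 2 - 1] + cells[n // 2]) / 2
                assert s.loc[p, g] == pytest.approx(med, abs=1e-12)

    def test_invariant_to_sample_order_within_group(self, default_dataset):
        ds = default_dataset
        rng = np.random.default_rng(1)
        cols = list(ds.matrix.sample_ids)
        rng.shuffle(cols)
        shuffled = cs.ExpressionMatrix(ds.matrix.data[cols])
        pd.testing.assert_frame_equal(
            cs.group_summaries(shuffled, ds.samples),
            cs.group_summaries(ds.matrix, ds.samples),
        )
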