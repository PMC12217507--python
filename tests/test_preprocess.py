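import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from paragi import (
    CountMatrix,
    FoldChangeTable,
    LibraryAnnotation,
    ReferenceSets,
    aggregate_gene_lfc,
    guide_lfc,
    normalize_counts,
    qc_cohens_d,
)
from paragi.preprocess import pooled_cohens_d


def _cm(cols: dict, arrays=None) -> CountMatrix:
    arrays = arrays or [f"a{i}" for i in range(len(next(iter(cols.values()))))]
    return CountMatrix(pd.DataFrame(cols, index=arrays), "T0")


class TestNormalize:
    def test_hand_example(self):
        # (5,5,10) + pc 5 -> (10,10,15); /35 * depth 10
        cm = _cm({"T0": [5, 5, 10], "D": [5, 5, 10]})
        out = normalize_counts(cm, pseudocount=5, depth=10)
        np.testing.assert_allclose(
            out["T0"], [2.857142857142857, 2.857142857142857,
                        4.285714285714286])

    def test_zero_pseudocount_depth_equal_colsum_is_identity(self):
        cm = _cm({"T0": [5, 5, 10], "D": [2, 3, 15]})
        out = normalize_counts(cm, pseudocount=0, depth=20)
        np.testing.assert_allclose(out["T0"], [5, 5, 10])
        np.testing.assert_allclose(out["D"], [2, 3, 15])

    def test_columns_sum_to_fixed_depth(self):
        rng = np.random.default_rng(0)
        cm = _cm({"T0": rng.integers(0, 1000, 50),
                  "D": rng.integers(0, 1000, 50)})
        out = normalize_counts(cm)  # defaults: pc 5, depth 1e7
        np.testing.assert_allclose(out.sum(axis=0), [1e7, 1e7], rtol=1e-12)

    def test_all_zero_column_without_pseudocount_errors(self):
        cm = _cm({"T0": [0, 0], "D": [1, 1]})
        with pytest.raises(ValueError, match="zero total"):
            normalize_counts(cm, pseudocount=0)

    @given(st.integers(1, 6))
    def test_idempotent_on_normalized_matrix(self, n):
        """Depth-normalizing an already-normalized matrix (pc 0) is the
        identity."""
        rng = np.random.default_rng(n)
        cm = _cm({"T0": rng.integers(1, 100, 8), "D": rng.integers(1, 100, 8)})
        once = normalize_counts(cm, pseudocount=0, depth=1e7)
        twice = (once / once.sum(axis=0)) * 1e7
        np.testing.assert_allclose(once, twice, rtol=1e-12)


class TestGuideLfc:
    def test_endpoint_equal_t0_gives_zero(self):
        norm = pd.DataFrame({"T0": [3.0, 7.0], "D": [3.0, 7.0]},
                            index=["a", "b"])
        assert guide_lfc(norm, "T0").tolist() == [0.0, 0.0]

    def test_doubling_gives_lfc_one(self):
        norm = pd.DataFrame({"T0": [3.0], "D": [6.0]}, index=["a"])
        assert guide_lfc(norm, "T0").iloc[0] == pytest.approx(1.0)

    def test_replicate_endpoints_averaged_at_lfc_level(self):
        # per-endpoint LFCs -1 and -3 -> combined -2
        norm = pd.DataFrame({"T0": [4.0], "E1": [2.0], "E2": [0.5]},
                            index=["a"])
        assert guide_lfc(norm, "T0").iloc[0] == pytest.approx(-2.0)

    def test_zero_t0_guarded(self):
        norm = pd.DataFrame({"T0": [0.0], "D": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="T0"):
            guide_lfc(norm, "T0")

    @given(st.floats(-4, 4))
    def test_location_equivariance(self, c):
        """Scaling all endpoint counts by 2^c shifts every LFC by c."""
        rng = np.random.default_rng(0)
        base = pd.DataFrame({"T0": rng.uniform(1, 100, 10),
                             "D": rng.uniform(1, 100, 10)})
        shifted = base.copy()
        shifted["D"] = shifted["D"] * 2.0 ** c
        np.testing.assert_allclose(
            guide_lfc(shifted, "T0"), guide_lfc(base, "T0") + c, atol=1e-9)


class TestAggregate:
    def _fct(self, lfcs, arrays):
        return FoldChangeTable(
            guide=pd.DataFrame({"s1": lfcs}, index=arrays))

    def test_mean_of_three_guides(self):
        ann = LibraryAnnotation.from_records(
            [(f"g{i}", "G", None, "none") for i in range(3)])
        fct = aggregate_gene_lfc(self._fct([-1, -2, -3],
                                           ["g0", "g1", "g2"]), ann)
        assert fct.gene_value(("G",), "s1") == pytest.approx(-2.0)

    def test_pair_arrays_never_mix_with_singles(self):
        ann = LibraryAnnotation.from_records([
            ("s", "A", None, "none"),
            ("p", "A", "B", "none"),
        ])
        fct = aggregate_gene_lfc(self._fct([-1.0, -5.0], ["s", "p"]), ann)
        assert fct.gene_value(("A",), "s1") == pytest.approx(-1.0)
        assert fct.gene_value(("A", "B"), "s1") == pytest.approx(-5.0)

    def test_single_array_pair_is_identity(self):
        ann = LibraryAnnotation.from_records([("p", "A", "B", "none")])
        fct = aggregate_gene_lfc(self._fct([-0.7], ["p"]), ann)
        assert fct.gene_value(("A", "B"), "s1") == pytest.approx(-0.7)

    def test_grand_mean_preserved_within_target_set(self):
        rng = np.random.default_rng(1)
        lfcs = rng.normal(size=6)
        ann = LibraryAnnotation.from_records(
            [(f"g{i}", "G", None, "none") for i in range(6)])
        fct = aggregate_gene_lfc(self._fct(lfcs, [f"g{i}" for i in range(6)]),
                                 ann)
        assert fct.gene_value(("G",), "s1") == pytest.approx(lfcs.mean())

    def test_unannotated_array_is_error(self):
        ann = LibraryAnnotation.from_records([("known", "A", None, "none")])
        with pytest.raises(ValueError, match="missing from"):
            aggregate_gene_lfc(self._fct([0.0, 1.0], ["known", "ghost"]), ann)


class TestCohensD:
    def test_hand_computation(self):
        # ess (-3,-1), non (1,-1): means -2, 0; sample vars 2, 2
        # pooled sd = sqrt(((1)*2 + (1)*2) / 2) = sqrt(2); D = 2/sqrt(2)
        d = pooled_cohens_d(np.array([1.0, -1.0]), np.array([-3.0, -1.0]))
        assert d == pytest.approx(2.0 / math.sqrt(2.0))

    def test_degenerate_pooled_sd_is_undefined(self):
        assert pooled_cohens_d(np.array([0.0, 0.0]),
                               np.array([-2.0, -2.0, -2.0])) is None

    @given(st.floats(-5, 5))
    def test_shift_invariance_and_antisymmetry(self, c):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(1.0, 1.0, size=8)
        d = pooled_cohens_d(x, y)
        assert pooled_cohens_d(x + c, y + c) == pytest.approx(d)
        assert pooled_cohens_d(y, x) == pytest.approx(-d)

    def test_qc_report_from_controls(self):
        ann = LibraryAnnotation.from_records(
            [(f"e{i}", f"E{i}", None, "essential_ctrl") for i in range(3)]
            + [(f"n{i}", f"N{i}", None, "nonessential_ctrl")
               for i in range(3)])
        guide = pd.DataFrame(
            {"s1": [-3.0, -2.0, -1.0, 0.5, 0.0, -0.5]},
            index=[f"e{i}" for i in range(3)] + [f"n{i}" for i in range(3)])
        fct = aggregate_gene_lfc(FoldChangeTable(guide=guide), ann)
        refs = ReferenceSets()
        report = qc_cohens_d(fct, ann, refs, level="gene")
        # non mean 0 (var 0.25), ess mean -2 (var 1);
        # pooled sd = sqrt((2*1 + 2*0.25)/4) = sqrt(0.625)
        assert report.cohens_d["s1"] == pytest.approx(2.0 / math.sqrt(0.625))
        assert report.n_essential_ctrl == 3

    def test_qc_degenerate_flagged(self):
        ann = LibraryAnnotation.from_records(
            [(f"e{i}", f"E{i}", None, "essential_ctrl") for i in range(3)]
            + [(f"n{i}", f"N{i}", None, "nonessential_ctrl")
               for i in range(3)])
        guide = pd.DataFrame({"s1": [-2.0] * 3 + [0.0] * 3},
                             index=list(ann.table.index))
        fct = aggregate_gene_lfc(FoldChangeTable(guide=guide), ann)
        report = qc_cohens_d(fct, ann, ReferenceSets())
        assert report.cohens_d["s1"] is None
        assert "s1" in report.undefined
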