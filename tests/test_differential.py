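"""Fold changes, unpaired t-tests, volcano calls, enrichment input."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from msoxome.differential import (
    DOWN,
    NA,
    NS,
    UP,
    CrossBatchError,
    check_same_batch,
    differential_table,
    fold_change,
    select_enrichment_input,
    unpaired_t,
    volcano_classify,
)

from conftest import make_table


def pooled_t_pvalue(a, b):
    """Independent textbook oracle: pooled-variance two-sample t, two-sided."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    return 2.0 * special.stdtr(df, -abs(t))


class TestFoldChange:
    @pytest.mark.parametrize(
        "wt,fad,expected",
        [
            ([100, 100], [200, 200], 2.0),
            ([10, 20, 30], [10, 20, 30], 1.0),
            ([50, 150], [300, 100], 2.0),
            ([100, np.nan], [50, np.nan, 50], 0.5),  # missing excluded
        ],
    )
    def test_examples(self, wt, fad, expected):
        assert fold_change(wt, fad) == pytest.approx(expected)

    def test_all_missing_group_is_nan(self):
        assert np.isnan(fold_change([np.nan, np.nan], [1, 2]))


class TestUnpairedT:
    def test_identical_groups(self):
        assert unpaired_t([1, 2, 3], [1, 2, 3], on_log2=False) == pytest.approx(1.0)

    def test_matches_textbook_pooled_t(self):
        p = unpaired_t([1, 2, 3], [4, 5, 6], on_log2=False)
        assert p == pytest.approx(pooled_t_pvalue([1, 2, 3], [4, 5, 6]), abs=1e-12)

    def test_group_swap_symmetric(self):
        a, b = [1.0, 2.5, 3.0, 4.0], [2.0, 6.0, 7.0]
        assert unpaired_t(a, b) == pytest.approx(unpaired_t(b, a))

    def test_insufficient_n_gives_nan(self):
        assert np.isnan(unpaired_t([1, 2], [3, 4, 5]))

    def test_constant_equal_groups(self):
        assert unpaired_t([5, 5, 5], [5, 5, 5], on_log2=False) == 1.0

    def test_log2_requires_positive(self):
        with pytest.raises(ValueError):
            unpaired_t([0.0, 1, 2], [1, 2, 3], on_log2=True)

    @given(
        st.lists(st.floats(min_value=1, max_value=1e6), min_size=3, max_size=10),
        st.lists(st.floats(min_value=1, max_value=1e6), min_size=3, max_size=10),
        st.floats(min_value=0.001, max_value=1000),
    )
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, wt, fad, c):
        """Multiplying all AUC by c > 0 leaves fc ratio and p unchanged."""
        p1 = unpaired_t(wt, fad)
        p2 = unpaired_t([c * v for v in wt], [c * v for v in fad])
        if np.isnan(p1):
            assert np.isnan(p2)
        else:
            assert p2 == pytest.approx(p1, rel=1e-9)
        f1, f2 = fold_change(wt, fad), fold_change([c * v for v in wt], [c * v for v in fad])
        assert f2 == pytest.approx(f1, rel=1e-9)


class TestVolcano:
    @pytest.mark.parametrize(
        "fc,p,call",
        [
            (2.5, 0.05, UP),
            (2.0, 0.1, UP),  # boundary inclusive
            (1.0, 0.001, NS),
            (0.4, 0.09, DOWN),
            (0.5, 0.1, DOWN),
            (3.0, 0.2, NS),  # fails p
            (float("nan"), 0.01, NA),
        ],
    )
    def test_examples(self, fc, p, call):
        assert volcano_classify(fc, p) == call

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            volcano_classify(1.0, 0.5, fc_up=1.0, fc_down=2.0)

    @given(
        st.lists(st.floats(min_value=1, max_value=1e5), min_size=3, max_size=8),
        st.lists(st.floats(min_value=1, max_value=1e5), min_size=3, max_size=8),
    )
    @settings(max_examples=100, derandomize=True)
    def test_label_swap_antisymmetry(self, wt, fad):
        """Swapping groups maps fc → 1/fc and UP ↔ DOWN."""
        fc, p = fold_change(wt, fad), unpaired_t(wt, fad)
        fc_swapped = fold_change(fad, wt)
        assert fc_swapped == pytest.approx(1.0 / fc, rel=1e-9)
        if not np.isnan(p):
            swap = {UP: DOWN, DOWN: UP, NS: NS}
            assert volcano_classify(fc_swapped, p) == swap[volcano_classify(fc, p)]


class TestEnrichmentInput:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["peptidoform", "protein", "log2fc", "p"])

    def test_threshold_boundaries(self):
        res = self._results(
            [
                ("a", "P1", 4.2, 0.08),  # retained
                ("b", "P2", 3.9, 0.01),  # excluded: log2fc below 4
                ("c", "P3", 4.0, 0.1),  # retained: both boundaries inclusive
                ("d", "P4", 5.0, 0.2),  # excluded: p too large
            ]
        )
        out = select_enrichment_input(res)
        assert list(out["peptidoform"]) == ["a", "c"]

    def test_empty(self):
        out = select_enrichment_input(self._results([]))
        assert out.empty


class TestDifferentialTable:
    def test_cross_batch_guard(self, toy_design):
        with pytest.raises(CrossBatchError):
            check_same_batch(
                toy_design,
                toy_design.samples(timepoint="3m", genotype="WT"),
                toy_design.samples(timepoint="9m", genotype="WT"),
            )

    def test_within_batch_table(self, toy_design):
        samples = toy_design.samples(timepoint="3m")
        wt = toy_design.samples(timepoint="3m", genotype="WT")
        rows = []
        # planted 4x upregulation with tight replicate spread
        up_auc = [100, 110, 95, 105, 400, 410, 395, 420]
        flat_auc = [100, 104, 99, 101, 100, 103, 98, 102]
        rows.append(("A[M]KR", "P1", up_auc))
        rows.append(("C[M]KR", "P2", flat_auc))
        table = make_table(rows, samples)
        out = differential_table(table, toy_design, "3m")
        assert list(out["call"]) == [UP, NS]
        assert out.loc[0, "fc"] == pytest.approx(
            np.mean(up_auc[4:]) / np.mean(up_auc[:4])
        )
        assert out.loc[0, "n_wt"] == len(wt)
        # BH q never smaller than p
        assert (out["q"] >= out["p"] - 1e-15).all()

    def test_recovers_planted_effects(self, small_study):
        """Strongly oxidation-induced proteins come out UP at every batch."""
        from msoxome.speciation import extract_msox
        from msoxome.synthetic import study_table

        induced = set(
            small_study.truth.peptides.loc[
                small_study.truth.peptides["induced"], "protein"
            ]
        )
        table = extract_msox(study_table(small_study, "9m"))
        out = differential_table(table, small_study.design, "9m")
        # induced oxidized forms can fall below the LOD in wild-type mice;
        # the guarantee is for peptidoforms testable in both groups
        testable = out[(out["n_wt"] >= 3) & (out["n_fad"] >= 3)]
        induced_calls = testable.loc[testable["protein"].isin(induced), "call"]
        assert len(induced_calls) > 0
        assert (induced_calls == UP).all()
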