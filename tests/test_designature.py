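"""Cohort-specific DE filter cascade and signed-rank refinement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crconset.config import PipelineConfig
from crconset.designature import (
    UniqueGeneCall,
    call_significant,
    call_unique_degs,
    de_table_from_counts,
    normalize_counts,
    per_patient_lfc,
    refine_signature,
    size_factors,
)
from crconset.io import PairedExpressionMatrix
from crconset.simulate import (
    SimulationSpec,
    simulate_expression_with_signature,
    simulate_paired_counts,
)


def de_table(rows):
    """rows: {gene: (base_mean, lfc, padj)}"""
    return pd.DataFrame(
        [(g, *v) for g, v in rows.items()],
        columns=["gene_id", "base_mean", "lfc", "padj"],
    ).set_index("gene_id")


def _pair_meta(n, cohort="early", prefix="P"):
    rows = []
    for i in range(n):
        rows.append((f"{prefix}{i}_T", f"{prefix}{i}", "tumor", cohort))
        rows.append((f"{prefix}{i}_N", f"{prefix}{i}", "normal", cohort))
    return pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "tissue", "cohort"]
    ).set_index("sample_id")


class TestNormalization:
    def test_identical_columns_stay_identical(self):
        raw = pd.DataFrame({"P0_T": [10, 20, 30, 5], "P0_N": [10, 20, 30, 5]},
                           index=list("abcd"))
        expr = normalize_counts(raw, _pair_meta(1))
        assert np.allclose(expr.values["P0_T"], expr.values["P0_N"])

    def test_doubled_column_normalizes_back(self):
        # 5-gene median-of-ratios oracle: doubling a column doubles its factor
        raw = pd.DataFrame(
            {"P0_T": [10, 20, 30, 40, 50], "P0_N": [20, 40, 60, 80, 100]},
            index=list("abcde"),
        )
        sf = size_factors(raw)
        assert sf["P0_N"] / sf["P0_T"] == pytest.approx(2.0)
        expr = normalize_counts(raw, _pair_meta(1))
        assert np.allclose(expr.values["P0_T"], expr.values["P0_N"])

    def test_all_zero_gene_flagged(self):
        raw = pd.DataFrame(
            {"P0_T": [10, 0, 30], "P0_N": [10, 0, 30]}, index=list("abc")
        )
        with pytest.warns(UserWarning, match="all-zero"):
            expr = normalize_counts(raw, _pair_meta(1))
        assert expr.values.attrs["all_zero_genes"] == ["b"]
        assert expr.values.loc["b"].nunique() == 1

    def test_all_zero_sample_rejected(self):
        raw = pd.DataFrame({"P0_T": [1, 2], "P0_N": [0, 0]}, index=list("ab"))
        with pytest.raises(ValueError, match="P0_N"):
            normalize_counts(raw, _pair_meta(1))


class TestPerPatientLfc:
    def test_arithmetic(self):
        meta = _pair_meta(1)
        vals = pd.DataFrame({"P0_T": [5.0], "P0_N": [3.0]}, index=["g"])
        lfc = per_patient_lfc(PairedExpressionMatrix(vals, meta))
        assert lfc.loc["g", "P0"] == 2.0

    def test_equal_tissues_give_zero(self):
        meta = _pair_meta(2)
        vals = pd.DataFrame(
            {c: [4.0, 7.0] for c in meta.index}, index=["g1", "g2"]
        )
        assert (per_patient_lfc(PairedExpressionMatrix(vals, meta)) == 0).all().all()

    def test_matches_elementwise_loop(self, rng):
        meta = _pair_meta(6)
        vals = pd.DataFrame(
            rng.normal(size=(10, 12)), index=[f"g{i}" for i in range(10)],
            columns=meta.index,
        )
        expr = PairedExpressionMatrix(vals, meta)
        lfc = per_patient_lfc(expr)
        for g in vals.index:
            for p in expr.patients:
                assert lfc.loc[g, p] == pytest.approx(
                    vals.loc[g, f"{p}_T"] - vals.loc[g, f"{p}_N"]
                )


class TestCallSignificant:
    def test_rules_and_boundaries(self):
        table = de_table(
            {
                "up": (100, 2.0, 0.01),
                "at_mean_boundary": (50, 2.0, 0.01),  # strict > 50 excludes
                "down": (60, -1.5, 0.04),
                "missing_padj": (100, 2.0, np.nan),
                "weak_lfc": (100, 0.5, 0.001),
            }
        )
        sig = call_significant(table)
        assert sig["up"] == {"up"}
        assert sig["down"] == {"down"}


class TestCallUniqueDegs:
    def test_late_cohort_not_significant_rule(self):
        eo = de_table({"g": (100, 2.0, 0.01)})
        lo = de_table({"g": (80, 0.1, 0.6)})
        [call] = call_unique_degs(eo, lo)
        assert (call.direction, call.rule_fired) == ("up", "locrc_not_significant")

    def test_small_lfc_difference_not_unique(self):
        eo = de_table({"g": (100, 2.0, 0.01)})
        lo = de_table({"g": (90, 1.6, 0.01)})
        assert call_unique_degs(eo, lo) == []

    def test_opposite_significant_directions_fire_lfc_difference(self):
        eo = de_table({"g": (60, 1.2, 0.01)})
        lo = de_table({"g": (70, -1.2, 0.01)})
        [call] = call_unique_degs(eo, lo)
        assert (call.direction, call.rule_fired) == ("up", "lfc_difference")

    def test_gene_missing_from_one_table_excluded(self):
        eo = de_table({"g": (100, 2.0, 0.01), "only_eo": (100, 3.0, 0.001)})
        lo = de_table({"g": (80, 0.1, 0.6)})
        calls = call_unique_degs(eo, lo)
        assert [c.gene_id for c in calls] == ["g"]

    def test_recovers_planted_genes_exactly(self, spec):
        counts, meta, truth = simulate_paired_counts(spec)
        eo_meta = meta[meta["cohort"] == "early"]
        lo_meta = meta[meta["cohort"] == "late"]
        eo = de_table_from_counts(counts[eo_meta.index], eo_meta)
        lo = de_table_from_counts(counts[lo_meta.index], lo_meta)
        calls = call_unique_degs(eo, lo)
        got_up = {c.gene_id for c in calls if c.direction == "up"}
        got_down = {c.gene_id for c in calls if c.direction == "down"}
        assert got_up == set(truth.unique_up)
        assert got_down == set(truth.unique_down)


class TestRefineSignature:
    @staticmethod
    def _expr(diffs_by_gene, n, cohort, prefix):
        meta = _pair_meta(n, cohort, prefix)
        genes = list(diffs_by_gene)
        vals = pd.DataFrame(0.0, index=genes, columns=meta.index)
        for g, diffs in diffs_by_gene.items():
            for i, d in enumerate(diffs):
                vals.loc[g, f"{prefix}{i}_N"] = 5.0
                vals.loc[g, f"{prefix}{i}_T"] = 5.0 + d
        return PairedExpressionMatrix(vals, meta)

    @staticmethod
    def _cand(gene, direction="up"):
        return UniqueGeneCall(gene, direction, "locrc_not_significant",
                              (100.0, 2.0, 0.01), (100.0, 0.0, 0.9))

    def test_clear_early_and_null_late_retained(self):
        strong = 2.0 + 0.01 * np.arange(8)
        eo = self._expr({"g": strong}, 8, "early", "E")
        lo = self._expr({"g": np.zeros(8)}, 8, "late", "L")
        [sig] = refine_signature([self._cand("g")], eo, lo)
        assert sig.qualifying_rule == "lo_nonsig"

    def test_same_direction_small_difference_excluded(self):
        strong = 2.0 + 0.01 * np.arange(8)
        eo = self._expr({"g": strong}, 8, "early", "E")
        lo = self._expr({"g": strong * 0.9}, 8, "late", "L")
        assert refine_signature([self._cand("g")], eo, lo) == []

    def test_opposite_directions_retained(self):
        strong = 2.0 + 0.01 * np.arange(8)
        eo = self._expr({"g": strong}, 8, "early", "E")
        lo = self._expr({"g": -strong}, 8, "late", "L")
        [sig] = refine_signature([self._cand("g")], eo, lo)
        assert sig.qualifying_rule == "opposite_direction"

    def test_too_few_pairs_rejected(self):
        eo = self._expr({"g": np.arange(4) + 1.0}, 4, "early", "E")
        lo = self._expr({"g": np.zeros(8)}, 8, "late", "L")
        with pytest.raises(ValueError, match="pairs"):
            refine_signature([self._cand("g")], eo, lo)

    def test_recovers_planted_signature_exactly(self, spec):
        eo, lo, candidates, truth = simulate_expression_with_signature(spec)
        sig = refine_signature(candidates, eo, lo)
        assert sorted(s.gene_id for s in sig) == sorted(truth.signature_genes)
        # refinement output is a subset of its candidate input
        assert {s.gene_id for s in sig} <= {c.gene_id for c in candidates}


table_strategy = st.dictionaries(
    st.text(alphabet="abcdefgh", min_size=1, max_size=3),
    st.tuples(
        st.floats(min_value=0, max_value=500),
        st.floats(min_value=-4, max_value=4),
        st.one_of(st.none(), st.floats(min_value=0, max_value=1)),
    ),
    min_size=1,
    max_size=12,
)


class TestFilterProperties:
    @settings(max_examples=60, deadline=None)
    @given(rows=table_strategy)
    def test_unique_calls_are_subset_of_early_significant(self, rows):
        table = de_table({g: (bm, lfc, np.nan if p is None else p)
                          for g, (bm, lfc, p) in rows.items()})
        sig = call_significant(table)
        calls = call_unique_degs(table, table)
        assert {c.gene_id for c in calls} <= sig["up"] | sig["down"]

    @settings(max_examples=60, deadline=None)
    @given(rows=table_strategy)
    def test_loosening_thresholds_never_shrinks_significant_set(self, rows):
        table = de_table({g: (bm, lfc, np.nan if p is None else p)
                          for g, (bm, lfc, p) in rows.items()})
        tight = call_significant(table, PipelineConfig())
        loose = call_significant(
            table,
            PipelineConfig(de_padj=0.2, de_lfc=0.5, de_base_mean=10.0),
        )
        assert tight["up"] <= loose["up"]
        assert tight["down"] <= loose["down"]
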