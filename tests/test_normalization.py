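import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from qpcrkit.data_io import CtRecord, CtTable, ROLE_UNKNOWN
from qpcrkit.errors import InsufficientDataError, QpcrError
from qpcrkit.normalization import (
    NormalizedExpression,
    bh_adjust,
    export_exp_dataset,
    expression_ratios,
    normalize_targets,
    normalized_from_frame,
)
from qpcrkit.synthetic import SimulationDesign, generate_dataset

from conftest import make_unknown
from oracles import bh_brute, pooled_t_brute


def flat_table(target_shift=0.0, n_per_type=3):
    """Ref + target genes over CTL/TRT; target shifted by Ct cycles in TRT."""
    records = []
    for gene in ("RefA", "RefB", "Target"):
        for t, shift in (("CTL", 0.0), ("TRT", target_shift if gene == "Target" else 0.0)):
            for i in range(n_per_type):
                records.append(make_unknown(gene, f"{t}{i}", t, 20.0 + shift))
    return CtTable(records)


class TestNormalizeTargets:
    def test_identical_profiles_give_unit_values(self):
        normed = normalize_targets(
            flat_table(), control="CTL", ref_genes=["RefA", "RefB"]
        )
        assert all(ne.value == pytest.approx(1.0, abs=1e-12) for ne in normed)
        assert {ne.gene for ne in normed} == {"Target"}

    def test_one_cycle_lower_doubles_treated(self):
        normed = normalize_targets(
            flat_table(target_shift=-1.0), control="CTL", ref_genes=["RefA", "RefB"]
        )
        for ne in normed:
            expected = 2.0 if ne.type == "TRT" else 1.0
            assert ne.value == pytest.approx(expected, abs=1e-12)

    def test_control_geometric_mean_is_one(self, default_dataset):
        table, truth = default_dataset
        refs = list(truth.design.ref_genes[:5])
        normed = normalize_targets(table, control="C05", ref_genes=refs)
        by_gene = {}
        for ne in normed:
            if ne.type == "C05":
                by_gene.setdefault(ne.gene, []).append(ne.log2_value)
        for gene, logs in by_gene.items():
            assert np.mean(logs) == pytest.approx(0.0, abs=1e-10)

    def test_log2_value_consistency(self, default_dataset):
        table, truth = default_dataset
        normed = normalize_targets(
            table, control="C05", ref_genes=truth.design.ref_genes[:3]
        )
        for ne in normed:
            assert ne.log2_value == pytest.approx(math.log2(ne.value), abs=1e-12)

    def test_ref_listed_as_target_is_error(self):
        with pytest.raises(QpcrError, match="RefA"):
            normalize_targets(
                flat_table(), "CTL", ["RefA"], targets=["RefA", "Target"]
            )

    def test_missing_gene_named_in_error(self):
        with pytest.raises(QpcrError, match="Ghost"):
            normalize_targets(flat_table(), "CTL", ["Ghost"])

    def test_missing_control_type_is_error(self):
        with pytest.raises(QpcrError, match="XXX"):
            normalize_targets(flat_table(), "XXX", ["RefA"])

    def test_n_refs_takes_prefix_of_user_order(self):
        table = flat_table()
        a = normalize_targets(table, "CTL", ["RefA", "RefB"], n_refs=1)
        b = normalize_targets(table, "CTL", ["RefA"])
        assert [ne.value for ne in a] == [ne.value for ne in b]

    def test_five_ref_pipeline_shape(self, default_dataset):
        # canonical shape: 5 refs, control C05, 9 targets + 14 unused refs
        table, truth = default_dataset
        refs = truth.design.ref_genes[:5]
        normed = normalize_targets(
            table, "C05", refs, n_refs=5, targets=truth.design.target_genes
        )
        n_samples = len(truth.design.samples)
        assert len(normed) == 9 * n_samples


class TestExpressionRatios:
    def test_identical_groups_give_unit_ratio_p_one(self):
        normed = normalize_targets(flat_table(), "CTL", ["RefA", "RefB"])
        rows = expression_ratios(normed, control="CTL")
        assert len(rows) == 1
        assert rows[0].ratio == pytest.approx(1.0, abs=1e-12)
        assert rows[0].p == 1.0 and rows[0].t_stat == 0.0

    def test_two_fold_limit_case(self):
        rng = np.random.default_rng(0)
        normed = []
        for i in range(5):
            normed.append(
                NormalizedExpression("T", f"c{i}", "CTL", 1.0, 0.0 + rng.normal(0, 1e-9))
            )
            normed.append(
                NormalizedExpression("T", f"t{i}", "TRT", 2.0, 1.0 + rng.normal(0, 1e-9))
            )
        rows = expression_ratios(normed, control="CTL")
        assert rows[0].ratio == pytest.approx(2.0, abs=1e-6)
        assert rows[0].p < 1e-12

    def test_matches_textbook_pooled_t(self):
        ctrl_logs = [0.1, -0.2, 0.05]
        trt_logs = [0.9, 1.4, 1.1]
        normed = [
            NormalizedExpression("T", f"c{i}", "CTL", 2.0**v, v)
            for i, v in enumerate(ctrl_logs)
        ] + [
            NormalizedExpression("T", f"t{i}", "TRT", 2.0**v, v)
            for i, v in enumerate(trt_logs)
        ]
        rows = expression_ratios(normed, control="CTL")
        d, se, t, df = pooled_t_brute(ctrl_logs, trt_logs)
        p = 2 * stats.t.sf(abs(t), df)
        assert rows[0].ratio == pytest.approx(2.0**d, abs=1e-10)
        assert rows[0].se_ratio == pytest.approx(2.0**d * math.log(2) * se, abs=1e-10)
        assert rows[0].t_stat == pytest.approx(t, abs=1e-10)
        assert rows[0].p == pytest.approx(p, abs=1e-10)

    def test_side_with_one_sample_is_error(self):
        normed = [
            NormalizedExpression("T", "c1", "CTL", 1.0, 0.0),
            NormalizedExpression("T", "c2", "CTL", 1.0, 0.0),
            NormalizedExpression("T", "t1", "TRT", 2.0, 1.0),
        ]
        with pytest.raises(InsufficientDataError, match="TRT"):
            expression_ratios(normed, control="CTL")

    def test_p_adj_family_is_whole_call(self, default_dataset):
        table, truth = default_dataset
        normed = normalize_targets(
            table, "C05", truth.design.ref_genes[:5],
            targets=truth.design.target_genes,
        )
        rows = expression_ratios(normed, control="C05")
        assert len(rows) == 9 * 2  # 9 targets x 2 non-control types
        expected = bh_brute([r.p for r in rows])
        for row, e in zip(rows, expected):
            assert row.p_adj == pytest.approx(e, abs=1e-12)
            assert row.p_adj >= row.p - 1e-15

    def test_welch_option(self):
        ctrl = [0.0, 0.1, -0.1, 0.05]
        trt = [1.0, 2.0, 0.5]
        normed = [
            NormalizedExpression("T", f"c{i}", "CTL", 2.0**v, v)
            for i, v in enumerate(ctrl)
        ] + [
            NormalizedExpression("T", f"t{i}", "TRT", 2.0**v, v)
            for i, v in enumerate(trt)
        ]
        rows = expression_ratios(normed, control="CTL", equal_var=False)
        ref = stats.ttest_ind(np.array(trt), np.array(ctrl), equal_var=False)
        assert rows[0].t_stat == pytest.approx(ref.statistic, abs=1e-10)
        assert rows[0].p == pytest.approx(ref.pvalue, abs=1e-10)


class TestBhAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-15
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2, abs=1e-15)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.04] * 5), [0.04] * 5, atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_brute_force_oracle_random(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            p = rng.uniform(0, 1, rng.integers(1, 25)).tolist()
            np.testing.assert_allclose(bh_adjust(p), bh_brute(p), atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_property_monotone_in_sorted_order(self, pvals):
        adj = bh_adjust(pvals)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all((adj >= np.array(pvals) - 1e-15) & (adj <= 1.0))


class TestExport:
    def test_row_count_and_round_trip(self, tmp_path, default_dataset):
        table, truth = default_dataset
        normed = normalize_targets(
            table, "C05", truth.design.ref_genes[:5],
            targets=truth.design.target_genes,
        )
        df = export_exp_dataset(normed, tmp_path)
        assert len(df) == len(normed)
        assert (tmp_path / "Exp_R.tsv").exists()

        from qpcrkit.data_io import read_stage_output

        back = normalized_from_frame(read_stage_output(tmp_path, "Exp_R"))
        rows_a = expression_ratios(normed, control="C05")
        rows_b = expression_ratios(back, control="C05")
        for a, b in zip(rows_a, rows_b):
            assert a.ratio == pytest.approx(b.ratio, abs=1e-12)
            assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_empty_export_rejected(self):
        with pytest.raises(ValueError):
            export_exp_dataset([])


class TestNormalizerCancellation:
    def test_loading_offset_cancels_exactly(self, default_dataset):
        table, truth = default_dataset
        refs = truth.design.ref_genes[:5]
        targets = truth.design.target_genes

        def run(t):
            normed = normalize_targets(t, "C05", refs, targets=targets)
            return expression_ratios(normed, control="C05")

        base = run(table)
        # simulate a pipetting error: +1.7 Ct for every gene of one sample
        bumped = CtTable(
            [
                CtRecord(
                    r.gene,
                    r.sample,
                    r.type,
                    r.serial,
                    r.ct + (1.7 if r.sample == "A05_s2" else 0.0),
                    r.role,
                )
                for r in table.records
            ]
        )
        for a, b in zip(base, run(bumped)):
            assert b.ratio == pytest.approx(a.ratio, abs=1e-10)
            assert b.p == pytest.approx(a.p, abs=1e-10)


class TestDesignedFoldRecovery:
    def test_six_fold_recovered(self):
        ratios_seen, sig = [], 0
        for seed in range(20):
            design = SimulationDesign(
                seed=seed,
                n_ref_genes=3,
                n_target_genes=1,
                types=("C05", "T05"),
                n_samples_per_type=10,
                ref_noise_sds=(0.02, 0.02, 0.02),
                target_noise_sd=0.25,
                fold_changes={("Tgt1", "T05"): 6.0},
                ct_noise_sd=0.02,
            )
            table, _ = generate_dataset(design)
            normed = normalize_targets(
                table, "C05", design.ref_genes, targets=["Tgt1"]
            )
            rows = expression_ratios(normed, control="C05")
            ratios_seen.append(rows[0].ratio)
            if rows[0].p_adj < 0.05:
                sig += 1
        assert 5.0 <= np.mean(ratios_seen) <= 7.2
        assert sig >= 18
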