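"""Dual-evidence calling rules and cross-method reconciliation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import noiseless_expected_keys, run_pipeline
from mitoedit import calling
from mitoedit.calling import (
    CallingError,
    ReconcilePolicy,
    call_rnaseq,
    call_sanger,
    categorize_level,
    merge_samples,
    reconcile,
    rnaseq_level,
    sanger_level,
)
from mitoedit.reference import ORFRecord
from mitoedit.simulate import SimulationConfig


def _counts_row(gene="g", pos=4, ref="C", a=0, c=0, g=0, t=0):
    return dict(gene=gene, pos=pos, ref=ref,
                a_count=a, c_count=c, g_count=g, t_count=t)


def _counts_df(rows):
    return pd.DataFrame(rows)


PANEL = {"g": ORFRecord(gene_id="g", cds_seq="ATGCCCGATCACTAA")}  # Cs at 4,5,6,9,11


class TestRnaseqLevel:
    @pytest.mark.parametrize(
        "a,c,g,t,expected",
        [(0, 50, 0, 50, 0.50), (0, 100, 0, 0, 0.0), (2, 70, 1, 27, 0.27)],
    )
    def test_t_over_total_depth(self, a, c, g, t, expected):
        assert rnaseq_level(_counts_row(a=a, c=c, g=g, t=t)) == pytest.approx(expected)

    def test_non_c_reference_rejected(self):
        with pytest.raises(CallingError, match="only at C reference"):
            rnaseq_level(_counts_row(ref="A", a=100))

    def test_scale_invariance(self):
        base = _counts_row(a=2, c=70, g=1, t=27)
        scaled = _counts_row(a=20, c=700, g=10, t=270)
        assert rnaseq_level(base) == pytest.approx(rnaseq_level(scaled))


class TestSangerLevel:
    @pytest.mark.parametrize(
        "peak_c,peak_t,expected", [(30, 70, 0.70), (0, 5, 1.0), (9, 1, 0.10)]
    )
    def test_t_over_c_plus_t(self, peak_c, peak_t, expected):
        assert sanger_level(peak_c, peak_t) == pytest.approx(expected)

    def test_both_zero_errors(self):
        with pytest.raises(CallingError, match="both C and T peaks"):
            sanger_level(0, 0)

    def test_scale_invariance(self):
        assert sanger_level(30, 70) == pytest.approx(sanger_level(3, 7))


class TestMergeSamples:
    def test_two_identical_tables_double_every_count(self):
        t = _counts_df([_counts_row(c=70, t=30), _counts_row(pos=5, c=90, t=10)])
        merged = merge_samples([t, t])
        assert (merged.c_count == [140, 180]).all()
        assert (merged.t_count == [60, 20]).all()

    def test_single_table_identity(self):
        t = _counts_df([_counts_row(c=70, t=30)])
        merged = merge_samples([t])
        assert merged[["a_count", "c_count", "g_count", "t_count"]].values.tolist() \
            == [[0, 70, 0, 30]]

    def test_merge_is_depth_weighted_not_mean_of_levels(self):
        s1 = _counts_df([_counts_row(c=90, t=10)])    # level 0.10
        s2 = _counts_df([_counts_row(c=160, t=40)])   # level 0.20
        merged = merge_samples([s1, s2])
        level = rnaseq_level(merged.iloc[0])
        assert level == pytest.approx(50 / 300)
        assert level != pytest.approx((0.10 + 0.20) / 2)

    def test_union_of_positions(self):
        s1 = _counts_df([_counts_row(pos=4, c=10)])
        s2 = _counts_df([_counts_row(pos=5, c=20)])
        merged = merge_samples([s1, s2])
        assert sorted(merged.pos) == [4, 5]

    def test_conflicting_reference_base_fatal(self):
        s1 = _counts_df([_counts_row(ref="C", c=10)])
        s2 = _counts_df([_counts_row(ref="T", t=10)])
        with pytest.raises(CallingError, match="conflicting reference"):
            merge_samples([s1, s2])


class TestCallRnaseq:
    def test_threshold_is_inclusive(self):
        counts = _counts_df([
            _counts_row(pos=4, c=95, t=5),    # 0.05 -> no
            _counts_row(pos=5, c=90, t=10),   # 0.10 -> yes (>= threshold)
            _counts_row(pos=6, c=50, t=50),   # 0.50 -> yes
        ])
        calls, levels = call_rnaseq(counts, PANEL)
        assert sorted(calls.pos) == [5, 6]
        assert sorted(levels.pos) == [4, 5, 6]

    def test_flank_rows_discarded_before_calling(self):
        counts = _counts_df([
            dict(gene="g", pos=0, ref="C", a_count=0, c_count=0,
                 g_count=0, t_count=100),
            dict(gene="g", pos=16, ref="C", a_count=0, c_count=0,
                 g_count=0, t_count=100),
            _counts_row(pos=4, c=40, t=60),
        ])
        calls, levels = call_rnaseq(counts, PANEL)
        assert sorted(calls.pos) == [4]
        assert sorted(levels.pos) == [4]

    def test_min_depth_filter(self):
        counts = _counts_df([_counts_row(pos=4, c=1, t=1)])
        calls, _ = call_rnaseq(counts, PANEL, min_depth=10)
        assert calls.empty

    def test_unknown_gene_fatal(self):
        counts = _counts_df([_counts_row(gene="nope", c=10)])
        with pytest.raises(CallingError, match="unknown gene"):
            call_rnaseq(counts, PANEL)

    def test_reference_mismatch_fatal(self):
        counts = _counts_df([_counts_row(pos=1, ref="C", c=10)])  # panel has A
        with pytest.raises(CallingError, match="mismatch"):
            call_rnaseq(counts, PANEL)

    def test_high_level_sites_all_called_under_noise(self):
        # planted levels >= 0.12 at depth ~500: per-site miss probability
        # is below 1e-6, so every planted site must be called
        cfg = SimulationConfig(
            n_orfs=5, length_range=(1200, 1200), sites_per_orf=20,
            decoys_per_orf=0, rnaseq_only_per_orf=0, borderline_per_orf=0,
            level_range=(0.12, 0.95), mean_coverage=500.0,
            coverage_dispersion=0.0, sequencing_error_rate=0.002,
            n_samples=1, random_seed=8,
        )
        from mitoedit.simulate import generate_panel, simulate_rnaseq_counts

        sim = generate_panel(cfg)
        counts = simulate_rnaseq_counts(sim)
        calls, _ = call_rnaseq(counts, sim.records)
        called = set(zip(calls.gene, calls.pos))
        planted = set(zip(sim.truth.gene, sim.truth.pos))
        assert planted <= called


class TestCallSanger:
    def _obs(self, levels, gene="g", pos=4, height=100.0):
        return pd.DataFrame([
            dict(gene=gene, pos=pos, replicate=i + 1,
                 peak_c=height * (1 - lv), peak_t=height * lv)
            for i, lv in enumerate(levels)
        ])

    def test_two_of_three_rule_pass(self):
        calls = call_sanger(self._obs([0.15, 0.12, 0.04]), PANEL)
        assert len(calls) == 1
        assert calls.sanger_pass.iloc[0] == 2
        assert calls.sanger_level.iloc[0] == pytest.approx(np.mean([0.15, 0.12, 0.04]))

    def test_one_passing_replicate_not_called(self):
        calls = call_sanger(self._obs([0.15, 0.08, 0.04]), PANEL)
        assert calls.empty

    def test_noiseless_uniform_levels(self):
        frames = [self._obs([0.5, 0.5, 0.5], pos=p) for p in (4, 5, 6, 9, 11)]
        calls = call_sanger(pd.concat(frames, ignore_index=True), PANEL)
        assert len(calls) == 5
        assert np.allclose(calls.sanger_level, 0.5)
        assert (calls.sanger_pass == 3).all()

    def test_duplicate_replicate_id_fatal(self):
        obs = self._obs([0.5, 0.5])
        obs.loc[1, "replicate"] = 1
        with pytest.raises(CallingError, match="duplicate replicate"):
            call_sanger(obs, PANEL)


class TestCategorize:
    @pytest.mark.parametrize(
        "level,cat",
        [(0.95, "EH"), (0.90, "EH"), (0.89, "H"), (0.60, "H"),
         (0.30, "M"), (0.59, "M"), (0.10, "L"), (0.29, "L"), (1.0, "EH")],
    )
    def test_half_open_bins(self, level, cat):
        assert categorize_level(level) == cat

    def test_below_threshold_errors(self):
        with pytest.raises(CallingError, match="below"):
            categorize_level(0.09)

    @given(st.floats(min_value=0.10, max_value=1.0,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=200, derandomize=True)
    def test_partition_every_level_in_exactly_one_bin(self, level):
        assert categorize_level(level) in {"L", "M", "H", "EH"}


class TestReconcile:
    def _sanger_calls(self, rows):
        return pd.DataFrame(rows, columns=["gene", "pos", "sanger_level",
                                           "sanger_pass"])

    def _levels(self, rows):
        return pd.DataFrame(rows, columns=["gene", "pos", "rnaseq_level",
                                           "rnaseq_depth"])

    def test_borderline_rnaseq_level_retained(self):
        # Sanger-passed site whose RNA-seq level sits just under 10%
        final = reconcile(
            self._sanger_calls([("g", 4, 0.12, 2)]),
            self._levels([("g", 4, 0.09, 800)]),
        )
        assert final.status.iloc[0] == "accepted"
        assert final.evidence.iloc[0] == "sanger"
        assert final.category.iloc[0] == "L"

    def test_rnaseq_only_candidate_rejected(self):
        final = reconcile(
            self._sanger_calls([]),
            self._levels([("g", 4, 0.11, 500)]),
        )
        assert final.status.iloc[0] == "rejected_rnaseq_only"
        assert final.evidence.iloc[0] == "rnaseq"

    def test_concordant_site_carries_both_evidence_flags(self):
        final = reconcile(
            self._sanger_calls([("g", 4, 0.52, 3)]),
            self._levels([("g", 4, 0.50, 500)]),
        )
        assert final.status.iloc[0] == "accepted"
        assert final.evidence.iloc[0] == "sanger+rnaseq"
        assert final.category.iloc[0] == "M"

    def test_sanger_site_without_rnaseq_coverage_accepted(self):
        final = reconcile(
            self._sanger_calls([("g", 4, 0.30, 3)]),
            self._levels([]),
        )
        assert final.status.iloc[0] == "accepted"

    def test_sanger_site_with_deeply_discordant_rnaseq_rejected(self):
        final = reconcile(
            self._sanger_calls([("g", 4, 0.15, 2)]),
            self._levels([("g", 4, 0.01, 900)]),
        )
        assert final.status.iloc[0] == "rejected_below_threshold"

    def test_site_ids_are_gene_dash_position(self):
        final = reconcile(
            self._sanger_calls([("g", 4, 0.5, 3)]),
            self._levels([("g", 4, 0.5, 100)]),
        )
        assert final.site_id.iloc[0] == "g-4"


class TestPipelineProperties:
    def test_noiseless_oracle_equivalence(self, noiseless_run):
        """Noise-free run: accepted set == independently recomputed truth."""
        expected_keys = noiseless_expected_keys(noiseless_run)
        accepted_keys = set(zip(noiseless_run.accepted.gene,
                                noiseless_run.accepted.pos))
        assert accepted_keys == expected_keys

    def test_raising_threshold_never_adds_accepted_sites(self, default_run):
        sanger_obs = default_run.sanger
        counts = default_run.counts
        panel = default_run.panel_sim.records
        merged = merge_samples(
            [g for _, g in counts.groupby("sample_id", sort=True)]
        )
        n_prev = None
        for thr in (0.05, 0.10, 0.20, 0.40, 0.60):
            _, levels = call_rnaseq(merged, panel, thr)
            sc = call_sanger(sanger_obs, panel, thr)
            policy = ReconcilePolicy(threshold=thr)
            accepted = calling.accepted_sites(reconcile(sc, levels, policy))
            if n_prev is not None:
                assert len(accepted) <= n_prev
            n_prev = len(accepted)

    def test_every_accepted_site_has_category_and_evidence(self, default_run):
        acc = default_run.accepted
        assert acc.category.isin(["L", "M", "H", "EH"]).all()
        assert acc.evidence.str.contains("sanger").all()

    def test_no_false_calls_at_unplanted_positions(self, default_run):
        # with depth ~500 and error 0.2%, a spurious 10% T fraction at an
        # unedited C has probability < 1e-60 (binomial tail); none may occur
        truth = default_run.panel_sim.truth
        planted = set(zip(truth.gene, truth.pos))
        accepted = set(zip(default_run.accepted.gene, default_run.accepted.pos))
        assert accepted <= planted

    def test_recall_of_strong_sites_across_seeds(self):
        # planted level >= 0.15: recall must reach 0.99 over 10 seeds
        total = found = 0
        for seed in range(10):
            cfg = SimulationConfig(n_orfs=3, length_range=(600, 900),
                                   mean_coverage=300.0, random_seed=seed)
            run = run_pipeline(cfg)
            truth = run.panel_sim.truth
            strong = truth[(truth.site_class == "real")
                           & (truth.true_level >= 0.15)]
            accepted = set(zip(run.accepted.gene, run.accepted.pos))
            total += len(strong)
            found += sum((g, p) in accepted
                         for g, p in zip(strong.gene, strong.pos))
        assert total > 100
        assert found / total >= 0.99
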