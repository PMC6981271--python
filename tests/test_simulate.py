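"""Synthetic pull-down generator and ground-truth evaluation."""

import collections

import numpy as np
import pytest

from nsafpull import (
    CallClass,
    FilterPolicy,
    SimulationConfig,
    VolcanoCall,
    apply_filters,
    classify,
    compute_nsaf,
    differential_table,
    evaluate_calls,
    simulate_pulldown,
)


def _run_pipeline(records, design):
    nsaf = compute_nsaf(apply_filters(records, FilterPolicy()), design)
    return classify(differential_table(nsaf, design))


class TestSimulatePulldown:
    def test_default_config_shape_and_determinism(self):
        cfg = SimulationConfig(seed=7)
        recs1, design1, truth1 = simulate_pulldown(cfg)
        recs2, design2, truth2 = simulate_pulldown(cfg)
        assert len(recs1) == 530
        assert design1.sample_ids == ["P1", "P2", "P3", "NP1", "NP2", "NP3"]
        assert recs1 == recs2
        assert truth1 == truth2
        labels = collections.Counter(truth1.labels.values())
        assert labels == {"BACKGROUND": 500, "SPIKED_P": 15, "SPIKED_NP": 15}

    def test_every_protein_detected_and_filters_pass(self):
        recs, design, _ = simulate_pulldown(SimulationConfig(seed=3))
        assert all(r.total_spc() >= 1 for r in recs)
        assert apply_filters(recs, FilterPolicy()) == recs
        lo, hi = SimulationConfig().length_range
        assert all(lo <= r.length_aa <= hi for r in recs)

    def test_different_seeds_differ(self):
        r1, _, _ = simulate_pulldown(SimulationConfig(seed=1))
        r2, _, _ = simulate_pulldown(SimulationConfig(seed=2))
        assert r1 != r2

    def test_invalid_config_lists_offending_fields(self):
        cfg = SimulationConfig(fold_change=-1, replicates_per_condition=1)
        with pytest.raises(ValueError) as err:
            simulate_pulldown(cfg)
        assert "fold_change" in str(err.value)
        assert "replicates_per_condition" in str(err.value)

    def test_spikes_are_enriched_in_their_condition(self):
        recs, design, truth = simulate_pulldown(SimulationConfig(seed=5))
        by_acc = {r.accession: r for r in recs}
        p_cols = design.samples_for("P")
        np_cols = design.samples_for("NP")
        spiked_p = [a for a, lab in truth.labels.items() if lab == "SPIKED_P"]
        ratio = np.mean(
            [
                sum(by_acc[a].spc[c] for c in p_cols)
                / max(1, sum(by_acc[a].spc[c] for c in np_cols))
                for a in spiked_p
            ]
        )
        assert ratio > 3  # 8-fold enrichment up to sampling noise

    def test_fold_change_one_is_null_like(self):
        cfg = SimulationConfig(fold_change=1.0, seed=9)
        recs, design, truth = simulate_pulldown(cfg)
        calls = _run_pipeline(recs, design)
        ev = evaluate_calls(calls, truth)
        # spiked proteins are indistinguishable from background: few calls
        assert ev["n_called_P"] + ev["n_called_NP"] < 0.05 * len(calls)

    def test_zero_dispersion_is_poisson(self):
        cfg = SimulationConfig(
            n_background=200, n_spiked_P=0, n_spiked_NP=0,
            count_dispersion=0.0, seed=4,
        )
        recs, _, _ = simulate_pulldown(cfg)
        assert all(r.total_spc() >= 1 for r in recs)


class TestEvaluateCalls:
    def _truth_and_calls(self):
        recs, design, truth = simulate_pulldown(
            SimulationConfig(n_background=20, n_spiked_P=3, n_spiked_NP=2, seed=1)
        )
        return truth

    def test_perfect_calls_score_one(self):
        truth = self._truth_and_calls()
        label_map = {
            "SPIKED_P": CallClass.P_SIGNIFICANT,
            "SPIKED_NP": CallClass.NP_SIGNIFICANT,
            "BACKGROUND": CallClass.NON_SIGNIFICANT,
        }
        calls = [
            VolcanoCall(acc, 0.0, 0.0, label_map[lab])
            for acc, lab in truth.labels.items()
        ]
        ev = evaluate_calls(calls, truth)
        assert ev["recall_P"] == ev["precision_P"] == 1.0
        assert ev["recall_NP"] == ev["precision_NP"] == 1.0
        assert ev["fpr_background"] == 0.0

    def test_all_non_significant_scores_zero_recall(self):
        truth = self._truth_and_calls()
        calls = [
            VolcanoCall(acc, 0.0, 0.0, CallClass.NON_SIGNIFICANT)
            for acc in truth.labels
        ]
        ev = evaluate_calls(calls, truth)
        assert ev["recall_P"] == 0.0
        assert ev["fpr_background"] == 0.0
        assert np.isnan(ev["precision_P"])

    def test_hand_tallied_confusion_matrix(self):
        """Full pipeline at seed 7 vs an independent tally over the outputs."""
        recs, design, truth = simulate_pulldown(SimulationConfig(seed=7))
        calls = _run_pipeline(recs, design)
        ev = evaluate_calls(calls, truth)
        tally = collections.Counter(
            (truth.labels[c.accession], c.class_label.value) for c in calls
        )
        n_spiked_p = sum(1 for v in truth.labels.values() if v == "SPIKED_P")
        called_p = sum(v for (_, cl), v in tally.items() if cl == "P_SIGNIFICANT")
        tp = tally[("SPIKED_P", "P_SIGNIFICANT")]
        assert ev["recall_P"] == pytest.approx(tp / n_spiked_p)
        assert ev["precision_P"] == pytest.approx(tp / called_p)
        bg_fp = sum(
            v
            for (lab, cl), v in tally.items()
            if lab == "BACKGROUND" and cl != "NON_SIGNIFICANT"
        )
        assert ev["fpr_background"] == pytest.approx(bg_fp / 500)

    def test_accession_mismatch_rejected(self):
        truth = self._truth_and_calls()
        calls = [
            VolcanoCall("OTHER", 0.0, 0.0, CallClass.NON_SIGNIFICANT)
        ]
        with pytest.raises(ValueError, match="accession"):
            evaluate_calls(calls, truth)


class TestPipelineSymmetry:
    def test_label_swap_mirrors_everything(self):
        """Swapping P/NP labels negates a, preserves p, and mirrors calls."""
        recs, design, _ = simulate_pulldown(
            SimulationConfig(n_background=120, n_spiked_P=5, n_spiked_NP=5, seed=13)
        )
        filtered = apply_filters(recs, FilterPolicy())
        fwd = differential_table(compute_nsaf(filtered, design), design)
        swapped_design = design.swap_conditions()
        rev = differential_table(
            compute_nsaf(filtered, swapped_design), swapped_design
        )
        mirror = {
            CallClass.P_SIGNIFICANT: CallClass.NP_SIGNIFICANT,
            CallClass.NP_SIGNIFICANT: CallClass.P_SIGNIFICANT,
            CallClass.NON_SIGNIFICANT: CallClass.NON_SIGNIFICANT,
        }
        calls_fwd = classify(fwd)
        calls_rev = classify(rev)
        for f, r, cf, cr in zip(fwd, rev, calls_fwd, calls_rev):
            assert r.a == -f.a
            assert r.p_value == f.p_value
            assert r.b == f.b
            assert cr.class_label == mirror[cf.class_label]
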