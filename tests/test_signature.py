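"""Feedback signature: changes, clustering, evaluation, survival, stratification."""

import numpy as np
import pandas as pd
import pytest

from txfeedback import (Signature, build_signature, pattern_delta_survival,
                        signature_enrichment, stratify_by_marker,
                        treatment_changes)
from txfeedback.errors import InputError, TxFeedbackError
from txfeedback.preprocess import ExpressionBundle


def _two_arm_bundle(treated, control):
    samples = ["s.control.1", "s.control.2", "s.drug.1", "s.drug.2"]
    meta = pd.DataFrame({
        "background": "bg", "treatment": ["control", "control", "drug", "drug"],
        "replicate": [1, 2, 1, 2]}, index=samples)
    values = pd.DataFrame([control + treated], index=["g"], columns=samples)
    return ExpressionBundle(values=values, sample_meta=meta)


class TestTreatmentChanges:
    def test_mean_difference(self):
        b = _two_arm_bundle(treated=[5.0, 7.0], control=[3.0, 5.0])
        ch = treatment_changes(b)
        assert ch.loc["g", "bg|drug"] == pytest.approx(2.0)

    def test_identical_arms_zero(self):
        b = _two_arm_bundle(treated=[4.0, 4.0], control=[4.0, 4.0])
        assert treatment_changes(b).loc["g", "bg|drug"] == 0.0

    def test_zero_noise_changes_match_planted_deltas(self, zero_noise):
        from txfeedback import collapse_probes
        cfg, t, b = zero_noise
        ch = treatment_changes(collapse_probes(b), control_treatment=cfg.control)
        expected = t.A_true.to_numpy() @ t.P_true.to_numpy()
        expected = pd.DataFrame(expected, index=t.A_true.index, columns=t.P_true.columns)
        g = sorted(t.signature_truth["up"])[0]  # feedback-program gene
        for bg in cfg.backgrounds:
            for drug in cfg.drugs:
                want = expected.loc[g, f"{bg}|{drug}"] - expected.loc[g, f"{bg}|{cfg.control}"]
                assert ch.loc[g, f"{bg}|{drug}"] == pytest.approx(want, abs=1e-9)

    def test_missing_arm_skipped(self):
        b = _two_arm_bundle(treated=[5.0, 7.0], control=[3.0, 5.0])
        ch = treatment_changes(b, control_treatment="absent")
        assert ch.empty


class TestBuildSignature:
    def test_separated_clusters_split_exactly(self):
        up_rows = {f"u{i}": [1.0, 1.1, 0.9, 1.0] for i in range(4)}
        down_rows = {f"d{i}": [-1.0, -0.9, -1.1, -1.0] for i in range(3)}
        changes = pd.DataFrame({**up_rows, **down_rows}).T
        sig = build_signature(changes, list(changes.index), "u0")
        assert sig.up == set(up_rows)
        assert sig.down == set(down_rows)

    def test_known_growth_factor_receptor_composition(self):
        # two-group change structure reproducing the published membership split
        up = ["EGFR", "ERBB2", "IGF1R", "PTEN", "BMP2", "BMP4"]
        down = ["VEGFA", "TGFA", "FGFR4", "TGFBR3"]
        rng = np.random.default_rng(0)
        rows = {g: 0.8 + 0.1 * rng.normal(size=5) for g in up}
        rows.update({g: -0.8 + 0.1 * rng.normal(size=5) for g in down})
        sig = build_signature(pd.DataFrame(rows).T, up + down, "EGFR")
        assert sig.up == set(up)
        assert sig.down == set(down)

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(1)
        rows = {f"u{i}": 1 + 0.1 * rng.normal(size=4) for i in range(3)}
        rows.update({f"d{i}": -1 + 0.1 * rng.normal(size=4) for i in range(3)})
        changes = pd.DataFrame(rows).T
        sig1 = build_signature(changes, list(changes.index), "u0")
        sig2 = build_signature(changes.iloc[::-1], list(changes.index)[::-1], "u0")
        assert sig1.up == sig2.up and sig1.down == sig2.down

    def test_shift_invariant_under_correlation_metric(self):
        rng = np.random.default_rng(2)
        rows = {f"a{i}": np.array([1, 2, 3, 4.0]) + 0.1 * rng.normal(size=4)
                for i in range(3)}
        rows.update({f"b{i}": np.array([4, 3, 2, 1.0]) + 0.1 * rng.normal(size=4)
                     for i in range(3)})
        changes = pd.DataFrame(rows).T
        sig1 = build_signature(changes, list(changes.index), "a0", metric="correlation")
        sig2 = build_signature(changes + 7.5, list(changes.index), "a0",
                               metric="correlation")
        assert sig1.up == sig2.up and sig1.down == sig2.down

    def test_planted_membership_recovered(self, collapsed, truth, sim_cfg):
        changes = treatment_changes(collapsed, control_treatment=sim_cfg.control)
        targets = sorted(truth.tf_targets["AP2A"])
        sig = build_signature(changes, targets, truth.signature_truth["reference"])
        correct = (len(sig.up & truth.signature_truth["up"])
                   + len(sig.down & truth.signature_truth["down"]))
        assert correct / len(targets) >= 0.9

    def test_identical_profiles_degenerate(self):
        changes = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]}).T
        with pytest.raises(TxFeedbackError):
            build_signature(changes, ["a", "b"], "a")

    def test_reference_must_be_target(self):
        changes = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]}).T
        with pytest.raises(InputError):
            build_signature(changes, ["a", "b"], "z")


class TestSignatureEnrichment:
    def _changes(self, seed=0, n_up=5, n_bg=20, n_contrasts=6):
        rng = np.random.default_rng(seed)
        shared = rng.normal(size=n_contrasts)
        rows = {"ref": shared + 0.1 * rng.normal(size=n_contrasts)}
        for i in range(n_up):
            rows[f"u{i}"] = shared + 0.3 * rng.normal(size=n_contrasts)
        for i in range(n_bg):
            rows[f"b{i}"] = rng.normal(size=n_contrasts)
        return pd.DataFrame(rows).T

    def test_planted_up_set_enriched(self):
        changes = self._changes()
        sig = Signature(reference_gene="ref",
                        up={"ref"} | {f"u{i}" for i in range(5)}, down=set())
        res, table = signature_enrichment(changes, sig)
        assert res.p_value < 0.05
        assert "ref" not in table.index

    def test_reference_row_excluded_from_statistics(self):
        changes = self._changes()
        sig = Signature(reference_gene="ref",
                        up={"ref", "u0", "u1"}, down=set())
        _, table = signature_enrichment(changes, sig)
        assert "ref" not in table.index
        assert table["in_up_set"].sum() == 2

    def test_top_ranked_up_genes_reach_exact_minimum(self):
        # 3 up genes holding the top 3 ranks among 8 -> p = 1 / C(8,3)
        changes = self._changes(seed=1, n_up=3, n_bg=5)
        sig = Signature(reference_gene="ref",
                        up={"ref", "u0", "u1", "u2"}, down=set())
        res, table = signature_enrichment(changes, sig)
        ranked = table["in_up_set"].to_numpy()
        if ranked[:3].all():            # planted construction puts them on top
            assert res.p_value == pytest.approx(1 / 56)

    def test_planted_cohort_up_set_enriched(self, collapsed, truth, sim_cfg):
        changes = treatment_changes(collapsed, control_treatment=sim_cfg.control)
        st = truth.signature_truth
        sig = Signature(reference_gene=st["reference"], up=set(st["up"]),
                        down=set(st["down"]))
        res, _ = signature_enrichment(changes, sig)
        assert res.p_value < 0.05

    def test_too_few_contrasts_rejected(self):
        changes = pd.DataFrame({"ref": [1.0, 2.0], "a": [2.0, 1.0]}).T
        sig = Signature(reference_gene="ref", up={"ref", "a"}, down=set())
        with pytest.raises(InputError):
            signature_enrichment(changes, sig)


class TestPatternDeltaSurvival:
    def test_exact_anticorrelation(self, truth):
        deltas = []
        for bg, drug in truth.survival_true.index:
            deltas.append(truth.P_true.loc["feedback", f"{bg}|{drug}"]
                          - truth.P_true.loc["feedback", f"{bg}|control"])
        survival = pd.Series(-np.asarray(deltas), index=truth.survival_true.index)
        r, _ = pattern_delta_survival(truth.P_true, survival, "feedback")
        assert r == pytest.approx(-1.0)

    def test_constant_survival_rejected(self, truth):
        survival = pd.Series(0.5, index=truth.survival_true.index)
        with pytest.raises(InputError):
            pattern_delta_survival(truth.P_true, survival, "feedback")

    def test_planted_fixture_strongly_anticorrelated(self, truth):
        r, p = pattern_delta_survival(truth.P_true, truth.survival_true, "feedback")
        assert r <= -0.9

    def test_missing_control_rejected(self, truth):
        P = truth.P_true.drop(columns=["Mock|control"])
        with pytest.raises(InputError):
            pattern_delta_survival(P, truth.survival_true, "feedback")


class TestStratify:
    def _bundle(self, values):
        samples = [f"s{i}" for i in range(len(values))]
        meta = pd.DataFrame({"background": "x", "treatment": "t", "replicate": 1},
                            index=samples)
        return ExpressionBundle(values=pd.DataFrame([values], index=["M"],
                                                    columns=samples),
                                sample_meta=meta)

    def test_mean_threshold(self):
        labels, thr = stratify_by_marker(self._bundle([4.0, 6.0]), "M")
        assert thr == 5.0
        assert list(labels) == ["low", "high"]

    def test_all_equal_labeled_high(self):
        labels, _ = stratify_by_marker(self._bundle([3.0, 3.0, 3.0]), "M")
        assert (labels == "high").all()

    def test_explicit_threshold(self):
        labels, thr = stratify_by_marker(self._bundle([5.0, 6.0]), "M",
                                         threshold=5.4)
        assert thr == 5.4
        assert list(labels) == ["low", "high"]

    def test_partition_is_complete(self, collapsed):
        marker = collapsed.values.index[0]
        labels, _ = stratify_by_marker(collapsed, marker)
        assert set(labels.index) == set(collapsed.values.columns)
        assert set(labels.unique()) <= {"low", "high"}

    def test_missing_marker_rejected(self):
        with pytest.raises(InputError):
            stratify_by_marker(self._bundle([1.0]), "absent")
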