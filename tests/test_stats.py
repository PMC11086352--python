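"""Unit tests for the inhibitory-component statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgsynergy import (
    build_paired_contrast, component_modulation, find_inhibitory_channels,
    group_compare, inhibitory_proportion, paired_style_test,
)

STYLES = ["FL", "FS", "SL", "SS"]


def _record(cluster=1, subject="s01", side="L", task="t1", style="FL",
            age_group="mid", expertise="senior", proportion=0.1):
    return dict(cluster=cluster, subject=subject, side=side, task=task,
                style=style, age_group=age_group, expertise=expertise,
                proportion=proportion)


class TestInhibitoryProportion:
    @pytest.mark.parametrize(
        "w, expected",
        [([0.8, -0.2], 0.2), ([0.5, 0.3, 0.2], 0.0), ([-3.0, 1.0], 0.75)],
    )
    def test_hand_computed_values(self, w, expected):
        assert inhibitory_proportion(w) == expected

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=20),
           st.floats(0.01, 100))
    @settings(max_examples=60, deadline=None)
    def test_scale_and_permutation_invariance(self, w, scale):
        w = np.asarray(w)
        if np.abs(w).sum() == 0:
            return
        p = inhibitory_proportion(w)
        assert 0.0 <= p <= 1.0
        assert inhibitory_proportion(scale * w) == pytest.approx(p)
        assert inhibitory_proportion(w[::-1]) == pytest.approx(p)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            inhibitory_proportion([0.0, 0.0])


class TestGroupCompare:
    def test_fully_separated_groups_flagged(self):
        rows = []
        for g, vals in [("under30", [0.01, 0.02, 0.03]),
                        ("mid", [0.11, 0.12, 0.13]),
                        ("over50", [0.21, 0.22, 0.23])]:
            for i, v in enumerate(vals):
                rows.append(_record(subject=f"{g}{i}", age_group=g,
                                    proportion=v))
        out = group_compare(pd.DataFrame(rows), "age_group", alpha=0.05)
        assert len(out) == 1
        assert out.iloc[0].p_value < 0.05 and out.iloc[0].significant

    def test_identical_values_never_flagged(self):
        rows = [_record(subject=f"s{i}", age_group=g, proportion=0.2)
                for i, g in enumerate(["under30"] * 4 + ["mid"] * 4)]
        out = group_compare(pd.DataFrame(rows), "age_group", alpha=0.05)
        assert out.iloc[0].p_value == pytest.approx(1.0)
        assert not out.iloc[0].significant

    def test_single_group_cell_skipped(self):
        rows = [_record(subject=f"s{i}") for i in range(5)]  # all 'mid'
        out = group_compare(pd.DataFrame(rows), "age_group")
        assert out.empty

    def test_singleton_group_flagged_with_caveat(self):
        rows = [_record(subject=f"s{i}", age_group="mid",
                        proportion=0.1 + 0.01 * i) for i in range(5)]
        rows.append(_record(subject="s9", age_group="over50", proportion=0.9))
        out = group_compare(pd.DataFrame(rows), "age_group")
        assert out.iloc[0].singleton_group

    def test_subject_aggregation_reduces_to_one_value_per_subject(self):
        rows = [_record(subject="sA", age_group="mid", proportion=p)
                for p in (0.1, 0.2, 0.3)]
        rows += [_record(subject="sB", age_group="under30", proportion=p)
                 for p in (0.15, 0.25)]
        rows += [_record(subject="sC", age_group="under30", proportion=0.4)]
        out = group_compare(pd.DataFrame(rows), "age_group",
                            aggregate_subjects=True)
        assert out.iloc[0].n_per_group == {"mid": 1, "under30": 2}


class TestPairedContrast:
    def test_single_matched_pair(self):
        rows = [_record(style="FL", proportion=0.3),
                _record(style="SL", proportion=0.1)]
        c = build_paired_contrast(pd.DataFrame(rows), "tempo")
        assert len(c.pairs) == 1
        assert c.pairs.iloc[0]["diff"] == pytest.approx(0.2)  # fast - slow
        assert c.n_unmatched == 0

    def test_missing_partner_reported_unmatched(self):
        rows = [_record(style="FL", proportion=0.3)]
        c = build_paired_contrast(pd.DataFrame(rows), "tempo")
        assert len(c.pairs) == 0
        assert c.n_unmatched == 1

    def test_duplicate_instances_averaged_before_pairing(self):
        rows = [_record(style="FL", proportion=0.1),
                _record(style="FL", proportion=0.3),
                _record(style="SL", proportion=0.1)]
        c = build_paired_contrast(pd.DataFrame(rows), "tempo")
        assert c.pairs.iloc[0]["value_a"] == pytest.approx(0.2)

    def test_force_sign_convention_soft_minus_loud(self):
        rows = [_record(style="FS", proportion=0.4),
                _record(style="FL", proportion=0.1)]
        c = build_paired_contrast(pd.DataFrame(rows), "force")
        assert c.pairs.iloc[0]["diff"] == pytest.approx(0.3)


class TestPairedStyleTest:
    def _pairs(self, diffs, base=0.3):
        rows = []
        for i, d in enumerate(diffs):
            rows.append(_record(subject=f"s{i}", style="FL",
                                proportion=base + d))
            rows.append(_record(subject=f"s{i}", style="SL", proportion=base))
        return build_paired_contrast(pd.DataFrame(rows), "tempo")

    def test_constant_shift_detected_with_direction(self):
        out = paired_style_test(self._pairs([0.1] * 15))
        row = out.iloc[0]
        assert row.significant and row.p_value < 0.05
        assert row.median_diff > 0 and row.direction == "higher at fast"

    def test_balanced_signs_not_flagged(self):
        out = paired_style_test(self._pairs([0.1, -0.1] * 10))
        assert out.iloc[0].p_value > 0.05
        assert out.iloc[0].direction == "none"

    def test_single_pair_skipped(self):
        out = paired_style_test(self._pairs([0.1]))
        assert out.empty

    def test_all_zero_differences_degenerate(self):
        out = paired_style_test(self._pairs([0.0] * 6))
        assert out.iloc[0].degenerate and not out.iloc[0].significant

    def test_power_for_small_absolute_shift(self):
        """A 0.1 absolute proportion shift with 12 pairs, against noise at
        the generator's trial-to-trial level, is detected in >= 80% of
        seeded replicates — and never with the wrong direction."""
        rng = np.random.default_rng(99)
        detected = 0
        n_rep = 50
        for _ in range(n_rep):
            noise = 0.02 * rng.standard_normal(12)
            out = paired_style_test(self._pairs(list(0.1 + noise)))
            row = out.iloc[0]
            assert row.direction != "lower at fast"
            detected += bool(row.significant)
        assert detected / n_rep >= 0.8


class TestFindInhibitoryChannels:
    def test_negative_in_one_style_included(self):
        a = np.array([[-0.05, 0.3], [-0.05, 0.3]])  # mean ch0 < 0
        b = np.array([[0.02, 0.3], [0.02, 0.3]])
        assert list(find_inhibitory_channels({"F": a, "S": b})) == [0]

    def test_positive_everywhere_excluded(self):
        a = np.full((3, 2), 0.2)
        assert len(find_inhibitory_channels({"F": a, "S": a})) == 0

    def test_exact_zero_mean_excluded(self):
        a = np.array([[0.0, 0.1], [0.0, 0.1]])
        assert len(find_inhibitory_channels({"F": a, "S": a})) == 0


class TestComponentModulation:
    def _inputs(self, n_subjects=8, shift=0.0, seed=0, base=-0.3):
        """Weights with channel 0 inhibitory; `shift` added at fast trials."""
        rng = np.random.default_rng(seed)
        rows, weights = [], []
        for i in range(n_subjects):
            for task in ("t1", "t2"):
                for style in STYLES:
                    w = np.array([base, 0.5, 0.8]) + 0.02 * rng.standard_normal(3)
                    if style[0] == "F":
                        w[0] += shift
                    weights.append(w)
                    rows.append({"subject": f"s{i}", "side": "L",
                                 "task": task, "style": style,
                                 "trial_id": f"{i}{task}{style}",
                                 "synergy_index": 0})
        prov = pd.DataFrame(rows)
        return np.vstack(weights), prov, np.ones(len(rows), int)

    def test_planted_shift_flagged_less_negative(self):
        W, prov, cl = self._inputs(shift=0.08)
        out = component_modulation(W, prov, cl, "tempo", min_pairs=10)
        row = out[out.channel == 0].iloc[0]
        assert row.significant and row.sign == "less_negative"
        others = out[out.channel != 0]
        assert not others.significant.any()

    def test_too_few_pairs_excluded(self):
        W, prov, cl = self._inputs(n_subjects=2)  # 2 x 2 x 2 = 8 pairs < 10
        out = component_modulation(W, prov, cl, "tempo", min_pairs=10)
        assert out.empty

    def test_force_sign_convention(self):
        # soft weight -0.1 vs loud -0.2 -> soft - loud = +0.1 (less negative)
        rng = np.random.default_rng(1)
        rows, weights = [], []
        for i in range(12):
            for style in STYLES:
                w = np.array([-0.2 if style[1] == "L" else -0.1, 0.5])
                w = w + 0.005 * rng.standard_normal(2)
                weights.append(w)
                rows.append({"subject": f"s{i}", "side": "L", "task": "t",
                             "style": style, "trial_id": f"{i}{style}",
                             "synergy_index": 0})
        out = component_modulation(np.vstack(weights), pd.DataFrame(rows),
                                   np.ones(len(rows), int), "force",
                                   min_pairs=10)
        row = out[out.channel == 0].iloc[0]
        assert row.mean_diff == pytest.approx(0.1, abs=0.02)
        assert row.sign == "less_negative"

    def test_noninhibitory_channels_not_tested(self):
        W, prov, cl = self._inputs()
        out = component_modulation(W, prov, cl, "tempo", min_pairs=10)
        assert set(out.channel) == {0}
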