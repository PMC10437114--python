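"""Mixed-effects group contrasts, BH adjustment, ROI statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fnirsglm.group_level import (
    default_contrasts,
    fdr_adjust,
    fit_group,
    roi_group_stats,
    significant_counts,
    significant_set,
)
from fnirsglm.paradigm import CONDITIONS, CONTROL_CONDITION


def bh_oracle(p):
    """Brute-force Benjamini-Hochberg: p_adj_(i) = min_{j>=i} (m p_(j) / j)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for rank_i, i in enumerate(order, start=1):
        candidates = [
            m * p[j] / rank_j
            for rank_j, j in enumerate(order, start=1)
            if rank_j >= rank_i
        ]
        adj[i] = min(1.0, min(candidates))
    return adj


def make_betas(n_subjects, effects, tau=1.0, sigma=0.3, seed=0, channels=None):
    """Long-format first-level coefficients with known condition effects.

    ``effects``: {channel: {condition: true amplitude}}; every channel gets a
    subject random intercept of SD ``tau`` and residual noise of SD ``sigma``.
    """
    rng = np.random.default_rng(seed)
    channels = channels or sorted(effects)
    rows = []
    for s in range(n_subjects):
        for ch in channels:
            offset = rng.normal(0, tau)
            for cond in CONDITIONS:
                true = effects.get(ch, {}).get(cond, 0.0)
                rows.append(
                    {
                        "subject": s,
                        "channel": ch,
                        "condition": cond,
                        "beta": true + offset + rng.normal(0, sigma),
                    }
                )
    return pd.DataFrame(rows)


class TestFdrAdjust:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust(np.array([0.037])), [0.037])

    def test_worked_example_matches_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(fdr_adjust(p), bh_oracle(p))

    def test_equal_ps_are_a_fixed_point(self):
        p = np.full(7, 0.2)
        np.testing.assert_allclose(fdr_adjust(p), 0.2)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle(self, p):
        p = np.array(p)
        adj = fdr_adjust(p)
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
        assert np.all(adj >= p - 1e-12)  # adjustment never lowers a p-value
        # order preservation
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.1, 1.5]))


class TestFitGroup:
    def test_recovers_true_contrast_within_three_se(self):
        betas = make_betas(
            12,
            {"S2-D3": {"NMES+AI": 3.0}},
            channels=["S2-D3", "S1-D1"],
            seed=5,
        )
        stats = fit_group(betas, default_contrasts())
        row = stats[(stats.contrast == "NMES+AI - NMES+LO") & (stats.channel == "S2-D3")]
        assert abs(row.beta.iloc[0] - 3.0) < 3 * row.se.iloc[0]
        assert row.t.iloc[0] == pytest.approx(row.beta.iloc[0] / row.se.iloc[0])
        assert row.n_subjects.iloc[0] == 12

    def test_matches_paired_difference_oracle_in_balanced_design(self):
        """With one observation per subject x condition, the mixed-model
        fixed-effect difference equals the paired mean difference."""
        betas = make_betas(10, {"ch": {"NMES+AE": 2.0}}, channels=["ch"], seed=2)
        stats = fit_group(betas, [("NMES+AE", CONTROL_CONDITION)])
        wide = betas.pivot_table(index="subject", columns="condition", values="beta")
        d = wide["NMES+AE"] - wide[CONTROL_CONDITION]
        assert stats.beta.iloc[0] == pytest.approx(d.mean(), abs=1e-6)

    def test_identical_subject_betas_degenerate_variance_handled(self):
        rows = []
        for s in range(5):
            for j, cond in enumerate(CONDITIONS):
                rows.append({"subject": s, "channel": "ch", "condition": cond,
                             "beta": float(j)})
        stats = fit_group(pd.DataFrame(rows), default_contrasts())
        # zero within-subject variance: estimates exact, flagged degenerate
        np.testing.assert_allclose(
            stats.set_index("contrast")["beta"]
            [["NMES+AO - NMES+LO", "NMES+AE - NMES+LO", "NMES+AI - NMES+LO"]],
            [1.0, 2.0, 3.0], atol=1e-6,
        )

    def test_fewer_than_two_subjects_rejected(self):
        betas = make_betas(1, {}, channels=["ch"])
        with pytest.raises(ValueError, match="2 subjects"):
            fit_group(betas, default_contrasts())

    def test_incomplete_conditions_rejected(self):
        betas = make_betas(4, {}, channels=["ch"])
        betas = betas[~((betas.subject == 0) & (betas.condition == "NMES+AE"))]
        with pytest.raises(ValueError, match="incomplete"):
            fit_group(betas, default_contrasts())

    def test_p_fdr_never_below_p(self):
        betas = make_betas(8, {}, channels=[f"c{i}" for i in range(6)], seed=3)
        stats = fit_group(betas, default_contrasts())
        assert np.all(stats.p_fdr >= stats.p - 1e-12)
        assert np.all((stats.p_fdr > 0) & (stats.p_fdr <= 1))


class TestSignificantSet:
    def _stats(self, p_fdr):
        return pd.DataFrame(
            {
                "contrast": ["c"] * len(p_fdr),
                "channel": [f"ch{i}" for i in range(len(p_fdr))],
                "beta": 1.0, "se": 1.0, "t": 1.0,
                "p": p_fdr, "p_fdr": p_fdr,
            }
        )

    def test_all_ones_give_empty_set(self):
        assert len(significant_set(self._stats([1.0, 1.0]), 0.05)) == 0

    def test_alpha_one_returns_everything_below_one(self):
        stats = self._stats([0.2, 0.9, 0.5])
        assert len(significant_set(stats, 1.0)) == 3

    def test_counts_per_contrast(self):
        stats = self._stats([0.01, 0.2, 0.03])
        assert significant_counts(stats, 0.05) == {"c": 2}

    def test_only_signal_channel_flagged_with_controlled_false_rate(self):
        """Across repeated null-plus-one-signal groups, the signal channel is
        flagged and null channels are rarely flagged."""
        n_reps, false_flags, hits = 20, 0, 0
        null_channels = [f"n{i}" for i in range(9)]
        for rep in range(n_reps):
            betas = make_betas(
                10, {"sig": {"NMES+AI": 4.0}}, channels=["sig"] + null_channels,
                tau=1.0, sigma=0.3, seed=100 + rep,
            )
            stats = fit_group(betas, [("NMES+AI", CONTROL_CONDITION)])
            sig = set(significant_set(stats, 0.05)["channel"])
            hits += "sig" in sig
            false_flags += len(sig - {"sig"})
        assert hits >= 0.8 * n_reps
        assert false_flags / (n_reps * len(null_channels)) <= 0.1


class TestRoiGroupStats:
    def test_uniform_channel_betas_conserved_per_roi(self, montage):
        rows = []
        rng = np.random.default_rng(0)
        for s in range(6):
            for j, cond in enumerate(CONDITIONS):
                value = float(j) + rng.normal(0, 0.1)
                for ch in montage.channel_names:
                    rows.append({"subject": s, "channel": ch, "condition": cond,
                                 "beta": value})
        betas = pd.DataFrame(rows)
        roi = roi_group_stats(betas, montage, default_contrasts())
        chan = fit_group(betas, default_contrasts())
        # every channel shares the subject value, so every ROI repeats the
        # channel-level contrast estimate
        for contrast_name in roi.contrast.unique():
            r = roi[roi.contrast == contrast_name]["beta"].to_numpy()
            c = chan[chan.contrast == contrast_name]["beta"].iloc[0]
            np.testing.assert_allclose(r, c, atol=1e-6)

    def test_t_equals_beta_over_se_everywhere(self, montage):
        betas = make_betas(
            8, {"S2-D3": {"NMES+AI": 3.0}}, channels=montage.channel_names, seed=17
        )
        roi = roi_group_stats(betas, montage, default_contrasts())
        assert len(roi) == 3 * 6  # contrasts x ROIs
        np.testing.assert_allclose(roi.t, roi.beta / roi.se, rtol=1e-9)
        assert np.all(roi.p_fdr >= roi.p - 1e-12)
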