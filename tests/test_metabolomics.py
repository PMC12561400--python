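"""Differential screening chain: filters, t-tests, overlaps, FDR, SM/Cer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bmage.errors import DomainError
from bmage.metabolomics import (
    DifferentialScreen,
    bh_fdr,
    differential,
    direction_consistent_overlap,
    exclude_confounded,
    filter_missing,
    normalize_log_median,
    sm_cer_ratio,
)

from conftest import matrix_from_array


def _two_group_matrix(rng, n_per_group=10, n_features=5, shift=None):
    """Log-normal two-group matrix; ``shift`` adds log2 offsets to group B."""
    base = rng.uniform(14, 20, size=n_features)
    a = np.exp2(base + rng.normal(0, 0.5, (n_per_group, n_features)))
    b_log = base + rng.normal(0, 0.5, (n_per_group, n_features))
    if shift is not None:
        b_log = b_log + np.asarray(shift)
    b = np.exp2(b_log)
    groups = ["A"] * n_per_group + ["B"] * n_per_group
    return matrix_from_array(np.vstack([a, b]), groups)


class TestFilterMissing:
    def test_majority_missing_feature_dropped(self, rng):
        arr = np.exp2(rng.uniform(10, 20, (10, 3)))
        arr[:6, 0] = 0.0  # 6/10 zeros -> 0.6 > 0.5, dropped
        arr[:5, 1] = 0.0  # exactly half missing is retained (strict >)
        m = matrix_from_array(arr, ["A"] * 5 + ["B"] * 5)
        kept = filter_missing(m, 0.5)
        assert kept.feature_ids == ["f001", "f002"]

    def test_no_zeros_identity(self, rng):
        arr = np.exp2(rng.uniform(10, 20, (6, 4)))
        m = matrix_from_array(arr, ["A"] * 3 + ["B"] * 3)
        kept = filter_missing(m)
        assert kept.feature_ids == m.feature_ids
        pd.testing.assert_frame_equal(kept.intensities, m.intensities)

    def test_empty_matrix_warns(self):
        m = matrix_from_array(np.empty((0, 0)), [])
        with pytest.warns(UserWarning):
            out = filter_missing(m)
        assert out.n_features == 0

    def test_bad_threshold_rejected(self, rng):
        m = matrix_from_array(np.ones((4, 2)), ["A", "A", "B", "B"])
        with pytest.raises(DomainError):
            filter_missing(m, 1.5)


class TestDifferential:
    def test_identical_groups_yield_no_hits(self, rng):
        block = np.exp2(rng.uniform(14, 20, (10, 8)))
        m = matrix_from_array(np.vstack([block, block]), ["A"] * 10 + ["B"] * 10)
        diff = differential(m, "A", "B")
        assert diff.table["significant"].sum() == 0
        assert np.allclose(diff.table["log2fc"], 0.0)

    def test_true_twofold_change_flagged_up(self, rng):
        # feature 0 carries log2FC = 1 with tiny noise among enough null
        # features that per-sample median centering stays anchored
        n_feat = 20
        shift = np.zeros(n_feat)
        shift[0] = 1.0
        base = rng.uniform(14, 20, size=n_feat)
        a = np.exp2(base + rng.normal(0, 0.05, (10, n_feat)))
        b = np.exp2(base + shift + rng.normal(0, 0.05, (10, n_feat)))
        m = matrix_from_array(np.vstack([a, b]), ["A"] * 10 + ["B"] * 10)
        diff = differential(m, "A", "B", normalized=normalize_log_median(m))
        row = diff.table.iloc[0]
        assert row["significant"] and row["direction"] == "up"
        assert row["log2fc"] == pytest.approx(1.0, abs=0.15)

    def test_small_fold_change_never_significant(self, rng):
        # |log2FC| = log2(1.1) ~ 0.138 < 0.26 stays below the effect cutoff
        # regardless of p, by the threshold arithmetic
        shift = np.full(5, np.log2(1.1))
        m = _two_group_matrix(rng, shift=shift)
        m.intensities.iloc[:, :] = np.exp2(
            np.log2(m.intensities.to_numpy())
        )  # no-op, keeps intensities positive
        diff = differential(m, "A", "B", normalized=np.log2(m.intensities))
        est_fc = diff.table["log2fc"].abs()
        assert (~diff.table.loc[est_fc <= 0.26, "significant"]).all()

    def test_degenerate_zero_variance_equal_means(self):
        arr = np.full((8, 2), 1024.0)
        m = matrix_from_array(arr, ["A"] * 4 + ["B"] * 4)
        diff = differential(m, "A", "B", normalized=np.log2(m.intensities))
        assert (diff.table["p_value"] == 1.0).all()

    def test_missing_group_rejected(self, rng):
        m = _two_group_matrix(rng)
        with pytest.raises(DomainError):
            differential(m, "A", "C")

    def test_contrast_swap_negates_log2fc_and_keeps_p(self, rng):
        m = _two_group_matrix(rng, shift=rng.normal(0, 1, 5))
        fwd = differential(m, "A", "B")
        rev = differential(m, "B", "A")
        assert np.allclose(fwd.table["log2fc"], -rev.table["log2fc"])
        assert np.allclose(fwd.table["p_value"], rev.table["p_value"])

    def test_estimator_wrapper_matches_function(self, rng):
        m = _two_group_matrix(rng, shift=[2, 0, 0, 0, 0])
        screen = DifferentialScreen(group_a="A", group_b="B").fit(m)
        direct = differential(filter_missing(m), "A", "B")
        pd.testing.assert_frame_equal(screen.diff_.table, direct.table)
        assert screen.n_significant_ == int(direct.table["significant"].sum())


class TestConfoundExclusionAndOverlap:
    def _mk_diff(self, features, sig, direction=None):
        direction = direction or {}
        table = pd.DataFrame(
            {
                "log2fc": [1.0 if direction.get(f, "up") == "up" else -1.0 for f in features],
                "p_value": [0.001 if f in sig else 0.9 for f in features],
                "q_value": np.nan,
                "direction": [direction.get(f, "up") for f in features],
                "significant": [f in sig for f in features],
            },
            index=pd.Index(features, name="feature_id"),
        )
        from bmage.metabolomics import DiffTable

        return DiffTable(table=table, group_a="A", group_b="B")

    def test_empty_confound_set_is_identity(self):
        nico = self._mk_diff(list("abcde"), sig={"a", "b"})
        veh = self._mk_diff(list("abcde"), sig=set())
        out = exclude_confounded(nico, veh)
        assert out.significant_features == ["a", "b"]

    def test_total_confounding_annihilates(self):
        nico = self._mk_diff(list("abc"), sig={"a", "b", "c"})
        veh = self._mk_diff(list("abc"), sig={"a", "b", "c"})
        assert exclude_confounded(nico, veh).significant_features == []

    def test_set_difference(self):
        nico = self._mk_diff(list("abcde"), sig={"a", "b", "c"})
        veh = self._mk_diff(list("abcde"), sig={"b"})
        assert exclude_confounded(nico, veh).significant_features == ["a", "c"]

    def test_overlap_identity_all_same_direction(self):
        d = self._mk_diff(list("abcd"), sig={"a", "c"}, direction={"a": "up", "c": "down"})
        shared = direction_consistent_overlap(d, d)
        assert shared.same_direction == ["a", "c"]
        assert shared.opposite_direction == []

    def test_overlap_negated_all_opposite(self):
        ref = self._mk_diff(list("abcd"), sig={"a", "c"}, direction={"a": "up", "c": "down"})
        test = self._mk_diff(list("abcd"), sig={"a", "c"}, direction={"a": "down", "c": "up"})
        shared = direction_consistent_overlap(ref, test)
        assert shared.same_direction == []
        assert shared.opposite_direction == ["a", "c"]

    def test_constructed_concordance_counts(self):
        # 2 concordant, 1 discordant, 2 not shared
        ref = self._mk_diff(
            list("abcde"), sig={"a", "b", "c", "d"},
            direction={"a": "up", "b": "down", "c": "up", "d": "up"},
        )
        test = self._mk_diff(
            list("abcde"), sig={"a", "b", "c", "e"},
            direction={"a": "up", "b": "down", "c": "down", "e": "up"},
        )
        shared = direction_consistent_overlap(ref, test)
        assert shared.counts == (2, 1)
        assert shared.same_direction == ["a", "b"]
        assert shared.opposite_direction == ["c"]


class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
            ([0.01, 0.02, 0.04], [0.03, 0.03, 0.04]),  # hand step-up computation
        ],
    )
    def test_worked_examples(self, p, expected):
        assert bh_fdr(p) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(DomainError):
            bh_fdr([-0.1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_never_below_raw_and_capped(self, p):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_monotone_in_sorted_order(self, p):
        order = np.argsort(p)
        q = bh_fdr(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_step_up_matches_direct_formula(self, rng):
        """Independent oracle: q_(i) = min_{j>=i} m p_(j) / j."""
        p = rng.uniform(size=25)
        m = len(p)
        order = np.argsort(p)
        ranked = p[order]
        q_sorted = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        assert bh_fdr(p) == pytest.approx(oracle, abs=1e-12)


class TestSmCerRatio:
    def _panel(self, sm, cer, groups, tissue="muscle"):
        n = len(sm)
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "group": groups,
                "tissue": tissue,
                "sm": sm,
                "cer": cer,
                "dhcer": np.ones(n),
            }
        )

    def test_equal_sm_cer_gives_unit_ratios(self):
        values = [2.0, 3.0, 4.0, 2.5, 3.5, 4.5]
        panel = self._panel(values, values, ["A"] * 3 + ["B"] * 3)
        ratios, tests = sm_cer_ratio(panel, "A", "B")
        assert np.allclose(ratios["sm_cer_ratio"], 1.0)
        assert tests.loc["muscle", "p_value"] == pytest.approx(1.0)

    def test_doubling_sm_doubles_ratios(self, rng):
        sm = rng.uniform(1, 5, 8)
        cer = rng.uniform(1, 5, 8)
        panel = self._panel(sm, cer, ["A"] * 4 + ["B"] * 4)
        doubled = panel.assign(sm=2 * panel["sm"])
        r1, _ = sm_cer_ratio(panel, "A", "B")
        r2, _ = sm_cer_ratio(doubled, "A", "B")
        assert np.allclose(r2["sm_cer_ratio"], 2 * r1["sm_cer_ratio"])

    def test_shifted_treatment_group_detected(self, rng):
        """+1 SD SM shift at n=6/group turns up as q<0.05 in the frozen draw."""
        rng = np.random.default_rng(99)
        frames = []
        for tissue, shift in [("muscle", 1.0), ("liver", 0.0)]:
            log_sm = 1.0 + 0.3 * rng.standard_normal(12)
            log_sm[6:] += shift * 0.3 * 3  # treated group shifted by 3 noise-SD
            log_cer = 0.5 + 0.3 * rng.standard_normal(12)
            frames.append(
                self._panel(np.exp(log_sm), np.exp(log_cer), ["A"] * 6 + ["B"] * 6, tissue)
            )
        _, tests = sm_cer_ratio(pd.concat(frames, ignore_index=True), "A", "B")
        assert tests.loc["muscle", "q_value"] < 0.05
        assert tests.loc["liver", "q_value"] > 0.05

    def test_nonpositive_cer_names_sample(self):
        panel = self._panel([1, 2, 3, 4], [1, 0.0, 3, 4], ["A", "A", "B", "B"])
        with pytest.raises(DomainError, match="s1"):
            sm_cer_ratio(panel, "A", "B")
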