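"""Trend templates, assignment, permutation null and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bmage.errors import DomainError
from bmage.trends import (
    FLAT_LABEL,
    TEMPLATE_ORDER,
    TrendMiner,
    assign_trend,
    permutation_null,
    template_shapes,
    trend_clusters,
    trend_enrichment,
)

#: time reversal swaps the monotone templates and fixes the peaked ones
#: (the tent shapes are palindromic, so a peak stays a peak)
REVERSAL_MAP = {
    "increase": "decrease",
    "decrease": "increase",
    "up_down": "up_down",
    "down_up": "down_up",
}


class TestTemplateShapes:
    @pytest.mark.parametrize("t", [3, 4, 5, 6])
    def test_centered_unit_norm_and_sign_symmetric(self, t):
        shapes = template_shapes(t)
        for label, vec in shapes.items():
            assert vec.sum() == pytest.approx(0.0, abs=1e-12)
            assert np.linalg.norm(vec) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(shapes["decrease"], -shapes["increase"])
        assert np.allclose(shapes["down_up"], -shapes["up_down"])

    def test_four_timepoint_canonical_shapes(self):
        shapes = template_shapes(4)
        assert np.allclose(shapes["increase"], np.array([-3, -1, 1, 3]) / math.sqrt(20))
        assert np.allclose(shapes["up_down"], np.array([-1, 1, 1, -1]) / 2.0)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(DomainError):
            template_shapes(2)


class TestAssignTrend:
    @pytest.mark.parametrize(
        "profile, label, sim",
        [
            ((1, 2, 3, 4), "increase", 1.0),
            ((4, 3, 2, 1), "decrease", 1.0),
            ((0, 5, 5, 0), "up_down", 1.0),  # matches normalized (-1,1,1,-1)
            ((5, 0, 0, 5), "down_up", 1.0),
        ],
    )
    def test_exact_template_profiles(self, profile, label, sim):
        a = assign_trend(profile)
        assert a.best_template == label
        assert a.similarity == pytest.approx(sim, abs=1e-12)

    def test_constant_profile_is_flat(self):
        assert assign_trend((2.0, 2.0, 2.0, 2.0)).best_template == FLAT_LABEL

    def test_nonfinite_rejected(self):
        with pytest.raises(DomainError):
            assign_trend((1.0, np.nan, 2.0, 3.0))

    @given(
        st.lists(st.floats(-10, 10), min_size=4, max_size=4),
    )
    def test_time_reversal_maps_to_mirror_template(self, profile):
        fwd = assign_trend(profile)
        rev = assign_trend(profile[::-1])
        if fwd.best_template == FLAT_LABEL:
            assert rev.best_template == FLAT_LABEL
        else:
            assert rev.best_template == REVERSAL_MAP[fwd.best_template]

    def test_similarity_equals_pearson_r(self, rng):
        profile = rng.normal(size=5)
        a = assign_trend(profile)
        shapes = template_shapes(5)
        oracle = max(
            ((lab, np.corrcoef(profile, shapes[lab])[0, 1]) for lab in TEMPLATE_ORDER),
            key=lambda t: t[1],
        )
        assert a.similarity == pytest.approx(oracle[1], abs=1e-12)
        assert a.best_template == oracle[0]


class TestPermutationNull:
    def test_four_timepoints_enumerate_24_permutations(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(5, 4)))
        null = permutation_null(profiles)
        assert len(null) == math.factorial(4)

    def test_single_profile_tallies_one_event_per_permutation(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(1, 4)))
        null = permutation_null(profiles)
        assert (null.sum(axis=1) == 1).all()

    def test_exchangeable_null_symmetry_between_increase_and_decrease(self):
        rng = np.random.default_rng(314)
        profiles = pd.DataFrame(rng.normal(size=(500, 4)))
        null = permutation_null(profiles)
        inc, dec = null["increase"].sum(), null["decrease"].sum()
        assert abs(inc - dec) / max(inc, dec) < 0.10

    def test_identity_permutation_included(self, rng):
        profiles = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]])
        null = permutation_null(profiles)
        # lexicographically first permutation is the identity
        assert null.iloc[0]["increase"] == 1


class TestTrendEnrichment:
    def _null_df(self, rows):
        return pd.DataFrame(rows, columns=list(TEMPLATE_ORDER))

    def test_zero_observed_gives_p_one(self):
        null = self._null_df([[1, 1, 0, 0]] * 4)
        enrich = trend_enrichment({"increase": 0, "decrease": 2}, null)
        assert enrich.loc["increase", "p_value"] == pytest.approx(1.0)

    def test_degenerate_all_events_one_template(self):
        null = self._null_df([[3, 0, 0, 0]] * 10)
        enrich = trend_enrichment({"increase": 3}, null)
        assert enrich.loc["increase", "p_value"] == pytest.approx(1.0)

    def test_closed_form_hypergeometric_tail(self):
        # M=8, K=4, n=2, k=2 -> C(4,2)/C(8,2) = 6/28
        null = self._null_df([[1, 1, 0, 0]] * 4)  # P=4, n=2 => M=8; K_inc=4
        enrich = trend_enrichment({"increase": 2, "decrease": 0}, null)
        assert enrich.loc["increase", "p_value"] == pytest.approx(6 / 28, abs=1e-12)

    def test_inconsistent_bookkeeping_rejected(self):
        null = self._null_df([[1, 1, 0, 0]] * 4)
        with pytest.raises(DomainError):
            trend_enrichment({"increase": 5, "decrease": 0}, null)


class TestTrendClustersAndMiner:
    def _fit(self, profiles, alpha=0.05):
        return TrendMiner(alpha=alpha).fit(pd.DataFrame(profiles))

    def test_no_significant_template_gives_empty_clusters(self):
        rng = np.random.default_rng(8)
        miner = self._fit(rng.normal(size=(40, 4)))
        clusters, overlap = trend_clusters(
            {"ctl": miner.assignments_}, {"ctl": miner.enrichment_}
        )
        assert clusters.empty and overlap.empty

    def test_injected_control_trend_yields_single_control_cluster(self):
        """Decrease injected in the control arm only -> one (ctl, decrease) cluster."""
        rng = np.random.default_rng(5)
        shapes = template_shapes(4)
        n_null, n_trend = 28, 12
        base = rng.normal(size=(n_null, 4)) * 0.3
        trend = 2.0 * shapes["decrease"] + rng.normal(size=(n_trend, 4)) * 0.3
        ctl = pd.DataFrame(np.vstack([trend, base]))
        trt = pd.DataFrame(rng.normal(size=(n_null + n_trend, 4)) * 0.3)
        m_ctl, m_trt = TrendMiner().fit(ctl), TrendMiner().fit(trt)
        clusters, _ = trend_clusters(
            {"ctl": m_ctl.assignments_, "trt": m_trt.assignments_},
            {"ctl": m_ctl.enrichment_, "trt": m_trt.enrichment_},
        )
        assert [(r["group"], r["template"]) for _, r in clusters.iterrows()] == [
            ("ctl", "decrease")
        ]
        member_taxa = set(map(int, clusters.iloc[0]["taxa"].split(",")))
        assert set(range(n_trend)) <= member_taxa

    def test_taxon_trending_in_both_groups_appears_in_overlap(self):
        rng = np.random.default_rng(6)
        shapes = template_shapes(4)
        def one_group(seed_shift):
            noise = rng.normal(size=(30, 4)) * 0.2
            block = noise.copy()
            block[:10] += 2.0 * shapes["increase"]
            return pd.DataFrame(block)
        m_a, m_b = TrendMiner().fit(one_group(0)), TrendMiner().fit(one_group(1))
        clusters, overlap = trend_clusters(
            {"a": m_a.assignments_, "b": m_b.assignments_},
            {"a": m_a.enrichment_, "b": m_b.enrichment_},
        )
        shared = set(m_a.assignments_.index[:10]) & set(overlap["taxon"].astype(int))
        assert shared  # the doubly-trending taxa land in the overlap list

    def test_miner_observed_counts_match_identity_permutation(self, rng):
        profiles = pd.DataFrame(rng.normal(size=(30, 4)))
        miner = TrendMiner().fit(profiles)
        observed = miner.assignments_["best_template"].value_counts()
        identity = miner.null_counts_.iloc[0]
        for template in TEMPLATE_ORDER:
            assert observed.get(template, 0) == identity[template]
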