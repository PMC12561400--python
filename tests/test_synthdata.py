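"""Generator contracts: determinism, effect calibration, closure, recovery."""

import numpy as np
import pandas as pd
import pytest

from bmage.errors import ConfigurationError
from bmage.synthdata import (
    CohortDesign,
    TrendSpec,
    generate_cohort,
    generate_taxa_series,
    write_study,
)


def cohens_d(a, b):
    na, nb = len(a), len(b)
    pooled = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    return (np.mean(b) - np.mean(a)) / np.sqrt(pooled)


class TestCohortGeneration:
    def test_same_seed_byte_identical_output(self, tmp_path, small_design):
        dir_a, dir_b = tmp_path / "a", tmp_path / "b"
        write_study(generate_cohort(small_design), dir_a)
        write_study(generate_cohort(small_design), dir_b)
        for path_a in sorted(dir_a.iterdir()):
            assert path_a.read_bytes() == (dir_b / path_a.name).read_bytes()

    def test_row_count_bookkeeping(self, small_study, small_design):
        expected = len(small_design.groups) * small_design.n_per_group
        for matrix in small_study.metabolites.values():
            assert matrix.n_samples == expected
            assert matrix.n_features == small_design.n_features_per_organ
        assert len(small_study.behavior) == expected

    def test_intensities_non_negative(self, small_study):
        for matrix in small_study.metabolites.values():
            assert (matrix.intensities.to_numpy() >= 0).all()

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(n_per_group=2), "n_per_group"),
            (dict(reversal_fraction=1.5), "reversal_fraction"),
            (dict(groups=("A", "A", "B", "C", "D")), "groups"),
            (dict(noise_sd=-1.0), "noise_sd"),
        ],
    )
    def test_invalid_design_names_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            generate_cohort(CohortDesign(**kwargs))

    def test_null_effect_mean_d_near_zero(self):
        """With aging_effect=0 the per-feature mean standardized difference
        over 50 Monte-Carlo cohorts stays below 0.2 for >= 90% of features."""
        n_feat = 12
        d_sum = np.zeros(n_feat)
        reps = 50
        for seed in range(reps):
            design = CohortDesign(
                organs=("plasma",),
                n_features_per_organ=n_feat,
                n_per_group=30,
                aging_effect=0.0,
                missing_rate=0.0,
                seed=seed,
            )
            study = generate_cohort(design)
            m = study.metabolites["plasma"]
            logged = np.log2(m.intensities.to_numpy())
            old = logged[(m.groups == "Old").to_numpy()]
            young = logged[(m.groups == "Young").to_numpy()]
            d_sum += np.array([cohens_d(young[:, j], old[:, j]) for j in range(n_feat)])
        mean_d = np.abs(d_sum / reps)
        assert (mean_d < 0.2).mean() >= 0.9

    def test_effect_calibration_converges_to_nominal(self):
        """Realized |d| for aging features approaches aging_effect at n=200."""
        design = CohortDesign(
            organs=("plasma",),
            n_features_per_organ=40,
            n_per_group=200,
            missing_rate=0.0,
            seed=3,
        )
        study = generate_cohort(design)
        m = study.metabolites["plasma"]
        truth = study.ground_truth.query("kind == 'metabolite'").set_index("item")
        logged = np.log2(m.intensities.to_numpy())
        old = logged[(m.groups == "Old").to_numpy()]
        young = logged[(m.groups == "Young").to_numpy()]
        d_values = []
        for j, feat in enumerate(m.feature_ids):
            if truth.loc[feat, "is_aging"]:
                d_values.append(abs(cohens_d(young[:, j], old[:, j])))
        mean_abs_d = np.mean(d_values)
        assert mean_abs_d == pytest.approx(design.aging_effect, rel=0.10)

    def test_behavior_metrics_correlate_with_latent_age(self, small_study):
        """Age-sensitive metrics carry the designed latent-factor coupling."""
        table = small_study.behavior
        latent = small_study.latent_age
        r_values = [
            abs(np.corrcoef(table[m], latent)[0, 1])
            for m in ("frame_distance", "rearing", "pausing_sniffing")
        ]
        assert min(r_values) > 0.3  # r ~ 0.5 by design, wide tolerance at n=40

    def test_ground_truth_consistent_with_design(self, small_study, small_design):
        truth = small_study.ground_truth.query("kind == 'metabolite'")
        per_organ = truth.groupby("organ")["is_aging"].sum()
        expected_aging = round(
            small_design.aging_fraction * small_design.n_features_per_organ
        )
        assert (per_organ == expected_aging).all()
        rev = truth.groupby("organ")["reversed"].sum()
        assert (rev == round(small_design.reversal_fraction * expected_aging)).all()


class TestTaxaSeries:
    def test_compositional_closure(self):
        spec = TrendSpec(n_taxa=25, assigned_template=("increase",) * 25)
        ts = generate_taxa_series(spec, 4, seed=0)
        rel = ts.counts[ts.taxa].div(ts.counts[ts.taxa].sum(axis=1), axis=0)
        assert np.allclose(rel.sum(axis=1), 1.0, atol=1e-9)
        assert (ts.counts[ts.taxa].to_numpy() >= 0).all()

    def test_noise_free_increase_is_strictly_monotone(self):
        spec = TrendSpec(
            n_taxa=10,
            assigned_template=("increase",) + ("null",) * 9,
            amplitude=1.0,
            overdispersion=0.0,
        )
        ts = generate_taxa_series(spec, 4, seed=1, groups=("ctl",))
        taxa = ts.taxa
        rel = ts.counts[taxa].div(ts.counts[taxa].sum(axis=1), axis=0)
        rel = rel.assign(tp=ts.counts["timepoint"]).groupby("tp").mean()
        assert (np.diff(rel[taxa[0]].to_numpy()) > 0).all()

    def test_deterministic_for_fixed_seed(self):
        spec = TrendSpec(n_taxa=15)
        a = generate_taxa_series(spec, 3, seed=9)
        b = generate_taxa_series(spec, 3, seed=9)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ConfigurationError, match="timepoints"):
            generate_taxa_series(TrendSpec(n_taxa=5, timepoints=2), 4, seed=0)

    def test_template_recovery_on_balanced_design(self):
        """Amplitude 2, overdispersion 0.3: >= 95% of trending taxa recover
        their injected template from group-mean profiles (regression check
        for the generator/miner pair; frozen seed)."""
        from bmage.microbiome import group_mean_log_profiles
        from bmage.trends import TEMPLATE_ORDER, assign_trends

        labels = tuple(np.repeat(TEMPLATE_ORDER, 50))
        spec = TrendSpec(n_taxa=200, assigned_template=labels)
        ts = generate_taxa_series(spec, 8, seed=7, groups=("ctl",))
        prof = group_mean_log_profiles(ts, "ctl")
        assigned = assign_trends(prof)["best_template"]
        truth = ts.ground_truth.set_index("taxon")["template"]
        assert (assigned == truth).mean() >= 0.95
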