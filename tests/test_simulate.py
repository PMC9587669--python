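import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from secircuit.simulate import (
    DoseResponseSpec,
    SimulationConfig,
    generate_annotation,
    generate_chipseq_samples,
    generate_dependency,
    generate_dose_response,
    generate_expression,
    generate_survival,
    generate_treatment_expression,
    stream,
)


class TestAnnotation:
    def test_deterministic_under_seed(self, default_config):
        a = generate_annotation(default_config)
        b = generate_annotation(default_config)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_gene_count_and_spacing_floor(self, default_config):
        tss = generate_annotation(default_config)
        assert len(tss) == default_config.n_genes
        pos = np.sort(tss.table["tss"].to_numpy())
        assert np.diff(pos).min() >= 0.2 * default_config.min_tss_spacing

    def test_driver_clearance_guaranteed(self, default_config):
        tss = generate_annotation(default_config)
        drivers = default_config.driver_genes
        dpos = np.array([tss.position(g)[1] for g in drivers])
        others = np.array([
            tss.position(g)[1] for g in tss.genes if g not in set(drivers)
        ])
        gap = np.abs(dpos[:, None] - others[None, :]).min()
        assert gap >= default_config.driver_clearance

    def test_genome_too_small_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=0, genome_length=500_000, n_genes=400)

    def test_different_seeds_differ(self):
        a = generate_annotation(SimulationConfig(seed=1))
        b = generate_annotation(SimulationConfig(seed=2))
        assert not a.table["tss"].equals(b.table["tss"])


class TestChipseq:
    def test_ground_truth_is_planted_set(self, default_config, study):
        assert study.ground_truth_se_genes == set(default_config.driver_genes)
        assert len(study.ground_truth_se_genes) == default_config.n_planted_se_genes

    def test_cluster_gaps_below_stitch_distance(self, default_config, study):
        # within the background-free margin around a driver, only its cluster
        for line, peaks in study.chipseq.items():
            for g in default_config.driver_genes:
                tss = study.annotation.position(g)[1]
                members = [
                    p for p in peaks
                    if tss <= p.interval.start <= tss + default_config.background_peak_margin - 5_000
                ]
                assert len(members) == default_config.cluster.peaks_per_cluster
                gaps = [
                    b.interval.start - a.interval.end
                    for a, b in zip(members, members[1:])
                ]
                assert max(gaps) < 12_500

    def test_clusters_avoid_promoter_windows(self, default_config, study):
        for g in default_config.driver_genes:
            tss = study.annotation.position(g)[1]
            for p in study.chipseq["LINE1"]:
                if tss <= p.interval.start <= tss + default_config.driver_clearance:
                    assert abs(p.interval.midpoint - tss) > 2_500

    def test_deterministic_under_seed(self, default_config, study):
        again, _ = generate_chipseq_samples(default_config, study.annotation)
        assert again["LINE3"] == study.chipseq["LINE3"]


class TestExpression:
    def test_planted_shift_within_t_interval(self, default_config, study):
        spec = default_config.expression
        m = study.expression["DS1"]
        g3 = m.values[m.samples_in_group("G3")]
        nc = m.values[m.samples_in_group("NC")]
        diff = (g3.mean(axis=1) - nc.mean(axis=1)).loc[
            sorted(study.ground_truth_se_genes)
        ]
        se = spec.noise_sd * np.sqrt(2.0 / spec.n_per_group)
        assert (np.abs(diff - spec.planted_log2_shift) < 3 * se).mean() > 0.95

    def test_null_gene_fdr_type_i_control(self, default_config, study):
        from secircuit.expression import differential_expression

        m = study.expression["DS1"]
        de = differential_expression(m, "G3", "NC")
        null_genes = [g for g in de.index if g not in study.ground_truth_se_genes]
        null = de.loc[null_genes]
        fp = ((null["log2fc"].abs() > 1) & (null["fdr"] < 0.05)).mean()
        assert fp <= 0.05

    def test_too_few_samples_rejected(self, default_config, study):
        cfg = dataclasses.replace(
            default_config,
            expression=dataclasses.replace(default_config.expression, n_per_group=1),
        )
        with pytest.raises(ValueError, match=">= 2"):
            generate_expression(cfg, study.annotation, study.ground_truth_se_genes)

    def test_treatment_design_suppresses_planted(self, default_config, study):
        t = study.treatment
        treated = t.values[t.samples_in_group("treated")].mean(axis=1)
        control = t.values[t.samples_in_group("control")].mean(axis=1)
        diff = (treated - control).loc[sorted(study.ground_truth_se_genes)]
        assert diff.mean() == pytest.approx(
            default_config.expression.treatment_log2_shift, abs=0.5
        )


class TestDependency:
    def test_fractions_match_normal_binomial_oracle(self, default_config, study):
        """Empirical dependent-call rates agree with the closed-form
        Binomial(n_lines, Phi((cut - mu)/sd)) tail for both gene classes."""
        spec = default_config.dependency
        n_lines = default_config.n_cell_lines
        dep = study.dependency.values
        planted = sorted(study.ground_truth_se_genes)
        neutral = [g for g in dep.index if g not in study.ground_truth_se_genes]

        def observed(genes):
            return float(((dep.loc[genes] < -0.1).sum(axis=1) >= 2).mean())

        def expected(mu, sd):
            p = stats.norm.cdf((-0.1 - mu) / sd)
            return float(1 - stats.binom.cdf(1, n_lines, p))

        exp_planted = expected(spec.dependent_mean, spec.dependent_sd)
        exp_neutral = expected(spec.neutral_mean, spec.neutral_sd)
        assert exp_planted >= 0.95  # planted genes are near-surely called
        assert observed(planted) >= 0.95
        # neutral rate matches its oracle within 3 binomial SEs
        se = np.sqrt(exp_neutral * (1 - exp_neutral) / len(neutral))
        assert abs(observed(neutral) - exp_neutral) < 3 * se

    def test_deterministic_under_seed(self, default_config, study):
        again = generate_dependency(
            default_config, study.ground_truth_se_genes, study.annotation
        )
        pd.testing.assert_frame_equal(again.values, study.dependency.values)


class TestSurvival:
    def test_hazard_free_scores_give_no_separation_bias(self, default_config):
        cfg = dataclasses.replace(
            default_config,
            survival=dataclasses.replace(default_config.survival, beta=0.0),
        )
        scores = pd.Series(
            stream(7, "scores").normal(size=100),
            index=[f"p{i}" for i in range(100)],
        )
        t = generate_survival(cfg, scores)
        assert len(t.table) == 100
        assert set(t.event) <= {0, 1}

    def test_censoring_rate_near_target(self, default_config):
        scores = pd.Series(
            stream(8, "scores").normal(size=2_000),
            index=[f"p{i}" for i in range(2_000)],
        )
        cfg = dataclasses.replace(
            default_config,
            survival=dataclasses.replace(default_config.survival, beta=0.0),
        )
        t = generate_survival(cfg, scores)
        censored = 1 - t.event.mean()
        assert censored == pytest.approx(cfg.survival.censoring_rate, abs=0.05)

    def test_nonfinite_hazard_rejected(self, default_config):
        with pytest.raises(ValueError):
            dataclasses.replace(
                default_config,
                survival=dataclasses.replace(
                    default_config.survival, baseline_hazard=float("nan")
                ),
            )


class TestDoseResponse:
    def test_half_effect_at_dm_without_noise(self, default_config):
        dr = generate_dose_response(default_config)
        spec = default_config.dose_response
        single = dr["single_drug1"]
        at_dm = single[np.isclose(single["dose"], spec.dm_1)]
        if len(at_dm):
            assert at_dm["viability"].iloc[0] == pytest.approx(0.5)
        fa = 1 - single["viability"].to_numpy()
        model = 1.0 / (1.0 + (spec.dm_1 / single["dose"].to_numpy()) ** spec.m_1)
        assert np.allclose(fa, model)

    def test_interaction_mode_validation(self, default_config):
        bad = dataclasses.replace(
            default_config,
            dose_response=DoseResponseSpec(interaction="synergistic", gamma=1.5),
        )
        with pytest.raises(ValueError, match="gamma < 1"):
            generate_dose_response(bad)
        with pytest.raises(ValueError, match="interaction"):
            generate_dose_response(dataclasses.replace(
                default_config,
                dose_response=DoseResponseSpec(interaction="bliss"),
            ))


class TestSeedPolicy:
    def test_streams_independent_by_name(self):
        a = stream(5, "alpha").normal(size=4)
        b = stream(5, "beta").normal(size=4)
        assert not np.allclose(a, b)
        assert np.allclose(a, stream(5, "alpha").normal(size=4))

    def test_config_invariants(self):
        with pytest.raises(ValueError, match="intra-cluster gap"):
            SimulationConfig(
                cluster=dataclasses.replace(
                    SimulationConfig().cluster, intra_cluster_gap=13_000
                )
            )
        with pytest.raises(ValueError, match="positive"):
            SimulationConfig(n_genes=0)
        with pytest.raises(ValueError, match="strict subset"):
            SimulationConfig(n_genes=10, n_planted_se_genes=10, genome_length=10**8)
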