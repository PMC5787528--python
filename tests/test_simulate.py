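"""Ground-truth bookkeeping and distributional behavior of the generator."""

import numpy as np
import pandas as pd
import pytest

from cacsomatic.errors import InvalidArgumentError
from cacsomatic.simulate import (SimConfig, generate_reference,
                                 simulate_clinical, simulate_cohort,
                                 simulate_duration_groups, simulate_expression,
                                 simulate_methylation_and_mutations)

PANEL = [("GENE1", "chrS", 101, 300), ("GENE2", "chrS", 501, 700)]


class TestReference:
    def test_gc_zero_forces_at_only(self):
        seq = generate_reference(10, gc_fraction=0.0, seed=1)
        assert set(seq) <= {"A", "T"} and len(seq) == 10

    def test_gc_fraction_within_3_binomial_sd(self):
        n = 10_000
        seq = generate_reference(n, gc_fraction=0.5, seed=7)
        gc = sum(b in "GC" for b in seq)
        sd = np.sqrt(n * 0.25)
        assert abs(gc - n * 0.5) < 3 * sd

    def test_determinism(self):
        assert generate_reference(500, 0.4, seed=42) == \
            generate_reference(500, 0.4, seed=42)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidArgumentError):
            generate_reference(2, 0.5, seed=0)


class TestCohort:
    def test_zero_somatic_rate_plants_nothing(self):
        cfg = SimConfig(n_samples=4, ref_length=800, panel=tuple(PANEL),
                        somatic_rate_per_gene=0.0, depth_mean=60, seed=3,
                        recurrent_artifact_n_samples=4)
        ref = generate_reference(800, 0.5, seed=3)
        _, truth = simulate_cohort(cfg, ref)
        assert all(len(v) == 0 for v in truth.somatic.values())

    def test_recurrent_artifact_in_exactly_n_samples(self):
        cfg = SimConfig(n_samples=20, ref_length=800, panel=tuple(PANEL),
                        depth_mean=60, recurrent_artifact_n_samples=9, seed=5)
        ref = generate_reference(800, 0.5, seed=5)
        _, truth = simulate_cohort(cfg, ref)
        carriers = [s for s in truth.samples
                    if any(v.kind == "recurrent" for v in truth.artifacts[s])]
        assert len(carriers) == 9

    def test_mean_depth_within_3_se(self):
        cfg = SimConfig(n_samples=2, ref_length=1500,
                        panel=(("G", "chrS", 1, 1000),), depth_mean=150,
                        somatic_rate_per_gene=0.0, germline_het_rate=0.0,
                        ffpe_ct_rate=0.0, biased_artifact_rate=0.0,
                        n_recurrent_artifacts=0,
                        recurrent_artifact_n_samples=2, seed=9)
        ref = generate_reference(1500, 0.5, seed=9)
        obs, _ = simulate_cohort(cfg, ref)
        depths = obs["S01"].groupby("pos").size()
        se = np.sqrt(150 / len(depths))
        assert abs(depths.mean() - 150) < 3 * se

    def test_truth_classes_are_disjoint_per_sample(self, small_cohort):
        _, _, _, truth = small_cohort
        for s in truth.samples:
            germ = {v.key for v in truth.germline[s]}
            som = {v.key for v in truth.somatic[s]}
            art = {v.key for v in truth.artifacts[s]}
            assert not (germ & som) and not (som & art)

    def test_determinism_of_observations(self):
        cfg = SimConfig(n_samples=2, ref_length=800, panel=tuple(PANEL),
                        depth_mean=50, recurrent_artifact_n_samples=2, seed=21)
        ref = generate_reference(800, 0.5, seed=21)
        obs1, _ = simulate_cohort(cfg, ref)
        obs2, _ = simulate_cohort(cfg, ref)
        for s in obs1:
            pd.testing.assert_frame_equal(obs1[s], obs2[s])

    def test_empty_panel_rejected(self):
        ref = generate_reference(100, 0.5, seed=0)
        with pytest.raises(InvalidArgumentError):
            simulate_cohort(SimConfig(panel=(), ref_length=100,
                                      recurrent_artifact_n_samples=1,
                                      n_samples=2), ref)

    def test_ffpe_artifacts_sit_below_snv_threshold(self, small_cohort):
        _, _, obs, truth = small_cohort
        for s in truth.samples:
            depth = obs[s].groupby("pos").size()
            for v in truth.artifacts[s]:
                if v.kind != "ffpe_ct":
                    continue
                alt_n = int(((obs[s]["pos"] == v.pos) &
                             (obs[s]["obs_allele"] == v.allele)).sum())
                assert alt_n / depth[v.pos] <= 0.05


class TestMethylation:
    # large enough that every methylation bin holds >= 1000 CpGs, the regime
    # the 3-SD Monte-Carlo tolerance is meant for
    REF = generate_reference(100_000, 0.5, seed=13)

    def test_zero_rates_give_zero_mutations(self):
        _, flags = simulate_methylation_and_mutations(self.REF, slope=0.0,
                                                      base_rate=0.0, seed=1)
        assert flags.sum() == 0

    def test_track_aligns_with_reference_cpgs(self):
        track, flags = simulate_methylation_and_mutations(self.REF, seed=2)
        assert len(track) == len(flags) > 0
        for pos in track["pos"].head(50):
            assert self.REF[pos - 1:pos + 1] == "CG"

    def test_per_bin_rates_match_theory_within_3_sd(self):
        base, slope = 0.01, 0.09
        track, flags = simulate_methylation_and_mutations(
            self.REF, slope=slope, base_rate=base, seed=3)
        levels = track["level"].to_numpy()
        for lo in np.arange(0, 1, 0.2):
            sel = (levels >= lo) & (levels < lo + 0.2)
            n = sel.sum()
            expected = base + slope * levels[sel].mean()
            sd = np.sqrt(expected * (1 - expected) / n)
            assert abs(flags[sel].mean() - expected) < 3 * sd

    def test_invalid_rates_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_methylation_and_mutations(self.REF, slope=0.5,
                                               base_rate=0.6, seed=0)


class TestExpression:
    def test_cohort_of_6_plus_11_has_17_samples(self):
        mat, labels, _ = simulate_expression(cluster_sizes=(6, 11), seed=1)
        assert mat.shape[1] == 17 and (labels == "A").sum() == 6

    def test_module_genes_elevated_in_cluster_a(self):
        mat, labels, module = simulate_expression(effect=1.5, seed=2)
        loga = np.log10(mat.loc[module, labels == "A"]).mean(axis=1)
        logb = np.log10(mat.loc[module, labels == "B"]).mean(axis=1)
        assert (loga - logb).mean() == pytest.approx(1.5, abs=0.2)

    def test_values_nonnegative_and_null_effect_flat(self):
        mat, labels, module = simulate_expression(effect=0.0, seed=3)
        assert (mat.to_numpy() >= 0).all()
        diff = (np.log10(mat.loc[module, labels == "A"]).mean(axis=1) -
                np.log10(mat.loc[module, labels == "B"]).mean(axis=1))
        assert abs(diff.mean()) < 0.2


class TestClinical:
    def test_determinism_and_schema(self, small_cohort):
        _, _, _, truth = small_cohort
        t1 = simulate_clinical(truth, carrier_gene="GENE1", seed=4)
        t2 = simulate_clinical(truth, carrier_gene="GENE1", seed=4)
        pd.testing.assert_frame_equal(t1, t2)
        assert set(t1["disease"]) <= {"UC", "CD"}
        assert (t1["duration_months"] > 0).all()

    def test_unknown_carrier_gene_rejected(self, small_cohort):
        _, _, _, truth = small_cohort
        with pytest.raises(InvalidArgumentError):
            simulate_clinical(truth, carrier_gene="NOSUCH", seed=0)

    def test_duration_groups_recover_configured_means(self):
        carrier, noncarrier = simulate_duration_groups(
            400, 400, mean_carrier=328, mean_noncarrier=215, seed=6)
        assert carrier.mean() == pytest.approx(328, rel=0.1)
        assert noncarrier.mean() == pytest.approx(215, rel=0.1)
        assert (carrier > 0).all() and (noncarrier > 0).all()
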