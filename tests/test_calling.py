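"""Unit behavior of the tumor-only caller: quality skips, strict clauses,
bias tests, and the cohort filters."""

import numpy as np
import pandas as pd
import pytest

from cacsomatic.calling import (AlleleObservations, CallerThresholds,
                                SiteCounts, VariantCall, call_indel, call_snv,
                                filter_common, filter_recurrent, pile_site,
                                run_caller)
from cacsomatic.errors import InvalidArgumentError

TH = CallerThresholds()


def _obs(n, allele="A", bq=35, mq=60, pos=10):
    return pd.DataFrame({
        "sample_id": "S1", "contig": "chr1", "pos": pos, "ref_base": "A",
        "obs_allele": allele, "base_quality": bq, "mapping_quality": mq,
        "read_pos_fraction": np.linspace(0.05, 0.95, n), "strand": "+",
    }, index=range(n))


class TestPileSite:
    def test_base_quality_skip_is_strictly_below_20(self):
        df = pd.concat([_obs(9), _obs(1, bq=19)], ignore_index=True)
        assert pile_site(df, TH).depth_pass == 9
        df = pd.concat([_obs(9), _obs(1, bq=20)], ignore_index=True)
        assert pile_site(df, TH).depth_pass == 10

    def test_mapping_quality_skip_is_strictly_below_10(self):
        df = pd.concat([_obs(9), _obs(1, mq=9)], ignore_index=True)
        assert pile_site(df, TH).depth_pass == 9
        df = pd.concat([_obs(9), _obs(1, mq=10)], ignore_index=True)
        assert pile_site(df, TH).depth_pass == 10

    def test_indels_exempt_from_base_quality_skip_only(self):
        df = pd.concat([_obs(8), _obs(1, allele="+TT", bq=2),
                        _obs(1, allele="+TT", bq=2, mq=9)], ignore_index=True)
        site = pile_site(df, TH)
        assert site.depth_pass == 9
        assert site.alleles["+TT"].count == 1

    def test_depth_is_sum_of_allele_counts(self):
        df = pd.concat([_obs(6), _obs(3, allele="G"), _obs(2, allele="+A")],
                       ignore_index=True)
        site = pile_site(df, TH)
        assert site.depth_pass == sum(a.count for a in site.alleles.values())

    def test_mixed_sites_rejected(self):
        df = pd.concat([_obs(2, pos=10), _obs(2, pos=11)], ignore_index=True)
        with pytest.raises(InvalidArgumentError):
            pile_site(df, TH)


def _site(depth, alt_count, alt="G", ref_attrs=True):
    rng = np.random.default_rng(5)
    site = SiteCounts(sample_id="S1", contig="chr1", pos=10, ref_base="A",
                      depth_pass=depth)

    def mk(n):
        return AlleleObservations(
            count=n, base_quality=rng.normal(35, 3, n),
            mapping_quality=np.full(n, 60.0),
            read_pos_fraction=rng.uniform(0, 1, n),
            strand=np.array(["+"] * n))

    if ref_attrs and depth - alt_count > 0:
        site.alleles["A"] = mk(depth - alt_count)
    site.alleles[alt] = mk(alt_count)
    return site


class TestCallSNV:
    def test_all_clauses_satisfied_passes(self):
        call = call_snv(_site(100, 10), "G", TH)
        assert call.passed and call.vaf == pytest.approx(0.10)

    def test_depth_boundary_is_strict(self):
        assert "lowdepth" in call_snv(_site(50, 10), "G", TH).filters
        assert "lowdepth" not in call_snv(_site(51, 10), "G", TH).filters

    def test_vaf_boundary_is_strict(self):
        assert "lowvaf" in call_snv(_site(200, 10), "G", TH).filters   # 5.0%
        assert "lowvaf" not in call_snv(_site(200, 11), "G", TH).filters

    def test_biased_read_positions_fail_rpbias(self):
        site = _site(150, 15)
        site.alleles["G"].read_pos_fraction = np.random.default_rng(3).uniform(
            0, 0.1, 15)
        call = call_snv(site, "G", TH)
        assert "rpbias" in call.filters and call.bias_p[2] <= 0.01

    def test_no_reference_reads_makes_bias_non_assessable(self):
        call = call_snv(_site(100, 100, ref_attrs=False), "G", TH)
        assert call.bias_p is None and call.passed

    def test_zero_count_allele_rejected(self):
        with pytest.raises(InvalidArgumentError):
            call_snv(_site(100, 10), "T", TH)


class TestCallIndel:
    def test_passing_indel(self):
        call = call_indel(_site(100, 21, alt="+TA"), "+TA", TH)
        assert call.passed and call.variant_type == "INDEL"

    def test_support_boundary_is_strict(self):
        assert "lowsupport" in call_indel(_site(100, 20, alt="+TA"), "+TA", TH).filters

    def test_low_vaf_indel(self):
        call = call_indel(_site(300, 25, alt="-G"), "-G", TH)
        assert "lowvaf" in call.filters and "lowsupport" not in call.filters

    def test_no_bias_tests_for_indels(self):
        assert call_indel(_site(100, 21, alt="+TA"), "+TA", TH).bias_p is None


def _vc(sample, pos, alt="G", filters=()):
    return VariantCall(sample_id=sample, contig="chr1", pos=pos, ref="A",
                       alt=alt, variant_type="SNV", depth=100, alt_count=20,
                       vaf=0.2, bias_p=(0.5, 0.5, 0.5), filters=set(filters))


class TestCohortFilters:
    def test_filter_common_is_allele_exact(self):
        calls = [_vc("S1", 10, "G"), _vc("S1", 10, "T"), _vc("S1", 20, "G")]
        filter_common(calls, {("chr1", 10, "A", "G")})
        assert [("dbsnp" in c.filters) for c in calls] == [True, False, False]

    def test_recurrence_boundary_more_than_8(self):
        cohort9 = {f"S{i}": [_vc(f"S{i}", 10)] for i in range(9)}
        filter_recurrent(cohort9, max_recurrence=8)
        assert all("recurrent" in calls[0].filters for calls in cohort9.values())
        cohort8 = {f"S{i}": [_vc(f"S{i}", 10)] for i in range(8)}
        filter_recurrent(cohort8, max_recurrence=8)
        assert all(calls[0].passed for calls in cohort8.values())

    def test_recurrence_is_idempotent(self):
        cohort = {f"S{i}": [_vc(f"S{i}", 10)] for i in range(10)}
        filter_recurrent(cohort, max_recurrence=8)
        snapshot = {s: [set(c.filters) for c in calls]
                    for s, calls in cohort.items()}
        filter_recurrent(cohort, max_recurrence=8)
        assert snapshot == {s: [set(c.filters) for c in calls]
                            for s, calls in cohort.items()}

    def test_passed_basis_ignores_bias_filtered_samples_raw_does_not(self):
        # 5 of 12 carriers lost a bias test; they still carry the allele
        cohort = {f"S{i}": [_vc(f"S{i}", 10, filters={"bqbias"} if i < 5 else ())]
                  for i in range(12)}
        filter_recurrent(cohort, max_recurrence=8, basis="passed")
        # only 7 samples count as detected under the 'passed' reading
        assert all("recurrent" not in c.filters
                   for calls in cohort.values() for c in calls)
        filter_recurrent(cohort, max_recurrence=8, basis="raw")
        # the raw reading sees the allele in all 12 samples
        assert all("recurrent" in c.filters
                   for calls in cohort.values() for c in calls)


class TestRunCaller:
    def test_unknown_contig_errors(self, small_cohort):
        _, ref, obs, truth = small_cohort
        with pytest.raises(InvalidArgumentError, match="contig"):
            run_caller(obs, {"other": ref}, set(), TH)

    def test_raising_thresholds_shrinks_passed_set(self, small_cohort):
        """Filter monotonicity: stricter thresholds yield a subset of calls."""
        _, ref, obs, truth = small_cohort
        reference = {truth.contig: ref}
        loose = run_caller(obs, reference, truth.mini_dbsnp, TH, panel=truth.panel)
        strict = run_caller(obs, reference, truth.mini_dbsnp,
                            CallerThresholds(min_depth=80, min_vaf_snv=0.2),
                            panel=truth.panel)
        loose_keys = {(s,) + c.key for s, cs in loose.calls.items()
                      for c in cs if c.passed}
        strict_keys = {(s,) + c.key for s, cs in strict.calls.items()
                       for c in cs if c.passed}
        assert strict_keys <= loose_keys

    def test_unreachable_depth_threshold_kills_all_calls(self, small_cohort):
        cfg, ref, obs, truth = small_cohort
        result = run_caller(obs, {truth.contig: ref}, truth.mini_dbsnp,
                            CallerThresholds(min_depth=10_000))
        assert all(not c.passed for cs in result.calls.values() for c in cs)

    def test_mutation_table_marks_genes_with_passed_calls(self, small_cohort):
        cfg, ref, obs, truth = small_cohort
        result = run_caller(obs, {truth.contig: ref}, truth.mini_dbsnp, TH,
                            panel=truth.panel)
        table = result.mutation_table
        for s in truth.samples:
            genes_hit = {c.pos for c in result.passed(s)}
            for gene, _, start, end in truth.panel:
                expected = any(start <= p <= end for p in genes_hit)
                assert bool(table.loc[s, gene]) == expected

    def test_accounting_conserves_candidates(self, small_cohort):
        cfg, ref, obs, truth = small_cohort
        result = run_caller(obs, {truth.contig: ref}, truth.mini_dbsnp, TH)
        for counts in result.counts.values():
            assert counts["candidates"] == counts["passed"] + \
                sum(counts["filtered_by_tag"].values())
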