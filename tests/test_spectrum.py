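"""96-class spectrum construction, CpG summaries, trend test, TpT→GpT flags."""

from itertools import product
from types import SimpleNamespace

import numpy as np
import pytest

from cacsomatic.errors import InvalidArgumentError, UndefinedTestError
from cacsomatic.simulate import generate_reference, simulate_methylation_and_mutations
from cacsomatic.spectrum import (LABELS_96, Spectrum96, classify_substitution,
                                 cochran_armitage_trend, compute_spectrum,
                                 ct_cpg_summary, methylation_trend_analysis,
                                 tpt_gpt_per_sample)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestClassify:
    def test_pyrimidine_center_unchanged(self):
        assert classify_substitution("ACG", "C", "T") == "A[C>T]G"

    def test_purine_center_strand_collapsed(self):
        # revcomp(AGT) = ACT; G>A maps to C>T
        assert classify_substitution("AGT", "G", "A") == "A[C>T]T"

    def test_exhaustive_enumeration_hits_96_classes_twice_each(self):
        """All 4x3x16 = 192 (context, alt) inputs map onto exactly 96 labels,
        each hit exactly twice (once per strand)."""
        from collections import Counter
        hits = Counter()
        for five, ref, three in product("ACGT", repeat=3):
            for alt in "ACGT":
                if alt == ref:
                    continue
                hits[classify_substitution(five + ref + three, ref, alt)] += 1
        assert len(hits) == 96 and set(hits.values()) == {2}
        assert set(hits) == set(LABELS_96)

    def test_strand_invariance(self):
        for five, ref, three in product("ACGT", repeat=3):
            for alt in "ACGT":
                if alt == ref:
                    continue
                fwd = classify_substitution(five + ref + three, ref, alt)
                rc_ctx = COMP[three] + COMP[ref] + COMP[five]
                rev = classify_substitution(rc_ctx, COMP[ref], COMP[alt])
                assert fwd == rev

    def test_ambiguous_base_unclassifiable(self):
        with pytest.raises(InvalidArgumentError):
            classify_substitution("ANG", "N", "T")


def _call(pos, ref, alt, passed=True, vtype="SNV"):
    return SimpleNamespace(contig="c", pos=pos, ref=ref, alt=alt,
                           variant_type=vtype, passed=passed, sample_id="S1")


class TestSpectrum:
    REF = {"c": "TACGTT"}

    def test_zero_calls_zero_vector(self):
        sp = compute_spectrum([], self.REF, sample_id="S1")
        assert sp.counts.sum() == 0 and sp.n_snvs == 0

    def test_single_call_lands_in_its_class(self):
        sp = compute_spectrum([_call(3, "C", "T")], self.REF)
        assert sp.as_series()["A[C>T]G"] == 1 and sp.n_snvs == 1

    def test_terminus_calls_excluded_with_count(self):
        sp = compute_spectrum([_call(1, "T", "A"), _call(3, "C", "T")], self.REF)
        assert sp.n_snvs == 1 and sp.n_excluded == 1

    def test_failed_and_indel_calls_ignored(self):
        calls = [_call(3, "C", "T", passed=False),
                 _call(3, "C", "+TT", vtype="INDEL")]
        assert compute_spectrum(calls, self.REF).n_snvs == 0

    def test_methylation_driven_mutations_fill_only_ncg_classes(self):
        ref = generate_reference(20_000, 0.5, seed=17)
        track, flags = simulate_methylation_and_mutations(ref, slope=0.2,
                                                          base_rate=0.05,
                                                          seed=17)
        calls = [_call(int(p), "C", "T")
                 for p in track.loc[flags, "pos"] if 1 < p < len(ref)]
        sp = compute_spectrum(calls, {"c": ref})
        cpg_classes = [f"{f}[C>T]G" for f in "ACGT"]
        assert sp.n_snvs > 50
        assert sp.as_series()[cpg_classes].sum() == sp.n_snvs


class TestCtCpGSummary:
    def test_zero_spectrum(self):
        assert ct_cpg_summary(Spectrum96("s", np.zeros(96, dtype=int))) == \
            (0, 0, 0.0, 0.0)

    def test_small_arithmetic(self):
        counts = np.zeros(96, dtype=int)
        counts[LABELS_96.index("A[C>T]G")] = 3
        counts[LABELS_96.index("A[C>T]T")] = 1
        n_ct, n_cpg, frac_ct, frac_cpg = ct_cpg_summary(Spectrum96("s", counts))
        assert (n_ct, n_cpg) == (4, 3)
        assert frac_ct == 1.0 and frac_cpg == pytest.approx(0.75)

    def test_cohort_scale_cpg_fraction(self):
        """A cohort with 450 of 716 C>T transitions at CpG reproduces the
        63% CpG share characteristic of deamination-driven colorectal
        tumors."""
        counts = np.zeros(96, dtype=int)
        counts[LABELS_96.index("A[C>T]G")] = 450
        counts[LABELS_96.index("A[C>T]A")] = 266
        counts[LABELS_96.index("A[T>C]A")] = 1517 - 716
        n_ct, n_cpg, frac_ct, frac_cpg = ct_cpg_summary(Spectrum96("s", counts))
        assert (n_ct, n_cpg) == (716, 450)
        assert frac_cpg == pytest.approx(0.628, abs=5e-4)
        assert frac_ct == pytest.approx(716 / 1517, abs=1e-9)


class TestTrend:
    def test_equal_rates_give_zero_statistic(self):
        res = cochran_armitage_trend([100] * 5, [10] * 5, range(5))
        assert res.T == pytest.approx(0.0, abs=1e-9)
        assert res.Z == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(0.5)

    def test_closed_form_matches_permutation_oracle(self):
        from oracles import trend_permutation_p
        n = [80, 80, 80]
        r = [4, 8, 14]
        res = cochran_armitage_trend(n, r, [0.1, 0.5, 0.9], sidedness="one")
        p_perm = trend_permutation_p(n, r, [0.1, 0.5, 0.9], n_perm=100_000,
                                     seed=1)
        mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / 100_000)
        assert res.p == pytest.approx(p_perm, abs=max(mc_err, 2e-3))

    def test_single_occupied_bin_is_undefined(self):
        with pytest.raises(UndefinedTestError):
            cochran_armitage_trend([100, 0], [5, 0], [0, 1])

    def test_scores_must_increase(self):
        with pytest.raises(InvalidArgumentError):
            cochran_armitage_trend([10, 10], [1, 2], [1, 1])

    def test_methylation_binning_and_sidedness(self):
        rng = np.random.default_rng(23)
        levels = rng.uniform(0, 1, 5000)
        mutated = rng.random(5000) < 0.01 + 0.09 * levels
        res = methylation_trend_analysis(levels, mutated)
        assert res.p < 1e-3 and res.Z > 3
        res2 = methylation_trend_analysis(levels, mutated, sidedness="two")
        assert res2.p == pytest.approx(min(1, 2 * res.p), rel=1e-9)

    def test_all_levels_in_one_bin_propagates_undefined(self):
        levels = np.full(200, 0.5)
        mutated = np.zeros(200, dtype=bool)
        mutated[:5] = True
        with pytest.raises(UndefinedTestError):
            methylation_trend_analysis(levels, mutated)


class TestTpTGpT:
    def _spectrum(self, count):
        counts = np.zeros(96, dtype=int)
        counts[LABELS_96.index("T[T>G]T")] = count
        return Spectrum96(f"s{count}", counts)

    def test_zero_spectrum_not_flagged(self):
        out = tpt_gpt_per_sample([self._spectrum(0)])
        assert out.loc[0, "tpt_gpt"] == 0 and not out.loc[0, "flagged"]

    @pytest.mark.parametrize("count,flagged", [(19, False), (20, True),
                                               (21, True), (48, True)])
    def test_inclusive_flag_boundary(self, count, flagged):
        out = tpt_gpt_per_sample([self._spectrum(count)])
        assert bool(out.loc[0, "flagged"]) is flagged

    def test_counts_sum_over_all_four_contexts(self):
        counts = np.zeros(96, dtype=int)
        for three in "ACGT":
            counts[LABELS_96.index(f"T[T>G]{three}")] = 5
        counts[LABELS_96.index("A[T>G]A")] = 7   # not TpT: excluded
        out = tpt_gpt_per_sample([Spectrum96("s", counts)])
        assert out.loc[0, "tpt_gpt"] == 20
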