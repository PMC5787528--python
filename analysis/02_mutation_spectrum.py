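#!/usr/bin/env python
"""Trinucleotide spectra, CpG C>T burden, methylation trend, TpT→GpT flags.

Reads the per-sample VCFs written by 01_simulate_and_call.py, classifies the
passed SNVs into the 96 strand-collapsed classes, summarizes the CpG share of
C>T transitions, and tests whether the CpG C>T mutation rate rises with
methylation (on a fresh methylation/mutation simulation over the same
reference, one-sided Cochran-Armitage trend test).

Writes results/spectrum/{spectrum96.tsv, summary.tsv, trend.tsv, tpt_gpt.tsv}.
"""

from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd

from cacsomatic import io
from cacsomatic.simulate import simulate_methylation_and_mutations
from cacsomatic.spectrum import (Spectrum96, compute_spectrum, ct_cpg_summary,
                                 methylation_trend_analysis, tpt_gpt_per_sample)

IN = Path("results/cohort")
OUT = Path("results/spectrum")
SEED = 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    reference = io.read_fasta(IN / "reference.fa")

    spectra = []
    for vcf in sorted((IN / "vcf").glob("*.vcf")):
        df = io.read_vcf_calls(vcf)
        calls = [SimpleNamespace(contig=r.contig, pos=r.pos, ref=r.ref,
                                 alt=r.alt, variant_type="SNV", passed=True)
                 for r in df.itertuples()
                 if r.filter == "PASS" and len(r.ref) == 1 and len(r.alt) == 1]
        spectra.append(compute_spectrum(calls, reference, sample_id=vcf.stem))
    mat = pd.DataFrame({sp.sample_id: sp.as_series() for sp in spectra})
    io.write_matrix(mat, OUT / "spectrum96.tsv", index_label="class")

    cohort = Spectrum96("cohort", mat.sum(axis=1).to_numpy())
    n_ct, n_cpg, frac_ct, frac_cpg = ct_cpg_summary(cohort)
    pd.Series({"n_snvs": cohort.n_snvs, "n_ct": n_ct, "n_ct_cpg": n_cpg,
               "fraction_ct": frac_ct, "fraction_cpg_of_ct": frac_cpg}
              ).to_csv(OUT / "summary.tsv", sep="\t", header=False)
    print(f"cohort: {cohort.n_snvs} SNVs, {n_ct} C>T "
          f"({100 * frac_ct:.0f}%), {n_cpg} at CpG ({100 * frac_cpg:.0f}% of C>T)")

    contig = next(iter(reference))
    track, flags = simulate_methylation_and_mutations(reference[contig],
                                                      slope=0.09,
                                                      base_rate=0.01, seed=SEED,
                                                      contig=contig)
    trend = methylation_trend_analysis(track["level"].to_numpy(), flags)
    pd.DataFrame({"bin_low": trend.bin_edges[:-1],
                  "bin_high": trend.bin_edges[1:],
                  "n_cpg": trend.n_per_bin, "n_mutated": trend.r_per_bin}
                 ).assign(Z=trend.Z, p=trend.p
                 ).to_csv(OUT / "trend.tsv", sep="\t", index=False)
    print(f"methylation trend over {len(track)} CpGs: Z={trend.Z:.2f}, "
          f"one-sided p={trend.p:.2e}")

    tpt = tpt_gpt_per_sample(spectra, flag_threshold=20)
    tpt.to_csv(OUT / "tpt_gpt.tsv", sep="\t", index=False)
    print(f"TpT→GpT burden >= 20 in {int(tpt['flagged'].sum())} of "
          f"{len(tpt)} samples")


if __name__ == "__main__":
    main()
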