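"""Tumor-only somatic variant calling for deep targeted panels.

The caller works from per-base pileup observations rather than alignments:
observations below the quality skips are discarded, per-site allele counts are
formed, and candidate non-reference alleles are called as SNVs or INDELs under
strict thresholds.  SNV candidates additionally face three read-attribute bias
tests (base quality, mapping quality, read position), each a two-sided
rank-sum comparison of alt-supporting against reference-supporting reads —
alleles whose supporting reads look systematically different from the
reference reads are artifacts, not variants.  Two cohort-level filters handle
what per-sample evidence cannot: known common (population) variants are tagged
``dbsnp``, and alleles detected in more samples than independent somatic
events plausibly allow are tagged ``recurrent``.

All threshold comparisons are strict: depth must exceed ``min_depth``, VAF
must exceed the SNV/INDEL thresholds, indel support must exceed
``min_indel_support``, bias p-values must exceed ``bias_alpha``, and the
recurrence filter removes alleles seen in more than ``max_recurrence``
samples.

Filters tag calls instead of deleting them, so every decision is auditable;
``passed`` is simply "no tags".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedTestError
from .stats import rank_sum_test

__all__ = [
    "CallerThresholds", "AlleleObservations", "SiteCounts", "VariantCall",
    "pile_site", "bias_test", "call_snv", "call_indel",
    "filter_common", "filter_recurrent", "run_caller", "CohortCallResult",
    "FILTER_CLAUSE_ORDER",
]

#: first-failing-clause order used for the manifest accounting view
FILTER_CLAUSE_ORDER = ["dbsnp", "lowdepth", "lowvaf", "lowsupport",
                       "bqbias", "mqbias", "rpbias", "recurrent"]


@dataclass(frozen=True)
class CallerThresholds:
    """Strict calling thresholds (a call requires the quantity to exceed the
    threshold, never to equal it)."""

    min_base_quality: int = 20      # observations with BQ < this are skipped
    min_mapping_quality: int = 10   # observations with MQ < this are skipped
    min_depth: int = 50             # call requires depth > min_depth
    min_vaf_snv: float = 0.05       # call requires VAF > min_vaf_snv
    min_vaf_indel: float = 0.10     # indel call requires VAF > min_vaf_indel
    min_indel_support: int = 20     # indel call requires support > this
    bias_alpha: float = 0.01        # call requires each bias p > alpha
    max_recurrence: int = 8         # discard alleles detected in > this many samples

    def __post_init__(self):
        if not (0 < self.min_vaf_snv < 1 and 0 < self.min_vaf_indel < 1):
            raise InvalidArgumentError("VAF thresholds must be in (0,1)")
        if not (0 < self.bias_alpha < 1):
            raise InvalidArgumentError("bias_alpha must be in (0,1)")
        for name in ("min_base_quality", "min_mapping_quality", "min_depth",
                     "min_indel_support", "max_recurrence"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")


@dataclass
class AlleleObservations:
    """Attribute vectors of the reads supporting one allele at one site."""

    count: int
    base_quality: np.ndarray
    mapping_quality: np.ndarray
    read_pos_fraction: np.ndarray
    strand: np.ndarray


@dataclass
class SiteCounts:
    """Post-skip allele counts and attributes at one site of one sample."""

    sample_id: str
    contig: str
    pos: int
    ref_base: str
    depth_pass: int
    alleles: dict[str, AlleleObservations] = field(default_factory=dict)

    @property
    def alt_alleles(self) -> list[str]:
        return [a for a in self.alleles if a != self.ref_base]


@dataclass
class VariantCall:
    sample_id: str
    contig: str
    pos: int
    ref: str
    alt: str
    variant_type: str               # "SNV" or "INDEL"
    depth: int
    alt_count: int
    vaf: float
    bias_p: tuple[float, float, float] | None   # (BQ, MQ, read position); SNV only
    filters: set[str] = field(default_factory=set)

    @property
    def passed(self) -> bool:
        return not self.filters

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def first_failing_tag(self) -> str | None:
        for tag in FILTER_CLAUSE_ORDER:
            if tag in self.filters:
                return tag
        return None


def _is_indel(allele: str) -> bool:
    return allele.startswith(("+", "-"))


def _site_counts_from_arrays(sample_id, contig, pos, ref_base, allele, bq, mq,
                             rpf, strand) -> SiteCounts:
    """Build SiteCounts from post-skip attribute arrays of one site."""
    site = SiteCounts(sample_id=sample_id, contig=contig, pos=int(pos),
                      ref_base=ref_base, depth_pass=len(allele))
    for a in pd.unique(np.asarray(allele, dtype=object)):
        sel = np.asarray(allele) == a
        site.alleles[str(a)] = AlleleObservations(
            count=int(sel.sum()),
            base_quality=np.asarray(bq)[sel].astype(float),
            mapping_quality=np.asarray(mq)[sel].astype(float),
            read_pos_fraction=np.asarray(rpf)[sel].astype(float),
            strand=np.asarray(strand)[sel],
        )
    return site


def pile_site(observations: pd.DataFrame, thresholds: CallerThresholds) -> SiteCounts:
    """Count alleles at one site, skipping low-quality observations.

    Observations with base quality below ``min_base_quality`` or mapping
    quality below ``min_mapping_quality`` are excluded from all counts; indel
    observations are exempt from the base-quality skip (an indel has no single
    base call) but not from the mapping-quality skip.

    All rows must share (sample_id, contig, pos, ref_base).
    """
    df = pd.DataFrame(observations)
    if df.empty:
        raise InvalidArgumentError("pile_site requires at least one observation")
    for col in ("sample_id", "contig", "pos", "ref_base"):
        if df[col].nunique() != 1:
            raise InvalidArgumentError(f"mixed {col} in pile_site input")
    indel = df["obs_allele"].map(_is_indel).to_numpy()
    keep = (df["mapping_quality"].to_numpy() >= thresholds.min_mapping_quality) & (
        indel | (df["base_quality"].to_numpy() >= thresholds.min_base_quality))
    sub = df.loc[keep]
    first = df.iloc[0]
    if sub.empty:
        return SiteCounts(sample_id=str(first["sample_id"]),
                          contig=str(first["contig"]), pos=int(first["pos"]),
                          ref_base=str(first["ref_base"]), depth_pass=0)
    return _site_counts_from_arrays(
        str(first["sample_id"]), str(first["contig"]), int(first["pos"]),
        str(first["ref_base"]), sub["obs_allele"].to_numpy(dtype=object),
        sub["base_quality"].to_numpy(), sub["mapping_quality"].to_numpy(),
        sub["read_pos_fraction"].to_numpy(), sub["strand"].to_numpy())


def bias_test(ref_values, alt_values) -> float:
    """Two-sided rank-sum p-value comparing alt- against ref-supporting reads
    on one read attribute.  Raises :class:`UndefinedTestError` when either
    vector is empty (the caller treats the test as non-assessable)."""
    return rank_sum_test(alt_values, ref_values, alternative="two_sided")


def _make_call(site: SiteCounts, allele: str, variant_type: str,
               filters: set[str], bias_p) -> VariantCall:
    obs = site.alleles[allele]
    return VariantCall(sample_id=site.sample_id, contig=site.contig,
                       pos=site.pos, ref=site.ref_base, alt=allele,
                       variant_type=variant_type, depth=site.depth_pass,
                       alt_count=obs.count,
                       vaf=obs.count / site.depth_pass if site.depth_pass else 0.0,
                       bias_p=bias_p, filters=filters)


def call_snv(site: SiteCounts, alt_allele: str, thresholds: CallerThresholds) -> VariantCall:
    """Evaluate one SNV candidate allele against the calling clauses.

    A failed clause attaches its tag: depth not exceeding ``min_depth`` →
    ``lowdepth``; VAF not exceeding ``min_vaf_snv`` → ``lowvaf``; any of the
    three bias p-values not exceeding ``bias_alpha`` → ``bqbias`` / ``mqbias``
    / ``rpbias``.  If the site has no reference-allele reads the bias tests
    are non-assessable and treated as passing (``bias_p`` is None).
    """
    if _is_indel(alt_allele):
        raise InvalidArgumentError("call_snv requires a base allele; use call_indel")
    if alt_allele == site.ref_base:
        raise InvalidArgumentError("alt allele equals the reference base")
    obs = site.alleles.get(alt_allele)
    if obs is None or obs.count == 0:
        raise InvalidArgumentError(f"allele {alt_allele!r} has no observations")

    filters: set[str] = set()
    if not site.depth_pass > thresholds.min_depth:
        filters.add("lowdepth")
    vaf = obs.count / site.depth_pass
    if not vaf > thresholds.min_vaf_snv:
        filters.add("lowvaf")

    ref_obs = site.alleles.get(site.ref_base)
    bias_p = None
    if ref_obs is not None and ref_obs.count > 0:
        ps = []
        for attr, tag in (("base_quality", "bqbias"),
                          ("mapping_quality", "mqbias"),
                          ("read_pos_fraction", "rpbias")):
            try:
                p = bias_test(getattr(ref_obs, attr), getattr(obs, attr))
            except UndefinedTestError:
                p = 1.0
            ps.append(p)
            if not p > thresholds.bias_alpha:
                filters.add(tag)
        bias_p = tuple(ps)
    return _make_call(site, alt_allele, "SNV", filters, bias_p)


def call_indel(site: SiteCounts, indel_allele: str, thresholds: CallerThresholds) -> VariantCall:
    """Evaluate one INDEL candidate: depth > ``min_depth``, VAF >
    ``min_vaf_indel`` and support reads > ``min_indel_support``; no bias
    tests are applied to indels."""
    if not _is_indel(indel_allele):
        raise InvalidArgumentError("call_indel requires a +SEQ/-SEQ allele")
    obs = site.alleles.get(indel_allele)
    if obs is None or obs.count == 0:
        raise InvalidArgumentError(f"allele {indel_allele!r} has no observations")
    filters: set[str] = set()
    if not site.depth_pass > thresholds.min_depth:
        filters.add("lowdepth")
    if not obs.count / site.depth_pass > thresholds.min_vaf_indel:
        filters.add("lowvaf")
    if not obs.count > thresholds.min_indel_support:
        filters.add("lowsupport")
    return _make_call(site, indel_allele, "INDEL", filters, None)


def filter_common(calls: list[VariantCall], common) -> list[VariantCall]:
    """Tag calls whose (contig, pos, ref, alt) is a known common variant with
    ``dbsnp``.  Matching is allele-exact; ordering is preserved."""
    common = set(common)
    for c in calls:
        if c.key in common:
            c.filters.add("dbsnp")
    return calls


def _detected(call: VariantCall, basis: str) -> bool:
    if basis == "raw":
        # allele meets the per-sample evidence clauses (depth/VAF/support),
        # regardless of bias or dbSNP status
        return not ({"lowdepth", "lowvaf", "lowsupport"} & call.filters)
    if basis == "passed":
        return not (call.filters - {"recurrent"})
    raise InvalidArgumentError(f"unknown recurrence_basis {basis!r}")


def filter_recurrent(cohort_calls: dict[str, list[VariantCall]],
                     max_recurrence: int = 8,
                     basis: str = "raw") -> dict[str, list[VariantCall]]:
    """Tag cohort-recurrent alleles.

    For each (contig, pos, ref, alt), the number of samples in which the
    allele is *detected* is counted once over the full cohort; alleles
    detected in more than ``max_recurrence`` samples gain the ``recurrent``
    tag in every sample carrying them.  ``basis`` selects the detection
    reading: ``"raw"`` (default) counts samples where the allele meets the
    depth/VAF/support clauses; ``"passed"`` counts samples where it passes
    every other filter.  The operation is idempotent.
    """
    counts: dict[tuple, int] = {}
    for calls in cohort_calls.values():
        seen = set()
        for c in calls:
            if c.key not in seen and _detected(c, basis):
                counts[c.key] = counts.get(c.key, 0) + 1
                seen.add(c.key)
    bad = {k for k, n in counts.items() if n > max_recurrence}
    for calls in cohort_calls.values():
        for c in calls:
            if c.key in bad:
                c.filters.add("recurrent")
    return cohort_calls


# ------------------------------------------------------------------ cohort run

@dataclass
class CohortCallResult:
    calls: dict[str, list[VariantCall]]          # all candidates, tagged
    mutation_table: pd.DataFrame | None          # samples x genes, 0/1
    counts: dict[str, dict]                      # per-sample accounting

    def passed(self, sample_id: str) -> list[VariantCall]:
        return [c for c in self.calls[sample_id] if c.passed]


def _candidate_sites(df: pd.DataFrame, thresholds: CallerThresholds):
    """Yield SiteCounts for every site of one sample with >= 1 surviving
    non-reference observation.  Vectorized quality skips; per-site assembly
    only where a candidate exists."""
    sample_id = str(df["sample_id"].iloc[0])
    allele = df["obs_allele"].to_numpy(dtype=object)
    indel = np.array([a[0] in "+-" for a in allele])
    keep = (df["mapping_quality"].to_numpy() >= thresholds.min_mapping_quality) & (
        indel | (df["base_quality"].to_numpy() >= thresholds.min_base_quality))
    sub = df.loc[keep]
    for contig, cdf in sub.groupby("contig", sort=True, observed=True):
        pos = cdf["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        al = cdf["obs_allele"].to_numpy(dtype=object)[order]
        rb = cdf["ref_base"].to_numpy(dtype=object)[order]
        bq = cdf["base_quality"].to_numpy()[order]
        mq = cdf["mapping_quality"].to_numpy()[order]
        rpf = cdf["read_pos_fraction"].to_numpy()[order]
        strand = cdf["strand"].to_numpy(dtype=object)[order]
        alt_pos = np.unique(pos[al != rb])
        lo = np.searchsorted(pos, alt_pos, side="left")
        hi = np.searchsorted(pos, alt_pos, side="right")
        for p, i, j in zip(alt_pos, lo, hi):
            yield _site_counts_from_arrays(sample_id, str(contig), int(p),
                                           str(rb[i]), al[i:j], bq[i:j],
                                           mq[i:j], rpf[i:j], strand[i:j])


def run_caller(observations, reference: dict[str, str], common,
               thresholds: CallerThresholds | None = None,
               panel=None, recurrence_basis: str = "raw") -> CohortCallResult:
    """Run the full calling pipeline over a cohort.

    Parameters
    ----------
    observations
    	Cohort observation DataFrame (observation TSV schema) or a mapping
    	sample_id -> DataFrame.
    reference
        Mapping contig -> sequence.
    common
        Set of (contig, pos, ref, alt) common-variant sites.
    panel
        Optional list of (gene, contig, start, end), 1-based inclusive; when
        given, a samples x genes 0/1 mutation table is built from passed calls.
    recurrence_basis
        Detection reading for the recurrence filter (see
        :func:`filter_recurrent`).
    """
    thresholds = thresholds or CallerThresholds()
    if isinstance(observations, pd.DataFrame):
        groups = {str(s): g for s, g in
                  observations.groupby("sample_id", sort=True, observed=True)}
    else:
        groups = {str(s): g for s, g in observations.items()}

    cohort_calls: dict[str, list[VariantCall]] = {}
    counts: dict[str, dict] = {}
    for sample_id, df in groups.items():
        bad = set(df["contig"].unique()) - set(reference)
        if bad:
            raise InvalidArgumentError(
                f"sample {sample_id}: contig(s) {sorted(bad)} absent from reference")
        calls: list[VariantCall] = []
        for site in _candidate_sites(df, thresholds):
            for alt in site.alt_alleles:
                if _is_indel(alt):
                    calls.append(call_indel(site, alt, thresholds))
                else:
                    calls.append(call_snv(site, alt, thresholds))
        filter_common(calls, common)
        calls.sort(key=lambda c: (c.contig, c.pos, c.alt))
        cohort_calls[sample_id] = calls
        counts[sample_id] = {"observations": int(len(df)),
                             "candidates": len(calls)}
    filter_recurrent(cohort_calls, thresholds.max_recurrence, recurrence_basis)

    for sample_id, calls in cohort_calls.items():
        acct = {tag: 0 for tag in FILTER_CLAUSE_ORDER}
        n_pass = 0
        for c in calls:
            tag = c.first_failing_tag
            if tag is None:
                n_pass += 1
            else:
                acct[tag] += 1
        counts[sample_id].update(passed=n_pass, filtered_by_tag=acct)

    mutation_table = None
    if panel is not None:
        samples = sorted(cohort_calls)
        genes = [g for g, _, _, _ in panel]
        mat = pd.DataFrame(0, index=samples, columns=genes, dtype=int)
        for sample_id, calls in cohort_calls.items():
            for c in calls:
                if not c.passed:
                    continue
                for gene, contig, start, end in panel:
                    if c.contig == contig and start <= c.pos <= end:
                        mat.loc[sample_id, gene] = 1
        mutation_table = mat
    return CohortCallResult(calls=cohort_calls, mutation_table=mutation_table,
                            counts=counts)
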