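"""Synthetic-cohort generator with known ground truth.

The generator emits every input the pipeline consumes — per-base pileup
observations for a targeted gene panel, a reference sequence, a mini common-
variant list, a CpG methylation track with methylation-driven C>T mutations,
a two-cluster expression matrix, and a clinical table — together with a
ground-truth record of every planted signal, so each downstream filter and
test can be scored against what was actually planted.

The observation model mirrors deep targeted sequencing of FFPE tumor tissue:

* per-site depth is Poisson(``depth_mean``);
* reference-supporting reads draw base quality from a discretized
  Normal(35, 3) clipped to [2, 41], mapping quality 60 with a small
  contamination at 0 (these MQ-0 reads exercise the caller's quality skip),
  and read-position fraction Uniform(0, 1);
* true variants (germline and somatic) draw read attributes from the same
  null distributions — a real variant's reads look like everyone else's;
* FFPE-like deamination artifacts are C>T (G>A on the minus strand) at
  realized VAF below the 5% SNV threshold;
* "biased" artifacts have one shifted attribute (default: read-position
  fraction Uniform(0, 0.1), i.e. alt support clustered at read ends);
* recurrent artifacts share an identical (site, allele) across a fixed
  number of samples;
* sequencing errors scatter singleton wrong bases at ``error_rate``.

Coordinates are 1-based inclusive throughout, matching pileup convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .io import CLINICAL_COLUMNS

__all__ = [
    "SimConfig", "SimTruth", "PlantedVariant", "default_panel",
    "generate_reference", "simulate_cohort",
    "simulate_methylation_and_mutations", "simulate_expression",
    "simulate_clinical", "simulate_duration_groups", "score_against_truth",
]

_BASES = np.array(list("ACGT"))


def default_panel(ref_length: int = 26_000,
                  gene_length: int = 250) -> list[tuple[str, str, int, int]]:
    """An 8-gene targeted panel laid out with intergenic gaps.

    Gene names follow the recurrently mutated genes of a colitis-associated
    cancer panel; the coordinates are synthetic.
    """
    names = ["TP53", "APC", "KRAS", "SMAD4", "RNF43", "LTBP4", "TGFBR2", "PIK3CA"]
    spacing = ref_length // len(names)
    panel = []
    for i, name in enumerate(names):
        start = i * spacing + 100
        panel.append((name, "panel_ref", start, start + gene_length - 1))
    if panel[-1][3] > ref_length:
        raise InvalidArgumentError("reference too short for the default panel")
    return panel


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a 20-sample deep-panel cohort: mean depth 150, somatic
    events at VAF 0.15-0.40 (indels 0.20-0.50, set to clear both the 10% VAF
    and the >20 support-read clauses at this depth), FFPE-like C>T artifacts
    at VAF 0.01-0.04, attribute-shifted artifacts at VAF 0.08-0.20, and one
    artifact allele recurring in exactly 9 samples.
    """

    n_samples: int = 20
    ref_length: int = 26_000
    gc_fraction: float = 0.45
    panel: tuple = None                     # list of (gene, contig, start, end)
    depth_mean: float = 150.0
    germline_het_rate: float = 0.003        # P(site is population-polymorphic)
    germline_carrier_prob: float = 0.7      # P(sample is het at a pop site)
    dbsnp_coverage: float = 0.95            # P(pop site listed in mini-dbSNP)
    somatic_rate_per_gene: dict | float = 0.6   # per-sample P(somatic hit in gene)
    somatic_vaf_range: tuple = (0.15, 0.40)
    somatic_indel_fraction: float = 0.2
    somatic_indel_vaf_range: tuple = (0.20, 0.50)
    error_rate: float = 0.002               # per-base miscall probability
    ffpe_ct_rate: float = 0.01              # per C/G site, per sample
    ffpe_vaf_range: tuple = (0.01, 0.04)
    biased_artifact_rate: float = 0.0015    # per site, per sample
    biased_vaf_range: tuple = (0.08, 0.20)
    biased_read_pos_max: float = 0.1        # shifted alt read-position upper bound
    n_recurrent_artifacts: int = 1
    recurrent_artifact_n_samples: int = 9
    recurrent_vaf_range: tuple = (0.15, 0.35)
    base_quality_mean: float = 35.0
    base_quality_sd: float = 3.0
    mapping_quality: int = 60
    mq_zero_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("germline_het_rate", "germline_carrier_prob",
                     "dbsnp_coverage", "error_rate", "ffpe_ct_rate",
                     "biased_artifact_rate", "mq_zero_fraction",
                     "somatic_indel_fraction", "gc_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InvalidArgumentError(f"{name} must be in [0,1]")
        if self.depth_mean <= 0:
            raise InvalidArgumentError("depth_mean must be > 0")
        for name in ("somatic_vaf_range", "somatic_indel_vaf_range",
                     "ffpe_vaf_range", "biased_vaf_range", "recurrent_vaf_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi <= 1):
                raise InvalidArgumentError(f"{name} must satisfy 0 < lo < hi <= 1")
        if self.recurrent_artifact_n_samples > self.n_samples:
            raise InvalidArgumentError(
                "recurrent_artifact_n_samples cannot exceed n_samples")

    def resolved_panel(self) -> list[tuple[str, str, int, int]]:
        return list(self.panel) if self.panel is not None \
            else default_panel(self.ref_length)

    def gene_rates(self) -> dict[str, float]:
        genes = [g for g, _, _, _ in self.resolved_panel()]
        if isinstance(self.somatic_rate_per_gene, dict):
            return {g: float(self.somatic_rate_per_gene.get(g, 0.0)) for g in genes}
        return {g: float(self.somatic_rate_per_gene) for g in genes}


@dataclass(frozen=True)
class PlantedVariant:
    sample_id: str
    contig: str
    pos: int
    ref: str
    allele: str
    vaf: float
    kind: str           # germline_het | somatic | ffpe_ct | biased | recurrent
    gene: str | None = None

    @property
    def key(self):
        return (self.contig, self.pos, self.ref, self.allele)


@dataclass
class SimTruth:
    panel: list
    contig: str
    mini_dbsnp: set = field(default_factory=set)
    germline: dict[str, list[PlantedVariant]] = field(default_factory=dict)
    somatic: dict[str, list[PlantedVariant]] = field(default_factory=dict)
    artifacts: dict[str, list[PlantedVariant]] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return sorted(self.somatic)

    def somatic_gene_carriers(self, gene: str) -> set[str]:
        return {s for s, vs in self.somatic.items()
                if any(v.gene == gene for v in vs)}


def generate_reference(length: int, gc_fraction: float = 0.45,
                       seed: int = 0) -> str:
    """An i.i.d. random sequence with P(G) + P(C) = ``gc_fraction``."""
    if length < 3:
        raise InvalidArgumentError("length must be >= 3 (no trinucleotide "
                                   "context possible below that)")
    if not (0 <= gc_fraction <= 1):
        raise InvalidArgumentError("gc_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _other_base(rng, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[rng.integers(3)]


def _random_indel(rng, reference: str, pos: int) -> str:
    """A pileup-spelled indel anchored at ``pos`` (1-based)."""
    size = int(rng.integers(1, 4))
    if rng.random() < 0.5 or pos + size > len(reference):
        return "+" + "".join(rng.choice(_BASES, size=size))
    return "-" + reference[pos:pos + size]


def _null_attributes(rng, n: int, cfg: SimConfig):
    bq = np.clip(np.rint(rng.normal(cfg.base_quality_mean, cfg.base_quality_sd,
                                    n)), 2, 41).astype(int)
    mq = np.where(rng.random(n) < cfg.mq_zero_fraction, 0,
                  cfg.mapping_quality).astype(int)
    rpf = rng.uniform(0, 1, n)
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    return bq, mq, rpf, strand


def simulate_cohort(config: SimConfig, reference: str):
    """Generate per-sample observation frames and the ground truth.

    Returns ``(observations, truth)`` where ``observations`` maps sample_id
    to an observation DataFrame (schema of the observation TSV) and ``truth``
    is a :class:`SimTruth`.
    """
    cfg = config
    panel = cfg.resolved_panel()
    if not panel:
        raise InvalidArgumentError("panel must not be empty")
    contig = panel[0][1]
    for gene, ctg, start, end in panel:
        if not (1 <= start <= end <= len(reference)):
            raise InvalidArgumentError(f"gene {gene} interval outside reference")

    rng = np.random.default_rng(cfg.seed)
    sites = np.concatenate([np.arange(start, end + 1)
                            for _, _, start, end in panel])
    sites = np.unique(sites)
    n_sites = len(sites)
    ref_at = np.array([reference[p - 1] for p in sites])
    site_gene = {}
    for gene, _, start, end in panel:
        for p in range(start, end + 1):
            site_gene[p] = gene

    truth = SimTruth(panel=panel, contig=contig)
    samples = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    for s in samples:
        truth.germline[s] = []
        truth.somatic[s] = []
        truth.artifacts[s] = []

    # population germline sites, shared across the cohort
    pop_mask = rng.random(n_sites) < cfg.germline_het_rate
    pop_idx = np.flatnonzero(pop_mask)
    pop_alt = np.array([_other_base(rng, ref_at[i]) for i in pop_idx]) \
        if len(pop_idx) else np.array([], dtype=str)
    pop_in_dbsnp = rng.random(len(pop_idx)) < cfg.dbsnp_coverage
    for i, alt, listed in zip(pop_idx, pop_alt, pop_in_dbsnp):
        if listed:
            truth.mini_dbsnp.add((contig, int(sites[i]), str(ref_at[i]), str(alt)))
    pop_carrier = rng.random((cfg.n_samples, len(pop_idx))) < cfg.germline_carrier_prob

    # recurrent artifact alleles, each planted in exactly the configured
    # number of samples
    reserved = set(pop_idx.tolist())
    recurrent_defs = []
    for _ in range(cfg.n_recurrent_artifacts):
        while True:
            i = int(rng.integers(n_sites))
            if i not in reserved:
                break
        reserved.add(i)
        allele = _other_base(rng, ref_at[i])
        carriers = rng.choice(cfg.n_samples,
                              size=cfg.recurrent_artifact_n_samples,
                              replace=False)
        recurrent_defs.append((i, allele, set(carriers.tolist())))

    gene_rates = cfg.gene_rates()
    observations: dict[str, pd.DataFrame] = {}
    for si, sample_id in enumerate(samples):
        depth = rng.poisson(cfg.depth_mean, n_sites)
        used = set(reserved)
        events = []   # (site_index, allele, count, PlantedVariant)

        for j, i in enumerate(pop_idx):
            if pop_carrier[si, j] and depth[i] > 0:
                count = int(rng.binomial(depth[i], 0.5))
                if count == 0:
                    count = 1   # a carrier always leaves at least one read
                v = PlantedVariant(sample_id, contig, int(sites[i]),
                                   str(ref_at[i]), str(pop_alt[j]), 0.5,
                                   "germline_het", site_gene.get(int(sites[i])))
                truth.germline[sample_id].append(v)
                events.append((i, v.allele, count, v))

        for gene, _, start, end in panel:
            if rng.random() >= gene_rates[gene]:
                continue
            gene_sites = np.flatnonzero((sites >= start) & (sites <= end))
            for _ in range(50):
                i = int(rng.choice(gene_sites))
                if i not in used:
                    break
            else:
                continue
            used.add(i)
            if depth[i] == 0:
                continue
            is_indel = rng.random() < cfg.somatic_indel_fraction
            if is_indel:
                vaf = rng.uniform(*cfg.somatic_indel_vaf_range)
                allele = _random_indel(rng, reference, int(sites[i]))
            else:
                vaf = rng.uniform(*cfg.somatic_vaf_range)
                allele = _other_base(rng, ref_at[i])
            count = int(rng.binomial(depth[i], vaf))
            if count == 0:
                count = 1
            v = PlantedVariant(sample_id, contig, int(sites[i]),
                               str(ref_at[i]), allele, float(vaf),
                               "somatic", gene)
            truth.somatic[sample_id].append(v)
            events.append((i, allele, count, v))

        # FFPE-like deamination: C>T / G>A at realized VAF below the SNV cut
        cg_idx = np.flatnonzero(np.isin(ref_at, ["C", "G"]))
        ffpe_sel = cg_idx[rng.random(len(cg_idx)) < cfg.ffpe_ct_rate]
        for i in ffpe_sel:
            if i in used or depth[i] == 0:
                continue
            used.add(int(i))
            vaf = rng.uniform(*cfg.ffpe_vaf_range)
            count = max(1, int(np.floor(vaf * depth[i])))
            allele = "T" if ref_at[i] == "C" else "A"
            v = PlantedVariant(sample_id, contig, int(sites[i]),
                               str(ref_at[i]), allele, float(vaf),
                               "ffpe_ct", site_gene.get(int(sites[i])))
            truth.artifacts[sample_id].append(v)
            events.append((int(i), allele, count, v))

        # attribute-shifted artifacts
        bias_sel = np.flatnonzero(rng.random(n_sites) < cfg.biased_artifact_rate)
        for i in bias_sel:
            if i in used or depth[i] == 0:
                continue
            used.add(int(i))
            vaf = rng.uniform(*cfg.biased_vaf_range)
            count = max(1, int(np.rint(vaf * depth[i])))
            allele = _other_base(rng, ref_at[i])
            v = PlantedVariant(sample_id, contig, int(sites[i]),
                               str(ref_at[i]), allele, float(vaf),
                               "biased", site_gene.get(int(sites[i])))
            truth.artifacts[sample_id].append(v)
            events.append((int(i), allele, count, v))

        for i, allele, carriers in recurrent_defs:
            if si not in carriers or depth[i] == 0:
                continue
            vaf = rng.uniform(*cfg.recurrent_vaf_range)
            count = max(1, int(rng.binomial(depth[i], vaf)))
            v = PlantedVariant(sample_id, contig, int(sites[i]),
                               str(ref_at[i]), allele, float(vaf),
                               "recurrent", site_gene.get(int(sites[i])))
            truth.artifacts[sample_id].append(v)
            events.append((int(i), allele, count, v))

        # remaining reads are reference, a few of which are sequencing errors
        alt_total = np.zeros(n_sites, dtype=int)
        for i, _, count, _ in events:
            alt_total[i] += count
        ref_count = np.maximum(depth - alt_total, 0)
        err = rng.binomial(ref_count, cfg.error_rate)
        ref_count = ref_count - err

        pos_parts = [np.repeat(sites, ref_count)]
        allele_parts = [np.repeat(ref_at, ref_count)]
        n_err = int(err.sum())
        if n_err:
            err_sites = np.repeat(np.arange(n_sites), err)
            offs = rng.integers(1, 4, n_err)
            base_codes = np.searchsorted(_BASES, ref_at[err_sites])
            err_alleles = _BASES[(base_codes + offs) % 4]
            pos_parts.append(sites[err_sites])
            allele_parts.append(err_alleles)
        planted_rpf_override = []
        for i, allele, count, v in events:
            pos_parts.append(np.full(count, sites[i]))
            allele_parts.append(np.full(count, allele, dtype=object))
            planted_rpf_override.append((count, v.kind))

        pos_all = np.concatenate(pos_parts)
        allele_all = np.concatenate([np.asarray(a, dtype=object)
                                     for a in allele_parts])
        n_total = len(pos_all)
        bq, mq, rpf, strand = _null_attributes(rng, n_total, cfg)
        # biased artifact reads draw a shifted read-position distribution
        offset = n_total - sum(c for c, _ in planted_rpf_override)
        for count, kind in planted_rpf_override:
            if kind == "biased":
                rpf[offset:offset + count] = rng.uniform(
                    0, cfg.biased_read_pos_max, count)
            offset += count

        ref_base_all = np.array([reference[p - 1] for p in pos_all])
        df = pd.DataFrame({
            "sample_id": sample_id,
            "contig": contig,
            "pos": pos_all.astype(int),
            "ref_base": ref_base_all,
            "obs_allele": allele_all,
            "base_quality": bq,
            "mapping_quality": mq,
            "read_pos_fraction": rpf,
            "strand": strand,
        })
        df = df.sort_values("pos", kind="stable", ignore_index=True)
        observations[sample_id] = df
    return observations, truth


# -------------------------------------------------- methylation and mutations

def simulate_methylation_and_mutations(reference: str, beta_levels=None,
                                       slope: float = 0.09,
                                       base_rate: float = 0.01,
                                       seed: int = 0,
                                       contig: str = "panel_ref"):
    """Plant C>T mutations at CpG sites with methylation-dependent rates.

    Each CpG (a plus-strand C followed by G) mutates with probability
    ``base_rate + slope * methylation``.  ``beta_levels`` supplies per-CpG
    methylation fractions aligned to the CpG positions of the reference; when
    omitted they are drawn Uniform(0, 1).

    Returns ``(track, flags)``: a 1-based (contig, pos, level) methylation
    track aligned 1:1 with the reference's CpG cytosines, and the boolean
    mutation flags.
    """
    if slope < 0:
        raise InvalidArgumentError("slope must be >= 0")
    if base_rate < 0 or base_rate + slope > 1:
        raise InvalidArgumentError("need 0 <= base_rate and base_rate + slope <= 1")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(reference.encode(), dtype="S1")
    cpg_pos = np.flatnonzero((arr[:-1] == b"C") & (arr[1:] == b"G")) + 1  # 1-based C
    if beta_levels is None:
        levels = rng.uniform(0, 1, len(cpg_pos))
    else:
        levels = np.asarray(beta_levels, dtype=float)
        if levels.shape != cpg_pos.shape:
            raise InvalidArgumentError(
                f"beta_levels length {len(levels)} does not match the "
                f"{len(cpg_pos)} CpG sites of the reference")
        if np.any((levels < 0) | (levels > 1)):
            raise InvalidArgumentError("methylation levels must be in [0,1]")
    flags = rng.random(len(cpg_pos)) < base_rate + slope * levels
    track = pd.DataFrame({"contig": contig, "pos": cpg_pos.astype(int),
                          "level": levels})
    return track, flags


# ------------------------------------------------------------------ expression

def simulate_expression(n_genes: int = 1000, cluster_sizes=(6, 11),
                        n_module_genes: int = 50, effect: float = 1.5,
                        noise_sd: float = 0.3, seed: int = 0):
    """A two-cluster expression matrix on the FPKM scale.

    Module genes have their log10 mean shifted up by ``effect`` in cluster A
    samples (default 1.5, i.e. 5 noise SDs — a strongly separated subtype).
    Returns ``(matrix, labels, module_genes)`` with a genes x samples
    DataFrame of nonnegative values and the true cluster label per sample.
    """
    if n_module_genes > n_genes:
        raise InvalidArgumentError("n_module_genes cannot exceed n_genes")
    n_a, n_b = cluster_sizes
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    samples = [f"E{i + 1:02d}" for i in range(n_a + n_b)]
    labels = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples, name="cluster")
    mu = rng.normal(1.0, 0.5, n_genes)
    log_expr = mu[:, None] + rng.normal(0, noise_sd, (n_genes, n_a + n_b))
    module = np.arange(n_module_genes)
    log_expr[np.ix_(module, np.arange(n_a))] += effect
    mat = pd.DataFrame(np.power(10.0, log_expr), index=genes, columns=samples)
    return mat, labels, [genes[i] for i in module]


# -------------------------------------------------------------------- clinical

def simulate_duration_groups(n_carrier: int, n_noncarrier: int,
                             mean_carrier: float = 328.0,
                             mean_noncarrier: float = 215.0,
                             shape: float = 4.0, seed: int = 0):
    """IBD durations (months) for carrier / non-carrier groups, drawn from
    Gamma distributions with the stated means (shape fixed, scale = mean/shape
    so durations are positive and right-skewed like real disease durations)."""
    if mean_carrier <= 0 or mean_noncarrier <= 0:
        raise InvalidArgumentError("duration means must be > 0")
    rng = np.random.default_rng(seed)
    carrier = rng.gamma(shape, mean_carrier / shape, n_carrier)
    noncarrier = rng.gamma(shape, mean_noncarrier / shape, n_noncarrier)
    return carrier, noncarrier


def simulate_clinical(truth: SimTruth, duration_mean_carrier: float = 328.0,
                      duration_mean_noncarrier: float = 215.0,
                      carrier_gene: str = "RNF43", seed: int = 0) -> pd.DataFrame:
    """Per-patient covariates with IBD duration shifted in carriers of
    ``carrier_gene`` somatic mutations.

    Categorical covariate frequencies mirror the margins of a 90-patient IBD
    cancer cohort: 64% ulcerative colitis / 36% Crohn's disease; histology
    68% well/moderately/poorly differentiated vs 32% mucinous or signet-ring;
    extent recorded for UC only (81% pancolitis); stage distributed
    0/I/II/III/IV/NA at 4/14/40/29/7/6%.
    """
    if duration_mean_carrier <= 0 or duration_mean_noncarrier <= 0:
        raise InvalidArgumentError("duration means must be > 0")
    genes = {g for g, _, _, _ in truth.panel}
    if carrier_gene not in genes:
        raise InvalidArgumentError(f"carrier gene {carrier_gene!r} not in panel")
    rng = np.random.default_rng(seed)
    carriers = truth.somatic_gene_carriers(carrier_gene)
    rows = []
    shape = 4.0
    for s in truth.samples:
        mean = duration_mean_carrier if s in carriers else duration_mean_noncarrier
        duration = rng.gamma(shape, mean / shape)
        disease = "UC" if rng.random() < 58 / 90 else "CD"
        histology = "well_mod_poor" if rng.random() < 59 / 87 else "mucinous_signet"
        if disease == "UC":
            extent = "pancolitis" if rng.random() < 47 / 58 else "limited"
        else:
            extent = "NA"
        stage = rng.choice(["0", "I", "II", "III", "IV", "NA"],
                           p=np.array([4, 13, 36, 26, 6, 5]) / 90)
        anal_muc = bool(disease == "CD" and histology == "mucinous_signet"
                        and rng.random() < 0.5)
        rows.append({"sample_id": s, "disease": disease,
                     "duration_months": float(duration), "histology": histology,
                     "extent": extent, "stage": stage,
                     "site_anal_mucinous": anal_muc})
    return pd.DataFrame(rows, columns=CLINICAL_COLUMNS)


# ------------------------------------------------------------------- scoring

def score_against_truth(truth: SimTruth, result) -> dict:
    """Score a :class:`~cacsomatic.calling.CohortCallResult` against planted
    truth.

    Returns recall/precision over planted somatic events plus per-artifact-
    class capture rates: an FFPE artifact is captured when its candidate call
    carries ``lowvaf`` (or it left no surviving candidate at all); a biased
    artifact when it carries a bias tag; a recurrent artifact instance when
    it carries ``recurrent``; a dbSNP-listed germline carrier when it carries
    ``dbsnp``.  Residual germline calls that pass everything are counted, not
    removed.
    """
    calls_by_key = {}
    for sample, calls in result.calls.items():
        for c in calls:
            calls_by_key[(sample,) + c.key] = c

    somatic_keys = {(s,) + v.key for s, vs in truth.somatic.items() for v in vs}
    passed_keys = {(s,) + c.key for s, calls in result.calls.items()
                   for c in calls if c.passed}
    tp = len(somatic_keys & passed_keys)
    n_somatic = len(somatic_keys)
    n_passed = len(passed_keys)

    def _capture(kind, want_tags, allow_missing=False):
        hit = total = 0
        for s, vs in truth.artifacts.items():
            for v in vs:
                if v.kind != kind:
                    continue
                total += 1
                c = calls_by_key.get((s,) + v.key)
                if c is None:
                    hit += int(allow_missing)
                elif c.filters & want_tags:
                    hit += 1
        return hit / total if total else float("nan"), total

    ffpe_rate, n_ffpe = _capture("ffpe_ct", {"lowvaf"}, allow_missing=True)
    bias_rate, n_biased = _capture("biased", {"bqbias", "mqbias", "rpbias"})
    rec_rate, n_rec = _capture("recurrent", {"recurrent"})

    db_hit = db_total = 0
    residual_germline_passed = 0
    for s, vs in truth.germline.items():
        for v in vs:
            c = calls_by_key.get((s,) + v.key)
            if v.key in truth.mini_dbsnp:
                db_total += 1
                if c is not None and "dbsnp" in c.filters:
                    db_hit += 1
            if c is not None and c.passed:
                residual_germline_passed += 1

    return {
        "n_somatic_planted": n_somatic,
        "n_passed_calls": n_passed,
        "true_positives": tp,
        "recall": tp / n_somatic if n_somatic else float("nan"),
        "precision": tp / n_passed if n_passed else float("nan"),
        "ffpe_lowvaf_rate": ffpe_rate, "n_ffpe": n_ffpe,
        "biased_bias_tag_rate": bias_rate, "n_biased": n_biased,
        "recurrent_tag_rate": rec_rate, "n_recurrent_instances": n_rec,
        "dbsnp_tag_rate": db_hit / db_total if db_total else float("nan"),
        "n_dbsnp_germline": db_total,
        "residual_germline_passed": residual_germline_passed,
    }
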