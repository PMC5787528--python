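"""Readers and writers for every on-disk format the pipeline touches.

Coordinate policy: everything in memory is 1-based inclusive (pileup
convention).  The only 0-based half-open format is the bedMethyl-like
methylation TSV, converted at the boundary.

The per-base observation stream uses a native TSV dialect (one row per
sequenced base or indel observation, schema in :data:`OBS_COLUMNS`); alignment
files are upstream of this pipeline.  Indel alleles are spelled pileup-style,
``+SEQ`` for an insertion after the anchor base and ``-SEQ`` for a deletion of
the following bases; the VCF writer re-anchors them to the padded VCF
representation.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidArgumentError, ParseError, SchemaError

__all__ = [
    "OBS_COLUMNS", "CLINICAL_COLUMNS", "VCF_FILTER_TAGS",
    "read_observations", "write_observations",
    "read_common_variants", "write_common_variants_vcf",
    "write_vcf", "read_vcf_calls",
    "read_fasta", "write_fasta",
    "read_methylation", "write_methylation",
    "read_matrix", "write_matrix",
    "read_clinical", "write_clinical",
]

OBS_COLUMNS = ["sample_id", "contig", "pos", "ref_base", "obs_allele",
               "base_quality", "mapping_quality", "read_pos_fraction", "strand"]

CLINICAL_COLUMNS = ["sample_id", "disease", "duration_months", "histology",
                    "extent", "stage", "site_anal_mucinous"]

#: one FILTER tag per calling clause, fixed for auditability
VCF_FILTER_TAGS = ["lowdepth", "lowvaf", "bqbias", "mqbias", "rpbias",
                   "lowsupport", "dbsnp", "recurrent"]

_ALLELE_RE = re.compile(r"^([ACGT]|[+-][ACGT]+)$")


# ---------------------------------------------------------------- observations

def read_observations(path) -> pd.DataFrame:
    """Read an observation TSV into a DataFrame, validating the schema.

    Rows are returned in file order.  Malformed rows raise :class:`ParseError`
    with a 1-based line number (the header is line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "contig": str,
                                                "ref_base": str, "obs_allele": str,
                                                "strand": str})
    except ValueError as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df[OBS_COLUMNS]
    _validate_observations(df, str(path))
    return df


def _validate_observations(df: pd.DataFrame, source: str = "<memory>") -> None:
    def _bad(mask, what):
        if mask.any():
            i = int(np.flatnonzero(np.asarray(mask))[0])
            raise ParseError(f"{source}: {what} (row value "
                             f"{df.iloc[i].to_dict()!r})", line=i + 2)

    for col in ("pos", "base_quality", "mapping_quality"):
        vals = pd.to_numeric(df[col], errors="coerce")
        _bad(vals.isna(), f"non-numeric {col}")
        _bad(vals != vals.astype(int), f"non-integer {col}")
    _bad(df["pos"].astype(int) < 1, "pos must be >= 1 (1-based)")
    _bad(df["base_quality"].astype(int) < 0, "negative base_quality")
    _bad(df["mapping_quality"].astype(int) < 0, "negative mapping_quality")
    rpf = pd.to_numeric(df["read_pos_fraction"], errors="coerce")
    _bad(rpf.isna() | (rpf < 0) | (rpf > 1), "read_pos_fraction outside [0,1]")
    _bad(~df["ref_base"].isin(list("ACGT")), "ref_base not in {A,C,G,T}")
    _bad(~df["strand"].isin(["+", "-"]), "strand not in {+,-}")
    _bad(~df["obs_allele"].map(lambda a: bool(_ALLELE_RE.match(str(a)))),
         "obs_allele not a base or +SEQ/-SEQ indel")


def write_observations(df: pd.DataFrame, path) -> None:
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {', '.join(missing)}")
    df[OBS_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


# ------------------------------------------------------------- common variants

def read_common_variants(path) -> set[tuple[str, int, str, str]]:
    """Read a dbSNP-style site list as a set of (contig, pos, ref, alt).

    Accepts VCF v4.x (multi-allelic rows expanded, one entry per ALT) or a
    headered 4-column TSV (contig, pos, ref, alt).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or first.startswith("#CHROM"):
        return _read_common_vcf(path)
    return _read_common_tsv(path)


def _read_common_vcf(path: Path) -> set[tuple[str, int, str, str]]:
    import pysam

    out: set[tuple[str, int, str, str]] = set()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if not re.fullmatch(r"[ACGTacgt]+", alt or ""):
                    raise ParseError(f"{path}: unparseable ALT {alt!r} at "
                                     f"{rec.chrom}:{rec.pos}")
                out.add((rec.chrom, int(rec.pos), rec.ref.upper(), alt.upper()))
    return out


def _read_common_tsv(path: Path) -> set[tuple[str, int, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ["contig", "pos", "ref", "alt"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    out = set()
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            pos = int(row.pos)
        except ValueError:
            raise ParseError(f"{path}: non-integer pos {row.pos!r}",
                             line=i + 2) from None
        if not re.fullmatch(r"[ACGT]+|[+-][ACGT]+", str(row.alt)):
            raise ParseError(f"{path}: unparseable alt {row.alt!r}", line=i + 2)
        out.add((str(row.contig), pos, str(row.ref).upper(), str(row.alt).upper()))
    return out


def write_common_variants_vcf(sites, reference: dict[str, str] | None, path) -> None:
    """Write a (contig, pos, ref, alt) site set as a minimal sites-only VCF."""
    sites = sorted(sites)
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if reference:
            for name, seq in reference.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for contig, pos, ref, alt in sites:
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")


# ----------------------------------------------------------------------- VCF

def _sig6(x: float) -> str:
    return f"{x:.6g}"


def _vcf_ref_alt(call, reference: dict[str, str] | None):
    """Map a call's pileup-spelled allele to padded VCF REF/ALT."""
    ref, alt = call.ref, call.alt
    if alt.startswith("+"):                      # insertion after the anchor
        return ref, ref + alt[1:]
    if alt.startswith("-"):                      # deletion of following bases
        return ref + alt[1:], ref
    return ref, alt


def write_vcf(calls, sample_id: str, path, reference: dict[str, str] | None = None) -> None:
    """Write VariantCalls for one sample as minimal VCF v4.2.

    ``calls`` must already be sorted by (contig, pos); the writer refuses to
    sort silently.
    """
    keys = [(c.contig, c.pos) for c in calls]
    if keys != sorted(keys):
        raise InvalidArgumentError("calls must be sorted by (contig, pos)")
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##cacsomatic_sample={sample_id}\n")
        if reference:
            for name, seq in reference.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        for tag, desc in [
            ("lowdepth", "Read depth not > min_depth"),
            ("lowvaf", "Variant allele frequency not above threshold"),
            ("bqbias", "Base quality bias p <= alpha"),
            ("mqbias", "Mapping quality bias p <= alpha"),
            ("rpbias", "Read position bias p <= alpha"),
            ("lowsupport", "Indel support reads not > threshold"),
            ("dbsnp", "Matches a common-variant site"),
            ("recurrent", "Identical allele detected in too many samples"),
        ]:
            fh.write(f'##FILTER=<ID={tag},Description="{desc}">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth after quality skips">\n')
        fh.write('##INFO=<ID=ALTC,Number=1,Type=Integer,Description="Alt-supporting reads">\n')
        fh.write('##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">\n')
        fh.write('##INFO=<ID=BQB,Number=1,Type=Float,Description="Base quality bias p">\n')
        fh.write('##INFO=<ID=MQB,Number=1,Type=Float,Description="Mapping quality bias p">\n')
        fh.write('##INFO=<ID=RPB,Number=1,Type=Float,Description="Read position bias p">\n')
        fh.write('##INFO=<ID=BIASNA,Number=0,Type=Flag,Description="Bias tests not assessable (no reference-allele reads)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            ref, alt = _vcf_ref_alt(c, reference)
            info = [f"DP={c.depth}", f"ALTC={c.alt_count}", f"VAF={_sig6(c.vaf)}"]
            if c.bias_p is not None:
                bq, mq, rp = c.bias_p
                info += [f"BQB={_sig6(bq)}", f"MQB={_sig6(mq)}", f"RPB={_sig6(rp)}"]
            elif c.variant_type == "SNV":
                info.append("BIASNA")
            filt = "PASS" if not c.filters else ";".join(sorted(c.filters))
            fh.write(f"{c.contig}\t{c.pos}\t.\t{ref}\t{alt}\t.\t{filt}\t"
                     f"{';'.join(info)}\n")


def read_vcf_calls(path) -> pd.DataFrame:
    """Parse back a VCF written by :func:`write_vcf` into a DataFrame."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            filters = [f for f in rec.filter.keys() if f != "PASS"]
            for alt in (rec.alts or []):
                rows.append({
                    "contig": rec.chrom, "pos": int(rec.pos),
                    "ref": rec.ref, "alt": alt,
                    "filter": ";".join(sorted(filters)) if filters else "PASS",
                    "depth": rec.info.get("DP"),
                    "alt_count": rec.info.get("ALTC"),
                    "vaf": rec.info.get("VAF"),
                })
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "filter",
                                       "depth", "alt_count", "vaf"])


# --------------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise SchemaError(f"{path}: duplicate contig name {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(contigs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------- methylation

def read_methylation(path) -> pd.DataFrame:
    """Read a bedMethyl-like TSV (contig, 0-based start, end, level).

    Returns a DataFrame with 1-based ``pos`` and ``level`` columns.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    need = ["contig", "start", "end", "level"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    if ((df["level"] < 0) | (df["level"] > 1)).any():
        raise SchemaError(f"{path}: methylation level outside [0,1]")
    out = pd.DataFrame({"contig": df["contig"],
                        "pos": df["start"].astype(int) + 1,
                        "level": df["level"].astype(float)})
    return out


def write_methylation(track: pd.DataFrame, path) -> None:
    """Write a 1-based (contig, pos, level) track as bedMethyl-like TSV."""
    out = pd.DataFrame({"contig": track["contig"],
                        "start": track["pos"].astype(int) - 1,
                        "end": track["pos"].astype(int),
                        "level": track["level"].astype(float)})
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ------------------------------------------------------------------ matrices

def read_matrix(path) -> pd.DataFrame:
    """Read a labeled numeric TSV matrix (rows labeled by first column)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        raise SchemaError(f"{path}: duplicate column labels")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise SchemaError(f"{path}: duplicate row labels")
    if not all(np.issubdtype(d, np.number) for d in df.dtypes):
        raise SchemaError(f"{path}: non-numeric matrix values")
    return df


def write_matrix(df: pd.DataFrame, path, index_label: str = "gene") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


# ------------------------------------------------------------------ clinical

def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    df = df[CLINICAL_COLUMNS].copy()
    df["duration_months"] = pd.to_numeric(df["duration_months"])
    if (df["duration_months"].dropna() < 0).any():
        raise SchemaError(f"{path}: negative duration_months")
    df["site_anal_mucinous"] = df["site_anal_mucinous"].astype(bool)
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s) {', '.join(missing)}")
    df[CLINICAL_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")
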