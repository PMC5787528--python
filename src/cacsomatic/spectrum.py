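"""96-class trinucleotide mutation spectra and CpG methylation trend analysis.

Single-base substitutions are strand-collapsed onto the pyrimidine reference
base: a substitution at a purine is reported on the opposite strand, so every
class has a C or T at the center.  With six substitution types and 4 x 4
flanking contexts this yields the conventional 96 classes, ordered
C>A, C>G, C>T, T>A, T>C, T>G, then 5' base, then 3' base (alphabetical) —
the community signature ordering.

The module also quantifies the CpG C>T burden (spontaneous deamination of
5-methylcytosine leaves C>T at methylated CpG sites), tests whether the C>T
mutation rate of CpG sites rises with their methylation level
(Cochran-Armitage trend test over methylation bins), and flags samples with
an excess of TpT→GpT substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import InvalidArgumentError, UndefinedTestError

__all__ = [
    "SUBSTITUTION_TYPES", "LABELS_96", "label_index",
    "classify_substitution", "compute_spectrum", "Spectrum96",
    "ct_cpg_summary", "cochran_armitage_trend", "TrendResult",
    "methylation_trend_analysis", "tpt_gpt_per_sample",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"

SUBSTITUTION_TYPES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

LABELS_96 = [f"{five}[{sub}]{three}"
             for sub in SUBSTITUTION_TYPES
             for five in _BASES
             for three in _BASES]

_LABEL_INDEX = {lab: i for i, lab in enumerate(LABELS_96)}


def label_index(label: str) -> int:
    return _LABEL_INDEX[label]


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def classify_substitution(trinucleotide: str, ref: str, alt: str) -> str:
    """Return the 96-class label of a substitution in its reference context.

    ``trinucleotide`` is the reference 3-mer centered on the mutated base.  If
    the reference base is a purine the context is reverse-complemented and the
    alt base complemented, so the reported center is always a pyrimidine.

    Raises :class:`InvalidArgumentError` for ambiguous bases (N), a center
    mismatch, or alt == ref; such calls are unclassifiable.
    """
    trinucleotide = trinucleotide.upper()
    ref, alt = ref.upper(), alt.upper()
    if len(trinucleotide) != 3:
        raise InvalidArgumentError("context must be a 3-mer")
    if any(b not in _BASES for b in trinucleotide + ref + alt):
        raise InvalidArgumentError(f"ambiguous base in {trinucleotide}/{ref}>{alt}")
    if trinucleotide[1] != ref:
        raise InvalidArgumentError("ref does not match the center of the context")
    if alt == ref:
        raise InvalidArgumentError("alt equals ref")
    if ref in "AG":
        trinucleotide = _revcomp(trinucleotide)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return f"{trinucleotide[0]}[{ref}>{alt}]{trinucleotide[2]}"


@dataclass
class Spectrum96:
    sample_id: str
    counts: np.ndarray                  # 96-vector of nonnegative ints
    n_excluded: int = 0                 # unclassifiable calls (termini, N)

    @property
    def n_snvs(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=LABELS_96, name=self.sample_id)


def compute_spectrum(calls, reference: dict[str, str],
                     sample_id: str | None = None) -> Spectrum96:
    """Count passed SNV calls of one sample over the 96 classes.

    ``calls`` is an iterable of VariantCall-like objects (attributes contig,
    pos, ref, alt, variant_type, passed).  Calls at contig termini have no
    trinucleotide context and are excluded (counted in ``n_excluded``).
    """
    counts = np.zeros(96, dtype=int)
    n_excluded = 0
    sid = sample_id
    for c in calls:
        if getattr(c, "variant_type", "SNV") != "SNV" or not getattr(c, "passed", True):
            continue
        if sid is None:
            sid = getattr(c, "sample_id", None)
        seq = reference.get(c.contig)
        if seq is None or not (1 <= c.pos <= len(seq)):
            raise InvalidArgumentError(f"call at {c.contig}:{c.pos} outside reference")
        if c.pos == 1 or c.pos == len(seq):
            n_excluded += 1
            continue
        tri = seq[c.pos - 2:c.pos + 1]
        try:
            counts[_LABEL_INDEX[classify_substitution(tri, c.ref, c.alt)]] += 1
        except InvalidArgumentError:
            n_excluded += 1
    return Spectrum96(sample_id=sid or "", counts=counts, n_excluded=n_excluded)


def ct_cpg_summary(spectrum: Spectrum96):
    """CpG C>T burden of one spectrum.

    Returns ``(n_ct, n_ct_cpg, fraction_ct, fraction_cpg_of_ct)`` where
    ``n_ct`` sums all 16 N[C>T]N classes, ``n_ct_cpg`` the four N[C>T]G
    classes, ``fraction_ct`` = n_ct / n_snvs and ``fraction_cpg_of_ct`` =
    n_ct_cpg / n_ct (fractions are 0 when their denominator is 0).
    """
    s = spectrum.as_series()
    n_ct = int(sum(s[f"{f}[C>T]{t}"] for f in _BASES for t in _BASES))
    n_ct_cpg = int(sum(s[f"{f}[C>T]G"] for f in _BASES))
    n = spectrum.n_snvs
    return (n_ct, n_ct_cpg,
            n_ct / n if n else 0.0,
            n_ct_cpg / n_ct if n_ct else 0.0)


@dataclass
class TrendResult:
    bin_edges: np.ndarray
    n_per_bin: np.ndarray               # CpGs per bin
    r_per_bin: np.ndarray               # mutated CpGs per bin
    scores: np.ndarray
    T: float
    Z: float
    p: float
    sidedness: str                      # "one" (increasing) or "two"


def cochran_armitage_trend(n_per_bin, r_per_bin, scores,
                           sidedness: str = "one") -> TrendResult:
    """Cochran-Armitage test for a monotone trend in binomial proportions.

    With bin sizes n_i, event counts r_i, ordered scores s_i, R = Σ r_i and
    N = Σ n_i, the statistic is T = Σ s_i (r_i − n_i R/N) with variance
    Var = (R/N)(1 − R/N)[Σ n_i s_i² − (Σ n_i s_i)²/N]; Z = T/√Var is referred
    to the standard normal.  ``sidedness="one"`` tests for an increasing
    trend; ``"two"`` is two-sided.
    """
    n = np.asarray(n_per_bin, dtype=float)
    r = np.asarray(r_per_bin, dtype=float)
    s = np.asarray(scores, dtype=float)
    if not (len(n) == len(r) == len(s)) or len(n) < 2:
        raise InvalidArgumentError("need k >= 2 aligned bins")
    if np.any(r > n) or np.any(r < 0) or np.any(n < 0):
        raise InvalidArgumentError("need 0 <= r_i <= n_i")
    if np.any(np.diff(s) <= 0):
        raise InvalidArgumentError("scores must be strictly increasing")
    N, R = n.sum(), r.sum()
    if R < 1:
        raise UndefinedTestError("no events observed")
    T = float(np.sum(s * (r - n * R / N)))
    var = (R / N) * (1 - R / N) * (np.sum(n * s ** 2) - np.sum(n * s) ** 2 / N)
    if var <= 0:
        raise UndefinedTestError("zero trend variance (all data in one bin "
                                 "or all CpGs mutated)")
    Z = T / np.sqrt(var)
    if sidedness == "one":
        p = float(_st.norm.sf(Z))
    elif sidedness == "two":
        p = float(2 * _st.norm.sf(abs(Z)))
    else:
        raise InvalidArgumentError(f"unknown sidedness {sidedness!r}")
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return TrendResult(bin_edges=np.array([]), n_per_bin=n.astype(int),
                       r_per_bin=r.astype(int), scores=s, T=T, Z=float(Z),
                       p=p, sidedness=sidedness)


def methylation_trend_analysis(levels, mutated, bin_edges=None,
                               sidedness: str = "one") -> TrendResult:
    """Bin CpG sites by methylation level and test for a rising mutation rate.

    ``levels`` are per-CpG methylation fractions in [0,1]; ``mutated`` the
    aligned boolean C>T flags.  Default binning: five equal-width bins on
    [0,1], scored at bin midpoints.  Empty bins contribute n_i = 0.
    """
    levels = np.asarray(levels, dtype=float)
    mutated = np.asarray(mutated, dtype=bool)
    if levels.shape != mutated.shape:
        raise InvalidArgumentError("levels and mutated flags must align 1:1")
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 1.0, 6)
    edges = np.asarray(bin_edges, dtype=float)
    idx = np.clip(np.digitize(levels, edges[1:-1]), 0, len(edges) - 2)
    k = len(edges) - 1
    n = np.bincount(idx, minlength=k)
    r = np.bincount(idx, weights=mutated.astype(float), minlength=k)
    scores = (edges[:-1] + edges[1:]) / 2
    res = cochran_armitage_trend(n, r, scores, sidedness=sidedness)
    res.bin_edges = edges
    return res


def tpt_gpt_per_sample(spectra, flag_threshold: int = 20) -> pd.DataFrame:
    """Per-sample TpT→GpT burden: the sum of the four T[T>G]N classes
    (strand-collapsed, so a plus-strand ApA→ApC event is the same class).
    Samples with ``flag_threshold`` or more such SNVs are flagged (inclusive
    boundary)."""
    rows = []
    for sp in spectra:
        s = sp.as_series()
        count = int(sum(s[f"T[T>G]{t}"] for t in _BASES))
        rows.append({"sample_id": sp.sample_id, "tpt_gpt": count,
                     "flagged": count >= flag_threshold})
    return pd.DataFrame(rows, columns=["sample_id", "tpt_gpt", "flagged"])
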