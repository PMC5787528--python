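"""Expression normalization and Ward clustering of tumor transcriptomes.

The stage mirrors a standard bulk RNA-seq subtype analysis: raw gene counts
are converted to FPKM-UQ (upper-quartile normalization: count x 1e9 /
(gene_length x UQ), with UQ the 75th percentile of a sample's nonzero gene
counts — the TCGA convention), genes not expressed in every sample are
dropped, values are log10(1+x)-transformed and z-scored per gene, and samples
are clustered agglomeratively with Euclidean distance and Ward's
variance-minimizing linkage (heights on the distance scale, i.e. the
"ward.D2" dialect).  A matrix provenance tag records how far along this chain
a matrix is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hc

from .association import ContingencyResult, fisher_exact_2x2
from .errors import InvalidArgumentError

__all__ = [
    "PROVENANCE_ORDER", "get_provenance", "set_provenance",
    "fpkm_uq", "filter_expressed_all", "log_scale",
    "ward_cluster", "ClusterResult", "cluster_mutation_association",
]

PROVENANCE_ORDER = ["counts", "fpkm_uq", "log", "scaled"]

_PROV_ATTR = "cacsomatic_provenance"


def get_provenance(m: pd.DataFrame) -> str | None:
    return m.attrs.get(_PROV_ATTR)


def set_provenance(m: pd.DataFrame, stage: str) -> pd.DataFrame:
    """Record a matrix's processing stage; transitions only move forward."""
    if stage not in PROVENANCE_ORDER:
        raise InvalidArgumentError(f"unknown provenance stage {stage!r}")
    prev = get_provenance(m)
    if prev is not None and PROVENANCE_ORDER.index(stage) < PROVENANCE_ORDER.index(prev):
        raise InvalidArgumentError(f"provenance cannot move back from {prev!r} "
                                   f"to {stage!r}")
    m.attrs[_PROV_ATTR] = stage
    return m


def fpkm_uq(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Convert a genes x samples integer count matrix to FPKM-UQ."""
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise InvalidArgumentError(f"missing gene length(s), e.g. {missing}")
    if (lengths <= 0).any():
        raise InvalidArgumentError("gene lengths must be > 0")
    vals = counts.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals != np.round(vals)):
        raise InvalidArgumentError("counts must be nonnegative integers")
    uq = np.empty(counts.shape[1])
    for j, sample in enumerate(counts.columns):
        nz = vals[:, j][vals[:, j] > 0]
        if nz.size == 0:
            raise InvalidArgumentError(f"sample {sample!r} has all-zero counts; "
                                       "upper quartile undefined")
        uq[j] = np.percentile(nz, 75)
    out = counts.astype(float) * 1e9 / np.outer(lengths.to_numpy(), uq)
    out = pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return set_provenance(out, "fpkm_uq")


def filter_expressed_all(m: pd.DataFrame) -> pd.DataFrame:
    """Retain exactly the genes with a positive value in every sample."""
    keep = (m > 0).all(axis=1)
    out = m.loc[keep].copy()
    out.attrs = dict(m.attrs)
    if out.empty:
        import warnings
        warnings.warn("no gene is expressed in all samples", stacklevel=2)
    return out


def log_scale(m: pd.DataFrame) -> pd.DataFrame:
    """log10(1+x) then per-gene z-scoring (mean 0, SD 1 with n-1 denominator).

    Genes with zero variance after the log transform carry no clustering
    information and are dropped (their number is recorded in
    ``attrs["n_dropped_zero_variance"]``)."""
    vals = m.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise InvalidArgumentError("expression values must be nonnegative")
    logged = np.log10(1.0 + vals)
    sd = logged.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        import warnings
        warnings.warn(f"dropped {n_dropped} zero-variance gene(s)", stacklevel=2)
    z = (logged[keep] - logged[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    out = pd.DataFrame(z, index=m.index[keep], columns=m.columns)
    out.attrs = dict(m.attrs)
    out.attrs["n_dropped_zero_variance"] = n_dropped
    return set_provenance(out, "scaled")


@dataclass
class ClusterResult:
    samples: list[str]
    linkage: np.ndarray                 # scipy linkage matrix (n-1 x 4)
    assignments: pd.Series              # sample -> cluster label at k
    k: int

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.linkage[:, :3],
                            columns=["node_i", "node_j", "height"])


def ward_cluster(m: pd.DataFrame, k: int = 2) -> ClusterResult:
    """Cluster samples (columns) with Euclidean distance and Ward linkage.

    Assignments come from cutting the merge tree into ``k`` groups; cluster
    labels are arbitrary but stable for a given input.
    """
    n = m.shape[1]
    if not (2 <= k <= n):
        raise InvalidArgumentError(f"k must be in [2, n_samples]; got k={k}, n={n}")
    X = m.to_numpy(dtype=float).T            # samples x features
    if not np.all(np.isfinite(X)):
        raise InvalidArgumentError("matrix must be fully numeric and finite")
    Z = _hc.linkage(X, method="ward")
    labels = _hc.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(samples=list(m.columns), linkage=Z,
                         assignments=pd.Series(labels, index=m.columns),
                         k=k)


def cluster_mutation_association(result: ClusterResult,
                                 pathway_flags: pd.Series,
                                 label: str = "cluster~pathway") -> ContingencyResult:
    """Fisher test of pathway-mutation carriage between the two clusters.

    ``pathway_flags`` is a per-sample boolean (e.g. "carries a Wnt-pathway
    mutation"); requires a k=2 clustering with aligned sample ids.
    """
    if result.k != 2:
        raise InvalidArgumentError("association requires a k=2 clustering")
    flags = pathway_flags.reindex(result.samples)
    if flags.isna().any():
        raise InvalidArgumentError("pathway flags missing for some samples")
    a = result.assignments
    labels = sorted(a.unique())
    table = [[int(((a == lab) & flags.astype(bool)).sum()),
              int(((a == lab) & ~flags.astype(bool)).sum())]
             for lab in labels]
    return fisher_exact_2x2(table, label=label)
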