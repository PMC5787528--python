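"""Cohort mutation-phenotype statistics.

Categorical comparisons use Fisher's exact test (two-sided by the
point-probability rule), continuous covariates the Wilcoxon rank-sum test
(the same engine that backs the caller's bias filters), and multiple testing
within each declared family is controlled by the Benjamini-Hochberg step-up
procedure.  Tumor stage is treated as an ordered numeric covariate (0-4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st
from statsmodels.stats.multitest import multipletests

from .errors import InvalidArgumentError
from .stats import rank_sum_test

__all__ = [
    "ContingencyResult", "fisher_exact_2x2", "bh_adjust",
    "wilcoxon_rank_sum", "gene_clinical_association",
    "compare_cohort_frequencies", "STAGE_ORDER",
]

STAGE_ORDER = {"0": 0, "I": 1, "II": 2, "III": 3, "IV": 4}

_FISHER_ALTS = {"two_sided": "two-sided", "two-sided": "two-sided",
                "greater": "greater", "less": "less"}


@dataclass
class ContingencyResult:
    table: np.ndarray
    odds_ratio: float                   # ad/bc; inf/0 at zero cells
    p: float
    label: str = ""


def fisher_exact_2x2(table, alternative: str = "two_sided",
                     label: str = "") -> ContingencyResult:
    """Fisher's exact test on a 2x2 table of nonnegative counts.

    The two-sided p-value sums the probabilities of all tables (with the
    observed margins) whose hypergeometric probability does not exceed that of
    the observed table.  The odds ratio is the sample ratio ad/bc, with
    inf / 0 conventions at zero cells.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise InvalidArgumentError("table must be 2x2")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise InvalidArgumentError("cells must be nonnegative integers")
    if t.sum() == 0:
        raise InvalidArgumentError("at least one margin must be positive")
    a, b, c, d = t.ravel()
    try:
        alt = _FISHER_ALTS[alternative]
    except KeyError:
        raise InvalidArgumentError(f"unknown alternative {alternative!r}") from None
    p = float(_st.fisher_exact(t.astype(int), alternative=alt).pvalue)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan if a * d == b * c == 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    return ContingencyResult(table=t.astype(int), odds_ratio=float(odds),
                             p=min(p, 1.0), label=label)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values, returned in input order.

    q_(i) = min over j >= i of (m/j) p_(j), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(x, y, alternative: str = "two_sided") -> float:
    """Wilcoxon rank-sum p-value; shared engine with the caller's bias tests
    (exact in the tie-free small-n regime, tie-corrected normal approximation
    with continuity correction otherwise)."""
    return rank_sum_test(x, y, alternative=alternative)


def gene_clinical_association(mutations: pd.DataFrame, clinical: pd.DataFrame,
                              spec: list[tuple[str, str, str]]) -> pd.DataFrame:
    """Run a declared family of gene-covariate association tests.

    ``mutations`` is a samples x genes 0/1 table; ``clinical`` a per-sample
    covariate table indexed or keyed by ``sample_id``; ``spec`` lists
    (gene, covariate, test) rows with test ``"fisher"`` (covariate is binary /
    two-level categorical) or ``"wilcoxon"`` (continuous or ordered; stage is
    mapped to 0-4).  NA covariate values are dropped pairwise; a covariate
    that is all-NA yields no result row.  BH correction is applied across the
    rows of the family.
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns \
        else clinical
    common_samples = mutations.index.intersection(clin.index)
    if len(common_samples) == 0:
        raise InvalidArgumentError("no shared sample ids between tables")
    rows = []
    for gene, covariate, test in spec:
        if gene not in mutations.columns:
            raise InvalidArgumentError(f"unknown gene {gene!r}")
        if covariate not in clin.columns:
            raise InvalidArgumentError(f"unknown covariate {covariate!r}")
        mut = mutations.loc[common_samples, gene]
        cov = clin.loc[common_samples, covariate]
        if covariate == "stage":
            cov = cov.map(STAGE_ORDER)
        ok = cov.notna()
        if not ok.any():
            continue  # all-NA covariate: dropped, no result row
        mut, cov = mut[ok], cov[ok]
        if test == "fisher":
            levels = sorted(pd.unique(cov))
            if len(levels) > 2:
                raise InvalidArgumentError(
                    f"fisher test needs a two-level covariate; {covariate!r} "
                    f"has levels {levels}")
            if len(levels) < 2:
                continue  # degenerate covariate: test undefined, no result row
            tab = [[int(((mut == 1) & (cov == levels[0])).sum()),
                    int(((mut == 1) & (cov == levels[1])).sum())],
                   [int(((mut == 0) & (cov == levels[0])).sum()),
                    int(((mut == 0) & (cov == levels[1])).sum())]]
            res = fisher_exact_2x2(tab, label=f"{gene}~{covariate}")
            rows.append({"gene": gene, "covariate": covariate, "test": test,
                         "statistic": res.odds_ratio, "p": res.p})
        elif test == "wilcoxon":
            x = cov[mut == 1].to_numpy(dtype=float)
            y = cov[mut == 0].to_numpy(dtype=float)
            if x.size == 0 or y.size == 0:
                continue  # one group empty: test undefined for this gene
            rows.append({"gene": gene, "covariate": covariate, "test": test,
                         "statistic": float(np.mean(x) - np.mean(y)),
                         "p": wilcoxon_rank_sum(x, y)})
        else:
            raise InvalidArgumentError(f"unknown test {test!r}")
    out = pd.DataFrame(rows, columns=["gene", "covariate", "test",
                                      "statistic", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out


def compare_cohort_frequencies(table_a: pd.DataFrame,
                               table_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mutation-frequency comparison between two cohorts.

    Both inputs are samples x genes 0/1 tables; the comparison is restricted
    to shared genes.  Each gene gets a Fisher test on mutated/wildtype x
    cohort; BH correction runs across the shared genes; stars mark q < 0.01
    (**) and q < 0.05 (*).
    """
    genes = [g for g in table_a.columns if g in set(table_b.columns)]
    if not genes:
        raise InvalidArgumentError("cohorts share no genes")
    na, nb = len(table_a), len(table_b)
    rows = []
    for g in genes:
        ma, mb = int(table_a[g].sum()), int(table_b[g].sum())
        res = fisher_exact_2x2([[ma, mb], [na - ma, nb - mb]], label=g)
        rows.append({"gene": g, "freq_a": ma / na, "freq_b": mb / nb,
                     "p": res.p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["stars"] = np.where(out["q"] < 0.01, "**",
                            np.where(out["q"] < 0.05, "*", ""))
    return out
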