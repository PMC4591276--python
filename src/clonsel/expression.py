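"""Two-sample differential expression without replicates.

With a single sensitive and a single resistant library, per-gene
differential expression is assessed with the exact conditional binomial
test: conditioned on the gene's total count n = count_s + count_r, the
sensitive count is Binomial(n, lib_s / (lib_s + lib_r)) under the null
of equal relative expression.  The two-sided p-value sums the
probabilities of all outcomes no more likely than the observed one.
This is the canonical exact test for comparing two sequencing libraries
when no replicate-based dispersion estimate is possible; with n of one,
it cannot distinguish biological from technical variability, so the
fold-change gate does most of the biological filtering.

A gene is called differentially expressed when its pseudocount-protected
normalized fold change is >= fc_min in either direction AND its
Benjamini-Hochberg adjusted p-value is <= adj_p_max.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .variants import DEFAULT_THRESHOLDS, Thresholds

#: relative tolerance for outcome-probability ties (same convention as
#: the Fisher test)
TIE_REL_TOL = 1e-7

#: pseudocount protecting the fold change at zero counts
PSEUDOCOUNT = 0.5

EXPRESSION_COLUMNS = [
    "gene", "count_sensitive", "count_resistant", "lib_sensitive",
    "lib_resistant", "fold_change", "direction", "tested", "p_raw",
    "p_adj", "is_de",
]


def de_test(count_s: int, count_r: int, lib_s: float, lib_r: float) -> float:
    """Exact conditional binomial two-sided p-value for one gene.

    Returns 1.0 when the gene has no counts at all.
    """
    if count_s < 0 or count_r < 0:
        raise ValueError("counts must be non-negative")
    if lib_s <= 0 or lib_r <= 0:
        raise ValueError("library sizes must be positive")
    count_s, count_r = int(count_s), int(count_r)
    n = count_s + count_r
    if n == 0:
        return 1.0
    p0 = lib_s / (lib_s + lib_r)
    ks = np.arange(n + 1)
    lf = gammaln(np.arange(n + 2) + 0.0 + 1.0)
    logpmf = (lf[n] - lf[ks] - lf[n - ks]
              + ks * np.log(p0) + (n - ks) * np.log1p(-p0))
    pmf = np.exp(logpmf)
    p_obs = pmf[count_s]
    p = float(pmf[pmf <= p_obs * (1.0 + TIE_REL_TOL)].sum())
    return min(1.0, p)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(counts: pd.DataFrame,
            thresholds: Thresholds = DEFAULT_THRESHOLDS,
            lib_sizes: tuple[float, float] | None = None) -> pd.DataFrame:
    """Call differentially expressed genes between two samples.

    Parameters
    ----------
    counts
        DataFrame with columns ``gene, count_sensitive,
        count_resistant``; gene symbols must be unique.
    lib_sizes
        ``(lib_sensitive, lib_resistant)``; defaults to the column
        sums.

    Returns
    -------
    One row per gene with the normalized fold change
    ``((count_r + 0.5)/lib_r) / ((count_s + 0.5)/lib_s)``, direction,
    raw and BH-adjusted p and the DE flag.  Genes with zero counts in
    both samples are excluded from testing and from the BH denominator
    (``tested`` False, p-values NaN).
    """
    required = ["gene", "count_sensitive", "count_resistant"]
    missing = [c for c in required if c not in counts.columns]
    if missing:
        raise ValueError(f"count table lacks columns {missing}")
    if counts["gene"].duplicated().any():
        dup = counts.loc[counts["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene symbol {dup!r}")
    if (counts[["count_sensitive", "count_resistant"]] < 0).any().any():
        raise ValueError("counts must be non-negative")

    cs = counts["count_sensitive"].to_numpy(dtype=int)
    cr = counts["count_resistant"].to_numpy(dtype=int)
    if lib_sizes is None:
        lib_s, lib_r = float(cs.sum()), float(cr.sum())
    else:
        lib_s, lib_r = (float(x) for x in lib_sizes)
    if lib_s <= 0 or lib_r <= 0:
        raise ValueError("library sizes must be positive")

    fc = ((cr + PSEUDOCOUNT) / lib_r) / ((cs + PSEUDOCOUNT) / lib_s)
    direction = np.where(fc >= 1.0, "up", "down")
    tested = (cs + cr) > 0

    p_raw = np.full(len(counts), np.nan)
    p_raw[tested] = [de_test(a, b, lib_s, lib_r)
                     for a, b in zip(cs[tested], cr[tested])]
    p_adj = np.full(len(counts), np.nan)
    p_adj[tested] = benjamini_hochberg(p_raw[tested])

    effect = np.maximum(fc, 1.0 / fc)
    is_de = tested & (effect >= thresholds.fc_min) & (p_adj <= thresholds.adj_p_max)

    return pd.DataFrame({
        "gene": counts["gene"].to_numpy(),
        "count_sensitive": cs,
        "count_resistant": cr,
        "lib_sensitive": lib_s,
        "lib_resistant": lib_r,
        "fold_change": fc,
        "direction": direction,
        "tested": tested,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "is_de": is_de,
    }, columns=EXPRESSION_COLUMNS)


def de_gene_table(records: pd.DataFrame) -> pd.DataFrame:
    """DE-only rows sorted by |log fold change| descending."""
    de = records[records["is_de"]].copy()
    if len(de):
        order = np.abs(np.log(de["fold_change"].to_numpy()))
        de = de.iloc[np.argsort(-order, kind="stable")]
    return de.reset_index(drop=True)


def load_gene_counts(path) -> pd.DataFrame:
    """Read a ``gene count_sensitive count_resistant`` TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    required = ["gene", "count_sensitive", "count_resistant"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene count table lacks columns {missing}")
    return df[required]
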