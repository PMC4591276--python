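"""Clonal-selection calls from paired allele counts.

Each included variant is tested for a shift of its alternative allele
ratio (AAR) between the sensitive and the resistant sample with a
two-sided Fisher exact test on the 2x2 table

    [[ref_sensitive, alt_sensitive],
     [ref_resistant, alt_resistant]].

Variants with p <= fisher_alpha and |dAAR| >= delta_aar_min are called
``selected_up`` (AAR rises under treatment) or ``selected_down``; the
remaining variants with AAR > ancestral_aar_min in *both* samples are
assigned to the ancestral tumor clone, and everything else is
``unclassified``.  The four categories are mutually exclusive and
exhaustive.  No multiplicity correction is applied across variants:
the caller uses a fixed per-variant alpha, not an FDR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .variants import DEFAULT_THRESHOLDS, KEY, Thresholds

CATEGORIES = ("selected_up", "selected_down", "ancestral", "unclassified")

#: relative tolerance when comparing hypergeometric point probabilities
#: to the observed table's (tables tied up to this tolerance count into
#: the two-sided p-value)
TIE_REL_TOL = 1e-7

_LOGFACT = np.zeros(1)


def _logfact(n: int) -> np.ndarray:
    """Cached log-factorials 0..n (grown on demand)."""
    global _LOGFACT
    if n >= len(_LOGFACT):
        size = max(n + 1, 2 * len(_LOGFACT))
        _LOGFACT = gammaln(np.arange(size) + 1.0)
    return _LOGFACT


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value of the table [[a, b], [c, d]].

    Sums hypergeometric point probabilities of all tables with the same
    margins whose probability does not exceed the observed table's
    (relative tie tolerance :data:`TIE_REL_TOL`).  Degenerate margins
    (an empty row or column) give p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError(f"counts must be non-negative integers, got {(a, b, c, d)}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if row1 == 0 or row1 == n_total or col1 == 0 or col1 == n_total:
        return 1.0
    lf = _logfact(n_total)
    kmin = max(0, col1 - (n_total - row1))
    kmax = min(row1, col1)
    ks = np.arange(kmin, kmax + 1)
    logpmf = (lf[row1] - lf[ks] - lf[row1 - ks]
              + lf[n_total - row1] - lf[col1 - ks] - lf[n_total - row1 - col1 + ks]
              - (lf[n_total] - lf[col1] - lf[n_total - col1]))
    pmf = np.exp(logpmf)
    p_obs = pmf[a - kmin]
    p = float(pmf[pmf <= p_obs * (1.0 + TIE_REL_TOL)].sum())
    return min(1.0, p)


@dataclass(frozen=True)
class ClonalCall:
    """Classification of one variant."""

    category: str
    fisher_p: float
    delta_aar: float
    aar_sensitive: float
    aar_resistant: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not 0.0 < self.fisher_p <= 1.0:
            raise ValueError(f"fisher_p must lie in (0, 1], got {self.fisher_p!r}")


def classify_variant(ref_s, alt_s, ref_r, alt_r,
                     thresholds: Thresholds = DEFAULT_THRESHOLDS) -> ClonalCall:
    """Classify one variant from both samples' allele counts.

    Both samples must have data and non-zero depth (the inclusion
    filter guarantees this for pipeline input); otherwise a ValueError
    is raised.
    """
    counts = [ref_s, alt_s, ref_r, alt_r]
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in counts):
        raise ValueError("missing counts: variant should have been filtered out")
    ref_s, alt_s, ref_r, alt_r = (int(v) for v in counts)
    depth_s = ref_s + alt_s
    depth_r = ref_r + alt_r
    if depth_s == 0 or depth_r == 0:
        raise ValueError("zero depth: AAR undefined; variant should have been filtered out")
    aar_s = alt_s / depth_s
    aar_r = alt_r / depth_r
    delta = aar_r - aar_s
    p = fisher_exact_two_sided(ref_s, alt_s, ref_r, alt_r)

    if p <= thresholds.fisher_alpha and delta >= thresholds.delta_aar_min:
        category = "selected_up"
    elif p <= thresholds.fisher_alpha and delta <= -thresholds.delta_aar_min:
        category = "selected_down"
    elif aar_s > thresholds.ancestral_aar_min and aar_r > thresholds.ancestral_aar_min:
        category = "ancestral"
    else:
        category = "unclassified"
    return ClonalCall(category=category, fisher_p=p, delta_aar=delta,
                      aar_sensitive=aar_s, aar_resistant=aar_r)


def classify_table(merged: pd.DataFrame,
                   thresholds: Thresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Classify every record of a (filtered) merged table.

    Returns the table's key columns plus ``aar_sensitive,
    aar_resistant, delta_aar, fisher_p, category`` (and ``gene`` if the
    input carries one).
    """
    records = []
    carry = [c for c in ("gene",) if c in merged.columns]
    for _, row in merged.iterrows():
        call = classify_variant(row["ref_s"], row["alt_s"],
                                row["ref_r"], row["alt_r"], thresholds)
        rec = {k: row[k] for k in KEY if k in merged.columns}
        for c in carry:
            rec[c] = row[c]
        rec.update(aar_sensitive=call.aar_sensitive,
                   aar_resistant=call.aar_resistant,
                   delta_aar=call.delta_aar,
                   fisher_p=call.fisher_p,
                   category=call.category)
        records.append(rec)
    columns = [c for c in KEY if c in merged.columns] + carry + [
        "aar_sensitive", "aar_resistant", "delta_aar", "fisher_p", "category"]
    return pd.DataFrame(records, columns=columns)


def calls_from_af_pairs(af_sensitive, af_resistant, depth: int = 100,
                        thresholds: Thresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Classify variants given only per-sample allele fractions.

    Reconstructs integer allele counts at an assumed uniform depth
    (``alt = round(AF * depth)``) and runs :func:`classify_variant`.
    Useful for re-analyzing published mutant-AF tables where raw counts
    are not reported.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rows = []
    for af_s, af_r in zip(af_sensitive, af_resistant, strict=True):
        alt_s = round(float(af_s) * depth)
        alt_r = round(float(af_r) * depth)
        call = classify_variant(depth - alt_s, alt_s, depth - alt_r, alt_r, thresholds)
        rows.append({"aar_sensitive": call.aar_sensitive,
                     "aar_resistant": call.aar_resistant,
                     "delta_aar": call.delta_aar,
                     "fisher_p": call.fisher_p,
                     "category": call.category})
    return pd.DataFrame(rows)


def summarize_calls(calls: pd.DataFrame) -> dict:
    """Per-category counts plus per-direction variant lists.

    The ``selected_up``/``selected_down`` lists are sorted by
    |delta_aar| descending and keep report-style columns (gene and
    per-sample AARs) when present.
    """
    counts = {cat: int((calls["category"] == cat).sum()) if len(calls) else 0
              for cat in CATEGORIES}
    lists = {}
    for cat in ("selected_up", "selected_down"):
        sub = calls[calls["category"] == cat] if len(calls) else calls
        if len(sub):
            sub = sub.reindex(sub["delta_aar"].abs()
                              .sort_values(ascending=False, kind="mergesort").index)
        lists[cat] = sub.reset_index(drop=True)
    return {"counts": counts,
            "n_tested": int(len(calls)),
            "selected_up": lists["selected_up"],
            "selected_down": lists["selected_down"]}
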