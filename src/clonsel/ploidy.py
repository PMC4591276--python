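"""Regional ploidy and allelic imbalance from heterozygous-site AARs.

"Ploidy" here is the total number of parental alleles in a large
genomic region.  At a heterozygous site inside a region of ploidy k
where m copies carry the alternative allele, the expected alternative
allele ratio is m/k, so the set of het-site AARs in a region identifies
the allelic configuration m:(k-m).  Because expression-derived AARs
only identify the *ratio*, the reported k is the smallest ploidy
consistent with it (m/k in lowest terms): e.g. a 6:2 region is
reported as unbalanced tetraploidy (3:1).  Absolute copy number is not
identifiable from these data and is not claimed.

The fit maximizes, over candidate ratios r = m/k (coprime, k <= k_max),
the mirrored binomial mixture log-likelihood

    sum_i log[ 1/2 * Binom(alt_i | depth_i, r)
             + 1/2 * Binom(alt_i | depth_i, 1 - r) ],

mirrored because either parental haplotype may carry the alternative
allele.  The mixture is symmetric in r <-> 1-r, so candidates are
restricted to r >= 1/2 and the reported m is oriented afterwards by
the empirical mean AAR.  A BIC-style penalty 0.5*ln(n)*(k-2)
discourages needlessly fine ratios; ties break toward smaller k, then
toward the more balanced ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PLOIDY_PREFIX = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa",
                 7: "hepta", 8: "octa", 9: "nona", 10: "deca"}

#: report label for a region without allelic imbalance
NO_IMBALANCE = "-"
NO_CALL_LABEL = "no-call"


@dataclass(frozen=True)
class PloidySegment:
    """Ploidy/imbalance call for one genomic region of one sample.

    ``ploidy_k`` and ``alt_copies_m`` are ``None`` when the region has
    too few usable heterozygous sites ("no call").  ``balanced`` is
    True iff the best configuration is m/k = 1/2, reported as absence
    of allelic imbalance.
    """

    chrom: str
    start: int  # 1-based, closed
    end: int
    sample_id: str
    ploidy_k: Optional[int]
    alt_copies_m: Optional[int]
    balanced: Optional[bool]
    loglik: float
    n_sites: int

    def __post_init__(self) -> None:
        if self.ploidy_k is not None:
            if not (1 <= self.alt_copies_m <= self.ploidy_k - 1):
                raise ValueError("alt_copies_m must lie in [1, k-1]")
            if math.gcd(self.alt_copies_m, self.ploidy_k) != 1:
                raise ValueError("m/k must be in lowest terms")

    @property
    def label(self) -> str:
        """Report vocabulary: '-' (balanced), '<prefix>-ploidy', or 'no-call'."""
        if self.ploidy_k is None:
            return NO_CALL_LABEL
        if self.balanced:
            return NO_IMBALANCE
        return f"{PLOIDY_PREFIX[self.ploidy_k]}-ploidy"

    @property
    def region(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def candidate_ratios(k_max: int = 10) -> list[tuple[int, int]]:
    """Coprime (m, k) pairs with 1/2 <= m/k < 1 and 2 <= k <= k_max."""
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    out = []
    for k in range(2, k_max + 1):
        for m in range(1, k):
            if math.gcd(m, k) == 1 and 2 * m >= k:
                out.append((m, k))
    return out


def known_polymorphic_keys(annotations: pd.DataFrame) -> set[tuple]:
    """Variant keys of dbSNP-identified (germline-polymorphic) sites.

    Expression-based allelic-imbalance estimation should rest on
    germline heterozygous polymorphisms; restricting to catalogued
    dbSNP sites keeps somatic subclone variants (whose allele ratios
    track clone fractions, not regional ploidy) out of the fit.
    """
    known = annotations[annotations["dbsnp_id"].notna()]
    return set(zip(known["chrom"].astype(str), known["pos"].astype(int),
                   known["ref"].astype(str), known["alt"].astype(str)))


def collect_het_sites(merged: pd.DataFrame, sample: str,
                      region: Optional[tuple[str, int, int]] = None,
                      min_depth: int = 20,
                      aar_window: tuple[float, float] = (0.10, 0.90),
                      restrict_keys: Optional[set] = None) -> pd.DataFrame:
    """Select heterozygous-looking sites for the ploidy fit.

    Parameters
    ----------
    merged
        Merged variant table.
    sample
        ``"sensitive"`` or ``"resistant"``.
    region
        Optional ``(chrom, start, end)``, 1-based closed.
    min_depth, aar_window
        Only sites with depth >= min_depth and AAR strictly inside the
        open window are kept (extreme ratios are likelier hom calls or
        artifacts than informative het sites).
    restrict_keys
        Optional set of ``(chrom, pos, ref, alt)`` keys to which the
        selection is restricted (see :func:`known_polymorphic_keys`).

    Returns
    -------
    DataFrame with columns ``alt`` and ``depth``.
    """
    suffix = {"sensitive": "s", "resistant": "r"}.get(sample)
    if suffix is None:
        raise ValueError(f"sample must be 'sensitive' or 'resistant', got {sample!r}")
    ref = merged[f"ref_{suffix}"].to_numpy(dtype=float)
    alt = merged[f"alt_{suffix}"].to_numpy(dtype=float)
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(depth > 0, alt / depth, np.nan)
    lo, hi = aar_window
    mask = (depth >= min_depth) & (ratio > lo) & (ratio < hi)
    if region is not None:
        chrom, start, end = region
        pos = merged["pos"].to_numpy()
        mask &= (merged["chrom"].to_numpy() == chrom) & (pos >= start) & (pos <= end)
    if restrict_keys is not None:
        keys = list(zip(merged["chrom"].astype(str), merged["pos"].astype(int),
                        merged["ref"].astype(str), merged["alt"].astype(str)))
        mask &= np.fromiter((k in restrict_keys for k in keys), dtype=bool,
                            count=len(keys))
    return pd.DataFrame({"alt": alt[mask].astype(int),
                         "depth": depth[mask].astype(int)})


def _mixture_loglik(alt: np.ndarray, depth: np.ndarray, r: np.ndarray,
                    overdispersion: Optional[float]) -> np.ndarray:
    """Log-likelihood of each candidate ratio (columns) over sites (rows)."""
    a = alt[:, None]
    d = depth[:, None]
    rr = r[None, :]
    if overdispersion is None:
        lp1 = stats.binom.logpmf(a, d, rr)
        lp2 = stats.binom.logpmf(a, d, 1.0 - rr)
    else:
        s = overdispersion  # beta-binomial concentration; larger = less dispersed
        lp1 = stats.betabinom.logpmf(a, d, rr * s, (1.0 - rr) * s)
        lp2 = stats.betabinom.logpmf(a, d, (1.0 - rr) * s, rr * s)
    m = np.maximum(lp1, lp2)
    return (m + np.log(0.5 * np.exp(lp1 - m) + 0.5 * np.exp(lp2 - m))).sum(axis=0)


def score_grid(alt: Sequence[int], depth: Sequence[int], k_max: int = 10,
               overdispersion: Optional[float] = None) -> pd.DataFrame:
    """Per-candidate log-likelihoods and penalized scores.

    Exposed so the model choice can be audited: the selected candidate
    is the row maximizing ``score`` (ties toward smaller k, then
    smaller ratio).
    """
    alt = np.asarray(alt, dtype=int)
    depth = np.asarray(depth, dtype=int)
    if len(alt) != len(depth):
        raise ValueError("alt and depth must have equal length")
    cands = candidate_ratios(k_max)
    r = np.array([m / k for m, k in cands])
    loglik = _mixture_loglik(alt, depth, r, overdispersion)
    n = len(alt)
    penalty = np.array([0.5 * math.log(max(n, 1)) * (k - 2) for _, k in cands])
    return pd.DataFrame({
        "m": [m for m, _ in cands],
        "k": [k for _, k in cands],
        "ratio": r,
        "loglik": loglik,
        "score": loglik - penalty,
    })


def fit_region_ploidy(sites: pd.DataFrame, chrom: str = "", start: int = 1,
                      end: int = 1, sample_id: str = "", k_max: int = 10,
                      min_sites: int = 20,
                      overdispersion: Optional[float] = None) -> PloidySegment:
    """Fit the allelic configuration of one region from its het sites.

    Regions with fewer than ``min_sites`` usable sites are reported as
    "no call" rather than fitted.
    """
    n = len(sites)
    if n < min_sites:
        return PloidySegment(chrom=chrom, start=start, end=end,
                             sample_id=sample_id, ploidy_k=None,
                             alt_copies_m=None, balanced=None,
                             loglik=float("nan"), n_sites=n)
    grid = score_grid(sites["alt"], sites["depth"], k_max=k_max,
                      overdispersion=overdispersion)
    order = grid.sort_values(["score", "k", "ratio"],
                             ascending=[False, True, True],
                             kind="mergesort")
    best = order.iloc[0]
    m, k = int(best["m"]), int(best["k"])
    balanced = (2 * m == k)
    # orient m by which haplotype the data favor (the mixture itself is
    # symmetric in m <-> k-m)
    mean_aar = float(sites["alt"].sum() / sites["depth"].sum())
    if not balanced and mean_aar < 0.5:
        m = k - m
    return PloidySegment(chrom=chrom, start=start, end=end, sample_id=sample_id,
                         ploidy_k=k, alt_copies_m=m, balanced=balanced,
                         loglik=float(best["loglik"]), n_sites=n)


def fit_grid(merged: pd.DataFrame, regions: pd.DataFrame, sample: str,
             sample_id: Optional[str] = None,
             annotations: Optional[pd.DataFrame] = None,
             **fit_kwargs) -> list[PloidySegment]:
    """Fit every region of a fixed segment grid for one sample.

    ``regions`` has columns ``chrom, start, end`` (1-based closed).
    When an annotation table is given, the fit is restricted to
    dbSNP-identified (germline-polymorphic) sites.
    """
    restrict = known_polymorphic_keys(annotations) \
        if annotations is not None else None
    out = []
    for _, reg in regions.iterrows():
        region = (str(reg["chrom"]), int(reg["start"]), int(reg["end"]))
        sites = collect_het_sites(merged, sample, region=region,
                                  restrict_keys=restrict,
                                  **{k: v for k, v in fit_kwargs.items()
                                     if k in ("min_depth", "aar_window")})
        seg = fit_region_ploidy(
            sites, chrom=region[0], start=region[1], end=region[2],
            sample_id=sample_id or sample,
            **{k: v for k, v in fit_kwargs.items()
               if k in ("k_max", "min_sites", "overdispersion")})
        out.append(seg)
    return out


def compare_segments(sensitive_segments: Sequence[PloidySegment],
                     resistant_segments: Sequence[PloidySegment]) -> pd.DataFrame:
    """Rows of the segment grid where the two samples' calls differ.

    Mirrors the published layout: one row per differing region with
    the sensitive and resistant labels ('-' = no allelic imbalance).
    """
    s_by_region = {seg.region: seg for seg in sensitive_segments}
    r_by_region = {seg.region: seg for seg in resistant_segments}
    if set(s_by_region) != set(r_by_region):
        only_s = sorted(set(s_by_region) - set(r_by_region))
        only_r = sorted(set(r_by_region) - set(s_by_region))
        raise ValueError(
            f"segment grids differ between samples; sensitive-only: {only_s}, "
            f"resistant-only: {only_r}")
    rows = []
    for seg in sensitive_segments:
        other = r_by_region[seg.region]
        if seg.label != other.label:
            rows.append({"region": seg.region,
                         "sensitive": seg.label,
                         "resistant": other.label})
    return pd.DataFrame(rows, columns=["region", "sensitive", "resistant"])


def load_region_grid(path) -> pd.DataFrame:
    """Load a segment grid from BED (0-based half-open on disk).

    Converted to the package's 1-based closed convention.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start0", "end"],
                     dtype={0: str})
    out = pd.DataFrame({"chrom": df["chrom"],
                        "start": df["start0"].astype(int) + 1,
                        "end": df["end"].astype(int)})
    if (out["start"] > out["end"]).any():
        raise ValueError(f"{path}: empty or inverted BED interval")
    return out


def write_region_grid(regions: pd.DataFrame, path) -> None:
    """Write a 1-based closed grid as BED (0-based half-open)."""
    bed = pd.DataFrame({"chrom": regions["chrom"],
                        "start0": regions["start"].astype(int) - 1,
                        "end": regions["end"].astype(int)})
    bed.to_csv(path, sep="\t", index=False, header=False)


def segments_to_frame(segments: Sequence[PloidySegment]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": s.chrom, "start": s.start, "end": s.end,
        "sample_id": s.sample_id, "ploidy_k": s.ploidy_k,
        "alt_copies_m": s.alt_copies_m, "balanced": s.balanced,
        "label": s.label, "loglik": s.loglik, "n_sites": s.n_sites,
    } for s in segments])
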