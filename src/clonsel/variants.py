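"""Merged variant table construction from per-sample allele counts.

The merged variant table is the union, over a sensitive/resistant sample
pair, of every transcriptome position carrying at least one alternative
allele read in either sample.  Each row keeps both samples' reference and
alternative read counts (bases at phred >= 20 only, a property of the
upstream pileup) and the derived alternative allele ratio

    AAR = alt_count / (ref_count + alt_count),

the per-sample abundance measure used by the downstream clonal-selection
test.  A site observed in only one sample is retained with the other
sample's counts *missing* (NaN), which is distinct from an observed
depth of zero and never treated as evidence of absence.

Coordinates are 1-based and fully closed, as in VCF.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

#: genotype labels
HOM_REF = "hom_ref"
NON_HOM_REF = "non_hom_ref"
NO_CALL = "no_call"

#: column order of the per-sample count TSV dialect
COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "ref_count", "alt_count"]

#: variant key shared by every table in the package
KEY = ["chrom", "pos", "ref", "alt"]

MERGED_COLUMNS = KEY + ["ref_s", "alt_s", "ref_r", "alt_r", "aar_s", "aar_r"]


@dataclass(frozen=True)
class Thresholds:
    """Analysis-wide cutoffs shared by all pipeline stages.

    Attributes
    ----------
    base_qual_min : int
        Minimum base phred quality for a read base to be counted
        (applied upstream, in the pileup; documented here).
    align_score_min : int
        Minimum alignment score of a read (applied upstream).
    depth_min_strict : int
        Inclusion requires strictly more than this many reads at the
        site in *both* samples.
    ceu_af_max : float
        Maximum 1000 Genomes CEU alternative-allele frequency for a
        catalogued somatic (COSMIC) variant to stay included.
    fisher_alpha : float
        Per-variant significance level of the two-sided Fisher exact
        test on allele counts.
    delta_aar_min : float
        Minimum |AAR_resistant - AAR_sensitive| for a significant
        variant to be called selected.
    ancestral_aar_min : float
        Non-selected variants with AAR strictly above this value in
        both samples are assigned to the ancestral tumor clone.
    fc_min, adj_p_max : float
        Differential-expression gates: normalized fold change >= fc_min
        (in either direction) and BH-adjusted p <= adj_p_max.
    genotype_min_alt, genotype_min_aar :
        Definition of the non-homozygous-reference genotype estimate:
        at least ``genotype_min_alt`` alternative reads and an AAR of at
        least ``genotype_min_aar``.
    """

    base_qual_min: int = 20
    align_score_min: int = 20
    depth_min_strict: int = 10
    ceu_af_max: float = 0.05
    fisher_alpha: float = 1e-3
    delta_aar_min: float = 0.1
    ancestral_aar_min: float = 0.30
    fc_min: float = 2.5
    adj_p_max: float = 0.01
    genotype_min_alt: int = 2
    genotype_min_aar: float = 0.05

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not value > 0:
                raise ValueError(f"threshold {f.name} must be positive, got {value!r}")
        for name in ("ceu_af_max", "fisher_alpha", "adj_p_max",
                     "genotype_min_aar", "delta_aar_min", "ancestral_aar_min"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"threshold {name} must lie in (0, 1), got {value!r}")


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class SampleAlleleCounts:
    """Reference/alternative read counts of one sample at one site."""

    sample_id: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError(
                f"allele counts must be non-negative, got "
                f"({self.ref_count}, {self.alt_count}) for {self.sample_id!r}"
            )

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def aar(self) -> float | None:
        """Alternative allele ratio; ``None`` when the site has no coverage."""
        if self.depth == 0:
            return None
        return self.alt_count / self.depth


def aar(ref_count, alt_count):
    """Vectorized AAR; NaN where depth is zero or counts are missing."""
    ref = np.asarray(ref_count, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(depth > 0, alt / depth, np.nan)
    return out


def _load_counts_tsv(path: Path) -> pd.DataFrame:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != COUNT_COLUMNS:
            raise ValueError(
                f"{path}: expected header {COUNT_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(COUNT_COLUMNS):
                raise ValueError(f"{path}: malformed row at line {lineno}: {row!r}")
            chrom, pos, ref, alt, ref_count, alt_count = row
            try:
                pos_i = int(pos)
                ref_i = int(ref_count)
                alt_i = int(alt_count)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed row at line {lineno}: {exc}"
                ) from None
            if pos_i < 1 or ref_i < 0 or alt_i < 0:
                raise ValueError(
                    f"{path}: invalid position or counts at line {lineno}"
                )
            rows.append((chrom, pos_i, ref, alt, ref_i, alt_i))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def _load_counts_vcf(path: Path, sample_id: str | None = None) -> pd.DataFrame:
    from cyvcf2 import VCF  # htslib import deferred to first use

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    if sample_id is None:
        si = 0
    else:
        try:
            si = samples.index(sample_id)
        except ValueError:
            raise ValueError(f"{path}: sample {sample_id!r} not in {samples}") from None
    rows = []
    for variant in vcf:
        try:
            ad = variant.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ValueError(
                f"{path}: record {variant.CHROM}:{variant.POS} lacks the "
                "per-sample allele-depth (AD) field"
            )
        depths = [max(int(x), 0) for x in np.atleast_1d(ad[si])]
        ref_count = depths[0] if depths else 0
        # multi-allelic rows decompose into one record per alternative allele
        for j, alt in enumerate(variant.ALT):
            alt_count = depths[j + 1] if j + 1 < len(depths) else 0
            rows.append((variant.CHROM, variant.POS, variant.REF, alt,
                         ref_count, alt_count))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


def load_sample_counts(path, fmt: str = "auto", sample_id: str | None = None) -> pd.DataFrame:
    """Load one sample's per-site allele counts.

    Parameters
    ----------
    path
        A TSV in the ``chrom pos ref alt ref_count alt_count`` dialect,
        or a VCF 4.x file with a per-sample AD (allele depth) FORMAT
        field.  Multi-allelic VCF rows are decomposed into one record
        per alternative allele.
    fmt
        ``"tsv"``, ``"vcf"`` or ``"auto"`` (by file extension).
    sample_id
        For multi-sample VCFs, which sample column to read (default:
        first).

    Returns
    -------
    DataFrame with columns ``chrom pos ref alt ref_count alt_count``,
    sorted by key.  Sites with zero depth are retained (their AAR is
    undefined downstream).
    """
    path = Path(path)
    if fmt == "auto":
        name = path.name.lower()
        fmt = "vcf" if (name.endswith(".vcf") or name.endswith(".vcf.gz")) else "tsv"
    if fmt == "tsv":
        df = _load_counts_tsv(path)
    elif fmt == "vcf":
        df = _load_counts_vcf(path, sample_id=sample_id)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    dup = df.duplicated(KEY)
    if dup.any():
        first = df.loc[dup.idxmax(), KEY].tolist()
        raise ValueError(f"{path}: duplicate variant key {first}")
    return df.sort_values(KEY, kind="mergesort").reset_index(drop=True)


def build_merged_table(sensitive_counts: pd.DataFrame,
                       resistant_counts: pd.DataFrame) -> pd.DataFrame:
    """Merge two samples' counts into the merged variant table.

    The result is the union over sites with at least one alternative
    allele read in either sample.  A site absent from one sample's
    input is retained with that sample's counts missing (NaN).

    Raises
    ------
    ValueError
        If the two inputs disagree on the reference allele at a shared
        position.
    """
    s = sensitive_counts.rename(columns={"ref_count": "ref_s", "alt_count": "alt_s"})
    r = resistant_counts.rename(columns={"ref_count": "ref_r", "alt_count": "alt_r"})
    merged = s.merge(r, on=KEY, how="outer")

    refs = merged.groupby(["chrom", "pos"])["ref"].nunique()
    conflicts = refs[refs > 1]
    if len(conflicts):
        sites = ", ".join(f"{c}:{p}" for c, p in conflicts.index)
        raise ValueError(f"conflicting reference allele at site(s): {sites}")

    keep = (merged["alt_s"] >= 1) | (merged["alt_r"] >= 1)  # NaN compares False
    merged = merged.loc[keep].copy()
    merged["aar_s"] = aar(merged["ref_s"], merged["alt_s"])
    merged["aar_r"] = aar(merged["ref_r"], merged["alt_r"])
    merged = merged.sort_values(KEY, kind="mergesort").reset_index(drop=True)
    return merged[MERGED_COLUMNS]


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def estimate_genotype(ref_count, alt_count,
                      thresholds: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """Estimate a site genotype from one sample's allele counts.

    ``non_hom_ref`` iff alt_count >= genotype_min_alt and
    AAR >= genotype_min_aar; ``no_call`` when the sample has no data or
    zero depth; ``hom_ref`` otherwise.
    """
    if _is_missing(ref_count) or _is_missing(alt_count):
        return NO_CALL
    ref_count = int(ref_count)
    alt_count = int(alt_count)
    if ref_count < 0 or alt_count < 0:
        raise ValueError("allele counts must be non-negative")
    depth = ref_count + alt_count
    if depth == 0:
        return NO_CALL
    if alt_count >= thresholds.genotype_min_alt and \
            alt_count / depth >= thresholds.genotype_min_aar:
        return NON_HOM_REF
    return HOM_REF


def write_merged_table(merged: pd.DataFrame, path) -> None:
    merged.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.10g")


def read_merged_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in MERGED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: merged table lacks columns {missing}")
    return df[MERGED_COLUMNS]
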