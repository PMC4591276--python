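"""Annotation-driven inclusion filter for merged-table variants.

A variant enters the clonal-selection analysis only if all of the
following hold:

1. its genotype is estimated non-homozygous-reference in at least one
   sample;
2. both samples cover the site with strictly more than
   ``depth_min_strict`` reads;
3. it is exonic and not synonymous;
4. it is not inside a segmental duplication (a mapping-artifact-prone
   region); and
5. one evidence branch admits it:

   a. catalogued somatic (COSMIC) and, if a 1000 Genomes CEU frequency
      is reported, that frequency is below ``ceu_af_max``;
   b. novel (neither 1000g CEU nor dbSNP) and predicted deleterious by
      SIFT *or* PolyPhen2-HDIV;
   c. dbSNP-known but absent from 1000g CEU, and predicted deleterious
      by SIFT *and* PolyPhen2-HDIV.

Variants present in 1000g CEU but not in COSMIC have no admitting
branch and are excluded.  PolyPhen2 "possibly_damaging" does not count
as deleterious.  Records without an annotation are excluded and
reported separately as "unannotated".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .variants import (DEFAULT_THRESHOLDS, KEY, NON_HOM_REF, Thresholds,
                       estimate_genotype)

LOCATION_CLASSES = frozenset(
    {"exonic", "splicing", "intronic", "intergenic", "UTR", "other"})
EXONIC_CLASSES = frozenset(
    {"nonsynonymous", "synonymous", "stopgain", "stoploss",
     "frameshift", "nonframeshift", "unknown"})
SIFT_CALLS = frozenset({"deleterious", "tolerated"})
POLYPHEN_CALLS = frozenset({"deleterious", "benign", "possibly_damaging"})

#: fixed evaluation order of the filter rules (audit-trace order)
RULES = ("genotype", "depth", "coding", "segdup", "evidence")

ANNOTATION_COLUMNS = KEY + [
    "gene", "location_class", "exonic_class", "in_cosmic", "dbsnp_id",
    "ceu_af", "sift", "polyphen_hdiv", "in_segdup",
]


@dataclass(frozen=True)
class AnnotationRecord:
    """Annovar-style annotation of one variant key."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    location_class: str
    exonic_class: str = "unknown"
    in_cosmic: bool = False
    dbsnp_id: Optional[str] = None
    ceu_af: Optional[float] = None
    sift: Optional[str] = None
    polyphen_hdiv: Optional[str] = None
    in_segdup: bool = False

    def __post_init__(self) -> None:
        if self.location_class not in LOCATION_CLASSES:
            raise ValueError(f"unknown location_class {self.location_class!r}")
        if self.exonic_class not in EXONIC_CLASSES:
            raise ValueError(f"unknown exonic_class {self.exonic_class!r}")
        if self.sift is not None and self.sift not in SIFT_CALLS:
            raise ValueError(f"unknown sift call {self.sift!r}")
        if self.polyphen_hdiv is not None and self.polyphen_hdiv not in POLYPHEN_CALLS:
            raise ValueError(f"unknown polyphen_hdiv call {self.polyphen_hdiv!r}")
        if self.ceu_af is not None and not 0.0 <= self.ceu_af <= 1.0:
            raise ValueError(f"ceu_af must lie in [0, 1], got {self.ceu_af!r}")


def evidence_branch(ann: AnnotationRecord,
                    thresholds: Thresholds = DEFAULT_THRESHOLDS,
                    cosmic_by_position: bool = False) -> Optional[str]:
    """Name of the admitting evidence branch, or ``None`` if none passes.

    ``cosmic_by_position`` is accepted for API symmetry with annotation
    sources that record COSMIC membership by position only; the flag is
    interpreted upstream when building the annotation table, so here it
    does not change the decision.
    """
    ceu_absent = ann.ceu_af is None
    if ann.in_cosmic and (ceu_absent or ann.ceu_af < thresholds.ceu_af_max):
        return "cosmic"
    sift_del = ann.sift == "deleterious"
    poly_del = ann.polyphen_hdiv == "deleterious"
    if ceu_absent and ann.dbsnp_id is None and (sift_del or poly_del):
        return "novel_deleterious"
    if ceu_absent and ann.dbsnp_id is not None and (sift_del and poly_del):
        return "dbsnp_deleterious"
    return None


def passes_inclusion(record: Mapping,
                     ann: Optional[AnnotationRecord],
                     thresholds: Thresholds = DEFAULT_THRESHOLDS):
    """Evaluate the inclusion decision tree for one merged-table record.

    Parameters
    ----------
    record
        Mapping (e.g. a merged-table row) with keys ``ref_s, alt_s,
        ref_r, alt_r``; missing counts are NaN/None.
    ann
        The variant's annotation, or ``None`` if unannotated.

    Returns
    -------
    (include, reason_trace)
        ``include`` is True iff every rule passes.  ``reason_trace`` is
        an ordered list of ``(rule, verdict)`` pairs covering every
        rule evaluated; an unannotated record yields the single entry
        ``("annotation", "unannotated")``.
    """
    if ann is None:
        return False, [("annotation", "unannotated")]

    gt_s = estimate_genotype(record["ref_s"], record["alt_s"], thresholds)
    gt_r = estimate_genotype(record["ref_r"], record["alt_r"], thresholds)
    ok_genotype = NON_HOM_REF in (gt_s, gt_r)

    def _depth(ref, alt) -> float:
        if ref is None or alt is None:
            return math.nan
        return float(ref) + float(alt)

    depth_s = _depth(record["ref_s"], record["alt_s"])
    depth_r = _depth(record["ref_r"], record["alt_r"])
    # NaN comparisons are False, so a missing sample fails the depth rule
    ok_depth = bool(depth_s > thresholds.depth_min_strict) and \
        bool(depth_r > thresholds.depth_min_strict)

    ok_coding = ann.location_class == "exonic" and ann.exonic_class != "synonymous"
    ok_segdup = not ann.in_segdup
    branch = evidence_branch(ann, thresholds)

    trace = [
        ("genotype", "pass" if ok_genotype else "fail"),
        ("depth", "pass" if ok_depth else "fail"),
        ("coding", "pass" if ok_coding else "fail"),
        ("segdup", "pass" if ok_segdup else "fail"),
        ("evidence", branch if branch is not None else "fail"),
    ]
    include = ok_genotype and ok_depth and ok_coding and ok_segdup and branch is not None
    return include, trace


def _parse_bool(value, path, lineno: int | None = None):
    s = str(value).strip().lower()
    if s in {"1", "true", "yes", "t"}:
        return True
    if s in {"0", "false", "no", "f", ""}:
        return False
    where = f" at line {lineno}" if lineno is not None else ""
    raise ValueError(f"{path}: cannot parse boolean {value!r}{where}")


def load_annotations(path) -> pd.DataFrame:
    """Load the annotation TSV (empty string = field absent)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: annotation table lacks columns {missing}")
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["pos"].astype(int),
        "ref": df["ref"],
        "alt": df["alt"],
        "gene": df["gene"],
        "location_class": df["location_class"],
        "exonic_class": df["exonic_class"].replace("", "unknown"),
        "in_cosmic": df["in_cosmic"].map(lambda v: _parse_bool(v, path)),
        "dbsnp_id": df["dbsnp_id"].replace("", None),
        "ceu_af": pd.to_numeric(df["ceu_af"].replace("", None), errors="raise"),
        "sift": df["sift"].replace("", None),
        "polyphen_hdiv": df["polyphen_hdiv"].replace("", None),
        "in_segdup": df["in_segdup"].map(lambda v: _parse_bool(v, path)),
    })
    dup = out.duplicated(KEY)
    if dup.any():
        first = out.loc[dup.idxmax(), KEY].tolist()
        raise ValueError(f"{path}: duplicate annotation key {first}")
    return out


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False, na_rep="")


def annotation_from_row(row: Mapping) -> AnnotationRecord:
    """Build an :class:`AnnotationRecord` from an annotation-table row."""
    def _opt(v):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    ceu = _opt(row["ceu_af"])
    return AnnotationRecord(
        chrom=str(row["chrom"]), pos=int(row["pos"]),
        ref=str(row["ref"]), alt=str(row["alt"]), gene=str(row["gene"]),
        location_class=str(row["location_class"]),
        exonic_class=str(row["exonic_class"]),
        in_cosmic=bool(row["in_cosmic"]),
        dbsnp_id=_opt(row["dbsnp_id"]),
        ceu_af=None if ceu is None else float(ceu),
        sift=_opt(row["sift"]),
        polyphen_hdiv=_opt(row["polyphen_hdiv"]),
        in_segdup=bool(row["in_segdup"]),
    )


def apply_filter(merged: pd.DataFrame, annotations: pd.DataFrame,
                 thresholds: Thresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Apply the inclusion decision tree to every merged-table record.

    Returns a copy of ``merged`` with one audit column per rule
    (``rule_<name>``), an ``include`` flag and a ``reason`` column
    ("pass", the first failing rule, or "unannotated").
    """
    ann_index = {}
    for _, row in annotations.iterrows():
        rec = annotation_from_row(row)
        ann_index[(rec.chrom, rec.pos, rec.ref, rec.alt)] = rec

    out = merged.copy()
    includes, reasons = [], []
    rule_cols: dict[str, list] = {r: [] for r in RULES}
    genes = []
    for _, row in merged.iterrows():
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        ann = ann_index.get(key)
        include, trace = passes_inclusion(row, ann, thresholds)
        includes.append(include)
        genes.append(ann.gene if ann is not None else "")
        if ann is None:
            for r in RULES:
                rule_cols[r].append("unannotated")
            reasons.append("unannotated")
            continue
        verdicts = dict(trace)
        for r in RULES:
            rule_cols[r].append(verdicts[r])
        if include:
            reasons.append("pass")
        else:
            reasons.append(next(r for r in RULES if verdicts[r] == "fail"))
    out["gene"] = genes
    for r in RULES:
        out[f"rule_{r}"] = rule_cols[r]
    out["include"] = includes
    out["reason"] = reasons
    return out


def filter_summary(filtered: pd.DataFrame) -> dict:
    """Record counts at each step of the filter (audit summary)."""
    total = len(filtered)
    reasons = filtered["reason"].value_counts().to_dict()
    return {
        "total": total,
        "included": int(filtered["include"].sum()),
        "unannotated": int(reasons.get("unannotated", 0)),
        "excluded_by_rule": {r: int(reasons.get(r, 0)) for r in RULES},
    }
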