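"""Synthetic sensitive/resistant sample pairs with known truth.

The generator emulates the study design the downstream stages analyze:
an ancestral tumor clone carrying heterozygous variants, a resistant
subclone that is (nearly) absent before treatment and expands under
drug pressure, regional ploidy states that shift heterozygous-site
allele ratios away from 1:1, and negative-binomial gene expression
with planted fold changes.  Every simulated variant, segment and gene
is recorded in a truth table so recovery can be measured exactly.

Expected alternative allele ratios (AARs):

* ancestral het variant in a region with m of k alt-bearing alleles:
  ``ancestral_fraction * m/k`` in both samples;
* resistant-subclone-private variant (diploid region):
  ``subclone_fraction * 1/2`` per sample, i.e. ~0 before treatment and
  ``0.35`` at the default resistant fraction 0.7 — the de-novo
  appearance pattern of a positively selected mutation;
* depleted variant (carried by the cells the subclone replaces):
  ``(1 - subclone_fraction) * 1/2`` per sample;
* germline het site: ``m/k`` of its segment in each sample.

Sequencing noise: site depth is negative-binomial (mean, dispersion);
alternative reads at truly reference-homozygous sites appear at a
per-base error rate (default 0.1%), which exercises the merged table's
">= 1 alternative allele" inclusion rule.  All randomness flows from a
single explicitly passed seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .ploidy import PLOIDY_PREFIX, write_region_grid
from .read_overlap import ReadPair
from .selection_filter import ANNOTATION_COLUMNS
from .variants import COUNT_COLUMNS

logger = logging.getLogger(__name__)

CATEGORIES = ("ancestral", "selected_up", "selected_down", "neutral")

#: cancer-gene symbols cycled onto planted selected variants so reports
#: read like the real analysis
CANCER_GENE_POOL = (
    "TP53", "NRAS", "HSPG2", "MACF1", "ECT2", "POLG", "PKD1", "SF3B3",
    "NR2F6", "UBE4B", "SYNJ2", "HPD", "EMC10", "CKAP2L", "PDLIM4",
)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CloneModel:
    """Clonal composition and sequencing parameters of a sample pair."""

    ancestral_fraction: float = 1.0
    resistant_subclone_fraction_sensitive: float = 0.0
    resistant_subclone_fraction_resistant: float = 0.7
    n_ancestral_variants: int = 2000
    n_selected_variants: int = 150
    n_depleted_variants: int = 80
    n_neutral_variants: int = 2000
    mean_depth: float = 100.0
    depth_dispersion: float = 5.0
    error_rate: float = 1e-3

    def __post_init__(self) -> None:
        fracs = {
            "ancestral_fraction": self.ancestral_fraction,
            "resistant_subclone_fraction_sensitive":
                self.resistant_subclone_fraction_sensitive,
            "resistant_subclone_fraction_resistant":
                self.resistant_subclone_fraction_resistant,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        for name in ("n_ancestral_variants", "n_selected_variants",
                     "n_depleted_variants", "n_neutral_variants"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")


@dataclass(frozen=True)
class SegmentPlan:
    """Planned allelic configuration of one genomic region, per sample."""

    chrom: str
    start: int
    end: int
    k_sensitive: int = 2
    m_sensitive: int = 1
    k_resistant: int = 2
    m_resistant: int = 1
    n_het_sites: int = 80

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid segment interval {self.chrom}:{self.start}-{self.end}")
        for k, m in ((self.k_sensitive, self.m_sensitive),
                     (self.k_resistant, self.m_resistant)):
            if k < 2 or not 1 <= m <= k - 1:
                raise ValueError(f"invalid allelic configuration m={m}, k={k}")
        if self.n_het_sites < 0:
            raise ValueError("n_het_sites must be non-negative")

    @property
    def ratio_sensitive(self) -> float:
        return self.m_sensitive / self.k_sensitive

    @property
    def ratio_resistant(self) -> float:
        return self.m_resistant / self.k_resistant

    @property
    def shared(self) -> bool:
        return (self.k_sensitive, self.m_sensitive) == \
            (self.k_resistant, self.m_resistant)


@dataclass(frozen=True)
class AnnotationPlan:
    """Mixture weights controlling the realism of planted annotations."""

    neutral_segdup_fraction: float = 0.10
    neutral_exonic_fraction: float = 0.30
    ancestral_cosmic_fraction: float = 0.30
    ancestral_dbsnp_fraction: float = 0.40
    deleterious_fraction: float = 0.50

    def __post_init__(self) -> None:
        for f in ("neutral_segdup_fraction", "neutral_exonic_fraction",
                  "ancestral_cosmic_fraction", "ancestral_dbsnp_fraction",
                  "deleterious_fraction"):
            if not 0.0 <= getattr(self, f) <= 1.0:
                raise ValueError(f"{f} must lie in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth of one simulated pair.

    ``variants``: one row per simulated site (category, source, true
    AARs, segment); ``segments``: planned per-sample allelic
    configurations with report labels; ``de_genes``: planted expression
    truth when expression was simulated alongside.
    """

    variants: pd.DataFrame
    segments: pd.DataFrame
    de_genes: Optional[pd.DataFrame] = None


@dataclass
class SimulatedPair:
    counts_sensitive: pd.DataFrame
    counts_resistant: pd.DataFrame
    annotations: pd.DataFrame
    truth: TruthTable
    region_grid: pd.DataFrame


def default_ploidy_plan() -> list[SegmentPlan]:
    """Balanced diploid background plus the imbalance patterns the
    analysis is meant to detect: a resistant-only unbalanced
    tetraploidy, a resistant-only unbalanced pentaploidy, and a
    sensitive-only unbalanced triploidy."""
    return [
        SegmentPlan("chr1", 1, 50_000_000, 2, 1, 2, 1),
        SegmentPlan("chr2", 1, 50_000_000, 2, 1, 2, 1),
        SegmentPlan("chr12", 1, 40_000_000, 2, 1, 4, 3),
        SegmentPlan("chr17", 1, 25_000_000, 2, 1, 5, 4),
        SegmentPlan("chr22", 1, 30_000_000, 3, 2, 2, 1),
    ]


def expected_segment_label(k: int, m: int) -> str:
    """Report label implied by a planned configuration (lowest terms)."""
    g = math.gcd(m, k)
    k, m = k // g, m // g
    if 2 * m == k:
        return "-"
    return f"{PLOIDY_PREFIX[k]}-ploidy"


def _require_seed(seed) -> int:
    if seed is None or not isinstance(seed, (int, np.integer)):
        raise ValueError(
            "a fixed integer seed is required for reproducible simulation")
    return int(seed)


def _unique_positions(rng: np.random.Generator, start: int, end: int,
                      n: int) -> np.ndarray:
    """Draw n distinct 1-based positions in [start, end]."""
    span = end - start + 1
    if n > span:
        raise ValueError(f"cannot place {n} distinct positions in a span of {span}")
    taken: list[int] = []
    seen: set[int] = set()
    while len(taken) < n:
        draw = rng.integers(start, end + 1, size=2 * (n - len(taken)) + 8)
        for p in draw:
            p = int(p)
            if p not in seen:
                seen.add(p)
                taken.append(p)
                if len(taken) == n:
                    break
    return np.array(taken)


def _alleles(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_idx], _BASES[alt_idx]


def _category_from_aars(aar_s: float, aar_r: float,
                        min_delta: float = 0.1,
                        ancestral_min: float = 0.30) -> str:
    delta = aar_r - aar_s
    if delta >= min_delta:
        return "selected_up"
    if delta <= -min_delta:
        return "selected_down"
    if aar_s > ancestral_min and aar_r > ancestral_min:
        return "ancestral"
    return "neutral"


def simulate_pair(clone_model: Optional[CloneModel] = None,
                  ploidy_plan: Optional[Sequence[SegmentPlan]] = None,
                  annotation_plan: Optional[AnnotationPlan] = None,
                  seed: int = 0) -> SimulatedPair:
    """Simulate one sensitive/resistant pair with full truth.

    Somatic variants (ancestral clone, resistant-subclone-private,
    depleted, and reference-homozygous noise sites) are placed in
    segments whose allelic configuration is shared between the two
    samples, so their true AAR difference is purely clonal.  Each
    segment additionally carries germline heterozygous sites at its
    planned m/k ratio, which drive the ploidy stage; where the planned
    configuration differs between samples, those sites' truth category
    follows their true AARs.

    Identical seeds produce byte-identical outputs.
    """
    seed = _require_seed(seed)
    cm = clone_model if clone_model is not None else CloneModel()
    plan = list(ploidy_plan) if ploidy_plan is not None else default_ploidy_plan()
    ap = annotation_plan if annotation_plan is not None else AnnotationPlan()
    if not plan:
        raise ValueError("ploidy plan must contain at least one segment")
    rng = np.random.default_rng(seed)

    shared = [s for s in plan if s.shared]
    diploid_shared = [s for s in shared
                      if (s.k_sensitive, s.m_sensitive) == (2, 1)]
    n_somatic = (cm.n_ancestral_variants + cm.n_selected_variants
                 + cm.n_depleted_variants + cm.n_neutral_variants)
    if n_somatic and not shared:
        raise ValueError("ploidy plan needs at least one segment with a "
                         "configuration shared by both samples to host "
                         "somatic variants")
    subclone_home = diploid_shared or shared

    rows = []  # (segment_index, category, source, true_aar_s, true_aar_r)

    def _place(n: int, segments: Sequence[SegmentPlan], category: str,
               source: str, aar_fn) -> None:
        if n == 0:
            return
        seg_idx = rng.integers(0, len(segments), size=n)
        for i in range(n):
            seg = segments[int(seg_idx[i])]
            aar_s, aar_r = aar_fn(seg)
            cat = category if category is not None else \
                _category_from_aars(aar_s, aar_r)
            rows.append((plan.index(seg), cat, source, aar_s, aar_r))

    f_s = cm.resistant_subclone_fraction_sensitive
    f_r = cm.resistant_subclone_fraction_resistant
    _place(cm.n_ancestral_variants, shared, "ancestral", "ancestral",
           lambda seg: (cm.ancestral_fraction * seg.ratio_sensitive,
                        cm.ancestral_fraction * seg.ratio_resistant))
    _place(cm.n_selected_variants, subclone_home, "selected_up", "subclone",
           lambda seg: (f_s * seg.ratio_sensitive, f_r * seg.ratio_resistant))
    _place(cm.n_depleted_variants, subclone_home, "selected_down", "subclone",
           lambda seg: ((1.0 - f_s) * seg.ratio_sensitive,
                        (1.0 - f_r) * seg.ratio_resistant))
    _place(cm.n_neutral_variants, shared, "neutral", "error",
           lambda seg: (0.0, 0.0))
    for seg in plan:
        _place(seg.n_het_sites, [seg], None, "germline_het",
               lambda s: (s.ratio_sensitive, s.ratio_resistant))

    n_sites = len(rows)
    seg_index = np.array([r[0] for r in rows])
    category = np.array([r[1] for r in rows])
    source = np.array([r[2] for r in rows])
    true_aar_s = np.array([r[3] for r in rows])
    true_aar_r = np.array([r[4] for r in rows])

    # positions: per segment, distinct; variant order is the planting order
    pos = np.zeros(n_sites, dtype=int)
    for si, seg in enumerate(plan):
        idx = np.where(seg_index == si)[0]
        if len(idx):
            pos[idx] = _unique_positions(rng, seg.start, seg.end, len(idx))
    ref, alt = _alleles(rng, n_sites)

    nb_p = cm.depth_dispersion / (cm.depth_dispersion + cm.mean_depth)
    depth_s = rng.negative_binomial(cm.depth_dispersion, nb_p, size=n_sites)
    depth_r = rng.negative_binomial(cm.depth_dispersion, nb_p, size=n_sites)
    p_s = np.where(true_aar_s > 0, true_aar_s, cm.error_rate)
    p_r = np.where(true_aar_r > 0, true_aar_r, cm.error_rate)
    alt_s = rng.binomial(depth_s, p_s)
    alt_r = rng.binomial(depth_r, p_r)

    chroms = np.array([plan[i].chrom for i in seg_index])
    segment_id = np.array([f"{plan[i].chrom}:{plan[i].start}-{plan[i].end}"
                           for i in seg_index])

    def _counts(depth, alt_count):
        return pd.DataFrame({
            "chrom": chroms, "pos": pos, "ref": ref, "alt": alt,
            "ref_count": depth - alt_count, "alt_count": alt_count,
        }, columns=COUNT_COLUMNS).sort_values(
            ["chrom", "pos", "ref", "alt"], kind="mergesort").reset_index(drop=True)

    annotations = _plant_annotations(rng, ap, chroms, pos, ref, alt,
                                     category, source)

    truth_variants = pd.DataFrame({
        "chrom": chroms, "pos": pos, "ref": ref, "alt": alt,
        "category": category, "source": source,
        "true_aar_sensitive": true_aar_s, "true_aar_resistant": true_aar_r,
        "segment_id": segment_id,
    }).sort_values(["chrom", "pos", "ref", "alt"],
                   kind="mergesort").reset_index(drop=True)

    truth_segments = pd.DataFrame([{
        "chrom": s.chrom, "start": s.start, "end": s.end,
        "k_sensitive": s.k_sensitive, "m_sensitive": s.m_sensitive,
        "k_resistant": s.k_resistant, "m_resistant": s.m_resistant,
        "label_sensitive": expected_segment_label(s.k_sensitive, s.m_sensitive),
        "label_resistant": expected_segment_label(s.k_resistant, s.m_resistant),
    } for s in plan])

    region_grid = truth_segments[["chrom", "start", "end"]].copy()

    return SimulatedPair(
        counts_sensitive=_counts(depth_s, alt_s),
        counts_resistant=_counts(depth_r, alt_r),
        annotations=annotations,
        truth=TruthTable(variants=truth_variants, segments=truth_segments),
        region_grid=region_grid,
    )


def _plant_annotations(rng, ap: AnnotationPlan, chroms, pos, ref, alt,
                       category, source) -> pd.DataFrame:
    """Annotation table exercising every branch of the inclusion filter.

    Subclone-planted variants are catalogued somatic mutations (COSMIC,
    exonic non-synonymous) so the published filter admits them;
    ancestral variants are a mixture of COSMIC hits, dbSNP/1000g
    germline polymorphisms and novel variants with mixed predictor
    calls; noise sites are mostly non-coding, with a configurable
    fraction inside segmental duplications.
    """
    n = len(pos)
    gene = np.array([f"GENE{i:06d}" for i in range(n)], dtype=object)
    location = np.full(n, "exonic", dtype=object)
    exonic = np.full(n, "nonsynonymous", dtype=object)
    in_cosmic = np.zeros(n, dtype=bool)
    dbsnp = np.full(n, "", dtype=object)
    ceu = np.full(n, np.nan)
    sift = np.full(n, "", dtype=object)
    polyphen = np.full(n, "", dtype=object)
    segdup = np.zeros(n, dtype=bool)

    pool_i = 0
    for i in range(n):
        u = rng.random(4)
        if source[i] == "subclone":
            in_cosmic[i] = True
            gene[i] = CANCER_GENE_POOL[pool_i % len(CANCER_GENE_POOL)] \
                if pool_i < len(CANCER_GENE_POOL) else f"CG{pool_i:04d}"
            pool_i += 1
            sift[i] = "deleterious" if u[0] < ap.deleterious_fraction else "tolerated"
            polyphen[i] = "deleterious" if u[1] < ap.deleterious_fraction else "benign"
        elif source[i] == "ancestral":
            if u[0] < ap.ancestral_cosmic_fraction:
                in_cosmic[i] = True
                if u[1] < 0.3:
                    ceu[i] = rng.uniform(0.0, 0.049)
            elif u[0] < ap.ancestral_cosmic_fraction + ap.ancestral_dbsnp_fraction:
                dbsnp[i] = f"rs{int(rng.integers(10_000, 99_999_999))}"
                ceu[i] = rng.uniform(0.05, 0.5)
            else:
                sift[i] = "deleterious" if u[1] < ap.deleterious_fraction else "tolerated"
                polyphen[i] = "deleterious" if u[2] < ap.deleterious_fraction \
                    else ("possibly_damaging" if u[3] < 0.5 else "benign")
        elif source[i] == "germline_het":
            dbsnp[i] = f"rs{int(rng.integers(10_000, 99_999_999))}"
            ceu[i] = rng.uniform(0.1, 0.5)
            if u[0] < 0.5:
                location[i] = "intronic"
                exonic[i] = "unknown"
            else:
                exonic[i] = "synonymous"
        else:  # sequencing-noise site
            if u[0] < ap.neutral_exonic_fraction:
                exonic[i] = "synonymous" if u[1] < 0.5 else "nonsynonymous"
            else:
                location[i] = "intronic" if u[1] < 0.5 else "intergenic"
                exonic[i] = "unknown"
            segdup[i] = bool(u[2] < ap.neutral_segdup_fraction)

    ann = pd.DataFrame({
        "chrom": chroms, "pos": pos, "ref": ref, "alt": alt, "gene": gene,
        "location_class": location, "exonic_class": exonic,
        "in_cosmic": in_cosmic,
        "dbsnp_id": pd.Series(dbsnp).replace("", None),
        "ceu_af": ceu,
        "sift": pd.Series(sift).replace("", None),
        "polyphen_hdiv": pd.Series(polyphen).replace("", None),
        "in_segdup": segdup,
    }, columns=ANNOTATION_COLUMNS)
    return ann.sort_values(["chrom", "pos", "ref", "alt"],
                           kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression

def default_de_plan(n_genes: int) -> pd.DataFrame:
    """60 planted DE genes: up-regulation at folds 3/5/8, down-regulation
    at 1/3, 1/5, 1/8 and a single strong 17-fold down-regulated gene
    (the BH3-only-factor collapse pattern)."""
    if n_genes < 120:
        raise ValueError("need at least 120 genes for the default plan")
    idx = np.linspace(0, n_genes - 1, 60, dtype=int)
    folds = ([3.0, 5.0, 8.0] * 10) + ([1 / 3, 1 / 5, 1 / 8] * 9) + [1 / 17] + [1 / 5, 1 / 8]
    return pd.DataFrame({"gene_index": idx, "fold_change": folds[:60]})


def simulate_expression(n_genes: int = 5000,
                        de_plan: Optional[pd.DataFrame] = None,
                        library_sizes: tuple[float, float] = (1.0, 1.0),
                        seed: int = 0,
                        dispersion: float = 1000.0,
                        base_mean: float = 100.0,
                        min_de_mean: float = 300.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-sample gene count table with planted fold changes.

    ``de_plan`` maps gene indices to multiplicative fold changes applied
    to the resistant mean (values < 1 are down-regulation); fold changes
    must be positive.  Non-DE genes share means across samples up to the
    library-size factors.  Planted genes get a floor on their baseline
    mean (``min_de_mean``) so the planted effect is observable at the
    simulated library depth.

    The default negative-binomial size of 1000 (dispersion 0.001) makes
    counts nearly Poisson: the generator's null emulates *sequencing
    sampling noise only*, which is exactly the null model of the
    replicate-free exact conditional binomial DE test downstream.
    Residual biological variability between cultures is deliberately
    not modeled — with one library per condition no test can estimate
    it, and planting it would only demonstrate the well-known
    anticonservativeness of replicate-free DE (see the methods note).
    Pass a smaller ``dispersion`` (e.g. 50, i.e. ~15% extra CV) to
    emulate overdispersed culture pairs.

    Returns ``(counts, truth)``.
    """
    seed = _require_seed(seed)
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    lib_s, lib_r = library_sizes
    if lib_s <= 0 or lib_r <= 0:
        raise ValueError("library size factors must be positive")
    rng = np.random.default_rng(seed)
    if de_plan is None:
        de_plan = default_de_plan(n_genes) if n_genes >= 120 else \
            pd.DataFrame({"gene_index": [], "fold_change": []})
    fold = np.ones(n_genes)
    for _, row in de_plan.iterrows():
        gi = int(row["gene_index"])
        fc = float(row["fold_change"])
        if fc <= 0:
            raise ValueError(f"planted fold change must be positive, got {fc}")
        if not 0 <= gi < n_genes:
            raise ValueError(f"gene index {gi} out of range")
        fold[gi] = fc

    base = rng.lognormal(mean=np.log(base_mean), sigma=1.0, size=n_genes)
    planted = fold != 1.0
    base[planted] = np.maximum(base[planted], min_de_mean)
    mu_s = base * lib_s
    mu_r = base * fold * lib_r
    counts_s = rng.negative_binomial(dispersion, dispersion / (dispersion + mu_s))
    counts_r = rng.negative_binomial(dispersion, dispersion / (dispersion + mu_r))

    genes = [f"G{i:06d}" for i in range(n_genes)]
    counts = pd.DataFrame({"gene": genes, "count_sensitive": counts_s,
                           "count_resistant": counts_r})
    effect = np.maximum(fold, 1.0 / fold)
    truth = pd.DataFrame({
        "gene": genes,
        "fold_change": fold,
        "direction": np.where(fold >= 1.0, "up", "down"),
        "is_de_true": planted & (effect >= 2.5),
    })
    return counts, truth


# ---------------------------------------------------------------------------
# raw reads

def simulate_read_pairs(fragment_lengths: Sequence[int],
                        read_length: int = 101,
                        seed: int = 0,
                        quality_range: tuple[int, int] = (30, 40)
                        ) -> tuple[list[ReadPair], pd.DataFrame]:
    """Simulate error-free FR read pairs from given fragment lengths.

    R1 is the first ``read_length`` bases of the fragment, R2 the
    reverse complement of the last ``read_length`` bases; fragments
    shorter than ``2 * read_length`` therefore produce overlapping
    mates.  Fragments shorter than one read are skipped with a logged
    warning.  The truth table records each kept pair's fragment and the
    geometric overlap ``max(0, 2*read_length - fragment_length)``.
    """
    seed = _require_seed(seed)
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    qlo, qhi = quality_range
    if not (0 <= qlo <= qhi <= 41):
        raise ValueError("quality_range must satisfy 0 <= lo <= hi <= 41")
    rng = np.random.default_rng(seed)
    pairs: list[ReadPair] = []
    truth_rows = []
    for i, frag_len in enumerate(fragment_lengths):
        frag_len = int(frag_len)
        if frag_len < read_length:
            logger.warning("skipping fragment %d: length %d < read length %d",
                           i, frag_len, read_length)
            continue
        frag = "".join(_BASES[rng.integers(0, 4, size=frag_len)])
        q1 = "".join(chr(33 + int(q))
                     for q in rng.integers(qlo, qhi + 1, size=read_length))
        q2 = "".join(chr(33 + int(q))
                     for q in rng.integers(qlo, qhi + 1, size=read_length))
        pair = ReadPair(
            id=f"frag{i:06d}",
            seq1=frag[:read_length], qual1=q1,
            seq2="".join(reversed(frag[-read_length:]))
                 .translate(str.maketrans("ACGTN", "TGCAN")), qual2=q2,
        )
        pairs.append(pair)
        truth_rows.append({"id": pair.id, "fragment": frag,
                           "fragment_length": frag_len,
                           "overlap_len": max(0, 2 * read_length - frag_len)})
    truth = pd.DataFrame(truth_rows,
                         columns=["id", "fragment", "fragment_length", "overlap_len"])
    return pairs, truth


# ---------------------------------------------------------------------------
# configuration and file output

def default_config() -> dict:
    """Nested key/value configuration covering every plan parameter."""
    return {
        "seed": 0,
        "clone_model": {},
        "ploidy_plan": [
            {"chrom": s.chrom, "start": s.start, "end": s.end,
             "k_sensitive": s.k_sensitive, "m_sensitive": s.m_sensitive,
             "k_resistant": s.k_resistant, "m_resistant": s.m_resistant,
             "n_het_sites": s.n_het_sites}
            for s in default_ploidy_plan()],
        "annotation_plan": {},
        "expression": {"n_genes": 2000, "library_sizes": [1.0, 1.0]},
        "reads": {"n_pairs": 200, "read_length": 101,
                  "fragment_mean": 175, "fragment_sd": 70},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def simulate_from_config(cfg: dict, seed: Optional[int] = None) -> SimulatedPair:
    seed = _require_seed(cfg.get("seed", 0) if seed is None else seed)
    cm = CloneModel(**cfg.get("clone_model", {}))
    plan_cfg = cfg.get("ploidy_plan")
    plan = [SegmentPlan(**s) for s in plan_cfg] if plan_cfg else None
    ap = AnnotationPlan(**cfg.get("annotation_plan", {}))
    return simulate_pair(cm, plan, ap, seed=seed)


def fragment_lengths_from_config(cfg: dict, seed: Optional[int] = None) -> np.ndarray:
    reads = cfg.get("reads", {})
    seed = _require_seed(cfg.get("seed", 0) if seed is None else seed)
    rng = np.random.default_rng(seed + 1)
    n = int(reads.get("n_pairs", 200))
    mean = float(reads.get("fragment_mean", 175))
    sd = float(reads.get("fragment_sd", 70))
    read_length = int(reads.get("read_length", 101))
    frags = np.rint(rng.normal(mean, sd, size=n)).astype(int)
    return np.clip(frags, read_length, None)


def write_pair(sim: SimulatedPair, outdir) -> dict:
    """Write all generator outputs as plain-text files; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts_sensitive": outdir / "counts_sensitive.tsv",
        "counts_resistant": outdir / "counts_resistant.tsv",
        "annotations": outdir / "annotations.tsv",
        "truth_variants": outdir / "truth_variants.tsv",
        "truth_segments": outdir / "truth_segments.tsv",
        "region_grid": outdir / "region_grid.bed",
    }
    sim.counts_sensitive.to_csv(paths["counts_sensitive"], sep="\t", index=False)
    sim.counts_resistant.to_csv(paths["counts_resistant"], sep="\t", index=False)
    sim.annotations.to_csv(paths["annotations"], sep="\t", index=False, na_rep="")
    sim.truth.variants.to_csv(paths["truth_variants"], sep="\t", index=False)
    sim.truth.segments.to_csv(paths["truth_segments"], sep="\t", index=False)
    write_region_grid(sim.region_grid, paths["region_grid"])
    return {k: str(v) for k, v in paths.items()}
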