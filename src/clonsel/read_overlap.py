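"""Merge overlapping paired-end mates and re-split without overlap.

Short RNA fragments sequenced in 2x101 bp paired-end mode yield R1/R2
mates that overlap in the middle of the fragment.  Counting both mates
would double-count every base in the overlap, biasing allele counts and
coverage.  This module detects the overlap (longest suffix of R1
matching a prefix of the reverse-complemented R2 within a mismatch
budget), reconstructs the fragment taking each overlap base from the
mate with the higher phred quality, and splits the fragment into two
reads that cover it exactly once.  Pairs without detectable overlap
pass through unchanged.

Orientation is assumed FR (R2 stored reverse-complemented), the
standard Illumina layout.  Adapter and quality trimming are upstream
concerns and are not re-implemented here.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_RATE = 0.1


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read with per-base phred+33 quality strings."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if not self.seq1 or not self.seq2:
            raise ValueError(f"{self.id}: empty mate sequence")
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")
        for seq in (self.seq1, self.seq2):
            if not set(seq) <= ALPHABET:
                bad = sorted(set(seq) - ALPHABET)
                raise ValueError(f"{self.id}: invalid bases {bad}")


@dataclass(frozen=True)
class MergedFragment:
    """A merged fragment and its two non-overlapping derived reads."""

    id: str
    seq: str
    qual: str
    overlap_len: int
    read1: tuple[str, str]  # (seq, qual) covering seq[:split]
    read2: tuple[str, str]  # (seq, qual) covering seq[split:]

    def __post_init__(self) -> None:
        if self.read1[0] + self.read2[0] != self.seq:
            raise ValueError(f"{self.id}: split reads do not tile the fragment")


def detect_overlap(pair: ReadPair,
                   min_overlap: int = DEFAULT_MIN_OVERLAP,
                   max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE) -> Optional[int]:
    """Length of the longest acceptable R1/R2 overlap, or ``None``.

    Scans overlap lengths from the longest possible downwards and
    returns the first (hence longest) length >= min_overlap whose
    mismatch fraction against reverse-complement(R2) is
    <= max_mismatch_rate.  ``N`` matches nothing and always counts as a
    mismatch.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not 0.0 <= max_mismatch_rate < 0.5:
        raise ValueError("max_mismatch_rate must lie in [0, 0.5)")
    rc2 = reverse_complement(pair.seq2)
    longest = min(len(pair.seq1), len(pair.seq2))
    for ov in range(longest, min_overlap - 1, -1):
        s1 = pair.seq1[-ov:]
        s2 = rc2[:ov]
        mismatches = sum(1 for a, b in zip(s1, s2)
                         if a != b or a == "N" or b == "N")
        if mismatches <= max_mismatch_rate * ov:
            return ov
    return None


def merge_and_split(pair: ReadPair, overlap_len: int) -> MergedFragment:
    """Merge a pair with a known overlap and split the fragment.

    In the overlap each base (and quality) is taken from the mate with
    the higher phred score, ties going to R1.  The fragment is split at
    floor(len/2), so the two output reads tile it exactly once.
    """
    if overlap_len < 1:
        raise ValueError("overlap_len must be >= 1; pairs without overlap pass through")
    if overlap_len > min(len(pair.seq1), len(pair.seq2)):
        raise ValueError(
            f"{pair.id}: overlap {overlap_len} exceeds mate length "
            f"{min(len(pair.seq1), len(pair.seq2))}")
    rc2 = reverse_complement(pair.seq2)
    rq2 = pair.qual2[::-1]
    left_len = len(pair.seq1) - overlap_len

    seq = [pair.seq1[:left_len]]
    qual = [pair.qual1[:left_len]]
    for i in range(overlap_len):
        b1, q1 = pair.seq1[left_len + i], pair.qual1[left_len + i]
        b2, q2 = rc2[i], rq2[i]
        if q2 > q1:  # phred+33 strings order like phred scores
            seq.append(b2)
            qual.append(q2)
        else:
            seq.append(b1)
            qual.append(q1)
    seq.append(rc2[overlap_len:])
    qual.append(rq2[overlap_len:])
    merged_seq = "".join(seq)
    merged_qual = "".join(qual)

    split = len(merged_seq) // 2
    return MergedFragment(
        id=pair.id,
        seq=merged_seq,
        qual=merged_qual,
        overlap_len=overlap_len,
        read1=(merged_seq[:split], merged_qual[:split]),
        read2=(merged_seq[split:], merged_qual[split:]),
    )


def process_pair(pair: ReadPair,
                 min_overlap: int = DEFAULT_MIN_OVERLAP,
                 max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE):
    """Detect, merge and split one pair.

    Returns ``(records, overlap_len)`` where ``records`` is a list of
    ``(id, seq, qual)`` output reads: the two split reads for an
    overlapping pair, or the original mates (byte-identical, R2 still
    in its stored orientation) otherwise.
    """
    ov = detect_overlap(pair, min_overlap, max_mismatch_rate)
    if ov is None:
        return ([(pair.id + "/1", pair.seq1, pair.qual1),
                 (pair.id + "/2", pair.seq2, pair.qual2)], 0)
    frag = merge_and_split(pair, ov)
    return ([(pair.id + "/1", *frag.read1),
             (pair.id + "/2", *frag.read2)], ov)


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Iterate synchronized R1/R2 FASTQ files (gzip-transparent)."""
    with _open_text(r1_path) as fh1, _open_text(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2, strict=True):
            rid = t1.split()[0]
            rid2 = t2.split()[0]
            base = rid[:-2] if rid.endswith(("/1", "/2")) else rid
            base2 = rid2[:-2] if rid2.endswith(("/1", "/2")) else rid2
            if base != base2:
                raise ValueError(f"unsynchronized mates: {rid!r} vs {rid2!r}")
            yield ReadPair(id=base, seq1=s1.upper(), qual1=q1,
                           seq2=s2.upper(), qual2=q2)


def write_fastq(records, path) -> None:
    """Write ``(id, seq, qual)`` records as 4-line FASTQ (gzip-transparent)."""
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def merge_fastq(r1_path, r2_path, out_path,
                min_overlap: int = DEFAULT_MIN_OVERLAP,
                max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE) -> dict:
    """File-level merge-and-split; returns pair/merge counts."""
    n_pairs = 0
    n_merged = 0

    def _records():
        nonlocal n_pairs, n_merged
        for pair in read_fastq_pairs(r1_path, r2_path):
            recs, ov = process_pair(pair, min_overlap, max_mismatch_rate)
            n_pairs += 1
            if ov:
                n_merged += 1
            yield from recs

    write_fastq(_records(), out_path)
    stats = {"pairs_in": n_pairs, "pairs_merged": n_merged,
             "reads_out": 2 * n_pairs}
    logger.info("merge-reads: %(pairs_in)d pairs in, %(pairs_merged)d merged, "
                "%(reads_out)d reads out", stats)
    return stats
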