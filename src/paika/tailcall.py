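"""Poly(A) tail calling from aligned long reads.

Long-read (CCS) alignments leave the untemplated poly(A) tail of each
transcript as a soft-clipped segment at the transcript's 3' end.  This module
turns aligned records into per-read tail calls and per-gene tail statistics:

1. extract the 3' soft clip as the candidate tail (strand-aware);
2. extend the tail with any run of A's at the 3' end of the aligned query,
   which aligners tend to absorb into the alignment by mistake;
3. classify: reads without a 3' clip are discarded, candidate tails with
   fewer than 4 A's among their first 8 bases are rejected as low quality,
   and reads below a consensus-pass threshold (default 7) are filtered;
4. per gene, keep genes with at least ``min_transcripts`` accepted tails
   (default 10) and report the geometric mean tail length, the natural
   location statistic for the roughly lognormal within-gene length
   distribution.

Condition-level comparison (medians of per-gene geometric means, binned
transcript-level length fractions, quantile-trimmed supports) lives in
:func:`compare_conditions`.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import gmean

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedRead",
    "TailStatus",
    "TailCall",
    "GeneTailSummary",
    "TailComparison",
    "GeneInterval",
    "GeneAnnotation",
    "HardClippedTailError",
    "extract_soft_clip_tail",
    "aligned_query_suffix",
    "extend_a_tract",
    "classify_tail",
    "call_tail",
    "assign_to_gene",
    "summarize_gene_tails",
    "compare_conditions",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class HardClippedTailError(ValueError):
    """The 3' end of the read is hard-clipped: the tail sequence is unavailable."""


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples; reject malformed input."""
    if not cigar or cigar == "*":
        raise ValueError(f"unparseable CIGAR: {cigar!r}")
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return [(int(n), op) for n, op in ops]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignedRead:
    """One mapped long-read record, stored in alignment orientation."""

    read_id: str
    seq: str
    cigar: str
    is_reverse: bool
    ref_name: str
    ref_start: int
    passes: Optional[int] = None
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        ops = parse_cigar(self.cigar)
        qlen = sum(n for n, op in ops if op in _QUERY_OPS)
        if qlen != len(self.seq):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.seq)} does not match "
                f"CIGAR query length {qlen}"
            )
        if self.passes is not None and self.passes < 0:
            raise ValueError(f"{self.read_id}: negative pass count")

    @property
    def cigar_ops(self) -> list[tuple[int, str]]:
        return parse_cigar(self.cigar)

    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the aligned span on the reference."""
        return self.ref_start + sum(n for n, op in self.cigar_ops if op in _REF_OPS)


class TailStatus(str, Enum):
    ACCEPTED = "ACCEPTED"
    REJECTED_NO_CLIP = "REJECTED_NO_CLIP"
    REJECTED_LOW_A = "REJECTED_LOW_A"
    FILTERED_LOW_PASS = "FILTERED_LOW_PASS"


@dataclass
class TailCall:
    """Classified poly(A) tail of one read; tail_seq is transcript 5'->3'."""

    read_id: str
    tail_seq: str
    status: TailStatus
    gene_id: Optional[str] = None
    passes: Optional[int] = None

    @property
    def tail_len(self) -> int:
        return len(self.tail_seq)


@dataclass
class GeneTailSummary:
    gene_id: str
    tail_lengths: list[int]

    @property
    def n_transcripts(self) -> int:
        return len(self.tail_lengths)

    @property
    def geom_mean_len(self) -> float:
        return float(gmean(self.tail_lengths))


@dataclass
class TailComparison:
    """Condition-level tail-length comparison (A vs B)."""

    per_gene: pd.DataFrame  # columns: gene_id, geom_mean_a, geom_mean_b
    median_a: float
    median_b: float
    bin_edges: np.ndarray
    bin_fractions: pd.DataFrame  # index: bin label, columns: a, b
    support_a: tuple[float, float]
    support_b: tuple[float, float]
    trim_quantile: float


# ---------------------------------------------------------------------------
# per-read operations


def _transcript_view(read: AlignedRead) -> tuple[str, list[tuple[int, str]]]:
    """Return (sequence, cigar ops) reoriented so transcript 3' is at the right."""
    ops = read.cigar_ops
    if read.is_reverse:
        return reverse_complement(read.seq), ops[::-1]
    return read.seq, ops


def extract_soft_clip_tail(read: AlignedRead) -> str:
    """Extract the soft-clipped candidate tail at the transcript's 3' end.

    For forward-strand alignments this is the trailing S segment of the stored
    sequence; for reverse-strand alignments the reverse complement of the
    leading S segment.  Returns "" when no 3' soft clip exists.

    Raises
    ------
    HardClippedTailError
        If the outermost 3' operation is a hard clip, so the tail bases were
        not stored with the record.
    """
    tseq, tops = _transcript_view(read)
    if tops[-1][1] == "H":
        raise HardClippedTailError(
            f"{read.read_id}: 3' end hard-clipped, tail sequence unavailable"
        )
    if tops[-1][1] != "S":
        return ""
    return tseq[-tops[-1][0]:]


def aligned_query_suffix(read: AlignedRead, max_len: int = 50) -> str:
    """The aligned (non-clipped) query immediately upstream of the 3' tail.

    Reported in transcript orientation; at most ``max_len`` bases, which is
    ample for A-tract extension.
    """
    tseq, tops = _transcript_view(read)
    trail = 0
    for n, op in reversed(tops):
        if op in ("S", "H"):
            trail += n if op == "S" else 0
        else:
            break
    lead = 0
    for n, op in tops:
        if op in ("S", "H"):
            lead += n if op == "S" else 0
        else:
            break
    aligned = tseq[lead: len(tseq) - trail] if trail else tseq[lead:]
    return aligned[-max_len:]


def extend_a_tract(aligned_3prime_suffix: str, candidate_tail: str) -> str:
    """Move the terminal A-run of the aligned suffix onto the front of the tail.

    Aligners frequently absorb the first bases of the poly(A) tail into the
    alignment when the reference happens to continue in A; the maximal run of
    consecutive A's at the 3' end of the aligned query is therefore treated as
    part of the tail.  N never counts as A.  Idempotent.
    """
    run = 0
    for base in reversed(aligned_3prime_suffix):
        if base in ("A", "a"):
            run += 1
        else:
            break
    if run == 0:
        return candidate_tail
    return aligned_3prime_suffix[len(aligned_3prime_suffix) - run:].upper() + candidate_tail


def classify_tail(
    candidate_tail: str,
    passes: Optional[int] = None,
    min_passes: int = 7,
    *,
    enforce_pass_filter: bool = True,
    read_id: str = "",
    gene_id: Optional[str] = None,
) -> TailCall:
    """Classify an A-tract-extended candidate tail.

    Rules, in order: an empty candidate means the read had no 3' soft clip and
    is discarded (REJECTED_NO_CLIP); fewer than 4 A's among the first
    min(8, len) bases rejects the tail as low quality (REJECTED_LOW_A) — a
    tail of length < 4 therefore always fails; a known pass count below
    ``min_passes`` filters the read (FILTERED_LOW_PASS); anything else is
    ACCEPTED.
    """
    tail = candidate_tail.upper()
    if set(tail) - set("ACGTN"):
        raise ValueError(f"non-ACGTN characters in tail: {candidate_tail!r}")
    if not tail:
        return TailCall(read_id, "", TailStatus.REJECTED_NO_CLIP, gene_id, passes)
    head = tail[: min(8, len(tail))]
    if head.count("A") < 4:
        return TailCall(read_id, tail, TailStatus.REJECTED_LOW_A, gene_id, passes)
    if enforce_pass_filter and passes is not None and passes < min_passes:
        return TailCall(read_id, tail, TailStatus.FILTERED_LOW_PASS, gene_id, passes)
    return TailCall(read_id, tail, TailStatus.ACCEPTED, gene_id, passes)


def call_tail(
    read: AlignedRead,
    min_passes: int = 7,
    *,
    enforce_pass_filter: bool = True,
) -> TailCall:
    """Full per-read pipeline: extract, A-tract-extend, classify."""
    candidate = extract_soft_clip_tail(read)
    if not candidate:
        return TailCall(
            read.read_id, "", TailStatus.REJECTED_NO_CLIP, read.gene_id, read.passes
        )
    candidate = extend_a_tract(aligned_query_suffix(read), candidate)
    return classify_tail(
        candidate,
        read.passes,
        min_passes,
        enforce_pass_filter=enforce_pass_filter,
        read_id=read.read_id,
        gene_id=read.gene_id,
    )


# ---------------------------------------------------------------------------
# gene assignment


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    ref_name: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: degenerate interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


class GeneAnnotation:
    """Strand-aware gene interval index over named references."""

    def __init__(self, intervals: Iterable[GeneInterval] = ()):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self.intervals: list[GeneInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GeneInterval) -> None:
        self.intervals.append(iv)
        self._trees.setdefault((iv.ref_name, iv.strand), IntervalTree()).addi(
            iv.start, iv.end, iv
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, ref_name: str, start: int, end: int, strand: str) -> list[GeneInterval]:
        tree = self._trees.get((ref_name, strand))
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(start, end)]


def assign_to_gene(read: AlignedRead, annotation: GeneAnnotation) -> Optional[str]:
    """Assign a read to the gene its aligned span overlaps on the same strand.

    Ties are broken by largest overlap, then lexicographically smallest
    gene_id.  Returns None when nothing overlaps (including unknown
    references, which are logged but not an error).
    """
    strand = "-" if read.is_reverse else "+"
    hits = annotation.overlapping(read.ref_name, read.ref_start, read.ref_end, strand)
    if not hits:
        logger.debug("read %s: no gene overlap on %s:%s", read.read_id, read.ref_name, strand)
        return None

    def overlap(iv: GeneInterval) -> int:
        return min(iv.end, read.ref_end) - max(iv.start, read.ref_start)

    best = min(hits, key=lambda iv: (-overlap(iv), iv.gene_id))
    return best.gene_id


# ---------------------------------------------------------------------------
# per-gene statistics and condition comparison


def summarize_gene_tails(
    calls: Iterable[TailCall], min_transcripts: int = 10
) -> list[GeneTailSummary]:
    """Per-gene tail statistics over ACCEPTED calls.

    Genes with fewer than ``min_transcripts`` accepted tails are dropped; the
    reported location statistic is the geometric mean length.
    """
    by_gene: dict[str, list[int]] = {}
    for call in calls:
        if call.status is not TailStatus.ACCEPTED or call.gene_id is None:
            continue
        by_gene.setdefault(call.gene_id, []).append(call.tail_len)
    return [
        GeneTailSummary(gene_id, lengths)
        for gene_id, lengths in sorted(by_gene.items())
        if len(lengths) >= min_transcripts
    ]


def _accepted_lengths(calls: Iterable[TailCall]) -> np.ndarray:
    return np.array(
        [c.tail_len for c in calls if c.status is TailStatus.ACCEPTED], dtype=float
    )


def compare_conditions(
    summaries_a: Sequence[GeneTailSummary],
    summaries_b: Sequence[GeneTailSummary],
    all_calls_a: Iterable[TailCall],
    all_calls_b: Iterable[TailCall],
    bins: Sequence[float] = (5, 90, 200),
    trim_quantile: float = 0.02,
) -> TailComparison:
    """Compare tail lengths between two conditions processed identically.

    The pairwise table is restricted to genes summarized in both conditions;
    the condition medians are medians of per-gene geometric means over that
    shared set.  Transcript-level length histograms over ``bins`` report the
    fraction of binned transcripts per bin (fractions sum to 1 over covered
    bins), and the distribution support is trimmed symmetrically at
    ``trim_quantile`` per tail, mirroring a 2% central-cutoff presentation.
    """
    a_means = {s.gene_id: s.geom_mean_len for s in summaries_a}
    b_means = {s.gene_id: s.geom_mean_len for s in summaries_b}
    shared = sorted(set(a_means) & set(b_means))
    if not shared:
        warnings.warn("no genes summarized in both conditions", stacklevel=2)
    per_gene = pd.DataFrame(
        {
            "gene_id": shared,
            "geom_mean_a": [a_means[g] for g in shared],
            "geom_mean_b": [b_means[g] for g in shared],
        }
    )
    median_a = float(per_gene["geom_mean_a"].median()) if shared else float("nan")
    median_b = float(per_gene["geom_mean_b"].median()) if shared else float("nan")

    edges = np.asarray(bins, dtype=float)
    labels = [f"{edges[i]:g}-{edges[i+1]:g}" for i in range(len(edges) - 1)]
    fractions = {}
    supports = {}
    for key, calls in (("a", all_calls_a), ("b", all_calls_b)):
        lengths = _accepted_lengths(calls)
        if lengths.size:
            counts, _ = np.histogram(lengths, bins=edges)
            total = counts.sum()
            fractions[key] = counts / total if total else np.zeros(len(labels))
            supports[key] = (
                float(np.quantile(lengths, trim_quantile)),
                float(np.quantile(lengths, 1 - trim_quantile)),
            )
        else:
            fractions[key] = np.zeros(len(labels))
            supports[key] = (float("nan"), float("nan"))
    bin_fractions = pd.DataFrame(fractions, index=labels)

    return TailComparison(
        per_gene=per_gene,
        median_a=median_a,
        median_b=median_b,
        bin_edges=edges,
        bin_fractions=bin_fractions,
        support_a=supports["a"],
        support_b=supports["b"],
        trim_quantile=trim_quantile,
    )
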