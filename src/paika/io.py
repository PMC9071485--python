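"""Readers and writers for the pipeline's on-disk formats.

Alignments are read from the SAM text dialect through pysam; because the
header is optional in this pipeline's inputs, a line-level fallback parser
handles files whose headers lack @SQ records (which pysam cannot resolve).
Annotations come as BED6 (0-based half-open) or GFF3 (1-based closed,
converted on read).  Tables are plain TSV.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
import pysam

from .tailcall import (
    AlignedRead,
    GeneAnnotation,
    GeneInterval,
    GeneTailSummary,
    TailCall,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_alignments",
    "write_alignments",
    "read_annotation",
    "read_gene_list",
    "write_tail_table",
    "write_gene_summaries",
    "read_expression_tables",
]

_SKIP_FLAGS = 0x100 | 0x800 | 0x400 | 0x4  # secondary, supplementary, duplicate, unmapped


def _from_pysam(rec: pysam.AlignedSegment, pass_tag: str) -> Optional[AlignedRead]:
    if rec.flag & _SKIP_FLAGS:
        return None
    if rec.query_sequence is None or rec.cigarstring is None:
        raise ValueError(f"record {rec.query_name}: missing sequence or CIGAR")
    passes = rec.get_tag(pass_tag) if rec.has_tag(pass_tag) else None
    return AlignedRead(
        read_id=rec.query_name,
        seq=rec.query_sequence,
        cigar=rec.cigarstring,
        is_reverse=rec.is_reverse,
        ref_name=rec.reference_name,
        ref_start=rec.reference_start,
        passes=int(passes) if passes is not None else None,
    )


def _parse_sam_line(line: str, pass_tag: str) -> Optional[AlignedRead]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 11:
        raise ValueError("fewer than 11 SAM fields")
    qname, flag, rname, pos, _, cigar, _, _, _, seq = fields[:10]
    flag = int(flag)
    if flag & _SKIP_FLAGS:
        return None
    if seq == "*" or cigar == "*" or rname == "*":
        raise ValueError("missing sequence, CIGAR, or reference")
    passes = None
    for tag in fields[11:]:
        name, typ, value = tag.split(":", 2)
        if name == pass_tag and typ in ("i", "f"):
            passes = int(float(value))
    return AlignedRead(
        read_id=qname,
        seq=seq,
        cigar=cigar,
        is_reverse=bool(flag & 0x10),
        ref_name=rname,
        ref_start=int(pos) - 1,  # SAM POS is 1-based
        passes=passes,
    )


def _read_sam_fallback(path: str, pass_tag: str, strict: bool) -> Iterator[AlignedRead]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("@"):
                continue
            try:
                read = _parse_sam_line(line, pass_tag)
            except (ValueError, IndexError) as exc:
                if strict:
                    raise ValueError(f"{path}: malformed SAM record at line {lineno}: {exc}")
                logger.warning("%s: skipping malformed line %d (%s)", path, lineno, exc)
                continue
            if read is not None:
                yield read


def read_alignments(
    path: str, pass_tag: str = "np", strict: bool = False
) -> Iterator[AlignedRead]:
    """Yield primary, non-duplicate, mapped records from a SAM file.

    Secondary, supplementary, duplicate-flagged, and unmapped records are
    dropped (the pipeline's de-duplication step).  The optional integer pass
    tag (default "np") carries the CCS pass count.  Malformed records are
    skipped with a logged line number, or raised in ``strict`` mode.
    """
    try:
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            records = []
            for rec in sam:
                read = _from_pysam(rec, pass_tag)
                if read is not None:
                    records.append(read)
        yield from records
        return
    except (ValueError, OSError, NotImplementedError) as exc:
        logger.info("%s: pysam could not parse (%s); falling back to line parser", path, exc)
    yield from _read_sam_fallback(path, pass_tag, strict)


def write_alignments(
    path: str, reads: Iterable[AlignedRead], references: dict[str, int], pass_tag: str = "np"
) -> None:
    """Write reads as headered SAM (via pysam) against the given references."""
    names = list(references)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": name, "LN": length} for name, length in references.items()],
        }
    )
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for read in reads:
            rec = pysam.AlignedSegment(header)
            rec.query_name = read.read_id
            rec.query_sequence = read.seq
            rec.cigarstring = read.cigar
            rec.flag = 0x10 if read.is_reverse else 0
            rec.reference_id = names.index(read.ref_name)
            rec.reference_start = read.ref_start
            rec.mapping_quality = 60
            if read.passes is not None:
                rec.set_tag(pass_tag, read.passes, value_type="i")
            out.write(rec)


def read_annotation(path: str, fmt: Optional[str] = None) -> GeneAnnotation:
    """Read gene intervals from BED6 or GFF3 into 0-based half-open form.

    ``fmt`` is "bed" or "gff3"; inferred from the extension when omitted.
    GFF3 coordinates (1-based closed) are converted on read; only features of
    type ``gene`` are kept.  Empty input yields an empty annotation with a
    warning.
    """
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {"bed": "bed", "gff": "gff3", "gff3": "gff3", "gtf": "gff3"}.get(
            ext.lstrip("."), None
        )
        if fmt is None:
            raise ValueError(f"cannot infer annotation format from {path!r}")
    ann = GeneAnnotation()
    if fmt == "bed":
        try:
            table = pd.read_csv(
                path,
                sep="\t",
                comment="#",
                header=None,
                usecols=range(6),
                names=["chrom", "start", "end", "name", "score", "strand"],
            )
        except pd.errors.EmptyDataError:
            table = pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
        for row in table.itertuples(index=False):
            ann.add(GeneInterval(str(row.name), str(row.chrom), int(row.start), int(row.end), str(row.strand)))
    elif fmt == "gff3":
        import gffutils

        db = gffutils.create_db(
            path, ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
        )
        for feat in db.features_of_type("gene"):
            gene_id = feat.attributes.get("ID", [feat.id])[0]
            # GFF3 is 1-based closed; gffutils keeps those coordinates
            ann.add(GeneInterval(gene_id, feat.seqid, feat.start - 1, feat.end, feat.strand))
    else:
        raise ValueError(f"unknown annotation format: {fmt!r}")
    if len(ann) == 0:
        logger.warning("%s: annotation is empty", path)
    return ann


def read_gene_list(path: str) -> frozenset:
    """One gene id per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return frozenset(
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        )


def write_tail_table(path: str, calls: Iterable[TailCall]) -> None:
    pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "gene_id": c.gene_id if c.gene_id is not None else "",
                "tail_len": c.tail_len,
                "status": c.status.value,
                "passes": c.passes if c.passes is not None else "",
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


def write_gene_summaries(path: str, summaries: Iterable[GeneTailSummary]) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "n_transcripts": s.n_transcripts,
                "geom_mean_len": s.geom_mean_len,
            }
            for s in summaries
        ]
    ).to_csv(path, sep="\t", index=False)


def read_expression_tables(
    counts_path: str, samples_path: str, lengths_path: Optional[str] = None
):
    """Load a count/TPM matrix, its sample sheet, and optional gene lengths.

    The count matrix is genes x samples TSV with the gene id in the first
    column; the sample sheet needs columns sample, condition, timepoint_h,
    replicate; the lengths table needs columns gene, length.
    """
    from .dynamics import ExpressionMatrix

    values = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t").set_index("sample")
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t")
        lengths = lt.set_index("gene")["length"].astype(float)
    return ExpressionMatrix(values, samples, lengths)
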