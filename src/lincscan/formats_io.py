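"""Readers and writers for the standard formats the tool touches.

Internal conventions, applied uniformly at parse time:

* coordinates are 0-based half-open (BED native; GTF/GFF3 1-based closed and
  WIG 1-based are converted on input);
* genome sequences are uppercase over ``{A, C, G, T, N}`` — IUPAC ambiguity
  codes are masked to ``N``;
* unstranded records (``.``) are treated as ``+`` with a logged warning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO

from . import CoordinateError, ParseError, ValidationError

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase ``{A,C,G,T,N}`` string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: strand plus ordered exon intervals on a chromosome.

    ``exons`` are 0-based half-open ``(start, end)`` tuples, sorted ascending
    and non-overlapping.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: empty exon [{start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def length(self) -> int:
        """Spliced length: sum of exon lengths."""
        return sum(end - start for start, end in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic start of first exon and end of last exon."""
        return self.exons[0][0], self.exons[-1][1]


class GenomeSequence:
    """Mapping chromosome name -> uppercase ``{A,C,G,T,N}`` string."""

    def __init__(self, sequences: dict[str, str]):
        self._seqs = sequences

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        try:
            return len(self._seqs[chrom])
        except KeyError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence ``[start, end)``; errors if outside the chromosome."""
        if chrom not in self._seqs:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise CoordinateError(
                f"interval [{start},{end}) outside {chrom} (length {len(seq)})"
            )
        return seq[start:end]


class ConservationTrack:
    """Sparse per-base conservation scores in [0, 1]; absent positions are missing."""

    def __init__(self) -> None:
        self._scores: dict[str, dict[int, float]] = {}

    def set(self, chrom: str, pos: int, score: float) -> None:
        if not (0.0 <= score <= 1.0):
            raise ValidationError(
                f"conservation score {score} at {chrom}:{pos} outside [0, 1]"
            )
        chrom_scores = self._scores.setdefault(chrom, {})
        if pos in chrom_scores and chrom_scores[pos] != score:
            logger.warning(
                "conservation position %s:%d set twice; last record wins", chrom, pos
            )
        chrom_scores[pos] = score

    def get(self, chrom: str, pos: int, default: float = 0.0) -> float:
        return self._scores.get(chrom, {}).get(pos, default)

    def n_positions(self) -> int:
        return sum(len(d) for d in self._scores.values())


def _normalize_strand(strand: str, context: str) -> str:
    if strand in ("+", "-"):
        return strand
    if strand == ".":
        logger.warning("%s: unstranded record treated as '+'", context)
        return "+"
    raise ValidationError(f"{context}: invalid strand {strand!r}")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def parse_bed(path: str) -> list[TranscriptModel]:
    """Parse a BED12 (blocked) or BED6 (single-exon) file into transcript models."""
    transcripts: list[TranscriptModel] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) not in (6, 12):
                raise ParseError(
                    f"{path}:{lineno}: expected 6 or 12 BED columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                chrom_end = int(fields[2])
                name = fields[3]
                strand = _normalize_strand(fields[5], f"{path}:{lineno}")
                if len(fields) == 12:
                    block_count = int(fields[9])
                    block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                    block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
                else:
                    block_count = 1
                    block_sizes = [chrom_end - chrom_start]
                    block_starts = [0]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if len(block_sizes) != block_count or len(block_starts) != block_count:
                raise ParseError(
                    f"{path}:{lineno}: blockCount={block_count} does not match "
                    f"blockSizes/blockStarts lengths "
                    f"({len(block_sizes)}/{len(block_starts)})"
                )
            exons = tuple(
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(block_starts, block_sizes)
            )
            try:
                transcripts.append(
                    TranscriptModel(name, chrom, strand, exons)
                )
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return transcripts


def to_bed12_line(tx: TranscriptModel) -> str:
    """Serialize a transcript model as one BED12 line (round-trip exact)."""
    chrom_start, chrom_end = tx.span
    sizes = ",".join(str(end - start) for start, end in tx.exons)
    starts = ",".join(str(start - chrom_start) for start, end in tx.exons)
    return "\t".join(
        [
            tx.chrom,
            str(chrom_start),
            str(chrom_end),
            tx.transcript_id,
            "0",
            tx.strand,
            str(chrom_start),
            str(chrom_start),
            "0",
            str(len(tx.exons)),
            sizes,
            starts,
        ]
    )


def write_bed(transcripts: list[TranscriptModel], path: str) -> None:
    with open(path, "w") as handle:
        for tx in transcripts:
            handle.write(to_bed12_line(tx) + "\n")


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

_GTF_TXID = re.compile(r'transcript_id\s+"([^"]+)"')
_GFF3_PARENT = re.compile(r"(?:^|;)\s*Parent=([^;]+)")
_GFF3_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")


def _exon_transcript_id(attributes: str) -> str | None:
    match = _GTF_TXID.search(attributes)
    if match:
        return match.group(1)
    match = _GFF3_PARENT.search(attributes)
    if match:
        return match.group(1).split(",")[0]
    match = _GFF3_ID.search(attributes)
    if match:
        return match.group(1)
    return None


def parse_gtf(path: str) -> list[TranscriptModel]:
    """Parse exon rows of a GTF or GFF3 file into transcript models.

    Handles both attribute dialects (``transcript_id "x"`` and
    ``Parent=x``/``ID=x``).  1-based closed coordinates are converted to
    0-based half-open; exon order in the file is irrelevant.
    """
    # tx id -> (chrom, strand, [exons], first lineno)
    groups: dict[str, tuple[str, str, list[tuple[int, int]], int]] = {}
    order: list[str] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            if fields[2].lower() != "exon":
                continue
            chrom = fields[0]
            try:
                start = int(fields[3]) - 1  # 1-based closed -> 0-based half-open
                end = int(fields[4])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric coordinate") from None
            strand = _normalize_strand(fields[6], f"{path}:{lineno}")
            tx_id = _exon_transcript_id(fields[8])
            if tx_id is None:
                raise ParseError(
                    f"{path}:{lineno}: exon without transcript identifier "
                    "(no transcript_id / Parent / ID attribute)"
                )
            if tx_id not in groups:
                groups[tx_id] = (chrom, strand, [], lineno)
                order.append(tx_id)
            known_chrom, known_strand, exons, first_line = groups[tx_id]
            if chrom != known_chrom:
                raise ValidationError(
                    f"{path}: transcript {tx_id!r} has exons on multiple "
                    f"chromosomes ({known_chrom}, {chrom})"
                )
            if strand != known_strand:
                raise ValidationError(
                    f"{path}: transcript {tx_id!r} mixes strands "
                    f"({known_strand}, {strand})"
                )
            exons.append((start, end))
    transcripts = []
    for tx_id in order:
        chrom, strand, exons, first_line = groups[tx_id]
        try:
            transcripts.append(
                TranscriptModel(tx_id, chrom, strand, tuple(sorted(exons)))
            )
        except ValidationError as exc:
            raise ValidationError(f"{path} (near line {first_line}): {exc}") from None
    return transcripts


def write_gtf(transcripts: list[TranscriptModel], path: str, source: str = "lincscan") -> None:
    """Write exon rows in GTF dialect (1-based closed coordinates)."""
    with open(path, "w") as handle:
        for tx in transcripts:
            for start, end in tx.exons:
                attrs = f'gene_id "{tx.transcript_id}"; transcript_id "{tx.transcript_id}";'
                handle.write(
                    "\t".join(
                        [
                            tx.chrom,
                            source,
                            "exon",
                            str(start + 1),
                            str(end),
                            ".",
                            tx.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def parse_annotation(path: str) -> list[TranscriptModel]:
    """Dispatch on file extension: .bed -> BED, .gtf/.gff/.gff3 -> GTF/GFF3."""
    lower = path.lower()
    if lower.endswith(".bed"):
        return parse_bed(path)
    if lower.endswith((".gtf", ".gff", ".gff3")):
        return parse_gtf(path)
    raise ParseError(
        f"{path}: cannot infer annotation format from extension "
        "(expected .bed, .gtf, .gff or .gff3)"
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> GenomeSequence:
    """Load a multi-record FASTA; uppercase, non-ACGTN masked to N."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        name = record.id
        if name in sequences:
            raise ValidationError(f"{path}: duplicate chromosome name {name!r}")
        seq = str(record.seq).upper()
        masked = _NON_ACGTN.sub("N", seq)
        if masked != seq:
            logger.warning("%s: ambiguous bases in %s masked to N", path, name)
        sequences[name] = masked
    if not sequences:
        raise ParseError(f"{path}: no FASTA records found")
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path: str, width: int = 80) -> None:
    with open(path, "w") as handle:
        for chrom in genome.chroms():
            handle.write(f">{chrom}\n")
            seq = genome.fetch(chrom, 0, genome.length(chrom))
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Conservation tracks (WIG fixedStep / variableStep, bedGraph)
# ---------------------------------------------------------------------------

def read_conservation(path: str) -> ConservationTrack:
    """Read a text conservation track into a sparse per-base score map.

    Accepts WIG fixedStep, WIG variableStep, and bedGraph; WIG 1-based starts
    become 0-based internally, bedGraph intervals are expanded per base.
    Later records overwrite earlier ones at the same position.
    """
    track = ConservationTrack()
    mode: str | None = None  # "fixed" | "variable" | None (bedGraph fallback)
    chrom = ""
    pos = 0
    step = 1
    span = 1
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split()
            head = fields[0]
            if head in ("fixedStep", "variableStep"):
                params = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
                if "chrom" not in params:
                    raise ParseError(f"{path}:{lineno}: {head} without chrom=")
                chrom = params["chrom"]
                span = int(params.get("span", 1))
                if head == "fixedStep":
                    if "start" not in params:
                        raise ParseError(f"{path}:{lineno}: fixedStep without start=")
                    mode = "fixed"
                    pos = int(params["start"]) - 1  # WIG is 1-based
                    step = int(params.get("step", 1))
                else:
                    mode = "variable"
                continue
            try:
                if mode == "fixed":
                    if len(fields) != 1:
                        raise ParseError(
                            f"{path}:{lineno}: fixedStep data line must be one value"
                        )
                    score = float(fields[0])
                    _store_span(track, chrom, pos, span, score, path, lineno)
                    pos += step
                elif mode == "variable":
                    if len(fields) != 2:
                        raise ParseError(
                            f"{path}:{lineno}: variableStep data line must be "
                            "'position value'"
                        )
                    p = int(fields[0]) - 1
                    score = float(fields[1])
                    _store_span(track, chrom, p, span, score, path, lineno)
                elif len(fields) == 4:
                    start, end = int(fields[1]), int(fields[2])
                    score = float(fields[3])
                    _store_span(
                        track, fields[0], start, end - start, score, path, lineno
                    )
                else:
                    raise ParseError(
                        f"{path}:{lineno}: unrecognized track line {line!r} "
                        "(expected WIG header, WIG data, or 4-column bedGraph)"
                    )
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed numeric field") from None
    return track


def _store_span(
    track: ConservationTrack,
    chrom: str,
    start: int,
    length: int,
    score: float,
    path: str,
    lineno: int,
) -> None:
    if not (0.0 <= score <= 1.0):
        raise ValidationError(
            f"{path}:{lineno}: conservation score {score} outside [0, 1]"
        )
    for p in range(start, start + length):
        track.set(chrom, p, score)


def write_bedgraph(track: ConservationTrack, path: str) -> None:
    """Serialize a track as bedGraph, merging runs of equal adjacent scores."""
    with open(path, "w") as handle:
        for chrom in sorted(track._scores):
            positions = sorted(track._scores[chrom])
            scores = track._scores[chrom]
            run_start = None
            prev_pos = None
            prev_score = None
            for p in positions:
                s = scores[p]
                if run_start is not None and p == prev_pos + 1 and s == prev_score:
                    prev_pos = p
                    continue
                if run_start is not None:
                    handle.write(
                        f"{chrom}\t{run_start}\t{prev_pos + 1}\t{prev_score:.3f}\n"
                    )
                run_start = p
                prev_pos = p
                prev_score = s
            if run_start is not None:
                handle.write(
                    f"{chrom}\t{run_start}\t{prev_pos + 1}\t{prev_score:.3f}\n"
                )


# ---------------------------------------------------------------------------
# Sequence extraction and prediction output
# ---------------------------------------------------------------------------

def extract_sequence(tx: TranscriptModel, genome: GenomeSequence) -> str:
    """Spliced transcript sequence, 5'->3' (minus strand reverse-complemented)."""
    parts = [genome.fetch(tx.chrom, start, end) for start, end in tx.exons]
    seq = "".join(parts)
    if tx.strand == "-":
        seq = reverse_complement(seq)
    return seq


PREDICTION_HEADER = ("transcript_id", "label", "noncoding_score")


def write_predictions(predictions, path: str) -> None:
    """Write the 3-column TSV prediction report (scores to 4 decimals)."""
    with open(path, "w") as handle:
        handle.write("\t".join(PREDICTION_HEADER) + "\n")
        for pred in predictions:
            handle.write(
                f"{pred.transcript_id}\t{pred.label}\t{pred.noncoding_score:.4f}\n"
            )


def read_predictions(path: str):
    """Read a prediction TSV back into (id, label, score) Prediction tuples."""
    from .svm_model import Prediction

    preds = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != PREDICTION_HEADER:
            raise ParseError(
                f"{path}: unexpected header {header!r}; "
                f"expected {list(PREDICTION_HEADER)}"
            )
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns")
            try:
                score = float(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric score") from None
            preds.append(Prediction(fields[0], fields[1], score))
    return preds


def read_truth(path: str) -> dict[str, str]:
    """Read a 2-column (transcript_id, label) TSV; labels 'noncoding'/'coding'."""
    truth: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and fields[1] not in ("noncoding", "coding"):
                continue  # header row
            if fields[1] not in ("noncoding", "coding"):
                raise ValidationError(
                    f"{path}:{lineno}: label must be 'noncoding' or 'coding', "
                    f"got {fields[1]!r}"
                )
            truth[fields[0]] = fields[1]
    return truth
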