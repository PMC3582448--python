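"""Dataset curation filters and a synthetic two-class corpus generator.

The generator emits a genome FASTA, BED12 + GTF annotations, a per-base
conservation bedGraph, and a truth table, with the two classes separated the
way real data is: coding transcripts carry one long embedded ORF, GC-biased
codon usage and high exonic conservation; non-coding transcripts are AT-biased
random sequence with low conservation and only spurious short ORFs.
Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import ValidationError
from .formats_io import (
    ConservationTrack,
    GenomeSequence,
    TranscriptModel,
    reverse_complement,
    write_bed,
    write_bedgraph,
    write_fasta,
    write_gtf,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for the generated two-class corpus."""

    n_coding: int = 200
    n_noncoding: int = 200
    length_range: tuple[int, int] = (400, 1200)
    orf_length_range: tuple[int, int] = (240, 900)  # nt, multiples of 3
    cons_mean_coding: float = 0.75
    cons_mean_noncoding: float = 0.12
    cons_sd: float = 0.12
    coding_codon_bias: float = 0.7  # 0 = uniform codons, larger = more GC-rich
    noncoding_gc: float = 0.34  # GC fraction of non-coding composition
    exon_count_range: tuple[int, int] = (1, 4)
    intron_range: tuple[int, int] = (60, 300)
    intergenic_gap_range: tuple[int, int] = (100, 400)
    transcripts_per_chrom: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coding < 0 or self.n_noncoding < 0:
            raise ValidationError("class sizes must be non-negative")
        if self.length_range[0] <= 200:
            raise ValidationError(
                "minimum transcript length must exceed 200 nt "
                f"(got {self.length_range[0]})"
            )
        if self.length_range[0] > self.length_range[1]:
            raise ValidationError("invalid transcript length range")
        lo, hi = self.orf_length_range
        if lo % 3 or hi % 3:
            raise ValidationError("ORF length bounds must be multiples of 3")
        if lo < 9 or lo > hi:
            raise ValidationError("invalid ORF length range")
        if lo > self.length_range[0] - 6:
            raise ValidationError(
                f"minimum ORF length {lo} does not fit in the minimum "
                f"transcript length {self.length_range[0]}"
            )
        for mean in (self.cons_mean_coding, self.cons_mean_noncoding):
            if not (0.0 <= mean <= 1.0):
                raise ValidationError("conservation means must lie in [0, 1]")
        if self.exon_count_range[0] < 1:
            raise ValidationError("exon count must be >= 1")


@dataclass
class GeneratedTranscript:
    """Internal generator log entry: where everything was placed."""

    transcript_id: str
    label: str  # "coding" | "noncoding"
    tx_sequence: str  # 5'->3' spliced sequence
    orf_start: int | None  # transcript offset of embedded ORF (coding only)
    orf_length: int | None
    model: TranscriptModel


@dataclass
class SyntheticCorpus:
    spec: SyntheticSpec
    genome: GenomeSequence
    transcripts: list[TranscriptModel]
    track: ConservationTrack
    truth: dict[str, str]
    log: list[GeneratedTranscript]


@dataclass
class CuratedSplit:
    """Balanced training set plus held-out remainder, with filter provenance."""

    train_pos: list[TranscriptModel]
    train_neg: list[TranscriptModel]
    test_pos: list[TranscriptModel]
    test_neg: list[TranscriptModel]
    log: dict[str, int]


# ---------------------------------------------------------------------------
# Curation filters
# ---------------------------------------------------------------------------

def filter_by_length(
    transcripts: list[TranscriptModel], min_nt: int = 200
) -> tuple[list[TranscriptModel], int]:
    """Keep transcripts whose spliced length is strictly greater than ``min_nt``."""
    kept = [tx for tx in transcripts if tx.length > min_nt]
    return kept, len(transcripts) - len(kept)


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    for a_start, a_end in a.exons:
        for b_start, b_end in b.exons:
            if a_start < b_end and b_start < a_end:
                return True
    return False


def cross_annotation_filter(
    candidates: list[TranscriptModel],
    coding_reference: list[TranscriptModel],
    mode: str = "exclude_overlap",
) -> list[TranscriptModel]:
    """Cross-source consistency filter.

    ``exclude_overlap`` drops candidates with same-strand exonic overlap
    (>= 1 bp) against any reference transcript; ``require_consistent`` keeps
    candidates whose id or exact exon structure appears in the reference.
    """
    if mode == "exclude_overlap":
        by_chrom: dict[tuple[str, str], list[TranscriptModel]] = {}
        for ref in coding_reference:
            by_chrom.setdefault((ref.chrom, ref.strand), []).append(ref)
        kept = []
        for tx in candidates:
            refs = by_chrom.get((tx.chrom, tx.strand), ())
            if not any(_exonic_overlap(tx, ref) for ref in refs):
                kept.append(tx)
        return kept
    if mode == "require_consistent":
        ref_ids = {ref.transcript_id for ref in coding_reference}
        ref_structures = {
            (ref.chrom, ref.strand, ref.exons) for ref in coding_reference
        }
        return [
            tx
            for tx in candidates
            if tx.transcript_id in ref_ids
            or (tx.chrom, tx.strand, tx.exons) in ref_structures
        ]
    raise ValidationError(
        f"unknown filter mode {mode!r} "
        "(expected 'exclude_overlap' or 'require_consistent')"
    )


def make_split(
    positives: list[TranscriptModel],
    negatives: list[TranscriptModel],
    seed: int = 0,
) -> CuratedSplit:
    """Half the positives plus an equal number of negatives into training.

    The remainder of both classes becomes the testing pool; selection is
    deterministic from ``seed``.
    """
    if not positives or not negatives:
        raise ValidationError("both classes must be non-empty")
    n_train = len(positives) // 2
    if n_train == 0:
        raise ValidationError("too few positives to split")
    if len(negatives) < n_train:
        raise ValidationError(
            f"need at least {n_train} negatives to balance training, "
            f"have {len(negatives)}"
        )
    rng = np.random.default_rng(seed)
    pos_pick = set(rng.choice(len(positives), size=n_train, replace=False).tolist())
    neg_pick = set(rng.choice(len(negatives), size=n_train, replace=False).tolist())
    train_pos = [tx for i, tx in enumerate(positives) if i in pos_pick]
    test_pos = [tx for i, tx in enumerate(positives) if i not in pos_pick]
    train_neg = [tx for i, tx in enumerate(negatives) if i in neg_pick]
    test_neg = [tx for i, tx in enumerate(negatives) if i not in neg_pick]
    log = {
        "n_pos": len(positives),
        "n_neg": len(negatives),
        "train_pos": len(train_pos),
        "train_neg": len(train_neg),
        "test_pos": len(test_pos),
        "test_neg": len(test_neg),
    }
    return CuratedSplit(train_pos, train_neg, test_pos, test_neg, log)


# ---------------------------------------------------------------------------
# Synthetic corpus generation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _codon_weights(bias: float) -> np.ndarray:
    gc_counts = np.array([c.count("G") + c.count("C") for c in _NON_STOP_CODONS])
    w = np.exp(bias * gc_counts)
    return w / w.sum()


def _coding_sequence(
    rng: np.random.Generator, spec: SyntheticSpec, length: int
) -> tuple[str, int, int]:
    """Sequence of ``length`` with one embedded complete ORF; returns (seq, start, len)."""
    lo, hi = spec.orf_length_range
    hi = min(hi, ((length - 6) // 3) * 3)
    n_codon_choices = (hi - lo) // 3 + 1
    orf_len = lo + 3 * int(rng.integers(0, n_codon_choices))
    weights = _codon_weights(spec.coding_codon_bias)
    n_internal = orf_len // 3 - 2  # minus start and stop codons
    internal = "".join(
        _NON_STOP_CODONS[i] for i in rng.choice(len(_NON_STOP_CODONS), size=n_internal, p=weights)
    )
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    orf = "ATG" + internal + stop
    offset = int(rng.integers(0, length - orf_len + 1))
    left = _random_sequence(rng, offset, 0.5)
    right = _random_sequence(rng, length - orf_len - offset, 0.5)
    return left + orf + right, offset, orf_len


def _split_exons(
    rng: np.random.Generator, spec: SyntheticSpec, length: int
) -> list[int]:
    """Exon lengths summing to ``length``, each at least 30 nt."""
    lo, hi = spec.exon_count_range
    n_exons = int(rng.integers(lo, hi + 1))
    n_exons = max(1, min(n_exons, length // 30))
    extra = rng.multinomial(length - 30 * n_exons, np.full(n_exons, 1.0 / n_exons))
    return [30 + int(e) for e in extra]


def generate_corpus(spec: SyntheticSpec) -> SyntheticCorpus:
    """Build the in-memory corpus (genome, models, track, truth, placement log)."""
    rng = np.random.default_rng(spec.seed)
    entries: list[tuple[str, str]] = [
        (f"cod{i + 1:05d}", "coding") for i in range(spec.n_coding)
    ] + [(f"nc{i + 1:05d}", "noncoding") for i in range(spec.n_noncoding)]
    order = rng.permutation(len(entries))

    chrom_parts: dict[str, list[str]] = {}
    chrom_cursor: dict[str, int] = {}
    log: list[GeneratedTranscript] = []
    track = ConservationTrack()
    truth: dict[str, str] = {}

    for rank, idx in enumerate(order):
        tx_id, label = entries[idx]
        chrom = f"chr{rank // spec.transcripts_per_chrom + 1}"
        parts = chrom_parts.setdefault(chrom, [])
        cursor = chrom_cursor.get(chrom, 0)

        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        if label == "coding":
            tx_seq, orf_start, orf_len = _coding_sequence(rng, spec, length)
            cons_mean = spec.cons_mean_coding
        else:
            tx_seq = _random_sequence(rng, length, spec.noncoding_gc)
            orf_start = orf_len = None
            cons_mean = spec.cons_mean_noncoding
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        exon_lengths = _split_exons(rng, spec, length)

        # Transcript pieces in 5'->3' order; genomic exon i (ascending) holds
        # piece i on +, and the reverse complement of piece n-1-i on -.
        pieces = []
        offset = 0
        for el in exon_lengths:
            pieces.append(tx_seq[offset : offset + el])
            offset += el
        if strand == "+":
            genomic_pieces = pieces
        else:
            genomic_pieces = [reverse_complement(p) for p in reversed(pieces)]

        gap = int(
            rng.integers(spec.intergenic_gap_range[0], spec.intergenic_gap_range[1] + 1)
        )
        parts.append(_random_sequence(rng, gap, 0.5))
        cursor += gap

        exons: list[tuple[int, int]] = []
        for i, piece in enumerate(genomic_pieces):
            if i > 0:
                intron = int(
                    rng.integers(spec.intron_range[0], spec.intron_range[1] + 1)
                )
                parts.append(_random_sequence(rng, intron, 0.5))
                cursor += intron
            start = cursor
            parts.append(piece)
            cursor += len(piece)
            exons.append((start, cursor))
            scores = np.clip(
                rng.normal(cons_mean, spec.cons_sd, size=len(piece)), 0.0, 1.0
            )
            for pos, score in zip(range(start, cursor), scores):
                track.set(chrom, pos, round(float(score), 3))
        chrom_cursor[chrom] = cursor

        model = TranscriptModel(tx_id, chrom, strand, tuple(exons))
        truth[tx_id] = "noncoding" if label == "noncoding" else "coding"
        log.append(
            GeneratedTranscript(tx_id, label, tx_seq, orf_start, orf_len, model)
        )

    # trailing intergenic pad so no exon touches a chromosome end
    genome_seqs = {}
    for chrom in sorted(chrom_parts, key=lambda c: int(c[3:])):
        pad = _random_sequence(rng, 100, 0.5)
        genome_seqs[chrom] = "".join(chrom_parts[chrom]) + pad

    transcripts = [entry.model for entry in log]
    return SyntheticCorpus(
        spec=spec,
        genome=GenomeSequence(genome_seqs),
        transcripts=transcripts,
        track=track,
        truth=truth,
        log=log,
    )


def write_corpus(corpus: SyntheticCorpus, outdir: str) -> dict[str, str]:
    """Serialize the corpus; returns the mapping of artifact name -> path."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "bed": os.path.join(outdir, "transcripts.bed"),
        "gtf": os.path.join(outdir, "transcripts.gtf"),
        "conservation": os.path.join(outdir, "cons.bedGraph"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "spec": os.path.join(outdir, "spec.json"),
    }
    write_fasta(corpus.genome, paths["genome"])
    write_bed(corpus.transcripts, paths["bed"])
    write_gtf(corpus.transcripts, paths["gtf"])
    write_bedgraph(corpus.track, paths["conservation"])
    with open(paths["truth"], "w") as handle:
        handle.write("transcript_id\tlabel\n")
        for tx in corpus.transcripts:
            handle.write(f"{tx.transcript_id}\t{corpus.truth[tx.transcript_id]}\n")
    with open(paths["spec"], "w") as handle:
        json.dump(asdict(corpus.spec), handle, indent=2)
        handle.write("\n")
    logger.info("synthetic corpus written to %s", outdir)
    return paths
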