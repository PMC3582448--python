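"""Per-transcript features: conservation mean, ORF length/proportion, k-mers.

The feature vector layout is fixed by :class:`FeatureConfig`:
``[conservation, orf_length, orf_proportion, kmer_1 ... kmer_n]`` (conservation
omitted when disabled).  Raw vectors are min-max scaled to [0, 1] with
parameters learned on the training set only.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from . import ValidationError
from .formats_io import ConservationTrack, GenomeSequence, TranscriptModel, extract_sequence

logger = logging.getLogger(__name__)

#: The six named di/tri-nucleotides used by default.
DEFAULT_KMERS = ("GC", "CT", "TAG", "TGT", "ACG", "TCG")

STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))
START_CODON = "ATG"


@dataclass(frozen=True)
class FeatureConfig:
    """Which features to compute and in what order."""

    kmers: tuple[str, ...] = DEFAULT_KMERS
    use_conservation: bool = True

    def __post_init__(self) -> None:
        seen = set()
        for kmer in self.kmers:
            if kmer != kmer.upper() or set(kmer) - set("ACGT"):
                raise ValidationError(f"k-mer {kmer!r} must be uppercase over ACGT")
            if len(kmer) not in (2, 3):
                raise ValidationError(f"k-mer {kmer!r} must have length 2 or 3")
            if kmer in seen:
                raise ValidationError(f"duplicate k-mer {kmer!r}")
            seen.add(kmer)

    @property
    def feature_order(self) -> tuple[str, ...]:
        base = ("conservation",) if self.use_conservation else ()
        return base + ("orf_length", "orf_proportion") + self.kmers

    def to_dict(self) -> dict:
        return {"kmers": list(self.kmers), "use_conservation": self.use_conservation}

    @classmethod
    def from_dict(cls, data: dict) -> "FeatureConfig":
        return cls(
            kmers=tuple(data.get("kmers", DEFAULT_KMERS)),
            use_conservation=bool(data.get("use_conservation", True)),
        )


@dataclass(frozen=True)
class ORFResult:
    """Longest ATG -> first-in-frame-stop open reading frame (stop included)."""

    found: bool
    start: int = 0
    end: int = 0

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class FeatureVector:
    transcript_id: str
    names: tuple[str, ...]
    values: np.ndarray
    scaled: bool = False


@dataclass
class FeatureTable:
    """Feature vectors for many transcripts sharing one feature order."""

    ids: list[str]
    names: tuple[str, ...]
    X: np.ndarray  # shape (n, len(names)), raw unless noted
    scaled: bool = False

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature (min, max) observed on the training set."""

    mins: tuple[float, ...]
    maxs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mins) != len(self.maxs):
            raise ValidationError("scaler min/max length mismatch")
        for lo, hi in zip(self.mins, self.maxs):
            if hi < lo:
                raise ValidationError(f"scaler max {hi} < min {lo}")


def find_longest_orf(seq: str) -> ORFResult:
    """Longest complete ORF in the three forward frames of ``seq``.

    An ORF runs from an exact ``ATG`` to the first in-frame stop codon
    (``TAA``/``TAG``/``TGA``), stop included in the length.  A codon
    containing ``N`` is ambiguous: it never matches the start or a stop, and
    it invalidates any candidate ORF that would read through it (it might
    hide a stop).  Ties go to the 5'-most start.
    """
    n = len(seq)
    if n < 6:
        return ORFResult(found=False)
    # per-frame sorted "events": stop codons end an ORF, N codons break it
    events_by_frame: list[list[tuple[int, bool]]] = [[], [], []]
    starts: list[int] = []
    for i in range(n - 2):
        codon = seq[i : i + 3]
        if codon == START_CODON:
            starts.append(i)
        elif codon in STOP_CODONS:
            events_by_frame[i % 3].append((i, True))
        elif "N" in codon:
            events_by_frame[i % 3].append((i, False))
    best_start = -1
    best_len = 0
    for s in starts:
        events = events_by_frame[s % 3]
        j = bisect_left(events, (s + 3, False))
        if j == len(events):
            continue
        pos, is_stop = events[j]
        if not is_stop:
            continue
        length = pos + 3 - s
        if length > best_len:  # ascending scan => first hit is 5'-most on ties
            best_len = length
            best_start = s
    if best_start < 0:
        return ORFResult(found=False)
    return ORFResult(found=True, start=best_start, end=best_start + best_len)


def orf_features(seq: str) -> tuple[float, float]:
    """(ORF length in nt, ORF length / transcript length); (0, 0) if no ORF."""
    if not seq:
        raise ValidationError("cannot compute ORF features of an empty sequence")
    orf = find_longest_orf(seq)
    if not orf.found:
        return 0.0, 0.0
    return float(orf.length_nt), orf.length_nt / len(seq)


def kmer_frequency(seq: str, kmer: str) -> float:
    """Overlapping-window frequency of ``kmer``, N-containing windows excluded.

    Denominator is the number of windows free of ``N``; returns 0 when no
    valid window exists.
    """
    k = len(kmer)
    if len(seq) < k:
        logger.warning("sequence shorter than k-mer %r; frequency set to 0", kmer)
        return 0.0
    count = 0
    valid = 0
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if "N" in window:
            continue
        valid += 1
        if window == kmer:
            count += 1
    if valid == 0:
        return 0.0
    return count / valid


def conservation_feature(tx: TranscriptModel, track: ConservationTrack) -> float:
    """Mean per-base conservation over all exonic positions; missing bases score 0."""
    total = 0.0
    for start, end in tx.exons:
        for pos in range(start, end):
            total += track.get(tx.chrom, pos, 0.0)
    return total / tx.length


def build_feature_vector(
    tx: TranscriptModel,
    genome: GenomeSequence,
    track: ConservationTrack | None,
    cfg: FeatureConfig = FeatureConfig(),
) -> FeatureVector:
    """Assemble the raw feature vector for one transcript in ``cfg.feature_order``."""
    seq = extract_sequence(tx, genome)
    values: list[float] = []
    if cfg.use_conservation:
        if track is None:
            raise ValidationError(
                "feature config requires conservation but no track was given"
            )
        values.append(conservation_feature(tx, track))
    orf_len, orf_prop = orf_features(seq)
    values.append(orf_len)
    values.append(orf_prop)
    for kmer in cfg.kmers:
        values.append(kmer_frequency(seq, kmer))
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"non-finite feature for transcript {tx.transcript_id}")
    return FeatureVector(tx.transcript_id, cfg.feature_order, arr)


def build_feature_table(
    transcripts: list[TranscriptModel],
    genome: GenomeSequence,
    track: ConservationTrack | None,
    cfg: FeatureConfig = FeatureConfig(),
) -> FeatureTable:
    vectors = [build_feature_vector(tx, genome, track, cfg) for tx in transcripts]
    X = (
        np.stack([v.values for v in vectors])
        if vectors
        else np.empty((0, len(cfg.feature_order)))
    )
    return FeatureTable([v.transcript_id for v in vectors], cfg.feature_order, X)


def fit_scaler(X: np.ndarray) -> ScalerParams:
    """Learn per-feature (min, max) on training data (needs >= 2 rows)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("scaler fitting needs at least 2 feature vectors")
    return ScalerParams(
        mins=tuple(float(v) for v in X.min(axis=0)),
        maxs=tuple(float(v) for v in X.max(axis=0)),
    )


def apply_scaler(X: np.ndarray, params: ScalerParams) -> np.ndarray:
    """Min-max scale to [0, 1], clamped; constant features map to 0."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mins = np.asarray(params.mins)
    maxs = np.asarray(params.maxs)
    if X.shape[1] != mins.shape[0]:
        raise ValidationError(
            f"feature count {X.shape[1]} does not match scaler ({mins.shape[0]})"
        )
    span = maxs - mins
    constant = span == 0
    safe_span = np.where(constant, 1.0, span)
    scaled = np.clip((X - mins) / safe_span, 0.0, 1.0)
    scaled[:, constant] = 0.0
    return scaled
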