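from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lincscan import ValidationError
from lincscan.feature_extraction import (
    DEFAULT_KMERS,
    FeatureConfig,
    apply_scaler,
    build_feature_vector,
    conservation_feature,
    find_longest_orf,
    fit_scaler,
    kmer_frequency,
    orf_features,
)
from lincscan.formats_io import ConservationTrack, GenomeSequence, TranscriptModel
from oracles import brute_force_kmer_frequency, brute_force_longest_orf


# ---------------------------------------------------------------------------
# ORF detection
# ---------------------------------------------------------------------------

def test_orf_single_complete():
    orf = find_longest_orf("ATGAAATAG")
    assert orf.found and orf.start == 0 and orf.length_nt == 9


def test_orf_longest_wins():
    # derived by brute-force enumeration: ORF at offset 6 (length 12) beats
    # the one at offset 0 (length 6)
    seq = "ATGTAAATGAAAAAATGA"
    assert brute_force_longest_orf(seq) == (True, 6, 12)
    orf = find_longest_orf(seq)
    assert (orf.found, orf.start, orf.length_nt) == (True, 6, 12)


def test_orf_no_start_codon():
    orf = find_longest_orf("CCCCCC")
    assert not orf.found and orf.length_nt == 0


def test_orf_n_breaks_codon():
    # derived via the brute-force oracle with the N-masking rule
    seq = "ATGNAATAG"
    assert brute_force_longest_orf(seq) == (False, 0, 0)
    assert not find_longest_orf(seq).found


def test_orf_empty_and_short():
    assert not find_longest_orf("").found
    assert not find_longest_orf("ATG").found


def test_orf_tie_breaks_to_five_prime():
    # two disjoint ORFs of equal length; the 5'-most start must win
    seq = "ATGTAA" + "C" + "ATGTGA"
    orf = find_longest_orf(seq)
    assert orf.start == 0 and orf.length_nt == 6


def test_orf_invariants_on_found():
    seq = "CCATGAAACCCGGGTAGTT"
    orf = find_longest_orf(seq)
    assert orf.found
    assert orf.length_nt % 3 == 0
    assert seq[orf.start : orf.start + 3] == "ATG"
    assert seq[orf.end - 3 : orf.end] in {"TAA", "TAG", "TGA"}


@settings(max_examples=300, deadline=None)
@given(
    st.text(alphabet="ACGT", min_size=0, max_size=400),
)
def test_orf_matches_brute_force(seq):
    found, start, length = brute_force_longest_orf(seq)
    orf = find_longest_orf(seq)
    assert (orf.found, orf.length_nt) == (found, length)
    if found:
        assert orf.start == start


@settings(max_examples=150, deadline=None)
@given(st.text(alphabet="ACGTN", min_size=0, max_size=300))
def test_orf_matches_brute_force_with_n(seq):
    found, start, length = brute_force_longest_orf(seq)
    orf = find_longest_orf(seq)
    assert (orf.found, orf.start if found else 0, orf.length_nt) == (found, start, length)


# ---------------------------------------------------------------------------
# ORF-derived features
# ---------------------------------------------------------------------------

def test_orf_features_whole_transcript():
    assert orf_features("ATGAAATAG") == (9.0, 1.0)


def test_orf_features_half_proportion():
    rng = np.random.default_rng(5)
    while True:
        flank = "".join(rng.choice(list("CG"), size=75))  # C/G flanks: no ATG, no stop
        orf = "ATG" + "GGC" * 48 + "TAA"  # 150 nt
        seq = flank + orf + flank
        if brute_force_longest_orf(seq)[2] == 150:
            break
    length, proportion = orf_features(seq)
    assert length == 150.0
    assert proportion == pytest.approx(0.5)


def test_orf_features_no_orf():
    assert orf_features("CCCCCC") == (0.0, 0.0)


def test_orf_features_empty_error():
    with pytest.raises(ValidationError):
        orf_features("")


@settings(max_examples=100, deadline=None)
@given(st.text(alphabet="ACGT", min_size=1, max_size=300))
def test_orf_proportion_in_unit_interval(seq):
    length, proportion = orf_features(seq)
    assert 0.0 <= proportion <= 1.0
    # proportion 1 iff the transcript is exactly one complete ORF
    if proportion == 1.0:
        assert seq.startswith("ATG") and seq[-3:] in {"TAA", "TAG", "TGA"}
        assert len(seq) % 3 == 0


# ---------------------------------------------------------------------------
# k-mer frequencies
# ---------------------------------------------------------------------------

def test_kmer_direct_count():
    assert kmer_frequency("ACGACG", "CG") == pytest.approx(2 / 5)


def test_kmer_absent():
    assert kmer_frequency("ACGACG", "GC") == 0.0


def test_kmer_n_excluded_from_denominator():
    # derived: windows AN, NC, CG -> one valid window, one match
    assert brute_force_kmer_frequency("ANCG", "CG") == 1.0
    assert kmer_frequency("ANCG", "CG") == 1.0


def test_kmer_short_sequence_zero():
    assert kmer_frequency("A", "CG") == 0.0


def test_kmer_all_n_zero():
    assert kmer_frequency("NNNN", "CG") == 0.0


@settings(max_examples=100, deadline=None)
@given(st.text(alphabet="ACGTN", min_size=2, max_size=200),
       st.sampled_from(DEFAULT_KMERS))
def test_kmer_matches_brute_force(seq, kmer):
    assert kmer_frequency(seq, kmer) == pytest.approx(
        brute_force_kmer_frequency(seq, kmer)
    )


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet="ACGT", min_size=2, max_size=200))
def test_dinucleotide_frequencies_sum_to_one(seq):
    kmers = [a + b for a in "ACGT" for b in "ACGT"]
    total = sum(kmer_frequency(seq, k) for k in kmers)
    assert total == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

def _track(scores: dict[int, float]) -> ConservationTrack:
    track = ConservationTrack()
    for pos, score in scores.items():
        track.set("c", pos, score)
    return track


def test_conservation_mean_over_exons():
    tx = TranscriptModel("t", "c", "+", ((0, 2), (5, 7)))
    track = _track({0: 1.0, 1: 1.0, 5: 0.0, 6: 0.0})
    assert conservation_feature(tx, track) == pytest.approx(0.5)


def test_conservation_empty_track():
    tx = TranscriptModel("t", "c", "+", ((0, 4),))
    assert conservation_feature(tx, ConservationTrack()) == 0.0


def test_conservation_missing_positions_count_zero():
    tx = TranscriptModel("t", "c", "+", ((0, 2),))
    assert conservation_feature(tx, _track({0: 0.8})) == pytest.approx(0.4)


def test_conservation_exon_order_invariant():
    track = _track({p: 0.1 * p for p in range(10)})
    exons = [(0, 3), (4, 6), (8, 10)]
    values = []
    for perm in ([0, 1, 2], [2, 0, 1], [1, 2, 0]):
        fake_tx = SimpleNamespace(
            chrom="c", exons=[exons[i] for i in perm], length=7
        )
        values.append(conservation_feature(fake_tx, track))
    assert values[0] == pytest.approx(values[1]) == pytest.approx(values[2])


# ---------------------------------------------------------------------------
# Feature vector assembly
# ---------------------------------------------------------------------------

def test_feature_order_layout():
    cfg = FeatureConfig()
    assert cfg.feature_order == (
        "conservation", "orf_length", "orf_proportion",
        "GC", "CT", "TAG", "TGT", "ACG", "TCG",
    )
    assert len(cfg.feature_order) == 9
    no_cons = FeatureConfig(use_conservation=False)
    assert no_cons.feature_order[0] == "orf_length"


def test_feature_config_validation():
    with pytest.raises(ValidationError):
        FeatureConfig(kmers=("gc",))
    with pytest.raises(ValidationError):
        FeatureConfig(kmers=("ACGT",))
    with pytest.raises(ValidationError):
        FeatureConfig(kmers=("GC", "GC"))


def test_build_feature_vector_components_agree(small_corpus):
    from lincscan.formats_io import extract_sequence

    cfg = FeatureConfig()
    entry = next(e for e in small_corpus.log if e.label == "coding")
    vec = build_feature_vector(entry.model, small_corpus.genome, small_corpus.track, cfg)
    seq = extract_sequence(entry.model, small_corpus.genome)
    expected = [conservation_feature(entry.model, small_corpus.track)]
    expected.extend(orf_features(seq))
    expected.extend(kmer_frequency(seq, k) for k in cfg.kmers)
    np.testing.assert_allclose(vec.values, expected)
    assert vec.values[2] > 0.3  # long embedded ORF -> high proportion


def test_build_feature_vector_minus_strand_equivalent():
    # minus-strand transcript whose genomic content encodes the same 5'->3'
    # sequence as a plus-strand construction gives an identical vector
    from lincscan.formats_io import reverse_complement

    tx_seq = "ATGAAACCCGGGTAA" * 20
    genome_plus = GenomeSequence({"c": tx_seq})
    genome_minus = GenomeSequence({"c": reverse_complement(tx_seq)})
    n = len(tx_seq)
    plus = TranscriptModel("t", "c", "+", ((0, n),))
    minus = TranscriptModel("t", "c", "-", ((0, n),))
    cfg = FeatureConfig(use_conservation=False)
    v_plus = build_feature_vector(plus, genome_plus, None, cfg)
    v_minus = build_feature_vector(minus, genome_minus, None, cfg)
    np.testing.assert_allclose(v_plus.values, v_minus.values)


def test_build_feature_vector_no_atg():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("CG"), size=201))
    genome = GenomeSequence({"c": seq})
    tx = TranscriptModel("t", "c", "+", ((0, 201),))
    vec = build_feature_vector(tx, genome, ConservationTrack(), FeatureConfig())
    assert vec.values[1] == 0.0 and vec.values[2] == 0.0


def test_build_feature_vector_requires_track_when_configured():
    genome = GenomeSequence({"c": "ACGT" * 100})
    tx = TranscriptModel("t", "c", "+", ((0, 400),))
    with pytest.raises(ValidationError):
        build_feature_vector(tx, genome, None, FeatureConfig())


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

def test_scaler_basic():
    params = fit_scaler(np.array([[2.0], [4.0], [6.0]]))
    scaled = apply_scaler(np.array([[2.0], [4.0], [6.0]]), params)
    np.testing.assert_allclose(scaled.ravel(), [0.0, 0.5, 1.0])


def test_scaler_clamps_out_of_range():
    params = fit_scaler(np.array([[2.0], [6.0]]))
    assert apply_scaler(np.array([[10.0]]), params)[0, 0] == 1.0
    assert apply_scaler(np.array([[-5.0]]), params)[0, 0] == 0.0


def test_scaler_constant_feature_maps_to_zero():
    params = fit_scaler(np.array([[3.0, 1.0], [3.0, 2.0]]))
    scaled = apply_scaler(np.array([[3.0, 1.5]]), params)
    assert scaled[0, 0] == 0.0


def test_scaler_needs_two_vectors():
    with pytest.raises(ValidationError):
        fit_scaler(np.array([[1.0, 2.0]]))


@settings(max_examples=100, deadline=None)
@given(
    st.lists(
        st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
        min_size=2, max_size=20,
    )
)
def test_scale_unscale_round_trip(values):
    X = np.array(values).reshape(-1, 1)
    params = fit_scaler(X)
    lo, hi = params.mins[0], params.maxs[0]
    if hi <= lo:
        return
    scaled = apply_scaler(X, params)
    recovered = scaled * (hi - lo) + lo
    # 1e-12 relative to the feature's span (exact for O(1) feature values)
    np.testing.assert_allclose(recovered.ravel(), X.ravel(), atol=1e-12 * max(1.0, hi - lo))
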