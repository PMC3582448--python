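"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: they re-derive expected
values by direct enumeration so the fast implementations can be checked
against them.
"""

from __future__ import annotations

import math

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_longest_orf(seq: str) -> tuple[bool, int, int]:
    """Enumerate every ATG, walk codons to the first stop; longest wins.

    Returns (found, start, length); ties broken by 5'-most start.  Codons
    containing N never match ATG or a stop, and an ambiguous (N-containing)
    codon aborts the candidate ORF: it might hide a stop.
    """
    best = (False, 0, 0)
    for i in range(len(seq)):
        if seq[i : i + 3] != "ATG":
            continue
        j = i + 3
        while j + 3 <= len(seq):
            codon = seq[j : j + 3]
            if "N" in codon:
                break
            if codon in STOPS:
                length = j + 3 - i
                if length > best[2]:
                    best = (True, i, length)
                break
            j += 3
    return best


def brute_force_kmer_frequency(seq: str, kmer: str) -> float:
    k = len(kmer)
    windows = [seq[i : i + k] for i in range(len(seq) - k + 1)]
    valid = [w for w in windows if "N" not in w]
    if not valid:
        return 0.0
    return sum(1 for w in valid if w == kmer) / len(valid)


def mcc_by_correlation(tp: int, fp: int, tn: int, fn: int) -> float:
    """MCC as the Pearson correlation of truth/prediction indicator vectors."""
    import numpy as np

    truth = [1] * (tp + fn) + [0] * (tn + fp)
    pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
    matrix = np.corrcoef(truth, pred)
    return float(matrix[0, 1])


def trapezoid_auc_from_points(points) -> float:
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def exhaustive_pair_auc(scores, labels01) -> float:
    """AUC as P(score_pos > score_neg) + 0.5 P(tie) over all pairs."""
    pos = [s for s, y in zip(scores, labels01) if y == 1]
    neg = [s for s, y in zip(scores, labels01) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
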