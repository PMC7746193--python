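"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (hand-coded
genetic code, naive ECDF / pair-count / substring scans) so that it shares no
code path with the package implementation it checks.
"""

from __future__ import annotations

import math

# Standard genetic code, typed in by hand (not derived from any library).
_BASES = "TCAG"
_AA_ORDER = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
GENETIC_CODE = {
    a + b + c: _AA_ORDER[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def classify_oracle(codon: str, offset: int, alt: str) -> str:
    """Translate-and-compare classification of a single SNV."""
    ref_aa = GENETIC_CODE[codon]
    assert ref_aa != "*"
    mutated = codon[:offset] + alt + codon[offset + 1 :]
    alt_aa = GENETIC_CODE[mutated]
    if alt_aa == "*":
        return "nonsense"
    return "synonymous" if alt_aa == ref_aa else "missense"


def enumerate_oracle(codon: str) -> tuple[int, int, int]:
    """(synonymous, missense, nonsense) over the codon's 9 substitutions."""
    tally = {"synonymous": 0, "missense": 0, "nonsense": 0}
    for offset in range(3):
        for alt in "ACGT":
            if alt != codon[offset]:
                tally[classify_oracle(codon, offset, alt)] += 1
    return tally["synonymous"], tally["missense"], tally["nonsense"]


SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")


def ecdf(sample, t: float) -> float:
    return sum(1 for v in sample if v <= t) / len(sample)


def ks_oracle(x, y) -> float:
    """sup |ECDF_x - ECDF_y| evaluated on the pooled points."""
    return max(abs(ecdf(x, t) - ecdf(y, t)) for t in list(x) + list(y))


def mwu_oracle(x, y) -> float:
    """#{x_i > y_j} + 0.5 * #ties by exhaustive pair counting."""
    w = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                w += 1.0
            elif xi == yj:
                w += 0.5
    return w


def hotspot_oracle(positions, values, threshold: float, min_run: int):
    """All-substrings scan for maximal runs strictly above threshold.

    ``positions`` must be sorted; index gaps break runs.
    """
    n = len(positions)
    above = [
        math.isfinite(values[i]) and values[i] > threshold for i in range(n)
    ]
    runs = []
    for i in range(n):
        for j in range(i, n):
            # contiguous positions, all above, maximal on both sides
            if not all(above[i : j + 1]):
                continue
            if any(
                positions[k + 1] != positions[k] + 1 for k in range(i, j)
            ):
                continue
            left_closed = (
                i == 0
                or not above[i - 1]
                or positions[i - 1] != positions[i] - 1
            )
            right_closed = (
                j == n - 1
                or not above[j + 1]
                or positions[j + 1] != positions[j] + 1
            )
            if left_closed and right_closed and j - i + 1 >= min_run:
                runs.append((positions[i], positions[j]))
    return runs
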