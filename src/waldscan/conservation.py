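"""Per-column conservation scoring, 9-grade binning and percent identity.

Scores are a weighted-entropy statistic: for each alignment column mapped to a
reference residue, ``score = 1 - H / ln(20)`` where ``H`` is the Shannon
entropy of the weighted residue frequencies (gaps and unknown residues
excluded). Grades follow the familiar 1-9 convention with 9 the most
conserved; they come from nine equal-width bins spanning the observed score
range. This is a tree-free approximation of empirical-Bayes conservation
rates, not a reimplementation of them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AMINO_ACIDS, GAP, UNKNOWN, AlignmentSet, Domain, column_position_map

_SYMBOLS = AMINO_ACIDS + GAP + UNKNOWN
_SYM_INDEX = {s: i for i, s in enumerate(_SYMBOLS)}
_N_AA = len(AMINO_ACIDS)
_LN20 = math.log(20.0)

#: columns with a larger fraction of gaps/unknowns than this are not graded
DEFAULT_MAX_GAP_FRACTION = 0.5


def _encode(aln: AlignmentSet) -> np.ndarray:
    """Alignment as an int matrix (sequences x columns) over the 22 symbols."""
    flat = "".join(aln.sequences)
    codes = np.frombuffer(flat.encode("ascii"), dtype=np.uint8)
    lookup = np.zeros(128, dtype=np.int8)
    for sym, idx in _SYM_INDEX.items():
        lookup[ord(sym)] = idx
    return lookup[codes].reshape(aln.n_sequences, aln.n_columns)


def sequence_weights(aln: AlignmentSet) -> dict[str, float]:
    """Position-based sequence weights, normalized to sum to 1.

    Each column contributes ``1/(r * s_a)`` to every sequence carrying residue
    ``a`` there, with ``r`` the number of distinct residues in the column and
    ``s_a`` the number of sequences carrying ``a``. Gap and unknown cells
    contribute nothing.
    """
    matrix = _encode(aln)
    n_seq, n_col = matrix.shape
    counts = np.zeros((n_col, len(_SYMBOLS)), dtype=np.int64)
    cols = np.broadcast_to(np.arange(n_col), matrix.shape)
    np.add.at(counts, (cols.ravel(), matrix.ravel()), 1)

    residue_counts = counts[:, :_N_AA]
    r = (residue_counts > 0).sum(axis=1)  # distinct residues per column
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(
            residue_counts > 0, 1.0 / (r[:, None] * residue_counts), 0.0
        )
    # gap / unknown cells contribute 0
    contrib = np.concatenate(
        [contrib, np.zeros((n_col, len(_SYMBOLS) - _N_AA))], axis=1
    )
    raw = contrib[np.arange(n_col)[None, :], matrix].sum(axis=1)
    total = raw.sum()
    if total <= 0:  # alignment of pure gaps; fall back to equal weights
        raw = np.ones(n_seq)
        total = float(n_seq)
    weights = raw / total
    return dict(zip(aln.ids, weights.tolist()))


@dataclass(frozen=True)
class ConservationProfile:
    """Conservation score, 1-9 grade and gap fraction per reference position.

    ``grade`` is 0 where the score is undefined (gap fraction above the
    threshold or an empty column).
    """

    positions: np.ndarray
    scores: np.ndarray  # NaN where undefined
    grades: np.ndarray  # int, 0 = ungraded
    gap_fractions: np.ndarray

    def score_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.positions, name="score")

    def grade_series(self) -> pd.Series:
        return pd.Series(self.grades, index=self.positions, name="grade")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "score": self.scores,
                "grade": self.grades,
                "gap_fraction": self.gap_fractions,
            }
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tscore\tgrade\tgap_fraction\n")
            for pos, score, grade, gf in zip(
                self.positions, self.scores, self.grades, self.gap_fractions
            ):
                s = "NA" if math.isnan(score) else f"{score:.6f}"
                g = "NA" if grade == 0 else str(int(grade))
                fh.write(f"{pos}\t{s}\t{g}\t{gf:.6f}\n")


def column_scores(
    aln: AlignmentSet,
    weights: dict[str, float] | None = None,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted-entropy conservation scores on reference positions.

    Returns ``(positions, scores, gap_fractions)``; scores are NaN where the
    gap fraction exceeds ``max_gap_fraction`` or no residues are present.
    """
    if weights is None:
        weights = sequence_weights(aln)
    w = np.array([weights[sid] for sid in aln.ids], dtype=float)
    matrix = _encode(aln)
    n_seq, n_col = matrix.shape

    weighted = np.zeros((n_col, len(_SYMBOLS)))
    cols = np.broadcast_to(np.arange(n_col), matrix.shape)
    np.add.at(
        weighted,
        (cols.ravel(), matrix.ravel()),
        np.broadcast_to(w[:, None], matrix.shape).ravel(),
    )
    residue_mass = weighted[:, :_N_AA]
    totals = residue_mass.sum(axis=1)
    gap_fraction = (matrix >= _N_AA).mean(axis=0)  # '-' and 'X' both non-residues

    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = residue_mass / totals[:, None]
        plogp = np.where(freqs > 0, freqs * np.log(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    scores = 1.0 - entropy / _LN20
    scores[(totals <= 0) | (gap_fraction > max_gap_fraction)] = np.nan

    colmap = column_position_map(aln)
    ref_cols = np.array(sorted(colmap), dtype=int) - 1
    positions = np.array([colmap[c + 1] for c in ref_cols], dtype=int)
    return positions, scores[ref_cols], gap_fraction[ref_cols]


def grade_profile(scores: np.ndarray) -> np.ndarray:
    """Bin scores into 9 equal-width grades over [min, max]; 9 = most conserved.

    A constant profile maps to grade 5 everywhere. NaN scores get grade 0.
    """
    scores = np.asarray(scores, dtype=float)
    grades = np.zeros(scores.shape, dtype=int)
    defined = np.isfinite(scores)
    if not defined.any():
        return grades
    lo = scores[defined].min()
    hi = scores[defined].max()
    if hi == lo:
        grades[defined] = 5
        return grades
    raw = 1 + np.floor(9.0 * (scores[defined] - lo) / (hi - lo))
    grades[defined] = np.clip(raw, 1, 9).astype(int)
    return grades


def conservation_profile(
    aln: AlignmentSet,
    weights: dict[str, float] | None = None,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
) -> ConservationProfile:
    """Score every reference position and attach 1-9 grades."""
    positions, scores, gap_fractions = column_scores(aln, weights, max_gap_fraction)
    return ConservationProfile(
        positions=positions,
        scores=scores,
        grades=grade_profile(scores),
        gap_fractions=gap_fractions,
    )


def grade_distribution(profile: ConservationProfile, dom: Domain) -> dict[int, int]:
    """Counts per grade 1-9 inside a domain; key 0 counts ungraded positions."""
    counts = {g: 0 for g in range(10)}
    for pos, grade in zip(profile.positions, profile.grades):
        if dom.start <= pos <= dom.end:
            counts[int(grade)] += 1
    return counts


def pairwise_identity(aln: AlignmentSet, id_a: str, id_b: str) -> float:
    """Percent identity over columns where both rows are non-gap.

    Unknown residues ('X') never count as a match. Raises ``ValueError`` when
    no jointly non-gap column exists.
    """
    seq_a = aln.sequence(id_a)
    seq_b = aln.sequence(id_b)
    shared = 0
    matches = 0
    for a, b in zip(seq_a, seq_b):
        if a == GAP or b == GAP:
            continue
        shared += 1
        if a == b and a != UNKNOWN:
            matches += 1
    if shared == 0:
        raise ValueError(f"{id_a} and {id_b} share no jointly non-gap columns")
    return 100.0 * matches / shared
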