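"""Per-residue dN/dS mutational-tolerance landscape.

The per-position ratio is the observed missense:synonymous SNV ratio divided
by the possible missense:synonymous ratio obtained by enumerating all nine
single-nucleotide substitutions of each codon, i.e. a composition-corrected
tolerance score. Counts are pooled over a sliding window of codons (window 1
gives raw per-codon values), with a pseudocount keeping the ratio finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .core import (
    CODON_TO_AA,
    MISSENSE,
    NONSENSE,
    NUCLEOTIDES,
    SYNONYMOUS,
    CodingSequence,
    Domain,
    VariantTable,
    classify_snv,
)

DEFAULT_WINDOW = 21
DEFAULT_PSEUDOCOUNT = 0.5


@lru_cache(maxsize=None)
def enumerate_codon_snvs(codon: str) -> tuple[int, int, int]:
    """Counts of (synonymous, missense, nonsense) among the codon's 9 SNVs."""
    codon = codon.upper()
    if CODON_TO_AA.get(codon, "*") == "*":
        raise ValueError(f"not a sense codon: {codon!r}")
    syn = mis = non = 0
    for offset in range(3):
        for alt in NUCLEOTIDES:
            if alt == codon[offset]:
                continue
            consequence = classify_snv(codon, offset, alt)
            if consequence == SYNONYMOUS:
                syn += 1
            elif consequence == MISSENSE:
                mis += 1
            else:
                non += 1
    assert syn + mis + non == 9
    return syn, mis, non


def possible_counts(cds: CodingSequence) -> pd.DataFrame:
    """Per-residue possible SNV counts: columns possible_syn/mis/non."""
    rows = [enumerate_codon_snvs(codon) for codon in cds.codons()]
    frame = pd.DataFrame(
        rows,
        columns=["possible_syn", "possible_mis", "possible_non"],
        index=pd.RangeIndex(1, cds.protein_length + 1, name="position"),
    )
    return frame


def observed_counts(variants: VariantTable, protein_length: int) -> pd.DataFrame:
    """Per-residue observed missense/synonymous SNV presence counts.

    Every distinct SNV record counts once, whatever its allele count; nonsense
    and frameshift records contribute to neither column.
    """
    frame = pd.DataFrame(
        0,
        columns=["obs_mis", "obs_syn"],
        index=pd.RangeIndex(1, protein_length + 1, name="position"),
    )
    for record in variants:
        if not record.is_snv or not 1 <= record.protein_pos <= protein_length:
            continue
        if record.consequence == MISSENSE:
            frame.at[record.protein_pos, "obs_mis"] += 1
        elif record.consequence == SYNONYMOUS:
            frame.at[record.protein_pos, "obs_syn"] += 1
    return frame


@dataclass(frozen=True)
class ToleranceLandscape:
    """Windowed per-position dN/dS with the underlying counts."""

    table: pd.DataFrame  # index: position; possible_*, obs_*, dnds (NaN = undefined)
    window: int
    pseudocount: float

    @property
    def dnds(self) -> pd.Series:
        return self.table["dnds"]

    @property
    def n_undefined(self) -> int:
        return int(self.table["dnds"].isna().sum())

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "position\tpossible_mis\tpossible_syn\tpossible_non\t"
                "obs_mis\tobs_syn\tdnds\n"
            )
            for pos, row in self.table.iterrows():
                dnds = "NA" if np.isnan(row["dnds"]) else f"{row['dnds']:.6f}"
                fh.write(
                    f"{pos}\t{int(row['possible_mis'])}\t{int(row['possible_syn'])}\t"
                    f"{int(row['possible_non'])}\t{int(row['obs_mis'])}\t"
                    f"{int(row['obs_syn'])}\t{dnds}\n"
                )


def _window_sums(values: np.ndarray, half: int) -> np.ndarray:
    """Sliding-window sums truncated at the sequence ends."""
    cumulative = np.concatenate([[0], np.cumsum(values)])
    n = len(values)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return cumulative[hi + 1] - cumulative[lo]


def dnds_landscape(
    possible: pd.DataFrame,
    observed: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ToleranceLandscape:
    """Composition-corrected dN/dS per position.

    For position ``i`` let ``m, s`` be observed missense/synonymous counts and
    ``M, S`` the possible counts summed over the window centred at ``i``
    (truncated at the protein ends); then
    ``dnds_i = ((m + c) / (s + c)) / (M / S)``. Positions whose window has
    ``M == 0`` or ``S == 0`` are NaN.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not possible.index.equals(observed.index):
        raise ValueError("possible and observed tables cover different positions")
    half = window // 2
    m = _window_sums(observed["obs_mis"].to_numpy(float), half)
    s = _window_sums(observed["obs_syn"].to_numpy(float), half)
    big_m = _window_sums(possible["possible_mis"].to_numpy(float), half)
    big_s = _window_sums(possible["possible_syn"].to_numpy(float), half)
    with np.errstate(divide="ignore", invalid="ignore"):
        dnds = ((m + pseudocount) / (s + pseudocount)) / (big_m / big_s)
    dnds[(big_m == 0) | (big_s == 0)] = np.nan
    table = pd.concat([possible, observed], axis=1)
    table["dnds"] = dnds
    return ToleranceLandscape(table=table, window=window, pseudocount=pseudocount)


def domain_dnds_values(
    landscape: ToleranceLandscape, dom: Domain, stride: int = 1
) -> tuple[pd.Series, int]:
    """Defined dN/dS values inside a domain, plus the count of undefined ones.

    ``stride`` subsamples every ``stride``-th position (from the domain start);
    use the landscape's window as the stride to obtain approximately
    independent values from a smoothed landscape.
    """
    series = landscape.dnds.loc[dom.start : dom.end]
    if stride > 1:
        series = series.iloc[::stride]
    n_undefined = int(series.isna().sum())
    return series.dropna(), n_undefined
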