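"""Core domain types, coordinate conventions and file-format I/O.

Conventions used throughout the package:

* Protein coordinates are 1-based inclusive; CDS coordinates are 1-based.
* Codon ``i`` covers CDS nucleotides ``3i-2 .. 3i`` and encodes residue ``i``.
* The alignment gap symbol is ``'-'``; the unknown residue ``'X'`` is accepted
  but never counted as a residue match.
* Tabular files are tab-separated, ``'.'`` decimal, lines starting with ``'#'``
  are comments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
MSA_ALPHABET = frozenset(AMINO_ACIDS + GAP + UNKNOWN)
NUCLEOTIDES = "ACGT"

SYNONYMOUS = "synonymous"
MISSENSE = "missense"
NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"


class FormatError(ValueError):
    """Malformed input file."""


class ConsistencyError(ValueError):
    """Inputs are individually valid but mutually inconsistent."""


def _codon_to_aa(table_id: int = 1) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


#: codon -> single-letter amino acid, stops mapped to '*'
CODON_TO_AA: dict[str, str] = _codon_to_aa()


def classify_snv(codon: str, offset: int, alt_nt: str, table_id: int = 1) -> str:
    """Classify the single-nucleotide substitution ``codon[offset] -> alt_nt``.

    Parameters
    ----------
    codon:
        Sense codon (three of ``ACGT``).
    offset:
        0-based position within the codon.
    alt_nt:
        Substituted nucleotide, different from the reference one.

    Returns
    -------
    One of ``"synonymous"``, ``"missense"``, ``"nonsense"``.
    """
    codon = codon.upper()
    alt_nt = alt_nt.upper()
    mapping = CODON_TO_AA if table_id == 1 else _codon_to_aa(table_id)
    aa = mapping.get(codon)
    if aa is None or aa == "*":
        raise ValueError(f"not a sense codon: {codon!r}")
    if not 0 <= offset <= 2:
        raise ValueError(f"codon offset out of range: {offset}")
    if alt_nt not in NUCLEOTIDES:
        raise ValueError(f"invalid nucleotide: {alt_nt!r}")
    if alt_nt == codon[offset]:
        raise ValueError("alt nucleotide equals the reference nucleotide")
    alt_codon = codon[:offset] + alt_nt + codon[offset + 1 :]
    alt_aa = mapping[alt_codon]
    if alt_aa == "*":
        return NONSENSE
    return SYNONYMOUS if alt_aa == aa else MISSENSE


@dataclass(frozen=True)
class Domain:
    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid domain bounds {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def positions(self) -> range:
        return range(self.start, self.end + 1)

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class ProteinAnnotation:
    """Protein length plus a set of non-overlapping domain intervals."""

    protein_id: str
    length: int
    domains: tuple[Domain, ...]

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("protein length must be positive")
        seen: list[Domain] = []
        for dom in self.domains:
            if dom.end > self.length:
                raise ValueError(
                    f"domain {dom.name} ({dom.start}..{dom.end}) exceeds protein "
                    f"length {self.length}"
                )
            for other in seen:
                if dom.start <= other.end and other.start <= dom.end:
                    raise ValueError(f"domains {other.name} and {dom.name} overlap")
            seen.append(dom)

    def domain(self, name: str) -> Domain:
        for dom in self.domains:
            if dom.name == name:
                return dom
        raise KeyError(f"no domain named {name!r}")


def read_annotation(path: str | Path) -> ProteinAnnotation:
    with open(path) as fh:
        payload = json.load(fh)
    try:
        domains = tuple(
            Domain(d["name"], int(d["start"]), int(d["end"]))
            for d in payload["domains"]
        )
        return ProteinAnnotation(payload["protein_id"], int(payload["length"]), domains)
    except KeyError as exc:
        raise FormatError(f"annotation JSON missing key {exc}") from exc


def write_annotation(annotation: ProteinAnnotation, path: str | Path) -> None:
    payload = {
        "protein_id": annotation.protein_id,
        "length": annotation.length,
        "domains": [
            {"name": d.name, "start": d.start, "end": d.end}
            for d in annotation.domains
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


@dataclass(frozen=True)
class AlignmentSet:
    """An aligned set of protein sequences with a designated reference row."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    reference_id: str

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(self.ids) < 2:
            raise FormatError("alignment needs at least 2 records")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")
        if self.reference_id not in self.ids:
            raise KeyError(f"reference id {self.reference_id!r} not in alignment")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate sequence ids in alignment")
        for sid, seq in zip(self.ids, self.sequences):
            bad = set(seq) - MSA_ALPHABET
            if bad:
                raise FormatError(f"illegal symbols {sorted(bad)} in record {sid!r}")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def sequence(self, sequence_id: str) -> str:
        try:
            return self.sequences[self.ids.index(sequence_id)]
        except ValueError as exc:
            raise KeyError(f"no sequence {sequence_id!r}") from exc

    @property
    def reference_sequence(self) -> str:
        return self.sequence(self.reference_id)

    @property
    def reference_length(self) -> int:
        ref = self.reference_sequence
        return sum(1 for c in ref if c != GAP)


def read_msa(path: str | Path, reference_id: str) -> AlignmentSet:
    """Read an aligned FASTA file into an :class:`AlignmentSet`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise FormatError(f"{path}: alignment needs at least 2 records")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    return AlignmentSet(ids, seqs, reference_id)


def write_msa(aln: AlignmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.sequences):
            fh.write(f">{sid}\n{seq}\n")


def column_position_map(aln: AlignmentSet) -> dict[int, int]:
    """Map alignment columns (1-based) to reference residue positions (1-based).

    Columns where the reference row holds a gap are absent from the map.
    """
    mapping: dict[int, int] = {}
    pos = 0
    for col, symbol in enumerate(aln.reference_sequence, start=1):
        if symbol != GAP:
            pos += 1
            mapping[col] = pos
    return mapping


@dataclass(frozen=True)
class CodingSequence:
    """In-frame nucleotide sequence of the reference protein (no stop codon)."""

    nucleotides: str
    codon_table: int = 1

    def __post_init__(self) -> None:
        nt = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", nt)
        if len(nt) % 3 != 0:
            raise FormatError(f"CDS length {len(nt)} not divisible by 3")
        bad = set(nt) - set(NUCLEOTIDES)
        if bad:
            raise FormatError(f"illegal nucleotides {sorted(bad)}")
        protein = str(Seq(nt).translate(table=self.codon_table))
        if "*" in protein:
            raise FormatError(f"internal stop codon at residue {protein.index('*') + 1}")

    @property
    def protein_length(self) -> int:
        return len(self.nucleotides) // 3

    @property
    def protein(self) -> str:
        return str(Seq(self.nucleotides).translate(table=self.codon_table))

    def codon(self, position: int) -> str:
        """Codon encoding residue ``position`` (1-based)."""
        if not 1 <= position <= self.protein_length:
            raise IndexError(f"residue position {position} out of range")
        return self.nucleotides[3 * position - 3 : 3 * position]

    def codons(self) -> list[str]:
        nt = self.nucleotides
        return [nt[i : i + 3] for i in range(0, len(nt), 3)]


def read_cds_fasta(path: str | Path) -> CodingSequence:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise FormatError(f"{path}: expected exactly one CDS record, found {len(records)}")
    return CodingSequence(str(records[0].seq).upper())


def write_cds_fasta(cds: CodingSequence, path: str | Path, name: str = "cds") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n{cds.nucleotides}\n")


@dataclass(frozen=True)
class VariantRecord:
    cds_pos: int
    ref_nt: str
    alt_nt: str
    consequence: str
    protein_pos: int
    allele_count: int
    hom_count: int

    def __post_init__(self) -> None:
        if self.hom_count > self.allele_count:
            raise ValueError("hom_count exceeds allele_count")
        if self.consequence not in (SYNONYMOUS, MISSENSE, NONSENSE, FRAMESHIFT):
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_nt) == 1 and len(self.alt_nt) == 1


@dataclass(frozen=True)
class VariantTable:
    records: tuple[VariantRecord, ...]
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_consequence(self, consequence: str) -> tuple[VariantRecord, ...]:
        return tuple(r for r in self.records if r.consequence == consequence)


_VARIANT_COLUMNS = ("cds_pos", "ref_nt", "alt_nt", "allele_count", "hom_count")


def read_variant_table(path: str | Path, cds: CodingSequence | None = None) -> VariantTable:
    """Read a population variant TSV, reclassifying consequences from ``cds``.

    Rows whose ``ref_nt`` contradicts the coding sequence are dropped; the
    number of dropped rows is reported on the returned table.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records: list[VariantRecord] = []
    rejected = 0
    for row in df.itertuples(index=False):
        try:
            cds_pos = int(row.cds_pos)
            allele_count = int(row.allele_count)
            hom_count = int(row.hom_count)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric field in row {row}") from exc
        ref_nt = str(row.ref_nt).upper()
        alt_nt = str(row.alt_nt).upper()
        protein_pos = math.ceil(cds_pos / 3)
        is_snv = len(ref_nt) == 1 and len(alt_nt) == 1
        if cds is not None and is_snv:
            if not 1 <= cds_pos <= len(cds.nucleotides):
                rejected += 1
                continue
            if cds.nucleotides[cds_pos - 1] != ref_nt:
                rejected += 1
                continue
            offset = (cds_pos - 1) % 3
            consequence = classify_snv(cds.codon(protein_pos), offset, alt_nt)
        elif not is_snv:
            consequence = FRAMESHIFT
        else:
            consequence = str(getattr(row, "consequence", "")).strip()
            if consequence not in (SYNONYMOUS, MISSENSE, NONSENSE, FRAMESHIFT):
                raise FormatError(
                    f"{path}: no CDS given and no usable consequence column"
                )
        records.append(
            VariantRecord(
                cds_pos=cds_pos,
                ref_nt=ref_nt,
                alt_nt=alt_nt,
                consequence=consequence,
                protein_pos=protein_pos,
                allele_count=allele_count,
                hom_count=hom_count,
            )
        )
    return VariantTable(tuple(records), n_rejected=rejected)


def write_variant_table(table: VariantTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cds_pos\tref_nt\talt_nt\tallele_count\thom_count\tconsequence\n")
        for r in table.records:
            fh.write(
                f"{r.cds_pos}\t{r.ref_nt}\t{r.alt_nt}\t{r.allele_count}\t"
                f"{r.hom_count}\t{r.consequence}\n"
            )


@dataclass(frozen=True)
class ScoreMatrix:
    """Per-position x per-substitution pathogenicity scores on a 0-100 scale.

    ``scores[position]`` maps each of the 19 non-reference amino acids to its
    score; the reference amino acid at a position carries no entry.
    """

    protein_id: str
    scores: Mapping[int, Mapping[str, float]]

    def __post_init__(self) -> None:
        for pos, subs in self.scores.items():
            if len(subs) != 19:
                raise ConsistencyError(
                    f"position {pos}: expected 19 substitution scores, got {len(subs)}"
                )
            for aa, value in subs.items():
                if aa not in AMINO_ACIDS:
                    raise ValueError(f"position {pos}: invalid amino acid {aa!r}")
                if not 0.0 <= value <= 100.0:
                    raise ValueError(
                        f"position {pos} substitution {aa}: score {value} outside [0, 100]"
                    )

    @property
    def positions(self) -> list[int]:
        return sorted(self.scores)

    def position_means(self) -> dict[int, float]:
        """Arithmetic mean of the 19 substitution scores at each position."""
        return {
            pos: sum(subs.values()) / 19.0 for pos, subs in sorted(self.scores.items())
        }


def read_score_matrix(path: str | Path, reference_protein: str) -> ScoreMatrix:
    """Read a saturation score TSV (rows = positions, columns = amino acids).

    A column for the position's reference amino acid, if present, is dropped.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "pos" not in df.columns:
        raise FormatError(f"{path}: missing 'pos' column")
    aa_columns = [c for c in df.columns if c in set(AMINO_ACIDS)]
    if len(aa_columns) < 19:
        raise FormatError(f"{path}: expected >=19 amino-acid columns, got {len(aa_columns)}")
    if len(df) != len(reference_protein):
        raise ConsistencyError(
            f"{path}: {len(df)} score rows but reference protein has "
            f"{len(reference_protein)} residues"
        )
    scores: dict[int, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        pos = int(getattr(row, "pos"))
        if not 1 <= pos <= len(reference_protein):
            raise ConsistencyError(f"{path}: position {pos} outside reference protein")
        ref_aa = reference_protein[pos - 1]
        subs: dict[str, float] = {}
        for aa in aa_columns:
            value = getattr(row, aa)
            if aa == ref_aa or (isinstance(value, float) and math.isnan(value)):
                continue
            value = float(value)
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{path}: score {value} at position {pos} outside [0, 100]")
            subs[aa] = value
        scores[pos] = subs
    return ScoreMatrix(protein_id="", scores=scores)


def write_score_matrix(matrix: ScoreMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\t" + "\t".join(AMINO_ACIDS) + "\n")
        for pos in matrix.positions:
            subs = matrix.scores[pos]
            cells = [str(subs[aa]) if aa in subs else "NA" for aa in AMINO_ACIDS]
            fh.write(f"{pos}\t" + "\t".join(cells) + "\n")


def slice_by_domain(
    values: Mapping[int, float] | pd.Series,
    dom: Domain,
    protein_length: int | None = None,
) -> pd.Series:
    """Restrict a position-indexed series to a domain's closed interval.

    Positions absent from ``values`` are silently dropped; order follows
    ascending position.
    """
    if protein_length is not None and dom.end > protein_length:
        raise IndexError(
            f"domain {dom.name} ({dom.start}..{dom.end}) outside protein of "
            f"length {protein_length}"
        )
    if isinstance(values, pd.Series):
        items = values.items()
    else:
        items = values.items()
    pairs = sorted((pos, v) for pos, v in items if dom.start <= pos <= dom.end)
    return pd.Series(
        [v for _, v in pairs], index=[p for p, _ in pairs], dtype=float, name=dom.name
    )
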