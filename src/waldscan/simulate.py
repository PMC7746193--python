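"""Synthetic input-bundle generator with known ground truth.

Emulates the statistical structure the analysis assumes: gamma site-rate
heterogeneity modulated per domain, a star-phylogeny ortholog alignment,
independent per-SNV population sampling thinned by per-domain purifying
selection, and a saturation score matrix anti-correlated with site rate and
carrying planted high-score stretches.

Each component draws from its own deterministic substream of the master seed,
so adding a component never perturbs the others.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .core import (
    AMINO_ACIDS,
    CODON_TO_AA,
    MISSENSE,
    NONSENSE,
    NUCLEOTIDES,
    SYNONYMOUS,
    AlignmentSet,
    CodingSequence,
    Domain,
    ProteinAnnotation,
    ScoreMatrix,
    VariantRecord,
    VariantTable,
    classify_snv,
    write_annotation,
    write_cds_fasta,
    write_msa,
    write_score_matrix,
    write_variant_table,
)

_SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon in _SENSE_CODONS:
    _AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], []).append(_codon)

#: per-codon (offset, alt, consequence) for all 9 SNVs, precomputed once
_CODON_SNVS: dict[str, list[tuple[int, str, str]]] = {
    codon: [
        (offset, alt, classify_snv(codon, offset, alt))
        for offset in range(3)
        for alt in NUCLEOTIDES
        if alt != codon[offset]
    ]
    for codon in _SENSE_CODONS
}


@dataclass(frozen=True)
class DomainSpec:
    name: str
    start: int
    end: int
    rate_multiplier: float = 1.0  # site-rate scaling (conservation structure)
    missense_retention: float = 1.0  # fraction of missense SNVs surviving selection


@dataclass(frozen=True)
class PlantedStretch:
    start: int
    end: int
    boost: float


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    protein_id: str = "SYNPROT"
    protein_length: int = 521
    domains: tuple[DomainSpec, ...] = (
        DomainSpec("D1", 146, 337, rate_multiplier=0.5, missense_retention=0.2),
        DomainSpec("D2", 341, 521, rate_multiplier=1.5, missense_retention=0.8),
    )
    n_taxa: int = 30
    mean_divergence: float = 0.5
    divergences: tuple[float, ...] | None = None  # explicit per-taxon levels
    gamma_shape: float = 1.0
    background_rate: float = 1.0
    background_retention: float = 1.0
    syn_inclusion: float = 0.3  # per-SNV inclusion probability (synonymous)
    nonsense_retention: float = 0.1
    hom_probability: float = 0.05
    allele_geometric_p: float = 0.3
    score_beta0: float = -2.0
    score_beta1: float = 3.5
    score_noise_sd: float = 8.0
    planted_stretches: tuple[PlantedStretch, ...] = (
        PlantedStretch(170, 177, 45.0),
        PlantedStretch(217, 219, 45.0),
        PlantedStretch(259, 261, 45.0),
        PlantedStretch(377, 379, 45.0),
    )
    gap_rate: float = 0.0

    def __post_init__(self) -> None:
        for prob in (self.syn_inclusion, self.nonsense_retention, self.background_retention):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for dom in self.domains:
            if not 0.0 < dom.missense_retention <= 1.0:
                raise ValueError(f"retention for {dom.name} must be in (0, 1]")
        for stretch in self.planted_stretches:
            if not any(d.start <= stretch.start and stretch.end <= d.end for d in self.domains):
                raise ValueError(
                    f"planted stretch {stretch.start}..{stretch.end} not inside a domain"
                )

    @property
    def annotation(self) -> ProteinAnnotation:
        return ProteinAnnotation(
            self.protein_id,
            self.protein_length,
            tuple(Domain(d.name, d.start, d.end) for d in self.domains),
        )

    def taxon_divergences(self) -> np.ndarray:
        if self.divergences is not None:
            d = np.asarray(self.divergences, dtype=float)
            if len(d) != self.n_taxa or (d < 0).any():
                raise ValueError("divergences must give one nonnegative value per taxon")
            return d
        # evenly spread levels with the requested mean
        return np.linspace(0.2, 1.8, self.n_taxa) * self.mean_divergence

    def domain_of(self, position: int) -> DomainSpec | None:
        for dom in self.domains:
            if dom.start <= position <= dom.end:
                return dom
        return None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        domains = payload.pop("domains", None)
        stretches = payload.pop("planted_stretches", None)
        kwargs = dict(payload)
        if domains is not None:
            kwargs["domains"] = tuple(DomainSpec(**d) for d in domains)
        if stretches is not None:
            kwargs["planted_stretches"] = tuple(PlantedStretch(**s) for s in stretches)
        return cls(**kwargs)


def null_config(seed: int = 0, protein_length: int = 2562) -> SyntheticConfig:
    """A no-domain-difference configuration for calibration studies."""
    third = protein_length // 2 - 21
    return SyntheticConfig(
        seed=seed,
        protein_length=protein_length,
        domains=(
            DomainSpec("D1", 1, third, rate_multiplier=1.0, missense_retention=0.2),
            DomainSpec(
                "D2",
                third + 1,
                2 * third,
                rate_multiplier=1.0,
                missense_retention=0.2,
            ),
        ),
        planted_stretches=(),
    )


def _rng(seed: int, component: str) -> np.random.Generator:
    """Deterministic per-component substream of the master seed."""
    digest = hashlib.sha256(component.encode()).digest()
    offset = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, offset]))


def simulate_protein_and_cds(cfg: SyntheticConfig) -> tuple[str, CodingSequence]:
    """Uniform random protein; codon drawn uniformly among synonymous codons."""
    rng = _rng(cfg.seed, "protein")
    aa_idx = rng.integers(0, len(AMINO_ACIDS), size=cfg.protein_length)
    protein = "".join(AMINO_ACIDS[i] for i in aa_idx)
    codons = []
    for aa in protein:
        options = _AA_TO_CODONS[aa]
        codons.append(options[rng.integers(0, len(options))])
    return protein, CodingSequence("".join(codons))


def site_rates(cfg: SyntheticConfig) -> np.ndarray:
    """Gamma(shape, mean 1) site rates scaled by the domain multiplier."""
    rng = _rng(cfg.seed, "rates")
    g = rng.gamma(cfg.gamma_shape, 1.0 / cfg.gamma_shape, size=cfg.protein_length)
    multipliers = np.full(cfg.protein_length, cfg.background_rate)
    for dom in cfg.domains:
        multipliers[dom.start - 1 : dom.end] = dom.rate_multiplier
    return g * multipliers


def simulate_msa(
    cfg: SyntheticConfig, reference: str, rates: np.ndarray
) -> AlignmentSet:
    """Star-phylogeny alignment: site i on taxon k differs from the reference
    with probability ``1 - exp(-r_i * d_k)``, substituting a uniform other
    residue. Gapless unless ``gap_rate`` > 0."""
    rng = _rng(cfg.seed, "msa")
    divergences = cfg.taxon_divergences()
    ref_codes = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    ref_idx = np.array([aa_index[chr(c)] for c in ref_codes])

    p_diff = 1.0 - np.exp(-np.outer(divergences, rates))
    mutate = rng.random(p_diff.shape) < p_diff
    shift = rng.integers(1, len(AMINO_ACIDS), size=p_diff.shape)
    taxa_idx = np.where(mutate, (ref_idx[None, :] + shift) % len(AMINO_ACIDS), ref_idx)
    aa_array = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)
    rows = aa_array[taxa_idx]
    if cfg.gap_rate > 0:
        gaps = rng.random(rows.shape) < cfg.gap_rate
        rows = np.where(gaps, ord("-"), rows)
    ids = [cfg.protein_id] + [f"taxon{k + 1:03d}" for k in range(cfg.n_taxa)]
    seqs = [reference] + [bytes(row).decode("ascii") for row in rows]
    return AlignmentSet(tuple(ids), tuple(seqs), cfg.protein_id)


_CONSEQ_CODE = {SYNONYMOUS: 0, MISSENSE: 1, NONSENSE: 2}


def simulate_population_variants(cfg: SyntheticConfig, cds: CodingSequence) -> VariantTable:
    """Independent per-SNV sampling thinned by per-domain selection.

    Each of the 9 SNVs of every codon is included with probability
    ``syn_inclusion`` (synonymous), ``syn_inclusion * retention(domain)``
    (missense) or ``syn_inclusion * nonsense_retention`` (nonsense).
    """
    rng = _rng(cfg.seed, "variants")
    length = cds.protein_length
    codons = cds.codons()

    offsets = np.empty(9 * length, dtype=np.int64)
    alts = np.empty(9 * length, dtype="U1")
    conseq = np.empty(9 * length, dtype=np.int64)
    for i, codon in enumerate(codons):
        for j, (offset, alt, consequence) in enumerate(_CODON_SNVS[codon]):
            k = 9 * i + j
            offsets[k] = offset
            alts[k] = alt
            conseq[k] = _CONSEQ_CODE[consequence]

    retention = np.full(length, cfg.background_retention)
    for dom in cfg.domains:
        retention[dom.start - 1 : dom.end] = dom.missense_retention
    retention_per_snv = np.repeat(retention, 9)
    probs = np.where(
        conseq == 0,
        cfg.syn_inclusion,
        np.where(
            conseq == 1,
            cfg.syn_inclusion * retention_per_snv,
            cfg.syn_inclusion * cfg.nonsense_retention,
        ),
    )
    keep = rng.random(9 * length) < probs
    idx = np.flatnonzero(keep)
    alleles = 1 + rng.geometric(cfg.allele_geometric_p, size=idx.size)
    homs = rng.random(idx.size) < cfg.hom_probability

    code_to_name = {v: k for k, v in _CONSEQ_CODE.items()}
    records = []
    for k, allele_count, hom in zip(idx, alleles, homs):
        codon_i = int(k // 9)
        offset = int(offsets[k])
        cds_pos = 3 * codon_i + offset + 1
        hom_count = 1 if hom else 0
        records.append(
            VariantRecord(
                cds_pos=cds_pos,
                ref_nt=cds.nucleotides[cds_pos - 1],
                alt_nt=str(alts[k]),
                consequence=code_to_name[int(conseq[k])],
                protein_pos=codon_i + 1,
                allele_count=int(max(allele_count, 2 * hom_count)),
                hom_count=hom_count,
            )
        )
    return VariantTable(tuple(records))


def simulate_score_matrix(
    cfg: SyntheticConfig, reference: str, rates: np.ndarray
) -> ScoreMatrix:
    """Scores anti-correlated with site rate, plus planted stretch boosts.

    base_i = 100 * logistic(beta0 + beta1 * (1 - rate_i / max rate)); each of
    the 19 substitutions adds Gaussian noise; planted boosts apply before
    clamping to [0, 100].
    """
    rng = _rng(cfg.seed, "scores")
    norm = rates / rates.max() if rates.max() > 0 else rates
    logit = cfg.score_beta0 + cfg.score_beta1 * (1.0 - norm)
    base = 100.0 / (1.0 + np.exp(-logit))
    boost = np.zeros(cfg.protein_length)
    for stretch in cfg.planted_stretches:
        boost[stretch.start - 1 : stretch.end] += stretch.boost
    noise = rng.normal(0.0, cfg.score_noise_sd, size=(cfg.protein_length, 19))
    raw = base[:, None] + boost[:, None] + noise
    clamped = np.clip(raw, 0.0, 100.0)

    scores: dict[int, dict[str, float]] = {}
    for pos in range(1, cfg.protein_length + 1):
        ref_aa = reference[pos - 1]
        others = [aa for aa in AMINO_ACIDS if aa != ref_aa]
        scores[pos] = {
            aa: round(float(v), 4) for aa, v in zip(others, clamped[pos - 1])
        }
    return ScoreMatrix(protein_id=cfg.protein_id, scores=scores)


@dataclass(frozen=True)
class SyntheticDataset:
    config: SyntheticConfig
    protein: str
    cds: CodingSequence
    alignment: AlignmentSet
    variants: VariantTable
    matrix: ScoreMatrix
    rates: np.ndarray

    @property
    def annotation(self) -> ProteinAnnotation:
        return self.config.annotation

    def truth(self) -> dict:
        return {
            "seed": self.config.seed,
            "protein_id": self.config.protein_id,
            "protein_length": self.config.protein_length,
            "site_rates": [round(float(r), 6) for r in self.rates],
            "domains": [
                {
                    "name": d.name,
                    "start": d.start,
                    "end": d.end,
                    "rate_multiplier": d.rate_multiplier,
                    "missense_retention": d.missense_retention,
                }
                for d in self.config.domains
            ],
            "planted_stretches": [
                {"start": s.start, "end": s.end, "boost": s.boost}
                for s in self.config.planted_stretches
            ],
            "syn_inclusion": self.config.syn_inclusion,
            "nonsense_retention": self.config.nonsense_retention,
        }


def simulate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate the complete in-memory bundle for a configuration."""
    protein, cds = simulate_protein_and_cds(cfg)
    rates = site_rates(cfg)
    alignment = simulate_msa(cfg, protein, rates)
    variants = simulate_population_variants(cfg, cds)
    matrix = simulate_score_matrix(cfg, protein, rates)
    return SyntheticDataset(
        config=cfg,
        protein=protein,
        cds=cds,
        alignment=alignment,
        variants=variants,
        matrix=matrix,
        rates=rates,
    )


def generate_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> SyntheticDataset:
    """Write a full input bundle plus ground truth; same seed, same bytes.

    Files: ``msa.fasta``, ``cds.fasta``, ``variants.tsv``, ``scores.tsv``,
    ``domains.json``, ``truth.json``.
    """
    dataset = simulate_dataset(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_msa(dataset.alignment, out / "msa.fasta")
    write_cds_fasta(dataset.cds, out / "cds.fasta", name=cfg.protein_id)
    write_variant_table(dataset.variants, out / "variants.tsv")
    write_score_matrix(dataset.matrix, out / "scores.tsv")
    write_annotation(dataset.annotation, out / "domains.json")
    (out / "truth.json").write_text(
        json.dumps(dataset.truth(), indent=2, sort_keys=True) + "\n"
    )
    return dataset
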