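"""Domain-comparison statistics, the composite verdict and the pipeline driver.

Conventions: no continuity/Yates correction, two-sided asymptotic p-values,
no multiple-testing adjustment; the Mann-Whitney statistic follows the
"first sample greater" pair-count convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import conservation, hotspots, tolerance
from .core import (
    MISSENSE,
    AlignmentSet,
    CodingSequence,
    ConsistencyError,
    Domain,
    ProteinAnnotation,
    ScoreMatrix,
    VariantTable,
    read_annotation,
    read_cds_fasta,
    read_msa,
    read_score_matrix,
    read_variant_table,
    slice_by_domain,
)

logger = logging.getLogger("waldscan")

GOF_MODELS = ("equal", "length", "possible")


def chi2_homogeneity(table: Sequence[Sequence[float]] | np.ndarray):
    """Pearson homogeneity chi-squared on an r x c count table.

    All-zero columns are dropped before testing; df = (r-1)(c-1) on the
    reduced table; no continuity correction.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise ValueError("expected a 2-D count table")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    counts = counts[:, counts.sum(axis=0) > 0]
    counts = counts[counts.sum(axis=1) > 0, :]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("degenerate table after dropping empty margins")
    result = stats.chi2_contingency(counts, correction=False)
    return float(result.statistic), int(result.dof), float(result.pvalue)


def chi2_goodness_of_fit(
    observed: Sequence[float],
    model: str = "equal",
    lengths: Sequence[int] | None = None,
    possible: Sequence[float] | None = None,
):
    """Goodness-of-fit chi-squared of per-domain counts against a model.

    ``model`` selects the expected-count weights: ``equal`` (uniform across
    domains), ``length`` (proportional to domain residue counts) or
    ``possible`` (proportional to possible-SNV opportunity).
    """
    observed = np.asarray(observed, dtype=float)
    if model not in GOF_MODELS:
        raise ValueError(f"unknown expectation model {model!r}")
    if model == "equal":
        weights = np.ones_like(observed)
    elif model == "length":
        if lengths is None:
            raise ValueError("model 'length' needs domain lengths")
        weights = np.asarray(lengths, dtype=float)
    else:
        if possible is None:
            raise ValueError("model 'possible' needs possible-SNV counts")
        weights = np.asarray(possible, dtype=float)
    expected = observed.sum() * weights / weights.sum()
    if (expected <= 0).any():
        raise ValueError("zero expected count under the chosen model")
    statistic = float(((observed - expected) ** 2 / expected).sum())
    df = len(observed) - 1
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def ks_two_sample(x: Sequence[float], y: Sequence[float], method: str = "asymp"):
    """Two-sided two-sample Kolmogorov-Smirnov: D = sup |ECDF_x - ECDF_y|."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    result = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(result.statistic), float(result.pvalue)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]):
    """Mann-Whitney with W = #{x_i > y_j} + 0.5 * #ties (first-sample-greater).

    p-value is the tie-corrected two-sided normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    result = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(result.statistic), float(result.pvalue)


def oneway_anova_tukey(groups: Mapping[str, Sequence[float]]):
    """One-way ANOVA F plus Tukey HSD adjusted pairwise p-values."""
    names = list(groups)
    samples = [np.asarray(groups[n], dtype=float) for n in names]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs at least two values")
    pooled = np.concatenate(samples)
    if np.allclose(pooled, pooled[0]):
        raise ValueError("zero variance everywhere: F undefined")
    f_result = stats.f_oneway(*samples)
    tukey = stats.tukey_hsd(*samples)
    pairwise = {
        f"{names[i]}|{names[j]}": float(tukey.pvalue[i, j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
    }
    return float(f_result.statistic), float(f_result.pvalue), pairwise


@dataclass(frozen=True)
class DomainSummary:
    name: str
    length: int
    observed_missense: int
    possible_missense: int
    mean_grade: float
    mean_dnds: float
    hotspot_positions: int

    @property
    def oe_ratio(self) -> float:
        return self.observed_missense / self.possible_missense

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "length": self.length,
            "observed_missense": self.observed_missense,
            "possible_missense": self.possible_missense,
            "oe_ratio": self.oe_ratio,
            "mean_grade": self.mean_grade,
            "mean_dnds": self.mean_dnds,
            "hotspot_positions": self.hotspot_positions,
        }


def walds_domain_verdict(a: DomainSummary, b: DomainSummary):
    """Score the four tolerability criteria and name the less tolerant domain.

    Criteria won by a domain: lower O/E ratio, higher mean conservation grade,
    more hotspot positions, lower mean dN/dS. A tie on a criterion scores 0.5
    to each side; the domain totalling >= 3 of 4 is the verdict, otherwise
    "inconclusive".
    """
    score_a = 0.0
    criteria = {}
    comparisons = [
        ("lower_oe", a.oe_ratio, b.oe_ratio, True),
        ("higher_mean_grade", a.mean_grade, b.mean_grade, False),
        ("more_hotspot_positions", a.hotspot_positions, b.hotspot_positions, False),
        ("lower_mean_dnds", a.mean_dnds, b.mean_dnds, True),
    ]
    for key, va, vb, lower_wins in comparisons:
        if va == vb or (np.isnan(va) and np.isnan(vb)):
            criteria[key] = "tie"
            score_a += 0.5
        elif (va < vb) == lower_wins:
            criteria[key] = a.name
            score_a += 1.0
        else:
            criteria[key] = b.name
    score_b = 4.0 - score_a
    if score_a >= 3.0:
        winner = a.name
    elif score_b >= 3.0:
        winner = b.name
    else:
        winner = "inconclusive"
    return {
        "walds_domain": winner,
        "scores": {a.name: score_a, b.name: score_b},
        "criteria": criteria,
    }


@dataclass(frozen=True)
class AnalysisParams:
    window: int = tolerance.DEFAULT_WINDOW
    pseudocount: float = tolerance.DEFAULT_PSEUDOCOUNT
    percentile: float = hotspots.DEFAULT_PERCENTILE
    min_run: int = hotspots.DEFAULT_MIN_RUN
    dps_cutoff: float = hotspots.DEFAULT_DPS_CUTOFF
    gof_model: str = "equal"
    max_gap_fraction: float = conservation.DEFAULT_MAX_GAP_FRACTION
    dnds_stride: int = 1

    def to_dict(self) -> dict:
        return {
            "window": self.window,
            "pseudocount": self.pseudocount,
            "percentile": self.percentile,
            "min_run": self.min_run,
            "dps_cutoff": self.dps_cutoff,
            "gof_model": self.gof_model,
            "max_gap_fraction": self.max_gap_fraction,
            "dnds_stride": self.dnds_stride,
        }


@dataclass(frozen=True)
class ComparisonReport:
    params: AnalysisParams
    grade_chi2: dict
    count_gof: dict
    dps_ks: dict
    dnds_ks: dict
    dnds_mwu: dict
    domains: dict
    verdict: dict
    identity_anova: dict | None = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "grade_chi2": self.grade_chi2,
            "count_gof": self.count_gof,
            "dps_ks": self.dps_ks,
            "dnds_ks": self.dnds_ks,
            "dnds_mwu": self.dnds_mwu,
            "identity_anova": self.identity_anova,
            "domains": self.domains,
            "verdict": self.verdict,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)


def analyze(
    aln: AlignmentSet,
    cds: CodingSequence,
    variants: VariantTable,
    matrix: ScoreMatrix,
    annotation: ProteinAnnotation,
    domain_a: str,
    domain_b: str,
    params: AnalysisParams = AnalysisParams(),
):
    """Run the full domain comparison on in-memory inputs.

    Returns ``(report, profile, landscape, hotspot_set)``.
    """
    length = annotation.length
    if cds.protein_length != length:
        raise ConsistencyError(
            f"CDS encodes {cds.protein_length} residues but annotation says {length}"
        )
    if aln.reference_length != length:
        raise ConsistencyError(
            f"MSA reference has {aln.reference_length} residues but annotation "
            f"says {length}"
        )
    if len(matrix.scores) != length:
        raise ConsistencyError(
            f"score matrix covers {len(matrix.scores)} positions but annotation "
            f"says {length}"
        )
    dom_a = annotation.domain(domain_a)
    dom_b = annotation.domain(domain_b)

    profile = conservation.conservation_profile(
        aln, max_gap_fraction=params.max_gap_fraction
    )
    possible = tolerance.possible_counts(cds)
    observed = tolerance.observed_counts(variants, length)
    landscape = tolerance.dnds_landscape(
        possible, observed, window=params.window, pseudocount=params.pseudocount
    )
    means = hotspots.position_mean_dps(matrix)
    threshold = hotspots.critical_value(means, params.percentile)
    hotspot_set = hotspots.call_hotspots(
        means, threshold, min_run=params.min_run, percentile=params.percentile
    )

    # conservation-grade homogeneity between the two domains
    dist_a = conservation.grade_distribution(profile, dom_a)
    dist_b = conservation.grade_distribution(profile, dom_b)
    table = [[dist_a[g] for g in range(1, 10)], [dist_b[g] for g in range(1, 10)]]
    chi2, df, p = chi2_homogeneity(table)
    grade_chi2 = {"chi2": chi2, "df": df, "p": p}

    # observed missense counts vs the expectation model
    obs_counts = []
    possible_mis = []
    for dom in (dom_a, dom_b):
        dom_obs = slice_by_domain(observed["obs_mis"], dom, length)
        dom_possible = slice_by_domain(possible["possible_mis"], dom, length)
        obs_counts.append(int(dom_obs.sum()))
        possible_mis.append(int(dom_possible.sum()))
    gof_chi2, gof_df, gof_p = chi2_goodness_of_fit(
        obs_counts,
        model=params.gof_model,
        lengths=[dom_a.length, dom_b.length],
        possible=possible_mis,
    )
    count_gof = {
        "chi2": gof_chi2,
        "df": gof_df,
        "p": gof_p,
        "model": params.gof_model,
        "observed": {dom_a.name: obs_counts[0], dom_b.name: obs_counts[1]},
        "oe_ratio": {
            dom_a.name: obs_counts[0] / possible_mis[0],
            dom_b.name: obs_counts[1] / possible_mis[1],
        },
    }

    # DPS distributions (full and >cutoff subset)
    dps_a = slice_by_domain(means, dom_a, length)
    dps_b = slice_by_domain(means, dom_b, length)
    d_full, p_full = ks_two_sample(dps_a, dps_b)
    dps_ks = {"full": {"D": d_full, "p": p_full}, "cutoff": params.dps_cutoff}
    high_a = hotspots.high_dps_subset(dps_a, params.dps_cutoff)
    high_b = hotspots.high_dps_subset(dps_b, params.dps_cutoff)
    if len(high_a) >= 2 and len(high_b) >= 2:
        d_high, p_high = ks_two_sample(high_a, high_b)
        dps_ks["above_cutoff"] = {"D": d_high, "p": p_high}
    else:
        dps_ks["above_cutoff"] = None

    # dN/dS distribution and location comparisons
    dnds_a, _ = tolerance.domain_dnds_values(landscape, dom_a, params.dnds_stride)
    dnds_b, _ = tolerance.domain_dnds_values(landscape, dom_b, params.dnds_stride)
    d_dnds, p_dnds = ks_two_sample(dnds_a, dnds_b)
    w_dnds, p_mwu = mann_whitney_u(dnds_a, dnds_b)
    dnds_ks = {"D": d_dnds, "p": p_dnds}
    dnds_mwu = {"W": w_dnds, "p": p_mwu}

    summaries = {}
    for dom, obs_mis, poss_mis, dnds_vals in (
        (dom_a, obs_counts[0], possible_mis[0], dnds_a),
        (dom_b, obs_counts[1], possible_mis[1], dnds_b),
    ):
        grades = [
            g
            for pos, g in zip(profile.positions, profile.grades)
            if dom.start <= pos <= dom.end and g > 0
        ]
        summaries[dom.name] = DomainSummary(
            name=dom.name,
            length=dom.length,
            observed_missense=obs_mis,
            possible_missense=poss_mis,
            mean_grade=float(np.mean(grades)) if grades else float("nan"),
            mean_dnds=float(np.mean(dnds_vals)) if len(dnds_vals) else float("nan"),
            hotspot_positions=hotspot_set.positions_in(dom),
        )
    verdict = walds_domain_verdict(summaries[dom_a.name], summaries[dom_b.name])

    report = ComparisonReport(
        params=params,
        grade_chi2=grade_chi2,
        count_gof=count_gof,
        dps_ks=dps_ks,
        dnds_ks=dnds_ks,
        dnds_mwu=dnds_mwu,
        domains={name: s.to_dict() for name, s in summaries.items()},
        verdict=verdict,
    )
    return report, profile, landscape, hotspot_set


def _summary_text(report: ComparisonReport) -> str:
    lines = ["domain comparison summary", "========================="]
    for name, dom in sorted(report.domains.items()):
        lines.append(
            f"{name}: length={dom['length']} observed_missense={dom['observed_missense']} "
            f"O/E={dom['oe_ratio']:.4f} mean_grade={dom['mean_grade']:.3f} "
            f"mean_dnds={dom['mean_dnds']:.4f} hotspot_positions={dom['hotspot_positions']}"
        )
    lines.append(
        f"grade chi2 = {report.grade_chi2['chi2']:.4f} "
        f"(df={report.grade_chi2['df']}, p={report.grade_chi2['p']:.4g})"
    )
    lines.append(
        f"count gof chi2 = {report.count_gof['chi2']:.4f} "
        f"(df={report.count_gof['df']}, p={report.count_gof['p']:.4g}, "
        f"model={report.count_gof['model']})"
    )
    lines.append(
        f"DPS KS D = {report.dps_ks['full']['D']:.4f} (p={report.dps_ks['full']['p']:.4g})"
    )
    lines.append(f"dN/dS KS D = {report.dnds_ks['D']:.4f} (p={report.dnds_ks['p']:.4g})")
    lines.append(f"dN/dS MWU W = {report.dnds_mwu['W']:.1f} (p={report.dnds_mwu['p']:.4g})")
    lines.append(f"verdict: {report.verdict['walds_domain']}")
    return "\n".join(lines) + "\n"


def run_full_analysis(
    msa_path: str | Path,
    cds_path: str | Path,
    variants_path: str | Path,
    scores_path: str | Path,
    domains_path: str | Path,
    domain_a: str,
    domain_b: str,
    out_dir: str | Path,
    reference_id: str | None = None,
    params: AnalysisParams = AnalysisParams(),
) -> ComparisonReport:
    """File-based pipeline entry point; writes all output artefacts to out_dir.

    Outputs: ``conservation.tsv``, ``landscape.tsv``, ``hotspots.tsv``,
    ``report.json`` and ``summary.txt``. Re-running on identical inputs
    produces byte-identical files.
    """
    for path in (msa_path, cds_path, variants_path, scores_path, domains_path):
        if not Path(path).exists():
            raise FileNotFoundError(f"missing input file: {path}")
    annotation = read_annotation(domains_path)
    aln = read_msa(msa_path, reference_id or annotation.protein_id)
    cds = read_cds_fasta(cds_path)
    variants = read_variant_table(variants_path, cds)
    if variants.n_rejected:
        logger.warning("rejected %d variant rows with ref/CDS mismatch", variants.n_rejected)
    matrix = read_score_matrix(scores_path, cds.protein)

    report, profile, landscape, hotspot_set = analyze(
        aln, cds, variants, matrix, annotation, domain_a, domain_b, params
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    profile.write_tsv(out / "conservation.tsv")
    landscape.write_tsv(out / "landscape.tsv")
    hotspot_set.write_tsv(out / "hotspots.tsv")
    payload = report.to_dict()
    payload["hotspots"] = hotspot_set.to_dict()
    (out / "report.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    (out / "summary.txt").write_text(_summary_text(report))
    return report
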