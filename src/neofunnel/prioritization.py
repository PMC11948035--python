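"""Candidate-neoantigen prioritization: rank aggregation and filter cascade.

A somatic missense mutation becomes a candidate neoantigen when it clears
five criteria:

1. binding       — median MHC-I percentile rank across the predictor roster,
                   minimized over the mutation's 8-11-mer windows, <= 2%
2. tumor_support — >= 20x depth and VAF >= 0.1 in the tumor at both the DNA
                   and the RNA level
3. normal_absent — >= 20x depth and VAF <= 0.01 in the matched normal
4. expressed     — TPM >= 1 for both the gene and the transcript
5. not_germline  — tumor DNA VAF <= 0.6 (a near-heterozygous or higher
                   fraction suggests a germline variant that escaped the
                   matched-normal subtraction)

All thresholds are inclusive. The funnel's intermediate "expressed" stage
(the 1164 -> 123 style reduction) uses the transcriptome-confirmation rule:
tumor RNA depth >= 20, RNA VAF >= 0.1 and gene TPM >= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median as _sample_median
from typing import Iterable, Mapping, Optional, Sequence

from .neoepitope import PeptideWindow, enumerate_mutant_windows, mutate_protein
from .variant_io import (
    BindingPrediction,
    NeofunnelError,
    ProteinSequence,
    SomaticVariant,
)

log = logging.getLogger(__name__)

CRITERIA = ("binding", "tumor_support", "normal_absent", "expressed", "not_germline")


class UndefinedVAFError(NeofunnelError):
    """VAF requested at an uncovered site (depth == 0)."""


class MissingPredictionError(NeofunnelError):
    """A peptide window has no binding predictions."""


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the five-criterion cascade (defaults as published)."""

    max_median_rank_pct: float = 2.0
    min_depth_tumor: int = 20
    min_vaf_tumor: float = 0.10
    min_depth_normal: int = 20
    max_vaf_normal: float = 0.01
    min_tpm: float = 1.0
    max_dna_vaf_germline: float = 0.6

    def __post_init__(self) -> None:
        for name in (
            "max_median_rank_pct",
            "min_depth_tumor",
            "min_vaf_tumor",
            "min_depth_normal",
            "max_vaf_normal",
            "min_tpm",
            "max_dna_vaf_germline",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"FilterConfig.{name} must be non-negative")
        for name in ("min_vaf_tumor", "max_vaf_normal", "max_dna_vaf_germline"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"FilterConfig.{name} must lie in [0, 1]")


@dataclass(frozen=True)
class CandidateNeoantigen:
    """A variant's evaluation against the five criteria."""

    variant: SomaticVariant
    best_window: Optional[PeptideWindow]
    best_median_rank: float
    criterion_flags: dict[str, bool]
    passed: bool

    def __post_init__(self) -> None:
        if set(self.criterion_flags) != set(CRITERIA):
            raise ValueError(f"criterion_flags must be exactly {CRITERIA}")
        if self.passed != all(self.criterion_flags.values()):
            raise ValueError("passed must equal the conjunction of the five flags")


@dataclass
class FunnelReport:
    """Counts along the funnel plus per-criterion failure tallies."""

    n_input: int
    n_expressed: int
    n_candidates: int
    criterion_failures: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.n_input >= self.n_expressed >= self.n_candidates >= 0:
            raise ValueError(
                "funnel counts must be non-increasing: "
                f"{self.n_input} >= {self.n_expressed} >= {self.n_candidates}"
            )


def compute_vaf(alt: int, depth: int) -> float:
    """Variant allele frequency alt/depth; undefined at depth 0."""
    if depth == 0:
        raise UndefinedVAFError(
            f"VAF undefined at uncovered site (alt={alt}, depth=0)"
        )
    if not 0 <= alt <= depth:
        raise ValueError(f"alt ({alt}) must lie in [0, depth={depth}]")
    return alt / depth


def median_rank(predictions: Sequence[BindingPrediction]) -> float:
    """Sample median percentile rank of one peptide across predictors.

    Even counts use the mean of the two central order statistics. All
    predictions must refer to the same (peptide, allele).
    """
    if not predictions:
        raise MissingPredictionError("median_rank: no predictions supplied")
    keys = {(p.peptide, p.allele) for p in predictions}
    if len(keys) > 1:
        raise ValueError(f"median_rank: mixed peptide/allele inputs {sorted(keys)}")
    return float(_sample_median([p.percentile_rank for p in predictions]))


def _median_of_ranks(ranks: Sequence[float]) -> float:
    return float(_sample_median(ranks))


def group_ranks_by_peptide(
    predictions: Iterable[BindingPrediction],
    allele: Optional[str] = None,
    expected_algorithms: int = 8,
) -> dict[str, float]:
    """Per-peptide median rank across algorithms, optionally allele-filtered.

    Peptides with fewer predictions than the configured roster are scored on
    what is available, with a warning (incomplete predictor coverage).
    """
    ranks: dict[str, list[float]] = {}
    for p in predictions:
        if allele is not None and p.allele != allele:
            continue
        ranks.setdefault(p.peptide, []).append(p.percentile_rank)
    short = [pep for pep, r in ranks.items() if len(r) < expected_algorithms]
    if short:
        log.warning(
            "%d peptide(s) have fewer than %d algorithm predictions "
            "(median taken over available ranks); first: %s",
            len(short), expected_algorithms, short[0],
        )
    return {pep: _median_of_ranks(r) for pep, r in ranks.items()}


def best_median_rank_per_variant(
    windows: Sequence[PeptideWindow],
    peptide_medians: Mapping[str, float],
) -> tuple[float, PeptideWindow]:
    """Minimum median rank over a variant's windows (strongest binder).

    Ties broken toward the shorter window, then the smaller start position.
    """
    if not windows:
        raise MissingPredictionError("variant has no peptide windows")
    missing = [w.sequence for w in windows if w.sequence not in peptide_medians]
    if missing:
        raise MissingPredictionError(
            f"no binding predictions for peptide(s): {', '.join(sorted(set(missing)))}"
        )
    best = min(windows, key=lambda w: (peptide_medians[w.sequence], w.length, w.start))
    return peptide_medians[best.sequence], best


def _tpm(expression: Mapping[str, float], feature: str, variant_id: str) -> float:
    if feature not in expression:
        log.warning(
            "%s: feature %s absent from expression table; treated as not expressed",
            variant_id, feature,
        )
        return float("-inf")
    return expression[feature]


def evaluate_variant(
    variant: SomaticVariant,
    expression: Mapping[str, float],
    best_median_rank: float,
    config: FilterConfig = FilterConfig(),
    best_window: Optional[PeptideWindow] = None,
) -> CandidateNeoantigen:
    """Apply the five criteria to one variant.

    A gene or transcript missing from the expression map fails the
    "expressed" criterion with a warning rather than raising, so partial
    annotations degrade gracefully.
    """
    vaf_dna = compute_vaf(variant.tumor_dna_alt, max(variant.tumor_dna_depth, 1)) \
        if variant.tumor_dna_depth else 0.0
    vaf_rna = compute_vaf(variant.tumor_rna_alt, max(variant.tumor_rna_depth, 1)) \
        if variant.tumor_rna_depth else 0.0
    vaf_normal = compute_vaf(variant.normal_alt, max(variant.normal_depth, 1)) \
        if variant.normal_depth else 1.0  # uncovered normal cannot certify absence

    flags = {
        "binding": best_median_rank <= config.max_median_rank_pct,
        "tumor_support": (
            variant.tumor_dna_depth >= config.min_depth_tumor
            and vaf_dna >= config.min_vaf_tumor
            and variant.tumor_rna_depth >= config.min_depth_tumor
            and vaf_rna >= config.min_vaf_tumor
        ),
        "normal_absent": (
            variant.normal_depth >= config.min_depth_normal
            and vaf_normal <= config.max_vaf_normal
        ),
        "expressed": (
            _tpm(expression, variant.gene, variant.variant_id) >= config.min_tpm
            and _tpm(expression, variant.transcript, variant.variant_id)
            >= config.min_tpm
        ),
        "not_germline": vaf_dna <= config.max_dna_vaf_germline,
    }
    return CandidateNeoantigen(
        variant=variant,
        best_window=best_window,
        best_median_rank=best_median_rank,
        criterion_flags=flags,
        passed=all(flags.values()),
    )


def transcriptome_confirmed(
    variant: SomaticVariant,
    expression: Mapping[str, float],
    config: FilterConfig = FilterConfig(),
) -> bool:
    """The funnel's intermediate stage: mutation confirmed expressed.

    RNA VAF >= 0.1, RNA depth >= 20 and gene TPM >= 1 (the transcriptome
    confirmation that reduces the exome mutation list before binding and
    germline screening).
    """
    if variant.tumor_rna_depth < config.min_depth_tumor:
        return False
    if compute_vaf(variant.tumor_rna_alt, variant.tumor_rna_depth) < config.min_vaf_tumor:
        return False
    return _tpm(expression, variant.gene, variant.variant_id) >= config.min_tpm


def evaluate_cohort(
    variants: Sequence[SomaticVariant],
    proteins: Mapping[str, ProteinSequence],
    expression: Mapping[str, float],
    predictions: Iterable[BindingPrediction],
    config: FilterConfig = FilterConfig(),
    allele: Optional[str] = None,
    expected_algorithms: int = 8,
) -> list[CandidateNeoantigen]:
    """Evaluate every variant row independently; preserves input order."""
    peptide_medians = group_ranks_by_peptide(
        predictions, allele=allele, expected_algorithms=expected_algorithms
    )
    evaluations: list[CandidateNeoantigen] = []
    for variant in variants:
        if variant.transcript not in proteins:
            raise NeofunnelError(
                f"{variant.variant_id}: no protein sequence for transcript "
                f"{variant.transcript}"
            )
        try:
            mut_protein = mutate_protein(
                proteins[variant.transcript],
                variant.protein_pos,
                variant.aa_ref,
                variant.aa_alt,
            )
            windows = enumerate_mutant_windows(
                mut_protein, variant.protein_pos, source_variant=variant.variant_id
            )
            best_rank, best_window = best_median_rank_per_variant(
                windows, peptide_medians
            )
        except NeofunnelError as exc:
            raise type(exc)(f"{variant.variant_id}: {exc}") from exc
        evaluations.append(
            evaluate_variant(
                variant, expression, best_rank, config, best_window=best_window
            )
        )
    return evaluations


def _mutation_key(v: SomaticVariant) -> tuple:
    # mutation identity ignoring the transcript: multi-transcript rows of the
    # same protein change collapse to one reported candidate
    return (v.gene, v.protein_pos, v.aa_ref, v.aa_alt)


def run_funnel(
    variants: Sequence[SomaticVariant],
    proteins: Mapping[str, ProteinSequence],
    expression: Mapping[str, float],
    predictions: Iterable[BindingPrediction],
    config: FilterConfig = FilterConfig(),
    allele: Optional[str] = None,
    expected_algorithms: int = 8,
) -> tuple[list[CandidateNeoantigen], FunnelReport]:
    """The full prioritization funnel.

    Returns the passing candidates (one per mutation, best-passing
    transcript row, sorted ascending by best median rank with ties broken by
    variant id) and a :class:`FunnelReport` with the stage counts and
    per-criterion failure tallies over all input rows.
    """
    evaluations = evaluate_cohort(
        variants, proteins, expression, predictions,
        config=config, allele=allele, expected_algorithms=expected_algorithms,
    )
    n_expressed = sum(
        transcriptome_confirmed(v, expression, config) for v in variants
    )
    failures = {
        c: sum(not e.criterion_flags[c] for e in evaluations) for c in CRITERIA
    }
    # best passing row per mutation
    best_by_mutation: dict[tuple, CandidateNeoantigen] = {}
    for e in evaluations:
        if not e.passed:
            continue
        key = _mutation_key(e.variant)
        incumbent = best_by_mutation.get(key)
        if incumbent is None or (
            (e.best_median_rank, e.variant.variant_id)
            < (incumbent.best_median_rank, incumbent.variant.variant_id)
        ):
            best_by_mutation[key] = e
    candidates = sorted(
        best_by_mutation.values(),
        key=lambda e: (e.best_median_rank, e.variant.variant_id),
    )
    report = FunnelReport(
        n_input=len(variants),
        n_expressed=n_expressed,
        n_candidates=len(candidates),
        criterion_failures=failures,
    )
    log.info(
        "funnel: %d input -> %d expressed -> %d candidates; failures per "
        "criterion: %s", report.n_input, report.n_expressed,
        report.n_candidates, failures,
    )
    return candidates, report
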