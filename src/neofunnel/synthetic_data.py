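"""Ground-truth-annotated synthetic inputs for every pipeline stage.

The study's sequencing data are unreleased, so this module generates inputs
that emulate their statistical structure with machine-readable planted
truth: a somatic-variant cohort whose funnel counts are enforced exactly
(e.g. 1164 exome mutations -> 123 transcriptome-confirmed -> 19 candidate
neoantigens), bulk expression matrices with planted rank correlations
between genes and signature scores (Gaussian copula), and two-arm survival
data with a planted hazard ratio.

A single global seed fans out to per-table substreams
(:class:`numpy.random.SeedSequence`), so adding one table never perturbs the
others. Planted filter failures are spread round-robin across the criteria
so every predicate path of the cascade is exercised. Amino-acid composition
is uniform over the 20-letter alphabet — no homology realism, which the
predicate logic never inspects.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .neoepitope import enumerate_mutant_windows, mutate_protein
from .prioritization import FilterConfig
from .signature_scoring import GeneSet, SurvivalRecord
from .variant_io import (
    DEFAULT_ALGORITHMS,
    DEFAULT_ALLELE,
    BindingPrediction,
    NeofunnelError,
    ProteinSequence,
    SomaticVariant,
    write_binding_predictions,
    write_expression_table,
    write_proteins_fasta,
    write_variant_table,
)

log = logging.getLogger(__name__)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# planted failure modes, cycled round-robin
_STAGE_FAILS = ("rna_depth", "rna_vaf", "gene_tpm")          # break expression stage
_CANDIDATE_FAILS = ("binding", "dna_support", "normal", "transcript_tpm", "germline")


@dataclass(frozen=True)
class CohortTruth:
    """What was planted: which variants should survive each funnel stage."""

    planted_expressed: frozenset[str]
    planted_candidates: frozenset[str]
    violations: dict[str, str]  # variant_id -> planted failure mode
    seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "planted_expressed": sorted(self.planted_expressed),
                    "planted_candidates": sorted(self.planted_candidates),
                    "violations": self.violations,
                },
                indent=2,
            )
        )


@dataclass
class SyntheticCohort:
    variants: list[SomaticVariant]
    expression: dict[str, float]
    predictions: list[BindingPrediction]
    proteins: dict[str, ProteinSequence]
    truth: CohortTruth

    def write(self, outdir) -> dict[str, Path]:
        """Write the TSV/FASTA dialects the pipeline readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "variants": outdir / "variants.tsv",
            "expression": outdir / "expression.tsv",
            "predictions": outdir / "predictions.tsv",
            "proteins": outdir / "proteins.fasta",
            "truth": outdir / "truth.json",
        }
        write_variant_table(self.variants, paths["variants"])
        write_expression_table(self.expression, paths["expression"])
        write_binding_predictions(self.predictions, paths["predictions"])
        write_proteins_fasta(self.proteins.values(), paths["proteins"])
        self.truth.to_json(paths["truth"])
        return paths


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[rng.integers(0, 20, size=length)])


def _alt_count(
    rng: np.random.Generator, depth: int, vaf_lo: float, vaf_hi: float
) -> int:
    """An alt count whose VAF falls inclusively inside [vaf_lo, vaf_hi].

    The target VAF is beta(2, 2)-distributed across the interval; the count
    is then clipped so the realized alt/depth honors the bounds exactly.
    """
    lo = math.ceil(vaf_lo * depth)
    hi = math.floor(vaf_hi * depth)
    if hi < lo:  # depth too small to realize the interval; take the boundary
        return min(lo, depth)
    target = vaf_lo + (vaf_hi - vaf_lo) * rng.beta(2.0, 2.0)
    return int(np.clip(round(target * depth), lo, hi))


def _below_vaf(rng: np.random.Generator, depth: int, vaf: float) -> int:
    """An alt count with alt/depth strictly below ``vaf``."""
    hi = math.ceil(vaf * depth) - 1
    return int(rng.integers(0, hi + 1)) if hi > 0 else 0


def generate_variant_cohort(
    n_total: int,
    n_expressed: int,
    n_candidates: int,
    seed: int,
    config: FilterConfig = FilterConfig(),
    protein_length: tuple[int, int] = (100, 1000),
    algorithms: Sequence[str] = DEFAULT_ALGORITHMS,
    allele: str = DEFAULT_ALLELE,
) -> SyntheticCohort:
    """A missense-variant cohort with an exactly planted funnel shape.

    Exactly ``n_candidates`` variants satisfy all five criteria, exactly
    ``n_expressed`` satisfy the transcriptome-confirmation stage, and every
    other variant carries one planted, recorded violation. Deterministic per
    seed; peptide windows are globally unique across variants so predictor
    ranks are unambiguous.
    """
    if not n_total >= n_expressed >= n_candidates >= 0:
        raise NeofunnelError(
            f"infeasible cohort sizes: need n_total >= n_expressed >= "
            f"n_candidates >= 0, got ({n_total}, {n_expressed}, {n_candidates})"
        )
    ss = np.random.SeedSequence(seed)
    rng_protein, rng_variant, rng_expr, rng_pred = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    perm = rng_variant.permutation(n_total)
    candidate_idx = set(perm[:n_candidates].tolist())
    expressed_idx = set(perm[:n_expressed].tolist())

    d_lo, d_hi = 20, 200  # sequencing depth range, reads

    variants: list[SomaticVariant] = []
    expression: dict[str, float] = {}
    predictions: list[BindingPrediction] = []
    proteins: dict[str, ProteinSequence] = {}
    violations: dict[str, str] = {}
    planted_expressed: set[str] = set()
    planted_candidates: set[str] = set()
    seen_peptides: set[str] = set()

    stage_fail_cycle = 0
    cand_fail_cycle = 0

    for i in range(n_total):
        vid = f"var{i + 1:05d}"
        gene = f"Gene{i + 1:05d}"
        transcript = f"Tx{i + 1:05d}"
        is_candidate = i in candidate_idx
        is_expressed = i in expressed_idx

        # protein + mutation site; redraw on (rare) cross-variant peptide
        # sequence collision so predictor ranks stay unambiguous
        while True:
            length = int(rng_protein.integers(protein_length[0], protein_length[1] + 1))
            sequence = _random_protein(rng_protein, length)
            pos = int(rng_protein.integers(1, length + 1))
            aa_ref = sequence[pos - 1]
            aa_alt = str(rng_protein.choice(_AA[_AA != aa_ref]))
            protein = ProteinSequence(transcript, sequence)
            mut_protein = mutate_protein(protein, pos, aa_ref, aa_alt)
            window_seqs = sorted(
                {w.sequence for w in enumerate_mutant_windows(mut_protein, pos, vid)}
            )
            if not any(s in seen_peptides for s in window_seqs):
                break
        seen_peptides.update(window_seqs)
        proteins[transcript] = protein

        # ---- default (passing) draws for every compartment ----
        dna_depth = int(rng_variant.integers(d_lo, d_hi + 1))
        rna_depth = int(rng_variant.integers(d_lo, d_hi + 1))
        normal_depth = int(rng_variant.integers(100, d_hi + 1))
        dna_alt = _alt_count(
            rng_variant, dna_depth, config.min_vaf_tumor, config.max_dna_vaf_germline
        )
        rna_alt = _alt_count(rng_variant, rna_depth, config.min_vaf_tumor, 0.9)
        normal_alt = int(
            rng_variant.integers(0, math.floor(config.max_vaf_normal * normal_depth) + 1)
        )
        gene_tpm = 1.0 + float(rng_expr.lognormal(1.0, 1.0))
        tx_tpm = 1.0 + float(rng_expr.lognormal(1.0, 1.0))
        binding_good = True  # one window with median rank <= threshold

        # ---- planted violation ----
        if is_candidate:
            planted_candidates.add(vid)
            planted_expressed.add(vid)
        elif is_expressed:
            planted_expressed.add(vid)
            mode = _CANDIDATE_FAILS[cand_fail_cycle % len(_CANDIDATE_FAILS)]
            cand_fail_cycle += 1
            violations[vid] = mode
            if mode == "binding":
                binding_good = False
            elif mode == "dna_support":
                dna_depth = int(rng_variant.integers(5, config.min_depth_tumor))
                dna_alt = _alt_count(rng_variant, dna_depth, config.min_vaf_tumor, 0.6)
            elif mode == "normal":
                normal_alt = _alt_count(rng_variant, normal_depth, 0.02, 0.3)
            elif mode == "transcript_tpm":
                tx_tpm = float(rng_expr.uniform(0.0, 0.95))
            elif mode == "germline":
                dna_alt = _alt_count(rng_variant, dna_depth, 0.65, 0.95)
        else:
            mode = _STAGE_FAILS[stage_fail_cycle % len(_STAGE_FAILS)]
            stage_fail_cycle += 1
            violations[vid] = mode
            if mode == "rna_depth":
                rna_depth = int(rng_variant.integers(5, config.min_depth_tumor))
                rna_alt = _alt_count(rng_variant, rna_depth, config.min_vaf_tumor, 0.9)
            elif mode == "rna_vaf":
                rna_alt = _below_vaf(rng_variant, rna_depth, config.min_vaf_tumor)
            elif mode == "gene_tpm":
                gene_tpm = float(rng_expr.uniform(0.0, 0.95))

        variants.append(
            SomaticVariant(
                variant_id=vid,
                gene=gene,
                transcript=transcript,
                protein_pos=pos,
                aa_ref=aa_ref,
                aa_alt=aa_alt,
                tumor_dna_depth=dna_depth,
                tumor_dna_alt=dna_alt,
                tumor_rna_depth=rna_depth,
                tumor_rna_alt=rna_alt,
                normal_depth=normal_depth,
                normal_alt=normal_alt,
            )
        )
        expression[gene] = round(gene_tpm, 4)
        expression[transcript] = round(tx_tpm, 4)

        # ---- predictor ranks per unique window sequence ----
        n_seqs = len(window_seqs)
        max_rank = config.max_median_rank_pct
        good_idx = int(rng_pred.integers(0, n_seqs)) if binding_good else -1
        lo_ranks = rng_pred.uniform(0.05, max_rank * 0.95, size=len(algorithms))
        hi_ranks = rng_pred.uniform(
            max_rank * 1.25, 95.0, size=(n_seqs, len(algorithms))
        )
        for j, pep in enumerate(window_seqs):
            ranks = lo_ranks if j == good_idx else hi_ranks[j]
            for algorithm, rank in zip(algorithms, ranks):
                predictions.append(
                    BindingPrediction(
                        peptide=pep,
                        allele=allele,
                        algorithm=algorithm,
                        percentile_rank=round(float(rank), 4),
                    )
                )

    truth = CohortTruth(
        planted_expressed=frozenset(planted_expressed),
        planted_candidates=frozenset(planted_candidates),
        violations=violations,
        seed=seed,
    )
    return SyntheticCohort(variants, expression, predictions, proteins, truth)


# ---------------------------------------------------------------------------
# Correlated bulk expression (Gaussian copula)
# ---------------------------------------------------------------------------

Entity = Union[str, GeneSet]


def _entity_name(entity: Entity) -> str:
    return entity if isinstance(entity, str) else entity.name


def generate_correlated_expression(
    n_samples: int,
    n_genes: int,
    planted: Sequence[tuple[Entity, Entity, float]],
    seed: int,
    signature_loading_noise: float = 0.05,
) -> pd.DataFrame:
    """A genes x samples matrix with planted Spearman rank correlations.

    Each planted triple names two quantities — a gene symbol or a
    :class:`GeneSet` (whose member genes all load on one shared latent
    factor) — and the target Spearman rho between them. Latent variables are
    drawn from a Gaussian copula with pairwise Pearson correlation
    ``2 sin(pi rho / 6)`` (the exact Spearman-to-Pearson map for bivariate
    normals) and pushed through a monotone map to non-negative expression,
    so gene-gene rank correlations hit the target exactly in distribution;
    gene-signature correlations attenuate slightly through the ssGSEA score.
    Remaining genes are independent log-normal background.
    """
    if n_samples < 2:
        raise NeofunnelError("need at least 2 samples")
    if n_samples < 10:
        log.warning(
            "n_samples=%d is very small; empirical correlations are unstable",
            n_samples,
        )
    entities: list[Entity] = []
    names_seen: set[str] = set()
    for a, b, rho in planted:
        if not -1.0 < rho < 1.0:
            raise NeofunnelError(f"planted rho {rho} must lie in (-1, 1)")
        for e in (a, b):
            if _entity_name(e) not in names_seen:
                names_seen.add(_entity_name(e))
                entities.append(e)

    q = len(entities)
    index = {_entity_name(e): k for k, e in enumerate(entities)}
    latent_corr = np.eye(q)
    for a, b, rho in planted:
        r = 2.0 * math.sin(math.pi * rho / 6.0)
        ia, ib = index[_entity_name(a)], index[_entity_name(b)]
        latent_corr[ia, ib] = latent_corr[ib, ia] = r
    eigvals = np.linalg.eigvalsh(latent_corr)
    if eigvals.min() < -1e-10:
        raise NeofunnelError(
            "planted correlations are jointly inconsistent "
            "(latent matrix not positive semi-definite)"
        )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chol = np.linalg.cholesky(latent_corr + 1e-12 * np.eye(q))
    z = rng.standard_normal((n_samples, q)) @ chol.T  # samples x entities

    gene_rows: dict[str, np.ndarray] = {}
    for e, zk in zip(entities, z.T):
        if isinstance(e, str):
            gene_rows[e] = np.exp(1.0 + zk)
        else:
            for g in e.genes:
                eps = rng.standard_normal(n_samples)
                gene_rows[g] = np.exp(1.0 + zk + signature_loading_noise * eps)

    if len(gene_rows) > n_genes:
        raise NeofunnelError(
            f"planted quantities name {len(gene_rows)} genes but n_genes={n_genes}"
        )
    n_background = n_genes - len(gene_rows)
    background = np.exp(rng.normal(1.0, 1.0, size=(n_background, n_samples)))
    for k in range(n_background):
        gene_rows[f"Bkg{k + 1:05d}"] = background[k]

    samples = [f"S{j + 1:04d}" for j in range(n_samples)]
    return pd.DataFrame(gene_rows, index=samples).T


# ---------------------------------------------------------------------------
# Two-arm survival
# ---------------------------------------------------------------------------


def generate_survival(
    n_per_arm: int,
    hazard_ratio: float,
    censor_rate: float,
    seed: int,
    baseline_median_months: float = 20.0,
) -> tuple[tuple[list[str], list[str]], list[SurvivalRecord]]:
    """Two-arm exponential survival with a planted hazard ratio.

    Arm A has the baseline hazard (median ``baseline_median_months``); arm
    B's hazard is scaled by ``hazard_ratio`` (> 1 means B dies faster). Each
    subject is independently censored with probability ``censor_rate`` at a
    uniform time before its event. Returns the two arms' sample ids and the
    pooled records.
    """
    if hazard_ratio <= 0:
        raise NeofunnelError(f"hazard_ratio must be > 0, got {hazard_ratio}")
    if not 0.0 <= censor_rate < 1.0:
        raise NeofunnelError(f"censor_rate must lie in [0, 1), got {censor_rate}")
    if n_per_arm < 1:
        raise NeofunnelError("need at least 1 subject per arm")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lam = math.log(2.0) / baseline_median_months

    records: list[SurvivalRecord] = []
    groups: tuple[list[str], list[str]] = ([], [])
    for arm, (label, hazard) in enumerate(
        (("A", lam), ("B", lam * hazard_ratio))
    ):
        times = rng.exponential(1.0 / hazard, size=n_per_arm)
        censored = rng.uniform(size=n_per_arm) < censor_rate
        fractions = rng.uniform(size=n_per_arm)
        for k in range(n_per_arm):
            sample = f"{label}{k + 1:04d}"
            groups[arm].append(sample)
            t = times[k]
            event = True
            if censored[k]:
                t = max(t * fractions[k], 1e-9)
                event = False
            records.append(SurvivalRecord(sample=sample, time=float(t), event=event))
    return groups, records
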