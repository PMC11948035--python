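"""Readers and writers for the tabular and sequence artifacts of the pipeline.

All tables are tab-delimited UTF-8 text with a mandatory header row; unknown
extra columns are ignored so upstream annotation tools can add fields freely.
Protein positions are 1-based throughout, matching the ``p.G238C`` style of
protein-change notation. MHC percentile ranks are stored on the 0-100 percent
scale (a criterion of "<= 2%" compares against 2.0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Roster of MHC-I binding predictors whose percentile ranks are aggregated.
#: Real predictors are out of scope; the names label columns of the
#: prediction table produced upstream (or by the synthetic stub).
DEFAULT_ALGORITHMS: tuple[str, ...] = (
    "NetMHCpan",
    "NetMHC",
    "NetMHCcons",
    "PickPocket",
    "MHCflurry",
    "SMM",
    "SMMPBMC",
    "MHCnuggetsI",
)

DEFAULT_ALLELE = "H-2Kb"


class NeofunnelError(Exception):
    """Base class for all package errors."""


class TableFormatError(NeofunnelError):
    """A table is structurally malformed (missing column, bad header...)."""


class RecordValidationError(NeofunnelError):
    """A record violates a domain invariant; message names the offender."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SomaticVariant:
    """One annotated missense mutation with tri-compartment read support.

    Depth/alt counts are carried for tumor DNA, tumor RNA and the matched
    normal DNA so the filter cascade can compute a variant allele frequency
    (VAF = alt / depth) in each compartment.
    """

    variant_id: str
    gene: str
    transcript: str
    protein_pos: int
    aa_ref: str
    aa_alt: str
    tumor_dna_depth: int
    tumor_dna_alt: int
    tumor_rna_depth: int
    tumor_rna_alt: int
    normal_depth: int
    normal_alt: int

    def __post_init__(self) -> None:
        if self.protein_pos < 1:
            raise RecordValidationError(
                f"{self.variant_id}: protein_pos must be >= 1, got {self.protein_pos}"
            )
        for aa, label in ((self.aa_ref, "aa_ref"), (self.aa_alt, "aa_alt")):
            if aa not in AMINO_ACIDS:
                raise RecordValidationError(
                    f"{self.variant_id}: {label} {aa!r} is not a standard amino acid"
                )
        if self.aa_ref == self.aa_alt:
            raise RecordValidationError(
                f"{self.variant_id}: aa_ref == aa_alt ({self.aa_ref}); not a missense change"
            )
        for compartment in ("tumor_dna", "tumor_rna", "normal"):
            depth = getattr(self, f"{compartment}_depth")
            alt = getattr(self, f"{compartment}_alt")
            if depth < 0 or alt < 0:
                raise RecordValidationError(
                    f"{self.variant_id}: negative read count in {compartment}"
                )
            if alt > depth:
                raise RecordValidationError(
                    f"{self.variant_id}: {compartment}_alt ({alt}) exceeds "
                    f"{compartment}_depth ({depth})"
                )

    @property
    def identity_key(self) -> tuple:
        return (self.gene, self.transcript, self.protein_pos, self.aa_ref, self.aa_alt)

    @property
    def protein_change(self) -> str:
        """e.g. ``G238C`` — the field's compact missense notation."""
        return f"{self.aa_ref}{self.protein_pos}{self.aa_alt}"


@dataclass(frozen=True)
class BindingPrediction:
    """One predictor's percentile rank for one peptide-allele pair.

    Lower rank = stronger predicted binding; ranks are percent in [0, 100].
    """

    peptide: str
    allele: str
    algorithm: str
    percentile_rank: float

    def __post_init__(self) -> None:
        if len(self.peptide) not in (8, 9, 10, 11):
            raise RecordValidationError(
                f"peptide {self.peptide!r}: length {len(self.peptide)} outside 8-11"
            )
        bad = set(self.peptide) - AMINO_ACIDS
        if bad:
            raise RecordValidationError(
                f"peptide {self.peptide!r}: invalid residues {sorted(bad)}"
            )
        if not 0.0 <= self.percentile_rank <= 100.0:
            raise RecordValidationError(
                f"peptide {self.peptide!r} / {self.algorithm}: percentile rank "
                f"{self.percentile_rank} outside [0, 100]"
            )


@dataclass(frozen=True)
class ProteinSequence:
    """Amino-acid sequence of one transcript's protein product."""

    transcript: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise RecordValidationError(f"{self.transcript}: empty protein sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise RecordValidationError(
                f"{self.transcript}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


VARIANT_COLUMNS = (
    "variant_id",
    "gene",
    "transcript",
    "protein_pos",
    "aa_ref",
    "aa_alt",
    "tumor_dna_depth",
    "tumor_dna_alt",
    "tumor_rna_depth",
    "tumor_rna_alt",
    "normal_depth",
    "normal_alt",
)

_INT_FIELDS = (
    "protein_pos",
    "tumor_dna_depth",
    "tumor_dna_alt",
    "tumor_rna_depth",
    "tumor_rna_alt",
    "normal_depth",
    "normal_alt",
)


# ---------------------------------------------------------------------------
# Table readers
# ---------------------------------------------------------------------------


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: file has no header row") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return df


def read_variant_table(path) -> list[SomaticVariant]:
    """Read a somatic missense-variant TSV into validated records.

    Row order is preserved. Duplicate identity keys
    (gene, transcript, protein_pos, aa_ref, aa_alt) are rejected.
    """
    df = _read_tsv(path, VARIANT_COLUMNS)
    variants: list[SomaticVariant] = []
    seen: set[tuple] = set()
    for idx, row in df.iterrows():
        kwargs = {c: row[c] for c in VARIANT_COLUMNS}
        for field in _INT_FIELDS:
            try:
                kwargs[field] = int(kwargs[field])
            except (TypeError, ValueError) as exc:
                raise TableFormatError(
                    f"{path} row {idx + 2}: {field}={kwargs[field]!r} is not an integer"
                ) from exc
        variant = SomaticVariant(**kwargs)
        if variant.identity_key in seen:
            raise RecordValidationError(
                f"{variant.variant_id}: duplicate variant identity "
                f"{variant.identity_key}"
            )
        seen.add(variant.identity_key)
        variants.append(variant)
    return variants


def read_expression_table(path) -> dict[str, float]:
    """Read a two-column (feature_id, level) TSV into a TPM map.

    Duplicate feature ids are rejected (the TPM would be ambiguous);
    negative levels are invalid.
    """
    df = _read_tsv(path, ("feature_id", "level"))
    expression: dict[str, float] = {}
    for idx, row in df.iterrows():
        feature = row["feature_id"]
        try:
            level = float(row["level"])
        except (TypeError, ValueError) as exc:
            raise TableFormatError(
                f"{path} row {idx + 2}: level {row['level']!r} is not numeric"
            ) from exc
        if level < 0:
            raise RecordValidationError(
                f"{feature}: negative expression level {level}"
            )
        if feature in expression:
            raise RecordValidationError(
                f"{feature}: duplicate feature_id (ambiguous TPM)"
            )
        expression[feature] = level
    return expression


def read_binding_predictions(path) -> list[BindingPrediction]:
    """Read (peptide, allele, algorithm, percentile_rank) TSV rows."""
    df = _read_tsv(path, ("peptide", "allele", "algorithm", "percentile_rank"))
    predictions: list[BindingPrediction] = []
    for idx, row in df.iterrows():
        try:
            rank = float(row["percentile_rank"])
        except (TypeError, ValueError) as exc:
            raise TableFormatError(
                f"{path} row {idx + 2}: percentile_rank "
                f"{row['percentile_rank']!r} is not numeric"
            ) from exc
        predictions.append(
            BindingPrediction(
                peptide=row["peptide"],
                allele=row["allele"],
                algorithm=row["algorithm"],
                percentile_rank=rank,
            )
        )
    return predictions


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_proteins_fasta(path) -> dict[str, ProteinSequence]:
    """Read protein FASTA keyed by transcript id (the record id)."""
    proteins: dict[str, ProteinSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in proteins:
            raise RecordValidationError(f"{record.id}: duplicate protein record")
        proteins[record.id] = ProteinSequence(record.id, str(record.seq))
    return proteins


def write_proteins_fasta(proteins: Iterable[ProteinSequence], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.transcript, description="")
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def peptide_record_id(peptide, variant: SomaticVariant) -> str:
    """FASTA id ``{gene}_{ref}{pos}{alt}|len{L}|off{k}`` (Daglb_G238C style)."""
    return (
        f"{variant.gene}_{variant.protein_change}"
        f"|len{len(peptide.sequence)}|off{peptide.mut_offset}"
    )


def write_peptides_fasta(
    peptides: Sequence, path, variants_by_id: dict[str, SomaticVariant]
) -> None:
    """Write mutant peptide windows or long peptides as FASTA.

    ``peptides`` may mix PeptideWindow and LongPeptide objects; each carries a
    ``source_variant`` id resolved against ``variants_by_id`` to build the
    gene_protein-change record id. An empty list yields an empty file with a
    warning (nothing to synthesize, not an error).
    """
    if not peptides:
        log.warning("write_peptides_fasta: empty peptide list -> empty file %s", path)
        Path(path).write_text("")
        return
    records = []
    for pep in peptides:
        variant = variants_by_id[pep.source_variant]
        records.append(
            SeqRecord(Seq(pep.sequence), id=peptide_record_id(pep, variant), description="")
        )
    SeqIO.write(records, str(path), "fasta")


def read_peptides_fasta(path) -> list[tuple[str, str]]:
    """Round-trip reader: list of (record id, sequence) in file order."""
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


# ---------------------------------------------------------------------------
# Writers for tables (used by the synthetic generator and CLI)
# ---------------------------------------------------------------------------


def write_variant_table(variants: Iterable[SomaticVariant], path) -> None:
    rows = [{c: getattr(v, c) for c in VARIANT_COLUMNS} for v in variants]
    pd.DataFrame(rows, columns=list(VARIANT_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_expression_table(expression: dict[str, float], path) -> None:
    df = pd.DataFrame(
        {"feature_id": list(expression.keys()), "level": list(expression.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def write_binding_predictions(predictions: Iterable[BindingPrediction], path) -> None:
    rows = [
        {
            "peptide": p.peptide,
            "allele": p.allele,
            "algorithm": p.algorithm,
            "percentile_rank": p.percentile_rank,
        }
        for p in predictions
    ]
    pd.DataFrame(
        rows, columns=["peptide", "allele", "algorithm", "percentile_rank"]
    ).to_csv(path, sep="\t", index=False)
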