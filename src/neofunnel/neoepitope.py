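"""Mutant-peptide construction.

Applies a missense mutation to a protein, enumerates every 8-11-mer window
covering the altered residue (the candidate short epitopes scored against an
MHC-I allele such as H-2Kb), and designs the 17-AA long vaccine peptide with
the mutation at the center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .variant_io import NeofunnelError, ProteinSequence, RecordValidationError

log = logging.getLogger(__name__)

SHORT_PEPTIDE_LENGTHS = (8, 9, 10, 11)
LONG_PEPTIDE_FLANK = 8  # residues each side -> 17-mer when both flanks fit


class ReferenceMismatchError(NeofunnelError):
    """Protein residue at the annotated position differs from aa_ref.

    Signals stale annotation: the variant table and the protein FASTA
    disagree about the reference proteome.
    """


@dataclass(frozen=True)
class PeptideWindow:
    """An 8-11-mer mutant peptide and where the altered residue sits in it.

    ``start`` is the 1-based position of the window's first residue in the
    protein; ``mut_offset`` is the 0-based index of the altered residue
    within ``sequence``.
    """

    sequence: str
    length: int
    mut_offset: int
    start: int
    source_variant: str

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise RecordValidationError(
                f"{self.source_variant}: window length field {self.length} != "
                f"sequence length {len(self.sequence)}"
            )
        if not 0 <= self.mut_offset < self.length:
            raise RecordValidationError(
                f"{self.source_variant}: mut_offset {self.mut_offset} outside window"
            )


@dataclass(frozen=True)
class LongPeptide:
    """The synthesizable long peptide (<=17 AA, mutation centered).

    Near a protein terminus the peptide is clipped to the protein bounds —
    a synthesizable peptide must be a real subsequence — so its length drops
    below 17 and the mutation sits as close to center as the protein allows.
    """

    sequence: str
    mut_offset: int
    source_variant: str

    def __post_init__(self) -> None:
        if len(self.sequence) > 2 * LONG_PEPTIDE_FLANK + 1:
            raise RecordValidationError(
                f"{self.source_variant}: long peptide exceeds "
                f"{2 * LONG_PEPTIDE_FLANK + 1} AA"
            )
        if not 0 <= self.mut_offset < len(self.sequence):
            raise RecordValidationError(
                f"{self.source_variant}: mut_offset {self.mut_offset} outside peptide"
            )


def _check_position(protein: ProteinSequence, protein_pos: int) -> None:
    if not 1 <= protein_pos <= len(protein):
        raise RecordValidationError(
            f"{protein.transcript}: protein_pos {protein_pos} outside protein "
            f"of length {len(protein)}"
        )


def mutate_protein(
    protein: ProteinSequence, protein_pos: int, aa_ref: str, aa_alt: str
) -> ProteinSequence:
    """Substitute aa_alt at the 1-based ``protein_pos``, checking aa_ref.

    Raises :class:`ReferenceMismatchError` if the protein does not carry
    aa_ref at that position.
    """
    _check_position(protein, protein_pos)
    found = protein.sequence[protein_pos - 1]
    if found != aa_ref:
        raise ReferenceMismatchError(
            f"{protein.transcript} position {protein_pos}: expected reference "
            f"residue {aa_ref}, found {found}"
        )
    seq = protein.sequence
    mutated = seq[: protein_pos - 1] + aa_alt + seq[protein_pos:]
    return ProteinSequence(protein.transcript, mutated)


def enumerate_mutant_windows(
    mut_protein: ProteinSequence,
    protein_pos: int,
    source_variant: str = "",
    lengths: tuple[int, ...] = SHORT_PEPTIDE_LENGTHS,
) -> list[PeptideWindow]:
    """Every distinct window of the given lengths covering ``protein_pos``.

    A window of length ``l`` starting at 1-based ``s`` covers the site iff
    ``s <= protein_pos <= s + l - 1`` and lies fully inside the protein.
    Output is deduplicated on (sequence, length, mut_offset) and sorted by
    (length, start). A protein shorter than the smallest requested length
    yields no windows (logged, not an error). At an interior site
    (>= 10 residues from both termini for lengths 8-11) the count is
    8 + 9 + 10 + 11 = 38.
    """
    _check_position(mut_protein, protein_pos)
    seq = mut_protein.sequence
    n = len(seq)
    if n < min(lengths):
        log.warning(
            "%s: protein of length %d shorter than smallest window (%d); no windows",
            mut_protein.transcript, n, min(lengths),
        )
    windows: list[PeptideWindow] = []
    seen: set[tuple[str, int, int]] = set()
    for length in sorted(lengths):
        lo = max(1, protein_pos - length + 1)
        hi = min(protein_pos, n - length + 1)
        for start in range(lo, hi + 1):
            window = seq[start - 1 : start - 1 + length]
            offset = protein_pos - start
            key = (window, length, offset)
            if key in seen:
                continue
            seen.add(key)
            windows.append(
                PeptideWindow(
                    sequence=window,
                    length=length,
                    mut_offset=offset,
                    start=start,
                    source_variant=source_variant,
                )
            )
    return windows


def design_long_peptide(
    mut_protein: ProteinSequence,
    protein_pos: int,
    source_variant: str = "",
    flank: int = LONG_PEPTIDE_FLANK,
) -> LongPeptide:
    """The long vaccine peptide: ``flank`` residues each side of the mutation.

    Residues max(1, p-flank) .. min(L, p+flank); 17-mer with the mutation at
    offset 8 whenever both flanks fit, clipped to the protein near a terminus.
    """
    _check_position(mut_protein, protein_pos)
    n = len(mut_protein)
    start = max(1, protein_pos - flank)
    end = min(n, protein_pos + flank)
    return LongPeptide(
        sequence=mut_protein.sequence[start - 1 : end],
        mut_offset=protein_pos - start,
        source_variant=source_variant,
    )
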