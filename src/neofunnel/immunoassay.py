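"""Closed-form immunoassay calculations.

ELISPOT positivity calls (IFN-γ spot-forming cells strictly above the
threshold), LDH-release cytotoxicity from low/high-control absorbances, and
relative qPCR quantification by the 2^-ΔΔCt method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .variant_io import RecordValidationError

log = logging.getLogger(__name__)

ELISPOT_POSITIVITY_THRESHOLD = 500


@dataclass(frozen=True)
class ElispotResult:
    peptide_id: str
    spots: int
    positive: bool


@dataclass(frozen=True)
class AbsorbanceTriplet:
    """OD490 readings: sample well, spontaneous-release (low) control and
    maximal-release (high) control."""

    sample: float
    low_control: float
    high_control: float

    def __post_init__(self) -> None:
        if self.high_control == self.low_control:
            raise RecordValidationError(
                "high and low control absorbances are equal; "
                "cytotoxicity undefined"
            )


@dataclass(frozen=True)
class CytotoxicityResult:
    percent: float
    out_of_range: bool  # outside [0, 100]: kept unclamped for QC


def call_elispot(
    spots: int, peptide_id: str = "", threshold: int = ELISPOT_POSITIVITY_THRESHOLD
) -> ElispotResult:
    """Positive iff the spot count is strictly above the threshold.

    The boundary is exclusive: exactly ``threshold`` spots is negative.
    """
    if spots < 0:
        raise RecordValidationError(
            f"{peptide_id or 'ELISPOT'}: negative spot count {spots}"
        )
    return ElispotResult(peptide_id=peptide_id, spots=int(spots), positive=spots > threshold)


def cytotoxicity(t: AbsorbanceTriplet) -> CytotoxicityResult:
    """Percent lysis: (sample - low) / (high - low) * 100.

    Values outside [0, 100] (sample below spontaneous release or above
    maximal release) are returned as-is with ``out_of_range`` set, never
    clamped — out-of-range wells are a QC signal.
    """
    pct = (t.sample - t.low_control) / (t.high_control - t.low_control) * 100.0
    out = not 0.0 <= pct <= 100.0
    if out:
        log.warning("cytotoxicity %.1f%% outside [0, 100]: check controls", pct)
    return CytotoxicityResult(percent=pct, out_of_range=out)


def fold_change_ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression 2^-ΔΔCt against a reference gene (e.g. GAPDH).

    ΔΔCt = (Ct_target,sample - Ct_ref,sample) - (Ct_target,control - Ct_ref,control).
    """
    for name, ct in (
        ("ct_target_sample", ct_target_sample),
        ("ct_ref_sample", ct_ref_sample),
        ("ct_target_control", ct_target_control),
        ("ct_ref_control", ct_ref_control),
    ):
        if ct <= 0:
            raise RecordValidationError(f"{name}: Ct must be a positive cycle count")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_control - ct_ref_control)
    return float(2.0 ** -ddct)
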