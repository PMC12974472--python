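"""Gel-lane quantification: band intensities to species fractions.

Quantification follows the standard densitometry rule: the fraction of each
species is its band intensity divided by the total band intensity of the
lane.  Fluorescent labelling makes intensities proportional to molar
amounts, so fractions are invariant to detector gain.  Two gel modes exist:
high-resolution sequencing gels resolve substrate, abortive AMP-DNA and
sealed product as three bands; mini-gels do not resolve AMP-DNA from
substrate, in which case the substrate band carries the merged signal and
only the product fraction is meaningful.

Inputs are assumed background-corrected band volumes; image analysis is out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["LaneQuant", "SpeciesFractions", "EmptyLaneError",
           "lane_fractions", "fractions_to_concentrations"]


class EmptyLaneError(ValueError):
    """All band intensities in a lane are zero."""


@dataclass(frozen=True)
class LaneQuant:
    """Band intensities for one gel lane with its condition labels.

    ``resolved_intermediate=False`` marks mini-gel lanes where AMP-DNA
    co-migrates with substrate: ``intensity_intermediate`` must then be
    ``None`` and ``intensity_substrate`` holds the merged band.
    """

    lane: str
    enzyme_label: str
    substrate_label: str
    enzyme_conc: float
    time_s: float
    intensity_substrate: float
    intensity_product: float
    intensity_intermediate: float | None = None
    resolved_intermediate: bool = True

    def __post_init__(self):
        intensities = [self.intensity_substrate, self.intensity_product]
        if self.resolved_intermediate:
            if self.intensity_intermediate is None:
                raise ValueError("resolved lane requires intensity_intermediate")
            intensities.append(self.intensity_intermediate)
        elif self.intensity_intermediate is not None:
            raise ValueError("unresolved lane must not carry an intermediate band")
        if any(i < 0 for i in intensities):
            raise ValueError("band intensities must be >= 0")

    @property
    def condition(self) -> str:
        return f"{self.enzyme_label}|{self.substrate_label}|{self.enzyme_conc:g}nM"


@dataclass(frozen=True)
class SpeciesFractions:
    """Per-lane species fractions; they sum to 1 exactly.

    ``fraction_intermediate`` is ``None`` for unresolved (mini-gel) lanes,
    where ``fraction_substrate`` covers the merged substrate + AMP-DNA band.
    """

    fraction_substrate: float
    fraction_product: float
    fraction_intermediate: float | None = None


def lane_fractions(lane: LaneQuant) -> SpeciesFractions:
    """Species fractions: band intensity over total lane intensity."""
    inter = lane.intensity_intermediate if lane.resolved_intermediate else 0.0
    total = lane.intensity_substrate + lane.intensity_product + inter
    if total <= 0:
        raise EmptyLaneError(f"lane {lane.lane!r} has zero total intensity")
    return SpeciesFractions(
        fraction_substrate=lane.intensity_substrate / total,
        fraction_product=lane.intensity_product / total,
        fraction_intermediate=(inter / total if lane.resolved_intermediate else None),
    )


def fractions_to_concentrations(fractions: SpeciesFractions,
                                substrate_conc: float) -> dict:
    """Convert lane fractions to species concentrations (nM).

    Multiplies each fraction by the initial substrate concentration — the
    exact inverse of the fraction computation when intensities are
    proportional to amounts.
    """
    out = {
        "substrate": fractions.fraction_substrate * substrate_conc,
        "sealed": fractions.fraction_product * substrate_conc,
    }
    if fractions.fraction_intermediate is not None:
        out["intermediate"] = fractions.fraction_intermediate * substrate_conc
    return out
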