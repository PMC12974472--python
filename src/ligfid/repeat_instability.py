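"""Somatic CAG repeat expansion indices from fragment-analysis peak tables.

Somatic expansion of the HTT CAG repeat is quantified from capillary-
electrophoresis traces of repeat-spanning PCR products (GeneMapper-style
peak tables of fragment size and peak height).  The expansion index of a
trace is computed relative to a reference (modal) allele:

1. discard peaks whose height is below a relative threshold (default 5% of
   the tallest peak of the trace);
2. restrict to peaks longer than the reference repeat;
3. normalise the retained heights to sum to one;
4. the index is the height-weighted mean repeat-unit gain over the
   reference.

In mouse cohorts the reference is the modal allele of the liver trace of the
same mouse: the liver contains a repeat-stable cell population whose modal
length tracks the inherited allele even as the unstable hepatocyte
population expands with age.  Cohort comparisons use per-stratum (age x
tissue) one-way ANOVA with Tukey-adjusted pairwise genotype contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PeakTable",
    "InstabilityConfig",
    "ExpansionResult",
    "to_repeat_units",
    "call_modal",
    "expansion_index",
    "cohort_expansion",
    "compare_groups",
    "significance_tier",
]


def significance_tier(p: float) -> str:
    """Symbol tier for a p-value (thresholds 0.05 / 0.01 / 0.001 / 0.0001)."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class PeakTable:
    """One fragment-analysis trace: peak positions and heights.

    Positions are either repeat units or fragment sizes in bp
    (``position_units``); they must be strictly increasing with
    non-negative heights and at least one peak.
    """

    sample_id: str
    positions: np.ndarray
    heights: np.ndarray
    position_units: str = "repeats"
    mouse_id: str = ""
    tissue: str = ""
    genotype: str = ""
    age_months: float = float("nan")

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        hts = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "heights", hts)
        if pos.ndim != 1 or pos.shape != hts.shape or pos.size == 0:
            raise ValueError("positions and heights must be matching non-empty 1-D arrays")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("peak positions must be strictly increasing")
        if np.any(hts < 0):
            raise ValueError("peak heights must be >= 0")
        if self.position_units not in ("repeats", "bp"):
            raise ValueError("position_units must be 'repeats' or 'bp'")


@dataclass(frozen=True)
class InstabilityConfig:
    """Conventions of the expansion-index computation.

    ``threshold_fraction`` is relative to the tallest peak of the whole
    trace, with a >= comparison at the boundary.  ``signed`` switches on an
    instability-index mode that also includes contractions (peaks below the
    reference, with negative gains); off by default since expansion indices
    are the reported quantity.
    """

    threshold_fraction: float = 0.05
    reference_policy: str = "liver_modal"
    bp_per_repeat: int = 3
    bp_offset: float = 0.0
    signed: bool = False
    reference_guard: float = 10.0

    def __post_init__(self):
        if not 0 <= self.threshold_fraction < 1:
            raise ValueError("threshold_fraction must be in [0, 1)")
        if self.reference_policy not in ("liver_modal", "self_modal"):
            raise ValueError("reference_policy must be 'liver_modal' or 'self_modal'")
        if self.bp_per_repeat != 3:
            raise ValueError("CAG repeats are 3 bp per unit")


@dataclass(frozen=True)
class ExpansionResult:
    """Expansion index of one trace relative to a reference allele."""

    sample_id: str
    modal_repeat: float
    reference_repeat: float
    expansion_index: float
    n_peaks_retained: int
    weights: dict = field(default_factory=dict)  # repeat -> normalized weight


def to_repeat_units(table: PeakTable, config: InstabilityConfig | None = None) -> PeakTable:
    """Convert a bp-sized peak table to repeat units.

    ``repeat = round((bp - bp_offset) / 3)``; bp peaks that collapse onto
    the same integer repeat are merged by height summation.  Tables already
    in repeat units pass through unchanged.
    """
    config = config or InstabilityConfig()
    if table.position_units == "repeats":
        return table
    repeats = np.rint((table.positions - config.bp_offset) / config.bp_per_repeat)
    merged: dict[float, float] = {}
    for r, h in zip(repeats, table.heights):
        merged[r] = merged.get(r, 0.0) + h
    pos = np.array(sorted(merged), dtype=float)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("non-monotone repeat positions after conversion")
    hts = np.array([merged[r] for r in pos])
    return replace(table, positions=pos, heights=hts, position_units="repeats")


def call_modal(table: PeakTable) -> float:
    """Position of the tallest peak; exact ties break toward the smaller repeat."""
    idx = int(np.argmax(table.heights))  # argmax returns the first maximum
    return float(table.positions[idx])


def expansion_index(
    table: PeakTable,
    reference_repeat: float,
    config: InstabilityConfig | None = None,
) -> ExpansionResult:
    """Threshold-filtered, height-weighted mean repeat gain over a reference.

    The relative height threshold is applied to the whole trace before
    restricting to peaks beyond the reference.  An empty retained set yields
    index 0 with zero retained peaks.
    """
    config = config or InstabilityConfig()
    if table.position_units != "repeats":
        raise ValueError("table must be in repeat units (use to_repeat_units)")
    pos, hts = table.positions, table.heights
    if reference_repeat < pos.min() - config.reference_guard:
        warnings.warn(
            f"reference {reference_repeat} more than {config.reference_guard} "
            f"repeats below the smallest peak of {table.sample_id!r}",
            stacklevel=2)

    cutoff = config.threshold_fraction * hts.max()
    keep = hts >= cutoff
    if config.signed:
        keep &= pos != reference_repeat
    else:
        keep &= pos > reference_repeat
    modal = call_modal(table)
    if not keep.any() or hts[keep].sum() == 0:
        return ExpansionResult(sample_id=table.sample_id, modal_repeat=modal,
                               reference_repeat=float(reference_repeat),
                               expansion_index=0.0, n_peaks_retained=0)
    w = hts[keep] / hts[keep].sum()
    gains = pos[keep] - reference_repeat
    return ExpansionResult(
        sample_id=table.sample_id, modal_repeat=modal,
        reference_repeat=float(reference_repeat),
        expansion_index=float(w @ gains),
        n_peaks_retained=int(keep.sum()),
        weights={float(p): float(wi) for p, wi in zip(pos[keep], w)},
    )


def cohort_expansion(tables, config: InstabilityConfig | None = None) -> pd.DataFrame:
    """Expansion indices for a panel of mice, referenced per the config policy.

    Under ``liver_modal`` every tissue of a mouse is referenced to the modal
    allele of that mouse's liver trace (mice without a liver trace raise a
    ``ValueError`` listing the ids).  Returns a long-format table with one
    row per (mouse, tissue).
    """
    config = config or InstabilityConfig()
    tables = [to_repeat_units(t, config) for t in tables]
    by_mouse: dict[str, list[PeakTable]] = {}
    for t in tables:
        by_mouse.setdefault(t.mouse_id, []).append(t)

    if config.reference_policy == "liver_modal":
        missing = [m for m, ts in by_mouse.items()
                   if not any(t.tissue == "liver" for t in ts)]
        if missing:
            raise ValueError(f"missing liver trace for mice: {sorted(missing)}")

    rows = []
    for mouse in sorted(by_mouse):
        ts = by_mouse[mouse]
        if config.reference_policy == "liver_modal":
            liver = next(t for t in ts if t.tissue == "liver")
            reference = call_modal(liver)
        for t in sorted(ts, key=lambda t: t.tissue):
            ref = reference if config.reference_policy == "liver_modal" else call_modal(t)
            res = expansion_index(t, ref, config)
            rows.append({
                "mouse": mouse, "genotype": t.genotype, "age_months": t.age_months,
                "tissue": t.tissue, "reference_repeat": res.reference_repeat,
                "modal_repeat": res.modal_repeat,
                "expansion_index": res.expansion_index,
                "n_peaks_retained": res.n_peaks_retained,
            })
    return pd.DataFrame(rows)


def compare_groups(cohort: pd.DataFrame, group_col: str = "genotype") -> pd.DataFrame:
    """Per-stratum one-way ANOVA with Tukey-adjusted pairwise comparisons.

    Strata are (age, tissue) combinations; groups are genotypes.  Strata
    with fewer than two groups of at least two observations are skipped with
    a warning.  Returns one row per stratum per pairwise contrast, carrying
    the stratum-level F and p alongside the Tukey-adjusted pairwise p and
    its significance tier.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rows = []
    for (age, tissue), sub in cohort.groupby(["age_months", "tissue"]):
        counts = sub.groupby(group_col)["expansion_index"].count()
        usable = counts[counts >= 2]
        if len(usable) < 2:
            warnings.warn(f"stratum age={age}, tissue={tissue} skipped: "
                          "needs >= 2 groups with >= 2 observations", stacklevel=2)
            continue
        sub = sub[sub[group_col].isin(usable.index)]
        groups = [g["expansion_index"].to_numpy()
                  for _, g in sub.groupby(group_col)]
        f_stat, p = stats.f_oneway(*groups)
        tukey = pairwise_tukeyhsd(sub["expansion_index"].to_numpy(),
                                  sub[group_col].to_numpy())
        res = tukey.summary().data[1:]
        for g1, g2, meandiff, p_adj, *_ in res:
            rows.append({
                "age_months": age, "tissue": tissue,
                "F": float(f_stat), "p_anova": float(p),
                "group1": g1, "group2": g2,
                "mean_difference": float(meandiff),
                "p_tukey": float(p_adj),
                "tier": significance_tier(float(p_adj)),
            })
    return pd.DataFrame(rows)
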