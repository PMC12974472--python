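"""Synthetic-data generators for every pipeline input.

Each generator emulates the statistical structure of one raw-data stream of
the study — gel-based ligation time courses, active-site titrations,
fragment-analysis repeat traces and viability plates — and records its own
ground truth so downstream estimates can be scored as parameter recoveries.
All randomness flows through one seeded `numpy` generator per call
(identical seed and parameters give bit-identical output); band and peak
noise is multiplicative lognormal since intensities are strictly positive.

The default ligation schemes are synthetic calibration targets whose
implied steady-state parameters mirror the measured phenotypes of the
wild-type and K845N ligase on canonical (C:G) and 8-oxoG:A nicks —
microscopic rate constants themselves are not measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gel_quant import LaneQuant
from .mechanism import (KineticScheme, scheme_from_steady_state,
                        scheme_steady_state, simulate_timecourse)
from .repeat_instability import PeakTable

__all__ = [
    "NoiseModel",
    "TraceSpec",
    "default_schemes",
    "make_ligation_dataset",
    "make_titration_dataset",
    "make_fragment_trace",
    "make_cohort",
    "make_viability_plate",
    "make_mf_table",
    "make_ct_table",
]


@dataclass(frozen=True)
class NoiseModel:
    """Noise levels for the generators (all multiplicative CVs) plus a seed."""

    intensity_cv: float = 0.05
    height_cv: float = 0.05
    plate_cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.intensity_cv, self.height_cv, self.plate_cv) < 0:
            raise ValueError("all CVs must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise factors with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2, sigma=sigma, size=size)


def default_schemes() -> dict:
    """Ground-truth schemes for {WT, K845N} x {C:G, 8-oxoG:A}.

    Calibrated so the implied steady-state parameters reproduce the
    measured pattern: near-normal canonical activity for the variant
    (k_cat 0.52 vs 0.20 /s), a severe k_cat defect and mostly-abortive
    turnover (abortive fraction 0.51 vs 0.93) on the oxidized mispair.
    """
    return {
        ("WT", "C:G"): scheme_from_steady_state(0.52, 100.0, 0.10),
        ("WT", "8-oxoG:A"): scheme_from_steady_state(0.152, 150.0, 0.51),
        ("K845N", "C:G"): scheme_from_steady_state(0.20, 190.0, 0.18),
        ("K845N", "8-oxoG:A"): scheme_from_steady_state(0.00608, 345.0, 0.93),
    }


@dataclass
class LigationDataset:
    """Synthetic gel-quantified ligation dataset with its ground truth."""

    lanes: list          # of LaneQuant
    frame: pd.DataFrame  # same content, tabular
    truth: dict          # (enzyme, substrate) -> scheme steady-state dict
    gains: dict          # lane id -> proportionality constant


def make_ligation_dataset(
    schemes: dict,
    substrate_grid,
    times,
    enzyme_conc: float,
    noise: NoiseModel,
    replicates: int = 1,
    resolved: bool = True,
) -> LigationDataset:
    """Gel lanes for simulated time courses under each scheme.

    For every (condition, substrate concentration, replicate) a time course
    is simulated and each time point becomes one lane whose band
    intensities are proportional to the species amounts (substrate band
    carries enzyme-bound DNA, as on a denaturing gel) with a per-lane gain
    and multiplicative lognormal noise per band.
    """
    if len(schemes) < 2:
        raise ValueError("need at least two conditions")
    rng = noise.rng()
    times = np.asarray(times, dtype=float)
    lanes, rows = [], []
    truth = {cond: scheme_steady_state(s) for cond, s in schemes.items()}
    gains = {}
    for (enzyme, substrate), scheme in sorted(schemes.items()):
        for s0 in np.asarray(substrate_grid, dtype=float):
            course = simulate_timecourse(scheme, enzyme_conc, s0, times,
                                         enzyme_label=enzyme,
                                         substrate_label=substrate)
            for rep in range(replicates):
                for j, t in enumerate(times):
                    lane_id = f"{enzyme}|{substrate}|S{s0:g}|r{rep}|t{t:g}"
                    gain = rng.uniform(0.8, 1.2)
                    gains[lane_id] = gain
                    f = _lognormal_factors(rng, noise.intensity_cv, 3)
                    sub_band = gain * (course.S[j] + course.bound[j]) * f[0]
                    int_band = gain * course.I[j] * f[1]
                    prod_band = gain * course.P[j] * f[2]
                    if not resolved:
                        sub_band = sub_band + int_band
                    lane = LaneQuant(
                        lane=lane_id, enzyme_label=enzyme,
                        substrate_label=substrate, enzyme_conc=enzyme_conc,
                        time_s=float(t),
                        intensity_substrate=sub_band,
                        intensity_product=prod_band,
                        intensity_intermediate=int_band if resolved else None,
                        resolved_intermediate=resolved)
                    lanes.append(lane)
                    rows.append({
                        "lane": lane_id, "enzyme": enzyme,
                        "substrate_context": substrate,
                        "enzyme_conc_nM": enzyme_conc,
                        "substrate_conc_nM": s0, "replicate": rep,
                        "time_s": float(t),
                        "intensity_substrate": sub_band,
                        "intensity_intermediate": int_band if resolved else np.nan,
                        "intensity_product": prod_band,
                        "resolved": resolved})
    return LigationDataset(lanes=lanes, frame=pd.DataFrame(rows),
                           truth=truth, gains=gains)


def make_titration_dataset(
    active_fraction: float,
    nominal_enzyme,
    dna_conc: float,
    noise: NoiseModel,
) -> pd.DataFrame:
    """Single-turnover titration table: product vs nominal enzyme.

    Product amplitude is ``min(active_fraction * nominal, dna_conc)`` with
    multiplicative noise.  The nominal-enzyme grid must bracket the
    breakpoint ``dna_conc / active_fraction`` or the titration is
    unidentifiable.
    """
    if not 0 < active_fraction <= 1:
        raise ValueError("active_fraction must be in (0, 1]")
    x = np.asarray(nominal_enzyme, dtype=float)
    breakpoint = dna_conc / active_fraction
    if not (x.min() < breakpoint < x.max()):
        raise ValueError(
            f"nominal-enzyme grid must bracket the breakpoint {breakpoint:g} nM")
    rng = noise.rng()
    product = np.minimum(active_fraction * x, dna_conc)
    product = product * _lognormal_factors(rng, noise.intensity_cv, x.size)
    return pd.DataFrame({"nominal_enzyme_nM": x, "product_nM": product})


@dataclass(frozen=True)
class TraceSpec:
    """Population model behind one synthetic repeat trace.

    A ``stable_fraction`` of cells keeps the inherited repeat length; the
    rest gain repeats with a right-skewed (discretized gamma) distribution
    of mean ``expansion_mean`` and standard deviation
    ``expansion_dispersion``.  PCR stutter adds geometrically decaying
    satellite peaks below each true allele.
    """

    inherited_repeat: int = 111
    expansion_mean: float = 8.0
    expansion_dispersion: float = 4.0
    stutter_decay: float = 0.25
    stable_fraction: float = 0.4
    bp_offset: float = 0.0
    bp_per_repeat: int = 3

    def __post_init__(self):
        if not 0 <= self.stable_fraction <= 1:
            raise ValueError("stable_fraction must be in [0, 1]")
        if not 0 <= self.stutter_decay < 1:
            raise ValueError("stutter_decay must be in [0, 1)")
        if self.bp_per_repeat != 3:
            raise ValueError("CAG repeats are 3 bp per unit")
        if self.expansion_mean < 0 or self.expansion_dispersion < 0:
            raise ValueError("expansion mean and dispersion must be >= 0")

    def gain_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact repeat-gain mass function (gains, probabilities).

        Gain 0 carries the stable fraction; gains >= 1 carry the expanded
        fraction with gamma mass discretized to unit bins and renormalised.
        """
        if self.stable_fraction == 1 or self.expansion_mean == 0:
            return np.array([0]), np.array([1.0])
        mean, sd = self.expansion_mean, max(self.expansion_dispersion, 1e-9)
        shape = (mean / sd) ** 2
        scale = sd * sd / mean
        g_max = max(int(np.ceil(mean + 10 * sd)), 2)
        gains = np.arange(1, g_max + 1)
        cdf = stats.gamma.cdf
        mass = cdf(gains + 0.5, shape, scale=scale) - cdf(gains - 0.5, shape, scale=scale)
        if mass.sum() <= 0:
            mass = np.zeros_like(mass)
            mass[0] = 1.0
        mass = mass / mass.sum() * (1.0 - self.stable_fraction)
        gains = np.concatenate([[0], gains])
        probs = np.concatenate([[self.stable_fraction], mass])
        return gains, probs

    def true_expansion_index(self) -> float:
        """Height-weighted mean gain above the inherited allele, no threshold."""
        gains, probs = self.gain_pmf()
        tail = gains > 0
        if probs[tail].sum() == 0:
            return 0.0
        w = probs[tail] / probs[tail].sum()
        return float(w @ gains[tail])


def make_fragment_trace(
    spec: TraceSpec,
    noise: NoiseModel,
    sample_id: str = "synthetic",
    scale: float = 10_000.0,
    stutter_max: int = 6,
    units: str = "repeats",
    **labels,
) -> tuple[PeakTable, dict]:
    """One synthetic repeat-size trace with its ground truth.

    Allele mass is placed at ``inherited_repeat + gain``; each allele sheds
    downward stutter peaks at ``decay**j`` of its height for ``j = 1 ..
    stutter_max`` units below.  Heights get multiplicative lognormal noise.
    Returns the peak table and a truth dict holding the spec, the exact
    gain mass function and the true (threshold-free) expansion index.
    """
    rng = noise.rng()
    gains, probs = spec.gain_pmf()
    heights: dict[int, float] = {}
    for g, p in zip(gains, probs):
        if p <= 0:
            continue
        allele = spec.inherited_repeat + int(g)
        heights[allele] = heights.get(allele, 0.0) + p
        for j in range(1, stutter_max + 1):
            contrib = p * spec.stutter_decay ** j
            if contrib < 1e-9:
                break
            heights[allele - j] = heights.get(allele - j, 0.0) + contrib
    repeats = np.array(sorted(heights), dtype=float)
    hts = np.array([heights[int(r)] for r in repeats]) * scale
    hts = hts * _lognormal_factors(rng, noise.height_cv, hts.size)
    positions = repeats
    if units == "bp":
        positions = spec.bp_offset + spec.bp_per_repeat * repeats
    table = PeakTable(sample_id=sample_id, positions=positions, heights=hts,
                      position_units=units, **labels)
    truth = {"spec": spec, "gains": gains, "probs": probs,
             "true_index": spec.true_expansion_index()}
    return table, truth


def make_cohort(
    expansion_mean_by_genotype: dict,
    n_mice: int,
    noise: NoiseModel,
    age_months: float = 6.0,
    inherited_repeat: int = 111,
    tissues: tuple = ("striatum", "liver"),
    liver_attenuation: float = 0.6,
    **spec_kwargs,
) -> tuple[list, dict]:
    """Synthetic mouse panel: one trace per mouse per tissue.

    Each genotype gets ``n_mice`` mice; the striatum expands with the
    genotype's ``expansion_mean`` and the liver with an attenuated mean
    (its stable cell population keeps the modal allele at the inherited
    length, which is what makes it usable as the reference).  Returns the
    peak tables and a truth dict mapping (mouse, tissue) to the trace
    ground truth.
    """
    rng = np.random.default_rng(noise.seed)
    tables, truth = [], {}
    for genotype, mean in sorted(expansion_mean_by_genotype.items()):
        for i in range(n_mice):
            mouse = f"{genotype}_m{i}"
            for tissue in tissues:
                tissue_mean = mean * (liver_attenuation if tissue == "liver" else 1.0)
                spec = TraceSpec(
                    inherited_repeat=inherited_repeat,
                    expansion_mean=tissue_mean,
                    expansion_dispersion=max(0.5 * tissue_mean, 1.0),
                    stable_fraction=0.6 if tissue == "liver" else 0.4,
                    **spec_kwargs)
                sub_noise = NoiseModel(
                    intensity_cv=noise.intensity_cv, height_cv=noise.height_cv,
                    plate_cv=noise.plate_cv,
                    seed=int(rng.integers(0, 2**31 - 1)))
                table, t = make_fragment_trace(
                    spec, sub_noise, sample_id=f"{mouse}_{tissue}",
                    mouse_id=mouse, tissue=tissue, genotype=genotype,
                    age_months=age_months)
                tables.append(table)
                truth[(mouse, tissue)] = t
    return tables, truth


def make_viability_plate(
    effects: pd.DataFrame,
    replicates: int,
    noise: NoiseModel,
    technical: int = 3,
    baseline_signal: float = 1e6,
) -> pd.DataFrame:
    """Raw ATP-signal plate from a table of expected viabilities.

    ``effects`` has columns ``group``, ``dose_uM``, ``recovery_h`` and
    ``percent`` (expected % of untreated).  Untreated (dose 0) wells are
    added automatically at 100% for every (group, recovery) stratum that
    lacks them.  Each of ``replicates`` biological replicates gets
    ``technical`` wells per condition with multiplicative lognormal noise.
    """
    required = {"group", "dose_uM", "recovery_h", "percent"}
    if not required <= set(effects.columns):
        raise ValueError(f"effects table needs columns {sorted(required)}")
    rng = noise.rng()
    eff = effects.copy()
    extra = []
    for (group, rec), sub in eff.groupby(["group", "recovery_h"]):
        if not (sub["dose_uM"] == 0).any():
            extra.append({"group": group, "dose_uM": 0.0,
                          "recovery_h": rec, "percent": 100.0})
    if extra:
        eff = pd.concat([eff, pd.DataFrame(extra)], ignore_index=True)

    rows = []
    for _, r in eff.sort_values(["group", "recovery_h", "dose_uM"]).iterrows():
        mean_signal = baseline_signal * r["percent"] / 100.0
        for rep in range(replicates):
            f = _lognormal_factors(rng, noise.plate_cv, technical)
            for tech in range(technical):
                rows.append({
                    "group": r["group"], "dose_uM": r["dose_uM"],
                    "recovery_h": r["recovery_h"], "replicate": rep,
                    "technical": tech,
                    "signal": mean_signal * f[tech]})
    return pd.DataFrame(rows)


def make_mf_table(
    effects: pd.DataFrame,
    replicates: int,
    noise: NoiseModel,
) -> pd.DataFrame:
    """Mutation-frequency table from expected per-dose fold effects.

    ``effects`` has columns ``group``, ``dose_uM`` and ``mf`` (expected
    mutation frequency); each biological replicate gets multiplicative
    lognormal noise.
    """
    required = {"group", "dose_uM", "mf"}
    if not required <= set(effects.columns):
        raise ValueError(f"effects table needs columns {sorted(required)}")
    rng = noise.rng()
    rows = []
    for _, r in effects.sort_values(["group", "dose_uM"]).iterrows():
        f = _lognormal_factors(rng, noise.plate_cv, replicates)
        for rep in range(replicates):
            rows.append({"group": r["group"], "dose_uM": r["dose_uM"],
                         "replicate": rep, "mf": r["mf"] * f[rep]})
    return pd.DataFrame(rows)


def make_ct_table(
    fold_by_group: dict,
    n_per_group: int,
    noise_sd: float,
    seed: int = 0,
    target: str = "Lig1",
    housekeeping: tuple = ("Ppia", "Actb", "Gusb"),
    housekeeping_ct: float = 20.0,
    target_delta: float = 5.0,
) -> pd.DataFrame:
    """qPCR Ct table with known expression fold changes per group.

    The control group (fold 1) has target Ct ``housekeeping_ct +
    target_delta``; a group with fold f has target Ct lower by log2(f).
    Additive normal noise of ``noise_sd`` cycles on every Ct measurement.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, fold in fold_by_group.items():
        for i in range(n_per_group):
            sample = f"{group}_{i}"
            for gene in housekeeping:
                rows.append({"sample": sample, "group": group, "gene": gene,
                             "ct": housekeeping_ct + rng.normal(0, noise_sd)})
            ct_target = housekeeping_ct + target_delta - np.log2(fold)
            rows.append({"sample": sample, "group": group, "gene": target,
                         "ct": ct_target + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)
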