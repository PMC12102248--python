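"""Dissolved phosphite and phosphate in Neoarchean-Paleoproterozoic surface seawater.

The reconstruction inverts the linear sorption isotherm: if banded iron
formations precipitated as hydrous ferric oxide (HFO) in the photic zone,
the dissolved concentration of a P species at the time of deposition is

    [P]_d  =  (1 / K_ads) * (P_ads / Fe_ads)            [µM]

where the sorbed-P/sorbed-Fe molar ratio is taken from the rock (bulk Fe and
a P-species partition of bulk P) and K_ads from co-precipitation
experiments.  Two sources of uncertainty are bracketed by scenarios:

* Extraction representativeness — the mild EDTA-NaOH leach recovers only a
  few percent of total P.  Either the species ratio in the extract equals
  that in the rock (``ratio``), or the leach recovered *all* rock-hosted
  phosphite (``complete``), which minimises the phosphite inventory.
* Metamorphic phosphite — burial metamorphism of ferruginous sediment can
  reduce some phosphate to phosphite.  Either none of the measured
  phosphite is metamorphic (yield 0), or a published experimental yield
  (0.075% of the coexisting phosphate pool at 350 °C) is subtracted, or
  (scenario 5) all of it is metamorphic, in which case no primary seawater
  phosphite can be estimated at all.

Scenario grid: 1 = ratio/no-metamorphic, 2a/2b = ratio/experimental yield,
3 = complete/no-metamorphic, 4a/4b = complete/experimental yield,
5 = all phosphite metamorphic (estimation not possible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .sorption import ValidationError

logger = logging.getLogger(__name__)

M_P = 30.974    # g/mol
M_FE = 55.845   # g/mol

#: Yield of metamorphic P(V) -> P(III) reduction at 350 °C (0.075%),
#: used by scenarios 2b and 4b.
METAMORPHIC_YIELD_350C = 0.00075

#: Adsorption coefficients used for the seawater estimates: the pH 6.75
#: values (consistent with estimated Archean seawater pH) in Si-bearing
#: artificial seawater.  µM⁻¹; fully configurable.
DEFAULT_KADS_P5 = 0.026
DEFAULT_KADS_P3 = 0.0005

Assumption = Literal["ratio", "complete"]
SCENARIO_IDS = ("1", "2a", "2b", "3", "4a", "4b", "5")


@dataclass(frozen=True)
class BifSample:
    """Per-sample extract speciation (ppm of rock) plus bulk P and Fe."""

    sample_id: str
    formation: str
    extract_p3: float   # phosphite, ppm rock basis
    extract_p5: float   # phosphate, ppm rock basis
    extract_pp: float   # pyrophosphate, ppm rock basis
    total_p: float      # bulk rock, ppm
    total_fe: float     # bulk rock, wt%

    def __post_init__(self) -> None:
        for name in ("extract_p3", "extract_p5", "extract_pp", "total_p", "total_fe"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.total_fe > 70:
            raise ValidationError(f"total_fe {self.total_fe} wt% exceeds 70 wt%")
        extract_sum = self.extract_p3 + self.extract_p5 + self.extract_pp
        if extract_sum > self.total_p * (1 + 1e-9):
            raise ValidationError(
                f"extract species sum {extract_sum:.4g} ppm exceeds bulk total P {self.total_p:.4g} ppm"
            )


@dataclass(frozen=True)
class ScenarioSpec:
    """One bracketing scenario: extraction assumption x metamorphic yield."""

    id: str
    extraction_assumption: Assumption
    metamorphic_yield: float    # fraction of coexisting P(V) converted to P(III)
    all_metamorphic: bool = False  # scenario 5: no primary phosphite estimable

    def __post_init__(self) -> None:
        if self.id not in SCENARIO_IDS:
            raise ValidationError(f"unknown scenario id {self.id!r}; valid: {SCENARIO_IDS}")
        if not (0.0 <= self.metamorphic_yield <= 1.0):
            raise ValidationError(f"metamorphic_yield must be in [0, 1], got {self.metamorphic_yield}")


def default_scenarios(
    yield_a: float | None = None,
    yield_b: float = METAMORPHIC_YIELD_350C,
) -> list[ScenarioSpec]:
    """The scenario grid.

    ``yield_a`` (scenarios 2a/4a) comes from a separate published experiment
    and has no default here: those scenarios are included only when a value
    is supplied.
    """
    scenarios = [
        ScenarioSpec("1", "ratio", 0.0),
        ScenarioSpec("2b", "ratio", yield_b),
        ScenarioSpec("3", "complete", 0.0),
        ScenarioSpec("4b", "complete", yield_b),
        ScenarioSpec("5", "ratio", 0.0, all_metamorphic=True),
    ]
    if yield_a is not None:
        scenarios.insert(1, ScenarioSpec("2a", "ratio", yield_a))
        scenarios.insert(4, ScenarioSpec("4a", "complete", yield_a))
    return scenarios


# ---------------------------------------------------------------------------
# the estimation chain

def partition_bif_phosphorus(sample: BifSample, assumption: Assumption) -> tuple[float, float]:
    """Partition bulk rock P into phosphite and phosphate pools (ppm).

    ``ratio``: the extract's species proportions are applied to bulk total P
    (pyrophosphate counts in the denominator as measured dissolved P but is
    not itself projected to seawater).  ``complete``: the leach recovered all
    rock phosphite, so the phosphite pool is the extract value and all the
    remainder of bulk P is phosphate.
    """
    if assumption == "ratio":
        denom = sample.extract_p3 + sample.extract_p5 + sample.extract_pp
        if denom <= 0:
            raise ValidationError(
                f"extract species sum is zero for {sample.sample_id}: ratio partition undefined"
            )
        p3 = sample.total_p * sample.extract_p3 / denom
        p5 = sample.total_p * sample.extract_p5 / denom
    elif assumption == "complete":
        p3 = sample.extract_p3
        p5 = sample.total_p - sample.extract_p3
    else:
        raise ValidationError(f"unknown extraction assumption {assumption!r}")
    return p3, p5


def metamorphic_correct(p3_bif: float, p5_bif: float, yield_: float) -> tuple[float, bool]:
    """Subtract the metamorphically produced phosphite from the rock pool.

    The secondary phosphite is modelled as ``yield_`` times the coexisting
    phosphate pool; the primary (seawater-sorbed) phosphite is floored at
    zero, with a flag when flooring occurred.
    """
    if not (0.0 <= yield_ <= 1.0):
        raise ValidationError(f"yield must be in [0, 1], got {yield_}")
    primary = p3_bif - yield_ * p5_bif
    if primary < 0:
        return 0.0, True
    return primary, False


def dissolved_concentration(p_bif_ppm: float, fe_bif_wt_pct: float, kads: float) -> float:
    """Invert the isotherm: dissolved seawater concentration in µM.

    The rock-based sorbed-P/sorbed-Fe molar ratio is
    (p_bif [g/g] / M_P) / (fe_bif [g/g] / M_Fe); dividing by K_ads (µM⁻¹)
    gives the dissolved concentration in µM.
    """
    if fe_bif_wt_pct <= 0:
        raise ValidationError(f"bulk Fe must be > 0 wt%, got {fe_bif_wt_pct}")
    if kads <= 0:
        raise ValidationError(f"K_ads must be > 0, got {kads}")
    molar_ratio = (p_bif_ppm * 1e-6 / M_P) / (fe_bif_wt_pct * 1e-2 / M_FE)
    return molar_ratio / kads


def phosphite_fraction(p3_d: float, p5_d: float) -> float:
    """Phosphite as a percentage of total dissolved inorganic P."""
    total = p3_d + p5_d
    if total <= 0:
        raise ValidationError("both dissolved concentrations are zero: fraction undefined")
    return 100.0 * p3_d / total


# ---------------------------------------------------------------------------
# scenario table

@dataclass(frozen=True)
class SeawaterEstimate:
    sample_id: str
    formation: str
    scenario_id: str
    p3_dissolved: float      # µM; 0 and flagged for scenario 5
    p5_dissolved: float      # µM
    p3_fraction: float | None  # % of dissolved inorganic P; None when undefined
    p3_floored: bool         # metamorphic correction drove phosphite below 0
    p3_not_estimable: bool   # scenario 5: all phosphite metamorphic


@dataclass(frozen=True)
class KadsPair:
    kads_p5: float = DEFAULT_KADS_P5
    kads_p3: float = DEFAULT_KADS_P3

    def __post_init__(self) -> None:
        if self.kads_p5 <= 0 or self.kads_p3 <= 0:
            raise ValidationError("both K_ads values must be > 0")


def estimate_sample(sample: BifSample, kads: KadsPair, scenario: ScenarioSpec) -> SeawaterEstimate:
    """Chain partition -> metamorphic correction -> isotherm inversion for one sample."""
    p3_bif, p5_bif = partition_bif_phosphorus(sample, scenario.extraction_assumption)
    if scenario.all_metamorphic:
        p3_primary, floored = 0.0, False
    else:
        p3_primary, floored = metamorphic_correct(p3_bif, p5_bif, scenario.metamorphic_yield)
    p3_d = dissolved_concentration(p3_primary, sample.total_fe, kads.kads_p3)
    p5_d = dissolved_concentration(p5_bif, sample.total_fe, kads.kads_p5)
    frac = phosphite_fraction(p3_d, p5_d) if (p3_d + p5_d) > 0 else None
    if scenario.all_metamorphic:
        frac = None
    return SeawaterEstimate(
        sample_id=sample.sample_id,
        formation=sample.formation,
        scenario_id=scenario.id,
        p3_dissolved=p3_d,
        p5_dissolved=p5_d,
        p3_fraction=frac,
        p3_floored=floored,
        p3_not_estimable=scenario.all_metamorphic,
    )


def run_scenarios(
    samples: Sequence[BifSample],
    kads: KadsPair | None = None,
    scenarios: Sequence[ScenarioSpec] | None = None,
) -> pd.DataFrame:
    """Per-sample seawater estimates for every scenario.

    Returns a tidy frame with one row per sample x scenario; aggregate with
    :func:`formation_ranges` and render with :func:`format_table`.
    """
    if kads is None:
        kads = KadsPair()
    if scenarios is None:
        scenarios = default_scenarios()
    if not samples:
        raise ValidationError("need at least one sample")
    rows = []
    for sc in scenarios:
        for s in samples:
            est = estimate_sample(s, kads, sc)
            rows.append(vars(est) | {})
    df = pd.DataFrame(rows)
    # deterministic order regardless of input ordering
    return df.sort_values(["scenario_id", "formation", "sample_id"]).reset_index(drop=True)


def formation_ranges(estimates: pd.DataFrame) -> pd.DataFrame:
    """(min, max) of the dissolved estimates per formation x scenario."""
    g = estimates.groupby(["formation", "scenario_id"], sort=True)
    out = g.agg(
        p3_min=("p3_dissolved", "min"),
        p3_max=("p3_dissolved", "max"),
        p5_min=("p5_dissolved", "min"),
        p5_max=("p5_dissolved", "max"),
        n_samples=("sample_id", "count"),
        any_floored=("p3_floored", "any"),
        not_estimable=("p3_not_estimable", "any"),
    ).reset_index()
    return out


def _render_conc(value: float) -> str:
    """Three-decimal µM rendering; sub-0.5 nM values print as '0.000*'."""
    if value < 0.0005:
        return "0.000*"
    return f"{value:.3f}"


def format_table(ranges: pd.DataFrame) -> pd.DataFrame:
    """Report-style formation x scenario table of concentration ranges (µM).

    Sub-0.5 nM endpoints render as "0.000*"; scenario-5 phosphite renders
    as "ENP" (estimation not possible: all phosphite metamorphic).
    """
    rows = []
    for _, r in ranges.iterrows():
        if r["not_estimable"]:
            p3 = "ENP"
        else:
            p3 = f"{_render_conc(r['p3_min'])}–{_render_conc(r['p3_max'])}"
        p5 = f"{_render_conc(r['p5_min'])}–{_render_conc(r['p5_max'])}"
        rows.append(
            {
                "formation": r["formation"],
                "scenario": r["scenario_id"],
                "P(III) (µM)": p3,
                "P(V) (µM)": p5,
            }
        )
    return pd.DataFrame(rows)


def samples_to_frame(samples: Iterable[BifSample]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in samples])


def frame_to_samples(df: pd.DataFrame) -> list[BifSample]:
    cols = list(BifSample.__dataclass_fields__)
    return [BifSample(**{c: row[c] for c in cols}) for _, row in df.iterrows()]
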