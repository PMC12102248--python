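"""Adsorption coefficients from hydrous-ferric-oxide co-precipitation experiments.

Banded iron formations are assumed to have precipitated as hydrous ferric
oxide (HFO) in the photic zone.  Co-precipitation experiments with Fe(II)
and dissolved phosphate (P(V)) or phosphite (P(III)) measure how strongly
each species is removed with the precipitate.  In the studied concentration
range the isotherm is linear,

    P_ads / Fe_ads = K_ads * [P]_d

where ``P_ads`` and ``Fe_ads`` are sorbed (adsorbed + lattice-incorporated)
phosphorus and iron in µM, ``[P]_d`` is dissolved P at equilibrium in µM,
and ``K_ads`` (µM⁻¹) is the adsorption coefficient.  This module turns raw
experiment records (including the dilution bookkeeping from pH titration)
into sorption points, fits K_ads by ordinary least squares with or without
a forced zero intercept, and compares coefficients between species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_SPECIES = ("PV", "PIII")
VALID_MATRICES = ("DI", "DiluSeaSi", "SeaSi")


class ValidationError(ValueError):
    """Raised when a record or simulation spec violates its invariants."""


@dataclass(frozen=True)
class SorptionExperiment:
    """One co-precipitation run.

    Concentrations are as measured in the sampled aliquot, which may have
    been diluted by the NaOH/HCl additions used to hold pH; multiply by
    ``dilution_factor`` to recover in-vessel values.
    """

    species: str           # "PV" or "PIII"
    matrix: str            # "DI", "DiluSeaSi" or "SeaSi"
    ph: float
    duration_h: float
    p_initial: float       # µM, in vessel before precipitation
    p_final_dissolved: float   # µM, measured in the (diluted) aliquot
    fe_initial: float      # µM
    fe_final_dissolved: float  # µM, measured in the (diluted) aliquot
    dilution_factor: float = 1.0
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if self.species not in VALID_SPECIES:
            raise ValidationError(f"species must be one of {VALID_SPECIES}, got {self.species!r}")
        if self.matrix not in VALID_MATRICES:
            raise ValidationError(f"matrix must be one of {VALID_MATRICES}, got {self.matrix!r}")
        if self.p_initial < 0:
            raise ValidationError(f"p_initial must be >= 0, got {self.p_initial}")
        if self.dilution_factor < 1:
            raise ValidationError(f"dilution_factor must be >= 1, got {self.dilution_factor}")
        if self.fe_initial <= 0:
            raise ValidationError(f"fe_initial must be > 0, got {self.fe_initial}")


@dataclass(frozen=True)
class SorptionPoint:
    """One point of the linear isotherm: x = dissolved P (µM), y = sorbed-P/sorbed-Fe."""

    x: float
    y: float
    negative_sorbed: bool = False  # y < 0 from measurement noise; kept, flagged


@dataclass(frozen=True)
class IsothermFit:
    """Least-squares estimate of the adsorption coefficient K_ads (µM⁻¹)."""

    kads: float
    intercept: float
    stderr_kads: float
    r_squared: float
    n_points: int
    forced_origin: bool


def compute_sorbed(exp: SorptionExperiment) -> SorptionPoint:
    """Convert an experiment record into an isotherm point.

    Aliquot concentrations are scaled back to in-vessel values with the
    dilution factor; sorbed amounts follow by mass balance against the
    initial load.

    Raises
    ------
    ValidationError
        If no Fe precipitated (sorbed Fe <= 0), the ratio is undefined.
    """
    p_final = exp.p_final_dissolved * exp.dilution_factor
    fe_final = exp.fe_final_dissolved * exp.dilution_factor
    sorbed_p = exp.p_initial - p_final
    sorbed_fe = exp.fe_initial - fe_final
    if sorbed_fe <= 0:
        raise ValidationError(
            f"sorbed Fe = {sorbed_fe:.4g} µM <= 0: no precipitate formed, "
            "sorbed-P/sorbed-Fe ratio is undefined"
        )
    y = sorbed_p / sorbed_fe
    negative = y < 0
    if negative:
        logger.warning(
            "negative sorbed P (%.4g µM) for replicate %s; retained and flagged",
            sorbed_p, exp.replicate_id,
        )
    return SorptionPoint(x=p_final, y=y, negative_sorbed=negative)


def fit_kads(
    points: Sequence[SorptionPoint],
    forced_origin: bool = False,
    average_replicates: bool = False,
) -> IsothermFit:
    """Fit the linear isotherm y = K_ads * x (+ intercept) by unweighted OLS.

    Parameters
    ----------
    points
        Isotherm points; mildly negative y (measurement noise) are retained.
    forced_origin
        Fix the intercept at 0 (slope = Σxy/Σx²).  Published trend lines for
        seawater-estimate coefficients go through the origin; free-intercept
        fits are used to display raw phosphite sorption data.
    average_replicates
        Pre-average replicate points sharing the same x before fitting
        (default: fit raw points).
    """
    x = np.asarray([p.x for p in points], dtype=float)
    y = np.asarray([p.y for p in points], dtype=float)
    if average_replicates and x.size:
        df = pd.DataFrame({"x": x, "y": y}).groupby("x", as_index=False).mean()
        x, y = df["x"].to_numpy(), df["y"].to_numpy()
    n = x.size
    min_n = 1 if forced_origin else 2
    if n < min_n:
        raise ValidationError(f"need at least {min_n} points, got {n}")

    if forced_origin:
        sxx = float(np.dot(x, x))
        if sxx == 0:
            raise ValidationError("all x are zero: forced-origin slope undefined")
        slope = float(np.dot(x, y)) / sxx
        intercept = 0.0
        resid = y - slope * x
        dof = n - 1
        stderr = math.sqrt(float(np.dot(resid, resid)) / dof / sxx) if dof > 0 else 0.0
        ss_tot = float(np.dot(y, y))  # uncentred R² for through-origin fit
        r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 1.0
    else:
        sxx = float(np.sum((x - x.mean()) ** 2))
        if sxx == 0:
            raise ValidationError("all x identical: free-intercept fit is singular")
        sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
        slope = sxy / sxx
        intercept = float(y.mean() - slope * x.mean())
        resid = y - (slope * x + intercept)
        dof = n - 2
        stderr = math.sqrt(float(np.dot(resid, resid)) / dof / sxx) if dof > 0 else 0.0
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 1.0

    return IsothermFit(
        kads=slope,
        intercept=intercept,
        stderr_kads=stderr,
        r_squared=r2,
        n_points=n,
        forced_origin=forced_origin,
    )


def kads_fold_ratio(fit_pv: IsothermFit | float, fit_piii: IsothermFit | float) -> float:
    """How many times more strongly P(V) sorbs than P(III): K_ads(PV)/K_ads(PIII).

    Accepts fits or bare coefficients.  Round the result for report display
    (e.g. 0.039/0.0011 -> 35, 0.021/0.0008 -> 26).
    """
    kv = fit_pv.kads if isinstance(fit_pv, IsothermFit) else float(fit_pv)
    k3 = fit_piii.kads if isinstance(fit_piii, IsothermFit) else float(fit_piii)
    if k3 <= 0:
        raise ValidationError(f"P(III) K_ads must be > 0, got {k3}")
    return kv / k3


def experiments_to_points(experiments: Iterable[SorptionExperiment]) -> list[SorptionPoint]:
    """Map a collection of experiment records to isotherm points."""
    return [compute_sorbed(e) for e in experiments]


def experiments_to_frame(experiments: Iterable[SorptionExperiment]) -> pd.DataFrame:
    """Tabulate experiment records (CSV-ready, columns mirror the dataclass)."""
    return pd.DataFrame([vars(e) for e in experiments])


def frame_to_experiments(df: pd.DataFrame) -> list[SorptionExperiment]:
    """Inverse of :func:`experiments_to_frame`."""
    cols = [f for f in SorptionExperiment.__dataclass_fields__]
    return [SorptionExperiment(**{c: row[c] for c in cols}) for _, row in df.iterrows()]
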