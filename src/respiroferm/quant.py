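"""Culture quantitation: specific uptake rates, intracellular concentration
correction, growth-rate estimation from plate-reader curves, and molar yields.

The formulas are the standard ones for batch-culture physiology:

* specific substrate uptake rate  r = μ · Δc_substrate / Δc_biomass
  (mmol gCDW⁻¹ h⁻¹ from a growth rate in h⁻¹, substrate deltas in mM and
  biomass deltas in g L⁻¹ over a phase of steady uptake);
* intracellular concentration from an extract:
  c_intracellular = c_measured · (vol_EF / (vol_EF + biovolume))⁻¹ with
  biovolume = harvested CDW [mg] · cell-specific volume (default 2 µL/mg).
  This corrects for the dilution of the cell volume into the extraction
  fluid exactly as printed; whether a further normalisation to the
  biovolume fraction is applied downstream is a reporting choice left to
  the caller (see docs/methods.md);
* growth rate as the maximum slope of ln(OD) over sliding windows, after
  blank subtraction and conversion of plate readings to cuvette OD values
  (default factor 4.35).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

PLATE_TO_CUVETTE_FACTOR = 4.35
CELL_SPECIFIC_VOLUME_UL_PER_MG = 2.0


@dataclass
class UptakeRateInput:
    """Inputs of the specific-uptake-rate formula (per-phase deltas)."""

    mu: float  # growth rate, h^-1
    c_gluc_start: float  # substrate at phase start, mmol/L
    c_gluc_end: float  # substrate at phase end, mmol/L
    c_bio_start: float  # dry biomass at phase start, g/L
    c_bio_end: float  # dry biomass at phase end, g/L

    def __post_init__(self) -> None:
        for name in ("c_gluc_start", "c_gluc_end", "c_bio_start", "c_bio_end"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def specific_uptake_rate(inp: UptakeRateInput) -> float:
    """Specific substrate uptake rate, mmol gCDW^-1 h^-1."""
    d_bio = inp.c_bio_end - inp.c_bio_start
    if d_bio <= 0:
        raise ValueError("undefined rate: biomass did not increase over the phase")
    return inp.mu * (inp.c_gluc_start - inp.c_gluc_end) / d_bio


@dataclass
class IntracellularQuantInput:
    """Inputs of the endometabolome dilution correction."""

    c_measured: float  # measured concentration in the extract (any unit)
    vol_ef: float  # extraction-fluid volume, µL
    cdw_harvested: float  # harvested cell dry weight, mg
    cell_specific_volume: float = CELL_SPECIFIC_VOLUME_UL_PER_MG  # µL/mg

    def __post_init__(self) -> None:
        if self.vol_ef < 0 or self.cdw_harvested < 0 or self.cell_specific_volume < 0:
            raise ValueError("volumes and masses must be non-negative")


def biovolume(inp: IntracellularQuantInput) -> float:
    """Harvested cell volume in µL (CDW × cell-specific volume)."""
    return inp.cdw_harvested * inp.cell_specific_volume


def intracellular_concentration(inp: IntracellularQuantInput) -> float:
    """Dilution-corrected concentration, same unit as ``c_measured``.

    Always ≥ the measured concentration; equal iff no cells were harvested.
    """
    if inp.vol_ef == 0:
        raise ValueError("extraction-fluid volume must be positive")
    bv = biovolume(inp)
    return inp.c_measured * (inp.vol_ef + bv) / inp.vol_ef


@dataclass
class GrowthCurve:
    """A plate-reader OD600 time series.

    ``plate_to_cuvette_factor`` converts microtiter-plate absorbances to
    cuvette-equivalent OD600 (applied after blank subtraction).
    """

    time: np.ndarray  # hours, strictly increasing
    od: np.ndarray
    plate_to_cuvette_factor: float = PLATE_TO_CUVETTE_FACTOR
    blank: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time.shape != self.od.shape:
            raise ValueError("time and od must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.plate_to_cuvette_factor <= 0:
            raise ValueError("plate-to-cuvette factor must be positive")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "GrowthCurve":
        return cls(
            time=frame["time_h"].to_numpy(), od=frame["od600"].to_numpy(), **kwargs
        )

    def corrected(self) -> np.ndarray:
        return (self.od - self.blank) * self.plate_to_cuvette_factor


@dataclass
class GrowthRateFit:
    rate: float  # h^-1
    window: Tuple[float, float]  # time span of the fitted window, h
    r_squared: float
    n_points: int = 0


def estimate_growth_rate(
    curve: Union[GrowthCurve, pd.DataFrame],
    window: int = 6,
    min_r_squared: float = 0.999,
) -> GrowthRateFit:
    """Maximum specific growth rate by sliding-window log-linear regression.

    The slope of ln(OD) vs time is fitted on every window of ``window``
    consecutive blank-subtracted positive readings; the reported rate is the
    maximum slope among windows whose fit reaches ``min_r_squared``, falling
    back to the best-fitting window when none qualifies.  The strict default
    threshold keeps windows whose ln-residual scatter is below ~1% of the
    window's dynamic range: at low OD the additive read noise dominates the
    signal and would otherwise inflate the maximum.  The rate is invariant
    to rescaling of the OD axis, hence to the plate-to-cuvette factor.
    """
    if isinstance(curve, pd.DataFrame):
        curve = GrowthCurve.from_frame(curve)
    if window < 2:
        raise ValueError("window must span at least two points")
    od = curve.corrected()
    mask = od > 0
    if mask.sum() < window:
        raise ValueError(
            "not enough positive blank-subtracted readings for the fit window"
        )
    t = curve.time[mask]
    ln_od = np.log(od[mask])

    fits = []
    for i in range(len(t) - window + 1):
        tw = t[i:i + window]
        yw = ln_od[i:i + window]
        slope, intercept = np.polyfit(tw, yw, 1)
        residuals = yw - (slope * tw + intercept)
        ss_res = float(np.sum(residuals**2))
        ss_tot = float(np.sum((yw - yw.mean()) ** 2))
        r2 = 1.0 if ss_tot < 1e-30 else 1.0 - ss_res / ss_tot
        fits.append((slope, (tw[0], tw[-1]), r2))
    qualified = [f for f in fits if f[2] >= min_r_squared]
    pool = qualified if qualified else [max(fits, key=lambda f: f[2])]
    slope, span, r2 = max(pool, key=lambda f: f[0])
    return GrowthRateFit(rate=slope, window=span, r_squared=r2, n_points=window)


def molar_yield(product_conc: float, substrate_conc_consumed: float) -> float:
    """Product formed per substrate consumed, mol/mol (same concentration
    unit for both)."""
    if substrate_conc_consumed <= 0:
        raise ValueError("consumed substrate must be positive")
    if product_conc < 0:
        raise ValueError("product concentration must be non-negative")
    return product_conc / substrate_conc_consumed


def read_growth_csv(path, **kwargs) -> GrowthCurve:
    """Read a growth-curve CSV with columns time_h, od600 [, blank]."""
    frame = pd.read_csv(path)
    if not {"time_h", "od600"} <= set(frame.columns):
        raise ValueError("growth CSV needs columns time_h and od600")
    if "blank" in frame.columns and "blank" not in kwargs:
        kwargs["blank"] = float(frame["blank"].iloc[0])
    return GrowthCurve.from_frame(frame, **kwargs)
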