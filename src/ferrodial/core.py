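"""The dialyzability statistic.

After the simulated intestinal phase, iron is split between the dialysate
(the bath outside the membrane, amount ``D`` mg) and the retentate inside
the tube (amount ``T`` mg).  Because passive dialysis stops at
concentration equilibrium, the iron still inside the tube at the dialysate
concentration is credited to the bioaccessible pool:

    Dr = (Cd - Cc) * Vt * R / 1000

with ``Cd`` the dialysate solution concentration (ug/mL), ``Cc`` the blank
(control digestion) concentration, ``Vt`` the dialysis-tube volume (mL)
and ``R`` the dilution factor relating the analyzed solution to the
dialysate.  Relative bioaccessibility is then

    B% = (D + Dr) / (T + D) * 100.

Amounts are recovered from measured digest concentrations by

    amount_mg = max(0, C - Cc) * V * R / (1000 * f)

where ``V`` is the final digest volume (mL), ``R`` any further dilution
applied before measurement, and ``f`` the share of the physical fraction
that was digested (e.g. a 5 mL aliquot of the 500 mL bath: f = 0.01; 1 g
of ~50 g membrane residue: f = 0.02).  Negative blank-corrected
differences are clamped to zero: concentrations below the blank are
measurement noise, and amounts are physically non-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .design import Fraction

__all__ = [
    "FractionMeasurement", "BlankReference", "DialysisGeometry",
    "BioaccessibilityResult", "UndefinedBioaccessibilityError",
    "fraction_amount", "equilibrium_correction", "bioaccessibility",
    "compute_sample", "compute_table",
]


class UndefinedBioaccessibilityError(ValueError):
    """Raised when no iron was recovered in either fraction (T + D = 0)."""


def _check_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValueError(f"{name} must be finite, got {value}")


@dataclass(frozen=True)
class FractionMeasurement:
    """One ICP-OES measurement of one digested fraction.

    ``sample`` optionally carries the digestion identity so that paired
    fractions can be checked for consistency.
    """

    concentration: float          # ug/mL in the analyzed digest solution
    digest_volume: float          # mL of the final diluted digest
    dilution_factor: float = 1.0  # extra dilution before measurement
    sample_mass_fraction: float = 1.0  # share of the fraction digested
    sample: Optional[tuple] = None

    def __post_init__(self) -> None:
        _check_finite(concentration=self.concentration,
                      digest_volume=self.digest_volume,
                      dilution_factor=self.dilution_factor,
                      sample_mass_fraction=self.sample_mass_fraction)
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.digest_volume <= 0:
            raise ValueError("digest_volume must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if not 0 < self.sample_mass_fraction <= 1:
            raise ValueError("sample_mass_fraction must be in (0, 1]")


@dataclass(frozen=True)
class BlankReference:
    """Concentration measured in the reagent-blank digestion (Cc)."""

    blank_concentration: float = 0.0

    def __post_init__(self) -> None:
        _check_finite(blank_concentration=self.blank_concentration)
        if self.blank_concentration < 0:
            raise ValueError("blank_concentration must be >= 0")


@dataclass(frozen=True)
class DialysisGeometry:
    """Membrane geometry for the equilibrium correction.

    Defaults reflect the protocol: ~50 mL of diluted digest inside the
    tube, a 500 mL water bath outside, and a 5 -> 10 mL dialysate digest
    dilution (``dr_dilution_factor`` = 2) relating the analyzed solution
    back to the bath concentration.
    """

    tube_volume: float = 50.0
    bath_volume: float = 500.0
    dr_dilution_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.tube_volume <= 0 or self.bath_volume <= 0:
            raise ValueError("volumes must be > 0")
        if self.dr_dilution_factor < 1:
            raise ValueError("dr_dilution_factor must be >= 1")


@dataclass(frozen=True)
class BioaccessibilityResult:
    sample: tuple
    dialysate_mg: float       # D
    retentate_mg: float       # T
    equilibrium_mg: float     # Dr
    bioaccessibility_percent: float  # B%


def fraction_amount(measurement: FractionMeasurement,
                    blank: BlankReference) -> float:
    """Blank-corrected iron amount (mg) in a digested fraction."""
    net = max(0.0, measurement.concentration - blank.blank_concentration)
    return (net * measurement.digest_volume * measurement.dilution_factor
            / (1000.0 * measurement.sample_mass_fraction))


def equilibrium_correction(cd: float, cc: float, tube_volume: float,
                           dilution_factor: float) -> float:
    """Dr (mg): iron inside the tube at the dialysate concentration."""
    _check_finite(cd=cd, cc=cc, tube_volume=tube_volume,
                  dilution_factor=dilution_factor)
    if tube_volume <= 0:
        raise ValueError("tube_volume must be > 0")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    return max(0.0, cd - cc) * tube_volume * dilution_factor / 1000.0


def bioaccessibility(d: float, dr: float, t: float) -> float:
    """B% = (D + Dr) / (T + D) * 100."""
    _check_finite(d=d, dr=dr, t=t)
    if d < 0 or dr < 0 or t < 0:
        raise ValueError("amounts must be >= 0")
    if d + t == 0:
        raise UndefinedBioaccessibilityError(
            "no iron recovered in either fraction (T + D = 0)")
    return (d + dr) / (t + d) * 100.0


def compute_sample(dialysate: FractionMeasurement,
                   retentate: FractionMeasurement,
                   blank: BlankReference,
                   geometry: DialysisGeometry = DialysisGeometry(),
                   *,
                   blank_correct_dialysate: bool = True,
                   ) -> BioaccessibilityResult:
    """Full per-digestion computation: D, T, Dr and B%.

    Both fractions must carry the same digestion identity when one is
    attached.  ``blank_correct_dialysate=False`` computes D from the raw
    dialysate concentration (the published formula corrects only Dr
    explicitly; blank-corrected D is the default).
    """
    if (dialysate.sample is not None and retentate.sample is not None
            and dialysate.sample != retentate.sample):
        raise ValueError(
            f"fraction identities differ: {dialysate.sample!r} vs "
            f"{retentate.sample!r}")
    if blank_correct_dialysate:
        d = fraction_amount(dialysate, blank)
    else:
        d = fraction_amount(dialysate, BlankReference(0.0))
    t = fraction_amount(retentate, blank)
    dr = equilibrium_correction(dialysate.concentration,
                                blank.blank_concentration,
                                geometry.tube_volume,
                                geometry.dr_dilution_factor)
    b = bioaccessibility(d, dr, t)
    sample = dialysate.sample or retentate.sample or ()
    return BioaccessibilityResult(sample, d, t, dr, b)


# ---------------------------------------------------------------------------
# tabular front end

#: Column schema of the per-sample measurement table.
MEASUREMENT_COLUMNS = [
    "product_id", "diet", "batch", "replicate", "fraction",
    "concentration_ug_per_ml", "digest_volume_ml", "dilution_factor",
    "sample_mass_fraction",
]

RESULT_COLUMNS = ["product_id", "diet", "batch", "replicate",
                  "D_mg", "T_mg", "Dr_mg", "B_percent"]


def infer_blank(measurements: pd.DataFrame) -> BlankReference:
    """Blank concentration = mean dialysate concentration over blank rows
    (rows with no diet); zero when the table has no blanks."""
    blanks = measurements[measurements["diet"].isna()
                          & (measurements["fraction"] == Fraction.DIALYSATE.value)]
    if blanks.empty:
        return BlankReference(0.0)
    return BlankReference(float(blanks["concentration_ug_per_ml"].mean()))


def compute_table(measurements: pd.DataFrame,
                  geometry: DialysisGeometry = DialysisGeometry(),
                  blank: Optional[BlankReference] = None,
                  *,
                  blank_correct_dialysate: bool = True) -> pd.DataFrame:
    """Apply :func:`compute_sample` to every digestion in a measurement
    table, pairing dialysate and retentate rows by identity.

    Blank digestions (rows with no diet) supply the blank concentration
    and are excluded from the output.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in measurements.columns]
    if missing:
        raise ValueError(f"measurement table missing columns {missing}")
    if blank is None:
        blank = infer_blank(measurements)
    cc = blank.blank_concentration

    # vectorized composition of fraction_amount / equilibrium_correction /
    # bioaccessibility; equivalence with the scalar path is property-tested
    keys = ["product_id", "diet", "batch", "replicate"]
    samples = measurements[measurements["diet"].notna()]
    dial = samples[samples["fraction"] == Fraction.DIALYSATE.value]
    ret = samples[samples["fraction"] == Fraction.RETENTATE.value]
    merged = dial.merge(ret, on=keys, suffixes=("_d", "_t"),
                        how="outer", indicator=True)
    incomplete = merged[merged["_merge"] != "both"]
    if not incomplete.empty:
        key = tuple(incomplete.iloc[0][keys])
        raise ValueError(f"digestion {key} lacks a paired fraction row")

    def _amount(prefix: str, conc_offset: float) -> np.ndarray:
        conc = merged[f"concentration_ug_per_ml_{prefix}"].to_numpy(float)
        v = merged[f"digest_volume_ml_{prefix}"].to_numpy(float)
        r = merged[f"dilution_factor_{prefix}"].to_numpy(float)
        f = merged[f"sample_mass_fraction_{prefix}"].to_numpy(float)
        return np.clip(conc - conc_offset, 0.0, None) * v * r / (1000.0 * f)

    d = _amount("d", cc if blank_correct_dialysate else 0.0)
    t = _amount("t", cc)
    cd = merged["concentration_ug_per_ml_d"].to_numpy(float)
    dr = (np.clip(cd - cc, 0.0, None) * geometry.tube_volume
          * geometry.dr_dilution_factor / 1000.0)
    if np.any(d + t == 0):
        bad = merged.loc[(d + t) == 0].iloc[0]
        raise UndefinedBioaccessibilityError(
            f"no iron recovered for digestion {tuple(bad[keys])}")
    out = merged[keys].copy()
    out["D_mg"] = d
    out["T_mg"] = t
    out["Dr_mg"] = dr
    out["B_percent"] = (d + dr) / (t + d) * 100.0
    out["product_id"] = out["product_id"].astype("Int64")
    out["batch"] = out["batch"].astype(int)
    out["replicate"] = out["replicate"].astype(int)
    return out.reset_index(drop=True)
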