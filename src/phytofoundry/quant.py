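"""Protein quantification from plate-reader data.

Absolute quantification uses the split-luciferase peptide-tag system: an
11-residue HiBiT tag on the expressed protein complements an added 18-kDa
partner to reconstitute a luciferase, so luminescence is proportional to
tagged-protein concentration.  A standard curve of purified control protein
(default calibrated range 0.01–2 nM) is fitted by ordinary least squares,
diluted CFPS readings (typically 10^4–10^6-fold dilutions) are
back-calculated through it, and molar concentrations convert to mass
concentration via the dimensional identity µg/ml = µM × kDa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ReplicateAlignmentError, StandardCurveError

DEFAULT_RANGE_NM = (0.01, 2.0)


@dataclass
class StandardCurve:
    """Linear luminescence response: RLU = slope × [nM] + intercept."""

    points: list[tuple[float, float]]
    slope: float
    intercept: float
    r_squared: float
    calibrated_range_nm: tuple[float, float] = DEFAULT_RANGE_NM

    @property
    def usable(self) -> bool:
        return self.slope > 0


@dataclass
class QuantResult:
    """Back-calculated concentration of one diluted CFPS sample."""

    raw_rlu: float
    dilution_factor: float
    conc_nM_diluted: float
    conc_uM_original: float
    mass_conc_ug_per_ml: Optional[float] = None
    flags: set[str] = field(default_factory=set)


def fit_standard_curve(
    points: Sequence[tuple[float, float]],
    calibrated_range_nm: tuple[float, float] = DEFAULT_RANGE_NM,
) -> StandardCurve:
    """Ordinary least-squares fit of luminescence against concentration.

    Requires at least two distinct concentrations; a non-positive slope is
    retained but the curve reports ``usable = False``.
    """
    pts = [(float(c), float(r)) for c, r in points]
    concs = [c for c, _ in pts]
    if len(set(concs)) < 2:
        raise StandardCurveError(
            "standard curve needs >= 2 distinct concentrations"
        )
    result = stats.linregress(concs, [r for _, r in pts])
    return StandardCurve(
        points=pts,
        slope=float(result.slope),
        intercept=float(result.intercept),
        r_squared=float(result.rvalue) ** 2,
        calibrated_range_nm=calibrated_range_nm,
    )


def back_calculate(
    raw_rlu: float,
    curve: StandardCurve,
    dilution_factor: float,
    mw_kda: Optional[float] = None,
) -> QuantResult:
    """Invert the standard curve and undo the dilution.

    Flags: ``out_of_range`` when the diluted concentration falls outside the
    calibrated range, ``below_blank`` when the raw signal is below the fitted
    intercept.
    """
    if not curve.usable:
        raise StandardCurveError("standard curve slope is not positive")
    if dilution_factor < 1:
        raise DomainError("dilution_factor must be >= 1")
    diluted_nm = (raw_rlu - curve.intercept) / curve.slope
    original_um = diluted_nm * dilution_factor / 1000.0
    flags: set[str] = set()
    lo, hi = curve.calibrated_range_nm
    if not lo <= diluted_nm <= hi:
        flags.add("out_of_range")
    if raw_rlu < curve.intercept:
        flags.add("below_blank")
    mass = None
    if mw_kda is not None and original_um > 0:
        mass = convert_molar_to_mass(original_um, mw_kda)
    return QuantResult(
        raw_rlu=raw_rlu,
        dilution_factor=dilution_factor,
        conc_nM_diluted=diluted_nm,
        conc_uM_original=original_um,
        mass_conc_ug_per_ml=mass,
        flags=flags,
    )


def convert_molar_to_mass(conc_um: float, mw_kda: float) -> float:
    """µg/ml = µM × kDa (dimensional identity)."""
    if not conc_um > 0 or not mw_kda > 0:
        raise DomainError("concentration and molecular weight must be > 0")
    return conc_um * mw_kda


@dataclass
class ReplicateSummary:
    mean: float
    sd: float
    n: int
    soluble_fraction: Optional[float] = None
    flags: set[str] = field(default_factory=set)


def summarize_replicates(
    values: Sequence[float],
    soluble_values: Optional[Sequence[float]] = None,
) -> ReplicateSummary:
    """Mean and sample SD (n−1 denominator) of replicate measurements.

    With paired soluble measurements, the soluble fraction is computed per
    replicate then averaged; fractions above 1 are clamped and flagged.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 1:
        raise DomainError("need at least one replicate")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else math.nan
    flags: set[str] = set()
    fraction = None
    if soluble_values is not None:
        sol = np.asarray(soluble_values, dtype=float)
        if sol.shape != vals.shape:
            raise ReplicateAlignmentError(
                f"soluble ({sol.size}) and total ({vals.size}) lengths differ"
            )
        fractions = sol / vals
        if (fractions > 1).any():
            flags.add("soluble_exceeds_total")
            fractions = np.minimum(fractions, 1.0)
        fraction = float(fractions.mean())
    return ReplicateSummary(mean=mean, sd=sd, n=int(vals.size), soluble_fraction=fraction, flags=flags)


def select_timepoint(
    kinetic: pd.DataFrame, time_min: float = 18.0
) -> pd.DataFrame:
    """Per-well signal at the timestamp nearest ``time_min``.

    Kinetic luminescence reads stabilize after a few minutes; the 18-min
    read is the conventional comparison point.  Expects columns
    ``well``, ``time_min`` and ``signal``.
    """
    required = {"well", "time_min", "signal"}
    if not required <= set(kinetic.columns):
        raise DomainError(f"kinetic frame needs columns {sorted(required)}")
    idx = (
        (kinetic["time_min"] - time_min).abs().groupby(kinetic["well"]).idxmin()
    )
    return kinetic.loc[idx, ["well", "time_min", "signal"]].reset_index(drop=True)


def gfp_relative(samples: pd.DataFrame, reference_well: str) -> pd.DataFrame:
    """Fluorescence of each well as a ratio to a named reference well."""
    if not {"well", "signal"} <= set(samples.columns):
        raise DomainError("samples frame needs columns ['well', 'signal']")
    ref = samples.loc[samples["well"] == reference_well, "signal"]
    if ref.empty:
        raise DomainError(f"reference well {reference_well!r} absent")
    out = samples.copy()
    out["relative"] = out["signal"] / float(ref.iloc[0])
    return out
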