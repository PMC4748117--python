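"""Isotope data reduction: calibration and corrections for nitrate isotope analysis.

Raw δ¹⁵N, δ¹⁸O and δ¹⁷O measured on N₂O (and O₂ from its thermal
decomposition) are calibrated to the AIR (nitrogen) and VSMOW (oxygen)
scales against international nitrate reference materials, then corrected
for two instrument-level artefacts:

* the mass-independent overlap of ¹⁴N¹⁴N¹⁷O with ¹⁵N¹⁴N¹⁶O at mass 45,
  which inflates calibrated δ¹⁵N by ``xcorr`` ‰ for every 1‰ of Δ¹⁷O;
* oxygen exchange between the nitrate-derived N₂O and laboratory water,
  which mixes a fraction ``f`` of the water's δ¹⁸O into the measurement.

The ¹⁷O anomaly Δ¹⁷O = δ¹⁷O − λ·δ¹⁸O (λ = 0.52, the slope of the
terrestrial fractionation line) quantifies mass-independent atmospheric
ozone chemistry: terrestrial nitrate sits at Δ¹⁷O ≈ 0, atmospherically
oxidized nitrate well above it.

All delta values are carried in ‰ on the AIR/VSMOW scales throughout; no
ratio-space conversion is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TFL_SLOPE",
    "REFERENCE_VALUES",
    "ValidationError",
    "CalibrationError",
    "CorrectionParameters",
    "RunEntry",
    "RawIsotopeRun",
    "SampleRecord",
    "delta17O_excess",
    "estimate_xcorr",
    "correct_d15N_mass_overlap",
    "correct_d18O_water_exchange",
    "calibrate_linear",
    "apply_corrections",
]

#: Slope of the terrestrial fractionation line in δ¹⁷O–δ¹⁸O space.
TFL_SLOPE = 0.52

#: Accepted reference values (‰) for the nitrate isotope standards used in
#: calibration.  USGS values are community-accepted scale anchors; GSI-NO-3
#: is an internal standard of the Geological Survey of Israel.  Editable:
#: pass your own mapping to :func:`calibrate_linear` or
#: :func:`estimate_xcorr` if your laboratory uses different assignments.
REFERENCE_VALUES: dict[str, dict[str, float]] = {
    "USGS-32": {"d15N": 180.0, "d18O": 25.7},
    "USGS-34": {"d15N": -1.8, "d18O": -27.9, "D17O": -0.1},
    "USGS-35": {"d15N": 2.7, "d18O": 57.5, "D17O": 21.56},
    "GSI-NO-3": {"d15N": 1.3, "d18O": 14.13},
    "IAEA-NO-3": {"d15N": 4.7, "d18O": 25.6},
}

VALID_GROUPS = frozenset({"snow", "inflow", "lake", "snowmelt", "other"})


class ValidationError(ValueError):
    """Invalid input data (non-finite values, bad parameters, bad labels)."""


class CalibrationError(ValueError):
    """A calibration could not be established from the standards provided."""


@dataclass
class CorrectionParameters:
    """Parameters of the data-reduction step.

    Attributes
    ----------
    xcorr : float
        δ¹⁵N inflation per unit Δ¹⁷O, ‰/‰.  Default 0.1.
    exchange_fraction : float
        Fraction of N₂O oxygen exchanged with laboratory water, in [0, 1).
        Default 0.13.
    water_d18O : float
        δ¹⁸O of the laboratory water (‰ VSMOW).
    tfl_slope : float
        λ of the terrestrial fractionation line (> 0).  Default 0.52.
    """

    xcorr: float = 0.1
    exchange_fraction: float = 0.13
    water_d18O: float = 0.0
    tfl_slope: float = TFL_SLOPE

    def __post_init__(self) -> None:
        if not 0.0 <= self.exchange_fraction < 1.0:
            raise ValidationError(
                f"exchange_fraction must be in [0, 1), got {self.exchange_fraction}"
            )
        if not self.tfl_slope > 0:
            raise ValidationError(f"tfl_slope must be > 0, got {self.tfl_slope}")


@dataclass
class RunEntry:
    """One injection in an analytical run (sample or standard)."""

    sample_id: str
    role: str = "unknown"  # "unknown" (sample) or "standard"
    standard_name: Optional[str] = None
    raw_d15N: float = math.nan
    raw_d18O: float = math.nan
    raw_d17O: Optional[float] = None


@dataclass
class RawIsotopeRun:
    """A run sheet: the injections of one analytical session."""

    run_id: str
    entries: list[RunEntry] = field(default_factory=list)

    def standards(self) -> list[RunEntry]:
        return [e for e in self.entries if e.role == "standard"]


@dataclass
class SampleRecord:
    """One analysis-ready water or snow sample.

    Delta values in ‰ (δ¹⁵N on AIR, oxygen on VSMOW); concentrations in
    μM N.  ``D17O`` is the ¹⁷O anomaly; when δ¹⁷O could not be measured
    (too little nitrate) it is None and ``d15N_corrected_flag`` is False,
    meaning the mass-overlap correction could not be applied.
    """

    sample_id: str
    group: str
    d15N: float
    d18O: float
    d17O: Optional[float] = None
    D17O: Optional[float] = None
    no3_uM: float = 0.0
    nh4_uM: float = 0.0
    d15N_corrected_flag: bool = True

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r} for sample {self.sample_id!r}; "
                f"expected one of {sorted(VALID_GROUPS)}"
            )
        if self.no3_uM < 0 or self.nh4_uM < 0:
            raise ValidationError(
                f"negative concentration on sample {self.sample_id!r}"
            )
        if self.d17O is not None and self.D17O is None:
            self.D17O = delta17O_excess(self.d17O, self.d18O)
        if self.d17O is not None and self.D17O is not None:
            expect = self.d17O - TFL_SLOPE * self.d18O
            if abs(self.D17O - expect) > 1e-9:
                raise ValidationError(
                    f"inconsistent D17O on sample {self.sample_id!r}: "
                    f"stored {self.D17O}, d17O - 0.52*d18O = {expect}"
                )
        if self.D17O is None:
            self.d15N_corrected_flag = False


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValidationError(f"{name} must be finite, got {v}")


def delta17O_excess(d17O: float, d18O: float, tfl_slope: float = TFL_SLOPE) -> float:
    """¹⁷O anomaly: Δ¹⁷O = δ¹⁷O − λ·δ¹⁸O (‰).

    Zero on the terrestrial fractionation line; positive for nitrate whose
    oxygen was acquired from atmospheric ozone chemistry.
    """
    _require_finite(d17O=d17O, d18O=d18O, tfl_slope=tfl_slope)
    return d17O - tfl_slope * d18O


def estimate_xcorr(
    d15N_cal_std: float,
    d15N_true_std: float,
    D17O_cal_std: float,
    standard_name: str = "USGS-35",
) -> float:
    """Estimate the δ¹⁵N-per-Δ¹⁷O overlap coefficient from a standard.

    The coefficient is the calibrated-minus-true δ¹⁵N offset of a
    high-Δ¹⁷O standard divided by its calibrated Δ¹⁷O:
    ``(δ¹⁵N_cal − δ¹⁵N_true) / Δ¹⁷O_cal``, in ‰ per ‰.
    """
    _require_finite(
        d15N_cal_std=d15N_cal_std,
        d15N_true_std=d15N_true_std,
        D17O_cal_std=D17O_cal_std,
    )
    if D17O_cal_std == 0:
        raise ZeroDivisionError(
            f"cannot estimate the overlap coefficient from standard "
            f"{standard_name!r}: its calibrated Δ¹⁷O is zero"
        )
    return (d15N_cal_std - d15N_true_std) / D17O_cal_std


def correct_d15N_mass_overlap(
    d15N_cal: float,
    D17O_sample: Optional[float],
    xcorr: float = 0.1,
) -> float:
    """Remove the mass-independent isotopologue overlap from δ¹⁵N.

    Returns ``δ¹⁵N_cal − xcorr·Δ¹⁷O``.  When the sample's Δ¹⁷O is
    unavailable (None or NaN) the input is returned unchanged; callers
    tracking provenance should clear ``d15N_corrected_flag`` in that case
    (see :func:`apply_corrections`).
    """
    if D17O_sample is None or (
        isinstance(D17O_sample, float) and math.isnan(D17O_sample)
    ):
        return d15N_cal
    _require_finite(d15N_cal=d15N_cal, D17O_sample=D17O_sample, xcorr=xcorr)
    return d15N_cal - xcorr * D17O_sample


def correct_d18O_water_exchange(
    d18O_measured: float,
    water_d18O: float,
    f: float = 0.13,
) -> float:
    """Invert the two-component mixing of nitrate oxygen with water oxygen.

    A fraction ``f`` of the oxygen in the measured N₂O derives from
    laboratory water rather than the original nitrate, so the measurement
    is ``(1−f)·δ¹⁸O_nitrate + f·δ¹⁸O_water``.  This solves for the nitrate
    value: ``(δ¹⁸O_measured − f·δ¹⁸O_water)/(1 − f)``.  No kinetic
    fractionation term is included.
    """
    _require_finite(d18O_measured=d18O_measured, water_d18O=water_d18O, f=f)
    if not 0.0 <= f < 1.0:
        raise ValidationError(f"exchange fraction must be in [0, 1), got {f}")
    return (d18O_measured - f * water_d18O) / (1.0 - f)


_RAW_ATTR = {"d15N": "raw_d15N", "d18O": "raw_d18O", "d17O": "raw_d17O"}


def calibrate_linear(
    run: RawIsotopeRun,
    tracer: str,
    reference_values: Optional[dict[str, dict[str, float]]] = None,
) -> tuple[float, float, dict[str, float]]:
    """Per-run OLS calibration of one tracer against the run's standards.

    Regresses the accepted reference values on the raw measured values of
    the standards in ``run`` (ordinary least squares); with exactly two
    standards this is the exact two-point line.  Returns
    ``(slope, intercept, calibrated)`` where ``calibrated`` maps every
    entry's ``sample_id`` to ``slope·raw + intercept``.

    Parameters
    ----------
    tracer : str
        "d15N", "d18O" or "d17O".
    reference_values : mapping, optional
        ``standard_name -> {tracer: ‰}``; defaults to
        :data:`REFERENCE_VALUES`.
    """
    if tracer not in _RAW_ATTR:
        raise ValidationError(f"unknown tracer {tracer!r}")
    refs = REFERENCE_VALUES if reference_values is None else reference_values
    attr = _RAW_ATTR[tracer]

    raw_std, true_std = [], []
    for e in run.standards():
        if e.standard_name is None or e.standard_name not in refs:
            continue
        ref = refs[e.standard_name]
        if tracer not in ref:
            continue
        raw = getattr(e, attr)
        if raw is None or not math.isfinite(raw):
            continue
        raw_std.append(raw)
        true_std.append(ref[tracer])

    if len(set(zip(raw_std, true_std))) < 2:
        raise CalibrationError(
            f"run {run.run_id!r}: need at least two distinct standards with "
            f"reference values for {tracer}, found {len(set(raw_std))}"
        )
    if len(set(raw_std)) < 2:
        raise CalibrationError(
            f"run {run.run_id!r}: standards have identical raw {tracer} values"
        )

    slope, intercept = np.polyfit(np.asarray(raw_std), np.asarray(true_std), 1)
    calibrated: dict[str, float] = {}
    for e in run.entries:
        raw = getattr(e, attr)
        if raw is None or not math.isfinite(raw):
            continue
        calibrated[e.sample_id] = float(slope) * raw + float(intercept)
    return float(slope), float(intercept), calibrated


def apply_corrections(
    records: Sequence[SampleRecord],
    params: Optional[CorrectionParameters] = None,
) -> list[SampleRecord]:
    """Apply the δ¹⁵N mass-overlap and δ¹⁸O water-exchange corrections.

    Returns new records; inputs are not modified.  Samples without Δ¹⁷O
    keep their δ¹⁵N and get ``d15N_corrected_flag=False``.  δ¹⁷O is
    rebuilt from the corrected δ¹⁸O and the (exchange-invariant) Δ¹⁷O so
    that the anomaly identity keeps holding.
    """
    params = params or CorrectionParameters()
    out = []
    for r in records:
        d18O = correct_d18O_water_exchange(
            r.d18O, params.water_d18O, params.exchange_fraction
        )
        if r.D17O is not None:
            d15N = correct_d15N_mass_overlap(r.d15N, r.D17O, params.xcorr)
            flag = True
            d17O = r.D17O + params.tfl_slope * d18O
        else:
            d15N, flag, d17O = r.d15N, False, None
        out.append(
            SampleRecord(
                sample_id=r.sample_id,
                group=r.group,
                d15N=d15N,
                d18O=d18O,
                d17O=d17O,
                D17O=r.D17O,
                no3_uM=r.no3_uM,
                nh4_uM=r.nh4_uM,
                d15N_corrected_flag=flag,
            )
        )
    return out
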