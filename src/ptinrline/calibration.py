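"""Fitting and applying the PT/INR line.

The PT/INR line is an ordinary least-squares regression of y = ln(observed
PT) on x = ln(certified INR) over a set of certified calibrant plasmas run
on one analyzer:

    y = m·x + b .

Inverting the line assigns a harmonized INR directly from a sample's PT,
bypassing the analyzer's local ISI/MNPT conversion:

    ln(INR_corrected) = (-b/m) + (1/m)·ln(PT),   INR_corrected = e^x .

The slope of the line approximates 1/ISI for data generated under the
conventional INR model INR = (PT/MNPT)^ISI, and the intercept is
ln(MNPT-like PT at INR 1); the line subsumes both into a single empirical
calibration per analyzer.  Natural logarithms are used throughout.

A whole-blood point-of-care method cannot be run against plasma calibrants
and is passed through uncorrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datasets import CalibrantSet, Measurement, MethodProfile, SampleRecord
from .errors import ConfigurationError, DegenerateDesignError, ValidationError

__all__ = [
    "CalibrationLine",
    "fit_ptinr_line",
    "fit_line_from_corrected",
    "predict_pt",
    "correct_inr",
    "compute_inr",
    "correct_table",
    "correct_frame",
]


@dataclass(frozen=True)
class CalibrationLine:
    """A fitted PT/INR line for one analyzer.

    ``slope_m`` and ``intercept_b`` are on the ln scale (y = ln PT in
    ln-seconds, x = ln INR dimensionless); ``r_squared`` is the coefficient
    of determination of the ln-scale fit.
    """

    method_id: str
    slope_m: float
    intercept_b: float
    r_squared: float
    n_points: int
    fit_basis: str = "replicate_means"  # | "all_replicates"

    def __post_init__(self) -> None:
        if not self.slope_m > 0:
            raise ValidationError(
                f"{self.method_id}: PT/INR line slope must be positive "
                f"(PT increases with INR), got {self.slope_m}"
            )
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValidationError(f"r_squared {self.r_squared} outside [0, 1]")
        if self.n_points < 3:
            raise ValidationError(f"line fitted on {self.n_points} < 3 points")

    def to_dict(self) -> dict:
        return {
            "method_id": self.method_id,
            "slope_m": self.slope_m,
            "intercept_b": self.intercept_b,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "fit_basis": self.fit_basis,
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "CalibrationLine":
        return cls(**{k: doc[k] for k in
                      ("method_id", "slope_m", "intercept_b", "r_squared",
                       "n_points", "fit_basis")})


def _ols_loglog(x: np.ndarray, y: np.ndarray, method_id: str, fit_basis: str,
                ) -> CalibrationLine:
    if len(np.unique(x)) < 3:
        raise DegenerateDesignError(
            f"{method_id}: need >= 3 distinct certified INR levels, "
            f"got {len(np.unique(x))}"
        )
    if np.ptp(x) == 0:
        raise DegenerateDesignError(f"{method_id}: zero variance in ln(INR certified)")
    res = sps.linregress(x, y)
    ss_res = float(np.sum((y - (res.slope * x + res.intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationLine(
        method_id=method_id,
        slope_m=float(res.slope),
        intercept_b=float(res.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=len(x),
        fit_basis=fit_basis,
    )


def fit_ptinr_line(
    calibrants: CalibrantSet, fit_basis: str = "replicate_means"
) -> CalibrationLine:
    """OLS fit of ln(observed PT) on ln(certified INR).

    With ``fit_basis="replicate_means"`` (the default, matching a
    duplicate-measurement calibration design) replicate PTs are averaged on
    the seconds scale per calibrant before the ln transform; with
    ``"all_replicates"`` every replicate contributes its own point.
    """
    if fit_basis not in ("replicate_means", "all_replicates"):
        raise ValidationError(f"unknown fit_basis {fit_basis!r}")
    xs, ys = [], []
    for cal in calibrants.calibrants:
        if fit_basis == "replicate_means":
            xs.append(math.log(cal.inr_certified))
            ys.append(math.log(float(np.mean(cal.pt_observed_replicates))))
        else:
            for pt in cal.pt_observed_replicates:
                xs.append(math.log(cal.inr_certified))
                ys.append(math.log(pt))
    return _ols_loglog(np.asarray(xs), np.asarray(ys), calibrants.method_id, fit_basis)


def fit_line_from_corrected(df: pd.DataFrame, method_id: str) -> CalibrationLine:
    """Back-derive an analyzer's PT/INR line from already-corrected results.

    A corrected INR is, by construction, on the line of its analyzer, so
    regressing ln(PT) on ln(corrected INR) over a corrected sample table
    recovers the line (up to the rounding of the published values).  This is
    how the bundled study's lines are reconstructed, since its raw calibrant
    readings were published elsewhere.
    """
    sub = df[[f"{method_id}_pt_sec", f"{method_id}_inr_corrected"]].dropna()
    x = np.log(sub[f"{method_id}_inr_corrected"].to_numpy(float))
    y = np.log(sub[f"{method_id}_pt_sec"].to_numpy(float))
    return _ols_loglog(x, y, method_id, "replicate_means")


def predict_pt(inr, line: CalibrationLine):
    """Expected PT (s) at a given INR under the line: exp(m·ln INR + b)."""
    inr = np.asarray(inr, dtype=float)
    if np.any(inr <= 0):
        raise ValidationError("INR must be positive")
    out = np.exp(line.slope_m * np.log(inr) + line.intercept_b)
    return float(out) if out.ndim == 0 else out


def correct_inr(pt_seconds, line: CalibrationLine):
    """Harmonized INR from a PT via the inverted line:
    exp((-b/m) + (1/m)·ln PT).  Strictly increasing in PT."""
    pt = np.asarray(pt_seconds, dtype=float)
    if np.any(pt <= 0):
        raise ValidationError("PT must be positive")
    out = np.exp(-line.intercept_b / line.slope_m + np.log(pt) / line.slope_m)
    return float(out) if out.ndim == 0 else out


def compute_inr(pt_seconds, profile: MethodProfile):
    """Conventional instrument INR, (PT/MNPT)^ISI."""
    if profile.mnpt is None:
        raise ConfigurationError(
            f"{profile.method_id}: MNPT required to compute a conventional INR"
        )
    pt = np.asarray(pt_seconds, dtype=float)
    if np.any(pt <= 0):
        raise ValidationError("PT must be positive")
    out = (pt / profile.mnpt) ** profile.isi
    return float(out) if out.ndim == 0 else out


def correct_table(
    records: Sequence[SampleRecord],
    lines: Mapping[str, CalibrationLine],
    profiles: Sequence[MethodProfile],
    rounding: int | None = 2,
) -> list[SampleRecord]:
    """Fill ``inr_corrected`` for every non-missing entry of every correctable
    method; non-correctable (whole-blood) methods pass through unchanged.

    Corrected values are rounded to ``rounding`` decimal places (default 2,
    the reporting precision of clinical INRs); pass ``None`` to keep full
    precision.  Missing entries stay missing.
    """
    by_id = {p.method_id: p for p in profiles}
    for p in profiles:
        if p.correctable and p.method_id not in lines:
            raise ConfigurationError(
                f"no calibration line supplied for correctable method {p.method_id}"
            )
    out: list[SampleRecord] = []
    for rec in records:
        meas: dict[str, Measurement | None] = {}
        for mid, m in rec.measurements.items():
            prof = by_id.get(mid)
            if m is None or prof is None or not prof.correctable:
                meas[mid] = m
                continue
            corrected = correct_inr(m.pt_seconds, lines[mid])
            if rounding is not None:
                corrected = round(corrected, rounding)
            meas[mid] = Measurement(m.pt_seconds, m.inr_reported, corrected)
        out.append(SampleRecord(rec.sample_id, rec.cohort, meas))
    return out


def correct_frame(
    df: pd.DataFrame,
    lines: Mapping[str, CalibrationLine],
    profiles: Sequence[MethodProfile],
    rounding: int | None = 2,
) -> pd.DataFrame:
    """DataFrame counterpart of :func:`correct_table`."""
    df = df.copy()
    for p in profiles:
        if not p.correctable:
            continue
        if p.method_id not in lines:
            raise ConfigurationError(
                f"no calibration line supplied for correctable method {p.method_id}"
            )
        pt = df[f"{p.method_id}_pt_sec"]
        corrected = pd.Series(np.nan, index=df.index)
        ok = pt.notna()
        corrected[ok] = correct_inr(pt[ok].to_numpy(float), lines[p.method_id])
        if rounding is not None:
            corrected = corrected.round(rounding)
        df[f"{p.method_id}_inr_corrected"] = corrected
    return df
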