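"""Synthetic calibrant sets and multi-analyzer cohorts.

The generator emulates the structure the analysis assumes.  Each subject has
one latent "true" INR; each analyzer observes a prothrombin time generated
by its *true* calibration,

    PT = MNPT_true * trueINR**(1/ISI_true) * exp(eta),   eta ~ Normal(0, cv),

i.e. multiplicative log-normal measurement noise with coefficient of
variation ``cv`` on the PT, and reports the conventional instrument INR
(PT/MNPT)**ISI computed with its *labelled* ISI and MNPT.  When labelled
and true calibrations coincide the conversion cancels and every analyzer
estimates the same true INR — the concordant null.  Inter-method
discordance is produced by letting the labelled values deviate from the
true ones (a mis-assigned local ISI or a stale MNPT), giving reported
INR = c * trueINR**(ISI_lab/ISI_true) with a method-specific exponent and
offset, which is exactly the kind of disagreement a PT/INR line correction
(calibrated against the true line) removes.  Calibrant plasmas follow the
same model expressed through a
true PT/INR line: replicate PTs at a certified INR are
exp(m*ln(INR) + b) * exp(eta).  The log-normal noise makes the ln-scale
regression model exact, so fits with noise -> 0 recover the generating line
to machine precision — the main lever the test-suite uses.

Default cohort composition mirrors the bundled study: 20 normal (control)
subjects with true INR ~ Normal(1.0, 0.05), and 100 warfarin-therapy
subjects with a right-skewed log-normal true INR covering roughly 1.2-5.5
with its mode near 2.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import compute_inr
from .datasets import (
    Calibrant,
    CalibrantSet,
    Measurement,
    MethodProfile,
    SampleRecord,
)
from .errors import ValidationError

__all__ = [
    "CohortSpec",
    "LineSpec",
    "default_sim_profiles",
    "discordant_calibrations",
    "simulate_cohort",
    "simulate_calibrants",
    "true_line_for",
]

# Warfarin true-INR log-normal: mode exp(mu - sigma^2) = 2.5 with sigma = 0.35
# puts ~95% of draws in 1.4-5.6, matching a stabilized anticoagulation clinic.
_WARFARIN_SIGMA = 0.35
_WARFARIN_MU = math.log(2.5) + _WARFARIN_SIGMA**2


def default_sim_profiles() -> tuple[MethodProfile, ...]:
    """The four study analyzers with simulation-default MNPTs.

    MNPT defaults (12.5 s for the rabbit-brain analyzers, 10.5 s for the
    recombinant-human plasma analyzer, 11.5 s for the whole-blood device)
    are fixture choices mimicking the normal-sample PT ranges of the bundled
    dataset, not published constants.
    """
    return (
        MethodProfile("coaguchek_xs", "recombinant_human", 1.01,
                      matrix="whole_blood", correctable=False, mnpt=11.5),
        MethodProfile("utmb_stago", "rabbit_brain", 1.25, mnpt=12.5),
        MethodProfile("arup_stago", "rabbit_brain", 1.28, mnpt=12.5),
        MethodProfile("bcs_xp", "recombinant_human", 1.02, mnpt=10.5),
    )


#: Default discordant scenario: each analyzer's true (ISI, MNPT) deviates
#: from its label by a realistic margin (ISI mis-assigned by 5-8%, MNPT
#: stale by ~2%), largest for the high-ISI rabbit-brain reagents.
_DISCORDANT_TRUTH: dict[str, tuple[float, float]] = {
    "coaguchek_xs": (0.96, 11.8),
    "utmb_stago": (1.35, 12.2),
    "arup_stago": (1.20, 12.8),
    "bcs_xp": (1.08, 10.3),
}


def discordant_calibrations(
    profiles: Sequence[MethodProfile] | None = None,
) -> dict[str, tuple[float, float]]:
    """True (ISI, MNPT) per method for the default discordant scenario."""
    profiles = default_sim_profiles() if profiles is None else profiles
    return {p.method_id: _DISCORDANT_TRUTH[p.method_id] for p in profiles}


@dataclass
class CohortSpec:
    """Design of a simulated comparison cohort.

    ``true_calibrations`` maps a method id to the (ISI, MNPT) actually
    governing its PT generation; methods not listed use their labelled
    profile values (concordant).
    """

    n_control: int = 20
    n_warfarin: int = 100
    control_inr_mean: float = 1.0
    control_inr_sd: float = 0.05
    warfarin_log_mu: float = _WARFARIN_MU
    warfarin_log_sigma: float = _WARFARIN_SIGMA
    profiles: tuple[MethodProfile, ...] = field(default_factory=default_sim_profiles)
    true_calibrations: Mapping[str, tuple[float, float]] | None = None
    noise_cv: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_warfarin < 0:
            raise ValidationError("cohort sizes must be non-negative")
        if self.noise_cv < 0:
            raise ValidationError("noise CV must be non-negative")
        for p in self.profiles:
            if p.mnpt is None:
                raise ValidationError(f"profile {p.method_id} needs an MNPT to simulate")
        if self.true_calibrations:
            for mid, (isi_t, mnpt_t) in self.true_calibrations.items():
                if isi_t <= 0 or mnpt_t <= 0:
                    raise ValidationError(f"true calibration for {mid} must be positive")


@dataclass
class LineSpec:
    """Design of a simulated calibrant run: a true PT/INR line plus noise."""

    slope_m: float = 0.8
    intercept_b: float = math.log(12.5)
    n_levels: int = 20
    inr_range: tuple[float, float] = (0.9, 4.5)
    n_replicates: int = 2
    noise_cv: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.inr_range
        if not (0 < lo < hi):
            raise ValidationError("inr_range endpoints must be positive and increasing")
        if self.n_levels < 3:
            raise ValidationError("need at least 3 certified levels")
        if self.n_replicates < 1:
            raise ValidationError("need at least 1 replicate")
        if self.noise_cv < 0:
            raise ValidationError("noise CV must be non-negative")


def true_line_for(
    profile: MethodProfile,
    true_calibrations: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[float, float]:
    """(slope, intercept) of the true PT/INR line of a simulated analyzer:
    ln PT = (1/ISI_true)·ln INR + ln MNPT_true.  This is the line a
    certified calibrant run would measure."""
    if true_calibrations and profile.method_id in true_calibrations:
        isi_t, mnpt_t = true_calibrations[profile.method_id]
    else:
        if profile.mnpt is None:
            raise ValidationError(f"profile {profile.method_id} has no MNPT")
        isi_t, mnpt_t = profile.isi, profile.mnpt
    return 1.0 / isi_t, math.log(mnpt_t)


def simulate_cohort(spec: CohortSpec) -> tuple[list[SampleRecord], pd.DataFrame]:
    """Draw a cohort; returns (records, ground-truth table).

    The truth table has one row per subject with the latent true INR and,
    per method, the noiseless PT — everything a recovery test needs.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_control + spec.n_warfarin
    true_inr = np.empty(n)
    true_inr[: spec.n_control] = np.abs(
        rng.normal(spec.control_inr_mean, spec.control_inr_sd, spec.n_control)
    )
    true_inr[spec.n_control :] = rng.lognormal(
        spec.warfarin_log_mu, spec.warfarin_log_sigma, spec.n_warfarin
    )
    ids = [f"{i + 1}N" for i in range(spec.n_control)] + [
        f"{i + 1}A" for i in range(spec.n_warfarin)
    ]
    cohorts = ["control"] * spec.n_control + ["warfarin"] * spec.n_warfarin

    truth_rows = {"sample_id": ids, "cohort": cohorts, "true_inr": true_inr}
    pts: dict[str, np.ndarray] = {}
    for p in spec.profiles:
        m_true, b_true = true_line_for(p, spec.true_calibrations)
        noiseless = np.exp(m_true * np.log(true_inr) + b_true)
        eta = rng.normal(0.0, spec.noise_cv, n) if spec.noise_cv > 0 else np.zeros(n)
        pts[p.method_id] = noiseless * np.exp(eta)
        truth_rows[f"{p.method_id}_pt_true"] = noiseless

    records = []
    for i in range(n):
        meas = {
            p.method_id: Measurement(
                float(pts[p.method_id][i]),
                float(compute_inr(pts[p.method_id][i], p)),
            )
            for p in spec.profiles
        }
        records.append(SampleRecord(ids[i], cohorts[i], meas))
    return records, pd.DataFrame(truth_rows)


def simulate_calibrants(spec: LineSpec, method_id: str = "sim") -> CalibrantSet:
    """Draw a calibrant run from a true line.

    Certified INR levels are evenly spaced on the ln scale across
    ``inr_range``; each replicate PT is exp(m·ln INR + b)·exp(eta).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.inr_range
    inr_levels = np.exp(np.linspace(math.log(lo), math.log(hi), spec.n_levels))
    cals = []
    for j, inr in enumerate(inr_levels):
        pt_true = math.exp(spec.slope_m * math.log(inr) + spec.intercept_b)
        eta = (
            rng.normal(0.0, spec.noise_cv, spec.n_replicates)
            if spec.noise_cv > 0
            else np.zeros(spec.n_replicates)
        )
        reps = tuple(float(pt_true * math.exp(e)) for e in eta)
        cals.append(Calibrant(f"C{j + 1:02d}", float(inr), reps))
    return CalibrantSet(method_id, cals)
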