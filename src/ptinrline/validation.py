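"""Monte-Carlo validation of the statistical machinery.

Simulation-based checks that the implemented tests hold their nominal
type-I error, that the calibration fit recovers its generating line, and
that the PT/INR line correction actually reduces inter-method disagreement
under a discordant scenario.  Used by the test-suite, the acceptance
script and the analysis drivers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .calibration import correct_frame, fit_ptinr_line
from .datasets import records_to_frame
from .simulate import (
    CohortSpec,
    LineSpec,
    default_sim_profiles,
    discordant_calibrations,
    simulate_calibrants,
    simulate_cohort,
    true_line_for,
)
from .stats import (
    ContingencyTable,
    chi_squared_homogeneity,
    contingency_from_columns,
    mauchly_test,
    rm_anova,
)

__all__ = [
    "type_i_error_rm_anova",
    "type_i_error_mauchly",
    "type_i_error_chi_squared",
    "slope_recovery_error",
    "correction_benefit",
]

#: Null bin probabilities for the chi-squared type-I simulation: the pooled
#: category distribution of the bundled study (all four methods combined).
NULL_BIN_PROBS = np.array([143, 197, 94, 35, 10], dtype=float) / 479


def type_i_error_rm_anova(n_reps: int = 1000, n: int = 120, k: int = 4,
                          seed: int = 0, alpha: float = 0.05) -> float:
    """Rejection rate of the GG-corrected repeated-measures ANOVA under a
    compound-symmetric null (subject random effect, no condition effect)."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_reps):
        X = rng.normal(0, 1.0, (n, 1)) + rng.normal(0, 0.5, (n, k))
        rej += rm_anova(X).p_gg < alpha
    return rej / n_reps


def type_i_error_mauchly(n_reps: int = 1000, n: int = 120, k: int = 4,
                         seed: int = 0, alpha: float = 0.05) -> float:
    """Rejection rate of Mauchly's test under an exchangeable
    (compound-symmetric, hence spherical) covariance."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_reps):
        X = rng.normal(0, 1.0, (n, 1)) + rng.normal(0, 0.5, (n, k))
        rej += mauchly_test(X).p_value < alpha
    return rej / n_reps


def type_i_error_chi_squared(n_reps: int = 1000, group_size: int = 120,
                             n_groups: int = 4, probs: np.ndarray | None = None,
                             seed: int = 0, alpha: float = 0.05) -> float:
    """Rejection rate of the homogeneity test when every group draws from
    the same multinomial."""
    rng = np.random.default_rng(seed)
    probs = NULL_BIN_PROBS if probs is None else np.asarray(probs, float)
    labels = tuple(f"g{i}" for i in range(n_groups))
    cols = tuple(f"c{i}" for i in range(len(probs)))
    rej = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse expected cells are the point
        for _ in range(n_reps):
            counts = rng.multinomial(group_size, probs, size=n_groups)
            tab = ContingencyTable(labels, cols, counts).drop_empty_columns()
            rej += chi_squared_homogeneity(tab).p_value < alpha
    return rej / n_reps


def slope_recovery_error(n_seeds: int = 100, noise_cv: float = 0.01,
                         slope_m: float = 0.8, seed: int = 0) -> float:
    """Relative error (fraction) of the mean fitted slope across seeds
    against the generating slope, at the stated calibrant noise."""
    slopes = []
    for i in range(n_seeds):
        cs = simulate_calibrants(
            LineSpec(slope_m=slope_m, noise_cv=noise_cv, seed=seed + i)
        )
        slopes.append(fit_ptinr_line(cs).slope_m)
    return abs(float(np.mean(slopes)) - slope_m) / slope_m


def correction_benefit(n_seeds: int = 100, seed: int = 0, noise_cv: float = 0.03,
                       calibrant_noise_cv: float = 0.01) -> pd.DataFrame:
    """Before/after chi-squared per seed under the discordant scenario.

    Each seed simulates a study-sized cohort whose analyzers report INRs
    through mis-assigned local ISI/MNPT values, fits PT/INR lines from
    calibrants drawn from each analyzer's true line, corrects, and computes
    the between-method homogeneity chi-squared on raw and corrected INRs.
    """
    profiles = default_sim_profiles()
    truth = discordant_calibrations(profiles)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(n_seeds):
            recs, _ = simulate_cohort(
                CohortSpec(seed=seed + s, noise_cv=noise_cv, true_calibrations=truth)
            )
            df = records_to_frame(recs)
            raw_cols = {
                p.method_id: df[f"{p.method_id}_inr"].dropna().to_numpy()
                for p in profiles
            }
            chi_raw = chi_squared_homogeneity(
                contingency_from_columns(raw_cols).drop_empty_columns()
            )
            lines = {}
            for i, p in enumerate(profiles):
                if not p.correctable:
                    continue
                m_t, b_t = true_line_for(p, truth)
                cs = simulate_calibrants(
                    LineSpec(slope_m=m_t, intercept_b=b_t,
                             noise_cv=calibrant_noise_cv,
                             seed=seed + 100_000 + 10 * s + i),
                    method_id=p.method_id,
                )
                lines[p.method_id] = fit_ptinr_line(cs)
            dfc = correct_frame(df, lines, profiles)
            cor_cols = {
                p.method_id: dfc[
                    f"{p.method_id}_inr_corrected" if p.correctable
                    else f"{p.method_id}_inr"
                ].dropna().to_numpy()
                for p in profiles
            }
            chi_cor = chi_squared_homogeneity(
                contingency_from_columns(cor_cols).drop_empty_columns()
            )
            rows.append({
                "seed": seed + s,
                "chi2_before": chi_raw.statistic,
                "p_before": chi_raw.p_value,
                "chi2_after": chi_cor.statistic,
                "p_after": chi_cor.p_value,
                "reduced": chi_cor.statistic < chi_raw.statistic,
            })
    return pd.DataFrame(rows)
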