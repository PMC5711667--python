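"""Inter-method agreement statistics.

Everything needed to ask "do k analyzers measuring the same samples agree?":

* binning of INR values into the clinical decision categories and the
  resulting methods-by-category contingency table;
* Pearson's chi-squared test of homogeneity of the binned distributions;
* Mauchly's test of sphericity on the contrast-transformed covariance of the
  repeated measurements;
* the Greenhouse-Geisser epsilon and the one-way repeated-measures ANOVA with
  GG-adjusted degrees of freedom;
* pairwise paired t-tests.

The test statistics are computed from their textbook definitions; scipy
supplies only the chi-squared, F and t distribution functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDesignError, ValidationError

__all__ = [
    "DEFAULT_INR_EDGES",
    "ContingencyTable",
    "ChiSquaredResult",
    "SphericityResult",
    "RmAnovaResult",
    "PairedTResult",
    "bin_inr",
    "contingency_from_columns",
    "chi_squared_homogeneity",
    "orthonormal_contrasts",
    "mauchly_test",
    "gg_epsilon",
    "rm_anova",
    "paired_t",
    "format_p",
]

#: Clinical INR category edges: <2, [2,3), [3,4), [4,5), >=5.
DEFAULT_INR_EDGES: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0)

#: Display threshold below which a p-value is additionally shown as "<2e-16",
#: mirroring the customary output of R.
P_DISPLAY_FLOOR = 2.2e-16


def format_p(p: float) -> str:
    """Display form of a p-value; values below 2.2e-16 print as ``<2e-16``."""
    return "<2e-16" if p < P_DISPLAY_FLOOR else f"{p:.3g}"


@dataclass(frozen=True)
class ContingencyTable:
    """Methods-by-category count matrix with totals."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match labels "
                f"({len(self.row_labels)} x {len(self.col_labels)})"
            )
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def drop_empty_columns(self) -> "ContingencyTable":
        """Remove categories observed by no method (their chi-squared
        contribution is undefined)."""
        keep = self.col_totals > 0
        return ContingencyTable(
            self.row_labels,
            tuple(l for l, k in zip(self.col_labels, keep) if k),
            self.counts[:, keep],
        )

    def to_dict(self) -> dict:
        return {
            "row_labels": list(self.row_labels),
            "col_labels": list(self.col_labels),
            "counts": self.counts.tolist(),
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "ContingencyTable":
        return cls(tuple(doc["row_labels"]), tuple(doc["col_labels"]),
                   np.asarray(doc["counts"], dtype=int))


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": self.df,
                "p_value": self.p_value, "p_display": format_p(self.p_value),
                "expected": np.asarray(self.expected).tolist()}


@dataclass(frozen=True)
class SphericityResult:
    w_statistic: float
    chi2_approx: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"w_statistic": self.w_statistic, "chi2_approx": self.chi2_approx,
                "df": self.df, "p_value": self.p_value,
                "p_display": format_p(self.p_value)}


@dataclass(frozen=True)
class RmAnovaResult:
    f_statistic: float
    df_num: float
    df_den: float
    gg_epsilon: float
    p_uncorrected: float
    p_gg: float
    n_complete: int

    def to_dict(self) -> dict:
        return {"f_statistic": self.f_statistic, "df_num": self.df_num,
                "df_den": self.df_den, "gg_epsilon": self.gg_epsilon,
                "p_uncorrected": self.p_uncorrected, "p_gg": self.p_gg,
                "p_gg_display": format_p(self.p_gg), "n_complete": self.n_complete}


@dataclass(frozen=True)
class PairedTResult:
    method_pair: tuple[str, str]
    t_statistic: float
    df: int
    p_value: float
    n_pairs: int

    def to_dict(self) -> dict:
        return {"method_pair": list(self.method_pair), "t_statistic": self.t_statistic,
                "df": self.df, "p_value": self.p_value,
                "p_display": format_p(self.p_value), "n_pairs": self.n_pairs}


def bin_inr(values: Sequence[float], edges: Sequence[float] = DEFAULT_INR_EDGES,
            ) -> np.ndarray:
    """Counts of INR values in [-inf, e1), [e1, e2), ..., [ek, inf).

    Intervals are half-open on the right, so an INR exactly at an edge falls
    in the upper category (2.00 counts as "2 <= INR < 3").  Values are
    rounded to 2 decimals first — the precision at which INRs are reported
    and at which the categories are defined.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 1 or np.any(np.diff(edges) <= 0):
        raise ValidationError("edges must be strictly increasing")
    vals = np.round(np.asarray(values, dtype=float), 2)
    if vals.size == 0:
        return np.zeros(len(edges) + 1, dtype=int)
    idx = np.searchsorted(edges, vals, side="right")
    return np.bincount(idx, minlength=len(edges) + 1)


def contingency_from_columns(
    columns: Mapping[str, Sequence[float]],
    edges: Sequence[float] = DEFAULT_INR_EDGES,
    col_labels: Sequence[str] | None = None,
) -> ContingencyTable:
    """Bin one value list per method into a shared contingency table."""
    edges = tuple(edges)
    if col_labels is None:
        lo = ["inr_lt_%g" % edges[0]]
        mid = ["inr_%g_to_%g" % (a, b) for a, b in zip(edges, edges[1:])]
        col_labels = lo + mid + ["inr_ge_%g" % edges[-1]]
    counts = np.vstack([bin_inr(v, edges) for v in columns.values()])
    return ContingencyTable(tuple(columns), tuple(col_labels), counts)


def chi_squared_homogeneity(table: ContingencyTable) -> ChiSquaredResult:
    """Pearson chi-squared test that all methods share one category
    distribution.

    Expected counts are ``row_total * col_total / grand_total``; no
    continuity correction is applied.  Expected cells below 5 are tolerated
    with a warning (pooling sparse categories is left to the caller).
    """
    obs = table.counts.astype(float)
    if np.any(table.row_totals == 0) or np.any(table.col_totals == 0):
        raise DegenerateDesignError(
            "contingency table has an empty row or column margin; drop it first "
            "(see ContingencyTable.drop_empty_columns)"
        )
    expected = np.outer(table.row_totals, table.col_totals) / table.grand_total
    if np.any(expected < 5):
        warnings.warn(
            f"{int((expected < 5).sum())} expected cell(s) below 5; the "
            "chi-squared approximation may be inaccurate",
            stacklevel=2,
        )
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return ChiSquaredResult(stat, df, float(sps.chi2.sf(stat, df)), expected)


def orthonormal_contrasts(k: int) -> np.ndarray:
    """A k x (k-1) matrix whose columns are orthonormal contrasts
    (orthogonal to the unit vector).  Normalized Helmert basis."""
    C = np.zeros((k, k - 1))
    for j in range(1, k):
        C[:j, j - 1] = 1.0
        C[j, j - 1] = -j
        C[:, j - 1] /= np.sqrt(j * (j + 1))
    return C


def _contrast_covariance(data: np.ndarray, contrasts: np.ndarray | None,
                         ) -> tuple[np.ndarray, int, int]:
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValidationError("data must be an n x k matrix")
    n, k = X.shape
    if k < 2:
        raise ValidationError("need at least 2 repeated conditions")
    if n <= k:
        raise DegenerateDesignError(f"need n > k complete cases, got n={n}, k={k}")
    if np.isnan(X).any():
        raise ValidationError("data must be complete (no missing cells)")
    C = orthonormal_contrasts(k) if contrasts is None else np.asarray(contrasts, float)
    if C.shape != (k, k - 1):
        raise ValidationError(f"contrast matrix must be {k} x {k - 1}")
    S = np.cov(X, rowvar=False, ddof=1)
    return C.T @ S @ C, n, k


def mauchly_test(data: np.ndarray, contrasts: np.ndarray | None = None,
                 ) -> SphericityResult:
    """Mauchly's test of sphericity for an n x k repeated-measures matrix.

    W = det(Sc) / (trace(Sc)/(k-1))**(k-1) on the contrast-transformed
    sample covariance Sc; the chi-squared approximation uses
    -(n-1)·d·ln W with d = 1 - (2(k-1)^2 + (k-1) + 2) / (6(k-1)(n-1)) and
    df = k(k-1)/2 - 1.  W is invariant to the choice of orthonormal
    contrast basis.
    """
    Sc, n, k = _contrast_covariance(data, contrasts)
    p_ = k - 1
    det = float(np.linalg.det(Sc))
    mean_eig = float(np.trace(Sc)) / p_
    if mean_eig == 0:
        # zero contrast variance: conditions identical for every subject,
        # sphericity holds trivially
        return SphericityResult(1.0, 0.0, k * (k - 1) // 2 - 1, 1.0)
    if det <= 0 or mean_eig < 0:
        warnings.warn(
            "contrast covariance is singular; reporting W at machine floor",
            stacklevel=2,
        )
        W = np.finfo(float).tiny
    else:
        W = min(det / mean_eig**p_, 1.0)
    d = 1.0 - (2 * p_**2 + p_ + 2) / (6.0 * p_ * (n - 1))
    chi2 = max(-(n - 1) * d * np.log(W), 0.0)
    df = k * (k - 1) // 2 - 1
    return SphericityResult(float(W), float(chi2), df, float(sps.chi2.sf(chi2, df)))


def gg_epsilon(data: np.ndarray, contrasts: np.ndarray | None = None) -> float:
    """Greenhouse-Geisser epsilon: (trace Sc)^2 / ((k-1)·trace(Sc^2)),
    clamped to [1/(k-1), 1].  Equals 1 under sphericity; the lower bound is
    attained when a single contrast carries all the variance."""
    Sc, _, k = _contrast_covariance(data, contrasts)
    tr = float(np.trace(Sc))
    tr2 = float(np.trace(Sc @ Sc))
    if tr2 <= 0:
        return 1.0  # zero contrast variance: trivially spherical
    eps = tr**2 / ((k - 1) * tr2)
    return float(min(max(eps, 1.0 / (k - 1)), 1.0))


def rm_anova(data: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    Classical within-subject decomposition of an n x k complete matrix:
    SS_total = SS_condition + SS_subject + SS_error, F = MS_condition /
    MS_error on ((k-1), (k-1)(n-1)) df; ``p_gg`` evaluates the same F at
    epsilon-deflated degrees of freedom.
    """
    X = np.asarray(data, dtype=float)
    eps = gg_epsilon(X)  # validates shape/completeness too
    n, k = X.shape
    grand = X.mean()
    cond_mean = X.mean(axis=0)
    subj_mean = X.mean(axis=1)
    ss_cond = n * float(((cond_mean - grand) ** 2).sum())
    ss_subj = k * float(((subj_mean - grand) ** 2).sum())
    # residual SS computed directly (not by subtraction) so that degenerate
    # inputs with zero interaction give exactly zero
    resid = X - cond_mean[None, :] - subj_mean[:, None] + grand
    ss_err = float((resid**2).sum())
    ss_tot = float(((X - grand) ** 2).sum())
    df_num, df_den = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df_den
    tol = 1e-12 * max(ss_tot, 1.0)
    if ms_err <= tol / df_den:
        f = 0.0 if ss_cond <= tol else np.inf
    else:
        f = (ss_cond / df_num) / ms_err
    p_unc = float(sps.f.sf(f, df_num, df_den))
    p_gg = float(sps.f.sf(f, eps * df_num, eps * df_den))
    return RmAnovaResult(float(f), float(df_num), float(df_den), eps,
                         p_unc, p_gg, n)


def paired_t(x: Sequence[float], y: Sequence[float],
             method_pair: tuple[str, str] = ("x", "y")) -> PairedTResult:
    """Two-sided paired t-test on differences d = x - y.

    t = mean(d) / (sd(d)/sqrt(n)), df = n - 1.  Degenerate cases: identical
    inputs give t = 0, p = 1; zero-variance differences with nonzero mean
    give p = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d arrays of equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("inputs must be pairwise complete")
    n = len(x)
    if n < 2:
        raise DegenerateDesignError("need at least 2 pairs")
    d = x - y
    sd = float(d.std(ddof=1))
    mean = float(d.mean())
    if sd == 0:
        if mean == 0:
            return PairedTResult(method_pair, 0.0, n - 1, 1.0, n)
        warnings.warn("zero-variance differences with nonzero mean; p = 0",
                      stacklevel=2)
        t = np.inf if mean > 0 else -np.inf
        return PairedTResult(method_pair, float(t), n - 1, 0.0, n)
    t = mean / (sd / np.sqrt(n))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return PairedTResult(method_pair, float(t), n - 1, p, n)
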