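"""Descriptive statistics of the amount of hearing-aid use.

Works on the day matrix A: pooled day-level moments, per-user mean daily
hours and within-user day-to-day SD, a light/medium/heavy segmentation at
the quartiles of per-user means, pooled-variance t contrasts with Cohen's
d, and the quadratic (no-intercept) curve relating a user's average use to
their variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import DayUseMatrix


def daily_hours(day_vector: np.ndarray) -> float:
    """Hours of use in one day: sum of the 18 hourly minutes / 60."""
    return float(np.asarray(day_vector, dtype=float).sum() / 60.0)


def coefficient_of_variation(mean: float, sd: float) -> float:
    """Between-user coefficient of variation, SD / mean."""
    return sd / mean


@dataclass
class SegmentContrast:
    segments: tuple[str, str]
    t_stat: float
    p_value: float
    cohens_d: float


@dataclass
class VariabilityCurveFit:
    """Least-squares fit of within-user SD on mean use: y = b1*x + b2*x^2."""

    b1: float
    b2: float
    r_squared: float

    @property
    def peak_hours(self) -> float | None:
        """Location of the curve's maximum, -b1/(2*b2), when concave."""
        if self.b2 < 0:
            return -self.b1 / (2.0 * self.b2)
        return None


@dataclass
class CohortUseSummary:
    pooled_mean: float  # hours/day over all retained days
    pooled_sd: float
    users: pd.DataFrame  # user_id, n_days, mean_hours, within_sd, segment
    q1: float
    q3: float
    cv: float
    contrasts: dict[str, SegmentContrast]
    curve: VariabilityCurveFit

    def summary(self) -> str:
        lines = [
            "Amount of hearing-aid use",
            "-" * 41,
            f"days: {int(self.users['n_days'].sum())}   users: {len(self.users)}",
            f"pooled day mean {self.pooled_mean:.2f} h (SD {self.pooled_sd:.2f})",
            f"user means: CV {self.cv:.3f}, Q1 {self.q1:.2f} h, Q3 {self.q3:.2f} h",
        ]
        sizes = self.users["segment"].value_counts()
        lines.append(
            "segments: "
            + ", ".join(f"{s}={int(sizes.get(s, 0))}" for s in ("light", "medium", "heavy"))
        )
        for name, c in self.contrasts.items():
            lines.append(
                f"within-SD {name}: t={c.t_stat:.2f}, p={c.p_value:.2e}, d={c.cohens_d:.2f}"
            )
        f = self.curve
        peak = f.peak_hours
        lines.append(
            f"variability curve y = {f.b1:.3f}x {f.b2:+.3f}x^2 "
            f"(R2={f.r_squared:.2f}"
            + (f", max at {peak:.1f} h)" if peak is not None else ")")
        )
        return "\n".join(lines)


def segment_contrast(
    group_a: np.ndarray, group_b: np.ndarray, labels: tuple[str, str] = ("a", "b")
) -> SegmentContrast:
    """Two-sample pooled-variance t-test plus Cohen's d (pooled SD)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both segments must be non-empty")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    d = 0.0 if pooled == 0 else (a.mean() - b.mean()) / pooled
    return SegmentContrast(labels, float(t), float(p), float(d))


def fit_variability_curve(
    mean_hours: np.ndarray, within_sd: np.ndarray
) -> VariabilityCurveFit:
    """Fit within-user SD on (x, x^2) without intercept.

    R^2 is computed against the zero-prediction baseline, the convention
    consistent with a through-the-origin fit.
    """
    x = np.asarray(mean_hours, dtype=float)
    y = np.asarray(within_sd, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 users to fit the curve")
    X = np.column_stack([x, x**2])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float((y**2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return VariabilityCurveFit(float(beta[0]), float(beta[1]), r2)


def cohort_use_summary(A: DayUseMatrix) -> CohortUseSummary:
    """Pooled and per-user use statistics, segments, contrasts, curve."""
    hours = A.values.sum(axis=1) / 60.0
    df = pd.DataFrame({"user_id": A.user_ids, "hours": hours})
    users = (
        df.groupby("user_id")["hours"]
        .agg(n_days="size", mean_hours="mean", within_sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    if len(users) < 2:
        raise ValueError("need at least 2 users")

    q1, q3 = np.percentile(users["mean_hours"], [25, 75])  # linear interpolation
    seg = np.where(
        users["mean_hours"] < q1, "light", np.where(users["mean_hours"] > q3, "heavy", "medium")
    )
    users["segment"] = seg

    valid = users.dropna(subset=["within_sd"])
    by = {s: valid.loc[valid["segment"] == s, "within_sd"].to_numpy() for s in
          ("light", "medium", "heavy")}
    contrasts = {}
    for other in ("light", "heavy"):
        if by["medium"].size >= 2 and by[other].size >= 2:
            contrasts[f"medium_vs_{other}"] = segment_contrast(
                by["medium"], by[other], ("medium", other)
            )

    curve = fit_variability_curve(
        valid["mean_hours"].to_numpy(), valid["within_sd"].to_numpy()
    )
    return CohortUseSummary(
        pooled_mean=float(hours.mean()),
        pooled_sd=float(hours.std(ddof=1)),
        users=users,
        q1=float(q1),
        q3=float(q3),
        cv=coefficient_of_variation(
            float(users["mean_hours"].mean()), float(users["mean_hours"].std(ddof=1))
        ),
        contrasts=contrasts,
        curve=curve,
    )
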