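"""Synthetic cohort generator for hour-resolved hearing-aid usage logs.

Real wear-time logs from smartphone-connected hearing aids are proprietary,
so every downstream stage of the pipeline is exercised on a simulated cohort
with known ground truth.  Each user belongs to one of three behavioral
groups (A: predominantly full days of use, B: predominantly afternoon use,
C: predominantly sporadic evening use) or is a "noise" user with no
predominant pattern.  A user's days are drawn from a Dirichlet mixture over
three archetypal day shapes, with a small rate of atypical (flat-random)
days, hour-level noise, and occasional disconnection windows during which
the hourly log is masked and only a per-window minute counter survives.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOURS = np.arange(6, 24)  # clock hours 6..23 -> 18 hourly features
N_HOURS = 18

GROUPS = ("A", "B", "C", "noise")
ARCHETYPES = ("full_day", "afternoon", "sporadic_evening")
#: which archetype each non-noise group predominantly experiences
GROUP_ARCHETYPE = {"A": "full_day", "B": "afternoon", "C": "sporadic_evening"}


def _curve(segments: dict[tuple[int, int], float]) -> np.ndarray:
    """Build an 18-value minutes/hour curve from {(first_hour, last_hour): minutes}."""
    out = np.zeros(N_HOURS)
    for (lo, hi), v in segments.items():
        out[lo - 6 : hi - 6 + 1] = v
    return out


@dataclass(frozen=True)
class ArchetypeTemplate:
    """Mean hourly shape of one archetypal day of hearing-aid use.

    ``mean_curve`` holds minutes of use for clock hours 6..23.  Jitter SDs
    act on the day level: onset jitter shifts the whole active period by a
    whole number of hours, duration jitter stretches or truncates its tail,
    and hourly noise perturbs the minutes within active hours.
    """

    name: str
    mean_curve: np.ndarray
    onset_jitter_sd: float = 1.0
    duration_jitter_sd: float = 1.0
    hourly_noise_sd: float = 5.0

    def __post_init__(self) -> None:
        curve = np.asarray(self.mean_curve, dtype=float)
        if curve.shape != (N_HOURS,):
            raise ValueError(f"mean_curve must have {N_HOURS} values")
        if curve.min() < 0 or curve.max() > 60:
            raise ValueError("mean_curve values must lie in [0, 60]")
        object.__setattr__(self, "mean_curve", curve)


def default_templates() -> dict[str, ArchetypeTemplate]:
    """The three archetypal day shapes.

    full_day: on ~7-22 (shoulder hours at 30 min); afternoon: on ~11-22
    with no morning mass; sporadic_evening: <4 h total, all after 17:00.
    """
    return {
        "full_day": ArchetypeTemplate(
            "full_day", _curve({(6, 6): 30, (7, 21): 55, (22, 22): 30})
        ),
        "afternoon": ArchetypeTemplate(
            "afternoon", _curve({(11, 21): 55, (22, 22): 30})
        ),
        "sporadic_evening": ArchetypeTemplate(
            "sporadic_evening", _curve({(18, 20): 40})
        ),
    }


@dataclass
class CohortConfig:
    """Parameters of the simulated cohort.

    Defaults reproduce the study conditions: ~28.5 logged days per user
    (SD 18), group shares ~49/15/20/15%, the predominant day type
    experienced ~60% of the time within each group, and 3% atypical days.
    """

    n_users: int = 500
    days_per_user: tuple[float, float] = (28.5, 18.0)
    group_weights: tuple[float, float, float, float] = (0.494, 0.154, 0.198, 0.154)
    dominant_proportion: float = 0.60
    mixture_concentration: float = 10.0
    day_type_weights_global: tuple[float, float, float] | None = None
    atypical_day_rate: float = 0.03
    disconnect_rate: float = 0.05
    disconnect_full_use_prob: float = 0.5
    binaural_perturbation_sd: float = 2.0
    start_date: str = "2021-03-01"
    period_days: int = 120
    seed: int = 0
    templates: dict[str, ArchetypeTemplate] = field(default_factory=default_templates)

    def __post_init__(self) -> None:
        if self.n_users < 0:
            raise ValueError("n_users must be non-negative")
        if abs(sum(self.group_weights) - 1.0) > 1e-9:
            raise ValueError("group_weights must sum to 1")
        if not (1 / 3 < self.dominant_proportion <= 1.0):
            raise ValueError("dominant_proportion must lie in (1/3, 1]")
        if self.mixture_concentration <= 0:
            raise ValueError("mixture_concentration must be positive")

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Generative labels: user group, per-day day type, disconnection windows."""

    user_groups: pd.DataFrame  # user_id, group
    day_types: pd.DataFrame  # user_id, date, day_type
    windows: pd.DataFrame  # user_id, date, start_hour, end_hour, counter_minutes


def sample_user_mixture(
    group: str, config: CohortConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw a user's day-type probability vector (full_day, afternoon, sporadic).

    Groups A/B/C draw from a Dirichlet whose mean puts ``dominant_proportion``
    on the group's predominant archetype and splits the rest evenly; noise
    users draw from the flat Dirichlet(1, 1, 1).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}")
    if group == "noise":
        return rng.dirichlet(np.ones(3))
    mean = np.full(3, (1.0 - config.dominant_proportion) / 2.0)
    mean[ARCHETYPES.index(GROUP_ARCHETYPE[group])] = config.dominant_proportion
    if not np.isfinite(config.mixture_concentration):
        return mean
    return rng.dirichlet(mean * config.mixture_concentration)


def sample_day_vector(
    day_type: str, template: ArchetypeTemplate, rng: np.random.Generator
) -> np.ndarray:
    """Draw one 18-hour day profile from an archetype template."""
    if template.name != day_type:
        raise ValueError("template does not match day_type")
    return _sample_day_batch(template, 1, rng)[0]


def _sample_day_batch(
    template: ArchetypeTemplate, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized draw of n days from one template.

    Onset jitter rolls the active period by whole hours; duration jitter
    extends the tail at the template's closing level or cuts it; hourly
    noise is added to active hours only (inactive hours stay exactly zero),
    then everything is clamped to [0, 60].
    """
    curve = template.mean_curve
    active = np.nonzero(curve)[0]
    if active.size == 0:
        return np.zeros((n, N_HOURS))
    first, last = active[0], active[-1]

    shift = np.rint(rng.normal(0.0, template.onset_jitter_sd, size=n)).astype(int)
    dur = np.rint(rng.normal(0.0, template.duration_jitter_sd, size=n)).astype(int)

    h = np.arange(N_HOURS)[None, :]  # (1, 18)
    idx = h - shift[:, None]  # template index for each output hour
    base = np.where((idx >= 0) & (idx < N_HOURS), curve[np.clip(idx, 0, N_HOURS - 1)], 0.0)

    shifted_last = (last + shift)[:, None]
    end = shifted_last + dur[:, None]
    out = np.where(h <= np.minimum(shifted_last, end), base, 0.0)
    out = np.where((h > shifted_last) & (h <= end), curve[last], out)

    is_active = out > 0
    out = out + is_active * rng.normal(0.0, template.hourly_noise_sd, size=out.shape)
    return np.clip(np.where(is_active, out, 0.0), 0.0, 60.0)


def _sample_day_types(
    groups: np.ndarray,
    days_per_user: np.ndarray,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day archetype labels and per-user mixtures."""
    mixtures = np.vstack(
        [sample_user_mixture(g, config, rng) for g in groups]
    ) if len(groups) else np.zeros((0, 3))
    if config.day_type_weights_global is not None:
        w = np.asarray(config.day_type_weights_global, dtype=float)
        mixtures = np.tile(w / w.sum(), (len(groups), 1))
    labels = []
    for u, n_days in enumerate(days_per_user):
        atypical = rng.random(n_days) < config.atypical_day_rate
        draws = rng.choice(3, size=n_days, p=mixtures[u])
        day_labels = np.array(ARCHETYPES, dtype=object)[draws]
        day_labels[atypical] = "atypical"
        labels.append(day_labels)
    return (np.concatenate(labels) if labels else np.array([], dtype=object)), mixtures


def inject_disconnections(
    log: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask hourly minutes inside randomly placed disconnection windows.

    Each day independently gets at most one window (probability
    ``disconnect_rate``) of 1-4 hours within 6..23.  With probability
    ``disconnect_full_use_prob`` the window is rewritten as full-time use
    (60 min/h) before masking.  The per-window counter records the true
    binaurally-resolved minutes inside the window; inside the window the
    emitted hourly minutes are absent (NaN) and the connection flag is 0.
    Returns (masked log, windows table).
    """
    log = log.copy()
    cols = ["user_id", "date", "start_hour", "end_hour", "counter_minutes"]
    days = log[["user_id", "date"]].drop_duplicates().reset_index(drop=True)
    hit = rng.random(len(days)) < config.disconnect_rate
    if not hit.any():
        return log, pd.DataFrame(columns=cols)

    chosen = days[hit].copy()
    length = rng.integers(1, 5, size=len(chosen))
    start = 6 + rng.integers(0, N_HOURS - length + 1)
    full = rng.random(len(chosen)) < config.disconnect_full_use_prob
    chosen["start_hour"] = start
    chosen["end_hour"] = start + length - 1  # inclusive last hour
    chosen["full"] = full

    merged = log.merge(chosen, on=["user_id", "date"], how="left")
    in_window = (
        merged["start_hour"].notna()
        & (merged["hour"] >= merged["start_hour"])
        & (merged["hour"] <= merged["end_hour"])
    ).to_numpy()
    force_full = in_window & merged["full"].eq(True).to_numpy()
    log.loc[force_full, "minutes"] = 60.0

    # counters use the binaural max so the resolved series is conserved exactly
    resolved = (
        log[in_window]
        .groupby(["user_id", "date", "hour"], sort=False)["minutes"]
        .max()
        .groupby(["user_id", "date"], sort=False)
        .sum()
        .rename("counter_minutes")
        .reset_index()
    )
    windows = chosen.merge(resolved, on=["user_id", "date"], how="left")
    windows["counter_minutes"] = windows["counter_minutes"].fillna(0.0)

    log.loc[in_window, "minutes"] = np.nan
    log.loc[in_window, "connected"] = 0
    return log, windows[cols].reset_index(drop=True)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the hour-resolved usage log and its ground truth.

    The log is long-format with columns (user_id, date, hour, side, minutes,
    connected); both ears are emitted, the right being a small perturbation
    of the left so binaural resolution is exercised.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_users
    if n == 0:
        empty_log = pd.DataFrame(
            columns=["user_id", "date", "hour", "side", "minutes", "connected"]
        )
        gt = GroundTruth(
            pd.DataFrame(columns=["user_id", "group"]),
            pd.DataFrame(columns=["user_id", "date", "day_type"]),
            pd.DataFrame(
                columns=["user_id", "date", "start_hour", "end_hour", "counter_minutes"]
            ),
        )
        return empty_log, gt

    user_ids = np.array([f"u{i:05d}" for i in range(n)])
    groups = rng.choice(GROUPS, size=n, p=np.asarray(config.group_weights))
    mu, sd = config.days_per_user
    n_days = np.maximum(1, np.rint(rng.normal(mu, sd, size=n))).astype(int)
    start_offsets = rng.integers(0, config.period_days, size=n)

    day_user = np.repeat(np.arange(n), n_days)
    within = np.concatenate([np.arange(k) for k in n_days])
    dates = (
        np.datetime64(config.start_date)
        + start_offsets[day_user]
        + within.astype("timedelta64[D]")
    )

    day_types, _ = _sample_day_types(groups, n_days, config, rng)

    # draw all day vectors, batched by archetype
    total_days = int(n_days.sum())
    left = np.empty((total_days, N_HOURS))
    for name in ARCHETYPES:
        mask = day_types == name
        if mask.any():
            left[mask] = _sample_day_batch(config.templates[name], int(mask.sum()), rng)
    mask = day_types == "atypical"
    if mask.any():
        left[mask] = rng.uniform(0.0, 60.0, size=(int(mask.sum()), N_HOURS))

    right = np.clip(
        left + rng.normal(0.0, config.binaural_perturbation_sd, size=left.shape),
        0.0,
        60.0,
    )
    right[left == 0] = 0.0  # an ear not worn logs nothing on either side

    frames = []
    for side, values in (("L", left), ("R", right)):
        frames.append(
            pd.DataFrame(
                {
                    "user_id": np.repeat(user_ids[day_user], N_HOURS),
                    "date": np.repeat(dates, N_HOURS),
                    "hour": np.tile(HOURS, total_days),
                    "side": side,
                    "minutes": values.ravel(),
                    "connected": 1,
                }
            )
        )
    log = pd.concat(frames, ignore_index=True)
    log["date"] = pd.to_datetime(log["date"])

    log, windows = inject_disconnections(log, config, rng)
    log = log.sort_values(["user_id", "date", "hour", "side"], kind="mergesort").reset_index(
        drop=True
    )

    truth = GroundTruth(
        user_groups=pd.DataFrame({"user_id": user_ids, "group": groups}),
        day_types=pd.DataFrame(
            {
                "user_id": user_ids[day_user],
                "date": pd.to_datetime(dates),
                "day_type": day_types,
            }
        ),
        windows=windows,
    )
    return log, truth


def write_cohort(log: pd.DataFrame, truth: GroundTruth, outdir) -> None:
    """Write logs.csv / windows.csv / truth.csv (masked hours omitted from logs)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    emitted = log.dropna(subset=["minutes"]).copy()
    emitted["date"] = pd.to_datetime(emitted["date"]).dt.strftime("%Y-%m-%d")
    emitted.to_csv(outdir / "logs.csv", index=False)
    w = truth.windows.copy()
    if len(w):
        w["date"] = pd.to_datetime(w["date"]).dt.strftime("%Y-%m-%d")
    w.to_csv(outdir / "windows.csv", index=False)
    t = truth.day_types.merge(truth.user_groups, on="user_id")
    t["date"] = pd.to_datetime(t["date"]).dt.strftime("%Y-%m-%d")
    t[["user_id", "group", "date", "day_type"]].to_csv(outdir / "truth.csv", index=False)
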