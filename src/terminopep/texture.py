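"""Texture profile analysis (TPA) of two-cycle compression curves.

A TPA instrument compresses a sample twice at constant speed and records
force (gf) against time (s). The four standard parameters are

* hardness — peak force of the first compression cycle (gf);
* cohesiveness — total area of cycle 2 / total area of cycle 1;
* springiness — contact duration of cycle 2 / contact duration of cycle 1
  (a time ratio; at constant probe speed this equals the distance ratio);
* resilience — withdrawal area / compression area within cycle 1.

Group comparisons against the raw control use Dunnett's many-to-one
procedure (familywise error controlled under the multivariate-t null).
Single-cycle curves are rejected: cohesiveness and springiness are
undefined without a second compression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TPACurve", "TPAParams", "Episode", "segment_cycles", "compute_tpa",
    "dunnett_vs_control", "simulate_tpa_curve", "read_tpa_curve",
]


@dataclass
class TPACurve:
    """A force-time record with a contact threshold (gf).

    Samples below ``contact_threshold`` (after baseline correction) are
    treated as probe-off-sample.
    """

    time: np.ndarray
    force: np.ndarray
    contact_threshold: float = 1e-3

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.shape != self.force.shape or self.time.size < 4:
            raise ValueError("time and force must be equal-length series (>= 4 points)")
        if not (np.diff(self.time) > 0).all():
            raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class TPAParams:
    hardness: float          # gf
    cohesiveness: float      # dimensionless, typically in [0, 1]
    springiness: float       # dimensionless
    resilience: float        # dimensionless

    def __post_init__(self) -> None:
        if self.hardness <= 0:
            raise ValueError("hardness must be positive")
        if self.cohesiveness < 0 or self.resilience < 0:
            raise ValueError("cohesiveness and resilience must be non-negative")


@dataclass(frozen=True)
class Episode:
    """A maximal above-threshold contact run, split at its force peak."""

    start: int               # index of first above-threshold sample
    stop: int                # index one past the last above-threshold sample
    peak: int                # index of the maximum force within the run


def _baseline_correct(force: np.ndarray, threshold: float) -> np.ndarray:
    """Subtract the modal pre-contact force and clip at zero.

    The mode is taken over samples preceding the first threshold crossing,
    after rounding to 3 decimals (instrument quantization scale).
    """
    above = np.flatnonzero(force > threshold)
    if above.size == 0 or above[0] == 0:
        return np.clip(force, 0.0, None)
    pre = np.round(force[: above[0]], 3)
    vals, counts = np.unique(pre, return_counts=True)
    baseline = float(vals[np.argmax(counts)])
    return np.clip(force - baseline, 0.0, None)


def segment_cycles(
    curve: TPACurve, min_gap: float = 0.5
) -> tuple[Episode, Episode, np.ndarray]:
    """Find the two compression episodes of a TPA curve.

    Episodes are maximal above-threshold runs after baseline correction;
    runs separated by sub-threshold gaps shorter than ``min_gap`` seconds
    are merged (noise flicker near the contact toes). Returns the two
    episodes and the baseline-corrected force. Fewer than two episodes is a
    hard error (single-cycle curve).
    """
    force = _baseline_correct(curve.force, curve.contact_threshold)
    above = force > curve.contact_threshold
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    stops = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(force))

    runs: list[list[int]] = []
    for s, e in zip(starts, stops):
        if runs and curve.time[s] - curve.time[runs[-1][1] - 1] < min_gap:
            runs[-1][1] = e
        else:
            runs.append([s, e])
    if len(runs) < 2:
        raise ValueError("single-cycle curve: two compression episodes required")

    episodes = []
    for s, e in runs[:2]:
        peak = s + int(np.argmax(force[s:e]))
        episodes.append(Episode(start=s, stop=e, peak=peak))
    return episodes[0], episodes[1], force


def _contact_duration(ep: Episode, t: np.ndarray, f: np.ndarray) -> float:
    """Episode duration between the interpolated zero-force edge crossings.

    The leading and trailing flanks are linearly extended to zero force, so
    durations are exact for piecewise-linear pulses rather than quantized
    to the sampling step or biased by the contact threshold.
    """
    t_on = t[ep.start]
    if ep.start > 0 and f[ep.start] > f[ep.start - 1]:
        t_on = t[ep.start - 1] - f[ep.start - 1] / (
            f[ep.start] - f[ep.start - 1]
        ) * (t[ep.start] - t[ep.start - 1])
    t_off = t[ep.stop - 1]
    if ep.stop < len(f) and f[ep.stop - 1] > f[ep.stop]:
        t_off = t[ep.stop - 1] + f[ep.stop - 1] / (
            f[ep.stop - 1] - f[ep.stop]
        ) * (t[ep.stop] - t[ep.stop - 1])
    return float(t_off - t_on)


def compute_tpa(curve: TPACurve) -> TPAParams:
    """Derive the four TPA parameters from a two-cycle curve.

    Areas use trapezoidal integration of force over time; contact durations
    span each episode's above-threshold run with the threshold crossings
    interpolated to sub-sample precision.
    """
    ep1, ep2, force = segment_cycles(curve)
    t = curve.time

    def area(a: int, b: int) -> float:
        return float(np.trapezoid(force[a:b], t[a:b]))

    area1 = area(ep1.start, ep1.stop)
    if area1 <= 0:
        raise ValueError("zero area in the first compression cycle")
    area2 = area(ep2.start, ep2.stop)
    dur1 = _contact_duration(ep1, t, force)
    dur2 = _contact_duration(ep2, t, force)
    compression1 = area(ep1.start, ep1.peak + 1)
    withdrawal1 = area(ep1.peak, ep1.stop)
    if compression1 <= 0:
        raise ValueError("zero compression area in the first cycle")
    return TPAParams(
        hardness=float(force[ep1.peak]),
        cohesiveness=area2 / area1,
        springiness=float(dur2 / dur1),
        resilience=withdrawal1 / compression1,
    )


def dunnett_vs_control(
    groups: Mapping[str, Sequence[float]],
    control_label: str,
    alpha: float = 0.05,
) -> dict[str, dict[str, float | bool]]:
    """Dunnett many-to-one comparison of every group against the control.

    Returns per-treatment-group adjusted p-values and significance flags at
    ``alpha``. If every observation in every group is identical the
    comparison is degenerate and all adjusted p-values are reported as 1;
    zero pooled variance with unequal means is a hard error.
    """
    if control_label not in groups:
        raise KeyError(f"control group {control_label!r} not found")
    if len(groups) < 2:
        raise ValueError("need at least one treatment group besides the control")
    control = np.asarray(groups[control_label], dtype=float)
    labels = [g for g in groups if g != control_label]
    samples = [np.asarray(groups[g], dtype=float) for g in labels]
    if control.size < 2 or any(s.size < 2 for s in samples):
        raise ValueError("every group needs n >= 2")

    pooled_sse = sum(
        float(((x - x.mean()) ** 2).sum()) for x in [control, *samples]
    )
    means = [x.mean() for x in [control, *samples]]
    if pooled_sse == 0.0:
        if np.ptp(means) == 0.0:
            return {
                g: {"mean": float(np.mean(groups[g])), "p_adjusted": 1.0,
                    "significant": False}
                for g in labels
            }
        raise ValueError("zero pooled variance with unequal group means")

    res = stats.dunnett(*samples, control=control, rng=np.random.default_rng(0))
    return {
        g: {
            "mean": float(np.mean(groups[g])),
            "p_adjusted": float(p),
            "significant": bool(p < alpha),
        }
        for g, p in zip(labels, res.pvalue)
    }


def simulate_tpa_curve(
    true_params: TPAParams,
    noise_sd: float,
    rng: np.random.Generator,
    cycle1_duration: float = 20.0,
    rest: float = 5.0,
    lead: float = 2.0,
    sample_rate: float = 1000.0,
    contact_threshold: float | None = None,
) -> TPACurve:
    """Piecewise-linear two-pulse curve whose analytic parameters are known.

    Cycle 1 is a triangle of height ``hardness`` and duration
    ``cycle1_duration`` with its apex placed so the withdrawal/compression
    area ratio equals ``resilience``; cycle 2 is a symmetric triangle sized
    so the area and duration ratios equal ``cohesiveness`` and
    ``springiness``. Additive Gaussian noise (``noise_sd`` gf) is applied
    and the force is clipped at zero.
    """
    H, C, S, R = (
        true_params.hardness, true_params.cohesiveness,
        true_params.springiness, true_params.resilience,
    )
    d1 = cycle1_duration
    apex_frac = 1.0 / (1.0 + R)          # withdrawal/compression area = R
    d2 = S * d1
    h2 = C * H / S                       # area2/area1 = C
    total = lead + d1 + rest + d2 + lead
    t = np.arange(0.0, total, 1.0 / sample_rate)
    # include the exact pulse vertices so trapezoidal integration and the
    # peak sample are exact for any apex position, not just on-grid ones
    vertices = np.array([
        lead, lead + d1 * apex_frac, lead + d1,
        lead + d1 + rest, lead + d1 + rest + d2 / 2, lead + d1 + rest + d2,
    ])
    t = np.union1d(t, vertices)

    def triangle(t0: float, dur: float, height: float, frac: float) -> np.ndarray:
        tt = t - t0
        up = height * tt / (dur * frac)
        down = height * (dur - tt) / (dur * (1 - frac))
        return np.clip(np.minimum(up, down), 0.0, None) * ((tt >= 0) & (tt <= dur))

    force = triangle(lead, d1, H, apex_frac) + triangle(lead + d1 + rest, d2, h2, 0.5)
    if noise_sd > 0:
        force = np.clip(force + rng.normal(0.0, noise_sd, size=force.size), 0.0, None)
    if contact_threshold is None:
        contact_threshold = max(1e-3, 5.0 * noise_sd)
    return TPACurve(time=t, force=force, contact_threshold=contact_threshold)


def read_tpa_curve(path, contact_threshold: float = 1e-3) -> TPACurve:
    """Read a curve CSV with columns ``time_s, force_gf``."""
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("time_s", "force_gf"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return TPACurve(
        time=df["time_s"].to_numpy(float),
        force=df["force_gf"].to_numpy(float),
        contact_threshold=contact_threshold,
    )
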