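"""Windowed, weighted and cumulative GC skew; origin/terminus prediction.

GC skew is the strand asymmetry (G-C)/(G+C) measured in windows tiled over
the molecule.  On circular replicons the cumulative skew curve typically
reaches its minimum near the replication origin and its maximum near the
terminus, because the leading strand of each replichore is G-enriched.  The
optional w/c weighting rescales each window's skew by window length over
total length, expressing its contribution relative to the whole molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import AnnotatedReplicon


@dataclass(frozen=True)
class SkewParams:
    """Windowing parameters.  ``weighting`` applies the w/c factor."""

    window_bp: int = 500
    step_bp: int = 100
    weighting: bool = True

    def validate(self, total_length: int, circular: bool) -> None:
        if not 0 < self.step_bp <= self.window_bp:
            raise ValueError("require 0 < step_bp <= window_bp")
        if self.window_bp > total_length and not circular:
            raise ValueError(
                f"window_bp {self.window_bp} exceeds linear molecule "
                f"length {total_length}")
        if self.window_bp > total_length:
            raise ValueError("window_bp exceeds molecule length")


@dataclass
class SkewProfile:
    """Per-window skew values plus the running (cumulative) sum of raw skew."""

    replicon_id: str
    total_length: int
    circular: bool
    params: SkewParams
    window_starts: np.ndarray = field(repr=False)
    window_centers: np.ndarray = field(repr=False)
    raw_skew: np.ndarray = field(repr=False)
    weighted_skew: np.ndarray = field(repr=False)
    cumulative: np.ndarray = field(repr=False)
    degenerate: np.ndarray = field(repr=False)  # windows with G+C == 0

    @property
    def n_windows(self) -> int:
        return len(self.raw_skew)


@dataclass(frozen=True)
class OriTerCall:
    """Origin/terminus prediction from cumulative-skew extrema.

    ``confidence`` is the max-min amplitude of the (detrended, on circular
    molecules) cumulative curve; a no-call has ``called=False`` and zero
    confidence.
    """

    ori_position: int | None
    ter_position: int | None
    ori_value: float
    ter_value: float
    confidence: float
    called: bool = True


def window_skew(replicon: AnnotatedReplicon, params: SkewParams) -> SkewProfile:
    """Tile windows at ``step_bp`` and compute (G-C)/(G+C) per window.

    Windows wrap past the origin on circular molecules so the tiling covers
    every start position ``1, 1+step, ...`` up to the molecule length; on
    linear molecules only fully contained windows are emitted.  Windows with
    G+C == 0 get raw skew 0 and a degenerate flag.
    """
    n = replicon.length
    if n == 0:
        raise ValueError("empty replicon")
    params.validate(n, replicon.circular)
    w, step = params.window_bp, params.step_bp

    arr = np.frombuffer(replicon.sequence.encode(), dtype=np.uint8)
    is_g = (arr == ord("G")).astype(np.int64)
    is_c = (arr == ord("C")).astype(np.int64)
    if replicon.circular:
        starts = np.arange(0, n, step)
        is_g = np.concatenate([is_g, is_g[:w]])
        is_c = np.concatenate([is_c, is_c[:w]])
    else:
        starts = np.arange(0, n - w + 1, step)
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    g = cg[starts + w] - cg[starts]
    c = cc[starts + w] - cc[starts]
    denom = g + c
    degenerate = denom == 0
    raw = np.where(degenerate, 0.0, (g - c) / np.where(degenerate, 1, denom))
    weighted = raw * (w / n) if params.weighting else raw.copy()
    centers = (starts + w // 2) % n + 1
    return SkewProfile(
        replicon_id=replicon.id, total_length=n, circular=replicon.circular,
        params=params, window_starts=starts + 1, window_centers=centers,
        raw_skew=raw, weighted_skew=weighted, cumulative=np.cumsum(raw),
        degenerate=degenerate)


def predict_ori_ter(profile: SkewProfile, ori_at: str = "min") -> OriTerCall:
    """Place ori at the cumulative-skew minimum and ter at the maximum.

    On circular profiles the extremum search runs on the mean-detrended
    cumulative curve: subtracting the per-window mean closes the curve over
    a full revolution, which makes the call independent of where the
    deposited sequence happens to start (rotation equivariance).  Ties are
    broken toward the smallest coordinate.  ``ori_at='max'`` flips the
    convention, since the deposited strand orientation of a plasmid is
    arbitrary.
    """
    if profile.n_windows < 3:
        raise ValueError("need at least 3 windows to call ori/ter")
    if bool(profile.degenerate.all()):
        return OriTerCall(None, None, 0.0, 0.0, 0.0, called=False)
    curve = profile.cumulative.astype(float)
    if profile.circular:
        curve = curve - profile.raw_skew.mean() * np.arange(1, len(curve) + 1)
    i_min = int(np.argmin(curve))
    i_max = int(np.argmax(curve))
    if ori_at == "max":
        i_min, i_max = i_max, i_min
    lo, hi = float(np.min(curve)), float(np.max(curve))
    return OriTerCall(
        ori_position=int(profile.window_centers[i_min]),
        ter_position=int(profile.window_centers[i_max]),
        ori_value=float(curve[i_min]), ter_value=float(curve[i_max]),
        confidence=hi - lo)


def profile_table(profile: SkewProfile):
    """Profile as a DataFrame (one row per window) for TSV output."""
    import pandas as pd

    return pd.DataFrame({
        "window_start": profile.window_starts,
        "window_center": profile.window_centers,
        "raw_skew": profile.raw_skew,
        "weighted_skew": profile.weighted_skew,
        "cumulative": profile.cumulative,
        "degenerate": profile.degenerate.astype(int),
    })


def plot_profile(profile: SkewProfile, call: OriTerCall | None, path) -> None:
    """Write a two-panel skew/cumulative plot to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    x = profile.window_centers
    ax1.plot(x, profile.raw_skew, lw=0.8)
    ax1.axhline(0, color="grey", lw=0.5)
    ax1.set_ylabel("(G-C)/(G+C)")
    ax2.plot(x, profile.cumulative, lw=0.8, color="tab:orange")
    ax2.set_ylabel("cumulative skew")
    ax2.set_xlabel("position (bp)")
    if call is not None and call.called:
        for ax in (ax1, ax2):
            ax.axvline(call.ori_position, color="green", lw=0.8, ls="--")
            ax.axvline(call.ter_position, color="red", lw=0.8, ls="--")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
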