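"""Worm locomotion metrics from centroid tracks.

Tracks are centroid positions sampled at 8 frames/s for a nominal 5 min
assay, with a per-frame direction label (forward / backward / pause)
supplied by the tracker or the synthetic generator.  The analysis applies
the study-design filters — animals leaving the field of view in the first
3 min, or averaging below 100 µm/s, are excluded — then scores reversal
bouts (backward runs lasting strictly more than 4 frames, i.e. more than
500 ms) and per-animal distance/speed/bout metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FPS",
    "Track",
    "ReversalBout",
    "filter_tracks",
    "detect_reversals",
    "track_metrics",
    "cohort_metrics",
]

FPS = 8.0
PAUSE_SPEED_UM_S = 20.0  # below this frame speed a frame counts as paused
MIN_MEAN_SPEED_UM_S = 100.0
FOV_GRACE_S = 180.0
MIN_REVERSAL_FRAMES = 4  # a reversal must be STRICTLY longer than this


@dataclass
class Track:
    """One worm's centroid track (µm) with per-frame direction labels."""

    worm_id: str
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    direction: np.ndarray | None = None  # "forward" | "backward" | "pause"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if len(self.t_s) < 2:
            raise ValueError("a track needs at least 2 frames")
        if not np.all(np.diff(self.t_s) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=object)

    def frame_speeds(self) -> np.ndarray:
        """Per-step speed in µm/s (length n-1)."""
        dt = np.diff(self.t_s)
        step = np.hypot(np.diff(self.x_um), np.diff(self.y_um))
        return step / dt

    def mean_speed(self, pause_speed: float = PAUSE_SPEED_UM_S) -> float:
        """Mean speed over moving frames (pauses excluded)."""
        v = self.frame_speeds()
        moving = v >= pause_speed
        if self.direction is not None:
            moving &= self.direction[:-1] != "pause"
        return float(v[moving].mean()) if moving.any() else 0.0


@dataclass
class ReversalBout:
    start_frame: int  # first backward frame
    end_frame: int  # last backward frame (inclusive)
    duration_s: float
    distance_um: float


def filter_tracks(
    tracks: list[Track],
    fov_bounds: tuple[float, float, float, float] | None = None,
    min_mean_speed: float = MIN_MEAN_SPEED_UM_S,
    fov_grace_s: float = FOV_GRACE_S,
    pause_speed: float = PAUSE_SPEED_UM_S,
) -> tuple[list[Track], dict]:
    """Apply the assay exclusion rules.

    Excludes tracks that leave the field of view (``fov_bounds`` =
    (xmin, ymin, xmax, ymax), when given) before ``fov_grace_s``, and
    tracks whose pause-excluded mean speed is below ``min_mean_speed``
    µm/s.  Returns the kept tracks and a log of exclusion counts.
    """
    kept: list[Track] = []
    log = {"fov": 0, "slow": 0, "kept": 0}
    for tr in tracks:
        if fov_bounds is not None:
            xmin, ymin, xmax, ymax = fov_bounds
            out = (
                (tr.x_um < xmin) | (tr.x_um > xmax)
                | (tr.y_um < ymin) | (tr.y_um > ymax)
            )
            if out.any() and tr.t_s[np.argmax(out)] < fov_grace_s:
                log["fov"] += 1
                continue
        if tr.mean_speed(pause_speed) < min_mean_speed:
            log["slow"] += 1
            continue
        kept.append(tr)
    log["kept"] = len(kept)
    return kept, log


def detect_reversals(
    track: Track, min_frames: int = MIN_REVERSAL_FRAMES
) -> list[ReversalBout]:
    """Maximal backward runs lasting strictly more than ``min_frames``.

    At 8 fps, more than 4 frames means more than 500 ms of backward
    locomotion.  Directions must be supplied on the track.
    """
    if track.direction is None:
        raise ValueError(
            "detect_reversals needs per-frame directions; supply the "
            "tracker's direction column on the Track"
        )
    back = np.asarray(track.direction == "backward")
    bouts: list[ReversalBout] = []
    step = np.hypot(np.diff(track.x_um), np.diff(track.y_um))
    i = 0
    n = len(back)
    while i < n:
        if back[i]:
            j = i
            while j + 1 < n and back[j + 1]:
                j += 1
            run = j - i + 1
            if run > min_frames:
                # distance covered over steps taken while backward
                hi = min(j + 1, len(track.t_s) - 1)
                dist = float(step[i:hi].sum())
                bouts.append(
                    ReversalBout(
                        start_frame=i,
                        end_frame=j,
                        duration_s=float(track.t_s[hi] - track.t_s[i]),
                        distance_um=dist,
                    )
                )
            i = j + 1
        else:
            i += 1
    return bouts


def track_metrics(
    track: Track,
    bouts: list[ReversalBout] | None = None,
    pause_speed: float = PAUSE_SPEED_UM_S,
) -> dict:
    """Per-animal locomotion metrics.

    Returns total path distance (mm), pause-excluded mean speed (µm/s),
    reversal count and rate (events/min), reverse distance (µm) and mean
    bout duration (s), and mean forward-run distance (mm) / duration (s)
    between consecutive reversals.
    """
    if bouts is None:
        bouts = detect_reversals(track) if track.direction is not None else []
    step = np.hypot(np.diff(track.x_um), np.diff(track.y_um))
    duration_s = float(track.t_s[-1] - track.t_s[0])
    total_mm = float(step.sum()) / 1000.0

    reverse_um = float(sum(b.distance_um for b in bouts))
    reverse_s = float(sum(b.duration_s for b in bouts))

    # forward runs = spans between consecutive reversal bouts
    marks = [(-1, -1)] + [(b.start_frame, b.end_frame) for b in bouts] + [
        (len(track.t_s) - 1, len(track.t_s) - 1)
    ]
    fwd_dist, fwd_dur = [], []
    for (_, prev_end), (next_start, _) in zip(marks[:-1], marks[1:]):
        s, e = prev_end + 1, next_start
        if e > s:
            fwd_dist.append(float(step[s:e].sum()))
            fwd_dur.append(float(track.t_s[e] - track.t_s[s]))
    return {
        "worm_id": track.worm_id,
        "duration_s": duration_s,
        "total_distance_mm": total_mm,
        "mean_speed_um_s": track.mean_speed(pause_speed),
        "n_reversals": len(bouts),
        "reversals_per_min": len(bouts) / (duration_s / 60.0),
        "reverse_distance_um": reverse_um,
        "reverse_duration_s": reverse_s / len(bouts) if bouts else 0.0,
        "forward_run_distance_mm": float(np.mean(fwd_dist)) / 1000.0 if fwd_dist else 0.0,
        "forward_run_duration_s": float(np.mean(fwd_dur)) if fwd_dur else 0.0,
    }


def cohort_metrics(tracks: list[Track], **kwargs) -> pd.DataFrame:
    """Metrics for every track, one row per worm."""
    return pd.DataFrame([track_metrics(t, **kwargs) for t in tracks])
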