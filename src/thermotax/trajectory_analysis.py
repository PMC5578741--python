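"""Microfluidic trajectory analysis: from particle detections to the
thermal migration coefficient (TMC).

The pipeline mirrors the assay's processing order and each stage only
removes or groups records, never altering coordinates:

1. particle filters (size and shape),
2. nearest-neighbor track linking,
3. motility filter (cross-channel vs flow-direction spread),
4. path-length filter,
5. position histogram and TMC.

Coordinates are in pixels with X the cross-channel axis (the thermal
gradient direction) and Y the flow axis; frames are 0-based.  The TMC
summarizes the pooled cross-channel positions of viable (motile, long
enough) trajectories:

    TMC = -2 [ (mean(X) - Xmin) / (Xmax - Xmin) - 0.5 ],

which is +1 when all cells pool at the left cutoff Xmin and -1 at the
right cutoff Xmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "ParticleDetection",
    "Trajectory",
    "TrackConfig",
    "TMCResult",
    "GradientMap",
    "EmptyDataError",
    "filter_particles",
    "link_nearest_neighbor",
    "classify_motile",
    "filter_path_length",
    "run_pipeline",
    "viable_positions",
    "position_histogram",
    "compute_tmc",
    "position_to_temperature",
    "detections_frame",
    "tracks_to_frame",
    "tracks_from_frame",
]

DETECTION_COLUMNS = ["frame", "x", "y", "area", "eccentricity"]


class EmptyDataError(ValueError):
    """No data left after filtering."""


@dataclass(frozen=True)
class ParticleDetection:
    """One thresholded particle: centroid, size and shape."""

    frame: int
    x: float
    y: float
    area: float
    eccentricity: float


def detections_frame(detections) -> pd.DataFrame:
    """Convert a sequence of :class:`ParticleDetection` (or dicts) to a
    DataFrame with the canonical detection columns."""
    if isinstance(detections, pd.DataFrame):
        return detections[DETECTION_COLUMNS].copy()
    rows = [
        d if isinstance(d, dict) else
        {"frame": d.frame, "x": d.x, "y": d.y, "area": d.area,
         "eccentricity": d.eccentricity}
        for d in detections
    ]
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


@dataclass
class Trajectory:
    """A linked track: per-point frame indices and pixel positions.

    ``motile``/``viable`` flags are filled by the pipeline stages; they are
    None until classified.
    """

    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    motile: bool | None = None
    viable: bool | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.frames) < 1:
            raise ValueError("trajectory needs at least one point")
        if len(self.frames) != len(self.x) or len(self.frames) != len(self.y):
            raise ValueError("frame/x/y lengths differ")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def path_length(self) -> float:
        """Cumulative step displacement in pixels (traveled distance)."""
        if len(self) < 2:
            return 0.0
        return float(np.sum(np.hypot(np.diff(self.x), np.diff(self.y))))


@dataclass(frozen=True)
class TrackConfig:
    """Filtering and linking thresholds of the tracking pipeline.

    Defaults follow the assay: particles under 5 px or with eccentricity
    above 0.95 are noise; tracks with std(Y)/std(X) of 18 or more are
    non-motile (flow-advected); tracks traveling under 10 px are dropped.
    ``link_max_px`` caps the per-frame linking distance at roughly 3x the
    per-frame flow displacement (30 µm/s at 12 fps and 0.3 µm/px is
    8.33 px/frame).
    """

    area_min: float = 5.0
    ecc_max: float = 0.95
    motility_ratio_max: float = 18.0
    min_path_px: float = 10.0
    link_max_px: float = 25.0
    fps: float = 12.0
    px_um: float = 0.3

    def __post_init__(self) -> None:
        for name in ("area_min", "ecc_max", "motility_ratio_max",
                     "min_path_px", "link_max_px", "fps", "px_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Stage 1: particle filters
# ---------------------------------------------------------------------------


def filter_particles(detections, cfg: TrackConfig | None = None) -> pd.DataFrame:
    """Drop detections smaller than ``area_min`` px or with eccentricity
    above ``ecc_max``; order is preserved.

    The thresholds are strict: area exactly ``area_min`` and eccentricity
    exactly ``ecc_max`` are kept.
    """
    cfg = cfg or TrackConfig()
    df = detections_frame(detections)
    keep = (df["area"] >= cfg.area_min) & (df["eccentricity"] <= cfg.ecc_max)
    return df.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Stage 2: nearest-neighbor linking
# ---------------------------------------------------------------------------


def link_nearest_neighbor(detections, cfg: TrackConfig | None = None) -> list[Trajectory]:
    """Concatenate per-frame centroids into tracks by nearest-neighbor
    assignment.

    Frame by frame, candidate (track, detection) pairs are processed in
    ascending distance order; a pair links if both are still unclaimed and
    the distance is at most ``link_max_px``.  Unmatched detections start
    new tracks; a track that finds no match is terminated (tracks never
    span a gap).  Deterministic for a given input order.
    """
    cfg = cfg or TrackConfig()
    df = detections_frame(detections)
    done: list[Trajectory] = []
    active: list[dict] = []  # each: {"frames": [...], "x": [...], "y": [...]}
    if len(df) == 0:
        return done

    for frame, grp in df.groupby("frame", sort=True):
        # retire tracks that skipped a frame (no gap allowance)
        fresh = [t for t in active if t["frames"][-1] == frame - 1]
        done.extend(
            Trajectory(t["frames"], t["x"], t["y"])
            for t in active
            if t["frames"][-1] != frame - 1
        )
        active = fresh
        px = grp["x"].to_numpy(float)
        py = grp["y"].to_numpy(float)
        n_det = len(px)
        matched_det = np.zeros(n_det, dtype=bool)
        matched_trk = np.zeros(len(active), dtype=bool)
        if active:
            last = np.array([(t["x"][-1], t["y"][-1]) for t in active])
            dist = cdist(last, np.column_stack([px, py]))
            order = np.argsort(dist, axis=None, kind="stable")
            for flat in order:
                ti, di = divmod(int(flat), n_det)
                if dist[ti, di] > cfg.link_max_px:
                    break
                if matched_trk[ti] or matched_det[di]:
                    continue
                matched_trk[ti] = matched_det[di] = True
                active[ti]["frames"].append(int(frame))
                active[ti]["x"].append(px[di])
                active[ti]["y"].append(py[di])
        # terminate tracks that found no detection this frame
        still = []
        for ti, t in enumerate(active):
            if matched_trk[ti]:
                still.append(t)
            else:
                done.append(Trajectory(t["frames"], t["x"], t["y"]))
        active = still
        for di in np.flatnonzero(~matched_det):
            active.append({"frames": [int(frame)], "x": [px[di]], "y": [py[di]]})

    done.extend(Trajectory(t["frames"], t["x"], t["y"]) for t in active)
    return done


# ---------------------------------------------------------------------------
# Stages 3-4: motility and path-length filters
# ---------------------------------------------------------------------------


def classify_motile(traj: Trajectory, cfg: TrackConfig | None = None) -> bool:
    """Motile iff std(Y)/std(X) < ``motility_ratio_max`` (strict).

    Non-motile cells ride the flow (Y) and barely move cross-channel (X),
    so their spread ratio is large; std(X) = 0 counts as non-motile.
    Population standard deviation over all trajectory points.
    """
    cfg = cfg or TrackConfig()
    if len(traj) < 2:
        raise ValueError("motility classification needs at least 2 points")
    sx = float(np.std(traj.x))
    sy = float(np.std(traj.y))
    if sx == 0.0:
        return False
    return sy / sx < cfg.motility_ratio_max


def filter_path_length(traj: Trajectory, cfg: TrackConfig | None = None) -> bool:
    """Viable iff the traveled distance is at least ``min_path_px``."""
    cfg = cfg or TrackConfig()
    return traj.path_length >= cfg.min_path_px


def run_pipeline(detections, cfg: TrackConfig | None = None) -> list[Trajectory]:
    """Particle filters -> linking -> motility -> path-length flags.

    Returns all tracks with ``motile`` and ``viable`` flags set; viable
    means motile and long enough.  Single-point tracks are flagged
    non-viable without a motility call.
    """
    cfg = cfg or TrackConfig()
    tracks = link_nearest_neighbor(filter_particles(detections, cfg), cfg)
    for t in tracks:
        if len(t) < 2:
            t.motile = False
            t.viable = False
            continue
        t.motile = classify_motile(t, cfg)
        t.viable = bool(t.motile and filter_path_length(t, cfg))
    return tracks


def viable_positions(tracks) -> np.ndarray:
    """Pool the X-positions of every point of every viable trajectory."""
    xs = [t.x for t in tracks if t.viable]
    if not xs:
        raise EmptyDataError("no viable trajectory points")
    return np.concatenate(xs)


# ---------------------------------------------------------------------------
# Stage 5: histogram and TMC
# ---------------------------------------------------------------------------


def position_histogram(tracks_or_x, bin_edges) -> tuple[np.ndarray, np.ndarray]:
    """Relative frequency of pooled X-positions over the given bins.

    Normalized by the total number of measurements, so the frequencies sum
    to 1 (points outside the bins are not counted against the total).
    """
    x = _as_positions(tracks_or_x)
    counts, edges = np.histogram(x, bins=bin_edges)
    total = counts.sum()
    if total == 0:
        raise EmptyDataError("no positions fall inside the histogram bins")
    return counts / total, edges


def _as_positions(tracks_or_x) -> np.ndarray:
    if isinstance(tracks_or_x, (list, tuple)) and tracks_or_x and isinstance(
        tracks_or_x[0], Trajectory
    ):
        return viable_positions(tracks_or_x)
    x = np.asarray(tracks_or_x, dtype=float).ravel()
    if x.size == 0:
        raise EmptyDataError("no positions given")
    return x


@dataclass(frozen=True)
class TMCResult:
    """Thermal migration coefficient with its provenance.

    ``tmc`` is +1 when all viable positions sit at the left cutoff
    ``x_min`` (formula convention; use ``warm_positive`` in
    :func:`compute_tmc` to flip the sign if the warm wall is at high X).
    """

    tmc: float
    n_points: int
    x_min: float
    x_max: float
    bin_edges: np.ndarray
    frequencies: np.ndarray


def compute_tmc(
    tracks_or_x,
    x_min: float | None = None,
    x_max: float | None = None,
    n_bins: int = 20,
    warm_positive: bool = False,
) -> TMCResult:
    """TMC = -2 [(mean(X) - Xmin)/(Xmax - Xmin) - 0.5] over pooled viable X.

    ``x_min``/``x_max`` are the channel cutoffs in pixels; when omitted they
    default to the observed extremes (supply them for cross-run
    comparability).  Positions are clipped to [x_min, x_max].  With
    ``warm_positive`` the sign is negated so that accumulation at the warm
    (high-X) wall reports +1.
    """
    x = _as_positions(tracks_or_x)
    x_min = float(np.min(x)) if x_min is None else float(x_min)
    x_max = float(np.max(x)) if x_max is None else float(x_max)
    if x_min >= x_max:
        raise ValueError(f"x_min ({x_min}) must be < x_max ({x_max})")
    x = np.clip(x, x_min, x_max)
    tmc = -2.0 * ((float(np.mean(x)) - x_min) / (x_max - x_min) - 0.5)
    if warm_positive:
        tmc = -tmc
    edges = np.linspace(x_min, x_max, n_bins + 1)
    freqs, edges = position_histogram(x, edges)
    return TMCResult(
        tmc=float(tmc), n_points=int(x.size), x_min=x_min, x_max=x_max,
        bin_edges=edges, frequencies=freqs,
    )


# ---------------------------------------------------------------------------
# Temperature mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GradientMap:
    """Linear wall-to-wall temperature gradient across the channel."""

    x_left: float
    x_right: float
    T_left: float
    T_right: float

    def __post_init__(self) -> None:
        if self.x_left >= self.x_right:
            raise ValueError("x_left must be < x_right")


def position_to_temperature(x, g: GradientMap):
    """Linearly interpolate temperature at cross-channel position ``x``.

    Raises for positions outside the channel walls.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < g.x_left) or np.any(x_arr > g.x_right):
        raise ValueError("position outside the channel walls")
    T = g.T_left + (x_arr - g.x_left) / (g.x_right - g.x_left) * (g.T_right - g.T_left)
    return T if T.ndim else float(T)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------


def tracks_to_frame(tracks) -> pd.DataFrame:
    """Long-format table: track_id, frame, x, y, motile, viable."""
    rows = []
    for tid, t in enumerate(tracks):
        for f, x, y in zip(t.frames, t.x, t.y):
            rows.append((tid, int(f), float(x), float(y),
                         bool(t.motile), bool(t.viable)))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "motile", "viable"])


def tracks_from_frame(df: pd.DataFrame) -> list[Trajectory]:
    """Inverse of :func:`tracks_to_frame`."""
    tracks = []
    for _, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(
            Trajectory(
                grp["frame"].to_numpy(), grp["x"].to_numpy(), grp["y"].to_numpy(),
                motile=bool(grp["motile"].iloc[0]), viable=bool(grp["viable"].iloc[0]),
            )
        )
    return tracks
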