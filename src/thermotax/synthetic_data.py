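"""Seeded synthetic inputs with known ground truth.

Emulates the statistical structure of the microfluidic assay and the
plate-reader growth experiments so the analysis pipeline can be exercised
end to end without wet-lab data:

* cell trajectories advected by flow along Y in a 500 µm channel, with an
  optional cross-channel (X) drift bias for motile cells and reflecting
  channel walls;
* spurious small or elongated detections that the particle filters must
  remove;
* a linear wall-to-wall temperature gradient;
* sigmoidal (logistic) growth curves with a baseline and Gaussian noise.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .growth_analysis import GrowthCurve
from .trajectory_analysis import DETECTION_COLUMNS, GradientMap

__all__ = [
    "TrajectorySimConfig",
    "GrowthSimConfig",
    "gen_trajectories",
    "gen_spurious_particles",
    "gen_growth_curve",
    "gen_gradient",
]


@dataclass(frozen=True)
class TrajectorySimConfig:
    """Conditions of the simulated tracking experiment.

    Channel geometry and flow follow the assay: a 500 µm wide channel
    (1667 px at 0.3 µm/px), 30 µm/s flow imaged at 12 frames/s
    (8.33 px/frame along Y).  Motile cells swim with run-and-tumble
    persistence: a per-axis velocity of magnitude ``swim_px`` (default
    6 px/frame, about 22 µm/s) whose direction reverses with probability
    ``p_turn`` per frame, plus Gaussian jitter of SD ``sigma_px`` and a
    mean cross-channel bias ``drift_px``, all on top of the Y advection.
    Non-motile cells only jitter in X (SD 0.1 px) while riding the flow.
    ``n_frames`` defaults to 60 (a ~5 s transit of the imaged field).
    X is reflected at the channel walls [0, channel_px].
    """

    n_motile: int = 25
    n_nonmotile: int = 10
    drift_px: float = 0.0
    sigma_px: float = 1.0
    swim_px: float = 6.0
    p_turn: float = 0.1
    flow_px: float = 30.0 / 12.0 / 0.3  # 8.33 px/frame
    channel_px: float = 500.0 / 0.3     # 1667 px
    n_frames: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_motile < 0 or self.n_nonmotile < 0:
            raise ValueError("cell counts must be >= 0")
        if self.channel_px <= 0 or self.n_frames < 1:
            raise ValueError("channel_px must be > 0 and n_frames >= 1")
        if not (0.0 <= self.p_turn <= 1.0):
            raise ValueError("p_turn must be in [0, 1]")


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold positions into [lo, hi] by reflection at both walls."""
    width = hi - lo
    x = np.mod(x - lo, 2.0 * width)
    return lo + np.where(x > width, 2.0 * width - x, x)


def gen_trajectories(cfg: TrajectorySimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-frame particle detections and their true tracks.

    Returns
    -------
    detections : DataFrame
        Columns frame, x, y, area, eccentricity — what the tracking
        pipeline consumes.  Rows are shuffled within each frame.  Areas are
        drawn >= 5 px and eccentricities < 0.95, so every simulated cell
        survives the particle filters.
    truth : DataFrame
        Same rows plus ``track_id`` and ``motile`` ground-truth columns,
        in (track_id, frame) order.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_motile + cfg.n_nonmotile
    if n == 0 or cfg.n_frames == 0:
        empty = pd.DataFrame(columns=DETECTION_COLUMNS)
        truth = pd.DataFrame(columns=DETECTION_COLUMNS + ["track_id", "motile"])
        return empty, truth

    x0 = rng.uniform(0.0, cfg.channel_px, size=n)
    y0 = rng.uniform(0.0, 2000.0, size=n)  # dilute cells along the flow axis
    X = np.empty((cfg.n_frames, n))
    Y = np.empty((cfg.n_frames, n))
    X[0] = x0
    Y[0] = y0

    nm = cfg.n_motile
    steps_x = np.zeros((cfg.n_frames - 1, n))
    steps_y = np.full((cfg.n_frames - 1, n), cfg.flow_px)
    if nm and cfg.n_frames > 1:
        def telegraph():
            # persistent ±1 run directions, reversing with prob p_turn/frame
            d0 = rng.choice([-1.0, 1.0], size=nm)
            flips = rng.random((cfg.n_frames - 1, nm)) < cfg.p_turn
            return d0 * np.cumprod(np.where(flips, -1.0, 1.0), axis=0)

        steps_x[:, :nm] = (
            cfg.drift_px
            + cfg.swim_px * telegraph()
            + rng.normal(0.0, cfg.sigma_px, size=(cfg.n_frames - 1, nm))
        )
        steps_y[:, :nm] += cfg.swim_px * telegraph() + rng.normal(
            0.0, cfg.sigma_px, size=(cfg.n_frames - 1, nm)
        )
    X[1:] = x0 + np.cumsum(steps_x, axis=0)
    X = _reflect(X, 0.0, cfg.channel_px)
    if cfg.n_nonmotile:
        # non-motile: independent small jitter about the anchor, not a walk
        X[:, nm:] = _reflect(
            x0[nm:] + rng.normal(0.0, 0.1, size=(cfg.n_frames, cfg.n_nonmotile)),
            0.0, cfg.channel_px,
        )
    Y[1:] = y0 + np.cumsum(steps_y, axis=0)

    frames = np.repeat(np.arange(cfg.n_frames), n)
    ids = np.tile(np.arange(n), cfg.n_frames)
    truth = pd.DataFrame(
        {
            "frame": frames,
            "x": X.ravel(),
            "y": Y.ravel(),
            "area": rng.integers(5, 26, size=n * cfg.n_frames).astype(float),
            "eccentricity": rng.uniform(0.0, 0.9, size=n * cfg.n_frames),
            "track_id": ids,
            "motile": ids < nm,
        }
    )
    # detections: shuffle within each frame so linking cannot rely on order
    perm = np.concatenate(
        [f * n + rng.permutation(n) for f in range(cfg.n_frames)]
    )
    detections = truth.iloc[perm][DETECTION_COLUMNS].reset_index(drop=True)
    truth = truth.sort_values(["track_id", "frame"]).reset_index(drop=True)
    return detections, truth


def gen_spurious_particles(
    n_small: int,
    n_elongated: int,
    seed: int = 0,
    n_frames: int = 60,
    channel_px: float = 500.0 / 0.3,
) -> pd.DataFrame:
    """Detections that the particle filters must remove.

    ``n_small`` records have area < 5 px; ``n_elongated`` have
    eccentricity > 0.95 (strictly, so boundary values stay valid).
    """
    if n_small < 0 or n_elongated < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    n = n_small + n_elongated
    area = np.concatenate(
        [rng.integers(1, 5, size=n_small), rng.integers(5, 26, size=n_elongated)]
    ).astype(float)
    ecc = np.concatenate(
        [rng.uniform(0.0, 0.9, size=n_small), rng.uniform(0.9501, 0.9999, size=n_elongated)]
    )
    return pd.DataFrame(
        {
            "frame": rng.integers(0, n_frames, size=n),
            "x": rng.uniform(0.0, channel_px, size=n),
            "y": rng.uniform(0.0, 1000.0, size=n),
            "area": area,
            "eccentricity": ecc,
        },
        columns=DETECTION_COLUMNS,
    )


@dataclass(frozen=True)
class GrowthSimConfig:
    """Logistic growth with lag: od(t) = baseline + K/(1 + e^{-r (t - t0)}).

    Defaults emulate a plate-reader well in minimal medium: carrying
    capacity 0.6 OD, rate 0.6/h, midpoint 6 h, 0.01 OD baseline, Gaussian
    read noise, 16 h sampled every 0.1 h.
    """

    K: float = 0.6
    r: float = 0.6
    t0: float = 6.0
    baseline: float = 0.01
    sigma: float = 0.01
    t_end: float = 16.0
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K <= 0 or self.r <= 0 or self.dt <= 0:
            raise ValueError("K, r and dt must be positive")


def gen_growth_curve(cfg: GrowthSimConfig) -> GrowthCurve:
    """Seeded logistic OD600 curve, clipped positive."""
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.t_end + cfg.dt / 2.0, cfg.dt)
    od = cfg.baseline + cfg.K / (1.0 + np.exp(-cfg.r * (t - cfg.t0)))
    if cfg.sigma > 0:
        od = od + rng.normal(0.0, cfg.sigma, size=len(t))
    return GrowthCurve(t, np.maximum(od, 1e-4))


def gen_gradient(
    T_left: float = 23.5,
    T_right: float = 41.5,
    x_left: float = 0.0,
    x_right: float = 500.0 / 0.3,
) -> GradientMap:
    """Linear wall-to-wall gradient; defaults span 23.5–41.5 °C across the
    1667 px (500 µm) channel with the cold wall on the left."""
    return GradientMap(x_left=x_left, x_right=x_right, T_left=T_left, T_right=T_right)
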