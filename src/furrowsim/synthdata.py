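"""Synthetic particle tracks and membrane-length profile tables.

These generators emulate the two experimental data streams the analysis
pipelines consume:

* **Tracks** — 0.5 µm beads injected into the cellularizing embryo and
  imaged for ~10 min.  The ``viscous`` model is planar Brownian motion with
  diffusion coefficient D (MSD = 4Dτ); the ``kelvin_voigt`` model is an
  Ornstein–Uhlenbeck process (Brownian motion in a harmonic trap) whose MSD
  saturates at a plateau, the negative control for an elastic medium.

* **Profiles** — per-embryo lateral membrane lengths versus position
  (signed cell count from the ventral midline, −10…9).  ``double_peak``
  emulates the late wild-type pattern (longest membranes peripheral in the
  furrow), ``single_peak`` the anillin-knockdown pattern (longest membranes
  central), ``flat`` a null pattern for calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticTrackSet",
    "SyntheticProfileSet",
    "simulate_tracks",
    "synth_length_profiles",
]

TRACK_MODELS = ("viscous", "kelvin_voigt")
PROFILE_PATTERNS = ("single_peak", "double_peak", "flat")


@dataclass
class SyntheticTrackSet:
    """Uniformly sampled 2D tracks: ``data`` has columns
    (track_id, t, x, y)."""

    data: pd.DataFrame
    model_label: str
    dt: float
    params: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def positions(self) -> np.ndarray:
        """(n_tracks, n_samples, 2) array."""
        n = self.n_tracks
        m = len(self.data) // n
        return self.data[["x", "y"]].to_numpy().reshape(n, m, 2)

    def times(self) -> np.ndarray:
        return self.data["t"].to_numpy()[: len(self.data) // self.n_tracks]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, model_label="viscous", dt=None) -> "SyntheticTrackSet":
        df = pd.read_csv(path)
        if dt is None:
            t = df["t"].to_numpy()
            dt = float(np.min(np.diff(np.unique(t))))
        return cls(data=df, model_label=model_label, dt=dt)


def simulate_tracks(
    model: str,
    params: dict | None = None,
    n_tracks: int = 100,
    dt: float = 1.0,
    duration: float = 600.0,
    seed: int | None = None,
) -> SyntheticTrackSet:
    """Simulate bead tracks in 2D.

    ``viscous``: increments ~ N(0, 2 D dt) per axis, so the ensemble MSD is
    4 D τ.  Default D = 0.0075 µm²/s, which puts the 10-minute MSD at
    18 µm².

    ``kelvin_voigt``: overdamped bead in a harmonic trap,
    dx = −(x/τ_r) dt + √(2D) dW, with relaxation time ``tau_r`` (s); the MSD
    plateaus at 4 D τ_r (2 D τ_r per axis).

    Timestamps are strictly increasing with uniform interval ``dt``; the
    same ``seed`` reproduces tracks bit for bit.
    """
    if model not in TRACK_MODELS:
        raise ValueError(f"unknown track model {model!r}; choose from {TRACK_MODELS}")
    if dt <= 0 or duration < dt:
        raise ValueError("require dt > 0 and duration >= dt")
    params = dict(params or {})
    D = params.setdefault("D", 0.0075)
    if D < 0:
        raise ValueError("diffusion coefficient must be non-negative")

    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps + 1) * dt

    if model == "viscous":
        steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_tracks, n_steps, 2))
        pos = np.concatenate(
            [np.zeros((n_tracks, 1, 2)), np.cumsum(steps, axis=1)], axis=1
        )
    else:
        tau_r = params.setdefault("tau_r", 5.0)
        if tau_r <= 0:
            raise ValueError("tau_r must be positive")
        # exact OU update over one sampling interval, started from the
        # stationary trap distribution so the MSD plateau 4·D·τ_r holds at
        # every lag
        a = np.exp(-dt / tau_r)
        sd = np.sqrt(D * tau_r * (1.0 - a * a))
        pos = np.zeros((n_tracks, n_steps + 1, 2))
        pos[:, 0] = rng.normal(0.0, np.sqrt(D * tau_r), size=(n_tracks, 2))
        for k in range(1, n_steps + 1):
            pos[:, k] = a * pos[:, k - 1] + rng.normal(0.0, sd, size=(n_tracks, 2))

    frames = []
    for i in range(n_tracks):
        frames.append(
            pd.DataFrame({"track_id": i, "t": t, "x": pos[i, :, 0], "y": pos[i, :, 1]})
        )
    data = pd.concat(frames, ignore_index=True)
    return SyntheticTrackSet(data=data, model_label=model, dt=dt, params=params, seed=seed)


@dataclass
class SyntheticProfileSet:
    """Per-embryo membrane-length tables: ``data`` has columns
    (embryo_id, position, length_um)."""

    data: pd.DataFrame
    pattern: str
    noise: float
    seed: int | None = None

    @property
    def n_embryos(self) -> int:
        return self.data["embryo_id"].nunique()

    def matrix(self) -> pd.DataFrame:
        """Embryos × positions matrix of lengths."""
        return self.data.pivot(index="embryo_id", columns="position", values="length_um")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pattern="unknown", noise=float("nan")) -> "SyntheticProfileSet":
        return cls(data=pd.read_csv(path), pattern=pattern, noise=noise)


def _mean_profile(pattern: str, positions: np.ndarray, baseline: float, amplitude: float):
    x = positions + 0.5  # cell-centre offset so the pattern is mirror symmetric
    if pattern == "flat":
        return np.full_like(x, baseline, dtype=float)
    if pattern == "single_peak":
        return baseline + amplitude * np.exp(-(x / 3.5) ** 2)
    # double_peak: two symmetric bumps peripheral in the furrow, local
    # minimum at the midline
    return baseline + amplitude * (
        np.exp(-((x - 6.0) / 2.5) ** 2) + np.exp(-((x + 6.0) / 2.5) ** 2)
    )


def synth_length_profiles(
    pattern: str,
    n_embryos: int = 10,
    amplitude: float = 8.0,
    noise: float = 2.0,
    baseline: float = 25.0,
    positions: tuple[int, int] = (-10, 9),
    seed: int | None = None,
) -> SyntheticProfileSet:
    """Generate per-embryo membrane-length profiles.

    The mean profile is the chosen spatial pattern (µm); each embryo adds
    i.i.d. Gaussian measurement noise per position plus a small embryo-level
    offset (half the per-position noise), emulating embryo-to-embryo size
    variation.  Lengths are clipped to stay positive.
    """
    if pattern not in PROFILE_PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {PROFILE_PATTERNS}")
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    if noise < 0:
        raise ValueError("noise must be non-negative")

    rng = np.random.default_rng(seed)
    pos = np.arange(positions[0], positions[1] + 1)
    mean = _mean_profile(pattern, pos, baseline, amplitude)

    rows = []
    for e in range(n_embryos):
        offset = rng.normal(0.0, 0.5 * noise)
        lengths = mean + offset + rng.normal(0.0, noise, size=len(pos))
        lengths = np.clip(lengths, 0.1, None)
        rows.append(pd.DataFrame({"embryo_id": e, "position": pos, "length_um": lengths}))
    data = pd.concat(rows, ignore_index=True)
    return SyntheticProfileSet(data=data, pattern=pattern, noise=noise, seed=seed)
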