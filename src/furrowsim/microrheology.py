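"""Passive and active microrheology of the cytoplasm.

Mean-squared displacement (MSD) of tracked beads distinguishes viscous from
elastic media: in a viscous fluid the MSD grows linearly with lag time
(〈r²(τ)〉 = 4Dτ in 2D), whereas elastic confinement makes it sub-linear and
ultimately bounded.  The bead pull-release experiment probes the same
question actively: in a purely viscous medium a bead dragged to a new
position stays there after the force is removed (no recoil), while an
elastic medium springs it back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthdata import SyntheticTrackSet

__all__ = [
    "MSDCurve",
    "RecoilResult",
    "msd",
    "rms_displacement",
    "linearity_test",
    "recoil_fraction",
]


@dataclass
class MSDCurve:
    """Ensemble- and time-averaged MSD versus lag time.

    ``n_pairs[k]`` counts the displacement pairs that entered lag ``lags[k]``
    (pooled over tracks and overlapping windows), exposing the growing
    uncertainty at long lags.
    """

    lags: np.ndarray
    values: np.ndarray
    n_pairs: np.ndarray
    estimator: str = "time_averaged"

    def at(self, lag: float) -> float:
        """MSD at the grid lag closest to ``lag``."""
        return float(self.values[int(np.argmin(np.abs(self.lags - lag)))])


def msd(tracks: SyntheticTrackSet, max_lag: float | None = None) -> MSDCurve:
    """Time-and-ensemble averaged MSD with overlapping windows.

    For every lag k·dt, averages |r(t+τ) − r(t)|² over all window starts in
    every track.  ``max_lag`` beyond the track duration is truncated with a
    warning.
    """
    pos = tracks.positions()  # (n_tracks, n_samples, 2)
    n_tracks, n_samples, _ = pos.shape
    if n_tracks < 1 or n_samples < 2:
        raise ValueError("need at least one track with two samples")
    dt = tracks.dt
    duration = (n_samples - 1) * dt
    if max_lag is None:
        max_lag = duration
    elif max_lag > duration:
        warnings.warn(
            f"max_lag {max_lag} s exceeds track duration {duration} s; truncating",
            stacklevel=2,
        )
        max_lag = duration
    k_max = max(1, int(round(max_lag / dt)))

    lags = np.arange(1, k_max + 1) * dt
    values = np.empty(k_max)
    n_pairs = np.empty(k_max, dtype=int)
    for k in range(1, k_max + 1):
        d = pos[:, k:, :] - pos[:, :-k, :]
        sq = np.sum(d * d, axis=2)
        values[k - 1] = sq.mean()
        n_pairs[k - 1] = sq.size
    return MSDCurve(lags=lags, values=values, n_pairs=n_pairs)


def rms_displacement(msd_value: float) -> float:
    """Root of an MSD value, reported at the conventional one-decimal
    rounding (an 18 µm² MSD is a 4.2 µm typical displacement)."""
    if msd_value < 0:
        raise ValueError("MSD must be non-negative")
    return round(float(np.sqrt(msd_value)), 1)


def linearity_test(
    curve: MSDCurve,
    alpha_threshold: float = 0.9,
) -> dict:
    """Log-log slope of the MSD curve and viscous/elastic classification.

    Fits log MSD = α log τ + c by least squares over all positive-MSD lags
    (requires ≥ 5 lags spanning at least one decade).  Returns α, its
    standard error (from fit residuals), a 95% confidence interval and the
    classification: ``viscous`` when α ≥ ``alpha_threshold``, otherwise
    ``elastic``.
    """
    keep = curve.values > 0
    lags, vals = curve.lags[keep], curve.values[keep]
    if len(lags) < 5 or lags.max() / lags.min() < 10.0:
        raise ValueError("need >= 5 positive-MSD lags spanning >= 1 decade")
    x, y = np.log(lags), np.log(vals)
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    alpha = float(coef[0])
    n = len(x)
    dof = max(n - 2, 1)
    s2 = float(res[0]) / dof if len(res) else 0.0
    se = float(np.sqrt(s2 / np.sum((x - x.mean()) ** 2)))
    return {
        "alpha": alpha,
        "stderr": se,
        "ci95": (alpha - 1.96 * se, alpha + 1.96 * se),
        "classification": "viscous" if alpha >= alpha_threshold else "elastic",
    }


@dataclass
class RecoilResult:
    release_time: float
    pull_displacement: float
    recoil_displacement: float
    fraction: float
    classification: str


def recoil_fraction(
    track: np.ndarray,
    times: np.ndarray,
    release_time: float,
    window: float,
    viscous_threshold: float = 0.05,
) -> RecoilResult:
    """Quantify bead recoil after force release.

    ``track`` is (n, 2) positions over ``times`` spanning the pull phase and
    at least ``window`` seconds beyond ``release_time``.  Displacements are
    projected on the pull axis (start → position at release); the recoil
    fraction is the backwards displacement within the window divided by the
    net pull displacement.  Classified ``viscous`` below
    ``viscous_threshold`` ("no detectable recoil"), else ``viscoelastic``.
    """
    track = np.asarray(track, float)
    times = np.asarray(times, float)
    if times[0] > release_time or times[-1] < release_time + window:
        raise ValueError("track must span [pull start, release_time + window]")
    i_rel = int(np.searchsorted(times, release_time, side="right") - 1)
    i_end = int(np.searchsorted(times, release_time + window, side="right") - 1)
    pull_vec = track[i_rel] - track[0]
    pull = float(np.linalg.norm(pull_vec))
    if pull == 0.0:
        raise ValueError("zero net pull displacement; pull axis undefined")
    axis = pull_vec / pull
    end_proj = float((track[i_end] - track[0]) @ axis)
    recoil = pull - end_proj  # positive when the bead moved back toward start
    frac = max(recoil, 0.0) / pull
    return RecoilResult(
        release_time=release_time,
        pull_displacement=pull,
        recoil_displacement=recoil,
        fraction=frac,
        classification="viscous" if frac < viscous_threshold else "viscoelastic",
    )
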