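"""Lateral mean-square displacement and diffusion coefficients.

The lateral MSD is averaged over all molecules of a species and all time
origins at each lag (FFT accumulation, with a direct reference method
available), after removing the per-leaflet lateral centre-of-motion
drift.  The 2-D diffusion coefficient is the MSD slope over a central
lag window divided by 4, converted with 1 A^2/ns = 1e-7 cm^2/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import Trajectory
from .geometry import min_image_displacement

__all__ = ["MSDResult", "lateral_msd", "fit_diffusion", "windowed_diffusion", "unwrap_lateral"]

A2_PER_NS_TO_CM2_PER_S = 1e-7


@dataclass
class MSDResult:
    species: str
    lags_ns: np.ndarray
    msd_A2: np.ndarray
    n_molecules: int
    window_label: str = "full"
    D_cm2_s: float | None = None
    D_stderr: float | None = None
    fit_range_ns: tuple[float, float] | None = None


def unwrap_lateral(wrapped: np.ndarray, box_xy) -> np.ndarray:
    """Unwrap lateral positions assuming per-frame steps < box/2."""
    steps = min_image_displacement(np.diff(wrapped, axis=0), box_xy, mode="xy")
    out = np.empty_like(wrapped)
    out[0] = wrapped[0]
    out[1:] = wrapped[0] + np.cumsum(steps, axis=0)
    return out


def _msd_fft(r: np.ndarray) -> np.ndarray:
    """Time-origin averaged MSD of (T, N, d) positions via FFT."""
    T = r.shape[0]
    flat = r.reshape(T, -1)
    nfft = 1 << (2 * T - 1).bit_length()
    fk = np.fft.rfft(flat, n=nfft, axis=0)
    acf = np.fft.irfft(fk * np.conj(fk), n=nfft, axis=0)[:T].real
    # S1 recursion: Q starts at 2*sum(|r|^2) and shrinks from both ends per lag
    D = (flat**2).reshape(T, r.shape[1], r.shape[2]).sum(axis=2)  # (T, N)
    acf_mol = acf.reshape(T, r.shape[1], r.shape[2]).sum(axis=2)  # (T, N)
    msd = np.empty((T, r.shape[1]))
    Q = 2.0 * D.sum(axis=0)
    msd[0] = Q / T - 2.0 * acf_mol[0] / T
    for tau in range(1, T):
        Q = Q - D[tau - 1] - D[T - tau]
        msd[tau] = Q / (T - tau) - 2.0 * acf_mol[tau] / (T - tau)
    return msd.mean(axis=1)


def _msd_direct(r: np.ndarray) -> np.ndarray:
    """Naive O(T^2) time-origin averaged MSD (oracle path)."""
    T = r.shape[0]
    out = np.zeros(T)
    for tau in range(1, T):
        d = r[tau:] - r[:-tau]
        out[tau] = np.mean(np.sum(d * d, axis=-1))
    return out


def _species_positions(traj: Trajectory, species: str) -> tuple[np.ndarray, np.ndarray]:
    f0 = traj[0]
    sel = f0.select_molecules(species=species, lipids_only=True)
    if len(sel) == 0:
        raise ValueError(f"species {species} absent from trajectory")
    T = len(traj)
    xy = np.empty((T, len(sel), 2))
    for t, f in enumerate(traj):
        xy[t] = f.head_centroids(sel)[:, :2]
    return xy, f0.leaflets[sel].astype(str)


def lateral_msd(
    traj: Trajectory,
    species: str,
    use_unwrapped: np.ndarray | None = None,
    remove_drift: bool = True,
    method: str = "fft",
    window_label: str = "full",
) -> MSDResult:
    """Lateral MSD(tau) for one species, averaged over molecules/origins.

    Stored frames hold wrapped coordinates; they are unwrapped with the
    minimum-image step rule (valid while per-frame displacements stay
    below half the box).  Pass ``use_unwrapped`` (T, n_mol, 2) to skip
    unwrapping, e.g. with a generator's exact ground-truth walk.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 frames for an MSD")
    if use_unwrapped is not None:
        xy = np.asarray(use_unwrapped, dtype=float)
        leaflets = traj[0].leaflets[traj[0].select_molecules(species=species, lipids_only=True)].astype(str)
        if xy.shape[1] != len(leaflets):
            raise ValueError("use_unwrapped molecule count does not match the species selection")
    else:
        wrapped, leaflets = _species_positions(traj, species)
        box = traj[0].box
        max_step = np.abs(min_image_displacement(np.diff(wrapped, axis=0), box[:2], mode="xy")).max() if len(wrapped) > 1 else 0
        if max_step > min(box[0], box[1]) / 2 - 1e-9:
            raise ValueError(
                "cannot unwrap: per-frame displacements reach half the box; "
                "store more frequent frames or pass use_unwrapped positions"
            )
        xy = unwrap_lateral(wrapped, box[:2])
    if remove_drift:
        for leaf in np.unique(leaflets):
            m = leaflets == leaf
            drift = xy[:, m, :].mean(axis=1, keepdims=True)
            xy[:, m, :] = xy[:, m, :] - (drift - drift[0])
    msd = _msd_fft(xy) if method == "fft" else _msd_direct(xy)
    msd[0] = 0.0
    times = traj.times
    lags = times - times[0]
    return MSDResult(species=species, lags_ns=lags, msd_A2=msd, n_molecules=xy.shape[1], window_label=window_label)


def fit_diffusion(msd: MSDResult, fit_fraction: tuple[float, float] = (0.1, 0.5)) -> MSDResult:
    """Least-squares line over a central lag window; D = slope / 4.

    Short lags carry crossover effects and long lags few origins, so the
    default fit uses 10-50% of the maximum lag.  A negative fitted slope
    is reported with its sign after a warning.
    """
    lo, hi = fit_fraction
    max_lag = msd.lags_ns[-1]
    mask = (msd.lags_ns >= lo * max_lag) & (msd.lags_ns <= hi * max_lag) & (msd.lags_ns > 0)
    if mask.sum() < 10:
        raise ValueError(f"only {int(mask.sum())} lags inside the fit window; need >= 10")
    res = stats.linregress(msd.lags_ns[mask], msd.msd_A2[mask])
    if res.slope < 0:
        warnings.warn("negative MSD slope: reporting D with its sign", stacklevel=2)
    msd.D_cm2_s = res.slope / 4.0 * A2_PER_NS_TO_CM2_PER_S
    msd.D_stderr = res.stderr / 4.0 * A2_PER_NS_TO_CM2_PER_S
    msd.fit_range_ns = (float(lo * max_lag), float(hi * max_lag))
    return msd


def windowed_diffusion(
    traj: Trajectory,
    species: str,
    window_ns: float = 1000.0,
    fit_fraction: tuple[float, float] = (0.1, 0.5),
) -> pd.DataFrame:
    """Independent MSD + fit per consecutive non-overlapping time window."""
    times = traj.times
    span = times[-1] - times[0]
    if window_ns > span + 1e-9:
        raise ValueError(f"window ({window_ns} ns) longer than trajectory ({span:.1f} ns)")
    rows = []
    t0 = times[0]
    w = 0
    while t0 + window_ns <= times[-1] + 1e-9:
        idx = np.flatnonzero((times >= t0 - 1e-9) & (times <= t0 + window_ns + 1e-9))
        sub = Trajectory([traj[i] for i in idx], dt=traj.dt)
        msd = fit_diffusion(lateral_msd(sub, species, window_label=f"{t0:.0f}-{t0 + window_ns:.0f} ns"), fit_fraction)
        rows.append(
            {
                "window_start_ns": t0,
                "window_end_ns": t0 + window_ns,
                "D_cm2_s": msd.D_cm2_s,
                "D_stderr": msd.D_stderr,
            }
        )
        t0 += window_ns
        w += 1
    return pd.DataFrame(rows)
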