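"""Electrogram post-processing: activation maps, ATa maps, beat selection.

Activation is marked at the steepest negative deflection of the unipolar
signal (sub-sample refined).  Repolarization is summarized per channel by
the area under the atrial T wave,

    ATa = integral_{ta+T1}^{ta+T2} (phi(t) - phi(ta+T2)) dt
          / ((T2 - T1) * sigma_phi),

a dimensionless marker of local repolarization gradients: the baseline is
anchored at the upper integration bound (isoelectric just after the end of
atrial repolarization) and amplitude is normalized by the standard deviation
of the whole signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .electrogram import EgmSet

__all__ = [
    "ActivationMap",
    "ATaMap",
    "BeatWindow",
    "detect_activation",
    "activation_map",
    "smooth_map",
    "compute_ata",
    "ata_map",
    "delta_ata",
    "locate_peak",
    "select_beats",
    "export_map_csv",
    "export_map_vtk",
]

DEFAULT_T1 = 35.0    # ms, lower ATa bound for simulated signals
DEFAULT_T2 = 300.0   # ms, upper ATa bound


class FlatSignalError(ValueError):
    """No deflection to detect in the waveform."""


@dataclass
class ActivationMap:
    values: np.ndarray          # (n,) activation times, ms
    positions: np.ndarray       # (n, 3)
    smoothed: bool = False
    space_constant: float = np.nan
    beat_id: int = 0


@dataclass
class ATaMap:
    values: np.ndarray          # (n,) dimensionless
    positions: np.ndarray
    t1: float = DEFAULT_T1
    t2: float = DEFAULT_T2
    smoothed: bool = False
    space_constant: float = np.nan
    beat_id: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.t1 < self.t2 <= 300.0):
            raise ValueError("need 0 < T1 < T2 <= 300 ms")


@dataclass
class BeatWindow:
    """Atrial activity interval of one beat."""

    earliest: float             # ms, earliest atrial activation
    latest: float               # ms, latest atrial activation
    accepted: bool = True

    @property
    def start(self) -> float:
        return self.earliest

    @property
    def end(self) -> float:
        # atrial APD is always < 300 ms, so repolarization has finished here
        return self.latest + 300.0


def detect_activation(waveform: np.ndarray, fs: float = 1000.0,
                      window: tuple[float, float] | None = None) -> float:
    """Activation time (ms): steepest negative derivative of the unipolar
    signal within the window, refined by parabolic interpolation."""
    w = np.asarray(waveform, dtype=float)
    if w.std() == 0:
        raise FlatSignalError("flat signal: no activation to detect")
    dt = 1000.0 / fs
    deriv = np.gradient(w, dt)
    t = np.arange(len(w)) * dt
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
        if not mask.any():
            raise ValueError("empty detection window")
    else:
        mask = np.ones(len(w), dtype=bool)
    idx = np.where(mask)[0]
    k = idx[int(np.argmin(deriv[idx]))]
    # parabolic refinement around the derivative minimum
    if 0 < k < len(w) - 1:
        y0, y1, y2 = deriv[k - 1], deriv[k], deriv[k + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-15 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    return (k + shift) * dt


def activation_map(egm: EgmSet, window: tuple[float, float] | None = None,
                   beat_id: int = 0) -> ActivationMap:
    """Per-channel activation detection over an electrogram set."""
    values = np.array([
        detect_activation(w, egm.fs, window) for w in egm.waveforms
    ])
    return ActivationMap(values=values, positions=egm.positions,
                         beat_id=beat_id)


def smooth_map(m, space_constant: float = 5.0):
    """Gaussian spatial filter over channel positions.

    value_i <- sum_j w_ij v_j / sum_j w_ij,  w_ij = exp(-d_ij^2 / (2 s^2)),
    with Euclidean inter-channel distances.
    """
    if space_constant <= 0:
        raise ValueError("space constant must be positive")
    pos = m.positions
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * space_constant ** 2))
    sm = (w @ m.values) / w.sum(axis=1)
    import copy

    out = copy.copy(m)
    out.values = sm
    out.smoothed = True
    out.space_constant = space_constant
    return out


def compute_ata(waveform: np.ndarray, t_a: float, t1: float = DEFAULT_T1,
                t2: float = DEFAULT_T2, fs: float = 1000.0,
                sigma_phi: float | None = None) -> float:
    """Area under the atrial T wave of one waveform (trapezoidal)."""
    w = np.asarray(waveform, dtype=float)
    dt = 1000.0 / fs
    t = np.arange(len(w)) * dt
    lo, hi = t_a + t1, t_a + t2
    if hi > t[-1] + 1e-9:
        raise ValueError(
            f"ATa window [{lo:.0f}, {hi:.0f}] ms exceeds the record"
        )
    sigma = w.std() if sigma_phi is None else sigma_phi
    if sigma <= 0:
        raise ValueError("sigma_phi must be positive for a non-trivial ATa")
    grid = np.arange(lo, hi + 0.5 * dt, dt)
    vals = np.interp(grid, t, w)
    baseline = float(np.interp(hi, t, w))
    area = np.trapezoid(vals - baseline, grid)
    return float(area / ((t2 - t1) * sigma))


def ata_map(egm: EgmSet, activation: ActivationMap, t1: float = DEFAULT_T1,
            t2: float = DEFAULT_T2, beat_id: int = 0) -> ATaMap:
    values = np.array([
        compute_ata(w, ta, t1, t2, egm.fs)
        for w, ta in zip(egm.waveforms, activation.values)
    ])
    return ATaMap(values=values, positions=egm.positions, t1=t1, t2=t2,
                  beat_id=beat_id)


def delta_ata(map_a: ATaMap, map_b: ATaMap) -> ATaMap:
    """Elementwise difference of two ATa maps on the same channel set."""
    if len(map_a.values) != len(map_b.values) or not np.allclose(
            map_a.positions, map_b.positions):
        raise ValueError("ATa maps are on different channel sets")
    out = ATaMap(values=map_a.values - map_b.values,
                 positions=map_a.positions, t1=map_a.t1, t2=map_a.t2)
    return out


def locate_peak(delta_map: ATaMap, signed: str = "abs",
                uniform_tol: float = 1e-12) -> np.ndarray:
    """Location of the extremum of a difference map.

    ``signed`` selects |delta| ("abs"), maximum ("pos") or minimum ("neg").
    A spatially uniform difference map carries no localizing information and
    raises ``ValueError``.
    """
    v = delta_map.values
    if np.ptp(v) <= uniform_tol:
        raise ValueError("difference map is uniform: no localizable peak")
    if signed == "abs":
        k = int(np.argmax(np.abs(v)))
    elif signed == "pos":
        k = int(np.argmax(v))
    elif signed == "neg":
        k = int(np.argmin(v))
    else:
        raise ValueError("signed must be abs/pos/neg")
    return delta_map.positions[k]


def select_beats(beats: list[BeatWindow],
                 qt_intervals: list[tuple[float, float]]) -> list[BeatWindow]:
    """Keep beats whose atrial activity interval overlaps no QT interval.

    Overlap is closed-interval: a shared endpoint counts as overlap
    (conservative rejection).
    """
    out = []
    for b in beats:
        ok = all(b.end < q0 or b.start > q1 for q0, q1 in qt_intervals)
        out.append(BeatWindow(b.earliest, b.latest, accepted=ok))
    return [b for b in out if b.accepted]


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def export_map_csv(m, path) -> None:
    import pandas as pd

    df = pd.DataFrame({
        "channel": np.arange(len(m.values)),
        "x_mm": m.positions[:, 0],
        "y_mm": m.positions[:, 1],
        "z_mm": m.positions[:, 2],
        "value": m.values,
    })
    df.to_csv(path, index=False)


def export_map_vtk(surface, values: np.ndarray, path,
                   name: str = "map") -> None:
    """Write a legacy-ASCII VTK polydata file with one point scalar field."""
    values = np.asarray(values, dtype=float)
    if len(values) != surface.n_nodes:
        raise ValueError("one value per surface node required")
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{name}\nASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {surface.n_nodes} float\n")
        for p in surface.nodes:
            f.write(f"{p[0]:.6g} {p[1]:.6g} {p[2]:.6g}\n")
        m = len(surface.triangles)
        f.write(f"POLYGONS {m} {4 * m}\n")
        for t in surface.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        f.write(f"POINT_DATA {surface.n_nodes}\n")
        f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        for v in values:
            f.write(f"{v:.6g}\n")
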