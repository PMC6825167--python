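"""Electrode montages on the unit sphere.

All spatial computations downstream (alpha topography, volume-conduction
mixing, spherical-spline CSD) work with unit-sphere electrode positions,
so the montage is stored as labels plus radius-1 Cartesian coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Occipital region of interest used for all alpha summaries.
ROI_CHANNELS = ("Oz", "POz", "O1", "O2")

_SUPPORTED_LAYOUTS = {64: "biosemi64"}


@dataclass(frozen=True)
class Montage:
    """Electrode labels with unit-sphere positions.

    Parameters
    ----------
    labels
        Unique channel names; must contain the occipital ROI channels.
    positions
        ``(n, 3)`` Cartesian coordinates, each with unit norm.
    """

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "labels", tuple(self.labels))
        if pos.shape != (len(self.labels), 3):
            raise ValueError(
                f"positions shape {pos.shape} does not match {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels in montage")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("montage positions must lie on the unit sphere")
        missing = [ch for ch in ROI_CHANNELS if ch not in self.labels]
        if missing:
            raise ValueError(f"montage lacks required ROI channels: {missing}")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def position(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]

    def angles_from(self, label: str) -> np.ndarray:
        """Great-circle angle (rad) of every electrode from ``label``."""
        ref = self.position(label)
        cosang = np.clip(self.positions @ ref, -1.0, 1.0)
        return np.arccos(cosang)

    def pairwise_cos(self) -> np.ndarray:
        """Matrix of cos(angle) between all electrode pairs."""
        return np.clip(self.positions @ self.positions.T, -1.0, 1.0)


def _fit_sphere_center(points: np.ndarray) -> np.ndarray:
    """Least-squares sphere centre of a point cloud."""
    A = np.c_[2.0 * points, np.ones(len(points))]
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def build_montage(n_channels: int = 64) -> Montage:
    """Standard 10-10 montage with ``n_channels`` electrodes.

    Positions come from the standard montage set shipped with MNE,
    re-centred on a least-squares sphere fit and projected to radius 1.
    Only layouts containing the occipital ROI are supported.
    """
    if n_channels < 4:
        raise ValueError(
            f"n_channels={n_channels}: at least the 4 ROI channels "
            f"{ROI_CHANNELS} are required"
        )
    if n_channels not in _SUPPORTED_LAYOUTS:
        raise ValueError(
            f"no packaged layout with {n_channels} channels; "
            f"supported: {sorted(_SUPPORTED_LAYOUTS)}"
        )
    import mne

    std = mne.channels.make_standard_montage(_SUPPORTED_LAYOUTS[n_channels])
    ch_pos = std.get_positions()["ch_pos"]
    labels = list(ch_pos)
    pts = np.array([ch_pos[ch] for ch in labels])
    centre = _fit_sphere_center(pts)
    rel = pts - centre
    rel /= np.linalg.norm(rel, axis=1, keepdims=True)
    return Montage(tuple(labels), rel)


def save_montage_csv(montage: Montage, path) -> None:
    """Write a montage as CSV with columns label,x,y,z."""
    import pandas as pd

    df = pd.DataFrame(montage.positions, columns=["x", "y", "z"])
    df.insert(0, "label", montage.labels)
    df.to_csv(path, index=False, float_format="%.12g")


def load_montage_csv(path) -> Montage:
    """Read a label,x,y,z CSV written by :func:`save_montage_csv`."""
    import pandas as pd

    df = pd.read_csv(path)
    pos = df[["x", "y", "z"]].to_numpy(float)
    # tolerate rounding from the CSV text representation
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(tuple(df["label"]), pos)
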