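"""Electrode montages on the unit sphere.

A :class:`Montage` is an ordered set of channel labels with 3-D positions on
the unit sphere.  It is the geometric basis for spherical-spline channel
interpolation and the surface-Laplacian spatial filter, both of which only
need inter-electrode angles (cosine distances), so a unit sphere with an
idealized 10-10 layout is sufficient: the recording system reports labels
only, not digitized positions.

Coordinate convention: +x through the right preauricular point, +y through
the nasion, +z through the vertex (RAS-like).  Positions are dimensionless
unit vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Montage", "load_montage", "default_montage", "DEFAULT_CHANNELS"]

#: The 30 scalp channels of the default cap, in recording order.
DEFAULT_CHANNELS = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "C3", "Cz", "C4",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "O2",
)


@dataclass(frozen=True)
class Montage:
    """Ordered channel labels with unit-sphere positions."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must have shape (n_channels, 3)")
        if len(labels) != pos.shape[0]:
            raise ValueError(
                f"label count ({len(labels)}) != position count ({pos.shape[0]})"
            )
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate channel labels: {dupes}")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm electrode position")
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("positions must lie on the unit sphere (norm 1 ± 1e-9)")
        pos = pos.copy()
        pos.setflags(write=False)
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """Index of ``label``, raising a named KeyError when absent."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def cosine_distances(self) -> np.ndarray:
        """Pairwise cos(angle) between electrodes, clipped to [-1, 1]."""
        return np.clip(self.positions @ self.positions.T, -1.0, 1.0)

    def subset(self, labels: "list[str] | tuple[str, ...]") -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage(tuple(labels), self.positions[idx])


def load_montage(path: "str | Path") -> Montage:
    """Read an sfp-like whitespace-delimited ``label x y z`` file.

    Positions are renormalized onto the unit sphere; file order is preserved.
    Lines starting with ``#`` and blank lines are ignored.
    """
    labels: list[str] = []
    rows: list[list[float]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 'label x y z', got {raw!r}")
        label, *coords = parts
        if label in labels:
            raise ValueError(f"{path}:{lineno}: duplicate channel label {label!r}")
        xyz = [float(c) for c in coords]
        norm = float(np.linalg.norm(xyz))
        if norm == 0.0:
            raise ValueError(f"{path}:{lineno}: zero-norm position for {label!r}")
        labels.append(label)
        rows.append([c / norm for c in xyz])
    if not labels:
        raise ValueError(f"{path}: no electrode records found")
    return Montage(tuple(labels), np.array(rows))


# ---------------------------------------------------------------------------
# Idealized 10-10 construction
#
# Outer ring at 72 deg inclination from the vertex, 18 deg azimuthal steps;
# midline electrodes at 18 deg steps along the nasion-inion arc; all other
# electrodes placed on the great-circle arc running from the ring electrode
# of their row through the midline electrode of the same row, at even arc
# fractions (the standard 10-10 subdivision rule).
# ---------------------------------------------------------------------------

_RING_AZ = {  # azimuth (deg) from +x toward +y; inclination fixed at 72 deg
    "T8": 0, "FT8": 18, "F8": 36, "AF8": 54, "FP2": 72, "FPz": 90,
    "FP1": 108, "AF7": 126, "F7": 144, "FT7": 162, "T7": 180, "TP7": 198,
    "P7": 216, "PO7": 234, "O1": 252, "Oz": 270, "O2": 288, "PO8": 306,
    "P8": 324, "TP8": 342,
}

_MIDLINE = {  # anterior angle (deg) from vertex; negative = posterior
    "Fz": 36, "FCz": 18, "Cz": 0, "CPz": -18, "Pz": -36, "POz": -54,
}

# label -> (left ring anchor, midline anchor, arc fraction from ring anchor)
_ARC = {
    "F3": ("F7", "Fz", 0.5), "F4": ("F8", "Fz", 0.5),
    "FC5": ("FT7", "FCz", 0.25), "FC1": ("FT7", "FCz", 0.75),
    "FC2": ("FT8", "FCz", 0.75), "FC6": ("FT8", "FCz", 0.25),
    "C3": ("T7", "Cz", 0.5), "C4": ("T8", "Cz", 0.5),
    "CP5": ("TP7", "CPz", 0.25), "CP1": ("TP7", "CPz", 0.75),
    "CP2": ("TP8", "CPz", 0.75), "CP6": ("TP8", "CPz", 0.25),
    "P3": ("P7", "Pz", 0.5), "P4": ("P8", "Pz", 0.5),
    "PO3": ("PO7", "POz", 0.5), "PO4": ("PO8", "POz", 0.5),
}


def _ring(label: str) -> np.ndarray:
    incl = np.deg2rad(72.0)
    az = np.deg2rad(_RING_AZ[label])
    return np.array([np.sin(incl) * np.cos(az), np.sin(incl) * np.sin(az), np.cos(incl)])


def _midline(label: str) -> np.ndarray:
    b = np.deg2rad(_MIDLINE[label])
    return np.array([0.0, np.sin(b), np.cos(b)])


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    return (np.sin((1 - t) * omega) * a + np.sin(t * omega) * b) / np.sin(omega)


def _position(label: str) -> np.ndarray:
    if label in _RING_AZ:
        return _ring(label)
    if label in _MIDLINE:
        return _midline(label)
    ring, mid, frac = _ARC[label]
    return _slerp(_ring(ring), _midline(mid), frac)


def default_montage() -> Montage:
    """The packaged 30-channel cap with idealized 10-10 positions."""
    pos = np.array([_position(l) for l in DEFAULT_CHANNELS])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return Montage(DEFAULT_CHANNELS, pos)
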