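"""30-channel scalp montage with 2-D unit-disc positions.

Channel set matches a 32-channel 10-20 active cap with the two mastoid
channels consumed by referencing (mastoid reference is treated as already
applied). Positions are schematic top-view coordinates (x: left->right,
y: back->front) inside the unit disc; they drive the frontocentral component
topographies and the sensor adjacency used by cluster formation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "default_montage", "DEFAULT_ROI"]

DEFAULT_ROI = ("F3", "Fz", "F4", "FC1", "FC2")

_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.26, 0.85),
    "Fp2": (0.26, 0.85),
    "F7": (-0.73, 0.52),
    "F3": (-0.39, 0.45),
    "Fz": (0.00, 0.45),
    "F4": (0.39, 0.45),
    "F8": (0.73, 0.52),
    "FC5": (-0.60, 0.25),
    "FC1": (-0.22, 0.23),
    "FC2": (0.22, 0.23),
    "FC6": (0.60, 0.25),
    "T7": (-0.90, 0.00),
    "C3": (-0.45, 0.00),
    "Cz": (0.00, 0.00),
    "C4": (0.45, 0.00),
    "T8": (0.90, 0.00),
    "CP5": (-0.60, -0.25),
    "CP1": (-0.22, -0.23),
    "CP2": (0.22, -0.23),
    "CP6": (0.60, -0.25),
    "P7": (-0.73, -0.52),
    "P3": (-0.39, -0.45),
    "Pz": (0.00, -0.45),
    "P4": (0.39, -0.45),
    "P8": (0.73, -0.52),
    "PO9": (-0.55, -0.78),
    "O1": (-0.26, -0.85),
    "Oz": (0.00, -0.90),
    "O2": (0.26, -0.85),
    "PO10": (0.55, -0.78),
}


@dataclass(frozen=True)
class Montage:
    names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2)
    roi: tuple[str, ...] = DEFAULT_ROI

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        if self.positions.shape != (len(self.names), 2):
            raise ValueError("positions must be (n_channels, 2)")
        if np.any(np.linalg.norm(self.positions, axis=1) > 1.0 + 1e-9):
            raise ValueError("positions must lie within the unit disc")
        missing = set(self.roi) - set(self.names)
        if missing:
            raise ValueError(f"ROI channels not in montage: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def roi_indices(self) -> np.ndarray:
        return np.array([self.index(n) for n in self.roi])

    def subset(self, names: tuple[str, ...]) -> "Montage":
        idx = [self.index(n) for n in names]
        roi = tuple(n for n in self.roi if n in names)
        return Montage(tuple(names), self.positions[idx], roi or names[:1])


def default_montage() -> Montage:
    names = tuple(_POSITIONS)
    positions = np.array([_POSITIONS[n] for n in names])
    return Montage(names=names, positions=positions)
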