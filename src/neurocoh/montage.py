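"""Channel montages: labeled sensor layouts with schematic head-plane positions.

A montage names the channels, places them on a 2-D head plane (arbitrary
units, nose up), and tags each with a coarse scalp region so that
edge-level results can be summarised topographically (frontal, midline, ...).

The default fixture montage has 32 channels on a 10-20-like grid: large
enough to exercise region summaries (496 channel pairs) while staying
desk-scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

#: The recognised region tags.
REGIONS = (
    "frontal-left",
    "frontal-right",
    "midline",
    "central",
    "parietal",
    "occipital",
    "temporal-left",
    "temporal-right",
)


@dataclass(frozen=True)
class Montage:
    """A labeled EEG sensor layout.

    Parameters
    ----------
    labels
        Unique channel identifiers.
    positions
        ``(n_channels, 2)`` head-plane coordinates (arbitrary units, nose up).
    regions
        Per-channel scalp-region tag; one of :data:`REGIONS`.
    """

    labels: tuple[str, ...]
    positions: tuple[tuple[float, float], ...]
    regions: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ConfigurationError("montage needs at least 2 channels")
        if len(set(self.labels)) != len(self.labels):
            raise ConfigurationError("montage labels must be unique")
        if len(self.positions) != len(self.labels) or len(self.regions) != len(self.labels):
            raise ConfigurationError("positions/regions must match labels in length")
        bad = set(self.regions) - set(REGIONS)
        if bad:
            raise ConfigurationError(f"unknown region tags: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def region_of(self, label: str) -> str:
        return self.regions[self.index(label)]

    def position_array(self) -> np.ndarray:
        return np.asarray(self.positions, dtype=float)

    def subset(self, keep: list[str]) -> "Montage":
        """Montage restricted to ``keep`` (original order preserved)."""
        keep_set = set(keep)
        missing = keep_set - set(self.labels)
        if missing:
            raise ConfigurationError(f"labels not in montage: {sorted(missing)}")
        idx = [i for i, lab in enumerate(self.labels) if lab in keep_set]
        return Montage(
            labels=tuple(self.labels[i] for i in idx),
            positions=tuple(self.positions[i] for i in idx),
            regions=tuple(self.regions[i] for i in idx),
        )

    def drop(self, remove: list[str]) -> "Montage":
        """Montage with ``remove`` channels excluded."""
        return self.subset([lab for lab in self.labels if lab not in set(remove)])


# Schematic 10-20-like coordinates: x grows to the right ear, y to the nose.
_DEFAULT_32 = [
    # label, x, y, region
    ("Fp1", -0.31, 0.95, "frontal-left"),
    ("Fp2", 0.31, 0.95, "frontal-right"),
    ("AF3", -0.35, 0.80, "frontal-left"),
    ("AF4", 0.35, 0.80, "frontal-right"),
    ("F7", -0.80, 0.59, "frontal-left"),
    ("F3", -0.40, 0.55, "frontal-left"),
    ("Fz", 0.00, 0.55, "midline"),
    ("F4", 0.40, 0.55, "frontal-right"),
    ("F8", 0.80, 0.59, "frontal-right"),
    ("FC5", -0.65, 0.30, "frontal-left"),
    ("FC1", -0.25, 0.28, "central"),
    ("FC2", 0.25, 0.28, "central"),
    ("FC6", 0.65, 0.30, "frontal-right"),
    ("T7", -1.00, 0.00, "temporal-left"),
    ("C3", -0.50, 0.00, "central"),
    ("Cz", 0.00, 0.00, "midline"),
    ("C4", 0.50, 0.00, "central"),
    ("T8", 1.00, 0.00, "temporal-right"),
    ("CP5", -0.65, -0.30, "parietal"),
    ("CP1", -0.25, -0.28, "central"),
    ("CP2", 0.25, -0.28, "central"),
    ("CP6", 0.65, -0.30, "parietal"),
    ("P7", -0.80, -0.59, "parietal"),
    ("P3", -0.40, -0.55, "parietal"),
    ("Pz", 0.00, -0.55, "midline"),
    ("P4", 0.40, -0.55, "parietal"),
    ("P8", 0.80, -0.59, "parietal"),
    ("PO3", -0.35, -0.80, "occipital"),
    ("PO4", 0.35, -0.80, "occipital"),
    ("O1", -0.31, -0.95, "occipital"),
    ("Oz", 0.00, -0.98, "midline"),
    ("O2", 0.31, -0.95, "occipital"),
]


def default_montage() -> Montage:
    """The 32-channel fixture montage on a schematic 10-20-like grid."""
    return Montage(
        labels=tuple(r[0] for r in _DEFAULT_32),
        positions=tuple((r[1], r[2]) for r in _DEFAULT_32),
        regions=tuple(r[3] for r in _DEFAULT_32),
    )
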