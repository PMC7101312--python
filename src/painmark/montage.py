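"""64-channel extended 10-20 scalp montage.

Channel coordinates are an azimuthal-equidistant projection of the standard
10-05 electrode positions onto the unit disc (vertex at the origin, nasion
towards +y, right ear towards +x, radius normalised so the lowest electrode
ring sits on the unit circle).  The named groups collect the electrodes that
carry the evoked structure of interest: the central group over the vertex /
premotor cortex, the parietal group over the right parietal lobe, and the
"selected" group of discriminative electrodes over central and neighbouring
centro-parietal / fronto-temporal sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "default_montage", "CHANNELS_64"]

# (label, x, y): azimuthal projection of 10-05 positions, unit disc.
CHANNELS_64: tuple[tuple[str, float, float], ...] = (
    ("Fp1", -0.3096, +0.8827),
    ("Fpz", +0.0011, +0.9020),
    ("Fp2", +0.3105, +0.8825),
    ("AF7", -0.5990, +0.7490),
    ("AF3", -0.3014, +0.6872),
    ("AFz", +0.0019, +0.6566),
    ("AF4", +0.3125, +0.6801),
    ("AF8", +0.5992, +0.7488),
    ("F7", -0.8296, +0.5015),
    ("F5", -0.6201, +0.4620),
    ("F3", -0.4083, +0.4316),
    ("F1", -0.1995, +0.4131),
    ("Fz", +0.0022, +0.4094),
    ("F2", +0.2139, +0.4175),
    ("F4", +0.4202, +0.4402),
    ("F6", +0.6306, +0.4627),
    ("F8", +0.8288, +0.5041),
    ("FT7", -0.9531, +0.1666),
    ("FC5", -0.7014, +0.1693),
    ("FC3", -0.4556, +0.1720),
    ("FC1", -0.2217, +0.1693),
    ("FCz", +0.0023, +0.1699),
    ("FC2", +0.2286, +0.1737),
    ("FC4", +0.4640, +0.1767),
    ("FC6", +0.7049, +0.1767),
    ("FT8", +0.9509, +0.1792),
    ("T7", -0.9358, -0.1781),
    ("C5", -0.6860, -0.1176),
    ("C3", -0.4472, -0.0796),
    ("C1", -0.2164, -0.0598),
    ("Cz", +0.0023, -0.0517),
    ("C2", +0.2277, -0.0582),
    ("C4", +0.4585, -0.0745),
    ("C6", +0.6940, -0.1062),
    ("T8", +0.9385, -0.1657),
    ("TP7", -0.8195, -0.4446),
    ("CP5", -0.6105, -0.3571),
    ("CP3", -0.4004, -0.2961),
    ("CP1", -0.1957, -0.2607),
    ("CPz", +0.0021, -0.2519),
    ("CP2", +0.2115, -0.2594),
    ("CP4", +0.4145, -0.2902),
    ("CP6", +0.6224, -0.3444),
    ("TP8", +0.8232, -0.4383),
    ("P7", -0.6352, -0.6441),
    ("P5", -0.4872, -0.5525),
    ("P3", -0.3288, -0.4887),
    ("P1", -0.1610, -0.4530),
    ("Pz", +0.0018, -0.4403),
    ("P2", +0.1768, -0.4459),
    ("P4", +0.3409, -0.4812),
    ("P6", +0.4922, -0.5503),
    ("P8", +0.6398, -0.6399),
    ("PO7", -0.4298, -0.7643),
    ("PO5", -0.3424, -0.7025),
    ("PO3", -0.2389, -0.6598),
    ("POz", +0.0013, -0.6301),
    ("PO4", +0.2417, -0.6628),
    ("PO6", +0.3501, -0.6988),
    ("PO8", +0.4345, -0.7620),
    ("O1", -0.2146, -0.8203),
    ("Oz", +0.0008, -0.8190),
    ("O2", +0.2181, -0.8195),
    ("Iz", +0.0000, -1.0000),
)

DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "central": ("Cz", "C4", "C6"),
    "parietal": ("P2", "P4", "P6"),
    "selected": ("Cz", "C4", "C6", "CP6", "FT8"),
}


@dataclass(frozen=True)
class Montage:
    """Ordered electrode labels, 2-D scalp positions and named groups."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2), unit disc
    groups: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("montage labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 2):
            raise ValueError(
                f"positions shape {pos.shape} does not match {len(self.labels)} labels"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("montage positions must be finite")
        if np.any(np.hypot(pos[:, 0], pos[:, 1]) > 1.0 + 1e-9):
            raise ValueError("montage positions must lie within the unit disc")
        for name, members in self.groups.items():
            unknown = [m for m in members if m not in self.labels]
            if unknown:
                raise ValueError(f"group {name!r} has unknown channels {unknown}")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        """Position of *label* in channel order."""
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(lb) for lb in labels], dtype=int)

    def group_indices(self, name: str) -> np.ndarray:
        if name not in self.groups:
            raise KeyError(f"no group named {name!r}")
        return self.indices(self.groups[name])

    def position(self, label: str) -> np.ndarray:
        return self.positions[self.index(label)]

    def distances_from(self, label: str) -> np.ndarray:
        """Euclidean scalp distance of every channel from *label*."""
        ref = self.position(label)
        return np.hypot(*(self.positions - ref).T)


def default_montage() -> Montage:
    """The 64-channel extended 10-20 montage used throughout the package."""
    labels = tuple(row[0] for row in CHANNELS_64)
    positions = np.array([[row[1], row[2]] for row in CHANNELS_64])
    return Montage(labels=labels, positions=positions, groups=dict(DEFAULT_GROUPS))
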