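"""The fixed 16-electrode montage used throughout the package.

Sixteen scalp sites from the international 10-10 system, referenced to
linked earlobes. ``UNIT_SPHERE_POSITIONS`` holds standard 10-10 electrode
positions projected onto the unit sphere (head-centred coordinates, x right,
y anterior, z superior); they are used only for spherical spline
interpolation, where the absolute head radius is irrelevant.
"""

from __future__ import annotations

import numpy as np

#: Canonical channel order; every recording in this package uses it.
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F8", "F3", "F4", "Fz", "FCz",
    "C3", "C4", "Cz", "P7", "P8", "Pz", "O1", "O2",
)

N_CHANNELS = len(CHANNELS)

# Standard 10-10 positions, unit-sphere projection.
UNIT_SPHERE_POSITIONS: dict[str, tuple[float, float, float]] = {
    "Fp1": (-0.3300, 0.9407, -0.0784),
    "Fp2": (0.3309, 0.9404, -0.0784),
    "F7": (-0.8476, 0.5124, -0.1378),
    "F8": (0.8461, 0.5146, -0.1390),
    "F3": (-0.5952, 0.6292, 0.4998),
    "F4": (0.6066, 0.6355, 0.4776),
    "Fz": (0.0035, 0.6608, 0.7506),
    "FCz": (0.0041, 0.2951, 0.9554),
    "C3": (-0.7069, -0.1258, 0.6961),
    "C4": (0.7210, -0.1171, 0.6830),
    "Cz": (0.0040, -0.0911, 0.9958),
    "P7": (-0.7019, -0.7118, -0.0241),
    "P8": (0.7068, -0.7070, -0.0246),
    "Pz": (0.0028, -0.7006, 0.7136),
    "O1": (-0.2523, -0.9647, 0.0758),
    "O2": (0.2564, -0.9636, 0.0756),
}

_CANONICAL = {name.lower(): name for name in CHANNELS}


def canonicalize_channel(name: str) -> str | None:
    """Map a channel label to its canonical montage spelling.

    Case-insensitive; tolerates an ``"EEG "`` prefix and reference suffixes
    such as ``"-A1"`` that some EDF exporters append. Returns ``None`` when
    the label does not belong to the montage.
    """
    key = name.strip()
    if key.upper().startswith("EEG "):
        key = key[4:]
    key = key.split("-")[0].strip().lower()
    return _CANONICAL.get(key)


def positions_array(channels: tuple[str, ...] = CHANNELS) -> np.ndarray:
    """Unit-sphere coordinates for ``channels`` as an (n, 3) array."""
    return np.asarray([UNIT_SPHERE_POSITIONS[c] for c in channels], dtype=float)
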