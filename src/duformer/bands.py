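"""Canonical EEG frequency-band table.

Seven bands spanning 1-50 Hz. The model is trained once per band on a
band-filtered copy of the signal, so the table is shared by the synthetic
generator, the preprocessing pipeline, and the experiment runners.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges {self.low}-{self.high} Hz")


#: The seven canonical bands, in ascending frequency order.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("Delta", 1.0, 4.0),
    BandDefinition("Theta", 4.0, 8.0),
    BandDefinition("Alpha1", 8.0, 10.5),
    BandDefinition("Alpha2", 10.5, 13.0),
    BandDefinition("Beta1", 13.0, 20.0),
    BandDefinition("Beta2", 20.0, 30.0),
    BandDefinition("Gamma", 30.0, 50.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)

_BY_NAME = {b.name.lower(): b for b in CANONICAL_BANDS}


def get_band(name: str) -> BandDefinition:
    """Look up a canonical band by (case-insensitive) name."""
    try:
        return _BY_NAME[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown band {name!r}; valid bands: {', '.join(BAND_NAMES)}"
        ) from None
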