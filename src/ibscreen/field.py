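"""In-memory container for one acquisition site (a multi-channel field)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: canonical channel names, in acquisition order
CHANNEL_AGGREGATE = "aggregate"  # red channel: tagged aggregation-prone protein
CHANNEL_ORGANELLE = "organelle"  # green channel: organelle (mitochondria) marker

CHANNEL_ORDER = (CHANNEL_AGGREGATE, CHANNEL_ORGANELLE)


@dataclass
class ImageField:
    """One acquisition site: named 2-D intensity grids plus pixel metadata.

    Channels are stored in a dict keyed by channel name; all grids share one
    shape and intensities are finite and non-negative (16-bit camera counts,
    kept as integers until preprocessing converts to float).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float | None = None
    provenance: str = ""
    field_id: str = "field_0"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ImageField needs at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                raise ValueError(f"channel {name!r} has non-finite or negative pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel_names(self) -> list[str]:
        """Channel names in canonical order (aggregate first)."""
        ordered = [c for c in CHANNEL_ORDER if c in self.channels]
        ordered += [c for c in self.channels if c not in ordered]
        return ordered
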