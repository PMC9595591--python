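"""Shared containers and constants for per-well image analysis."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

#: Channel roles of a multichannel field, in page order of the TIFF files
#: this package reads and writes.  "marker" is the neurochemical-identity
#: channel (TH / tdTomato / ChAT...), "map2" the somatodendritic marker,
#: "syt1" the synaptotagmin-1 immunofluorescence, "nuclei" the DAPI-like
#: nuclear stain.
CHANNEL_ROLES: tuple[str, ...] = ("marker", "map2", "syt1", "nuclei")

#: Population classes used for vulnerable-vs-resilient comparisons.
VULNERABLE_POPULATIONS: frozenset[str] = frozenset({"SNc", "LC", "R", "DMV"})
RESILIENT_POPULATIONS: frozenset[str] = frozenset({"VTA", "XII", "STR"})


class ConfigError(ValueError):
    """Invalid run configuration or manifest, raised before any computation."""


@dataclass
class ImageField:
    """A multichannel 2D fluorescence field with physical pixel size.

    Pixel (row, col) has physical coordinates ``(col, row) * pixel_size_um``
    (0-based pixel centers).  Channels are float arrays of identical shape,
    keyed by role (see :data:`CHANNEL_ROLES`).
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    field_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(
                f"channel {role!r} not present; have {sorted(self.channels)}"
            ) from None

    def to_tiff(self, path: str | Path) -> None:
        """Write one TIFF page per channel (role order per CHANNEL_ROLES,
        then any extras), with roles and pixel size in the image description."""
        roles = [r for r in CHANNEL_ROLES if r in self.channels]
        roles += [r for r in self.channels if r not in roles]
        stack = np.stack([self.channels[r].astype(np.float32) for r in roles])
        desc = json.dumps(
            {"roles": roles, "pixel_size_um": self.pixel_size_um, "field_id": self.field_id}
        )
        tifffile.imwrite(path, stack, description=desc, photometric="minisblack")

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_size_um: float | None = None) -> "ImageField":
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            desc = tif.pages[0].description
        meta = {}
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            pass
        roles = meta.get("roles", list(CHANNEL_ROLES[: stack.shape[0]]))
        px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
        if px is None:
            raise ValueError(f"{path}: pixel size neither embedded nor supplied")
        if stack.ndim == 2:
            stack = stack[None]
        channels = {role: stack[i].astype(float) for i, role in enumerate(roles)}
        return cls(channels, float(px), field_id=str(meta.get("field_id", Path(path).stem)))
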