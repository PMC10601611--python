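"""Multi-channel image container and TIFF I/O.

A :class:`CellImage` is a named set of equal-shape 2-D rasters plus the pixel
geometry. Channel names are free-form but the pipeline recognises the roles
``thylakoid`` (pigment autofluorescence used for segmentation and radial
profiling; ``pc``/``chl`` are accepted aliases), ``fish`` and ``gfp``.
Images are held as float arrays; the acquisition bit depth only matters when
writing to disk, where values are clipped to the 12-bit range of the source
instrument.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

#: channel-role aliases accepted wherever a role is requested
ROLE_ALIASES = {
    "pc": "thylakoid",
    "chl": "thylakoid",
    "tm": "thylakoid",
}


@dataclass
class CellImage:
    """Named 2-D channels sharing one pixel grid.

    Parameters
    ----------
    channels
        Mapping of channel name to a 2-D float array. All channels must have
        the same shape.
    pixel_size_nm
        Physical pixel edge in nanometres (square pixels).
    bit_depth
        Acquisition bit depth; sets the clipping range on export.
    """

    channels: dict[str, np.ndarray]
    pixel_size_nm: float = 24.0
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if not self.channels:
            raise ValueError("CellImage needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have mismatched shapes: {shapes}")
        self.channels = {
            k: np.asarray(v, dtype=float) for k, v in self.channels.items()
        }

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    def channel(self, role: str) -> np.ndarray:
        """Return the raster for ``role``, resolving pigment aliases."""
        if role in self.channels:
            return self.channels[role]
        resolved = ROLE_ALIASES.get(role)
        if resolved is not None and resolved in self.channels:
            return self.channels[resolved]
        raise KeyError(
            f"channel {role!r} not present; available: {sorted(self.channels)}"
        )

    def has_channel(self, role: str) -> bool:
        try:
            self.channel(role)
            return True
        except KeyError:
            return False

    def copy(self) -> "CellImage":
        return CellImage(
            {k: v.copy() for k, v in self.channels.items()},
            pixel_size_nm=self.pixel_size_nm,
            bit_depth=self.bit_depth,
        )

    # ------------------------------------------------------------------ I/O

    def to_tiff(self, path) -> None:
        """Write a multi-page TIFF, one page per channel, 16-bit.

        Values are rounded and clipped to ``[0, 2**bit_depth - 1]`` so the
        file honours the source instrument's dynamic range even though the
        container is 16-bit. Channel names and pixel size go into the image
        description as JSON.
        """
        names = list(self.channels)
        lo, hi = 0, 2**self.bit_depth - 1
        stack = np.stack(
            [np.clip(np.rint(self.channels[n]), lo, hi).astype(np.uint16) for n in names]
        )
        meta = {
            "channels": names,
            "pixel_size_nm": self.pixel_size_nm,
            "bit_depth": self.bit_depth,
        }
        tifffile.imwrite(path, stack, description=json.dumps(meta))

    @classmethod
    def from_tiff(cls, path, channel_names: list[str] | None = None) -> "CellImage":
        """Read a multi-page TIFF written by :meth:`to_tiff` or elsewhere.

        If the file carries no JSON channel metadata, ``channel_names`` must
        be given (one per page, in page order).
        """
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            desc = tif.pages[0].description or ""
        if stack.ndim == 2:
            stack = stack[None]
        meta: dict = {}
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            pass
        names = channel_names or meta.get("channels")
        if names is None or len(names) != len(stack):
            raise ValueError(
                "channel names unavailable or wrong length; pass channel_names "
                f"matching the {len(stack)} pages"
            )
        return cls(
            {n: stack[i].astype(float) for i, n in enumerate(names)},
            pixel_size_nm=float(meta.get("pixel_size_nm", 24.0)),
            bit_depth=int(meta.get("bit_depth", 12)),
        )
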