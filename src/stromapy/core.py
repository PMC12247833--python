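"""Core containers shared across the pipeline.

Coordinate conventions
----------------------
Images are 2D arrays indexed ``[row, col]`` (0-based). Physical coordinates
are in micrometres with ``x = col * pixel_size_um`` and
``y = row * pixel_size_um`` (y increases downward, matching image display).
Pixel ``(r, c)`` has its *center* at ``(c * px, r * px)`` µm; the containing
pixel of a continuous point is the one whose center is nearest
(``round(x / px)``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

__all__ = ["ChannelStack"]


@dataclass
class ChannelStack:
    """Named, co-registered 2D intensity channels plus the physical pixel size.

    Parameters
    ----------
    channels
        Mapping from channel name (e.g. ``"DAPI"``, ``"FN"``) to a 2D float
        array of raw grey levels. All channels must share one shape.
    pixel_size_um
        Physical edge length of a pixel in micrometres.
    image_id
        Identifier used in cell tables and manifests.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    image_id: str = "image"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.channels:
            raise ValueError("ChannelStack needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        shape = shapes.pop()
        if len(shape) != 2:
            raise ValueError("channels must be 2D images")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def names(self) -> list[str]:
        return list(self.channels)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not in stack (have {sorted(self.channels)})"
            ) from None

    # ------------------------------------------------------------------ I/O
    def write_tiff(self, path: str | Path) -> None:
        """Write a multi-page TIFF, one page per channel, plus a JSON sidecar
        recording channel names, pixel size and image id."""
        path = Path(path)
        data = np.stack([self.channels[n] for n in self.names]).astype(np.float32)
        tifffile.imwrite(path, data, photometric="minisblack")
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {
                    "channels": self.names,
                    "pixel_size_um": self.pixel_size_um,
                    "image_id": self.image_id,
                }
            )
        )

    @classmethod
    def read_tiff(
        cls,
        path: str | Path,
        channel_names: list[str] | None = None,
        pixel_size_um: float | None = None,
        image_id: str | None = None,
    ) -> "ChannelStack":
        """Read a multi-page TIFF; metadata from the sidecar unless given."""
        path = Path(path)
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        meta: Mapping = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        names = channel_names or meta.get("channels")
        if names is None:
            names = [f"C{i}" for i in range(data.shape[0])]
        if len(names) != data.shape[0]:
            raise ValueError(
                f"{len(names)} channel names for {data.shape[0]} TIFF pages"
            )
        px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
        if px is None:
            raise ValueError("pixel_size_um not given and absent from sidecar")
        return cls(
            channels=dict(zip(names, data)),
            pixel_size_um=float(px),
            image_id=image_id or meta.get("image_id", path.stem),
        )
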