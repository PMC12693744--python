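"""PNG reading/writing via Pillow (8-bit RGB or grayscale)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["read_image", "write_image"]


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG as uint8; RGB images come back H x W x 3, grayscale H x W."""
    with Image.open(path) as im:
        if im.mode in ("L", "I;16"):
            return np.asarray(im.convert("L"), dtype=np.uint8)
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def write_image(path: str | Path, arr: np.ndarray) -> None:
    a = np.asarray(arr)
    if a.dtype == bool:
        a = a.astype(np.uint8) * 255
    Image.fromarray(a.astype(np.uint8)).save(str(path))
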