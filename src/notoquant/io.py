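"""Readers and writers: images, tables, masks, JSON — with provenance.

Every tabular output starts with a single ``#`` comment line carrying the
package version and the configuration hash of the run that produced it;
readers here skip such lines.  The CSV dialect is fixed (comma, UTF-8, header
row, '.' decimal) so reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


def provenance_line(version: str, config_hash: str) -> str:
    return f"# notoquant={version} config_sha256={config_hash}"


def write_gray_image(path: str | Path, image: np.ndarray, description: str = "") -> None:
    """Single-channel image to TIFF (any suffix .tif/.tiff) or PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image, description=description)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, image)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")


def read_gray_image(path: str | Path) -> np.ndarray:
    """Read a single-channel image; rejects colour data."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a single-channel 2D image (shape {arr.shape})")
    return arr


def write_table(
    path: str | Path, df: pd.DataFrame, version: str, config_hash: str
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(provenance_line(version, config_hash) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_json(path: str | Path, obj: dict, version: str, config_hash: str) -> None:
    payload = {"provenance": {"notoquant": version, "config_sha256": config_hash}, **obj}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def mask_to_png(path: str | Path, pixels: np.ndarray) -> None:
    """Binary mask as an 8-bit PNG (255 = notochord)."""
    iio.imwrite(Path(path), (pixels.astype(np.uint8) * 255))


def mask_to_csv(path: str | Path, pixels: np.ndarray) -> None:
    """Mask as a CSV coordinate list (x, y)."""
    ys, xs = np.nonzero(pixels)
    pd.DataFrame({"x": xs, "y": ys}).to_csv(Path(path), index=False, lineterminator="\n")


def profile_to_csv(path: str | Path, profile) -> None:
    pd.DataFrame(
        {"arc_position": profile.arc_positions, "intensity": profile.intensities}
    ).to_csv(Path(path), index=False, lineterminator="\n")
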