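"""Quadrat-photo percent-cover estimation.

Percent vegetation cover is estimated from a downward photograph of the
quadrat (pre-cropped to the quadrat frame) in three steps:

1. boost the image's saturation by a large factor (default 30) to wash out
   shading differences while preserving hue, and therefore the rank order
   of the R, G, B channels of every non-gray pixel;
2. classify a pixel as vegetation when its green digital number strictly
   exceeds both the red and the blue digital numbers (moss counts as green,
   rocks and logs as non-green simply because they are not green-dominant);
3. report the fraction of qualifying pixels over the whole image.

The classifier is deliberately primitive — no segmentation, no vegetation
indices — which is what makes it auditable: it is exactly reproducible
from the pixel values alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from skimage.color import hsv2rgb, rgb2hsv

from .synthetic import QuadratImage

__all__ = [
    "CoverRecord",
    "boost_saturation",
    "classify_green",
    "estimate_cover",
    "batch_estimate",
    "read_image",
]

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class CoverRecord:
    """Green-cover estimate for one quadrat image.

    ``green_fraction`` is exactly ``n_green / n_total``.
    """

    quadrat_id: str
    green_fraction: float
    n_green: int
    n_total: int


def _as_pixels(img: QuadratImage | np.ndarray) -> np.ndarray:
    px = img.pixels if isinstance(img, QuadratImage) else np.asarray(img)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("expected an H x W x 3 RGB array")
    if px.dtype != np.uint8:
        raise ValueError("expected 8-bit (uint8) digital numbers")
    return px


def boost_saturation(
    img: QuadratImage | np.ndarray, factor: float = 30.0
) -> np.ndarray:
    """Scale HSV saturation by ``factor`` (clipped at 1), preserving hue.

    Gray pixels (S = 0) are untouched; for any pixel with distinct channel
    values the channel rank order is unchanged because hue and value are
    preserved and only the spread between max and min channels grows.
    """
    if factor <= 0:
        raise ValueError("saturation factor must be positive")
    px = _as_pixels(img)
    hsv = rgb2hsv(px)  # float64 in [0, 1]
    hsv[..., 1] = np.minimum(1.0, factor * hsv[..., 1])
    out = hsv2rgb(hsv) * 255.0
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def classify_green(img: QuadratImage | np.ndarray) -> np.ndarray:
    """Binary mask: 1 where G strictly exceeds both R and B, else 0.

    Ties (including gray pixels) classify as non-green.
    """
    px = _as_pixels(img)
    r = px[..., 0].astype(np.int16)
    g = px[..., 1].astype(np.int16)
    b = px[..., 2].astype(np.int16)
    return ((g > r) & (g > b)).astype(np.uint8)


def estimate_cover(
    img: QuadratImage | np.ndarray,
    factor: float = 30.0,
    boost: bool = True,
    quadrat_id: str = "",
) -> CoverRecord:
    """Estimate green cover as the fraction of green-dominant pixels.

    ``boost=False`` skips the saturation standardization; on images whose
    pixels all have pairwise-distinct channel values the two paths agree
    exactly, since the boost preserves channel rank order.
    """
    px = _as_pixels(img)
    if px.shape[0] * px.shape[1] == 0:
        raise ValueError("cannot estimate cover of a zero-pixel image")
    if not quadrat_id and isinstance(img, QuadratImage):
        quadrat_id = img.quadrat_id
    work = boost_saturation(px, factor) if boost else px
    mask = classify_green(work)
    n_green = int(mask.sum())
    n_total = int(mask.size)
    return CoverRecord(quadrat_id, n_green / n_total, n_green, n_total)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG as 8-bit RGB; alpha channels are dropped."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def batch_estimate(
    image_dir: str | Path,
    output_csv: str | Path | None = None,
    factor: float = 30.0,
    boost: bool = True,
    save_masks: str | Path | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Estimate cover for every readable PNG/JPEG in a directory.

    Returns the cover table (ordered by filename) and the list of files
    that could not be read; unreadable files are logged and skipped.
    Optionally writes the table as CSV and the binary masks as 1-bit PNGs.
    """
    image_dir = Path(image_dir)
    paths = sorted(
        p for p in image_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
    )
    if not paths:
        raise FileNotFoundError(f"no PNG/JPEG images found in {image_dir}")
    if save_masks is not None:
        Path(save_masks).mkdir(parents=True, exist_ok=True)
    rows, skipped = [], []
    for path in paths:
        try:
            px = read_image(path)
        except (OSError, UnidentifiedImageError) as exc:
            logger.warning("skipping unreadable image %s: %s", path.name, exc)
            skipped.append(path.name)
            continue
        rec = estimate_cover(px, factor=factor, boost=boost, quadrat_id=path.stem)
        rows.append(
            {
                "quadrat_id": rec.quadrat_id,
                "green_fraction": rec.green_fraction,
                "n_green": rec.n_green,
                "n_total": rec.n_total,
            }
        )
        if save_masks is not None:
            work = boost_saturation(px, factor) if boost else px
            mask = classify_green(work)
            Image.fromarray(mask * 255).convert("1").save(
                Path(save_masks) / f"{path.stem}_mask.png"
            )
    if skipped:
        logger.warning("skipped %d unreadable image(s)", len(skipped))
    table = pd.DataFrame(
        rows, columns=["quadrat_id", "green_fraction", "n_green", "n_total"]
    )
    if output_csv is not None:
        table.to_csv(output_csv, index=False)
    return table, skipped
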