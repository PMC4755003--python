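"""Multi-resolution image pyramids and tissue detection.

A scanned slide (or tile) is represented as a four-level pyramid L0..L3,
L0 at full resolution and each subsequent level block-mean downsampled by a
fixed integer factor.  Tissue-bearing regions are found on the coarse L3
raster by tiling it into grid blocks and classifying pixels as background
(bright and unsaturated — white space) or tissue; tissue blocks are then
mapped back to L0 rectangles for single-cell analysis.

Coordinates are 0-based with x = column (rightward) and y = row (downward);
all rectangles are half-open ``(x0, y0, x1, y1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from skimage.color import rgb2hsv

from .config import PipelineConfig

N_LEVELS = 4

#: Rec. 709 luma weights used for the luminance channel.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class PyramidImage:
    """Four-level RGB pyramid with physical scale.

    ``levels[0]`` is L0 (full resolution); each level is uint8 RGB of shape
    ``(h, w, 3)`` with ``dims(L_{k+1}) == ceil(dims(L_k) / downsample_factor)``.
    ``mpp_L0`` is microns per pixel at L0 (isotropic).
    """

    levels: tuple[np.ndarray, ...]
    downsample_factor: int
    mpp_L0: float

    def __post_init__(self):
        if len(self.levels) != N_LEVELS:
            raise ValueError(f"pyramid needs exactly {N_LEVELS} levels")
        if self.mpp_L0 <= 0:
            raise ValueError("mpp_L0 must be positive")
        f = self.downsample_factor
        for k in range(N_LEVELS - 1):
            hi, lo = self.levels[k], self.levels[k + 1]
            want = (-(-hi.shape[0] // f), -(-hi.shape[1] // f))
            if lo.shape[:2] != want:
                raise ValueError(
                    f"level {k + 1} has shape {lo.shape[:2]}, expected {want} "
                    f"for factor {f}"
                )

    @property
    def level0(self) -> np.ndarray:
        return self.levels[0]

    @property
    def level3(self) -> np.ndarray:
        return self.levels[3]

    @property
    def l3_to_l0_scale(self) -> int:
        """Linear scale from L3 pixel coordinates to L0."""
        return self.downsample_factor ** (N_LEVELS - 1)


@dataclass(frozen=True)
class GridBlock:
    """One tile of the L3 grid with its tissue classification."""

    row: int
    col: int
    rect_L3: tuple[int, int, int, int]  # half-open (x0, y0, x1, y1)
    tissue_fraction: float
    is_tissue: bool


def _block_mean(img: np.ndarray, factor: int) -> np.ndarray:
    """Mean-pool an (h, w, 3) raster by ``factor``; partial edge blocks use
    their actual area, so the global mean is preserved exactly."""
    h, w = img.shape[:2]
    rows = np.arange(0, h, factor)
    cols = np.arange(0, w, factor)
    acc = np.add.reduceat(np.add.reduceat(img.astype(np.float64), rows, axis=0), cols, axis=1)
    rh = np.diff(np.append(rows, h))
    cw = np.diff(np.append(cols, w))
    area = rh[:, None] * cw[None, :]
    return acc / area[:, :, None]


def _as_rgb(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"expected an RGB raster, got shape {arr.shape}")
    return np.ascontiguousarray(arr[:, :, :3]).astype(np.uint8)


def _read_pages(path: Path) -> list[np.ndarray]:
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            return [page.asarray() for page in tf.pages]
    return [np.asarray(Image.open(path).convert("RGB"))]


def load_pyramid(
    image: np.ndarray | str | Path,
    mpp_L0: float = 0.5,
    downsample_factor: int = 4,
) -> PyramidImage:
    """Build or validate a four-level pyramid.

    ``image`` is either an in-memory RGB raster, a single-page image file
    (PNG or TIFF) — in which case L1..L3 are computed by block-mean
    downsampling — or a multi-page TIFF whose four pages are taken as L0..L3
    and validated against ``downsample_factor``.
    """
    if downsample_factor < 2:
        raise ValueError("downsample_factor must be >= 2")

    if isinstance(image, (str, Path)):
        pages = _read_pages(Path(image))
    else:
        pages = [image]

    if len(pages) not in (1, N_LEVELS):
        raise ValueError(f"expected 1 or {N_LEVELS} pages, got {len(pages)}")

    rgb = [_as_rgb(p) for p in pages]
    if any(lvl.shape[0] == 0 or lvl.shape[1] == 0 for lvl in rgb):
        raise ValueError("zero-sized image")

    if len(rgb) == 1:
        levels = [rgb[0]]
        for _ in range(N_LEVELS - 1):
            levels.append(np.clip(np.rint(_block_mean(levels[-1], downsample_factor)), 0, 255).astype(np.uint8))
    else:
        levels = rgb  # validated by PyramidImage.__post_init__

    return PyramidImage(tuple(levels), downsample_factor, float(mpp_L0))


def background_mask(rgb: np.ndarray, t_lum: float = 220.0, t_sat: float = 0.08) -> np.ndarray:
    """White-space mask: a pixel is background iff it is both bright
    (luminance >= ``t_lum`` on the 0-255 scale) and nearly grey
    (HSV saturation <= ``t_sat``)."""
    arr = np.asarray(rgb, dtype=np.float64)
    lum = arr[:, :, :3] @ _LUMA
    sat = rgb2hsv(np.asarray(rgb)[:, :, :3])[:, :, 1]
    return (lum >= t_lum) & (sat <= t_sat)


def detect_tissue_blocks(
    p: PyramidImage,
    block_size_L3: int | None = None,
    t_lum: float | None = None,
    t_sat: float | None = None,
    min_tissue_fraction: float | None = None,
    config: PipelineConfig | None = None,
) -> list[GridBlock]:
    """Tile L3 into grid blocks and flag the tissue-bearing ones.

    The last row/column of blocks may be partial; partial blocks are kept
    and their tissue fraction uses the actual block area.  Every block is
    returned (tissue or not), so the caller can report full coverage.
    """
    cfg = config or PipelineConfig()
    bs = block_size_L3 if block_size_L3 is not None else cfg.block_size
    if bs < 4:
        raise ValueError("block_size_L3 must be >= 4")
    t_lum = cfg.t_lum if t_lum is None else t_lum
    t_sat = cfg.t_sat if t_sat is None else t_sat
    min_frac = cfg.min_tissue_fraction if min_tissue_fraction is None else min_tissue_fraction

    l3 = p.level3
    h, w = l3.shape[:2]
    tissue = ~background_mask(l3, t_lum=t_lum, t_sat=t_sat)

    blocks: list[GridBlock] = []
    for row, y0 in enumerate(range(0, h, bs)):
        y1 = min(y0 + bs, h)
        for col, x0 in enumerate(range(0, w, bs)):
            x1 = min(x0 + bs, w)
            frac = float(tissue[y0:y1, x0:x1].mean())
            blocks.append(GridBlock(row, col, (x0, y0, x1, y1), frac, frac >= min_frac))
    return blocks


def map_block_to_level0(p: PyramidImage, b: GridBlock) -> tuple[int, int, int, int]:
    """Scale a block's L3 rectangle up to L0, clipped to the L0 bounds.

    Half-open rectangles keep disjoint blocks disjoint after scaling.
    """
    x0, y0, x1, y1 = b.rect_L3
    h3, w3 = p.level3.shape[:2]
    if not (0 <= x0 < x1 <= w3 and 0 <= y0 < y1 <= h3):
        raise ValueError(f"block rect {b.rect_L3} outside L3 bounds {(w3, h3)}")
    s = p.l3_to_l0_scale
    h0, w0 = p.level0.shape[:2]
    return (x0 * s, y0 * s, min(x1 * s, w0), min(y1 * s, h0))


def blocks_to_frame(slide_id: str, blocks: list[GridBlock]):
    """Block report as a DataFrame matching the CSV contract."""
    import pandas as pd

    return pd.DataFrame(
        {
            "slide_id": slide_id,
            "row": [b.row for b in blocks],
            "col": [b.col for b in blocks],
            "x0_L3": [b.rect_L3[0] for b in blocks],
            "y0_L3": [b.rect_L3[1] for b in blocks],
            "x1_L3": [b.rect_L3[2] for b in blocks],
            "y1_L3": [b.rect_L3[3] for b in blocks],
            "tissue_fraction": [b.tissue_fraction for b in blocks],
            "is_tissue": [b.is_tissue for b in blocks],
        }
    )
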