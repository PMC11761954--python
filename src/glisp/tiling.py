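"""Slide tiling: whitespace-filtered 256x256 patch extraction and MIL bag sampling.

A slide (an RGB image array, or a PNG/JPEG/TIFF file) is cut into a
non-overlapping grid of ``patch_size`` tiles, anchored at the origin of the
region-of-interest bounding box. Tiles are half-open ``[x, x+256) x [y, y+256)``
rectangles in 0-based, top-left-origin, level-0 pixel coordinates — the
repo-wide convention. Tiles with more than ``max_whitespace`` whitespace
(every colour channel at or above ``white_threshold``) are discarded; when
more than ``max_patches_per_slide`` survive, a seeded uniform subsample is
kept, which makes the "approximately 50 patches per file" protocol exactly
reproducible.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PATCH_SIZE = 256

MANIFEST_COLUMNS = ["patch_path", "slide_id", "case_id", "x", "y", "mpp", "whitespace_fraction"]


@dataclass
class PatchImage:
    """One 256x256 RGB tile with its slide/case provenance."""

    pixels: np.ndarray  # (256, 256, 3) uint8
    slide_id: str
    case_id: str
    x: int  # level-0 pixel column of the top-left corner
    y: int  # level-0 pixel row of the top-left corner
    mpp: float = 0.5

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        _check_patch_array(self.pixels)


def _check_patch_array(a: np.ndarray, size: int = PATCH_SIZE) -> None:
    if a.ndim != 3 or a.shape != (size, size, 3):
        raise ValueError(f"patch must be ({size}, {size}, 3) RGB, got shape {a.shape}")
    if a.dtype != np.uint8:
        if np.issubdtype(a.dtype, np.integer) and a.min() >= 0 and a.max() <= 255:
            return
        raise ValueError(f"patch must be 8-bit RGB, got dtype {a.dtype}")


@dataclass
class RoiMask:
    """Region-of-interest: a shapely (multi)polygon or a boolean raster, level-0 coords."""

    geometry: object  # shapely geometry or bool ndarray
    slide_id: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.geometry, np.ndarray):
            if self.geometry.dtype != bool:
                self.geometry = self.geometry.astype(bool)
            if not self.geometry.any():
                raise ValueError("ROI raster is empty")
        else:
            if self.geometry.is_empty:
                raise ValueError("ROI polygon is empty")
            minx, miny = self.geometry.bounds[:2]
            if minx < 0 or miny < 0:
                raise ValueError("ROI coordinates must be non-negative")

    @classmethod
    def from_geojson(cls, path: str | Path, slide_id: str = "") -> "RoiMask":
        from shapely.geometry import shape
        from shapely.ops import unary_union

        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") == "FeatureCollection":
            geoms = [shape(f["geometry"]) for f in gj["features"]]
        elif gj.get("type") == "Feature":
            geoms = [shape(gj["geometry"])]
        else:
            geoms = [shape(gj)]
        return cls(unary_union(geoms), slide_id=slide_id)

    @classmethod
    def from_png(cls, path: str | Path, slide_id: str = "") -> "RoiMask":
        from PIL import Image

        mask = np.asarray(Image.open(path).convert("L")) > 127
        return cls(mask, slide_id=slide_id)

    def bounds(self) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) bounding box, half-open, level-0 pixels."""
        if isinstance(self.geometry, np.ndarray):
            rows = np.flatnonzero(self.geometry.any(axis=1))
            cols = np.flatnonzero(self.geometry.any(axis=0))
            return int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1
        minx, miny, maxx, maxy = self.geometry.bounds
        return int(np.floor(minx)), int(np.floor(miny)), int(np.ceil(maxx)), int(np.ceil(maxy))

    def contains_tile(self, x: int, y: int, size: int) -> bool:
        """True when the whole half-open tile lies inside the ROI."""
        if isinstance(self.geometry, np.ndarray):
            h, w = self.geometry.shape
            if x < 0 or y < 0 or x + size > w or y + size > h:
                return False
            return bool(self.geometry[y : y + size, x : x + size].all())
        from shapely.geometry import box

        return bool(self.geometry.contains(box(x, y, x + size, y + size)))


@dataclass
class SlideBag:
    """A fixed-size multiset of patch indices (or encodings) from one slide."""

    slide_id: str
    case_id: str
    members: np.ndarray  # indices into the slide's retained-patch list
    sampling_seed: int

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class TilingConfig:
    patch_size: int = PATCH_SIZE
    white_threshold: int = 220
    max_whitespace: float = 0.5
    max_patches_per_slide: int = 50
    target_mpp: float = 0.5
    seed: int = 0
    extra: dict = field(default_factory=dict)


def whitespace_fraction(patch: PatchImage | np.ndarray, white_threshold: int = 220) -> float:
    """Fraction of pixels whose R, G and B are all >= ``white_threshold``."""
    pixels = patch.pixels if isinstance(patch, PatchImage) else np.asarray(patch)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an RGB array (H, W, 3), got shape {pixels.shape}")
    white = (pixels >= white_threshold).all(axis=2)
    return float(white.mean())


def load_slide(source: str | Path | np.ndarray) -> np.ndarray:
    """Read a slide image as an (H, W, 3) uint8 RGB array."""
    if isinstance(source, np.ndarray):
        img = source
    else:
        path = Path(source)
        if not path.exists():
            raise IOError(f"slide not readable: {path}")
        if path.suffix.lower() in {".tif", ".tiff", ".svs"}:
            import tifffile

            img = tifffile.imread(path)
        else:
            from PIL import Image

            img = np.asarray(Image.open(path).convert("RGB"))
    img = np.asarray(img)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    if img.dtype != np.uint8:
        img = np.clip(img, 0, 255).astype(np.uint8)
    return img


def _resample_to_mpp(img: np.ndarray, native_mpp: float, target_mpp: float) -> tuple[np.ndarray, float]:
    """Bilinear rescale so one pixel covers ``target_mpp`` microns; returns scale."""
    if abs(native_mpp - target_mpp) < 1e-9:
        return img, 1.0
    from skimage.transform import resize

    scale = native_mpp / target_mpp
    out_shape = (max(1, round(img.shape[0] * scale)), max(1, round(img.shape[1] * scale)))
    resized = resize(img, out_shape, order=1, preserve_range=True, anti_aliasing=scale < 1)
    return np.clip(resized, 0, 255).astype(np.uint8), scale


def extract_patches(
    slide: str | Path | np.ndarray,
    roi: RoiMask | None = None,
    config: TilingConfig | None = None,
    slide_id: str = "slide",
    case_id: str = "case",
    native_mpp: float | None = None,
) -> list[PatchImage]:
    """Grid-tile a slide into filtered patches.

    Tiles are anchored at the ROI bounding-box origin (slide origin when no
    ROI), stride ``patch_size`` (no overlap), clipped to slide bounds. Tiles
    failing the whitespace filter, or falling outside a supplied ROI, are
    dropped. A seeded uniform subsample enforces ``max_patches_per_slide``.
    """
    cfg = config or TilingConfig()
    img = load_slide(slide)
    scale = 1.0
    if native_mpp is not None:
        img, scale = _resample_to_mpp(img, native_mpp, cfg.target_mpp)
    h, w = img.shape[:2]
    size = cfg.patch_size

    if roi is not None:
        x0, y0, x1, y1 = roi.bounds()
        if x0 >= w or y0 >= h:
            raise ValueError(f"ROI bounds {roi.bounds()} outside slide {w}x{h}")
        x1, y1 = min(x1, w), min(y1, h)
    else:
        x0, y0, x1, y1 = 0, 0, w, h

    kept: list[PatchImage] = []
    for y in range(y0, y1 - size + 1, size):
        for x in range(x0, x1 - size + 1, size):
            if roi is not None and not roi.contains_tile(x, y, size):
                continue
            tile = img[y : y + size, x : x + size]
            if whitespace_fraction(tile, cfg.white_threshold) > cfg.max_whitespace:
                continue
            lx = int(round(x / scale))
            ly = int(round(y / scale))
            kept.append(PatchImage(tile, slide_id=slide_id, case_id=case_id,
                                   x=lx, y=ly, mpp=cfg.target_mpp))

    if not kept:
        log.warning("slide %s: zero tiles survived the whitespace filter", slide_id)
        return kept

    if len(kept) > cfg.max_patches_per_slide:
        rng = np.random.default_rng(cfg.seed)
        idx = np.sort(rng.choice(len(kept), size=cfg.max_patches_per_slide, replace=False))
        kept = [kept[i] for i in idx]
    return kept


def sample_bag(patches: list, k: int = 32, seed: int = 0,
               slide_id: str | None = None, case_id: str | None = None) -> SlideBag:
    """Draw a bag of ``k`` patch indices, without replacement when possible.

    Slides with fewer than ``k`` retained patches are completed by sampling
    with replacement so the bag size stays fixed for the MIL model; such
    bags are logged as degenerate.
    """
    n = len(patches)
    if n == 0:
        raise ValueError("cannot sample a bag from an empty patch list")
    if k < 1:
        raise ValueError("bag size k must be >= 1")
    rng = np.random.default_rng(seed)
    if n >= k:
        members = rng.choice(n, size=k, replace=False)
    else:
        log.debug("degenerate bag: %d patches < bag size %d, sampling with replacement", n, k)
        members = np.concatenate([np.arange(n), rng.choice(n, size=k - n, replace=True)])
    first = patches[0]
    return SlideBag(
        slide_id=slide_id or getattr(first, "slide_id", ""),
        case_id=case_id or getattr(first, "case_id", ""),
        members=np.asarray(members, dtype=np.intp),
        sampling_seed=seed,
    )


def patches_to_manifest(patches: list[PatchImage], white_threshold: int = 220,
                        patch_paths: list[str] | None = None) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(patches):
        rows.append({
            "patch_path": patch_paths[i] if patch_paths else f"{p.slide_id}_{p.x}_{p.y}.png",
            "slide_id": p.slide_id,
            "case_id": p.case_id,
            "x": p.x,
            "y": p.y,
            "mpp": p.mpp,
            "whitespace_fraction": whitespace_fraction(p, white_threshold),
        })
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def write_patches(patches: list[PatchImage], out_dir: str | Path,
                  white_threshold: int = 220) -> pd.DataFrame:
    """Save patch PNGs plus the manifest CSV; returns the manifest."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in patches:
        name = f"{p.slide_id}_x{p.x}_y{p.y}.png"
        Image.fromarray(p.pixels).save(out / name)
        paths.append(name)
    manifest = patches_to_manifest(patches, white_threshold, patch_paths=paths)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_patch_images(manifest: pd.DataFrame, root: str | Path) -> np.ndarray:
    """Load the PNGs referenced by a manifest into an (N, 256, 256, 3) array."""
    from PIL import Image

    root = Path(root)
    arrs = [np.asarray(Image.open(root / p).convert("RGB")) for p in manifest["patch_path"]]
    return np.stack(arrs).astype(np.uint8)
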