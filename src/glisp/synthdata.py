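"""Seeded synthetic cohorts: tissue-like patches with a plantable MIL signal.

The generator emulates the data structure the framework trains on — cases,
each with one or more slides, each slide with ~40-50 retained 256x256 RGB
patches, and a case-level binary status per genetic task — without any
download. Patches are Gaussian-random-field "eosin" backgrounds with
"hematoxylin" nuclei-like blobs placed on a jittered grid (blue-noise-like
spacing). A positive case's *witness* patches carry the class signal as a
shift in blob density and blob hue proportional to ``effect_size``; the
witness rate controls what fraction of a positive case's patches are
informative, which is exactly the multiple-instance structure that motivates
attention pooling.

The defaults are the study conditions used by the end-to-end experiments:
200 cases, 1 slide/case, 40 patches/slide, prevalence 0.5, effect size 2.0,
witness rate 1.0. Every level (cohort, case, patch) is deterministic under
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .labels import GeneLabelTable
from .tiling import MANIFEST_COLUMNS, PATCH_SIZE, whitespace_fraction

__all__ = [
    "BackgroundParams",
    "SynthConfig",
    "SynthCohort",
    "generate_patch",
    "generate_cohort",
    "make_toy_fixtures",
]


@dataclass(frozen=True)
class BackgroundParams:
    """Texture model constants (8-bit RGB space).

    The eosin background stays strictly below the default whitespace
    threshold (220 across all channels) by construction, so every generated
    patch passes the tiling filter.
    """

    base_rgb: tuple[int, int, int] = (214, 168, 194)  # eosin-like pink
    nucleus_rgb: tuple[int, int, int] = (104, 78, 152)  # hematoxylin-like purple
    coarse_amp: float = 0.14
    fine_amp: float = 0.07
    pixel_noise_sd: float = 2.5
    cell_px: int = 24  # jittered-grid cell for blob placement
    occupancy: float = 0.45  # baseline fraction of occupied grid cells
    radius_range: tuple[float, float] = (3.2, 6.0)
    # per-unit-effect signal: relative blob-density increase and RGB hue shift
    density_gain: float = 0.35
    hue_shift: tuple[float, float, float] = (-9.0, -4.0, 10.0)


@dataclass
class SynthConfig:
    n_cases: int = 200
    slides_per_case: int = 1
    patches_per_slide: int = 40
    prevalence: float = 0.5
    effect_size: float = 2.0  # texture shift magnitude; 0 = no signal
    witness_rate: float = 1.0  # fraction of a positive case's patches with signal
    tasks: tuple[str, ...] = ("idh",)
    signal_task: str = "idh"  # the task whose status drives the texture signal
    background: BackgroundParams = field(default_factory=BackgroundParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 < self.witness_rate <= 1.0:
            raise ValueError("witness_rate must be in (0, 1]")
        if self.signal_task not in self.tasks:
            raise ValueError("signal_task must be one of tasks")


def _random_field(rng: np.random.Generator, low_res: int, sigma: float,
                  upsample: int) -> np.ndarray:
    """Unit-variance smooth field on a 256x256 grid, built at low resolution."""
    f = gaussian_filter(rng.standard_normal((low_res, low_res)), sigma, mode="wrap")
    f /= f.std() + 1e-12
    if upsample > 1:
        f = np.repeat(np.repeat(f, upsample, axis=0), upsample, axis=1)
    return f[:PATCH_SIZE, :PATCH_SIZE]


def generate_patch(params: BackgroundParams, signal: bool, effect_size: float,
                   rng: np.random.Generator) -> np.ndarray:
    """One 256x256x3 uint8 tissue-like patch; ``signal`` plants the class effect."""
    es = float(effect_size) if signal else 0.0

    coarse = _random_field(rng, 32, 2.0, 8)
    fine = _random_field(rng, 128, 2.0, 2)
    shade = 1.0 + params.coarse_amp * coarse + params.fine_amp * fine
    np.clip(shade, 0.72, 1.22, out=shade)
    img = np.asarray(params.base_rgb, dtype=np.float32) * shade[..., None]

    occupancy = min(0.95, params.occupancy * (1.0 + params.density_gain * es))
    color = np.asarray(params.nucleus_rgb, dtype=np.float32)
    color = np.clip(color + es * np.asarray(params.hue_shift, dtype=np.float32), 0, 255)

    cell = params.cell_px
    ncell = PATCH_SIZE // cell
    occupied = rng.random((ncell, ncell)) < occupancy
    jitter = rng.random((ncell, ncell, 2))
    radii = rng.uniform(*params.radius_range, size=(ncell, ncell))
    rmax = params.radius_range[1]
    stamp = int(2 * rmax + 5)  # local window side covering radius + soft edge
    off = np.arange(stamp, dtype=np.float32)
    for gy, gx in zip(*np.nonzero(occupied)):
        r = radii[gy, gx]
        cx = gx * cell + rmax + jitter[gy, gx, 0] * (cell - 2 * rmax)
        cy = gy * cell + rmax + jitter[gy, gx, 1] * (cell - 2 * rmax)
        x0 = max(0, int(cx) - stamp // 2)
        y0 = max(0, int(cy) - stamp // 2)
        x1 = min(PATCH_SIZE, x0 + stamp)
        y1 = min(PATCH_SIZE, y0 + stamp)
        dx = off[: x1 - x0] + (x0 - cx)
        dy = off[: y1 - y0] + (y0 - cy)
        dist = np.sqrt(dx[None, :] ** 2 + dy[:, None] ** 2)
        alpha = np.clip((r - dist) / 1.5 + 1.0, 0.0, 1.0) * 0.85
        win = img[y0:y1, x0:x1]
        win += alpha[..., None] * (color - win)

    img += params.pixel_noise_sd * rng.standard_normal(img.shape, dtype=np.float32)
    return np.clip(img, 0, 255).astype(np.uint8)


@dataclass
class SynthCohort:
    """In-memory synthetic cohort in the exact shape of the real-data interfaces."""

    images: np.ndarray  # (N, 256, 256, 3) uint8, rows aligned with manifest
    manifest: pd.DataFrame  # tiling-format manifest
    labels: GeneLabelTable
    truth: pd.DataFrame  # per-patch witness flags + case status of the signal task
    config: SynthConfig

    def case_ids(self) -> list[str]:
        return sorted(self.manifest["case_id"].unique())

    def write(self, out_dir: str | Path) -> None:
        """Materialize as PNGs + manifest.csv + labels.csv (the CLI layout)."""
        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, row in self.manifest.iterrows():
            Image.fromarray(self.images[i]).save(out / row["patch_path"])
        self.manifest.to_csv(out / "manifest.csv", index=False)
        self.labels.to_csv(out / "labels.csv")
        self.truth.to_csv(out / "truth.csv", index=False)


def generate_cohort(config: SynthConfig | None = None, **overrides) -> SynthCohort:
    """Generate a full cohort: images + manifest + label table + ground truth."""
    cfg = replace(config, **overrides) if config is not None else SynthConfig(**overrides)
    root_ss = np.random.SeedSequence(cfg.seed)
    case_status_rng = np.random.default_rng(root_ss.spawn(1)[0])

    statuses = {}
    for task in cfg.tasks:
        statuses[task] = (case_status_rng.random(cfg.n_cases) < cfg.prevalence).astype(int)
    sig = statuses[cfg.signal_task]
    if sig.min() == sig.max():  # degenerate draw on tiny cohorts: force both classes
        sig[0] = 1 - sig[0]

    n_side = 8  # fictitious tile-grid width for manifest coordinates
    images, man_rows, truth_rows, label_rows = [], [], [], []
    case_seeds = root_ss.spawn(cfg.n_cases)
    for ci in range(cfg.n_cases):
        case_id = f"case{ci:04d}"
        positive = bool(sig[ci])
        for task in cfg.tasks:
            label_rows.append({"case_id": case_id, "task": task,
                               "status": int(statuses[task][ci])})
        slide_seeds = case_seeds[ci].spawn(cfg.slides_per_case)
        for si in range(cfg.slides_per_case):
            slide_id = f"{case_id}_s{si}"
            slide_rng = np.random.default_rng(slide_seeds[si])
            n = cfg.patches_per_slide
            witness = np.zeros(n, dtype=bool)
            if positive:
                n_w = max(1, round(cfg.witness_rate * n))
                witness[slide_rng.choice(n, size=n_w, replace=False)] = True
            for pi in range(n):
                patch = generate_patch(cfg.background, bool(witness[pi]),
                                       cfg.effect_size, slide_rng)
                x = (pi % n_side) * PATCH_SIZE
                y = (pi // n_side) * PATCH_SIZE
                images.append(patch)
                man_rows.append({
                    "patch_path": f"{slide_id}_x{x}_y{y}.png",
                    "slide_id": slide_id,
                    "case_id": case_id,
                    "x": x,
                    "y": y,
                    "mpp": 0.5,
                    "whitespace_fraction": whitespace_fraction(patch),
                })
                truth_rows.append({
                    "patch_path": f"{slide_id}_x{x}_y{y}.png",
                    "slide_id": slide_id,
                    "case_id": case_id,
                    "witness": bool(witness[pi]),
                    "case_status": int(positive),
                })

    return SynthCohort(
        images=np.stack(images),
        manifest=pd.DataFrame(man_rows, columns=MANIFEST_COLUMNS),
        labels=GeneLabelTable(pd.DataFrame(label_rows)),
        truth=pd.DataFrame(truth_rows),
        config=cfg,
    )


def make_toy_fixtures(seed: int = 7) -> dict:
    """Small deterministic asset set for fast tests.

    Returns a dict with a miniature cohort (6 cases, 1 slide each, 40 patches
    each), the bundled external-cohort confusion matrix, and the exhaustive
    diagnosis truth table (marker/histology combination -> expected call).
    """
    from .reference import EXTERNAL_VALIDATION_CONFUSION
    from .workflow import reference_truth_table

    cohort = generate_cohort(SynthConfig(n_cases=6, slides_per_case=1,
                                         patches_per_slide=40, seed=seed))
    return {
        "cohort": cohort,
        "confusion_matrix": EXTERNAL_VALIDATION_CONFUSION.copy(),
        "truth_table": reference_truth_table(),
    }
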