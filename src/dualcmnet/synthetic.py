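"""Synthetic maize-kernel data: reflectance spectra, single-kernel RGB images
and multi-kernel scenes.

The generators emulate the statistical structure of a bench-top acquisition
of 11 maize varieties: full-range reflectance spectra (350-2500 nm, 2151
points) whose inter-class differences are concentrated in the 1400-1600 nm
and 2000-2300 nm bands (protein/fat/starch absorption features), and kernel
images that differ in ellipse morphology (length/width) and coat colour
(yellow vs. orange).  Every generator is a pure function of its config and
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .errors import ConfigurationError, PlacementError, ValidationError

# ---------------------------------------------------------------------------
# Wavelength grid and variety profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WavelengthGrid:
    """Fixed reflectance wavelength grid: 350..2500 nm in 1 nm steps."""

    start_nm: int = 350
    end_nm: int = 2500
    step_nm: int = 1

    def __post_init__(self):
        if self.length != 2151:
            raise ValidationError("wavelength grid must have 2151 points")

    @property
    def length(self) -> int:
        return (self.end_nm - self.start_nm) // self.step_nm + 1

    def values(self) -> np.ndarray:
        return np.arange(self.start_nm, self.end_nm + 1, self.step_nm, dtype=float)


@dataclass(frozen=True)
class VarietyProfile:
    class_id: int
    name: str
    length_mm: float
    length_sd_mm: float
    width_mm: float
    width_sd_mm: float
    color: str  # "yellow" | "orange"
    protein_pct: float
    fat_pct: float
    starch_pct: float

    def __post_init__(self):
        if not (self.length_mm > self.width_mm > 0):
            raise ValidationError(f"{self.name}: need length > width > 0")
        if self.color not in ("yellow", "orange"):
            raise ValidationError(f"{self.name}: color must be yellow or orange")


def default_profiles() -> list[VarietyProfile]:
    """The 11 study varieties, class-coded 0-10 in their published order."""
    rows = [
        # name, length, l_sd, width, w_sd, color, protein, fat, starch
        ("JiDan209", 10.5, 0.5, 9.0, 0.4, "yellow", 10.02, 4.55, 68.50),
        ("JiDan626", 11.2, 0.5, 8.6, 0.4, "yellow", 8.66, 3.99, 75.62),
        ("JiDan505", 12.3, 0.6, 8.3, 0.4, "orange", 9.59, 4.70, 73.27),
        ("JiDan27", 10.8, 0.5, 9.2, 0.4, "yellow", 8.46, 4.06, 75.23),
        ("JiDan407", 11.5, 0.6, 8.2, 0.4, "yellow", 10.03, 3.23, 76.60),
        ("JiDan50", 12.0, 0.6, 7.5, 0.4, "yellow", 9.51, 4.31, 72.60),
        ("JiDan83", 11.0, 0.5, 8.8, 0.4, "yellow", 10.92, 3.66, 73.62),
        ("JiDan953", 11.0, 0.5, 8.8, 0.4, "yellow", 8.81, 3.67, 77.33),
        ("JiDan436", 11.8, 0.6, 8.0, 0.4, "yellow", 10.65, 3.57, 76.39),
        ("LY9915", 12.2, 0.6, 8.5, 0.4, "orange", 10.58, 4.99, 73.30),
        ("ZhengDan958", 10.2, 0.5, 8.0, 0.4, "yellow", 8.47, 3.92, 73.42),
    ]
    return [VarietyProfile(i, *r) for i, r in enumerate(rows)]


@dataclass
class SyntheticConfig:
    n_classes: int = 11
    n_spectra_per_class: int = 150
    n_images_per_class: int = 1000
    noise_sd: float = 0.01
    class_effect_scale: float = 0.05
    rng_seed: int = 0
    canvas_px: int = 256
    px_per_mm: float = 8.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_classes < 1:
            raise ValidationError("n_classes must be >= 1")


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

# Reflectance anchors: the characteristic peak/valley wavelengths of maize
# kernel spectra, plus endpoints and one shape helper at 1850 nm so that
# both 1780 and 1915 nm are genuine local minima.  Heights are free
# parameters chosen as a plausible concave reflectance profile.
_BASE_ANCHORS = (
    (350, 0.15), (863, 0.55), (980, 0.45), (1105, 0.58), (1175, 0.50),
    (1295, 0.56), (1450, 0.35), (1680, 0.48), (1780, 0.32), (1850, 0.36),
    (1915, 0.28), (2015, 0.40), (2500, 0.10),
)

#: Wavelength windows carrying the class-discriminative composition signal.
DISCRIMINATIVE_WINDOWS = ((1400.0, 1600.0), (2000.0, 2300.0))


def base_curve(grid: WavelengthGrid | None = None) -> np.ndarray:
    """Monotone-safe cubic interpolation through the peak/valley anchors."""
    grid = grid or WavelengthGrid()
    wl, refl = zip(*_BASE_ANCHORS)
    return PchipInterpolator(np.array(wl), np.array(refl))(grid.values())


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def class_effect(profile: VarietyProfile, profiles: list[VarietyProfile],
                 scale: float, grid: WavelengthGrid | None = None) -> np.ndarray:
    """Additive class signature: 3 Gaussian bumps confined to the two
    discriminative windows, amplitudes set by the z-scored composition."""
    grid = grid or WavelengthGrid()
    wl = grid.values()
    zp = _zscore(np.array([p.protein_pct for p in profiles]))
    zf = _zscore(np.array([p.fat_pct for p in profiles]))
    zs = _zscore(np.array([p.starch_pct for p in profiles]))
    idx = [p.class_id for p in profiles].index(profile.class_id)
    amps = scale * np.array([zp[idx], zf[idx], zs[idx]])
    # centres drawn once per class from a class-keyed stream, so the
    # signature is stable across configs and sample counts
    crng = np.random.default_rng([911, profile.class_id])
    windows = [DISCRIMINATIVE_WINDOWS[0], DISCRIMINATIVE_WINDOWS[1],
               DISCRIMINATIVE_WINDOWS[1]]
    eff = np.zeros_like(wl)
    for amp, (lo, hi) in zip(amps, windows):
        c = crng.uniform(lo + 20, hi - 20)
        w = crng.uniform(20.0, 45.0)
        bump = amp * np.exp(-0.5 * ((wl - c) / w) ** 2)
        bump[(wl < lo) | (wl > hi)] = 0.0  # strictly confined to the window
        eff += bump
    return eff


def gen_spectra(config: SyntheticConfig,
                profiles: list[VarietyProfile] | None = None) -> pd.DataFrame:
    """Generate labelled reflectance spectra.

    Returns a DataFrame with a ``label`` column followed by 2151 columns
    named by integer wavelength; values clipped to [0, 1].
    """
    profiles = profiles if profiles is not None else default_profiles()
    by_id = {p.class_id: p for p in profiles}
    for cid in range(config.n_classes):
        if cid not in by_id:
            raise ConfigurationError(f"no profile for class_id {cid}")
    grid = WavelengthGrid()
    base = base_curve(grid)
    rng = np.random.default_rng(config.rng_seed)
    rows, labels = [], []
    for cid in range(config.n_classes):
        mean = base + class_effect(by_id[cid], profiles,
                                   config.class_effect_scale, grid)
        spectra = np.tile(mean, (config.n_spectra_per_class, 1))
        if config.noise_sd > 0:
            spectra += rng.normal(0.0, config.noise_sd, spectra.shape)
        if config.noise_sd > 0 or config.class_effect_scale > 0:
            spectra = np.clip(spectra, 0.0, 1.0)
        rows.append(spectra)
        labels.extend([cid] * config.n_spectra_per_class)
    data = np.vstack(rows) if rows else np.empty((0, grid.length))
    cols = [str(int(w)) for w in grid.values()]
    df = pd.DataFrame(data, columns=cols)
    df.insert(0, "label", labels)
    return df


def spectra_to_arrays(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a spectra table into (values, labels)."""
    y = df["label"].to_numpy(dtype=int)
    X = df.drop(columns="label").to_numpy(dtype=np.float32)
    return X, y


# ---------------------------------------------------------------------------
# Kernel images
# ---------------------------------------------------------------------------

COLOR_REFS = {"yellow": (225, 185, 60), "orange": (230, 130, 40)}
_COLOR_JITTER_SD = 10.0
_SPECKLE_SD = 8.0


def _draw_kernel(canvas: np.ndarray, center_rc, semi_r, semi_c, rotation,
                 color_ref, rng) -> tuple[int, int, int, int]:
    """Draw one speckled elliptical kernel; returns its half-open box
    (x_min, y_min, x_max, y_max)."""
    from skimage.draw import ellipse

    rr, cc = ellipse(center_rc[0], center_rc[1], semi_r, semi_c,
                     shape=canvas.shape[:2], rotation=rotation)
    color = np.array(color_ref, float) + rng.normal(0, _COLOR_JITTER_SD, 3)
    px = color[None, :] + rng.normal(0, _SPECKLE_SD, (rr.size, 3))
    canvas[rr, cc] = np.clip(px, 0, 255).astype(np.uint8)
    return int(cc.min()), int(rr.min()), int(cc.max()) + 1, int(rr.max()) + 1


def gen_kernel_images(config: SyntheticConfig,
                      profiles: list[VarietyProfile] | None = None
                      ) -> tuple[list[np.ndarray], np.ndarray]:
    """Render single-kernel RGB images on a black background.

    Returns (images, labels); each image is uint8 (canvas_px, canvas_px, 3).
    """
    profiles = profiles if profiles is not None else default_profiles()
    by_id = {p.class_id: p for p in profiles}
    for cid in range(config.n_classes):
        if cid not in by_id:
            raise ConfigurationError(f"no profile for class_id {cid}")
    rng = np.random.default_rng(config.rng_seed)
    size, ppm = config.canvas_px, config.px_per_mm
    images, labels = [], []
    for cid in range(config.n_classes):
        prof = by_id[cid]
        if (prof.length_mm + 4 * prof.length_sd_mm) * ppm >= size:
            raise ValidationError(
                f"canvas {size}px too small for {prof.name} at {ppm} px/mm")
        for _ in range(config.n_images_per_class):
            canvas = np.zeros((size, size, 3), np.uint8)
            L = rng.normal(prof.length_mm, prof.length_sd_mm) * ppm
            W = rng.normal(prof.width_mm, prof.width_sd_mm) * ppm
            theta = rng.uniform(-np.pi, np.pi)
            _draw_kernel(canvas, (size / 2, size / 2), L / 2, W / 2, theta,
                         COLOR_REFS[prof.color], rng)
            images.append(canvas)
            labels.append(cid)
    return images, np.asarray(labels, int)


# ---------------------------------------------------------------------------
# Multi-kernel scenes
# ---------------------------------------------------------------------------


def gen_scene(n_kernels: int, layout_seed: int = 0,
              profiles: list[VarietyProfile] | None = None,
              canvas_px: int = 1024, px_per_mm: float = 6.0
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One scene of ``n_kernels`` non-overlapping kernels on a black board.

    Kernels are laid out on a jittered grid — emulating kernels arranged in
    regular groups on an acquisition board — which guarantees pairwise
    disjoint bounding boxes.  Returns (image, boxes, labels); boxes are
    0-based half-open (x_min, y_min, x_max, y_max).
    """
    if n_kernels < 0:
        raise ValidationError("n_kernels must be >= 0")
    profiles = profiles if profiles is not None else default_profiles()
    canvas = np.zeros((canvas_px, canvas_px, 3), np.uint8)
    if n_kernels == 0:
        return canvas, np.empty((0, 4), int), np.empty(0, int)
    rng = np.random.default_rng(layout_seed)
    side = int(np.ceil(np.sqrt(n_kernels)))
    cell = canvas_px / side
    boxes, labels = [], []
    k = 0
    for gi in range(side):
        for gj in range(side):
            if k >= n_kernels:
                break
            prof = profiles[k % len(profiles)]
            placed = False
            for _ in range(20):  # bounded retries within the cell
                a = rng.normal(prof.length_mm, prof.length_sd_mm) * px_per_mm / 2
                b = rng.normal(prof.width_mm, prof.width_sd_mm) * px_per_mm / 2
                theta = rng.uniform(-np.pi, np.pi)
                # half-extents of the rotated ellipse's bounding box
                hr = np.hypot(a * np.cos(theta), b * np.sin(theta))
                hc = np.hypot(a * np.sin(theta), b * np.cos(theta))
                margin_r = cell / 2 - hr - 2
                margin_c = cell / 2 - hc - 2
                if margin_r < 0 or margin_c < 0:
                    continue
                cr = (gi + 0.5) * cell + rng.uniform(-margin_r, margin_r)
                ccen = (gj + 0.5) * cell + rng.uniform(-margin_c, margin_c)
                box = _draw_kernel(canvas, (cr, ccen), a, b, theta,
                                   COLOR_REFS[prof.color], rng)
                boxes.append(box)
                labels.append(prof.class_id)
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"cannot place kernel {k} without overlap: cell "
                    f"{cell:.0f}px too small at {px_per_mm} px/mm")
            k += 1
    return canvas, np.asarray(boxes, int), np.asarray(labels, int)


# ---------------------------------------------------------------------------
# Disk I/O helpers (CSV / PNG external interfaces)
# ---------------------------------------------------------------------------


def write_spectra_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_spectra_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_images(images, labels, out_dir) -> None:
    """PNG files under ``class_<id>/`` subdirectories."""
    import os

    from PIL import Image

    counters: dict[int, int] = {}
    for img, lab in zip(images, labels):
        d = os.path.join(out_dir, f"class_{int(lab)}")
        os.makedirs(d, exist_ok=True)
        i = counters.get(int(lab), 0)
        Image.fromarray(img).save(os.path.join(d, f"kernel_{i:04d}.png"))
        counters[int(lab)] = i + 1


def write_scene(image, boxes, png_path, boxes_csv_path) -> None:
    from PIL import Image

    Image.fromarray(image).save(png_path)
    pd.DataFrame(boxes, columns=["x_min", "y_min", "x_max", "y_max"]) \
        .to_csv(boxes_csv_path, index=False)
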