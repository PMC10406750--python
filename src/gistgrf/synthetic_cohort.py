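"""Synthetic screening-mammogram cohorts with planted difficulty structure.

Real screening archives with reader-panel annotations are access-restricted,
so this module generates image cohorts and reader panels carrying the
statistical structure the pipeline assumes:

* each case has four views (left/right craniocaudal CC and mediolateral
  oblique MLO); the breast is a bright half-ellipse attached to the
  chest-wall side on a dark background, with a triangular pectoral wedge of
  higher mean intensity on MLO views and an optional detached corner label
  block;
* parenchymal texture is band-limited correlated Gaussian noise on a uniform
  base level; "difficult" cases have their noise variance and correlation
  length scaled by ``1 + effect_size`` in all four views, so the planted
  class difference is controllable down to an exact null (effect_size 0);
* a reader panel rates every case; readers false-positive (rating 3-5) with
  a higher probability on difficult cases, and a small fraction of
  reader-cases receive a duplicate second rating to exercise the
  highest-rating collapse rule.

The geometry is deliberately schematic: the point is controllable texture
statistics under the exact masking/cropping contract of the preprocessing
stage, not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .preprocessing import MammogramImage, write_tiff

__all__ = ["CohortConfig", "SyntheticCase", "generate_cohort", "simulate_reader_panel", "write_cohort"]

# intensity model on the 8-bit scale (scaled up for deeper bit depths)
BREAST_LEVEL = 140.0
BACKGROUND_LEVEL = 5.0
NOISE_STD = 10.0
PECTORAL_BOOST = 30.0
LABEL_VALUE = 220.0
LABEL_SIZE = 20

DENSITY_CATEGORIES = ("A", "B", "C", "D")


@dataclass
class CohortConfig:
    """Generator settings; defaults are the reference study conditions."""

    n_cases: int
    image_height: int = 512
    image_width: int = 512
    effect_size: float = 1.0
    noise_correlation_length: float = 4.0
    label_artifact: bool = True
    n_readers: int = 130
    fp_rate_easy: float = 0.1
    fp_rate_difficult: float = 0.6
    duplicate_fraction: float = 0.05
    density_mix: tuple[float, float, float, float] = (0.10, 0.40, 0.40, 0.10)
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValueError("n_cases must be >= 2")
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("image_height/image_width must be >= 32")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_correlation_length <= 0:
            raise ValueError("noise_correlation_length must be positive")
        if self.n_readers < 1:
            raise ValueError("n_readers must be >= 1")
        for name in ("fp_rate_easy", "fp_rate_difficult", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fp_rate_difficult < self.fp_rate_easy:
            raise ValueError("fp_rate_difficult must be >= fp_rate_easy")
        self.density_mix = tuple(float(v) for v in self.density_mix)
        if len(self.density_mix) != 4 or any(v < 0 for v in self.density_mix):
            raise ValueError("density_mix must be 4 non-negative proportions")
        if abs(sum(self.density_mix) - 1.0) > 1e-9:
            raise ValueError("density_mix must sum to 1")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "density_mix" in data:
            data["density_mix"] = tuple(data["density_mix"])
        return cls(**data)


@dataclass
class SyntheticCase:
    case_id: str
    difficulty_class: str  # "difficult" | "easy"
    bd_category: str
    images: dict  # (view, laterality) -> MammogramImage

    def __post_init__(self) -> None:
        if len(self.images) != 4:
            raise ValueError("a case must have exactly 4 images")
        depths = {img.bit_depth for img in self.images.values()}
        if len(depths) != 1:
            raise ValueError("all images of a case must share one bit depth")


def _correlated_noise(rng: np.random.Generator, shape, corr_len: float, std: float) -> np.ndarray:
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=corr_len, mode="reflect")
    s = smooth.std()
    if s == 0:
        return np.zeros(shape)
    return smooth * (std / s)


def _breast_mask_geometry(
    rng: np.random.Generator, h: int, w: int, laterality: str
) -> np.ndarray:
    """Half-ellipse attached to the chest-wall edge (left for L, right for R)."""
    b = 0.42 * h * rng.uniform(0.9, 1.1)  # vertical semi-axis
    a = 0.78 * w * rng.uniform(0.9, 1.1)  # horizontal semi-axis
    rr = np.arange(h)[:, None] - h / 2.0
    cc = np.arange(w)[None, :]
    if laterality == "R":
        cc = (w - 1) - cc
    return (rr / b) ** 2 + (cc / a) ** 2 <= 1.0


def _pectoral_wedge(h: int, w: int, laterality: str) -> np.ndarray:
    """Triangular wedge at the top chest-wall corner (MLO views only)."""
    depth = int(0.45 * h)
    width = int(0.30 * w)
    rr = np.arange(h)[:, None]
    cc = np.arange(w)[None, :]
    if laterality == "R":
        cc = (w - 1) - cc
    return (rr < depth) & (cc < width * (1.0 - rr / depth))


def _render_image(
    rng: np.random.Generator,
    config: CohortConfig,
    view: str,
    laterality: str,
    difficult: bool,
) -> np.ndarray:
    h, w = config.image_height, config.image_width
    scale = 2 ** (config.bit_depth - 8)
    img = np.full((h, w), BACKGROUND_LEVEL, dtype=np.float64)
    breast = _breast_mask_geometry(rng, h, w, laterality)

    # difficult cases: noise variance and correlation length scaled by 1+effect
    boost = 1.0 + (config.effect_size if difficult else 0.0)
    std = NOISE_STD * np.sqrt(boost)
    corr = config.noise_correlation_length * boost
    texture = BREAST_LEVEL + _correlated_noise(rng, (h, w), corr, std)
    img[breast] = texture[breast]

    if view == "MLO":
        wedge = _pectoral_wedge(h, w, laterality) & breast
        img[wedge] += PECTORAL_BOOST

    if config.label_artifact:
        # high-intensity block in the corner away from the chest wall,
        # detached from the breast
        r0 = 4
        c0 = 4 if laterality == "R" else w - 4 - LABEL_SIZE
        img[r0 : r0 + LABEL_SIZE, c0 : c0 + LABEL_SIZE] = LABEL_VALUE

    img = np.clip(img * scale, 0, 2**config.bit_depth - 1)
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    return img.astype(dtype)


def generate_cohort(config: CohortConfig) -> list[SyntheticCase]:
    """Generate ``n_cases`` four-view cases, half of them difficult (ties to easy).

    Deterministic given ``config.seed``: same config always yields
    byte-identical pixel arrays.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    n_difficult = n // 2
    classes = np.array(["difficult"] * n_difficult + ["easy"] * (n - n_difficult))
    rng.shuffle(classes)
    densities = rng.choice(DENSITY_CATEGORIES, size=n, p=config.density_mix)

    cases = []
    width = max(4, len(str(n)))
    for idx in range(n):
        case_id = f"case{idx:0{width}d}"
        difficult = classes[idx] == "difficult"
        images = {}
        for view in ("CC", "MLO"):
            for lat in ("L", "R"):
                pixels = _render_image(rng, config, view, lat, difficult)
                images[(view, lat)] = MammogramImage(
                    pixels, case_id, view, lat, bit_depth=config.bit_depth
                )
        cases.append(
            SyntheticCase(
                case_id=case_id,
                difficulty_class=str(classes[idx]),
                bd_category=str(densities[idx]),
                images=images,
            )
        )
    return cases


def simulate_reader_panel(
    cases: list[SyntheticCase], config: CohortConfig
) -> pd.DataFrame:
    """Simulate a reader panel rating every case.

    Each reader rates each case once; a reader false-positives (uniform
    rating 3-5) with probability ``fp_rate_difficult`` on difficult cases and
    ``fp_rate_easy`` on easy ones, otherwise rates normal/benign (uniform
    1-2). A ``duplicate_fraction`` of reader-cases receive an independent
    second rating from the same distribution, exercising the
    highest-rating collapse downstream.
    """
    if not cases:
        raise ValueError("empty case list")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    rows = []
    for reader_idx in range(config.n_readers):
        reader_id = f"reader{reader_idx:04d}"
        for case in cases:
            fp_rate = (
                config.fp_rate_difficult
                if case.difficulty_class == "difficult"
                else config.fp_rate_easy
            )
            n_ratings = 2 if rng.random() < config.duplicate_fraction else 1
            for _ in range(n_ratings):
                if rng.random() < fp_rate:
                    rating = int(rng.integers(3, 6))
                else:
                    rating = int(rng.integers(1, 3))
                rows.append((reader_id, case.case_id, rating))
    return pd.DataFrame(rows, columns=["reader_id", "case_id", "rating"])


def write_cohort(
    cases: list[SyntheticCase], reports: pd.DataFrame, out_dir
) -> Path:
    """Write images (TIFF), reader reports, truth and a manifest; return manifest path.

    Layout: ``images/<case>_<view>_<lat>.tif``, ``reports.csv``
    (reader_id, case_id, rating), ``truth.csv`` (case_id, difficulty_class)
    and ``manifest.csv`` (case_id, view, laterality, bd_category, path).
    """
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in cases:
        for (view, lat), image in sorted(case.images.items()):
            rel = f"images/{case.case_id}_{view}_{lat}.tif"
            write_tiff(out / rel, image)
            rows.append((case.case_id, view, lat, case.bd_category, rel))
    manifest = pd.DataFrame(
        rows, columns=["case_id", "view", "laterality", "bd_category", "path"]
    )
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    reports.to_csv(out / "reports.csv", index=False)
    pd.DataFrame(
        [(c.case_id, c.difficulty_class) for c in cases],
        columns=["case_id", "difficulty_class"],
    ).to_csv(out / "truth.csv", index=False)
    return manifest_path
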