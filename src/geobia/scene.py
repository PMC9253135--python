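"""Synthetic riparian scenes with a nested two-scale class structure.

A scene stands in for sub-meter aerial imagery of a floodplain mosaic:
a 13-class land-cover map nested inside a 7-class map (every fine class
has exactly one parent), three spectral bands (near-infrared, red,
green), a canopy-height raster, and pixel-perfect truth maps at both
scales.  Patches come from a Voronoi tessellation of random sites, so
they are irregular, contiguous, and resemble hand-delineated polygons.
Pixel values are class mean reflectance plus a class-specific directional
sinusoid (the texture a Gabor bank can detect) plus Gaussian noise.

Generation is a pure function of (configuration, seed): the same seed
reproduces a scene bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .raster import MultibandImage, Raster, read_raster, write_raster

__all__ = [
    "ClassScheme",
    "ClassAppearance",
    "SyntheticScene",
    "default_scheme",
    "default_appearance",
    "showcase_scheme_appearance",
    "generate_scene",
    "scene_to_files",
    "scene_from_files",
    "regenerate",
]


@dataclass(frozen=True)
class ClassScheme:
    """Nested class schemes: fine sub-classes, coarse super-classes."""

    sub_classes: tuple[str, ...]
    super_classes: tuple[str, ...]
    parent_of: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.parent_of) != set(self.sub_classes):
            raise ValueError("parent_of must map every sub-class")
        bad = set(self.parent_of.values()) - set(self.super_classes)
        if bad:
            raise ValueError(f"unknown super-classes: {sorted(bad)}")

    def sub_code(self, name: str) -> int:
        return self.sub_classes.index(name)

    def super_code(self, name: str) -> int:
        return self.super_classes.index(name)

    def parent_codes(self) -> np.ndarray:
        """Array mapping sub-class code -> super-class code."""
        return np.array(
            [self.super_code(self.parent_of[s]) for s in self.sub_classes],
            dtype=np.int32,
        )


@dataclass(frozen=True)
class ClassAppearance:
    """Spectral, textural and structural appearance of one sub-class.

    Reflectance means are unitless in [0, 1]; the texture is an additive
    sinusoid (wavelength in pixels, orientation in degrees) shared across
    bands; canopy height is in meters.
    """

    nir: float
    red: float
    green: float
    noise_sd: float = 0.02
    texture_wavelength: float = 8.0
    texture_orientation: float = 0.0
    texture_amplitude: float = 0.0
    height_mean: float = 0.0
    height_sd: float = 0.0

    def __post_init__(self) -> None:
        for band in (self.nir, self.red, self.green):
            if not 0.0 <= band <= 1.0:
                raise ValueError("reflectance means must lie in [0, 1]")
        if self.noise_sd < 0 or self.height_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.texture_wavelength <= 1:
            raise ValueError("texture wavelength must exceed 1 pixel")


@dataclass(frozen=True)
class SyntheticScene:
    """A generated scene plus everything needed to regenerate it."""

    image: MultibandImage
    chm: Raster
    truth_sub: Raster
    truth_super: Raster
    scheme: ClassScheme
    appearance: dict[str, ClassAppearance]
    seed: int
    n_patches: int
    cell_size: float = 1.0

    def __post_init__(self) -> None:
        parents = self.scheme.parent_codes()
        if not np.array_equal(
            parents[self.truth_sub.values], self.truth_super.values
        ):
            raise ValueError("truth_super must equal parent_of(truth_sub)")
        shapes = {
            self.image.shape,
            self.chm.shape,
            self.truth_sub.shape,
            self.truth_super.shape,
        }
        if len(shapes) != 1:
            raise ValueError("scene rasters must share dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.chm.shape


def default_scheme() -> ClassScheme:
    """The 7-class / 13-class wetland vegetation schemes."""
    super_classes = (
        "forest",
        "marsh",
        "agriculture",
        "developed",
        "open water",
        "grass/forbs",
        "sand/mud",
    )
    sub_classes = (
        "agriculture",
        "developed",
        "grass/forbs",
        "open water",
        "road/levee",
        "sand/mud",
        "scrub-shrub",
        "shallow marsh",
        "submerged aquatic vegetation",
        "upland forest",
        "wet forest",
        "wet meadow",
        "wet shrub",
    )
    parent_of = {
        "agriculture": "agriculture",
        "developed": "developed",
        "grass/forbs": "grass/forbs",
        "open water": "open water",
        "road/levee": "developed",
        "sand/mud": "sand/mud",
        "scrub-shrub": "forest",
        "shallow marsh": "marsh",
        "submerged aquatic vegetation": "open water",
        "upland forest": "forest",
        "wet forest": "forest",
        "wet meadow": "marsh",
        "wet shrub": "marsh",
    }
    return ClassScheme(sub_classes, super_classes, parent_of)


def default_appearance() -> dict[str, ClassAppearance]:
    """Moderately separable riparian appearance table.

    Reflectances follow the usual ordering (vegetation bright in NIR and
    dark in red, water dark everywhere, bare surfaces flat across bands).
    Several cross-parent pairs are deliberately close in spectrum and
    height — wet meadow vs. grass/forbs, wet shrub vs. scrub-shrub,
    road/levee vs. sand/mud — the kind of confusion a coarser-scale
    context can resolve.  Forest classes carry the strongest directional
    textures.
    """
    a = ClassAppearance
    return {
        "agriculture": a(0.46, 0.28, 0.30, 0.07, 12.0, 0.0, 0.05, 0.4, 0.2),
        "developed": a(0.34, 0.33, 0.32, 0.08, 5.0, 90.0, 0.03, 5.0, 2.0),
        "grass/forbs": a(0.51, 0.17, 0.25, 0.10, 5.0, 30.0, 0.02, 0.4, 0.2),
        "open water": a(0.05, 0.09, 0.12, 0.03, 25.0, 0.0, 0.01, 0.0, 0.0),
        "road/levee": a(0.33, 0.34, 0.33, 0.05, 30.0, 45.0, 0.02, 0.2, 0.1),
        "sand/mud": a(0.36, 0.38, 0.36, 0.06, 25.0, 10.0, 0.01, 0.1, 0.1),
        "scrub-shrub": a(0.47, 0.15, 0.22, 0.10, 7.0, 60.0, 0.05, 3.0, 1.0),
        "shallow marsh": a(0.40, 0.16, 0.22, 0.08, 6.0, 120.0, 0.04, 0.8, 0.4),
        "submerged aquatic vegetation": a(
            0.12, 0.12, 0.16, 0.04, 15.0, 80.0, 0.02, 0.0, 0.0
        ),
        "upland forest": a(0.55, 0.12, 0.20, 0.09, 9.0, 135.0, 0.06, 18.0, 4.0),
        "wet forest": a(0.52, 0.13, 0.21, 0.09, 18.0, 45.0, 0.07, 15.0, 4.0),
        "wet meadow": a(0.49, 0.18, 0.26, 0.10, 8.0, 150.0, 0.02, 0.5, 0.2),
        "wet shrub": a(0.45, 0.16, 0.23, 0.10, 8.0, 100.0, 0.05, 2.5, 1.0),
    }


def showcase_scheme_appearance() -> tuple[ClassScheme, dict[str, ClassAppearance]]:
    """A constructed best case for the hierarchy mechanism (synthetic).

    Sub-classes are spectrally identical within each super-class; the
    super-classes sit on a tight reflectance ladder (adjacent steps small
    against the heavy pixel noise), so parent identity is ambiguous at
    the sub-object scale but recoverable at the super-object scale, where
    spatial averaging suppresses the noise.  Within a parent, sub-class
    identity is carried by canopy-height tiers that repeat across
    parents, so height alone never reveals the parent.
    """
    scheme = default_scheme()
    parents = scheme.parent_codes()
    tiers = (0.5, 6.0, 14.0)
    appearance: dict[str, ClassAppearance] = {}
    rank_within: dict[int, int] = {}
    for code, name in enumerate(scheme.sub_classes):
        g = int(parents[code])
        rank = rank_within.get(g, 0)
        rank_within[g] = rank + 1
        appearance[name] = ClassAppearance(
            nir=0.30 + 0.012 * g,
            red=0.30 - 0.010 * g,
            green=0.30,
            noise_sd=0.15,
            texture_wavelength=8.0,
            texture_orientation=0.0,
            texture_amplitude=0.0,
            height_mean=tiers[rank % len(tiers)],
            height_sd=0.25,
        )
    return scheme, appearance


def generate_scene(
    scheme: ClassScheme,
    appearance: dict[str, ClassAppearance],
    width: int,
    height: int,
    n_patches: int,
    seed: int,
    cell_size: float = 1.0,
) -> SyntheticScene:
    """Generate one scene (see module docstring for the model).

    The first len(sub_classes) patch sites receive each sub-class exactly
    once (in a seeded random order); remaining sites draw uniformly, so
    every class is present in every scene.
    """
    if width < 64 or height < 64:
        raise ValueError("width and height must be >= 64")
    n_sub = len(scheme.sub_classes)
    if n_patches < n_sub:
        raise ValueError("n_patches must be >= the number of sub-classes")
    missing = set(scheme.sub_classes) - set(appearance)
    if missing:
        raise ValueError(f"appearance missing for: {sorted(missing)}")
    unknown = set(appearance) - set(scheme.sub_classes)
    if unknown:
        raise ValueError(f"appearance for unknown sub-classes: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    sites_flat = rng.choice(width * height, size=n_patches, replace=False)
    sites = np.stack([sites_flat // width, sites_flat % width], axis=1)
    patch_class = np.concatenate(
        [
            rng.permutation(n_sub),
            rng.integers(0, n_sub, size=n_patches - n_sub),
        ]
    ).astype(np.int32)

    rows, cols = np.mgrid[0:height, 0:width]
    grid = np.stack([rows.ravel(), cols.ravel()], axis=1)
    _, nearest = cKDTree(sites).query(grid)
    truth_sub = patch_class[nearest].reshape(height, width)
    truth_super = scheme.parent_codes()[truth_sub]

    order = list(scheme.sub_classes)
    mean = {
        b: np.array([getattr(appearance[c], b) for c in order])
        for b in ("nir", "red", "green")
    }
    noise_sd = np.array([appearance[c].noise_sd for c in order])
    h_mean = np.array([appearance[c].height_mean for c in order])
    h_sd = np.array([appearance[c].height_sd for c in order])

    texture = np.zeros((height, width))
    x = cols.astype(float)
    y = rows.astype(float)
    for code, name in enumerate(order):
        app = appearance[name]
        if app.texture_amplitude == 0:
            continue
        mask = truth_sub == code
        if not mask.any():
            continue
        th = np.radians(app.texture_orientation)
        phase = (x * np.cos(th) + y * np.sin(th)) / app.texture_wavelength
        texture[mask] = app.texture_amplitude * np.sin(2 * np.pi * phase[mask])

    sd_map = noise_sd[truth_sub]
    bands = {}
    for b in ("nir", "red", "green"):
        noise = rng.standard_normal((height, width)) * sd_map
        bands[b] = Raster(
            mean[b][truth_sub] + texture + noise, cell_size=cell_size
        )
    chm_noise = rng.standard_normal((height, width)) * h_sd[truth_sub]
    chm = Raster(
        np.maximum(h_mean[truth_sub] + chm_noise, 0.0), cell_size=cell_size
    )

    return SyntheticScene(
        image=MultibandImage(bands["nir"], bands["red"], bands["green"]),
        chm=chm,
        truth_sub=Raster(truth_sub.astype(np.int32), cell_size=cell_size),
        truth_super=Raster(truth_super.astype(np.int32), cell_size=cell_size),
        scheme=scheme,
        appearance=dict(appearance),
        seed=seed,
        n_patches=n_patches,
        cell_size=cell_size,
    )


def scene_to_files(scene: SyntheticScene, directory: str | Path) -> list[Path]:
    """Write rasters as TIFF plus a JSON config; round-trips exactly."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, raster in (
        ("image.tif", scene.image),
        ("chm.tif", scene.chm),
        ("truth_sub.tif", scene.truth_sub),
        ("truth_super.tif", scene.truth_super),
    ):
        write_raster(d / name, raster)
        paths.append(d / name)
    height, width = scene.shape
    config = {
        "scheme": {
            "sub_classes": list(scene.scheme.sub_classes),
            "super_classes": list(scene.scheme.super_classes),
            "parent_of": scene.scheme.parent_of,
        },
        "appearance": {k: asdict(v) for k, v in scene.appearance.items()},
        "seed": scene.seed,
        "n_patches": scene.n_patches,
        "cell_size": scene.cell_size,
        "width": width,
        "height": height,
    }
    cfg = d / "scene_config.json"
    cfg.write_text(json.dumps(config, indent=2))
    paths.append(cfg)
    return paths


def _config_from_json(d: Path) -> dict:
    return json.loads((d / "scene_config.json").read_text())


def scene_from_files(directory: str | Path) -> SyntheticScene:
    """Read back a scene written by :func:`scene_to_files`."""
    d = Path(directory)
    cfg = _config_from_json(d)
    scheme = ClassScheme(
        tuple(cfg["scheme"]["sub_classes"]),
        tuple(cfg["scheme"]["super_classes"]),
        dict(cfg["scheme"]["parent_of"]),
    )
    appearance = {
        k: ClassAppearance(**v) for k, v in cfg["appearance"].items()
    }
    cell = cfg["cell_size"]
    image = read_raster(d / "image.tif", cell_size=cell)
    return SyntheticScene(
        image=image,
        chm=read_raster(d / "chm.tif", cell_size=cell),
        truth_sub=read_raster(d / "truth_sub.tif", cell_size=cell),
        truth_super=read_raster(d / "truth_super.tif", cell_size=cell),
        scheme=scheme,
        appearance=appearance,
        seed=cfg["seed"],
        n_patches=cfg["n_patches"],
        cell_size=cell,
    )


def regenerate(directory: str | Path) -> SyntheticScene:
    """Regenerate the scene from the stored config (must match the files)."""
    cfg = _config_from_json(Path(directory))
    scheme = ClassScheme(
        tuple(cfg["scheme"]["sub_classes"]),
        tuple(cfg["scheme"]["super_classes"]),
        dict(cfg["scheme"]["parent_of"]),
    )
    appearance = {k: ClassAppearance(**v) for k, v in cfg["appearance"].items()}
    return generate_scene(
        scheme,
        appearance,
        width=cfg["width"],
        height=cfg["height"],
        n_patches=cfg["n_patches"],
        seed=cfg["seed"],
        cell_size=cfg["cell_size"],
    )
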