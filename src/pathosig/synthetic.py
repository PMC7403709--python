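"""Synthetic H&E-like tile images and labeled cohorts.

Real rectal-cancer biopsy slides cannot be redistributed, so this module
fabricates the raw material the rest of the pipeline consumes: 512x512
RGB "tile" images whose second-order texture statistics differ between
the two outcome classes (poor response, PR, vs non-PR), pseudo
whole-slide images with polygonal tumor annotations, and patient cohorts
whose clinical covariates follow the marginal frequencies observed in a
120-patient primary dataset (~49% PR prevalence).

Tiles are fields of randomly oriented elliptical "nuclei" (dark
H&E-purple) scattered by a homogeneous Poisson process over a pink
background, rendered with 2x supersampling for anti-aliasing, plus
additive Gaussian speckle.  The PR class differs from non-PR by a higher
nucleus density and stronger speckle, both scaled by a single
dimensionless ``effect_size``; at ``effect_size=0`` the two classes
share one distribution exactly.

Reproducibility: one root seed; per-patient and per-tile generators are
derived by counter (``SeedSequence(seed, spawn_key=...)``) so any tile
can be regenerated in isolation, in any order, bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse
from skimage.draw import polygon2mask

__all__ = [
    "TextureClassParams",
    "SyntheticCohortConfig",
    "SyntheticPatient",
    "SyntheticCohort",
    "generate_tile_image",
    "generate_pseudo_wsi",
    "generate_cohort",
    "class_params",
    "TABLE1_PRIMARY_MARGINS",
]

# H&E-like palette: eosin-pink background, hematoxylin-purple nuclei.
HE_BACKGROUND = (230, 200, 220)
HE_NUCLEUS = (90, 60, 130)

#: Marginal covariate frequencies of the 120-patient primary dataset
#: (counts pooled over both response groups).
TABLE1_PRIMARY_MARGINS: dict[str, dict[str, float]] = {
    "gender": {"male": 80 / 120, "female": 40 / 120},
    "t_stage": {"T2": 3 / 120, "T3": 49 / 120, "T4": 68 / 120},
    "n_stage": {"N0": 23 / 120, "N1": 77 / 120, "N2": 20 / 120},
    "cea": {"normal": 68 / 120, "abnormal": 52 / 120},
}
AGE_MEAN, AGE_SD = 55.7, 11.1


@dataclass(frozen=True)
class TextureClassParams:
    """Rendering parameters of one tile class.

    ``nucleus_density`` is the expected number of nuclei per pixel^2 of
    the homogeneous Poisson process; radii are in pixels; intensities
    are 8-bit per-channel levels; ``speckle_sd`` is the SD of additive
    Gaussian noise in gray levels.
    """

    nucleus_density: float = 2.2e-3
    nucleus_radius_mean: float = 6.0
    nucleus_radius_sd: float = 1.5
    nucleus_intensity: tuple[int, int, int] = HE_NUCLEUS
    background_intensity: tuple[int, int, int] = HE_BACKGROUND
    speckle_sd: float = 8.0

    def __post_init__(self) -> None:
        for name in ("nucleus_intensity", "background_intensity"):
            vals = getattr(self, name)
            if len(vals) != 3 or any(not (0 <= v <= 255) for v in vals):
                raise ValueError(f"{name} must be three values in [0, 255]")
        if self.nucleus_density < 0:
            raise ValueError("nucleus_density must be >= 0")
        if self.nucleus_radius_mean <= 0:
            raise ValueError("nucleus_radius_mean must be > 0")
        if self.nucleus_radius_sd < 0 or self.speckle_sd < 0:
            raise ValueError("SD parameters must be >= 0")


def class_params(effect_size: float) -> tuple[TextureClassParams, TextureClassParams]:
    """(non-PR, PR) rendering parameters separated by ``effect_size``.

    The PR class gets ``(1 + 0.5*effect_size)`` times the nucleus density
    and ``2*effect_size`` extra gray levels of speckle; at 0 the classes
    coincide.
    """
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    base = TextureClassParams()
    pr = replace(
        base,
        nucleus_density=base.nucleus_density * (1.0 + 0.5 * effect_size),
        speckle_sd=base.speckle_sd + 2.0 * effect_size,
    )
    return base, pr


def _sample_nuclei(
    params: TextureClassParams, size: int, rng: np.random.Generator
) -> list[tuple[float, float, float, float, float]]:
    """Poisson-process nucleus sample: (row, col, r_radius, c_radius, theta)."""
    n = rng.poisson(params.nucleus_density * size * size)
    nuclei = []
    for _ in range(n):
        r, c = rng.uniform(0, size, size=2)
        rr = max(0.8, rng.normal(params.nucleus_radius_mean, params.nucleus_radius_sd))
        cc = max(0.8, rng.normal(params.nucleus_radius_mean, params.nucleus_radius_sd))
        theta = rng.uniform(0, np.pi)
        nuclei.append((r, c, rr, cc, theta))
    return nuclei


def _render(
    params: TextureClassParams,
    size: int,
    rng: np.random.Generator,
    supersample: int = 2,
) -> np.ndarray:
    ss = supersample
    alpha = np.zeros((size * ss, size * ss), dtype=np.float32)
    for r, c, rr, cc, theta in _sample_nuclei(params, size, rng):
        rows, cols = _draw_ellipse(
            r * ss, c * ss, rr * ss, cc * ss, shape=alpha.shape, rotation=theta
        )
        alpha[rows, cols] = 1.0
    # block-mean down to target size -> fractional edge coverage (anti-aliasing)
    alpha = alpha.reshape(size, ss, size, ss).mean(axis=(1, 3))
    bg = np.asarray(params.background_intensity, dtype=np.float64)
    nu = np.asarray(params.nucleus_intensity, dtype=np.float64)
    img = bg[None, None, :] * (1.0 - alpha[..., None]) + nu[None, None, :] * alpha[..., None]
    if params.speckle_sd > 0:
        img = img + rng.normal(0.0, params.speckle_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_tile_image(
    params: TextureClassParams, seed: "int | np.random.SeedSequence | None" = None,
    size: int = 512,
) -> np.ndarray:
    """One ``size`` x ``size`` RGB tile; bit-identical for a fixed seed."""
    rng = np.random.default_rng(seed)
    return _render(params, size, rng)


def generate_pseudo_wsi(
    width: int,
    height: int,
    roi_polygon: np.ndarray,
    params: TextureClassParams,
    seed: "int | None" = None,
):
    """Pseudo whole-slide image: texture inside the polygon, glass outside.

    ``roi_polygon`` is an (n, 2) array of (row, col) vertices at source
    magnification.  Returns ``(image, RoiAnnotation)``; pixels outside
    the polygon are blank white (255), emulating glass/background.
    """
    from .tiling import RoiAnnotation  # local import to avoid a cycle

    poly = np.asarray(roi_polygon, dtype=np.float64)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("roi_polygon must be an (n>=3, 2) array of (row, col)")
    annotation = RoiAnnotation(polygons=[poly], magnification="x400")
    if poly[:, 0].min() < 0 or poly[:, 1].min() < 0:
        raise ValueError("polygon extends outside the image (negative coords)")
    if poly[:, 0].max() > height or poly[:, 1].max() > width:
        raise ValueError("polygon extends outside the image bounds")
    rng = np.random.default_rng(seed)
    size = max(height, width)
    img = _render(params, size, rng)[:height, :width]
    mask = polygon2mask((height, width), poly)
    img = img.copy()
    img[~mask] = 255
    return img, annotation


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study-design knobs of a synthetic cohort.

    Defaults emulate the observed study composition: 151 patients,
    PR prevalence 59/120 (the primary-dataset rate), and 3-6 manually
    selected tumor tiles per patient (667 tiles over 151 patients).
    ``density_jitter_cv`` adds per-tile lognormal variation of nucleus
    density within each class, standing in for intra-class biological
    heterogeneity.
    """

    n_patients: int = 151
    pr_prevalence: float = 59 / 120
    tiles_per_patient_min: int = 3
    tiles_per_patient_max: int = 6
    effect_size: float = 1.0
    tile_size: int = 512
    density_jitter_cv: float = 0.15
    seed: int = 0
    covariate_freqs: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in TABLE1_PRIMARY_MARGINS.items()}
    )

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not (0.0 < self.pr_prevalence < 1.0):
            raise ValueError("pr_prevalence must lie strictly in (0, 1)")
        if self.tiles_per_patient_min < 1:
            raise ValueError("tiles_per_patient_min must be >= 1")
        if self.tiles_per_patient_max < self.tiles_per_patient_min:
            raise ValueError("tiles_per_patient_max < tiles_per_patient_min")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    label: str  # "PR" or "non-PR"
    age: int
    gender: str
    t_stage: str
    n_stage: str
    cea: str
    tile_ids: tuple[str, ...]


def _sample_categorical(rng: np.random.Generator, freqs: dict[str, float]) -> str:
    cats = list(freqs)
    p = np.asarray([freqs[c] for c in cats], dtype=np.float64)
    return cats[rng.choice(len(cats), p=p / p.sum())]


class SyntheticCohort:
    """A generated cohort: patient table plus lazily rendered tile images.

    Tile images are regenerated on demand from counter-derived
    substreams, so a full cohort never has to be held in memory.
    """

    def __init__(self, config: SyntheticCohortConfig):
        self.config = config
        self.params_nonpr, self.params_pr = class_params(config.effect_size)
        self.patients: list[SyntheticPatient] = []
        self._tile_owner: dict[str, tuple[int, int, str]] = {}
        for i in range(config.n_patients):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(0, i))
            )
            label = "PR" if rng.random() < config.pr_prevalence else "non-PR"
            n_tiles = int(
                rng.integers(config.tiles_per_patient_min, config.tiles_per_patient_max + 1)
            )
            pid = f"P{i:03d}"
            tile_ids = tuple(f"{pid}_T{j:02d}" for j in range(n_tiles))
            freqs = config.covariate_freqs
            patient = SyntheticPatient(
                patient_id=pid,
                label=label,
                age=int(np.clip(np.rint(rng.normal(AGE_MEAN, AGE_SD)), 25, 90)),
                gender=_sample_categorical(rng, freqs["gender"]),
                t_stage=_sample_categorical(rng, freqs["t_stage"]),
                n_stage=_sample_categorical(rng, freqs["n_stage"]),
                cea=_sample_categorical(rng, freqs["cea"]),
                tile_ids=tile_ids,
            )
            self.patients.append(patient)
            for j, tid in enumerate(tile_ids):
                self._tile_owner[tid] = (i, j, label)

    @property
    def tile_ids(self) -> list[str]:
        return [tid for p in self.patients for tid in p.tile_ids]

    def tile_params(self, tile_id: str) -> TextureClassParams:
        """Class parameters of one tile, with per-tile density jitter applied."""
        i, j, label = self._tile_owner[tile_id]
        base = self.params_pr if label == "PR" else self.params_nonpr
        cv = self.config.density_jitter_cv
        if cv <= 0:
            return base
        rng = np.random.default_rng(
            np.random.SeedSequence(self.config.seed, spawn_key=(1, i, j, 0))
        )
        sigma = np.sqrt(np.log1p(cv * cv))
        jitter = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
        return replace(base, nucleus_density=base.nucleus_density * jitter)

    def tile_image(self, tile_id: str) -> np.ndarray:
        i, j, _ = self._tile_owner[tile_id]
        params = self.tile_params(tile_id)
        seq = np.random.SeedSequence(self.config.seed, spawn_key=(1, i, j, 1))
        return generate_tile_image(params, seq, size=self.config.tile_size)

    def iter_tiles(self):
        """Yield (tile_id, patient_id, image) over the whole cohort."""
        for p in self.patients:
            for tid in p.tile_ids:
                yield tid, p.patient_id, self.tile_image(tid)

    def patient_table(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": p.patient_id,
                "label": p.label,
                "age": p.age,
                "gender": p.gender,
                "t_stage": p.t_stage,
                "n_stage": p.n_stage,
                "cea": p.cea,
                "tile_ids": ";".join(p.tile_ids),
            }
            for p in self.patients
        ]
        return pd.DataFrame(rows)

    def write(self, outdir, write_images: bool = True) -> None:
        """Write cohort.csv and (optionally) every tile as PNG."""
        from pathlib import Path

        from PIL import Image

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.patient_table().to_csv(outdir / "cohort.csv", index=False)
        if write_images:
            tiles_dir = outdir / "tiles"
            tiles_dir.mkdir(exist_ok=True)
            for tid, _, img in self.iter_tiles():
                Image.fromarray(img).save(tiles_dir / f"{tid}.png")


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Build a cohort per ``config`` (images rendered lazily)."""
    return SyntheticCohort(config)
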