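"""Synthetic data with known ground truth for both analysis engines.

Three generators mirror the study design of a parapatric species pair on a
small coastal strip:

* two smooth habitat-suitability surfaces with partially overlapping optima
  (a Gaussian kernel around each species' environmental optimum, bounded in
  (0, 1] like logistic niche-model output);
* occurrence localities sampled at cell centers, without replacement,
  with probability proportional to suitability — so "unique localities"
  holds by construction and no point ever falls on zero suitability;
* 2-D landmark samples built from a known mean shape plus a common
  allometric vector, an optional sympatric displacement added to one
  species, isotropic landmark noise, and nuisance rotation/translation/scale
  transforms (recorded, so alignment tests can recover the injected shapes).

Every generator is deterministic given its config, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .grids import SuitabilityGrid
from .shape import LandmarkSample, centroid_size

__all__ = [
    "GridSimConfig",
    "MorphoSimConfig",
    "default_mean_shape",
    "gen_suitability_grids",
    "gen_localities",
    "gen_landmark_sample",
]

GROUP_ORDER = ("species_a-allopatric", "species_a-sympatric",
               "species_b-allopatric", "species_b-sympatric")


@dataclass(frozen=True)
class GridSimConfig:
    """Parameters of the two-species suitability landscape.

    Defaults emulate the southern Brazilian coastal plain study window
    (lon 53-47W, lat 34-27S at 0.1 degree cells) with 29 and 45 localities
    for the two species and optima offset along the coast so the suitable
    areas overlap partially.
    """

    n_rows: int = 70
    n_cols: int = 60
    origin_lon: float = -53.0
    origin_lat: float = -34.0
    cell_size: float = 0.1
    optimum_a: tuple[float, float] = (-50.2, -30.0)
    optimum_b: tuple[float, float] = (-50.8, -31.2)
    bandwidth: float = 1.2
    n_localities_a: int = 29
    n_localities_b: int = 45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


def gen_suitability_grids(
        config: GridSimConfig) -> tuple[SuitabilityGrid, SuitabilityGrid]:
    """Two suitability grids on one georeference, Gaussian around each optimum.

    Cell value = exp(-(planar distance from cell center to optimum)^2 /
    bandwidth^2), hence in (0, 1] with 1.0 exactly at an optimum-centered
    cell.  Deterministic (no randomness enters the surfaces).
    """
    grids = []
    for optimum in (config.optimum_a, config.optimum_b):
        proto = SuitabilityGrid(
            np.zeros((config.n_rows, config.n_cols)),
            config.origin_lon, config.origin_lat, config.cell_size)
        lon, lat = proto.cell_centers()
        d2 = (lon - optimum[0]) ** 2 + (lat - optimum[1]) ** 2
        proto.values = np.exp(-d2 / config.bandwidth ** 2)
        grids.append(proto)
    return grids[0], grids[1]


def gen_localities(grid: SuitabilityGrid, n: int, species_label: str,
                   seed: int) -> pd.DataFrame:
    """Sample n occurrence points at cell centers, p proportional to suitability.

    Sampling is without replacement, so returned localities are unique by
    construction; cells with zero or nodata suitability are never drawn.
    """
    values = grid.values
    lon, lat = grid.cell_centers()
    positive = np.isfinite(values) & (values > 0)
    flat_idx = np.nonzero(positive.ravel())[0]
    if n > len(flat_idx):
        raise ValueError(
            f"cannot draw {n} localities from {len(flat_idx)} "
            "positive-suitability cells without replacement")
    if n == 0:
        return pd.DataFrame(columns=["species", "lon", "lat"])
    weights = values.ravel()[flat_idx]
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat_idx, size=n, replace=False,
                        p=weights / weights.sum())
    return pd.DataFrame({
        "species": species_label,
        "lon": lon.ravel()[chosen],
        "lat": lat.ravel()[chosen],
    })


def default_mean_shape(k: int) -> np.ndarray:
    """A k-landmark reference shape: evenly spaced points on an ellipse,
    centered and scaled to unit centroid size (a skull-outline stand-in)."""
    theta = 2 * np.pi * np.arange(k) / k
    shape = np.column_stack([np.cos(theta), 0.6 * np.sin(theta)])
    shape -= shape.mean(axis=0)
    return shape / centroid_size(shape)


def _tangent_unit_vector(rng: np.random.Generator, mean_shape: np.ndarray,
                         k: int) -> np.ndarray:
    """Random unit 2k-vector representing a pure shape change.

    Projected to have zero centroid shift per coordinate axis and no
    component along the mean shape, so adding it to the mean changes neither
    position nor (to first order) centroid size — the injected magnitude is
    then recovered exactly by alignment.
    """
    v = rng.standard_normal(2 * k)
    v = v.reshape(k, 2)
    v -= v.mean(axis=0)
    v = v.ravel()
    m = mean_shape.ravel()
    v -= (v @ m) / (m @ m) * m
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class MorphoSimConfig:
    """Parameters of the four-group landmark sample.

    Defaults emulate the skull series behind the displacement analysis:
    30 landmarks, group sizes (22, 17, 24, 22) for speciesA-allopatric,
    speciesA-sympatric, speciesB-allopatric, speciesB-sympatric (85 skulls),
    centroid sizes around 9.7 +/- 0.7, and magnitudes chosen so simulated
    group mean-shape distances fall in the low-10^-2 range typical of
    congeneric skulls.  ``delta`` shifts the speciesB-sympatric mean along
    ``displacement_vector``; delta = 0 is the no-displacement null.  When
    ``mean_shape``, ``allometric_vector`` or ``displacement_vector`` is None
    a deterministic default is derived from the seed.
    """

    k_landmarks: int = 30
    mean_shape: np.ndarray | None = None
    allometric_vector: np.ndarray | None = None
    displacement_vector: np.ndarray | None = None
    delta: float = 0.03
    cs_mean: float = 9.7
    cs_sd: float = 0.7
    noise_sd: float = 0.01
    group_sizes: tuple[int, int, int, int] = (22, 17, 24, 22)
    seed: int = 0
    with_size_covariates: bool = True
    max_retries: int = 10

    def __post_init__(self) -> None:
        if self.k_landmarks < 3:
            raise ValueError("need at least 3 landmarks")
        if min(self.group_sizes) < 2:
            raise ValueError("all four group sizes must be >= 2")
        if self.cs_mean <= 0 or self.cs_sd <= 0:
            raise ValueError("centroid-size parameters must be positive")
        if self.delta < 0 or self.noise_sd < 0:
            raise ValueError("delta and noise_sd must be non-negative")
        if self.mean_shape is not None:
            ms = np.asarray(self.mean_shape, dtype=float)
            if ms.shape != (self.k_landmarks, 2):
                raise ValueError("mean_shape must be (k_landmarks, 2)")
            if np.abs(ms.mean(axis=0)).max() > 1e-9:
                raise ValueError("mean_shape centroid must be at the origin")
            if abs(centroid_size(ms) - 1.0) > 1e-9:
                raise ValueError("mean_shape must have unit centroid size")


def gen_landmark_sample(config: MorphoSimConfig) -> LandmarkSample:
    """Draw the four-group landmark sample with recorded nuisance transforms.

    Per specimen: centroid size CS from a normal law truncated at CS > 0;
    shape vector = mean_shape + allometric_vector * (CS - cs_mean)
    (+ delta * displacement_vector for speciesB-sympatric specimens)
    + isotropic N(0, noise_sd) landmark noise; the configuration is scaled
    to CS, rotated by a random angle and translated.  The injected shapes,
    rotations and translations are kept in ``sample.nuisance`` so alignment
    tests can compare recovered against injected shape.
    """
    k = config.k_landmarks
    rng = np.random.default_rng(config.seed)
    mean_shape = (np.asarray(config.mean_shape, dtype=float)
                  if config.mean_shape is not None else default_mean_shape(k))
    if config.allometric_vector is not None:
        allo = np.asarray(config.allometric_vector, dtype=float).ravel()
    else:
        allo = 0.005 * _tangent_unit_vector(rng, mean_shape, k)
    if config.displacement_vector is not None:
        disp = np.asarray(config.displacement_vector, dtype=float).ravel()
    else:
        disp = _tangent_unit_vector(rng, mean_shape, k)
    if allo.size != 2 * k or disp.size != 2 * k:
        raise ValueError("allometric/displacement vectors must have length 2k")

    n = sum(config.group_sizes)
    labels = np.repeat(GROUP_ORDER, config.group_sizes)
    a, b = (-config.cs_mean / config.cs_sd), np.inf  # truncate at CS > 0
    cs = truncnorm.rvs(a, b, loc=config.cs_mean, scale=config.cs_sd,
                       size=n, random_state=rng)

    coords = np.empty((n, k, 2))
    true_shapes = np.empty((n, k, 2))
    angles = rng.uniform(0, 2 * np.pi, size=n)
    translations = rng.uniform(-10, 10, size=(n, 2))
    for i in range(n):
        for _ in range(config.max_retries):
            shape = mean_shape.ravel() + allo * (cs[i] - config.cs_mean)
            if labels[i] == "species_b-sympatric":
                shape = shape + config.delta * disp
            shape = shape + rng.normal(0.0, config.noise_sd, size=2 * k)
            shape = shape.reshape(k, 2)
            shape -= shape.mean(axis=0)
            size = centroid_size(shape)
            if size > 1e-9:
                break
        else:
            raise RuntimeError(
                f"specimen {i}: configuration degenerated to zero centroid "
                f"size after {config.max_retries} retries")
        true_shapes[i] = shape / size
        c, s = np.cos(angles[i]), np.sin(angles[i])
        rot = np.array([[c, -s], [s, c]])
        coords[i] = (true_shapes[i] * cs[i]) @ rot.T + translations[i]

    species = np.array([lab.split("-")[0] for lab in labels])
    context = np.array([lab.split("-")[1] for lab in labels])
    skull_length = body_mass = None
    if config.with_size_covariates:
        skull_length = 50.0 * cs + rng.normal(0, 10.0, size=n)
        body_mass = 25.0 * cs + rng.normal(0, 30.0, size=n)
    return LandmarkSample(
        coords=coords,
        ids=[f"sim_{i:03d}" for i in range(n)],
        species=species,
        context=context,
        skull_length=skull_length,
        body_mass=body_mass,
        nuisance={
            "true_shapes": true_shapes,
            "centroid_sizes": cs,
            "angles": angles,
            "translations": translations,
            "mean_shape": mean_shape,
            "allometric_vector": allo,
            "displacement_vector": disp,
        },
    )
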