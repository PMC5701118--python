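"""Landmark I/O, generalized Procrustes superimposition and allometry.

Shape analysis works on configurations of k homologous 2-D landmarks per
specimen.  Generalized Procrustes Analysis (GPA) removes the non-shape
effects — position, orientation and scale — leaving each specimen as a point
in a linearized (tangent) shape space at the consensus; centroid size is kept
alongside as the size measure.  Allometry, the dependence of shape on size,
is removed by regressing every shape variable on centroid size and keeping
the residuals.

The estimators follow the scikit-learn protocol (``fit`` / ``transform``,
fitted attributes with a trailing underscore) so the whole chain composes
with sklearn pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, TextIO

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "LandmarkSample",
    "AlignedSample",
    "AllometryModel",
    "read_tps",
    "write_tps",
    "load_landmark_sample",
    "centroid_size",
    "GeneralizedProcrustes",
    "AllometryRegression",
    "gpa_align",
    "allometry_correct",
]


@dataclass
class LandmarkSample:
    """An ordered collection of k-landmark 2-D configurations.

    ``coords`` has shape (n_specimens, k, 2).  ``species`` and ``context``
    (sympatric / allopatric) may be None when no metadata accompanies the
    landmarks.  ``scale`` factors from TPS SCALE= lines are already applied.
    """

    coords: np.ndarray
    ids: list[str]
    species: np.ndarray | None = None
    context: np.ndarray | None = None
    skull_length: np.ndarray | None = None
    body_mass: np.ndarray | None = None
    nuisance: dict | None = None  # simulator-recorded transforms, for oracles

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("coords must have shape (n, k, 2)")
        if self.coords.shape[1] < 3:
            raise ValueError("need at least 3 landmarks")
        if not np.isfinite(self.coords).all():
            raise ValueError("landmark coordinates must be finite")
        if len(self.ids) != len(self.coords):
            raise ValueError("ids and coords length mismatch")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def k_landmarks(self) -> int:
        return self.coords.shape[1]

    def group_labels(self) -> np.ndarray:
        """Four-level group factor 'species-context' per specimen."""
        if self.species is None or self.context is None:
            raise ValueError("sample has no species/context metadata")
        return np.array([f"{s}-{c}" for s, c in zip(self.species, self.context)])


@dataclass
class AlignedSample:
    """Output of GPA: superimposed shapes plus size and diagnostics."""

    aligned: np.ndarray          # (n, k, 2), centered, unit centroid size
    consensus: np.ndarray        # (k, 2), unit centroid size
    centroid_sizes: np.ndarray   # (n,)
    n_iter: int
    final_change: float
    sample: LandmarkSample | None = None

    def shape_matrix(self) -> np.ndarray:
        """Shape variables as an (n, 2k) matrix (x1,y1,...,xk,yk)."""
        return self.aligned.reshape(self.aligned.shape[0], -1)


@dataclass
class AllometryModel:
    """Pooled multivariate regression of shape on centroid size."""

    slope_vector: np.ndarray       # (2k,)
    intercept_vector: np.ndarray   # (2k,)
    percent_predicted: float       # % of total shape SS explained by size
    residuals: np.ndarray          # (n, 2k), deviations re-added around mean
    provenance: str = "allometry-residual"


# ---------------------------------------------------------------------------
# TPS format


def read_tps(source: str | Path | TextIO) -> LandmarkSample:
    """Parse a TPS landmark file into a LandmarkSample.

    Each block is an ``LM=k`` line, k coordinate lines, then optional
    ``ID=``, ``IMAGE=`` and ``SCALE=`` lines; SCALE multiplies the stored
    coordinates once.  Species/context metadata come from a sidecar CSV via
    :func:`load_landmark_sample`.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    configs: list[np.ndarray] = []
    ids: list[str] = []
    scales: list[float] = []
    i, block = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise ValueError(f"TPS block {block}: expected LM=, got {line!r}")
        k = int(line.split("=", 1)[1])
        coords = []
        i += 1
        while i < len(lines) and len(coords) < k:
            parts = lines[i].split()
            if len(parts) != 2:
                raise ValueError(
                    f"TPS block {block}: expected {k} coordinate lines, "
                    f"found {len(coords)} before {lines[i]!r}")
            coords.append([float(parts[0]), float(parts[1])])
            i += 1
        if len(coords) != k:
            raise ValueError(f"TPS block {block}: LM={k} but file ended after "
                             f"{len(coords)} coordinate lines")
        spec_id, scale = f"specimen_{block}", 1.0
        while i < len(lines):
            line = lines[i].strip()
            if not line:
                i += 1
                continue
            key, _, value = line.partition("=")
            key = key.upper()
            if key == "LM":
                break
            if key == "ID":
                spec_id = value.strip()
            elif key == "SCALE":
                scale = float(value)
            elif key != "IMAGE":
                raise ValueError(f"TPS block {block}: unknown line {line!r}")
            i += 1
        configs.append(np.asarray(coords) * scale)
        ids.append(spec_id)
        scales.append(scale)
        block += 1
    if not configs:
        raise ValueError("TPS file contains no landmark blocks")
    ks = {c.shape[0] for c in configs}
    if len(ks) > 1:
        raise ValueError(f"inconsistent landmark counts across blocks: {ks}")
    return LandmarkSample(np.stack(configs), ids)


def write_tps(sample: LandmarkSample, sink: str | Path | TextIO) -> None:
    """Write a LandmarkSample as TPS (coordinates already scale-applied)."""
    chunks = []
    for config, spec_id in zip(sample.coords, sample.ids):
        chunks.append(f"LM={config.shape[0]}")
        for x, y in config:
            chunks.append(f"{float(x)!r} {float(y)!r}")
        chunks.append(f"ID={spec_id}")
    text = "\n".join(chunks) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text)


def load_landmark_sample(tps_source, metadata_source) -> LandmarkSample:
    """Read TPS landmarks and join the sidecar metadata CSV by specimen id.

    The CSV needs columns id,species,context; skull_length and body_mass are
    optional.  Every specimen in the TPS file must appear in the metadata.
    """
    sample = read_tps(tps_source)
    meta = pd.read_csv(metadata_source, dtype={"id": str})
    for col in ("id", "species", "context"):
        if col not in meta.columns:
            raise ValueError(f"metadata CSV missing column {col!r}")
    meta = meta.set_index("id")
    missing = [sid for sid in sample.ids if sid not in meta.index]
    if missing:
        raise ValueError(f"metadata missing for specimens: {missing}")
    rows = meta.loc[sample.ids]
    sample.species = rows["species"].to_numpy()
    sample.context = rows["context"].to_numpy()
    for col in ("skull_length", "body_mass"):
        if col in rows.columns:
            setattr(sample, col, rows[col].to_numpy(dtype=float))
    return sample


# ---------------------------------------------------------------------------
# Size and superimposition


def centroid_size(coords: np.ndarray) -> float | np.ndarray:
    """Square root of summed squared landmark distances from the centroid.

    Accepts one (k, 2) configuration or a stack (n, k, 2); scales linearly
    with the configuration and is invariant to rotation and translation.
    """
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=-2, keepdims=True)
    cs = np.sqrt((centered ** 2).sum(axis=(-2, -1)))
    return float(cs) if cs.ndim == 0 else cs


def _as_configs(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] % 2:
            raise ValueError("flattened shapes need an even column count")
        X = X.reshape(X.shape[0], -1, 2)
    if X.ndim != 3 or X.shape[2] != 2:
        raise ValueError("expected (n, k, 2) or (n, 2k) landmark data")
    return X


def _optimal_rotation(config: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix aligning ``config`` to ``target`` (least squares).

    Reflections are disallowed (determinant forced positive): specimens are
    digitized in a consistent orientation, so an improper fit is an error of
    the data, not a valid superimposition.
    """
    u, _, vt = np.linalg.svd(config.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


class GeneralizedProcrustes(BaseEstimator, TransformerMixin):
    """Generalized Procrustes Analysis for 2-D landmark configurations.

    ``fit`` runs the iterative superimposition on the training sample:
    each configuration is centered and scaled to unit centroid size (full
    Procrustes), rotated to the current consensus by the SVD solution, and
    the consensus is re-estimated as the landmark-wise mean rescaled to unit
    centroid size, until the consensus moves less than ``tol``
    (root-sum-square) or ``max_iter`` is reached.  The Procrustes objective
    (summed squared distance to the consensus) is checked to be
    non-increasing at every iteration.

    ``transform`` superimposes configurations onto the fitted consensus and
    returns the (n, 2k) matrix of tangent-space shape variables.

    Parameters
    ----------
    tol : float, consensus-change convergence threshold (default 1e-10).
    max_iter : int, iteration cap (default 100).

    Attributes
    ----------
    consensus_ : (k, 2) mean shape, unit centroid size.
    aligned_ : (n, k, 2) superimposed training configurations.
    centroid_sizes_ : (n,) centroid sizes of the raw training configurations.
    n_iter_ : iterations used.  final_change_ : last consensus change.
    sse_path_ : per-iteration Procrustes objective values.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None):
        configs = _as_configs(X)
        n = configs.shape[0]
        if n < 2:
            raise ValueError("GPA needs at least 2 specimens")
        cs = centroid_size(configs)
        if np.any(cs <= 0):
            bad = np.nonzero(cs <= 0)[0].tolist()
            raise ValueError(f"degenerate configurations (zero centroid size) "
                             f"at indices {bad}")
        unit = (configs - configs.mean(axis=1, keepdims=True)) \
            / cs[:, None, None]

        consensus = unit[0].copy()
        aligned = unit.copy()
        sse_path: list[float] = []
        n_iter, change = 0, np.inf
        for n_iter in range(1, self.max_iter + 1):
            for i in range(n):
                aligned[i] = unit[i] @ _optimal_rotation(unit[i], consensus)
            sse = float(((aligned - consensus) ** 2).sum())
            if sse_path and sse > sse_path[-1] + 1e-12 * (1.0 + sse_path[-1]):
                raise AssertionError(
                    "GPA objective increased: "
                    f"{sse_path[-1]} -> {sse} at iteration {n_iter}")
            sse_path.append(sse)
            mean = aligned.mean(axis=0)
            new_consensus = mean / centroid_size(mean)
            change = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
            consensus = new_consensus
            if change < self.tol:
                break
        # final pass so every specimen is aligned to the converged consensus
        for i in range(n):
            aligned[i] = unit[i] @ _optimal_rotation(unit[i], consensus)

        self.consensus_ = consensus
        self.aligned_ = aligned
        self.centroid_sizes_ = cs
        self.n_iter_ = n_iter
        self.final_change_ = change
        self.sse_path_ = np.asarray(sse_path)
        return self

    def transform(self, X) -> np.ndarray:
        configs = _as_configs(X)
        cs = centroid_size(configs)
        if np.any(cs <= 0):
            raise ValueError("degenerate configuration in transform input")
        unit = (configs - configs.mean(axis=1, keepdims=True)) \
            / cs[:, None, None]
        out = np.empty_like(unit)
        for i in range(len(unit)):
            out[i] = unit[i] @ _optimal_rotation(unit[i], self.consensus_)
        return out.reshape(len(out), -1)

    def fit_transform(self, X, y=None, **fit_params) -> np.ndarray:
        self.fit(X)
        return self.aligned_.reshape(len(self.aligned_), -1)


class AllometryRegression(BaseEstimator, TransformerMixin):
    """Pooled OLS of every shape variable on centroid size.

    ``fit(X, sizes)`` regresses each of the 2k aligned coordinates on
    centroid size across all specimens (pooled over species and contexts).
    ``transform(X, sizes)`` returns the size-corrected shape matrix: the
    regression residuals re-added around the fitted mean shape, so corrected
    shapes live in the same coordinates as the input.

    Attributes
    ----------
    slope_ : (2k,) allometric vector (shape change per unit centroid size).
    intercept_ : (2k,).
    mean_shape_ : (2k,) column means of the training shape matrix.
    percent_predicted_ : share (0-100) of total shape sum of squares
        explained by size.
    """

    def fit(self, X, sizes):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected an (n, 2k) shape matrix")
        sizes = np.asarray(sizes, dtype=float)
        if len(sizes) != len(X):
            raise ValueError("sizes length must match specimen count")
        if len(X) < 3:
            raise ValueError("allometry regression needs >= 3 specimens")
        s_centered = sizes - sizes.mean()
        ss_size = float(s_centered @ s_centered)
        if ss_size <= 0:
            raise ValueError("centroid sizes have zero variance; use the "
                             "raw aligned shapes instead")
        self.mean_shape_ = X.mean(axis=0)
        Xc = X - self.mean_shape_
        self.slope_ = (s_centered @ Xc) / ss_size
        self.intercept_ = self.mean_shape_ - self.slope_ * sizes.mean()
        predicted = np.outer(s_centered, self.slope_)
        ss_total = float((Xc ** 2).sum())
        ss_pred = float((predicted ** 2).sum())
        self.percent_predicted_ = 100.0 * ss_pred / ss_total if ss_total else 0.0
        self.sizes_mean_ = float(sizes.mean())
        return self

    def transform(self, X, sizes=None) -> np.ndarray:
        if sizes is None:
            raise ValueError("transform needs the centroid sizes")
        X = np.asarray(X, dtype=float)
        sizes = np.asarray(sizes, dtype=float)
        fitted = self.intercept_ + np.outer(sizes, self.slope_)
        return X - fitted + self.mean_shape_

    def fit_transform(self, X, sizes=None, **fit_params) -> np.ndarray:
        self.fit(X, sizes)
        return self.transform(X, sizes)


# ---------------------------------------------------------------------------
# Functional wrappers


def gpa_align(sample: LandmarkSample | np.ndarray, tol: float = 1e-10,
              max_iter: int = 100) -> AlignedSample:
    """Run GPA on a sample and return the aligned bundle."""
    src = sample if isinstance(sample, LandmarkSample) else None
    coords = sample.coords if src is not None else np.asarray(sample)
    gpa = GeneralizedProcrustes(tol=tol, max_iter=max_iter).fit(coords)
    return AlignedSample(
        aligned=gpa.aligned_,
        consensus=gpa.consensus_,
        centroid_sizes=gpa.centroid_sizes_,
        n_iter=gpa.n_iter_,
        final_change=gpa.final_change_,
        sample=src,
    )


def allometry_correct(aligned: AlignedSample) -> AllometryModel:
    """Fit the pooled allometry regression and return the residual shapes."""
    X = aligned.shape_matrix()
    model = AllometryRegression().fit(X, aligned.centroid_sizes)
    residuals = model.transform(X, aligned.centroid_sizes)
    return AllometryModel(
        slope_vector=model.slope_,
        intercept_vector=model.intercept_,
        percent_predicted=model.percent_predicted_,
        residuals=residuals,
    )
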