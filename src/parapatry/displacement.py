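"""Group-level tests of character displacement in shape space.

All statistics operate on the common tangent-space shape matrix produced by
GPA (optionally allometry-corrected) with a four-level grouping factor:
speciesA-allopatric, speciesA-sympatric, speciesB-allopatric,
speciesB-sympatric.

* size ANOVA: one-way ANOVA with Tukey HSD contrasts on scalar size measures
  (centroid size, skull length, body mass);
* between-group PCA: rotation of shape space onto the principal axes of the
  (unweighted) group means — an ordination that, unlike canonical variate
  analysis, does not distort distances;
* Procrustes distances between group mean shapes, with permutation tests;
* the displacement test: observed d_sym - d_allo (inter-species mean-shape
  distance in sympatry minus in allopatry) against a null built by
  reshuffling the sympatric/allopatric labels within each species.

Resampling p-values use the add-one convention p = (b + 1) / (B + 1), so a
resampling p-value is never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "SizeAnovaResult",
    "DistanceTestResult",
    "DisplacementResult",
    "size_anova",
    "group_mean_shapes",
    "procrustes_distance",
    "permutation_mean_test",
    "BetweenGroupPCA",
    "bg_pca",
    "displacement_bootstrap",
]


@dataclass
class SizeAnovaResult:
    measure: str
    F: float
    df_between: int
    df_within: int
    p: float
    tukey: pd.DataFrame  # columns: group1, group2, meandiff, p_adj


@dataclass(frozen=True)
class DistanceTestResult:
    group_a: str
    group_b: str
    D: float
    n_perm: int
    p: float
    seed: int


@dataclass(frozen=True)
class DisplacementResult:
    d_sym: float
    d_allo: float
    d_diff: float
    n_boot: int
    p: float
    seed: int


def size_anova(values, labels, measure: str = "size",
               with_tukey: bool = True) -> SizeAnovaResult:
    """One-way ANOVA across group levels plus Tukey HSD pairwise contrasts.

    NaN values (e.g. specimens lacking a body-mass record) are dropped.
    Groups left with fewer than 2 observations are excluded from the Tukey
    table with a warning.  ``with_tukey=False`` skips the pairwise table
    (useful in calibration loops).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    levels = [g for g in pd.unique(labels)]
    groups = [values[labels == g] for g in levels]
    if len(levels) < 2:
        raise ValueError("ANOVA needs at least two non-empty groups")
    df_between = len(levels) - 1
    df_within = len(values) - len(levels)
    constant = np.allclose(values, values[0])
    if constant:
        F, p = 0.0, 1.0  # no variance anywhere: F is 0/0, define as no effect
    else:
        F, p = stats.f_oneway(*groups)

    if not with_tukey:
        return SizeAnovaResult(
            measure, float(F), df_between, df_within, float(p),
            pd.DataFrame(columns=["group1", "group2", "meandiff", "p_adj"]))

    small = [g for g, v in zip(levels, groups) if len(v) < 2]
    if small:
        warnings.warn(f"groups excluded from Tukey (n < 2): {small}",
                      stacklevel=2)
    keep_tukey = ~np.isin(labels, small)
    if constant:
        pairs = list(combinations(pd.unique(labels[keep_tukey]), 2))
        tukey = pd.DataFrame(
            [{"group1": a, "group2": b, "meandiff": 0.0, "p_adj": 1.0}
             for a, b in pairs])
    elif len(pd.unique(labels[keep_tukey])) >= 2:
        res = pairwise_tukeyhsd(values[keep_tukey], labels[keep_tukey])
        tukey = pd.DataFrame(
            res.summary().data[1:],
            columns=[str(c) for c in res.summary().data[0]],
        )[["group1", "group2", "meandiff", "p-adj"]].rename(
            columns={"p-adj": "p_adj"})
    else:
        tukey = pd.DataFrame(columns=["group1", "group2", "meandiff", "p_adj"])
    return SizeAnovaResult(measure, float(F), df_between, df_within,
                           float(p), tukey)


def group_mean_shapes(shapes: np.ndarray, labels) -> dict[str, np.ndarray]:
    """Column-wise mean shape per group, keyed by label (insertion order)."""
    shapes = np.asarray(shapes, dtype=float)
    labels = np.asarray(labels)
    means = {}
    for g in pd.unique(labels):
        members = shapes[labels == g]
        if len(members) == 0:
            raise ValueError(f"group {g!r} is empty")
        means[g] = members.mean(axis=0)
    return means


def procrustes_distance(mean_a: np.ndarray, mean_b: np.ndarray) -> float:
    """Distance between two commonly-superimposed shapes.

    Root-sum-square of coordinate-wise differences in the shared GPA/tangent
    frame; the shapes are *not* re-superimposed pairwise, preserving the
    distances of the common alignment.
    """
    a = np.asarray(mean_a, dtype=float).ravel()
    b = np.asarray(mean_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("shapes have different landmark counts")
    return float(np.sqrt(((a - b) ** 2).sum()))


def permutation_mean_test(shapes: np.ndarray, labels, group_a: str,
                          group_b: str, n_perm: int = 10_000,
                          seed: int = 0,
                          exact: bool = False) -> DistanceTestResult:
    """Permutation test of the mean-shape distance between two groups.

    The statistic is the Procrustes distance between the two group means;
    the null shuffles the specimens of the two groups across the two labels
    (group sizes preserved) ``n_perm`` times.  p = (#{D* >= D} + 1) /
    (n_perm + 1).  With ``exact=True`` every distinct assignment of
    specimens to the first group is enumerated instead (feasible for small
    samples) and p is the exact proportion of assignments with D* >= D;
    the observed assignment is one of them, so p > 0.
    """
    shapes = np.asarray(shapes, dtype=float)
    labels = np.asarray(labels)
    ia = np.nonzero(labels == group_a)[0]
    ib = np.nonzero(labels == group_b)[0]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("both groups need at least 2 specimens")
    pool = shapes[np.concatenate([ia, ib])]
    na = len(ia)
    observed = procrustes_distance(pool[:na].mean(axis=0),
                                   pool[na:].mean(axis=0))
    if exact:
        splits = list(combinations(range(len(pool)), na))
        count = 0
        for split in splits:
            in_a = np.zeros(len(pool), dtype=bool)
            in_a[list(split)] = True
            d = procrustes_distance(pool[in_a].mean(axis=0),
                                    pool[~in_a].mean(axis=0))
            if d >= observed - 1e-12:
                count += 1
        return DistanceTestResult(group_a, group_b, observed, len(splits),
                                  count / len(splits), seed)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pool))
        d = procrustes_distance(pool[perm[:na]].mean(axis=0),
                                pool[perm[na:]].mean(axis=0))
        if d >= observed - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return DistanceTestResult(group_a, group_b, observed, n_perm, p, seed)


def pairwise_mean_tests(shapes: np.ndarray, labels, n_perm: int = 10_000,
                        seed: int = 0) -> list[DistanceTestResult]:
    """All pairwise permutation mean tests (6 pairs for four groups)."""
    levels = list(pd.unique(np.asarray(labels)))
    ss = np.random.SeedSequence(seed).spawn(
        len(list(combinations(levels, 2))))
    out = []
    for child, (a, b) in zip(ss, combinations(levels, 2)):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        out.append(permutation_mean_test(shapes, labels, a, b,
                                         n_perm=n_perm, seed=sub_seed))
    return out


class BetweenGroupPCA(BaseEstimator, TransformerMixin):
    """Between-group PCA: principal axes of the group mean shapes.

    The axes are the eigenvectors of the covariance of the *unweighted*
    group means (each group counts once); all specimens are then projected
    onto them.  Because the projection is an orthonormal rotation of shape
    space, inter-specimen distances within the retained subspace are
    distances of the original space — no distortion, in contrast to
    canonical variate analysis.  At most (number of groups - 1) axes have
    nonzero between-mean variance and are retained.

    Attributes
    ----------
    components_ : (m, 2k) orthonormal axes.
    group_means_ : dict label -> (2k,) mean.
    explained_variance_ratio_ : share of *total specimen* variance captured
        by each axis (sums to < 1 in general).
    mean_ : (2k,) grand mean of specimens used for centering scores.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X, y=None):
        if y is None:
            raise ValueError("BetweenGroupPCA requires group labels y")
        X = np.asarray(X, dtype=float)
        labels = np.asarray(y)
        means = group_mean_shapes(X, labels)
        if len(means) < 2:
            raise ValueError("between-group PCA needs >= 2 groups")
        M = np.stack(list(means.values()))
        Mc = M - M.mean(axis=0)
        # eigenvectors of the group-mean covariance via SVD of centered means
        _, s, vt = np.linalg.svd(Mc, full_matrices=False)
        nonzero = s > 1e-12 * max(1.0, s.max())
        m = int(nonzero.sum())
        if self.n_components is not None:
            m = min(m, self.n_components)
        self.components_ = vt[:m]
        self.group_means_ = means
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        total_var = float((Xc ** 2).sum())
        scores = Xc @ self.components_.T
        axis_ss = (scores ** 2).sum(axis=0)
        self.explained_variance_ratio_ = (
            axis_ss / total_var if total_var > 0 else np.zeros(m))
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def axis_deformations(self, scale: float | None = None) -> list:
        """Consensus +/- an excursion along each axis, as (k, 2) shape pairs.

        The default excursion is the root-mean-square score on the axis.
        """
        shapes = []
        for j, axis in enumerate(self.components_):
            if scale is None:
                sc = float(np.sqrt(
                    np.mean((self.transform(
                        np.stack(list(self.group_means_.values())))[:, j]) ** 2)))
            else:
                sc = scale
            plus = (self.mean_ + sc * axis).reshape(-1, 2)
            minus = (self.mean_ - sc * axis).reshape(-1, 2)
            shapes.append((minus, plus))
        return shapes


@dataclass
class BGPCAResult:
    axes: np.ndarray
    scores: np.ndarray
    percent_variance: np.ndarray
    group_means: dict


def bg_pca(shapes: np.ndarray, labels) -> BGPCAResult:
    """Functional wrapper around :class:`BetweenGroupPCA`."""
    est = BetweenGroupPCA().fit(shapes, labels)
    return BGPCAResult(
        axes=est.components_,
        scores=est.transform(shapes),
        percent_variance=100.0 * est.explained_variance_ratio_,
        group_means=est.group_means_,
    )


def _parse_groups(labels) -> tuple[np.ndarray, np.ndarray]:
    """Split 'species-context' labels into species and context arrays."""
    species, context = [], []
    for lab in labels:
        sp, _, ctx = str(lab).rpartition("-")
        if ctx not in ("sympatric", "allopatric") or not sp:
            raise ValueError(
                f"label {lab!r} is not of the form species-sympatric/"
                "species-allopatric")
        species.append(sp)
        context.append(ctx)
    return np.asarray(species), np.asarray(context)


def _d_diff(shapes: np.ndarray, species: np.ndarray,
            context: np.ndarray) -> tuple[float, float, float]:
    sp_levels = pd.unique(species)
    if len(sp_levels) != 2:
        raise ValueError("displacement test needs exactly two species")
    a, b = sp_levels
    means = {}
    for sp in (a, b):
        for ctx in ("sympatric", "allopatric"):
            members = shapes[(species == sp) & (context == ctx)]
            if len(members) == 0:
                raise ValueError(f"group {sp}-{ctx} is empty")
            means[sp, ctx] = members.mean(axis=0)
    d_sym = procrustes_distance(means[a, "sympatric"], means[b, "sympatric"])
    d_allo = procrustes_distance(means[a, "allopatric"],
                                 means[b, "allopatric"])
    return d_sym, d_allo, d_sym - d_allo


def displacement_bootstrap(shapes: np.ndarray, labels, n_boot: int = 1_000,
                           seed: int = 0) -> DisplacementResult:
    """Test whether inter-species shape divergence is larger in sympatry.

    The statistic is d_diff = d_sym - d_allo, the Procrustes distance
    between the two species' mean shapes in sympatry minus the same distance
    in allopatry.  The null reshuffles the sympatric/allopatric labels
    *within each species independently* (group sizes preserved; specimens
    never move between species) and recomputes d_diff ``n_boot`` times;
    p = (#{d_diff* >= d_diff} + 1) / (n_boot + 1).  Symmetric in the two
    species by construction.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    shapes = np.asarray(shapes, dtype=float)
    species, context = _parse_groups(np.asarray(labels))
    d_sym, d_allo, observed = _d_diff(shapes, species, context)
    rng = np.random.default_rng(seed)
    sp_levels = pd.unique(species)
    idx = {sp: np.nonzero(species == sp)[0] for sp in sp_levels}
    count = 0
    ctx_null = context.copy()
    for _ in range(n_boot):
        for sp in sp_levels:
            members = idx[sp]
            ctx_null[members] = context[members][rng.permutation(len(members))]
        _, _, d = _d_diff(shapes, species, ctx_null)
        if d >= observed - 1e-12:
            count += 1
    p = (count + 1) / (n_boot + 1)
    return DisplacementResult(d_sym, d_allo, observed, n_boot, p, seed)
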