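"""Per-view data depths: the agnostic radiomic profile of a lesion.

Each lesion is re-expressed as a 6-vector of data depths, one per semantic
feature view, measuring how central the lesion's feature sub-vector is with
respect to the pooled cohort of all lesions. The default depth is the
Mahalanobis depth

    MD(x) = 1 / (1 + (x - mu)' Sigma^{-1} (x - mu)),

with ``mu``/``Sigma`` the cohort-wide sample mean/covariance of the view.
Spatial and (approximate) projection depths are provided for comparison;
exact halfspace depth is omitted for combinatorial cost, projection depth
standing in for it. Depths are affine invariant (Mahalanobis exactly; the
others after robust standardisation), which is what makes the profile
"agnostic": scanner- or software-specific feature scalings cancel out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .core_model_io import CohortDataset, FeatureGroupMap, LesionRecord

logger = logging.getLogger("lesionforest")

DepthKind = Literal["mahalanobis", "spatial", "projection"]

#: Condition-number ceiling above which the covariance is ridge-regularised.
COND_THRESHOLD = 1e8
#: Base ridge, in units of trace(Sigma)/d; escalated x10 until well-conditioned.
BASE_RIDGE = 1e-8


@dataclass
class ViewReference:
    """Location/scatter of one view fitted on the pooled cohort of lesions."""

    view: str
    feature_names: tuple[str, ...]
    mean: np.ndarray
    covariance: np.ndarray
    regularization: float
    n_fit: int

    def __post_init__(self) -> None:
        self._chol = cho_factor(self.covariance)

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    def squared_mahalanobis(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != self.mean.shape:
            raise ValueError(
                f"dimension mismatch: x has shape {x.shape}, "
                f"reference {self.view!r} expects {self.mean.shape}"
            )
        diff = x - self.mean
        return float(diff @ cho_solve(self._chol, diff))


@dataclass
class DepthProfile:
    """The 6 per-view depth values forming a lesion's agnostic profile."""

    patient_id: str
    lesion_id: str
    depths: np.ndarray  # ordered as FeatureGroupMap.view_names


def _view_matrix(
    lesions: Sequence[LesionRecord], view: str, group_map: FeatureGroupMap
) -> tuple[np.ndarray, tuple[str, ...]]:
    names = group_map.features_in_view(view)
    X = np.array([[l.features[f] for f in names] for l in lesions], dtype=float)
    return X, names


def fit_view_reference(
    lesions: Sequence[LesionRecord],
    view: str,
    group_map: FeatureGroupMap | None = None,
    ridge: bool = True,
) -> ViewReference:
    """Fit the cohort-wide mean and covariance of one view.

    The covariance uses denominator ``n - 1``. If its condition number
    exceeds :data:`COND_THRESHOLD`, a ridge ``eps * trace(Sigma)/d`` is added
    to the diagonal, with ``eps`` starting at :data:`BASE_RIDGE` and escalated
    tenfold until the matrix is well conditioned; every escalation is logged
    and the final ridge is recorded on the reference. With ``ridge=False`` a
    singular view raises an error naming its constant feature(s).
    """
    group_map = group_map or FeatureGroupMap.default()
    if len(lesions) < 2:
        raise ValueError("need at least two lesions to fit a view reference")
    X, names = _view_matrix(lesions, view, group_map)
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)

    d = cov.shape[0]
    constant = [names[j] for j in range(d) if np.isclose(cov[j, j], 0.0)]
    scale = cov.trace() / d
    if scale <= 0:
        # Every feature constant: fall back to an absolute unit ridge scale.
        scale = 1.0
    eps = 0.0
    cov_reg = cov
    while np.linalg.cond(cov_reg) > COND_THRESHOLD:
        if not ridge:
            raise ValueError(
                f"singular covariance in view {view!r}"
                + (f"; constant feature(s): {constant}" if constant else "")
            )
        eps = BASE_RIDGE if eps == 0.0 else eps * 10.0
        if eps > 1.0:
            raise ValueError(
                f"covariance of view {view!r} not regularisable"
                + (f"; constant feature(s): {constant}" if constant else "")
            )
        cov_reg = cov + eps * scale * np.eye(d)
    if eps:
        logger.info("view %s: ridge regularisation eps=%g applied", view, eps)
    return ViewReference(
        view=view,
        feature_names=names,
        mean=mean,
        covariance=cov_reg,
        regularization=eps * scale if eps else 0.0,
        n_fit=X.shape[0],
    )


def mahalanobis_depth(x: np.ndarray, ref: ViewReference) -> float:
    """Mahalanobis depth ``1 / (1 + d_M^2(x))`` in ``(0, 1]``; 1 iff x = mu."""
    return 1.0 / (1.0 + ref.squared_mahalanobis(x))


def spatial_depth(x: np.ndarray, sample: np.ndarray) -> float:
    """Spatial depth ``1 - || mean of unit vectors (x - y)/||x - y|| ||``.

    A sample point coinciding with ``x`` contributes a zero vector (documented
    convention). Values lie in [0, 1]; the spatial median attains the maximum.
    """
    x = np.asarray(x, dtype=float)
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    if sample.shape[0] < 2:
        raise ValueError("spatial depth needs a sample of size >= 2")
    diff = x[None, :] - sample
    norms = np.linalg.norm(diff, axis=1)
    nonzero = norms > 0
    units = np.zeros_like(diff)
    units[nonzero] = diff[nonzero] / norms[nonzero, None]
    return float(1.0 - np.linalg.norm(units.mean(axis=0)))


def projection_depth(
    x: np.ndarray,
    sample: np.ndarray,
    n_directions: int = 500,
    seed: int = 0,
    directions: np.ndarray | None = None,
) -> float:
    """Approximate projection depth over random unit directions.

    Outlyingness is ``sup_u |u'x - median(u'S)| / MAD(u'S)`` approximated over
    ``n_directions`` random unit vectors (deterministic given ``seed``);
    depth is ``1 / (1 + outlyingness)``. Directions with zero MAD are skipped
    and logged. An explicit direction matrix overrides the random draw.
    """
    x = np.asarray(x, dtype=float)
    sample = np.atleast_2d(np.asarray(sample, dtype=float))
    d = sample.shape[1]
    if directions is None:
        if n_directions < 1:
            raise ValueError("n_directions must be >= 1")
        rng = np.random.default_rng(seed)
        directions = rng.standard_normal((n_directions, d))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    directions = directions / np.linalg.norm(directions, axis=1, keepdims=True)

    proj = sample @ directions.T  # (n, m)
    med = np.median(proj, axis=0)
    mad = np.median(np.abs(proj - med[None, :]), axis=0)
    ok = mad > 0
    if not ok.all():
        logger.debug("projection depth: skipped %d zero-MAD directions", (~ok).sum())
    if not ok.any():
        raise ValueError("all projection directions have zero MAD")
    out = np.abs(x @ directions[ok].T - med[ok]) / mad[ok]
    return float(1.0 / (1.0 + out.max()))


def _robust_standardise(X: np.ndarray) -> np.ndarray:
    """Scale columns to unit MAD (fallback SD) for non-affine-invariant depths."""
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med[None, :]), axis=0)
    sd = X.std(axis=0, ddof=1)
    scale = np.where(mad > 0, mad, np.where(sd > 0, sd, 1.0))
    return (X - med[None, :]) / scale[None, :]


def compute_depth_profiles(
    cohort: CohortDataset,
    depth_kind: DepthKind = "mahalanobis",
    n_directions: int = 500,
    seed: int = 0,
) -> list[DepthProfile]:
    """Compute one per-view depth profile per lesion.

    References are fitted once on the pooled cohort (all patients' lesions)
    and reused for every lesion; conventional SUV-derived features never
    enter. Deterministic for ``mahalanobis``/``spatial`` and for
    ``projection`` given the seed.
    """
    group_map = cohort.group_map
    lesions = cohort.lesions
    n = len(lesions)
    depths = np.empty((n, len(group_map.view_names)))

    for v, view in enumerate(group_map.view_names):
        if depth_kind == "mahalanobis":
            ref = fit_view_reference(lesions, view, group_map)
            X, _ = _view_matrix(lesions, view, group_map)
            for i in range(n):
                depths[i, v] = mahalanobis_depth(X[i], ref)
        else:
            X, _ = _view_matrix(lesions, view, group_map)
            Z = _robust_standardise(X)
            if depth_kind == "spatial":
                for i in range(n):
                    depths[i, v] = spatial_depth(Z[i], Z)
            elif depth_kind == "projection":
                rng = np.random.default_rng(seed)
                dirs = rng.standard_normal((n_directions, Z.shape[1]))
                for i in range(n):
                    depths[i, v] = projection_depth(Z[i], Z, directions=dirs)
            else:
                raise ValueError(f"unknown depth kind {depth_kind!r}")
    return [
        DepthProfile(l.patient_id, l.lesion_id, depths[i].copy())
        for i, l in enumerate(lesions)
    ]


def profiles_frame(
    profiles: Sequence[DepthProfile], view_names: Sequence[str] = None
) -> pd.DataFrame:
    """Tabulate depth profiles: index (patient_id, lesion_id), one column per view."""
    if view_names is None:
        view_names = FeatureGroupMap.default().view_names
    index = pd.MultiIndex.from_tuples(
        [(p.patient_id, p.lesion_id) for p in profiles],
        names=["patient_id", "lesion_id"],
    )
    return pd.DataFrame(
        np.vstack([p.depths for p in profiles]), index=index, columns=list(view_names)
    )


def view_correlation_matrix(profiles: Sequence[DepthProfile] | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between the view-depth columns.

    Symmetric with unit diagonal; a constant column yields NaN correlations
    (reported as missing rather than raising).
    """
    frame = profiles if isinstance(profiles, pd.DataFrame) else profiles_frame(profiles)
    if len(frame) < 3:
        raise ValueError("need at least 3 profiles for a correlation matrix")
    corr = frame.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def sequential_rank_agreement(
    rank_lists: Sequence[Sequence], depth_cut: int | None = None
) -> np.ndarray:
    """Sequential rank agreement of two or more rankings of the same items.

    ``rank_lists`` are orderings (best first) of one common item set. For each
    list depth ``d`` the statistic is the pooled standard deviation of the
    items' ranks across lists, restricted to items appearing in the top ``d``
    of at least one list. Identical lists give an identically-zero curve;
    larger values mean poorer agreement.
    """
    lists = [list(r) for r in rank_lists]
    if len(lists) < 2:
        raise ValueError("need at least two rank lists")
    item_set = set(lists[0])
    for r in lists[1:]:
        if set(r) != item_set:
            raise ValueError("rank lists cover different item sets")
    n = len(item_set)
    if depth_cut is None:
        depth_cut = n
    depth_cut = min(depth_cut, n)

    # ranks[item] = vector of 1-based ranks across lists
    ranks = {item: np.empty(len(lists)) for item in item_set}
    for j, r in enumerate(lists):
        for pos, item in enumerate(r, start=1):
            ranks[item][j] = pos

    curve = np.empty(depth_cut)
    seen: set = set()
    for d in range(1, depth_cut + 1):
        for r in lists:
            seen.add(r[d - 1])
        variances = [np.var(ranks[item], ddof=1) for item in seen]
        curve[d - 1] = float(np.sqrt(np.mean(variances)))
    return curve


def depth_ranking(frame: pd.DataFrame) -> list:
    """Order lesions by decreasing mean depth across views (ties by id)."""
    mean_depth = frame.mean(axis=1)
    order = sorted(frame.index, key=lambda ix: (-mean_depth.loc[ix], ix))
    return order
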