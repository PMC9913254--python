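"""Cohort-wide lesion phenotyping by minibatch K-means on depth profiles.

All lesions' 6-dimensional depth profiles are clustered irrespective of the
patient they belong to; each cluster is a lesion *phenotype* whose mean
profile acts as a pattern template. The number of phenotypes ``k`` is chosen
by an exhaustive grid search maximising the mean silhouette width (the grid's
inertia and Davies-Bouldin scores are returned too so a user can re-select).
Fitted clusters are characterised against the conventional SUV quantities
(SUV_max, TLA, GLCM entropy) with two-sided Mann-Whitney U tests and against
the anatomical site with a chi-squared test on the contingency table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import MiniBatchKMeans
from sklearn.metrics import davies_bouldin_score, silhouette_score

from .core_model_io import SITES, LesionRecord

logger = logging.getLogger("lesionforest")

DEFAULT_SEED = 20823
DEFAULT_BATCH_SIZE = 32
DEFAULT_N_INIT = 10
DEFAULT_MAX_ITER = 300


def significance_flag(p: float) -> str:
    """Star convention: *** <0.001, ** <0.01, * <0.05, . <0.1."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


@dataclass
class PhenotypeModel:
    """A fitted lesion clustering.

    Labels are canonicalised to 1..k with classes ordered by decreasing size
    (ties by original cluster index), so "Cluster 1" is reproducible.
    """

    k: int
    centroids: np.ndarray  # (k, 6)
    labels: dict[tuple[str, str], int]  # (patient_id, lesion_id) -> 1..k
    inertia: float
    seed: int
    k_grid: pd.DataFrame | None = field(default=None, repr=False)

    def labels_for(self, frame: pd.DataFrame) -> np.ndarray:
        return np.array([self.labels[key] for key in frame.index])


@dataclass
class PhenotypeTemplate:
    """Mean depth profile of one phenotype class."""

    cls: int
    mean_profile: np.ndarray
    n_lesions: int


def fit_minibatch_kmeans(
    frame: pd.DataFrame,
    k: int,
    seed: int = DEFAULT_SEED,
    batch_size: int = DEFAULT_BATCH_SIZE,
    n_init: int = DEFAULT_N_INIT,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PhenotypeModel:
    """Fit minibatch K-means on a depth-profile frame (rows = lesions).

    Deterministic given ``seed``; the best of ``n_init`` initialisations by
    inertia is kept. Labels are patient-agnostic.
    """
    n = len(frame)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for n={n} lesions")
    X = frame.to_numpy(dtype=float)
    if k == 1:
        # closed-form optimum: the grand mean
        centroid = X.mean(axis=0, keepdims=True)
        labels = {key: 1 for key in frame.index}
        inertia = float(((X - centroid) ** 2).sum())
        return PhenotypeModel(1, centroid, labels, inertia, seed)
    km = MiniBatchKMeans(
        n_clusters=k,
        random_state=seed,
        batch_size=batch_size,
        n_init=n_init,
        max_iter=max_iter,
    )
    raw = km.fit_predict(X)

    # Canonicalise: order classes by size descending, ties by raw index.
    sizes = np.bincount(raw, minlength=k)
    order = sorted(range(k), key=lambda c: (-sizes[c], c))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = {key: relabel[c] for key, c in zip(frame.index, raw)}
    centroids = km.cluster_centers_[order]
    # Inertia recomputed against the final (possibly reordered) centroids.
    inertia = float(((X - centroids[np.array([labels[key] for key in frame.index]) - 1]) ** 2).sum())
    return PhenotypeModel(k=k, centroids=centroids, labels=labels, inertia=inertia, seed=seed)


def select_k(
    frame: pd.DataFrame,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = DEFAULT_SEED,
    **fit_kwargs,
) -> tuple[int, PhenotypeModel, pd.DataFrame]:
    """Exhaustive grid search over ``k``; selects maximal mean silhouette.

    Returns ``(k_star, model, score_table)`` where the table has one row per
    grid value with silhouette, Davies-Bouldin and inertia columns.
    """
    n = len(frame)
    if not 2 <= k_min <= k_max <= n - 1:
        raise ValueError(f"invalid k grid [{k_min}, {k_max}] for n={n}")
    X = frame.to_numpy(dtype=float)
    rows = []
    models: dict[int, PhenotypeModel] = {}
    for k in range(k_min, k_max + 1):
        model = fit_minibatch_kmeans(frame, k, seed=seed, **fit_kwargs)
        lab = model.labels_for(frame)
        n_classes = len(np.unique(lab))
        if n_classes < 2:
            sil, db = np.nan, np.nan
        else:
            sil = float(silhouette_score(X, lab))
            db = float(davies_bouldin_score(X, lab))
        rows.append({"k": k, "silhouette": sil, "davies_bouldin": db, "inertia": model.inertia})
        models[k] = model
    table = pd.DataFrame(rows).set_index("k")
    if table["silhouette"].isna().all():
        raise ValueError("silhouette undefined for every k in the grid")
    k_star = int(table["silhouette"].idxmax())
    model = models[k_star]
    model.k_grid = table
    return k_star, model, table


def cluster_templates(
    model: PhenotypeModel, frame: pd.DataFrame
) -> list[PhenotypeTemplate]:
    """Per-class mean profiles (pattern templates), ordered by class label.

    An empty class (possible when minibatch K-means collapses a centroid) is
    dropped with a warning.
    """
    lab = model.labels_for(frame)
    X = frame.to_numpy(dtype=float)
    templates = []
    for cls in range(1, model.k + 1):
        mask = lab == cls
        if not mask.any():
            warnings.warn(f"phenotype class {cls} is empty; dropped", stacklevel=2)
            continue
        templates.append(
            PhenotypeTemplate(cls=cls, mean_profile=X[mask].mean(axis=0), n_lesions=int(mask.sum()))
        )
    return templates


def _numeric_row(name: str, values: dict[int, np.ndarray]) -> dict:
    groups = sorted(values)
    row: dict[str, object] = {"variable": name, "kind": "numeric"}
    for g in groups:
        x = values[g]
        row[f"median_{g}"] = float(np.median(x))
        row[f"sd_{g}"] = float(np.std(x, ddof=1)) if len(x) > 1 else np.nan
        row[f"q3_{g}"] = float(np.quantile(x, 0.75))
        row[f"n_{g}"] = len(x)
    if len(groups) == 2:
        stat = stats.mannwhitneyu(values[groups[0]], values[groups[1]], alternative="two-sided")
        row["p_value"] = float(stat.pvalue)
    return row


def characterize_clusters(
    model: PhenotypeModel, lesions: Sequence[LesionRecord]
) -> pd.DataFrame:
    """Characterise phenotype classes against SUV_max, TLA, GLCM entropy, site.

    For ``k = 2`` (the intended use) numeric variables are compared with a
    two-sided Mann-Whitney U test and the site distribution with a
    chi-squared test (no Yates correction) on the k x 3 contingency table;
    group medians, SDs and third quartiles are reported alongside. For
    ``k != 2`` numeric tests are run pairwise with a warning.
    """
    by_key = {l.key: l for l in lesions}
    cls_of = {key: c for key, c in model.labels.items() if key in by_key}
    classes = sorted(set(cls_of.values()))
    numeric_vars = {
        "SUV_max": lambda l: l.suv_max,
        "TLA": lambda l: l.tla,
        "GLCM_Entropy": lambda l: l.glcm_entropy,
    }

    rows = []
    if len(classes) == 2:
        pairs = [tuple(classes)]
    else:
        warnings.warn(
            f"characterize_clusters expects k=2; running pairwise tests for k={len(classes)}",
            stacklevel=2,
        )
        pairs = list(combinations(classes, 2))

    for a, b in pairs:
        for name, getter in numeric_vars.items():
            values = {
                g: np.array([getter(by_key[key]) for key, c in cls_of.items() if c == g])
                for g in (a, b)
            }
            row = _numeric_row(name, values)
            row["pair"] = f"{a}v{b}"
            rows.append(row)

    # Site contingency over all classes; empty site columns are dropped.
    table = np.array(
        [
            [sum(1 for key, c in cls_of.items() if c == g and by_key[key].site == s) for s in SITES]
            for g in classes
        ]
    )
    keep = table.sum(axis=0) > 0
    if (~keep).any():
        logger.warning("dropping empty site categories from chi-squared: %s",
                       [s for s, k_ in zip(SITES, keep) if not k_])
    table = table[:, keep]
    if table.shape[1] >= 2 and (table.sum(axis=1) > 0).all():
        chi2 = stats.chi2_contingency(table, correction=False)
        if (chi2.expected_freq < 5).any():
            logger.warning("site chi-squared has expected counts < 5")
        site_p = float(chi2.pvalue)
    else:
        site_p = np.nan
    site_row: dict[str, object] = {"variable": "site", "kind": "categorical", "p_value": site_p, "pair": "all"}
    for g, counts in zip(classes, table):
        site_row[f"counts_{g}"] = counts.tolist()
    rows.append(site_row)

    out = pd.DataFrame(rows)
    out["flag"] = [significance_flag(p) if np.isfinite(p) else "" for p in out["p_value"].fillna(np.nan)]
    return out
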