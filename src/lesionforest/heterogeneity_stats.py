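"""Patient-level heterogeneity labels and association testing.

A patient whose lesions all fall in one cohort-wide phenotype class is
*homogeneous*; lesions spread over several classes make the patient
*heterogeneous*. Labels and tree descriptors are associated with clinical
variables using non-parametric tests: Mann-Whitney U for a numeric variable
against two groups, Kruskal-Wallis when the grouping has more than two
levels, Spearman rank correlation for numeric-numeric pairs and a
chi-squared test for categorical-categorical pairs. Raw p-values are
reported without multiple-testing correction (a Benjamini-Hochberg column is
carried as a clearly-marked extra).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model_io import CohortDataset
from .lesion_phenotyping import PhenotypeModel, significance_flag

logger = logging.getLogger("lesionforest")


@dataclass
class PatientHeterogeneityLabel:
    patient_id: str
    n_distinct_classes: int
    label: str  # "homogeneous" | "heterogeneous"


def label_patients(
    model: PhenotypeModel, cohort: CohortDataset
) -> list[PatientHeterogeneityLabel]:
    """Label each patient by the number of distinct phenotype classes.

    ``homogeneous`` iff all the patient's lesions share one class.
    """
    classes: dict[str, set[int]] = {c.patient_id: set() for c in cohort.clinical}
    for lesion in cohort.lesions:
        try:
            cls = model.labels[lesion.key]
        except KeyError:
            raise ValueError(
                f"lesion {lesion.key} absent from phenotype model"
            ) from None
        classes[lesion.patient_id].add(cls)
    out = []
    for pid in classes:
        if not classes[pid]:
            raise ValueError(f"patient {pid!r} absent from phenotype model")
        n = len(classes[pid])
        out.append(
            PatientHeterogeneityLabel(
                pid, n, "homogeneous" if n == 1 else "heterogeneous"
            )
        )
    return out


def labels_frame(labels: Sequence[PatientHeterogeneityLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(l) for l in labels]
    ).set_index("patient_id")


def oligo_multi_status(n_lesions: int, cutoff: Literal[3, 5, "both"] = 3) -> str:
    """Metastatic-burden category from the lesion count.

    Cutoff 3: oligo iff n < 3; cutoff 5: oligo iff n < 5; ``"both"`` gives
    the three levels ``<3``, ``3<=n<5`` and ``>=5``.
    """
    if n_lesions < 1:
        raise ValueError("lesion count must be >= 1")
    if cutoff == 3:
        return "oligo" if n_lesions < 3 else "multi"
    if cutoff == 5:
        return "oligo" if n_lesions < 5 else "multi"
    if cutoff == "both":
        if n_lesions < 3:
            return "<3"
        if n_lesions < 5:
            return "3<=n<5"
        return ">=5"
    raise ValueError(f"unknown cutoff {cutoff!r}")


def _bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up q-values (extra, non-primary output)."""
    mask = p.notna()
    q = pd.Series(np.nan, index=p.index)
    pv = p[mask].to_numpy()
    m = len(pv)
    if m == 0:
        return q
    order = np.argsort(pv)
    ranked = pv[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[mask] = out
    return q


def _is_numeric(series: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(series) and series.nunique(dropna=True) > 2


def _test_pair(x: pd.Series, y: pd.Series) -> tuple[str, float, int]:
    """Choose and run the association test for one (descriptor, variable) pair.

    Returns (test name, p-value, n used); missing values are dropped
    pairwise. Pairs where a group empties return NaN rather than raising.
    """
    df = pd.concat({"x": x, "y": y}, axis=1).dropna()
    n = len(df)
    if n < 4:
        return ("not-computable", np.nan, n)
    x_num, y_num = _is_numeric(df["x"]), _is_numeric(df["y"])
    try:
        if x_num and y_num:
            rho = stats.spearmanr(df["x"], df["y"])
            return ("spearman", float(rho.pvalue), n)
        if x_num != y_num:
            num = df["x"] if x_num else df["y"]
            cat = df["y"] if x_num else df["x"]
            groups = [num[cat == level].to_numpy(dtype=float) for level in cat.unique()]
            groups = [g for g in groups if len(g) > 0]
            if len(groups) < 2 or min(len(g) for g in groups) < 2:
                return ("not-computable", np.nan, n)
            if len(groups) == 2:
                res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
                return ("mann-whitney", float(res.pvalue), n)
            res = stats.kruskal(*groups)
            return ("kruskal-wallis", float(res.pvalue), n)
        table = pd.crosstab(df["x"], df["y"]).to_numpy()
        table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
        if min(table.shape) < 2:
            return ("not-computable", np.nan, n)
        res = stats.chi2_contingency(table, correction=False)
        return ("chi-squared", float(res.pvalue), n)
    except ValueError:
        return ("not-computable", np.nan, n)


def _group_summaries(x: pd.Series, y: pd.Series) -> dict:
    """Median/SD/Q3 per group for a numeric-vs-2-group pair (Table style)."""
    df = pd.concat({"x": x, "y": y}, axis=1).dropna()
    out = {}
    for level in df["y"].unique():
        vals = df.loc[df["y"] == level, "x"].to_numpy(dtype=float)
        out[f"median[{level}]"] = float(np.median(vals)) if len(vals) else np.nan
        out[f"sd[{level}]"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        out[f"q3[{level}]"] = float(np.quantile(vals, 0.75)) if len(vals) else np.nan
    return out


def compare_groups(
    patient_frame: pd.DataFrame,
    group_col: str,
    variables: Sequence[str],
) -> pd.DataFrame:
    """Compare clinical variables between patient groups (label-style table).

    ``patient_frame`` has one row per patient; ``group_col`` is a categorical
    grouping (e.g. homogeneous/heterogeneous). Numeric variables are reported
    with per-group median/SD/Q3 and a Mann-Whitney (2 groups) or
    Kruskal-Wallis (more) p-value; categorical variables with counts and a
    chi-squared p-value. Missing values are removed pairwise.
    """
    rows = []
    for var in variables:
        x = patient_frame[var]
        y = patient_frame[group_col]
        test, p, n = _test_pair(x, y)
        row: dict[str, object] = {"variable": var, "test": test, "p_value": p, "n": n}
        if _is_numeric(x.dropna()):
            row.update(_group_summaries(x, y))
        else:
            counts = pd.crosstab(x, y)
            row["counts"] = {
                str(ix): counts.loc[ix].to_dict() for ix in counts.index
            }
        rows.append(row)
    out = pd.DataFrame(rows).set_index("variable")
    out["flag"] = out["p_value"].map(
        lambda p: significance_flag(p) if np.isfinite(p) else ""
    )
    out["bh_q"] = _bh_adjust(out["p_value"])  # extra, not a primary output
    return out


def descriptor_associations(
    patient_frame: pd.DataFrame,
    descriptor_cols: Sequence[str],
    variable_cols: Sequence[str],
) -> pd.DataFrame:
    """Association table keyed by (descriptor, clinical variable).

    Test selection per pair: Mann-Whitney U (numeric vs 2-level), Kruskal-
    Wallis (numeric vs >2-level), Spearman (numeric vs numeric), chi-squared
    (categorical vs categorical). Each cell reports the n actually used after
    pairwise-complete missing-value removal.
    """
    rows = []
    for desc in descriptor_cols:
        for var in variable_cols:
            test, p, n = _test_pair(patient_frame[desc], patient_frame[var])
            rows.append(
                {"descriptor": desc, "variable": var, "test": test, "p_value": p, "n": n}
            )
    out = pd.DataFrame(rows).set_index(["descriptor", "variable"])
    out["flag"] = out["p_value"].map(
        lambda p: significance_flag(p) if np.isfinite(p) else ""
    )
    out["bh_q"] = _bh_adjust(out["p_value"])  # extra, not a primary output
    return out
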