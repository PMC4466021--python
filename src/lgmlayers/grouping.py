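"""Correlation structure of the GCM ensemble and hierarchical grouping.

For each bioclim variable, models are compared by the Pearson correlation of
their layers across all shared unmasked cells, then clustered
agglomeratively on the correlation distance d = 1 - r (complete linkage by
default) and the tree cut into k = 4 groups. The per-variable group table
has the shape of a model-selection table (rows = models, columns = BIO1..19,
entries = group id); a consensus grouping clusters the mean of the
per-variable distance matrices.

Group ids are renumbered by order of first appearance in the model roster so
tables are reproducible under model reordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from .bioclim import BIO_NAMES, PRECIPITATION_BIOS, TEMPERATURE_BIOS
from .ensemble import EnsembleCube

__all__ = [
    "CorrelationMatrix",
    "ClusterResult",
    "pairwise_model_correlation",
    "cluster_models",
    "consensus_cluster",
    "group_table",
    "correlation_summary",
    "variable_family",
]


def variable_family(variable: str) -> str:
    if variable in TEMPERATURE_BIOS:
        return "temperature"
    if variable in PRECIPITATION_BIOS:
        return "precipitation"
    raise ValueError(f"unknown bioclim variable {variable!r}")


@dataclass
class CorrelationMatrix:
    """Model-by-model Pearson r for one variable (NaN where undefined)."""

    table: pd.DataFrame
    variable: str = ""
    flagged_models: list = field(default_factory=list)

    @property
    def models(self) -> list[str]:
        return list(self.table.index)

    def distance(self) -> pd.DataFrame:
        return 1.0 - self.table


def pairwise_model_correlation(
    cube: EnsembleCube,
    variable: str,
    min_shared_cells: int = 3,
) -> CorrelationMatrix:
    """Pearson r between every model pair over shared unmasked cells.

    A model with zero variance over the shared cells yields NaN entries and
    is flagged. Cells are weighted uniformly.
    """
    slab = np.asarray(cube.data.sel(variable=variable))  # (M, ny, nx)
    M = slab.shape[0]
    flat = slab.reshape(M, -1)
    models = cube.models
    r = np.eye(M)
    flagged: set[str] = set()
    for i in range(M):
        for j in range(i + 1, M):
            ok = np.isfinite(flat[i]) & np.isfinite(flat[j])
            if ok.sum() < min_shared_cells:
                raise ValueError(
                    f"models {models[i]} and {models[j]} share only {int(ok.sum())} cells"
                )
            xi, xj = flat[i, ok], flat[j, ok]
            si, sj = xi.std(), xj.std()
            if si == 0 or sj == 0:
                r[i, j] = r[j, i] = np.nan
                if si == 0:
                    flagged.add(models[i])
                if sj == 0:
                    flagged.add(models[j])
            else:
                r[i, j] = r[j, i] = float(np.corrcoef(xi, xj)[0, 1])
    table = pd.DataFrame(r, index=models, columns=models)
    return CorrelationMatrix(table=table, variable=variable, flagged_models=sorted(flagged))


@dataclass
class ClusterResult:
    """Group labels at the requested cut plus the full merge tree."""

    labels: dict  # model_id -> group id (1-based, renumbered by roster order)
    k: int
    linkage_matrix: np.ndarray
    models: list
    method: str
    degenerate: bool = False

    def groups(self) -> dict:
        out: dict = {}
        for m, g in self.labels.items():
            out.setdefault(g, []).append(m)
        return out

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with branch lengths from merge heights."""
        tree = to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.models[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def _renumber_by_roster(raw_labels: np.ndarray, models: list) -> dict:
    mapping: dict = {}
    labels: dict = {}
    for m, lab in zip(models, raw_labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        labels[m] = mapping[lab]
    return labels


def cluster_models(
    corr: CorrelationMatrix | pd.DataFrame,
    k: int = 4,
    method: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of models on correlation distance 1 - r.

    The dendrogram is cut into at most k groups. All-identical models
    (every distance 0) collapse to fewer groups and are flagged degenerate.
    """
    table = corr.table if isinstance(corr, CorrelationMatrix) else corr
    models = list(table.index)
    n = len(models)
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}], got {k}")
    d = 1.0 - np.asarray(table, dtype=float)
    if np.isnan(d).any():
        raise ValueError("correlation matrix has undefined entries; mask models first")
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, 2.0)
    Z = linkage(squareform(d, checks=False), method=method)
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = _renumber_by_roster(raw, models)
    n_groups = len(set(labels.values()))
    return ClusterResult(
        labels=labels,
        k=k,
        linkage_matrix=Z,
        models=models,
        method=method,
        degenerate=n_groups < min(k, n),
    )


def consensus_cluster(
    matrices: dict[str, CorrelationMatrix],
    k: int = 4,
    method: str = "complete",
) -> ClusterResult:
    """Cluster on the mean of the per-variable distance matrices.

    This is the all-variables grouping; averaging distances is one of the
    two reasonable conventions (the other being correlation of stacked
    layers) and is recorded in the result metadata.
    """
    names = list(matrices)
    models = matrices[names[0]].models
    dsum = np.zeros((len(models), len(models)))
    for cm in matrices.values():
        if cm.models != models:
            raise ValueError("all matrices must share the model roster")
        dsum += 1.0 - np.asarray(cm.table, dtype=float)
    mean_d = pd.DataFrame(1.0 - dsum / len(matrices), index=models, columns=models)
    result = cluster_models(CorrelationMatrix(table=mean_d, variable="consensus"), k, method)
    return result


def group_table(results: dict[str, ClusterResult]) -> pd.DataFrame:
    """Model-by-variable table of group ids (rows = models, cols = BIO1..19)."""
    variables = [v for v in BIO_NAMES if v in results] or list(results)
    models = results[variables[0]].models
    data = {v: [results[v].labels[m] for m in models] for v in variables}
    return pd.DataFrame(data, index=models)


def correlation_summary(matrices: dict[str, CorrelationMatrix]) -> pd.DataFrame:
    """Long-format table of all between-model correlations.

    Columns: variable, model_i, model_j, r, family (temperature for
    BIO1-BIO11, precipitation for BIO12-BIO19). One row per unordered model
    pair per variable.
    """
    rows = []
    for variable, cm in matrices.items():
        fam = variable_family(variable)
        models = cm.models
        arr = np.asarray(cm.table)
        for i in range(len(models)):
            for j in range(i + 1, len(models)):
                rows.append(
                    {
                        "variable": variable,
                        "model_i": models[i],
                        "model_j": models[j],
                        "r": arr[i, j],
                        "family": fam,
                    }
                )
    return pd.DataFrame(rows)


def _box_stats(r: np.ndarray) -> dict:
    q1, q2, q3 = np.nanpercentile(r, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = r[np.isfinite(r) & ((r < lo) | (r > hi))]
    return {
        "q1": q1, "median": q2, "q3": q3,
        "n_outliers": int(outliers.size),
        "outliers": outliers.tolist(),
    }


def model_family_summary(long_table: pd.DataFrame) -> pd.DataFrame:
    """Per model and variable family: quartiles of its correlations with all
    other models, plus outliers by the 1.5 x IQR boxplot rule."""
    rows = []
    models = sorted(set(long_table["model_i"]) | set(long_table["model_j"]))
    for model in models:
        mine = long_table[(long_table["model_i"] == model) | (long_table["model_j"] == model)]
        for fam, sub in mine.groupby("family"):
            rows.append({"model": model, "family": fam, **_box_stats(sub["r"].to_numpy())})
    return pd.DataFrame(rows)


def variable_summary(long_table: pd.DataFrame) -> pd.DataFrame:
    """Per variable: quartiles and outliers of the between-model correlations."""
    rows = []
    for variable, sub in long_table.groupby("variable", sort=False):
        rows.append({"variable": variable, **_box_stats(sub["r"].to_numpy())})
    return pd.DataFrame(rows)
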