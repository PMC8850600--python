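"""Correlation-matrix PCA over the final animal-period dataset and a
silhouette-based check of cluster structure.

Variables are standardized (so the eigen-decomposition acts on their
correlation matrix); the categorical genetic group enters as
reference-coded indicator columns, documented in the result.  Loadings use
a deterministic sign convention (each component's largest-magnitude loading
is positive) so repeated runs agree exactly.  The silhouette of the group
labels in PC1/PC2 space quantifies whether the claimed clusters are
present; it is an extension of the visual cluster reading, not a formula
from the underlying study design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .behaviors import GENETIC_GROUPS, GENETIC_GROUP_REFERENCE

DEFAULT_PCA_VARIABLES = (
    "intake_frequency",
    "iadg_observed",
    "supplement_level",
    "forage_mass_kg_ha",
    "cp_pct",
    "ndf_pct",
    "adf_pct",
    "leaf_pct",
    "stem_pct",
)


@dataclass
class PCAResult:
    loadings: pd.DataFrame            # variables × components
    variance_explained_pct: np.ndarray  # descending, sums to 100
    scores: pd.DataFrame              # observations × components
    variable_importance_pct: pd.DataFrame  # squared-loading share per component
    variables: tuple[str, ...]


def _encode(table: pd.DataFrame, variables: tuple[str, ...], include_group: bool) -> pd.DataFrame:
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"missing variable(s): {', '.join(missing)}")
    X = table[list(variables)].astype(float).copy()
    if include_group and "genetic_group" in table.columns:
        present = set(table["genetic_group"])
        for level in GENETIC_GROUPS:
            # indicators only for levels present, so absent levels do not
            # inject zero-variance columns
            if level == GENETIC_GROUP_REFERENCE or level not in present:
                continue
            X[f"group_{level}"] = (table["genetic_group"] == level).astype(float)
    return X


def run_pca(
    table: pd.DataFrame,
    variables: tuple[str, ...] = DEFAULT_PCA_VARIABLES,
    include_group: bool = True,
) -> PCAResult:
    """Eigen-decomposition of the correlation matrix of the standardized data."""
    X = _encode(table, variables, include_group)
    if len(X) < 3:
        raise ValueError("PCA needs at least 3 rows")
    sd = X.std(ddof=1)
    dead = sd[sd == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance variable(s): {', '.join(map(str, dead))}")
    Z = (X - X.mean()) / sd
    corr = np.asarray(Z.corr())
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-magnitude loading of each component positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    comps = [f"PC{i + 1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=X.columns, columns=comps)
    scores = pd.DataFrame(Z.to_numpy() @ eigvec, index=table.index, columns=comps)
    var_pct = 100.0 * eigval / eigval.sum()
    importance = pd.DataFrame(
        100.0 * eigvec**2 / (eigvec**2).sum(axis=0),
        index=X.columns,
        columns=comps,
    )
    return PCAResult(
        loadings=loadings,
        variance_explained_pct=var_pct,
        scores=scores,
        variable_importance_pct=importance,
        variables=tuple(X.columns),
    )


def two_component_variability(result: PCAResult | np.ndarray) -> float:
    """Total variance percentage carried by PC1 + PC2."""
    pct = (
        result.variance_explained_pct
        if isinstance(result, PCAResult)
        else np.asarray(result, dtype=float)
    )
    if pct.size < 2:
        raise ValueError("need at least two components")
    return float(pct[0] + pct[1])


def group_separation(scores: pd.DataFrame, groups) -> float:
    """Mean silhouette of the given grouping in PC1/PC2 space (Euclidean)."""
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    singles = labels[counts < 2]
    if singles.size:
        raise ValueError(f"singleton group(s): {', '.join(map(str, singles))}")
    pts = scores[["PC1", "PC2"]].to_numpy()
    return float(silhouette_score(pts, groups, metric="euclidean"))
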