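"""Normalization, differential expression, clustering, and PC1 pathology link.

Differential expression follows the fold-change + t-test rule used throughout
small-n animal transcriptomics: a feature is called ``up`` when its linear
fold change exceeds 1.5 with t-test p < 0.05, ``down`` when the fold change is
below 0.67 with p < 0.05, else ``ns``. Both inequalities are strict, so a fold
change of exactly 1.5 (or 0.67) is not significant. The t-test is a
two-sided Student (pooled-variance) test on log2 CPM values — at n = 3 per
group the pooled test holds its nominal type-I rate, where the
Satterthwaite approximation is visibly conservative; fold changes are
ratios of linear group-mean CPM with a symmetric pseudocount so that
reversing the contrast inverts the fold change exactly.

No multiple-testing correction enters the call (the rule is a raw-p rule); a
BH-adjusted column is emitted for information only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .errors import ConstantInputError, MissingGroupError, ValidationError
from .io import ExpressionMatrix

__all__ = [
    "cpm",
    "log2_cpm",
    "call_degs",
    "deg_counts",
    "ward_cluster",
    "WardTree",
    "pc1_pathology",
    "Pc1Result",
]

FC_UP = 1.5
FC_DOWN = 0.67
ALPHA = 0.05


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def cpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Counts-per-million per sample (every column sums to 1e6)."""
    values = matrix.values.astype(float)
    libsize = values.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValidationError(f"all-zero sample column(s): {list(zero.index)}")
    return values / libsize * 1e6


def log2_cpm(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount); the working scale for tests, clustering, PCA."""
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    return np.log2(cpm(matrix) + pseudocount)


# ---------------------------------------------------------------------------
# DEG calling
# ---------------------------------------------------------------------------


def _group_columns(matrix: ExpressionMatrix, group: str, min_n: int = 2) -> list[str]:
    cols = matrix.samples_in(group)
    if len(cols) < min_n:
        raise MissingGroupError(
            f"group {group!r} has {len(cols)} sample(s); need >= {min_n}"
        )
    return cols


def call_degs(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fc_up: float = FC_UP,
    fc_down: float = FC_DOWN,
    alpha: float = ALPHA,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential expression of ``group_b`` versus ``group_a``.

    Returns a per-feature table with columns ``feature, mean_a, mean_b,
    fold_change, log2_fc, p_value, p_adj, call`` where ``fold_change`` is
    ``(mean_b + pc) / (mean_a + pc)`` on linear CPM and ``call`` applies the
    strict fold-change + p rule. ``p_adj`` (BH) is informational only.
    """
    if not (0 < fc_down < 1 < fc_up):
        raise ValidationError("need fc_down < 1 < fc_up")
    cols_a = _group_columns(matrix, group_a)
    cols_b = _group_columns(matrix, group_b)
    lin = cpm(matrix)
    log = np.log2(lin + pseudocount)

    mean_a = lin[cols_a].mean(axis=1)
    mean_b = lin[cols_b].mean(axis=1)
    fold = (mean_b + pseudocount) / (mean_a + pseudocount)

    res = stats.ttest_ind(
        log[cols_b].to_numpy(), log[cols_a].to_numpy(), axis=1, equal_var=True
    )
    p = np.asarray(res.pvalue, dtype=float)

    p_adj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]

    with np.errstate(invalid="ignore"):
        up = (fold.to_numpy() > fc_up) & (p < alpha)
        down = (fold.to_numpy() < fc_down) & (p < alpha)
    call = np.where(up, "up", np.where(down, "down", "ns"))

    out = pd.DataFrame(
        {
            "feature": matrix.feature_ids,
            "mean_a": mean_a.to_numpy(),
            "mean_b": mean_b.to_numpy(),
            "fold_change": fold.to_numpy(),
            "log2_fc": np.log2(fold.to_numpy()),
            "p_value": p,
            "p_adj": p_adj,
            "call": call,
        }
    )
    out.attrs["contrast"] = (group_a, group_b)
    out.attrs["params"] = {
        "fc_up": fc_up,
        "fc_down": fc_down,
        "alpha": alpha,
        "pseudocount": pseudocount,
        "test": "student_t_on_log2_cpm",
    }
    return out


def deg_counts(
    matrix: ExpressionMatrix,
    groups: list[str] | None = None,
    **deg_kwargs,
) -> pd.DataFrame:
    """Symmetric DEG-count table over all unordered group pairs."""
    if groups is None:
        groups = matrix.groups
    missing = [g for g in groups if g not in set(matrix.design)]
    if missing:
        raise MissingGroupError(f"group(s) absent from design: {missing}")
    table = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            degs = call_degs(matrix, a, b, **deg_kwargs)
            n = int((degs["call"] != "ns").sum())
            table.loc[a, b] = n
            table.loc[b, a] = n
    return table


# ---------------------------------------------------------------------------
# Ward hierarchical clustering of samples
# ---------------------------------------------------------------------------


@dataclass
class WardTree:
    """Sample dendrogram from Ward linkage on Euclidean log2-CPM distances."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster labels at ``n_clusters`` clusters."""
        flat = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with branch lengths from merge heights."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def ward_cluster(log_matrix: pd.DataFrame) -> WardTree:
    """Ward linkage over samples (columns) of a normalized matrix."""
    if log_matrix.shape[1] < 2:
        raise ValidationError("clustering needs >= 2 samples")
    data = log_matrix.to_numpy().T  # samples x features
    linkage = hierarchy.linkage(data, method="ward")
    return WardTree(linkage=linkage, labels=list(log_matrix.columns))


# ---------------------------------------------------------------------------
# PC1 versus pathology
# ---------------------------------------------------------------------------


@dataclass
class Pc1Result:
    coords: pd.Series  # per-sample PC1 coordinate
    explained_fraction: float
    r: float
    p: float


def pc1_pathology(
    log_matrix: pd.DataFrame,
    scores: pd.Series,
    design: pd.Series | None = None,
    positive_group: str = "OC",
) -> Pc1Result:
    """First principal component of samples, correlated with pathology scores.

    PC1 is extracted from the feature-centered log2-CPM matrix by SVD. The
    sign of a principal axis is arbitrary, so it is fixed by convention: the
    mean coordinate of ``positive_group`` samples is made positive (pathology
    worsens toward positive PC1). The per-sample coordinates are then
    correlated (Pearson) with the per-animal pathology score.

    Parameters
    ----------
    log_matrix
        features x samples normalized matrix.
    scores
        Pathology score per sample id (e.g. GSI); must cover all samples and
        must not be constant.
    design
        Optional sample -> group labels used for the sign convention.
    """
    samples = list(log_matrix.columns)
    missing = [s for s in samples if s not in scores.index]
    if missing:
        raise ValidationError(f"pathology score missing for sample(s): {missing}")
    y = scores.loc[samples].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise ConstantInputError("pathology scores are constant; correlation undefined")

    X = log_matrix.to_numpy().T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    coords = u[:, 0] * s[0]
    var = s**2
    explained = float(var[0] / var.sum()) if var.sum() > 0 else 0.0

    sign = 0.0
    if design is not None:
        in_group = [i for i, smp in enumerate(samples) if design.get(smp) == positive_group]
        if in_group:
            sign = float(np.sign(coords[in_group].mean()))
    if sign == 0.0:
        # fall back: largest-magnitude coordinate positive
        sign = float(np.sign(coords[np.argmax(np.abs(coords))])) or 1.0
    coords = coords * sign

    r, p = stats.pearsonr(coords, y)
    return Pc1Result(
        coords=pd.Series(coords, index=samples, name="pc1"),
        explained_fraction=explained,
        r=float(r),
        p=float(p),
    )
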