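"""Coexpression and ceRNA network inference.

The network layer follows the correlation-threshold construction common to
bulk coexpression studies: the adjacency between two genes is a power of the
Pearson correlation of their expression profiles (soft power beta, default 1,
i.e. plain thresholding), and only the strongest correlations enter the
graph. Three edge families exist:

* ``coexpression`` — |r| >= 0.8 between any feature pair (unsigned rule);
* ``miRNA-target`` — r <= -0.8 between a miRNA and a predicted target, where
  the pair must also appear in the supplied target map (signed rule: miRNAs
  repress, so only negative correlation is evidence);
* ceRNA legs ``lncRNA-miRNA`` (r <= -0.8, correlation-only: no lncRNA target
  map is assumed) and ``lncRNA-mRNA`` (r >= +0.8, the sign implied by sponge
  logic: a lncRNA that sequesters a miRNA rises and falls with the miRNA's
  targets).

A sponge triad (lncRNA, miRNA, mRNA) is emitted when all three legs pass.
Correlation p-values come from the exact t transform
``t = r * sqrt((n-2) / (1-r^2))``; BH adjustment is applied within each edge
family, and edge weights are ``-log10(p_adj)`` as used for edge breadth in
network figures. A filtered view keeps edges (and the triads they support)
with adjusted p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .differential import log2_cpm
from .errors import (
    ConstantInputError,
    SampleMismatchError,
    ValidationError,
)
from .io import ExpressionMatrix, TargetMap

__all__ = [
    "CorrelationMatrix",
    "correlate",
    "power_adjacency",
    "coexpression_edges",
    "mirna_target_edges",
    "CernaNetwork",
    "build_cerna",
    "bh_adjust",
]

CORR_THRESHOLD = 0.8
MIRNA_R_MAX = -0.8
ADJ_P_MAX = 0.05

EDGE_COLUMNS = [
    "source",
    "target",
    "interaction_type",
    "r",
    "adjacency",
    "p",
    "p_adj",
    "weight",
    "significant",
]

_P_FLOOR = 1e-300  # keeps -log10 finite for r = +/-1 exactly


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (statsmodels)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    """Pearson correlations (and p-values) between feature profiles.

    Symmetric when built from one matrix (diagonal 1, p-values BH-adjusted
    over the strictly upper triangle); rectangular when built from a pair of
    matrices sharing samples (BH over all entries).
    """

    r: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    n_samples: int
    symmetric: bool

    @property
    def row_features(self) -> list[str]:
        return list(self.r.index)

    @property
    def col_features(self) -> list[str]:
        return list(self.r.columns)


def _standardize_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    arr = df.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=0)
    constant = list(df.index[sd == 0])
    if constant:
        warnings.warn(
            f"excluding {len(constant)} constant feature(s) from correlation",
            stacklevel=3,
        )
        df = df.drop(index=constant)
        arr = df.to_numpy(dtype=float)
        sd = arr.std(axis=1, ddof=0)
    centered = arr - arr.mean(axis=1, keepdims=True)
    z = centered / sd[:, None]
    return pd.DataFrame(z, index=df.index, columns=df.columns), constant


def _corr_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via the exact t transform (n-2 df)."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return p


def correlate(
    matrix: pd.DataFrame, other: pd.DataFrame | None = None
) -> CorrelationMatrix:
    """Pearson correlation of feature profiles across shared samples.

    Parameters
    ----------
    matrix, other
        features x samples DataFrames (already normalized, e.g. log2 CPM).
        With ``other`` given, a rectangular cross-correlation is computed;
        columns of both inputs must be identical (same samples, same order).
        Constant features are excluded with a warning.
    """
    n = matrix.shape[1]
    if n < 3:
        raise ValidationError(f"correlation needs >= 3 samples, got {n}")
    za, dropped_a = _standardize_rows(matrix)
    if za.shape[0] == 0:
        raise ConstantInputError("all features are constant")
    symmetric = other is None
    if symmetric:
        zb = za
    else:
        if list(other.columns) != list(matrix.columns):
            raise SampleMismatchError("inputs do not share identical sample columns")
        zb, _ = _standardize_rows(other)
        if zb.shape[0] == 0:
            raise ConstantInputError("all features of second matrix are constant")

    r = za.to_numpy() @ zb.to_numpy().T / n
    r = np.clip(r, -1.0, 1.0)
    if symmetric:
        np.fill_diagonal(r, 1.0)
    p = _corr_p(r, n)

    p_adj = np.ones_like(p)
    if symmetric:
        iu = np.triu_indices(len(za), k=1)
        if iu[0].size:
            adj = bh_adjust(p[iu])
            p_adj[iu] = adj
            p_adj = np.minimum(p_adj, p_adj.T)
        np.fill_diagonal(p_adj, 0.0)
        np.fill_diagonal(p, 0.0)
    else:
        p_adj = bh_adjust(p.ravel()).reshape(p.shape)

    idx, cols = za.index, zb.index
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        p_adj=pd.DataFrame(p_adj, index=idx, columns=cols),
        n_samples=n,
        symmetric=symmetric,
    )


def power_adjacency(r: float | np.ndarray, beta: float = 1.0) -> np.ndarray:
    """Soft-threshold adjacency |r|^beta (beta = 1 reduces to |r|)."""
    if beta <= 0:
        raise ValidationError("beta must be > 0")
    return np.abs(r) ** beta


# ---------------------------------------------------------------------------
# edge construction
# ---------------------------------------------------------------------------


def _edge_frame(records: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(records, columns=EDGE_COLUMNS)


def coexpression_edges(
    corr: CorrelationMatrix,
    threshold: float = CORR_THRESHOLD,
    beta: float = 1.0,
    interaction_type: str = "coexpression",
    signed: str = "abs",
    adj_p_max: float = ADJ_P_MAX,
) -> pd.DataFrame:
    """Edges from a correlation matrix at the |r| >= threshold rule.

    ``signed`` selects the thresholding rule: ``"abs"`` keeps |r| >= threshold
    (the coexpression "strongest correlations" rule, inclusive), ``"neg"``
    keeps r <= -threshold, ``"pos"`` keeps r >= +threshold. The adjacency
    |r|^beta and the correlation sign are recorded on each edge.
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must lie in (0, 1], got {threshold}")
    if signed not in ("abs", "neg", "pos"):
        raise ValidationError(f"unknown sign rule {signed!r}")
    rarr = corr.r.to_numpy()
    if signed == "abs":
        mask = np.abs(rarr) >= threshold
    elif signed == "neg":
        mask = rarr <= -threshold
    else:
        mask = rarr >= threshold
    if corr.symmetric:
        mask &= np.triu(np.ones_like(mask, dtype=bool), k=1)
    ii, jj = np.nonzero(mask)
    rows = np.asarray(corr.r.index)
    cols = np.asarray(corr.r.columns)
    r = rarr[ii, jj]
    p = corr.p.to_numpy()[ii, jj]
    p_adj = corr.p_adj.to_numpy()[ii, jj]
    out = pd.DataFrame(
        {
            "source": rows[ii],
            "target": cols[jj],
            "interaction_type": interaction_type,
            "r": r,
            "adjacency": power_adjacency(r, beta),
            "p": p,
            "p_adj": p_adj,
            "weight": -np.log10(np.maximum(p_adj, _P_FLOOR)),
            "significant": p_adj < adj_p_max,
        },
        columns=EDGE_COLUMNS,
    )
    return out.reset_index(drop=True)


def mirna_target_edges(
    mirna_log: pd.DataFrame,
    target_log: pd.DataFrame,
    target_map: TargetMap,
    r_max: float = MIRNA_R_MAX,
    target_layer: str = "mRNA",
    adj_p_max: float = ADJ_P_MAX,
) -> pd.DataFrame:
    """Target-map-constrained miRNA repression edges.

    An edge (miRNA, target) is kept iff the pair is predicted in the target
    map *and* the sample-wise Pearson correlation is at most ``r_max``
    (default -0.8, the signed negative-correlation rule). The BH family is
    the set of expressed map pairs, i.e. the hypotheses actually examined.
    """
    if not -1 <= r_max < 0:
        raise ValidationError(f"r_max must lie in [-1, 0), got {r_max}")
    pairs = sorted(target_map.for_layer(target_layer))
    expressed = [
        (m, t) for m, t in pairs if m in mirna_log.index and t in target_log.index
    ]
    if not expressed:
        warnings.warn(
            "no target-map pair is expressed in both matrices; empty edge set",
            stacklevel=2,
        )
        return _edge_frame([])
    corr = correlate(mirna_log, target_log)
    records = []
    rvals, pvals = [], []
    usable = [
        (m, t)
        for m, t in expressed
        if m in corr.r.index and t in corr.r.columns  # constant rows may drop
    ]
    for m, t in usable:
        rvals.append(float(corr.r.at[m, t]))
        pvals.append(float(corr.p.at[m, t]))
    p_adj = bh_adjust(np.array(pvals))
    for (m, t), r, p, pa in zip(usable, rvals, pvals, p_adj):
        if r > r_max:
            continue
        records.append(
            {
                "source": m,
                "target": t,
                "interaction_type": "miRNA-target",
                "r": r,
                "adjacency": float(abs(r)),
                "p": p,
                "p_adj": float(pa),
                "weight": float(-np.log10(max(pa, _P_FLOOR))),
                "significant": bool(pa < adj_p_max),
            }
        )
    return _edge_frame(records)


# ---------------------------------------------------------------------------
# ceRNA network
# ---------------------------------------------------------------------------

TRIAD_COLUMNS = ["lncrna", "mirna", "mrna", "r_lm", "r_mg", "r_lg", "min_p_adj"]


@dataclass
class CernaNetwork:
    """Typed ceRNA network: nodes, signed weighted edges, sponge triads."""

    nodes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "layer", "regulation"])
    )
    edges: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EDGE_COLUMNS))
    triads: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=TRIAD_COLUMNS)
    )
    params: dict = field(default_factory=dict)

    @property
    def triad_tuples(self) -> set[tuple[str, str, str]]:
        return {
            (row.lncrna, row.mirna, row.mrna)
            for row in self.triads.itertuples(index=False)
        }

    def filtered(self, adj_p_max: float = ADJ_P_MAX) -> "CernaNetwork":
        """View keeping edges with adjusted p below the cut, and surviving triads."""
        edges = self.edges[self.edges["p_adj"] < adj_p_max].reset_index(drop=True)
        triads = _triads_from_edges(edges)
        keep_ids = set(edges["source"]) | set(edges["target"])
        nodes = self.nodes[self.nodes["id"].isin(keep_ids)].reset_index(drop=True)
        params = dict(self.params, adj_p_max=adj_p_max)
        return CernaNetwork(nodes=nodes, edges=edges, triads=triads, params=params)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for row in self.nodes.itertuples(index=False):
            g.add_node(row.id, layer=row.layer, regulation=row.regulation)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.source,
                row.target,
                interaction_type=row.interaction_type,
                r=row.r,
                p_adj=row.p_adj,
                weight=row.weight,
            )
        return g


def _triads_from_edges(edges: pd.DataFrame) -> pd.DataFrame:
    lm = edges[edges["interaction_type"] == "lncRNA-miRNA"]
    mg = edges[edges["interaction_type"] == "miRNA-target"]
    lg = edges[edges["interaction_type"] == "lncRNA-mRNA"]
    lg_pairs = {
        (row.source, row.target): row for row in lg.itertuples(index=False)
    }
    by_mirna: dict[str, list] = {}
    for row in lm.itertuples(index=False):
        by_mirna.setdefault(row.target, []).append(row)
    records = []
    for g_row in mg.itertuples(index=False):
        m, g = g_row.source, g_row.target
        for l_row in by_mirna.get(m, []):
            l = l_row.source
            lg_row = lg_pairs.get((l, g))
            if lg_row is None:
                continue
            records.append(
                {
                    "lncrna": l,
                    "mirna": m,
                    "mrna": g,
                    "r_lm": l_row.r,
                    "r_mg": g_row.r,
                    "r_lg": lg_row.r,
                    "min_p_adj": min(l_row.p_adj, g_row.p_adj, lg_row.p_adj),
                }
            )
    df = pd.DataFrame(records, columns=TRIAD_COLUMNS)
    return df.sort_values(["lncrna", "mirna", "mrna"], kind="mergesort").reset_index(
        drop=True
    )


def _node_regulation(feature: str, deg_table: pd.DataFrame | None) -> str:
    if deg_table is None:
        return "na"
    hit = deg_table.loc[deg_table["feature"] == feature, "call"]
    return str(hit.iloc[0]) if len(hit) else "na"


def build_cerna(
    lnc_matrix: ExpressionMatrix,
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    target_map: TargetMap,
    deg_tables: dict[str, pd.DataFrame] | None = None,
    threshold: float = CORR_THRESHOLD,
    require_lnc_mrna_positive: bool = True,
    lnc_target_map: bool = False,
    adj_p_max: float = ADJ_P_MAX,
    pseudocount: float = 1.0,
) -> CernaNetwork:
    """Infer the lncRNA-miRNA-mRNA ceRNA network.

    A sponge triad (l, m, g) is emitted iff r(l, m) <= -threshold,
    r(m, g) <= -threshold with (m, g) in the target map, and (by default)
    r(l, g) >= +threshold — the sign pattern of a lncRNA sequestering a miRNA
    and thereby de-repressing its target. ``require_lnc_mrna_positive=False``
    drops the third condition. ``lnc_target_map=True`` additionally restricts
    lncRNA-miRNA edges to pairs present in the target map with lncRNA targets.

    ``deg_tables`` (mapping layer -> DEG table for one contrast) annotates
    node regulation directions.
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"threshold must lie in (0, 1], got {threshold}")
    samples = mrna_matrix.sample_ids
    for other in (mirna_matrix, lnc_matrix):
        if other.sample_ids != samples:
            raise SampleMismatchError(
                "expression layers must share identical samples in identical order"
            )
    deg_tables = deg_tables or {}

    lnc_log = log2_cpm(lnc_matrix, pseudocount)
    mi_log = log2_cpm(mirna_matrix, pseudocount)
    mrna_log = log2_cpm(mrna_matrix, pseudocount)

    # miRNA -> mRNA repression edges (target-map constrained)
    mg_edges = mirna_target_edges(
        mi_log, mrna_log, target_map, r_max=-threshold, adj_p_max=adj_p_max
    )

    # lncRNA - miRNA edges (negative; correlation-only unless a lncRNA map is used)
    lm_corr = correlate(lnc_log, mi_log)
    lm_edges = coexpression_edges(
        lm_corr,
        threshold=threshold,
        interaction_type="lncRNA-miRNA",
        signed="neg",
        adj_p_max=adj_p_max,
    )
    if lnc_target_map:
        allowed = {(t, m) for m, t, lay in target_map.pairs if lay == "lncRNA"}
        keep = [
            (row.source, row.target) in allowed
            for row in lm_edges.itertuples(index=False)
        ]
        lm_edges = lm_edges[keep].reset_index(drop=True)

    # lncRNA - mRNA edges (positive leg of the sponge pattern)
    lg_corr = correlate(lnc_log, mrna_log)
    lg_edges = coexpression_edges(
        lg_corr,
        threshold=threshold,
        interaction_type="lncRNA-mRNA",
        signed="pos" if require_lnc_mrna_positive else "abs",
        adj_p_max=adj_p_max,
    )

    nonempty = [f for f in (lm_edges, mg_edges, lg_edges) if len(f)]
    edges = (
        pd.concat(nonempty, ignore_index=True) if nonempty else _edge_frame([])
    )
    triads = _triads_from_edges(edges)

    node_records = []
    layer_tables = {
        "lncRNA": (lnc_matrix, deg_tables.get("lncRNA")),
        "miRNA": (mirna_matrix, deg_tables.get("miRNA")),
        "mRNA": (mrna_matrix, deg_tables.get("mRNA")),
    }
    in_edges = set(edges["source"]) | set(edges["target"])
    for layer, (mat, table) in layer_tables.items():
        for fid in mat.feature_ids:
            if fid in in_edges:
                node_records.append(
                    {
                        "id": fid,
                        "layer": layer,
                        "regulation": _node_regulation(fid, table),
                    }
                )
    nodes = pd.DataFrame(node_records, columns=["id", "layer", "regulation"])

    params = {
        "threshold": threshold,
        "require_lnc_mrna_positive": require_lnc_mrna_positive,
        "lnc_target_map": lnc_target_map,
        "adj_p_max": adj_p_max,
        "n_samples": len(samples),
    }
    return CernaNetwork(nodes=nodes, edges=edges, triads=triads, params=params)
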