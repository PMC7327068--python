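"""Readers and writers for every on-disk artifact of the pipeline.

All files are plain TSV (gene descriptions contain commas), UTF-8, Unix
newlines, with a fixed column order, so that a write followed by a read is an
identity and byte-level output is reproducible. Feature identifiers are opaque
strings; the RNA layer of a matrix is declared by the caller, never inferred
from the ids.

Formats
-------
expression    feature_id column + one column per sample (features x samples)
sample sheet  columns ``sample``, ``group``
target map    columns ``mirna_id``, ``target_id``, ``target_layer``
GMT           standard tab-separated ``name  description  gene...`` lines
SIF           ``source  interaction  target`` (Cytoscape-loadable)
edge attrs    columns ``source target interaction_type r p_adj weight``
histology     glomeruli: ``animal group g01..g40``; tubulointerstitium:
              ``animal group injury_percent masson_percent``
Ct table      columns ``sample group gene ct``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    DuplicateFeatureError,
    DuplicateSampleError,
    MalformedGmtError,
    MissingGroupError,
    NegativeValueError,
    NonNumericValueError,
    UnassignedSampleError,
    ValidationError,
)

LAYERS = ("mRNA", "miRNA", "lncRNA")
TARGET_LAYERS = ("mRNA", "lncRNA")

EDGE_ATTR_COLUMNS = ["source", "target", "interaction_type", "r", "p_adj", "weight"]


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A features x samples abundance table for one RNA layer.

    Parameters
    ----------
    layer
        One of ``mRNA``, ``miRNA``, ``lncRNA``.
    values
        DataFrame with feature ids as index and sample ids as columns;
        finite, non-negative.
    design
        Series mapping every sample id to its group label.
    """

    layer: str
    values: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        idx = self.values.index
        if idx.duplicated().any():
            dups = idx[idx.duplicated()].unique().tolist()
            raise DuplicateFeatureError(f"duplicate feature id(s): {dups}")
        cols = self.values.columns
        if cols.duplicated().any():
            raise DuplicateSampleError(
                f"duplicate sample id(s): {cols[cols.duplicated()].unique().tolist()}"
            )
        missing = [s for s in cols if s not in self.design.index]
        if missing:
            raise UnassignedSampleError(f"sample(s) without group assignment: {missing}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
            raise NonNumericValueError("expression values must be finite numbers")
        if (arr < 0).any():
            raise NegativeValueError("expression values must be >= 0")
        # keep only the design rows for present samples, in column order
        self.design = self.design.loc[list(cols)]
        self.design.name = "group"
        self.design.index.name = "sample"

    # -- convenience accessors ------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.design:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group: str) -> list[str]:
        if group not in set(self.design):
            raise MissingGroupError(f"group {group!r} not present in design")
        return [s for s in self.sample_ids if self.design[s] == group]


@dataclass(frozen=True)
class TargetMap:
    """Predicted (miRNA, target) interaction pairs with target layer labels."""

    pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for m, t, layer in self.pairs:
            if layer not in TARGET_LAYERS:
                raise ValidationError(
                    f"target_layer {layer!r} for pair ({m}, {t}) not in {TARGET_LAYERS}"
                )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, str]]) -> "TargetMap":
        return cls(frozenset(tuple(p) for p in pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple) -> bool:
        if len(pair) == 2:  # (mirna, target) regardless of layer
            return any((pair[0], pair[1]) == (m, t) for m, t, _ in self.pairs)
        return tuple(pair) in self.pairs

    def for_layer(self, layer: str) -> set[tuple[str, str]]:
        return {(m, t) for m, t, lay in self.pairs if lay == layer}

    def targets_of(self, mirna: str, layer: str = "mRNA") -> set[str]:
        return {t for m, t, lay in self.pairs if m == mirna and lay == layer}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.pairs)
        return pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_layer"])


@dataclass
class PathwaySets:
    """Named gene sets with free-text descriptions (GMT content)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"pathway {name!r} has an empty gene set")
            # collapse duplicates, preserving first-seen order
            self.sets[name] = list(dict.fromkeys(str(g) for g in genes))
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def genes(self, name: str) -> set[str]:
        return set(self.sets[name])


# ---------------------------------------------------------------------------
# expression + sample sheet
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> pd.Series:
    """Read a two-column (sample, group) TSV into a sample -> group Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ValidationError(f"sample sheet {path} lacks required column {col!r}")
    if df["sample"].duplicated().any():
        raise DuplicateSampleError(
            f"duplicate sample(s) in sheet: {df.loc[df['sample'].duplicated(), 'sample'].tolist()}"
        )
    if df[["sample", "group"]].isna().any().any():
        raise ValidationError("sample sheet contains empty cells")
    design = df.set_index("sample")["group"]
    design.index.name = "sample"
    return design


def write_sample_sheet(design: pd.Series, path: str | Path) -> None:
    df = design.rename("group").rename_axis("sample").reset_index()
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_expression(
    path: str | Path, sample_sheet_path: str | Path, layer: str
) -> ExpressionMatrix:
    """Read an expression TSV plus sample sheet into a validated matrix.

    Column order is taken from the file. Raises a distinct error for each
    corruption: duplicate feature ids, samples missing from the sheet,
    non-numeric or negative cells.
    """
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    if raw.shape[1] < 2:
        raise ValidationError(f"expression file {path} has no sample columns")
    feat_col = raw.columns[0]
    if raw[feat_col].duplicated().any():
        raise DuplicateFeatureError(
            f"duplicate feature id(s) in {path}: "
            f"{raw.loc[raw[feat_col].duplicated(), feat_col].unique().tolist()}"
        )
    values = raw.set_index(feat_col)
    values.index.name = "feature_id"
    numeric = values.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        colmask = numeric.isna().any(axis=0)
        col = colmask[colmask].index[0]
        row = numeric.index[numeric[col].isna()][0]
        raise NonNumericValueError(
            f"non-numeric or missing value at feature {row!r}, sample {col!r} in {path}"
        )
    design = read_sample_sheet(sample_sheet_path)
    return ExpressionMatrix(layer=layer, values=numeric, design=design)


def write_expression(
    matrix: ExpressionMatrix,
    path: str | Path,
    sample_sheet_path: str | Path | None = None,
) -> None:
    matrix.values.rename_axis("feature_id").to_csv(
        path, sep="\t", lineterminator="\n"
    )
    if sample_sheet_path is not None:
        write_sample_sheet(matrix.design, sample_sheet_path)


# ---------------------------------------------------------------------------
# target map
# ---------------------------------------------------------------------------


def read_target_map(path: str | Path) -> TargetMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = ["mirna_id", "target_id", "target_layer"]
    for col in need:
        if col not in df.columns:
            raise ValidationError(f"target map {path} lacks required column {col!r}")
    if df[need].isna().any().any():
        raise ValidationError(f"target map {path} contains empty cells")
    return TargetMap.from_pairs(df[need].itertuples(index=False, name=None))


def write_target_map(tmap: TargetMap, path: str | Path) -> None:
    tmap.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> PathwaySets:
    """Parse a GMT file. A line with fewer than 3 fields is an error, not a skip."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MalformedGmtError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); need >= 3"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise MalformedGmtError(f"{path}:{lineno}: pathway {name!r} has no genes")
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return PathwaySets(sets=sets, descriptions=descriptions)


def write_gmt(pathways: PathwaySets, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name in pathways:
            genes = pathways.sets[name]
            desc = pathways.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# network export (Cytoscape SIF + attribute table)
# ---------------------------------------------------------------------------


def write_edge_list(network, sif_path: str | Path, attr_path: str | Path) -> None:
    """Export a network's edges as SIF plus an attribute TSV.

    ``network`` is anything with an ``edges`` DataFrame holding the columns
    ``source, target, interaction_type, r, p_adj, weight`` (a
    :class:`~cernaflow.networks.CernaNetwork`, or the DataFrame itself).
    An empty network yields a zero-line SIF and a header-only attribute TSV.
    """
    edges = network if isinstance(network, pd.DataFrame) else network.edges
    with open(sif_path, "w", encoding="utf-8", newline="\n") as fh:
        for row in edges.itertuples(index=False):
            fh.write(f"{row.source}\t{row.interaction_type}\t{row.target}\n")
    out = edges.reindex(columns=EDGE_ATTR_COLUMNS)
    out.to_csv(attr_path, sep="\t", index=False, lineterminator="\n")


def read_edge_list(attr_path: str | Path) -> pd.DataFrame:
    """Read an edge attribute TSV back into a DataFrame (round-trip of export)."""
    df = pd.read_csv(attr_path, sep="\t", dtype={"source": str, "target": str})
    missing = [c for c in EDGE_ATTR_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"edge attribute file {attr_path} lacks column(s) {missing}")
    return df[EDGE_ATTR_COLUMNS]


# ---------------------------------------------------------------------------
# histology
# ---------------------------------------------------------------------------

N_GLOMERULI = 40
GRADE_COLUMNS = [f"g{i:02d}" for i in range(1, N_GLOMERULI + 1)]


@dataclass
class HistologyTables:
    """Per-animal semiquantitative histopathology readouts.

    ``glomeruli`` holds 40 graded glomeruli (grades 0-4) per animal;
    ``tubulo`` holds the percent injured tubulointerstitial area and the
    Masson-positive (fibrotic) area percentage.
    """

    glomeruli: pd.DataFrame  # animal, group, g01..g40
    tubulo: pd.DataFrame  # animal, group, injury_percent, masson_percent

    def __post_init__(self) -> None:
        for col in ["animal", "group", *GRADE_COLUMNS]:
            if col not in self.glomeruli.columns:
                raise ValidationError(f"glomeruli table lacks column {col!r}")
        grades = self.glomeruli[GRADE_COLUMNS].to_numpy()
        if not np.isin(grades, [0, 1, 2, 3, 4]).all():
            raise ValidationError("glomerulus grades must be integers in 0..4")
        for col in ("animal", "group", "injury_percent"):
            if col not in self.tubulo.columns:
                raise ValidationError(f"tubulointerstitial table lacks column {col!r}")
        pct = self.tubulo["injury_percent"].to_numpy(dtype=float)
        if ((pct < 0) | (pct > 100)).any():
            raise ValidationError("injury_percent must lie in [0, 100]")


def read_histology(glomeruli_path: str | Path, tubulo_path: str | Path) -> HistologyTables:
    glom = pd.read_csv(glomeruli_path, sep="\t", dtype={"animal": str, "group": str})
    tub = pd.read_csv(tubulo_path, sep="\t", dtype={"animal": str, "group": str})
    return HistologyTables(glomeruli=glom, tubulo=tub)


def write_histology(
    tables: HistologyTables, glomeruli_path: str | Path, tubulo_path: str | Path
) -> None:
    tables.glomeruli.to_csv(glomeruli_path, sep="\t", index=False, lineterminator="\n")
    tables.tubulo.to_csv(tubulo_path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# qPCR Ct table
# ---------------------------------------------------------------------------

CT_COLUMNS = ["sample", "group", "gene", "ct"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str, "gene": str})
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"Ct table {path} lacks column(s) {missing}")
    if df[CT_COLUMNS].isna().any().any():
        raise ValidationError(f"Ct table {path} contains empty cells")
    return df[CT_COLUMNS]


def write_ct_table(ct: pd.DataFrame, path: str | Path) -> None:
    ct[CT_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")
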