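"""Closed-form histopathology and qPCR scores.

Implements the semiquantitative renal scores used to stage interstitial
fibrosis in the rat model — the glomerular sclerosis index (GSI) over 40
graded glomeruli per animal, the tubulointerstitial injury index (TII) from
the percent injured area — together with 2^-ddCT relative qPCR quantification
and Table-style group summaries (mean +/- SD with significance marks against
the model and normal control groups).
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MissingGroupError, ValidationError
from .io import GRADE_COLUMNS, N_GLOMERULI, HistologyTables

__all__ = [
    "gsi",
    "tii",
    "ddct",
    "group_summary",
    "significance_mark",
    "score_histology",
]


def gsi(grades: Sequence[int] | Mapping[int, int]) -> float:
    """Glomerular sclerosis index of one animal.

    Each of the 40 scored glomeruli carries a grade 0-4 (0 normal; 1-4 by
    quartile of cross-sectional sclerosis). The index is the weighted mean

        GSI = (N1*1 + N2*2 + N3*3 + N4*4) / 40

    where ``Nk`` counts glomeruli of grade ``k``.

    Parameters
    ----------
    grades
        Either the raw list of exactly 40 grades, or a mapping
        ``{grade: count}`` whose counts sum to 40.
    """
    if isinstance(grades, Mapping):
        counts = {int(k): int(v) for k, v in grades.items()}
        if any(k not in range(5) for k in counts):
            raise ValidationError(f"grade keys must be in 0..4, got {sorted(counts)}")
        if any(v < 0 for v in counts.values()):
            raise ValidationError("grade counts must be >= 0")
        total = sum(counts.values())
        if total != N_GLOMERULI:
            raise ValidationError(f"grade counts must sum to {N_GLOMERULI}, got {total}")
        weighted = sum(k * v for k, v in counts.items())
    else:
        arr = np.asarray(list(grades))
        if arr.size != N_GLOMERULI:
            raise ValidationError(f"expected {N_GLOMERULI} grades, got {arr.size}")
        if not np.isin(arr, [0, 1, 2, 3, 4]).all():
            raise ValidationError("grades must be integers in 0..4")
        weighted = int(arr.sum())
    return weighted / N_GLOMERULI


# TII bins: 0 only for no deformity at all; then <10, <25, <50, <75, >=75 %.
# Boundary values (exactly 10/25/50/75) go to the higher grade, consistent
# with the ">= 75" top bin.
_TII_UPPER = (10.0, 25.0, 50.0, 75.0)


def tii(injury_percent: float) -> int:
    """Tubulointerstitial injury index: grade 0-5 from percent injured area."""
    p = float(injury_percent)
    if not np.isfinite(p) or p < 0 or p > 100:
        raise ValidationError(f"injury percent must lie in [0, 100], got {injury_percent}")
    if p == 0:
        return 0
    for grade, upper in enumerate(_TII_UPPER, start=1):
        if p < upper:
            return grade
    return 5


def ddct(
    ct_table: pd.DataFrame,
    reference_gene: str = "Gapdh",
    calibrator_group: str = "NC",
) -> pd.DataFrame:
    """Relative expression by the 2^-ddCT method.

    dCT = target Ct - reference-gene Ct, per sample; ddCT subtracts the mean
    dCT of the calibrator group; relative expression is 2^-ddCT (so the
    calibrator group averages ~1 and one cycle of ddCT halves expression).

    Parameters
    ----------
    ct_table
        Long-format table with columns ``sample, group, gene, ct``.
    reference_gene
        Housekeeping gene used for normalization (GAPDH by convention).
    calibrator_group
        Group whose mean dCT anchors ddCT = 0.

    Returns
    -------
    DataFrame with columns
    ``sample, group, gene, ct, reference_ct, delta_ct, delta_delta_ct, rel_expr``.
    """
    need = {"sample", "group", "gene", "ct"}
    if not need.issubset(ct_table.columns):
        raise ValidationError(f"Ct table needs columns {sorted(need)}")
    ref = ct_table[ct_table["gene"] == reference_gene]
    if ref.empty:
        raise ValidationError(f"reference gene {reference_gene!r} absent from Ct table")
    if ref["sample"].duplicated().any():
        raise ValidationError(f"multiple {reference_gene!r} Ct values for one sample")
    ref_ct = ref.set_index("sample")["ct"]

    targets = ct_table[ct_table["gene"] != reference_gene].copy()
    missing = set(targets["sample"]) - set(ref_ct.index)
    if missing:
        raise ValidationError(
            f"sample(s) lack a {reference_gene!r} Ct: {sorted(missing)}"
        )
    targets["reference_ct"] = targets["sample"].map(ref_ct)
    targets["delta_ct"] = targets["ct"] - targets["reference_ct"]

    cal = targets[targets["group"] == calibrator_group]
    if cal.empty:
        raise MissingGroupError(f"calibrator group {calibrator_group!r} is empty")
    cal_mean = cal.groupby("gene")["delta_ct"].mean()
    missing_genes = set(targets["gene"]) - set(cal_mean.index)
    if missing_genes:
        raise MissingGroupError(
            f"gene(s) unmeasured in calibrator group: {sorted(missing_genes)}"
        )
    targets["delta_delta_ct"] = targets["delta_ct"] - targets["gene"].map(cal_mean)
    targets["rel_expr"] = 2.0 ** (-targets["delta_delta_ct"])
    cols = [
        "sample",
        "group",
        "gene",
        "ct",
        "reference_ct",
        "delta_ct",
        "delta_delta_ct",
        "rel_expr",
    ]
    return targets[cols].reset_index(drop=True)


def significance_mark(p: float, symbol: str = "*") -> str:
    """Tiered mark: three symbols below 0.001, two below 0.01, one below 0.05."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return symbol * 3
    if p < 0.01:
        return symbol * 2
    if p < 0.05:
        return symbol
    return ""


_MARK_WORD = {"*": "stars", "#": "hashes"}


def group_summary(
    values: Mapping[str, Sequence[float]],
    reference_groups: Sequence[str] = ("OC", "NC"),
    mark_symbols: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Mean +/- SD per group with significance marks against reference groups.

    Reproduces the physiology-table layout of small-animal studies: each group
    is compared with the model control (``*`` marks) and the normal control
    (``#`` marks) by a two-sided Welch t-test; one/two/three symbols at
    p < 0.05 / 0.01 / 0.001. SD is the sample (n-1) standard deviation.

    Parameters
    ----------
    values
        Mapping group label -> sequence of per-animal measurements
        (>= 2 values per group).
    reference_groups
        Groups every other group is tested against; a group compared with
        itself gets no mark.
    """
    if mark_symbols is None:
        mark_symbols = {"OC": "*", "NC": "#"}
    arrays = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    for g, arr in arrays.items():
        if arr.size < 2:
            raise ValidationError(f"group {g!r} has {arr.size} value(s); need >= 2")
    for ref in reference_groups:
        if ref not in arrays:
            raise MissingGroupError(f"reference group {ref!r} absent")

    rows = []
    for g, arr in arrays.items():
        row: dict[str, object] = {
            "group": g,
            "n": int(arr.size),
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)),
        }
        for ref in reference_groups:
            symbol = mark_symbols.get(ref, "*")
            word = _MARK_WORD.get(symbol, "marks")
            if g == ref:
                p = float("nan")
            else:
                p = float(
                    stats.ttest_ind(arr, arrays[ref], equal_var=False).pvalue
                )
            row[f"p_vs_{ref}"] = p
            row[f"{word}_vs_{ref}"] = significance_mark(p, symbol)
        rows.append(row)
    return pd.DataFrame(rows)


def score_histology(tables: HistologyTables) -> pd.DataFrame:
    """Per-animal GSI and TII from the histology tables.

    Returns a DataFrame ``animal, group, gsi, injury_percent, tii`` (plus
    ``masson_percent`` when present).
    """
    glom = tables.glomeruli
    scores = pd.DataFrame(
        {
            "animal": glom["animal"],
            "group": glom["group"],
            "gsi": [
                gsi(row) for row in glom[GRADE_COLUMNS].to_numpy(dtype=int)
            ],
        }
    )
    tub = tables.tubulo.set_index("animal")
    scores["injury_percent"] = scores["animal"].map(tub["injury_percent"])
    scores["tii"] = scores["injury_percent"].map(tii)
    if "masson_percent" in tub.columns:
        scores["masson_percent"] = scores["animal"].map(tub["masson_percent"])
    return scores
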