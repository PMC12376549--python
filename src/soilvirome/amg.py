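"""Auxiliary metabolic gene (AMG) retention, categorisation and Z-scoring.

AMG candidates come from viral-genome annotation with an auxiliary score
(1 = confidently metabolic and virus-encoded, 5 = likely not an AMG) and a
set of single-letter flags. The retention rule keeps candidates with
auxiliary score 1-3 that carry a metabolism flag (M) or Pfam-metabolism
flag (F) and none of the disqualifying flags (V viral-function, A
attachment, P peptidase, T transposon, B adjacent-to-transposon) —
the flag convention of the annotation tool the scores come from; both flag
sets are configurable.

Retained AMGs are categorised by KEGG level-2 pathway category and by
CAZyme class parsed from the family label prefix (GH, GT, PL, CE, AA,
CBM), and per-gene abundances are Z-score normalised across treatments.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

REQUIRE_FLAGS = frozenset("MF")
EXCLUDE_FLAGS = frozenset("VAPTB")
KNOWN_FLAGS = frozenset("MFVAPTBEKJ")
SCORE_RANGE = (1, 3)
CAZYME_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")

_KO_MAP: pd.Series | None = None


def _parse_flags(raw) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return frozenset()
    letters = {c for c in str(raw) if c.isalpha()}
    unknown = letters - KNOWN_FLAGS
    if unknown:
        warnings.warn(f"unknown AMG flag letters ignored: {sorted(unknown)}")
        letters -= unknown
    return frozenset(letters)


def filter_amgs(
    candidates: pd.DataFrame,
    require_flags: Iterable[str] = REQUIRE_FLAGS,
    exclude_flags: Iterable[str] = EXCLUDE_FLAGS,
    score_range: tuple[int, int] = SCORE_RANGE,
) -> pd.DataFrame:
    """Retain candidates passing the score/flag rule; duplicates collapsed.

    Retain iff auxiliary_score in [score_range] AND flags intersect
    ``require_flags`` AND flags are disjoint from ``exclude_flags``.
    The predicate is pure: row order never changes the retained set, and
    re-filtering retained rows is a no-op.
    """
    require = frozenset(require_flags)
    exclude = frozenset(exclude_flags)
    lo, hi = score_range
    flags = candidates["flags"].map(_parse_flags)
    score = candidates["auxiliary_score"].astype(int)
    keep = (
        score.between(lo, hi)
        & flags.map(lambda s: bool(s & require))
        & flags.map(lambda s: not (s & exclude))
    )
    return (
        candidates[keep]
        .drop_duplicates(subset="gene_id", keep="first")
        .sort_values("gene_id", ignore_index=True)
    )


def combine_calls(a: pd.DataFrame, b: pd.DataFrame, how: str = "union") -> pd.DataFrame:
    """Combine two callers' retained tables keyed by gene_id."""
    if how == "union":
        out = pd.concat([a, b], ignore_index=True).drop_duplicates(subset="gene_id")
    elif how == "intersection":
        out = a[a["gene_id"].isin(set(b["gene_id"]))]
    else:
        raise ValueError(f"unknown combination mode: {how!r}")
    return out.sort_values("gene_id", ignore_index=True)


def _ko_level2_map() -> pd.Series:
    global _KO_MAP
    if _KO_MAP is None:
        path = resources.files("soilvirome").joinpath("data/kegg_level2.tsv")
        with resources.as_file(path) as p:
            table = pd.read_csv(p, sep="\t")
        _KO_MAP = table.set_index("ko_id")["kegg_level2"]
    return _KO_MAP


def cazyme_class(family) -> str:
    """CAZyme class from the leading letters of a family label (GT2 -> GT)."""
    if family is None or (isinstance(family, float) and np.isnan(family)) or family == "":
        return ""
    label = str(family).strip()
    for cls in sorted(CAZYME_CLASSES, key=len, reverse=True):
        if label.upper().startswith(cls):
            return cls
    warnings.warn(f"unparseable CAZyme family label: {label!r}")
    return "unclassified"


def categorize(retained: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count retained AMGs by KEGG level-2 category and by CAZyme class.

    A gene's level-2 category comes from its ``kegg_level2`` column when
    present, else from the packaged KO -> category table; genes lacking
    both a KO and a CAZyme label are counted as "unclassified".
    """
    df = retained.copy()
    ko_map = _ko_level2_map()

    def level2(row) -> str:
        lvl = row.get("kegg_level2", "")
        if isinstance(lvl, str) and lvl:
            return lvl
        ko = row.get("ko_id", "")
        if isinstance(ko, str) and ko:
            return ko_map.get(ko, "unclassified")
        return ""

    df["kegg_level2_resolved"] = df.apply(level2, axis=1)
    df["cazyme_class"] = df.get("cazyme_family", pd.Series("", index=df.index)).map(cazyme_class)

    unlabeled = (df["kegg_level2_resolved"] == "") & (df["cazyme_class"] == "")
    df.loc[unlabeled, "kegg_level2_resolved"] = "unclassified"

    kegg_counts = (
        df.loc[df["kegg_level2_resolved"] != "", "kegg_level2_resolved"]
        .value_counts().rename_axis("kegg_level2").reset_index(name="n_genes")
        .sort_values(["kegg_level2"], ignore_index=True)
    )
    caz_counts = (
        df.loc[df["cazyme_class"] != "", "cazyme_class"]
        .value_counts().rename_axis("cazyme_class").reset_index(name="n_genes")
        .sort_values(["cazyme_class"], ignore_index=True)
    )
    return kegg_counts, caz_counts


def zscore_by_treatment(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-score of a genes x treatments abundance matrix.

    z = (x - mean) / SD with sample SD (ddof=1); rows constant across
    treatments map to all zeros. Fewer than two treatments is an error
    (the Z-score is undefined).
    """
    if matrix.shape[1] < 2:
        raise ValueError("Z-scoring needs at least two treatments")
    x = matrix.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
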