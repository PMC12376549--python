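"""Lysogenic vs potentially lytic classification of retained viral contigs.

A contig is called lysogenic when it carries at least one lysogeny marker
protein annotation (integrase, transposase, invertase, recombinase,
excisionase) or when an external lifestyle predictor calls it lysogenic
(union merge by default, since the external tool is supplementary).
Every remaining contig is a potential lytic virus — classification is a
partition, never a third state.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

#: marker-protein classes that count as lysogeny evidence
MARKER_LEXICON = frozenset(
    {"integrase", "transposase", "invertase", "recombinase", "excisionase"}
)

LYSOGENIC = "lysogenic"
LYTIC = "lytic"


def classify_lifestyle(
    contig_ids: Sequence[str],
    markers: pd.DataFrame | None = None,
    external: pd.DataFrame | None = None,
    merge: str = "union",
) -> pd.DataFrame:
    """One lifestyle call per contig.

    Parameters
    ----------
    contig_ids : the retained viral contigs to classify.
    markers : frame with columns contig_id, gene_id, marker_class. Only
        rows whose marker_class is in the lysogeny lexicon are evidence.
    external : optional frame with columns contig_id, prediction
        ("lysogenic"/"lytic"). Unknown contig ids are ignored with a warning.
    merge : "union" (marker OR external), "markers-only", "external-only".
    """
    if merge not in ("union", "markers-only", "external-only"):
        raise ValueError(f"unknown merge mode: {merge!r}")
    known = set(contig_ids)

    marker_ev: dict[str, list[str]] = {c: [] for c in contig_ids}
    if markers is not None and len(markers):
        unknown = set(markers["contig_id"]) - known
        if unknown:
            raise ValueError(f"marker rows reference unknown contigs: {sorted(unknown)}")
        for _, row in markers.iterrows():
            if row["marker_class"] in MARKER_LEXICON:
                marker_ev[row["contig_id"]].append(str(row["marker_class"]))

    external_ev: set[str] = set()
    if external is not None and len(external):
        unknown = set(external["contig_id"]) - known
        if unknown:
            warnings.warn(
                f"external predictions for unknown contigs ignored: {sorted(unknown)}"
            )
        ext = external[external["contig_id"].isin(known)]
        external_ev = set(ext.loc[ext["prediction"] == LYSOGENIC, "contig_id"])

    rows = []
    for cid in contig_ids:
        has_marker = bool(marker_ev[cid]) and merge != "external-only"
        has_external = cid in external_ev and merge != "markers-only"
        evidence = sorted(set(marker_ev[cid])) if has_marker else []
        if has_external:
            evidence.append("external")
        rows.append({
            "contig_id": cid,
            "call": LYSOGENIC if (has_marker or has_external) else LYTIC,
            "evidence": ";".join(evidence),
        })
    return pd.DataFrame(rows, columns=["contig_id", "call", "evidence"])


def lifestyle_proportions(
    calls: pd.DataFrame,
    abundance: pd.DataFrame | None = None,
    weighting: str = "abundance",
) -> pd.DataFrame:
    """Per-sample lysogenic/lytic fractions.

    ``weighting="abundance"`` uses each contig's share of the sample's
    total abundance (RPKM); ``"count"`` uses the unweighted fraction of
    contigs present (abundance > 0) in the sample, or of all contigs when
    no abundance matrix is given. Samples with zero total abundance get
    missing fractions.
    """
    if weighting not in ("abundance", "count"):
        raise ValueError(f"unknown weighting: {weighting!r}")
    is_lys = calls.set_index("contig_id")["call"] == LYSOGENIC

    if abundance is None:
        frac = float(is_lys.mean())
        return pd.DataFrame(
            [{"sample_id": "all", "frac_lysogenic": frac, "frac_lytic": 1 - frac}]
        )

    missing = set(abundance.index) - set(is_lys.index)
    if missing:
        raise ValueError(f"abundance rows without a lifestyle call: {sorted(missing)}")
    lys = is_lys.reindex(abundance.index).to_numpy()

    rows = []
    for sample in abundance.columns:
        col = abundance[sample].to_numpy(dtype=float)
        total = col.sum()
        if total <= 0:
            warnings.warn(f"sample {sample!r} has zero total abundance")
            frac = np.nan
        elif weighting == "abundance":
            frac = col[lys].sum() / total
        else:
            present = col > 0
            frac = lys[present].mean()
        rows.append({
            "sample_id": sample,
            "frac_lysogenic": frac,
            "frac_lytic": 1 - frac if np.isfinite(frac) else np.nan,
        })
    return pd.DataFrame(rows, columns=["sample_id", "frac_lysogenic", "frac_lytic"])
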