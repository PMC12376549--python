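"""Virus-host linking by three evidence channels.

1. CRISPR spacer matching — each host spacer is scanned ungapped against
   every viral contig on both strands; a window qualifies when its Hamming
   distance d satisfies d <= 2 AND identity (L-d)/L >= 95% (both printed
   thresholds applied conjunctively; the effective mismatch budget is
   min(2, floor(0.05 L)), which makes the 2-mismatch allowance unreachable
   for spacers shorter than 40 nt — a documented tension between the two
   printed rules). A ``rule="union"`` switch applies either threshold alone.
2. tRNA matching — same ungapped scan at identity >= 95% (no absolute
   mismatch cap).
3. Genomic homology — pre-computed tabular hits filtered at identity >= 70,
   query coverage >= 75%, e-value <= 1e-3, bit score >= 50 and alignment
   length >= 2500 bp (all inclusive, as printed).

Short-query channels report no e-value: ungapped near-exact matching at
these identity levels subsumes the e-value cutoff at this scale.
Coordinates are 0-based half-open on the forward strand of the virus.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd

from ._util import encode, hamming_windows, revcomp, validate_nt

LINK_COLUMNS = [
    "virus_id", "host_id", "channel", "query_id", "identity",
    "mismatches", "strand", "start", "end",
]

SPACER_MAX_MISMATCH = 2
SPACER_MIN_IDENTITY = 0.95
TRNA_MIN_IDENTITY = 0.95
HOM_MIN_IDENTITY = 70.0
HOM_MIN_QCOV = 75.0
HOM_MAX_EVALUE = 1e-3
HOM_MIN_BITSCORE = 50.0
HOM_MIN_LENGTH = 2500
MIN_SPACER_LEN = 20


def _scan_channel(
    queries: pd.DataFrame,
    viral_seqs: Mapping[str, str],
    channel: str,
    id_col: str,
    budget_fn,
) -> pd.DataFrame:
    """Both-strand ungapped scan of short host queries over viral contigs."""
    encoded = {vid: encode(seq) for vid, seq in viral_seqs.items()}
    rows = []
    for _, q in queries.iterrows():
        seq = str(q["sequence"]).upper()
        validate_nt(seq, f"{channel} {q[id_col]}")
        L = len(seq)
        budget = budget_fn(L)
        fwd = encode(seq)
        rev = encode(revcomp(seq))
        for vid, contig in encoded.items():
            for strand, query_arr in (("+", fwd), ("-", rev)):
                for pos, d in hamming_windows(contig, query_arr, budget):
                    rows.append({
                        "virus_id": vid,
                        "host_id": q["host_contig_id"],
                        "channel": channel,
                        "query_id": q[id_col],
                        "identity": 100.0 * (L - d) / L,
                        "mismatches": d,
                        "strand": strand,
                        "start": pos,
                        "end": pos + L,
                    })
    return pd.DataFrame(rows, columns=LINK_COLUMNS)


def match_spacers(
    spacers: pd.DataFrame,
    viral_seqs: Mapping[str, str],
    max_mismatch: int = SPACER_MAX_MISMATCH,
    min_identity: float = SPACER_MIN_IDENTITY,
    rule: str = "intersection",
) -> pd.DataFrame:
    """CRISPR protospacer search; one link row per qualifying window.

    ``rule="intersection"`` (default) requires d <= max_mismatch AND
    (L-d)/L >= min_identity; ``"union"`` accepts either.
    """
    if rule not in ("intersection", "union"):
        raise ValueError(f"unknown rule: {rule!r}")
    short = spacers.loc[spacers["sequence"].str.len() < MIN_SPACER_LEN, "spacer_id"]
    if len(short):
        raise ValueError(f"spacers shorter than {MIN_SPACER_LEN} nt: {list(short)}")

    def budget(L: int) -> int:
        ident_budget = int(np.floor((1 - min_identity) * L))
        if rule == "intersection":
            return min(max_mismatch, ident_budget)
        return max(max_mismatch, ident_budget)

    return _scan_channel(spacers, viral_seqs, "spacer", "spacer_id", budget)


def match_trnas(
    trnas: pd.DataFrame,
    viral_seqs: Mapping[str, str],
    min_identity: float = TRNA_MIN_IDENTITY,
) -> pd.DataFrame:
    """tRNA-based host linking: full-length ungapped match at >= min_identity."""
    def budget(L: int) -> int:
        return int(np.floor((1 - min_identity) * L))

    return _scan_channel(trnas, viral_seqs, "trna", "trna_id", budget)


def filter_homology_hits(
    hits: pd.DataFrame,
    query_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Filter tabular homology hits into links; all thresholds inclusive.

    Accepts either a ``qcov`` column or the 12-column tabular dialect plus
    ``query_lengths`` (virus contig lengths) from which query coverage is
    computed as (qend - qstart + 1) / length * 100.
    """
    required = {"pident", "length", "evalue", "bitscore"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"homology table missing columns: {sorted(missing)}")
    df = hits.copy()
    if "qcov" not in df.columns:
        if query_lengths is None:
            raise ValueError("need a qcov column or query_lengths to compute coverage")
        for i, row in df.iterrows():
            if row["qseqid"] not in query_lengths:
                raise ValueError(f"row {i}: unknown query contig {row['qseqid']!r}")
        qlen = df["qseqid"].map(query_lengths).astype(float)
        df["qcov"] = (df["qend"] - df["qstart"] + 1) / qlen * 100.0

    bad = df[(df["pident"] < 0) | (df["pident"] > 100) | (df["length"] <= 0)]
    if len(bad):
        raise ValueError(f"malformed homology rows at lines: {list(bad.index)}")

    keep = (
        (df["pident"] >= HOM_MIN_IDENTITY)
        & (df["qcov"] >= HOM_MIN_QCOV)
        & (df["evalue"] <= HOM_MAX_EVALUE)
        & (df["bitscore"] >= HOM_MIN_BITSCORE)
        & (df["length"] >= HOM_MIN_LENGTH)
    )
    kept = df[keep]
    out = pd.DataFrame({
        "virus_id": kept["qseqid"],
        "host_id": kept["sseqid"],
        "channel": "homology",
        "query_id": kept["qseqid"],
        "identity": kept["pident"].astype(float),
        "mismatches": kept.get("mismatch", pd.Series(np.nan, index=kept.index)),
        "strand": np.where(kept["sstart"] <= kept["send"], "+", "-")
        if "sstart" in kept.columns else "+",
        "start": (kept["qstart"] - 1) if "qstart" in kept.columns else np.nan,
        "end": kept["qend"] if "qend" in kept.columns else np.nan,
    })
    return out.reset_index(drop=True)[LINK_COLUMNS]


def merge_links(
    *channel_tables: pd.DataFrame,
    taxonomy: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge channel link tables into unique virus-host pairs + host range.

    Returns (pairs, host_range). ``pairs`` has one row per (virus, host)
    with the sorted set of supporting channels; merging an already merged
    table is a no-op. ``host_range`` classifies each virus as specialist
    (all links to one host taxon, or one host contig when no taxonomy is
    given) or generalist.
    """
    frames = [t for t in channel_tables if t is not None and len(t)]
    if not frames:
        pairs = pd.DataFrame(columns=["virus_id", "host_id", "channels", "n_evidence"])
        return pairs, pd.DataFrame(columns=["virus_id", "n_hosts", "host_range"])
    cat = pd.concat(frames, ignore_index=True)
    if "channels" in cat.columns and "channel" not in cat.columns:
        cat = cat.rename(columns={"channels": "channel"})
    exploded = cat.assign(channel=cat["channel"].astype(str).str.split(",")).explode("channel")
    pairs = (
        exploded.groupby(["virus_id", "host_id"])["channel"]
        .agg(lambda s: ",".join(sorted(set(s))))
        .reset_index()
        .rename(columns={"channel": "channels"})
    )
    pairs["n_evidence"] = pairs["channels"].str.count(",") + 1
    pairs = pairs.sort_values(["virus_id", "host_id"], ignore_index=True)

    if taxonomy is not None:
        missing = set(pairs["host_id"]) - set(taxonomy)
        if missing:
            warnings.warn(
                f"no taxonomy for hosts {sorted(missing)}; host range at contig level"
            )
            taxon = pairs["host_id"]
        else:
            taxon = pairs["host_id"].map(taxonomy)
    else:
        taxon = pairs["host_id"]
    n_hosts = taxon.groupby(pairs["virus_id"]).nunique()
    host_range = pd.DataFrame({
        "virus_id": n_hosts.index,
        "n_hosts": n_hosts.to_numpy(),
        "host_range": np.where(n_hosts.to_numpy() == 1, "specialist", "generalist"),
    }).reset_index(drop=True)
    return pairs, host_range
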