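"""Viral-contig triage: primary screen, tripartite filtering, greedy clustering.

The retention pipeline applied to viral candidate contigs is:

1. primary screen — detector score >= 0.5, and removal of contigs with
   < 50% completeness or > 10% contamination (removal inequalities are
   strict, so boundary values survive);
2. tripartite criteria on per-contig gene-annotation counts:
   criterion 1: >= 5 genes with viral-protein-family (VPF) hits, < 20% of
   genes with KEGG Orthology annotations, <= 40% of genes covered by Pfam;
   criterion 2: VPF gene count >= Pfam gene count and VPF genes >= 60% of
   all genes;
3. greedy clustering at 95% nucleotide identity of contigs longer than
   5 kb, keeping the longest sequence of each cluster as representative.

Criteria are conjunctive by default (`admission="all"`); `admission="any"`
admits contigs passing either criterion 1 or criterion 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import edlib
import numpy as np
import pandas as pd

from ._util import revcomp

REQUIRED_FEATURES = (
    "contig_id", "length", "n_genes", "n_vpf_hit_genes", "n_kegg_genes",
    "n_pfam_genes", "detector_score", "completeness", "contamination",
)

#: default thresholds, as printed in the source protocol
MIN_SCORE = 0.5
MIN_COMPLETENESS = 50.0
MAX_CONTAMINATION = 10.0
MIN_VPF_HITS = 5
MAX_KEGG_FRAC = 0.20
MAX_PFAM_FRAC = 0.40
MIN_VPF_FRAC = 0.60
MIN_RETAIN_LEN = 5000   # retained if strictly greater
CLUSTER_IDENTITY = 0.95


class TriageInputError(ValueError):
    pass


@dataclass
class ScreenResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)


def _get(f: Mapping, key: str):
    try:
        v = f[key]
    except (KeyError, IndexError) as exc:
        raise TriageInputError(f"missing feature field: {key!r}") from exc
    if v is None or (isinstance(v, float) and np.isnan(v)):
        raise TriageInputError(f"missing feature field: {key!r}")
    return v


def screen_primary(f: Mapping) -> ScreenResult:
    """Primary detector/quality screen for one contig's features.

    Passes iff detector_score >= 0.5 AND completeness >= 50 AND
    contamination <= 10. Removal conditions are the strict inequalities
    "< 50% completeness" and "> 10% contamination", so boundary values pass.
    """
    reasons = []
    if not _get(f, "detector_score") >= MIN_SCORE:
        reasons.append("score")
    if _get(f, "completeness") < MIN_COMPLETENESS:
        reasons.append("completeness")
    if _get(f, "contamination") > MAX_CONTAMINATION:
        reasons.append("contamination")
    return ScreenResult(not reasons, reasons)


def tripartite_filter(f: Mapping) -> tuple[bool, bool, list[str]]:
    """Evaluate tripartite criteria 1 and 2 on one contig's gene counts.

    Returns (criterion1, criterion2, reasons). Contigs with no called genes
    fail both criteria with reason "no genes" rather than raising, so
    fragmentary contigs do not abort a run.
    """
    n = _get(f, "n_genes")
    if n <= 0:
        return False, False, ["no genes"]
    vpf = _get(f, "n_vpf_hit_genes")
    kegg = _get(f, "n_kegg_genes")
    pfam = _get(f, "n_pfam_genes")
    reasons = []
    c1 = True
    if not vpf >= MIN_VPF_HITS:
        c1 = False
        reasons.append("vpf_hits")
    if not kegg / n < MAX_KEGG_FRAC:
        c1 = False
        reasons.append("kegg_frac")
    if not pfam / n <= MAX_PFAM_FRAC:
        c1 = False
        reasons.append("pfam_frac")
    c2 = True
    if not vpf >= pfam:
        c2 = False
        reasons.append("vpf_lt_pfam")
    if not vpf / n >= MIN_VPF_FRAC:
        c2 = False
        reasons.append("vpf_frac")
    return c1, c2, reasons


def pairwise_identity(a: str, b: str) -> float:
    """Nucleotide identity between two sequences for greedy clustering.

    The shorter sequence is aligned against the best window of the longer
    (infix alignment, both strands); identity = (L_short - d) / L_short
    with d the edit distance. Symmetric by construction: the query role is
    decided by (length, then lexicographic order), never by argument order.
    """
    if (len(a), a) <= (len(b), b):
        short, long_ = a, b
    else:
        short, long_ = b, a
    best = edlib.align(short, long_, mode="HW", task="distance")["editDistance"]
    rc = edlib.align(revcomp(short), long_, mode="HW", task="distance")["editDistance"]
    d = min(best, rc)
    return max(0.0, (len(short) - d) / len(short))


_KMER = 15


def _kmers(seq: str) -> set[str]:
    """Both-strand k-mer set (reverse-strand matches share k-mers too)."""
    rc = revcomp(seq)
    return {seq[i:i + _KMER] for i in range(len(seq) - _KMER + 1)} \
        | {rc[i:i + _KMER] for i in range(len(rc) - _KMER + 1)}


def _meets_identity(a: str, b: str, threshold: float,
                    kmers_a: set[str] | None, kmers_b: set[str] | None) -> bool:
    """Bounded identity test used by greedy clustering.

    Same convention as :func:`pairwise_identity`, but the edit-distance
    search is capped at the mismatch budget, and a shared-k-mer prefilter
    skips hopeless pairs: if d <= (1-t)*L the alignment contains an exact
    run of >= L/(d+1) bp, so when that bound is >= the k-mer size the
    prefilter is exact, not heuristic.
    """
    if (len(a), a) <= (len(b), b):
        short, long_ = a, b
        ks, kl = kmers_a, kmers_b
    else:
        short, long_ = b, a
        ks, kl = kmers_b, kmers_a
    budget = int(np.floor((1 - threshold) * len(short)))
    guaranteed_run = len(short) // (budget + 1)
    if ks is not None and kl is not None and guaranteed_run >= _KMER:
        if not (ks & kl):
            return False
    for query in (short, revcomp(short)):
        res = edlib.align(query, long_, mode="HW", task="distance", k=budget)
        if res["editDistance"] != -1:
            return True
    return False


def cluster_greedy(
    sequences: Mapping[str, str],
    identity_threshold: float = CLUSTER_IDENTITY,
    min_len: int = MIN_RETAIN_LEN,
) -> pd.DataFrame:
    """Greedy length-sorted clustering with longest-member representatives.

    Contigs of length <= ``min_len`` are dropped before clustering (the
    retention rule is strictly "> 5 kb"). Remaining contigs are sorted by
    descending length (ties broken by contig id) and each joins the first
    cluster whose representative it matches at >= ``identity_threshold``,
    else founds a new cluster. The representative is the longest member.

    Returns a frame with columns contig_id, cluster_id, is_representative.
    Empty input yields an empty frame.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    order = sorted(
        (cid for cid, s in sequences.items() if len(s) > min_len),
        key=lambda cid: (-len(sequences[cid]), cid),
    )
    reps: list[str] = []
    assignment: dict[str, int] = {}
    kmer_cache: dict[str, set[str]] = {}
    for cid in order:
        seq = sequences[cid]
        kmer_cache[cid] = _kmers(seq)
        for k, rep in enumerate(reps):
            if _meets_identity(seq, sequences[rep], identity_threshold,
                               kmer_cache[cid], kmer_cache[rep]):
                assignment[cid] = k
                break
        else:
            assignment[cid] = len(reps)
            reps.append(cid)
    rows = [
        {"contig_id": cid, "cluster_id": k, "is_representative": cid == reps[k]}
        for cid, k in assignment.items()
    ]
    return pd.DataFrame(rows, columns=["contig_id", "cluster_id", "is_representative"])


def run_triage(
    features: pd.DataFrame,
    sequences: Mapping[str, str],
    identity_threshold: float = CLUSTER_IDENTITY,
    min_len: int = MIN_RETAIN_LEN,
    admission: str = "all",
) -> pd.DataFrame:
    """Apply the full retention pipeline; one verdict row per input contig.

    ``retained`` is true only for cluster representatives among contigs
    passing the primary screen, the tripartite criteria (conjunctive under
    ``admission="all"``, disjunctive under ``"any"``) and the > ``min_len``
    length rule.
    """
    if admission not in ("all", "any"):
        raise ValueError("admission must be 'all' or 'any'")
    if features.empty:
        return pd.DataFrame(columns=[
            "contig_id", "passed_primary", "passed_criterion1", "passed_criterion2",
            "passed_length", "retained", "cluster_id", "is_representative", "reasons",
        ])
    missing = [c for c in features["contig_id"] if c not in sequences]
    if missing:
        raise TriageInputError(f"contigs absent from FASTA: {missing}")

    rows = []
    for _, f in features.iterrows():
        primary = screen_primary(f)
        c1, c2, treasons = tripartite_filter(f)
        length_ok = _get(f, "length") > min_len
        reasons = list(primary.reasons) + treasons
        if not length_ok:
            reasons.append("length")
        advanced = c1 and c2 if admission == "all" else c1 or c2
        rows.append({
            "contig_id": f["contig_id"],
            "passed_primary": primary.passed,
            "passed_criterion1": c1,
            "passed_criterion2": c2,
            "passed_length": bool(length_ok),
            "pre_cluster_pass": primary.passed and advanced and length_ok,
            "reasons": ";".join(reasons),
        })
    verdicts = pd.DataFrame(rows).sort_values("contig_id", ignore_index=True)

    survivors = {r["contig_id"]: sequences[r["contig_id"]]
                 for r in rows if r["pre_cluster_pass"]}
    clusters = cluster_greedy(survivors, identity_threshold, min_len)
    verdicts = verdicts.merge(clusters, on="contig_id", how="left")
    verdicts["is_representative"] = (
        verdicts["is_representative"].astype("boolean").fillna(False).astype(bool)
    )
    verdicts["retained"] = verdicts["pre_cluster_pass"] & verdicts["is_representative"]
    return verdicts.drop(columns="pre_cluster_pass")


def retained_sequences(verdicts: pd.DataFrame, sequences: Mapping[str, str]) -> dict[str, str]:
    keep = verdicts.loc[verdicts["retained"], "contig_id"]
    return {cid: sequences[cid] for cid in keep}
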