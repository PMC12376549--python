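"""Brute-force oracles, independent of the pipeline code they check.

Each oracle re-derives a verdict from first principles (literal inequality
evaluation, exhaustive window enumeration, exhaustive pairwise ranges) so
that agreement with the pipeline is a two-route check, not a tautology.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def triage_oracle(f: dict) -> bool:
    """Literal evaluation of every printed retention inequality."""
    if not (f["detector_score"] >= 0.5):
        return False
    if f["completeness"] < 50:
        return False
    if f["contamination"] > 10:
        return False
    n = f["n_genes"]
    if n <= 0:
        return False
    if not (f["n_vpf_hit_genes"] >= 5):
        return False
    if not (f["n_kegg_genes"] / n < 0.20):
        return False
    if not (f["n_pfam_genes"] / n <= 0.40):
        return False
    if not (f["n_vpf_hit_genes"] >= f["n_pfam_genes"]):
        return False
    if not (f["n_vpf_hit_genes"] / n >= 0.60):
        return False
    if not (f["length"] > 5000):
        return False
    return True


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def spacer_oracle(contig: str, spacer: str, max_mismatch: int = 2,
                  min_identity: float = 0.95) -> list[tuple[int, str, int]]:
    """Every qualifying window by exhaustive both-strand Hamming scan.

    Returns (start, strand, mismatches) for windows with d <= max_mismatch
    AND (L - d)/L >= min_identity.
    """
    L = len(spacer)
    out = []
    for strand, query in (("+", spacer), ("-", revcomp(spacer))):
        for i in range(len(contig) - L + 1):
            d = 0
            for a, b in zip(contig[i:i + L], query):
                if a != b:
                    d += 1
                    if d > max_mismatch:
                        break
            if d <= max_mismatch and (L - d) / L >= min_identity:
                out.append((i, strand, d))
    return out


def amg_oracle(score: int, flags: str) -> bool:
    fset = set(flags)
    return (1 <= score <= 3) and bool(fset & set("MF")) and not (fset & set("VAPTB"))


def anosim_r_oracle(dist: np.ndarray, labels) -> float:
    """ANOSIM R from its definition, with explicit rank averaging."""
    n = dist.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    values = [dist[i, j] for i, j in pairs]
    order = sorted(range(len(values)), key=lambda k: values[k])
    ranks = [0.0] * len(values)
    k = 0
    while k < len(order):
        j = k
        while j + 1 < len(order) and values[order[j + 1]] == values[order[k]]:
            j += 1
        avg = (k + j) / 2 + 1
        for t in range(k, j + 1):
            ranks[order[t]] = avg
        k = j + 1
    labels = list(labels)
    within = [ranks[k] for k, (i, j) in enumerate(pairs) if labels[i] == labels[j]]
    between = [ranks[k] for k, (i, j) in enumerate(pairs) if labels[i] != labels[j]]
    m = len(pairs)
    return (float(np.mean(between)) - float(np.mean(within))) / (m / 2)


def anosim_exact_p_oracle(dist: np.ndarray, labels) -> tuple[float, float]:
    """Exact permutation p over all distinct label arrangements."""
    labels = list(labels)
    r_obs = anosim_r_oracle(dist, labels)
    perms = sorted(set(itertools.permutations(labels)))
    r_all = [anosim_r_oracle(dist, p) for p in perms]
    p = np.mean([r >= r_obs - 1e-12 for r in r_all])
    return r_obs, float(p)


def duncan_3group_oracle(groups: list[np.ndarray], alpha: float = 0.05) -> dict:
    """Direct pairwise Duncan computation for exactly three groups.

    Returns {'separated': set of frozenset pairs of group indices}.
    """
    from scipy import stats as sps

    assert len(groups) == 3
    means = np.array([g.mean() for g in groups])
    ns = np.array([len(g) for g in groups])
    sse = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df = int(ns.sum() - 3)
    mse = sse / df
    n_h = 3 / np.sum(1.0 / ns)
    order = np.argsort(-means)            # descending
    sep = set()
    # widest range first: positions 0 vs 2 span r=3, adjacent pairs span r=2
    def crit(r):
        level = 1 - (1 - alpha) ** (r - 1)
        return sps.studentized_range.ppf(1 - level, r, df) * np.sqrt(mse / n_h)

    outer = means[order[0]] - means[order[2]] > crit(3)
    if outer:
        sep.add(frozenset((int(order[0]), int(order[2]))))
        if means[order[0]] - means[order[1]] > crit(2):
            sep.add(frozenset((int(order[0]), int(order[1]))))
        if means[order[1]] - means[order[2]] > crit(2):
            sep.add(frozenset((int(order[1]), int(order[2]))))
    return {"separated": sep}
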