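"""Shared low-level helpers: seeded sub-streams and nucleotide utilities."""

from __future__ import annotations

import zlib

import numpy as np

ALPHABET = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


def substream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator for a named sub-stream of one global seed.

    Every source of randomness in the package draws from a stream derived
    from (seed, label), so module-level outputs are individually
    reproducible under a single integer seed.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    idx = rng.integers(0, 4, size=length)
    return "".join(ALPHABET[i] for i in idx)


def validate_nt(seq: str, what: str = "sequence") -> None:
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} in {what} (A/C/G/T only)")


def encode(seq: str) -> np.ndarray:
    """Byte-encode a nucleotide string for vectorised window comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def hamming_windows(contig: np.ndarray, query: np.ndarray, budget: int) -> list[tuple[int, int]]:
    """All start positions where query matches contig with <= budget mismatches.

    Ungapped scan; returns (0-based start, mismatch count) pairs.
    """
    L = len(query)
    if L > len(contig):
        return []
    windows = np.lib.stride_tricks.sliding_window_view(contig, L)
    dists = (windows != query).sum(axis=1)
    hits = np.nonzero(dists <= budget)[0]
    return [(int(p), int(dists[p])) for p in hits]
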