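"""Synthetic soil-virome communities with planted, machine-readable truth.

The generator emulates every input the decision pipeline consumes — viral
candidate contigs with annotation-count features, lysogeny marker tables,
CRISPR spacer / tRNA / homology-hit tables, AMG candidate tables, read
counts and a microcosm CO2 series — while recording in a TruthTable what
was planted and whether each planted entity should survive the pipeline's
printed thresholds. Every downstream stage is thereby testable without any
external data.

Defaults mirror the study conditions the pipeline was designed around:
4 treatments x 3 replicates (12 samples), a planted lysogenic fraction of
0.21, spacer mismatch plan (0, 1, 2, 3), and a 35-day microcosm sampled on
days 1, 3, 5, 7, 14, 21, 28 and 35 under virus-addition (VS) and
no-virus (NS) treatments.

All randomness flows from one integer seed through named sub-streams, so
identical configurations give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import random_seq, revcomp, substream
from . import io as svio

_FLAG_SETS = ("M", "F", "MF", "MV", "V", "", "FB", "MT")
_CAZYME_FAMILIES = ("GH13", "GT2", "PL1", "CE4", "", "AA3", "CBM50", "GH5")
_KOS = ("K01601", "K01176", "K00845", "K01810", "", "K02703", "K00030", "")
_FAIL_MODES = ("score", "completeness", "contamination", "kegg_frac",
               "pfam_frac", "vpf_hits", "vpf_frac", "length")
_HOM_MODES = ("pass", "low_identity", "short", "low_qcov",
              "high_evalue", "low_bitscore")
_TRNA_MISMATCH_PLAN = (0, 2, 3, 4, 6)

FEATURE_COLUMNS = [
    "contig_id", "length", "n_genes", "n_vpf_hit_genes", "n_kegg_genes",
    "n_pfam_genes", "detector_score", "completeness", "contamination",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic community; see module docstring."""

    seed: int = 0
    n_viral_contigs: int = 120
    n_host_contigs: int = 12
    length_range: tuple[int, int] = (3000, 12000)
    frac_true_viral: float = 0.4
    frac_lysogenic: float = 0.21
    n_spacers: int = 24
    n_decoy_spacers: int = 8
    spacer_len_range: tuple[int, int] = (28, 45)
    spacer_mismatch_plan: tuple[int, ...] = (0, 1, 2, 3)
    n_trna_links: int = 6
    trna_len_range: tuple[int, int] = (60, 100)
    n_homology_links: int = 6
    homology_block_len: int = 3000
    n_samples: int = 12
    n_treatments: int = 4
    read_depth: int = 200_000
    group_effect: float = 1.0
    abundance_mode: str = "dirichlet"   # "dirichlet" | "equal"
    n_amg_candidates: int = 40
    plant_boundary_features: bool = True
    microcosm_days: tuple[int, ...] = (1, 3, 5, 7, 14, 21, 28, 35)
    n_replicates: int = 3

    def validate(self) -> None:
        for name in ("frac_true_viral", "frac_lysogenic"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.length_range[0] <= 0 or self.length_range[0] > self.length_range[1]:
            raise ConfigError(f"bad length_range {self.length_range}")
        if self.frac_true_viral > 0 and self.length_range[1] <= 5000:
            raise ConfigError(
                "retainable contigs need length_range to extend beyond 5 kb"
            )
        if self.spacer_len_range[0] < 20:
            raise ConfigError("spacers must be at least 20 nt")
        if self.spacer_len_range[0] > self.length_range[1]:
            raise ConfigError("spacer longer than every target contig")
        if max(self.spacer_mismatch_plan, default=0) > self.spacer_len_range[0] - 2:
            raise ConfigError(
                "infeasible spacer_mismatch_plan: more mismatches than "
                "plantable positions in the shortest spacer"
            )
        if self.abundance_mode not in ("dirichlet", "equal"):
            raise ConfigError(f"unknown abundance_mode {self.abundance_mode!r}")
        if any(np.diff(self.microcosm_days) <= 0):
            raise ConfigError("microcosm day grid must be strictly increasing")


@dataclass
class TruthTable:
    """Planted ground truth: one row per planted entity."""

    contigs: pd.DataFrame      # contig_id, is_viral, is_lysogenic, should_retain, reasons
    links: pd.DataFrame        # virus_id, host_id, channel, query_id, mismatches,
    #                            identity, strand, start, planted, should_pass
    amgs: pd.DataFrame         # gene_id, should_retain, cazyme_class, kegg_level2
    samples: pd.DataFrame      # sample_id, treatment
    abundances: pd.DataFrame   # contigs x samples planted relative abundances

    def to_json(self, path: str | Path) -> None:
        svio.write_json({
            "contigs": self.contigs,
            "links": self.links,
            "amgs": self.amgs,
            "samples": self.samples,
            "abundances": {
                "contig_id": list(self.abundances.index),
                "sample_id": list(self.abundances.columns),
                "values": self.abundances.to_numpy().tolist(),
            },
        }, path)


@dataclass
class SyntheticCommunity:
    config: SynthConfig
    viral_seqs: dict[str, str]
    host_seqs: dict[str, str]
    features: pd.DataFrame
    markers: pd.DataFrame
    spacers: pd.DataFrame
    trnas: pd.DataFrame
    homhits: pd.DataFrame
    amgs: pd.DataFrame
    truth: TruthTable


# --------------------------------------------------------------- features

def _passing_features(rng: np.random.Generator, cfg: SynthConfig) -> dict:
    lo = max(cfg.length_range[0], 5001)
    length = int(rng.integers(lo, cfg.length_range[1] + 1))
    n = int(rng.integers(10, 25))
    vpf = int(rng.integers(int(np.ceil(0.7 * n)), n + 1))
    kegg = int(rng.integers(0, (n - 1) // 5 + 1))         # kegg/n < 0.2
    pfam = int(rng.integers(0, min(2 * n // 5, vpf) + 1))  # pfam/n <= 0.4, <= vpf
    return {
        "length": length, "n_genes": n, "n_vpf_hit_genes": vpf,
        "n_kegg_genes": kegg, "n_pfam_genes": pfam,
        "detector_score": round(float(rng.uniform(0.6, 1.0)), 3),
        "completeness": round(float(rng.uniform(60, 100)), 1),
        "contamination": round(float(rng.uniform(0, 8)), 1),
    }


def _failing_features(rng: np.random.Generator, cfg: SynthConfig, mode: str) -> dict:
    f = _passing_features(rng, cfg)
    n = f["n_genes"]
    if mode == "score":
        f["detector_score"] = round(float(rng.uniform(0.0, 0.49)), 3)
    elif mode == "completeness":
        f["completeness"] = round(float(rng.uniform(0, 49.9)), 1)
    elif mode == "contamination":
        f["contamination"] = round(float(rng.uniform(10.5, 40)), 1)
    elif mode == "kegg_frac":
        f["n_kegg_genes"] = int(rng.integers((n + 4) // 5, n + 1))
    elif mode == "pfam_frac":
        f["n_pfam_genes"] = int(rng.integers(2 * n // 5 + 1, n + 1))
    elif mode == "vpf_hits":
        f["n_vpf_hit_genes"] = int(rng.integers(0, 5))
        f["n_pfam_genes"] = min(f["n_pfam_genes"], f["n_vpf_hit_genes"])
    elif mode == "vpf_frac":
        n = int(rng.integers(12, 25))
        vpf = max(5, n // 2)                                # >= 5, < 0.6 n
        f.update(n_genes=n, n_vpf_hit_genes=vpf,
                 n_kegg_genes=int(rng.integers(0, (n - 1) // 5 + 1)),
                 n_pfam_genes=int(rng.integers(0, min(2 * n // 5, vpf) + 1)))
    elif mode == "length":
        f["length"] = int(rng.integers(2500, 5001))
    else:                                                    # pragma: no cover
        raise ValueError(mode)
    return f


def _boundary_features() -> list[dict]:
    """Feature rows sitting exactly on each printed threshold boundary."""
    base = dict(length=6000, n_genes=10, n_vpf_hit_genes=7, n_kegg_genes=1,
                n_pfam_genes=2, detector_score=0.9, completeness=90.0,
                contamination=0.0)
    rows = [
        dict(base, detector_score=0.50),
        dict(base, detector_score=0.49),
        dict(base, completeness=50.0),
        dict(base, completeness=49.9),
        dict(base, contamination=10.0),
        dict(base, contamination=10.1),
        dict(base, n_genes=1000, n_vpf_hit_genes=600, n_kegg_genes=199, n_pfam_genes=300),
        dict(base, n_genes=1000, n_vpf_hit_genes=600, n_kegg_genes=200, n_pfam_genes=300),
        dict(base, n_genes=10, n_vpf_hit_genes=6, n_kegg_genes=1, n_pfam_genes=4),
        dict(base, n_genes=1000, n_vpf_hit_genes=600, n_kegg_genes=100, n_pfam_genes=401),
        dict(base, n_genes=8, n_vpf_hit_genes=5, n_kegg_genes=1, n_pfam_genes=2),
        dict(base, n_genes=6, n_vpf_hit_genes=4, n_kegg_genes=1, n_pfam_genes=2),
        dict(base, n_genes=10, n_vpf_hit_genes=6, n_kegg_genes=1, n_pfam_genes=2),
        dict(base, n_genes=100, n_vpf_hit_genes=59, n_kegg_genes=10, n_pfam_genes=40),
        dict(base, length=5001),
        dict(base, length=5000),
    ]
    for i, row in enumerate(rows):
        row["contig_id"] = f"vb_{i:02d}"
    return rows


def _truth_verdict(f: dict) -> tuple[bool, list[str]]:
    """Re-apply the printed retention inequalities to one feature row."""
    reasons = []
    if not f["detector_score"] >= 0.5:
        reasons.append("score")
    if f["completeness"] < 50:
        reasons.append("completeness")
    if f["contamination"] > 10:
        reasons.append("contamination")
    n = f["n_genes"]
    if n <= 0:
        reasons.append("no genes")
    else:
        if not f["n_vpf_hit_genes"] >= 5:
            reasons.append("vpf_hits")
        if not f["n_kegg_genes"] / n < 0.20:
            reasons.append("kegg_frac")
        if not f["n_pfam_genes"] / n <= 0.40:
            reasons.append("pfam_frac")
        if not f["n_vpf_hit_genes"] >= f["n_pfam_genes"]:
            reasons.append("vpf_lt_pfam")
        if not f["n_vpf_hit_genes"] / n >= 0.60:
            reasons.append("vpf_frac")
    if not f["length"] > 5000:
        reasons.append("length")
    return not reasons, reasons


# ------------------------------------------------------------ sequence plants

def _free_position(rng: np.random.Generator, contig_len: int, L: int,
                   occupied: list[tuple[int, int]]) -> int:
    if L > contig_len:
        raise ConfigError(f"planted sequence of {L} bp exceeds contig of {contig_len} bp")
    for _ in range(200):
        pos = int(rng.integers(0, contig_len - L + 1))
        if all(pos + L <= s or pos >= e for s, e in occupied):
            occupied.append((pos, pos + L))
            return pos
    raise ConfigError("could not place planted sequence without overlap")


def _mutate(rng: np.random.Generator, seq: str, d: int) -> str:
    """Plant exactly d substitutions at distinct interior positions."""
    if d == 0:
        return seq
    L = len(seq)
    if d > L - 2:
        raise ConfigError(f"cannot plant {d} mismatches in a {L} nt sequence")
    positions = rng.choice(np.arange(1, L - 1), size=d, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(0, 3))]
    return "".join(out)


# ---------------------------------------------------------------- generator

def generate_community(config: SynthConfig) -> SyntheticCommunity:
    """Generate one community with planted truth; deterministic under seed."""
    config.validate()
    cfg = config

    # ---- viral candidate contigs and their annotation features
    rng_f = substream(cfg.seed, "features")
    n_pass = round(cfg.frac_true_viral * cfg.n_viral_contigs)
    feature_rows: list[dict] = []
    for i in range(cfg.n_viral_contigs):
        if i < n_pass:
            row = _passing_features(rng_f, cfg)
        else:
            row = _failing_features(rng_f, cfg, _FAIL_MODES[(i - n_pass) % len(_FAIL_MODES)])
        row["contig_id"] = f"vc_{i:04d}"
        feature_rows.append(row)
    regular_ids = [r["contig_id"] for r in feature_rows]
    if cfg.plant_boundary_features:
        feature_rows.extend(_boundary_features())

    # ---- dedicated homology-target contigs sized for query coverage
    hom_modes = [_HOM_MODES[i % len(_HOM_MODES)] for i in range(cfg.n_homology_links)]
    for i, mode in enumerate(hom_modes):
        block = 1500 if mode == "short" else cfg.homology_block_len
        vlen = round(block / 0.6) if mode == "low_qcov" else round(block / 0.85)
        row = _failing_features(rng_f, cfg, "length")
        row["length"] = vlen
        row["contig_id"] = f"vh_{i:02d}"
        feature_rows.append(row)

    features = pd.DataFrame(feature_rows)[FEATURE_COLUMNS]

    rng_s = substream(cfg.seed, "sequences")
    viral_seqs = {r["contig_id"]: random_seq(rng_s, r["length"]) for r in feature_rows}
    host_ids = [f"hc_{i:02d}" for i in range(cfg.n_host_contigs)]
    host_seqs = {h: random_seq(rng_s, int(rng_s.integers(8000, 15001))) for h in host_ids}

    contig_truth = []
    for r in feature_rows:
        ok, reasons = _truth_verdict(r)
        contig_truth.append({
            "contig_id": r["contig_id"], "is_viral": ok, "is_lysogenic": False,
            "should_retain": ok, "reasons": ";".join(reasons),
        })
    contig_truth = pd.DataFrame(contig_truth)

    # ---- lysogeny flags and marker annotations
    rng_l = substream(cfg.seed, "lysogeny")
    n_lys = round(cfg.frac_lysogenic * cfg.n_viral_contigs)
    lys_ids = set(np.array(regular_ids)[rng_l.choice(cfg.n_viral_contigs, n_lys, replace=False)])
    contig_truth.loc[contig_truth["contig_id"].isin(lys_ids), "is_lysogenic"] = True
    marker_classes = ("integrase", "transposase", "invertase", "recombinase", "excisionase")
    marker_rows = []
    for cid in regular_ids:
        if cid in lys_ids:
            for k in range(int(rng_l.integers(1, 3))):
                marker_rows.append({
                    "contig_id": cid, "gene_id": f"{cid}_g{k}",
                    "marker_class": marker_classes[int(rng_l.integers(0, len(marker_classes)))],
                    "source": "domain-table",
                })
        elif rng_l.random() < 0.1:   # decoy annotation that is not lysogeny evidence
            marker_rows.append({
                "contig_id": cid, "gene_id": f"{cid}_g0",
                "marker_class": "other", "source": "keyword",
            })
    markers = pd.DataFrame(marker_rows, columns=["contig_id", "gene_id", "marker_class", "source"])

    occupied: dict[str, list[tuple[int, int]]] = {cid: [] for cid in viral_seqs}
    link_truth: list[dict] = []

    # ---- CRISPR spacers: planted protospacers plus unplanted decoys
    rng_sp = substream(cfg.seed, "spacers")
    spacer_rows = []
    for i in range(cfg.n_spacers):
        L = int(rng_sp.integers(cfg.spacer_len_range[0], cfg.spacer_len_range[1] + 1))
        d = cfg.spacer_mismatch_plan[i % len(cfg.spacer_mismatch_plan)]
        spacer = random_seq(rng_sp, L)
        host = host_ids[i % len(host_ids)]
        virus = regular_ids[int(rng_sp.integers(0, n_pass))] if n_pass else regular_ids[0]
        strand = "+" if rng_sp.random() < 0.5 else "-"
        proto = _mutate(rng_sp, spacer, d)
        planted = proto if strand == "+" else revcomp(proto)
        pos = _free_position(rng_sp, len(viral_seqs[virus]), L, occupied[virus])
        seq = viral_seqs[virus]
        viral_seqs[virus] = seq[:pos] + planted + seq[pos + L:]
        sid = f"sp_{i:03d}"
        spacer_rows.append({"host_contig_id": host, "spacer_id": sid, "sequence": spacer})
        link_truth.append({
            "virus_id": virus, "host_id": host, "channel": "spacer", "query_id": sid,
            "mismatches": d, "identity": 100.0 * (L - d) / L, "strand": strand,
            "start": pos, "planted": True,
            "should_pass": d <= min(2, int(np.floor(0.05 * L))),
        })
    for i in range(cfg.n_decoy_spacers):
        L = int(rng_sp.integers(cfg.spacer_len_range[0], cfg.spacer_len_range[1] + 1))
        sid = f"spdecoy_{i:03d}"
        spacer_rows.append({
            "host_contig_id": host_ids[i % len(host_ids)],
            "spacer_id": sid, "sequence": random_seq(rng_sp, L),
        })
        link_truth.append({
            "virus_id": "", "host_id": host_ids[i % len(host_ids)], "channel": "spacer",
            "query_id": sid, "mismatches": np.nan, "identity": np.nan, "strand": "",
            "start": -1, "planted": False, "should_pass": False,
        })
    spacers = pd.DataFrame(spacer_rows, columns=["host_contig_id", "spacer_id", "sequence"])

    # ---- tRNA plants
    rng_t = substream(cfg.seed, "trnas")
    trna_rows = []
    for i in range(cfg.n_trna_links):
        L = int(rng_t.integers(cfg.trna_len_range[0], cfg.trna_len_range[1] + 1))
        d = _TRNA_MISMATCH_PLAN[i % len(_TRNA_MISMATCH_PLAN)]
        trna = random_seq(rng_t, L)
        host = host_ids[(i + 3) % len(host_ids)]
        virus = regular_ids[int(rng_t.integers(0, n_pass))] if n_pass else regular_ids[0]
        strand = "+" if rng_t.random() < 0.5 else "-"
        planted_seq = _mutate(rng_t, trna, d)
        planted_seq = planted_seq if strand == "+" else revcomp(planted_seq)
        pos = _free_position(rng_t, len(viral_seqs[virus]), L, occupied[virus])
        seq = viral_seqs[virus]
        viral_seqs[virus] = seq[:pos] + planted_seq + seq[pos + L:]
        tid = f"trna_{i:03d}"
        trna_rows.append({"host_contig_id": host, "trna_id": tid, "sequence": trna})
        link_truth.append({
            "virus_id": virus, "host_id": host, "channel": "trna", "query_id": tid,
            "mismatches": d, "identity": 100.0 * (L - d) / L, "strand": strand,
            "start": pos, "planted": True,
            "should_pass": d <= int(np.floor(0.05 * L)),
        })
    trnas = pd.DataFrame(trna_rows, columns=["host_contig_id", "trna_id", "sequence"])

    # ---- homologous blocks and their tabular hits
    rng_h = substream(cfg.seed, "homology")
    hom_rows = []
    for i, mode in enumerate(hom_modes):
        virus = f"vh_{i:02d}"
        vlen = len(viral_seqs[virus])
        block = 1500 if mode == "short" else cfg.homology_block_len
        identity = 0.65 if mode == "low_identity" else 0.95
        host = host_ids[(i + 5) % len(host_ids)]
        qstart = _free_position(rng_h, vlen, block, occupied[virus])
        n_sub = round((1 - identity) * block)
        block_seq = _mutate(rng_h, viral_seqs[virus][qstart:qstart + block], n_sub)
        hpos = int(rng_h.integers(0, len(host_seqs[host]) - block + 1))
        hseq = host_seqs[host]
        host_seqs[host] = hseq[:hpos] + block_seq + hseq[hpos + block:]
        pident = round(100.0 * (block - n_sub) / block, 2)
        evalue = 1e-2 if mode == "high_evalue" else 1e-50
        bitscore = 30.0 if mode == "low_bitscore" else round(1.8 * block * identity, 1)
        hom_rows.append({
            "qseqid": virus, "sseqid": host, "pident": pident, "length": block,
            "mismatch": n_sub, "gapopen": 0, "qstart": qstart + 1, "qend": qstart + block,
            "sstart": hpos + 1, "send": hpos + block, "evalue": evalue,
            "bitscore": bitscore,
        })
        qcov = 100.0 * block / vlen
        link_truth.append({
            "virus_id": virus, "host_id": host, "channel": "homology", "query_id": virus,
            "mismatches": n_sub, "identity": pident, "strand": "+", "start": qstart,
            "planted": True,
            "should_pass": bool(pident >= 70 and qcov >= 75 and evalue <= 1e-3
                                and bitscore >= 50 and block >= 2500),
        })
    homhits = pd.DataFrame(hom_rows, columns=svio.OUTFMT6_COLUMNS)

    # ---- AMG candidates spanning the score x flag grid
    rng_a = substream(cfg.seed, "amg")
    amg_rows, amg_truth = [], []
    grid = [(s, fl) for s in range(1, 6) for fl in _FLAG_SETS]
    for i in range(cfg.n_amg_candidates):
        score, flags = grid[i % len(grid)]
        fam = _CAZYME_FAMILIES[i % len(_CAZYME_FAMILIES)]
        ko = _KOS[i % len(_KOS)]
        gid = f"amg_{i:03d}"
        row = {
            "gene_id": gid, "contig_id": regular_ids[i % len(regular_ids)],
            "ko_id": ko, "auxiliary_score": score, "flags": flags,
            "cazyme_family": fam, "kegg_level2": "",
        }
        for t in range(1, cfg.n_treatments + 1):
            row[f"T{t}"] = round(float(rng_a.gamma(2.0, 1.0)), 4)
        amg_rows.append(row)
        fset = set(flags)
        amg_truth.append({
            "gene_id": gid,
            "should_retain": bool(1 <= score <= 3 and (fset & set("MF"))
                                  and not (fset & set("VAPTB"))),
            "cazyme_class": next((c for c in ("CBM", "GH", "GT", "PL", "CE", "AA")
                                  if fam.startswith(c)), ""),
            "kegg_level2": ko,
        })
    amgs = pd.DataFrame(amg_rows)

    # ---- sample groups and planted relative abundances
    rng_ab = substream(cfg.seed, "abundance")
    sample_ids = [f"s{j:02d}" for j in range(cfg.n_samples)]
    treatments = [f"T{j % cfg.n_treatments + 1}" for j in range(cfg.n_samples)]
    base = rng_ab.lognormal(0.0, 1.0, size=cfg.n_viral_contigs)
    cols = {}
    for j, sid in enumerate(sample_ids):
        if cfg.abundance_mode == "equal":
            p = np.full(cfg.n_viral_contigs, 1.0 / cfg.n_viral_contigs)
        else:
            mult = np.ones(cfg.n_viral_contigs)
            if cfg.group_effect > 0:
                t = j % cfg.n_treatments
                mult[np.arange(cfg.n_viral_contigs) % cfg.n_treatments == t] += cfg.group_effect
            p = rng_ab.dirichlet(base * mult)
        cols[sid] = p
    abundances = pd.DataFrame(cols, index=regular_ids)
    samples = pd.DataFrame({"sample_id": sample_ids, "treatment": treatments})

    truth = TruthTable(
        contigs=contig_truth,
        links=pd.DataFrame(link_truth),
        amgs=pd.DataFrame(amg_truth),
        samples=samples,
        abundances=abundances,
    )
    return SyntheticCommunity(cfg, viral_seqs, host_seqs, features, markers,
                              spacers, trnas, homhits, amgs, truth)


def generate_counts(truth: TruthTable, depth: int, seed: int) -> pd.DataFrame:
    """Multinomial read counts per sample from the planted abundances."""
    if depth <= 0:
        raise ConfigError(f"read depth must be positive, got {depth}")
    p = truth.abundances
    sums = p.sum(axis=0)
    if not np.allclose(sums, 1.0):
        raise ConfigError("planted per-sample abundances must sum to 1")
    rng = substream(seed, "counts")
    cols = {s: rng.multinomial(depth, p[s].to_numpy() / sums[s]) for s in p.columns}
    return pd.DataFrame(cols, index=p.index)


@dataclass
class MicrocosmSeries:
    """Interval CO2-C trapping series plus endpoint chemistry and truth."""

    series: pd.DataFrame     # sample_id, treatment, virus_addition, replicate, day, co2_c
    endpoints: pd.DataFrame  # sample_id, mbc, doc, suva254, bg, nag
    truth: pd.DataFrame      # sample_id, cumulative_co2_c, qco2, duration_days


def generate_microcosm(config: SynthConfig) -> MicrocosmSeries:
    """Synthetic 35-day incubation: VS/NS x treatments x replicates.

    Interval amounts decay over time; straw-returning treatments (even
    treatment numbers) respire more, and virus addition (VS) lowers
    respiration in straw-removal treatments, echoing the effect structure
    the pipeline's group statistics are meant to resolve. Truth stores the
    exact planted cumulative CO2-C and the implied qCO2.
    """
    config.validate()
    days = np.asarray(config.microcosm_days)
    rng = substream(config.seed, "microcosm")
    widths = np.diff(np.concatenate([[0], days]))
    series_rows, end_rows, truth_rows = [], [], []
    duration = float(days[-1])
    for t in range(1, config.n_treatments + 1):
        straw = t % 2 == 0
        for vs in ("VS", "NS"):
            for rep in range(1, config.n_replicates + 1):
                sid = f"{vs}_T{t}_r{rep}"
                rate = 0.08 * (1.8 if straw else 1.0)
                if vs == "VS" and not straw:
                    rate *= 0.8
                amounts = rate * widths * np.exp(-0.04 * days) \
                    * rng.uniform(0.85, 1.15, size=len(days))
                amounts = np.round(np.maximum(amounts, 1e-4), 5)
                mbc = round(float((0.25 if straw else 0.12)
                                  * (1.3 if vs == "VS" else 1.0)
                                  * rng.uniform(0.9, 1.1)), 5)
                for day, amt in zip(days, amounts):
                    series_rows.append({
                        "sample_id": sid, "treatment": f"T{t}", "virus_addition": vs,
                        "replicate": rep, "day": int(day), "co2_c": float(amt),
                    })
                end_rows.append({
                    "sample_id": sid, "mbc": mbc,
                    "doc": round(float(rng.uniform(0.05, 0.3)), 5),
                    "suva254": round(float(rng.uniform(1.0, 4.0)), 4),
                    "bg": round(float(rng.uniform(5, 40)), 3),
                    "nag": round(float(rng.uniform(2, 20)), 3),
                })
                total = float(np.sum(amounts))
                truth_rows.append({
                    "sample_id": sid, "cumulative_co2_c": total,
                    "qco2": total / (mbc * duration), "duration_days": duration,
                })
    return MicrocosmSeries(
        pd.DataFrame(series_rows), pd.DataFrame(end_rows), pd.DataFrame(truth_rows)
    )


# ----------------------------------------------------------------- writers

def write_community(comm: SyntheticCommunity, outdir: str | Path) -> None:
    """Write every interchange file of one synthetic community."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    svio.write_fasta(comm.viral_seqs, out / "contigs.fna")
    svio.write_fasta(comm.host_seqs, out / "hosts.fna")
    svio.write_table(comm.features, out / "features.tsv")
    svio.write_table(comm.markers, out / "markers.tsv")
    svio.write_table(comm.spacers, out / "spacers.tsv")
    svio.write_table(comm.trnas, out / "trnas.tsv")
    svio.write_outfmt6(comm.homhits, out / "homhits.tsv")
    svio.write_table(comm.amgs, out / "amgs.tsv")
    svio.write_table(comm.truth.samples, out / "metadata.tsv")
    counts = generate_counts(comm.truth, comm.config.read_depth, comm.config.seed)
    svio.write_table(counts.rename_axis("contig_id").reset_index(), out / "counts.tsv")
    micro = generate_microcosm(comm.config)
    svio.write_table(micro.series, out / "microcosm.tsv")
    svio.write_table(micro.endpoints, out / "microcosm_endpoints.tsv")
    comm.truth.to_json(out / "truth.json")
    svio.write_json(dataclasses.asdict(comm.config), out / "config.json")
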