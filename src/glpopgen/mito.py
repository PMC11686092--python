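"""Mitochondrial consensus sequences, haplotypes, diversity and networks.

Low-coverage WGS yields the mitochondrial genome at high depth as a
by-product, so per-individual consensus sequences can be called directly
from base counts: a site is called as its majority base when depth >= 4 and
the majority fraction >= 0.75, and masked to N otherwise (ties are N).

Identical consensus sequences collapse to haplotypes.  By default, sites
with an N in ANY individual are excluded globally before collapsing, which
keeps sequence identity a true equivalence relation; pairwise deletion is
available but can make "identity" intransitive and is guarded.  Haplotype
diversity is Hd = n(1 - sum p_i^2)/(n - 1).  The haplotype network is the
minimum spanning tree on pairwise base differences, with alternative edges
added where a direct link is exactly as long as the MST path it would
shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .glcore import BASES

__all__ = [
    "ConsensusSeq",
    "HaplotypeSet",
    "consensus_sequence",
    "collapse_haplotypes",
    "haplotype_diversity",
    "haplotype_summary",
    "haplotype_network",
    "write_fasta",
    "read_fasta",
]


@dataclass
class ConsensusSeq:
    id: str
    sequence: str  # over ACGTN, same length as the reference
    n_called: int
    n_masked: int


def consensus_sequence(
    base_counts: np.ndarray, individual_id: str = "",
    min_depth: int = 4, min_maf: float = 0.75,
) -> ConsensusSeq:
    """Call a consensus from per-site ACGT counts.

    A site is the majority base iff total depth >= ``min_depth`` and the
    majority fraction >= ``min_maf``; otherwise (including 50/50 ties) N.
    """
    counts = np.asarray(base_counts, dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("base counts must be non-negative")
    depth = counts.sum(axis=1)
    top = counts.max(axis=1)
    argtop = counts.argmax(axis=1)
    tie = (counts == top[:, None]).sum(axis=1) > 1
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(depth > 0, top / depth, 0.0)
    ok = (depth >= min_depth) & (frac >= min_maf) & ~tie
    seq = np.where(ok, np.array(list(BASES))[argtop], "N")
    called = int(ok.sum())
    return ConsensusSeq(
        id=individual_id, sequence="".join(seq),
        n_called=called, n_masked=len(seq) - called,
    )


@dataclass
class HaplotypeSet:
    haplotypes: dict[str, str]  # haplotype id -> representative sequence
    members: dict[str, list[str]]  # haplotype id -> individual ids
    pop_counts: pd.DataFrame  # haplotype x population counts
    distances: pd.DataFrame  # pairwise base differences between haplotypes
    kept_positions: np.ndarray  # reference positions used after masking
    diversity: pd.DataFrame = field(default_factory=pd.DataFrame)


def _global_mask(seqs: list[str]) -> np.ndarray:
    arr = np.array([list(s) for s in seqs])
    return ~np.any(arr == "N", axis=0)


def collapse_haplotypes(
    seqs: dict[str, str], masking: str = "global"
) -> tuple[dict[str, str], np.ndarray]:
    """Map individual -> haplotype key after the masking policy.

    ``masking='global'`` drops every position with an N in any individual,
    making identity transitive.  ``masking='pairwise'`` keeps full sequences
    and treats N as a wildcard when comparing - this can link A~B~C with
    A != C and is only allowed when it does not, otherwise it raises.
    """
    ids = list(seqs)
    raw = [seqs[i] for i in ids]
    if masking == "global":
        keep = _global_mask(raw)
        reduced = {
            i: "".join(np.array(list(s))[keep]) for i, s in zip(ids, raw)
        }
        return reduced, np.flatnonzero(keep) + 1
    if masking == "pairwise":
        def match(a: str, b: str) -> bool:
            return all(x == y or "N" in (x, y) for x, y in zip(a, b))

        groups: list[list[str]] = []
        for i in ids:
            placed = False
            for g in groups:
                if all(match(seqs[i], seqs[j]) for j in g):
                    g.append(i)
                    placed = True
                    break
            if not placed:
                groups.append([i])
        # Guard: equivalence must be consistent (no cross-group matches).
        for gi, g1 in enumerate(groups):
            for g2 in groups[gi + 1 :]:
                if any(match(seqs[a], seqs[b]) for a in g1 for b in g2):
                    raise ValueError(
                        "pairwise masking produced an intransitive identity; "
                        "use masking='global'"
                    )
        reduced = {}
        for g in groups:
            rep = g[0]
            for i in g:
                reduced[i] = seqs[rep]
        return reduced, np.arange(1, len(raw[0]) + 1)
    raise ValueError(f"unknown masking policy {masking!r}")


def haplotype_diversity(counts: np.ndarray) -> float:
    """Hd = n(1 - sum p_i^2)/(n - 1) from per-haplotype counts."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        return float("nan")
    p = counts / n
    return float(n * (1.0 - np.sum(p**2)) / (n - 1.0))


def haplotype_summary(
    seqs: list[ConsensusSeq] | dict[str, str],
    pops: dict[str, str],
    masking: str = "global",
) -> HaplotypeSet:
    """Collapse sequences into haplotypes and summarize per population.

    ``pops`` maps individual id -> population label.  Populations of size 1
    get Hd = NaN (flagged undefined).
    """
    if isinstance(seqs, list):
        seqs = {s.id: s.sequence for s in seqs}
    reduced, kept = collapse_haplotypes(seqs, masking=masking)
    uniq: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    assignment: dict[str, str] = {}
    for ind, s in reduced.items():
        if s not in uniq:
            uniq[s] = f"H{len(uniq) + 1}"
            members[uniq[s]] = []
        members[uniq[s]].append(ind)
        assignment[ind] = uniq[s]
    haps = {hid: s for s, hid in uniq.items()}
    hap_ids = list(haps)
    pop_labels = sorted(set(pops.values()))
    table = pd.DataFrame(0, index=hap_ids, columns=pop_labels)
    for ind, hid in assignment.items():
        table.loc[hid, pops[ind]] += 1
    arrs = {hid: np.frombuffer(haps[hid].encode(), dtype="S1")
            for hid in hap_ids}
    dist = pd.DataFrame(0, index=hap_ids, columns=hap_ids)
    for i, a in enumerate(hap_ids):
        for b in hap_ids[i + 1 :]:
            d = int(np.sum(arrs[a] != arrs[b]))
            dist.loc[a, b] = dist.loc[b, a] = d
    div_rows = []
    for p in pop_labels:
        counts = table[p].to_numpy()
        div_rows.append(
            {"pop": p, "n": int(counts.sum()),
             "n_haplotypes": int((counts > 0).sum()),
             "Hd": haplotype_diversity(counts)}
        )
    return HaplotypeSet(
        haplotypes=haps, members=members, pop_counts=table,
        distances=dist, kept_positions=kept,
        diversity=pd.DataFrame(div_rows),
    )


def haplotype_network(hapset: HaplotypeSet) -> pd.DataFrame:
    """Minimum-spanning-tree haplotype network with alternative links.

    Returns an edge list (hap1, hap2, distance, in_mst).  Non-MST pairs are
    offered as alternative links when their direct distance equals the total
    distance along the MST path between them (an equally parsimonious
    connection).
    """
    hap_ids = list(hapset.haplotypes)
    if len(hap_ids) < 2:
        raise ValueError("need at least two haplotypes")
    G = nx.Graph()
    for i, a in enumerate(hap_ids):
        for b in hap_ids[i + 1 :]:
            G.add_edge(a, b, weight=int(hapset.distances.loc[a, b]))
    mst = nx.minimum_spanning_tree(G, weight="weight")
    rows = [
        {"hap1": u, "hap2": v, "distance": d["weight"], "in_mst": True}
        for u, v, d in mst.edges(data=True)
    ]
    for i, a in enumerate(hap_ids):
        for b in hap_ids[i + 1 :]:
            if mst.has_edge(a, b):
                continue
            path = nx.shortest_path(mst, a, b)
            path_len = sum(
                mst[u][v]["weight"] for u, v in zip(path[:-1], path[1:])
            )
            direct = int(hapset.distances.loc[a, b])
            if direct == path_len:
                rows.append({"hap1": a, "hap2": b, "distance": direct,
                             "in_mst": False})
    return pd.DataFrame(rows, columns=["hap1", "hap2", "distance", "in_mst"])


def write_fasta(seqs: dict[str, str] | list[ConsensusSeq],
                path: str | Path) -> None:
    if isinstance(seqs, list):
        seqs = {s.id: s.sequence for s in seqs}
    with open(path, "w", newline="\n") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
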