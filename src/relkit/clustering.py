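"""Greedy centroid clustering for redundancy reduction.

Two uses in the pipeline: exact dedup (threshold 1.0) and 50 %-identity
centroid selection before motif discovery.  Sequences are processed in
length-descending order (ties broken lexicographically by id); each joins
the first existing cluster whose centroid identity meets the threshold,
otherwise it founds a new cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import _nw_kernel, encode_protein
from .core_seq import ProteinSeq, SequenceSet
from .homology_search import GAP_EXTEND, GAP_OPEN, blosum62


@dataclass
class Cluster:
    centroid_id: str
    member_ids: list[str] = field(default_factory=list)
    threshold: float = 1.0
    identities: dict[str, float] = field(default_factory=dict)


_SUB = None


def _sub() -> np.ndarray:
    global _SUB
    if _SUB is None:
        _SUB = blosum62()
    return _SUB


def pairwise_identity(a: ProteinSeq, b: ProteinSeq) -> float:
    """Identity over the optimal global alignment with free end gaps.

    Denominator: alignment columns including internal gaps, terminal
    (free) gap columns excluded.
    """
    if not a.residues or not b.residues:
        raise ValueError("sequences must be non-empty")
    if a.residues == b.residues:
        return 1.0
    ea, eb = encode_protein(a.residues), encode_protein(b.residues)
    _, n_id, n_col, n_term, _ = _nw_kernel(
        ea, eb, _sub(), GAP_OPEN, GAP_EXTEND, True)
    denom = n_col - n_term
    return n_id / denom if denom > 0 else 0.0


def greedy_cluster(seqs: SequenceSet, threshold: float,
                   ) -> list[Cluster]:
    """Greedy centroid clustering at the given identity threshold.

    Output order is founding order.  At threshold 1.0 membership reduces
    to substring containment (free-end identity), checked without
    alignment for speed.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    order = sorted(seqs, key=lambda r: (-len(r.residues), r.id))
    clusters: list[Cluster] = []
    for rec in order:
        placed = False
        for cl in clusters:
            centroid = seqs[cl.centroid_id]
            if threshold >= 1.0:
                ident = 1.0 if rec.residues in centroid.residues else 0.0
            else:
                ident = pairwise_identity(rec, centroid)
            if ident >= threshold:
                cl.member_ids.append(rec.id)
                cl.identities[rec.id] = ident
                placed = True
                break
        if not placed:
            clusters.append(Cluster(rec.id, [rec.id], threshold,
                                    {rec.id: 1.0}))
    return clusters


def centroids(clusters: list[Cluster], seqs: SequenceSet) -> SequenceSet:
    return seqs.subset([cl.centroid_id for cl in clusters])


def write_cluster_report(clusters: list[Cluster], path) -> None:
    """TSV: cluster_id, centroid_id, member_id, identity_to_centroid."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tcentroid_id\tmember_id\tidentity_to_centroid\n")
        for k, cl in enumerate(clusters):
            for mid in cl.member_ids:
                fh.write(f"{k}\t{cl.centroid_id}\t{mid}\t"
                         f"{cl.identities[mid]:.4f}\n")
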