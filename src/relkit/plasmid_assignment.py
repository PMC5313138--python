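"""Plasmid-localization calls by six-frame translated matching.

A protein is called plasmid-located when its best local alignment against
any translation frame of a (circular) plasmid reaches identity > 0.95
over coverage > 0.80 of the entire protein length.  A similarity mode
(positive-scoring substitutions counted as matches) is provided as an
option.  Calls are cross-tabulated against the two-clade partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._align import _sw_kernel, encode_protein
from .core_seq import NucSeq, ProteinSeq, SequenceSet, six_frame_translations
from .homology_search import GAP_EXTEND, GAP_OPEN, blosum62
from .phylogeny import CladePartition


@dataclass
class PlasmidRecord:
    id: str
    seq: NucSeq

    def __post_init__(self) -> None:
        if not self.seq.circular:
            raise ValueError("plasmid sequences must be circular")


@dataclass
class LocalizationCall:
    protein_id: str
    plasmid_id: str | None
    identity: float
    coverage: float
    positive: bool


def _doubled_frames(plasmid: PlasmidRecord) -> list:
    """Six-frame translations of the doubled sequence (minus one codon),
    so origin-spanning genes are seen unbroken."""
    bases = plasmid.seq.bases
    doubled = NucSeq(plasmid.id, bases + bases[:-3] if len(bases) > 3
                     else bases, circular=False)
    return six_frame_translations(doubled)


def translated_match(protein: ProteinSeq, plasmid: PlasmidRecord,
                     min_identity: float = 0.95, min_coverage: float = 0.80,
                     mode: str = "identity") -> LocalizationCall:
    """Best translated local alignment of the protein on the plasmid.

    ``mode='similarity'`` counts positive-scoring substitutions as matches.
    """
    if len(plasmid.seq.bases) < 3:
        raise ValueError("plasmid shorter than one codon")
    if mode not in ("identity", "similarity"):
        raise ValueError(f"unknown mode {mode!r}")
    sub = blosum62()
    qa = encode_protein(protein.residues)
    best = (0.0, 0.0, 0.0)  # score, identity, coverage
    for frame in _doubled_frames(plasmid):
        # split on stops: alignments cannot meaningfully cross a stop
        ta = encode_protein(frame.residues)
        score, qi, qj, ti, tj, n_id, n_col = _sw_kernel(
            qa, ta, sub, GAP_OPEN, GAP_EXTEND)
        if n_col == 0:
            continue
        if mode == "similarity":
            n_id = _count_positive(qa, ta, qi, qj, ti, tj, sub)
        ident = n_id / n_col
        cov = (qj - qi) / len(protein.residues)
        if score > best[0]:
            best = (score, ident, cov)
    _, ident, cov = best
    positive = ident > min_identity and cov > min_coverage
    return LocalizationCall(protein.id, plasmid.id if positive else None,
                            ident, cov, positive)


def _count_positive(qa, ta, qi, qj, ti, tj, sub) -> int:
    # re-run a small alignment over the matched spans to count positives
    from ._align import _nw_kernel
    _, _, _, _, pairs = _nw_kernel(qa[qi:qj], ta[ti:tj], sub,
                                   GAP_OPEN, GAP_EXTEND, False)
    n_pos = 0
    for a_idx, b_idx in pairs:
        if a_idx >= 0 and b_idx >= 0:
            if sub[qa[qi + a_idx], ta[ti + b_idx]] > 0:
                n_pos += 1
    return n_pos


def localize(proteins: SequenceSet, plasmids: list[PlasmidRecord],
             min_identity: float = 0.95, min_coverage: float = 0.80,
             mode: str = "identity") -> list[LocalizationCall]:
    """Best call per protein over the whole plasmid database."""
    calls = []
    for prot in proteins:
        best: LocalizationCall | None = None
        for pl in plasmids:
            call = translated_match(prot, pl, min_identity, min_coverage,
                                    mode)
            if (best is None
                    or (call.positive and not best.positive)
                    or (call.positive == best.positive
                        and call.identity * call.coverage
                        > best.identity * best.coverage)):
                best = call
            if best.positive:
                break  # first positive plasmid suffices
        calls.append(best)
    return calls


@dataclass
class CrossTab:
    counts: dict          # (clade, on_plasmid) -> count
    pct_on_plasmid_by_clade: dict
    pct_of_positives_in_clade: dict
    zero_denominator: bool


def clade_plasmid_crosstab(calls: list[LocalizationCall],
                           partition: CladePartition) -> CrossTab:
    """2x2 clade x plasmid-location counts and percentages."""
    by_id = {c.protein_id: c for c in calls}
    for leaf in partition.assignment:
        if leaf not in by_id:
            raise ValueError(f"protein {leaf!r} has no localization call")
    counts = {(c, flag): 0 for c in (1, 2) for flag in (True, False)}
    for leaf, clade in partition.assignment.items():
        counts[(clade, by_id[leaf].positive)] += 1
    total_pos = counts[(1, True)] + counts[(2, True)]
    zero = total_pos == 0
    pct_on = {}
    for c in (1, 2):
        tot = counts[(c, True)] + counts[(c, False)]
        pct_on[c] = 100.0 * counts[(c, True)] / tot if tot else 0.0
    pct_pos = {c: (100.0 * counts[(c, True)] / total_pos if total_pos
                   else 0.0) for c in (1, 2)}
    return CrossTab(counts, pct_on, pct_pos, zero)


def write_calls(calls: list[LocalizationCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tplasmid\tidentity\tcoverage\tcall\n")
        for c in sorted(calls, key=lambda c: c.protein_id):
            fh.write(f"{c.protein_id}\t{c.plasmid_id or '-'}\t"
                     f"{c.identity:.4f}\t{c.coverage:.4f}\t"
                     f"{'plasmid' if c.positive else 'none'}\n")


def write_crosstab(tab: CrossTab, path) -> None:
    with open(path, "w") as fh:
        fh.write("clade\ton_plasmid\tnot_on_plasmid\tpct_on_plasmid\t"
                 "pct_of_plasmid_positives\n")
        for c in (1, 2):
            fh.write(f"{c}\t{tab.counts[(c, True)]}\t"
                     f"{tab.counts[(c, False)]}\t"
                     f"{tab.pct_on_plasmid_by_clade[c]:.1f}\t"
                     f"{tab.pct_of_positives_in_clade[c]:.1f}\n")
        if tab.zero_denominator:
            fh.write("# zero positive calls: percentages of positives "
                     "reported as 0\n")
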