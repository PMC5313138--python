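"""Iterative PSSM homology search (psi-blast style, desk scale).

Round 1 scores the database with the seed's substitution-matrix rows; every
later round rebuilds a position-specific score matrix (PSSM) from the
accepted hit segments stacked by their alignment to the query, recalibrates
empirical Gumbel E-value statistics against shuffled decoys and rescans.
Membership is monotone: once accepted a member is never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from ._align import (AA_ORDER, X_CODE, _profile_kernel, _sw_kernel,
                     encode_protein)
from .core_seq import Msa, ProteinSeq, SequenceSet

GAP_OPEN = 11.0
GAP_EXTEND = 1.0

#: Robinson & Robinson amino-acid background frequencies (order AA_ORDER).
BACKGROUND = np.array([
    0.07805, 0.01925, 0.05364, 0.06295, 0.03856, 0.07377, 0.02199, 0.05142,
    0.05744, 0.09019, 0.02243, 0.04487, 0.05203, 0.04264, 0.05129, 0.07120,
    0.05841, 0.06441, 0.01330, 0.03216,
])
BACKGROUND /= BACKGROUND.sum()


def blosum62() -> np.ndarray:
    """BLOSUM62 as a 21x21 half-bit matrix in :data:`AA_ORDER` + X order.

    The X row/column is forced to -1 so that unknowns mismatch everything.
    """
    raw = substitution_matrices.load("BLOSUM62")
    mat = np.full((21, 21), -1.0)
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            mat[i, j] = raw[a, b]
    return mat


@dataclass
class PairwiseAlignment:
    score: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    identity_fraction: float
    n_columns: int


@dataclass
class Pssm:
    """Log-odds scores in half-bits, one row per query position."""

    width: int
    scores: np.ndarray  # (width, 21); column 20 is X
    background: np.ndarray  # (20,)
    pseudocount_weight: float

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("Pssm width must be >= 1")
        if self.scores.shape != (self.width, 21):
            raise ValueError("score matrix shape mismatch")


@dataclass
class SearchHit:
    target_id: str
    evalue: float
    bitscore: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    identity_fraction: float


@dataclass
class SearchRound:
    round_index: int
    members: set[str]
    converged: bool
    hits: list[SearchHit] = field(default_factory=list)


@dataclass
class PsiSearchResult:
    rounds: list[SearchRound]
    members: SequenceSet


def smith_waterman(a: ProteinSeq, b: ProteinSeq,
                   substitution: np.ndarray | None = None,
                   gap_open: float = GAP_OPEN,
                   gap_extend: float = GAP_EXTEND) -> PairwiseAlignment:
    """Optimal local alignment under affine gaps.

    Identity is counted as matching columns over all alignment columns
    (gap columns included).  Empty input yields score 0 and empty spans.
    """
    if substitution is None:
        substitution = blosum62()
    if len(a.residues) == 0 or len(b.residues) == 0:
        return PairwiseAlignment(0.0, (0, 0), (0, 0), 0.0, 0)
    ea, eb = encode_protein(a.residues), encode_protein(b.residues)
    score, ai, aj, bi, bj, n_id, n_col = _sw_kernel(
        ea, eb, substitution, gap_open, gap_extend)
    ident = n_id / n_col if n_col else 0.0
    return PairwiseAlignment(float(score), (int(ai), int(aj)),
                             (int(bi), int(bj)), ident, int(n_col))


def _pseudocount_profile(substitution: np.ndarray) -> np.ndarray:
    """q(a | b) from the half-bit matrix: p_a * 2^(s_ab/2), renormalized."""
    q = BACKGROUND[:, None] * np.power(2.0, substitution[:20, :20] / 2.0)
    return q / q.sum(axis=0, keepdims=True)


def build_pssm(seed_sites: Msa, background: np.ndarray | None = None,
               pseudocount_weight: float = 10.0) -> Pssm:
    """Build a half-bit log-odds PSSM from stacked member segments.

    Pseudocounts are substitution-derived (psi-blast style): the pseudocount
    distribution of a column is the average of BLOSUM62 conditional target
    frequencies of the observed residues, so a single-row profile with large
    ``pseudocount_weight`` approaches the plain substitution rows.
    """
    if background is None:
        background = BACKGROUND
    if seed_sites.n_rows < 1:
        raise ValueError("need at least one row")
    width = seed_sites.n_cols
    sub = blosum62()
    q_cond = _pseudocount_profile(sub)  # (20 target, 20 source)
    counts = np.zeros((width, 20))
    pseudo = np.zeros((width, 20))
    for row in seed_sites.rows:
        codes = encode_protein(row)
        for c, ch in enumerate(row):
            if ch == "-":
                continue
            code = codes[c]
            if code >= 20:
                continue
            counts[c, code] += 1
            pseudo[c] += q_cond[:, code]
    n_obs = counts.sum(axis=1)
    if np.any(n_obs == 0):
        bad = int(np.where(n_obs == 0)[0][0])
        raise ValueError(f"all-gap column {bad} in site alignment")
    pseudo /= n_obs[:, None]  # mean conditional profile per column
    w = pseudocount_weight
    freqs = (counts + w * pseudo) / (n_obs + w)[:, None]
    scores = np.full((width, 21), -1.0)
    scores[:, :20] = 2.0 * np.log2(freqs / background[None, :])
    return Pssm(width, scores, background.copy(), w)


def pssm_from_sequence(seq: ProteinSeq,
                       substitution: np.ndarray | None = None) -> Pssm:
    """PSSM whose rows are the substitution-matrix rows of the sequence."""
    if substitution is None:
        substitution = blosum62()
    codes = encode_protein(seq.residues)
    scores = substitution[codes].astype(float)
    return Pssm(len(codes), scores, BACKGROUND.copy(), np.inf)


def _shuffle_codes(codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    rng.shuffle(out)
    return out


def calibrate_evalues(pssm: Pssm, db: SequenceSet, n_decoys: int = 100,
                      seed: int = 0) -> tuple[float, float]:
    """Fit Karlin-Altschul style Gumbel parameters against shuffled decoys.

    Decoys are residue-shuffled copies of database sequences; the maximal
    profile alignment scores are fitted to a Gumbel law, giving
    ``E(S) = K * m * n * exp(-lambda * S)``.
    """
    if n_decoys < 100:
        raise ValueError("n_decoys must be >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(db), size=n_decoys)
    scores = np.empty(n_decoys)
    lengths = np.empty(n_decoys)
    for k, i in enumerate(idx):
        codes = encode_protein(db[int(i)].residues)
        dec = _shuffle_codes(codes, rng)
        s, *_ = _profile_kernel(pssm.scores, dec, GAP_OPEN, GAP_EXTEND)
        scores[k] = s
        lengths[k] = len(dec)
    if np.std(scores) < 1e-12:
        raise ValueError("degenerate decoy score distribution")
    # Gumbel method-of-moments: beta = sqrt(6)*sd/pi, mu = mean - gamma*beta
    beta = np.sqrt(6.0) * np.std(scores) / np.pi
    mu = np.mean(scores) - 0.5772156649 * beta
    lam = 1.0 / beta
    m = pssm.width
    n_mean = float(np.mean(lengths))
    K = np.exp(mu / beta) / (m * n_mean)
    return float(lam), float(K)


def evalue(score: float, lam: float, K: float, m: int, n_total: int) -> float:
    return float(K * m * n_total * np.exp(-lam * score))


def _stack_segments(query: ProteinSeq, alignments: dict[str, np.ndarray],
                    db: SequenceSet) -> Msa:
    """Stack accepted hit segments onto query columns; unaligned -> gap."""
    width = len(query.residues)
    ids = [query.id + "|query"]
    rows = [query.residues]
    for tid, pairs in alignments.items():
        row = ["-"] * width
        tseq = db[tid].residues
        for qpos, tpos in pairs:
            if qpos >= 0 and tpos >= 0:
                row[qpos] = tseq[tpos]
        ids.append(tid)
        rows.append("".join(row))
    return Msa(ids, rows)


def psi_search(seed: ProteinSeq, db: SequenceSet,
               evalue_threshold: float = 1e-15, max_rounds: int = 10,
               n_decoys: int = 120, seed_rng: int = 0,
               pseudocount_weight: float = 10.0) -> PsiSearchResult:
    """Iterative profile search collecting members above threshold.

    Deterministic given (db order, seed sequence, ``seed_rng``).
    """
    if len(db) == 0 or len(seed.residues) == 0:
        raise ValueError("seed and database must be non-empty")
    encoded = {rec.id: encode_protein(rec.residues) for rec in db}
    n_total = sum(len(rec.residues) for rec in db)
    members: set[str] = set()
    alignments: dict[str, np.ndarray] = {}
    rounds: list[SearchRound] = []
    pssm = pssm_from_sequence(seed)
    for r in range(1, max_rounds + 1):
        lam, K = calibrate_evalues(pssm, db, n_decoys=n_decoys,
                                   seed=seed_rng + r)
        hits: list[SearchHit] = []
        new_members: set[str] = set()
        for rec in db:
            s, qi, qj, ti, tj, pairs = _profile_kernel(
                pssm.scores, encoded[rec.id], GAP_OPEN, GAP_EXTEND)
            e = evalue(s, lam, K, pssm.width, n_total)
            if e <= evalue_threshold:
                n_col = len(pairs)
                n_id = 0
                for qpos, tpos in pairs:
                    if (qpos >= 0 and tpos >= 0
                            and seed.residues[qpos] == rec.residues[tpos]
                            and seed.residues[qpos] != "X"):
                        n_id += 1
                hits.append(SearchHit(rec.id, e, float(s) / 2.0,
                                      (int(qi), int(qj)), (int(ti), int(tj)),
                                      n_id / n_col if n_col else 0.0))
                if rec.id not in members:
                    new_members.add(rec.id)
                alignments[rec.id] = pairs
        members |= new_members
        if seed.id in db and seed.id not in members:
            raise RuntimeError(
                "internal consistency error: seed does not hit itself")
        converged = not new_members and r > 1
        rounds.append(SearchRound(r, set(members), converged, hits))
        if converged:
            break
        if members:
            site_msa = _stack_segments(seed, alignments, db)
            pssm = build_pssm(site_msa, pseudocount_weight=pseudocount_weight)
    return PsiSearchResult(rounds, db.subset(sorted(members)))


def write_search_report(result: PsiSearchResult, path) -> None:
    """TSV report: round, target_id, evalue, bitscore, identity, spans."""
    with open(path, "w") as fh:
        fh.write("round\ttarget_id\tevalue\tbitscore\tidentity\t"
                 "query_start\tquery_end\ttarget_start\ttarget_end\n")
        for rnd in result.rounds:
            for h in sorted(rnd.hits, key=lambda h: (h.evalue, h.target_id)):
                qs, qe = h.query_span
                ts, te = h.target_span
                fh.write(f"{rnd.round_index}\t{h.target_id}\t{h.evalue:.3g}\t"
                         f"{h.bitscore:.1f}\t{h.identity_fraction:.4f}\t"
                         f"{qs + 1}\t{qe}\t{ts + 1}\t{te}\n")
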