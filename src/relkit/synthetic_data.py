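"""Ground-truth generators for every pipeline stage.

Families of two clades carry planted PWM signatures with per-clade
presence probabilities; decoy proteins are i.i.d. background; circular
plasmids embed back-translated member CDSs, a phased-A-tract bent region
and an oriT cassette (direct repeats, inverted repeat, palindrome,
GC-rich window, nick 14-mer).  Every generator is deterministic given
(spec, seed) and emits a manifest used as the recovery oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Data import CodonTable

from ._align import AA_ORDER
from .core_seq import NucSeq, ProteinSeq, SequenceSet
from .dna_features import NICK_MOTIF


# ---------------------------------------------------------------------------
# specs

def make_pwm(consensus: str, strength: float = 0.9) -> np.ndarray:
    """Peaked PWM: ``strength`` on the consensus letter, rest uniform."""
    w = len(consensus)
    pwm = np.full((w, 20), (1.0 - strength) / 19.0)
    for i, ch in enumerate(consensus):
        pwm[i, AA_ORDER.index(ch)] = strength
    return pwm


@dataclass
class SignatureSpec:
    name: str
    pwm: np.ndarray
    presence: dict[int, float]  # clade (1|2) -> probability

    @property
    def width(self) -> int:
        return self.pwm.shape[0]


@dataclass
class FamilySpec:
    n_clade1: int
    n_clade2: int
    signatures: list[SignatureSpec]
    member_length: int = 120
    clade_divergence: float = 0.3
    member_divergence: float = 0.2
    background: np.ndarray | None = None
    id_prefix: str = "fam"

    def __post_init__(self) -> None:
        for sig in self.signatures:
            for p in sig.presence.values():
                if not 0.0 <= p <= 1.0:
                    raise ValueError("presence probability outside [0,1]")
        if self.signatures and not any(
                all(sig.presence.get(c, 0.0) >= 1.0 for c in (1, 2))
                for sig in self.signatures):
            raise ValueError(
                "at least one signature must be present in all members")
        for sig in self.signatures:
            if sig.width > self.member_length:
                raise ValueError(
                    f"signature {sig.name!r} wider than member length")


@dataclass
class GroundTruth:
    members: dict = field(default_factory=dict)
    plasmids: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"members": self.members, "plasmids": self.plasmids},
                      fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d.get("members", {}), d.get("plasmids", {}))


# ---------------------------------------------------------------------------
# protein generators

_UNIFORM_BG = np.full(20, 0.05)


def _sample_protein(rng: np.random.Generator, length: int,
                    bg: np.ndarray) -> np.ndarray:
    return rng.choice(20, size=length, p=bg)


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator,
            bg: np.ndarray) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(len(codes)) < rate
    out[mask] = rng.choice(20, size=int(mask.sum()), p=bg)
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(AA_ORDER[c] for c in codes)


def gen_family(spec: FamilySpec, seed: int = 0
               ) -> tuple[SequenceSet, GroundTruth]:
    """Two-clade family from a common ancestor with planted signatures."""
    rng = np.random.default_rng(seed)
    bg = spec.background if spec.background is not None else _UNIFORM_BG
    root = _sample_protein(rng, spec.member_length, bg)
    clade_anc = {c: _mutate(root, spec.clade_divergence, rng, bg)
                 for c in (1, 2)}
    truth = GroundTruth()
    records = []
    counts = {1: spec.n_clade1, 2: spec.n_clade2}
    for clade in (1, 2):
        for i in range(counts[clade]):
            sid = f"{spec.id_prefix}_c{clade}_{i:03d}"
            codes = _mutate(clade_anc[clade], spec.member_divergence, rng, bg)
            used: list[tuple[int, int]] = []
            sites = {}
            for sig in spec.signatures:
                if rng.random() >= sig.presence.get(clade, 0.0):
                    continue
                w = sig.width
                for _ in range(200):
                    start = int(rng.integers(0, spec.member_length - w + 1))
                    if all(start + w <= a or start >= b for a, b in used):
                        break
                else:
                    raise RuntimeError("could not place signature site")
                used.append((start, start + w))
                site = np.array([rng.choice(20, p=sig.pwm[k])
                                 for k in range(w)])
                codes[start:start + w] = site
                sites[sig.name] = start
            records.append(ProteinSeq(sid, _decode(codes)))
            truth.members[sid] = {"clade": clade, "sites": sites,
                                  "family": spec.id_prefix}
    return SequenceSet(records, source="gen_family"), truth


def gen_decoys(n: int, length_dist: int | tuple[int, int] = 120,
               composition: np.ndarray | None = None, seed: int = 0,
               id_prefix: str = "decoy") -> SequenceSet:
    """i.i.d. background sequences with no planted structure."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    bg = composition if composition is not None else _UNIFORM_BG
    bg = np.asarray(bg, dtype=float)
    bg = bg / bg.sum()
    records = []
    for i in range(n):
        if isinstance(length_dist, tuple):
            length = int(rng.integers(length_dist[0], length_dist[1] + 1))
        else:
            length = int(length_dist)
        codes = rng.choice(20, size=length, p=bg)
        records.append(ProteinSeq(f"{id_prefix}_{i:04d}", _decode(codes)))
    return SequenceSet(records, source="gen_decoys")


# ---------------------------------------------------------------------------
# plasmid generators

@dataclass
class CdsSpec:
    protein: ProteinSeq
    strand: str = "+"
    start: int | None = None      # 0-based; None -> placed by generator
    spans_origin: bool = False


@dataclass
class BentRegionSpec:
    center: int
    tract_len: int = 6
    copies: int = 10
    period: float = 10.5          # phased A-tracts, alternating 10/11 bp


@dataclass
class OriTSpec:
    start: int
    direct_repeat: str = "TGTGCAT"
    n_direct: int = 3
    inverted_arm: str = "GGCTTTTTGC"
    inverted_loop: str = "TGCC"
    palindrome: str = "TGGTACCA"
    gc_len: int = 30
    gc_fraction: float = 0.733
    nick_motif: str = NICK_MOTIF


@dataclass
class PlasmidSpec:
    plasmid_id: str
    length: int
    cds: list[CdsSpec] = field(default_factory=list)
    bent: BentRegionSpec | None = None
    orit: OriTSpec | None = None


_CODON_CHOICES: dict[str, list[str]] | None = None


def _codon_choices() -> dict[str, list[str]]:
    global _CODON_CHOICES
    if _CODON_CHOICES is None:
        table = CodonTable.unambiguous_dna_by_id[11]
        choices: dict[str, list[str]] = {}
        for codon, aa in table.forward_table.items():
            choices.setdefault(aa, []).append(codon)
        choices["*"] = sorted(table.stop_codons)
        _CODON_CHOICES = {aa: sorted(c) for aa, c in choices.items()}
    return _CODON_CHOICES


def back_translate(protein: ProteinSeq, rng: np.random.Generator) -> str:
    """Uniform-codon back-translation (table 11), stop codon appended."""
    choices = _codon_choices()
    codons = []
    for aa in protein.residues:
        opts = choices.get(aa)
        if opts is None:  # X: any sense codon
            opts = choices["L"]
        codons.append(opts[int(rng.integers(0, len(opts)))])
    codons.append(choices["*"][int(rng.integers(0, 3))])
    return "".join(codons)


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _bent_block(spec: BentRegionSpec, rng: np.random.Generator) -> str:
    parts = []
    for i in range(spec.copies):
        spacing = int(np.floor(spec.period)) + (i % 2 if spec.period % 1
                                                else 0)
        gap = spacing - spec.tract_len
        if gap < 0:
            raise ValueError("tract longer than period")
        parts.append("A" * spec.tract_len)
        parts.append("".join(rng.choice(list("CGT"), size=gap)))
    return "".join(parts)


def _gc_block(n: int, frac: float, rng: np.random.Generator) -> str:
    n_gc = int(round(frac * n))
    chars = (list(rng.choice(list("GC"), size=n_gc))
             + list(rng.choice(list("AT"), size=n - n_gc)))
    rng.shuffle(chars)
    return "".join(chars)


def _orit_block(spec: OriTSpec, rng: np.random.Generator
                ) -> tuple[str, dict]:
    """Assemble the cassette; coordinates are relative to the block."""
    parts: list[str] = []
    feats: dict = {}
    pos = 0

    def emit(s: str) -> int:
        nonlocal pos
        parts.append(s)
        start = pos
        pos += len(s)
        return start

    def spacer() -> None:
        emit("".join(rng.choice(list("ACGT"),
                                size=int(rng.integers(4, 9)))))

    feats["direct_repeats"] = []
    for _ in range(spec.n_direct):
        feats["direct_repeats"].append(emit(spec.direct_repeat))
        spacer()
    ir = (spec.inverted_arm + spec.inverted_loop
          + _revcomp(spec.inverted_arm))
    feats["inverted_repeat"] = emit(ir)
    spacer()
    feats["palindrome"] = emit(spec.palindrome)
    spacer()
    feats["gc_window"] = emit(_gc_block(spec.gc_len, spec.gc_fraction, rng))
    feats["nick_motif"] = emit(spec.nick_motif)
    feats["nick_position"] = pos  # 0-based base immediately 3' of motif
    return "".join(parts), feats


def gen_plasmid(spec: PlasmidSpec, seed: int = 0
                ) -> tuple[NucSeq, GroundTruth]:
    """Circular plasmid with planted CDSs, bent region and oriT cassette."""
    rng = np.random.default_rng(seed)
    n = spec.length
    seq = list("".join(rng.choice(list("ACGT"), size=n)))
    occupied: set[int] = set()
    feats: dict = {"length": n}

    def place(block: str, start: int, label: str) -> tuple[int, int]:
        if len(block) >= n:
            raise ValueError(f"{label} longer than plasmid")
        positions = {(start + k) % n for k in range(len(block))}
        if positions & occupied:
            raise ValueError(f"feature overlap at {label}")
        occupied.update(positions)
        for k, ch in enumerate(block):
            seq[(start + k) % n] = ch
        return start, start + len(block)

    truth = GroundTruth()
    cds_records = []
    cursor = 0
    for c in spec.cds:
        dna = back_translate(c.protein, rng)
        if c.strand == "-":
            dna = _revcomp(dna)
        if c.start is not None:
            start = c.start
        elif c.spans_origin:
            start = n - len(dna) // 2
        else:
            start = cursor
            cursor += len(dna) + 50
        s, e = place(dna, start, f"cds:{c.protein.id}")
        cds_records.append({"protein": c.protein.id, "start": s, "end": e,
                            "strand": c.strand,
                            "spans_origin": e > n})
    if spec.bent is not None:
        block = _bent_block(spec.bent, rng)
        start = spec.bent.center - len(block) // 2
        place(block, start % n, "bent_region")
        feats["bent_center"] = spec.bent.center % n
        feats["bent_span"] = len(block)
    if spec.orit is not None:
        block, ofeats = _orit_block(spec.orit, rng)
        place(block, spec.orit.start, "oriT")
        shifted = {}
        for key, val in ofeats.items():
            if isinstance(val, list):
                shifted[key] = [(spec.orit.start + v) % n for v in val]
            else:
                shifted[key] = (spec.orit.start + val) % n
        feats["orit"] = shifted
        feats["nick_position_1based"] = shifted["nick_position"] + 1
    feats["cds"] = cds_records
    truth.plasmids[spec.plasmid_id] = feats
    return NucSeq(spec.plasmid_id, "".join(seq), circular=True), truth
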