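"""Intrinsic DNA curvature (dinucleotide wedge model) and oriT features.

Curvature is computed from a 3D helical-axis path built by composing
per-dinucleotide twist/roll/tilt deflections; the profile is smoothed with
a sliding window and z-normalized.  Feature annotation covers direct and
inverted repeats, palindromes, GC windows and the relaxase nick site
located by its 14-mer recognition sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_seq import NucSeq, reverse_complement

DINUCLEOTIDES = [a + b for a in "ACGT" for b in "ACGT"]

#: Relaxase nick-site recognition sequence (the nick falls immediately 3').
NICK_MOTIF = "GAATCGGGGGCCGG"

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class WedgeParams:
    """Per-dinucleotide roll/tilt/twist wedge angles in degrees."""

    name: str
    roll: dict
    tilt: dict
    twist: dict

    def __post_init__(self) -> None:
        for table in (self.roll, self.tilt, self.twist):
            missing = set(DINUCLEOTIDES) - set(table)
            if missing:
                raise ValueError(f"missing dinucleotides: {sorted(missing)}")


def _aawedge() -> WedgeParams:
    # A-tract wedge model: only the AA step (TT on the complement-strand
    # reading) carries a wedge of ~8.4 degrees (roll -7.2, tilt -4.4);
    # helical repeat 10.5 bp/turn.  Values follow the classic A-tract
    # wedge literature; absolute magnitudes are not a numeric contract.
    roll = {d: 0.0 for d in DINUCLEOTIDES}
    tilt = {d: 0.0 for d in DINUCLEOTIDES}
    twist = {d: 360.0 / 10.5 for d in DINUCLEOTIDES}
    roll["AA"] = -7.2
    tilt["AA"] = -4.4
    roll["TT"] = -7.2
    tilt["TT"] = 4.4
    return WedgeParams("AAWedge", roll, tilt, twist)


def _cds() -> WedgeParams:
    # Full 16-dinucleotide roll/tilt set in the De Santis lineage
    # (uniform twist 34.6 deg); satisfies the complement-strand symmetry
    # roll(XY) == roll(revcomp(XY)), tilt(XY) == -tilt(revcomp(XY)).
    roll = {
        "AA": -5.4, "AC": -2.5, "AG": 1.0, "AT": -7.3,
        "CA": 6.8, "CC": 1.3, "CG": 4.6, "CT": 1.0,
        "GA": -2.4, "GC": -5.0, "GG": 1.3, "GT": -2.5,
        "TA": 0.0, "TC": -2.4, "TG": 6.8, "TT": -5.4,
    }
    tilt = {
        "AA": -0.5, "AC": -2.7, "AG": -1.6, "AT": 0.0,
        "CA": 0.4, "CC": 0.6, "CG": 0.0, "CT": 1.6,
        "GA": -1.7, "GC": 0.0, "GG": -0.6, "GT": 2.7,
        "TA": 0.0, "TC": 1.7, "TG": -0.4, "TT": 0.5,
    }
    twist = {d: 34.6 for d in DINUCLEOTIDES}
    return WedgeParams("CDS", roll, tilt, twist)


AAWEDGE = _aawedge()
CDS = _cds()
PARAMETER_SETS = {"AAWedge": AAWEDGE, "CDS": CDS}


def _rotation(twist: float, roll: float, tilt: float) -> np.ndarray:
    t, r, w = np.radians([tilt, roll, twist])
    cz, sz = np.cos(w), np.sin(w)
    cx, sx = np.cos(r), np.sin(r)
    cy, sy = np.cos(t), np.sin(t)
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
    rx = np.array([[1.0, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1.0, 0], [-sy, 0, cy]])
    return rz @ ry @ rx


def helical_path(seq_or_bases, params: WedgeParams) -> np.ndarray:
    """3D helical-axis points, one per dinucleotide step, unit rise.

    Steps containing N get zero wedge (twist only).  All-zero wedge
    angles produce collinear points.
    """
    bases = (seq_or_bases.bases if isinstance(seq_or_bases, NucSeq)
             else seq_or_bases)
    n_steps = len(bases) - 1
    if n_steps < 1:
        raise ValueError("need at least 2 bases")
    rots = {d: _rotation(params.twist[d], params.roll[d], params.tilt[d])
            for d in DINUCLEOTIDES}
    mean_twist = float(np.mean([params.twist[d] for d in DINUCLEOTIDES]))
    rot_n = _rotation(mean_twist, 0.0, 0.0)
    frame = np.eye(3)
    ez = np.array([0.0, 0.0, 1.0])
    points = np.empty((n_steps, 3))
    pos = np.zeros(3)
    for i in range(n_steps):
        step = bases[i:i + 2]
        frame = frame @ rots.get(step, rot_n)
        pos = pos + frame @ ez
        points[i] = pos
    return points


@dataclass
class CurvatureProfile:
    seq_id: str
    curvature: np.ndarray        # window 10, degrees per step
    curvature_angle: np.ndarray  # window 15, total chord angle in degrees
    window_curv: int
    window_angle: int
    circular: bool
    n_flagged_steps: int = 0


def _chord_angles(points: np.ndarray, w: int, n: int, offset: int
                  ) -> np.ndarray:
    """Angle at each of n positions between chords over [i-w,i] and [i,i+w]."""
    idx = np.arange(n) + offset
    v1 = points[idx] - points[idx - w]
    v2 = points[idx + w] - points[idx]
    dot = (v1 * v2).sum(axis=1)
    norm = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    cosang = np.clip(dot / np.maximum(norm, 1e-300), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def curvature_profile(seq: NucSeq, params: WedgeParams,
                      window_curv: int = 10, window_angle: int = 15
                      ) -> CurvatureProfile:
    """Per-position wedge-model curvature and curvature-angle.

    Curvature (window 10) is the chord angle divided by the window (degrees
    per step); the curvature-angle (window 15) is the total chord angle.
    Circular sequences wrap; linear edges are NaN.
    """
    n = len(seq.bases)
    wmax = max(window_curv, window_angle)
    if n <= 2 * wmax:
        raise ValueError("sequence shorter than curvature window")
    flagged = sum(1 for i in range(n - 1) if "N" in seq.bases[i:i + 2])
    if seq.circular:
        pad = wmax + 1
        ext = seq.bases[-pad:] + seq.bases + seq.bases[:pad]
        points = helical_path(ext, params)
        curv = _chord_angles(points, window_curv, n, pad) / window_curv
        ang = _chord_angles(points, window_angle, n, pad)
    else:
        points = helical_path(seq.bases, params)
        curv = np.full(n, np.nan)
        ang = np.full(n, np.nan)
        m = points.shape[0]
        for w, out, div in ((window_curv, curv, window_curv),
                            (window_angle, ang, 1)):
            nin = m - 2 * w
            if nin > 0:
                out[w:w + nin] = _chord_angles(points, w, nin, w) / div
    return CurvatureProfile(seq.id, curv, ang, window_curv, window_angle,
                            seq.circular, flagged)


def _smooth(values: np.ndarray, window: int, circular: bool) -> np.ndarray:
    """Centered moving average; NaNs excluded, edge weights renormalized."""
    n = len(values)
    if n < window:
        raise ValueError("profile shorter than smoothing window")
    half = window // 2
    valid = np.isfinite(values)
    filled = np.where(valid, values, 0.0)
    if circular:
        kernel_idx = np.arange(-half, window - half)
        sm = np.zeros(n)
        wt = np.zeros(n)
        for k in kernel_idx:
            sm += np.roll(filled, -k)
            wt += np.roll(valid.astype(float), -k)
    else:
        kern = np.ones(window)
        sm = np.convolve(filled, kern, mode="same")
        wt = np.convolve(valid.astype(float), kern, mode="same")
    return sm / np.maximum(wt, 1)


def smooth_normalize(values: np.ndarray, window: int = 600,
                     circular: bool = True) -> np.ndarray:
    """Centered moving average then z-transform to mean 0, sd 1.

    Circular profiles wrap; linear profiles use truncated windows with
    renormalized weights, and NaN entries are excluded.
    """
    smoothed = _smooth(np.asarray(values, dtype=float), window, circular)
    sd = smoothed.std()
    if sd < 1e-12:
        raise ValueError("degenerate constant profile after smoothing")
    return (smoothed - smoothed.mean()) / sd


def call_peaks(zprofile: np.ndarray, min_z: float = 2.0,
               min_separation: int = 1200, circular: bool = True
               ) -> list[int]:
    """Local maxima above ``min_z``, thinned greedily to ``min_separation``.

    Returns 1-based positions sorted by position.
    """
    z = np.asarray(zprofile, dtype=float)
    n = len(z)
    left = np.roll(z, 1)
    right = np.roll(z, -1)
    is_max = (z > left) & (z >= right)
    if not circular:
        is_max[0] = z[0] >= right[0]
        is_max[-1] = z[-1] > left[-1]
    cand = np.where(is_max & (z >= min_z))[0]
    cand = cand[np.argsort(-z[cand], kind="stable")]
    chosen: list[int] = []
    for c in cand:
        ok = True
        for s in chosen:
            dist = abs(int(c) - s)
            if circular:
                dist = min(dist, n - dist)
            if dist < min_separation:
                ok = False
                break
        if ok:
            chosen.append(int(c))
    return sorted(p + 1 for p in chosen)


def dinucleotide_shuffle(bases: str, rng: np.random.Generator,
                         max_tries: int = 200) -> str:
    """Shuffle preserving exact dinucleotide composition.

    Random Eulerian walk over the dinucleotide multigraph (same start and
    end symbol as the input); retries until a complete walk is found.
    """
    n = len(bases)
    if n < 3:
        return bases
    for _ in range(max_tries):
        edges: dict[str, list[str]] = {}
        for i in range(n - 1):
            edges.setdefault(bases[i], []).append(bases[i + 1])
        for v in edges:
            rng.shuffle(edges[v])
        out = [bases[0]]
        cur = bases[0]
        ok = True
        for _ in range(n - 1):
            nxt_list = edges.get(cur)
            if not nxt_list:
                ok = False
                break
            cur = nxt_list.pop()
            out.append(cur)
        if ok:
            return "".join(out)
    raise RuntimeError("dinucleotide shuffle failed to converge")


# ---------------------------------------------------------------------------
# repeats / palindromes

@dataclass
class RepeatHit:
    kind: str               # direct | inverted | palindrome
    arm1_start: int         # 1-based
    arm2_start: int         # 1-based
    arm_len: int
    loop_len: int
    mismatches: int

    def arms(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.arm1_start, self.arm1_start + self.arm_len - 1),
                (self.arm2_start, self.arm2_start + self.arm_len - 1))


def find_repeats(seq: NucSeq, min_arm: int = 4, max_loop: int = 20,
                 max_mismatch: int = 1) -> list[RepeatHit]:
    """Exhaustive direct/inverted repeat and palindrome scan.

    Inverted repeats grow outward from every (loop position, loop length)
    pair to the maximal arm with at most ``max_mismatch`` mismatches;
    palindromes are the loop-0 case.  Direct repeats are duplicated words
    extended rightward to maximal arm length, reported left-maximally.
    Quadratic scan, intended for feature-scale regions (<= ~5 kb).
    """
    s = seq.bases
    n = len(s)
    if n > 20000:
        raise ValueError("find_repeats is quadratic; pass a subregion")
    hits: list[RepeatHit] = []
    # inverted repeats / palindromes
    for g in range(0, max_loop + 1):
        for a in range(1, n):  # loop occupies [a, a+g)
            if a + g >= n:
                break
            mism = 0
            L = 0
            best = None
            while a - L - 1 >= 0 and a + g + L < n:
                c1 = s[a - L - 1]
                c2 = s[a + g + L]
                if _COMP.get(c2) != c1 or c1 == "N":
                    mism += 1
                    if mism > max_mismatch:
                        break
                L += 1
                if L >= min_arm:
                    best = (L, mism)
            if best is not None:
                L, mism = best
                # trim trailing mismatches off the arm ends
                while L > min_arm:
                    c1 = s[a - L]
                    c2 = s[a + g + L - 1]
                    if _COMP.get(c2) != c1 or c1 == "N":
                        L -= 1
                        mism -= 1
                    else:
                        break
                kind = "palindrome" if g == 0 else "inverted"
                hits.append(RepeatHit(kind, a - L + 1, a + g + 1, L, g, mism))
    # direct repeats (all start pairs; contained hits pruned below)
    for i in range(n):
        for j in range(i + min_arm, n):
            mism = 0
            L = 0
            best = None
            while i + L < j and j + L < n:
                if s[i + L] != s[j + L] or s[i + L] == "N":
                    mism += 1
                    if mism > max_mismatch:
                        break
                L += 1
                if L >= min_arm:
                    best = (L, mism)
            if best is not None:
                L, mism = best
                while L > min_arm and (s[i + L - 1] != s[j + L - 1]
                                       or s[i + L - 1] == "N"):
                    L -= 1
                    mism -= 1
                hits.append(RepeatHit("direct", i + 1, j + 1, L, j - i - L,
                                      mism))
    hits = _drop_contained(hits)
    hits.sort(key=lambda h: (h.arm1_start, h.arm2_start, -h.arm_len))
    return hits


def _drop_contained(hits: list[RepeatHit]) -> list[RepeatHit]:
    """Keep maximal-arm hits only: drop hits whose arms are both contained
    in a same-kind hit with a longer arm and no more mismatches."""
    out = []
    for h in hits:
        (a1, a2), (b1, b2) = h.arms()
        contained = False
        for other in hits:
            if other is h or other.kind != h.kind:
                continue
            if other.arm_len <= h.arm_len or other.mismatches > h.mismatches:
                continue
            (oa1, oa2), (ob1, ob2) = other.arms()
            if oa1 <= a1 and a2 <= oa2 and ob1 <= b1 and b2 <= ob2:
                contained = True
                break
        if not contained:
            out.append(h)
    return out


def gc_windows(seq: NucSeq, window: int = 30) -> np.ndarray:
    """GC percentage of every 1-bp-stepped window (wraps when circular).

    N bases are excluded from numerator and denominator; an all-N window
    yields NaN.
    """
    n = len(seq.bases)
    if window > n:
        raise ValueError("window longer than sequence")
    arr = np.frombuffer(seq.bases.encode(), dtype="S1")
    is_gc = ((arr == b"G") | (arr == b"C")).astype(float)
    is_n = (arr == b"N").astype(float)
    if seq.circular:
        is_gc = np.concatenate([is_gc, is_gc[:window - 1]])
        is_n = np.concatenate([is_n, is_n[:window - 1]])
        n_starts = n
    else:
        n_starts = n - window + 1
    cg = np.concatenate([[0.0], np.cumsum(is_gc)])
    cn = np.concatenate([[0.0], np.cumsum(is_n)])
    gc = cg[window:window + n_starts] - cg[:n_starts]
    nn = cn[window:window + n_starts] - cn[:n_starts]
    denom = window - nn
    with np.errstate(invalid="ignore", divide="ignore"):
        out = 100.0 * gc / denom
    out[denom == 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# nick site

@dataclass
class NickSite:
    position: int  # 1-based, immediately 3' of the recognition 14-mer
    strand: str
    ambiguous: bool = False


def locate_nick(seq: NucSeq, motif: str = NICK_MOTIF) -> list[NickSite]:
    """Locate nick site(s) from the recognition motif on either strand.

    The nick position is the first base 3' of the motif on the matched
    strand (wrapping on circular sequences).  Multiple occurrences are all
    returned and flagged ambiguous; no occurrence returns an empty list.
    """
    n = len(seq.bases)
    search = seq.bases + (seq.bases[:len(motif) - 1] if seq.circular else "")
    rc = motif.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
    sites: list[NickSite] = []
    for strand, pat in (("+", motif), ("-", rc)):
        start = 0
        while True:
            k = search.find(pat, start)
            if k < 0:
                break
            if strand == "+":
                pos0 = (k + len(motif)) % n if seq.circular else k + len(motif)
                if pos0 < n:
                    sites.append(NickSite(pos0 + 1, "+"))
            else:
                pos0 = (k - 1) % n if seq.circular else k - 1
                if pos0 >= 0:
                    sites.append(NickSite(pos0 + 1, "-"))
            start = k + 1
    if len(sites) > 1:
        sites = [NickSite(s.position, s.strand, True) for s in sites]
    return sites


# ---------------------------------------------------------------------------
# writers

def write_wiggle(profile: np.ndarray, seq_id: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"fixedStep chrom={seq_id} start=1 step=1\n")
        for v in profile:
            fh.write("NA\n" if not np.isfinite(v) else f"{v:.5f}\n")


def write_peaks_bed(peaks: list[int], seq_id: str, path) -> None:
    with open(path, "w") as fh:
        for p in peaks:  # 1-based -> BED 0-based half-open
            fh.write(f"{seq_id}\t{p - 1}\t{p}\tcurvature_peak\n")


def write_features_gff3(seq_id: str, repeats: list[RepeatHit],
                        nicks: list[NickSite], path, append: bool = False
                        ) -> None:
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            fh.write("##gff-version 3\n")
        for k, h in enumerate(repeats):
            (a1, a2), (b1, b2) = h.arms()
            attrs = (f"ID=rep{k};kind={h.kind};arm_len={h.arm_len};"
                     f"loop={h.loop_len};mismatches={h.mismatches};"
                     f"arm2_start={b1}")
            fh.write(f"{seq_id}\trelkit\t{h.kind}_repeat\t{a1}\t{b2}\t.\t+\t."
                     f"\t{attrs}\n")
        for k, s in enumerate(nicks):
            attrs = f"ID=nick{k};ambiguous={str(s.ambiguous).lower()}"
            fh.write(f"{seq_id}\trelkit\tnick_site\t{s.position}\t"
                     f"{s.position}\t.\t{s.strand}\t.\t{attrs}\n")
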