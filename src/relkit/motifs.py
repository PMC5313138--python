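"""Motif ("signature") discovery by ZOOPS expectation-maximization.

Discovery is sequential: fit a zero-or-one-occurrence-per-sequence mixture
by EM over a grid of candidate widths, keep the best motif if its E-value
passes the threshold, erase its sites and repeat.  Motif significance is
calibrated empirically: the same discovery procedure is run on
residue-shuffled copies of the input, a Gumbel law is moment-fitted to
the resulting maximized log-likelihood-ratio null (the appropriate family
for a maximum statistic), and the observed LLR is converted to a tail
p-value, Bonferroni-scaled by the number of widths tried.  Scanning uses exact position p-values obtained by
convolving the discretized column score distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import AA_ORDER, encode_protein
from .core_seq import ProteinSeq, SequenceSet

PSEUDO = 0.25


@dataclass
class Signature:
    name: str
    width: int
    pwm: np.ndarray            # (width, 20) probabilities, rows sum to 1
    evalue: float
    sites: list[tuple[str, int]] = field(default_factory=list)  # 0-based
    llr: float = 0.0
    zscore: float = 0.0

    def __post_init__(self) -> None:
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("pwm rows must sum to 1")

    def consensus(self) -> str:
        return "".join(AA_ORDER[i] for i in self.pwm.argmax(axis=1))


def info_content(pwm: np.ndarray) -> np.ndarray:
    """Per-column information content in bits: log2(20) - H(col)."""
    pwm = np.asarray(pwm, dtype=float)
    if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("pwm rows must sum to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pwm > 0, pwm * np.log2(pwm), 0.0)
    return np.log2(20.0) + plogp.sum(axis=1)


def _background(codes_list: list[np.ndarray]) -> np.ndarray:
    counts = np.ones(20)
    for codes in codes_list:
        valid = codes[codes < 20]
        counts += np.bincount(valid, minlength=20)
    return counts / counts.sum()


def _window_views(codes_list: list[np.ndarray], w: int) -> list[np.ndarray]:
    views = []
    for codes in codes_list:
        if len(codes) < w:
            views.append(np.empty((0, w), dtype=codes.dtype))
        else:
            views.append(np.lib.stride_tricks.sliding_window_view(codes, w))
    return views


def _score_windows(logodds: np.ndarray, win: np.ndarray) -> np.ndarray:
    if win.shape[0] == 0:
        return np.empty(0)
    w = win.shape[1]
    safe = np.minimum(win, 19)  # X scored as if min-informative
    sc = logodds[np.arange(w)[None, :], safe]
    sc[win >= 20] = 0.0
    return sc.sum(axis=1)


def _batch_windows(windows: list[np.ndarray]):
    """Stack per-sequence window views when all have equal position count."""
    shapes = {w.shape[0] for w in windows}
    if len(shapes) == 1 and windows and windows[0].shape[0] > 0:
        return np.stack(windows)
    return None


def _estep(windows, batch, logodds: np.ndarray, gamma: float):
    """ZOOPS E-step: per-sequence site posteriors and expected LLR.

    Returns (z_list_or_batch, total_z, expected_llr).
    """
    lg_no = np.log(max(1.0 - gamma, 1e-12))
    if batch is not None:
        S, P, w = batch.shape
        safe = np.minimum(batch, 19)
        sc = logodds[np.arange(w)[None, None, :], safe]
        sc[batch >= 20] = 0.0
        llr = sc.sum(axis=2)                      # (S, P)
        lw = llr + np.log(gamma / P)
        m = np.maximum(lw.max(axis=1), lg_no)
        num = np.exp(lw - m[:, None])
        den = np.exp(lg_no - m) + num.sum(axis=1)
        z = num / den[:, None]
        return z, float(z.sum()), float((z * llr).sum())
    zs = []
    z_tot = 0.0
    exp_llr = 0.0
    for win in windows:
        npos = win.shape[0]
        if npos == 0:
            zs.append(np.empty(0))
            continue
        w = win.shape[1]
        safe = np.minimum(win, 19)
        sc = logodds[np.arange(w)[None, :], safe]
        sc[win >= 20] = 0.0
        llr = sc.sum(axis=1)
        lw = llr + np.log(gamma / npos)
        m = max(lw.max(), lg_no)
        num = np.exp(lw - m)
        den = np.exp(lg_no - m) + num.sum()
        z = num / den
        zs.append(z)
        z_tot += float(z.sum())
        exp_llr += float((z * llr).sum())
    return zs, z_tot, exp_llr


def _em_zoops(windows: list[np.ndarray], bg: np.ndarray, w: int,
              pwm0: np.ndarray, n_iter: int, gamma0: float = 0.5,
              batch=None) -> tuple[np.ndarray, float, float]:
    """Run EM; returns (pwm, gamma, expected LLR of the last E-step)."""
    pwm = pwm0.copy()
    gamma = gamma0
    lbg = np.log(bg)
    n_seqs = sum(1 for win in windows if win.shape[0] > 0)
    exp_llr = 0.0
    cols = np.arange(w)
    for _ in range(n_iter):
        logodds = np.log(pwm) - lbg[None, :]
        z, z_tot, exp_llr = _estep(windows, batch, logodds, gamma)
        counts = PSEUDO * 20 * np.tile(bg, (w, 1))
        if batch is not None:
            safe = np.minimum(batch, 19)
            np.add.at(counts, (cols[None, None, :], safe),
                      z[:, :, None] * (batch < 20))
        else:
            for win, zi in zip(windows, z):
                if win.shape[0] == 0:
                    continue
                safe = np.minimum(win, 19)
                np.add.at(counts, (cols[None, :], safe),
                          zi[:, None] * (win < 20))
        pwm = counts / counts.sum(axis=1, keepdims=True)
        if n_seqs:
            gamma = min(max(z_tot / n_seqs, 1e-6), 1.0 - 1e-6)
    return pwm, gamma, exp_llr


def _hard_sites(windows: list[np.ndarray], pwm: np.ndarray,
                bg: np.ndarray, gamma: float, batch=None
                ) -> list[tuple[int, int]]:
    """Pick at most one site per sequence (posterior > 0.5)."""
    logodds = np.log(pwm) - np.log(bg)[None, :]
    z, _, _ = _estep(windows, batch, logodds, gamma)
    sites = []
    if batch is not None:
        best = np.argmax(z, axis=1)
        for si in range(z.shape[0]):
            if z[si, best[si]] > 0.5:
                sites.append((si, int(best[si])))
        return sites
    for si, zi in enumerate(z):
        if len(zi) == 0:
            continue
        b = int(np.argmax(zi))
        if zi[b] > 0.5:
            sites.append((si, b))
    return sites


def _site_llr(codes_list: list[np.ndarray], sites: list[tuple[int, int]],
              w: int, bg: np.ndarray) -> tuple[float, np.ndarray]:
    """Maximum-likelihood LLR (nats) of the hard site set vs background."""
    if not sites:
        return 0.0, np.tile(bg, (w, 1))
    counts = np.zeros((w, 20))
    for si, p in sites:
        win = codes_list[si][p:p + w]
        for c in range(w):
            if win[c] < 20:
                counts[c, win[c]] += 1
    n = counts.sum(axis=1)
    freqs = (counts + 1e-9) / np.maximum(n, 1e-9)[:, None]
    llr = float((counts * (np.log(freqs) - np.log(bg)[None, :])).sum())
    pwm = (counts + PSEUDO * 20 * bg[None, :])
    pwm /= pwm.sum(axis=1, keepdims=True)
    return llr, pwm


def _shift_refine(codes_list: list[np.ndarray],
                  sites: list[tuple[int, int]], w: int, bg: np.ndarray,
                  max_shift: int = 3):
    """Slide the whole site set left/right to the LLR-optimal phase."""
    best_llr, best_pwm = _site_llr(codes_list, sites, w, bg)
    best_sites = sites
    for d in range(-max_shift, max_shift + 1):
        if d == 0:
            continue
        shifted = []
        for si, p in sites:
            q = p + d
            if 0 <= q <= len(codes_list[si]) - w:
                shifted.append((si, q))
        if len(shifted) < len(sites):
            continue
        llr, pwm = _site_llr(codes_list, shifted, w, bg)
        if llr > best_llr:
            best_llr, best_pwm, best_sites = llr, pwm, shifted
    return best_llr, best_pwm, best_sites


def _discover_one(codes_list: list[np.ndarray], bg: np.ndarray, w: int,
                  rng: np.random.Generator, n_starts: int, em_iters: int
                  ) -> tuple[float, np.ndarray, float, list[tuple[int, int]]]:
    """Best single motif of width w: (llr, pwm, gamma, sites)."""
    windows = _window_views(codes_list, w)
    batch = _batch_windows(windows)
    starts = []
    for si, win in enumerate(windows):
        for p in range(win.shape[0]):
            starts.append((si, p))
    if not starts:
        return 0.0, np.tile(bg, (w, 1)), 0.0, []
    if len(starts) > n_starts:
        idx = rng.choice(len(starts), size=n_starts, replace=False)
        starts = [starts[i] for i in sorted(idx)]
    # short-EM screening from every start, then refine the best few
    screened = []
    for si, p in starts:
        win = windows[si][p]
        pwm0 = np.tile(bg, (w, 1)) * 0.3
        for c in range(w):
            if win[c] < 20:
                pwm0[c, win[c]] += 0.7
        pwm0 /= pwm0.sum(axis=1, keepdims=True)
        pwm1, g1, ellr = _em_zoops(windows, bg, w, pwm0, n_iter=2,
                                   batch=batch)
        screened.append((ellr, si, p, pwm1, g1))
    screened.sort(key=lambda t: (-t[0], t[1], t[2]))
    best = (0.0, np.tile(bg, (w, 1)), 0.0, [])
    for ellr0, si, p, pwm1, g1 in screened[:3]:
        pwm, g, _ = _em_zoops(windows, bg, w, pwm1, n_iter=em_iters,
                              gamma0=g1, batch=batch)
        sites = _hard_sites(windows, pwm, bg, g, batch=batch)
        llr, pwm_ml, sites = _shift_refine(codes_list, sites, w, bg)
        if llr > best[0]:
            best = (llr, pwm_ml, g, sites)
    return best


def _default_width_grid(width_range: tuple[int, int]) -> list[int]:
    lo, hi = width_range
    grid = [w for w in (6, 8, 10, 12, 15, 21, 29, 41, 50) if lo <= w <= hi]
    if not grid or grid[0] != lo:
        grid = sorted(set(grid) | {lo})
    return grid


def discover_signatures(seqs: SequenceSet, max_motifs: int = 10,
                        max_evalue: float = 1e-15,
                        width_range: tuple[int, int] = (6, 50),
                        seed: int = 0, n_starts: int = 100,
                        em_iters: int = 30, n_null: int = 8,
                        width_grid: list[int] | None = None
                        ) -> list[Signature]:
    """Sequential ZOOPS-EM signature discovery with empirical E-values."""
    records = list(seqs)
    if len(records) < 2:
        raise ValueError("need at least 2 sequences")
    rng = np.random.default_rng(seed)
    codes_list = [encode_protein(r.residues) for r in records]
    ids = [r.id for r in records]
    bg = _background(codes_list)
    if width_grid is None:
        width_grid = _default_width_grid(width_range)
    n_widths = len(width_grid)

    # empirical null of the maximized LLR, per width, on shuffled input
    null_stats: dict[int, tuple[float, float]] = {}
    for w in width_grid:
        llrs = []
        for _ in range(n_null):
            shuf = []
            for codes in codes_list:
                c = codes.copy()
                rng.shuffle(c)
                shuf.append(c)
            llr, *_ = _discover_one(shuf, bg, w, rng, n_starts, em_iters)
            llrs.append(llr)
        mu = float(np.mean(llrs))
        sd = float(np.std(llrs, ddof=1)) if len(llrs) > 1 else 1.0
        null_stats[w] = (mu, max(sd, 1e-6))

    work = [c.copy() for c in codes_list]
    occupied: dict[int, list[tuple[int, int]]] = {}
    signatures: list[Signature] = []
    for k in range(max_motifs):
        best = None
        for w in width_grid:
            llr, pwm, gamma, sites = _discover_one(work, bg, w, rng,
                                                   n_starts, em_iters)
            mu, sd = null_stats[w]
            z = (llr - mu) / sd
            p = _gumbel_tail(llr, mu, sd)
            if best is None or p < best[0] or (p == best[0]
                                              and z > best[1]):
                best = (p, z, w, llr, pwm, sites)
        p, z, w, llr, pwm, sites = best
        evalue = p * n_widths
        # sites landing on previously erased ground are noise; drop them
        sites = [(si, pos) for si, pos in sites
                 if all(pos + w <= a or pos >= b
                        for a, b in occupied.get(si, []))]
        if evalue > max_evalue or len(sites) < 2:
            break
        sig = Signature(f"sig{k + 1}", w, pwm, evalue,
                        [(ids[si], pos) for si, pos in sites], llr, z)
        signatures.append(sig)
        # erase sites: replace with background-sampled residues
        for si, pos in sites:
            work[si][pos:pos + w] = rng.choice(20, size=w, p=bg)
            occupied.setdefault(si, []).append((pos, pos + w))
    return signatures


def _gumbel_tail(x: float, mu: float, sd: float) -> float:
    """Upper tail of a moment-fitted Gumbel null (max-statistic family)."""
    beta = max(sd * np.sqrt(6.0) / np.pi, 1e-9)
    loc = mu - 0.5772156649 * beta
    t = (x - loc) / beta
    if t > 30:
        return float(np.exp(-t))
    return float(-np.expm1(-np.exp(-t)))


# ---------------------------------------------------------------------------
# scanning

def _exact_pvalue_table(signature: Signature, bg: np.ndarray,
                        scale: float = 20.0) -> tuple[np.ndarray, int]:
    """P(window score >= s) under background, by column convolution."""
    logodds = np.log2(signature.pwm / bg[None, :])
    ints = np.round(logodds * scale).astype(int)
    offset = 0
    pmf = np.array([1.0])
    lo_total = 0
    for c in range(signature.width):
        col = ints[c]
        lo, hi = int(col.min()), int(col.max())
        col_pmf = np.zeros(hi - lo + 1)
        for a in range(20):
            col_pmf[col[a] - lo] += bg[a]
        pmf = np.convolve(pmf, col_pmf)
        lo_total += lo
    tail = np.cumsum(pmf[::-1])[::-1]
    return tail, lo_total


def _best_site_pvalue(signature: Signature, codes: np.ndarray,
                      bg: np.ndarray, table, scale: float = 20.0) -> float:
    w = signature.width
    if len(codes) < w:
        return 1.0
    tail, lo_total = table
    logodds = np.log2(signature.pwm / bg[None, :])
    win = np.lib.stride_tricks.sliding_window_view(codes, w)
    safe = np.minimum(win, 19)
    sc = logodds[np.arange(w)[None, :], safe]
    sc[win >= 20] = 0.0
    best = float(sc.sum(axis=1).max())
    idx = int(np.floor(best * scale)) - lo_total
    if idx < 0:
        idx = 0
    if idx >= len(tail):
        return 0.0
    return float(tail[idx])


@dataclass
class ScanResult:
    signature: str
    flagged: dict[str, bool]
    evalues: dict[str, float]

    def flagged_ids(self) -> set[str]:
        return {k for k, v in self.flagged.items() if v}


def scan(signature: Signature, seqs: SequenceSet,
         evalue_threshold: float = 1e-6,
         background: np.ndarray | None = None) -> ScanResult:
    """Flag sequences containing the signature.

    The best-site p-value is converted to a sequence E-value as
    p x scannable positions x number of sequences; a sequence shorter
    than the motif is never flagged.
    """
    records = list(seqs)
    bg = background
    if bg is None:
        bg = _background([encode_protein(r.residues) for r in records])
    table = _exact_pvalue_table(signature, bg)
    n_seqs = len(records)
    flagged = {}
    evalues = {}
    for rec in records:
        codes = encode_protein(rec.residues)
        npos = max(len(codes) - signature.width + 1, 0)
        if npos == 0:
            flagged[rec.id] = False
            evalues[rec.id] = np.inf
            continue
        p = _best_site_pvalue(signature, codes, bg, table)
        e = p * npos * n_seqs
        evalues[rec.id] = e
        flagged[rec.id] = e <= evalue_threshold
    return ScanResult(signature.name, flagged, evalues)


def occurrence_table(signatures_by_family: dict[str, list[Signature]],
                     members_by_family: dict[str, SequenceSet],
                     evalue_threshold: float = 1e-6):
    """Percentage of each family's members containing each signature.

    Rows are (source family, signature); columns are target families;
    cells are percentages rounded to one decimal.
    """
    import pandas as pd
    for fam, members in members_by_family.items():
        if len(members) == 0:
            raise ValueError(f"empty member set for family {fam!r}")
    rows = []
    index = []
    cols = sorted(members_by_family)
    for fam_a in sorted(signatures_by_family):
        for sig in signatures_by_family[fam_a]:
            cells = []
            for fam_b in cols:
                members = members_by_family[fam_b]
                res = scan(sig, members, evalue_threshold)
                pct = 100.0 * len(res.flagged_ids()) / len(members)
                cells.append(round(pct, 1))
            rows.append(cells)
            index.append(f"{fam_a}:{sig.name}")
    return pd.DataFrame(rows, index=index, columns=cols)


# ---------------------------------------------------------------------------
# conservation shading

SIMILARITY_GROUPS = [set("ILMV"), set("KR"), set("DE"), set("FYW"), set("ST")]


def _similar(a: str, b: str) -> bool:
    if a == b and a != "-":
        return True
    return any(a in g and b in g for g in SIMILARITY_GROUPS)


def conservation_shading(region: str, family_consensuses: list[str]
                         ) -> np.ndarray:
    """Count, per residue, how many family consensuses it matches.

    Matching means identity or shared membership in a conservative
    similarity group ({ILMV}, {KR}, {DE}, {FYW}, {ST}).
    """
    for cons in family_consensuses:
        if len(cons) != len(region):
            raise ValueError("aligned lengths differ")
    out = np.zeros(len(region), dtype=int)
    for i, res in enumerate(region):
        out[i] = sum(_similar(res.upper(), cons[i].upper())
                     for cons in family_consensuses)
    return out


# ---------------------------------------------------------------------------
# MEME minimal format

def write_meme(signatures: list[Signature], path,
               background: np.ndarray | None = None) -> None:
    bg = background if background is not None else np.full(20, 0.05)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + AA_ORDER + "\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{a} {f:.5f}"
                          for a, f in zip(AA_ORDER, bg)) + "\n\n")
        for sig in signatures:
            fh.write(f"MOTIF {sig.name}\n")
            fh.write(f"letter-probability matrix: alength= 20 w= {sig.width}"
                     f" nsites= {len(sig.sites)} E= {sig.evalue:.2e}\n")
            for row in sig.pwm:
                fh.write(" " + " ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")
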