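"""TIR-pair discovery and TSD-anchored element boundary selection.

``find_tir_pairs`` enumerates, for every admissible (element start, element
end) coordinate pair, the maximal terminal-inverted-repeat arm length under
a mismatch budget; ``select_element`` then ranks candidate pairs by their
flanking 4-mers (target-site duplications), arm length and mismatch count.

Arm maximality: an arm is extended inward while the cumulative mismatch
count stays within budget, and is reported at the largest length whose
final position is a match (trailing mismatches never lengthen an arm).
This keeps reported TIR lengths identifiable — one length per element —
and makes the output equal to a brute-force enumeration oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_DENSE_STEPS = 16  # dense scan depth before switching to the sparse survivors


@dataclass(frozen=True)
class TIRPair:
    """An inverted-repeat arm pair within a locus (local coordinates)."""

    left_start: int
    left_end: int
    right_start: int
    right_end: int
    arm_length: int
    mismatches: int

    @property
    def arm_identity(self) -> float:
        return 100.0 * (self.arm_length - self.mismatches) / self.arm_length


@dataclass(frozen=True)
class ElementBoundary:
    contig: str
    start: int  # outer TIR edges, 0-based half-open (genomic once lifted)
    end: int
    tir: TIRPair
    left_tsd: str
    right_tsd: str
    tsd_canonical: bool
    score: float
    strand: str = "."


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


def find_tir_pairs(
    locus_seq: str,
    min_len: int = 10,
    max_len: int = 500,
    max_mismatch: int = 2,
    search_window: int | None = None,
    mismatch_frac: float | None = None,
) -> list[TIRPair]:
    """All maximal TIR pairs whose arms start/end within the edge windows.

    A pair is (i, j, L): left arm ``locus[i:i+L]`` equals the reverse
    complement of the right arm ``locus[j-L:j]`` with at most the budgeted
    mismatches; ``i`` lies in the first ``search_window`` bp and ``j`` in
    the last ``search_window`` bp (default: 25% of the locus).  With
    ``mismatch_frac`` set, the budget at arm length L is
    ``max(max_mismatch, floor(mismatch_frac * L))`` (long-TIR mode).
    """
    n = len(locus_seq)
    if n < 2 * min_len:
        raise ValueError("locus shorter than twice the minimum arm length")
    w = search_window if search_window is not None else max(n // 4, min_len)
    w = min(w, n)
    code = _encode(locus_seq)
    comp = np.where(code == 255, np.uint8(200), (3 - code).astype(np.uint8))

    def budget(length: int) -> int:
        if mismatch_frac is None:
            return max_mismatch
        return max(max_mismatch, int(mismatch_frac * length))

    I = np.arange(0, w, dtype=np.int64)                # left arm starts
    J = np.arange(n - w, n, dtype=np.int64) + 1        # right arm ends (exclusive)
    A, B = len(I), len(J)

    mm = np.zeros((A, B), dtype=np.uint16)
    best_len = np.zeros((A, B), dtype=np.int32)
    best_mm = np.zeros((A, B), dtype=np.uint16)
    # geometry: arms must not overlap: j - i >= 2L  <=>  (J - I) >= 2(d+1)
    span = J[None, :] - I[:, None]

    max_d = min(max_len, n // 2)
    d = 0
    while d < max_d and d < _DENSE_STEPS:
        left = code[I + d]
        rj = J - 1 - d
        ok_idx = rj >= 0
        right = np.where(ok_idx, comp[np.clip(rj, 0, n - 1)], np.uint8(201))
        eq = left[:, None] == right[None, :]
        geom = span >= 2 * (d + 1)
        mm += (~eq) & geom  # count mismatches only while geometrically live
        live = geom & (mm <= budget(d + 1))
        upd = eq & live
        best_len[upd] = d + 1
        best_mm[upd] = mm[upd]
        d += 1

    if d < max_d:
        sel = np.argwhere((mm <= budget(max_d)) & (span >= 2 * (d + 1)))
        si = I[sel[:, 0]]
        sj = J[sel[:, 1]]
        smm = mm[sel[:, 0], sel[:, 1]].astype(np.int64)
        sb_len = best_len[sel[:, 0], sel[:, 1]]
        sb_mm = best_mm[sel[:, 0], sel[:, 1]].astype(np.int64)
        alive = np.ones(len(si), dtype=bool)
        while d < max_d and alive.any():
            geom = (sj - si) >= 2 * (d + 1)
            rj = sj - 1 - d
            eq = np.zeros(len(si), dtype=bool)
            okg = geom & (rj >= 0)
            eq[okg] = code[si[okg] + d] == comp[rj[okg]]
            smm[okg & ~eq] += 1
            live = okg & (smm <= budget(d + 1))
            upd = eq & live
            sb_len[upd] = d + 1
            sb_mm[upd] = smm[upd]
            alive = live | (smm <= budget(max_d))  # may recover under frac budgets
            if mismatch_frac is None:
                alive = live
            d += 1
        best_len[sel[:, 0], sel[:, 1]] = sb_len
        best_mm[sel[:, 0], sel[:, 1]] = sb_mm

    found = np.argwhere(best_len >= min_len)
    pairs = []
    for ai, bj in found:
        L = int(best_len[ai, bj])
        i = int(I[ai])
        j = int(J[bj])
        pairs.append(
            TIRPair(left_start=i, left_end=i + L, right_start=j - L,
                    right_end=j, arm_length=L, mismatches=int(best_mm[ai, bj]))
        )
    pairs.sort(key=lambda p: (p.left_start, p.right_end))
    return pairs


def select_element(
    pairs: list[TIRPair],
    locus_seq: str,
    tsd_motif: str = "TTAA",
    contig: str = "locus",
    offset: int = 0,
) -> ElementBoundary | None:
    """Pick the element boundary among candidate TIR pairs.

    Ranking: (1) both flanking 4-mers equal the canonical motif; (2) both
    flanking 4-mers equal each other (non-canonical TSD); then longer arm,
    fewer mismatches, leftmost start.  Pairs whose flanking 4-mers cannot
    be read (too close to the locus edge) are skipped.  Returns None when
    no pair has matching flanks.
    """
    n = len(locus_seq)
    best = None
    best_key = None
    for p in pairs:
        i, j = p.left_start, p.right_end
        if i < 4 or j + 4 > n:
            continue
        left = locus_seq[i - 4 : i].upper()
        right = locus_seq[j : j + 4].upper()
        canonical = left == tsd_motif and right == tsd_motif
        equal = left == right
        if not (canonical or equal):
            continue
        key = (0 if canonical else 1, -p.arm_length, p.mismatches, i)
        if best_key is None or key < best_key:
            best_key = key
            best = (p, left, right, canonical)
    if best is None:
        return None
    p, left, right, canonical = best
    return ElementBoundary(
        contig=contig,
        start=offset + p.left_start,
        end=offset + p.right_end,
        tir=p,
        left_tsd=left,
        right_tsd=right,
        tsd_canonical=canonical,
        score=float(p.arm_length - p.mismatches),
    )
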