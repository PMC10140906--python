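"""Copy-number census: seed-and-extend nucleotide search, strict
coverage/identity filtering, and star-alignment consensus building.

Identity counts matches over all alignment columns including gap columns
(the stricter convention); coverage is the fraction of query bases inside
the local alignment.  Census thresholds are strict inequalities:
coverage > 40 and identity > 80 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import Align

from .annotation import INTACT_MIN_AA, OrfRecord
from .boundaries import ElementBoundary
from .io import revcomp

DEFAULT_WORD = 11
MIN_COVERAGE = 40.0
MIN_IDENTITY = 80.0
CONSENSUS_TRIGGER = 10  # consensus built only when copy count exceeds this


@dataclass(frozen=True)
class CopyHit:
    contig: str
    start: int
    end: int
    strand: str
    percent_identity: float
    query_coverage: float
    score: float
    query_id: str


@dataclass(frozen=True)
class FamilyCensus:
    family_id: str
    total_hits: int
    counted_copies: int
    full_copies: int
    intact_copies: int
    representative: str
    consensus_used: bool


def make_nucleotide_aligner(mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    aligner.mode = mode
    return aligner


_NT_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _NT_CODE[_b] = _i


def _nt_hashes(seq: str, k: int) -> np.ndarray:
    """Base-4 hash per k-mer; windows containing non-ACGT hash to -1."""
    codes = _NT_CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    h = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for t in range(k):
        window = codes[t : t + n]
        h = (h << 2) | np.maximum(window, 0)
        bad |= window < 0
    h[bad] = -1
    return h


class GenomeIndex:
    """Sorted exact k-mer index over the forward strand of every contig."""

    def __init__(self, genome: Mapping[str, str], word: int = DEFAULT_WORD):
        self.word = word
        self.genome = genome
        self._per_contig: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for contig, seq in genome.items():
            h = _nt_hashes(seq, word)
            order = np.argsort(h, kind="stable")
            self._per_contig[contig] = (h[order], order)

    def lookup(self, kmer_hash: int, contig: str) -> np.ndarray:
        sorted_h, order = self._per_contig[contig]
        lo = np.searchsorted(sorted_h, kmer_hash, side="left")
        hi = np.searchsorted(sorted_h, kmer_hash, side="right")
        return order[lo:hi]

    def contigs(self):
        return self._per_contig.keys()


def search_copies(
    query: str,
    genome: Mapping[str, str] | GenomeIndex,
    word: int = DEFAULT_WORD,
    query_id: str = "query",
    min_score: float = 50.0,
    aligner: Align.PairwiseAligner | None = None,
) -> list[CopyHit]:
    """Seed-and-extend nucleotide local search for copies of ``query``.

    Both query orientations are searched against the forward-strand index.
    Hits overlapping a higher-scoring hit by more than 50% are suppressed
    (one copy, one count).
    """
    if len(query) < 100:
        raise ValueError("query must be >= 100 bp")
    gi = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome, word)
    if aligner is None:
        aligner = make_nucleotide_aligner()
    raw: list[CopyHit] = []
    for strand, q in (("+", query), ("-", revcomp(query))):
        q_hashes = _nt_hashes(q, gi.word)
        stride = 4 if len(q) >= 1000 else 1
        n_words = len(range(0, len(q_hashes), stride))
        # spurious clusters carry a handful of anchors; genuine copies at
        # <= 20% divergence retain > 8% of their exact words
        min_anchors = max(2, int(0.02 * n_words))
        # seed positions grouped by contig (diagonal anchors)
        seeds: dict[str, list[int]] = {}
        for contig in gi.contigs():
            anchors: list[int] = []
            for p in range(0, len(q_hashes), stride):
                hq = int(q_hashes[p])
                if hq < 0:
                    continue
                for gpos in gi.lookup(hq, contig):
                    anchors.append(int(gpos) - p)
            if anchors:
                seeds[contig] = anchors
        for contig, anchors in seeds.items():
            anchors.sort()
            clusters: list[list[int]] = [[anchors[0]]]
            for a in anchors[1:]:
                if a - clusters[-1][-1] <= len(q):
                    clusters[-1].append(a)
                else:
                    clusters.append([a])
            seq = gi.genome[contig]
            for cl in clusters:
                if len(cl) < min_anchors:
                    continue
                ws = max(0, cl[0] - 50)
                we = min(len(seq), cl[-1] + len(q) + 50)
                window = seq[ws:we]
                score = aligner.score(window, q)
                if score < min_score:
                    continue
                aln = aligner.align(window, q)[0]
                t0 = int(aln.coordinates[0][0])
                t1 = int(aln.coordinates[0][-1])
                q0 = int(aln.coordinates[1][0])
                q1 = int(aln.coordinates[1][-1])
                matches, columns = _alignment_identity(aln)
                hit = CopyHit(
                    contig=contig,
                    start=ws + t0,
                    end=ws + t1,
                    strand=strand,
                    percent_identity=100.0 * matches / columns if columns else 0.0,
                    query_coverage=100.0 * (q1 - q0) / len(query),
                    score=float(score),
                    query_id=query_id,
                )
                raw.append(hit)
    return _suppress_overlaps(raw)


def _alignment_identity(aln) -> tuple[int, int]:
    a, b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches, len(a)


def _suppress_overlaps(hits: list[CopyHit]) -> list[CopyHit]:
    kept: list[CopyHit] = []
    for h in sorted(hits, key=lambda h: -h.score):
        ok = True
        for k in kept:
            if k.contig != h.contig:
                continue
            ov = min(k.end, h.end) - max(k.start, h.start)
            if ov > 0 and ov > 0.5 * (h.end - h.start):
                ok = False
                break
        if ok:
            kept.append(h)
    kept.sort(key=lambda h: (h.contig, h.start))
    return kept


def census(
    hits: Sequence[CopyHit],
    boundaries: Sequence[Optional[ElementBoundary]],
    orfs: Sequence[Optional[OrfRecord]],
    min_cov: float = MIN_COVERAGE,
    min_ident: float = MIN_IDENTITY,
    family_id: str = "family",
    representative: str = "",
    consensus_used: bool = False,
) -> FamilyCensus:
    """Count copies at strict thresholds and tabulate full/intact copies.

    A hit is counted iff coverage > ``min_cov`` AND identity > ``min_ident``
    (strict).  Counted hits with a resolved TIR/TSD boundary are *full*;
    full hits whose ORF reaches 500 aa are *intact*.
    """
    if not (len(hits) == len(boundaries) == len(orfs)):
        raise ValueError("hits, boundaries and orfs must be parallel")
    counted = full = intact = 0
    for h, b, o in zip(hits, boundaries, orfs):
        if not (h.query_coverage > min_cov and h.percent_identity > min_ident):
            continue
        counted += 1
        if b is not None:
            full += 1
            if o is not None and o.length >= INTACT_MIN_AA:
                intact += 1
    return FamilyCensus(
        family_id=family_id, total_hits=len(hits), counted_copies=counted,
        full_copies=full, intact_copies=intact,
        representative=representative, consensus_used=consensus_used,
    )


def build_consensus(copies: Sequence[str], representative: str,
                    aligner: Align.PairwiseAligner | None = None) -> str:
    """Majority consensus over a star alignment of copies to the representative.

    Each copy is globally aligned to the representative; per representative
    column the majority base wins (ties break to the representative's
    base); columns where gaps hold the majority are dropped.  Insertions
    relative to the representative are ignored.
    """
    if len(copies) < 2:
        raise ValueError("need at least 2 copies for a consensus")
    if aligner is None:
        aligner = make_nucleotide_aligner(mode="global")
    m = len(representative)
    counts = np.zeros((m, 5), dtype=np.int64)  # A C G T gap
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for copy in copies:
        aln = aligner.align(representative, copy)[0]
        a, b = str(aln[0]), str(aln[1])
        rp = 0
        for x, y in zip(a, b):
            if x == "-":
                continue  # insertion in copy: skipped
            counts[rp, base_idx.get(y, 4)] += 1
            rp += 1
    out = []
    for rp in range(m):
        row = counts[rp]
        if row[4] > row[:4].sum():
            continue  # gap-majority column dropped
        best = int(np.argmax(row[:4]))
        rep_base = representative[rp]
        if rep_base in base_idx and row[base_idx[rep_base]] == row[best]:
            out.append(rep_base)  # tie (or equal count) goes to representative
        else:
            out.append("ACGT"[best])
    return "".join(out)
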