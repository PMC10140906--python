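"""Transposase ORF prediction, diagnostic-domain scanning and element
classification (intact / full / truncated).

The transposase is single-ORF by element architecture, so gene prediction
reduces to a longest-ORF search over both strands.  Catalytic-triad and
CRD positions are located by global alignment to the bundled clade
consensus rather than by fixed indices, so residue losses (D->N, D->H)
are reported verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .boundaries import ElementBoundary
from .io import revcomp, translate
from .references import CladeProfile
from .seeding import make_protein_aligner

ORF_FLOOR_AA = 100  # minimum transposase length considered at all
INTACT_MIN_AA = 500  # intact elements must encode >= this many residues
STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfRecord:
    """Longest ORF of an element, in element-forward coordinates."""

    start: int
    end: int  # includes the stop codon
    strand: str
    protein: str

    @property
    def length(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class DomainScan:
    triad_positions: Optional[tuple[int, int, int]]
    triad_residues: Optional[tuple[str, str, str]]
    triad_intact: bool
    insertion_span: Optional[tuple[int, int]]
    crd_cysteine_positions: tuple[int, ...]
    crd_regular: bool
    notes: str = ""


@dataclass(frozen=True)
class ElementClass:
    label: str  # intact | full | truncated
    tir_tsd_detectable: bool
    transposase_aa: int


def find_longest_orf(element_seq: str, min_aa: int = ORF_FLOOR_AA) -> OrfRecord | None:
    """Longest ATG-initiated, stop-terminated ORF on either strand.

    Ties prefer the forward strand, then the 5'-most start on that strand.
    Coordinates are element-forward 0-based half-open, stop codon included.
    Returns None when no ORF reaches ``min_aa`` residues.
    """
    if len(element_seq) < 300:
        return None
    seq = element_seq.upper()
    n = len(seq)
    best: OrfRecord | None = None
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for off in range(3):
            start = None
            for p in range(off, n - 2, 3):
                codon = s[p : p + 3]
                if codon in STOPS:
                    if start is not None:
                        aa = (p - start) // 3
                        if aa >= min_aa:
                            a, b = start, p + 3
                            if strand == "-":
                                a, b = n - (p + 3), n - start
                            cand = OrfRecord(
                                start=a, end=b, strand=strand,
                                protein=translate(s[start:p]),
                            )
                            if _better(cand, best):
                                best = cand
                        start = None
                elif codon == "ATG" and start is None:
                    start = p
    return best


def _better(cand: OrfRecord, best: OrfRecord | None) -> bool:
    if best is None:
        return True
    if cand.length != best.length:
        return cand.length > best.length
    if cand.strand != best.strand:
        return cand.strand == "+"
    return cand.start < best.start


def scan_domains(protein: str, profile: CladeProfile,
                 score_floor: float | None = None) -> DomainScan:
    """Map the clade consensus' diagnostic positions onto ``protein``.

    The protein is globally aligned to the consensus; the three catalytic
    positions and the insertion-motif span are projected through the
    alignment, and the C-terminal 60 aa are scanned for >= 7 cysteines
    whose consecutive spacings sit within +/-2 of the consensus spacing.
    """
    if len(protein) < 100:
        raise ValueError("protein shorter than 100 aa")
    aligner = make_protein_aligner(mode="global")
    score = aligner.score(protein, profile.consensus)
    if score_floor is None:
        score_floor = 0.3 * len(profile.consensus)
    if score < score_floor:
        return DomainScan(
            triad_positions=None, triad_residues=None, triad_intact=False,
            insertion_span=None,
            crd_cysteine_positions=_cterm_cys(protein),
            crd_regular=_crd_regular(protein, profile),
            notes="alignment score below floor; triad unmapped",
        )
    aln = aligner.align(protein, profile.consensus)[0]
    cons_to_prot = _column_map(aln)

    mapped = [cons_to_prot.get(p) for p in profile.triad]
    if any(m is None for m in mapped):
        return DomainScan(
            triad_positions=None, triad_residues=None, triad_intact=False,
            insertion_span=_map_span(cons_to_prot, profile.insertion),
            crd_cysteine_positions=_cterm_cys(protein),
            crd_regular=_crd_regular(protein, profile),
            notes="catalytic position deleted in query",
        )
    positions = tuple(mapped)  # type: ignore[arg-type]
    residues = tuple(protein[p] for p in positions)
    return DomainScan(
        triad_positions=positions,
        triad_residues=residues,
        triad_intact=residues == ("D", "D", "D"),
        insertion_span=_map_span(cons_to_prot, profile.insertion),
        crd_cysteine_positions=_cterm_cys(protein),
        crd_regular=_crd_regular(protein, profile),
    )


def _column_map(aln) -> dict[int, int]:
    """consensus position -> protein position over aligned (non-gap) columns."""
    mapping: dict[int, int] = {}
    # aligned blocks: ((t_start, t_end), (q_start, q_end)) pairs
    for (ts, te), (qs, qe) in zip(*aln.aligned):
        for k in range(te - ts):
            mapping[qs + k] = ts + k
    return mapping


def _map_span(cons_to_prot: dict[int, int], span: tuple[int, int]):
    pts = [cons_to_prot[p] for p in range(span[0], span[1]) if p in cons_to_prot]
    if not pts:
        return None
    return (min(pts), max(pts) + 1)


def _cterm_cys(protein: str, window: int = 60) -> tuple[int, ...]:
    tail_start = max(0, len(protein) - window)
    return tuple(i for i in range(tail_start, len(protein)) if protein[i] == "C")


def _crd_regular(protein: str, profile: CladeProfile, tol: int = 2) -> bool:
    cys = _cterm_cys(protein)
    if len(cys) < 7:
        return False
    ref_spacing = profile.crd_spacing
    # slide over cysteine subsets of the consensus count
    k = len(ref_spacing) + 1
    for s in range(len(cys) - k + 1):
        spacing = tuple(b - a for a, b in zip(cys[s : s + k], cys[s + 1 : s + k]))
        if all(abs(a - b) <= tol for a, b in zip(spacing, ref_spacing)):
            return True
    return False


def classify_element(boundary: ElementBoundary | None,
                     orf: OrfRecord | None) -> ElementClass:
    """intact: detectable TIR+TSD and >= 500 aa ORF; full: detectable
    TIR+TSD; truncated: otherwise."""
    detectable = boundary is not None
    aa = orf.length if orf is not None else 0
    if detectable and aa >= INTACT_MIN_AA:
        label = "intact"
    elif detectable:
        label = "full"
    else:
        label = "truncated"
    return ElementClass(label=label, tir_tsd_detectable=detectable,
                        transposase_aa=aa)
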