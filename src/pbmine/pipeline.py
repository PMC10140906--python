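"""End-to-end orchestration: seeding -> boundaries -> annotation -> census
-> divergence -> comparative, plus truth-table evaluation and report
writing.

Coordinates are 0-based half-open everywhere in memory and in BED output;
the human-readable element table converts to 1-based closed coordinates at
write time (flagged in its header comment).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import annotation, boundaries, census, comparative, divergence, seeding
from .io import revcomp, write_bed6, write_fasta
from .references import ProteinReference, load_clade_profiles, load_references


@dataclass(frozen=True)
class RunConfig:
    """Every stage threshold, with the published defaults."""

    flank: int = 2000
    seed_min_score: float = 100.0
    seed_word_size: int = 5
    tir_min_len: int = 10
    tir_max_len: int = 500
    tir_max_mismatch: int = 2
    tir_mismatch_frac: Optional[float] = None
    tsd_motif: str = "TTAA"
    intact_min_aa: int = 500
    census_min_cov: float = 40.0
    census_min_ident: float = 80.0
    consensus_trigger: int = 10
    bin_width: float = 1.0
    recent_k: float = 2.0
    old_k: float = 15.0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass
class DetectedElement:
    element_id: str
    contig: str
    start: int
    end: int
    strand: str
    clade: str
    boundary: boundaries.ElementBoundary
    sequence: str
    orf: Optional[annotation.OrfRecord]
    scan: Optional[annotation.DomainScan]
    element_class: annotation.ElementClass

    @property
    def protein(self) -> Optional[str]:
        return self.orf.protein if self.orf else None


@dataclass
class FamilyResult:
    family_id: str
    clade: str
    elements: list[DetectedElement]
    census: census.FamilyCensus
    hits: list[census.CopyHit]
    landscape: Optional[divergence.DivergenceLandscape]
    age: Optional[divergence.AgeCall]
    consensus_seq: Optional[str]


@dataclass
class PipelineResult:
    config: RunConfig
    genome_bp: int
    seed_hits: list[seeding.SeedHit]
    loci: list[seeding.CandidateLocus]
    elements: list[DetectedElement]
    families: dict[str, FamilyResult]
    tree: Optional[comparative.PhyloTree]
    clade_assignments: dict[str, str]
    logo: Optional[comparative.TirLogo]
    identity: Optional[comparative.IdentityMatrix]
    timings: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class EvaluationReport:
    precision: float
    recall: float
    boundary_exact_fraction: float
    matched: int
    missed: int
    spurious: int
    statuses: dict[str, str]  # truth element_id -> exact|overlap|missed


def run_pipeline(
    genome: Mapping[str, str],
    config: RunConfig = RunConfig(),
    refs: Sequence[ProteinReference] | None = None,
) -> PipelineResult:
    """Run every stage on an in-memory genome. Deterministic given config."""
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    if refs is None:
        refs = load_references()
    search_refs = [r for r in refs if r.role != "outgroup"]
    profiles = load_clade_profiles(refs)
    clade_of_ref = {r.id: r.clade for r in refs}
    genome_bp = sum(len(s) for s in genome.values())
    contig_lengths = {c: len(s) for c, s in genome.items()}

    hits = seeding.protein_search(
        genome, search_refs, min_score=config.seed_min_score,
        word_size=config.seed_word_size,
    )
    timings["seeding"] = time.perf_counter() - t0

    loci = seeding.build_loci(hits, contig_lengths, flank=config.flank)

    t1 = time.perf_counter()
    elements: list[DetectedElement] = []
    window = config.flank + 100
    for li, locus in enumerate(loci):
        locus_seq = genome[locus.contig][locus.start : locus.end]
        pairs = boundaries.find_tir_pairs(
            locus_seq,
            min_len=config.tir_min_len,
            max_len=config.tir_max_len,
            max_mismatch=config.tir_max_mismatch,
            search_window=min(window, len(locus_seq)),
            mismatch_frac=config.tir_mismatch_frac,
        )
        boundary = boundaries.select_element(
            pairs, locus_seq, tsd_motif=config.tsd_motif,
            contig=locus.contig, offset=locus.start,
        )
        if boundary is None:
            continue
        seq = genome[locus.contig][boundary.start : boundary.end]
        orf = annotation.find_longest_orf(seq)
        clade = clade_of_ref.get(locus.best_reference_id, "A")
        if clade not in profiles:
            clade = next(iter(profiles))
        scan = None
        if orf is not None:
            scan = annotation.scan_domains(orf.protein, profiles[clade])
        cls = annotation.classify_element(boundary, orf)
        strand = orf.strand if orf is not None else "."
        elements.append(
            DetectedElement(
                element_id=f"elem{li + 1:04d}", contig=locus.contig,
                start=boundary.start, end=boundary.end, strand=strand,
                clade=clade, boundary=boundary, sequence=seq, orf=orf,
                scan=scan, element_class=cls,
            )
        )
    timings["boundaries"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    families = _census_families(genome, elements, config, genome_bp)
    timings["census"] = time.perf_counter() - t2

    t3 = time.perf_counter()
    tree, assignments, logo, ident = _comparative_stage(elements, refs)
    timings["comparative"] = time.perf_counter() - t3

    return PipelineResult(
        config=config, genome_bp=genome_bp, seed_hits=hits, loci=loci,
        elements=elements, families=families, tree=tree,
        clade_assignments=assignments, logo=logo, identity=ident,
        timings=timings,
    )


def _census_families(genome, elements, config, genome_bp):
    families: dict[str, FamilyResult] = {}
    if not elements:
        return families
    index = census.GenomeIndex(genome)
    by_clade: dict[str, list[DetectedElement]] = {}
    for e in elements:
        by_clade.setdefault(e.clade, []).append(e)
    for clade, members in sorted(by_clade.items()):
        family_id = f"fam{clade}"
        rep_elem = max(
            members,
            key=lambda e: (e.element_class.label == "intact", len(e.sequence)),
        )
        representative = rep_elem.sequence
        hits = census.search_copies(representative, index,
                                    query_id=family_id)
        consensus_seq = None
        consensus_used = False
        counted = [
            h for h in hits
            if h.query_coverage > config.census_min_cov
            and h.percent_identity > config.census_min_ident
        ]
        if len(counted) > config.consensus_trigger:
            copies = [_hit_seq(genome, h) for h in counted]
            consensus_seq = census.build_consensus(copies, representative)
            consensus_used = True
            hits = census.search_copies(consensus_seq, index,
                                        query_id=family_id)
            counted = [
                h for h in hits
                if h.query_coverage > config.census_min_cov
                and h.percent_identity > config.census_min_ident
            ]
        bnds, orfs = _match_hits_to_elements(hits, members)
        fam_census = census.census(
            hits, bnds, orfs,
            min_cov=config.census_min_cov, min_ident=config.census_min_ident,
            family_id=family_id,
            representative=consensus_seq or representative,
            consensus_used=consensus_used,
        )
        reference = consensus_seq or representative
        land = age = None
        if counted:
            try:
                land = divergence.landscape(
                    [_hit_seq(genome, h) for h in counted], reference,
                    genome_bp=genome_bp, bin_width=config.bin_width,
                    family_id=family_id,
                )
                age = divergence.call_age(land, recent_k=config.recent_k,
                                          old_k=config.old_k)
            except (divergence.SaturationError, ValueError):
                pass
        families[family_id] = FamilyResult(
            family_id=family_id, clade=clade, elements=members,
            census=fam_census, hits=hits, landscape=land, age=age,
            consensus_seq=consensus_seq,
        )
    return families


def _hit_seq(genome, hit: census.CopyHit) -> str:
    seq = genome[hit.contig][hit.start : hit.end]
    return revcomp(seq) if hit.strand == "-" else seq


def _match_hits_to_elements(hits, members):
    bnds: list[Optional[boundaries.ElementBoundary]] = []
    orfs: list[Optional[annotation.OrfRecord]] = []
    for h in hits:
        match = None
        for e in members:
            if e.contig != h.contig:
                continue
            ov = min(e.end, h.end) - max(e.start, h.start)
            if ov > 0 and ov > 0.5 * (h.end - h.start) and ov > 0.5 * (e.end - e.start):
                match = e
                break
        bnds.append(match.boundary if match else None)
        orfs.append(match.orf if match else None)
    return bnds, orfs


def _comparative_stage(elements, refs):
    proteins = [
        (e.element_id, e.clade, e.orf.protein)
        for e in elements
        if e.orf is not None and e.orf.length >= annotation.ORF_FLOOR_AA
    ]
    ref_entries = [(r.id, r.clade, r.sequence) for r in refs]
    labels = [p[0] for p in proteins] + [r[0] for r in ref_entries]
    clades = [p[1] for p in proteins] + [r[1] for r in ref_entries]
    seqs = [p[2] for p in proteins] + [r[2] for r in ref_entries]

    tree = assignments = ident = None
    if len(seqs) >= 3:
        ident = comparative.identity_matrix(seqs, labels, clades)
        dmat = (100.0 - ident.matrix) / 100.0
        np.fill_diagonal(dmat, 0.0)
        tree = comparative.nj_tree(dmat, labels)
        ref_labels = {r.id: r.clade for r in refs if r.role != "outgroup"}
        outgroup = [r.id for r in refs if r.role == "outgroup"]
        assignments = comparative.assign_clades(tree, ref_labels, outgroup)

    tirs = []
    for e in elements:
        t = e.boundary.tir
        loc = e.sequence
        tirs.append(loc[: t.arm_length])
        tirs.append(revcomp(loc[len(loc) - t.arm_length :]))
    logo = comparative.tir_logo(tirs) if len(tirs) >= 2 else None
    return tree, (assignments or {}), logo, ident


# ---------------------------------------------------------------------------
# evaluation against a truth table


def evaluate(
    predictions: Sequence[tuple[str, int, int]],
    truth: Sequence,
    overlap_frac: float = 0.5,
) -> EvaluationReport:
    """Score predicted element intervals against truth records.

    A prediction matches a truth record when the reciprocal overlap is at
    least ``overlap_frac`` of both intervals; a match is boundary-exact
    when coordinates are equal.  Each truth record and prediction is used
    at most once (greedy, largest overlap first).
    """
    ids = [r.element_id for r in truth]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate truth element ids")
    cands = []
    for pi, (contig, ps, pe) in enumerate(predictions):
        for ti, r in enumerate(truth):
            if r.contig != contig:
                continue
            ov = min(pe, r.end) - max(ps, r.start)
            if ov <= 0:
                continue
            if ov >= overlap_frac * (pe - ps) and ov >= overlap_frac * (r.end - r.start):
                cands.append((ov, pi, ti))
    cands.sort(reverse=True)
    used_p: set[int] = set()
    used_t: set[int] = set()
    statuses = {r.element_id: "missed" for r in truth}
    exact = 0
    for ov, pi, ti in cands:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        r = truth[ti]
        contig, ps, pe = predictions[pi]
        if ps == r.start and pe == r.end:
            statuses[r.element_id] = "exact"
            exact += 1
        else:
            statuses[r.element_id] = "overlap"
    matched = len(used_t)
    n_pred = len(predictions)
    n_truth = len(truth)
    return EvaluationReport(
        precision=len(used_p) / n_pred if n_pred else 1.0,
        recall=matched / n_truth if n_truth else 1.0,
        boundary_exact_fraction=exact / matched if matched else 0.0,
        matched=matched,
        missed=n_truth - matched,
        spurious=n_pred - len(used_p),
        statuses=statuses,
    )


# ---------------------------------------------------------------------------
# report writing


def write_reports(result: PipelineResult, outdir: str | Path) -> None:
    """Write every stage artifact (BED/TSV/FASTA/Newick/JSON) to a run dir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    write_bed6(
        ((h.contig, h.start, h.end, f"{h.reference_id}", h.score, h.strand)
         for h in result.seed_hits),
        out / "seed_hits.bed",
    )
    write_bed6(
        ((l.contig, l.start, l.end, l.best_reference_id, l.best_score, ".")
         for l in result.loci),
        out / "loci.bed",
    )
    write_bed6(
        ((e.contig, e.start, e.end, e.element_id, e.boundary.score, e.strand)
         for e in result.elements),
        out / "elements.bed",
    )

    rows = []
    for e in result.elements:
        t = e.boundary.tir
        rows.append({
            "element_id": e.element_id, "contig": e.contig,
            "start_1based": e.start + 1, "end_1based": e.end,
            "strand": e.strand, "clade": e.clade,
            "length_bp": e.end - e.start,
            "tir_length": t.arm_length, "tir_mismatches": t.mismatches,
            "tir_identity": round(t.arm_identity, 2),
            "left_tsd": e.boundary.left_tsd, "right_tsd": e.boundary.right_tsd,
            "tsd_canonical": e.boundary.tsd_canonical,
            "transposase_aa": e.element_class.transposase_aa,
            "class": e.element_class.label,
            "triad_intact": e.scan.triad_intact if e.scan else False,
            "triad_residues": "".join(e.scan.triad_residues)
            if e.scan and e.scan.triad_residues else ".",
            "crd_regular": e.scan.crd_regular if e.scan else False,
        })
    with open(out / "elements.tsv", "w") as fh:
        fh.write("# coordinates are 1-based closed; BED files are 0-based half-open\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)

    write_fasta(
        ((e.element_id, e.orf.protein) for e in result.elements if e.orf),
        out / "proteins.faa",
    )

    fam_rows = []
    cons_records = []
    land_rows = []
    for fid, fam in result.families.items():
        c = fam.census
        fam_rows.append({
            "family_id": fid, "clade": fam.clade,
            "total_hits": c.total_hits, "counted_copies": c.counted_copies,
            "full_copies": c.full_copies, "intact_copies": c.intact_copies,
            "consensus_used": c.consensus_used,
            "age": fam.age.label if fam.age else ".",
            "multi_wave": fam.age.multi_wave if fam.age else False,
            "wave_modes": ",".join(f"{m:g}" for m in fam.age.wave_modes)
            if fam.age else "",
        })
        cons_records.append((fid, c.representative))
        if fam.landscape:
            for start, cov in fam.landscape.bins:
                land_rows.append({"family_id": fid, "k_bin_start": start,
                                  "coverage_percent": cov})
    pd.DataFrame(fam_rows).to_csv(out / "census.tsv", sep="\t", index=False)
    pd.DataFrame(land_rows).to_csv(out / "landscape.tsv", sep="\t", index=False)
    write_fasta(cons_records, out / "family_queries.fna")

    if result.tree:
        (out / "tree.nwk").write_text(result.tree.newick + "\n")
    if result.clade_assignments:
        pd.DataFrame(
            [{"leaf": k, "clade": v} for k, v in result.clade_assignments.items()]
        ).to_csv(out / "clades.tsv", sep="\t", index=False)
    if result.logo:
        df = pd.DataFrame(result.logo.frequencies, columns=list("ACGT"))
        df["information_bits"] = result.logo.information_content
        df.to_csv(out / "tir_logo.tsv", sep="\t", index_label="position")
    if result.identity is not None:
        pd.DataFrame(result.identity.matrix, index=result.identity.labels,
                     columns=result.identity.labels).to_csv(
            out / "identity_full.tsv", sep="\t")

    report = {
        "config": json.loads(result.config.to_json()),
        "config_hash": result.config.config_hash,
        "genome_bp": result.genome_bp,
        "counts": {
            "seed_hits": len(result.seed_hits),
            "loci": len(result.loci),
            "elements": len(result.elements),
            "families": len(result.families),
        },
        "timings_sec": {k: round(v, 3) for k, v in result.timings.items()},
    }
    (out / "run.json").write_text(json.dumps(report, indent=1) + "\n")
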