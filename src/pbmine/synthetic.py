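"""Synthetic genomes with planted TTAA-specific DNA transposons.

Elements are planted with a known layout — terminal inverted repeats (TIRs),
a 4-bp target-site duplication on both flanks, and a single central ORF
reverse-translated from a bundled clade consensus transposase — at
configurable copy numbers, divergence waves (Kimura 2-parameter model) and
truncation rates.  A machine-readable truth table accompanies every genome
so downstream detection stages can be scored exactly.

Design notes
------------
* Background sequence is i.i.d. at the requested GC content.
* Master-copy TIRs are perfect reverse complements; the three interior
  bases adjacent to each TIR are set to ``AAA`` so the inverted repeat
  cannot extend inward by chance (keeps planted TIR length identifiable).
* An in-frame stop is placed immediately 5' of the transposase ATG so the
  planted ORF length equals the requested transposase length exactly.
* Divergence is substitution-only (no indels): copies are mutated so the
  *expected* Kimura 2-parameter distance to the master equals ``target_K``.
* Truncation removes a uniform-random 20–80% prefix or suffix, always
  destroying at least one TIR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io import revcomp
from .references import load_clade_profiles

TIR_MOTIF = "CACTA"  # conserved terminal motif used for planted TIRs

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

# standard-code codon choices per amino acid (first entry = preferred)
CODONS: dict[str, list[str]] = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}


class SaturationError(ValueError):
    """Requested divergence is beyond what the K2P machinery supports."""


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of one planted element family."""

    clade_label: str = "A"
    element_length: int = 2476
    tir_length: int = 14
    tsd: str = "TTAA"
    transposase_length: int = 580
    copy_count: int = 1
    divergence_waves: tuple[tuple[float, float], ...] = ((0.0, 1.0),)
    truncation_prob: float = 0.0
    ts_tv_ratio: float = 2.0
    tir_mismatches: int = 0  # mismatches planted into the right arm
    allow_unusual_length: bool = False
    family_id: str = ""

    def __post_init__(self) -> None:
        if self.clade_label not in ("A", "B", "C"):
            raise ValueError("clade_label must be one of A, B, C")
        if not self.allow_unusual_length and not 1300 <= self.element_length <= 3600:
            raise ValueError(
                "element_length outside the default 1.3-3.6 kb range "
                "(set allow_unusual_length=True to override)"
            )
        if self.tir_length < 5:
            raise ValueError("tir_length must be >= 5")
        if len(self.tsd) != 4:
            raise ValueError("tsd must be a 4-mer")
        if not 0.0 <= self.truncation_prob <= 1.0:
            raise ValueError("truncation_prob must be in [0, 1]")
        total = sum(f for _, f in self.divergence_waves)
        if abs(total - 1.0) > 1e-6:
            raise ValueError("divergence wave fractions must sum to 1")
        if self.copy_count < 1:
            raise ValueError("copy_count must be >= 1")
        if not self.family_id:
            object.__setattr__(self, "family_id", f"fam{self.clade_label}")


@dataclass(frozen=True)
class GeneratorConfig:
    genome_length: int = 1_000_000
    gc_content: float = 0.38
    contig_count: int = 1
    families: tuple[FamilySpec, ...] = (FamilySpec(),)
    seed: int = 0
    min_spacing: int = 6000  # bp kept between planted copies

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10 kb")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be in (0, 1)")
        if self.contig_count < 1:
            raise ValueError("contig_count must be >= 1")
        object.__setattr__(self, "families", tuple(self.families))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted copy (0-based half-open coordinates)."""

    element_id: str
    contig: str
    start: int
    end: int
    strand: str
    clade_label: str
    family_id: str
    tir_length: int
    tsd: str
    target_K: float
    truncated: bool
    transposase_length: int


@dataclass
class SyntheticGenome:
    contigs: dict[str, str]
    truth: list[TruthRecord]
    config: GeneratorConfig
    masters: dict[str, str]  # family_id -> master element sequence

    @property
    def genome_bp(self) -> int:
        return sum(len(s) for s in self.contigs.values())


# ---------------------------------------------------------------------------
# K2P forward model


def k2p_expected_pq(target_K: float, ts_tv_ratio: float) -> tuple[float, float]:
    """Expected observed transition/transversion fractions (P, Q) for a
    K2P process run to ``target_K`` percent expected distance.

    ``ts_tv_ratio`` is the rate ratio alpha/beta (transition rate over the
    per-type transversion rate).  Plugging the returned (P, Q) into the K2P
    estimator recovers ``target_K`` exactly.
    """
    if target_K < 0:
        raise ValueError("target_K must be >= 0")
    if target_K > 90:
        raise SaturationError(
            f"target_K={target_K} is beyond the supported K2P range (<= 90%)"
        )
    d = target_K / 100.0
    kappa = ts_tv_ratio
    if math.isinf(kappa):
        bt, at = 0.0, d
    else:
        if kappa < 0:
            raise ValueError("ts_tv_ratio must be >= 0")
        bt = d / (kappa + 2.0)
        at = kappa * bt
    P = 0.25 + 0.25 * math.exp(-4.0 * bt) - 0.5 * math.exp(-2.0 * (at + bt))
    Q = 0.5 - 0.5 * math.exp(-4.0 * bt)
    return P, Q


def mutate_copy(seq: str, target_K: float, ts_tv_ratio: float = 2.0,
                seed: int | np.random.Generator = 0) -> str:
    """Substitute bases so the expected K2P distance to ``seq`` is ``target_K``.

    Substitution-only (alignment-free divergence); non-ACGT characters are
    left untouched and transversions pick either alternative base equally.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    P, Q = k2p_expected_pq(target_K, ts_tv_ratio)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    valid = codes != 255
    u = rng.random(len(seq))
    tv_pick = rng.integers(0, 2, len(seq))  # drawn unconditionally: fixed stream
    out = codes.copy()
    ts = (u < P) & valid
    tv = (u >= P) & (u < P + Q) & valid
    out[ts] = (codes[ts] + 2) % 4
    out[tv] = (codes[tv] + np.where(tv_pick[tv] == 0, 1, 3)) % 4
    res = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    res[valid] = _BASES[out[valid]]
    return res.tobytes().decode()


# ---------------------------------------------------------------------------
# element construction


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate with uniform synonymous codon choice."""
    parts = []
    for aa in protein:
        opts = CODONS[aa]
        parts.append(opts[rng.integers(0, len(opts))])
    return "".join(parts)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)].tobytes().decode()


def _clade_protein(clade: str, length: int, rng: np.random.Generator) -> str:
    cons = load_clade_profiles()[clade].consensus
    if length <= len(cons):
        return cons[:length]
    aa = "ACDEFGHIKLMNPQRSTVWY"
    extra = "".join(aa[rng.integers(0, len(aa))] for _ in range(length - len(cons)))
    return cons + extra


def build_master_element(spec: FamilySpec, rng: np.random.Generator,
                         gc: float = 0.38) -> tuple[str, str]:
    """Build the undiverged master element for a family.

    Returns (element_sequence, transposase_protein).  Layout:
    ``TIR | AAA …pad… TAA | ATG cds TAA | …pad… AAA | revcomp(TIR)``.
    """
    tir = spec.tir_length
    protein = _clade_protein(spec.clade_label, spec.transposase_length, rng)
    cds = "ATG" + reverse_translate(protein[1:], rng) + "TAA" if protein[0] == "M" \
        else reverse_translate(protein, rng) + "TAA"
    if protein[0] != "M":
        raise ValueError("clade consensus must start with M")
    pad_total = spec.element_length - 2 * tir - len(cds)
    if pad_total < 12:
        raise ValueError(
            f"element_length {spec.element_length} too short for a "
            f"{spec.transposase_length} aa transposase with {tir} bp TIRs"
        )
    left_pad = pad_total // 2
    right_pad = pad_total - left_pad
    if tir >= len(TIR_MOTIF):
        left_tir = TIR_MOTIF + _random_dna(rng, tir - len(TIR_MOTIF), gc)
    else:
        left_tir = _random_dna(rng, tir, gc)
    right_tir = revcomp(left_tir)
    if spec.tir_mismatches:
        arm = list(right_tir)
        pos = rng.choice(len(arm), size=min(spec.tir_mismatches, len(arm)),
                         replace=False)
        for p in pos:
            arm[p] = "ACGT"[(_CODE[ord(arm[p])] + 1 + rng.integers(0, 3)) % 4]
        right_tir = "".join(arm)
    # AAA walls stop chance inward extension of the inverted repeat;
    # TAA just before ATG caps any upstream in-frame extension of the ORF.
    lpad = "AAA" + _random_dna(rng, left_pad - 6, gc) + "TAA"
    rpad = _random_dna(rng, right_pad - 3, gc) + "AAA"
    element = left_tir + lpad + cds + rpad + right_tir
    assert len(element) == spec.element_length
    return element, protein


def _wave_assignment(spec: FamilySpec, rng: np.random.Generator) -> np.ndarray:
    """Per-copy target K, with exact largest-remainder wave counts."""
    n = spec.copy_count
    fracs = np.array([f for _, f in spec.divergence_waves])
    means = np.array([k for k, _ in spec.divergence_waves])
    counts = np.floor(fracs * n).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(fracs * n - counts))
    for i in range(rem):
        counts[order[i % len(counts)]] += 1
    ks = np.repeat(means, counts)
    return rng.permutation(ks)


# ---------------------------------------------------------------------------
# genome assembly


def generate_genome(config: GeneratorConfig) -> SyntheticGenome:
    """Generate a genome plus truth table.  Deterministic in ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    per_contig = config.genome_length // config.contig_count
    contig_names = [f"contig_{i + 1}" for i in range(config.contig_count)]
    backgrounds = {
        name: _random_dna(rng, per_contig, config.gc_content)
        for name in contig_names
    }

    masters: dict[str, str] = {}
    plants: dict[str, list[tuple[int, str, TruthRecord]]] = {n: [] for n in contig_names}
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in contig_names}

    copy_no = 0
    for spec in config.families:
        master, _protein = build_master_element(spec, rng, config.gc_content)
        masters[spec.family_id] = master
        ks = _wave_assignment(spec, rng)
        for target_k in ks:
            copy_no += 1
            seq = mutate_copy(master, float(target_k), spec.ts_tv_ratio, rng)
            truncated = bool(rng.random() < spec.truncation_prob)
            if truncated:
                frac = rng.uniform(0.2, 0.8)
                cut = max(int(round(frac * len(seq))), spec.tir_length + 4)
                if rng.random() < 0.5:
                    seq = seq[cut:]  # left end (and left TIR) lost
                else:
                    seq = seq[:-cut]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = revcomp(seq)
            placed = False
            for _ in range(500):
                contig = contig_names[rng.integers(0, len(contig_names))]
                span = len(seq) + 2 * len(spec.tsd)
                hi = len(backgrounds[contig]) - span - 100
                if hi <= 100:
                    continue
                pos = int(rng.integers(100, hi))
                clash = any(
                    pos < e + config.min_spacing and pos + span > s - config.min_spacing
                    for s, e in occupied[contig]
                )
                if clash:
                    continue
                occupied[contig].append((pos, pos + span))
                rec = TruthRecord(
                    element_id=f"pb{copy_no:04d}",
                    contig=contig,
                    start=-1,  # filled during assembly
                    end=-1,
                    strand=strand,
                    clade_label=spec.clade_label,
                    family_id=spec.family_id,
                    tir_length=spec.tir_length,
                    tsd=spec.tsd,
                    target_K=float(target_k),
                    truncated=truncated,
                    transposase_length=spec.transposase_length,
                )
                plants[contig].append((pos, spec.tsd + seq + spec.tsd, rec))
                placed = True
                break
            if not placed:
                raise ValueError(
                    "genome too small to place all copies at the requested spacing"
                )

    contigs: dict[str, str] = {}
    truth: list[TruthRecord] = []
    for name in contig_names:
        bg = backgrounds[name]
        parts = []
        cursor = 0
        offset = 0
        for pos, insert, rec in sorted(plants[name], key=lambda t: t[0]):
            parts.append(bg[cursor:pos])
            tsd_len = len(rec.tsd)
            start = pos + offset + tsd_len
            truth.append(
                replace(rec, start=start, end=start + len(insert) - 2 * tsd_len)
            )
            parts.append(insert)
            offset += len(insert)
            cursor = pos
        parts.append(bg[cursor:])
        contigs[name] = "".join(parts)
    truth.sort(key=lambda r: (r.contig, r.start))
    return SyntheticGenome(contigs=contigs, truth=truth, config=config,
                           masters=masters)


def truth_table(genome: SyntheticGenome):
    """Truth records as a pandas DataFrame (0-based half-open coordinates)."""
    import pandas as pd

    return pd.DataFrame([r.__dict__ for r in genome.truth])
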