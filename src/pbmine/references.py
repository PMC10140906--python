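"""Access to the bundled reference transposase set and its annotation.

The bundle ships three clade consensus proteins (A, B, C) built on a common
scaffold, two extra members per clade, and four distant outgroup proteins.
Headers carry ``clade=<label> role=<consensus|reference|outgroup>``.
The JSON annotation records, per clade consensus: the catalytic triad
positions, the insertion-motif span, the conserved tryptophan, the CRD
cysteine positions, and domain spans (NTD, DDBD1, DDD, DDBD2, CRD) — all
0-based indices into the consensus protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

from .io import read_fasta_with_descriptions


@dataclass(frozen=True)
class ProteinReference:
    id: str
    clade: str  # "A"/"B"/"C" or "outgroup"
    role: str  # consensus | reference | outgroup
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty reference sequence for {self.id}")


@dataclass(frozen=True)
class CladeProfile:
    """Consensus protein plus diagnostic-feature coordinates for one clade."""

    clade: str
    consensus: str
    triad: tuple[int, int, int]
    insertion: tuple[int, int]
    trp: int
    crd_cys: tuple[int, ...]
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def crd_spacing(self) -> tuple[int, ...]:
        return tuple(b - a for a, b in zip(self.crd_cys, self.crd_cys[1:]))


def _parse_header(description: str) -> dict[str, str]:
    fields = {}
    for token in description.split()[1:]:
        if "=" in token:
            k, v = token.split("=", 1)
            fields[k] = v
    return fields


def load_references(path=None) -> list[ProteinReference]:
    """Load the bundled (or a user-supplied) reference protein FASTA."""
    if path is None:
        path = resources.files("pbmine.data") / "references.faa"
    refs = []
    seen = set()
    for rid, desc, seq in read_fasta_with_descriptions(str(path)):
        if rid in seen:
            raise ValueError(f"duplicate reference id {rid}")
        seen.add(rid)
        meta = _parse_header(desc)
        refs.append(
            ProteinReference(
                id=rid,
                clade=meta.get("clade", "reference"),
                role=meta.get("role", "reference"),
                sequence=seq,
            )
        )
    if not refs:
        raise ValueError(f"no references found in {path}")
    return refs


def load_clade_profiles(refs=None) -> dict[str, CladeProfile]:
    if refs is None:
        refs = load_references()
    annot = json.loads(
        (resources.files("pbmine.data") / "reference_annotation.json").read_text()
    )
    by_id = {r.id: r for r in refs}
    profiles = {}
    for clade, info in annot["clades"].items():
        cons = by_id[info["consensus_id"]].sequence
        profiles[clade] = CladeProfile(
            clade=clade,
            consensus=cons,
            triad=tuple(info["triad"]),
            insertion=tuple(info["insertion"]),
            trp=info["trp"],
            crd_cys=tuple(info["crd_cys"]),
            domains={k: tuple(v) for k, v in info["domains"].items()},
        )
    return profiles
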