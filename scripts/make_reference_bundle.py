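"""Regenerate the bundled reference transposase set.

Produces src/pbmine/data/references.faa and reference_annotation.json.
The bundle contains three clade consensus transposases (A, B, C) sharing a
common ancestral scaffold, two additional members per clade, and four
distantly related outgroup transposases.  Diagnostic features (catalytic
DDD triad, insertion motif, conserved tryptophan, regularly spaced CRD
cysteines) are held fixed across the in-group so the domain scanner has a
well-defined target.  Deterministic; run once, output is committed.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
LENGTH = 580
TRIAD = (250, 340, 440)
INSERTION = (380, 400)
TRP = 462
CRD_CYS = (522, 527, 533, 541, 546, 554, 559)
DOMAINS = {
    "NTD": (0, 100),
    "DDBD1": (100, 230),
    "DDD": (230, 460),
    "DDBD2": (460, 520),
    "CRD": (520, 580),
}

PROTECTED = {0, TRP, *TRIAD, *CRD_CYS, *range(*INSERTION)}


def random_protein(rng: np.random.Generator, n: int) -> list[str]:
    return [AA[i] for i in rng.integers(0, len(AA), n)]


def impose_motifs(seq: list[str], rng: np.random.Generator) -> None:
    seq[0] = "M"
    for p in TRIAD:
        seq[p] = "D"
    seq[TRP] = "W"
    for p in CRD_CYS:
        seq[p] = "C"
    # insertion motif: a fixed block between the 2nd and 3rd catalytic D
    motif = random_protein(rng, INSERTION[1] - INSERTION[0])
    for k, p in enumerate(range(*INSERTION)):
        seq[p] = motif[k]


def diverge(seq: list[str], rate: float, rng: np.random.Generator) -> list[str]:
    out = list(seq)
    for i in range(len(out)):
        if i in PROTECTED:
            continue
        if rng.random() < rate:
            choices = AA.replace(out[i], "")
            out[i] = choices[rng.integers(0, len(choices))]
    return out


def scrub_stray_cysteines(seq: list[str]) -> None:
    """Only the planted CRD cysteines may appear in the C-terminal 60 aa,
    so the regular-spacing scan has an unambiguous target."""
    for i in range(len(seq) - 60, len(seq)):
        if seq[i] == "C" and i not in CRD_CYS:
            seq[i] = "S"


def main() -> None:
    rng = np.random.default_rng(20230402)
    master = random_protein(rng, LENGTH)
    impose_motifs(master, rng)
    scrub_stray_cysteines(master)

    records: list[tuple[str, str, str]] = []  # (id, header_extra, seq)
    for clade in "ABC":
        cons = diverge(master, 0.35, rng)
        # restore motifs verbatim (insertion motif identical across clades)
        for p in PROTECTED:
            cons[p] = master[p]
        scrub_stray_cysteines(cons)
        records.append((f"PBcons_{clade}", f"clade={clade} role=consensus", "".join(cons)))
        for m in (1, 2):
            member = diverge(cons, 0.10, rng)
            scrub_stray_cysteines(member)
            records.append((f"PBref_{clade}{m}", f"clade={clade} role=reference", "".join(member)))
    for m in range(1, 5):
        og = random_protein(rng, 420)
        og[0] = "M"
        records.append((f"ISout_{m}", "clade=outgroup role=outgroup", "".join(og)))

    data_dir = pathlib.Path(__file__).resolve().parents[1] / "src" / "pbmine" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    with open(data_dir / "references.faa", "w") as fh:
        for rid, extra, seq in records:
            fh.write(f">{rid} {extra}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    annot = {
        "clades": {
            clade: {
                "consensus_id": f"PBcons_{clade}",
                "triad": list(TRIAD),
                "insertion": list(INSERTION),
                "crd_cys": list(CRD_CYS),
                "trp": TRP,
                "domains": {k: list(v) for k, v in DOMAINS.items()},
            }
            for clade in "ABC"
        }
    }
    with open(data_dir / "reference_annotation.json", "w") as fh:
        json.dump(annot, fh, indent=1)
    print("wrote", data_dir / "references.faa")


if __name__ == "__main__":
    main()
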