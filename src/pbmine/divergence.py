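"""Kimura 2-parameter divergence of copies against their family consensus,
divergence landscapes (genome coverage per K bin) and invasion-age calls.

K = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)] * 100, with P and Q the
transition/transversion fractions over gap-free aligned columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .census import make_nucleotide_aligner

RECENT_K = 2.0  # families with majority copy-bp below this are "recent"
OLD_K = 15.0    # families with majority copy-bp above this are "old"

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class SaturationError(ValueError):
    """The K2P estimator is undefined for the observed P/Q."""


@dataclass(frozen=True)
class SubstitutionCounts:
    aligned_sites: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.aligned_sites

    @property
    def Q(self) -> float:
        return self.transversions / self.aligned_sites


@dataclass(frozen=True)
class DivergenceLandscape:
    family_id: str
    bin_width: float
    bins: tuple[tuple[float, float], ...]  # (bin_start_K, genome_coverage_%)
    total_copy_bp: int
    genome_bp: int
    n_saturated: int = 0


@dataclass(frozen=True)
class AgeCall:
    family_id: str
    label: str  # recent | old | intermediate
    multi_wave: bool
    wave_modes: tuple[float, ...]


def count_substitutions(copy: str, consensus: str,
                        aligner: Align.PairwiseAligner | None = None
                        ) -> SubstitutionCounts:
    """Globally align and tally transitions/transversions over gap-free,
    N-free columns."""
    if len(copy) < 50 or len(consensus) < 50:
        raise ValueError("both sequences must be >= 50 bp")
    if aligner is None:
        aligner = make_nucleotide_aligner(mode="global")
    aln = aligner.align(consensus, copy)[0]
    a, b = str(aln[0]).upper(), str(aln[1]).upper()
    sites = ts = tv = 0
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        sites += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise ValueError("alignment has no gap-free columns")
    return SubstitutionCounts(aligned_sites=sites, transitions=ts,
                              transversions=tv)


def kimura_distance(P: float, Q: float) -> float:
    """K2P distance in percent; raises SaturationError outside the domain."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P saturated: P={P}, Q={Q}")
    return -0.5 * math.log(w1 * math.sqrt(w2)) * 100.0


def copy_divergence(copy: str, consensus: str) -> tuple[float, int]:
    """(K percent, aligned bp) of one copy against the consensus."""
    c = count_substitutions(copy, consensus)
    return kimura_distance(c.P, c.Q), c.aligned_sites


def landscape(
    copies: Sequence[str],
    consensus: str,
    genome_bp: int,
    bin_width: float = 1.0,
    family_id: str = "family",
) -> DivergenceLandscape:
    """Bin each copy's aligned bp at its K estimate; coverage per bin is
    summed copy bp over ``genome_bp`` x 100.  Saturated copies are excluded
    and counted."""
    if not copies:
        raise ValueError("no copies supplied")
    mass: dict[int, int] = {}
    total = 0
    saturated = 0
    for copy in copies:
        try:
            k, bp = copy_divergence(copy, consensus)
        except SaturationError:
            saturated += 1
            continue
        b = int(k // bin_width)
        mass[b] = mass.get(b, 0) + bp
        total += bp
    if not mass:
        raise SaturationError("all copies saturated")
    top = max(mass)
    bins = tuple(
        (i * bin_width, 100.0 * mass.get(i, 0) / genome_bp)
        for i in range(top + 1)
    )
    return DivergenceLandscape(
        family_id=family_id, bin_width=bin_width, bins=bins,
        total_copy_bp=total, genome_bp=genome_bp, n_saturated=saturated,
    )


def plot_landscape(ls: DivergenceLandscape, ax=None):
    """Optional bar rendering: x = K divergence bin (%), y = genome
    coverage (%).  Requires matplotlib (the ``plot`` extra)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    xs = [start for start, _ in ls.bins]
    ys = [cov for _, cov in ls.bins]
    ax.bar(xs, ys, width=ls.bin_width, align="edge", color="#4878a8")
    ax.set_xlabel("K divergence estimate (%)")
    ax.set_ylabel("genome coverage (%)")
    ax.set_title(ls.family_id)
    return ax


def call_age(ls: DivergenceLandscape, recent_k: float = RECENT_K,
             old_k: float = OLD_K) -> AgeCall:
    """Majority-mass age label plus amplification-wave detection.

    recent: majority of copy bp in bins entirely below ``recent_k``;
    old: majority of copy bp in bins entirely above ``old_k``; otherwise
    intermediate.  multi_wave when >= 2 local maxima, each holding >= 10%
    of copy bp, sit >= 3 bins apart.
    """
    if not ls.bins:
        raise ValueError("empty landscape")
    masses = [cov for _, cov in ls.bins]
    total = sum(masses)
    if total <= 0:
        raise ValueError("landscape holds no mass")
    recent_mass = sum(
        cov for start, cov in ls.bins if start + ls.bin_width <= recent_k
    )
    old_mass = sum(cov for start, cov in ls.bins if start > old_k)
    if recent_mass > 0.5 * total:
        label = "recent"
    elif old_mass > 0.5 * total:
        label = "old"
    else:
        label = "intermediate"

    peaks = []
    for i, m in enumerate(masses):
        if m < 0.10 * total or m <= 0:
            continue
        left = masses[i - 1] if i > 0 else -1.0
        right = masses[i + 1] if i + 1 < len(masses) else -1.0
        if m >= left and m >= right:
            peaks.append((m, i))
    peaks.sort(reverse=True)
    chosen: list[int] = []
    for _, i in peaks:
        if all(abs(i - j) >= 3 for j in chosen):
            chosen.append(i)
    chosen.sort()
    modes = tuple(ls.bins[i][0] + ls.bin_width / 2 for i in chosen)
    return AgeCall(
        family_id=ls.family_id,
        label=label,
        multi_wave=len(chosen) >= 2,
        wave_modes=modes,
    )
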