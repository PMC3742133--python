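"""The predictive promoter model (PPM): distance-constrained homotypic pairs.

A promoter fits the PPM when it carries at least one admissible pair of HMX1
binding sites inside the screening window: two sites whose start-to-start
distance lies within the constraint (default 90-190 nt), orientation
disregarded. Tiers relax the site strength required of the pair members:

* ``PPM``     — both members canonical (CAAGTG/CACTTG);
* ``LS_PPM``  — at least one canonical, the other may be a standalone core
  (CAAG/CTTG) site;
* ``VLS_PPM`` — any two sites (canonical or standalone core).

A "standalone" core hit is one whose span does not overlap any canonical
hit's span — a core embedded in a canonical site is the same physical site
and is never counted twice. Because every canonical site is also
core-strength, qualifying pairs nest across tiers:
``PPM pairs ⊆ LS pairs ⊆ VLS pairs``, hence
``fits(PPM) ⇒ fits(LS_PPM) ⇒ fits(VLS_PPM)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .errors import FormatError, InfeasibleError
from .motif_scan import CANONICAL, CORE, MotifHit, scan_window
from .promoter_io import PromoterWindow, WindowSpec

START_TO_START = "start-to-start"
GAP = "gap"


class Tier(Enum):
    PPM = "PPM"
    LS_PPM = "LS-PPM"
    VLS_PPM = "VLS-PPM"

    @property
    def label(self) -> str:
        return self.value


TIERS = (Tier.PPM, Tier.LS_PPM, Tier.VLS_PPM)


@dataclass(frozen=True)
class PairConstraint:
    """Admissible spacing between the two sites of a pair.

    ``measure`` selects how spacing is computed: ``start-to-start`` (distance
    between the 5'-most bases, the default and the measure that reproduces
    the published combination maxima) or ``gap`` (end of the first site to
    start of the second)."""

    min_distance: int = 90
    max_distance: int = 190
    measure: str = START_TO_START

    def __post_init__(self) -> None:
        if not 0 < self.min_distance <= self.max_distance:
            raise FormatError(
                f"need 0 < min_distance <= max_distance, got "
                f"[{self.min_distance}, {self.max_distance}]"
            )
        if self.measure not in (START_TO_START, GAP):
            raise FormatError(f"unknown distance measure {self.measure!r}")

    def distance(self, first: MotifHit, second: MotifHit) -> int:
        """Spacing of two hits with ``first.start_offset < second.start_offset``."""
        if self.measure == START_TO_START:
            return second.start_offset - first.start_offset
        return second.start_offset - first.end_offset

    def admits(self, distance: int) -> bool:
        return self.min_distance <= distance <= self.max_distance


@dataclass(frozen=True)
class PPMDefinition:
    tier: Tier = Tier.PPM
    window_spec: WindowSpec = field(default_factory=WindowSpec)
    pair_constraint: PairConstraint = field(default_factory=PairConstraint)
    min_pairs: int = 1

    def __post_init__(self) -> None:
        if self.min_pairs < 1:
            raise FormatError("min_pairs must be >= 1")


@dataclass(frozen=True)
class AdmissiblePair:
    hit_a: MotifHit
    hit_b: MotifHit
    distance: int

    def __post_init__(self) -> None:
        if self.hit_a.start_offset >= self.hit_b.start_offset:
            raise FormatError("pair members must be ordered by start offset")


def _standalone_sites(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Canonical hits plus core hits not overlapping any canonical span."""
    canonical = [h for h in hits if h.motif_name == CANONICAL.name]
    sites = list(canonical)
    for h in hits:
        if h.motif_name == CANONICAL.name:
            continue
        if not any(h.overlaps(c) for c in canonical):
            sites.append(h)
    sites.sort(key=lambda h: (h.start_offset, h.motif_name != CANONICAL.name))
    return sites


def _pair_qualifies(a: MotifHit, b: MotifHit, tier: Tier) -> bool:
    n_canonical = (a.motif_name == CANONICAL.name) + (b.motif_name == CANONICAL.name)
    if tier is Tier.PPM:
        return n_canonical == 2
    if tier is Tier.LS_PPM:
        return n_canonical >= 1
    return True


def enumerate_admissible_pairs(
    hits: Sequence[MotifHit], constraint: PairConstraint, tier: Tier
) -> list[AdmissiblePair]:
    """All unordered site pairs admissible under ``constraint`` whose
    composition matches ``tier``. ``hits`` may mix canonical and core hits and
    must be sorted by start offset; pair members never overlap each other, and
    output is sorted by (start_a, start_b)."""
    starts = [h.start_offset for h in hits]
    if starts != sorted(starts):
        raise FormatError("hits must be sorted by start_offset")
    sites = _standalone_sites(hits)
    pairs: list[AdmissiblePair] = []
    for a, b in itertools.combinations(sites, 2):
        if a.start_offset > b.start_offset:
            a, b = b, a
        if a.overlaps(b):
            continue
        if not _pair_qualifies(a, b, tier):
            continue
        d = constraint.distance(a, b)
        if constraint.admits(d):
            pairs.append(AdmissiblePair(a, b, d))
    pairs.sort(key=lambda p: (p.hit_a.start_offset, p.hit_b.start_offset))
    return pairs


@dataclass
class MatchEvidence:
    """Per-window scanning and pairing evidence, for reporting and screening."""

    window: PromoterWindow
    canonical_hit_count: int
    core_hit_count: int
    pairs_by_tier: dict[Tier, list[AdmissiblePair]]
    fits: dict[Tier, bool]

    @property
    def admissible_pairs(self) -> list[AdmissiblePair]:
        """Pairs for the strictest tier (PPM)."""
        return self.pairs_by_tier[Tier.PPM]

    def to_report(self) -> dict:
        spec = self.window.window_spec
        return {
            "gene_symbol": self.window.gene_symbol,
            "transcript_ids": list(self.window.transcript_ids),
            "canonical_hits": self.canonical_hit_count,
            "core_hits": self.core_hit_count,
            "fits": {tier.label: self.fits[tier] for tier in TIERS},
            "pairs": {
                tier.label: [
                    {
                        "start_a": spec.offset_to_signed(p.hit_a.start_offset),
                        "start_b": spec.offset_to_signed(p.hit_b.start_offset),
                        "distance": p.distance,
                        "members": [p.hit_a.motif_name, p.hit_b.motif_name],
                    }
                    for p in self.pairs_by_tier[tier]
                ]
                for tier in TIERS
            },
        }


def classify_window(window: PromoterWindow, ppm: PPMDefinition) -> MatchEvidence:
    """Scan a window for canonical and core sites and derive per-tier fits:
    a tier fits when it yields at least ``ppm.min_pairs`` admissible pairs."""
    canonical_hits = scan_window(window, CANONICAL)
    core_hits = scan_window(window, CORE)
    all_hits = sorted(
        canonical_hits + core_hits,
        key=lambda h: (h.start_offset, h.motif_name != CANONICAL.name),
    )
    pairs_by_tier = {
        tier: enumerate_admissible_pairs(all_hits, ppm.pair_constraint, tier)
        for tier in TIERS
    }
    fits = {tier: len(pairs_by_tier[tier]) >= ppm.min_pairs for tier in TIERS}
    return MatchEvidence(
        window=window,
        canonical_hit_count=len(canonical_hits),
        core_hit_count=len(core_hits),
        pairs_by_tier=pairs_by_tier,
        fits=fits,
    )


def motif_count_histogram(windows: Iterable[PromoterWindow]) -> tuple[int, int, int]:
    """Counts of windows containing (0, 1, >=2) canonical motifs."""
    zero = one = two_plus = 0
    for win in windows:
        n = len(scan_window(win, CANONICAL))
        if n == 0:
            zero += 1
        elif n == 1:
            one += 1
        else:
            two_plus += 1
    return zero, one, two_plus


def derive_distance_range(
    observed_distances: Sequence[int], granularity: int = 10
) -> PairConstraint:
    """Round the observed pair distances outward to a granularity-aligned
    range, as done when generalizing the training promoters into a framework:
    ``[floor(min/g)*g, ceil(max/g)*g]``."""
    if not observed_distances:
        raise FormatError("need at least one observed distance")
    if any(d <= 0 for d in observed_distances):
        raise FormatError("distances must be positive")
    lo = (min(observed_distances) // granularity) * granularity
    hi = math.ceil(max(observed_distances) / granularity) * granularity
    return PairConstraint(min_distance=max(lo, 1), max_distance=hi)


def _pairset_feasible(
    k: int, pairset: Sequence[tuple[int, int]], lo: int, hi: int, sep: int, span: int
) -> list[int] | None:
    """Feasibility of a difference-constraint system over site starts
    x_0 < x_1 < ... < x_{k-1}: consecutive sites separated by >= ``sep``
    (non-overlap), total span <= ``span``, and every pair (i, j) in
    ``pairset`` at start-distance within [lo, hi]. Returns a witness start
    vector, or None. Solved by Bellman-Ford on the constraint graph."""
    # Edge (u, v, w) encodes x_v - x_u <= w.
    edges: list[tuple[int, int, int]] = [(0, k - 1, span)]
    for i in range(k - 1):
        edges.append((i + 1, i, -sep))
    for i, j in pairset:
        edges.append((i, j, hi))
        edges.append((j, i, -lo))
    dist = [0] * k
    for it in range(k + 1):
        changed = False
        for u, v, w in edges:
            if dist[u] + w < dist[v]:
                dist[v] = dist[u] + w
                changed = True
        if not changed:
            break
    else:
        return None  # negative cycle -> infeasible
    base = dist[0]
    return [d - base for d in dist]


def max_simultaneous_pairs(
    k: int,
    constraint: PairConstraint | None = None,
    window_len: int = 450,
    motif_len: int = 6,
    return_witness: bool = False,
):
    """Maximum number of admissible pairs that ``k`` non-overlapping motifs
    can form simultaneously inside a window.

    The search is exhaustive over subsets of the C(k,2) candidate pairs,
    in decreasing size; a subset is achievable iff the corresponding system
    of difference constraints on the motif starts is feasible, which is
    decided exactly (any placement realizes the pair set of its admissible
    pairs, and any feasible pair set has an integer placement). With the
    default [90,190] range this gives 3 pairs for k=3 and 5 for k=4.
    """
    constraint = constraint or PairConstraint()
    if k < 1:
        raise FormatError("k must be >= 1")
    if k * motif_len > window_len:
        raise InfeasibleError(
            f"{k} motifs of length {motif_len} cannot fit in a {window_len}-nt window"
        )
    if constraint.measure == START_TO_START:
        lo, hi = constraint.min_distance, constraint.max_distance
    else:  # gap measure: start-distance bounds shift by the motif length
        lo, hi = constraint.min_distance + motif_len, constraint.max_distance + motif_len
    lo = max(lo, motif_len)  # pair members cannot overlap
    span = window_len - motif_len
    if k == 1:
        return (0, [0]) if return_witness else 0
    all_pairs = list(itertools.combinations(range(k), 2))
    for size in range(len(all_pairs), -1, -1):
        for pairset in itertools.combinations(all_pairs, size):
            witness = _pairset_feasible(k, pairset, lo, hi, motif_len, span)
            if witness is not None:
                return (size, witness) if return_witness else size
    raise AssertionError("unreachable: the empty pair set is always feasible")


def count_admissible_start_pairs(
    starts: Sequence[int], lo: int = 90, hi: int = 190
) -> int:
    """Pairs among sorted starts with start-to-start distance in [lo, hi];
    small helper used to verify placement witnesses."""
    return sum(
        1
        for a, b in itertools.combinations(sorted(starts), 2)
        if lo <= b - a <= hi
    )
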