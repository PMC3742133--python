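"""Distance-constrained pair enumeration, tier classification, and the
pair-combination maximization."""

import itertools
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppmscreen.errors import FormatError, InfeasibleError
from ppmscreen.motif_scan import CANONICAL, CORE, FORWARD, MotifHit
from ppmscreen.ppm_model import (
    GAP,
    TIERS,
    PairConstraint,
    PPMDefinition,
    Tier,
    classify_window,
    count_admissible_start_pairs,
    derive_distance_range,
    enumerate_admissible_pairs,
    max_simultaneous_pairs,
    motif_count_histogram,
)
from ppmscreen.promoter_io import reverse_complement

from conftest import make_window


def canonical_hits(starts):
    return [MotifHit(s, CANONICAL.name, FORWARD, 6) for s in sorted(starts)]


def core_hits(starts):
    return [MotifHit(s, CORE.name, FORWARD, 4) for s in sorted(starts)]


def brute_force_pairs(hits, constraint, tier):
    """Independent double loop over all hit pairs: canonical sites plus core
    hits clear of any canonical span, composition by tier, members
    non-overlapping, spacing within the constraint."""
    canonical = [h for h in hits if h.motif_name == "canonical"]
    sites = canonical + [
        h for h in hits
        if h.motif_name != "canonical" and not any(h.overlaps(c) for c in canonical)
    ]
    out = []
    for i in range(len(sites)):
        for j in range(len(sites)):
            a, b = sites[i], sites[j]
            if a.start_offset >= b.start_offset or a.overlaps(b):
                continue
            n_canon = sum(h.motif_name == "canonical" for h in (a, b))
            need = {Tier.PPM: n_canon == 2, Tier.LS_PPM: n_canon >= 1,
                    Tier.VLS_PPM: True}[tier]
            if need and constraint.admits(constraint.distance(a, b)):
                out.append((a.start_offset, b.start_offset))
    return sorted(set(out))


class TestEnumeratePairs:
    def test_single_pair_at_admissible_distance(self):
        pairs = enumerate_admissible_pairs(canonical_hits([10, 120]), PairConstraint(), Tier.PPM)
        assert len(pairs) == 1
        assert pairs[0].distance == 110

    @pytest.mark.parametrize("starts", [[10, 60], [10, 250]])
    def test_out_of_range_distances_excluded(self, starts):
        assert enumerate_admissible_pairs(canonical_hits(starts), PairConstraint(), Tier.PPM) == []

    def test_three_sites_three_pairs_when_span_admissible(self):
        # all three start-to-start distances (95, 95, 190) are admissible
        pairs = enumerate_admissible_pairs(canonical_hits([0, 95, 190]), PairConstraint(), Tier.PPM)
        assert [(p.hit_a.start_offset, p.hit_b.start_offset) for p in pairs] == \
            [(0, 95), (0, 190), (95, 190)]
        # the outer pair drops out once the span exceeds the maximum
        pairs = enumerate_admissible_pairs(canonical_hits([0, 96, 192]), PairConstraint(), Tier.PPM)
        assert [(p.hit_a.start_offset, p.hit_b.start_offset) for p in pairs] == \
            [(0, 96), (96, 192)]  # 0..192 spans 192 > 190
        pairs = enumerate_admissible_pairs(canonical_hits([0, 100, 200]), PairConstraint(), Tier.PPM)
        assert [(p.hit_a.start_offset, p.hit_b.start_offset) for p in pairs] == \
            [(0, 100), (100, 200)]

    def test_unsorted_input_rejected(self):
        hits = canonical_hits([10, 120])[::-1]
        with pytest.raises(FormatError, match="sorted"):
            enumerate_admissible_pairs(hits, PairConstraint(), Tier.PPM)

    def test_core_inside_canonical_is_not_a_second_site(self):
        # one canonical with its embedded CAAG, plus a standalone core 100 nt away
        hits = sorted(
            canonical_hits([10]) + core_hits([10, 110]),
            key=lambda h: h.start_offset,
        )
        assert enumerate_admissible_pairs(hits, PairConstraint(), Tier.PPM) == []
        ls = enumerate_admissible_pairs(hits, PairConstraint(), Tier.LS_PPM)
        assert [(p.hit_a.start_offset, p.hit_b.start_offset) for p in ls] == [(10, 110)]

    def test_gap_measure_shifts_admissibility(self):
        # start-to-start 96 = gap 90 for a 6-mer first member
        constraint = PairConstraint(measure=GAP)
        pairs = enumerate_admissible_pairs(canonical_hits([0, 96]), constraint, Tier.PPM)
        assert len(pairs) == 1 and pairs[0].distance == 90

    @given(
        canon=st.lists(st.integers(0, 440), max_size=5),
        cores=st.lists(st.integers(0, 440), max_size=5),
        tier=st.sampled_from(list(TIERS)),
    )
    def test_agrees_with_brute_force(self, canon, cores, tier):
        hits = sorted(
            canonical_hits(set(canon)) + core_hits(set(cores)),
            key=lambda h: h.start_offset,
        )
        got = enumerate_admissible_pairs(hits, PairConstraint(), tier)
        assert [(p.hit_a.start_offset, p.hit_b.start_offset) for p in got] == \
            brute_force_pairs(hits, PairConstraint(), tier)


class TestClassifyWindow:
    def test_mixed_orientation_canonical_pair_fits_ppm(self, plant):
        spec = PPMDefinition().window_spec
        win = plant([(spec.signed_to_offset(-200), "CAAGTG"),
                     (spec.signed_to_offset(-60), "CACTTG")])
        evidence = classify_window(win, PPMDefinition())
        assert evidence.fits[Tier.PPM]
        assert evidence.admissible_pairs[0].distance == 140

    def test_canonical_plus_core_fits_ls_not_ppm(self, plant):
        win = plant([(50, "CAAGTG"), (150, "CAAG")])
        evidence = classify_window(win, PPMDefinition())
        assert not evidence.fits[Tier.PPM]
        assert evidence.fits[Tier.LS_PPM]
        assert evidence.fits[Tier.VLS_PPM]

    def test_background_window_fits_nothing(self, plant):
        evidence = classify_window(plant([]), PPMDefinition())
        assert not any(evidence.fits.values())

    def test_tier_monotonicity_on_random_windows(self, rng):
        ppm = PPMDefinition()
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=450))
            fits = classify_window(make_window([(0, seq)]), ppm).fits
            assert (not fits[Tier.PPM] or fits[Tier.LS_PPM])
            assert (not fits[Tier.LS_PPM] or fits[Tier.VLS_PPM])

    def test_pair_distances_invariant_under_reverse_complement(self, plant):
        win = plant([(30, "CAAGTG"), (170, "CACTTG"), (300, "CAAGTG")])
        rc = make_window([(0, reverse_complement(win.sequence))])
        d1 = sorted(p.distance for p in classify_window(win, PPMDefinition()).admissible_pairs)
        d2 = sorted(p.distance for p in classify_window(rc, PPMDefinition()).admissible_pairs)
        assert d1 == d2


class TestHistogram:
    def test_training_set_decomposition(self, plant):
        wins = (
            [plant([(50, "CAAGTG"), (160, "CACTTG")]) for _ in range(3)]
            + [plant([(50, "CAAGTG")]) for _ in range(3)]
            + [plant([]) for _ in range(24)]
        )
        assert motif_count_histogram(wins) == (24, 3, 3)

    def test_empty_and_all_two_motif(self, plant):
        assert motif_count_histogram([]) == (0, 0, 0)
        wins = [plant([(10, "CAAGTG"), (200, "CAAGTG")]) for _ in range(5)]
        assert motif_count_histogram(wins) == (0, 0, 5)


class TestDeriveDistanceRange:
    @pytest.mark.parametrize(
        "distances,g,expected",
        [([93, 131, 187], 10, (90, 190)), ([100], 10, (100, 100)), ([95], 1, (95, 95))],
    )
    def test_outward_rounding(self, distances, g, expected):
        constraint = derive_distance_range(distances, granularity=g)
        assert (constraint.min_distance, constraint.max_distance) == expected

    def test_empty_rejected(self):
        with pytest.raises(FormatError):
            derive_distance_range([])


def brute_force_max_pairs(k, lo, hi, window_len, motif_len):
    best = 0
    positions = range(window_len - motif_len + 1)
    for combo in itertools.combinations(positions, k):
        if any(b - a < motif_len for a, b in zip(combo, combo[1:])):
            continue
        best = max(best, count_admissible_start_pairs(combo, lo, hi))
    return best


class TestMaxSimultaneousPairs:
    def test_published_maxima(self):
        assert max_simultaneous_pairs(2) == 1
        assert max_simultaneous_pairs(1) == 0
        assert max_simultaneous_pairs(3) == 3
        assert max_simultaneous_pairs(4) == 5

    def test_witness_placements_achieve_the_maximum(self):
        for k in (2, 3, 4, 5):
            count, starts = max_simultaneous_pairs(k, return_witness=True)
            assert len(starts) == k
            assert all(b - a >= 6 for a, b in zip(sorted(starts), sorted(starts)[1:]))
            assert max(starts) - min(starts) <= 444
            assert count_admissible_start_pairs(starts) == count

    @pytest.mark.parametrize(
        "k,lo,hi,window_len,motif_len",
        [(3, 5, 11, 30, 2), (4, 5, 11, 30, 2), (3, 4, 6, 20, 3), (4, 3, 9, 26, 2)],
    )
    def test_matches_exhaustive_search_on_small_windows(self, k, lo, hi, window_len, motif_len):
        constraint = PairConstraint(min_distance=lo, max_distance=hi)
        assert max_simultaneous_pairs(k, constraint, window_len, motif_len) == \
            brute_force_max_pairs(k, lo, hi, window_len, motif_len)

    def test_upper_bound_and_equality_condition(self):
        # max <= C(k,2), with equality iff (k-1)*min <= max
        for k, lo, hi in [(3, 90, 190), (4, 90, 190), (3, 50, 190), (4, 40, 190)]:
            got = max_simultaneous_pairs(k, PairConstraint(min_distance=lo, max_distance=hi))
            assert got <= math.comb(k, 2)
            assert (got == math.comb(k, 2)) == ((k - 1) * lo <= hi)

    def test_infeasible_packing_is_an_error(self):
        with pytest.raises(InfeasibleError):
            max_simultaneous_pairs(4, PairConstraint(), window_len=20, motif_len=6)
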