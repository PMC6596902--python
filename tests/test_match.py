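"""Primer/target matching: set semantics, mismatch profiles, window scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import IUPAC, brute_best_window, min_hamming, revcomp

from nrfatools.alphabet import NucSequence
from nrfatools.io import Primer
from nrfatools.match import (
    base_match,
    count_mismatches,
    locate_by_alignment,
    scan_best_window,
    scan_all_sites,
)

CODES = "ACGTRYSWKMBDHVN"

FWD = Primer("fwd", "CARTGYCAYA", "forward", three_prime_window=3)


@pytest.mark.parametrize(
    "p,t,mode,expected",
    [
        ("R", "A", "subset", True),
        ("R", "C", "subset", False),
        ("R", "N", "subset", False),
        ("R", "N", "intersect", True),
        ("N", "B", "subset", True),
        ("A", "R", "intersect", True),
        ("A", "-", "subset", False),
        ("A", ".", "intersect", False),
    ],
)
def test_base_match_examples(p, t, mode, expected):
    assert base_match(p, t, mode) is expected


def test_base_match_exhaustive_against_set_algebra():
    """Subset/intersect semantics over the full 15x15 IUPAC code table."""
    for p in CODES:
        for t in CODES:
            ps, ts = set(IUPAC[p]), set(IUPAC[t])
            assert base_match(p, t, "subset") == (ts <= ps)
            assert base_match(p, t, "intersect") == bool(ts & ps)


@pytest.mark.parametrize(
    "window,total,positions,three_prime",
    [
        ("CAATGTCATA", 0, (), 0),
        ("CACTGTCATA", 1, (2,), 0),
        ("CAATGTCATG", 1, (9,), 1),
        ("CGATGTCAAG", 3, (1, 8, 9), 2),
    ],
)
def test_count_mismatches_forward(window, total, positions, three_prime):
    profile = count_mismatches(FWD, window)
    assert profile.total == total
    assert profile.mismatch_positions == positions
    assert profile.three_prime_count == three_prime


def test_count_mismatches_gap_counts_as_mismatch():
    profile = count_mismatches(FWD, "CA-TGTCATA")
    assert profile.total == 1
    assert profile.mismatch_positions == (2,)


def test_count_mismatches_length_mismatch():
    with pytest.raises(ValueError, match="length"):
        count_mismatches(FWD, "CAT")


def test_reverse_primer_positions_are_primer_coordinates():
    """A mismatch at the start of the sense-strand window for a reverse
    primer sits at the primer's 3' end."""
    rev = Primer("rev", "CARTGYCAYA", "reverse", three_prime_window=3)
    sense_site = revcomp("CAATGTCATA")  # exact site on the sense strand
    assert count_mismatches(rev, sense_site).total == 0
    # corrupt the first sense base = last (3'-most) primer position
    corrupted = "G" + sense_site[1:] if sense_site[0] != "G" else "A" + sense_site[1:]
    profile = count_mismatches(rev, corrupted)
    assert profile.total == 1
    assert profile.mismatch_positions == (9,)
    assert profile.three_prime_count == 1


@given(st.data())
@settings(max_examples=300, derandomize=True)
def test_count_mismatches_equals_expand_and_minimize_oracle(data):
    """Mismatch totals agree with the brute-force expand-and-minimize
    oracle on random degenerate primer / concrete window pairs."""
    length = data.draw(st.integers(min_value=10, max_value=16))
    # cap degenerate positions so the oracle expansion stays small
    base = data.draw(
        st.lists(st.sampled_from("ACGT"), min_size=length, max_size=length)
    )
    n_degen = data.draw(st.integers(min_value=0, max_value=4))
    degen_pos = data.draw(
        st.lists(
            st.integers(min_value=0, max_value=length - 1),
            min_size=n_degen, max_size=n_degen, unique=True,
        )
    )
    for pos in degen_pos:
        base[pos] = data.draw(st.sampled_from("RYSWKMBDHVN"))
    primer_seq = "".join(base)
    window = "".join(
        data.draw(st.lists(st.sampled_from("ACGT"), min_size=length, max_size=length))
    )
    primer = Primer("p", primer_seq, "forward")
    assert count_mismatches(primer, window).total == min_hamming(primer_seq, window)


def test_locate_by_alignment_gap_and_structural_cases():
    primer = Primer("p", "CAATGTCATA", "forward")
    aligned = NucSequence("s", "GG--CAATGTCATAGG")
    profile = locate_by_alignment(primer, aligned, (4, 14))
    assert profile.total == 0
    assert profile.site.start == 2  # ungapped sense coordinates
    assert profile.site.end == 12

    gappy = NucSequence("s2", "GGCAAT-TCATAGG")
    profile = locate_by_alignment(primer, gappy, (2, 12))
    assert profile.total >= 1
    assert 4 in profile.mismatch_positions  # the gap column

    allgap = NucSequence("s3", "----------")
    profile = locate_by_alignment(primer, allgap, (0, 10))
    assert profile.total == len(primer)

    with pytest.raises(ValueError):
        locate_by_alignment(primer, aligned, (0, 99))
    # wrong-width column range reports a structural mismatch
    profile = locate_by_alignment(primer, aligned, (4, 12))
    assert profile.total == len(primer)


def test_scan_finds_planted_exact_site():
    rng = np.random.default_rng(5)
    background = "".join(rng.choice(list("ACGT"), size=200))
    planted = background[:90] + "CAATGTCATA" + background[90:]
    result = scan_best_window(FWD, NucSequence("s", planted))
    assert result.profile.total == 0
    assert result.site.start == 90
    assert result.unique


def test_scan_tie_breaks_leftmost_and_flags_non_unique():
    seq = NucSequence("s", "CAATGTCATA" + "G" * 30 + "CAATGTCATA")
    result = scan_best_window(FWD, seq)
    assert result.site.start == 0
    assert not result.unique


@pytest.mark.parametrize("orientation", ["forward", "reverse"])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_scan_equals_bruteforce_minimum(orientation, seed):
    """Scan-mode best window equals exhaustive enumeration on random
    kilobase-scale sequences, both orientations."""
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(list("ACGT"), size=1000))
    primer = Primer("p", "CARTGYCAYAWSGGNCT", orientation)
    result = scan_best_window(primer, NucSequence("s", residues))
    off, total = brute_best_window(primer.sequence, orientation, residues)
    assert result.site.start == off
    assert result.profile.total == total


def test_reverse_scan_mirrors_forward_scan_on_revcomp():
    """Matching a reverse primer equals matching it forward-oriented
    against the reverse complement, at mirrored coordinates."""
    rng = np.random.default_rng(9)
    residues = "".join(rng.choice(list("ACGT"), size=400))
    seq = NucSequence("s", residues)
    rev = Primer("r", "CARTGYCAYAWSGG", "reverse")
    fwd_twin = Primer("r", "CARTGYCAYAWSGG", "forward")
    r_res = scan_best_window(rev, seq)
    f_res = scan_best_window(fwd_twin, NucSequence("s_rc", revcomp(residues)))
    assert r_res.profile.total == f_res.profile.total
    mirrored_start = len(residues) - f_res.site.end
    # both scans must find equally good sites; coordinates mirror when unique
    if r_res.unique and f_res.unique:
        assert r_res.site.start == mirrored_start


def test_scan_all_sites_ceilings():
    seq = NucSequence("s", "CAATGTCATA" + "G" * 30 + "CACTGTCATA" + "G" * 30)
    hits = scan_all_sites(FWD, seq, max_total=0)
    assert [h.site.start for h in hits] == [0]
    hits = scan_all_sites(FWD, seq, max_total=1)
    assert [h.site.start for h in hits] == [0, 40]
    hits = scan_all_sites(FWD, seq, max_total=1, max_three_prime=0)
    assert len(hits) == 2  # the position-2 mismatch is not 3'-terminal
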