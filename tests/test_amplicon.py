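"""In-silico PCR, fragment sizing, length filtering, translation, motifs."""

import numpy as np
import pytest

from oracles import revcomp

from nrfatools.alphabet import NucSequence, PeptideSequence, reverse_complement
from nrfatools.amplicon import (
    check_diagnostic_residues,
    default_motifs,
    in_silico_pcr,
    length_filter,
    predict_fragments,
    translate_amplicon,
)
from nrfatools.io import ConfigError, Primer
from nrfatools.match import count_mismatches
from nrfatools.synthetic import DEMO_FORWARD, DEMO_REVERSE, PlantSpec, PlantedProfile, generate_reference_set

FWD = Primer("f", "CAATGTCATACG", "forward")
REV = Primer("r", "GGTACGTTACAT", "reverse")  # sense-strand site = revcomp of this


def _template(spacer_len=236, flank=25, seed=0):
    """Template with one planted exact site pair, outer span 260 nt."""
    rng = np.random.default_rng(seed)
    bg = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    product = FWD.sequence + bg(spacer_len) + revcomp(REV.sequence)
    return NucSequence("t", bg(flank) + product + bg(flank)), flank, len(product)


def test_pcr_finds_planted_product():
    template, flank, span = _template()
    assert span == 260
    amps = in_silico_pcr(template, FWD, REV, max_total=0, max_three_prime=0)
    assert len(amps) == 1
    amp = amps[0]
    assert (amp.start, amp.end, amp.length_nt) == (flank, flank + 260, 260)
    assert amp.sequence == template.residues[flank : flank + 260]


def test_pcr_no_reverse_site_yields_empty():
    rng = np.random.default_rng(1)
    bg = "".join(rng.choice(list("ACGT"), size=150))
    template = NucSequence("t", bg[:30] + FWD.sequence + bg[30:])
    assert in_silico_pcr(template, FWD, REV, 0, 0) == []


def test_pcr_rejects_wrong_orientations():
    template, *_ = _template()
    with pytest.raises(ConfigError):
        in_silico_pcr(template, REV, FWD)


def test_pcr_respects_max_product_length():
    template, *_ = _template()
    assert in_silico_pcr(template, FWD, REV, 0, 0, max_product_length=100) == []


def test_pcr_amplicons_self_verify():
    """Every returned product's terminal windows re-pass the ceilings."""
    template, *_ = _template(seed=3)
    for amp in in_silico_pcr(template, FWD, REV, max_total=2, max_three_prime=1):
        head = count_mismatches(FWD, amp.sequence[: len(FWD)])
        tail = count_mismatches(REV, amp.sequence[-len(REV):])
        assert head.total <= 2 and head.three_prime_count <= 1
        assert tail.total <= 2 and tail.three_prime_count <= 1


def test_pcr_strand_flip_mirrors_products():
    """PCR on the reverse complement of a template yields the same
    products with sequences reverse-complemented and coordinates mirrored."""
    template, *_ = _template(seed=7)
    flipped = NucSequence("t_rc", revcomp(template.residues))
    fwd_amps = in_silico_pcr(template, FWD, REV, 0, 0)
    # on the flipped strand the roles swap: REV's site reads forward
    swapped_fwd = Primer("f2", REV.sequence, "forward")
    swapped_rev = Primer("r2", FWD.sequence, "reverse")
    rev_amps = in_silico_pcr(flipped, swapped_fwd, swapped_rev, 0, 0)
    assert len(fwd_amps) == len(rev_amps) == 1
    a, b = fwd_amps[0], rev_amps[0]
    assert b.sequence == revcomp(a.sequence)
    assert b.start == len(template.residues) - a.end
    assert b.end == len(template.residues) - a.start


def test_multiplex_union_semantics():
    """A template carrying sites for two forward primers yields one
    product per forward when pooled with a shared reverse."""
    rng = np.random.default_rng(11)
    bg = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    fwd2 = Primer("f2", "TTGGCCAATGCA", "forward")
    template = NucSequence(
        "t",
        bg(20) + fwd2.sequence + bg(40) + FWD.sequence + bg(200)
        + revcomp(REV.sequence) + bg(20),
    )
    preds = predict_fragments([template], [FWD, fwd2], REV, max_total=0, max_three_prime=0)
    assert len(preds) == 1
    assert preds[0].n_products == 2
    assert preds[0].cross_specific  # two products on one template flagged
    l1, l2 = preds[0].product_lengths
    assert l2 - l1 == 40 + len(fwd2)  # offset between the two forward sites


def test_fragment_migration_window():
    template, *_ = _template()
    preds = predict_fragments([template], [FWD], REV, max_total=0, max_three_prime=0)
    assert preds[0].product_lengths == (260,)
    assert preds[0].migration_adjusted_ranges == ((256, 259),)


def test_length_filter_inclusive_defaults():
    reads = [NucSequence(f"r{n}", "A" * n) for n in (229, 230, 300, 301)]
    kept, rejected = length_filter(reads)
    assert [len(r) for r in kept] == [230, 300]
    assert [len(r) for r in rejected] == [229, 301]
    again, none_rejected = length_filter(kept)
    assert again == kept and none_rejected == []  # idempotent


def test_length_filter_empty_and_bad_config():
    kept, rejected = length_filter([])
    assert kept == [] and rejected == []
    with pytest.raises(ConfigError):
        length_filter([], min_nt=10, max_nt=5)


def test_translate_amplicon_in_frame_and_shifted():
    spec = PlantSpec("Z", [PlantedProfile((), ())], product_length=279)
    panel = generate_reference_set([spec], seed=5)
    amp = in_silico_pcr(panel.sequences[0], DEMO_FORWARD, DEMO_REVERSE)[0]
    assert amp.length_nt == 279
    result = translate_amplicon(amp, DEMO_FORWARD)
    assert result.ok
    assert len(result.peptide) == 93  # floor(279/3)
    assert "*" not in result.peptide.residues
    assert check_diagnostic_residues(result.peptide).passed

    shifted = NucSequence("shifted", amp.sequence[1:])
    shifted_result = translate_amplicon(shifted, DEMO_FORWARD)
    shifted_report = check_diagnostic_residues(shifted_result.peptide)
    assert not (shifted_result.ok and shifted_report.passed)
    assert not shifted_result.primer_recognized


def test_translate_amplicon_flags_foreign_reads():
    rng = np.random.default_rng(2)
    read = NucSequence("junk", "".join(rng.choice(list("ACGT"), size=90)))
    result = translate_amplicon(read, DEMO_FORWARD)
    assert not result.primer_recognized
    assert result.primer_mismatches > 2


@pytest.mark.parametrize(
    "peptide,motifs,found,passed",
    [
        ("ACDECHG", ["CXXCH"], (1,), True),
        ("ACXXCHG", ["CXXCH"], (1,), True),  # X in the peptide matches too
        ("AGDEFGH", ["CXXCH"], (-1,), False),
        ("MCAACHKKCDDCKW", ["CXXCH", "CXXCK"], (1, 8), True),
    ],
)
def test_check_diagnostic_residues(peptide, motifs, found, passed):
    report = check_diagnostic_residues(PeptideSequence("p", peptide), motifs)
    assert report.positions == found
    assert report.passed is passed


def test_motif_order_matters():
    # both motifs present but in the wrong order
    report = check_diagnostic_residues(
        PeptideSequence("p", "CDDCKWWWCAACH"), ["CXXCH", "CXXCK"]
    )
    assert all(p >= 0 for p in report.positions)
    assert not report.in_order
    assert not report.passed


def test_default_motifs_ship_cxxch():
    assert "CXXCH" in default_motifs()
    with pytest.raises(ConfigError):
        check_diagnostic_residues(PeptideSequence("p", "ACDEF"), [])
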