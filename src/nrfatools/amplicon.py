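"""In-silico PCR and amplicon QC.

Given forward and reverse primers and an ungapped template, every
primer-quality site on the sense strand is found by sliding-window
matching, upstream-forward/downstream-reverse sites are paired into
predicted products, and products are post-processed the way an amplicon
survey would: fragment-size prediction for capillary (AFLP-style) sizing,
length filtering to the expected product range, in-frame translation
anchored at the forward primer's 5' end, and screening of the translated
peptide for diagnostic residues (the heme c attachment motif CXXCH by
default).

Amplicon coordinates are primer-inclusive (the product spans the forward
primer's 5' end through the reverse-primer site), since downstream
translation is anchored at the forward primer's first base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from .alphabet import NucSequence, PeptideSequence, reverse_complement, translate
from .io import ConfigError, Primer
from .match import MismatchProfile, count_mismatches, scan_all_sites

__all__ = [
    "Amplicon",
    "FragmentPrediction",
    "TranslationResult",
    "MotifReport",
    "in_silico_pcr",
    "predict_fragments",
    "length_filter",
    "translate_amplicon",
    "check_diagnostic_residues",
    "default_motifs",
    "MIGRATION_SHIFT_RANGE",
]

logger = logging.getLogger("nrfatools")

#: Capillary-sized fragments migrate consistently 1–4 bp smaller than their
#: true length, so a product of length L is expected between L-4 and L-1.
MIGRATION_SHIFT_RANGE = (1, 4)

DEFAULT_MIN_LENGTH = 230
DEFAULT_MAX_LENGTH = 300


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product on the sense strand (primer-inclusive)."""

    template_id: str
    forward_primer: str
    reverse_primer: str
    start: int  # 0-based half-open on the ungapped sense strand
    end: int
    sequence: str
    fwd_mismatches: MismatchProfile
    rev_mismatches: MismatchProfile

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    def as_nucseq(self) -> NucSequence:
        return NucSequence(
            f"{self.template_id}|{self.forward_primer}|{self.reverse_primer}"
            f"|{self.start}-{self.end}",
            self.sequence,
        )


@dataclass(frozen=True)
class FragmentPrediction:
    """Expected product lengths for one template, with the observed-size
    window after the 1–4 bp migration shift of capillary sizing."""

    template_id: str
    product_lengths: tuple[int, ...]
    migration_adjusted_ranges: tuple[tuple[int, int], ...]
    n_products: int

    @property
    def cross_specific(self) -> bool:
        """More than one product on a single template suggests a secondary
        (potentially off-target) priming site."""
        return self.n_products > 1


def in_silico_pcr(
    template: NucSequence,
    forward: Primer,
    reverse: Primer,
    max_total: int = 2,
    max_three_prime: int = 1,
    max_product_length: int = 2000,
    mode: str = "subset",
) -> list[Amplicon]:
    """Predict PCR products of a primer pair on one template.

    All forward and reverse sites passing the mismatch ceilings are found
    by exhaustive window scan; every upstream-forward/downstream-reverse
    pairing within ``max_product_length`` yields one product. The default
    ceilings (total ≤ 2, at most one in the 3' end) are the outer bound of
    plausible priming. An empty result is a valid outcome.
    """
    if template.is_gapped:
        template = template.degap()
    if forward.orientation != "forward" or reverse.orientation != "reverse":
        raise ConfigError(
            f"in_silico_pcr needs one forward and one reverse primer, got "
            f"{forward.name}={forward.orientation}, {reverse.name}={reverse.orientation}"
        )
    fwd_sites = scan_all_sites(forward, template, max_total, max_three_prime, mode)
    rev_sites = scan_all_sites(reverse, template, max_total, max_three_prime, mode)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            if r.site.start < f.site.end:
                continue  # reverse site must lie strictly downstream
            length = r.site.end - f.site.start
            if length > max_product_length:
                continue
            products.append(
                Amplicon(
                    template_id=template.id,
                    forward_primer=forward.name,
                    reverse_primer=reverse.name,
                    start=f.site.start,
                    end=r.site.end,
                    sequence=template.residues[f.site.start : r.site.end],
                    fwd_mismatches=f,
                    rev_mismatches=r,
                )
            )
    if not products:
        logger.info(
            "no product for %s/%s on template %s",
            forward.name, reverse.name, template.id,
        )
    return products


def predict_fragments(
    templates: Sequence[NucSequence],
    forwards: Sequence[Primer],
    reverse: Primer,
    max_total: int = 2,
    max_three_prime: int = 1,
    max_product_length: int = 2000,
    mode: str = "subset",
) -> list[FragmentPrediction]:
    """Fragment-size predictions per template for a pair or multiplex pool.

    Multiplex pools take union semantics over the forward primers: a
    template carrying sites for several forwards yields one product per
    site pairing. Product lengths are reported sorted, each with its
    migration-adjusted observed-size window [L-4, L-1].
    """
    lo_shift, hi_shift = MIGRATION_SHIFT_RANGE
    out = []
    for template in templates:
        lengths: list[int] = []
        for fwd in forwards:
            for amp in in_silico_pcr(
                template, fwd, reverse, max_total, max_three_prime,
                max_product_length, mode,
            ):
                lengths.append(amp.length_nt)
        lengths.sort()
        out.append(
            FragmentPrediction(
                template_id=template.id,
                product_lengths=tuple(lengths),
                migration_adjusted_ranges=tuple(
                    (L - hi_shift, L - lo_shift) for L in lengths
                ),
                n_products=len(lengths),
            )
        )
    return out


def length_filter(
    seqs: Iterable,
    min_nt: int = DEFAULT_MIN_LENGTH,
    max_nt: int = DEFAULT_MAX_LENGTH,
) -> tuple[list, list]:
    """Keep sequences/amplicons whose length is within [min_nt, max_nt].

    Bounds are inclusive; defaults are the expected nrfA amplicon range of
    230–300 bp. Returns (kept, rejected); idempotent on its kept output.
    """
    if min_nt > max_nt:
        raise ConfigError(f"min length {min_nt} > max length {max_nt}")
    kept, rejected = [], []
    for s in seqs:
        n = s.length_nt if isinstance(s, Amplicon) else len(s)
        (kept if min_nt <= n <= max_nt else rejected).append(s)
    logger.info(
        "length filter [%d, %d]: kept %d, rejected %d",
        min_nt, max_nt, len(kept), len(rejected),
    )
    return kept, rejected


@dataclass(frozen=True)
class TranslationResult:
    peptide: PeptideSequence
    primer_recognized: bool
    primer_mismatches: int
    internal_stop: bool

    @property
    def ok(self) -> bool:
        return self.primer_recognized and not self.internal_stop


def translate_amplicon(
    read: NucSequence | Amplicon,
    forward: Primer,
    max_primer_mismatches: int = 2,
) -> TranslationResult:
    """Translate an amplicon in the frame anchored at the forward primer.

    The read must begin at (or be trimmed to) the forward primer's 5' end,
    which is in-frame with the target gene, so translation is frame 0.
    Reads whose leading bases do not resemble the primer (more than
    ``max_primer_mismatches`` mismatches) are flagged before translation;
    an internal stop codon flags a likely off-target or frameshifted read.
    Nothing is dropped silently — callers decide what to do with flags.
    """
    seq = read.as_nucseq() if isinstance(read, Amplicon) else read
    if seq.is_gapped:
        seq = seq.degap()
    if len(seq) < len(forward):
        raise ValueError(
            f"read {seq.id!r} ({len(seq)} nt) shorter than forward primer "
            f"({len(forward)} nt)"
        )
    head = count_mismatches(forward, seq.residues[: len(forward)])
    peptide = translate(seq, frame_offset=0)
    internal_stop = "*" in peptide.residues[:-1] if len(peptide) > 1 else False
    if internal_stop:
        logger.warning("read %s: internal stop codon after translation", seq.id)
    return TranslationResult(
        peptide=peptide,
        primer_recognized=head.total <= max_primer_mismatches,
        primer_mismatches=head.total,
        internal_stop=internal_stop,
    )


@dataclass(frozen=True)
class MotifReport:
    """Occurrence report of an ordered diagnostic-residue motif list."""

    motifs: tuple[str, ...]
    positions: tuple[int, ...]  # first occurrence, -1 if absent
    in_order: bool

    @property
    def passed(self) -> bool:
        return self.in_order and all(p >= 0 for p in self.positions)


def _motif_match_at(peptide: str, motif: str, offset: int) -> bool:
    return all(
        m == "X" or m == peptide[offset + i] for i, m in enumerate(motif)
    )


def _find_motif(peptide: str, motif: str, start: int = 0) -> int:
    for off in range(start, len(peptide) - len(motif) + 1):
        if _motif_match_at(peptide, motif, off):
            return off
    return -1


def default_motifs() -> list[str]:
    """Diagnostic residue motifs shipped with the package.

    Only the canonical heme c attachment motif CXXCH is a hard default;
    the packaged file is user-editable so the full set of residues
    diagnostic for a given protein family can be supplied.
    """
    text = resources.files("nrfatools").joinpath("data/motifs.txt").read_text()
    motifs = [
        line.strip().upper()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
    return motifs


def check_diagnostic_residues(
    peptide: PeptideSequence, motif_set: Sequence[str] | None = None
) -> MotifReport:
    """Screen a translated amplicon for ordered diagnostic residue motifs.

    Motifs are residue patterns with 'X' as wildcard (e.g. CXXCH). The
    report gives the first occurrence of each motif and whether all
    required motifs occur in order; overall pass requires both.
    """
    motifs = list(motif_set) if motif_set is not None else default_motifs()
    if not motifs:
        raise ConfigError("empty diagnostic motif set")
    residues = peptide.residues
    first = tuple(_find_motif(residues, m) for m in motifs)
    # in-order check: each successive motif must start at/after the
    # previous motif's start (overlapping motifs are tolerated)
    in_order = True
    cursor = 0
    for m in motifs:
        pos = _find_motif(residues, m, cursor)
        if pos < 0:
            in_order = False
            break
        cursor = pos
    return MotifReport(motifs=tuple(motifs), positions=first, in_order=in_order)
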