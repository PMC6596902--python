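"""Locate primer target regions and build positional mismatch profiles.

Matching is set-based over IUPAC codes. In the default *subset* mode a
target base matches when every base it could denote is among the primer's
degenerate options, so an ambiguous target base never gets credit it has
not earned; *intersect* mode only requires overlap. Gaps in the target
window always count as mismatches — a deletion in the annealing site
genuinely impairs priming.

Mismatch positions are reported in primer coordinates, 5'→3' of the primer
itself for both orientations, so "the 3' end" always means the extension
end regardless of strand.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .alphabet import (
    AlphabetError,
    GAP_CHARS,
    IUPAC_SETS,
    NucSequence,
    expand_degenerate,
    reverse_complement,
)
from .io import Primer

__all__ = [
    "TargetSite",
    "MismatchProfile",
    "ScanResult",
    "base_match",
    "count_mismatches",
    "locate_by_alignment",
    "scan_best_window",
    "scan_all_sites",
    "profiles_by_scan",
    "profiles_from_alignment",
]

# 4-bit base masks: one bit per concrete base, OR'd over an ambiguity set.
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_MASK = {code: sum(_BIT[b] for b in bases) for code, bases in IUPAC_SETS.items()}
for _g in GAP_CHARS:
    _CODE_MASK[_g] = 0

_MASK_LUT = np.zeros(128, dtype=np.uint8)
for _code, _mask in _CODE_MASK.items():
    _MASK_LUT[ord(_code)] = _mask
_VALID = np.zeros(128, dtype=bool)
for _code in _CODE_MASK:
    _VALID[ord(_code)] = True


def _encode(residues: str) -> np.ndarray:
    """Encode IUPAC residues as 4-bit masks; gaps encode to 0."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    if not _VALID[raw].all():
        bad = int(np.argmin(_VALID[raw]))
        raise AlphabetError(
            f"invalid nucleotide character {residues[bad]!r} at position {bad}"
        )
    return _MASK_LUT[raw]


@dataclass(frozen=True)
class TargetSite:
    """A primer-sized window on the ungapped sense strand of a template."""

    sequence_id: str
    start: int  # 0-based, half-open, ungapped sense coordinates
    end: int
    strand_matched_as: str  # "forward" | "reverse-complemented-primer"
    window: str  # target bases, degapped


@dataclass(frozen=True)
class MismatchProfile:
    """Mismatch count and positional classification for one primer/site pair.

    ``mismatch_positions`` are 0-based positions in primer coordinates
    (5'→3' of the primer); ``three_prime_count`` is how many fall within
    the primer's terminal ``three_prime_window`` bases.
    """

    site: TargetSite | None
    primer_name: str
    total: int
    mismatch_positions: tuple[int, ...]
    three_prime_count: int

    def reclassify(self, primer_length: int, three_prime_window: int) -> "MismatchProfile":
        """Recompute the 3'-end count for a different window length."""
        cutoff = primer_length - three_prime_window
        tp = sum(1 for p in self.mismatch_positions if p >= cutoff)
        return replace(self, three_prime_count=tp)


@dataclass(frozen=True)
class ScanResult:
    site: TargetSite
    profile: MismatchProfile
    unique: bool  # no other window achieves the same minimal total


def base_match(primer_base: str, target_base: str, mode: str = "subset") -> bool:
    """Set-based IUPAC match of one target base against one primer base.

    Target gaps are mismatches in both modes.
    """
    if mode not in ("subset", "intersect"):
        raise ValueError(f"mode must be 'subset' or 'intersect', got {mode!r}")
    tb = target_base.upper().replace("U", "T")
    if tb in GAP_CHARS:
        expand_degenerate(primer_base)  # still validate the primer side
        return False
    p = expand_degenerate(primer_base)
    t = expand_degenerate(tb)
    return t <= p if mode == "subset" else bool(t & p)


def _oriented_probe(primer: Primer) -> str:
    """Primer sequence as it reads on the sense strand."""
    if primer.orientation == "reverse":
        return reverse_complement(primer.sequence)
    return primer.sequence


def _window_to_primer_pos(primer: Primer, window_index: int) -> int:
    """Map a sense-strand window index to a primer 5'→3' coordinate."""
    if primer.orientation == "reverse":
        return len(primer) - 1 - window_index
    return window_index


def _mismatch_window_indices(
    probe_masks: np.ndarray, window_masks: np.ndarray, mode: str
) -> np.ndarray:
    if mode == "subset":
        ok = (window_masks & ~probe_masks) == 0
    elif mode == "intersect":
        ok = (window_masks & probe_masks) != 0
    else:
        raise ValueError(f"mode must be 'subset' or 'intersect', got {mode!r}")
    ok &= window_masks != 0  # gaps never match
    return np.flatnonzero(~ok)


def count_mismatches(
    primer: Primer,
    window: str,
    mode: str = "subset",
    site: TargetSite | None = None,
) -> MismatchProfile:
    """Per-position mismatch profile of a primer against a same-length window.

    The window is given on the sense strand; for a reverse primer the
    comparison is against the primer's reverse complement and positions are
    mapped back into primer 5'→3' coordinates.
    """
    window = window.upper().replace("U", "T")
    if len(window) != len(primer):
        raise ValueError(
            f"window length {len(window)} != primer {primer.name!r} "
            f"length {len(primer)}"
        )
    probe = _encode(_oriented_probe(primer))
    target = _encode(window)
    bad = _mismatch_window_indices(probe, target, mode)
    positions = tuple(sorted(_window_to_primer_pos(primer, int(i)) for i in bad))
    cutoff = len(primer) - primer.three_prime_window
    tp = sum(1 for p in positions if p >= cutoff)
    return MismatchProfile(
        site=site,
        primer_name=primer.name,
        total=len(positions),
        mismatch_positions=positions,
        three_prime_count=tp,
    )


def locate_by_alignment(
    primer: Primer,
    gapped_seq: NucSequence,
    column_range: tuple[int, int],
    mode: str = "subset",
) -> MismatchProfile:
    """Profile a primer against fixed columns of a multiple alignment.

    ``column_range`` (0-based, half-open) must span exactly the primer's
    target columns in the shared alignment coordinate system. Gap
    characters inside the window count as mismatches at their primer
    positions. If the column range does not have primer length (the
    alignment carries an insertion column the primer lacks), the site is
    reported as a structural mismatch with total = primer length.
    """
    lo, hi = column_range
    if not (0 <= lo < hi <= len(gapped_seq.residues)):
        raise ValueError(
            f"column range {column_range} outside alignment of width "
            f"{len(gapped_seq.residues)}"
        )
    window = gapped_seq.residues[lo:hi]
    degapped = "".join(ch for ch in window if ch not in GAP_CHARS)
    # ungapped sense coordinates of the window
    start = sum(1 for ch in gapped_seq.residues[:lo] if ch not in GAP_CHARS)
    site = TargetSite(
        sequence_id=gapped_seq.id,
        start=start,
        end=start + len(degapped),
        strand_matched_as=(
            "forward" if primer.orientation == "forward"
            else "reverse-complemented-primer"
        ),
        window=degapped,
    )
    if hi - lo != len(primer):
        return MismatchProfile(
            site=site,
            primer_name=primer.name,
            total=len(primer),
            mismatch_positions=tuple(range(len(primer))),
            three_prime_count=primer.three_prime_window,
        )
    return count_mismatches(primer, window, mode=mode, site=site)


def _window_totals(
    primer: Primer, residues: str, mode: str
) -> np.ndarray:
    """Mismatch total of the oriented primer at every window offset."""
    probe = _encode(_oriented_probe(primer))
    target = _encode(residues)
    L = len(probe)
    windows = np.lib.stride_tricks.sliding_window_view(target, L)
    if mode == "subset":
        ok = (windows & ~probe[None, :]) == 0
    else:
        ok = (windows & probe[None, :]) != 0
    ok &= windows != 0
    return (L - ok.sum(axis=1)).astype(np.int64)


def scan_best_window(
    primer: Primer, seq: NucSequence, mode: str = "subset"
) -> ScanResult:
    """Slide the oriented primer over the sense strand; return the best window.

    For reverse primers the reverse complement of the primer is slid.
    Ties are broken leftmost and flagged as non-unique. The input must be
    ungapped (degap first) and at least primer length.
    """
    if seq.is_gapped:
        seq = seq.degap()
    if len(seq) < len(primer):
        raise ValueError(
            f"sequence {seq.id!r} ({len(seq)} nt) shorter than primer "
            f"{primer.name!r} ({len(primer)} nt)"
        )
    totals = _window_totals(primer, seq.residues, mode)
    best = int(totals.argmin())  # argmin is leftmost on ties
    unique = int((totals == totals[best]).sum()) == 1
    window = seq.residues[best : best + len(primer)]
    site = TargetSite(
        sequence_id=seq.id,
        start=best,
        end=best + len(primer),
        strand_matched_as=(
            "forward" if primer.orientation == "forward"
            else "reverse-complemented-primer"
        ),
        window=window,
    )
    profile = count_mismatches(primer, window, mode=mode, site=site)
    return ScanResult(site=site, profile=profile, unique=unique)


def scan_all_sites(
    primer: Primer,
    seq: NucSequence,
    max_total: int,
    max_three_prime: int | None = None,
    mode: str = "subset",
) -> list[MismatchProfile]:
    """All windows whose mismatch profile passes the given ceilings.

    Used for in-silico PCR site finding, where secondary near-match sites
    (potential cross-specificity) matter as much as the best one.
    """
    if seq.is_gapped:
        seq = seq.degap()
    if len(seq) < len(primer):
        return []
    totals = _window_totals(primer, seq.residues, mode)
    hits = []
    for off in np.flatnonzero(totals <= max_total):
        off = int(off)
        window = seq.residues[off : off + len(primer)]
        site = TargetSite(
            sequence_id=seq.id,
            start=off,
            end=off + len(primer),
            strand_matched_as=(
                "forward" if primer.orientation == "forward"
                else "reverse-complemented-primer"
            ),
            window=window,
        )
        profile = count_mismatches(primer, window, mode=mode, site=site)
        if max_three_prime is not None and profile.three_prime_count > max_three_prime:
            continue
        hits.append(profile)
    return hits


def profiles_by_scan(
    primer: Primer, seqs: Sequence[NucSequence], mode: str = "subset"
) -> dict[str, MismatchProfile]:
    """Best-window profile per sequence (scan mode, for unaligned inputs)."""
    return {s.id: scan_best_window(primer, s, mode=mode).profile for s in seqs}


def profiles_from_alignment(
    primer: Primer,
    seqs: Sequence[NucSequence],
    column_range: tuple[int, int],
    mode: str = "subset",
) -> dict[str, MismatchProfile]:
    """Profile per sequence at fixed alignment columns (aligned mode)."""
    return {
        s.id: locate_by_alignment(primer, s, column_range, mode=mode) for s in seqs
    }
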