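"""Clade-structured synthetic reference panels with planted primer sites.

Every statistic the toolkit computes — mismatch totals, 3'-end
classification, clade coverage, product sizes, in-frame translation — has
an exact oracle on these panels because the truth is planted, not
estimated. Sequences embed a forward primer site, a spacer with codon
structure (random sense codons, no stops in the frame anchored at the
forward site, so translation QC is meaningful) and the reverse
complement of a reverse primer site, inside random flanks. A self-scan
guarantees that no unplanted window approaches primer quality: every
off-site window carries at least 5 mismatches, comfortably beyond the
most permissive coverage criterion, so scan-mode matching recovers the
planted profile and nothing else.

These panels emulate the clade structure and unequal clade sizes of real
reference sets but not phylogenetic covariance between sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet import IUPAC_SETS, NucSequence, reverse_complement, translate
from .alphabet import _CODON_TO_AA  # sense/stop codon table
from .coverage import ALL_CLADES, CRITERIA, CRITERION_IDS, CoverageTable
from .io import CladeMap, Primer
from .match import _window_totals

__all__ = [
    "UnsatisfiableSpecError",
    "PlantedProfile",
    "PlantSpec",
    "ReferenceSet",
    "Miniature",
    "DEMO_FORWARD",
    "DEMO_REVERSE",
    "generate_reference_set",
    "miniature_panel",
    "reference_scale_panel",
    "expected_coverage_from_truth",
    "MINIATURE_SCHEDULE",
]

#: Demo primers used throughout the synthetic fixtures. The forward primer
#: encodes six unambiguous codons, C-G-A-C-H-W, so a planted site carries a
#: genuine in-frame heme-attachment motif (CXXCH at residue 0) and can never
#: introduce a stop; the reverse primer's reverse complement is stop-free in
#: every reading frame for the same reason.
DEMO_FORWARD = Primer("synfwd", "TGYGGNGCNTGYCAYTGG", "forward")
DEMO_REVERSE = Primer("synrev", "YTGRAANGGRTCCATNGC", "reverse")

#: Minimum mismatches enforced at every unplanted window during self-scan.
BACKGROUND_FLOOR = 5

#: In-frame codons C-P-F-C-H planted in the spacer (codon 7 relative to the
#: forward primer's 5' end) whenever a forward site is present, so every
#: planted product carries an interior heme-attachment motif (CXXCH)
#: independent of primer-region mismatches — mirroring diagnostic residues
#: that sit between conserved domains rather than inside the priming site.
#: Codon choices keep the motif window ≥4 mismatches away from the demo
#: forward primer so the background self-scan is not violated; stop-free in
#: all three reading frames.
DIAGNOSTIC_SPACER_MOTIF = "TGTCCATTTTGTCAT"
_MOTIF_OFFSET_NT = 21

_BASES = ("A", "C", "G", "T")
_SENSE_CODONS = tuple(c for c, aa in _CODON_TO_AA.items() if aa != "*")


class UnsatisfiableSpecError(ValueError):
    """A plant specification cannot be realized (geometry or retry limit)."""


@dataclass(frozen=True)
class PlantedProfile:
    """Planted per-sequence mismatch positions, in primer 5'→3' coordinates.

    ``None`` for a primer means the site is absent from the sequence
    entirely (the sequence then fails every coverage criterion for that
    primer).
    """

    fwd_positions: tuple[int, ...] | None = ()
    rev_positions: tuple[int, ...] | None = ()


@dataclass
class PlantSpec:
    """One clade's worth of synthetic sequences."""

    clade: str
    profiles: list[PlantedProfile]
    product_length: int = 279  # outer-coordinate span, within the 230-300 range
    upstream_flank: int = 30
    downstream_flank: int = 21
    gc: float = 0.5


@dataclass
class ReferenceSet:
    sequences: list[NucSequence]
    clade_map: CladeMap
    truth: pd.DataFrame  # one row per (sequence, primer)
    forward: Primer
    reverse: Primer
    fwd_columns: tuple[int, int] | None = None  # set when geometry is uniform
    rev_columns: tuple[int, int] | None = None


def _mismatch_choices(primer: Primer, pos: int) -> tuple[str, ...]:
    allowed = IUPAC_SETS[primer.sequence[pos]]
    return tuple(b for b in _BASES if b not in allowed)


def _validate_positions(primer: Primer, positions: tuple[int, ...]) -> None:
    for p in positions:
        if not 0 <= p < len(primer):
            raise UnsatisfiableSpecError(
                f"planted position {p} outside primer {primer.name!r} "
                f"of length {len(primer)}"
            )
        if not _mismatch_choices(primer, p):
            raise UnsatisfiableSpecError(
                f"primer {primer.name!r} position {p} is fully degenerate (N); "
                f"no mismatching base exists"
            )


def _concrete_site(primer: Primer, positions: tuple[int, ...], rng) -> str:
    """One concrete expansion of the primer with mismatches planted."""
    site = [
        rng.choice(sorted(IUPAC_SETS[ch])) for ch in primer.sequence
    ]
    for p in positions:
        site[p] = rng.choice(_mismatch_choices(primer, p))
    return "".join(site)


def _random_bases(n: int, gc: float, rng) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=n, p=probs)) if n else ""


def _background_ok(
    primer: Primer, residues: str, planted_offset: int | None, planted_total: int
) -> bool:
    totals = _window_totals(primer, residues, "subset")
    floor = max(BACKGROUND_FLOOR, planted_total + 1)
    for off, t in enumerate(totals):
        if planted_offset is not None and off == planted_offset:
            if t != planted_total:
                return False  # planted site corrupted (shouldn't happen)
            continue
        if t < floor:
            return False
    return True


def _build_sequence(
    spec: PlantSpec,
    profile: PlantedProfile,
    forward: Primer,
    reverse: Primer,
    seq_id: str,
    rng,
    max_tries: int = 80,
) -> tuple[NucSequence, dict]:
    Lf, Lr, PL = len(forward), len(reverse), spec.product_length
    if profile.fwd_positions is not None and profile.rev_positions is not None:
        if PL < Lf + Lr:
            raise UnsatisfiableSpecError(
                f"product length {PL} < combined primer lengths {Lf + Lr}"
            )
    if profile.fwd_positions is not None:
        _validate_positions(forward, profile.fwd_positions)
    if profile.rev_positions is not None:
        _validate_positions(reverse, profile.rev_positions)

    for _ in range(max_tries):
        n_codons = -(-PL // 3)
        product = "".join(rng.choice(_SENSE_CODONS, size=n_codons))[:PL]
        body = list(product)
        if profile.fwd_positions is not None:
            body[:Lf] = _concrete_site(forward, profile.fwd_positions, rng)
            motif_end = _MOTIF_OFFSET_NT + len(DIAGNOSTIC_SPACER_MOTIF)
            if _MOTIF_OFFSET_NT >= Lf and motif_end <= PL - Lr:
                body[_MOTIF_OFFSET_NT:motif_end] = DIAGNOSTIC_SPACER_MOTIF
        if profile.rev_positions is not None:
            rev_site = _concrete_site(reverse, profile.rev_positions, rng)
            body[PL - Lr :] = reverse_complement(rev_site)
        product = "".join(body)
        if profile.fwd_positions is not None:
            # frame anchored at the forward 5' end must be stop-free
            if "*" in translate(product).residues:
                continue
        residues = (
            _random_bases(spec.upstream_flank, spec.gc, rng)
            + product
            + _random_bases(spec.downstream_flank, spec.gc, rng)
        )
        fwd_off = spec.upstream_flank if profile.fwd_positions is not None else None
        rev_off = (
            spec.upstream_flank + PL - Lr if profile.rev_positions is not None else None
        )
        if not _background_ok(
            forward, residues, fwd_off,
            len(profile.fwd_positions or ()),
        ):
            continue
        if not _background_ok(
            reverse, residues, rev_off,
            len(profile.rev_positions or ()),
        ):
            continue
        seq = NucSequence(seq_id, residues)
        geometry = {
            "fwd_start": fwd_off,
            "rev_start": rev_off,
            "product_length": PL
            if profile.fwd_positions is not None and profile.rev_positions is not None
            else None,
        }
        return seq, geometry
    raise UnsatisfiableSpecError(
        f"could not realize planted profile for {seq_id!r} in {max_tries} tries"
    )


def _truth_rows(
    seq_id: str, clade: str, primer: Primer, positions: tuple[int, ...] | None,
    start: int | None, product_length: int | None,
) -> dict:
    present = positions is not None
    cutoff = len(primer) - primer.three_prime_window
    return {
        "seq_id": seq_id,
        "clade": clade,
        "primer": primer.name,
        "site_present": present,
        "start": start if present else -1,
        "end": (start + len(primer)) if present else -1,
        "total": len(positions) if present else len(primer),
        "positions": ",".join(map(str, positions)) if present else "",
        "three_prime_count": (
            sum(1 for p in positions if p >= cutoff) if present
            else primer.three_prime_window
        ),
        "product_length": product_length if product_length else -1,
    }


def generate_reference_set(
    specs: list[PlantSpec],
    seed: int,
    forward: Primer = DEMO_FORWARD,
    reverse: Primer = DEMO_REVERSE,
) -> ReferenceSet:
    """Generate a clade-structured panel with planted, verified primer sites.

    Deterministic for a given seed. Each sequence is self-scanned after
    construction: any unplanted window within ``BACKGROUND_FLOOR``
    mismatches of either primer triggers a resample, so the planted
    profile is provably the best (and only near-match) site.
    """
    rng = np.random.default_rng(seed)
    sequences: list[NucSequence] = []
    clade_assign: dict[str, str] = {}
    rows: list[dict] = []
    uniform = len({(s.upstream_flank, s.product_length) for s in specs}) == 1
    for spec in specs:
        if not spec.profiles:
            raise UnsatisfiableSpecError(f"clade {spec.clade!r}: no profiles")
        for i, profile in enumerate(spec.profiles):
            seq_id = f"{spec.clade}_{i:03d}"
            seq, geom = _build_sequence(spec, profile, forward, reverse, seq_id, rng)
            sequences.append(seq)
            clade_assign[seq_id] = spec.clade
            rows.append(
                _truth_rows(seq_id, spec.clade, forward, profile.fwd_positions,
                            geom["fwd_start"], geom["product_length"])
            )
            rows.append(
                _truth_rows(seq_id, spec.clade, reverse, profile.rev_positions,
                            geom["rev_start"], geom["product_length"])
            )
    fwd_cols = rev_cols = None
    if uniform:
        up, pl = specs[0].upstream_flank, specs[0].product_length
        fwd_cols = (up, up + len(forward))
        rev_cols = (up + pl - len(reverse), up + pl)
    return ReferenceSet(
        sequences=sequences,
        clade_map=CladeMap(clade_assign),
        truth=pd.DataFrame(rows),
        forward=forward,
        reverse=reverse,
        fwd_columns=fwd_cols,
        rev_columns=rev_cols,
    )


def expected_coverage_from_truth(
    truth: pd.DataFrame,
    primer: Primer,
    three_prime_window: int | None = None,
) -> CoverageTable:
    """The coverage table implied by planted truth, by direct counting.

    Uses only the planted mismatch positions and the criterion
    definitions — no sequence matching — so it is an independent oracle
    for the full generate → match → coverage pipeline.
    """
    w = three_prime_window if three_prime_window is not None else primer.three_prime_window
    cutoff = len(primer) - w
    sub = truth[truth["primer"] == primer.name]
    counts: dict[str, dict[str, int]] = {}
    denom: dict[str, int] = {}
    for _, row in sub.iterrows():
        clade = row["clade"]
        denom[clade] = denom.get(clade, 0) + 1
        c = counts.setdefault(clade, {cid: 0 for cid in CRITERION_IDS})
        if not row["site_present"]:
            continue
        positions = (
            tuple(int(x) for x in row["positions"].split(",")) if row["positions"] else ()
        )
        total = len(positions)
        tp = sum(1 for p in positions if p >= cutoff)
        for cid, crit in CRITERIA.items():
            if total <= crit.max_total and tp <= crit.max_three_prime:
                c[cid] += 1
    clades = sorted(denom)
    df = pd.DataFrame.from_dict(
        {
            clade: [100.0 * counts[clade][cid] / denom[clade] for cid in CRITERION_IDS]
            for clade in clades
        },
        orient="index",
        columns=list(CRITERION_IDS),
    )
    pooled_n = sum(denom.values())
    df.loc[ALL_CLADES] = [
        100.0 * sum(counts[c][cid] for c in clades) / pooled_n for cid in CRITERION_IDS
    ]
    return CoverageTable(primer_name=primer.name, df=df, denominators=denom)


# ---------------------------------------------------------------------------
# Fixed miniature panel: 6 clades x 10 sequences with a planted coverage
# table known in advance. The schedule lists (total, three_prime_count)
# pairs relative to the default 3-nt 3' window; None = site absent.

MINIATURE_SCHEDULE: dict[str, list[tuple[int, int] | None]] = {
    "M1": [(0, 0)] * 10,
    "M2": [(0, 0)] * 5 + [(1, 0)] * 5,
    "M3": [(0, 0)] * 2 + [(1, 1)] * 4 + [(2, 0)] * 4,
    "M4": [(2, 2)] * 5 + [(3, 0)] * 5,
    "M5": [None] * 10,
    "M6": [(0, 0)] * 2 + [(1, 0)] * 3 + [(2, 1)] * 3 + [(2, 2)] * 2,
}

# deterministic position pools for the demo forward primer: interior
# positions avoid its fully degenerate N columns (5 and 8) and the
# default 3-nt 3' window; terminal positions fill from the 3' end inward
_FWD_INTERIOR = (0, 1, 2, 3, 4, 6)
_FWD_TERMINAL = (17, 16, 15)


def _positions_for(total: int, three_prime: int) -> tuple[int, ...]:
    if three_prime > total:
        raise ValueError("three_prime_count cannot exceed total")
    interior = _FWD_INTERIOR[: total - three_prime]
    terminal = _FWD_TERMINAL[:three_prime]
    return tuple(sorted(interior + terminal))


@dataclass
class Miniature:
    panel: ReferenceSet
    expected: CoverageTable  # for the forward primer, default 3' window


def miniature_panel(seed: int) -> Miniature:
    """A 60-sequence, 6-clade panel whose coverage table is known exactly.

    The planted (total, 3'-count) schedule is fixed; the seed varies only
    the concrete backgrounds and degenerate-base choices, so the expected
    table is identical for every seed. Running the full pipeline
    (match → coverage) must reproduce all 36 cells exactly.
    """
    specs = []
    for clade, schedule in MINIATURE_SCHEDULE.items():
        profiles = [
            PlantedProfile(fwd_positions=None, rev_positions=())
            if entry is None
            else PlantedProfile(fwd_positions=_positions_for(*entry), rev_positions=())
            for entry in schedule
        ]
        specs.append(PlantSpec(clade=clade, profiles=profiles))
    panel = generate_reference_set(specs, seed=seed)
    expected = expected_coverage_from_truth(panel.truth, panel.forward)
    return Miniature(panel=panel, expected=expected)


# ---------------------------------------------------------------------------
# Full-scale panel: 271 sequences over 18 clades (A..R) with unequal
# membership, mirroring the shape of a curated functional-gene reference
# panel. Planted profiles are drawn randomly per sequence, and the truth
# table provides the exact expected coverage.

_PANEL_CLADE_SIZES = {
    "A": 25, "B": 17, "C": 12, "D": 20, "E": 19, "F": 8, "G": 12, "H": 38,
    "I": 23, "J": 9, "K": 23, "L": 14, "M": 6, "N": 11, "O": 7, "P": 4,
    "Q": 11, "R": 12,
}


def _random_profile(primer: Primer, rng, p_absent: float = 0.08) -> tuple[int, ...] | None:
    if rng.random() < p_absent:
        return None
    total = int(rng.choice([0, 1, 2, 3, 4], p=[0.45, 0.2, 0.15, 0.1, 0.1]))
    if total == 0:
        return ()
    three_prime = int(rng.integers(0, min(total, primer.three_prime_window) + 1))
    cutoff = len(primer) - primer.three_prime_window
    interior_pool = [
        p for p in range(cutoff)
        if IUPAC_SETS[primer.sequence[p]] != frozenset(_BASES)
    ]
    terminal_pool = [
        p for p in range(cutoff, len(primer))
        if IUPAC_SETS[primer.sequence[p]] != frozenset(_BASES)
    ]
    three_prime = min(three_prime, len(terminal_pool))
    interior = rng.choice(interior_pool, size=total - three_prime, replace=False)
    terminal = rng.choice(terminal_pool, size=three_prime, replace=False)
    return tuple(sorted(int(x) for x in (*interior, *terminal)))


def reference_scale_panel(seed: int) -> ReferenceSet:
    """A 271-sequence, 18-clade synthetic panel with planted random profiles."""
    rng = np.random.default_rng(seed)
    specs = []
    for clade, n in _PANEL_CLADE_SIZES.items():
        profiles = [
            PlantedProfile(
                fwd_positions=_random_profile(DEMO_FORWARD, rng),
                rev_positions=_random_profile(DEMO_REVERSE, rng),
            )
            for _ in range(n)
        ]
        specs.append(PlantSpec(clade=clade, profiles=profiles))
    return generate_reference_set(specs, seed=int(rng.integers(0, 2**31 - 1)))
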