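"""Clade-stratified percent coverage under six mismatch criteria.

Coverage is the percent of reference sequences in a clade whose primer
target region matches the primer under a stated criterion. The six
criteria combine a mismatch-count ceiling with a positional rule on the
primer's 3' end, where mismatches disproportionately abort extension:

==========  =========  ==============
criterion   max total  max in 3' end
==========  =========  ==============
c0          0          (moot)
c1          1          unlimited
c2          2          unlimited
c1_no3p     1          0
c2_no3p     2          0
c2_one3p    2          1
==========  =========  ==============

Criteria are cumulative ("at most k mismatches"), so a perfect match
passes all six and within any row c0 ≤ c1 ≤ c2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import CladeMap, Primer, round_half_up
from .match import MismatchProfile

__all__ = [
    "MatchCriterion",
    "CRITERIA",
    "CRITERION_IDS",
    "CRITERION_LABELS",
    "CoverageTable",
    "passes",
    "clade_coverage",
    "compare_primers",
    "sweep_three_prime_window",
]

ALL_CLADES = "All Clades"


@dataclass(frozen=True)
class MatchCriterion:
    id: str
    max_total: int
    max_three_prime: float  # math.inf = no positional rule


CRITERIA: dict[str, MatchCriterion] = {
    "c0": MatchCriterion("c0", 0, math.inf),
    "c1": MatchCriterion("c1", 1, math.inf),
    "c2": MatchCriterion("c2", 2, math.inf),
    "c1_no3p": MatchCriterion("c1_no3p", 1, 0),
    "c2_no3p": MatchCriterion("c2_no3p", 2, 0),
    "c2_one3p": MatchCriterion("c2_one3p", 2, 1),
}

CRITERION_IDS = tuple(CRITERIA)

CRITERION_LABELS = {
    "c0": "0 mismatches",
    "c1": "1 mismatch",
    "c2": "2 mismatches",
    "c1_no3p": "1 mismatch not in the 3' end",
    "c2_no3p": "2 mismatches not in 3' end",
    "c2_one3p": "2 mismatches with one allowed in 3' end",
}


def passes(
    profile: MismatchProfile, criterion: MatchCriterion, cumulative: bool = True
) -> bool:
    """Whether a mismatch profile satisfies a criterion.

    Cumulative (default): total ≤ max_total and 3'-end count ≤
    max_three_prime. The non-default exact mode requires total ==
    max_total instead.
    """
    total_ok = (
        profile.total <= criterion.max_total
        if cumulative
        else profile.total == criterion.max_total
    )
    return total_ok and profile.three_prime_count <= criterion.max_three_prime


@dataclass
class CoverageTable:
    """Clade × criterion percent-coverage table for one primer.

    ``df`` holds full-precision percentages (clade rows, criterion
    columns, plus an 'All Clades' row pooled over all sequences — never
    the mean of clade rows). Rounding to the one-decimal presentation
    happens only in :meth:`rounded`.
    """

    primer_name: str
    df: pd.DataFrame
    denominators: dict[str, int]

    @property
    def clades(self) -> list[str]:
        return [c for c in self.df.index if c != ALL_CLADES]

    @property
    def all_clades_row(self) -> pd.Series:
        return self.df.loc[ALL_CLADES]

    def rounded(self) -> pd.DataFrame:
        return self.df.map(lambda v: round_half_up(v, 1))

    def check_invariants(self) -> None:
        """Assert the monotonicity relations implied by cumulative criteria."""
        for clade, row in self.df.iterrows():
            assert (row >= -1e-9).all() and (row <= 100 + 1e-9).all(), clade
            assert row["c0"] <= row["c1"] + 1e-9 <= row["c2"] + 2e-9, clade
            assert row["c1_no3p"] <= row["c1"] + 1e-9, clade
            assert row["c2_no3p"] <= row["c2_one3p"] + 1e-9 <= row["c2"] + 2e-9, clade
            assert row["c1_no3p"] <= row["c2_no3p"] + 1e-9, clade


def clade_coverage(
    profiles: Mapping[str, MismatchProfile] | Sequence[MismatchProfile],
    clades: CladeMap,
    primer: Primer,
    cumulative: bool = True,
) -> CoverageTable:
    """Build the clade-stratified six-criterion coverage table.

    Expects exactly one profile per sequence for this primer; every
    sequence id must be present in the clade map. Percentages are
    100 × passing / clade size; the All-Clades row uses the pooled
    denominator.
    """
    if not isinstance(profiles, Mapping):
        profiles = {p.site.sequence_id: p for p in profiles}
    if not profiles:
        raise ValueError("no mismatch profiles supplied")
    missing = clades.missing_ids(profiles.keys())
    if missing:
        raise KeyError(
            "sequence id(s) missing from clade map: " + ", ".join(sorted(missing)[:10])
        )
    counts: dict[str, dict[str, int]] = {}
    denominators: dict[str, int] = {}
    for sid, profile in profiles.items():
        clade = clades[sid]
        denominators[clade] = denominators.get(clade, 0) + 1
        row = counts.setdefault(clade, {cid: 0 for cid in CRITERION_IDS})
        for cid, criterion in CRITERIA.items():
            if passes(profile, criterion, cumulative=cumulative):
                row[cid] += 1
    for clade, n in denominators.items():
        if n == 0:
            raise ValueError(f"clade {clade!r} is empty")
    clade_order = sorted(denominators)
    data = {
        clade: [100.0 * counts[clade][cid] / denominators[clade] for cid in CRITERION_IDS]
        for clade in clade_order
    }
    pooled_n = sum(denominators.values())
    pooled = [
        100.0 * sum(counts[c][cid] for c in clade_order) / pooled_n
        for cid in CRITERION_IDS
    ]
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(CRITERION_IDS))
    df.loc[ALL_CLADES] = pooled
    return CoverageTable(primer_name=primer.name, df=df, denominators=denominators)


def compare_primers(tables: Sequence[CoverageTable]) -> pd.DataFrame:
    """Tidy long-format comparison of coverage tables across primers.

    Returns columns (primer, clade, criterion, percent, n,
    best_primer) where best_primer marks, per clade × criterion, the
    primer with the highest coverage — surfacing complementarity between
    forward primers (one primer rescuing a clade the other misses).
    """
    if not tables:
        raise ValueError("no coverage tables supplied")
    universe = set(tables[0].clades)
    for t in tables[1:]:
        if set(t.clades) != universe:
            raise ValueError(
                f"clade universe mismatch between {tables[0].primer_name!r} "
                f"and {t.primer_name!r}"
            )
    rows = []
    for t in tables:
        for clade in list(t.clades) + [ALL_CLADES]:
            n = t.denominators.get(clade, sum(t.denominators.values()))
            for cid in CRITERION_IDS:
                rows.append(
                    {
                        "primer": t.primer_name,
                        "clade": clade,
                        "criterion": cid,
                        "percent": float(t.df.loc[clade, cid]),
                        "n": n,
                    }
                )
    long = pd.DataFrame(rows)
    best = (
        long.loc[long.groupby(["clade", "criterion"])["percent"].idxmax()]
        .set_index(["clade", "criterion"])["primer"]
    )
    long["best_primer"] = [
        best.loc[(clade, crit)] for clade, crit in zip(long["clade"], long["criterion"])
    ]
    return long


def sweep_three_prime_window(
    profiles: Mapping[str, MismatchProfile],
    clades: CladeMap,
    primer: Primer,
    windows: Sequence[int] = (2, 3, 4),
    cumulative: bool = True,
) -> dict[int, CoverageTable]:
    """Coverage tables under alternative 3'-end window lengths.

    Published coverage tables rarely state how many terminal bases count
    as "the 3' end"; this sweep recomputes the position-conditional
    columns for each candidate window so the one that reproduces a
    reference table can be identified and documented.
    """
    out = {}
    for w in windows:
        reclassified = {
            sid: p.reclassify(len(primer), w) for sid, p in profiles.items()
        }
        out[w] = clade_coverage(
            reclassified, clades, primer.with_window(w), cumulative=cumulative
        )
    return out
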