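"""Position frequency matrices and information content for target regions.

The per-column conservation measure is the sequence-logo convention:
IC(pos) = 2 − H(pos) bits, with H the Shannon entropy of the normalized
base frequencies at that column, and per-base stack heights equal to
frequency × IC. Gaps are excluded from the normalization (logos stack
nucleotides only) but are tallied and reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alphabet import GAP_CHARS, IUPAC_SETS

__all__ = [
    "PositionFrequencyMatrix",
    "column_frequencies",
    "information_content",
    "render_logo",
]

logger = logging.getLogger("nrfatools")

_BASES = ("A", "C", "G", "T")


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts over a set of equal-length windows.

    ``counts`` is a (length × 4) DataFrame with columns A,C,G,T. Counts
    are floats because ambiguity codes may be spread fractionally over
    their expansions. At every position
    counts.sum + gap_count + ambiguous_count == n_sequences.
    """

    counts: pd.DataFrame
    gap_counts: np.ndarray
    ambiguous_counts: np.ndarray
    n_sequences: int

    @property
    def length(self) -> int:
        return len(self.counts)


def column_frequencies(
    windows: Sequence[str], ambiguity: str = "fractional"
) -> PositionFrequencyMatrix:
    """Count bases per column across equal-length windows.

    ``ambiguity``: 'fractional' spreads each ambiguity code evenly over
    its expansion (R adds 0.5 to A and 0.5 to G); 'exclude' tallies
    ambiguous observations separately without crediting any base. Gaps
    are always tallied separately.
    """
    if not windows:
        raise ValueError("no windows supplied")
    if ambiguity not in ("fractional", "exclude"):
        raise ValueError(f"ambiguity must be 'fractional' or 'exclude', got {ambiguity!r}")
    length = len(windows[0])
    for i, w in enumerate(windows):
        if len(w) != length:
            raise ValueError(
                f"ragged input: window {i} has length {len(w)}, expected {length}"
            )
    counts = np.zeros((length, 4), dtype=float)
    gaps = np.zeros(length, dtype=float)
    ambig = np.zeros(length, dtype=float)
    base_idx = {b: i for i, b in enumerate(_BASES)}
    for w in windows:
        for pos, ch in enumerate(w.upper().replace("U", "T")):
            if ch in GAP_CHARS:
                gaps[pos] += 1
            elif ch in base_idx:
                counts[pos, base_idx[ch]] += 1
            elif ch in IUPAC_SETS:
                if ambiguity == "fractional":
                    bases = IUPAC_SETS[ch]
                    share = 1.0 / len(bases)
                    for b in bases:
                        counts[pos, base_idx[b]] += share
                else:
                    ambig[pos] += 1
            else:
                raise ValueError(f"invalid character {ch!r} at window position {pos}")
    return PositionFrequencyMatrix(
        counts=pd.DataFrame(counts, columns=list(_BASES)),
        gap_counts=gaps,
        ambiguous_counts=ambig,
        n_sequences=len(windows),
    )


def information_content(
    pfm: PositionFrequencyMatrix, small_sample_correction: bool = False
) -> pd.DataFrame:
    """Per-position information content (bits) and per-base stack heights.

    Returns a DataFrame with columns ic, height_A..height_T. The optional
    small-sample correction subtracts e(n) = 3 / (2·ln2·n) from each
    column's IC (floored at 0), n being the non-gap observation count at
    that column; with hundreds of sequences it is negligible, so it is
    off by default in favour of determinism across inputs.

    A column with zero non-gap, non-ambiguous observations has undefined
    IC; it is reported as 0 with a warning.
    """
    rows = []
    for pos in range(pfm.length):
        col = pfm.counts.iloc[pos].to_numpy()
        n_obs = col.sum()
        if n_obs <= 0:
            logger.warning(
                "position %d: no non-gap observations; information content "
                "reported as 0", pos,
            )
            rows.append({"ic": 0.0, **{f"height_{b}": 0.0 for b in _BASES}})
            continue
        freqs = col / n_obs
        entropy = -sum(p * math.log2(p) for p in freqs if p > 0)
        ic = 2.0 - entropy
        if small_sample_correction:
            ic = max(0.0, ic - 3.0 / (2.0 * math.log(2) * n_obs))
        rows.append(
            {"ic": ic, **{f"height_{b}": f * ic for b, f in zip(_BASES, freqs)}}
        )
    return pd.DataFrame(rows)


def render_logo(ic_df: pd.DataFrame, path, title: str = "") -> None:
    """Minimal sequence-logo rendering: stacked letters scaled to heights.

    A thin presentation layer over the PFM/IC computation — the TSV
    outputs are the primary artifact.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(ic_df)), 2.5))
    for pos, row in ic_df.iterrows():
        bottom = 0.0
        stacked = sorted(_BASES, key=lambda b: row[f"height_{b}"])
        for b in stacked:
            h = row[f"height_{b}"]
            if h <= 0:
                continue
            ax.text(
                pos + 0.5, bottom + h / 2, b,
                ha="center", va="center", color=colors[b],
                fontsize=14, fontweight="bold",
                # scale glyph to its share of the stack
                transform=ax.transData,
            )
            ax.bar(pos + 0.5, h, bottom=bottom, width=0.9, alpha=0.08, color=colors[b])
            bottom += h
    ax.set_xlim(0, len(ic_df))
    ax.set_ylim(0, 2.05)
    ax.set_ylabel("bits")
    ax.set_xlabel("position")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
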