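"""IUPAC nucleotide alphabet operations: degeneracy, complementation, translation.

Degenerate primers use IUPAC ambiguity codes (R = A/G, Y = C/T, ..., N = any)
so that a single oligonucleotide anneals to several sequence variants. All
higher-level matching, coverage and amplicon logic is built on the set
semantics defined here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _iterproduct

from Bio.Data import CodonTable as _CodonTable

__all__ = [
    "AlphabetError",
    "NucSequence",
    "PeptideSequence",
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "GAP_CHARS",
    "expand_degenerate",
    "reverse_complement",
    "translate",
]


class AlphabetError(ValueError):
    """Raised when a sequence or primer contains a character outside the alphabet."""


#: IUPAC nucleotide ambiguity codes mapped to the concrete bases they denote.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: IUPAC-aware complement table; gaps complement to themselves.
IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    "-": "-", ".": ".",
}

GAP_CHARS = frozenset("-.")

_NUC_ALPHABET = frozenset(IUPAC_SETS) | GAP_CHARS
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | frozenset("X*")


def _normalize_nuc(residues: str) -> str:
    return residues.upper().replace("U", "T")


@dataclass
class NucSequence:
    """A nucleotide sequence over the IUPAC alphabet, optionally gapped.

    Residues are normalized to uppercase with U→T on construction; '-' and
    '.' are both accepted as alignment gap characters.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError(f"sequence {self.id!r}: empty residues")
        self.residues = _normalize_nuc(self.residues)
        for pos, ch in enumerate(self.residues):
            if ch not in _NUC_ALPHABET:
                raise AlphabetError(
                    f"sequence {self.id!r}: invalid nucleotide character "
                    f"{ch!r} at position {pos}"
                )

    @property
    def is_gapped(self) -> bool:
        return any(ch in GAP_CHARS for ch in self.residues)

    def degap(self) -> "NucSequence":
        """Return an ungapped copy (gap columns removed)."""
        if not self.is_gapped:
            return self
        ungapped = "".join(ch for ch in self.residues if ch not in GAP_CHARS)
        return NucSequence(self.id, ungapped, self.description)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PeptideSequence:
    """An amino-acid sequence; 'X' marks an unresolved codon, '*' a stop."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError(f"peptide {self.id!r}: empty residues")
        self.residues = self.residues.upper()
        for pos, ch in enumerate(self.residues):
            if ch not in _AA_ALPHABET:
                raise AlphabetError(
                    f"peptide {self.id!r}: invalid amino-acid character "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


def expand_degenerate(code: str) -> frozenset[str]:
    """Expand one IUPAC nucleotide code to its set of concrete bases.

    Concrete bases return singletons; gaps are rejected (a gap denotes the
    absence of a base, not an ambiguous one).
    """
    key = _normalize_nuc(code)
    try:
        return IUPAC_SETS[key]
    except KeyError:
        raise AlphabetError(f"invalid IUPAC nucleotide code {code!r}") from None


def reverse_complement(seq: NucSequence | str) -> NucSequence | str:
    """IUPAC-aware reverse complement; gaps are preserved in place.

    Accepts and returns either a bare string or a NucSequence (id suffixed
    with ``_rc``). A length-preserving involution.
    """
    if isinstance(seq, NucSequence):
        rc = reverse_complement(seq.residues)
        return NucSequence(seq.id + "_rc", rc, seq.description)
    out = []
    for pos, ch in enumerate(_normalize_nuc(seq)):
        try:
            out.append(IUPAC_COMPLEMENT[ch])
        except KeyError:
            raise AlphabetError(
                f"invalid nucleotide character {ch!r} at position {pos}"
            ) from None
    return "".join(reversed(out))


_STANDARD_TABLE = _CodonTable.unambiguous_dna_by_id[1]


def _build_codon_lookup() -> dict[str, str]:
    lut = dict(_STANDARD_TABLE.forward_table)
    for stop in _STANDARD_TABLE.stop_codons:
        lut[stop] = "*"
    return lut


_CODON_TO_AA = _build_codon_lookup()
_AMBIG_CACHE: dict[str, str] = {}


def _translate_codon(codon: str) -> str:
    """Translate one (possibly degenerate) codon.

    A degenerate codon resolves to a concrete amino acid only when every
    expansion agrees; mixed outcomes (including stop vs. sense) yield 'X'.
    All-stop expansions yield '*'.
    """
    aa = _CODON_TO_AA.get(codon)
    if aa is not None:
        return aa
    cached = _AMBIG_CACHE.get(codon)
    if cached is not None:
        return cached
    expansions = [expand_degenerate(ch) for ch in codon]
    outcomes = {
        _CODON_TO_AA["".join(bases)] for bases in _iterproduct(*expansions)
    }
    aa = outcomes.pop() if len(outcomes) == 1 else "X"
    _AMBIG_CACHE[codon] = aa
    return aa


def translate(seq: NucSequence | str, frame_offset: int = 0) -> PeptideSequence:
    """Translate an ungapped nucleotide sequence in the given frame.

    Codons are read from ``frame_offset`` (0, 1 or 2); trailing 1–2 nt that
    do not fill a codon are dropped. Standard codon table; stops render '*'.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    if isinstance(seq, str):
        seq = NucSequence("anonymous", seq)
    if seq.is_gapped:
        raise ValueError(f"sequence {seq.id!r} is gapped; degap before translation")
    nt = seq.residues[frame_offset:]
    peptide = "".join(
        _translate_codon(nt[i : i + 3]) for i in range(0, len(nt) - len(nt) % 3, 3)
    )
    if not peptide:
        return _empty_peptide(seq)
    return PeptideSequence(seq.id, peptide, seq.description)


def _empty_peptide(seq: NucSequence) -> PeptideSequence:
    # bypass the non-empty invariant check for the degenerate "too short" case
    pep = PeptideSequence.__new__(PeptideSequence)
    pep.id = seq.id
    pep.residues = ""
    pep.description = seq.description
    return pep
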