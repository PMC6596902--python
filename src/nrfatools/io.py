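"""Readers and writers: FASTA, clade-assignment tables, primer config, coverage TSV.

The toolkit consumes pre-built alignments and sidecar tables; it never
builds alignments itself. Clade assignments live in an external two-column
TSV rather than being parsed out of FASTA headers, because header
conventions vary between reference sets (strain names with spaces etc.).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO

from .alphabet import (
    AlphabetError,
    GAP_CHARS,
    IUPAC_SETS,
    NucSequence,
    PeptideSequence,
)

__all__ = [
    "ParseError",
    "ConfigError",
    "PanelError",
    "Primer",
    "CladeMap",
    "PrimerSet",
    "PrimerConfig",
    "read_fasta",
    "write_fasta",
    "read_clade_map",
    "write_clade_map",
    "read_primer_config",
    "write_coverage_table",
    "round_half_up",
    "validate_panel",
]

logger = logging.getLogger("nrfatools")


class ParseError(ValueError):
    """Malformed input file (FASTA, clade map)."""


class ConfigError(ValueError):
    """Invalid primer configuration or parameter combination."""


class PanelError(ValueError):
    """Reference panel fails a declared structural expectation."""


@dataclass(frozen=True)
class Primer:
    """A named degenerate oligonucleotide, written 5'→3'.

    ``three_prime_window`` is the number of terminal bases treated as "the
    3' end" when classifying mismatch positions; mismatches there are
    disproportionately disruptive to polymerase extension. Default 3 nt,
    the common convention for 3'-critical mismatches.
    """

    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"
    three_prime_window: int = 3

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if self.orientation not in ("forward", "reverse"):
            raise ConfigError(
                f"primer {self.name!r}: orientation must be 'forward' or "
                f"'reverse', got {self.orientation!r}"
            )
        if len(seq) < 10:
            raise ConfigError(
                f"primer {self.name!r}: length {len(seq)} < 10"
            )
        for pos, ch in enumerate(seq):
            if ch in GAP_CHARS:
                raise ConfigError(
                    f"primer {self.name!r}: gap character at position {pos}"
                )
            if ch not in IUPAC_SETS:
                raise ConfigError(
                    f"primer {self.name!r}: invalid IUPAC character {ch!r} "
                    f"at position {pos}"
                )
        if not 0 < self.three_prime_window < len(seq):
            raise ConfigError(
                f"primer {self.name!r}: three_prime_window must be in "
                f"[1, {len(seq) - 1}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_degenerate(self) -> int:
        return sum(1 for ch in self.sequence if len(IUPAC_SETS[ch]) > 1)

    @property
    def degeneracy(self) -> int:
        """Number of concrete oligos the degenerate sequence denotes."""
        n = 1
        for ch in self.sequence:
            n *= len(IUPAC_SETS[ch])
        return n

    def with_window(self, window: int) -> "Primer":
        return Primer(self.name, self.sequence, self.orientation, window)


class CladeMap:
    """Mapping sequence id → clade label; unmapped ids are explicit errors."""

    def __init__(self, mapping: Mapping[str, str]):
        for sid, clade in mapping.items():
            if not clade:
                raise ParseError(f"sequence {sid!r}: blank clade label")
        self._map = dict(mapping)

    def __getitem__(self, seq_id: str) -> str:
        try:
            return self._map[seq_id]
        except KeyError:
            raise KeyError(
                f"sequence id {seq_id!r} has no clade assignment"
            ) from None

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    def ids(self):
        return self._map.keys()

    @property
    def clades(self) -> list[str]:
        return sorted(set(self._map.values()))

    def clade_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for clade in self._map.values():
            sizes[clade] = sizes.get(clade, 0) + 1
        return sizes

    def missing_ids(self, seq_ids: Iterable[str]) -> list[str]:
        return [sid for sid in seq_ids if sid not in self._map]


@dataclass(frozen=True)
class PrimerSet:
    """A primer pair or multiplex pool: ≥1 forward primer, exactly 1 reverse."""

    name: str
    forwards: tuple[str, ...]
    reverse: str

    @property
    def multiplex(self) -> bool:
        return len(self.forwards) > 1


@dataclass
class PrimerConfig:
    primers: dict[str, Primer]
    sets: dict[str, PrimerSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ps in self.sets.values():
            for fwd in ps.forwards:
                if fwd not in self.primers:
                    raise ConfigError(f"set {ps.name!r}: unknown primer {fwd!r}")
                if self.primers[fwd].orientation != "forward":
                    raise ConfigError(
                        f"set {ps.name!r}: primer {fwd!r} is not a forward primer"
                    )
            if ps.reverse not in self.primers:
                raise ConfigError(f"set {ps.name!r}: unknown primer {ps.reverse!r}")
            if self.primers[ps.reverse].orientation != "reverse":
                raise ConfigError(
                    f"set {ps.name!r}: primer {ps.reverse!r} is not a reverse primer"
                )
            if not ps.forwards:
                raise ConfigError(f"set {ps.name!r}: needs at least one forward primer")


def read_fasta(path: str | Path, alphabet: str = "nuc"):
    """Read a FASTA file into NucSequence or PeptideSequence records.

    Record ids are the first whitespace-delimited header token; the full
    header is retained as the description. Gap characters ('-', '.') are
    preserved. Duplicate ids and illegal characters are parse errors.
    """
    path = Path(path)
    if alphabet not in ("nuc", "protein"):
        raise ValueError(f"alphabet must be 'nuc' or 'protein', got {alphabet!r}")
    records = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except FileNotFoundError:
        raise
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise ParseError(f"{path}: not valid FASTA ({exc})") from exc
    if not parsed:
        raise ParseError(f"{path}: empty or headerless FASTA file")
    for rec in parsed:
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        try:
            if alphabet == "nuc":
                records.append(NucSequence(rec.id, str(rec.seq), rec.description))
            else:
                records.append(PeptideSequence(rec.id, str(rec.seq), rec.description))
        except AlphabetError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    logger.info("read %d %s records from %s", len(records), alphabet, path)
    return records


def write_fasta(seqs, path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for seq in seqs:
            header = seq.id
            if seq.description and seq.description != seq.id:
                desc_tail = seq.description
                if desc_tail.startswith(seq.id):
                    desc_tail = desc_tail[len(seq.id):].strip()
                if desc_tail:
                    header = f"{seq.id} {desc_tail}"
            fh.write(f">{header}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def read_clade_map(path: str | Path) -> CladeMap:
    """Read a two-column TSV (sequence id TAB clade label)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(
                    f"{path}:{lineno}: expected 'id<TAB>clade', got {line!r}"
                )
            sid, clade = parts[0].strip(), parts[1].strip()
            if sid in mapping and mapping[sid] != clade:
                raise ParseError(
                    f"{path}:{lineno}: id {sid!r} assigned to both "
                    f"{mapping[sid]!r} and {clade!r}"
                )
            mapping[sid] = clade
    cm = CladeMap(mapping)
    logger.info(
        "clade map %s: %d sequences over %d clades (sizes: %s)",
        path, len(cm), len(cm.clades), cm.clade_sizes(),
    )
    return cm


def write_clade_map(clade_map: CladeMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, clade in clade_map.items():
            fh.write(f"{sid}\t{clade}\n")


def read_primer_config(path: str | Path) -> PrimerConfig:
    """Read a YAML primer configuration.

    Schema::

        primers:
          - name: fwdA
            sequence: GGNCARTGYCAYGCNTGG
            orientation: forward
            three_prime_window: 3   # optional, default 3
        sets:                        # optional
          - name: pairA
            forward: [fwdA]          # one or more -> multiplex pool
            reverse: revA
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "primers" not in doc:
        raise ConfigError(f"{path}: missing top-level 'primers' list")
    primers: dict[str, Primer] = {}
    for entry in doc["primers"]:
        try:
            primer = Primer(
                name=entry["name"],
                sequence=entry["sequence"],
                orientation=entry["orientation"],
                three_prime_window=int(entry.get("three_prime_window", 3)),
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: primer entry missing key {exc}") from exc
        if primer.name in primers:
            raise ConfigError(f"{path}: duplicate primer name {primer.name!r}")
        primers[primer.name] = primer
        logger.info(
            "primer %s: %d nt, %d degenerate positions (degeneracy %d)",
            primer.name, len(primer), primer.n_degenerate, primer.degeneracy,
        )
    sets: dict[str, PrimerSet] = {}
    for entry in doc.get("sets", []) or []:
        fwd = entry.get("forward")
        if isinstance(fwd, str):
            fwd = [fwd]
        if not fwd:
            raise ConfigError(f"{path}: set {entry.get('name')!r} lists no forward primer")
        ps = PrimerSet(name=entry["name"], forwards=tuple(fwd), reverse=entry["reverse"])
        if ps.name in sets:
            raise ConfigError(f"{path}: duplicate set name {ps.name!r}")
        sets[ps.name] = ps
    return PrimerConfig(primers=primers, sets=sets)


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero at `ndigits` decimals (84.05 → 84.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def write_coverage_table(table, path: str | Path) -> None:
    """Write a clade × six-criterion percent-coverage table as TSV.

    One row per clade plus an 'All Clades' row; percentages printed with
    exactly one decimal (half-up).
    """
    from .coverage import CRITERION_LABELS  # local import avoids a cycle

    path = Path(path)
    df = table.rounded()
    with open(path, "w") as fh:
        fh.write("clade\t" + "\t".join(CRITERION_LABELS[c] for c in df.columns) + "\n")
        for clade, row in df.iterrows():
            fh.write(str(clade) + "\t" + "\t".join(f"{v:.1f}" for v in row) + "\n")


def validate_panel(
    seqs,
    clade_map: CladeMap,
    expected_records: int | None = None,
    expected_clades: int | None = None,
) -> tuple[int, int]:
    """Verify the structure of a reference panel on ingest.

    Checks that every sequence has a clade assignment and, when expectations
    are declared (e.g. 271 records over 18 clades for the nrfA reference
    panel), that the record and clade counts match them exactly.
    """
    missing = clade_map.missing_ids(s.id for s in seqs)
    if missing:
        raise PanelError(
            f"{len(missing)} sequence id(s) missing from clade map: "
            + ", ".join(missing[:10])
        )
    n_records = len(seqs)
    n_clades = len({clade_map[s.id] for s in seqs})
    logger.info("panel: %d records over %d clades", n_records, n_clades)
    if expected_records is not None and n_records != expected_records:
        raise PanelError(
            f"expected {expected_records} records, found {n_records}"
        )
    if expected_clades is not None and n_clades != expected_clades:
        raise PanelError(
            f"expected {expected_clades} clades, found {n_clades}"
        )
    return n_records, n_clades
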