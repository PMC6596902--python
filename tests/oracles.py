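"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's matching machinery: degenerate
primers are expanded into every concrete oligo and compared by plain
character equality, and window scans enumerate every offset.
"""

from itertools import product

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def expand_oligo(seq):
    """Every concrete oligo a degenerate sequence denotes."""
    return ["".join(p) for p in product(*(IUPAC[ch] for ch in seq))]


def revcomp(seq):
    return "".join(COMPLEMENT[ch] for ch in reversed(seq))


def min_hamming(degenerate, window):
    """Expand-and-minimize mismatch count of a degenerate oligo vs a
    concrete window (equivalently: positions whose window base is outside
    the primer's set)."""
    assert len(degenerate) == len(window)
    return min(
        sum(a != b for a, b in zip(oligo, window))
        for oligo in expand_oligo(degenerate)
    )


def brute_best_window(primer_seq, orientation, residues):
    """Leftmost minimal-mismatch window by exhaustive enumeration."""
    probe = revcomp(primer_seq) if orientation == "reverse" else primer_seq
    L = len(probe)
    best_off, best_total = None, None
    for off in range(len(residues) - L + 1):
        window = residues[off : off + L]
        total = sum(
            1 for p, w in zip(probe, window) if w not in IUPAC[p]
        )
        if best_total is None or total < best_total:
            best_off, best_total = off, total
    return best_off, best_total
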