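# Methods

## Matching model

Primer/target comparison is set-based over the IUPAC ambiguity alphabet.
Each code denotes a base set; a target base matches a primer base in
*subset* mode (the default) iff the target's set is contained in the
primer's, and in *intersect* mode iff the sets overlap. Subset mode is
the default because a shaded "match" in an alignment figure means the
target base is one of the primer's degenerate options; an ambiguous
target base (say N against R) should not be credited as a match it has
not demonstrated. Intersect mode is retained as a flag for users who
prefer optimistic matching of ambiguous references.

Gaps in the target window ('-' or '.') count as mismatches at their
primer positions in both modes: a deletion inside the annealing site
genuinely impairs priming, and coverage denominators must span the whole
panel rather than silently excluding gapped sites. A window whose
alignment columns cannot carry the primer at all (an insertion column
the primer lacks) is scored as a structural mismatch with total = primer
length, the most conservative interpretation.

Mismatch positions are recorded in primer 5′→3′ coordinates for both
orientations, so the "3′ end" always refers to the extension terminus —
the chemistry behind position-conditional criteria. For a reverse primer
the sense-strand window is compared against the primer's reverse
complement and positions are mapped back; complementation is a bijection
on IUPAC sets, so this equals matching the primer directly on the
antisense strand.

Internally bases are encoded as 4-bit masks (one bit per concrete base)
and window scans compare all offsets with a vectorized sliding window;
tests cross-check this against a character-level brute-force oracle.

## Coverage criteria

Six criteria are computed per clade: 0, ≤1 and ≤2 total mismatches, plus
≤1 with none 3′-terminal, ≤2 with none, and ≤2 with at most one. The
criteria are cumulative ("at most k") rather than exact-k — that is the
reading under which any published six-column coverage table is
column-wise monotone — with exact-k available behind a flag. The pooled
All-Clades row is computed on summed counts over the pooled denominator,
never as the mean of clade percentages, because clade sizes are
deliberately unequal. Percentages are kept at full precision internally
and rounded half-up to one decimal only at presentation.

The length of "the 3′ end" is a convention, not a constant: it defaults
to 3 terminal bases (the common rule of thumb for 3′-critical
mismatches) and is configurable per primer. `sweep_three_prime_window`
recomputes the position-conditional columns for windows of 2–4 nt from
stored mismatch positions, so a user comparing against a published table
can identify and document the window that reproduces it. The
position-independent columns are invariant under this sweep, which the
test suite asserts.

Tie-breaking in scan mode is leftmost-window, with a uniqueness flag,
because multiple equally good sites do occur (secondary sites are the
mechanism behind cross-specific extra PCR products) and determinism
matters more than an arbitrary preference among ties.

## Consensus logos

Column frequencies are tallied over equal-length windows; ambiguity
codes are either spread fractionally over their expansion (default) or
tallied separately, and gaps are always tallied separately and excluded
from the frequency normalization — logo stacks show nucleotides only.
Information content is IC = 2 − H bits per column; the small-sample
correction e(n) = 3/(2·ln2·n) is available but off by default, since at
panel scale (hundreds of sequences) it is negligible and determinism
across differently-sized inputs is worth more. A column with no non-gap
observations has undefined IC and is reported as 0 with a warning rather
than raising, so a partially gapped alignment can still be summarized.

## In-silico PCR and fragment sizes

Site finding uses the exhaustive scan with ceilings total ≤ 2 and at
most 1 mismatch in the 3′ window — the most permissive coverage
criterion, treated as the outer bound of plausible priming — and every
upstream-forward/downstream-reverse pairing within a maximum product
length (default 2000 nt, a guard against pathological pairings, not a
biological claim) becomes a product. Products are primer-inclusive
(forward 5′ end through the reverse site) because downstream translation
is anchored at the forward primer's first base, which is in-frame with
the target gene. Multiplex pools take union semantics over forward
primers; more than one product on a template is flagged as potential
cross-specificity.

Fragment-size predictions carry a migration-adjusted observed window of
[L−4, L−1] for a product of true length L, reflecting the consistent
1–4 bp under-sizing of capillary fragment analysis against its ladder.

Amplicon QC: reads are length-filtered to an inclusive 230–300 nt window
(the expected product range for the nrfA assays this models), translated
in frame 0 from the forward primer's 5′ end with the standard codon
table (for mid-gene fragments the standard and bacterial tables agree on
sense codons), and screened for ordered diagnostic residue motifs with
'X' wildcards. Degenerate codons translate to a concrete amino acid only
when every expansion agrees, to 'X' otherwise — including codons that
could be stop or sense — so no residue is invented. Only the canonical
heme *c* attachment motif CXXCH ships as a default; the packaged motif
file is user-editable because family-specific diagnostic residue sets
belong to the user's reference literature, not to this package. Motif
positions are reported 0-based at the first occurrence. Reads whose
leading bases exceed the primer-recognition mismatch budget, and
translations containing internal stops, are flagged rather than dropped.

## Synthetic panels

The generator is the package's oracle factory: it plants primer sites
with exact, caller-specified mismatch positions inside sequences whose
every other window is guaranteed (by self-scan, with resampling) to
carry at least 5 mismatches against both primers — strictly beyond the
most permissive criterion — so matching provably recovers the planted
profile and nothing else. Planted products have codon structure: the
region from the forward site onward is built from random sense codons
and re-drawn until the frame-0 translation is stop-free, and an
in-frame C-P-F-C-H block is planted in the spacer so translated products
carry an interior diagnostic motif independent of primer-region
mismatches. Mismatch bases are drawn from outside the primer's set at
that position; fully degenerate (N) primer columns cannot host a planted
mismatch and are rejected as unsatisfiable.

Default geometry: 279-nt products (inside the 230–300 filter window and
yielding a 93-residue peptide), 30-nt upstream and 21-nt downstream
flanks, uniform base composition. The demo primers are 18-mers with five
degenerate positions each; the forward primer's six codons encode
C-G-A-C-H-W so exact sites also start with a CXXCH, and the reverse
primer's reverse complement is stop-free in all frames.

Two standard panels are provided. `miniature_panel` is a fixed 6-clade,
60-sequence panel whose planted (total, 3′-count) schedule spans all six
criteria boundaries; its expected coverage table is computed from the
schedule by direct counting and is identical for every seed (the seed
varies only backgrounds and degenerate-base choices).
`reference_scale_panel` is a 271-sequence, 18-clade panel with unequal
clade sizes and randomly drawn planted profiles, used to exercise the
aligned-mode pipeline at the scale of a curated reference panel,
including the on-ingest assertion of record and clade counts.

What these panels do not emulate: phylogenetic covariance between
sequences, indel structure inside target sites beyond gap columns
supplied in aligned mode, sequencing error, and chimeras. Passing tests
therefore demonstrate the correctness of the matching, counting,
stratification and QC machinery under known truth — not the field
performance of any particular primer on real communities, which depends
on the reference panel the user supplies.

## Problem sizes and determinism

The default test and acceptance runs use the 60-sequence miniature, the
271-sequence panel, 10,000 random primer/window pairs for the
mismatch-count oracle, 100 small random panels for monotonicity, and
kilobase-scale sequences for scan-vs-enumeration checks — sizes at which
every check runs in seconds while exercising each code path. All
randomness flows through explicit seeds (`numpy.random.default_rng`);
there is no global random state, and re-running any CLI subcommand with
the same inputs and seed produces byte-identical primary outputs, with
timestamps confined to the run manifest.
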