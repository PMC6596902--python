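# nrfatools

In-silico evaluation of degenerate PCR primers for functional-gene
surveys, built around the *nrfA* gene (pentaheme cytochrome *c* nitrite
reductase, the marker for dissimilatory nitrate reduction to ammonium).
The toolkit answers the questions a primer designer asks before ordering
oligos or interpreting an amplicon run:

- **Coverage** — what percent of a clade-stratified reference panel does
  a degenerate primer match under a given mismatch budget, and how do
  3′-end mismatches (which disproportionately abort extension) change
  the picture?
- **Conservation** — what do the primer target regions look like as a
  position frequency matrix / sequence logo?
- **Products** — which templates amplify, at what product sizes, and
  what fragment sizes should a capillary (AFLP-style) run report given
  the systematic 1–4 bp migration shift?
- **Amplicon QC** — do reads of the expected length (230–300 bp by
  default) translate cleanly in the frame anchored at the forward
  primer's 5′ end, and does the peptide carry the diagnostic residues
  (the heme *c* attachment motif C-X-X-C-H) expected of the target
  protein?

It is aimed at microbial ecologists validating primer sets against
curated reference alignments and at anyone running amplicon surveys of
phylogenetically diverse marker genes.

## The model

A degenerate primer is a word over the IUPAC ambiguity alphabet; each
code denotes a set of bases (R = {A,G}, …, N = {A,C,G,T}). A target base
*t* matches a primer base *p* in the default *subset* mode iff
set(*t*) ⊆ set(*p*) — an ambiguous target base gets no credit unless the
primer covers every base it could be. A window's **mismatch profile** is
the list of non-matching positions in primer 5′→3′ coordinates (so "the
3′ end" always means the extension end, for both orientations); gaps in
the target always count as mismatches.

**Coverage** of a clade under criterion (kₘₐₓ, k₃′) is

    cov = 100 · #{sequences : total ≤ kmax and three_prime ≤ k3'} / clade size

reported for six cumulative criteria: 0, ≤1, ≤2 mismatches, and the
position-conditional variants ≤1 with none 3′-terminal, ≤2 with none,
and ≤2 with at most one. The pooled "All Clades" row uses the summed
numerator and denominator, never the mean of clade rows. Logo
information content is IC = 2 − H (bits), H the Shannon entropy of the
column's base frequencies, with per-base stack heights frequency × IC.

Because published coverage tables rarely define how many terminal bases
count as "the 3′ end", the window length is configurable per primer
(default 3 nt) and `sweep_three_prime_window` recomputes the
position-conditional columns for windows 2–4 so the convention that
reproduces a reference table can be identified.

## Worked example

Generate a synthetic panel with planted primer sites, then compute its
coverage table:

```sh
nrfatools simulate --seed 77 --clades 2 --per-clade 3 --out demo
nrfatools coverage --fasta demo/panel.fasta --clades demo/clades.tsv \
    --primers demo/primers.yaml --out demo/cov
cat demo/cov/coverage_synfwd.tsv
```

which prints (seed 77):

```
clade	0 mismatches	1 mismatch	2 mismatches	1 mismatch not in the 3' end	2 mismatches not in 3' end	2 mismatches with one allowed in 3' end
S1	0.0	33.3	33.3	0.0	0.0	33.3
S2	66.7	66.7	100.0	66.7	100.0	100.0
All Clades	33.3	50.0	66.7	33.3	50.0	66.7
```

Each cell is the percent of that clade's sequences whose planted target
site satisfies the column's mismatch criterion; the generator's
`truth.tsv` lists the planted mismatch positions per sequence, so every
cell can be verified by hand. In-silico PCR on the same panel
(`nrfatools insilico-pcr … --set synthetic_pair`) reports one 279-nt
product per template carrying both sites, and `nrfatools sizes` adds the
migration-adjusted observed window 275–278 nt for each.

The library surface mirrors the CLI: `count_mismatches`,
`scan_best_window`, `locate_by_alignment`, `clade_coverage`,
`column_frequencies` / `information_content`, `in_silico_pcr`,
`predict_fragments`, `length_filter`, `translate_amplicon`,
`check_diagnostic_residues`, and the panel generators in
`nrfatools.synthetic`.

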