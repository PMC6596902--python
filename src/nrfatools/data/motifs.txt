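# Diagnostic residue motifs screened in translated amplicons, one per
# line, in the order they are expected to occur. 'X' is a single-residue
# wildcard. Only the canonical heme c attachment motif of multiheme
# cytochromes ships as the hard default; extend this list with the
# residues diagnostic for your protein family (e.g. the conserved NrfA
# residues between the third and fourth heme-binding domains).
CXXCH
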