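# plastaudit

Audit plastid gene presence, decay and loss across annotated plastomes, and
map loss events onto phylogenies.

Given a cohort of annotated plastome records (GenBank flat files), the
pipeline:

1. **extracts gene observations** (`plastaudit.genbank_io`) — gene/CDS
   features resolved into strand-corrected sequences, including
   inverted-repeat duplicates and origin-spanning features on circular
   molecules;
2. **infers per-gene reference lengths** (`plastaudit.reference_length`) —
   a length shared exactly by ≥ 50% of annotated samples wins (consensus);
   otherwise a two-pass mean is used in which the second pass drops samples
   deviating ≥ 30% from the first-pass mean;
3. **classifies every gene in every sample** (`plastaudit.classify`) into
   four states — *functional* (length within 80–120% of the reference, no
   internal stop codon), *truncated* (premature stop codon, plastid code),
   *pseudogenized* (length outside the 80–120% window), *lost* (absent or
   below 20% of the reference) — and assembles the sample × gene status
   matrix;
4. **builds supermatrices and alignment statistics**
   (`plastaudit.supermatrix`) — gene selection by ≥ 90% presence,
   concatenation with gap padding and a RAxML-style partition table,
   variable-site and missing-data percentages;
5. **counts loss events on a tree** (`plastaudit.treemap`) — generalized
   Fitch parsimony (exact on polytomies) with the root anchored at the
   ancestral "retained" state, plus a matrix-beside-tree SVG/PNG figure.

A seeded generator (`plastaudit.synthetic`) produces annotated plastome
cohorts with planted gene states along a simulated tree, alongside a truth
table, so the whole pipeline is testable without downloads.

## Command line

```sh
# generate a 12-sample synthetic cohort (GenBank files + tree + truth table)
plastaudit simulate -n 12 --seed 1 -o cohort/

# infer reference lengths, classify, and write the status matrix
plastaudit refs cohort/ -o refs.tsv
plastaudit classify cohort/ -o results/ --refs-tsv refs.tsv

# count minimal independent loss events per gene on a tree
plastaudit losses cohort/tree.nwk results/status_matrix.tsv -o losses.tsv

# render the status matrix beside the tree (SVG + PNG)
plastaudit render cohort/tree.nwk results/status_matrix.tsv -o figure.svg

# concatenate per-gene alignments and report alignment statistics
plastaudit supermatrix alignments/ -o supermatrix_out/
plastaudit stats alignments/*.fasta
```

`plastaudit classify` works on any directory of annotated plastome GenBank
files (`.gb`, `.gbk`, optionally gzipped), e.g. records downloaded from
NCBI.

## Notes on conventions

- Coordinates are 0-based half-open internally; GenBank's 1-based inclusive
  convention is converted at the I/O boundary.
- Threshold boundaries are strict ("below 80%", "above 120%", "below 20%"):
  a length ratio of exactly 0.20, 0.80 or 1.20 stays on the inside.
  Comparisons use exact rational arithmetic.
- When a gene has several annotated copies (inverted repeats), the longest
  copy represents the sample, both for reference-length inference and for
  classification.
- The premature-stop test uses the bacterial/plastid genetic code
  (translation table 11) and exempts the final complete codon.
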