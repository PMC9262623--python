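# tcrweave

Reconstruct full-length, correctly spliced T-cell receptor (TCR) coding
nucleotide sequences from the minimal `V gene / J gene / CDR3 junction`
triple that most repertoire studies report — plus the surrounding tooling
needed to trust the output: a batch driver with per-row error capture and
bicistronic linking, a tiled-tag read annotator with allele-level calls and
novel-allele inference, and a V(D)J recombination simulator that provides
exact ground truth for end-to-end validation.

## Who this is for

TCR sequences are usually published as a V gene, a J gene and a CDR3
junction — not as the complete coding sequence needed to synthesize,
clone and express the receptor. `tcrweave` regenerates that sequence:
it splices the correct leader 5' of the V, resolves the junction against
the germline, back-translates any non-templated residues, and appends the
locus-appropriate constant region (TRBJ1-n pairs with TRBC1, TRBJ2-n with
TRBC2; alpha chains take TRAC; other species must specify the constant
explicitly).

## The junction model

The CDR3 junction runs inclusively from the conserved V cysteine to the
conserved J phenylalanine (or equivalent residue located via the
[FWC]-G-x-G motif). Writing the junction as `C ... F`, the assembly is

```
extra5 + leader + V[: v_end] + fill + J[j_start :] + constant + extra3
```

with three input modes that differ only in how `fill` is obtained:

* **AA** — the longest junction prefix encodable by the V germline
  (allowing 3' exonucleolytic deletion of the V back to, but never past,
  the conserved Cys) and the longest junction suffix encodable by the J
  (anchored at the conserved terminal residue, extended leftward
  maximally) are taken from germline nucleotides; the remainder is
  back-translated using each residue's most common codon from a
  species-specific usage table (ties broken alphabetically).
* **NT** — identical decomposition after translating the provided
  nucleotides, but the non-templated span copies the provided bases
  verbatim. Germline-attributed residues still use germline codons, so a
  synonymous codon variant at a recombination edge (e.g. `AGT` for a
  germline-`AGC` serine) is normalised back to germline.
* **SL** (seamless) — the junction is supplied with flanking germline
  context; exact nucleotide-level overlaps (>= 10 nt each side) locate the
  cut points and the provided sequence is integrated verbatim, reproducing
  the rearranged nucleotide sequence exactly.

All three modes encode the same protein for the same rearrangement.

## Worked example

The package ships a small fully synthetic demonstration reference (real
IMGT-style gene names, generated sequences), so the CLI runs out of the
box; point `--reference` at an IMGT/GENE-DB FASTA for real loci.

```
$ tcrweave stitch -v TRBV2-1 -j TRBJ2-2 -c CQANSTNF
>TRBV2-1|TRBJ2-2|CQANSTNF|AA leader=0-48;v_germline=48-342;junction_fill=342-345;j_germline=345-402;constant=402-492
ATGGCCCTGAACTGTGGTCAGAAAACCGTGAGCCTTTGC...GGATCCAAATAA
```

The header records the segment offsets: a 48-nt leader, 294 nt of germline
V (the bare `TRBV2-1` call resolved to the prototypical `*01` allele; the
junction's `CQAN` prefix and `STNF` suffix were attributed to germline V
and J), a single codon-optimised fill codon (342–345), the trimmed J, and
the TRBC2 constant selected automatically from the TRBJ2 cluster. The
coding sequence is in frame and ends at the constant's stop codon.

Batch mode consumes a tab-separated table with `alpha_`/`beta_` column
prefixes (`name`, `<chain>_v_call`, `<chain>_j_call`, `<chain>_junction`,
optional mode/overrides/linker), writes a results TSV plus a JSON run
record, and exits 2 if any row fails:

```
$ tcrweave simulate -n 100 --seed 5 -o demo     # ground-truth inputs
$ tcrweave batch -i demo.batch.tsv -o out.tsv   # stitch all rows
INFO tcrweave: stitched 100/100 rows
```

Python API equivalents: `stitch()`, `process_batch()`, `annotate_read()`,
`infer_novel_alleles()`, `simulate_repertoire()` — see the module
docstrings.

## Annotation and novel alleles

`tcrweave annotate` calls V/J alleles by tiling 20-nt tags every 10 nt
across every allele and scoring collinear tag matches, reporting `v_jump`
/ `j_jump` values (`v_jump == 0` means the read covers the V-REGION
start — the full-length filter). A single-nucleotide variant relative to
the reference knocks out exactly two overlapping tags; `tcrweave novel`
clusters such recurrent breaks, applies abundance criteria (>= 10 distinct
recombinations for the gene, >= 5% of gene reads, >= 3 unique
recombinations, >= 10% of break reads, top-two rank) and emits inferred
alleles like `TRBV1-1*01_C101A` as IMGT-format FASTA ready to merge back
into the reference.

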