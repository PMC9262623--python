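# Methods

## Scope and model

`tcrweave` reconstructs the full coding sequence of a rearranged TCR chain
from its V gene, J gene and CDR3 junction. The model treats a chain as a
concatenation of blocks — leader (pre-spliced L-PART1+L-PART2), V-REGION,
junction, J-REGION remainder, constant region (one pre-spliced in-frame
block, no exon bookkeeping) — and assumes:

* the junction runs inclusively from the conserved V cysteine to the
  conserved J phenylalanine/tryptophan/cysteine;
* the conserved Cys is the 3'-most cysteine of the translated V-REGION,
  and the J terminal residue is the first residue of the [FWC]-G-x-G
  motif nearest the J 3' end (located by motif scan, not IMGT gapped
  numbering, so the reference needs no alignment metadata);
* leaders and constants are in frame with their V/J (true of IMGT
  release data and of the bundled fixture).

Constant-region exon variants (membrane vs secreted, TRGC duplications)
are out of scope; constants are single blocks.

## Junction attribution

V side: the junction prefix is matched against the translated V while
deleting 0, 1, 2, ... residues from the V 3' end, taking the longest
prefix matched over all deletions (ties to the smallest deletion). The
deletion search is capped so it never removes the conserved Cys; if no
match exists at any allowed deletion (junction does not begin with C),
the whole post-Cys region is removed, the junction becomes fully
non-templated on the V side and a warning is raised. The cap matters:
without deletion, a junction whose first divergent residue sits inside
the post-Cys germline motif (e.g. `CAST...` against germline `CASS`)
would force the full V to be retained and duplicate the motif. The
low-level `v_overlap_aa` helper defaults to zero deletions (a pure
suffix-prefix match); the stitcher calls the deletion-aware search.

J side: the junction's final residue must sit at the J's conserved
terminal residue — if it does not, the junction is incomplete and
stitching fails with a junction-anchor error (this is the dominant
failure class for real-world inputs). The match is then extended
leftward maximally. Because every shorter anchored match is a sub-match
of a longer one, "maximal V prefix, then maximal anchored J suffix" is
globally optimal in total germline attribution; the test suite checks
this against a brute-force enumeration of all split points.

Seamless mode: the longest prefix of the provided sequence occurring
exactly in the V (rightmost occurrence, i.e. least deletion) and the
longest suffix occurring exactly in the J (leftmost occurrence) locate
the cut points; both overlaps must be at least `sl_min_overlap`
(default 10 nt, configurable). There is no mismatch tolerance: a SNV in
the padding shortens the exact overlap and, below the minimum, fails the
stitch rather than silently falling back to NT mode — the seamless
guarantee is exactness. A provided sequence that breaks the reading
frame is an error, not a warning.

Non-canonical junctions (no leading C, no terminal F/W) warn rather than
error, because engineered or modified receptors are legitimate inputs; a
`strict` flag upgrades warnings to errors. Pseudogene (functionality P)
segments stitch only behind an explicit flag; F and ORF records are
usable by default. Partial records stitch with a warning.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `sl_min_overlap` | 10 nt | minimum exact seamless overlap per side |
| tag length / step | 20 / 10 nt | annotation tag tiling; interior positions double-covered |
| `min_tag_matches` | 2 | collinear tag matches required to call an allele |
| inference thresholds | 10 / 5% / 3 / 10% / top-2 | novel-allele criteria (distinct recombinations, gene-read fraction, unique recombinations, break-read fraction, genotype rank) |

Codon back-translation uses the packaged human codon-usage table
(standard human codon fractions; only the per-residue argmax matters),
with alphabetical tie-breaks so identical inputs always produce identical
output.

## Annotation

Tags are fixed-length 20-mers, so the multi-pattern scan is a hash-map
lookup over every read window — computationally equivalent to the
Aho–Corasick automaton usually used for this tiling, with no extra
dependency. Matches only count toward a call when they agree on a single
read-to-allele shift (collinearity), which suppresses chance k-mer hits;
all alleles attaining the maximal count are reported and ties flag the
read ambiguous. `v_jump` is the 5'-most matched V-tag offset within the
allele (0 = read covers the V start); `j_jump` mirrors it from the J 3'
end. The reverse complement is searched only when the forward strand has
no hits.

A substitution at least one tag-length from both allele ends knocks out
exactly the two grid tags covering it; `find_tag_breaks` reports windows
of exactly two consecutive failed tags with matched flanking tags, so
end-proximal variants (single-tag failures) and indels (shift-breaking)
are deliberately not candidates — the inference targets interior SNVs
only. Thresholds are applied per cluster of identical
(allele, window, spanning sequence); the top-two genotype rank is
computed over all break clusters of the gene, and a candidate must pass
all four thresholds and the rank. Variant positions are reported 1-based
in V-REGION coordinates and named `gene*allele_RefPosAlt`.

## Simulator and fixture reference

The simulator draws V/J alleles uniformly, trims uniformly on
[0, 8] nt at the V 3' and J 5' ends, inserts a bounded-geometric number
(p = 0.25, capped at 15, uniform bases) of non-templated nucleotides
(which subsumes D-gene content), and rejection-samples until the product
is in frame, stop-free, starts at the conserved C, ends in F/W/C and has
at least 8 junction residues. Trim and insertion distributions are
fixture knobs chosen to exercise every code path (including mid-codon
trims whose insertions recreate synonymous codons — the source of
NT-mode residual mismatches); they are not calibrated generation
probabilities. A >99% rejection rate over a 1000-draw window raises
rather than looping forever.

The bundled reference is fully synthetic: 8 V genes (300 nt, conserved
Cys at codon 96, post-Cys residues drawn from a set excluding C/G/F/W so
anchor scans are unambiguous), 6 J genes (60 nt, single [FWC]-G-x-G
anchor at codon 5), leaders (48 nt, ATG-initiated) and stop-terminated
constants (90 nt). Two genes carry a *02 allele differing by one interior
substitution — and deliberately no *02 leader, so the *01 fallback path
runs. Real gene names are reused purely so locus naming rules (TRBJ
cluster -> TRBC, TRAJ -> TRAC) are exercised; the sequences are random.

What passing tests therefore show: the assembly algebra, junction
decomposition, annotation and inference logic are exact on data matching
their assumptions. What they do not show: robustness to sequencing error
models other than isolated SNVs, real codon-boundary statistics, allele
diversity at real-locus scale, or UMI/merging artefacts — all upstream
concerns out of scope here.

## Numerical and design choices

* Determinism everywhere: all randomness flows through explicit integer
  seeds (numpy `default_rng`); batch reruns are byte-identical.
* Codon-table tie-breaks alphabetical; modal codon computed after
  per-residue normalisation (sums checked to 1e-6).
* The built-in linkers are the four standard GSG-prefixed 2A peptides
  (P2A/T2A/E2A/F2A). An IRES entry is deliberately not included: IRES
  elements are untranslated and do not fit the frame-through linking
  model (stop removal, single ORF); arbitrary literal linker sequences
  cover that use case explicitly.
* The 5' chain's trailing stop codon is removed before linking; a
  missing stop is accepted silently (engineered chains may lack one).
* Batch rows infer AA vs NT mode from the junction alphabet; seamless
  mode is never inferred and must be requested per row or per run.
* Degenerate inputs: empty junctions, junctions shorter than twice the
  seamless minimum, out-of-frame NT junctions, junctions encoding stops,
  and unanchorable terminal residues all fail with typed, stage-carrying
  errors; empty batch input yields empty output.

## Problem sizes used in validation

The shipped validation (test suite and `scripts/acceptance.py`) uses
1,000-rearrangement repertoires for fidelity measurements, 200 junctions
for the brute-force attribution oracle, 10,000 rows for batch robustness
and 100/1,000/10,000 rows for the runtime-scaling fit — sizes chosen so
the full validation completes in well under a minute while every
assertion remains exact (100%-identity checks, not approximations).

## Known limitations

* Gapped IMGT alignment coordinates are not used; anchor location relies
  on motif scans, which can misplace anchors in highly atypical genes.
* Only substitution variants are inferred; indel alleles surface as
  unresolved breaks.
* Constant-region exon structure, somatic hypermutation (immunoglobulin
  use), and nomenclature conversion from vendor-specific gene names are
  out of scope.
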