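"""Tiled-tag read annotation and novel-allele inference.

Every V and J allele is tiled with 20-nt tags overlapping by 10 nt, so each
interior allele position is covered by exactly two tags.  Reads are scanned
against the full tag set (all tags share one fixed length, so a hash-map
lookup over every read window performs the same multi-pattern scan an
Aho-Corasick automaton would); alleles are called at allele-level accuracy
by the maximal count of collinear tag matches, and "jump" values report how
far the read reaches into each gene: ``v_jump == 0`` means the read covers
the V-REGION start, which is the full-length filter used throughout.

A single-nucleotide variant relative to the recorded germline knocks out
exactly the two overlapping tags that cover it.  Recurrent two-tag breaks
that share an identical spanning sequence across many distinct
rearrangements are evidence of a novel allele rather than PCR/sequencing
error; candidates must (i) occur in a V gene with >= 10 distinct
unambiguously-called recombinations, (ii) account for >= 5% of the gene's
reads, (iii) appear in >= 3 unique recombinations, (iv) account for >= 10%
of the gene's break-containing reads, and additionally rank in the top two
break sequences for the gene (a diploid genotype can contribute at most
two alleles).  Passing candidates are named by suffixing the variant to the
base allele (e.g. ``TRAV27*01_A233G``) and can be appended to the reference
for re-annotation or stitching.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import AnnotationError
from .reference import (
    GeneIdentifier,
    ReferenceSet,
    SegmentRecord,
    SegmentType,
)
from .stitch import conserved_anchor_index, conserved_cys_index, translate

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlleleInfo:
    """Per-allele metadata cached in the tag index."""

    full_id: str
    gene_name: str
    segment_type: SegmentType
    length: int
    grid: list[int]  # tag offsets, including the 3'-anchored terminal tag
    cys_codon: Optional[int] = None  # V only: conserved Cys residue index
    anchor_codon: Optional[int] = None  # J only: conserved F/W/C residue index


class TagIndex:
    """Fixed-length tag lookup over every allele of every V/J gene."""

    def __init__(self, tag_length: int = 20, step: int = 10):
        self.tag_length = tag_length
        self.step = step
        self.tags: dict[str, list[tuple[str, int]]] = defaultdict(list)
        self.alleles: dict[str, AlleleInfo] = {}

    def add_allele(self, record: SegmentRecord) -> None:
        seq = record.sequence
        if len(seq) < self.tag_length:
            log.warning("allele %s shorter than tag length; skipped",
                        record.name)
            return
        last = len(seq) - self.tag_length
        grid = list(range(0, last + 1, self.step))
        if grid[-1] != last:
            grid.append(last)  # terminal tag anchored at the 3' end
        for off in grid:
            self.tags[seq[off : off + self.tag_length]].append((record.name, off))
        info = AlleleInfo(
            full_id=record.name,
            gene_name=record.id.gene_name,
            segment_type=record.segment_type,
            length=len(seq),
            grid=grid,
        )
        aa = translate(seq)
        if record.segment_type == SegmentType.VARIABLE:
            info.cys_codon = conserved_cys_index(aa)
        elif record.segment_type == SegmentType.JOINING:
            try:
                info.anchor_codon = conserved_anchor_index(aa)
            except Exception:
                info.anchor_codon = None
        self.alleles[record.name] = info


def build_tag_index(ref: ReferenceSet, tag_length: int = 20,
                    step: int = 10) -> TagIndex:
    """Tile tags across every V and J allele of the reference."""
    index = TagIndex(tag_length, step)
    for stype in (SegmentType.VARIABLE, SegmentType.JOINING):
        for rec in ref.records(stype):
            index.add_allele(rec)
    return index


@dataclass
class AnnotationResult:
    """Tag-based V/J calls for one read."""

    read_id: str
    v_calls: list[str]
    j_calls: list[str]
    v_jump: Optional[int]  # offset of 5'-most matched V tag within the allele
    j_jump: Optional[int]  # distance of 3'-most matched J tag from the J 3' end
    #: winning (shift, matched grid offsets) per called allele
    tag_hits: dict[str, tuple[int, tuple[int, ...]]]
    junction_nt: Optional[str] = None
    junction_aa: Optional[str] = None
    reversed: bool = False

    @property
    def v_ambiguous(self) -> bool:
        return len(self.v_calls) > 1

    @property
    def j_ambiguous(self) -> bool:
        return len(self.j_calls) > 1

    @property
    def ambiguous(self) -> bool:
        return self.v_ambiguous or self.j_ambiguous


def _collinear_hits(read: str, index: TagIndex):
    """Group tag matches by (allele, read-to-allele shift)."""
    groups: dict[tuple[str, int], set[int]] = defaultdict(set)
    tl = index.tag_length
    tags = index.tags
    for i in range(len(read) - tl + 1):
        for allele, off in tags.get(read[i : i + tl], ()):
            groups[(allele, i - off)].add(off)
    return groups


def annotate_read(read: str, index: TagIndex, read_id: str = "read",
                  min_tag_matches: int = 2) -> AnnotationResult:
    """Call V and J alleles for one read from collinear tag matches.

    Matched tag offsets only count toward a call when they agree on a single
    read-to-allele shift, which suppresses chance k-mer hits.  All alleles
    attaining the maximal collinear match count are reported; more than one
    flags the read ambiguous.  The forward strand is searched first and the
    reverse complement only when no forward tag matches at all.
    """
    read = read.strip().upper()
    was_reversed = False
    groups = _collinear_hits(read, index)
    if not groups:
        rc = reverse_complement(read)
        rc_groups = _collinear_hits(rc, index)
        if rc_groups:
            read, groups, was_reversed = rc, rc_groups, True

    best: dict[SegmentType, dict[str, tuple[int, tuple[int, ...]]]] = {
        SegmentType.VARIABLE: {},
        SegmentType.JOINING: {},
    }
    for (allele, shift), offsets in groups.items():
        stype = index.alleles[allele].segment_type
        cur = best[stype].get(allele)
        if cur is None or len(offsets) > len(cur[1]):
            best[stype][allele] = (shift, tuple(sorted(offsets)))

    def top(stype: SegmentType) -> tuple[list[str], dict]:
        cands = {a: hit for a, hit in best[stype].items()
                 if len(hit[1]) >= min_tag_matches}
        if not cands:
            return [], {}
        top_n = max(len(hit[1]) for hit in cands.values())
        winners = sorted(a for a, hit in cands.items()
                         if len(hit[1]) == top_n)
        return winners, {a: cands[a] for a in winners}

    v_calls, v_hits = top(SegmentType.VARIABLE)
    j_calls, j_hits = top(SegmentType.JOINING)

    v_jump = min(v_hits[v_calls[0]][1]) if v_calls else None
    j_jump = None
    if j_calls:
        info = index.alleles[j_calls[0]]
        hit = j_hits[j_calls[0]]
        j_jump = info.length - (max(hit[1]) + index.tag_length)

    result = AnnotationResult(
        read_id=read_id,
        v_calls=v_calls,
        j_calls=j_calls,
        v_jump=v_jump,
        j_jump=j_jump,
        tag_hits={**v_hits, **j_hits},
        reversed=was_reversed,
    )
    if len(v_calls) == 1 and len(j_calls) == 1:
        result.junction_nt, result.junction_aa = extract_junction(
            read, result, index)
    return result


def extract_junction(read: str, annotation: AnnotationResult,
                     index: TagIndex) -> tuple[Optional[str], Optional[str]]:
    """Read-verbatim junction from the V Cys codon to the J anchor codon.

    The conserved anchor positions of the called alleles are projected into
    read coordinates through the collinear tag shifts; the junction is
    absent when either anchor falls outside the read.
    """
    if annotation.ambiguous or not annotation.v_calls or not annotation.j_calls:
        return None, None
    v_info = index.alleles[annotation.v_calls[0]]
    j_info = index.alleles[annotation.j_calls[0]]
    if v_info.cys_codon is None or j_info.anchor_codon is None:
        return None, None
    v_shift = annotation.tag_hits[annotation.v_calls[0]][0]
    j_shift = annotation.tag_hits[annotation.j_calls[0]][0]
    start = v_shift + 3 * v_info.cys_codon
    end = j_shift + 3 * (j_info.anchor_codon + 1)
    if start < 0 or end > len(read) or end <= start:
        return None, None
    nt = read[start:end]
    aa = translate(nt) if len(nt) % 3 == 0 else None
    return nt, aa


@dataclass
class TagBreak:
    """A window of exactly two consecutive failed tags with matched flanks."""

    allele: str
    gene_name: str
    offsets: tuple[int, int]  # the two failed grid offsets
    span_start: int  # allele coordinate of the spanning sequence
    sequence: str  # read sequence across the failed window


def find_tag_breaks(read: str, annotation: AnnotationResult,
                    index: TagIndex) -> list[TagBreak]:
    """Locate two-consecutive-tag failures against the called V allele.

    A single substitution knocks out the two overlapping tags covering it
    while the flanking tags still match; the read sequence spanning the
    failed window is recorded for clustering.  Substitutions within half a
    tag of the allele ends knock out only one tag and are not reported.
    Reads without a single unambiguous V call yield nothing.
    """
    read = read.strip().upper()
    if annotation.v_ambiguous or not annotation.v_calls:
        return []
    allele = annotation.v_calls[0]
    info = index.alleles[allele]
    shift, matched = annotation.tag_hits[allele]
    matched_set = set(matched)
    tl = index.tag_length
    expected = [o for o in info.grid
                if shift + o >= 0 and shift + o + tl <= len(read)]
    breaks: list[TagBreak] = []
    i = 0
    while i < len(expected):
        if expected[i] in matched_set:
            i += 1
            continue
        run_start = i
        while i < len(expected) and expected[i] not in matched_set:
            i += 1
        run = expected[run_start:i]
        left_ok = run_start > 0  # flanking matched tag exists on both sides
        right_ok = i < len(expected)
        if len(run) == 2 and left_ok and right_ok:
            o1, o2 = run
            breaks.append(TagBreak(
                allele=allele,
                gene_name=info.gene_name,
                offsets=(o1, o2),
                span_start=o1,
                sequence=read[shift + o1 : shift + o2 + tl],
            ))
    return breaks


@dataclass
class AnnotatedRead:
    """A read plus its annotation, as consumed by the inference step."""

    read_id: str
    sequence: str
    annotation: AnnotationResult


def annotate_reads(reads: Iterable[tuple[str, str]],
                   index: TagIndex) -> list[AnnotatedRead]:
    """Annotate ``(read_id, sequence)`` pairs."""
    return [
        AnnotatedRead(rid, seq, annotate_read(seq, index, read_id=rid))
        for rid, seq in reads
    ]


@dataclass
class NovelAlleleCandidate:
    """An inferred single-nucleotide germline variant."""

    base_allele: GeneIdentifier
    position: int  # 1-based within the base allele V-REGION
    ref_base: str
    alt_base: str
    supporting_reads: int
    supporting_recombinations: int
    fraction_of_gene_reads: float
    fraction_of_break_reads: float
    identifier: str


def infer_novel_alleles(
    annotated: Sequence[AnnotatedRead],
    ref: ReferenceSet,
    index: TagIndex,
    min_gene_recombinations: int = 10,
    min_gene_read_fraction: float = 0.05,
    min_unique_recombinations: int = 3,
    min_break_read_fraction: float = 0.10,
    genotype_rank: int = 2,
) -> list[NovelAlleleCandidate]:
    """Infer novel single-nucleotide V alleles from one donor's reads.

    Only full-length (``v_jump == 0``), unambiguously called reads with an
    extractable junction participate.  Break windows are clustered by
    identical (allele, window, spanning sequence); clusters passing all four
    abundance criteria and ranking in the gene's top ``genotype_rank`` break
    sequences whose span differs from germline by exactly one substitution
    become candidates.  Multi-mismatch spans (indel-shifted or multi-variant)
    are left as unresolved breaks.
    """
    usable = [
        ar for ar in annotated
        if ar.annotation.v_jump == 0
        and not ar.annotation.ambiguous
        and len(ar.annotation.v_calls) == 1
        and ar.annotation.junction_nt
    ]
    gene_reads: dict[str, list[AnnotatedRead]] = defaultdict(list)
    for ar in usable:
        gene = index.alleles[ar.annotation.v_calls[0]].gene_name
        gene_reads[gene].append(ar)

    candidates: list[NovelAlleleCandidate] = []
    for gene, reads in sorted(gene_reads.items()):
        distinct = {ar.annotation.junction_nt for ar in reads}
        clusters: dict[tuple[str, tuple[int, int], str], list[AnnotatedRead]] = \
            defaultdict(list)
        break_read_ids: set[str] = set()
        for ar in reads:
            brs = find_tag_breaks(ar.sequence, ar.annotation, index)
            if brs:
                break_read_ids.add(ar.read_id)
            for br in brs:
                clusters[(br.allele, br.offsets, br.sequence)].append(ar)
        if not clusters:
            continue
        ranked = sorted(clusters.items(),
                        key=lambda kv: (-len(kv[1]), kv[0]))
        n_gene = len(reads)
        n_break = len(break_read_ids)
        for rank, ((allele, offsets, span), members) in enumerate(ranked, 1):
            n_members = len(members)
            member_recombs = {ar.annotation.junction_nt for ar in members}
            if (
                len(distinct) < min_gene_recombinations
                or n_members / n_gene < min_gene_read_fraction
                or len(member_recombs) < min_unique_recombinations
                or n_members / n_break < min_break_read_fraction
                or rank > genotype_rank
            ):
                continue
            base = ref.get(*_split(allele), SegmentType.VARIABLE)
            germline_span = base.sequence[offsets[0] : offsets[1] + index.tag_length]
            if len(germline_span) != len(span):
                continue  # length change: not a simple substitution
            diffs = [i for i, (a, b) in enumerate(zip(germline_span, span))
                     if a != b]
            if len(diffs) != 1:
                continue  # unresolved multi-mismatch break
            pos = offsets[0] + diffs[0] + 1
            ref_base, alt_base = germline_span[diffs[0]], span[diffs[0]]
            candidates.append(NovelAlleleCandidate(
                base_allele=base.id,
                position=pos,
                ref_base=ref_base,
                alt_base=alt_base,
                supporting_reads=n_members,
                supporting_recombinations=len(member_recombs),
                fraction_of_gene_reads=n_members / n_gene,
                fraction_of_break_reads=n_members / n_break,
                identifier=f"{base.name}_{ref_base}{pos}{alt_base}",
            ))
    return candidates


def _split(full_id: str) -> tuple[str, str]:
    gid = GeneIdentifier.parse(full_id)
    return gid.gene_name, gid.allele


def augment_reference(ref: ReferenceSet,
                      candidates: Sequence[NovelAlleleCandidate]) -> ReferenceSet:
    """Return a copy of the reference with candidate alleles applied.

    Each candidate becomes a new VARIABLE record whose allele name carries
    the variant suffix; both stitching and (re-indexed) annotation then
    accept the suffixed allele names.  Identifier collisions raise.
    """
    new = ref.copy()
    seen: set[str] = set()
    for cand in candidates:
        if cand.identifier in seen:
            raise AnnotationError(
                f"duplicate novel-allele identifier {cand.identifier}")
        seen.add(cand.identifier)
        base = new.get(cand.base_allele.gene_name, cand.base_allele.allele,
                       SegmentType.VARIABLE)
        if base is None:
            raise AnnotationError(
                f"base allele {cand.base_allele} missing from reference")
        idx = cand.position - 1
        if base.sequence[idx] != cand.ref_base:
            raise AnnotationError(
                f"{cand.identifier}: reference base mismatch at position "
                f"{cand.position}")
        seq = base.sequence[:idx] + cand.alt_base + base.sequence[idx + 1 :]
        allele = f"{cand.base_allele.allele}_{cand.ref_base}{cand.position}{cand.alt_base}"
        rec = SegmentRecord(
            id=GeneIdentifier(cand.base_allele.gene_name, allele),
            segment_type=SegmentType.VARIABLE,
            functionality=base.functionality,
            sequence=seq,
            species=base.species,
        )
        if new.get(rec.id.gene_name, rec.id.allele, SegmentType.VARIABLE):
            raise AnnotationError(
                f"novel allele {cand.identifier} already present in reference")
        new.add(rec, notice=False)
    return new
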