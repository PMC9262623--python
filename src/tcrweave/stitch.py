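"""Full-length TCR coding-sequence assembly from V/J/CDR3 descriptions.

A rearranged TCR chain is reconstructed as::

    extra5 + leader + V-germline + junction-fill + J-germline + constant + extra3

The CDR3 junction (conserved V cysteine through conserved J phenylalanine,
inclusive) may be given in three forms:

* ``AA`` -- amino acids.  The longest junction prefix encodable by the V
  germline (allowing 3' exonucleolytic deletion of the V back to, but never
  past, the conserved Cys) and the longest junction suffix encodable by the
  J germline (anchored at the conserved [FWC]-G-x-G motif residue) are taken
  from the germline nucleotide sequences; the non-templated remainder is
  back-translated with the most common codon per residue.
* ``NT`` -- exact junction nucleotides.  Decomposed like AA after
  translation, but the non-templated span copies the provided nucleotides
  verbatim.  Germline-attributed residues still use germline codons, so a
  synonymous variant codon at a recombination edge is replaced by its
  germline form.
* ``SL`` (seamless) -- junction nucleotides with flanking germline context.
  Overlap detection runs at the nucleotide level: the provided sequence's 5'
  end is matched against the progressively deleted V 3' end and its 3' end
  against the J; the provided sequence is then integrated verbatim between
  the trimmed germline flanks.

All three modes encode the same amino acid sequence for the same
rearrangement; seamless mode additionally reproduces the rearranged
nucleotide sequence exactly when the padding matches germline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .errors import (
    FrameError,
    JunctionAnchorError,
    SeamlessOverlapError,
    StitchError,
)
from .reference import (
    CodonUsageTable,
    ReferenceSet,
    SegmentRecord,
    SegmentType,
    chain_of,
    default_constant,
    resolve_segment,
)

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")
_DNA_RE = re.compile(r"^[ACGT]+$")
_STOPS = ("TAA", "TAG", "TGA")

#: Conserved junction-terminal residues found in functional J genes.
J_ANCHOR_RESIDUES = "FWC"
_ANCHOR_MOTIF = re.compile(r"[FWC]G.G")


def translate(nt: str, frame: int = 0) -> str:
    """Translate DNA with the standard code; ``*`` marks stops.

    The trailing partial codon, if any, is dropped.  Raises
    :class:`StitchError` on non-ACGT input.
    """
    nt = nt.upper()
    if nt and not _DNA_RE.match(nt):
        raise StitchError(f"non-ACGT character in sequence {nt[:30]!r}...",
                          stage="translate")
    sub = nt[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        return ""
    return str(Seq(sub).translate())


# ---------------------------------------------------------------------------
# junction decomposition primitives


def v_overlap_aa(v_aa: str, junction_aa: str, max_deletion: int = 0) -> int:
    """Number of junction residues attributable to the V germline.

    With ``max_deletion=0`` this is the length of the longest suffix of
    ``v_aa`` that is a prefix of ``junction_aa``.  Positive ``max_deletion``
    additionally allows up to that many residues to be deleted from the V
    3' end before matching (modelling exonucleolytic trimming), returning
    the longest junction prefix found over all allowed deletions.
    """
    used, _ = _v_attribution(v_aa, junction_aa, max_deletion)
    return used


def _v_attribution(
    v_aa: str, junction_aa: str, max_deletion: int
) -> tuple[int, int]:
    """Return ``(residues_used, v_deletions)`` maximizing germline overlap.

    Ties on overlap length are broken toward the smallest deletion.
    """
    n = len(v_aa)
    best_k, best_d = 0, 0
    for d in range(0, min(max_deletion, n - 1) + 1):
        trimmed = v_aa[: n - d]
        kmax = min(len(trimmed), len(junction_aa))
        for k in range(kmax, best_k, -1):
            if trimmed.endswith(junction_aa[:k]):
                best_k, best_d = k, d
                break
    return best_k, best_d


def conserved_cys_index(v_aa: str) -> int:
    """Residue index of the conserved second cysteine in a translated V.

    Located as the 3'-most cysteine; in functional V genes the junction-
    opening Cys sits within the last few residues of the V-REGION.
    Raises if the translation contains no cysteine.
    """
    idx = v_aa.rfind("C")
    if idx < 0:
        raise StitchError("no cysteine found in translated V gene",
                          stage="v_anchor")
    return idx


def conserved_anchor_index(j_aa: str) -> int:
    """Residue index of the conserved F/W/C terminating the junction in a J.

    Found by scanning the translation for the [FWC]-G-x-G motif nearest the
    3' end; the motif's first residue is the junction terminus.
    """
    matches = list(_ANCHOR_MOTIF.finditer(j_aa))
    if not matches:
        raise JunctionAnchorError(
            f"no [FWC]GxG motif in translated J gene {j_aa!r}"
        )
    return matches[-1].start()


def j_overlap_aa(
    j_aa: str, junction_remainder: str, anchor: Optional[int] = None
) -> int:
    """Number of junction residues attributable to the J germline.

    The junction's final residue is anchored at the J's conserved terminal
    residue (``anchor``, located by motif scan when not given) and the match
    is extended leftward maximally through the germline.  Raises
    :class:`JunctionAnchorError` when the final residue does not match the
    anchor -- such junctions are incomplete and unstitchable.
    """
    if not junction_remainder:
        raise JunctionAnchorError("empty junction remainder after V attribution")
    if anchor is None:
        anchor = conserved_anchor_index(j_aa)
    if junction_remainder[-1] != j_aa[anchor]:
        raise JunctionAnchorError(
            f"junction terminal residue {junction_remainder[-1]!r} does not "
            f"match the J conserved residue {j_aa[anchor]!r}"
        )
    k = 1
    while (
        k < len(junction_remainder)
        and k <= anchor
        and j_aa[anchor - k] == junction_remainder[-k - 1]
    ):
        k += 1
    return k


def fill_non_templated(aa: str, table: CodonUsageTable) -> str:
    """Back-translate residues using each residue's most common codon."""
    return "".join(table.modal_codon(res) for res in aa)


# ---------------------------------------------------------------------------
# request / result containers


@dataclass
class StitchRequest:
    """One rearrangement to assemble."""

    v_call: str
    j_call: str
    junction: str
    mode: str = "AA"  # AA | NT | SL
    constant_override: Optional[str] = None
    leader_override: Optional[str] = None
    extra_5prime: str = ""
    extra_3prime: str = ""
    species: Optional[str] = None
    chain: Optional[str] = None
    name: str = ""

    def __post_init__(self) -> None:
        self.v_call = self.v_call.strip()
        self.j_call = self.j_call.strip()
        self.junction = self.junction.strip().upper()
        self.mode = self.mode.strip().upper()
        self.extra_5prime = (self.extra_5prime or "").strip().upper()
        self.extra_3prime = (self.extra_3prime or "").strip().upper()
        if self.mode not in ("AA", "NT", "SL"):
            raise StitchError(f"unknown junction mode {self.mode!r}",
                              stage="request")


@dataclass
class JunctionDecomposition:
    """Germline attribution of a junction.

    ``junction_nt`` is the junction as it will appear in the stitched
    sequence; ``nt_fill_span`` is the half-open interval within it holding
    non-germline (codon-optimized or verbatim-copied) nucleotides.
    """

    v_residues_used: int
    j_residues_used: int
    non_templated_aa: str
    junction_nt: str
    nt_fill_span: tuple[int, int]
    v_deletions: int = 0
    j_anchor: int = 0
    # seamless bookkeeping: cut points in germline V/J coordinates
    sl_v_cut: Optional[int] = None
    sl_j_cut: Optional[int] = None


@dataclass
class StitchWarning:
    code: str
    message: str

    def __str__(self) -> str:
        return f"{self.code}: {self.message}"


@dataclass
class StitchResult:
    """Assembled sequence with a contiguous region breakdown and warnings."""

    sequence: str
    translation: str
    offsets: dict[str, tuple[int, int]]
    warnings: list[StitchWarning]
    decomposition: JunctionDecomposition
    request: StitchRequest
    v_record: SegmentRecord = None
    j_record: SegmentRecord = None

    @property
    def junction_interval(self) -> tuple[int, int]:
        """Span of the junction (V Cys codon .. J anchor codon) in sequence
        coordinates.  For seamless mode, the span of the provided sequence."""
        return self._junction_interval

    @property
    def variable_interval(self) -> tuple[int, int]:
        """Start of the V germline to end of the J germline."""
        return (self.offsets["v_germline"][0], self.offsets["j_germline"][1])

    @property
    def variable_nt(self) -> str:
        a, b = self.variable_interval
        return self.sequence[a:b]


# ---------------------------------------------------------------------------
# decomposition and assembly


def decompose_junction(
    req: StitchRequest,
    v: SegmentRecord,
    j: SegmentRecord,
    table: CodonUsageTable,
    sl_min_overlap: int = 10,
) -> tuple[JunctionDecomposition, list[StitchWarning]]:
    """Attribute the junction to germline V / fill / germline J.

    Raises :class:`StitchError` subclasses when the junction cannot be
    decomposed (unanchorable terminal residue, out-of-frame NT input,
    seamless overlap below the minimum).
    """
    warnings: list[StitchWarning] = []
    if req.mode == "SL":
        return _decompose_seamless(req, v, j, sl_min_overlap), warnings

    if req.mode == "NT":
        if not _DNA_RE.match(req.junction):
            raise StitchError("NT-mode junction contains non-ACGT characters",
                              stage="junction")
        if len(req.junction) % 3 != 0:
            raise FrameError(
                f"NT-mode junction length {len(req.junction)} is not a "
                "multiple of 3"
            )
        junction_aa = translate(req.junction)
        if "*" in junction_aa:
            raise StitchError("NT-mode junction encodes a stop codon",
                              stage="junction")
    else:
        if not _AA_RE.match(req.junction):
            raise StitchError("AA-mode junction contains non-amino-acid "
                              "characters", stage="junction")
        junction_aa = req.junction

    v_aa = translate(v.sequence)
    j_aa = translate(j.sequence)
    cys = conserved_cys_index(v_aa)
    anchor = conserved_anchor_index(j_aa)
    n = len(v_aa)

    if junction_aa[0] != "C":
        warnings.append(StitchWarning(
            "junction_no_cys", "junction does not begin with C"))
    if junction_aa[-1] not in J_ANCHOR_RESIDUES:
        warnings.append(StitchWarning(
            "junction_no_fw",
            "junction does not end with F/W (or locus-appropriate residue)"))

    v_used, v_del = _v_attribution(v_aa, junction_aa, max_deletion=n - cys - 1)
    if v_used == 0:
        # No junction prefix reachable by trimming back to the Cys: remove
        # the whole post-Cys region (Cys included) and fill everything.
        v_del = n - cys
        warnings.append(StitchWarning(
            "no_v_overlap",
            "no overlap between junction start and germline V; junction "
            "fully non-templated on the V side"))

    remainder = junction_aa[v_used:]
    j_used = j_overlap_aa(j_aa, remainder, anchor)

    L = len(junction_aa)
    non_templated = junction_aa[v_used : L - j_used]
    if req.mode == "NT":
        fill_nt = req.junction[3 * v_used : 3 * (L - j_used)]
    else:
        fill_nt = fill_non_templated(non_templated, table)

    v_part = v.sequence[3 * (n - v_del - v_used) : 3 * (n - v_del)]
    j_part = j.sequence[3 * (anchor + 1 - j_used) : 3 * (anchor + 1)]
    junction_nt = v_part + fill_nt + j_part
    span = (len(v_part), len(v_part) + len(fill_nt))
    return (
        JunctionDecomposition(
            v_residues_used=v_used,
            j_residues_used=j_used,
            non_templated_aa=non_templated,
            junction_nt=junction_nt,
            nt_fill_span=span,
            v_deletions=v_del,
            j_anchor=anchor,
        ),
        warnings,
    )


def _decompose_seamless(
    req: StitchRequest, v: SegmentRecord, j: SegmentRecord, min_overlap: int
) -> JunctionDecomposition:
    s = req.junction
    if not _DNA_RE.match(s):
        raise StitchError("SL-mode junction contains non-ACGT characters",
                          stage="junction")
    if len(s) < 2 * min_overlap:
        raise SeamlessOverlapError(
            f"seamless input of {len(s)} nt is shorter than twice the "
            f"minimum overlap ({min_overlap})"
        )
    # 5' side: longest prefix of the provided sequence found in the V;
    # rightmost occurrence = least germline deletion.
    v_seq, j_seq = v.sequence, j.sequence
    v_cut = None
    for k in range(min(len(s), len(v_seq)), min_overlap - 1, -1):
        pos = v_seq.rfind(s[:k])
        if pos >= 0:
            v_cut = pos
            break
    if v_cut is None:
        raise SeamlessOverlapError(
            f"no exact overlap of >= {min_overlap} nt between the provided "
            "sequence 5' end and the V gene"
        )
    # 3' side: longest suffix of the provided sequence found in the J;
    # leftmost occurrence = least germline deletion.
    j_cut = None
    for k in range(min(len(s), len(j_seq)), min_overlap - 1, -1):
        pos = j_seq.find(s[-k:])
        if pos >= 0:
            j_cut = pos + k
            break
    if j_cut is None:
        raise SeamlessOverlapError(
            f"no exact overlap of >= {min_overlap} nt between the provided "
            "sequence 3' end and the J gene"
        )
    return JunctionDecomposition(
        v_residues_used=0,
        j_residues_used=0,
        non_templated_aa="",
        junction_nt=s,
        nt_fill_span=(0, len(s)),
        sl_v_cut=v_cut,
        sl_j_cut=j_cut,
    )


def stitch(
    req: StitchRequest,
    ref: ReferenceSet,
    sl_min_overlap: int = 10,
    allow_pseudogenes: bool = False,
    strict: bool = False,
) -> StitchResult:
    """Assemble the full-length coding sequence for one rearrangement.

    Non-canonical junction boundaries and leader fallback produce coded
    warnings; ``strict`` upgrades warnings to errors.  Errors raised by the
    decomposition or reference lookups propagate with their failing stage.
    """
    warnings: list[StitchWarning] = []

    v_rec, _ = resolve_segment(ref, req.v_call, SegmentType.VARIABLE)
    j_rec, _ = resolve_segment(ref, req.j_call, SegmentType.JOINING)
    for rec in (v_rec, j_rec):
        if rec.functionality == "P":
            if not allow_pseudogenes:
                raise StitchError(
                    f"{rec.name} is a pseudogene; pass allow_pseudogenes to "
                    "stitch with it", stage="resolve")
            warnings.append(StitchWarning(
                "pseudogene", f"{rec.name} is annotated as a pseudogene"))
        if rec.partial:
            warnings.append(StitchWarning(
                "partial_reference",
                f"{rec.name} has only partial sequence recorded"))

    leader_call = req.leader_override or req.v_call
    leader_rec, lw = resolve_segment(ref, leader_call, SegmentType.LEADER)
    for msg in lw:
        warnings.append(StitchWarning("leader_fallback", msg))

    chain = req.chain or chain_of(req.v_call) or chain_of(req.j_call)
    const_rec, _ = default_constant(
        ref, req.j_call, chain=chain, species=req.species,
        override=req.constant_override,
    )

    decomp, dw = decompose_junction(
        req, v_rec, j_rec, ref.codon_table, sl_min_overlap=sl_min_overlap
    )
    warnings.extend(dw)

    if req.mode == "SL":
        v_block = v_rec.sequence[: decomp.sl_v_cut]
        j_block = j_rec.sequence[decomp.sl_j_cut :]
        fill = decomp.junction_nt
    else:
        n = len(v_rec.sequence) // 3
        v_block = v_rec.sequence[: 3 * (n - decomp.v_deletions)]
        j_block = j_rec.sequence[3 * (decomp.j_anchor + 1 - decomp.j_residues_used) :]
        a, b = decomp.nt_fill_span
        fill = decomp.junction_nt[a:b]

    parts = {
        "extra5": req.extra_5prime,
        "leader": leader_rec.sequence,
        "v_germline": v_block,
        "junction_fill": fill,
        "j_germline": j_block,
        "constant": const_rec.sequence,
        "extra3": req.extra_3prime,
    }
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for region, seq_part in parts.items():
        offsets[region] = (pos, pos + len(seq_part))
        pos += len(seq_part)
    sequence = "".join(parts.values())

    coding_len = len(sequence) - len(req.extra_5prime) - len(req.extra_3prime)
    if coding_len % 3 != 0:
        raise FrameError(
            f"assembled coding span of {coding_len} nt is not a multiple of "
            "3; check the provided junction context"
        )
    coding = sequence[offsets["leader"][0] : offsets["extra3"][0]]
    translation = translate(coding)
    if "*" in translation[:-1]:
        warnings.append(StitchWarning(
            "internal_stop", "translation contains an internal stop codon"))

    if strict and warnings:
        raise StitchError(
            "strict mode: " + "; ".join(str(w) for w in warnings),
            stage="strict")

    result = StitchResult(
        sequence=sequence,
        translation=translation,
        offsets=offsets,
        warnings=warnings,
        decomposition=decomp,
        request=req,
        v_record=v_rec,
        j_record=j_rec,
    )
    if req.mode == "SL":
        result._junction_interval = offsets["junction_fill"]
    else:
        # Cys codon start .. J anchor codon end
        start = offsets["junction_fill"][0] - (
            len(decomp.junction_nt) - (decomp.nt_fill_span[1] - decomp.nt_fill_span[0])
            - 3 * decomp.j_residues_used
        )
        result._junction_interval = (start, start + len(decomp.junction_nt))
    return result
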