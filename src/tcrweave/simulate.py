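"""V(D)J recombination simulator and bundled synthetic fixture reference.

The simulator provides ground truth for end-to-end testing of stitching and
annotation: it recombines germline V and J alleles from a
:class:`~tcrweave.reference.ReferenceSet`, applying exonucleolytic trimming
at the V 3' and J 5' ends and random non-templated insertion (which subsumes
any D contribution), then filters for in-frame, stop-free products whose
junction starts at the conserved Cys, ends in one of the conserved terminal
residues (F/W/C) and is at least eight residues long.

``fixture_reference`` builds a small, fully synthetic germline reference --
IMGT-style gene names with randomly generated sequences that satisfy the
structural constraints of real loci (V ends in a Cys-led motif, J carries a
single [FWC]-G-x-G anchor, leaders start with ATG, constants end with a
stop).  It is deterministic under its seed and small enough to hand-check.
Sequences are NOT biological; gene names are reused purely so that locus
naming rules (e.g. the TRBJ cluster -> TRBC pairing) can be exercised.

Trim and insertion distributions are fixture knobs, not biological claims:
trims are uniform on [0, max], insertion lengths bounded-geometric, inserted
bases uniform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import SimulationError
from .reference import (
    GeneIdentifier,
    ReferenceSet,
    SegmentRecord,
    SegmentType,
    chain_of,
    default_constant,
    packaged_codon_table,
    resolve_segment,
)
from .stitch import conserved_anchor_index, conserved_cys_index, translate

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_ALL_CODONS = sorted(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)
_NONSTOP_CODONS = [c for c in _ALL_CODONS if c not in _STOPS]

# codon choices per residue for constrained fixture positions
_CODONS_BY_AA: dict[str, list[str]] = {}
for _c in _NONSTOP_CODONS:
    _CODONS_BY_AA.setdefault(translate(_c), []).append(_c)

# residues allowed after the conserved Cys at the V 3' end: no C (the Cys
# must stay 3'-most), no G (avoids spurious single-residue junction-prefix
# matches inside the post-Cys region), no F/W (reserved for J anchors).
_POST_CYS_AA = "ASTLVNDEQ"
# J residues 5' of the anchor and in the tail: no F/W/C keeps the anchor
# motif unique within each J.
_J_SAFE_AA = "ASTLVNDEQGYIKMHPR"


def _rand_codons(rng: np.random.Generator, n: int,
                 choices: Sequence[str] = _NONSTOP_CODONS) -> str:
    return "".join(rng.choice(np.array(choices), size=n))


def _rand_aa_codons(rng: np.random.Generator, residues: str) -> str:
    return "".join(
        _CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))]
        for aa in residues
    )


def fixture_reference(seed: int = 0) -> ReferenceSet:
    """Deterministic synthetic germline reference for tests and demos.

    Contains 6 TRBV + 2 TRAV genes (two with a second allele), 4 TRBJ genes
    across both clusters + 2 TRAJ, TRBC1/TRBC2/TRAC constants and per-gene
    *01 leaders (the *02 alleles deliberately lack leaders so the *01
    fallback path is exercised).
    """
    rng = np.random.default_rng(seed)
    records: list[SegmentRecord] = []

    v_genes = ["TRBV1-1", "TRBV2-1", "TRBV3-1", "TRBV4-1", "TRBV5-1",
               "TRBV6-1", "TRAV1", "TRAV2"]
    j_genes = ["TRBJ1-1", "TRBJ1-2", "TRBJ2-1", "TRBJ2-2", "TRAJ1", "TRAJ2"]
    c_genes = ["TRBC1", "TRBC2", "TRAC"]
    variant_alleles = {"TRBV2-1", "TRAV2"}  # genes that also get a *02

    def add(gene: str, allele: str, stype: SegmentType, seq: str) -> None:
        records.append(SegmentRecord(
            id=GeneIdentifier(gene, allele), segment_type=stype,
            functionality="F", sequence=seq, species="human",
        ))

    for gene in v_genes:
        # 96 unconstrained codons + Cys + 3 post-Cys residues = 300 nt
        body = _rand_codons(rng, 96)
        cys = ["TGT", "TGC"][rng.integers(2)]
        post = "".join(_POST_CYS_AA[i]
                       for i in rng.integers(len(_POST_CYS_AA), size=3))
        seq = body + cys + _rand_aa_codons(rng, post)
        assert len(seq) == 300 and conserved_cys_index(translate(seq)) == 96
        add(gene, "01", SegmentType.VARIABLE, seq)
        leader = "ATG" + _rand_codons(rng, 15)
        add(gene, "01", SegmentType.LEADER, leader)
        if gene in variant_alleles:
            add(gene, "02", SegmentType.VARIABLE, _snv(seq, 150, rng))

    for gene in j_genes:
        while True:
            head = "".join(_J_SAFE_AA[i] for i in
                           rng.integers(len(_J_SAFE_AA) - 8, size=5))
            x = _J_SAFE_AA[rng.integers(len(_J_SAFE_AA) - 8)]
            tail = "".join(_J_SAFE_AA[i] for i in
                           rng.integers(len(_J_SAFE_AA), size=11))
            aa = head + "FG" + x + "G" + tail
            seq = _rand_aa_codons(rng, aa)
            try:
                if conserved_anchor_index(translate(seq)) == 5 and \
                        len(_re_anchor_hits(translate(seq))) == 1:
                    break
            except Exception:
                continue
        assert len(seq) == 60
        add(gene, "01", SegmentType.JOINING, seq)

    for gene in c_genes:
        add(gene, "01", SegmentType.CONSTANT, _rand_codons(rng, 29) + "TAA")

    return ReferenceSet("human", records, packaged_codon_table("human"))


def _re_anchor_hits(aa: str) -> list[int]:
    import re
    return [m.start() for m in re.finditer(r"[FWC]G.G", aa)]


def _snv(seq: str, pos: int, rng: np.random.Generator) -> str:
    """Substitute position ``pos`` with the first alternative base that
    keeps the affected codon stop-free."""
    for alt in "ACGT":
        if alt == seq[pos]:
            continue
        new = seq[:pos] + alt + seq[pos + 1 :]
        codon_start = pos - pos % 3
        if new[codon_start : codon_start + 3] not in _STOPS:
            return new
    raise SimulationError("no valid substitution found")  # pragma: no cover


# ---------------------------------------------------------------------------


@dataclass
class SimParams:
    """Simulation settings; ``seed`` fully determines the output."""

    n: int
    chain: str = "TRB"
    max_v_trim: int = 8
    max_j_trim: int = 8
    insert_p: float = 0.25  # geometric parameter; mean length ~3
    max_insert: int = 15
    min_junction_aa: int = 8
    terminal_residues: str = "FWC"
    seed: int = 1
    v_alleles: Optional[Sequence[str]] = None  # restrict draws, e.g. ["TRBV1-1*01"]
    j_alleles: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if self.n < 0 or self.max_v_trim < 0 or self.max_j_trim < 0:
            raise SimulationError("counts and trims must be non-negative")


@dataclass
class SimRecombination:
    """Ground truth for one simulated rearrangement."""

    name: str
    chain: str
    v_allele: GeneIdentifier
    j_allele: GeneIdentifier
    v_trim: int
    j_trim: int
    inserted_nt: str
    full_nt: str
    junction_nt: str
    junction_aa: str
    leader_len: int
    constant_len: int
    junction_start: int  # within full_nt
    junction_end: int
    non_templated_interval: tuple[int, int]  # within full_nt

    @property
    def variable_nt(self) -> str:
        """Start of the V-REGION to the end of the J-REGION."""
        return self.full_nt[self.leader_len : len(self.full_nt) - self.constant_len]

    @property
    def variable_aa(self) -> str:
        return translate(self.variable_nt)


def _candidate_alleles(ref: ReferenceSet, chain: str, stype: SegmentType,
                       restrict: Optional[Sequence[str]]) -> list[SegmentRecord]:
    if restrict is not None:
        recs = [resolve_segment(ref, call, stype)[0] for call in restrict]
    else:
        recs = [r for r in ref.records(stype)
                if r.id.gene_name.startswith(chain)]
    if not recs:
        raise SimulationError(f"no {stype.value} alleles for chain {chain}")
    return recs


def simulate_repertoire(ref: ReferenceSet, params: SimParams) -> list[SimRecombination]:
    """Draw ``params.n`` valid rearrangements by rejection sampling.

    Draws failing the in-frame, stop-free, minimum-length, Cys-start or
    terminal-residue filters are rejected and redrawn; a rejection rate
    above 99% over a 1000-draw window raises (pathological parameters).
    """
    rng = np.random.default_rng(params.seed)
    vs = _candidate_alleles(ref, params.chain, SegmentType.VARIABLE, params.v_alleles)
    js = _candidate_alleles(ref, params.chain, SegmentType.JOINING, params.j_alleles)

    sims: list[SimRecombination] = []
    attempts = 0
    accepted_in_window = 0
    while len(sims) < params.n:
        attempts += 1
        if attempts % 1000 == 0:
            if accepted_in_window < 10:
                raise SimulationError(
                    "rejection rate above 99% -- simulation parameters are "
                    "pathological for this reference")
            accepted_in_window = 0

        v = vs[rng.integers(len(vs))]
        j = js[rng.integers(len(js))]
        v_trim = int(rng.integers(params.max_v_trim + 1))
        j_trim = int(rng.integers(params.max_j_trim + 1))
        ins_len = min(int(rng.geometric(params.insert_p)) - 1, params.max_insert)
        ins = "".join(_BASES[rng.integers(4, size=ins_len)]) if ins_len else ""

        v_aa = translate(v.sequence)
        cys_nt = 3 * conserved_cys_index(v_aa)
        anchor_nt_end = 3 * (conserved_anchor_index(translate(j.sequence)) + 1)
        v_keep = len(v.sequence) - v_trim
        if v_keep < cys_nt + 3 or j_trim > anchor_nt_end - 3:
            continue  # trim would invade a conserved anchor codon
        junction_nt = v.sequence[cys_nt:v_keep] + ins + j.sequence[j_trim:anchor_nt_end]
        if len(junction_nt) % 3 != 0:
            continue
        junction_aa = translate(junction_nt)
        if (
            "*" in junction_aa
            or len(junction_aa) < params.min_junction_aa
            or junction_aa[0] != "C"
            or junction_aa[-1] not in params.terminal_residues
        ):
            continue

        leader, _ = resolve_segment(ref, str(v.id), SegmentType.LEADER)
        const, _ = default_constant(ref, j.id.gene_name, chain=params.chain)
        full = (leader.sequence + v.sequence[:v_keep] + ins
                + j.sequence[j_trim:] + const.sequence)
        jstart = len(leader.sequence) + cys_nt
        jend = len(leader.sequence) + v_keep + len(ins) + (anchor_nt_end - j_trim)
        nt_start = len(leader.sequence) + v_keep
        sims.append(SimRecombination(
            name=f"sim{len(sims):05d}",
            chain=params.chain,
            v_allele=v.id,
            j_allele=j.id,
            v_trim=v_trim,
            j_trim=j_trim,
            inserted_nt=ins,
            full_nt=full,
            junction_nt=junction_nt,
            junction_aa=junction_aa,
            leader_len=len(leader.sequence),
            constant_len=len(const.sequence),
            junction_start=jstart,
            junction_end=jend,
            non_templated_interval=(nt_start, nt_start + len(ins)),
        ))
        accepted_in_window += 1
    return sims


# ---------------------------------------------------------------------------
# adapters toward the stitcher and the annotator


def to_stitch_inputs(
    sims: Iterable[SimRecombination],
    mode: str = "AA",
    pad_5: int = 0,
    pad_3: int = 0,
):
    """Convert simulations to batch rows for the given junction mode.

    SL rows carry the true junction nucleotides extended by ``pad_5``/
    ``pad_3`` germline-context nucleotides taken from the simulated full
    sequence; pads exceeding the available V/J context are truncated with a
    logged warning.
    """
    from .batch import BatchRow, ChainInput

    mode = mode.upper()
    rows = []
    for sim in sims:
        if mode == "AA":
            junction = sim.junction_aa
        elif mode == "NT":
            junction = sim.junction_nt
        elif mode == "SL":
            p5 = min(pad_5, sim.junction_start - sim.leader_len)
            # keep the 3' pad inside the J gene so its suffix stays matchable
            j_avail = (len(sim.full_nt) - sim.constant_len) - sim.junction_end
            p3 = min(pad_3, j_avail)
            if p5 < pad_5 or p3 < pad_3:
                log.warning("%s: pads truncated to %d/%d (available context)",
                            sim.name, p5, p3)
            junction = sim.full_nt[sim.junction_start - p5 : sim.junction_end + p3]
        else:
            raise SimulationError(f"unknown mode {mode!r}")
        slot = "alpha" if sim.chain in ("TRA", "TRG") else "beta"
        rows.append(BatchRow(
            name=sim.name,
            chains={slot: ChainInput(
                v_call=str(sim.v_allele), j_call=str(sim.j_allele),
                junction=junction, mode=mode,
            )},
        ))
    return rows


@dataclass
class SimRead:
    """A read emitted for the annotator, with its ground-truth provenance."""

    read_id: str
    sequence: str
    sim: SimRecombination
    truncated: bool = False
    carrier: bool = False


def reads_for_annotation(
    sims: Iterable[SimRecombination],
    truncate_offset: int = 0,
) -> list[SimRead]:
    """Window full-length simulated molecules into annotator reads.

    With ``truncate_offset=0`` reads start exactly at the V-REGION start
    (v_jump of 0 after annotation); a positive offset emits 5'-truncated
    reads that the full-length filter should reject.
    """
    reads = []
    for sim in sims:
        start = sim.leader_len + truncate_offset
        reads.append(SimRead(
            read_id=f"{sim.name}/r",
            sequence=sim.full_nt[start:],
            sim=sim,
            truncated=truncate_offset > 0,
        ))
    return reads


def apply_snv(read: SimRead, position: int, alt_base: str) -> SimRead:
    """Return a copy of ``read`` with a substitution at 1-based V-REGION
    ``position`` (reads start at the V start, so read offset = position-1)."""
    idx = position - 1
    if idx < 0 or idx >= len(read.sequence):
        raise SimulationError(f"position {position} outside read")
    seq = read.sequence[:idx] + alt_base + read.sequence[idx + 1 :]
    return replace(read, sequence=seq, carrier=True)


def inject_snv_reads(
    sims: Sequence[SimRecombination],
    ref: ReferenceSet,
    gene: str,
    position: int,
    alt_base: str,
    carrier_fraction: float,
    seed: int,
    reads_per_sim: int = 1,
    carrier_reads_per_sim: Optional[int] = None,
) -> list[SimRead]:
    """Emit full-length reads where a fraction of one gene's reads carry a
    single-nucleotide variant.

    ``position`` is 1-based within the V allele; it must be interior to the
    germline-retained portion of every selected rearrangement.  Carrier
    rearrangements are chosen deterministically from ``seed``; ground-truth
    carrier labels are retained on the reads.  ``carrier_reads_per_sim``
    lets carriers be over-represented relative to ``reads_per_sim`` so read-
    versus recombination-level inference thresholds can be controlled
    independently.
    """
    gene_sims = [s for s in sims if s.v_allele.gene_name == gene]
    if not gene_sims:
        raise SimulationError(f"no simulated rearrangements use gene {gene!r}")
    allele_seq = resolve_segment(ref, str(gene_sims[0].v_allele),
                                 SegmentType.VARIABLE)[0].sequence
    if not (1 <= position <= len(allele_seq)):
        raise SimulationError(
            f"position {position} outside gene {gene} "
            f"(length {len(allele_seq)})")
    if alt_base not in "ACGT" or alt_base == allele_seq[position - 1]:
        raise SimulationError(
            f"alt base {alt_base!r} invalid or equal to the reference base "
            f"at position {position}")
    rng = np.random.default_rng(seed)
    n_carriers = int(round(carrier_fraction * len(gene_sims)))
    carrier_idx = set(
        rng.choice(len(gene_sims), size=n_carriers, replace=False).tolist()
    ) if n_carriers else set()
    carrier_reads = (carrier_reads_per_sim if carrier_reads_per_sim is not None
                     else reads_per_sim)

    out: list[SimRead] = []
    carrier_sims = {id(gene_sims[i]) for i in carrier_idx}
    for sim in sims:
        base = SimRead(read_id=f"{sim.name}/r0",
                       sequence=sim.full_nt[sim.leader_len :], sim=sim)
        if id(sim) in carrier_sims:
            if position - 1 >= len(sim.full_nt) - sim.leader_len:
                raise SimulationError(
                    f"position {position} outside read for {sim.name}")
            for i in range(carrier_reads):
                r = apply_snv(base, position, alt_base)
                out.append(replace(r, read_id=f"{sim.name}/r{i}"))
        else:
            for i in range(reads_per_sim):
                out.append(replace(base, read_id=f"{sim.name}/r{i}"))
    return out


# ---------------------------------------------------------------------------


@dataclass
class MismatchReport:
    """Positional comparison of a stitched sequence against ground truth."""

    positions: list[int]
    relative: list[float]
    length: int
    alignment_failure: bool = False

    @property
    def identical(self) -> bool:
        return not self.alignment_failure and not self.positions


def compare_sequences(truth: str, stitched: str) -> MismatchReport:
    """Positions of base mismatches between equal-length sequences.

    A length difference is reported as a single alignment failure rather
    than positional mismatches.  Relative positions are scaled to [0, 1]
    for histogramming along the variable domain.
    """
    if len(truth) != len(stitched):
        return MismatchReport([], [], len(truth), alignment_failure=True)
    pos = [i for i, (a, b) in enumerate(zip(truth, stitched)) if a != b]
    denom = max(len(truth) - 1, 1)
    return MismatchReport(pos, [p / denom for p in pos], len(truth))
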