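"""Germline reference handling for V(D)J sequence assembly.

This module reads IMGT/GENE-DB-dialect FASTA files (pipe-delimited headers)
into typed segment records, indexes them for gene*allele lookup, and loads
species codon-usage tables used to back-translate non-templated junction
residues.

The reference model mirrors how TCR expression constructs are built from
four kinds of germline block:

* ``LEADER`` -- the spliced signal-peptide exons (L-PART1+L-PART2) stored as
  one pre-joined block 5' of the V;
* ``VARIABLE`` -- the V-REGION, ending a few residues after the conserved
  second cysteine that opens the CDR3 junction;
* ``JOINING`` -- the J-REGION, carrying the conserved [FWC]-G-x-G motif
  whose first residue closes the junction;
* ``CONSTANT`` -- the spliced, in-frame constant-region coding block.
"""

from __future__ import annotations

import difflib
import importlib.resources
import io
import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

from .errors import (
    CodonTableError,
    ReferenceError,
    UnknownAlleleError,
    UnknownGeneError,
)

log = logging.getLogger(__name__)

_DNA_RE = re.compile(r"^[ACGT]+$")


class SegmentType(str, Enum):
    """Kind of germline block a record encodes."""

    LEADER = "LEADER"
    VARIABLE = "VARIABLE"
    JOINING = "JOINING"
    CONSTANT = "CONSTANT"


#: IMGT region labels (header field 5) mapped onto segment types.  Constant
#: regions may be described either as a single C-REGION or as pre-joined
#: exon lists (EX1+EX2+...).
_REGION_LABELS = {
    "L-PART1+L-PART2": SegmentType.LEADER,
    "V-REGION": SegmentType.VARIABLE,
    "J-REGION": SegmentType.JOINING,
    "C-REGION": SegmentType.CONSTANT,
}

_FUNCTIONALITY = {"F", "ORF", "P"}


def _region_from_label(label: str) -> SegmentType | None:
    label = label.strip()
    if label in _REGION_LABELS:
        return _REGION_LABELS[label]
    if label.startswith("EX"):
        return SegmentType.CONSTANT
    return None


@dataclass(frozen=True, order=True)
class GeneIdentifier:
    """IMGT-style ``gene*allele`` identity, e.g. ``TRBV6-5*01``.

    ``allele`` is two-digit text, optionally carrying an inferred-variant
    suffix such as ``01_A233G``.
    """

    gene_name: str
    allele: str = "01"

    @classmethod
    def parse(cls, text: str) -> "GeneIdentifier":
        text = text.strip()
        if "*" in text:
            gene, _, allele = text.partition("*")
            if not gene or not allele:
                raise ReferenceError(f"malformed gene identifier: {text!r}")
            return cls(gene, allele)
        if not text:
            raise ReferenceError("empty gene identifier")
        return cls(text, "01")

    def __str__(self) -> str:  # round-trips with parse()
        return f"{self.gene_name}*{self.allele}"


@dataclass
class SegmentRecord:
    """One germline sequence block with its identity and IMGT annotations."""

    id: GeneIdentifier
    segment_type: SegmentType
    functionality: str
    sequence: str
    partial: bool = False
    accession: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace(".", "").strip()
        if not self.sequence:
            raise ReferenceError(f"{self.id}: empty sequence")
        if not _DNA_RE.match(self.sequence):
            raise ReferenceError(f"{self.id}: non-ACGT characters in sequence")
        if self.functionality not in _FUNCTIONALITY:
            raise ReferenceError(
                f"{self.id}: unknown functionality {self.functionality!r}"
            )

    @property
    def name(self) -> str:
        return str(self.id)


def parse_imgt_fasta(text: str) -> list[SegmentRecord]:
    """Parse IMGT/GENE-DB-dialect FASTA content into segment records.

    Header fields are pipe-delimited: accession | gene*allele | species |
    functionality | region label | ... .  Functionality qualifiers in
    parentheses/brackets are stripped; alignment gaps ``.`` are removed from
    sequences.  Records with unmapped region labels or malformed headers are
    skipped with a logged warning.
    """
    entries: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    for line in io.StringIO(text):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                entries.append((header, "".join(chunks)))
            header, chunks = line[1:], []
        elif header is not None:
            chunks.append(line)
    if header is not None:
        entries.append((header, "".join(chunks)))
    if not entries:
        raise ReferenceError("no FASTA entries found in reference input")

    records: list[SegmentRecord] = []
    for head, seq in entries:
        fields = [f.strip() for f in head.split("|")]
        if len(fields) < 5:
            log.warning("skipping record with malformed header (<5 fields): %s", head)
            continue
        accession, name, species, functionality, label = fields[:5]
        functionality = functionality.strip("()[]")
        segment_type = _region_from_label(label)
        if segment_type is None:
            log.warning("skipping %s: unmapped region label %r", name, label)
            continue
        try:
            gid = GeneIdentifier.parse(name)
            rec = SegmentRecord(
                id=gid,
                segment_type=segment_type,
                functionality=functionality,
                sequence=seq,
                partial="partial" in head.lower(),
                accession=accession,
                species=species,
            )
        except ReferenceError as exc:
            log.warning("skipping %s: %s", name, exc)
            continue
        records.append(rec)
    return records


def write_imgt_fasta(records: Iterable[SegmentRecord], width: int = 60) -> str:
    """Serialize records back to the IMGT FASTA dialect read by this module."""
    _LABELS = {
        SegmentType.LEADER: "L-PART1+L-PART2",
        SegmentType.VARIABLE: "V-REGION",
        SegmentType.JOINING: "J-REGION",
        SegmentType.CONSTANT: "C-REGION",
    }
    out: list[str] = []
    for rec in records:
        partial = "partial" if rec.partial else ""
        head = "|".join(
            [
                rec.accession or "X00000",
                rec.name,
                rec.species,
                rec.functionality,
                _LABELS[rec.segment_type],
                "",
                "",
                "",
                "",
                "",
                "",
                "",
                "",
                partial,
            ]
        )
        out.append(f">{head}")
        for i in range(0, len(rec.sequence), width):
            out.append(rec.sequence[i : i + width])
    return "\n".join(out) + "\n"


class CodonUsageTable:
    """Per-residue relative codon frequencies with a deterministic mode.

    Frequencies are normalized to sum to 1 per residue; ``modal_codon``
    returns the most frequent codon, breaking ties alphabetically so
    back-translation is reproducible.
    """

    def __init__(self, freqs: Mapping[str, Mapping[str, float]]):
        self._freqs: dict[str, dict[str, float]] = {}
        for aa, codons in freqs.items():
            if not codons:
                raise CodonTableError(f"residue {aa!r} has no codons")
            total = float(sum(codons.values()))
            if total <= 0:
                raise CodonTableError(f"residue {aa!r} has zero total frequency")
            self._freqs[aa] = {c: v / total for c, v in codons.items()}

    @classmethod
    def from_tsv(cls, text: str) -> "CodonUsageTable":
        """Load from TSV with columns codon, amino_acid, fraction."""
        freqs: dict[str, dict[str, float]] = {}
        lines = [ln for ln in text.splitlines() if ln.strip()]
        start = 1 if lines and lines[0].lower().startswith("codon") else 0
        for ln in lines[start:]:
            parts = ln.split("\t")
            if len(parts) < 3:
                raise CodonTableError(f"malformed codon table row: {ln!r}")
            codon, aa, frac = parts[0].strip().upper(), parts[1].strip(), parts[2]
            if len(codon) != 3 or not _DNA_RE.match(codon):
                raise CodonTableError(f"invalid codon {codon!r}")
            freqs.setdefault(aa, {})[codon] = float(frac)
        if not freqs:
            raise CodonTableError("empty codon table")
        return cls(freqs)

    def frequencies(self, residue: str) -> dict[str, float]:
        try:
            return dict(self._freqs[residue])
        except KeyError:
            raise CodonTableError(f"no codons recorded for residue {residue!r}")

    def modal_codon(self, residue: str) -> str:
        codons = self.frequencies(residue)
        best = max(codons.values())
        return min(c for c, v in codons.items() if v == best)

    def residues(self) -> list[str]:
        return sorted(self._freqs)


def load_codon_table(text: str) -> CodonUsageTable:
    return CodonUsageTable.from_tsv(text)


def packaged_codon_table(species: str = "human") -> CodonUsageTable:
    """Load the codon-usage table bundled with the package."""
    name = f"codon_usage_{species.lower()}.tsv"
    try:
        data = (
            importlib.resources.files("tcrweave.data").joinpath(name).read_text()
        )
    except FileNotFoundError:
        raise CodonTableError(f"no packaged codon table for species {species!r}")
    return CodonUsageTable.from_tsv(data)


class ReferenceSet:
    """Indexed germline segments for one species plus a codon-usage table.

    Lookup is exact on ``(gene_name, allele, segment_type)``.  Additional or
    modified records (for example inferred novel alleles) can be merged on
    top; identical keys are overwritten with a logged notice.
    """

    def __init__(
        self,
        species: str,
        records: Iterable[SegmentRecord],
        codon_table: CodonUsageTable,
    ):
        self.species = species
        self.codon_table = codon_table
        self._index: dict[tuple[str, str, SegmentType], SegmentRecord] = {}
        for rec in records:
            self.add(rec, notice=False)

    # -- construction ------------------------------------------------------

    def add(self, record: SegmentRecord, notice: bool = True) -> None:
        key = (record.id.gene_name, record.id.allele, record.segment_type)
        if key in self._index and notice:
            log.info("overwriting existing record %s (%s)", record.name,
                     record.segment_type.value)
        self._index[key] = record

    def merge(self, records: Iterable[SegmentRecord]) -> None:
        for rec in records:
            self.add(rec)

    def copy(self) -> "ReferenceSet":
        new = ReferenceSet(self.species, [], self.codon_table)
        new._index = dict(self._index)
        return new

    # -- queries -----------------------------------------------------------

    def records(self, segment_type: SegmentType | None = None) -> list[SegmentRecord]:
        recs = [
            r
            for r in self._index.values()
            if segment_type is None or r.segment_type == segment_type
        ]
        return sorted(recs, key=lambda r: (r.segment_type.value, r.name))

    def genes(self, segment_type: SegmentType) -> list[str]:
        return sorted({g for g, _, t in self._index if t == segment_type})

    def alleles(self, gene_name: str, segment_type: SegmentType) -> list[str]:
        return sorted(
            a for g, a, t in self._index if g == gene_name and t == segment_type
        )

    def get(
        self, gene_name: str, allele: str, segment_type: SegmentType
    ) -> SegmentRecord | None:
        return self._index.get((gene_name, allele, segment_type))

    def checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for rec in self.records():
            h.update(
                f"{rec.name}|{rec.segment_type.value}|{rec.sequence}\n".encode()
            )
        return h.hexdigest()


def resolve_segment(
    ref: ReferenceSet, call: str, segment_type: SegmentType
) -> tuple[SegmentRecord, list[str]]:
    """Resolve a gene call to a stored segment record.

    A bare gene name defaults to the prototypical ``*01`` allele.  For LEADER
    requests the fallback chain is: exact allele, then the base allele of an
    inferred-variant suffix, then ``*01`` (with a warning message returned) --
    leaders are frequently unrecorded for minor alleles.

    Returns ``(record, warnings)``; raises :class:`UnknownGeneError` /
    :class:`UnknownAlleleError` on failure.
    """
    gid = GeneIdentifier.parse(call)
    genes = ref.genes(segment_type)
    warnings: list[str] = []
    if gid.gene_name not in genes:
        near = difflib.get_close_matches(gid.gene_name, genes, n=5, cutoff=0.4)
        raise UnknownGeneError(
            f"gene {gid.gene_name!r} not found in reference "
            f"({segment_type.value}); near matches: {near if near else genes[:8]}"
        )
    rec = ref.get(gid.gene_name, gid.allele, segment_type)
    if rec is not None:
        return rec, warnings
    if segment_type == SegmentType.LEADER:
        candidates = [gid.allele.split("_")[0], "01"]
        for allele in candidates:
            rec = ref.get(gid.gene_name, allele, segment_type)
            if rec is not None:
                warnings.append(
                    f"leader for {gid} not recorded; substituting *{allele} leader"
                )
                return rec, warnings
    raise UnknownAlleleError(
        f"allele {gid} not found in reference ({segment_type.value}); "
        f"known alleles: {ref.alleles(gid.gene_name, segment_type)}"
    )


_TRBJ_CLUSTER_RE = re.compile(r"^TRBJ(\d)")


def chain_of(call: str) -> str | None:
    """Infer the TCR locus (TRA/TRB/TRG/TRD) from a gene call prefix."""
    m = re.match(r"^(TR[ABGD])[VJC]", call.strip().upper())
    return m.group(1) if m else None


def default_constant(
    ref: ReferenceSet,
    j_call: str,
    chain: str | None = None,
    species: str | None = None,
    override: str | None = None,
) -> tuple[SegmentRecord, list[str]]:
    """Pick the constant region implied by the J gene.

    An explicit ``override`` always wins.  Otherwise, for beta chains the J
    gene's cluster digit selects the constant (TRBJ1-n -> TRBC1, TRBJ2-n ->
    TRBC2); other loci use their single constant (TRAC etc.).  Species other
    than human or mouse have too-variable locus architecture for defaulting,
    so an explicit constant is required there.
    """
    if override:
        return resolve_segment(ref, override, SegmentType.CONSTANT)
    species = (species or ref.species or "").lower()
    if species not in ("human", "mouse"):
        raise ReferenceError(
            f"species {species!r}: the constant region must be specified "
            "explicitly for non-human/non-mouse species"
        )
    chain = chain or chain_of(j_call)
    if chain is None:
        raise ReferenceError(f"cannot infer locus from J call {j_call!r}")
    if chain == "TRB":
        m = _TRBJ_CLUSTER_RE.match(j_call.strip().upper())
        if not m:
            raise ReferenceError(
                f"cannot derive TRBC cluster from J call {j_call!r}"
            )
        return resolve_segment(ref, f"TRBC{m.group(1)}", SegmentType.CONSTANT)
    return resolve_segment(ref, f"{chain}C", SegmentType.CONSTANT)
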