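"""High-throughput stitching driver.

Reads a tab-separated rearrangement table (AIRR-style column verbs with
``alpha_``/``beta_`` chain prefixes; gamma/delta chains use the same two
slots), stitches every row with per-row error capture so one bad row never
aborts a run, optionally links paired chains into a single bicistronic open
reading frame via a 2A peptide (the 5' chain's stop codon is removed so the
frame runs through), and writes a results table echoing the input columns.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import BatchError, StitchError, TcrweaveError
from .reference import ReferenceSet
from .stitch import StitchRequest, StitchResult, stitch

log = logging.getLogger(__name__)

CHAIN_SLOTS = ("alpha", "beta")
_CHAIN_FIELDS = ("v_call", "j_call", "junction", "mode", "constant",
                 "leader", "extra_5prime", "extra_3prime")
_ROW_FIELDS = ("linker", "link_order")

#: Built-in linkers: 2A self-cleaving peptides with an N-terminal GSG spacer.
#: Any other linker value is treated as a literal nucleotide sequence.
LINKERS = {
    "P2A": "GGAAGCGGAGCTACTAACTTCAGCCTGCTGAAGCAGGCTGGAGACGTGGAGGAGAACCCTGGACCT",
    "T2A": "GGAAGCGGAGAGGGCAGAGGAAGTCTGCTAACATGCGGTGACGTCGAGGAGAATCCTGGACCT",
    "E2A": "GGAAGCGGACAGTGTACTAATTATGCTCTCTTGAAATTGGCTGGAGATGTTGAGAGCAACCCTGGACCT",
    "F2A": "GGAAGCGGAGTGAAACAGACTTTGAATTTTGACCTTCTCAAGTTGGCGGGAGACGTGGAGTCCAACCCTGGACCT",
}

_STOPS = ("TAA", "TAG", "TGA")
_DNA = set("ACGT")


@dataclass
class ChainInput:
    """One chain's stitching inputs within a batch row."""

    v_call: str
    j_call: str
    junction: str
    mode: Optional[str] = None  # AA | NT | SL; None = infer from alphabet
    constant: Optional[str] = None
    leader: Optional[str] = None
    extra_5prime: str = ""
    extra_3prime: str = ""

    def resolved_mode(self) -> str:
        if self.mode:
            return self.mode.upper()
        # pure-DNA junctions default to NT; anything else is amino acids.
        # Seamless mode is never inferred -- it must be requested.
        return "NT" if set(self.junction.upper()) <= _DNA else "AA"


@dataclass
class BatchRow:
    name: str
    chains: dict[str, ChainInput] = field(default_factory=dict)
    linker: Optional[str] = None
    link_order: str = "alpha"  # which chain slot sits 5' in linked output

    def __post_init__(self) -> None:
        if self.linker and len(self.chains) < 2:
            raise BatchError(
                f"row {self.name!r}: a linker requires both chains")


@dataclass
class BatchResult:
    row: BatchRow
    results: dict[str, StitchResult] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    linked_sequence: Optional[str] = None
    link_error: Optional[str] = None

    @property
    def status(self) -> str:
        requested = set(self.row.chains)
        failed = set(self.errors)
        if requested and failed == requested:
            return "FAILED"
        if failed or self.link_error:
            return "PARTIAL"
        return "OK"


def read_batch(source) -> list[BatchRow]:
    """Read rows from a TSV file path, file object, or string content.

    A ``name`` column plus at least one complete chain block (``<slot>_v_call``,
    ``<slot>_j_call``, ``<slot>_junction``) is mandatory; unknown columns are
    ignored with a warning, and empty cells mean "absent".
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", dtype=str).fillna("")
    df.columns = [c.strip() for c in df.columns]

    known = {"name"} | {f"{slot}_{f}" for slot in CHAIN_SLOTS
                        for f in _CHAIN_FIELDS} | set(_ROW_FIELDS)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        log.warning("ignoring unknown batch columns: %s", unknown)

    missing = []
    if "name" not in df.columns:
        missing.append("name")
    chain_ok = [
        slot for slot in CHAIN_SLOTS
        if all(f"{slot}_{f}" in df.columns
               for f in ("v_call", "j_call", "junction"))
    ]
    if not chain_ok:
        missing.extend(["v_call", "j_call", "junction"])
    if missing:
        raise BatchError(
            f"batch file missing mandatory columns: {sorted(set(missing))}")

    rows: list[BatchRow] = []
    for _, r in df.iterrows():
        chains: dict[str, ChainInput] = {}
        for slot in chain_ok:
            triple = [str(r.get(f"{slot}_{f}", "")).strip()
                      for f in ("v_call", "j_call", "junction")]
            if not any(triple):
                continue
            chains[slot] = ChainInput(
                v_call=triple[0], j_call=triple[1], junction=triple[2],
                mode=str(r.get(f"{slot}_mode", "")).strip() or None,
                constant=str(r.get(f"{slot}_constant", "")).strip() or None,
                leader=str(r.get(f"{slot}_leader", "")).strip() or None,
                extra_5prime=str(r.get(f"{slot}_extra_5prime", "")).strip(),
                extra_3prime=str(r.get(f"{slot}_extra_3prime", "")).strip(),
            )
        rows.append(BatchRow(
            name=str(r.get("name", "")).strip(),
            chains=chains,
            linker=str(r.get("linker", "")).strip() or None,
            link_order=str(r.get("link_order", "")).strip() or "alpha",
        ))
    return rows


def resolve_linker(linker: str) -> tuple[str, Optional[str]]:
    """Map a linker name to nucleotides; unknown names are taken literally
    (with a warning message returned) when they are valid DNA."""
    if linker.upper() in LINKERS:
        return LINKERS[linker.upper()], None
    seq = linker.upper()
    if set(seq) <= _DNA:
        warn = None
        if not linker.isupper() or len(seq) < 9:
            warn = f"linker {linker!r} not a known name; using it literally"
        return seq, warn
    raise BatchError(
        f"linker {linker!r} is neither a known linker name nor DNA")


def link_chains(first: StitchResult, second: StitchResult,
                linker_nt: str, order: str = "first") -> str:
    """Concatenate two stitched chains through an in-frame linker.

    The trailing stop codon of the 5' chain is removed so the open reading
    frame runs through the linker into the 3' chain; a missing stop is not
    an error.  A linker whose length is not a multiple of 3 would shift the
    downstream frame and raises.
    """
    if len(linker_nt) % 3 != 0:
        raise BatchError(
            f"linker length {len(linker_nt)} is not a multiple of 3")
    five, three = (first, second) if order in ("first", "alpha", "ab") \
        else (second, first)
    seq5 = five.sequence
    if seq5[-3:] in _STOPS:
        seq5 = seq5[:-3]
    return seq5 + linker_nt + three.sequence


def process_batch(rows: Iterable[BatchRow], ref: ReferenceSet,
                  sl_min_overlap: int = 10,
                  allow_pseudogenes: bool = False) -> list[BatchResult]:
    """Stitch every row, capturing per-row errors.

    Every input row yields exactly one result, in input order; a row's
    failure never aborts the run, and failure reasons are recorded verbatim
    from the stitching error.
    """
    out: list[BatchResult] = []
    for row in rows:
        res = BatchResult(row=row)
        for slot, chain in row.chains.items():
            req = StitchRequest(
                v_call=chain.v_call, j_call=chain.j_call,
                junction=chain.junction, mode=chain.resolved_mode(),
                constant_override=chain.constant,
                leader_override=chain.leader,
                extra_5prime=chain.extra_5prime,
                extra_3prime=chain.extra_3prime,
                name=row.name,
            )
            try:
                res.results[slot] = stitch(
                    req, ref, sl_min_overlap=sl_min_overlap,
                    allow_pseudogenes=allow_pseudogenes)
            except TcrweaveError as exc:
                stage = getattr(exc, "stage", None)
                res.errors[slot] = f"[{stage}] {exc}" if stage else str(exc)
        if row.linker and len(res.results) == len(row.chains) == 2:
            try:
                linker_nt, warn = resolve_linker(row.linker)
                if warn:
                    log.warning("row %s: %s", row.name, warn)
                slots = sorted(row.chains)  # alpha, beta
                first_slot = row.link_order if row.link_order in slots else slots[0]
                second_slot = [s for s in slots if s != first_slot][0]
                res.linked_sequence = link_chains(
                    res.results[first_slot], res.results[second_slot],
                    linker_nt, order="first")
            except BatchError as exc:
                res.link_error = str(exc)
        out.append(res)
    return out


def results_frame(results: Iterable[BatchResult]) -> pd.DataFrame:
    """Tabulate batch results (input echo + stitched sequences + status)."""
    rows = []
    for res in results:
        rec: dict[str, object] = {"name": res.row.name}
        for slot in CHAIN_SLOTS:
            chain = res.row.chains.get(slot)
            if chain is None:
                continue
            rec[f"{slot}_v_call"] = chain.v_call
            rec[f"{slot}_j_call"] = chain.j_call
            rec[f"{slot}_junction"] = chain.junction
            rec[f"{slot}_mode"] = chain.resolved_mode()
            sr = res.results.get(slot)
            if sr is not None:
                rec[f"{slot}_stitched_nt"] = sr.sequence
                rec[f"{slot}_stitched_aa"] = sr.translation
                rec[f"{slot}_warnings"] = ";".join(str(w) for w in sr.warnings)
            else:
                rec[f"{slot}_error"] = res.errors.get(slot, "")
        if res.row.linker:
            rec["linker"] = res.row.linker
            rec["linked_nt"] = res.linked_sequence or ""
            if res.link_error:
                rec["link_error"] = res.link_error
        rec["status"] = res.status
        rows.append(rec)
    return pd.DataFrame(rows)


def write_batch_results(results: Iterable[BatchResult], path) -> pd.DataFrame:
    df = results_frame(results)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_batch_fasta(results: Iterable[BatchResult], handle) -> None:
    """Emit one FASTA record per stitched chain and per linked construct."""
    for res in results:
        for slot, sr in res.results.items():
            handle.write(f">{res.row.name}|{slot}|{sr.request.v_call}|"
                         f"{sr.request.j_call}\n{sr.sequence}\n")
        if res.linked_sequence:
            handle.write(f">{res.row.name}|linked|{res.row.linker}\n"
                         f"{res.linked_sequence}\n")
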