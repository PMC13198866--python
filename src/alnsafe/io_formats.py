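"""Sequence input and result serialisation.

FASTA reading is tolerant of copy-paste artefacts (internal whitespace,
terminal stop symbols) but always warns when it normalises.  Results are
written as deterministic JSON (machine-readable, exact counts as decimal
strings) and as a TSV of windows in human-oriented 1-based inclusive
coordinates.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass

from Bio import SeqIO

from .core_dag import AlignmentDag, align_optimal, alignment_rows
from .safety import SafetyResult

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "read_pair",
    "write_fasta",
    "write_result_json",
    "write_windows_tsv",
]


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    description: str
    residues: str


def read_fasta(text: str) -> list[SequenceRecord]:
    """Parse FASTA content into records, in file order.

    Residues are uppercased; internal whitespace is stripped with a
    warning; a terminal ``*`` stop symbol is stripped with a warning;
    duplicate record ids warn.  Zero records is an error.
    """
    # Biopython removes blanks inside sequence lines silently; scan the raw
    # text first so normalisation is warned about, not hidden.
    dirty: set[str] = set()
    current = None
    for line in text.splitlines():
        if line.startswith(">"):
            current = line[1:].split(None, 1)[0] if len(line) > 1 else ""
        elif current is not None and any(ch.isspace() for ch in line.strip()):
            dirty.add(current)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        residues = str(rec.seq)
        if rec.id in dirty or any(ch.isspace() for ch in residues):
            warnings.warn(
                f"record {rec.id!r}: internal whitespace removed from sequence",
                stacklevel=2,
            )
            residues = "".join(residues.split())
        residues = residues.upper()
        if residues.endswith("*"):
            warnings.warn(
                f"record {rec.id!r}: terminal stop symbol '*' stripped",
                stacklevel=2,
            )
            residues = residues[:-1]
        if rec.id in seen:
            warnings.warn(f"duplicate FASTA id {rec.id!r}", stacklevel=2)
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, rec.description, residues))
    if not records:
        raise ValueError("no FASTA records found in input")
    return records


def read_pair(text: str) -> tuple[SequenceRecord, SequenceRecord]:
    """Read exactly two non-empty records: the first is sequence A
    (vertical axis), the second sequence B (horizontal axis)."""
    records = read_fasta(text)
    if len(records) != 2:
        raise ValueError(
            f"expected exactly 2 FASTA records for alignment, found {len(records)}"
        )
    for rec in records:
        if not rec.residues:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
    return records[0], records[1]


def write_fasta(records: list[SequenceRecord], width: int = 60) -> str:
    out: list[str] = []
    for rec in records:
        header = rec.description if rec.description else rec.id
        out.append(f">{header}")
        for k in range(0, len(rec.residues), width):
            out.append(rec.residues[k : k + width])
    return "\n".join(out) + "\n"


def _json_dumps(obj) -> str:
    # Fixed formatting so that loads + dumps is byte-identical.
    return json.dumps(obj, indent=2, sort_keys=False, ensure_ascii=False) + "\n"


def write_result_json(
    result: SafetyResult,
    dag: AlignmentDag,
    ids: tuple[str, str] = ("seqA", "seqB"),
) -> str:
    """Serialise a safety computation as deterministic JSON.

    Window coordinates are 0-based half-open; supports are exact
    numerator/denominator pairs; the total alignment count is a decimal
    string so that values beyond 2**64 survive round-tripping.
    """
    opt_score, opt_path = align_optimal(dag.seq_a, dag.seq_b, dag.params)
    row_a, row_b = alignment_rows(dag.seq_a, dag.seq_b, opt_path)
    obj = {
        "sequences": {
            "a": {"id": ids[0], "length": result.len_a},
            "b": {"id": ids[1], "length": result.len_b},
        },
        "params": {
            "matrix": dag.params.matrix.name,
            "gap_open": dag.params.gap_open,
            "gap_extend": dag.params.gap_extend,
            "delta": dag.params.delta,
            "alpha": str(result.alpha),
        },
        "opt_score": opt_score,
        "num_alignments": str(result.total),
        "optimal_alignment": {"a": row_a, "b": row_b},
        "windows": [
            {
                "a_start": w.a_interval[0],
                "a_end": w.a_interval[1],
                "b_start": w.b_interval[0],
                "b_end": w.b_interval[1],
                "support_num": w.support.numerator,
                "support_den": w.support.denominator,
            }
            for w in result.windows
        ],
        "safe_coverage": {"a": result.safe_coverage_a, "b": result.safe_coverage_b},
    }
    return _json_dumps(obj)


_TSV_HEADER = (
    "a_start_1based\ta_end_1based\tb_start_1based\tb_end_1based\tsupport\tsupport_exact"
)


def write_windows_tsv(result: SafetyResult) -> str:
    """One row per window, coordinates 1-based inclusive (as labelled),
    support both as a 6-place decimal and as an exact rational."""
    lines = [_TSV_HEADER]
    for w in result.windows:
        a0, a1 = w.a_interval
        b0, b1 = w.b_interval
        dec = f"{w.support.numerator / w.support.denominator:.6f}"
        exact = f"{w.support.numerator}/{w.support.denominator}"
        lines.append(f"{a0 + 1}\t{a1}\t{b0 + 1}\t{b1}\t{dec}\t{exact}")
    return "\n".join(lines) + "\n"
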