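"""Projection of safety windows onto protein structure residues.

The input sequence (sequence A of the alignment) is matched to the
observed polymer residues of one chain of a PDB/mmCIF structure by
optimal global alignment under the IDENTITY matrix; positions aligned as
identities map to author residue numbers, everything else is explicitly
unmapped.  Observed residues (coordinate records) are used rather than
the declared full-length sequence, because the purpose of the mapping is
to annotate residues a structure viewer can actually colour.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping

import gemmi
import pandas as pd

from .core_dag import DIAGONAL, AlignmentParams, align_optimal
from .matrices import load_builtin_matrix
from .safety import SafetyResult

__all__ = [
    "ChainMap",
    "map_sequence_to_chain",
    "windows_to_residue_annotations",
    "annotations_to_tsv",
]


@dataclass(frozen=True)
class ChainMap:
    """Injective mapping from input-sequence positions to chain residues.

    ``mapping`` maps 0-based sequence positions to indices into
    ``residue_numbers`` (author numbering); positions absent from the
    mapping are unmapped (mismatched, inserted, or unobserved in the
    structure).
    """

    chain_id: str
    chain_sequence: str
    residue_numbers: tuple[int, ...]
    seq_length: int
    mapping: Mapping[int, int]
    identity: float


def _load_structure(structure: str, fmt: str | None = None) -> gemmi.Structure:
    text = structure
    if "\n" not in structure and os.path.exists(structure):
        path = structure
        text = open(path, encoding="utf-8", errors="replace").read()
        if fmt is None:
            fmt = "cif" if path.endswith((".cif", ".mmcif")) else "pdb"
    if fmt is None:
        head = text.lstrip()[:200]
        fmt = "cif" if (head.startswith("data_") or "_atom_site." in text) else "pdb"
    try:
        if fmt == "cif":
            block = gemmi.cif.read_string(text).sole_block()
            st = gemmi.make_structure_from_block(block)
        else:
            st = gemmi.read_pdb_string(text)
    except Exception as exc:
        raise ValueError(f"could not parse structure ({fmt}): {exc}") from exc
    st.setup_entities()
    return st


def map_sequence_to_chain(
    seq: str,
    structure: str,
    chain_id: str,
    fmt: str | None = None,
    min_identity: float = 0.30,
) -> ChainMap:
    """Align ``seq`` to the observed residues of ``chain_id`` and build
    the position mapping.

    Raises if the chain is missing (listing the available chains) or if
    alignment identity over aligned columns falls below ``min_identity``.
    """
    st = _load_structure(structure, fmt)
    if len(st) == 0:
        raise ValueError("structure contains no models")
    model = st[0]
    chain = None
    for c in model:
        if c.name == chain_id:
            chain = c
            break
    if chain is None:
        names = ", ".join(c.name for c in model) or "(none)"
        raise ValueError(f"chain {chain_id!r} not found; available chains: {names}")
    polymer = chain.get_polymer()
    if len(polymer) == 0:
        raise ValueError(f"chain {chain_id!r} has no polymer residues")
    one_letter = polymer.make_one_letter_sequence().upper()
    matrix = load_builtin_matrix("IDENTITY")
    chain_seq = "".join(ch if ch in matrix.alphabet else "X" for ch in one_letter)
    residue_numbers = tuple(res.seqid.num for res in polymer)

    params = AlignmentParams(matrix=matrix, gap_open=2, gap_extend=1, delta=0)
    _, path = align_optimal(seq, chain_seq, params)
    mapping: dict[int, int] = {}
    aligned = matches = 0
    for e in path:
        if e.kind != DIAGONAL:
            continue
        i, j, _ = e.frm
        aligned += 1
        if seq[i] == chain_seq[j]:
            matches += 1
            mapping[i] = j
    identity = matches / aligned if aligned else 0.0
    if identity < min_identity:
        raise ValueError(
            f"sequence does not match chain {chain_id!r}: "
            f"identity {identity:.1%} is below the {min_identity:.0%} threshold"
        )
    return ChainMap(
        chain_id=chain_id,
        chain_sequence=chain_seq,
        residue_numbers=residue_numbers,
        seq_length=len(seq),
        mapping=mapping,
        identity=identity,
    )


def windows_to_residue_annotations(
    result: SafetyResult, cmap: ChainMap
) -> tuple[pd.DataFrame, dict]:
    """Per-residue annotation rows for every window-covered, mapped
    position of sequence A.

    Returns a table with columns (chain, residue_number, window,
    support) plus a summary counting positions skipped because they are
    unmapped on the structure.
    """
    if result.len_a != cmap.seq_length:
        raise ValueError(
            f"chain map was built for a sequence of length {cmap.seq_length}, "
            f"but the safety result covers a sequence of length {result.len_a}"
        )
    rows = []
    skipped = covered = 0
    for widx, w in enumerate(result.windows):
        a0, a1 = w.a_interval
        for pos in range(a0, a1):
            covered += 1
            j = cmap.mapping.get(pos)
            if j is None:
                skipped += 1
                continue
            rows.append(
                {
                    "chain": cmap.chain_id,
                    "residue_number": cmap.residue_numbers[j],
                    "window": widx,
                    "support": float(w.support),
                }
            )
    df = pd.DataFrame(rows, columns=["chain", "residue_number", "window", "support"])
    summary = {"covered_positions": covered, "skipped_unmapped": skipped}
    return df, summary


def annotations_to_tsv(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", index=False, float_format="%.6f")
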