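"""Readers and writers for standard structure/sequence formats.

Supported: extended dot-bracket files, bpseq (1-based ``index base
partner`` lines, partner 0 = unpaired), connect (CT, six columns) and
FASTA (via Biopython).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .structures import Structure, parse_structure, write_structure

__all__ = [
    "read_dotbracket",
    "write_dotbracket",
    "read_bpseq",
    "write_bpseq",
    "read_ct",
    "write_ct",
    "read_fasta",
    "write_fasta",
]


def _lines(handle: TextIO | str | Path) -> list[str]:
    if isinstance(handle, (str, Path)):
        text = Path(handle).read_text()
    else:
        text = handle.read()
    return [
        ln.strip()
        for ln in text.splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]


def read_dotbracket(handle: TextIO | str | Path, validate=True) -> Structure:
    """Read the first non-comment line as an extended dot-bracket string."""
    lines = _lines(handle)
    if not lines:
        raise ValueError("empty dot-bracket file")
    return parse_structure(lines[0], validate=validate)


def write_dotbracket(S: Structure, handle: TextIO | str | Path) -> None:
    text = write_structure(S) + "\n"
    if isinstance(handle, (str, Path)):
        Path(handle).write_text(text)
    else:
        handle.write(text)


def read_bpseq(handle: TextIO | str | Path) -> tuple[str | None, Structure]:
    """Read a bpseq file; returns (sequence or None, structure).

    The sequence is None when every base column is the placeholder N.
    """
    rows = []
    for ln in _lines(handle):
        parts = ln.split()
        if len(parts) != 3:
            raise ValueError(f"malformed bpseq line: {ln!r}")
        rows.append((int(parts[0]), parts[1], int(parts[2])))
    rows.sort()
    n = rows[-1][0] if rows else 0
    if [r[0] for r in rows] != list(range(1, n + 1)):
        raise ValueError("bpseq indices are not 1..n")
    arcs = []
    for idx, _, partner in rows:
        if partner and partner < idx:
            continue
        if partner:
            arcs.append((idx, partner))
    for i, j in arcs:
        if rows[j - 1][2] != i:
            raise ValueError(f"asymmetric pairing {i}-{j} in bpseq")
    seq = "".join(r[1] for r in rows).upper().replace("T", "U")
    structure = Structure(n, arcs)
    return (None if set(seq) <= {"N"} else seq), structure


def write_bpseq(
    S: Structure, handle: TextIO | str | Path, seq: str | None = None
) -> None:
    p = S.partners()
    seq = seq or "N" * S.n
    if len(seq) != S.n:
        raise ValueError("sequence length does not match structure")
    body = "".join(
        f"{i} {seq[i - 1]} {p[i]}\n" for i in range(1, S.n + 1)
    )
    if isinstance(handle, (str, Path)):
        Path(handle).write_text(body)
    else:
        handle.write(body)


def read_ct(handle: TextIO | str | Path) -> tuple[str | None, Structure]:
    """Read a connect (CT) file: header line with n, then six columns
    ``index base prev next partner index``."""
    lines = _lines(handle)
    if not lines:
        raise ValueError("empty CT file")
    n = int(lines[0].split()[0])
    rows = []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        if len(parts) < 6:
            raise ValueError(f"malformed CT line: {ln!r}")
        rows.append((int(parts[0]), parts[1], int(parts[4])))
    arcs = [(i, p) for i, _, p in rows if p > i]
    seq = "".join(r[1] for r in rows).upper().replace("T", "U")
    structure = Structure(n, arcs)
    return (None if set(seq) <= {"N"} else seq), structure


def write_ct(
    S: Structure,
    handle: TextIO | str | Path,
    seq: str | None = None,
    name: str = "structure",
) -> None:
    p = S.partners()
    seq = seq or "N" * S.n
    if len(seq) != S.n:
        raise ValueError("sequence length does not match structure")
    out = [f"{S.n} {name}\n"]
    for i in range(1, S.n + 1):
        nxt = i + 1 if i < S.n else 0
        out.append(f"{i} {seq[i - 1]} {i - 1} {nxt} {p[i]} {i}\n")
    text = "".join(out)
    if isinstance(handle, (str, Path)):
        Path(handle).write_text(text)
    else:
        handle.write(text)


def read_fasta(handle: TextIO | str | Path) -> list[tuple[str, str]]:
    """All (id, sequence) records, uppercased with T mapped to U."""
    return [
        (rec.id, str(rec.seq).upper().replace("T", "U"))
        for rec in SeqIO.parse(handle, "fasta")
    ]


def write_fasta(
    records: Iterable[tuple[str, str]], handle: TextIO | str | Path
) -> None:
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecords, handle, "fasta")
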