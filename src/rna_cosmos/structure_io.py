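"""Readers and writers for the structure formats the tool touches.

Two input formats are supported:

* ``.dbn`` — FASTA-like blocks: a ``>name`` line, an optional nucleotide
  sequence line, and a dot-bracket line over ``(``, ``)``, ``.``.
* bpRNA ``.st`` — ``#``-prefixed headers followed by sequence, dot-bracket
  and structure-array lines; only the structure-array line is consumed.

Outputs are plain TSV: square score matrices and long-form pair tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The eight per-nucleotide structural codes: hairpin, multiloop, external
#: loop, internal loop, bulge, end, left- and right-handed stem side.
STRUCTURE_ALPHABET = frozenset("HMXIBELR")

#: Bracket characters that signal pseudoknots or other unsupported notation.
_PSEUDOKNOT_CHARS = set("[]{}<>") | set("abcdefghijklmnopqrstuvwxyz") | set(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
)

_SEQ_RE = re.compile(r"^[A-Za-z]+$")


class ParseError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class DotBracket:
    """A named dot-bracket secondary structure.

    Parameters
    ----------
    name:
        Record identifier.
    brackets:
        String over ``(``, ``)`` and ``.``; parentheses must balance.
    sequence:
        Optional nucleotide string of the same length.
    """

    name: str
    brackets: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.brackets:
            raise ValueError(f"record {self.name!r}: empty bracket string")
        bad = _check_balanced(self.brackets)
        if bad is not None:
            raise ValueError(
                f"record {self.name!r}: unbalanced brackets at position {bad}"
            )
        if self.sequence is not None and len(self.sequence) != len(self.brackets):
            raise ValueError(
                f"record {self.name!r}: sequence length {len(self.sequence)} "
                f"!= bracket length {len(self.brackets)}"
            )

    def __len__(self) -> int:
        return len(self.brackets)


@dataclass(frozen=True)
class StructureArray:
    """Per-nucleotide structural code string over the 8-letter alphabet."""

    name: str
    codes: str

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError(f"record {self.name!r}: empty structure array")
        for i, ch in enumerate(self.codes, start=1):
            if ch not in STRUCTURE_ALPHABET:
                raise ValueError(
                    f"record {self.name!r}: invalid structure code {ch!r} "
                    f"at position {i} (allowed: H,M,X,I,B,E,L,R)"
                )

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def length(self) -> int:
        return len(self.codes)


def _check_balanced(brackets: str) -> int | None:
    """Return the 1-based position of the first imbalance, or None."""
    depth = 0
    for i, ch in enumerate(brackets, start=1):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return i
    if depth != 0:
        # position of the last unmatched '('
        depth = 0
        last_open = None
        for i, ch in enumerate(brackets, start=1):
            if ch == "(":
                depth += 1
                last_open = i
            elif ch == ")":
                depth -= 1
        return last_open
    return None


def _classify_line(line: str, name: str, lineno: int) -> str:
    """Classify a record body line as 'sequence' or 'brackets'."""
    pk = [c for c in line if c in _PSEUDOKNOT_CHARS]
    if any(c in "()." for c in line):
        for i, c in enumerate(line, start=1):
            if c in _PSEUDOKNOT_CHARS:
                raise ParseError(
                    f"record {name!r} (line {lineno}): pseudoknots unsupported "
                    f"(bracket character {c!r} at position {i})"
                )
            if c not in "().":
                raise ParseError(
                    f"record {name!r} (line {lineno}): invalid character "
                    f"{c!r} at position {i} in bracket line"
                )
        return "brackets"
    if _SEQ_RE.fullmatch(line):
        return "sequence"
    raise ParseError(
        f"record {name!r} (line {lineno}): line is neither a nucleotide "
        f"sequence nor a dot-bracket string: {line[:40]!r}"
    )


def read_dbn(path: str | Path) -> list[DotBracket]:
    """Parse a ``.dbn`` file into an ordered list of :class:`DotBracket`.

    Each record is a ``>name`` line followed by an optional sequence line
    and a mandatory dot-bracket line. Raises :class:`ParseError` on
    unbalanced or pseudoknotted brackets, naming the offending record.
    """
    path = Path(path)
    records: list[DotBracket] = []
    name: str | None = None
    body: list[tuple[int, str]] = []

    def flush() -> None:
        nonlocal name, body
        if name is None:
            return
        seq: str | None = None
        brackets: str | None = None
        for lineno, line in body:
            kind = _classify_line(line, name, lineno)
            if kind == "sequence":
                if brackets is not None or seq is not None:
                    raise ParseError(
                        f"record {name!r} (line {lineno}): unexpected extra line"
                    )
                seq = line
            else:
                if brackets is not None:
                    raise ParseError(
                        f"record {name!r} (line {lineno}): multiple bracket lines"
                    )
                brackets = line
        if brackets is None:
            raise ParseError(f"record {name!r}: missing dot-bracket line")
        bad = _check_balanced(brackets)
        if bad is not None:
            raise ParseError(
                f"record {name!r}: unbalanced brackets at position {bad}"
            )
        records.append(DotBracket(name=name, brackets=brackets, sequence=seq))
        name, body = None, []

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].strip()
                if not name:
                    raise ParseError(f"line {lineno}: empty record name")
            else:
                if name is None:
                    raise ParseError(
                        f"line {lineno}: data before the first '>' header"
                    )
                body.append((lineno, line))
    flush()
    return records


def write_dbn(records: Iterable[DotBracket], path: str | Path) -> None:
    """Write records as ``.dbn`` blocks; round-trips through :func:`read_dbn`."""
    with Path(path).open("w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            if rec.sequence is not None:
                fh.write(rec.sequence + "\n")
            fh.write(rec.brackets + "\n")


def read_st(path: str | Path) -> StructureArray:
    """Read the structure array from a bpRNA ``.st`` file.

    Layout: ``#``-prefixed headers, then sequence, dot-bracket and
    structure-array lines; anything after the structure-array line
    (segment listings etc.) is ignored. The file's own dot-bracket is
    trusted, not re-annotated; the structure-array line is alphabet-checked.
    """
    path = Path(path)
    name = path.stem
    data_lines: list[str] = []
    with path.open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("#"):
                m = re.match(r"#\s*Name:\s*(\S.*)", line)
                if m:
                    name = m.group(1).strip()
                continue
            if line.strip():
                data_lines.append(line.strip())
    if len(data_lines) < 3:
        raise ParseError(
            f"{path.name}: expected sequence, dot-bracket and structure-array "
            f"lines; found {len(data_lines)} non-comment line(s)"
        )
    codes = data_lines[2]
    for i, ch in enumerate(codes, start=1):
        if ch not in STRUCTURE_ALPHABET:
            raise ParseError(
                f"{path.name}: unsupported structure code {ch!r} at position "
                f"{i} of the structure-array line"
            )
    return StructureArray(name=name, codes=codes)


def write_matrix(
    ids: Sequence[str], matrix: np.ndarray, path: str | Path
) -> None:
    """Write a symmetric score matrix as TSV (header row and index column).

    The matrix must be square, match ``len(ids)`` and be symmetric within
    1e-9; values are written with 6 decimal places.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = len(ids)
    if matrix.shape != (n, n):
        raise ValueError(
            f"matrix shape {matrix.shape} does not match {n} ids"
        )
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("matrix is not symmetric within 1e-9")
    df = pd.DataFrame(matrix, index=list(ids), columns=list(ids))
    df.to_csv(path, sep="\t", float_format="%.6f", index_label="id")


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a TSV score matrix written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(c) for c in df.columns]
    return ids, df.to_numpy(dtype=float)


def write_pairs(records: Iterable, path: str | Path) -> None:
    """Write ScoreRecords as a long-form TSV.

    Columns: id_a, id_b, cosine, penalty, score, k, fuzzy.
    """
    rows = [
        {
            "id_a": r.id_a,
            "id_b": r.id_b,
            "cosine": r.cosine,
            "penalty": r.penalty,
            "score": r.score,
            "k": r.k,
            "fuzzy": r.fuzzy,
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["id_a", "id_b", "cosine", "penalty", "score", "k", "fuzzy"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")
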