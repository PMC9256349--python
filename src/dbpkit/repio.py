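"""Reading protein sequences and residue-level representation matrices.

A protein is represented at residue level by an ``L x d`` real matrix: the
PSI-BLAST position-specific scoring matrix (PSSM, ``d = 20`` log-odds
mutation scores per position) or a per-residue embedding from a pretrained
protein language model (e.g. ``d = 1280`` for ESM-1b).  Raw matrices are
squashed entrywise through the logistic sigmoid before any pooling, so all
downstream feature values live in (0, 1).

Positions are 1-based in error messages, matching the usual notation for
sequence formulas; storage is ordinary 0-based numpy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import ConfigError, ConsistencyError, ParseError, ShapeError

#: PSI-BLAST PSSM column order; also the fixed amino-acid ordering used for
#: the per-type averaging features of every representation.
PSSM_ALPHABET: str = "ARNDCQEGHILKMFPSTWYV"

#: Default sequence filters: minimum chain length and forbidden letters.
DEFAULT_MIN_LENGTH: int = 50
DEFAULT_FORBIDDEN: frozenset[str] = frozenset("X")


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein sequence of one-letter amino-acid codes."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ConfigError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ResidueMatrix:
    """An ``L x d`` per-residue representation bound to a protein.

    ``source_kind`` is ``"pssm"`` or ``"embedding"``; ``normalized`` records
    whether the entries have already been squashed through the sigmoid.
    """

    protein_id: str
    source_kind: str
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ShapeError(
                f"matrix for {self.protein_id!r} must be 2-D with L>=1, d>=1; "
                f"got shape {values.shape}"
            )
        if self.source_kind not in ("pssm", "embedding"):
            raise ConfigError(f"unknown source_kind {self.source_kind!r}")
        object.__setattr__(self, "values", values)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly empty) multi-record FASTA file.

    Order is preserved and sequences are upper-cased.  A sequence line before
    the first header is a parse error naming the offending line.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: sequence data before any "
                    f"'>' header"
                )
            break
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]
    return records


def filter_records(
    records: Iterable[ProteinRecord],
    min_len: int = DEFAULT_MIN_LENGTH,
    forbidden: Iterable[str] = DEFAULT_FORBIDDEN,
) -> list[ProteinRecord]:
    """Drop chains shorter than ``min_len`` or containing a forbidden letter.

    The defaults implement the benchmark curation rule: remove chains with a
    length below 50 and chains containing the unknown-residue letter 'X'.
    The filter is total and idempotent; order is preserved.
    """
    if min_len < 1:
        raise ConfigError(f"min_len must be >= 1, got {min_len}")
    bad = frozenset(forbidden)
    return [
        r
        for r in records
        if len(r) >= min_len and not bad.intersection(r.sequence)
    ]


def _find_pssm_rows(lines: Sequence[str], path: Path) -> list[tuple[int, str]]:
    """Return (lineno, line) pairs for the per-residue score rows."""
    rows: list[tuple[int, str]] = []
    started = False
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            if started:
                break  # blank line after the block terminates it
            continue
        # A score row starts with an integer position then a residue letter.
        if tokens[0].isdigit() and len(tokens) > 1 and tokens[1].isalpha() \
                and len(tokens[1]) == 1:
            rows.append((lineno, line))
            started = True
        elif started:
            break
    if not rows:
        raise ParseError(f"{path}: no PSSM score rows found")
    return rows


def read_pssm_ascii(path: str | Path, record: ProteinRecord) -> ResidueMatrix:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm``) for ``record``.

    The layout is two header lines (a title and the amino-acid column
    letters) followed by one row per residue: position index, residue
    letter, twenty log-odds integers, twenty weighted percentages, and two
    trailing floats.  Only the log-odds block (the first twenty numeric
    columns, ordered ``A R N D C Q E G H I L K M F P S T W Y V``) is kept;
    the matrix is returned raw (unnormalized).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    rows = _find_pssm_rows(lines, path)
    if len(rows) != len(record):
        raise ShapeError(
            f"{path}: {len(rows)} score rows but sequence "
            f"{record.id!r} has length {len(record)}"
        )
    scores = np.empty((len(record), 20), dtype=float)
    for i, (lineno, line) in enumerate(rows):
        tokens = line.split()
        letter = tokens[1].upper()
        if letter != record.sequence[i]:
            raise ConsistencyError(
                f"{path}: line {lineno}: residue {letter!r} at position "
                f"{i + 1} does not match sequence letter "
                f"{record.sequence[i]!r}"
            )
        numeric = tokens[2:]
        if len(numeric) < 20:
            raise ShapeError(
                f"{path}: line {lineno}: expected 20 log-odds columns, "
                f"found {len(numeric)}"
            )
        try:
            scores[i] = [float(tok) for tok in numeric[:20]]
        except ValueError as exc:
            raise ParseError(
                f"{path}: line {lineno}: non-numeric score cell ({exc})"
            ) from None
    return ResidueMatrix(protein_id=record.id, source_kind="pssm",
                         values=scores, normalized=False)


def read_embedding(path: str | Path, record: ProteinRecord) -> ResidueMatrix:
    """Read a per-residue embedding matrix with ``L`` rows for ``record``.

    ``.npy`` files are loaded as binary arrays; anything else is parsed as a
    whitespace-delimited numeric text table.  ``d`` is inferred from the
    file.
    """
    path = Path(path)
    if path.suffix == ".npy":
        values = np.load(path)
    else:
        try:
            values = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from None
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ShapeError(f"{path}: expected a 2-D matrix, got ndim={values.ndim}")
    if values.shape[0] != len(record):
        raise ShapeError(
            f"{path}: {values.shape[0]} rows but sequence {record.id!r} "
            f"has length {len(record)}"
        )
    return ResidueMatrix(protein_id=record.id, source_kind="embedding",
                         values=values, normalized=False)


def sigmoid_normalize(m: ResidueMatrix) -> ResidueMatrix:
    """Apply ``x -> 1/(1+exp(-x))`` entrywise to a raw matrix.

    Normalizing an already-normalized matrix is an error, not a no-op: the
    sigmoid is not idempotent and silently reapplying it would corrupt the
    features.
    """
    if m.normalized:
        raise ConfigError(
            f"matrix for {m.protein_id!r} is already sigmoid-normalized"
        )
    from scipy.special import expit

    return replace(m, values=expit(m.values), normalized=True)
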