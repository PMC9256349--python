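"""Synthetic two-class residue-matrix datasets and PSSM-ASCII fixtures.

The generator emulates the shape of the real task — a labelled collection
of proteins, each carrying an ``L x d`` residue-level matrix — with a
controllable planted class signal: entries are i.i.d. Normal(0, sigma^2)
in raw-score space, and for positive-class proteins a constant shift
``delta`` is added to every entry of the first ``m`` (informative)
dimensions.  Planting the shift *before* sigmoid normalization exercises
the nonlinearity of the normalization step.  Sequences are drawn uniformly
over the 20 standard amino-acid letters, independent of the matrices, so
the per-type averaging acts as a randomized partition of the rows.

``write_pssm_fixture`` emits the PSI-BLAST ASCII layout consumed by
:func:`dbpkit.repio.read_pssm_ascii`, round-tripping an integer score
matrix exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError, ShapeError
from .repio import PSSM_ALPHABET, ProteinRecord, ResidueMatrix


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    n_pos: int
    n_neg: int
    d: int
    length_range: tuple[int, int] = (50, 100)
    informative_dims: int = 5
    effect_size: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0
    kind: str = "embedding"  # "embedding" or "pssm" (d=20, integer scores)

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if self.n_pos < 1 or self.n_neg < 1:
            raise ConfigError("need at least one protein per class")
        if not 2 <= lo <= hi:
            raise ConfigError("length_range must satisfy 2 <= min <= max")
        if not 0 <= self.informative_dims <= self.d:
            raise ConfigError("informative_dims must be in [0, d]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.kind not in ("embedding", "pssm"):
            raise ConfigError(f"unknown kind {self.kind!r}")
        if self.kind == "pssm" and self.d != 20:
            raise ConfigError("pssm-kind datasets require d = 20")

    @property
    def planted_dims(self) -> tuple[int, ...]:
        """0-based informative dimension indices (always the first m)."""
        return tuple(range(self.informative_dims))


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], list[ResidueMatrix], np.ndarray]:
    """Draw a labelled dataset of raw (unnormalized) residue matrices.

    Positives (label 1) come first.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.r_[np.ones(spec.n_pos, dtype=int),
                   np.zeros(spec.n_neg, dtype=int)]
    alphabet = np.array(list(PSSM_ALPHABET))
    records: list[ProteinRecord] = []
    matrices: list[ResidueMatrix] = []
    lo, hi = spec.length_range
    for i, label in enumerate(labels):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=L))
        values = rng.normal(0.0, spec.noise_sd, size=(L, spec.d))
        if label == 1 and spec.informative_dims > 0:
            values[:, : spec.informative_dims] += spec.effect_size
        if spec.kind == "pssm":
            values = np.clip(np.rint(values), -15, 15)
        records.append(ProteinRecord(id=f"syn{i:04d}", sequence=seq))
        matrices.append(ResidueMatrix(protein_id=f"syn{i:04d}",
                                      source_kind=spec.kind, values=values,
                                      normalized=False))
    return records, matrices, labels


def write_pssm_fixture(record: ProteinRecord, raw_scores: np.ndarray,
                       path: str | Path) -> Path:
    """Write an integer L x 20 score matrix in PSI-BLAST ASCII layout.

    Entries must be integers in [-15, 15]; the percentage block and the two
    trailing per-row floats are filled with zeros (they are never read).
    """
    raw_scores = np.asarray(raw_scores)
    if raw_scores.shape != (len(record), 20):
        raise ShapeError(
            f"expected a {len(record)}x20 score matrix, got "
            f"{raw_scores.shape}"
        )
    if not np.array_equal(raw_scores, np.rint(raw_scores)):
        raise ConfigError("PSSM fixture scores must be integers")
    if raw_scores.min() < -15 or raw_scores.max() > 15:
        raise ConfigError("PSSM fixture scores must lie in [-15, 15]")
    path = Path(path)
    letters = "  ".join(PSSM_ALPHABET)
    lines = [
        "Last position-specific scoring matrix computed, weighted, "
        "and normalized",
        f"            {letters}   {letters}",
    ]
    for i, row in enumerate(raw_scores.astype(int), start=1):
        scores = " ".join(f"{v:3d}" for v in row)
        percents = " ".join("  0" for _ in range(20))
        lines.append(
            f"{i:5d} {record.sequence[i - 1]}  {scores}  {percents}"
            f"  0.00 0.00"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_dataset(
    records: list[ProteinRecord],
    matrices: list[ResidueMatrix],
    labels: np.ndarray,
    outdir: str | Path,
) -> Path:
    """Emit the pipeline's on-disk input contract for a generated dataset.

    Writes ``sequences.fasta``, ``labels.tsv`` (id, label) and one matrix
    file per protein: ``<id>.pssm`` (PSSM ASCII) for integer pssm-kind
    matrices, ``<id>.txt`` (whitespace table) otherwise.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "sequences.fasta", "w") as fasta:
        for rec in records:
            fasta.write(f">{rec.id}\n{rec.sequence}\n")
    with open(outdir / "labels.tsv", "w") as lab:
        lab.write("id\tlabel\n")
        for rec, y in zip(records, labels):
            lab.write(f"{rec.id}\t{int(y)}\n")
    for rec, m in zip(records, matrices):
        if m.source_kind == "pssm":
            write_pssm_fixture(rec, m.values, outdir / f"{rec.id}.pssm")
        else:
            np.savetxt(outdir / f"{rec.id}.txt", m.values, fmt="%.8g")
    return outdir
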