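"""Sequence-level descriptors from residue-level matrices.

Four averaging operators pool an ``L x d`` residue matrix ``R = {R_1..R_L}``
into fixed-length descriptors:

* ``Avg``             — mean over all residues (``d`` features);
* ``Sep(k, s)``       — mean over residues at positions ``s, s+k, s+2k, ...``
  for ``k in {2, 3}`` and start ``s in 1..k`` (``5d`` features);
* ``AA(t)``           — mean over residues of amino-acid type ``t`` for the
  20 standard types (``20d`` features);
* ``Corr(phi)``       — mean squared componentwise difference between
  residues at sequence distance ``phi in {1, 2, 3}`` (``3d`` features), the
  PsePSSM-style sequence-order term.

The full assembly concatenates the blocks in that order, yielding ``29 d``
named features per protein: 580 for a PSSM (``d = 20``) and 37120 for an
ESM-1b embedding (``d = 1280``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ShapeError
from .repio import PSSM_ALPHABET, ProteinRecord, ResidueMatrix

logger = logging.getLogger(__name__)

#: Fixed enumeration order of the (k, s) separation pairs.
SEPARATION_PAIRS: tuple[tuple[int, int], ...] = (
    (2, 1), (2, 2), (3, 1), (3, 2), (3, 3),
)

ALL_CATEGORIES: tuple[str, ...] = ("avg", "sep", "aa", "corr")


@dataclass(frozen=True)
class FeatureSetSpec:
    """Which descriptor categories to assemble, and their parameter grids."""

    d: int
    categories: tuple[str, ...] = ALL_CATEGORIES
    k_values: tuple[int, ...] = (2, 3)
    phi_values: tuple[int, ...] = (1, 2, 3)
    aa_alphabet: str = PSSM_ALPHABET

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ConfigError(f"d must be >= 1, got {self.d}")
        unknown = set(self.categories) - set(ALL_CATEGORIES)
        if unknown:
            raise ConfigError(f"unknown feature categories: {sorted(unknown)}")
        if any(k < 2 for k in self.k_values):
            raise ConfigError("k values must be >= 2")
        if any(p < 1 for p in self.phi_values):
            raise ConfigError("phi values must be >= 1")
        if len(self.aa_alphabet) != 20 or len(set(self.aa_alphabet)) != 20:
            raise ConfigError("aa_alphabet must hold 20 distinct letters")

    @property
    def separation_pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (k, s) for k in sorted(self.k_values) for s in range(1, k + 1)
        )

    def feature_names(self) -> list[str]:
        """Deterministic names, one per assembled component.

        Grammar: ``avg_j``, ``sep_k{k}_s{s}_j``, ``aa_{T}_j``,
        ``corr_phi{p}_j`` with a 0-based dimension index ``j``.
        """
        dims = range(self.d)
        names: list[str] = []
        if "avg" in self.categories:
            names += [f"avg_{j}" for j in dims]
        if "sep" in self.categories:
            for k, s in self.separation_pairs:
                names += [f"sep_k{k}_s{s}_{j}" for j in dims]
        if "aa" in self.categories:
            for t in self.aa_alphabet:
                names += [f"aa_{t}_{j}" for j in dims]
        if "corr" in self.categories:
            for p in self.phi_values:
                names += [f"corr_phi{p}_{j}" for j in dims]
        return names

    @property
    def n_features(self) -> int:
        per_dim = 0
        if "avg" in self.categories:
            per_dim += 1
        if "sep" in self.categories:
            per_dim += len(self.separation_pairs)
        if "aa" in self.categories:
            per_dim += 20
        if "corr" in self.categories:
            per_dim += len(self.phi_values)
        return per_dim * self.d


def _require_normalized(m: ResidueMatrix) -> np.ndarray:
    if not m.normalized:
        raise ConfigError(
            f"matrix for {m.protein_id!r} must be sigmoid-normalized before "
            f"feature extraction"
        )
    return m.values


def avg_all(m: ResidueMatrix) -> np.ndarray:
    """Mean residue vector: component ``j`` is ``(1/L) sum_i m[i, j]``."""
    values = _require_normalized(m)
    return values.mean(axis=0)


def separation_count(L: int, k: int, s: int) -> int:
    """Size of the position subset ``{s, s+k, s+2k, ...} <= L``.

    Equals ``floor((L - s + k) / k)`` for ``1 <= s <= k <= L``.
    """
    return (L - s + k) // k


def avg_separation(m: ResidueMatrix, k: int, s: int) -> np.ndarray:
    """Mean over residues at 1-based positions ``s, s+k, s+2k, ... <= L``."""
    values = _require_normalized(m)
    L = values.shape[0]
    if not 1 <= s <= k:
        raise ConfigError(f"need 1 <= s <= k, got k={k}, s={s}")
    if s > L:
        raise ConfigError(
            f"start position s={s} exceeds sequence length L={L} "
            f"(empty subset)"
        )
    rows = values[s - 1::k]
    assert rows.shape[0] == separation_count(L, k, s)
    return rows.mean(axis=0)


def avg_by_aa(m: ResidueMatrix, seq: str, t: str) -> np.ndarray:
    """Mean over residues whose amino-acid type is ``t``.

    A type absent from the sequence yields the zero vector, keeping the
    per-type block at a fixed ``20 d`` width for every protein.
    """
    values = _require_normalized(m)
    if len(seq) != values.shape[0]:
        raise ShapeError(
            f"sequence length {len(seq)} != matrix rows {values.shape[0]}"
        )
    if t not in PSSM_ALPHABET:
        raise ConfigError(f"{t!r} is not a standard amino-acid letter")
    mask = np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord(t)
    if not mask.any():
        return np.zeros(values.shape[1])
    return values[mask].mean(axis=0)


def avg_correlation(m: ResidueMatrix, phi: int) -> np.ndarray:
    """Mean squared lag-``phi`` difference per component.

    Component ``j`` is ``(1/(L-phi)) sum_i (m[i,j] - m[i+phi,j])^2``.  For
    ``L <= phi`` there are no pairs; the zero vector is returned with a
    logged warning (unreachable for length-filtered data, but the operator
    is total).
    """
    values = _require_normalized(m)
    if phi < 1:
        raise ConfigError(f"phi must be >= 1, got {phi}")
    L = values.shape[0]
    if L <= phi:
        logger.warning(
            "avg_correlation: L=%d <= phi=%d for %r; returning zeros",
            L, phi, m.protein_id,
        )
        return np.zeros(values.shape[1])
    diff = values[:-phi] - values[phi:]
    return (diff * diff).mean(axis=0)


def assemble(m: ResidueMatrix, seq: str,
             spec: FeatureSetSpec) -> "FeatureVector":
    """Concatenate the configured descriptor blocks in fixed order.

    Order: ``avg`` | ``sep`` over the (k, s) grid | ``aa`` over the
    alphabet | ``corr`` over the phi grid.
    """
    if m.d != spec.d:
        raise ShapeError(f"matrix d={m.d} does not match spec d={spec.d}")
    if len(seq) != m.length:
        raise ShapeError(
            f"sequence length {len(seq)} != matrix rows {m.length}"
        )
    blocks: list[np.ndarray] = []
    if "avg" in spec.categories:
        blocks.append(avg_all(m))
    if "sep" in spec.categories:
        blocks += [avg_separation(m, k, s) for k, s in spec.separation_pairs]
    if "aa" in spec.categories:
        blocks += [avg_by_aa(m, seq, t) for t in spec.aa_alphabet]
    if "corr" in spec.categories:
        blocks += [avg_correlation(m, p) for p in spec.phi_values]
    return FeatureVector(
        protein_id=m.protein_id,
        names=spec.feature_names(),
        values=np.concatenate(blocks),
    )


@dataclass(frozen=True)
class FeatureVector:
    """Named sequence-level descriptors for one protein."""

    protein_id: str
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if len(self.names) != values.shape[0]:
            raise ShapeError(
                f"{len(self.names)} names vs {values.shape[0]} values"
            )
        object.__setattr__(self, "values", values)


@dataclass
class FeatureTable:
    """A samples-by-features matrix with ids, feature names and 0/1 labels.

    Label 1 marks the DNA-binding (positive) class.
    """

    ids: list[str]
    names: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ShapeError("feature values must be 2-D")
        n, p = self.values.shape
        if len(self.ids) != n or self.labels.shape != (n,):
            raise ShapeError("ids/labels length must match row count")
        if len(self.names) != p:
            raise ShapeError("names length must match column count")
        if len(set(self.names)) != p:
            raise ConfigError("feature names must be unique")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "FeatureTable":
        """Column subset in the given order (rows and labels unchanged)."""
        index = {n: j for j, n in enumerate(self.names)}
        try:
            cols = [index[n] for n in names]
        except KeyError as exc:
            raise ConfigError(f"unknown feature name {exc.args[0]!r}") from None
        return FeatureTable(ids=list(self.ids), names=list(names),
                            values=self.values[:, cols],
                            labels=self.labels.copy())

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.names)
        frame.insert(0, "id", self.ids)
        frame["label"] = self.labels
        return frame

    def to_csv(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = "\t") -> "FeatureTable":
        frame = pd.read_csv(path, sep=sep)
        if "id" not in frame.columns or "label" not in frame.columns:
            raise ConfigError(f"{path}: table needs 'id' and 'label' columns")
        names = [c for c in frame.columns if c not in ("id", "label")]
        return cls(ids=frame["id"].astype(str).tolist(), names=names,
                   values=frame[names].to_numpy(dtype=float),
                   labels=frame["label"].to_numpy(dtype=int))


def build_table(
    pairs: Iterable[tuple[ProteinRecord, ResidueMatrix]],
    labels: Sequence[int],
    spec: FeatureSetSpec,
) -> FeatureTable:
    """Assemble one FeatureVector per protein into a labelled table.

    Row order equals input order; all matrices must share ``d`` and every
    label must be 0 or 1.
    """
    pairs = list(pairs)
    labels = np.asarray(labels, dtype=int)
    if not pairs:
        raise ConfigError("cannot build a feature table from no proteins")
    if labels.shape != (len(pairs),):
        raise ShapeError(
            f"{len(pairs)} proteins but {labels.shape[0]} labels"
        )
    if not np.isin(labels, (0, 1)).all():
        raise ConfigError("labels must be binary (0/1)")
    dims = {m.d for _, m in pairs}
    if len(dims) != 1:
        raise ShapeError(f"mixed representation dimensions: {sorted(dims)}")
    vectors = [assemble(m, rec.sequence, spec) for rec, m in pairs]
    return FeatureTable(
        ids=[v.protein_id for v in vectors],
        names=vectors[0].names,
        values=np.vstack([v.values for v in vectors]),
        labels=labels,
    )
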