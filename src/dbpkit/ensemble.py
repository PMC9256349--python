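"""Accuracy-weighted soft-voting ensemble of trained member models.

Each member is a classifier trained on its own feature subset with its own
normalizer, carrying the pooled accuracy ``ACC_i`` it achieved under
five-fold cross-validation.  The ensemble weight of member ``i`` is

    w_i = ACC_i / sum_k ACC_k

and the ensemble class probability is the convex combination
``p_c = sum_i w_i p_{i,c}`` of the members' probability outputs.  A sample
is called DNA-binding (class 1) when ``p_1 >= 0.5``; the tie goes to the
positive class (configurable via ``threshold``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import joblib
import numpy as np

from .errors import ConfigError
from .evaluation import FittedModel
from .features import FeatureTable, FeatureVector


def compute_weights(cv_accs) -> np.ndarray:
    """Accuracy-proportional weights ``w_i = ACC_i / sum_k ACC_k``."""
    accs = np.asarray(cv_accs, dtype=float)
    if accs.size == 0:
        raise ConfigError("no member accuracies given")
    if (accs <= 0).any():
        raise ConfigError("member CV accuracies must be positive")
    return accs / accs.sum()


@dataclass
class MemberModel:
    """A trained model with its origin label and 5-fold-CV accuracy.

    ``feature_set`` names the representation table the member scores from
    (members of one ensemble may come from different feature sets, e.g.
    PSSM-derived and embedding-derived); it is the lookup key when a
    mapping of tables is passed at prediction time.
    """

    origin: str
    model: FittedModel
    cv_acc: float
    feature_set: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.cv_acc <= 1:
            raise ConfigError(
                f"member {self.origin!r}: cv_acc must be in (0, 1]"
            )
        if not self.model.names:
            raise ConfigError(f"member {self.origin!r}: empty feature subset")


@dataclass
class EnsemblePredictor:
    """Soft-voting ensemble over :class:`MemberModel` instances."""

    members: list[MemberModel]
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigError("ensemble needs at least one member")
        origins = [m.origin for m in self.members]
        if len(set(origins)) != len(origins):
            raise ConfigError("duplicate member origins in ensemble")
        self.weights = compute_weights([m.cv_acc for m in self.members])

    def predict_proba_table(
        self, data: FeatureTable | Mapping[str, FeatureTable]
    ) -> np.ndarray:
        """Ensemble (p_0, p_1) per row of raw full-feature table(s).

        ``data`` is a single table (all members score it) or a mapping
        from feature-set name to table, aligned row-by-row, from which
        each member picks its own set.
        """
        tables = data if isinstance(data, Mapping) else None
        first = next(iter(data.values())) if tables else data
        out = np.zeros((first.n_samples, 2))
        for member, w in zip(self.members, self.weights):
            if tables is not None:
                if member.feature_set not in tables:
                    raise ConfigError(
                        f"member {member.origin!r}: no table for feature "
                        f"set {member.feature_set!r}"
                    )
                table = tables[member.feature_set]
            else:
                table = data
            if table.n_samples != out.shape[0]:
                raise ConfigError("feature tables are not row-aligned")
            try:
                proba = member.model.predict_proba(table)
            except ConfigError as exc:
                raise ConfigError(
                    f"member {member.origin!r} cannot emit probabilities: "
                    f"{exc}"
                ) from None
            out += w * proba
        return out

    def predict_proba(self, sample: FeatureVector) -> tuple[float, float]:
        table = FeatureTable(ids=[sample.protein_id], names=list(sample.names),
                             values=sample.values[None, :], labels=[0])
        p0, p1 = self.predict_proba_table(table)[0]
        return float(p0), float(p1)

    def predict_class_table(
        self, data: FeatureTable | Mapping[str, FeatureTable],
        threshold: float = 0.5,
    ) -> np.ndarray:
        return (self.predict_proba_table(data)[:, 1] >= threshold).astype(int)

    def predict_class(self, sample: FeatureVector,
                      threshold: float = 0.5) -> int:
        return int(self.predict_proba(sample)[1] >= threshold)

    # -- persistence --------------------------------------------------------

    def save(self, outdir: str | Path) -> Path:
        """Write a JSON manifest plus one joblib file per member model."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {"members": []}
        for i, (member, w) in enumerate(zip(self.members, self.weights)):
            model_path = outdir / f"member_{i:02d}.joblib"
            joblib.dump(member.model, model_path)
            manifest["members"].append({
                "origin": member.origin,
                "feature_set": member.feature_set,
                "cv_acc": member.cv_acc,
                "weight": float(w),
                "model_file": model_path.name,
            })
        path = outdir / "ensemble.json"
        path.write_text(json.dumps(manifest, indent=2))
        return path

    @classmethod
    def load(cls, manifest_path: str | Path) -> "EnsemblePredictor":
        manifest_path = Path(manifest_path)
        manifest = json.loads(manifest_path.read_text())
        members = [
            MemberModel(
                origin=entry["origin"],
                model=joblib.load(manifest_path.parent / entry["model_file"]),
                cv_acc=entry["cv_acc"],
                feature_set=entry.get("feature_set", ""),
            )
            for entry in manifest["members"]
        ]
        return cls(members=members)
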