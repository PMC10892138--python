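"""Distribution-learning evaluation of a generated molecule set.

Implements the standard validity / uniqueness / novelty / mean-QED summary
(GuacaMol distribution-learning conventions: uniqueness over valid
molecules, novelty over unique-valid molecules, membership tested on
canonical SMILES) plus a per-molecule physicochemical property table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from . import chem

__all__ = ["MetricsReport", "PropertyReport", "compute_metrics", "property_report"]


@dataclass(frozen=True)
class MetricsReport:
    validity: float
    uniqueness: float
    novelty: float
    mean_qed: float
    n_generated: int

    def __post_init__(self) -> None:
        if self.n_generated < 1:
            raise ValueError("n_generated must be >= 1")
        for name in ("validity", "uniqueness", "novelty", "mean_qed"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "validity": self.validity,
            "uniqueness": self.uniqueness,
            "novelty": self.novelty,
            "mean_qed": self.mean_qed,
            "n_generated": self.n_generated,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compute_metrics(
    generated: Sequence[str], training_set: Iterable[str]
) -> MetricsReport:
    """Summarize a generated set against a training corpus.

    validity = |valid| / |generated|; uniqueness = |distinct canonical
    among valid| / |valid|; novelty = |distinct canonical not in training|
    / |distinct canonical|; mean_qed averages over valid molecules.
    Uniqueness, novelty and mean QED are 0 when nothing is valid.
    """
    generated = list(generated)
    if not generated:
        raise ValueError("generated set is empty")
    train = set(training_set)
    valid = [s for s in generated if chem.is_valid_smiles(s)]
    if not valid:
        return MetricsReport(0.0, 0.0, 0.0, 0.0, len(generated))
    canonical = [chem.canonicalize(s) for s in valid]
    distinct = set(canonical)
    novel = {s for s in distinct if s not in train}
    mean_qed = sum(chem.compute_qed(s) for s in valid) / len(valid)
    return MetricsReport(
        validity=len(valid) / len(generated),
        uniqueness=len(distinct) / len(valid),
        novelty=len(novel) / len(distinct),
        mean_qed=mean_qed,
        n_generated=len(generated),
    )


@dataclass(frozen=True)
class PropertyReport:
    """Per-molecule descriptor table (valid molecules only) with summaries."""

    table: pd.DataFrame

    @property
    def summary(self) -> pd.DataFrame:
        return self.table.drop(columns=["smiles"]).agg(["min", "max", "mean"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def property_report(generated: Sequence[str]) -> PropertyReport:
    """Descriptor table (MW, logP, HBD, HBA, rotatable bonds, rings) for
    every valid molecule in *generated*.  Errors if none is valid."""
    rows = []
    for s in generated:
        if not chem.is_valid_smiles(s):
            continue
        d = chem.compute_descriptors(s)
        rows.append({
            "smiles": s, "mw": d.mw, "logp": d.logp, "hbd": d.hbd,
            "hba": d.hba, "rotatable_bonds": d.rotatable_bonds, "rings": d.rings,
        })
    if not rows:
        raise ValueError("no valid molecules to report on")
    return PropertyReport(table=pd.DataFrame(rows))
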