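"""Reward composition for search-guided SMILES generation.

Four components — chemical validity, Rule-of-Five adherence, QED, and
(optionally) docking affinity — are combined into one scalar that the tree
search backpropagates.  The combination is a weighted sum with a hard
validity gate: an unparseable string scores exactly zero, which is what
drives the 100%-validity behaviour of the gated search.

Docking is isolated behind :class:`AffinityScorer`, a thin adapter that
shells out to an external program (AutoDock Vina style); tests inject a
mock with the same ``score`` signature, so no docking executable is ever
required in the loop unless the affinity weight is switched on.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, runtime_checkable

from . import chem

__all__ = [
    "RewardConfig",
    "RewardVector",
    "AffinityScorer",
    "AffinityConfigError",
    "AffinityError",
    "compute_reward",
    "score_affinity",
]


class AffinityConfigError(RuntimeError):
    """The docking adapter is misconfigured (e.g. executable missing)."""


class AffinityError(RuntimeError):
    """The external docking run failed; carries the captured diagnostics."""


@dataclass(frozen=True)
class RewardConfig:
    """Weights and gating for the composite reward.

    affinity_floor is the docking score (kcal/mol) mapped to an affinity
    component of 1.0; less negative scores scale linearly down to 0.
    """

    weight_validity: float = 1.0
    weight_ro5: float = 1.0
    weight_qed: float = 1.0
    weight_affinity: float = 0.0
    affinity_floor: float = -12.0
    validity_gate: bool = True

    def __post_init__(self) -> None:
        weights = (
            self.weight_validity,
            self.weight_ro5,
            self.weight_qed,
            self.weight_affinity,
        )
        if any(w < 0 for w in weights):
            raise ValueError("reward weights must be non-negative")
        if not any(w > 0 for w in weights):
            raise ValueError("at least one reward weight must be positive")
        if self.affinity_floor >= 0:
            raise ValueError("affinity_floor must be negative (kcal/mol)")

    @property
    def max_composite(self) -> float:
        """Upper bound of the composite scalar (all components at 1)."""
        return (
            self.weight_validity
            + self.weight_ro5
            + self.weight_qed
            + self.weight_affinity
        )


@dataclass(frozen=True)
class RewardVector:
    """Per-molecule reward components plus the composite scalar."""

    validity: int
    ro5: int
    qed: float
    composite: float
    affinity_kcal: float | None = None

    def to_dict(self) -> dict:
        d = {
            "validity": self.validity,
            "ro5": self.ro5,
            "qed": self.qed,
            "composite": self.composite,
        }
        if self.affinity_kcal is not None:
            d["affinity_kcal"] = self.affinity_kcal
        return d


@runtime_checkable
class SupportsAffinity(Protocol):
    def score(self, smiles: str, seed: int | None = None) -> float: ...


def affinity_component(affinity_kcal: float, affinity_floor: float) -> float:
    """Map a docking score to [0, 1]: 0 at >= 0 kcal/mol, 1 at the floor."""
    return min(max(affinity_kcal / affinity_floor, 0.0), 1.0)


def compute_reward(
    text: str,
    config: RewardConfig | None = None,
    scorer: SupportsAffinity | None = None,
    seed: int | None = None,
) -> RewardVector:
    """Score one candidate SMILES string.

    Invalid SMILES is an expected input and yields all-zero components (and,
    under the validity gate, a zero composite).  The affinity term is only
    computed when a scorer is supplied and its weight is positive; scorer
    failures propagate — a docking error is never silently scored as 0.
    """
    config = config or RewardConfig()
    if not chem.is_valid_smiles(text):
        return RewardVector(validity=0, ro5=0, qed=0.0, composite=0.0)

    ro5 = int(chem.passes_ro5(text))
    qed = chem.compute_qed(text)
    composite = (
        config.weight_validity * 1.0
        + config.weight_ro5 * ro5
        + config.weight_qed * qed
    )
    affinity_kcal: float | None = None
    if scorer is not None and config.weight_affinity > 0:
        affinity_kcal = scorer.score(text, seed=seed)
        composite += config.weight_affinity * affinity_component(
            affinity_kcal, config.affinity_floor
        )
    return RewardVector(
        validity=1, ro5=ro5, qed=qed, composite=composite, affinity_kcal=affinity_kcal
    )


_VINA_DEFAULT_TEMPLATE = (
    "vina --receptor {receptor} --ligand {ligand} "
    "--center_x {cx} --center_y {cy} --center_z {cz} "
    "--size_x {sx} --size_y {sy} --size_z {sz} "
    "--seed {seed} --out {out}"
)


@dataclass(frozen=True)
class AffinityScorer:
    """Adapter around an external docking program.

    The command template receives the receptor path verbatim plus the search
    box; ``{ligand}`` is a file containing the candidate SMILES (a wrapper
    script in the template is responsible for any format conversion the
    docking program needs).  The best (lowest) score in the program's output
    is returned.
    """

    receptor_spec: str
    box_center: tuple[float, float, float]
    box_size: tuple[float, float, float]
    command_template: str = _VINA_DEFAULT_TEMPLATE
    workdir: Path | None = None

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.box_size):
            raise ValueError("docking box sizes must be positive")

    def score(self, smiles: str, seed: int | None = None) -> float:
        return score_affinity(smiles, self, seed=seed)


def _parse_docking_scores(text: str) -> list[float]:
    """Pull affinity values out of Vina-style output.

    Accepts both the results table (``  1   -9.87   0.000   0.000``) and
    ``REMARK VINA RESULT: -9.87 ...`` lines.
    """
    scores: list[float] = []
    for line in text.splitlines():
        parts = line.split()
        if line.strip().startswith("REMARK VINA RESULT:") and len(parts) >= 4:
            scores.append(float(parts[3]))
        elif len(parts) >= 2 and parts[0].isdigit():
            try:
                scores.append(float(parts[1]))
            except ValueError:
                continue
    return scores


def score_affinity(text: str, scorer: AffinityScorer, seed: int | None = None) -> float:
    """Dock one ligand and return the best (lowest) score in kcal/mol."""
    if not chem.is_valid_smiles(text):
        raise chem.InvalidSmilesError(f"cannot dock invalid SMILES: {text!r}")
    executable = scorer.command_template.split()[0]
    if shutil.which(executable) is None:
        raise AffinityConfigError(
            f"docking executable {executable!r} not found on PATH"
        )
    with tempfile.TemporaryDirectory(dir=scorer.workdir) as tmp:
        ligand = Path(tmp) / "ligand.smi"
        out = Path(tmp) / "docked.out"
        ligand.write_text(text + "\n")
        cx, cy, cz = scorer.box_center
        sx, sy, sz = scorer.box_size
        cmd = scorer.command_template.format(
            ligand=ligand,
            receptor=scorer.receptor_spec,
            cx=cx, cy=cy, cz=cz, sx=sx, sy=sy, sz=sz,
            seed=0 if seed is None else seed,
            out=out,
        )
        proc = subprocess.run(
            cmd, shell=True, capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise AffinityError(
                f"docking command failed (exit {proc.returncode}):\n"
                f"stdout:\n{proc.stdout}\nstderr:\n{proc.stderr}"
            )
        blob = proc.stdout
        if out.exists():
            blob += "\n" + out.read_text()
        scores = _parse_docking_scores(blob)
        if not scores:
            raise AffinityError(
                f"no affinity score found in docking output:\n{proc.stdout}"
            )
        return min(scores)
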