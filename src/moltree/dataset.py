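"""Binding-record filtering, canonicalization, train/test splitting, and a
synthetic fixture generator.

The filtering rule mirrors the curation applied to BindingDB-style exports:
keep human records that carry a SMILES string and whose highest-priority
available potency measurement (IC50, else Kd, else EC50) is below 100 nM.
The priority is a chain, not a disjunction — a present-but-failing IC50
excludes the record even if a Kd would have passed.

The synthetic generator builds protein-ligand pair tables from a packaged
library of small valid SMILES templates and random protein sequences, with
a controllable fraction of records that violate the filter, so every
pipeline stage is testable without any external download.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import chem

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "BindingRecord",
    "PairDataset",
    "filter_binding_records",
    "split_train_test",
    "generate_synthetic_pairs",
    "template_smiles",
    "read_binding_tsv",
    "write_binding_tsv",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # the 20 standard residues; X also accepted
AFFINITY_CUTOFF_NM = 100.0
TARGET_ORGANISM = "Homo sapiens"


@dataclass(frozen=True)
class BindingRecord:
    """One measured protein-ligand interaction (affinities in nM)."""

    organism: str
    protein_seq: str
    smiles: str | None = None
    ic50_nM: float | None = None
    kd_nM: float | None = None
    ec50_nM: float | None = None

    def affinity_chain(self) -> float | None:
        """The highest-priority measurement that is present, or None."""
        for value in (self.ic50_nM, self.kd_nM, self.ec50_nM):
            if value is not None:
                return value
        return None


def _is_well_formed(rec: BindingRecord) -> bool:
    return all(
        v is None or (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0)
        for v in (rec.ic50_nM, rec.kd_nM, rec.ec50_nM)
    )


def filter_binding_records(records: Sequence[BindingRecord]) -> list[BindingRecord]:
    """Apply the curation criteria, preserving input order.

    Kept iff organism is human, a SMILES is present, and the first present
    affinity in priority order IC50 > Kd > EC50 is < 100 nM.  Records with
    no measurement at all, or with malformed (negative / non-finite)
    values, are dropped and counted in the log.
    """
    kept: list[BindingRecord] = []
    n_malformed = n_organism = n_no_smiles = n_affinity = 0
    for rec in records:
        if not _is_well_formed(rec):
            n_malformed += 1
            continue
        if rec.organism != TARGET_ORGANISM:
            n_organism += 1
            continue
        if not rec.smiles:
            n_no_smiles += 1
            continue
        affinity = rec.affinity_chain()
        if affinity is None or affinity >= AFFINITY_CUTOFF_NM:
            n_affinity += 1
            continue
        kept.append(rec)
    logger.info(
        "filter_binding_records: kept %d of %d (dropped: %d organism, "
        "%d missing-SMILES, %d affinity, %d malformed)",
        len(kept), len(records), n_organism, n_no_smiles, n_affinity, n_malformed,
    )
    return kept


@dataclass(frozen=True)
class PairDataset:
    """Canonicalized (protein sequence, SMILES) training pairs."""

    pairs: tuple[tuple[str, str], ...]

    @property
    def n_unique_proteins(self) -> int:
        return len({p for p, _ in self.pairs})

    @property
    def n_unique_ligands(self) -> int:
        return len({s for _, s in self.pairs})

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def from_records(cls, records: Iterable[BindingRecord]) -> "PairDataset":
        """Canonicalize the ligands; records whose SMILES does not parse are
        dropped with a logged count."""
        pairs: list[tuple[str, str]] = []
        n_invalid = 0
        for rec in records:
            if rec.smiles is None or not chem.is_valid_smiles(rec.smiles):
                n_invalid += 1
                continue
            pairs.append((rec.protein_seq, chem.canonicalize(rec.smiles)))
        if n_invalid:
            logger.info("PairDataset: dropped %d records with unparseable SMILES", n_invalid)
        return cls(pairs=tuple(pairs))


def split_train_test(
    ds: PairDataset, train_frac: float, seed: int
) -> tuple[PairDataset, PairDataset]:
    """Random exact partition into train (round(n*frac)) and test pairs."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    n = len(ds)
    if n < 2:
        raise ValueError("need at least 2 pairs to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = round(n * train_frac)
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    return (
        PairDataset(pairs=tuple(ds.pairs[i] for i in train_idx)),
        PairDataset(pairs=tuple(ds.pairs[i] for i in test_idx)),
    )


def template_smiles() -> list[str]:
    """The packaged library of small valid SMILES templates."""
    ref = resources.files("moltree.data") / "fragment_library.smi"
    with resources.as_file(ref) as path:
        return chem.read_smi(path)


def _random_protein(rng: np.random.Generator, lo: int = 50, hi: int = 300) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def generate_synthetic_pairs(
    n: int, seed: int, fail_fraction: float = 0.0
) -> list[BindingRecord]:
    """Emit *n* synthetic binding records.

    Exactly floor(n * fail_fraction) records violate one curation criterion
    (wrong organism, missing SMILES, or all affinities >= 100 nM); the rest
    pass.  Ligands are drawn from the packaged template library; proteins
    are random 50-300-residue sequences.  Deterministic given *seed*.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= fail_fraction < 1:
        raise ValueError("fail_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    templates = template_smiles()
    n_fail = int(n * fail_fraction)
    fail_at = set(rng.choice(n, size=n_fail, replace=False).tolist())

    records: list[BindingRecord] = []
    for i in range(n):
        protein = _random_protein(rng)
        smiles: str | None = str(rng.choice(templates))
        organism = TARGET_ORGANISM
        # which of IC50/Kd/EC50 is present: exercise the priority chain
        present = rng.integers(0, 3)
        value = float(rng.uniform(1.0, AFFINITY_CUTOFF_NM - 1.0))
        affinities: dict[str, float | None] = {"ic50_nM": None, "kd_nM": None, "ec50_nM": None}
        affinities[("ic50_nM", "kd_nM", "ec50_nM")[present]] = value
        if i in fail_at:
            mode = rng.integers(0, 3)
            if mode == 0:
                organism = str(rng.choice(["Mus musculus", "Rattus norvegicus", "Bos taurus"]))
            elif mode == 1:
                smiles = None
            else:
                for k in affinities:
                    affinities[k] = None if affinities[k] is None else float(
                        rng.uniform(AFFINITY_CUTOFF_NM, 10 * AFFINITY_CUTOFF_NM)
                    )
                # ensure at least one failing value is present
                if all(v is None for v in affinities.values()):
                    affinities["ic50_nM"] = float(rng.uniform(AFFINITY_CUTOFF_NM, 1000.0))
        records.append(
            BindingRecord(
                organism=organism,
                protein_seq=protein,
                smiles=smiles,
                **affinities,
            )
        )
    return records


# ---------------------------------------------------------------------------
# I/O: BindingDB-style TSV, .smi and FASTA writers

DEFAULT_COLUMNS = {
    "organism": "Target Source Organism According to Curator or DataSource",
    "ic50_nM": "IC50 (nM)",
    "kd_nM": "Kd (nM)",
    "ec50_nM": "EC50 (nM)",
    "smiles": "Ligand SMILES",
    "protein_seq": "BindingDB Target Chain Sequence",
}


def read_binding_tsv(path, columns: dict | None = None) -> list[BindingRecord]:
    """Read binding records from a TSV with configurable column names."""
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"TSV is missing required columns: {missing}")
    records: list[BindingRecord] = []
    for _, row in df.iterrows():
        def _num(col: str) -> float | None:
            raw = row[cols[col]]
            if pd.isna(raw) or str(raw).strip() == "":
                return None
            try:
                return float(str(raw).lstrip("<>").strip())
            except ValueError:
                return math.nan  # malformed: dropped (and counted) by the filter
        smiles = row[cols["smiles"]]
        records.append(
            BindingRecord(
                organism=str(row[cols["organism"]]),
                protein_seq=str(row[cols["protein_seq"]]),
                smiles=None if pd.isna(smiles) or str(smiles).strip() == "" else str(smiles),
                ic50_nM=_num("ic50_nM"),
                kd_nM=_num("kd_nM"),
                ec50_nM=_num("ec50_nM"),
            )
        )
    return records


def write_binding_tsv(path, records: Sequence[BindingRecord], columns: dict | None = None) -> None:
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    rows = [
        {
            cols["organism"]: r.organism,
            cols["ic50_nM"]: r.ic50_nM,
            cols["kd_nM"]: r.kd_nM,
            cols["ec50_nM"]: r.ec50_nM,
            cols["smiles"]: r.smiles,
            cols["protein_seq"]: r.protein_seq,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fasta(path, sequences: Sequence[str], names: Sequence[str] | None = None) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    names = names or [f"seq{i}" for i in range(len(sequences))]
    recs = [SeqRecord(Seq(s), id=n, description="") for s, n in zip(sequences, names)]
    seqio_write(recs, str(path), "fasta")


def write_pairs(ds: PairDataset, smi_path, fasta_path) -> None:
    """Write a pair dataset as a .smi file plus a protein FASTA (one entry
    per pair, index-aligned)."""
    chem.write_smi(smi_path, [s for _, s in ds.pairs],
                   names=[f"pair{i}" for i in range(len(ds))])
    write_fasta(fasta_path, [p for p, _ in ds.pairs],
                names=[f"pair{i}" for i in range(len(ds))])
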