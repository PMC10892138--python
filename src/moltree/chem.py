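"""Chemistry primitives: SMILES tokenization, validity, canonicalization,
descriptors, Lipinski's Rule of Five, and QED.

Everything downstream (rewards, metrics, decoders) treats a molecule as a
SMILES string and calls into this module; RDKit is the single source of
chemical truth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED

RDLogger.DisableLog("rdApp.*")  # parse failures are an expected input, not noise

__all__ = [
    "TokenizationError",
    "InvalidSmilesError",
    "TokenVocabulary",
    "MoleculeDescriptors",
    "Ro5Result",
    "tokenize_smiles",
    "detokenize",
    "is_valid_smiles",
    "canonicalize",
    "compute_descriptors",
    "check_ro5",
    "compute_qed",
    "read_smi",
    "write_smi",
]

BOS = "<bos>"
EOS = "<eos>"
PAD = "<pad>"

# SMILES lexer: bracket atoms first, then two-letter organic-subset elements,
# then single-letter atoms/aromatics, %nn ring closures, digits, bonds and
# punctuation.  Order matters: "Cl" must win over "C" + "l".
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]"  # bracket atom, e.g. [N+], [nH], [13C@H]
    r"|Br|Cl"  # two-letter organic-subset elements
    r"|[BCNOSPFI]"  # one-letter organic-subset elements
    r"|[bcnops]"  # aromatic atoms
    r"|%\d{2}"  # two-digit ring closure
    r"|[0-9]"  # ring closure digit
    r"|[=#$:/\\.\-+()*@])"  # bonds, branches, dots, stereo marks
)


class TokenizationError(ValueError):
    """A character in the SMILES string is not part of the grammar."""


class InvalidSmilesError(ValueError):
    """The SMILES string does not parse to a sanitizable molecule."""


def tokenize_smiles(text: str, vocab: "TokenVocabulary | None" = None) -> list[str]:
    """Split a SMILES string into grammar tokens.

    Multi-character atoms (``Cl``, ``Br``) and bracket atoms (``[N+]``,
    ``[nH]``) are single tokens; concatenating the result reproduces the
    input exactly.  If *vocab* is given, every token must be in it.

    Raises
    ------
    TokenizationError
        If a character does not start any token, or (with *vocab*) a token
        is out of vocabulary.  The message names the offending position.
    """
    if not text:
        raise TokenizationError("empty SMILES string")
    if any(ch.isspace() for ch in text):
        raise TokenizationError("SMILES string contains whitespace")
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise TokenizationError(
                f"unrecognized character {text[pos]!r} at position {pos} in {text!r}"
            )
        tok = m.group(0)
        if vocab is not None and tok not in vocab:
            raise TokenizationError(
                f"token {tok!r} at position {pos} is not in the vocabulary"
            )
        tokens.append(tok)
        pos = m.end()
    return tokens


def detokenize(tokens: Iterable[str]) -> str:
    """Inverse of :func:`tokenize_smiles`; specials are dropped."""
    specials = {BOS, EOS, PAD}
    return "".join(t for t in tokens if t not in specials)


@dataclass(frozen=True)
class TokenVocabulary:
    """Bijective token<->index map over SMILES tokens plus BOS/EOS/PAD.

    Specials occupy the first three indices so that masks are cheap; the
    chemical tokens follow in sorted order.
    """

    tokens: tuple[str, ...]
    bos: str = BOS
    eos: str = EOS
    pad: str = PAD

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens are not unique")
        for sp in (self.bos, self.eos, self.pad):
            if sp not in self.tokens:
                raise ValueError(f"special token {sp!r} missing from vocabulary")
        object.__setattr__(
            self, "_index", {t: i for i, t in enumerate(self.tokens)}
        )

    @classmethod
    def from_corpus(cls, smiles: Iterable[str]) -> "TokenVocabulary":
        """Build a frozen vocabulary from a training corpus."""
        chem_tokens: set[str] = set()
        for s in smiles:
            chem_tokens.update(tokenize_smiles(s))
        return cls(tokens=(PAD, BOS, EOS, *sorted(chem_tokens)))

    def __len__(self) -> int:
        return len(self.tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise TokenizationError(f"token {token!r} is not in the vocabulary")

    def token(self, index: int) -> str:
        return self.tokens[index]

    def encode(self, tokens: Sequence[str]) -> list[int]:
        return [self.index(t) for t in tokens]

    def decode(self, indices: Sequence[int]) -> list[str]:
        return [self.tokens[i] for i in indices]

    @property
    def bos_id(self) -> int:
        return self._index[self.bos]

    @property
    def eos_id(self) -> int:
        return self._index[self.eos]

    @property
    def pad_id(self) -> int:
        return self._index[self.pad]

    def to_dict(self) -> dict:
        return {"tokens": list(self.tokens), "bos": self.bos, "eos": self.eos, "pad": self.pad}

    @classmethod
    def from_dict(cls, d: dict) -> "TokenVocabulary":
        return cls(tokens=tuple(d["tokens"]), bos=d["bos"], eos=d["eos"], pad=d["pad"])


def _mol_from_smiles(text: str) -> Chem.Mol | None:
    if not isinstance(text, str) or not text or any(c.isspace() for c in text):
        return None
    return Chem.MolFromSmiles(text)  # sanitizes by default


def is_valid_smiles(text: str) -> bool:
    """True iff *text* parses to a sanitizable molecule. Never raises."""
    try:
        return _mol_from_smiles(text) is not None
    except Exception:
        return False


def _require_mol(text: str) -> Chem.Mol:
    mol = _mol_from_smiles(text)
    if mol is None:
        raise InvalidSmilesError(f"not a valid SMILES string: {text!r}")
    return mol


def canonicalize(text: str) -> str:
    """Return RDKit's canonical SMILES for a valid input.

    Idempotent; two encodings of the same molecule map to the same string.
    """
    return Chem.MolToSmiles(_require_mol(text))


@dataclass(frozen=True)
class MoleculeDescriptors:
    """Physicochemical descriptors used by the RO5 filter and property reports.

    mw is the average-isotope molecular weight in Da; logp a Crippen
    estimate; hbd/hba are Lipinski's donor (OH+NH) and acceptor (N+O)
    counts.
    """

    mw: float
    logp: float
    hbd: int
    hba: int
    rotatable_bonds: int
    rings: int

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("molecular weight must be positive")
        for name in ("hbd", "hba", "rotatable_bonds", "rings"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def compute_descriptors(text: str) -> MoleculeDescriptors:
    """Compute :class:`MoleculeDescriptors` for a valid SMILES string."""
    mol = _require_mol(text)
    return MoleculeDescriptors(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        rotatable_bonds=Lipinski.NumRotatableBonds(mol),
        rings=mol.GetRingInfo().NumRings(),
    )


@dataclass(frozen=True)
class Ro5Result:
    """Per-criterion outcome of Lipinski's Rule of Five."""

    mw_ok: bool
    logp_ok: bool
    hbd_ok: bool
    hba_ok: bool

    @property
    def passes(self) -> bool:
        return self.mw_ok and self.logp_ok and self.hbd_ok and self.hba_ok


# Inclusive bounds: a molecule sitting exactly on a threshold passes.
RO5_MW_MAX = 500.0
RO5_LOGP_MAX = 5.0
RO5_HBD_MAX = 5
RO5_HBA_MAX = 10


def check_ro5(desc: MoleculeDescriptors) -> Ro5Result:
    """Apply the four Rule-of-Five criteria (MW <= 500, logP <= 5,
    HBD <= 5, HBA <= 10) to a descriptor set."""
    return Ro5Result(
        mw_ok=desc.mw <= RO5_MW_MAX,
        logp_ok=desc.logp <= RO5_LOGP_MAX,
        hbd_ok=desc.hbd <= RO5_HBD_MAX,
        hba_ok=desc.hba <= RO5_HBA_MAX,
    )


def passes_ro5(text: str) -> bool:
    """Convenience: RO5 verdict straight from a SMILES string."""
    return check_ro5(compute_descriptors(text)).passes


def compute_qed(text: str) -> float:
    """Quantitative Estimate of Drug-likeness (Bickerton et al.), in [0, 1]."""
    return float(QED.qed(_require_mol(text)))


def read_smi(path) -> list[str]:
    """Read a .smi file: one SMILES per line, optional tab-separated name,
    '#' comment lines and blank lines ignored."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split("\t")[0].split()[0])
    return out


def write_smi(path, smiles: Iterable[str], names: Iterable[str] | None = None) -> None:
    with open(path, "w") as fh:
        if names is None:
            for s in smiles:
                fh.write(f"{s}\n")
        else:
            for s, n in zip(smiles, names):
                fh.write(f"{s}\t{n}\n")
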