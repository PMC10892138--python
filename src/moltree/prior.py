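"""Conditional autoregressive SMILES prior: a protein-sequence encoder and
SMILES decoder exposing next-token distributions.

The model is a self-contained NumPy encoder-decoder transformer (multi-head
scaled dot-product attention, sinusoidal positions, post-norm residual
blocks, Adam) written for corpus sizes where a few hundred protein-ligand
pairs and a two-layer, 64-dimensional configuration train in minutes on one
CPU.  The documented full-scale defaults (6 layers x 512 x 8 heads,
lr 1e-4, batch 5, 25 epochs) describe the same architecture at the scale
used for database-wide training, which is outside this package's test loop.

Decoding is pull-based: greedy, beam and MCTS all consume the single
``next_token_distribution(ctx, prefix)`` contract, so the deterministic
table-driven :class:`MockModel` substitutes freely for the transformer in
tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chem import TokenVocabulary, TokenizationError, is_valid_smiles, tokenize_smiles
from .dataset import AMINO_ACIDS

__all__ = [
    "TransformerConfig",
    "ProteinContext",
    "TransformerModel",
    "MockModel",
    "encode",
    "next_token_distribution",
    "train_toy",
]

_PROTEIN_ALPHABET = AMINO_ACIDS + "X"
_AA_INDEX = {aa: i + 1 for i, aa in enumerate(_PROTEIN_ALPHABET)}  # 0 is padding


@dataclass(frozen=True)
class TransformerConfig:
    """Architecture and optimization hyperparameters.

    The defaults are the full-scale training regime; :meth:`toy` returns the
    reduced configuration used throughout the test suite.
    """

    n_layers: int = 6
    d_model: int = 512
    n_heads: int = 8
    d_ff: int | None = None  # defaults to 4 * d_model
    learning_rate: float = 1e-4
    batch_size: int = 5
    n_epochs: int = 25
    max_protein_len: int = 500
    max_smiles_len: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_layers", "d_model", "n_heads", "batch_size", "n_epochs",
                     "max_protein_len", "max_smiles_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")

    @property
    def ff_dim(self) -> int:
        return self.d_ff if self.d_ff is not None else 4 * self.d_model

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    @classmethod
    def toy(cls, **overrides) -> "TransformerConfig":
        """Reduced configuration: 2 layers x 64 x 4 heads, fast learning
        rate, protein truncation at 300 residues."""
        base = dict(
            n_layers=2, d_model=64, n_heads=4, learning_rate=1e-3,
            batch_size=5, n_epochs=15, max_protein_len=300, max_smiles_len=80,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class ProteinContext:
    """Encoded protein representation consumed by the decoder.

    Carries the encoder output (one d_model vector per residue) plus the
    cross-attention keys/values precomputed per decoder layer, and is tied
    to the model instance that produced it.
    """

    memory: np.ndarray  # (length, d_model)
    cross_kv: list[tuple[np.ndarray, np.ndarray]]
    length: int
    _model: "TransformerModel" = field(repr=False)


# ---------------------------------------------------------------------------
# numerical building blocks (forward + hand-written backward)


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _ln_fwd(x, g, b, eps=1e-5):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    xhat = (x - mu) / np.sqrt(var + eps)
    return xhat * g + b, (xhat, var, g, eps)


def _ln_bwd(dout, cache):
    xhat, var, g, eps = cache
    dg = (dout * xhat).sum(axis=tuple(range(dout.ndim - 1)))
    db = dout.sum(axis=tuple(range(dout.ndim - 1)))
    dxhat = dout * g
    inv = 1.0 / np.sqrt(var + eps)
    dx = inv * (
        dxhat
        - dxhat.mean(-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(-1, keepdims=True)
    )
    return dx, dg, db


def _attn_fwd(q_in, kv_in, Wq, Wk, Wv, Wo, n_heads, mask=None, kv_cache=None):
    """Multi-head scaled dot-product attention over one sequence.

    q_in: (T, d); kv_in: (S, d).  mask, if given, is (T, S) additive
    (0 or -inf).  kv_cache, if given, is precomputed (Kh, Vh) and kv_in may
    be None (inference-only path).
    """
    T, d = q_in.shape
    dk = d // n_heads
    Q = q_in @ Wq
    Qh = Q.reshape(T, n_heads, dk).transpose(1, 0, 2)  # (h, T, dk)
    if kv_cache is not None:
        Kh, Vh = kv_cache
        K = V = None
    else:
        K = kv_in @ Wk
        V = kv_in @ Wv
        S = kv_in.shape[0]
        Kh = K.reshape(S, n_heads, dk).transpose(1, 0, 2)
        Vh = V.reshape(S, n_heads, dk).transpose(1, 0, 2)
    scores = Qh @ Kh.transpose(0, 2, 1) / np.sqrt(dk)
    if mask is not None:
        scores = scores + mask
    A = _softmax(scores, axis=-1)  # (h, T, S)
    Oh = A @ Vh
    O = Oh.transpose(1, 0, 2).reshape(T, d)
    out = O @ Wo
    cache = (q_in, kv_in, Qh, Kh, Vh, A, O, Wq, Wk, Wv, Wo, n_heads)
    return out, cache


def _attn_bwd(dout, cache):
    q_in, kv_in, Qh, Kh, Vh, A, O, Wq, Wk, Wv, Wo, n_heads = cache
    T, d = q_in.shape
    dk = d // n_heads
    dWo = O.T @ dout
    dO = dout @ Wo.T
    dOh = dO.reshape(T, n_heads, dk).transpose(1, 0, 2)
    dA = dOh @ Vh.transpose(0, 2, 1)
    dVh = A.transpose(0, 2, 1) @ dOh
    dscores = A * (dA - (dA * A).sum(-1, keepdims=True))
    dscores /= np.sqrt(dk)
    dQh = dscores @ Kh
    dKh = dscores.transpose(0, 2, 1) @ Qh
    dQ = dQh.transpose(1, 0, 2).reshape(T, d)
    S = Kh.shape[1]
    dK = dKh.transpose(1, 0, 2).reshape(S, d)
    dV = dVh.transpose(1, 0, 2).reshape(S, d)
    dq_in = dQ @ Wq.T
    dkv_in = dK @ Wk.T + dV @ Wv.T
    dWq = q_in.T @ dQ
    dWk = kv_in.T @ dK
    dWv = kv_in.T @ dV
    return dq_in, dkv_in, {"Wq": dWq, "Wk": dWk, "Wv": dWv, "Wo": dWo}


def _ffn_fwd(x, W1, b1, W2, b2):
    h = x @ W1 + b1
    a = np.maximum(h, 0.0)
    return a @ W2 + b2, (x, h, a, W1, W2)


def _ffn_bwd(dout, cache):
    x, h, a, W1, W2 = cache
    dW2 = a.T @ dout
    db2 = dout.sum(0)
    da = dout @ W2.T
    dh = da * (h > 0)
    dW1 = x.T @ dh
    db1 = dh.sum(0)
    dx = dh @ W1.T
    return dx, {"W1": dW1, "b1": db1, "W2": dW2, "b2": db2}


def _sinusoidal_positions(max_len: int, d_model: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    enc = np.zeros((max_len, d_model))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


# ---------------------------------------------------------------------------
# the model


class TransformerModel:
    """Encoder-decoder transformer over (protein sequence -> SMILES tokens)."""

    def __init__(self, config: TransformerConfig, vocab: TokenVocabulary):
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        self._init_params(rng)
        self._pos = _sinusoidal_positions(
            max(config.max_protein_len, config.max_smiles_len) + 2, config.d_model
        )
        self._adam_m: dict[str, np.ndarray] | None = None
        self._adam_v: dict[str, np.ndarray] | None = None
        self._adam_t = 0

    # -- parameters ---------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        d, dff, V = cfg.d_model, cfg.ff_dim, len(self.vocab)
        scale = 0.08  # seed-controlled uniform init

        def U(*shape):
            return rng.uniform(-scale, scale, size=shape)

        p = self.params
        p["Ep"] = U(len(_PROTEIN_ALPHABET) + 1, d)
        p["Es"] = U(V, d)
        for l in range(cfg.n_layers):
            for blk in (f"enc{l}_sa", f"dec{l}_sa", f"dec{l}_ca"):
                for w in ("Wq", "Wk", "Wv", "Wo"):
                    p[f"{blk}_{w}"] = U(d, d)
            for side in (f"enc{l}", f"dec{l}"):
                p[f"{side}_W1"] = U(d, dff)
                p[f"{side}_b1"] = np.zeros(dff)
                p[f"{side}_W2"] = U(dff, d)
                p[f"{side}_b2"] = np.zeros(d)
            p[f"enc{l}_ln1_g"] = np.ones(d); p[f"enc{l}_ln1_b"] = np.zeros(d)
            p[f"enc{l}_ln2_g"] = np.ones(d); p[f"enc{l}_ln2_b"] = np.zeros(d)
            for k in ("ln1", "ln2", "ln3"):
                p[f"dec{l}_{k}_g"] = np.ones(d); p[f"dec{l}_{k}_b"] = np.zeros(d)
        p["Wout"] = U(d, V)
        p["bout"] = np.zeros(V)

    # -- encoding -----------------------------------------------------------

    def protein_ids(self, protein_seq: str) -> np.ndarray:
        if not protein_seq:
            raise ValueError("protein sequence is empty")
        if len(protein_seq) > self.config.max_protein_len:
            raise ValueError(
                f"protein sequence length {len(protein_seq)} exceeds "
                f"max_protein_len={self.config.max_protein_len}"
            )
        try:
            return np.array([_AA_INDEX[aa] for aa in protein_seq])
        except KeyError as err:
            raise ValueError(f"illegal residue character {err.args[0]!r}") from None

    def _encoder_fwd(self, ids: np.ndarray):
        p, cfg = self.params, self.config
        x = p["Ep"][ids] * np.sqrt(cfg.d_model) + self._pos[: len(ids)]
        caches = []
        for l in range(cfg.n_layers):
            sa, c_sa = _attn_fwd(
                x, x, p[f"enc{l}_sa_Wq"], p[f"enc{l}_sa_Wk"],
                p[f"enc{l}_sa_Wv"], p[f"enc{l}_sa_Wo"], cfg.n_heads,
            )
            y, c_ln1 = _ln_fwd(x + sa, p[f"enc{l}_ln1_g"], p[f"enc{l}_ln1_b"])
            ff, c_ff = _ffn_fwd(y, p[f"enc{l}_W1"], p[f"enc{l}_b1"],
                                p[f"enc{l}_W2"], p[f"enc{l}_b2"])
            x, c_ln2 = _ln_fwd(y + ff, p[f"enc{l}_ln2_g"], p[f"enc{l}_ln2_b"])
            caches.append((c_sa, c_ln1, c_ff, c_ln2))
        return x, caches

    def encode(self, protein_seq: str) -> ProteinContext:
        """Encode one protein sequence into a reusable decoding context."""
        ids = self.protein_ids(protein_seq)
        memory, _ = self._encoder_fwd(ids)
        p, cfg = self.params, self.config
        dk = cfg.d_k
        cross_kv = []
        for l in range(cfg.n_layers):
            K = memory @ p[f"dec{l}_ca_Wk"]
            V = memory @ p[f"dec{l}_ca_Wv"]
            S = memory.shape[0]
            cross_kv.append((
                K.reshape(S, cfg.n_heads, dk).transpose(1, 0, 2),
                V.reshape(S, cfg.n_heads, dk).transpose(1, 0, 2),
            ))
        return ProteinContext(memory=memory, cross_kv=cross_kv,
                              length=len(protein_seq), _model=self)

    # -- decoding -----------------------------------------------------------

    def _decoder_fwd(self, ids: np.ndarray, memory: np.ndarray,
                     cross_kv=None, collect=None):
        p, cfg = self.params, self.config
        T = len(ids)
        x = p["Es"][ids] * np.sqrt(cfg.d_model) + self._pos[:T]
        causal = np.triu(np.full((T, T), -np.inf), k=1)
        caches = []
        for l in range(cfg.n_layers):
            sa, c_sa = _attn_fwd(
                x, x, p[f"dec{l}_sa_Wq"], p[f"dec{l}_sa_Wk"],
                p[f"dec{l}_sa_Wv"], p[f"dec{l}_sa_Wo"], cfg.n_heads, mask=causal,
            )
            y, c_ln1 = _ln_fwd(x + sa, p[f"dec{l}_ln1_g"], p[f"dec{l}_ln1_b"])
            ca, c_ca = _attn_fwd(
                y, memory, p[f"dec{l}_ca_Wq"], p[f"dec{l}_ca_Wk"],
                p[f"dec{l}_ca_Wv"], p[f"dec{l}_ca_Wo"], cfg.n_heads,
                kv_cache=None if cross_kv is None else cross_kv[l],
            )
            z, c_ln2 = _ln_fwd(y + ca, p[f"dec{l}_ln2_g"], p[f"dec{l}_ln2_b"])
            ff, c_ff = _ffn_fwd(z, p[f"dec{l}_W1"], p[f"dec{l}_b1"],
                                p[f"dec{l}_W2"], p[f"dec{l}_b2"])
            x, c_ln3 = _ln_fwd(z + ff, p[f"dec{l}_ln3_g"], p[f"dec{l}_ln3_b"])
            caches.append((c_sa, c_ln1, c_ca, c_ln2, c_ff, c_ln3))
            if collect is not None:
                collect.append({"self": c_sa[5], "cross": c_ca[5]})
        logits = x @ p["Wout"] + p["bout"]
        return logits, caches

    def _check_prefix(self, prefix: Sequence[str]) -> np.ndarray:
        if not prefix or prefix[0] != self.vocab.bos:
            raise ValueError("prefix must begin with the BOS token")
        return np.array(self.vocab.encode(prefix))

    def next_token_distribution(
        self, ctx: ProteinContext, prefix: Sequence[str]
    ) -> np.ndarray:
        """Probability vector over the vocabulary for the token following
        *prefix* (which must start with BOS)."""
        if ctx._model is not self:
            raise ValueError("context was produced by a different model instance")
        ids = self._check_prefix(prefix)
        if len(ids) > self.config.max_smiles_len:
            raise ValueError(
                f"prefix length {len(ids)} exceeds max_smiles_len="
                f"{self.config.max_smiles_len}"
            )
        logits, _ = self._decoder_fwd(ids, ctx.memory, cross_kv=ctx.cross_kv)
        return _softmax(logits[-1])

    def attention_weights(self, ctx: ProteinContext, prefix: Sequence[str]):
        """Per-layer self/cross attention matrices (h, T, S) for inspection."""
        ids = self._check_prefix(prefix)
        collect: list[dict] = []
        self._decoder_fwd(ids, ctx.memory, cross_kv=ctx.cross_kv, collect=collect)
        return collect

    # -- training -----------------------------------------------------------

    def _loss_and_grads(self, protein_ids, dec_in, targets, want_grads=True):
        p, cfg = self.params, self.config
        memory, enc_caches = self._encoder_fwd(protein_ids)
        logits, dec_caches = self._decoder_fwd(dec_in, memory)
        probs = _softmax(logits, axis=-1)
        T = len(targets)
        loss = -np.log(probs[np.arange(T), targets] + 1e-12).mean()
        if not want_grads:
            return loss, None
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = probs.copy()
        dlogits[np.arange(T), targets] -= 1.0
        dlogits /= T
        # output head; recover the final decoder activation from the last
        # layernorm cache
        xhat, var, g, eps = dec_caches[-1][5]
        x_out = xhat * g + p[f"dec{cfg.n_layers-1}_ln3_b"]
        grads["Wout"] = x_out.T @ dlogits
        grads["bout"] = dlogits.sum(0)
        dx = dlogits @ p["Wout"].T
        dmem = np.zeros_like(memory)
        for l in reversed(range(cfg.n_layers)):
            c_sa, c_ln1, c_ca, c_ln2, c_ff, c_ln3 = dec_caches[l]
            dzff, dg, db = _ln_bwd(dx, c_ln3)
            grads[f"dec{l}_ln3_g"] += dg; grads[f"dec{l}_ln3_b"] += db
            dff_in, ffg = _ffn_bwd(dzff, c_ff)
            for k, v in ffg.items():
                grads[f"dec{l}_{k}"] += v
            dz = dzff + dff_in
            dyca, dg, db = _ln_bwd(dz, c_ln2)
            grads[f"dec{l}_ln2_g"] += dg; grads[f"dec{l}_ln2_b"] += db
            dy_ca, dmem_l, ag = _attn_bwd(dyca, c_ca)
            for k, v in ag.items():
                grads[f"dec{l}_ca_{k}"] += v
            dmem += dmem_l
            dy = dyca + dy_ca
            dxsa, dg, db = _ln_bwd(dy, c_ln1)
            grads[f"dec{l}_ln1_g"] += dg; grads[f"dec{l}_ln1_b"] += db
            dx_sa_q, dx_sa_kv, ag = _attn_bwd(dxsa, c_sa)
            for k, v in ag.items():
                grads[f"dec{l}_sa_{k}"] += v
            dx = dxsa + dx_sa_q + dx_sa_kv
        np.add.at(grads["Es"], dec_in, dx * np.sqrt(cfg.d_model))
        # encoder backward
        dxe = dmem
        for l in reversed(range(cfg.n_layers)):
            c_sa, c_ln1, c_ff, c_ln2 = enc_caches[l]
            dyff, dg, db = _ln_bwd(dxe, c_ln2)
            grads[f"enc{l}_ln2_g"] += dg; grads[f"enc{l}_ln2_b"] += db
            dff_in, ffg = _ffn_bwd(dyff, c_ff)
            for k, v in ffg.items():
                grads[f"enc{l}_{k}"] += v
            dy = dyff + dff_in
            dxsa, dg, db = _ln_bwd(dy, c_ln1)
            grads[f"enc{l}_ln1_g"] += dg; grads[f"enc{l}_ln1_b"] += db
            dq, dkv, ag = _attn_bwd(dxsa, c_sa)
            for k, v in ag.items():
                grads[f"enc{l}_sa_{k}"] += v
            dxe = dxsa + dq + dkv
        np.add.at(grads["Ep"], protein_ids, dxe * np.sqrt(cfg.d_model))
        return loss, grads

    def _adam_step(self, grads: Mapping[str, np.ndarray]) -> None:
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        if self._adam_m is None:
            self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
            self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = b1 * self._adam_m[k] + (1 - b1) * g
            v = self._adam_v[k] = b2 * self._adam_v[k] + (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def mean_loss(self, encoded_pairs) -> float:
        losses = [
            self._loss_and_grads(pi, di, tg, want_grads=False)[0]
            for pi, di, tg in encoded_pairs
        ]
        return float(np.mean(losses))

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "config": self.config.__dict__,
            "vocab": self.vocab.to_dict(),
        }
        np.savez_compressed(path, __meta__=np.array(json.dumps(meta)), **self.params)

    @classmethod
    def load(cls, path) -> "TransformerModel":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["__meta__"]))
            config = TransformerConfig(**meta["config"])
            vocab = TokenVocabulary.from_dict(meta["vocab"])
            model = cls(config, vocab)
            for k in model.params:
                model.params[k] = npz[k]
        return model


# ---------------------------------------------------------------------------
# module-level contract functions (work for both real and mock models)


def encode(protein_seq: str, model) -> ProteinContext:
    """Encode a protein sequence with *model*; deterministic per instance."""
    return model.encode(protein_seq)


def next_token_distribution(model, ctx, prefix: Sequence[str]) -> np.ndarray:
    """Next-token probability vector; normalized over the model vocabulary."""
    return model.next_token_distribution(ctx, prefix)


class MockModel:
    """Deterministic table-driven stand-in for the transformer.

    ``transition_table`` maps a prefix token tuple (starting with BOS) to a
    probability mapping {token: prob} or a full vector over the vocabulary.
    An optional ``default`` distribution answers prefixes missing from the
    table; without it, an unknown prefix is an error.
    """

    def __init__(self, vocab: TokenVocabulary,
                 transition_table: Mapping[tuple, Mapping[str, float] | Sequence[float]],
                 default: Mapping[str, float] | Sequence[float] | None = None):
        self.vocab = vocab
        self.table = {
            tuple(k): self._to_vector(v) for k, v in transition_table.items()
        }
        self.default = None if default is None else self._to_vector(default)

    def _to_vector(self, dist) -> np.ndarray:
        if isinstance(dist, Mapping):
            vec = np.zeros(len(self.vocab))
            for tok, prob in dist.items():
                vec[self.vocab.index(tok)] = prob
        else:
            vec = np.asarray(dist, dtype=float)
            if vec.shape != (len(self.vocab),):
                raise ValueError("distribution vector has wrong length")
        if (vec < 0).any():
            raise ValueError("probabilities must be non-negative")
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError(f"distribution sums to {vec.sum()}, not 1")
        return vec

    def encode(self, protein_seq: str) -> None:
        return None  # the mock is unconditional

    def next_token_distribution(self, ctx, prefix: Sequence[str]) -> np.ndarray:
        if not prefix or prefix[0] != self.vocab.bos:
            raise ValueError("prefix must begin with the BOS token")
        for tok in prefix:
            if tok not in self.vocab:
                raise TokenizationError(f"token {tok!r} is not in the vocabulary")
        key = tuple(prefix)
        if key in self.table:
            return self.table[key]
        if self.default is not None:
            return self.default
        raise KeyError(f"no transition stored for prefix {key}")


# ---------------------------------------------------------------------------
# toy training


def _encode_pairs(pairs, model: TransformerModel):
    vocab = model.vocab
    out = []
    for protein, smiles in pairs:
        pi = model.protein_ids(protein)
        toks = tokenize_smiles(smiles, vocab)
        ids = vocab.encode(toks)
        dec_in = np.array([vocab.bos_id] + ids)
        targets = np.array(ids + [vocab.eos_id])
        if len(dec_in) > model.config.max_smiles_len:
            raise ValueError("SMILES longer than max_smiles_len")
        out.append((pi, dec_in, targets))
    return out


def train_toy(pairs, config: TransformerConfig,
              progress: bool = False) -> tuple[TransformerModel, dict]:
    """Train a transformer on (protein, SMILES) pairs by teacher forcing.

    Returns the model plus a history dict with initial/final mean
    cross-entropy.  Raises before any training if a SMILES is invalid or
    fewer than two pairs are given.  Reproducible given config.seed.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least 2 training pairs")
    for _, smiles in pairs:
        if not is_valid_smiles(smiles):
            raise ValueError(f"invalid SMILES in training pairs: {smiles!r}")
    vocab = TokenVocabulary.from_corpus(s for _, s in pairs)
    model = TransformerModel(config, vocab)
    encoded = _encode_pairs(pairs, model)
    rng = np.random.default_rng(config.seed + 1)

    initial_loss = model.mean_loss(encoded)
    epoch_losses: list[float] = []
    iterator = range(config.n_epochs)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="train_toy", unit="epoch")
    for _epoch in iterator:
        order = rng.permutation(len(encoded))
        running = []
        for start in range(0, len(order), config.batch_size):
            batch = [encoded[i] for i in order[start:start + config.batch_size]]
            acc: dict[str, np.ndarray] | None = None
            for pi, di, tg in batch:
                loss, grads = model._loss_and_grads(pi, di, tg)
                running.append(loss)
                if acc is None:
                    acc = grads
                else:
                    for k in acc:
                        acc[k] += grads[k]
            for k in acc:
                acc[k] /= len(batch)
            model._adam_step(acc)
        epoch_losses.append(float(np.mean(running)))
    final_loss = model.mean_loss(encoded)
    history = {
        "initial_loss": initial_loss,
        "final_loss": final_loss,
        "epoch_losses": epoch_losses,
    }
    return model, history
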