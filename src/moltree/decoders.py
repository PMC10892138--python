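"""Decoding strategies over the conditional prior: greedy, beam, and
reward-guided Monte Carlo Tree Search.

All three are pure over the model contract — they only ever call
``model.next_token_distribution(ctx, prefix)`` — so they run unchanged on
the NumPy transformer and on the deterministic table-driven mock.

The MCTS treats partial SMILES token sequences as tree nodes and iterates
four phases per simulation: UCT selection from the root, expansion of the
selected leaf with one child per vocabulary token of positive prior
probability, a rollout that completes the sequence by sampling from the
prior, and backpropagation of the rollout's scalar reward along the path to
the root.  The returned molecule is the highest-composite-reward *valid*
terminal sequence observed anywhere in the run; if no valid terminal was
seen within the budget the search fails loudly rather than emit an invalid
string.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import chem
from .rewards import RewardConfig, RewardVector, compute_reward

__all__ = [
    "TreeNode",
    "MCTSConfig",
    "GenerationResult",
    "NoValidMoleculeError",
    "greedy_decode",
    "beam_decode",
    "ucb_score",
    "mcts_generate",
]


class NoValidMoleculeError(RuntimeError):
    """The simulation budget was exhausted without one valid terminal."""


@dataclass
class TreeNode:
    """One node of the SMILES search tree.

    cum_reward (r_i) and n_visits (n_i) drive the UCT selection rule; the
    token path from the root (BOS) to a node spells a SMILES prefix.
    """

    token: str
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)
    n_visits: int = 0
    cum_reward: float = 0.0
    depth: int = 0  # generated tokens, excluding BOS
    terminal: bool = False

    def prefix(self) -> list[str]:
        """Token path from the root to this node, inclusive."""
        path: list[str] = []
        node: TreeNode | None = self
        while node is not None:
            path.append(node.token)
            node = node.parent
        return path[::-1]


@dataclass(frozen=True)
class MCTSConfig:
    """Search-budget and exploration parameters.

    c_explore is the UCB exploration constant (default 2); max_depth caps
    the SMILES token length d of the V^d search space.
    """

    c_explore: float = 2.0
    n_simulations: int = 200
    max_depth: int = 60
    rollouts_per_expansion: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.c_explore < 0:
            raise ValueError("c_explore must be non-negative")
        for name in ("n_simulations", "max_depth", "rollouts_per_expansion"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True)
class GenerationResult:
    smiles: str
    reward: RewardVector
    decoder: str
    simulations_used: int
    seed: int
    tree: "TreeNode | None" = field(default=None, repr=False, compare=False)


def _argmax_lowest_index(vec: np.ndarray) -> int:
    return int(np.argmax(vec))  # np.argmax already returns the first maximum


def greedy_decode(model, ctx, max_len: int = 100) -> list[str]:
    """Emit the argmax token at each step until EOS or *max_len* tokens.

    Ties go to the lowest vocabulary index.  Returns the generated chemical
    tokens (BOS/EOS stripped).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    vocab = model.vocab
    prefix = [vocab.bos]
    out: list[str] = []
    banned = [vocab.bos_id, vocab.pad_id]
    for _ in range(max_len):
        dist = model.next_token_distribution(ctx, prefix).copy()
        dist[banned] = 0.0  # BOS/PAD are never emitted
        tok = vocab.token(_argmax_lowest_index(dist))
        if tok == vocab.eos:
            break
        prefix.append(tok)
        out.append(tok)
    return out


def beam_decode(model, ctx, k: int, length_alpha: float = 0.0,
                max_len: int = 100) -> list[tuple[list[str], float]]:
    """Length-normalized beam search.

    Keeps the k best partial sequences per step under the score
    ``sum(log P(token)) / len**length_alpha`` (len counts generated tokens,
    EOS included).  Sequences that emit EOS or reach *max_len* move to a
    finished pool and compete in the final ranking.  Returns finished
    sequences (specials stripped) sorted by score, best first.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vocab = model.vocab
    # beams: (score, tiebreak index path, token list incl. BOS, logprob sum)
    beams = [(0.0, (), [vocab.bos], 0.0)]
    finished: list[tuple[float, tuple, list[str]]] = []
    for _step in range(max_len):
        candidates: list[tuple[float, tuple, list[str], float]] = []
        for _score, path, toks, logsum in beams:
            dist = model.next_token_distribution(ctx, toks)
            with np.errstate(divide="ignore"):
                logp = np.log(dist)
            gen_len = len(toks)  # tokens generated so far + this one, minus BOS
            for idx in range(len(dist)):
                tok = vocab.token(idx)
                if tok in (vocab.bos, vocab.pad):
                    continue
                if dist[idx] == 0.0:
                    continue  # unreachable extension: log-prob -inf
                new_logsum = logsum + logp[idx]
                norm = gen_len ** length_alpha if length_alpha != 0 else 1.0
                score = new_logsum / norm
                candidates.append((score, path + (idx,), toks + [tok], new_logsum))
        if not candidates:
            break
        candidates.sort(key=lambda c: (-c[0], c[1]))
        beams = []
        for score, path, toks, logsum in candidates[:k]:
            if toks[-1] == vocab.eos or len(toks) - 1 >= max_len:
                finished.append((score, path, toks))
            else:
                beams.append((score, path, toks, logsum))
        if not beams:
            break
    # any still-open beams at the length cap count as finished
    for score, path, toks, _ in beams:
        finished.append((score, path, toks))
    finished.sort(key=lambda c: (-c[0], c[1]))
    out = []
    for score, _path, toks in finished:
        stripped = [t for t in toks if t not in (vocab.bos, vocab.eos, vocab.pad)]
        out.append((stripped, float(score)))
    return out


def ucb_score(node: TreeNode, parent_visits: float, c_explore: float) -> float:
    """UCT value r_i/n_i + c * sqrt(ln(N_i)/n_i); +inf for unvisited nodes."""
    if parent_visits < 1:
        raise ValueError("parent_visits must be >= 1")
    if node.n_visits == 0:
        return math.inf
    exploit = node.cum_reward / node.n_visits
    explore = c_explore * math.sqrt(math.log(parent_visits) / node.n_visits)
    return exploit + explore


def _select_child(node: TreeNode, c_explore: float) -> TreeNode:
    # ties broken by child order == token index order
    best, best_score = None, -math.inf
    for child in node.children:
        s = ucb_score(child, max(node.n_visits, 1), c_explore)
        if s > best_score:
            best, best_score = child, s
    return best


def mcts_generate(model, ctx, reward_config: RewardConfig | None = None,
                  mcts_config: MCTSConfig | None = None,
                  scorer=None, collect_tree: bool = False) -> GenerationResult:
    """Generate one molecule by reward-guided tree search.

    Runs ``n_simulations`` iterations of selection, expansion, rollout and
    backpropagation, then returns the best-scoring valid terminal sequence
    observed.  Raises :class:`NoValidMoleculeError` if no rollout produced
    a valid SMILES — the search never returns an invalid molecule.
    """
    reward_config = reward_config or RewardConfig()
    mcts_config = mcts_config or MCTSConfig()
    vocab = model.vocab
    rng = np.random.default_rng(mcts_config.seed)
    root = TreeNode(token=vocab.bos)
    banned = {vocab.index(vocab.bos), vocab.index(vocab.pad)}

    best_smiles: str | None = None
    best_reward: RewardVector | None = None
    reward_cache: dict[str, RewardVector] = {}

    def score(tokens: list[str]) -> RewardVector:
        smiles = chem.detokenize(tokens)
        if smiles not in reward_cache:
            reward_cache[smiles] = compute_reward(
                smiles, reward_config, scorer, seed=mcts_config.seed
            )
        return reward_cache[smiles]

    def rollout(prefix: list[str], depth: int) -> list[str]:
        tokens = list(prefix)
        while depth < mcts_config.max_depth:
            dist = model.next_token_distribution(ctx, tokens)
            dist = dist.copy()
            dist[list(banned)] = 0.0
            total = dist.sum()
            if total <= 0:
                break
            dist /= total
            idx = int(rng.choice(len(dist), p=dist))
            tok = vocab.token(idx)
            if tok == vocab.eos:
                break
            tokens.append(tok)
            depth += 1
        return tokens

    for sim in range(mcts_config.n_simulations):
        # 1. selection: descend by max UCB until a leaf
        node = root
        while node.children:
            node = _select_child(node, mcts_config.c_explore)
        # 2. expansion: create all children with positive prior probability,
        # ordered by descending prior (so the first rollout follows the
        # model's preferred token; UCB takes over once visited)
        if not node.terminal:
            dist = model.next_token_distribution(ctx, node.prefix())
            order = sorted(
                (int(i) for i in np.flatnonzero(dist > 0)),
                key=lambda i: (-dist[i], i),
            )
            for idx in order:
                if idx in banned:
                    continue
                tok = vocab.token(int(idx))
                node.children.append(TreeNode(
                    token=tok, parent=node, depth=node.depth + 1,
                    terminal=(tok == vocab.eos
                              or node.depth + 1 >= mcts_config.max_depth),
                ))
            if node.children:
                node = node.children[0]  # first unvisited child rolls out
        # 3. simulation: complete the sequence by sampling from the prior
        for _ in range(mcts_config.rollouts_per_expansion):
            if node.terminal:
                tokens = node.prefix()
            else:
                tokens = rollout(node.prefix(), node.depth)
            rv = score(tokens)
            if rv.validity == 1 and (
                best_reward is None or rv.composite > best_reward.composite
            ):
                best_reward = rv
                best_smiles = chem.detokenize(tokens)
            # 4. backpropagation: update the path from the leaf to the root
            walker: TreeNode | None = node
            while walker is not None:
                walker.n_visits += 1
                walker.cum_reward += rv.composite
                walker = walker.parent

    if best_smiles is None:
        raise NoValidMoleculeError(
            f"no valid molecule found in {mcts_config.n_simulations} simulations"
        )
    return GenerationResult(
        smiles=best_smiles,
        reward=best_reward,
        decoder="mcts",
        simulations_used=mcts_config.n_simulations,
        seed=mcts_config.seed,
        tree=root if collect_tree else None,
    )
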