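"""Decoding strategies: greedy argmax paths, beam vs an exhaustive
enumeration oracle, UCT closed forms, and MCTS invariants."""

import math

import numpy as np
import pytest

from moltree import chem, decoders, prior, rewards
from moltree.chem import BOS, EOS
from moltree.decoders import MCTSConfig, TreeNode, ucb_score

from conftest import enumerate_completions, make_vocab, random_mock_model


class TestGreedy:
    def test_forced_single_token(self):
        vocab = make_vocab(["C"])
        mock = prior.MockModel(vocab, {
            (BOS,): {"C": 0.9, EOS: 0.1},
            (BOS, "C"): {EOS: 1.0},
        })
        assert decoders.greedy_decode(mock, None, max_len=10) == ["C"]

    def test_tie_breaks_to_lowest_index(self):
        vocab = make_vocab(["C", "N"])  # C sorts before N
        mock = prior.MockModel(vocab, {
            (BOS,): {"C": 0.5, "N": 0.5},
            (BOS, "C"): {EOS: 1.0},
        })
        assert decoders.greedy_decode(mock, None, max_len=10) == ["C"]

    def test_three_step_chain_matches_hand_trace(self):
        """Hand-traced argmax path through a three-step transition table."""
        vocab = make_vocab(["C", "O"])
        mock = prior.MockModel(vocab, {
            (BOS,): {"C": 0.6, "O": 0.3, EOS: 0.1},
            (BOS, "C"): {"O": 0.7, "C": 0.2, EOS: 0.1},
            (BOS, "C", "O"): {"C": 0.55, EOS: 0.45},
            (BOS, "C", "O", "C"): {EOS: 0.9, "C": 0.1},
        })
        assert decoders.greedy_decode(mock, None, max_len=10) == ["C", "O", "C"]

    def test_max_len_truncates(self):
        vocab = make_vocab(["C"])
        mock = prior.MockModel(vocab, {}, default={"C": 1.0})
        assert decoders.greedy_decode(mock, None, max_len=4) == ["C"] * 4


class TestBeam:
    def test_k1_equals_greedy_over_random_tables(self):
        """beam(k=1) reproduces greedy token-for-token on >= 100 random
        transition tables."""
        rng = np.random.default_rng(0)
        for trial in range(100):
            n_tokens = int(rng.integers(2, 4))
            max_len = int(rng.integers(2, 5))
            mock = random_mock_model(
                ["C", "N", "O"][:n_tokens], max_len, rng
            )
            greedy = decoders.greedy_decode(mock, None, max_len=max_len)
            beam = decoders.beam_decode(mock, None, k=1, max_len=max_len)
            assert beam[0][0] == greedy, f"trial {trial}"

    @pytest.mark.parametrize("length_alpha", [0.0, 0.7, 1.0])
    def test_top1_matches_enumeration_oracle(self, length_alpha):
        """With an exhaustive beam width, the top-ranked sequence equals the
        argmax over brute-force enumeration of all complete sequences
        (vocab <= 4, max_len <= 5, >= 50 random tables)."""
        rng = np.random.default_rng(7)
        for trial in range(50):
            n_tokens = int(rng.integers(1, 5))
            max_len = int(rng.integers(2, 6))
            chem_tokens = ["C", "N", "O", "S"][:n_tokens]
            mock = random_mock_model(chem_tokens, max_len, rng)
            k = (n_tokens + 1) ** max_len  # exhaustive: beam never prunes
            ranked = decoders.beam_decode(
                mock, None, k=k, length_alpha=length_alpha, max_len=max_len
            )
            completions = enumerate_completions(mock, max_len)
            scored = []
            for seq, logsum in completions:
                T = len(seq)  # EOS counts toward length
                scored.append((logsum / (T ** length_alpha), seq))
            best_score, best_seq = max(scored, key=lambda x: x[0])
            best_stripped = [t for t in best_seq if t != mock.vocab.eos]
            assert ranked[0][1] == pytest.approx(best_score), f"trial {trial}"
            assert ranked[0][0] == best_stripped, f"trial {trial}"

    def test_finished_sequences_compete_in_final_ranking(self):
        vocab = make_vocab(["C"])
        # ending immediately (prob .6) beats the longer continuation
        mock = prior.MockModel(vocab, {
            (BOS,): {EOS: 0.6, "C": 0.4},
            (BOS, "C"): {EOS: 1.0},
        })
        ranked = decoders.beam_decode(mock, None, k=4, max_len=3)
        assert ranked[0][0] == [] and ranked[0][1] == pytest.approx(math.log(0.6))

    def test_k_validation(self):
        vocab = make_vocab(["C"])
        mock = prior.MockModel(vocab, {(BOS,): {"C": 1.0}})
        with pytest.raises(ValueError):
            decoders.beam_decode(mock, None, k=0)


class TestUcb:
    def test_zero_when_ln_parent_is_zero(self):
        node = TreeNode(token="C", n_visits=1, cum_reward=0.0)
        assert ucb_score(node, parent_visits=1, c_explore=2.0) == 0.0

    def test_closed_form_at_parent_e(self):
        """r=1, n=1, N=e, c=2 gives 1 + 2*sqrt(1) = 3."""
        node = TreeNode(token="C", n_visits=1, cum_reward=1.0)
        assert ucb_score(node, parent_visits=math.e, c_explore=2.0) == pytest.approx(3.0)

    def test_unvisited_is_infinite(self):
        node = TreeNode(token="C", n_visits=0, cum_reward=123.0)
        assert ucb_score(node, parent_visits=50, c_explore=0.0) == math.inf

    def test_monotone_in_reward_and_visits(self):
        lo = TreeNode(token="C", n_visits=4, cum_reward=1.0)
        hi = TreeNode(token="C", n_visits=4, cum_reward=2.0)
        assert (ucb_score(hi, 10, 2.0) > ucb_score(lo, 10, 2.0))
        few = TreeNode(token="C", n_visits=2, cum_reward=1.0)
        many = TreeNode(token="C", n_visits=8, cum_reward=4.0)  # same mean
        assert ucb_score(few, 10, 2.0) > ucb_score(many, 10, 2.0)


def _ethanol_mock():
    """A table whose only positive-probability terminal string is CCO."""
    vocab = make_vocab(["C", "O"])
    return prior.MockModel(vocab, {
        (BOS,): {"C": 1.0},
        (BOS, "C"): {"C": 1.0},
        (BOS, "C", "C"): {"O": 1.0},
        (BOS, "C", "C", "O"): {EOS: 1.0},
    })


def _check_visit_conservation(node: TreeNode, max_reward: float) -> None:
    child_visits = sum(c.n_visits for c in node.children)
    assert node.n_visits >= child_visits
    assert node.cum_reward <= node.n_visits * max_reward + 1e-9
    for c in node.children:
        _check_visit_conservation(c, max_reward)


class TestMcts:
    def test_single_reachable_outcome(self):
        for budget in (1, 5, 40):
            res = decoders.mcts_generate(
                _ethanol_mock(), None,
                mcts_config=MCTSConfig(n_simulations=budget, max_depth=10, seed=0),
            )
            assert res.smiles == "CCO"
            assert res.reward.validity == 1

    def test_visit_count_conservation(self):
        """root visits == simulation budget; every node's visits bound the
        sum of its children's; cumulative reward respects the bound."""
        rng = np.random.default_rng(5)
        config = rewards.RewardConfig()
        for trial in range(5):
            mock = random_mock_model(["C", "N", "O"], 6, rng)
            mc = MCTSConfig(n_simulations=60, max_depth=6, seed=trial)
            res = decoders.mcts_generate(mock, None, config, mc, collect_tree=True)
            assert res.tree.n_visits == mc.n_simulations
            _check_visit_conservation(res.tree, config.max_composite)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(9)
        mock = random_mock_model(["C", "N", "O"], 6, rng)
        mc = MCTSConfig(n_simulations=80, max_depth=6, seed=123)
        a = decoders.mcts_generate(mock, None, mcts_config=mc)
        b = decoders.mcts_generate(mock, None, mcts_config=mc)
        assert a.smiles == b.smiles and a.reward == b.reward

    def test_never_returns_invalid_molecule(self):
        """Across many searches over random tables every returned molecule
        parses; unreachable-validity budgets raise instead of returning."""
        rng = np.random.default_rng(11)
        n_ok = 0
        for trial in range(20):
            mock = random_mock_model(["C", "N", "O", ")"], 5, rng)
            try:
                res = decoders.mcts_generate(
                    mock, None,
                    mcts_config=MCTSConfig(n_simulations=30, max_depth=5, seed=trial),
                )
            except decoders.NoValidMoleculeError:
                continue
            assert chem.is_valid_smiles(res.smiles)
            n_ok += 1
        assert n_ok > 0  # the property run actually exercised returns

    def test_no_valid_terminal_raises(self):
        vocab = make_vocab(["1"])  # a lone ring-bond digit can never parse
        mock = prior.MockModel(vocab, {}, default={"1": 0.5, EOS: 0.5})
        with pytest.raises(decoders.NoValidMoleculeError):
            decoders.mcts_generate(
                mock, None,
                mcts_config=MCTSConfig(n_simulations=10, max_depth=3, seed=0),
            )

    def test_exploitation_limit_converges_to_best_path(self):
        """With c=0 and a deterministic two-arm landscape, visits concentrate
        on the higher-reward arm and the search returns it."""
        vocab = make_vocab(["C", "O"])
        # "C" (methane) and "O" (water); methane has the higher QED
        mock = prior.MockModel(vocab, {
            (BOS,): {"C": 0.5, "O": 0.5},
            (BOS, "C"): {EOS: 1.0},
            (BOS, "O"): {EOS: 1.0},
        })
        assert chem.compute_qed("C") > chem.compute_qed("O")
        res = decoders.mcts_generate(
            mock, None,
            mcts_config=MCTSConfig(c_explore=0.0, n_simulations=50, max_depth=4, seed=2),
            collect_tree=True,
        )
        assert res.smiles == "C"
        by_token = {c.token: c for c in res.tree.children}
        assert by_token["C"].n_visits > by_token["O"].n_visits

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCTSConfig(c_explore=-1.0)
        with pytest.raises(ValueError):
            MCTSConfig(n_simulations=0)
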