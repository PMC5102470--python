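"""Tests of the MRMS selection criterion and the incremental greedy search."""

import numpy as np
import pytest

from mrmsn.infotheory import build_mim, conditional_entropy, entropy, mutual_information
from mrmsn.mrms import (
    MRMSConfig,
    default_k,
    mrms_score,
    relevance,
    select_regulators,
    significance,
)


def greedy_oracle(target, mim, symbols, alpha, k, t0, admissible=None):
    """Independent step-by-step replay of the incremental search, built
    directly on the public entropy estimators (no shared fast path)."""
    n = mim.shape[0]
    if admissible is None:
        cands = [j for j in range(n) if j != target]
    else:
        cands = [j for j in range(n) if admissible[j] and j != target]
    picks, scores = [], []
    if not cands:
        return picks, scores
    first = max(cands, key=lambda j: (mim[j, target], -j))
    picks.append(first)
    scores.append(mim[first, target])
    cands.remove(first)
    while len(picks) < k and cands:
        best, best_score = None, -np.inf
        for c in cands:
            h_v = conditional_entropy(symbols[target], [symbols[v] for v in picks])
            h_vc = conditional_entropy(
                symbols[target], [symbols[v] for v in picks] + [symbols[c]]
            )
            score = alpha * mim[c, target] + (1 - alpha) * max(0.0, h_v - h_vc)
            if score > best_score + 1e-12:  # epsilon-ties go to the smaller index
                best, best_score = c, score
        if best_score < t0:
            break
        picks.append(best)
        scores.append(best_score)
        cands.remove(best)
    return picks, scores


class TestCriterion:
    def test_relevance_reads_the_mim(self, rng):
        symbols = rng.integers(0, 3, size=(3, 30))
        mim = build_mim(symbols)
        for t in range(3):
            for c in range(3):
                if t != c:
                    assert relevance(t, c, mim) == pytest.approx(
                        mutual_information(symbols[c], symbols[t])
                    )

    def test_relevance_of_identical_genes_is_their_entropy(self):
        row = np.array([0, 1, 2, 0, 1, 2])
        mim = build_mim(np.stack([row, row]))
        assert relevance(0, 1, mim) == pytest.approx(entropy(row))

    def test_self_relevance_rejected(self):
        mim = np.eye(3)
        with pytest.raises(ValueError):
            relevance(1, 1, mim)

    def test_significance_with_empty_set_is_mutual_information(self, rng):
        symbols = rng.integers(0, 3, size=(4, 25))
        assert significance(1, 0, [], symbols) == pytest.approx(
            mutual_information(symbols[1], symbols[0])
        )

    def test_duplicated_information_has_zero_significance(self):
        # gene 2 carries the same symbols as already-selected gene 1
        symbols = np.array(
            [[0, 1, 0, 1, 1, 0], [0, 0, 1, 1, 0, 1], [0, 0, 1, 1, 0, 1]]
        )
        assert significance(2, 0, [1], symbols) == 0.0

    def test_significance_matches_two_conditional_entropies(self, rng):
        symbols = rng.integers(0, 3, size=(5, 40))
        V = [1, 3]
        expected = conditional_entropy(
            symbols[0], [symbols[1], symbols[3]]
        ) - conditional_entropy(symbols[0], [symbols[1], symbols[3], symbols[4]])
        assert significance(4, 0, V, symbols) == pytest.approx(expected)

    def test_candidate_already_selected_rejected(self, rng):
        symbols = rng.integers(0, 2, size=(3, 10))
        with pytest.raises(ValueError):
            significance(1, 0, [1], symbols)

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 0.9])
    def test_score_is_convex_combination(self, rng, alpha):
        symbols = rng.integers(0, 3, size=(5, 30))
        mim = build_mim(symbols)
        expected = alpha * relevance(0, 2, mim) + (1 - alpha) * significance(
            2, 0, [1], symbols
        )
        assert mrms_score(2, 0, [1], alpha, mim, symbols) == pytest.approx(expected)


class TestSelectRegulators:
    def test_k1_returns_argmax_mi_candidate(self, rng):
        symbols = rng.integers(0, 3, size=(5, 40))
        mim = build_mim(symbols)
        config = MRMSConfig(alpha=0.5, k=1, t0=0.0)
        sel = select_regulators(0, mim, symbols, config)
        row = mim[:, 0].copy()
        row[0] = -np.inf
        assert sel.regulators == [int(np.argmax(row))]

    def test_infinite_threshold_leaves_only_first_pick(self, rng):
        symbols = rng.integers(0, 3, size=(6, 40))
        mim = build_mim(symbols)
        config = MRMSConfig(alpha=0.5, k=4, t0=np.inf)
        sel = select_regulators(0, mim, symbols, config)
        assert len(sel.regulators) == 1
        assert sel.first_regulator == sel.regulators[0]

    def test_no_admissible_candidates_gives_empty_selection(self, rng):
        symbols = rng.integers(0, 2, size=(4, 10))
        mim = build_mim(symbols)
        config = MRMSConfig(alpha=0.5, k=2, t0=0.0)
        sel = select_regulators(0, mim, symbols, config, np.zeros(4, dtype=bool))
        assert sel.regulators == [] and sel.first_regulator is None

    def test_respects_budget_and_uniqueness(self, rng):
        for _ in range(10):
            symbols = rng.integers(0, 3, size=(6, 30))
            mim = build_mim(symbols)
            config = MRMSConfig(alpha=0.3, k=3, t0=0.0)
            sel = select_regulators(2, mim, symbols, config)
            assert len(sel.regulators) <= 3
            assert len(set(sel.regulators)) == len(sel.regulators)
            assert 2 not in sel.regulators

    def test_accepted_scores_meet_threshold(self, rng):
        symbols = rng.integers(0, 3, size=(6, 30))
        mim = build_mim(symbols)
        config = MRMSConfig(alpha=0.5, k=5, t0=0.2)
        sel = select_regulators(0, mim, symbols, config)
        assert all(s >= config.t0 for s in sel.scores[1:])

    def test_matches_bruteforce_greedy_replay(self, rng):
        for trial in range(30):
            n = int(rng.integers(3, 7))
            m = int(rng.integers(8, 20))
            symbols = rng.integers(0, 3, size=(n, m))
            mim = build_mim(symbols)
            alpha = float(rng.uniform(0.1, 0.9))
            k = int(rng.integers(1, n))
            t0 = float(rng.uniform(0.0, 0.5))
            target = int(rng.integers(0, n))
            sel = select_regulators(
                target, mim, symbols, MRMSConfig(alpha=alpha, k=k, t0=t0)
            )
            picks, scores = greedy_oracle(target, mim, symbols, alpha, k, t0)
            assert sel.regulators == picks
            assert sel.scores == pytest.approx(scores, abs=1e-10)

    def test_deterministic(self, rng):
        symbols = rng.integers(0, 3, size=(6, 25))
        mim = build_mim(symbols)
        config = MRMSConfig(alpha=0.4, k=3, t0=0.0)
        a = select_regulators(1, mim, symbols, config)
        b = select_regulators(1, mim, symbols, config)
        assert a.regulators == b.regulators and a.scores == b.scores


class TestConfig:
    def test_default_k_is_ceil_log2(self):
        assert [default_k(n) for n in (4, 10, 50, 5, 9)] == [2, 4, 6, 3, 4]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"alpha": 0.05, "k": 2, "t0": 0.0},
            {"alpha": 0.95, "k": 2, "t0": 0.0},
            {"alpha": 0.5, "k": 0, "t0": 0.0},
            {"alpha": 0.5, "k": 2, "t0": 0.0, "epsilon": 1.5},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MRMSConfig(**kwargs)
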