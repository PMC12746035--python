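"""Pattern matching, scoring and the GP loop."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gdpoet as g
from gdpoet.poet_engine import (
    Pattern, Token, _random_pattern, count_matches, ruleset_from_dict,
    ruleset_to_dict,
)

from conftest import random_peptide


def oracle_match(pattern: Pattern, seq: str) -> bool:
    """Independent exhaustive window scan with token semantics spelled out."""
    m = len(pattern.tokens)
    for i in range(len(seq) - m + 1):
        ok = True
        for tok, ch in zip(pattern.tokens, seq[i : i + m]):
            if tok.kind == "any":
                hit = True
            elif tok.kind == "literal":
                hit = ch in tok.residues
            else:
                hit = (ch not in tok.residues) if tok.negated else (ch in tok.residues)
            if not hit:
                ok = False
                break
        if ok:
            return True
    return False


class TestMatchPattern:
    @pytest.mark.parametrize(
        "pattern, seq, expected",
        [
            (g.motif("KK"), "DPDNDGTLDKKE", True),
            (g.motif("W"), "TQDSDDGMEDED", False),
            (
                Pattern("regex", (Token("class", frozenset("DE")), Token("any"),
                                  Token("class", frozenset("DE")))),
                "DPDNDGTLDKKE",
                True,  # the "DPD" window
            ),
            (g.parse_pattern("[^D].[DE]", "regex"), "DDDDDDDDDDDD", False),
        ],
    )
    def test_examples(self, pattern, seq, expected):
        assert g.match_pattern(pattern, seq) is expected
        assert oracle_match(pattern, seq) is expected

    def test_empty_sequence_matches_nothing(self):
        assert g.match_pattern(g.motif("A"), "") is False

    def test_invalid_residue_raises(self):
        with pytest.raises(g.AlphabetError, match="position 2"):
            g.match_pattern(g.motif("A"), "ABAA")

    @pytest.mark.parametrize("kind", ["motif", "regex"])
    def test_agrees_with_window_scan_oracle(self, kind):
        """10,000 random (pattern, sequence) pairs per dialect."""
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(10_000):
            pattern = _random_pattern(rng, kind)
            seq = random_peptide(rng)
            got = g.match_pattern(pattern, seq)
            assert got == oracle_match(pattern, seq)
            hits += got
        assert 0 < hits < 10_000  # both outcomes exercised

    def test_count_matches_overlapping_windows(self):
        assert count_matches(g.motif("DD"), "DDDD") == 3
        assert count_matches(g.parse_pattern("..", "regex"), "ACDE") == 3


class TestPredictScore:
    MODEL = g.RuleSet(
        (g.Rule(g.motif("DDD"), 0.5), g.Rule(g.motif("KK"), -0.3)), 1.0
    )

    def test_only_matching_rules_contribute(self):
        assert g.predict_score(self.MODEL, "DPDNDGTLDKKE") == pytest.approx(0.7)
        assert g.predict_score(self.MODEL, "TQDSDDGMEDED") == pytest.approx(1.0)

    def test_empty_ruleset_returns_baseline(self):
        assert g.predict_score(g.RuleSet((), 1.37), "ACDEFGHIKLMN") == 1.37

    def test_presence_vs_count_mode(self):
        model = g.RuleSet((g.Rule(g.motif("DD"), 0.1),), 1.0)
        assert g.predict_score(model, "DDDDACDEFGHI") == pytest.approx(1.1)
        assert g.predict_score(model, "DDDDACDEFGHI", mode="count") == pytest.approx(1.3)

    @given(st.randoms(use_true_random=False))
    def test_invariant_under_rule_permutation(self, pyrng):
        rng = np.random.default_rng(pyrng.randrange(2**31))
        rules = tuple(
            g.Rule(_random_pattern(rng, "motif"), float(rng.normal()))
            for _ in range(int(rng.integers(1, 8)))
        )
        seq = random_peptide(rng)
        base = g.predict_score(g.RuleSet(rules, 1.0), seq)
        shuffled = list(rules)
        pyrng.shuffle(shuffled)
        assert g.predict_score(g.RuleSet(tuple(shuffled), 1.0), seq) == pytest.approx(base)

    def test_non_matching_rule_is_neutral(self, planted_library):
        model = g.RuleSet((g.Rule(g.motif("DDD"), 0.8),), 1.0)
        extra = g.RuleSet(model.rules + (g.Rule(g.motif("WWWWW"), 5.0),), 1.0)
        for seq in planted_library.sequences:
            assert g.predict_score(extra, seq) == pytest.approx(
                g.predict_score(model, seq)
            )


class TestFitness:
    def test_exact_predictions_have_zero_rmse(self):
        data = g.TrainingSet(("AAAAAAAAAAAA", "DDDDDDDDDDDD"), (1.0, 1.0))
        cfg = g.EvolutionConfig(parsimony_penalty=0.0)
        rep = g.fitness(g.RuleSet((), 1.0), data, cfg)
        assert rep.rmse == 0.0
        assert rep.penalized_fitness == 0.0

    def test_hand_computed_rmse(self):
        data = g.TrainingSet(("AAAAAAAAAAAA", "CCCCCCCCCCCC"), (1.0, 2.0))
        cfg = g.EvolutionConfig(parsimony_penalty=0.0)
        rep = g.fitness(g.RuleSet((), 1.0), data, cfg)
        assert rep.rmse == pytest.approx(np.sqrt(0.5))

    def test_parsimony_penalty_counts_rules(self):
        data = g.TrainingSet(("AAAAAAAAAAAA",), (1.0,))
        cfg = g.EvolutionConfig(parsimony_penalty=0.01)
        bare = g.fitness(g.RuleSet((), 1.0), data, cfg)
        padded = g.fitness(g.RuleSet((g.Rule(g.motif("W"), 9.0),), 1.0), data, cfg)
        assert padded.rmse == bare.rmse  # W matches nothing
        assert padded.penalized_fitness - bare.penalized_fitness == pytest.approx(0.01)

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            g.fitness(g.RuleSet((), 1.0), g.TrainingSet((), ()), g.EvolutionConfig())


class TestVariation:
    def test_init_population_size_and_determinism(self, small_config):
        pop1 = g.init_population(small_config, np.random.default_rng(5))
        pop2 = g.init_population(small_config, np.random.default_rng(5))
        assert len(pop1) == small_config.population_size
        assert pop1 == pop2
        one_rule = g.EvolutionConfig(max_rules=1)
        pop = g.init_population(one_rule, np.random.default_rng(0))
        assert all(len(m) == 1 for m in pop)

    def test_mutation_identity_at_zero_rates(self):
        model = g.RuleSet((g.Rule(g.motif("DDD"), 0.8),), 1.0)
        cfg = g.EvolutionConfig(rule_mutation_rate=0.0, weight_mutation_sigma=0.0)
        assert g.mutate(model, cfg, np.random.default_rng(0)) == model

    @pytest.mark.parametrize("kind", ["motif", "regex"])
    def test_mutations_preserve_invariants(self, kind):
        """1000 mutations keep every rule-set invariant intact."""
        rng = np.random.default_rng(11)
        cfg = g.EvolutionConfig(max_rules=5)
        model = g.RuleSet(
            tuple(g.Rule(_random_pattern(rng, kind), 0.1) for _ in range(3)), 1.0, kind
        )
        for _ in range(1000):
            model = g.mutate(model, cfg, rng)
            assert len(model) <= cfg.max_rules
            assert model.kind == kind
            for rule in model.rules:
                assert 1 <= len(rule.pattern) <= 12
                assert np.isfinite(rule.weight)

    def test_mutation_never_exceeds_max_rules(self):
        cfg = g.EvolutionConfig(rule_mutation_rate=1.0, max_rules=2)
        model = g.RuleSet(
            (g.Rule(g.motif("AA"), 1.0), g.Rule(g.motif("CC"), 1.0)), 1.0
        )
        rng = np.random.default_rng(3)
        for _ in range(50):
            assert len(g.mutate(model, cfg, rng)) <= 2

    def test_crossover_conserves_rules(self):
        rng = np.random.default_rng(1)
        a = g.RuleSet(tuple(g.Rule(g.motif(c * 2), 1.0) for c in "ACD"), 1.0)
        b = g.RuleSet(tuple(g.Rule(g.motif(c * 2), -1.0) for c in "EF"), 2.0)
        c1, c2 = g.crossover(a, b, rng)
        assert len(c1) + len(c2) == 5
        assert sorted(r.pattern.text for r in c1.rules + c2.rules) == sorted(
            r.pattern.text for r in a.rules + b.rules
        )
        assert {c1.baseline, c2.baseline} == {1.0, 2.0}

    def test_crossover_of_empty_parents(self):
        empty = g.RuleSet((), 1.0)
        c1, c2 = g.crossover(empty, empty, np.random.default_rng(0))
        assert len(c1) == len(c2) == 0

    def test_crossover_kind_mismatch_rejected(self):
        a = g.RuleSet((), 1.0, "motif")
        b = g.RuleSet((), 1.0, "regex")
        with pytest.raises(ValueError, match="cross"):
            g.crossover(a, b, np.random.default_rng(0))

    def test_crossover_reproducible(self):
        a = g.RuleSet(tuple(g.Rule(g.motif(c * 2), 1.0) for c in "ACDE"), 1.0)
        b = g.RuleSet(tuple(g.Rule(g.motif(c * 3), -1.0) for c in "FGH"), 2.0)
        out1 = g.crossover(a, b, np.random.default_rng(9))
        out2 = g.crossover(a, b, np.random.default_rng(9))
        assert out1 == out2


class TestEvolve:
    def test_zero_generations_returns_initial_best(self, planted_library, small_config):
        cfg = g.EvolutionConfig(population_size=20, generations=0, rng_seed=0)
        best, history = g.evolve(planted_library, cfg)
        assert len(history) == 1
        assert g.fitness(best, planted_library, cfg).penalized_fitness == history[0]

    def test_history_non_increasing(self, planted_library, small_config):
        _, history = g.evolve(planted_library, small_config)
        assert len(history) == small_config.generations + 1
        assert all(a >= b for a, b in zip(history, history[1:]))

    def test_reproducible_from_seed(self, planted_library, small_config):
        out1 = g.evolve(planted_library, small_config)
        out2 = g.evolve(planted_library, small_config)
        assert out1[0] == out2[0]
        assert out1[1] == out2[1]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            g.EvolutionConfig(population_size=4, tournament_size=8)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        model = g.RuleSet(
            (
                g.Rule(g.parse_pattern("[DE].[^KR]W", "regex"), 0.25),
                g.Rule(g.parse_pattern("GG", "regex"), -0.5),
            ),
            1.1,
            "regex",
        )
        path = tmp_path / "model.json"
        g.save_ruleset(model, path)
        assert g.load_ruleset(path) == model

    def test_canonical_text_form(self):
        payload = ruleset_to_dict(
            g.RuleSet((g.Rule(g.parse_pattern("[ED].A", "regex"), 1.0),), 0.0, "regex")
        )
        assert payload["rules"][0]["pattern"] == "[DE].A"
        assert ruleset_from_dict(payload).rules[0].pattern.text == "[DE].A"
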