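"""Genetic-programming engine evolving weighted motif/regex rule sets.

The model of sequence function is deliberately simple: a rule set is a list
of (pattern, weight) pairs plus an intercept. A peptide's predicted r1 ratio
is the intercept plus the sum of weights of every rule whose pattern occurs
somewhere in the sequence (presence-based by default; an occurrence-count
mode is available for sensitivity analysis). Patterns come in two dialects:

* ``motif`` — a literal substring over the 20-letter alphabet;
* ``regex`` — a fixed-length token string where each position is a literal,
  a character class ``[XYZ]`` (optionally negated, ``[^XYZ]``) or the
  wildcard ``.``. No quantifiers or anchors: every pattern matches windows
  of exactly its own length, which keeps matching linear-time and makes an
  exhaustive window-scan oracle trivial.

Rule sets are evolved against a labelled peptide library by tournament
selection, uniform rule-exchange crossover, and a small set of structural
and numeric mutations, with elitism guaranteeing a monotone best fitness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from functools import cached_property
from typing import Iterable, Literal

import numpy as np

from .alphabet import AMINO_ACIDS, AA_SET, validate_sequence

PatternKind = Literal["motif", "regex"]

# ---------------------------------------------------------------------------
# Pattern representation


@dataclass(frozen=True)
class Token:
    """One fixed position of a pattern.

    ``kind`` is ``literal`` (single residue), ``class`` (residue set with an
    optional negation) or ``any`` (wildcard, regex dialect only).
    """

    kind: Literal["literal", "class", "any"]
    residues: frozenset[str] = frozenset()
    negated: bool = False

    def __post_init__(self) -> None:
        if self.kind == "literal":
            if len(self.residues) != 1 or not self.residues <= AA_SET:
                raise ValueError("literal token needs exactly one valid residue")
        elif self.kind == "class":
            if not self.residues or not self.residues < AA_SET:
                raise ValueError("class must be a non-empty proper subset of the alphabet")
        elif self.kind != "any":
            raise ValueError(f"unknown token kind {self.kind!r}")

    def matches(self, residue: str) -> bool:
        if self.kind == "any":
            return True
        inside = residue in self.residues
        return (not inside) if (self.kind == "class" and self.negated) else inside

    @property
    def text(self) -> str:
        if self.kind == "any":
            return "."
        if self.kind == "literal":
            return next(iter(self.residues))
        body = "".join(sorted(self.residues))
        return f"[^{body}]" if self.negated else f"[{body}]"


def literal(residue: str) -> Token:
    return Token("literal", frozenset(residue))


@dataclass(frozen=True)
class Pattern:
    """A fixed-length sequence pattern in the motif or restricted-regex dialect."""

    kind: PatternKind
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.tokens) <= 12:
            raise ValueError("pattern length must be in 1..12")
        if self.kind == "motif" and any(t.kind != "literal" for t in self.tokens):
            raise ValueError("motif patterns allow literal tokens only")
        if self.kind not in ("motif", "regex"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.tokens)

    @cached_property
    def text(self) -> str:
        """Canonical text form: literals, ``[XYZ]`` / ``[^XYZ]`` classes, ``.``."""
        return "".join(t.text for t in self.tokens)

    def matches_window(self, window: str) -> bool:
        return all(t.matches(c) for t, c in zip(self.tokens, window))


def motif(text: str) -> Pattern:
    """Build a motif pattern from a literal residue string."""
    return Pattern("motif", tuple(literal(c) for c in validate_sequence(text)))


def parse_pattern(text: str, kind: PatternKind = "regex") -> Pattern:
    """Parse the canonical text form back into a :class:`Pattern`."""
    if kind == "motif":
        return motif(text)
    tokens: list[Token] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == ".":
            tokens.append(Token("any"))
            i += 1
        elif ch == "[":
            j = text.index("]", i)
            body = text[i + 1 : j]
            negated = body.startswith("^")
            if negated:
                body = body[1:]
            tokens.append(Token("class", frozenset(body), negated))
            i = j + 1
        else:
            tokens.append(literal(ch))
            i += 1
    return Pattern("regex", tuple(tokens))


def match_pattern(pattern: Pattern, sequence: str) -> bool:
    """True iff some contiguous window of ``sequence`` satisfies every token.

    Motif patterns reduce to substring search. An empty sequence matches
    nothing (every pattern has length >= 1).
    """
    seq = validate_sequence(sequence)
    if pattern.kind == "motif":
        return pattern.text in seq
    n, m = len(seq), len(pattern)
    return any(pattern.matches_window(seq[i : i + m]) for i in range(n - m + 1))


def count_matches(pattern: Pattern, sequence: str) -> int:
    """Number of windows of ``sequence`` the pattern matches (may overlap)."""
    seq = validate_sequence(sequence)
    m = len(pattern)
    if pattern.kind == "motif":
        return sum(seq.startswith(pattern.text, i) for i in range(len(seq) - m + 1))
    return sum(pattern.matches_window(seq[i : i + m]) for i in range(len(seq) - m + 1))


# ---------------------------------------------------------------------------
# Rule sets and prediction


@dataclass(frozen=True)
class Rule:
    pattern: Pattern
    weight: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.weight):
            raise ValueError("rule weight must be finite")


@dataclass(frozen=True)
class RuleSet:
    """A GP individual: ordered rules plus an intercept (``baseline``).

    The baseline lets the model represent the free-Gd level (r1 ratio 1)
    with no rules at all; every matched rule then shifts the prediction.
    """

    rules: tuple[Rule, ...]
    baseline: float
    kind: PatternKind = "motif"

    def __post_init__(self) -> None:
        if any(r.pattern.kind != self.kind for r in self.rules):
            raise ValueError("all rules in a set must share the set's kind")
        if not math.isfinite(self.baseline):
            raise ValueError("baseline must be finite")

    def __len__(self) -> int:
        return len(self.rules)


ScoringMode = Literal["presence", "count"]


def predict_score(
    model: RuleSet, sequence: str, mode: ScoringMode = "presence"
) -> float:
    """Predicted r1 ratio: baseline + sum of weights of matching rules.

    In ``presence`` mode each rule contributes its weight at most once; in
    ``count`` mode the weight is multiplied by the number of matching
    windows. Invariant under rule reordering.
    """
    seq = validate_sequence(sequence)
    total = model.baseline
    for rule in model.rules:
        if mode == "count":
            total += rule.weight * count_matches(rule.pattern, seq)
        elif match_pattern(rule.pattern, seq):
            total += rule.weight
    return total


def ruleset_to_dict(model: RuleSet) -> dict:
    return {
        "schema": "gdpoet-model/1",
        "kind": model.kind,
        "baseline": model.baseline,
        "rules": [{"pattern": r.pattern.text, "weight": r.weight} for r in model.rules],
    }


def ruleset_from_dict(payload: dict) -> RuleSet:
    kind = payload["kind"]
    rules = tuple(
        Rule(parse_pattern(r["pattern"], kind), float(r["weight"]))
        for r in payload["rules"]
    )
    return RuleSet(rules, float(payload["baseline"]), kind)


def save_ruleset(model: RuleSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(ruleset_to_dict(model), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_ruleset(path) -> RuleSet:
    with open(path, encoding="utf-8") as fh:
        return ruleset_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Training data and fitness


@dataclass(frozen=True)
class TrainingSet:
    """Labelled 12-mer library: sequences with measured r1 ratios."""

    sequences: tuple[str, ...]
    labels: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError("sequences and labels differ in length")
        object.__setattr__(
            self, "sequences", tuple(validate_sequence(s) for s in self.sequences)
        )
        for y in self.labels:
            if not (math.isfinite(y) and y > 0):
                raise ValueError(f"labels must be finite and positive, got {y}")

    def __len__(self) -> int:
        return len(self.sequences)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, float]]) -> "TrainingSet":
        seqs, labels = zip(*records)
        return cls(tuple(seqs), tuple(float(y) for y in labels))

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=float)


@dataclass(frozen=True)
class EvolutionConfig:
    """Knobs of the GP run. None of these are dictated by the science; all
    defaults are exposed and recorded with every run."""

    population_size: int = 200
    generations: int = 500
    tournament_size: int = 4
    crossover_rate: float = 0.9
    rule_mutation_rate: float = 0.3
    weight_mutation_sigma: float = 0.1
    max_rules: int = 20
    parsimony_penalty: float = 0.001
    elitism_count: int = 1
    rng_seed: int = 0
    scoring_mode: ScoringMode = "presence"

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.tournament_size > self.population_size:
            raise ValueError("tournament_size cannot exceed population_size")
        for name in ("crossover_rate", "rule_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.elitism_count < 1:
            raise ValueError("elitism_count must be >= 1")
        if self.max_rules < 1:
            raise ValueError("max_rules must be >= 1")


@dataclass(frozen=True)
class FitnessReport:
    rmse: float
    penalized_fitness: float
    per_record_residuals: np.ndarray


class _Evaluator:
    """Caches per-pattern match vectors over a fixed training set so that
    re-scoring a population costs one small matrix sum per individual."""

    def __init__(self, data: TrainingSet, config: EvolutionConfig):
        if len(data) == 0:
            raise ValueError("training set must be non-empty")
        self.data = data
        self.config = config
        self.labels = data.label_array()
        self._cache: dict[tuple[str, str], np.ndarray] = {}

    def _vector(self, pattern: Pattern) -> np.ndarray:
        key = (pattern.kind, pattern.text)
        vec = self._cache.get(key)
        if vec is None:
            if self.config.scoring_mode == "count":
                vec = np.array(
                    [count_matches(pattern, s) for s in self.data.sequences],
                    dtype=float,
                )
            else:
                vec = np.array(
                    [match_pattern(pattern, s) for s in self.data.sequences],
                    dtype=float,
                )
            self._cache[key] = vec
        return vec

    def predictions(self, model: RuleSet) -> np.ndarray:
        pred = np.full(len(self.data), model.baseline)
        for rule in model.rules:
            pred += rule.weight * self._vector(rule.pattern)
        return pred

    def report(self, model: RuleSet) -> FitnessReport:
        residuals = self.predictions(model) - self.labels
        rmse = float(np.sqrt(np.mean(residuals**2)))
        penalized = rmse + self.config.parsimony_penalty * len(model)
        return FitnessReport(rmse, penalized, residuals)


def fitness(model: RuleSet, data: TrainingSet, config: EvolutionConfig) -> FitnessReport:
    """RMSE of predicted vs measured r1 ratio, plus a per-rule parsimony
    penalty (penalized = rmse + penalty * n_rules). Lower is better."""
    return _Evaluator(data, config).report(model)


# ---------------------------------------------------------------------------
# Variation operators

_INIT_LENGTHS = (2, 3, 4, 5, 6)


def _random_token(rng: np.random.Generator, kind: PatternKind) -> Token:
    if kind == "motif":
        return literal(AMINO_ACIDS[rng.integers(20)])
    u = rng.random()
    if u < 0.60:
        return literal(AMINO_ACIDS[rng.integers(20)])
    if u < 0.85:
        size = int(rng.integers(2, 5))
        members = frozenset(rng.choice(list(AMINO_ACIDS), size=size, replace=False))
        return Token("class", members, negated=bool(rng.random() < 0.2))
    return Token("any")


def _random_pattern(rng: np.random.Generator, kind: PatternKind) -> Pattern:
    length = int(rng.choice(_INIT_LENGTHS))
    return Pattern(kind, tuple(_random_token(rng, kind) for _ in range(length)))


def _random_rule(rng: np.random.Generator, kind: PatternKind) -> Rule:
    return Rule(_random_pattern(rng, kind), float(rng.normal(0.0, 1.0)))


def init_population(
    config: EvolutionConfig,
    rng: np.random.Generator,
    kind: PatternKind = "motif",
    baseline: float = 1.0,
) -> list[RuleSet]:
    """Random rule sets: 1..max_rules rules each, weights ~ Normal(0, 1),
    baseline typically the training-label mean."""
    population = []
    for _ in range(config.population_size):
        n_rules = int(rng.integers(1, config.max_rules + 1))
        rules = tuple(_random_rule(rng, kind) for _ in range(n_rules))
        population.append(RuleSet(rules, baseline, kind))
    return population


def _truncate(rules: tuple[Rule, ...], max_rules: int) -> tuple[Rule, ...]:
    if len(rules) <= max_rules:
        return rules
    # drop lowest-|weight| rules, preserving original order of the survivors
    order = sorted(range(len(rules)), key=lambda i: (-abs(rules[i].weight), i))
    keep = sorted(order[:max_rules])
    return tuple(rules[i] for i in keep)


def mutate(model: RuleSet, config: EvolutionConfig, rng: np.random.Generator) -> RuleSet:
    """Apply each mutation operator independently with probability
    ``rule_mutation_rate``; operators that would break an invariant are
    skipped. The input model is never modified."""
    rate = config.rule_mutation_rate
    rules = list(model.rules)
    base = model.baseline

    if rng.random() < rate and len(rules) < config.max_rules:  # add rule
        rules.insert(int(rng.integers(len(rules) + 1)), _random_rule(rng, model.kind))
    if rng.random() < rate and rules:  # delete rule
        rules.pop(int(rng.integers(len(rules))))
    if rng.random() < rate and config.weight_mutation_sigma > 0:
        # perturb one weight; the baseline competes with the rule weights
        idx = int(rng.integers(len(rules) + 1))
        delta = float(rng.normal(0.0, config.weight_mutation_sigma))
        if idx == len(rules):
            base += delta
        else:
            rules[idx] = replace(rules[idx], weight=rules[idx].weight + delta)
    if rng.random() < rate and rules:  # substitute one pattern token
        idx = int(rng.integers(len(rules)))
        pat = rules[idx].pattern
        pos = int(rng.integers(len(pat)))
        tokens = list(pat.tokens)
        tokens[pos] = _random_token(rng, model.kind)
        rules[idx] = replace(rules[idx], pattern=Pattern(model.kind, tuple(tokens)))
    if rng.random() < rate and rules:  # grow or shrink one pattern by one token
        idx = int(rng.integers(len(rules)))
        pat = rules[idx].pattern
        tokens = list(pat.tokens)
        grow = rng.random() < 0.5
        if grow and len(tokens) < 12:
            at_end = rng.random() < 0.5
            tok = _random_token(rng, model.kind)
            tokens.append(tok) if at_end else tokens.insert(0, tok)
        elif not grow and len(tokens) > 1:
            tokens.pop(-1 if rng.random() < 0.5 else 0)
        rules[idx] = replace(rules[idx], pattern=Pattern(model.kind, tuple(tokens)))

    return RuleSet(tuple(rules), base, model.kind)


def crossover(
    a: RuleSet,
    b: RuleSet,
    rng: np.random.Generator,
    max_rules: int | None = None,
) -> tuple[RuleSet, RuleSet]:
    """Uniform rule exchange: each parent rule goes to exactly one child, so
    the total rule count is conserved (children beyond ``max_rules`` drop
    their lowest-|weight| rules). Baselines are inherited one per child."""
    if a.kind != b.kind:
        raise ValueError(f"cannot cross {a.kind} with {b.kind} rule sets")
    pool = list(a.rules) + list(b.rules)
    to_first = rng.random(len(pool)) < 0.5
    c1 = tuple(r for r, f in zip(pool, to_first) if f)
    c2 = tuple(r for r, f in zip(pool, to_first) if not f)
    if max_rules is not None:
        c1, c2 = _truncate(c1, max_rules), _truncate(c2, max_rules)
    return RuleSet(c1, a.baseline, a.kind), RuleSet(c2, b.baseline, b.kind)


# ---------------------------------------------------------------------------
# Evolution loop


def _rank_key(item: tuple[int, RuleSet, FitnessReport]):
    idx, model, rep = item
    # ties: fewer rules first, then stable (earlier-created) index
    return (rep.penalized_fitness, len(model), idx)


def evolve(
    data: TrainingSet,
    config: EvolutionConfig,
    kind: PatternKind = "motif",
) -> tuple[RuleSet, list[float]]:
    """Run the GP and return the all-time best rule set plus the history of
    best penalized fitness per generation (length ``generations + 1``;
    non-increasing thanks to elitism). Fully reproducible from
    ``config.rng_seed``."""
    if len(data) == 0:
        raise ValueError("training set must be non-empty")
    rng = np.random.default_rng(config.rng_seed)
    evaluator = _Evaluator(data, config)
    baseline0 = float(np.mean(data.label_array()))

    population = init_population(config, rng, kind, baseline=baseline0)
    scored = [(i, m, evaluator.report(m)) for i, m in enumerate(population)]
    best = min(scored, key=_rank_key)
    history = [best[2].penalized_fitness]

    def tournament() -> RuleSet:
        picks = rng.integers(len(scored), size=config.tournament_size)
        return min((scored[i] for i in picks), key=_rank_key)[1]

    counter = len(scored)
    for _ in range(config.generations):
        elites = sorted(scored, key=_rank_key)[: config.elitism_count]
        next_pop: list[RuleSet] = [e[1] for e in elites]
        while len(next_pop) < config.population_size:
            p1, p2 = tournament(), tournament()
            if rng.random() < config.crossover_rate:
                c1, c2 = crossover(p1, p2, rng, config.max_rules)
            else:
                c1, c2 = p1, p2
            next_pop.append(mutate(c1, config, rng))
            if len(next_pop) < config.population_size:
                next_pop.append(mutate(c2, config, rng))
        scored = []
        for m in next_pop:
            scored.append((counter, m, evaluator.report(m)))
            counter += 1
        gen_best = min(scored, key=_rank_key)
        if _rank_key((best[0], best[1], best[2]))[:1] > _rank_key(gen_best)[:1]:
            best = gen_best
        history.append(best[2].penalized_fitness)

    return best[1], history
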