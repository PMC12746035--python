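"""Propose diverse high-scoring 12-mer candidates from a trained rule set.

One "epoch" of the evolve -> synthesize -> measure loop needs a small panel
of peptides that (a) the model scores highly and (b) differ enough from each
other and from the already-measured library to be informative. The sequence
space (20^12) rules out exhaustion, so candidates come from multi-restart
hill climbing over single-residue substitutions, followed by a greedy
maximal diverse subset under Hamming-distance constraints.

Presence-based scoring is piecewise constant: a rule contributes nothing
until its full pattern is present, so a strict-ascent climber stalls on wide
plateaus. Two standard remedies are used: sideways (equal-score) moves are
accepted, and half of the restarts are seeded by implanting the realization
of one positive-weight rule at a random window before climbing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alphabet import AMINO_ACIDS, PEPTIDE_LENGTH, validate_sequence
from .poet_engine import Pattern, RuleSet, TrainingSet, predict_score
from .records import PeptideRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignConfig:
    candidates_per_epoch: int = 10
    min_pairwise_distance: int = 3
    min_distance_to_training: int = 3
    search_restarts: int = 50
    search_steps: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.candidates_per_epoch < 0:
            raise ValueError("candidates_per_epoch must be >= 0")
        for name in ("min_pairwise_distance", "min_distance_to_training"):
            v = getattr(self, name)
            if not 0 <= v <= PEPTIDE_LENGTH:
                raise ValueError(f"{name} must be in 0..{PEPTIDE_LENGTH}")


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def _realize(pattern: Pattern, rng: np.random.Generator) -> str:
    """A concrete residue string satisfying every token of ``pattern``."""
    out = []
    for tok in pattern.tokens:
        if tok.kind == "literal":
            out.append(next(iter(tok.residues)))
        else:
            if tok.kind == "any":
                choices = AMINO_ACIDS
            elif tok.negated:
                choices = "".join(sorted(set(AMINO_ACIDS) - tok.residues))
            else:
                choices = "".join(sorted(tok.residues))
            out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _random_peptide(rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=PEPTIDE_LENGTH))


def _climb(
    model: RuleSet, start: str, steps: int, rng: np.random.Generator
) -> tuple[str, float]:
    seq = list(start)
    score = predict_score(model, start)
    for _ in range(steps):
        pos = int(rng.integers(PEPTIDE_LENGTH))
        old = seq[pos]
        new = AMINO_ACIDS[rng.integers(20)]
        if new == old:
            continue
        seq[pos] = new
        candidate = "".join(seq)
        cand_score = predict_score(model, candidate)
        if cand_score >= score:  # accept improvements and sideways moves
            score = cand_score
        else:
            seq[pos] = old
    return "".join(seq), score


def design_epoch(
    model: RuleSet,
    training: TrainingSet | None,
    config: DesignConfig,
    epoch: int = 1,
) -> list[PeptideRecord]:
    """One epoch of candidate proposals, sorted by descending predicted score.

    Every returned candidate is at Hamming distance >= ``min_pairwise_distance``
    from the other candidates and >= ``min_distance_to_training`` from every
    training sequence. Candidates failing diversity are skipped in score
    order (greedy maximal set); if the constraints are infeasible, the
    feasible subset is returned with a warning rather than padded.
    """
    rng = np.random.default_rng(config.rng_seed)
    if config.candidates_per_epoch == 0:
        return []

    positive = [r for r in model.rules if r.weight > 0]
    finals: dict[str, float] = {}
    for restart in range(config.search_restarts):
        start = _random_peptide(rng)
        if positive and restart % 2 == 0:
            rule = positive[int(rng.integers(len(positive)))]
            core = _realize(rule.pattern, rng)
            if len(core) <= PEPTIDE_LENGTH:
                at = int(rng.integers(PEPTIDE_LENGTH - len(core) + 1))
                start = start[:at] + core + start[at + len(core) :]
        seq, score = _climb(model, start, config.search_steps, rng)
        if seq not in finals or score > finals[seq]:
            finals[seq] = score

    ranked = sorted(finals.items(), key=lambda kv: (-kv[1], kv[0]))
    train_seqs = list(training.sequences) if training is not None else []
    chosen: list[tuple[str, float]] = []
    for seq, score in ranked:
        if len(chosen) == config.candidates_per_epoch:
            break
        if any(hamming(seq, t) < config.min_distance_to_training for t in train_seqs):
            continue
        if any(hamming(seq, c) < config.min_pairwise_distance for c, _ in chosen):
            continue
        chosen.append((seq, score))

    if len(chosen) < config.candidates_per_epoch:
        logger.warning(
            "diversity constraints left %d of %d requested candidates",
            len(chosen),
            config.candidates_per_epoch,
        )
    if training is not None and chosen:
        train_best = max(predict_score(model, s) for s in training.sequences)
        if chosen[0][1] < train_best:
            logger.warning(
                "local search saturated below the best training score "
                "(%.4f < %.4f)", chosen[0][1], train_best,
            )

    return [
        PeptideRecord(
            sequence=validate_sequence(seq),
            source=f"designed-epoch{epoch}",
            predicted_score=score,
            engine=model.kind,
            epoch=epoch,
        )
        for seq, score in chosen
    ]
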