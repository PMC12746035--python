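"""Synthetic inputs with the statistical structure the pipeline assumes.

Real screening data for this problem is a 74-peptide 12-mer library with
near-uniform residue usage and r1-ratio labels spanning roughly 0.9-2.3,
plus variable-TR dilution-series MRI curves per sample. Both are emulated
here from known ground truth so every pipeline stage can be tested
end-to-end without measurements: a planted rule set generates labels
(optionally with Gaussian noise), and the relaxivity forward model
generates signal curves from a planted r1.

Carrier peptides are created by implanting a planted rule's pattern at a
random window (overwriting), not by rejection sampling — this guarantees
the carrier fraction even at small library sizes. Every generator is
reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS, PEPTIDE_LENGTH
from .peptide_designer import _realize
from .poet_engine import RuleSet, Rule, TrainingSet, motif, predict_score
from .relaxometry import DEFAULT_TR_GRID_MS, DilutionSeries, SignalCurve
from .screen_analysis import ScreenTable, load_screen_fixture


def default_planted_model() -> RuleSet:
    """The default ground truth: baseline 1.0 (free-Gd level) plus a single
    acidic motif "DDD" worth +0.8, placing carriers near the top of the
    observed screening range (~1.8)."""
    return RuleSet((Rule(motif("DDD"), 0.8),), baseline=1.0, kind="motif")


@dataclass(frozen=True)
class GroundTruth:
    """Generative description of a synthetic screening library."""

    planted_model: RuleSet = field(default_factory=default_planted_model)
    noise_sd: float = 0.0
    library_size: int = 74
    motif_carrier_fraction: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.motif_carrier_fraction <= 1.0:
            raise ValueError("motif_carrier_fraction must be in [0, 1]")
        if self.library_size < 1:
            raise ValueError("library_size must be >= 1")
        for rule in self.planted_model.rules:
            if len(rule.pattern) > PEPTIDE_LENGTH:
                raise ValueError("planted pattern longer than the peptide length")


def simulate_library(truth: GroundTruth) -> TrainingSet:
    """Random 12-mer library labelled by the planted model.

    A ``motif_carrier_fraction`` subset has one planted rule's pattern
    implanted at a random window; residue usage is otherwise uniform.
    Labels are planted predictions plus Normal(0, noise_sd), floored just
    above zero to stay valid r1 ratios.
    """
    rng = np.random.default_rng(truth.rng_seed)
    n = truth.library_size
    seqs = [
        "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=PEPTIDE_LENGTH))
        for _ in range(n)
    ]
    n_carriers = int(round(truth.motif_carrier_fraction * n))
    carriers = rng.choice(n, size=n_carriers, replace=False)
    rules = truth.planted_model.rules
    for idx in carriers:
        rule = rules[int(rng.integers(len(rules)))] if rules else None
        if rule is None:
            break
        core = _realize(rule.pattern, rng)
        at = int(rng.integers(PEPTIDE_LENGTH - len(core) + 1))
        s = seqs[idx]
        seqs[idx] = s[:at] + core + s[at + len(core):]
    labels = []
    for s in seqs:
        y = predict_score(truth.planted_model, s)
        if truth.noise_sd > 0:
            y += float(rng.normal(0.0, truth.noise_sd))
        labels.append(max(y, 1e-6))
    return TrainingSet(tuple(seqs), tuple(labels))


def simulate_dilution(
    r1_true: float,
    t1_zero_ms: float,
    concentrations_mM: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2),
    noise_fraction: float = 0.0,
    rng_seed: int = 0,
    amplitude: float = 1000.0,
    sample_id: str = "synthetic",
    is_reference: bool = False,
) -> DilutionSeries:
    """Forward-model a dilution series as variable-TR signal curves.

    Per concentration c, T1 = 1 / (1/T1_0 + r1 * c); signals follow
    A * (1 - exp(-TR/T1)) on the default 9-TR grid plus Gaussian noise of
    sd ``noise_fraction * A``. At zero noise the full fit_t1 -> fit_r1
    pipeline recovers ``r1_true`` exactly (round-trip identity).
    """
    if r1_true < 0:
        raise ValueError("r1_true must be >= 0")
    if t1_zero_ms <= 0:
        raise ValueError("t1_zero_ms must be positive")
    rng = np.random.default_rng(rng_seed)
    trs = np.asarray(DEFAULT_TR_GRID_MS)
    points = []
    for i, c in enumerate(concentrations_mM):
        rate = 1.0 / (t1_zero_ms / 1000.0) + r1_true * c  # s^-1
        if rate <= 0:
            raise ValueError("parameters imply nonpositive T1")
        t1_ms = 1000.0 / rate
        clean = amplitude * (1.0 - np.exp(-trs / t1_ms))
        noisy = clean + noise_fraction * amplitude * rng.standard_normal(len(trs))
        curve = SignalCurve(
            tuple(trs), tuple(np.clip(noisy, 0.0, None)), well_id=f"{sample_id}-{i}"
        )
        points.append((float(c), curve))
    return DilutionSeries(tuple(points), sample_id=sample_id, is_reference=is_reference)


def make_screen_fixture() -> ScreenTable:
    """The packaged eleven-row screening table (measured, not simulated)."""
    return load_screen_fixture()
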