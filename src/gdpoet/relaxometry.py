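"""Longitudinal relaxivity from variable-repetition-time MRI data.

A variable-TR saturation-recovery acquisition samples the ideal signal curve

    S(TR) = A * (1 - exp(-TR / T1))

at a fixed TR grid (defaults to the nine repetition times of a preclinical
7 T protocol). Fitting each well's curve yields its T1; regressing the
relaxation rate 1/T1 (s^-1) on contrast-agent concentration [CA] (mM),

    1/T1 = 1/T1_0 + r1 * [CA],

gives the longitudinal relaxivity r1 (mM^-1 s^-1) as the slope and the
buffer rate 1/T1_0 as the intercept. The high-throughput screening metric is
the dimensionless r1 ratio: a sample's slope divided by the slope of a
peptide-free GdCl3 series measured under matched conditions (ratio 1 means
the peptide does not change Gd's relaxivity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

#: Repetition times (ms) of the default variable-TR protocol.
DEFAULT_TR_GRID_MS: tuple[float, ...] = (
    33.0, 122.0, 297.0, 497.0, 727.0, 1577.0, 2777.0, 4809.0, 12496.0,
)


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float = math.nan):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class SignalCurve:
    """Signal vs repetition time for one well (arbitrary units vs ms)."""

    tr_values: tuple[float, ...]
    signals: tuple[float, ...]
    well_id: str = ""

    def __post_init__(self) -> None:
        if len(self.tr_values) != len(self.signals):
            raise ValueError("tr_values and signals differ in length")
        if len(self.tr_values) < 3:
            raise ValueError("need at least 3 TR points to fit T1")
        trs = np.asarray(self.tr_values, dtype=float)
        if np.any(trs <= 0) or len(set(self.tr_values)) != len(self.tr_values):
            raise ValueError("TRs must be strictly positive and distinct")


@dataclass(frozen=True)
class DilutionSeries:
    """Per-concentration T1 (ms) or raw signal curves for one sample.

    ``points`` maps concentration (mM Gd) to either a fitted T1 in ms or a
    :class:`SignalCurve` still to be fitted. A valid series spans at least
    three distinct concentrations and includes a near-zero blank.
    """

    points: tuple[tuple[float, object], ...]
    sample_id: str = ""
    is_reference: bool = False

    def __post_init__(self) -> None:
        concs = [c for c, _ in self.points]
        if any(c < 0 for c in concs):
            raise ValueError("concentrations must be >= 0")
        distinct = sorted(set(concs))
        if len(distinct) < 3:
            raise ValueError("need >= 3 distinct concentrations")
        if distinct[0] > 0.05 * distinct[-1] + 1e-12:
            raise ValueError("series must include a near-zero blank dilution")


@dataclass(frozen=True)
class RelaxivityResult:
    r1: float                 # mM^-1 s^-1 (slope)
    intercept: float          # s^-1, estimates 1/T1_0
    r_squared: float
    slope_stderr: float
    n_points: int
    sample_id: str = ""


def _t1_initial_guess(trs: np.ndarray, sig: np.ndarray) -> float:
    """TR at which the signal first reaches (1 - 1/e) of its maximum,
    located by linear interpolation — the exact answer for a noiseless
    saturation-recovery curve."""
    target = (1.0 - math.exp(-1.0)) * float(np.max(sig))
    order = np.argsort(trs)
    trs, sig = trs[order], sig[order]
    above = np.nonzero(sig >= target)[0]
    if len(above) == 0:
        return float(trs[-1])
    i = above[0]
    if i == 0:
        return float(trs[0])
    t0, t1 = trs[i - 1], trs[i]
    s0, s1 = sig[i - 1], sig[i]
    if s1 == s0:
        return float(t1)
    return float(t0 + (target - s0) * (t1 - t0) / (s1 - s0))


def fit_t1(
    curve: SignalCurve, with_offset: bool = False
) -> tuple[float, float, float]:
    """Fit S(TR) = A (1 - exp(-TR/T1)) and return (t1_ms, amplitude, residual).

    ``with_offset`` adds a constant third parameter for noisy baselines.
    Raises :class:`FitError` on non-convergence and ValueError for
    degenerate (flat) curves whose T1 is below the smallest TR.
    """
    trs = np.asarray(curve.tr_values, dtype=float)
    sig = np.asarray(curve.signals, dtype=float)
    if np.any(sig < 0):
        raise ValueError("signals must be non-negative")

    t1_0 = max(_t1_initial_guess(trs, sig), 1e-3)
    a_0 = float(np.max(sig)) or 1.0

    if with_offset:
        def model(tr, a, t1, c):
            return a * (1.0 - np.exp(-tr / t1)) + c
        p0, bounds = (a_0, t1_0, 0.0), ([0, 1e-6, -np.inf], [np.inf, np.inf, np.inf])
    else:
        def model(tr, a, t1):
            return a * (1.0 - np.exp(-tr / t1))
        p0, bounds = (a_0, t1_0), ([0, 1e-6], [np.inf, np.inf])

    try:
        popt, _ = optimize.curve_fit(
            model, trs, sig, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"T1 fit did not converge for well {curve.well_id!r}: {exc}")
    residual = float(np.sqrt(np.mean((model(trs, *popt) - sig) ** 2)))
    amplitude, t1 = float(popt[0]), float(popt[1])
    if t1 <= float(np.min(trs)) / 10.0:
        raise FitError(
            f"degenerate fit for well {curve.well_id!r}: "
            f"T1={t1:.3g} ms is far below the smallest TR", residual,
        )
    return t1, amplitude, residual


def series_t1_values(series: DilutionSeries) -> list[tuple[float, float]]:
    """(concentration mM, T1 ms) pairs, fitting signal curves where needed."""
    out = []
    for conc, payload in series.points:
        if isinstance(payload, SignalCurve):
            t1, _, _ = fit_t1(payload)
        else:
            t1 = float(payload)
        if t1 <= 0:
            raise ValueError(f"nonpositive T1 ({t1}) at {conc} mM")
        out.append((conc, t1))
    return out


def fit_r1(series: DilutionSeries) -> RelaxivityResult:
    """Ordinary least squares of 1/T1 (s^-1) on concentration (mM).

    T1 values are converted from ms to s before inversion; the blank well
    enters the regression like any other point (the intercept estimates
    1/T1_0 rather than being pinned to the blank).
    """
    pairs = series_t1_values(series)
    concs = np.array([c for c, _ in pairs], dtype=float)
    rates = 1.0 / (np.array([t for _, t in pairs], dtype=float) / 1000.0)
    if np.ptp(concs) == 0:
        raise ValueError("zero concentration variance: cannot regress")
    res = stats.linregress(concs, rates)
    return RelaxivityResult(
        r1=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_stderr=float(res.stderr),
        n_points=len(pairs),
        sample_id=series.sample_id,
    )


def r1_ratio(sample: RelaxivityResult, reference: RelaxivityResult) -> float:
    """Sample r1 divided by the peptide-free reference r1 (dimensionless)."""
    if reference.r1 <= 0:
        raise ValueError(f"reference slope must be positive, got {reference.r1}")
    return sample.r1 / reference.r1


def rate_enhancement_ratio(
    sample_t1_ms: float,
    reference_t1_ms: float,
    blank_t1_ms: float,
) -> float:
    """Single-concentration screening alternative: ratio of rate enhancements
    (1/T1 - 1/T1_0) of sample vs reference at one matched concentration."""
    for name, v in (("sample", sample_t1_ms), ("reference", reference_t1_ms),
                    ("blank", blank_t1_ms)):
        if v <= 0:
            raise ValueError(f"nonpositive {name} T1")
    blank_rate = 1000.0 / blank_t1_ms
    ref = 1000.0 / reference_t1_ms - blank_rate
    if ref <= 0:
        raise ValueError("reference rate enhancement must be positive")
    return (1000.0 / sample_t1_ms - blank_rate) / ref


def plate_layout(
    sample_ids: list[str], n_dilutions: int = 7
) -> dict[str, tuple[str, int]]:
    """Map well labels of a 7-column x 5-row plate region to
    (sample_id, dilution index): one sample per row, dilutions along the
    phase-axis columns (dilution 0 = most concentrated)."""
    if len(sample_ids) > 5:
        raise ValueError("at most 5 sample rows fit in the homogeneous region")
    if not 1 <= n_dilutions <= 7:
        raise ValueError("n_dilutions must be in 1..7")
    rows = "ABCDE"
    return {
        f"{rows[r]}{c + 1}": (sid, c)
        for r, sid in enumerate(sample_ids)
        for c in range(n_dilutions)
    }
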