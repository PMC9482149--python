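"""Synthetic behavioural observers for pipeline testing.

No behavioural trial data are deposited for this system, so the package
carries a generative stand-in with the statistical structure the
analysis assumes: per-individual Bernoulli responses following a
log-normal psychometric function of stimulus level (with guess and
lapse rates), ordered ethogram event sequences whose severity escalates
with the stimulus' angular size, and re-emergence times that increase
with stimulus magnitude.  Every downstream stage — responder tables,
Wilson intervals, Fisher exact thresholds, correlations — can then be
exercised and its parameter-recovery behaviour measured.

The psychometric core is

    P(respond | level) = g + (1 - g - lam) * Phi((ln level - ln theta) / sigma)

with guess rate ``g`` (the control responds at this base rate), lapse
rate ``lam`` and threshold ``theta`` in stimulus-level units (Michelson
contrast or check width in degrees).  Between-individual variation
enters as a log-normal spread of individual thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .exceptions import ValidationError
from .geometry import ExpansionProfile
from .inference import determine_threshold
from .stimuli import CONTRAST_SERIES_BYTES, DisplayModel, michelson_contrast
from .trials import (
    Behavior,
    TransitionEvent,
    TrialRecord,
    build_response_table,
)

__all__ = [
    "ObserverParams",
    "SimulationDesign",
    "RecoveryReport",
    "psychometric_p",
    "simulate_trials",
    "recover_threshold",
    "RESOLUTION_CHECK_WIDTHS_DEG",
    "contrast_design",
    "resolution_design",
]

#: Check-width series (deg) of the resolution experiment.  The published
#: series spans 0.3-3.2 deg with eight members, of which only the range
#: endpoints and the 0.53 deg member are printed; the intermediate
#: values here are a fixed synthetic convention.
RESOLUTION_CHECK_WIDTHS_DEG: tuple[float, ...] = (0.3, 0.4, 0.53, 0.8, 1.1, 1.6, 2.2, 3.2)


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the synthetic observer population.

    ``threshold`` and ``slope`` act on the natural-log level scale.
    ``reemergence_base_s`` / ``reemergence_gain_s`` place re-emergence
    times at ``base + gain * ln(level / threshold)`` plus Gaussian noise
    for responding trials.  ``individual_sd`` is the SD of ln(threshold)
    across individuals.  ``stop_only_rate`` is the probability that a
    non-responding trial still shows a stop-feeding-only record (the
    event pattern the scoring rule excludes).
    """

    threshold: float = 0.45
    slope: float = 0.3
    guess_rate: float = 0.02
    lapse_rate: float = 0.02
    reemergence_base_s: float = 60.0
    reemergence_gain_s: float = 25.0
    reemergence_noise_sd_s: float = 10.0
    individual_sd: float = 0.15
    stop_only_rate: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold <= 0 or self.slope <= 0:
            raise ValidationError("threshold and slope must be > 0")
        if not (0 <= self.guess_rate <= 0.1 and 0 <= self.lapse_rate <= 0.1):
            raise ValidationError("guess and lapse rates must lie in [0, 0.1]")
        if self.guess_rate + self.lapse_rate >= 1:
            raise ValidationError("guess_rate + lapse_rate must be < 1")
        if min(self.reemergence_noise_sd_s, self.individual_sd) < 0:
            raise ValidationError("noise SDs must be >= 0")
        if not 0 <= self.stop_only_rate <= 1:
            raise ValidationError("stop_only_rate must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationDesign:
    """Level series and sampling plan of one simulated experiment."""

    experiment: str  # "contrast" | "resolution"
    levels: tuple[float, ...]
    n_individuals: int
    repeats: int = 2
    include_control: bool = True
    profile: ExpansionProfile = field(
        default_factory=lambda: ExpansionProfile(shape="linear", duration_s=5.0, alpha_max_deg=83.0)
    )

    def __post_init__(self) -> None:
        if self.experiment not in ("contrast", "resolution"):
            raise ValidationError(f"unknown experiment {self.experiment!r}")
        lv = tuple(float(v) for v in self.levels)
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValidationError("levels must be strictly increasing")
        if any(v <= 0 for v in lv):
            raise ValidationError("levels must be > 0")
        if self.n_individuals < 1 or self.repeats < 1:
            raise ValidationError("need n_individuals >= 1 and repeats >= 1")
        object.__setattr__(self, "levels", lv)


def contrast_design(n_individuals: int = 20, repeats: int = 2) -> SimulationDesign:
    """The contrast-sensitivity design: nine Michelson contrasts from the
    published byte series against background byte 255, plus a zero-
    contrast control, 20 individuals tested twice."""
    display = DisplayModel(gamma=1.0)
    levels = sorted(michelson_contrast(b, 255, display) for b in CONTRAST_SERIES_BYTES)
    return SimulationDesign(
        experiment="contrast",
        levels=tuple(levels),
        n_individuals=n_individuals,
        repeats=repeats,
        profile=ExpansionProfile(
            shape="exponential", duration_s=10.0, alpha_max_deg=83.0, alpha_start_deg=0.3
        ),
    )


def resolution_design(n_individuals: int = 19, repeats: int = 2) -> SimulationDesign:
    """The spatial-resolution design: eight check widths between 0.3 and
    3.2 deg plus an isoluminant control, 19 individuals tested twice."""
    return SimulationDesign(
        experiment="resolution",
        levels=RESOLUTION_CHECK_WIDTHS_DEG,
        n_individuals=n_individuals,
        repeats=repeats,
        profile=ExpansionProfile(shape="linear", duration_s=5.0, alpha_max_deg=83.0),
    )


def psychometric_p(level: float | None, params: ObserverParams, threshold: float | None = None) -> float:
    """Response probability at a stimulus level (control: ``level`` None
    or 0 maps to the guess rate)."""
    theta = params.threshold if threshold is None else threshold
    if level is None or level <= 0:
        return params.guess_rate
    z = (math.log(level) - math.log(theta)) / params.slope
    return params.guess_rate + (1.0 - params.guess_rate - params.lapse_rate) * float(norm.cdf(z))


# Ethogram escalation used for synthetic event sequences: stop feeding
# always first, then progressively severe withdrawals at larger angular
# sizes.  The exact timing distribution is a synthetic convention.
_ESCALATION = (
    Behavior.STOP_FEEDING,
    Behavior.PARTIAL_PROBOSCIS_WITHDRAWAL,
    Behavior.FULL_PROBOSCIS_WITHDRAWAL,
    Behavior.PARTIAL_EYESTALK_WITHDRAWAL,
    Behavior.FULL_EYESTALK_WITHDRAWAL,
)


def _event_sequence(rng: np.random.Generator, profile: ExpansionProfile) -> list[TransitionEvent]:
    """Ordered escalation for a responding trial.

    The number of transitions (2-5) is drawn at random; their angular
    positions are sorted draws from the upper part of the expansion, so
    severe events land at large angular sizes (full withdrawals late),
    matching the qualitative escalation structure of real withdrawal
    sequences.
    """
    n_events = int(rng.integers(2, len(_ESCALATION) + 1))
    lo = profile.alpha_max_deg * 0.03
    hi = profile.alpha_max_deg * 0.98
    # Bias angles toward the rapid-expansion end with a sqrt transform.
    u = np.sort(rng.uniform(0.0, 1.0, size=n_events))
    angles = lo + (hi - lo) * np.sqrt(u)
    return [
        TransitionEvent(cat, profile.time_to_reach(float(a)))
        for cat, a in zip(_ESCALATION[:n_events], angles)
    ]


def simulate_trials(
    design: SimulationDesign,
    params: ObserverParams,
    seed: int | None = None,
) -> list[TrialRecord]:
    """Simulate a full trial table for one experiment.

    Reproducible from the seed (``params.seed`` unless overridden): a
    single root seed sequence spawns one deterministic substream per
    individual, so per-individual draws are independent of simulation
    order.  Responding trials carry an escalating event sequence and a
    re-emergence time; non-responding trials are eventless or (with
    probability ``stop_only_rate``) stop-feeding-only.
    """
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    streams = root.spawn(design.n_individuals)
    trials: list[TrialRecord] = []
    conditions: list[tuple[str, float, bool]] = [
        (f"{design.experiment}-L{i:02d}", lv, False) for i, lv in enumerate(design.levels)
    ]
    if design.include_control:
        conditions.append((f"{design.experiment}-control", 0.0, True))
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        theta_i = params.threshold * math.exp(params.individual_sd * rng.standard_normal())
        for rep in range(1, design.repeats + 1):
            for stim_id, level, is_control in conditions:
                p = psychometric_p(None if is_control else level, params, threshold=theta_i)
                responded = rng.uniform() < p
                events: list[TransitionEvent] = []
                reemergence = None
                if responded:
                    events = _event_sequence(rng, design.profile)
                    ref_level = level if level > 0 else theta_i
                    reemergence = max(
                        0.0,
                        params.reemergence_base_s
                        + params.reemergence_gain_s * math.log(ref_level / theta_i)
                        + params.reemergence_noise_sd_s * rng.standard_normal(),
                    )
                elif rng.uniform() < params.stop_only_rate:
                    angle = design.profile.alpha_max_deg * rng.uniform(0.05, 0.5)
                    events = [
                        TransitionEvent(Behavior.STOP_FEEDING, design.profile.time_to_reach(angle))
                    ]
                trials.append(
                    TrialRecord(
                        individual_id=f"ind{i:02d}",
                        experiment=design.experiment,
                        stimulus_id=stim_id,
                        repeat_index=rep,
                        level=level,
                        is_control=is_control,
                        events=events,
                        reemergence_s=reemergence,
                    )
                )
    return trials


@dataclass(frozen=True)
class RecoveryReport:
    """Comparison of the inferred threshold with the generating one.

    With a discrete level series the identifiable target is not the
    generating threshold itself but the smallest designed level above
    it; ``matches_identifiable_target`` records whether the estimate
    hit that level.
    """

    estimated_level: float | None
    generating_threshold: float
    identifiable_target: float | None
    matches_identifiable_target: bool
    alpha_min_deg: float | None


def recover_threshold(
    trials: list[TrialRecord],
    design: SimulationDesign,
    params: ObserverParams,
    alpha: float = 0.05,
    m: int | None = None,
) -> RecoveryReport:
    """Run the threshold pipeline on simulated trials and compare the
    estimate with the generating threshold."""
    table = build_response_table(trials, design.experiment)
    result = determine_threshold(table, alpha=alpha, m=m)
    above = [lv for lv in design.levels if lv > params.threshold]
    target = min(above) if above else None
    return RecoveryReport(
        estimated_level=result.threshold_level,
        generating_threshold=params.threshold,
        identifiable_target=target,
        matches_identifiable_target=result.threshold_level == target,
        alpha_min_deg=result.alpha_min_deg,
    )
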