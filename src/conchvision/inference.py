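"""Threshold inference and the supporting statistical battery.

The behavioural threshold question is: which is the weakest stimulus —
the lowest Michelson contrast, or the narrowest checkerboard check —
whose responder count is significantly above the control loom's?  Each
stimulus level is compared with the control by Fisher's exact test,
p-values are Bonferroni-corrected over the family of levels, and the
threshold is the smallest level whose adjusted p-value clears the
significance level.  For the resolution experiment the minimum
resolvable angle is twice the threshold check width (one full angular
period of the finest detectable checkerboard).

The module exposes both the individual statistics (Wilson score
intervals, Spearman rank correlation with exact small-sample permutation
p-values, Fisher's exact test, paired Wilcoxon signed-rank, Bonferroni
correction) and a model/results pair in the statsmodels idiom:

>>> model = DetectionThresholdModel.from_trials(trials, "resolution")
>>> res = model.fit()
>>> res.threshold_level, res.alpha_min_deg
>>> print(res.summary())
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.proportion import proportion_confint

from .exceptions import DomainError, ValidationError
from .trials import ResponseTable, TrialRecord, build_response_table, reemergence_summary

__all__ = [
    "IntervalEstimate",
    "CorrelationResult",
    "TestResult",
    "ThresholdResult",
    "wilson_interval",
    "spearman",
    "fisher_exact",
    "bonferroni",
    "wilcoxon_signed_rank_paired",
    "determine_threshold",
    "DetectionThresholdModel",
    "DetectionThresholdResults",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntervalEstimate:
    """A proportion with a confidence interval."""

    point: float
    lower: float
    upper: float
    confidence: float = 0.95


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with its p-value."""

    rho: float
    p_value: float
    n: int
    method: str = "exact"  # "exact" permutation or "t-approx"


@dataclass(frozen=True)
class TestResult:
    """A hypothesis-test outcome, optionally multiplicity-adjusted."""

    p_value: float
    statistic: float
    n: int = 0
    adjusted_p: float | None = None
    m: int | None = None


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the threshold-determination rule.

    ``threshold_level`` is None when no level is significant versus
    control.  ``alpha_min_deg`` (resolution experiment only) is twice
    the threshold check width.  ``per_level`` holds the Fisher exact
    p-values and their Bonferroni adjustment per level.
    """

    experiment: str
    threshold_level: float | None
    alpha_min_deg: float | None
    per_level: pd.DataFrame
    alpha: float
    m: int


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> IntervalEstimate:
    """Wilson score interval for a binomial proportion ``k/n``."""
    if n <= 0:
        raise DomainError("n must be > 0")
    if not 0 <= k <= n:
        raise DomainError("need 0 <= k <= n")
    lower, upper = proportion_confint(k, n, alpha=1.0 - confidence, method="wilson")
    point = k / n
    # guard against floating-point excursions outside [0, 1] or past the point
    lower = min(max(float(lower), 0.0), point)
    upper = max(min(float(upper), 1.0), point)
    return IntervalEstimate(point=point, lower=lower, upper=upper, confidence=confidence)


def _exact_spearman_p(rank_x: np.ndarray, rank_y: np.ndarray) -> float:
    """Two-sided permutation p for Spearman rho by full enumeration.

    With ranks fixed, |rho| ordering is equivalent to |dot(rank_x, perm)
    - centre| ordering, so only a dot product per permutation is needed.
    Feasible for n <= 9 (9! = 362,880 permutations).
    """
    n = len(rank_x)
    centre = n * ((n + 1) / 2.0) ** 2
    rx = [float(v) for v in rank_x]
    obs = abs(sum(a * b for a, b in zip(rx, rank_y)) - centre)
    hits = 0
    total = 0
    for perm in itertools.permutations([float(v) for v in rank_y]):
        total += 1
        if abs(sum(a * b for a, b in zip(rx, perm)) - centre) >= obs - 1e-9:
            hits += 1
    return hits / total


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    The p-value is an exact two-sided permutation p (full enumeration)
    for n <= 9, and the t-distribution approximation otherwise.  A
    constant input vector leaves rho undefined (NaN, with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise DomainError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman rho is undefined", stacklevel=2)
        return CorrelationResult(rho=float("nan"), p_value=float("nan"), n=n, method="undefined")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        return CorrelationResult(rho=rho, p_value=_exact_spearman_p(rx, ry), n=n, method="exact")
    p = float(scipy.stats.spearmanr(x, y).pvalue)
    return CorrelationResult(rho=rho, p_value=p, n=n, method="t-approx")


def fisher_exact(k1: int, n1: int, k2: int, n2: int, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test comparing responder counts k1/n1 vs k2/n2.

    Two-sided p-values follow the probability-mass rule: the sum of
    hypergeometric probabilities of all tables (at fixed margins) no
    more probable than the observed one.  The statistic is the sample
    odds ratio.
    """
    for v, name in ((k1, "k1"), (n1, "n1"), (k2, "k2"), (n2, "n2")):
        if v < 0:
            raise DomainError(f"{name} must be >= 0")
    if k1 > n1 or k2 > n2:
        raise DomainError("need k <= n in both groups")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if table.sum() == 0:
        return TestResult(p_value=1.0, statistic=float("nan"), n=0)
    odds, p = scipy.stats.fisher_exact(table, alternative=alternative)
    return TestResult(p_value=float(p), statistic=float(odds), n=int(table.sum()))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``min(1, m * p)`` per p-value."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if m is None else int(m)
    if m < len(p):
        raise DomainError(f"m={m} smaller than the number of tests ({len(p)})")
    return np.minimum(1.0, m * p)


def wilcoxon_signed_rank_paired(a, b) -> TestResult:
    """Paired Wilcoxon signed-rank test.

    The statistic is V, the sum of the ranks of positive differences
    (``a - b``), after dropping zero differences.  P-values are exact
    for n <= 15 without ties in |differences| and use the normal
    approximation otherwise.  All-zero differences give V = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("a and b must be 1-D and of equal length")
    d = a - b
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return TestResult(p_value=1.0, statistic=0.0, n=0)
    ranks = scipy.stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 15 and not ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-sample normal-approx warnings
        res = scipy.stats.wilcoxon(d, alternative="two-sided", method=method)
    return TestResult(p_value=float(res.pvalue), statistic=v, n=n)


def determine_threshold(
    table: ResponseTable,
    alpha: float = 0.05,
    m: int | None = None,
    alternative: str = "two-sided",
) -> ThresholdResult:
    """Find the weakest stimulus level significantly above control.

    Each non-control level's responder count is compared with the
    control's by Fisher's exact test; p-values are Bonferroni-adjusted
    with family size ``m`` (default: the number of non-control levels —
    nine for the contrast series, eight for the resolution series).
    The threshold is the smallest level with adjusted p <= alpha; for
    the resolution experiment the minimum resolvable angle is reported
    as twice that check width.
    """
    ctrl = table.control
    if ctrl is None:
        raise ValidationError("response table has no control row")
    levels = table.treatment_levels
    if levels.empty:
        raise ValidationError("response table has no treatment levels")
    m = int(m) if m is not None else len(levels)
    records = []
    for row in levels.itertuples():
        t = fisher_exact(int(row.k), int(row.n), int(ctrl.k), int(ctrl.n), alternative=alternative)
        records.append((row.level, int(row.k), int(row.n), t.statistic, t.p_value))
    per_level = pd.DataFrame(records, columns=["level", "k", "n", "odds_ratio", "p_value"])
    per_level["p_adjusted"] = bonferroni(per_level["p_value"], m)
    per_level["significant"] = per_level["p_adjusted"] <= alpha
    sig = per_level.loc[per_level["significant"], "level"]
    threshold = float(sig.min()) if not sig.empty else None
    alpha_min = (
        2.0 * threshold if (threshold is not None and table.experiment == "resolution") else None
    )
    return ThresholdResult(
        experiment=table.experiment,
        threshold_level=threshold,
        alpha_min_deg=alpha_min,
        per_level=per_level,
        alpha=alpha,
        m=m,
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class DetectionThresholdModel:
    """Behavioural detection-threshold model for one looming experiment.

    Built either from raw trials (:meth:`from_trials`) or directly from
    a responder table (:meth:`from_response_table`).  ``fit`` runs the
    full battery: Wilson intervals per level, Fisher exact tests versus
    control with Bonferroni correction, the threshold rule, Spearman
    correlations of response probability and of re-emergence time with
    stimulus level, and the paired Wilcoxon check for a repeat effect.
    """

    def __init__(
        self,
        table: ResponseTable,
        trials: list[TrialRecord] | None = None,
    ) -> None:
        self.table = table
        self.trials = trials
        self.experiment = table.experiment

    @classmethod
    def from_trials(
        cls,
        trials: list[TrialRecord],
        experiment: str,
        per_individual: bool = False,
    ) -> "DetectionThresholdModel":
        table = build_response_table(trials, experiment, per_individual=per_individual)
        return cls(table, trials=[t for t in trials if t.experiment == experiment])

    @classmethod
    def from_response_table(cls, table: ResponseTable) -> "DetectionThresholdModel":
        return cls(table)

    @classmethod
    def from_dataframe(cls, levels: pd.DataFrame, experiment: str) -> "DetectionThresholdModel":
        """Build from a ``level, k, n, is_control`` DataFrame."""
        return cls(ResponseTable(experiment, levels.copy()))

    def fit(
        self,
        alpha: float = 0.05,
        m: int | None = None,
        confidence: float = 0.95,
        alternative: str = "two-sided",
    ) -> "DetectionThresholdResults":
        threshold = determine_threshold(self.table, alpha=alpha, m=m, alternative=alternative)
        per_level = threshold.per_level.copy()
        ci = [wilson_interval(int(r.k), int(r.n), confidence) for r in per_level.itertuples()]
        per_level.insert(3, "p_hat", [c.point for c in ci])
        per_level.insert(4, "wilson_lower", [c.lower for c in ci])
        per_level.insert(5, "wilson_upper", [c.upper for c in ci])

        level_corr = (
            spearman(per_level["level"], per_level["p_hat"]) if len(per_level) >= 3 else None
        )

        reemergence = reemergence_corr = None
        repeat_test = None
        if self.trials:
            reemergence = reemergence_summary(self.trials)
            if len(reemergence) >= 3:
                reemergence_corr = spearman(reemergence["level"], reemergence["reemergence_s"])
            repeat_test = self._repeat_effect()

        ctrl = self.table.control
        control_ci = wilson_interval(int(ctrl.k), int(ctrl.n), confidence) if ctrl is not None else None
        return DetectionThresholdResults(
            model=self,
            threshold=threshold,
            per_level=per_level,
            control=control_ci,
            control_counts=(int(ctrl.k), int(ctrl.n)) if ctrl is not None else None,
            level_correlation=level_corr,
            reemergence=reemergence,
            reemergence_correlation=reemergence_corr,
            repeat_test=repeat_test,
            confidence=confidence,
        )

    def _repeat_effect(self) -> TestResult:
        """Paired Wilcoxon on per-level response probabilities of the two
        repeats (no-repeat-effect check)."""
        probs: dict[int, pd.Series] = {}
        for rep in (1, 2):
            sub = [t for t in self.trials if t.repeat_index == rep and not t.is_control]
            tab = build_response_table(sub, self.experiment)
            df = tab.levels
            probs[rep] = (df["k"] / df["n"]).set_axis(df["level"])
        common = probs[1].index.intersection(probs[2].index)
        return wilcoxon_signed_rank_paired(probs[1][common].values, probs[2][common].values)


@dataclass
class DetectionThresholdResults:
    """Fitted detection-threshold results.

    Attributes
    ----------
    threshold : ThresholdResult
        The threshold rule's outcome (threshold level, minimum
        resolvable angle for the resolution experiment, per-level
        adjusted p-values).
    per_level : pandas.DataFrame
        One row per stimulus level: k, n, response probability with
        Wilson bounds, Fisher exact p and Bonferroni-adjusted p.
    level_correlation, reemergence_correlation : CorrelationResult
        Spearman correlations of response probability and of median
        re-emergence time with stimulus level.
    repeat_test : TestResult
        Paired Wilcoxon signed-rank comparing the two repeats.
    """

    model: DetectionThresholdModel
    threshold: ThresholdResult
    per_level: pd.DataFrame
    control: IntervalEstimate | None
    control_counts: tuple[int, int] | None
    level_correlation: CorrelationResult | None
    reemergence: pd.DataFrame | None
    reemergence_correlation: CorrelationResult | None
    repeat_test: TestResult | None
    confidence: float = 0.95

    @property
    def experiment(self) -> str:
        return self.model.experiment

    @property
    def threshold_level(self) -> float | None:
        return self.threshold.threshold_level

    @property
    def alpha_min_deg(self) -> float | None:
        return self.threshold.alpha_min_deg

    def summary(self) -> str:
        """Human-readable summary table in the statsmodels style."""
        unit = "Michelson contrast" if self.experiment == "contrast" else "check width (deg)"
        lines = [
            "Detection threshold model",
            "=" * 64,
            f"Experiment:        {self.experiment}",
            f"Stimulus level:    {unit}",
            f"Family size m:     {self.threshold.m}   alpha: {self.threshold.alpha}",
        ]
        if self.control_counts is not None:
            k, n = self.control_counts
            lines.append(f"Control:           {k}/{n} responders")
        lines.append("-" * 64)
        cols = ["level", "k", "n", "p_hat", "wilson_lower", "wilson_upper", "p_value", "p_adjusted"]
        lines.append(self.per_level[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        lines.append("-" * 64)
        if self.threshold_level is None:
            lines.append("Threshold:         none (no level significant vs control)")
        else:
            lines.append(f"Threshold level:   {self.threshold_level:g} ({unit})")
            if self.alpha_min_deg is not None:
                lines.append(f"Min resolvable angle (2x threshold): {self.alpha_min_deg:.2f} deg")
        if self.level_correlation is not None:
            c = self.level_correlation
            lines.append(f"Spearman level vs P(response): rho={c.rho:.3f}, p={c.p_value:.4g} (n={c.n})")
        if self.reemergence_correlation is not None:
            c = self.reemergence_correlation
            lines.append(f"Spearman level vs re-emergence: rho={c.rho:.3f}, p={c.p_value:.4g} (n={c.n})")
        if self.repeat_test is not None:
            t = self.repeat_test
            lines.append(f"Repeat effect (paired Wilcoxon): V={t.statistic:g}, p={t.p_value:.4g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Response probabilities with Wilson error bars versus level."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.per_level
        yerr = np.vstack([df["p_hat"] - df["wilson_lower"], df["wilson_upper"] - df["p_hat"]])
        ax.errorbar(df["level"], df["p_hat"], yerr=yerr, fmt="o-", capsize=3, color="darkgreen")
        if self.threshold_level is not None:
            ax.axvline(self.threshold_level, ls="--", color="grey", label="threshold")
            ax.legend()
        unit = "Michelson contrast" if self.experiment == "contrast" else "check width (deg)"
        ax.set_xlabel(unit)
        ax.set_ylabel("response probability")
        ax.set_ylim(-0.02, 1.02)
        return ax

    def to_dict(self) -> dict:
        """JSON-serialisable report of the headline quantities."""
        def corr(c):
            return None if c is None else {"rho": c.rho, "p_value": c.p_value, "n": c.n, "method": c.method}

        return {
            "experiment": self.experiment,
            "threshold_level": self.threshold_level,
            "alpha_min_deg": self.alpha_min_deg,
            "alpha": self.threshold.alpha,
            "m": self.threshold.m,
            "control": None if self.control_counts is None else list(self.control_counts),
            "per_level": self.per_level.to_dict(orient="records"),
            "level_correlation": corr(self.level_correlation),
            "reemergence_correlation": corr(self.reemergence_correlation),
            "repeat_test": None
            if self.repeat_test is None
            else {"V": self.repeat_test.statistic, "p_value": self.repeat_test.p_value, "n": self.repeat_test.n},
        }
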