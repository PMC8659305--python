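"""Synthetic estimation experiments with an underestimation bias.

Human estimates of large quantities are, on the log scale, well described by
Laplace distributions whose median underestimates the truth: the median
log-estimate m of a question with true value T follows m ~ gamma * log10(T)
with gamma ~ 0.9 < 1. This module generates questions, the group/condition
design and personal log-estimates with exactly that structure, so every
downstream stage (selection, influence model, fitting, accuracy statistics)
is testable without any external data.

Conventions
-----------
* Logarithms are base 10 throughout ("orders of magnitude").
* A raw estimate E maps to the normalized log-estimate X = log10(E / T);
  raw estimates are constrained to exceed 1, i.e. X > -log10(T).
* The Laplace width parameter is the mean absolute deviation from the
  median, which for an (untruncated) Laplace equals its scale b.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._common import ConfigurationError, DomainError, as_generator
from .social_selection import Condition

CATEGORIES = ("knowledge", "numerosity")
MAGNITUDES = ("moderate", "very_large")


@dataclass(frozen=True)
class QuestionSpec:
    """One quantity to estimate.

    Attributes
    ----------
    true_value : float
        T, in natural units; must exceed 1.
    log_true : float
        log10(T).
    center : float
        m_p, center (median) of the Laplace of log-estimates log10(E).
    width : float
        sigma_p, mean absolute deviation of log-estimates about the median.
    category, magnitude : str
        Descriptive tags carried through the pipeline (no sub-analysis).
    """

    question_id: str
    true_value: float
    log_true: float
    center: float
    width: float
    category: str = "knowledge"
    magnitude: str = "moderate"

    def __post_init__(self) -> None:
        if not self.true_value > 1:
            raise ConfigurationError(f"true_value must exceed 1, got {self.true_value}")
        if self.width < 0:
            raise ConfigurationError(f"width must be >= 0, got {self.width}")
        if not np.isfinite(self.center):
            raise ConfigurationError("center must be finite")


@dataclass
class GeneratorConfig:
    """Study-design and estimate-distribution parameters of the generator.

    Defaults are the experimental design emulated by the package: 18 groups
    of 12 subjects, 36 questions, an underestimation slope gamma_bias = 0.9,
    question centers scattered around gamma_bias * log_true with sd
    question_noise_sd, widths uniform in width_range and log10 true values
    uniform in log_true_range.
    """

    n_questions: int = 36
    n_groups: int = 18
    group_size: int = 12
    gamma_bias: float = 0.9
    question_noise_sd: float = 0.3
    width_range: tuple[float, float] = (0.3, 0.6)
    log_true_range: tuple[float, float] = (2.0, 7.0)
    seed: int = 0

    def validate(self) -> None:
        if self.group_size < 2:
            raise ConfigurationError("group_size must be >= 2")
        if not self.gamma_bias > 0:
            raise ConfigurationError("gamma_bias must be > 0")
        if self.question_noise_sd < 0:
            raise ConfigurationError("question_noise_sd must be >= 0")
        for name, rng_ in (("width_range", self.width_range), ("log_true_range", self.log_true_range)):
            lo, hi = rng_
            if not lo <= hi:
                raise ConfigurationError(f"{name} is reversed or empty: {rng_}")
        if self.width_range[0] < 0:
            raise ConfigurationError("width_range must be non-negative")
        if self.n_questions < 1 or self.n_groups < 1:
            raise ConfigurationError("n_questions and n_groups must be >= 1")


@dataclass(frozen=True)
class DesignAssignment:
    """Deterministic assignment (group, question) -> Condition.

    Satisfies the marginals of the emulated experiment: every group answers
    every question; per group each condition occurs exactly
    n_questions / n_conditions times; per (question, condition) exactly one
    group.
    """

    assignment: Mapping[tuple[int, str], Condition]
    conditions: tuple[Condition, ...]
    group_ids: tuple[int, ...]
    question_ids: tuple[str, ...]

    def condition_of(self, group_id: int, question_id: str) -> Condition:
        return self.assignment[(group_id, question_id)]

    def cells_of(self, condition: Condition) -> list[tuple[int, str]]:
        return [cell for cell, c in self.assignment.items() if c == condition]

    def records_per_condition(self, group_size: int) -> dict[Condition, int]:
        counts: dict[Condition, int] = {c: 0 for c in self.conditions}
        for c in self.assignment.values():
            counts[c] += group_size
        return counts


def generate_questions(config: GeneratorConfig, rng=None) -> list[QuestionSpec]:
    """Draw the question table.

    log_true ~ Uniform(log_true_range); center = gamma_bias * log_true +
    N(0, question_noise_sd); width ~ Uniform(width_range). Category tags
    alternate and the magnitude tag splits log_true_range at its midpoint.
    """
    config.validate()
    rng = as_generator(rng if rng is not None else config.seed)
    lo, hi = config.log_true_range
    log_true = rng.uniform(lo, hi, size=config.n_questions)
    noise = (
        rng.normal(0.0, config.question_noise_sd, size=config.n_questions)
        if config.question_noise_sd > 0
        else np.zeros(config.n_questions)
    )
    center = config.gamma_bias * log_true + noise
    wlo, whi = config.width_range
    width = rng.uniform(wlo, whi, size=config.n_questions)
    mid = 0.5 * (lo + hi)
    return [
        QuestionSpec(
            question_id=f"q{i:03d}",
            true_value=float(10.0 ** log_true[i]),
            log_true=float(log_true[i]),
            center=float(center[i]),
            width=float(width[i]),
            category=CATEGORIES[i % 2],
            magnitude="very_large" if log_true[i] >= mid else "moderate",
        )
        for i in range(config.n_questions)
    ]


def sample_truncated_laplace(center, width, lower_bound, n, rng=None) -> np.ndarray:
    """Exact inverse-CDF sampling of Laplace(center, b=width) | X > lower_bound.

    ``width`` is the mean absolute deviation of the *untruncated* Laplace,
    which equals its scale b. ``n`` may be an int or a shape tuple. With
    width = 0 the distribution is degenerate at ``center`` (an error if the
    center does not exceed the bound).
    """
    if width < 0:
        raise DomainError(f"width must be >= 0, got {width}")
    shape = (n,) if np.isscalar(n) else tuple(n)
    if int(np.prod(shape)) == 0:
        return np.empty(shape)
    if width == 0:
        if np.isfinite(lower_bound) and not center > lower_bound:
            raise DomainError(
                f"degenerate sample at center={center} violates lower_bound={lower_bound}"
            )
        return np.full(shape, float(center))
    rng = as_generator(rng)
    dist = stats.laplace(loc=center, scale=width)
    f_lo = dist.cdf(lower_bound) if np.isfinite(lower_bound) else 0.0
    u = rng.uniform(f_lo, 1.0, size=shape)
    return dist.ppf(u)


def sample_personal_estimates(question: QuestionSpec, n_subjects, rng=None) -> np.ndarray:
    """Personal log-estimates X_p = log10(E_p / T) for one question.

    Sampled from the question's truncated Laplace in log-estimate space and
    shifted by -log_true, so every raw estimate E_p = T * 10**X_p exceeds 1
    (equivalently X_p > -log_true).
    """
    if np.isscalar(n_subjects) and n_subjects < 1:
        raise DomainError("n_subjects must be >= 1")
    logs = sample_truncated_laplace(
        question.center, question.width, lower_bound=0.0, n=n_subjects, rng=rng
    )
    return logs - question.log_true


def build_design(config: GeneratorConfig, conditions: Sequence[Condition]) -> DesignAssignment:
    """Latin-square-style rotation of conditions over (group, question) cells.

    Requires n_groups = n_conditions and n_questions = 2 * n_conditions so
    that each group meets each condition exactly twice and each (question,
    condition) pair is covered by exactly one group. The construction is
    deterministic: condition index (g + q) mod n_conditions.
    """
    config.validate()
    n_cond = len(conditions)
    if len(set(conditions)) != n_cond:
        raise ConfigurationError("conditions must be distinct")
    if config.n_groups != n_cond:
        raise ConfigurationError(
            f"n_groups ({config.n_groups}) must equal the number of conditions ({n_cond})"
        )
    if config.n_questions != 2 * n_cond:
        raise ConfigurationError(
            f"n_questions ({config.n_questions}) must equal 2 x number of conditions ({n_cond})"
        )
    for c in conditions:
        if c.tau >= config.group_size:
            raise ConfigurationError(f"tau={c.tau} >= group_size={config.group_size}")
    group_ids = tuple(range(config.n_groups))
    question_ids = tuple(f"q{i:03d}" for i in range(config.n_questions))
    assignment = {
        (g, question_ids[q]): conditions[(g + q) % n_cond]
        for g in group_ids
        for q in range(config.n_questions)
    }
    return DesignAssignment(
        assignment=assignment,
        conditions=tuple(conditions),
        group_ids=group_ids,
        question_ids=question_ids,
    )
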