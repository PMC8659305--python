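"""Treatment-specific selection of the estimates shown to each subject.

Three treatments decide which ``tau`` log-estimates a focal subject receives
from the other members of their group:

* ``random`` — tau distinct other members chosen uniformly without replacement;
* ``median`` — the tau other members whose log-estimates are closest to the
  group median log-estimate ``m``;
* ``shifted_median`` — closest to the bias-compensated reference
  ``m' = m / gamma`` (with the underestimation slope ``gamma < 1``,
  ``m' > m`` whenever ``m > 0``), so the shared values statistically
  overshoot the group median toward the truth.

The group median ``m`` is computed over the whole group, including the focal
subject; only the *shared* values exclude the focal subject's own estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._common import ConfigurationError, DomainError, as_generator

TREATMENTS: tuple[str, ...] = ("random", "median", "shifted_median")
TAUS: tuple[int, ...] = (1, 3, 5, 7, 9, 11)


@dataclass(frozen=True, order=True)
class Condition:
    """One experimental condition: a treatment crossed with a number of
    shared estimates tau."""

    treatment: str
    tau: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ConfigurationError(f"unknown treatment {self.treatment!r}")
        if self.tau < 1:
            raise ConfigurationError(f"tau must be >= 1, got {self.tau}")

    @property
    def label(self) -> str:
        return f"{self.treatment}:tau={self.tau}"


def all_conditions(taus: Sequence[int] = TAUS) -> list[Condition]:
    """The full treatment x tau grid (18 conditions for the default taus)."""
    return [Condition(t, tau) for t in TREATMENTS for tau in taus]


@dataclass(frozen=True)
class SharedSet:
    """The social information delivered to one focal subject."""

    focal_subject: object
    values: tuple[float, ...]
    source_subjects: tuple[object, ...]

    def __post_init__(self) -> None:
        if self.focal_subject in self.source_subjects:
            raise ConfigurationError("focal subject cannot be a source of its own social information")
        if len(self.values) != len(self.source_subjects):
            raise ConfigurationError("values and source_subjects must align")


def group_median_log(group_logs: Sequence[float]) -> float:
    """Sample median of the group's log-estimates.

    For even counts this is the arithmetic mean of the two middle order
    statistics (the convention used throughout the package).
    """
    arr = np.asarray(group_logs, dtype=float)
    if arr.size == 0:
        raise DomainError("group_median_log of an empty sequence")
    return float(np.median(arr))


def shifted_median(m: float, gamma: float) -> float:
    """Bias-compensated reference value m' = m / gamma.

    With an underestimation slope gamma < 1 and m > 0, m' > m approximates
    the log of the true value. The formula is applied unconditionally; for
    m < 0 (possible in synthetic edge cases) m' < m.
    """
    if gamma <= 0:
        raise DomainError(f"gamma must be > 0, got {gamma}")
    return m / gamma


def select_shared(
    group_logs: Mapping[object, float],
    focal,
    condition: Condition,
    gamma: float = 0.9,
    rng=None,
) -> SharedSet:
    """Select the tau log-estimates shown to ``focal`` under ``condition``.

    Median and Shifted-Median selections are deterministic given the group's
    estimates; ties in |x - ref| prefer the smaller log-estimate, and among
    equal values the smaller subject id (iteration order of ``group_logs``).

    Parameters
    ----------
    group_logs
        Mapping subject id -> log-estimate for the whole group (focal
        included). Duplicated values are distinct items attached to subjects.
    gamma
        Underestimation slope used by the shifted-median reference.
    rng
        Seed or Generator; only consumed by the random treatment.
    """
    if focal not in group_logs:
        raise ConfigurationError(f"focal subject {focal!r} not in group")
    tau = condition.tau
    if tau >= len(group_logs):
        raise ConfigurationError(
            f"tau={tau} must be smaller than the group size {len(group_logs)}"
        )

    others = [(sid, x) for sid, x in group_logs.items() if sid != focal]

    if condition.treatment == "random":
        rng = as_generator(rng)
        idx = rng.choice(len(others), size=tau, replace=False)
        chosen = [others[i] for i in idx]
    else:
        m = group_median_log(list(group_logs.values()))
        ref = m if condition.treatment == "median" else shifted_median(m, gamma)
        # sort key: distance to ref, then smaller value, then input order (id)
        order = sorted(
            range(len(others)),
            key=lambda i: (abs(others[i][1] - ref), others[i][1], i),
        )
        chosen = [others[i] for i in order[:tau]]

    return SharedSet(
        focal_subject=focal,
        values=tuple(x for _, x in chosen),
        source_subjects=tuple(sid for sid, _ in chosen),
    )
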