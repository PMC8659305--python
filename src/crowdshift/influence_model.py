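"""Agent-based model of social-information integration.

Each agent holds a personal log-estimate X_p, receives tau log-estimates
selected by the treatment rule, summarizes them by their mean M (the log of
the geometric mean of the raw estimates) and dispersion
sigma = <|X_SI - M|>, and revises to

    X_s = (1 - S) * X_p + S * M,

where the sensitivity to social influence S is drawn from a spike-and-
Gaussian law: with probability P0 the agent keeps its estimate (S = 0
exactly), and with probability Pg = 1 - P0 it draws S ~ N(m_g, sigma_g).
The mixture is tied to the behavioral response surface by <S> = Pg * m_g,
where the expected sensitivity follows a linear cusp in the distance
D = M - X_p with a dispersion (similarity) term:

    <S>(D, sigma, tau) = alpha + beta_-/+ |D - D0| + beta' * sigma,

with beta_- applying for D < D0 and beta_+ for D >= D0. D0 < 0 and
beta_+ > beta_- encode the asymmetry effect (social information above one's
own estimate is weighted more); beta' < 0 encodes the similarity effect
(disparate social information is followed less). At tau = 1 the dispersion
is identically zero, so that block carries constant m_g, sigma_g and no
beta' term; for tau > 1, m_g and sigma_g depend linearly on sigma.

Reduced model variants switch individual mechanisms off: ``no_asymmetry``
forces D0 = 0 and beta_- = beta_+; ``no_similarity`` forces beta' = 0 and
constant m_g, sigma_g.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._common import ConfigurationError, DomainError, as_generator
from .social_selection import Condition, SharedSet
from .synthetic_data import DesignAssignment, QuestionSpec, sample_truncated_laplace

VARIANTS = ("full", "no_similarity", "no_asymmetry")

#: floors keeping the mixture well-defined where the linear laws in sigma
#: would cross zero; crossings are counted in GuardCounters.
MG_FLOOR = 1e-3
SG_FLOOR = 1e-3


@dataclass(frozen=True)
class Tau1Params:
    """Cusp and mixture constants for the single-shared-estimate block."""

    m_g: float
    sigma_g: float
    D0: float
    alpha: float
    beta_minus: float
    beta_plus: float


@dataclass(frozen=True)
class TauGt1Params:
    """Cusp constants plus sigma-linear mixture laws for tau > 1."""

    D0: float
    alpha: float
    beta_minus: float
    beta_plus: float
    beta_prime: float
    m_g_intercept: float
    m_g_slope: float
    sigma_g_intercept: float
    sigma_g_slope: float


@dataclass(frozen=True)
class InfluenceParams:
    """Behavioral parameters for one treatment: a tau = 1 block, a tau > 1
    block and the model variant."""

    tau1: Tau1Params
    tau_gt1: TauGt1Params
    variant: str = "full"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.tau1.sigma_g < 0:
            raise ConfigurationError("tau1.sigma_g must be >= 0")

    def as_variant(self, variant: str) -> "InfluenceParams":
        """Derive a reduced-model parameter set from this one.

        ``no_asymmetry`` sets D0 = 0 and both slopes to their mean;
        ``no_similarity`` zeroes beta' and the sigma-slopes of m_g/sigma_g
        (the intercepts are kept).
        """
        if variant == "full":
            return replace(self, variant="full")
        if variant == "no_asymmetry":
            b1 = 0.5 * (self.tau1.beta_minus + self.tau1.beta_plus)
            bg = 0.5 * (self.tau_gt1.beta_minus + self.tau_gt1.beta_plus)
            return InfluenceParams(
                tau1=replace(self.tau1, D0=0.0, beta_minus=b1, beta_plus=b1),
                tau_gt1=replace(self.tau_gt1, D0=0.0, beta_minus=bg, beta_plus=bg),
                variant="no_asymmetry",
            )
        if variant == "no_similarity":
            return InfluenceParams(
                tau1=self.tau1,
                tau_gt1=replace(
                    self.tau_gt1, beta_prime=0.0, m_g_slope=0.0, sigma_g_slope=0.0
                ),
                variant="no_similarity",
            )
        raise ConfigurationError(f"unknown variant {variant!r}")

    def to_dict(self) -> dict:
        return {"tau1": asdict(self.tau1), "tau_gt1": asdict(self.tau_gt1), "variant": self.variant}

    @classmethod
    def from_dict(cls, d: Mapping) -> "InfluenceParams":
        return cls(
            tau1=Tau1Params(**d["tau1"]),
            tau_gt1=TauGt1Params(**d["tau_gt1"]),
            variant=d.get("variant", "full"),
        )


def demo_params() -> dict[str, InfluenceParams]:
    """Plausible per-treatment parameters for demonstrations and recovery
    studies.

    These are the package's own fit-for-demo values (moderate herding,
    negative D0, beta_+ > beta_-, negative beta'), not estimates from any
    dataset; the package treats parameters strictly as inputs and the
    fitting module estimates them from data.
    """
    return {
        "random": InfluenceParams(
            tau1=Tau1Params(m_g=0.60, sigma_g=0.45, D0=-0.25, alpha=0.15,
                            beta_minus=0.10, beta_plus=0.20),
            tau_gt1=TauGt1Params(D0=-0.25, alpha=0.20, beta_minus=0.10, beta_plus=0.20,
                                 beta_prime=-0.15, m_g_intercept=0.70, m_g_slope=-0.25,
                                 sigma_g_intercept=0.30, sigma_g_slope=0.15),
        ),
        "median": InfluenceParams(
            tau1=Tau1Params(m_g=0.65, sigma_g=0.45, D0=-0.25, alpha=0.15,
                            beta_minus=0.10, beta_plus=0.20),
            tau_gt1=TauGt1Params(D0=-0.30, alpha=0.25, beta_minus=0.10, beta_plus=0.22,
                                 beta_prime=-0.25, m_g_intercept=0.75, m_g_slope=-0.30,
                                 sigma_g_intercept=0.28, sigma_g_slope=0.18),
        ),
        "shifted_median": InfluenceParams(
            tau1=Tau1Params(m_g=0.62, sigma_g=0.45, D0=-0.25, alpha=0.15,
                            beta_minus=0.10, beta_plus=0.20),
            tau_gt1=TauGt1Params(D0=-0.30, alpha=0.25, beta_minus=0.10, beta_plus=0.20,
                                 beta_prime=-0.25, m_g_intercept=0.72, m_g_slope=-0.28,
                                 sigma_g_intercept=0.28, sigma_g_slope=0.18),
        ),
    }


@dataclass
class GuardCounters:
    """Counts of numerical guard events during a simulation."""

    pg_clamped_low: int = 0
    pg_clamped_high: int = 0
    mg_floored: int = 0
    sg_floored: int = 0
    xs_floored: int = 0
    s_undefined: int = 0

    def as_dict(self) -> dict[str, int]:
        return asdict(self)

    def merge(self, other: "GuardCounters") -> None:
        for k, v in other.as_dict().items():
            setattr(self, k, getattr(self, k) + v)


@dataclass(frozen=True)
class SocialSummary:
    """Perceived central tendency and dispersion of the received estimates."""

    M: float
    sigma: float
    tau: int
    D: float


def social_summary(shared, X_p: float) -> SocialSummary:
    """Summarize a shared set: M = mean of the received log-estimates,
    sigma = mean absolute deviation about M, D = M - X_p."""
    values = np.asarray(shared.values if isinstance(shared, SharedSet) else shared, dtype=float)
    if values.size == 0:
        raise DomainError("social_summary of an empty shared set")
    M = float(values.mean())
    sigma = float(np.abs(values - M).mean())
    return SocialSummary(M=M, sigma=sigma, tau=int(values.size), D=M - float(X_p))


def expected_S(D, sigma, tau: int, params: InfluenceParams):
    """Raw linear-cusp expected sensitivity <S>(D, sigma, tau).

    Uses beta_- for D < D0 and beta_+ for D >= D0; the beta' * sigma term
    only applies for tau > 1. The value is *not* clamped to [0, 1]; clamping
    happens at the probability level inside :func:`draw_S`.
    """
    D = np.asarray(D, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if tau == 1:
        b = params.tau1
        out = b.alpha + np.where(D < b.D0, b.beta_minus, b.beta_plus) * np.abs(D - b.D0)
    else:
        b = params.tau_gt1
        out = (
            b.alpha
            + np.where(D < b.D0, b.beta_minus, b.beta_plus) * np.abs(D - b.D0)
            + b.beta_prime * sigma
        )
    return out if out.ndim else float(out)


def gaussian_params_at(sigma, tau: int, params: InfluenceParams,
                       counters: GuardCounters | None = None):
    """Mixture parameters (m_g, sigma_g) at a given social dispersion.

    tau = 1 uses the constant block; tau > 1 evaluates the linear laws in
    sigma, floored at small positive constants (floor events are counted).
    """
    sigma = np.asarray(sigma, dtype=float)
    if tau == 1:
        m_g = np.full_like(sigma, params.tau1.m_g)
        s_g = np.full_like(sigma, params.tau1.sigma_g)
    else:
        b = params.tau_gt1
        m_g = b.m_g_intercept + b.m_g_slope * sigma
        s_g = b.sigma_g_intercept + b.sigma_g_slope * sigma
        if counters is not None:
            counters.mg_floored += int(np.count_nonzero(m_g < MG_FLOOR))
            counters.sg_floored += int(np.count_nonzero(s_g < SG_FLOOR))
        m_g = np.maximum(m_g, MG_FLOOR)
        s_g = np.maximum(s_g, SG_FLOOR)
    if m_g.ndim:
        return m_g, s_g
    return float(m_g), float(s_g)


def _draw_S_array(D, sigma, tau, params, rng, counters: GuardCounters | None = None):
    """Vectorized spike-and-Gaussian draw of S at each (D, sigma)."""
    exp_s = expected_S(D, sigma, tau, params)
    m_g, s_g = gaussian_params_at(sigma, tau, params, counters)
    pg_raw = np.asarray(exp_s, dtype=float) / m_g
    if counters is not None:
        counters.pg_clamped_low += int(np.count_nonzero(pg_raw < 0))
        counters.pg_clamped_high += int(np.count_nonzero(pg_raw > 1))
    pg = np.clip(pg_raw, 0.0, 1.0)
    shape = np.broadcast(np.asarray(D, float), np.asarray(sigma, float)).shape
    u = rng.random(shape)
    gauss = rng.normal(np.broadcast_to(m_g, shape), np.broadcast_to(s_g, shape))
    return np.where(u < pg, gauss, 0.0)


def draw_S(summary: SocialSummary, params: InfluenceParams, rng=None,
           counters: GuardCounters | None = None) -> float:
    """Draw one sensitivity S for an agent.

    With probability Pg = clip(<S>/m_g, 0, 1) the value is Gaussian
    (m_g, sigma_g); otherwise it is exactly 0 (the agent keeps X_p). In the
    unclamped regime E[S] = <S> by construction.
    """
    rng = as_generator(rng)
    return float(
        _draw_S_array(summary.D, summary.sigma, summary.tau, params, rng, counters)
    )


def update_estimate(X_p, S, M, lower_bound=-np.inf):
    """Revised estimate X_s = (1 - S) X_p + S M, floored at ``lower_bound``
    (the raw-estimate > 1 constraint maps to lower_bound = -log10 T)."""
    X_s = (1.0 - np.asarray(S, float)) * np.asarray(X_p, float) + np.asarray(S, float) * np.asarray(M, float)
    return np.maximum(X_s, lower_bound)


# ---------------------------------------------------------------------------
# Experiment-scale simulation
# ---------------------------------------------------------------------------

@dataclass
class ConditionArrays:
    """Flat per-record arrays for one condition, concatenated over runs.

    S is the *measured* sensitivity (X_s - X_p)/(M - X_p); ``kept`` flags
    exact-keep records by provenance (X_s == X_p); ``defined`` flags records
    with M != X_p (S is NaN elsewhere).
    """

    condition: Condition
    question_idx: np.ndarray
    X_p: np.ndarray
    X_s: np.ndarray
    M: np.ndarray
    sigma: np.ndarray
    S: np.ndarray
    kept: np.ndarray
    defined: np.ndarray

    @property
    def D(self) -> np.ndarray:
        return self.M - self.X_p


@dataclass
class SimulationResult:
    records: pd.DataFrame | None
    sensitivities: dict[Condition, ConditionArrays] | None
    counters: GuardCounters
    questions: list[QuestionSpec]


def _params_for(params, treatment: str) -> InfluenceParams:
    if isinstance(params, InfluenceParams):
        return params
    return params[treatment]


def _select_shared_matrix(ell: np.ndarray, condition: Condition, gamma: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Vectorized selection: (runs, n) group log-estimates -> (runs, n, tau)
    shared values for every focal subject.

    Implements the same rules and tie-breaking as
    :func:`crowdshift.social_selection.select_shared` (distance to the
    reference, then smaller value, then smaller subject id).
    """
    R, n = ell.shape
    tau = condition.tau
    others_idx = np.array([[j for j in range(n) if j != i] for i in range(n)])
    vals = ell[:, others_idx]  # (R, n, n-1)
    if condition.treatment == "random":
        u = rng.random((R, n, n - 1))
        order = np.argsort(u, axis=-1)[..., :tau]
        return np.take_along_axis(vals, order, axis=-1)
    m = np.median(ell, axis=1)
    ref = m if condition.treatment == "median" else m / gamma
    dist = np.abs(vals - ref[:, None, None])
    perm1 = np.argsort(vals, axis=-1, kind="stable")  # value then id (input order)
    dist1 = np.take_along_axis(dist, perm1, axis=-1)
    perm2 = np.argsort(dist1, axis=-1, kind="stable")
    order = np.take_along_axis(perm1, perm2, axis=-1)[..., :tau]
    return np.take_along_axis(vals, order, axis=-1)


def simulate_experiment(
    questions: Sequence[QuestionSpec],
    design: DesignAssignment,
    params,
    gamma: float = 0.9,
    n_runs: int = 1,
    seed: int = 0,
    group_size: int = 12,
    collect: str = "records",
    include_shared: bool = True,
) -> SimulationResult:
    """Simulate ``n_runs`` replicates of the full experimental design.

    For every (group, question) cell: draw ``group_size`` personal
    log-estimates from the question's truncated Laplace, apply the cell's
    treatment selection, summarize, draw S per agent and update. All
    randomness flows from ``seed`` through one generator consumed in a fixed
    cell order, so identical seeds give bit-identical outputs.

    Parameters
    ----------
    params
        An :class:`InfluenceParams` (applied to every treatment) or a
        mapping treatment -> InfluenceParams.
    collect
        ``"records"`` returns a tidy DataFrame (one row per agent x cell x
        run); ``"sensitivities"`` returns compact per-condition float32
        arrays suited to large ``n_runs``.
    include_shared
        Only for ``"records"``: also build the semicolon-separated raw
        shared-estimate strings needed to write record CSVs (slow for very
        large simulations).
    """
    if collect not in ("records", "sensitivities"):
        raise ConfigurationError(f"unknown collect mode {collect!r}")
    rng = as_generator(seed)
    counters = GuardCounters()
    qmap = {q.question_id: q for q in questions}
    frames: list[pd.DataFrame] = []
    acc: dict[Condition, dict[str, list[np.ndarray]]] = {}
    q_index = {q.question_id: i for i, q in enumerate(questions)}

    for g in design.group_ids:
        for qid in design.question_ids:
            cond = design.condition_of(g, qid)
            q = qmap[qid]
            tp = _params_for(params, cond.treatment)
            ell = sample_truncated_laplace(q.center, q.width, 0.0, (n_runs, group_size), rng)
            sel = _select_shared_matrix(ell, cond, gamma, rng)
            M_ell = sel.mean(axis=-1)
            sigma = np.abs(sel - M_ell[..., None]).mean(axis=-1)
            if cond.tau == 1:
                sigma = np.zeros_like(sigma)
            D = M_ell - ell
            S_drawn = _draw_S_array(D, sigma, cond.tau, tp, rng, counters)
            ell_s = (1.0 - S_drawn) * ell + S_drawn * M_ell
            counters.xs_floored += int(np.count_nonzero(ell_s < 0.0))
            ell_s = np.maximum(ell_s, 0.0)

            X_p = ell - q.log_true
            X_s = ell_s - q.log_true
            M_X = M_ell - q.log_true
            defined = M_ell != ell
            counters.s_undefined += int(np.count_nonzero(~defined))
            with np.errstate(divide="ignore", invalid="ignore"):
                S_meas = np.where(defined, (ell_s - ell) / (M_ell - ell), np.nan)
            kept = ell_s == ell

            if collect == "sensitivities":
                d = acc.setdefault(cond, {k: [] for k in
                                          ("question_idx", "X_p", "X_s", "M", "sigma", "S", "kept", "defined")})
                nrec = ell.size
                d["question_idx"].append(np.full(nrec, q_index[qid], dtype=np.int32))
                d["X_p"].append(X_p.ravel().astype(np.float32))
                d["X_s"].append(X_s.ravel().astype(np.float32))
                d["M"].append(M_X.ravel().astype(np.float32))
                d["sigma"].append(sigma.ravel().astype(np.float32))
                d["S"].append(S_meas.ravel().astype(np.float32))
                d["kept"].append(kept.ravel())
                d["defined"].append(defined.ravel())
            else:
                runs = np.repeat(np.arange(n_runs), group_size)
                subjects = np.tile(np.arange(group_size), n_runs)
                frame = pd.DataFrame(
                    {
                        "run": runs,
                        "group": g,
                        "subject": subjects,
                        "question": qid,
                        "treatment": cond.treatment,
                        "tau": cond.tau,
                        "E_p": 10.0 ** ell.ravel(),
                        "E_s": 10.0 ** ell_s.ravel(),
                        "X_p": X_p.ravel(),
                        "X_s": X_s.ravel(),
                        "M": M_X.ravel(),
                        "sigma": sigma.ravel(),
                        "D": D.ravel(),
                        "S_drawn": S_drawn.ravel(),
                        "S": S_meas.ravel(),
                        "kept": kept.ravel(),
                        "s_defined": defined.ravel(),
                    }
                )
                if include_shared:
                    raw = 10.0 ** sel.reshape(-1, cond.tau)
                    frame["shared"] = [
                        ";".join(format(v, ".10g") for v in row) for row in raw
                    ]
                frames.append(frame)

    if collect == "sensitivities":
        tables = {
            cond: ConditionArrays(
                condition=cond,
                **{k: np.concatenate(v) for k, v in d.items()},
            )
            for cond, d in acc.items()
        }
        return SimulationResult(records=None, sensitivities=tables,
                                counters=counters, questions=list(questions))
    records = pd.concat(frames, ignore_index=True)
    return SimulationResult(records=records, sensitivities=None,
                            counters=counters, questions=list(questions))
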