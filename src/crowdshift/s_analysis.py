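"""Recovering the sensitivity model from estimation records.

The analysis inverts the update rule to the measured sensitivity
S = (X_s - X_p)/(M - X_p), restricts it to [-1.05, 2.05] (discarding
meaningless blow-ups when M is nearly equal to X_p), fits the
spike-and-Gaussian mixture per condition, locates the cusp bottom D0 on a
moving-bin mean-S curve, fits the linear cusp by closed-form least squares
over individual answers, and regresses the mixture parameters on the mean
social-information dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from ._common import DomainError
from .social_selection import Condition, TREATMENTS
from .influence_model import (
    ConditionArrays,
    InfluenceParams,
    Tau1Params,
    TauGt1Params,
)

#: analysis-side restriction of measured sensitivities
S_CLIP = (-1.05, 2.05)


def compute_S(X_p, X_s, M):
    """Measured sensitivity S = (X_s - X_p)/(M - X_p).

    Vectorized; undefined entries (M == X_p) come back as NaN and are
    flagged by the companion boolean mask.

    Returns
    -------
    (S, defined) : tuple of ndarray
    """
    X_p = np.asarray(X_p, float)
    X_s = np.asarray(X_s, float)
    M = np.asarray(M, float)
    defined = M != X_p
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(defined, (X_s - X_p) / (M - X_p), np.nan)
    if S.ndim == 0:
        return float(S), bool(defined)
    return S, defined


def clip_S(S, interval: tuple[float, float] = S_CLIP):
    """Keep sensitivities inside ``interval`` and report the removed
    fraction (NaN entries are dropped first and do not count)."""
    S = np.asarray(S, float)
    S = S[np.isfinite(S)]
    lo, hi = interval
    keep = (S >= lo) & (S <= hi)
    removed_fraction = 0.0 if S.size == 0 else float(np.count_nonzero(~keep) / S.size)
    return S[keep], removed_fraction


@dataclass(frozen=True)
class MixtureFit:
    """Spike-and-Gaussian fit of a sensitivity distribution.

    The spike weight follows from the constraint <S> = Pg * m_g, so
    P0 = 1 - <S>/m_g and mean_S = Pg * m_g hold by construction.
    """

    P0: float
    Pg: float
    m_g: float
    sigma_g: float
    mean_S: float
    n: int = 0


def fit_S_mixture(S_values, bin_width: float = 0.1, zero_mask=None) -> MixtureFit:
    """Fit f(S) = (1 - Pg) delta(S) + Pg N(m_g, sigma_g) to clipped
    sensitivities.

    The empirical density of the non-zero part (normalized by the *total*
    count, so it integrates to Pg) is fitted by nonlinear least squares
    against Pg(m_g) * N(S; m_g, sigma_g) with Pg = mean(S)/m_g substituted,
    leaving m_g and sigma_g free. Exact keeps should be identified by
    provenance (X_s == X_p); pass them as ``zero_mask``, otherwise exact
    zeros in ``S_values`` are used.
    """
    S = np.asarray(S_values, float)
    if S.size == 0:
        raise DomainError("fit_S_mixture of an empty sample")
    if zero_mask is None:
        zero_mask = S == 0.0
    else:
        zero_mask = np.asarray(zero_mask, bool)
    nonzero = S[~zero_mask]
    mean_S = float(S.mean())
    n = int(S.size)
    if nonzero.size == 0:
        return MixtureFit(P0=1.0, Pg=0.0, m_g=np.nan, sigma_g=np.nan, mean_S=mean_S, n=n)

    lo, hi = S_CLIP
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(nonzero, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / (n * bin_width)

    def model(x, m_g, sigma_g):
        pg = mean_S / m_g
        return pg / (np.sqrt(2 * np.pi) * sigma_g) * np.exp(-((x - m_g) ** 2) / (2 * sigma_g**2))

    p0 = (max(float(nonzero.mean()), 1e-3), max(float(nonzero.std()), 1e-3))
    try:
        popt, _ = optimize.curve_fit(
            model, centers, density, p0=p0,
            bounds=((1e-6, 1e-6), (np.inf, np.inf)), maxfev=10000,
        )
    except RuntimeError as err:  # pragma: no cover - diagnostic path
        raise DomainError(f"mixture fit did not converge: {err}") from err
    m_g, sigma_g = map(float, popt)
    pg = mean_S / m_g
    return MixtureFit(P0=1.0 - pg, Pg=pg, m_g=m_g, sigma_g=sigma_g, mean_S=mean_S, n=n)


def moving_bin_curve(
    D_values,
    S_values,
    bin_size: float = 1.0,
    step: float = 0.1,
    centers_range: tuple[float, float] = (-2.0, 2.0),
) -> np.ndarray:
    """Overlapping-bin mean-sensitivity curve <S>(D).

    For each bin center c on a grid with spacing ``step``, average S over
    records with |D - c| <= bin_size/2. With step < bin_size the same data
    are replicated across overlapping bins, trading resolution of the bin
    center against per-bin noise; step = bin_size degenerates to ordinary
    disjoint binning.

    Returns a structured array with fields ``center``, ``mean_S`` (NaN for
    empty bins) and ``count``.
    """
    D = np.asarray(D_values, float)
    S = np.asarray(S_values, float)
    ok = np.isfinite(D) & np.isfinite(S)
    D, S = D[ok], S[ok]
    lo, hi = centers_range
    n_centers = int(round((hi - lo) / step)) + 1
    centers = lo + step * np.arange(n_centers)
    half = bin_size / 2.0
    out = np.zeros(n_centers, dtype=[("center", float), ("mean_S", float), ("count", int)])
    for i, c in enumerate(centers):
        mask = np.abs(D - c) <= half
        cnt = int(np.count_nonzero(mask))
        out[i] = (c, S[mask].mean() if cnt else np.nan, cnt)
    return out


def d0_search_interval(treatment: str, tau: int) -> tuple[float, float]:
    """Search interval for the cusp bottom D0.

    Default [-1.2, 0.2]; the upper bound is 0.6 for the random treatment at
    tau = 3 and 5 and the median treatment at tau = 3, whose mean-S curves
    have a shallower bottom.
    """
    if (treatment, tau) in {("random", 3), ("random", 5), ("median", 3)}:
        return (-1.2, 0.6)
    return (-1.2, 0.2)


def fit_D0(curve, search_interval: tuple[float, float] = (-1.2, 0.2),
           window: float = 1.0) -> float:
    """Locate the cusp bottom on the moving-bin curve.

    The curve points are means of S over windows of size ``window``, so the
    fitted local model is the window average of the absolute-value cusp
    a + b_-(D0 - D)_+ + b_+(D - D0)_+: pure linear limbs once the window
    clears the vertex, and the exact quadratic blend
    [b_-(h-u)^2 + b_+(h+u)^2]/(4h) (u = c - D0, h = window/2) across it.
    Averaging an asymmetric cusp shifts the *minimum* of the binned curve
    toward the shallow side by up to (h)(b_+-b_-)/(b_++b_-), so fitting the
    raw V to the binned points would systematically misplace D0; the
    window-averaged model removes that bias. With ``window = 0`` the model
    reduces to the plain V (appropriate for disjoint narrow bins).

    D0 is scanned on a 0.01 grid over ``search_interval`` (the model is
    linear in the remaining parameters at fixed D0) and refined by a
    parabolic step through the best grid point and its neighbours.
    """
    curve = np.asarray(curve)
    lo, hi = search_interval
    pts = curve[(curve["count"] > 0) & (curve["center"] >= lo) & (curve["center"] <= hi)]
    if pts.shape[0] < 3:
        raise DomainError(
            f"need at least 3 populated curve points in {search_interval}, got {pts.shape[0]}"
        )
    c = pts["center"]
    y = pts["mean_S"]
    h = window / 2.0

    def design_at(d0: float) -> np.ndarray:
        u = c - d0
        if h == 0:
            left = np.maximum(-u, 0.0)
            right = np.maximum(u, 0.0)
        else:
            inside = np.abs(u) < h
            left = np.where(u <= -h, -u, np.where(inside, (h - u) ** 2 / (4 * h), 0.0))
            right = np.where(u >= h, u, np.where(inside, (h + u) ** 2 / (4 * h), 0.0))
        return np.column_stack([np.ones_like(c), left, right])

    def rss_at(d0: float) -> float:
        X = design_at(d0)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)

    grid = np.arange(lo, hi + 0.005, 0.01)
    rss = np.array([rss_at(d) for d in grid])
    i = int(np.argmin(rss))
    if 0 < i < len(grid) - 1:
        # parabolic refinement through the three best-neighbouring points
        y0, y1, y2 = rss[i - 1], rss[i], rss[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            return float(grid[i] + 0.01 * 0.5 * (y0 - y2) / denom)
    return float(grid[i])


def fit_D0_records(
    D_values,
    S_values,
    sigma_values,
    tau: int,
    search_interval: tuple[float, float] = (-1.2, 0.2),
    fit_interval: tuple[float, float] = (-2.5, 2.5),
) -> float:
    """Locate the cusp bottom by profiling the record-level least squares.

    For each candidate D0 on a 0.01 grid over ``search_interval`` the cusp
    alpha + beta_-/+ |D - D0| (+ beta' sigma for tau > 1) is solved in
    closed form over the individual answers with D in ``fit_interval``, and
    the D0 minimizing the residual sum of squares is returned (parabolic
    refinement through the best grid point). Unlike a fit to the moving-bin
    curve, this profile is not distorted by the interaction of the size-1
    averaging window with the strongly peaked density of D, so the vertex
    of an asymmetric cusp is recovered without systematic shift.
    """
    D = np.asarray(D_values, float)
    S = np.asarray(S_values, float)
    sig = np.asarray(sigma_values, float)
    lo, hi = fit_interval
    ok = np.isfinite(D) & np.isfinite(S) & (D >= lo) & (D <= hi)
    D, S, sig = D[ok], S[ok], sig[ok]
    if D.size < (4 if tau > 1 else 3):
        raise DomainError(f"too few records ({D.size}) in fit interval {fit_interval}")

    # Prefix sums over D-sorted records make the normal equations of the
    # split design O(1) per candidate D0.
    order = np.argsort(D, kind="stable")
    D, S, sig = D[order], S[order], sig[order]
    zeros = np.zeros(1)
    cs = {
        "n": np.concatenate([zeros, np.cumsum(np.ones_like(D))]),
        "d": np.concatenate([zeros, np.cumsum(D)]),
        "d2": np.concatenate([zeros, np.cumsum(D * D)]),
        "s": np.concatenate([zeros, np.cumsum(S)]),
        "sd": np.concatenate([zeros, np.cumsum(S * D)]),
        "g": np.concatenate([zeros, np.cumsum(sig)]),
        "gd": np.concatenate([zeros, np.cumsum(sig * D)]),
        "g2": np.concatenate([zeros, np.cumsum(sig * sig)]),
        "gs": np.concatenate([zeros, np.cumsum(sig * S)]),
    }
    total = {k: v[-1] for k, v in cs.items()}
    yty = float(S @ S)

    def rss_at(d0: float) -> float:
        k = int(np.searchsorted(D, d0, side="left"))
        nL, dL, d2L = cs["n"][k], cs["d"][k], cs["d2"][k]
        sL, sdL = cs["s"][k], cs["sd"][k]
        gL, gdL = cs["g"][k], cs["gd"][k]
        nR = total["n"] - nL
        dR = total["d"] - dL
        d2R = total["d2"] - d2L
        sR = total["s"] - sL
        sdR = total["sd"] - sdL
        gR = total["g"] - gL
        gdR = total["gd"] - gdL
        # sums of the regressors 1, a_- = (d0-D)+, a_+ = (D-d0)+ [, sigma]
        s01 = nL * d0 - dL
        s02 = dR - nR * d0
        s11 = nL * d0 * d0 - 2 * d0 * dL + d2L
        s22 = d2R - 2 * d0 * dR + nR * d0 * d0
        t1 = d0 * sL - sdL
        t2 = sdR - d0 * sR
        if tau > 1:
            s03 = total["g"]
            s13 = d0 * gL - gdL
            s23 = gdR - d0 * gR
            xtx = np.array([
                [total["n"], s01, s02, s03],
                [s01, s11, 0.0, s13],
                [s02, 0.0, s22, s23],
                [s03, s13, s23, total["g2"]],
            ])
            xty = np.array([total["s"], t1, t2, total["gs"]])
        else:
            xtx = np.array([
                [total["n"], s01, s02],
                [s01, s11, 0.0],
                [s02, 0.0, s22],
            ])
            xty = np.array([total["s"], t1, t2])
        try:
            coef = np.linalg.solve(xtx, xty)
        except np.linalg.LinAlgError:
            coef, *_ = np.linalg.lstsq(xtx, xty, rcond=None)
        return yty - float(coef @ xty)

    glo, ghi = search_interval
    grid = np.arange(glo, ghi + 0.005, 0.01)
    rss = np.array([rss_at(d) for d in grid])
    i = int(np.argmin(rss))
    if 0 < i < len(grid) - 1:
        y0, y1, y2 = rss[i - 1], rss[i], rss[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            return float(grid[i] + 0.01 * 0.5 * (y0 - y2) / denom)
    return float(grid[i])


@dataclass(frozen=True)
class CuspFit:
    """Linear-cusp fit <S> = alpha + beta_-/+ |D - D0| (+ beta' sigma)."""

    D0: float
    alpha: float
    beta_minus: float
    beta_plus: float
    beta_prime: float | None
    fit_interval: tuple[float, float]
    rss: float
    n: int


def cusp_fit_interval(treatment: str, tau: int) -> tuple[float, float]:
    """Per-condition D interval over which the cusp is fitted.

    Default [-2.5, 2.5], slightly restricted in a few conditions where the
    extreme-D tails are too thin to constrain the slopes.
    """
    special = {
        ("random", 1): (-1.65, 2.5),
        ("random", 11): (-1.65, 2.5),
        ("median", 7): (-1.9, 2.5),
        ("shifted_median", 3): (-2.0, 2.5),
        ("shifted_median", 9): (-1.2, 1.5),
    }
    return special.get((treatment, tau), (-2.5, 2.5))


def fit_cusp(
    D_values,
    S_values,
    sigma_values,
    D0: float,
    tau: int,
    fit_interval: tuple[float, float] = (-2.5, 2.5),
) -> CuspFit:
    """Closed-form least squares of the cusp over individual answers.

    Regressors: 1, |D - D0| 1[D < D0], |D - D0| 1[D >= D0], and sigma for
    tau > 1 (the dispersion term is excluded at tau = 1 where sigma is
    identically zero). All answers carry unit weight.
    """
    D = np.asarray(D_values, float)
    S = np.asarray(S_values, float)
    sig = np.asarray(sigma_values, float)
    lo, hi = fit_interval
    ok = np.isfinite(D) & np.isfinite(S) & (D >= lo) & (D <= hi)
    D, S, sig = D[ok], S[ok], sig[ok]
    if D.size < (4 if tau > 1 else 3):
        raise DomainError(f"too few records ({D.size}) in fit interval {fit_interval}")

    absd = np.abs(D - D0)
    cols = [np.ones_like(D), absd * (D < D0), absd * (D >= D0)]
    names = ["intercept", "left slope", "right slope"]
    if tau > 1:
        cols.append(sig)
        names.append("sigma")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        degenerate = [nm for nm, col in zip(names[1:], X.T[1:]) if np.ptp(col) == 0]
        raise DomainError(
            "rank-deficient cusp design; degenerate regressor(s): "
            + (", ".join(degenerate) if degenerate else "collinear combination")
        )
    coef, _, _, _ = np.linalg.lstsq(X, S, rcond=None)
    r = S - X @ coef
    return CuspFit(
        D0=float(D0),
        alpha=float(coef[0]),
        beta_minus=float(coef[1]),
        beta_plus=float(coef[2]),
        beta_prime=float(coef[3]) if tau > 1 else None,
        fit_interval=(lo, hi),
        rss=float(r @ r),
        n=int(D.size),
    )


@dataclass(frozen=True)
class LinearLaw:
    intercept: float
    slope: float

    def __call__(self, x):
        return self.intercept + self.slope * np.asarray(x, float)


@dataclass(frozen=True)
class ParamSigmaLaws:
    """Linear regressions of the mixture parameters on the mean dispersion."""

    Pg: LinearLaw
    m_g: LinearLaw
    sigma_g: LinearLaw
    product: LinearLaw  # Pg * m_g vs <sigma>


def regress_params_vs_sigma(fits: Sequence[tuple[MixtureFit, float]]) -> ParamSigmaLaws:
    """OLS of Pg, m_g, sigma_g and the product Pg*m_g on the per-condition
    mean dispersion <sigma> (conditions with tau > 1)."""
    if len(fits) < 2:
        raise DomainError("need at least two (fit, mean_sigma) points")
    sig = np.array([s for _, s in fits], float)

    def law(y):
        slope, intercept = np.polyfit(sig, np.asarray(y, float), 1)
        return LinearLaw(intercept=float(intercept), slope=float(slope))

    return ParamSigmaLaws(
        Pg=law([f.Pg for f, _ in fits]),
        m_g=law([f.m_g for f, _ in fits]),
        sigma_g=law([f.sigma_g for f, _ in fits]),
        product=law([f.Pg * f.m_g for f, _ in fits]),
    )


def quadratic_cross_term(pg_slope: float, mg_slope: float, sigma: float) -> float:
    """Magnitude of the quadratic term b b' sigma^2 that the product law
    Pg*m_g inherits from the two linear laws; of order 0.01 for slopes ~0.2
    at sigma ~0.5 and hence negligible against the linear trend."""
    return pg_slope * mg_slope * sigma**2


# ---------------------------------------------------------------------------
# Full per-treatment parameter estimation (closes the simulate -> fit loop)
# ---------------------------------------------------------------------------

@dataclass
class ConditionFit:
    condition: Condition
    mixture: MixtureFit
    cusp: CuspFit
    mean_sigma: float
    removed_fraction: float


def fit_condition(arrays: ConditionArrays) -> ConditionFit:
    """Run the full per-condition estimation chain on simulated or read
    records: clip S, mixture fit, moving-bin D0, cusp fit."""
    cond = arrays.condition
    defined = arrays.defined
    S_all = np.asarray(arrays.S, float)[defined]
    kept = np.asarray(arrays.kept, bool)[defined]
    D_all = np.asarray(arrays.D, float)[defined]
    sig_all = np.asarray(arrays.sigma, float)[defined]

    lo, hi = S_CLIP
    in_range = (S_all >= lo) & (S_all <= hi)
    removed = float(np.count_nonzero(~in_range) / max(S_all.size, 1))
    S, z, D, sig = S_all[in_range], kept[in_range], D_all[in_range], sig_all[in_range]

    mixture = fit_S_mixture(S, zero_mask=z)
    interval = cusp_fit_interval(cond.treatment, cond.tau)
    D0 = fit_D0_records(
        D, S, sig, cond.tau,
        search_interval=d0_search_interval(cond.treatment, cond.tau),
        fit_interval=interval,
    )
    cusp = fit_cusp(D, S, sig, D0, cond.tau, interval)
    return ConditionFit(
        condition=cond,
        mixture=mixture,
        cusp=cusp,
        mean_sigma=float(sig_all.mean()) if sig_all.size else np.nan,
        removed_fraction=removed,
    )


def fit_influence_params(
    tables: Mapping[Condition, ConditionArrays],
) -> tuple[dict[str, InfluenceParams], dict[Condition, ConditionFit]]:
    """Estimate a full per-treatment parameter set from per-condition record
    arrays.

    The tau = 1 block takes its mixture and cusp values from the tau = 1
    condition; the tau > 1 block averages the cusp parameters over tau > 1
    conditions and regresses the mixture parameters on the per-condition
    mean dispersion to obtain the linear m_g/sigma_g laws.
    """
    cond_fits = {cond: fit_condition(arr) for cond, arr in tables.items()}
    params: dict[str, InfluenceParams] = {}
    for tr in TREATMENTS:
        fits = {c.tau: f for c, f in cond_fits.items() if c.treatment == tr}
        if not fits:
            continue
        if 1 not in fits or len([t for t in fits if t > 1]) < 2:
            raise DomainError(
                f"treatment {tr!r} needs a tau=1 condition and >=2 tau>1 conditions"
            )
        f1 = fits[1]
        tau1 = Tau1Params(
            m_g=f1.mixture.m_g,
            sigma_g=f1.mixture.sigma_g,
            D0=f1.cusp.D0,
            alpha=f1.cusp.alpha,
            beta_minus=f1.cusp.beta_minus,
            beta_plus=f1.cusp.beta_plus,
        )
        gt = [fits[t] for t in sorted(fits) if t > 1]
        laws = regress_params_vs_sigma([(f.mixture, f.mean_sigma) for f in gt])
        tau_gt1 = TauGt1Params(
            D0=float(np.mean([f.cusp.D0 for f in gt])),
            alpha=float(np.mean([f.cusp.alpha for f in gt])),
            beta_minus=float(np.mean([f.cusp.beta_minus for f in gt])),
            beta_plus=float(np.mean([f.cusp.beta_plus for f in gt])),
            beta_prime=float(np.mean([f.cusp.beta_prime for f in gt])),
            m_g_intercept=laws.m_g.intercept,
            m_g_slope=laws.m_g.slope,
            sigma_g_intercept=laws.sigma_g.intercept,
            sigma_g_slope=laws.sigma_g.slope,
        )
        params[tr] = InfluenceParams(tau1=tau1, tau_gt1=tau_gt1, variant="full")
    return params, cond_fits
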