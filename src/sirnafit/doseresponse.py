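"""Four-parameter log-logistic (4PL) dose-response analysis.

The model is ``f(x) = c + (d - c) / (1 + (x/e)^b)``: ``c`` and ``d`` are the
lower and upper asymptotes, ``b`` the slope, and ``e`` the inflection
concentration — the dose at which the response is exactly halfway between
the asymptotes (ED50). In the oligo-oligo competition setting, a constant
amount of a co-transfected competitor shifts the titrated oligo's curve
horizontally; the shift is quantified as the fold change of inflection
points, and replicated log-ED50 estimates are compared across conditions by
one-way ANOVA followed by Tukey HSD at a chosen alpha.

Fitting is nonlinear least squares over ``(b, c, d, log e)`` — the log
parameterization keeps ``e`` positive and makes the fit equivariant under
rescaling of the concentration unit. Zero-concentration control wells are
excluded from the fit (the curve is undefined at x = 0) and serve only as a
sanity check on the upper asymptote.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import ValidationError


@dataclass
class DoseResponseData:
    """One titration series: concentrations (single consistent unit) and responses."""

    concentrations: np.ndarray
    responses: np.ndarray
    condition: str = ""
    replicate: int = 0

    def __post_init__(self):
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValidationError("concentrations and responses must have equal length")
        if (self.concentrations < 0).any():
            raise ValidationError("concentrations must be non-negative")


@dataclass
class DoseResponseFit:
    b: float
    c: float
    d: float
    e: float  # inflection concentration (ED50), same unit as input
    rss: float
    converged: bool
    se_e: float = float("nan")
    n_points: int = 0
    condition: str = ""
    replicate: int = 0

    def __call__(self, x):
        return eval_4pl(x, self.b, self.c, self.d, self.e)

    @property
    def midpoint_response(self) -> float:
        """Response at x = e; equals (c + d)/2 by construction."""
        return 0.5 * (self.c + self.d)


@dataclass
class ShiftResult:
    """Fold changes of inflection points vs a reference condition, with
    ANOVA and Tukey-HSD-adjusted pairwise p-values on log ED50."""

    fc: dict  # condition -> geometric-mean e ratio vs reference
    anova_p: float
    pairwise_p: dict  # frozenset({cond_a, cond_b}) -> adjusted p
    significant: dict  # same keys -> bool at alpha
    alpha: float
    reference: str


def eval_4pl(x, b: float, c: float, d: float, e: float):
    """Evaluate ``c + (d - c)/(1 + (x/e)^b)`` for positive x and e."""
    x = np.asarray(x, dtype=float)
    if e <= 0:
        raise ValidationError("inflection parameter e must be positive")
    if (x <= 0).any():
        raise ValidationError("4PL is defined for positive concentrations only")
    val = c + (d - c) / (1.0 + (x / e) ** b)
    return float(val) if val.ndim == 0 else val


def _initial_params(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Self-starting values: asymptotes from the response range, e from the
    median log concentration, slope from the mid-range log-linear trend."""
    c0, d0 = float(y.min()), float(y.max())
    if d0 - c0 <= 0:
        d0 = c0 + 1.0
    loge0 = float(np.median(np.log(x)))
    # slope of y against log x; at x = e, df/dlog(x) = -b (d - c)/4
    slope = np.polyfit(np.log(x), y, 1)[0]
    b0 = -4.0 * slope / (d0 - c0)
    if not np.isfinite(b0) or abs(b0) < 0.1:
        b0 = 1.0 if slope < 0 else -1.0
    b0 = float(np.clip(b0, -10, 10))
    return np.array([b0, c0, d0, loge0])


def fit_4pl(data: DoseResponseData, n_restarts: int = 5) -> DoseResponseFit:
    """Least-squares 4PL fit over (b, c, d, log e) with seeded multi-start.

    Requires >= 5 distinct positive concentrations and non-constant
    responses. On failure of the initial fit, up to ``n_restarts`` perturbed
    initializations (fixed internal seed) are tried; a fit that never
    converges is returned flagged, not raised.
    """
    pos = data.concentrations > 0
    x, y = data.concentrations[pos], data.responses[pos]
    if len(np.unique(x)) < 5:
        raise ValidationError("need at least 5 distinct positive concentrations")
    if np.ptp(y) == 0:
        raise ValidationError("responses are constant: no dose dependence to fit")

    def residuals(theta):
        b, c, d, loge = theta
        return c + (d - c) / (1.0 + (x / np.exp(loge)) ** b) - y

    theta0 = _initial_params(x, y)
    rng = np.random.default_rng(0)
    best = None
    for trial in range(n_restarts + 1):
        start = theta0 if trial == 0 else theta0 * (1 + 0.2 * rng.standard_normal(4))
        try:
            res = optimize.least_squares(residuals, start, method="lm", max_nfev=10000)
        except Exception:
            continue
        rss = float(2 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res)
        if best[1].success and trial >= 0 and best[0] <= np.var(y) * len(y) * 1e-6:
            break  # essentially perfect fit; no need for restarts
    if best is None:
        return DoseResponseFit(
            b=np.nan, c=np.nan, d=np.nan, e=np.nan, rss=np.nan, converged=False,
            n_points=len(x), condition=data.condition, replicate=data.replicate,
        )

    rss, res = best
    b, c, d, loge = res.x
    if b < 0:  # (x/e)^b with b<0 mirrors swapping c and d; canonicalize to b>0
        b, c, d = -b, d, c
        loge = loge  # unchanged
    e = float(np.exp(loge))

    # standard error of e via the Jacobian at the optimum (delta method on log e)
    se_e = float("nan")
    dof = len(x) - 4
    if res.success and dof > 0:
        J = res.jac
        try:
            cov = np.linalg.inv(J.T @ J) * (rss / dof)
            se_loge = float(np.sqrt(max(cov[3, 3], 0.0)))
            se_e = e * se_loge
        except np.linalg.LinAlgError:
            pass

    return DoseResponseFit(
        b=float(b), c=float(c), d=float(d), e=e, rss=rss,
        converged=bool(res.success and np.isfinite(res.x).all()),
        se_e=se_e, n_points=len(x),
        condition=data.condition, replicate=data.replicate,
    )


def ed50_fold_change(fit_condition: DoseResponseFit, fit_reference: DoseResponseFit) -> float:
    """Fold change of inflection points: e(condition) / e(reference)."""
    for f in (fit_condition, fit_reference):
        if not f.converged:
            raise ValidationError(
                f"fit for condition {f.condition!r} did not converge; fold change undefined"
            )
    return fit_condition.e / fit_reference.e


def compare_inflections(
    fits_by_condition: dict,
    alpha: float = 0.05,
    reference: str | None = None,
) -> ShiftResult:
    """One-way ANOVA + Tukey HSD across conditions on log-transformed ED50s.

    ``fits_by_condition`` maps condition label -> list of replicate
    :class:`DoseResponseFit` (or raw e estimates). Fold changes are
    geometric means vs the reference condition (default: first key).
    Every condition needs >= 2 replicates.
    """
    if len(fits_by_condition) < 2:
        raise ValidationError("need at least two conditions to compare")
    log_e: dict[str, np.ndarray] = {}
    for cond, fits in fits_by_condition.items():
        es = []
        for f in fits:
            if isinstance(f, DoseResponseFit):
                if not f.converged:
                    raise ValidationError(f"unconverged fit in condition {cond!r}")
                es.append(f.e)
            else:
                es.append(float(f))
        if len(es) < 2:
            raise ValidationError(f"condition {cond!r} has a single replicate")
        if (np.asarray(es) <= 0).any():
            raise ValidationError(f"non-positive ED50 in condition {cond!r}")
        log_e[cond] = np.log(np.asarray(es, dtype=float))

    conditions = list(log_e)
    if reference is None:
        reference = conditions[0]
    if reference not in log_e:
        raise ValidationError(f"reference condition {reference!r} not present")

    anova_p = float(stats.f_oneway(*log_e.values())[1])

    values = np.concatenate([log_e[c] for c in conditions])
    groups = np.concatenate([[c] * len(log_e[c]) for c in conditions])
    tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
    pairwise_p: dict[frozenset, float] = {}
    significant: dict[frozenset, bool] = {}
    for (g1, g2), p, rej in zip(
        itertools.combinations(tk.groupsunique, 2), tk.pvalues, tk.reject
    ):
        key = frozenset({str(g1), str(g2)})
        pairwise_p[key] = float(p)
        significant[key] = bool(rej)

    ref_gm = float(np.exp(log_e[reference].mean()))
    fc = {c: float(np.exp(log_e[c].mean())) / ref_gm for c in conditions}
    return ShiftResult(
        fc=fc, anova_p=anova_p, pairwise_p=pairwise_p,
        significant=significant, alpha=alpha, reference=reference,
    )
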