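"""Trace normalization, global perturbation fitting and hypothesis ranking.

The central question the fitting layer answers is *which microscopic step a
modulator perturbs*.  Kinetic traces from several conditions (a shared
control plus one or more modulator doses) are fitted simultaneously: the base
rate constants are shared across all conditions while each non-control
condition carries one multiplicative fold-change applied to the rate
constant(s) singled out by a :class:`PerturbationHypothesis`.  Competing
hypotheses (e.g. "the modulator accelerates primary nucleation" versus "it
accelerates secondary nucleation") are ranked by AIC.

The optimizer is basin-hopping over log10-transformed parameters with an
L-BFGS-B local polish, followed by a trust-region least-squares refinement
that also supplies local-curvature standard errors.  Identical seeds give
bit-identical results.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .kinetics import (
    IncompleteReactionError,
    KineticTrace,
    RateConstants,
    ReactionConditions,
    derive_parameters,
    half_time,
    mass_fraction_closed_form,
)

log = logging.getLogger(__name__)

HYPOTHESIS_TARGETS = ("none", "primary", "secondary_product", "k2_only", "kplus_only")


class NoAggregationSignalError(ValueError):
    """Raised when a raw trace shows no rise from baseline to plateau."""


@dataclass(frozen=True)
class PerturbationHypothesis:
    """A mechanistic hypothesis about which microscopic step a modulator hits.

    ``target`` selects the perturbed quantity: ``primary`` scales the product
    ``k_plus*k_n`` (implemented as a factor on ``k_n``), ``secondary_product``
    scales ``k_plus*k_2`` and ``k2_only`` scales ``k_2`` (both implemented as
    a factor on ``k_2``, which changes the product while leaving elongation
    untouched -- they differ in declared intent, not in algebra),
    ``kplus_only`` scales ``k_plus`` and ``none`` fits shared rates with no
    per-condition freedom.  ``factors`` optionally carries planted/known
    fold-changes keyed by condition label (control factor must be 1).
    """

    target: str
    factors: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.target not in HYPOTHESIS_TARGETS:
            raise ValueError(f"unknown hypothesis target {self.target!r}")
        if self.factors is not None:
            for label, f in self.factors.items():
                if not (math.isfinite(f) and f > 0):
                    raise ValueError(f"factor for {label!r} must be finite and positive")

    def apply(self, base: RateConstants, factor: float) -> RateConstants:
        """Rate constants of one condition under this hypothesis."""
        if self.target == "none":
            return base
        if self.target == "primary":
            return base.scaled(f_n=factor)
        if self.target in ("secondary_product", "k2_only"):
            return base.scaled(f_2=factor)
        return base.scaled(f_plus=factor)  # kplus_only


@dataclass(frozen=True)
class ConditionSpec:
    """Metadata of one experimental condition."""

    label: str
    conditions: ReactionConditions
    modulator_ratio: float = 0.0  # modulator:peptide molar ratio; 0 = control

    @property
    def is_control(self) -> bool:
        return self.modulator_ratio == 0.0


@dataclass
class ConditionData:
    """All replicate traces measured under one condition."""

    spec: ConditionSpec
    traces: list[KineticTrace]


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings (all deterministic given ``seed``).

    The search is in log10 space over ``bounds_decades`` decades centred on
    ``center`` (literature-scale Abeta42 values); per-condition fold-changes
    are bounded to ``factor_bounds``.
    """

    n_basinhop: int = 50
    seed: int = 0
    step_size: float = 0.7
    bounds_decades: float = 3.0
    center: RateConstants = field(
        default_factory=lambda: RateConstants(k_n=2e-5, k_plus=3e3, k_2=0.1)
    )
    factor_bounds: tuple[float, float] = (1e-2, 1e2)


@dataclass
class FitResult:
    """Outcome of a global fit under one hypothesis."""

    hypothesis: PerturbationHypothesis
    base_rates: RateConstants
    fitted_factors: dict[str, float]
    factor_log10_se: dict[str, float]
    apparent_rate_ratio: dict[str, float]
    rss: float
    aic: float
    n_obs: int
    n_params: int
    converged: bool
    seed: int
    wide_uncertainty: bool = False

    def summary(self) -> dict:
        """JSON-ready summary of the fit."""
        return {
            "hypothesis": self.hypothesis.target,
            "base_rates": {
                "k_n": self.base_rates.k_n,
                "k_plus": self.base_rates.k_plus,
                "k_2": self.base_rates.k_2,
                "n_c": self.base_rates.n_c,
                "n_2": self.base_rates.n_2,
            },
            "fitted_factors": dict(sorted(self.fitted_factors.items())),
            "apparent_rate_ratio": dict(sorted(self.apparent_rate_ratio.items())),
            "rss": self.rss,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "converged": self.converged,
            "wide_uncertainty": self.wide_uncertainty,
            "seed": self.seed,
        }


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------


def normalize_trace(
    raw: KineticTrace, baseline_window: float = 0.1, plateau_window: float = 0.1
) -> KineticTrace:
    """Map a raw fluorescence trace onto the [0, 1] mass-fraction scale.

    The baseline is the mean of the first ``baseline_window`` fraction of
    points, the plateau the mean of the last ``plateau_window`` fraction;
    the trace is transformed as ``(value - baseline)/(plateau - baseline)``.
    Idempotent on already-normalized sigmoids and inverse to any affine
    distortion of one.
    """
    if not 0 < baseline_window < 0.5 or not 0 < plateau_window < 0.5:
        raise ValueError("normalization windows must lie in (0, 0.5)")
    n = len(raw.values)
    nb = max(1, int(round(baseline_window * n)))
    np_ = max(1, int(round(plateau_window * n)))
    baseline = float(np.mean(raw.values[:nb]))
    plateau = float(np.mean(raw.values[-np_:]))
    if plateau <= baseline:
        raise NoAggregationSignalError(
            f"no aggregation signal in trace '{raw.label}': plateau {plateau:.4g} "
            f"<= baseline {baseline:.4g}"
        )
    values = (raw.values - baseline) / (plateau - baseline)
    return KineticTrace(raw.times, np.clip(values, -0.1, 1.1), label=raw.label, normalized=True)


# --------------------------------------------------------------------------
# global fitting
# --------------------------------------------------------------------------


def _pack_bounds(data, hypothesis, config):
    """Parameter vector layout: [log10 kn, log10 kp, log10 k2, log10 f_c ...]."""
    c = config.center
    lo = [math.log10(c.k_n) - config.bounds_decades,
          math.log10(c.k_plus) - config.bounds_decades,
          math.log10(c.k_2) - config.bounds_decades]
    hi = [math.log10(c.k_n) + config.bounds_decades,
          math.log10(c.k_plus) + config.bounds_decades,
          math.log10(c.k_2) + config.bounds_decades]
    x0 = [math.log10(c.k_n), math.log10(c.k_plus), math.log10(c.k_2)]
    perturbed = [cd.spec.label for cd in data if not cd.spec.is_control]
    if hypothesis.target != "none":
        for _ in perturbed:
            lo.append(math.log10(config.factor_bounds[0]))
            hi.append(math.log10(config.factor_bounds[1]))
            x0.append(0.0)
    return np.array(x0), np.array(lo), np.array(hi), perturbed


def _unpack(theta, hypothesis, perturbed, orders):
    n_c, n_2 = orders
    base = RateConstants(
        k_n=10.0 ** theta[0], k_plus=10.0 ** theta[1], k_2=10.0 ** theta[2],
        n_c=n_c, n_2=n_2,
    )
    factors = {}
    if hypothesis.target != "none":
        for i, label in enumerate(perturbed):
            factors[label] = 10.0 ** theta[3 + i]
    return base, factors


def _residuals(theta, data, hypothesis, perturbed, orders):
    base, factors = _unpack(theta, hypothesis, perturbed, orders)
    res = []
    for cd in data:
        f = factors.get(cd.spec.label, 1.0)
        rates = hypothesis.apply(base, f)
        try:
            params = derive_parameters(rates, cd.spec.conditions)
        except (ValueError, FloatingPointError):
            res.append(np.full(sum(len(tr.values) for tr in cd.traces), 1e3))
            continue
        # replicates usually share a grid; evaluate each unique grid once
        cache: dict[int, np.ndarray] = {}
        for tr in cd.traces:
            key = id(tr.times)
            if key not in cache:
                model = mass_fraction_closed_form(
                    tr.times, rates, cd.spec.conditions, params=params
                ).values
                cache[key] = model
            res.append(cache[key] - tr.values)
    out = np.concatenate(res)
    return np.where(np.isfinite(out), out, 1e3)


def fit_global(
    data: list[ConditionData],
    hypothesis: PerturbationHypothesis,
    config: FitConfig | None = None,
) -> FitResult:
    """Globally fit all conditions under one perturbation hypothesis.

    Minimizes the plain sum of squared residuals of the closed-form mass
    fraction against every point of every replicate (no per-trace weighting):
    base rate constants are shared, each non-control condition gets one
    fold-change on the hypothesis target.  Non-convergence returns the
    best-so-far result flagged ``converged=False`` rather than raising.
    """
    if config is None:
        config = FitConfig()
    if not any(cd.spec.is_control for cd in data):
        raise ValueError("fit_global requires at least one control condition")
    orders = (config.center.n_c, config.center.n_2)
    x0, lo, hi, perturbed = _pack_bounds(data, hypothesis, config)
    bounds = list(zip(lo, hi))

    def objective(theta):
        r = _residuals(theta, data, hypothesis, perturbed, orders)
        return float(r @ r)

    rng = np.random.default_rng(config.seed)
    minimizer_kwargs = {"method": "L-BFGS-B", "bounds": bounds}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        hop = optimize.basinhopping(
            objective,
            x0,
            niter=config.n_basinhop,
            seed=rng,
            stepsize=config.step_size,
            minimizer_kwargs=minimizer_kwargs,
            callback=lambda x, f, acc: log.debug(
                "basin-hop: f=%.6g accepted=%s", f, acc
            ),
        )
        theta_best = np.clip(hop.x, lo, hi)
        # trust-region polish; also provides the Jacobian for standard errors
        ls = optimize.least_squares(
            _residuals,
            theta_best,
            args=(data, hypothesis, perturbed, orders),
            bounds=(lo, hi),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
    theta = ls.x if ls.cost <= 0.5 * objective(theta_best) + 1e-30 else theta_best
    r = _residuals(theta, data, hypothesis, perturbed, orders)
    rss = float(r @ r)
    n_obs = len(r)
    n_params = len(theta)
    base, factors = _unpack(theta, hypothesis, perturbed, orders)
    for cd in data:
        if cd.spec.is_control:
            factors[cd.spec.label] = 1.0

    # local-curvature standard errors of the log10 parameters
    se = np.full(n_params, np.nan)
    try:
        J = ls.jac
        dof = max(n_obs - n_params, 1)
        cov = np.linalg.pinv(J.T @ J) * (rss / dof)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
        pass
    factor_se = {
        label: float(se[3 + i]) for i, label in enumerate(perturbed)
    } if hypothesis.target != "none" else {}
    wide = any(s > 1.0 for s in factor_se.values() if math.isfinite(s))
    if wide:
        warnings.warn(
            f"hypothesis {hypothesis.target!r}: some fold-changes are weakly "
            "identified (log10 s.e. > 1); interpret factors with caution",
            stacklevel=2,
        )

    # apparent k_plus*k_2 relative to control, the dose-response readout
    app = {}
    base_prod = base.k_plus * base.k_2
    for cd in data:
        pert = hypothesis.apply(base, factors.get(cd.spec.label, 1.0))
        app[cd.spec.label] = pert.k_plus * pert.k_2 / base_prod

    aic = n_obs * math.log(rss / n_obs) + 2.0 * (n_params + 1)
    converged = bool(hop.lowest_optimization_result.success or ls.success)
    return FitResult(
        hypothesis=hypothesis,
        base_rates=base,
        fitted_factors=factors,
        factor_log10_se=factor_se,
        apparent_rate_ratio=app,
        rss=rss,
        aic=aic,
        n_obs=n_obs,
        n_params=n_params,
        converged=converged,
        seed=config.seed,
        wide_uncertainty=wide,
    )


def compare_hypotheses(
    data: list[ConditionData],
    hypotheses: list[PerturbationHypothesis],
    config: FitConfig | None = None,
) -> list[FitResult]:
    """Fit every hypothesis and rank by AIC (ascending).

    Ties are broken by fewer parameters, then by declaration order; a fit
    that raises ranks last with ``aic = inf``.
    """
    if len(hypotheses) < 2:
        raise ValueError("compare_hypotheses needs at least two hypotheses")
    results = []
    for order, hyp in enumerate(hypotheses):
        try:
            res = fit_global(data, hyp, config)
        except Exception as exc:  # noqa: BLE001 - a failed fit must rank last
            log.warning("fit failed for hypothesis %r: %s", hyp.target, exc)
            res = FitResult(
                hypothesis=hyp,
                base_rates=(config or FitConfig()).center,
                fitted_factors={},
                factor_log10_se={},
                apparent_rate_ratio={},
                rss=math.inf,
                aic=math.inf,
                n_obs=0,
                n_params=0,
                converged=False,
                seed=(config or FitConfig()).seed,
            )
        results.append((res.aic, res.n_params, order, res))
    results.sort(key=lambda t: (t[0], t[1], t[2]))
    return [r for _, _, _, r in results]


# --------------------------------------------------------------------------
# half-time dose-response
# --------------------------------------------------------------------------


def halftime_dose_response(data: list[ConditionData]) -> pd.DataFrame:
    """Per-condition half-time summary across replicates.

    Returns a DataFrame with columns ``condition``, ``modulator_ratio``,
    ``n``, ``t50_mean``, ``t50_sem`` and ``n_excluded`` (replicates whose
    trace never reaches half completion are excluded and counted).
    """
    rows = []
    for cd in data:
        t50s = []
        excluded = 0
        for tr in cd.traces:
            try:
                t50s.append(half_time(tr))
            except IncompleteReactionError:
                excluded += 1
        if excluded:
            log.info(
                "condition %s: excluded %d incomplete replicate(s)",
                cd.spec.label, excluded,
            )
        t50s = np.asarray(t50s)
        rows.append(
            {
                "condition": cd.spec.label,
                "modulator_ratio": cd.spec.modulator_ratio,
                "n": len(t50s),
                "t50_mean": float(np.mean(t50s)) if len(t50s) else math.nan,
                "t50_sem": float(np.std(t50s, ddof=1) / math.sqrt(len(t50s)))
                if len(t50s) > 1
                else 0.0,
                "n_excluded": excluded,
            }
        )
    return pd.DataFrame(rows)
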