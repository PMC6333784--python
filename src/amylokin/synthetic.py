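"""Synthetic kinetic traces and fibril morphometry with planted ground truth.

The generator emulates the reference experimental campaign: ThT-monitored
aggregation of 2 uM Abeta42 at 37 C under quiescent conditions, unseeded and
with 5% or 25% pre-formed seeds, in the absence and presence of an
aminosterol modulator at peptide:modulator ratios of 10:1, 5:1 and 1:1, and
AFM/TEM morphometry of the end-point fibrils.  Traces are the closed-form
aggregate mass fraction under per-condition perturbed rate constants plus
i.i.d. additive Gaussian noise; fibril dimensions are lognormal (positive,
right-skewed).  Everything is deterministic per seed (numpy PCG64), and the
returned truth record is sufficient to regenerate every noiseless curve
bit-identically.

The frozen base rate constants were solved (once, at design time) so that the
fixture reproduces the anchor half-times of the emulated campaign: 1.00 h for
the unseeded control and 0.28 h / 0.19 h for the 25%-seeded control and its
five-fold-k2 counterpart.  The planted dose ladder on the secondary
nucleation rate constant is saturating and culminates at x5 for the equimolar
condition, the enhancement reported for this system.  Under these anchors the
model cannot additionally halve the unseeded half-time at the 5:1 dose (the
achievable reduction at fold-changes <= 5 is bounded near 0.65 of control);
see the methods note for the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .fitting import ConditionData, ConditionSpec, PerturbationHypothesis
from .kinetics import KineticTrace, RateConstants, ReactionConditions, mass_fraction_closed_form
from .morphometry import FibrilMeasurementSet

#: Frozen fixture base rate constants (uM, hours); see module docstring.
FIXTURE_RATES = RateConstants(k_n=1.802474e-4, k_plus=5.478306e2, k_2=1.573094e-3)
FIXTURE_M_TOTAL = 2.0  # uM
FIXTURE_SEED_LENGTH = 500.0  # monomers per seed fibril

#: Planted k2 fold-changes by peptide:modulator ratio (saturating dose ladder).
FIXTURE_DOSE_FACTORS = {0.1: 1.5, 0.2: 2.5, 1.0: 5.0}

#: Lognormal presets for fibril dimensions: (arithmetic mean, log-sd, units).
#: Means anchor the emulated end-point measurements (lengths in um,
#: heights/widths in nm); log-sds are chosen for realistic right skew.
MORPHOMETRY_PRESETS = {
    "control_length": (1.81, 0.50, "length", "AFM"),
    "treated_length": (0.63, 0.50, "length", "AFM"),
    "control_height": (4.2, 0.25, "height", "AFM"),
    "treated_height": (6.3, 0.25, "height", "AFM"),
    "control_width": (12.0, 0.20, "width", "TEM"),
    "treated_width": (15.0, 0.20, "width", "TEM"),
}

RNG_ALGORITHM = "numpy.random.Generator(PCG64)"


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one batch of synthetic kinetic traces."""

    rates: RateConstants
    conditions: tuple[ConditionSpec, ...]
    perturbation: PerturbationHypothesis
    noise_sd: float = 0.02
    replicates: int = 3
    t_max: float = 3.0
    n_points: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n_points < 8:
            raise ValueError("n_points must be >= 8")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        if self.perturbation.factors is not None:
            missing = [
                cs.label
                for cs in self.conditions
                if not cs.is_control and cs.label not in self.perturbation.factors
            ]
            if missing:
                raise ValueError(f"no planted factor for condition(s): {missing}")


def generate_tht_traces(spec: GeneratorSpec) -> tuple[list[ConditionData], dict]:
    """Generate noisy mass-fraction traces plus the ground-truth record.

    Each condition's noiseless curve is the closed-form solution under the
    planted perturbation of the base rates; replicates differ only in the
    Gaussian noise realization.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, spec.t_max, spec.n_points)
    data: list[ConditionData] = []
    truth_conditions = []
    for cs in spec.conditions:
        factor = 1.0
        if not cs.is_control and spec.perturbation.factors is not None:
            factor = spec.perturbation.factors[cs.label]
        rates = spec.perturbation.apply(spec.rates, factor)
        clean = mass_fraction_closed_form(t, rates, cs.conditions, label=cs.label).values
        traces = []
        for rep in range(spec.replicates):
            noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
            traces.append(
                KineticTrace(
                    t,
                    np.clip(noisy, -0.1, 1.1),
                    label=f"{cs.label}/r{rep}",
                    normalized=True,
                )
            )
        data.append(ConditionData(spec=cs, traces=traces))
        truth_conditions.append(
            {
                "label": cs.label,
                "m_total_uM": cs.conditions.m_total,
                "seed_fraction": cs.conditions.seed_fraction,
                "seed_length": cs.conditions.seed_length,
                "modulator_ratio": cs.modulator_ratio,
                "planted_factor": factor,
            }
        )
    truth = {
        "generator": "amylokin.synthetic.generate_tht_traces",
        "rng": RNG_ALGORITHM,
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
        "replicates": spec.replicates,
        "t_max_h": spec.t_max,
        "n_points": spec.n_points,
        "perturbation_target": spec.perturbation.target,
        "base_rates": {
            "k_n": spec.rates.k_n,
            "k_plus": spec.rates.k_plus,
            "k_2": spec.rates.k_2,
            "n_c": spec.rates.n_c,
            "n_2": spec.rates.n_2,
        },
        "conditions": truth_conditions,
    }
    return data, truth


def generate_fibril_dimensions(
    n: int,
    log_mean: float,
    log_sd: float,
    dimension: str,
    modality: str,
    seed: int = 0,
    condition: str = "",
) -> FibrilMeasurementSet:
    """Lognormal per-fibril measurements; deterministic per seed.

    ``log_mean``/``log_sd`` parameterize the underlying normal; the
    arithmetic mean of the sample is ``exp(log_mean + log_sd**2 / 2)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if log_sd < 0:
        raise ValueError("log_sd must be non-negative")
    rng = np.random.default_rng(seed)
    values = np.exp(rng.normal(log_mean, log_sd, size=n))
    return FibrilMeasurementSet(
        values=values, dimension=dimension, modality=modality, condition=condition
    )


def fibril_preset(name: str, n: int, seed: int = 0) -> FibrilMeasurementSet:
    """Draw from a named morphometry preset (see ``MORPHOMETRY_PRESETS``)."""
    mean, log_sd, dimension, modality = MORPHOMETRY_PRESETS[name]
    log_mean = math.log(mean) - log_sd**2 / 2.0  # arithmetic-mean anchoring
    return generate_fibril_dimensions(
        n, log_mean, log_sd, dimension, modality, seed=seed, condition=name
    )


@dataclass
class FixtureBundle:
    """The canonical synthetic campaign: trace series plus morphometry."""

    unseeded: list[ConditionData]
    seeded_5: list[ConditionData]
    seeded_25: list[ConditionData]
    morphometry: dict[str, FibrilMeasurementSet]
    truth: dict

    def all_series(self) -> dict[str, list[ConditionData]]:
        return {"unseeded": self.unseeded, "seeded_5": self.seeded_5, "seeded_25": self.seeded_25}


def _series_spec(seed_fraction: float, tag: str, t_max: float, seed: int, noise_sd: float,
                 replicates: int, n_points: int) -> GeneratorSpec:
    conds = [
        ConditionSpec(
            label=f"{tag}/control",
            conditions=ReactionConditions(FIXTURE_M_TOTAL, seed_fraction, FIXTURE_SEED_LENGTH),
            modulator_ratio=0.0,
        )
    ]
    for ratio in sorted(FIXTURE_DOSE_FACTORS):
        conds.append(
            ConditionSpec(
                label=f"{tag}/tro_{ratio:g}",
                conditions=ReactionConditions(FIXTURE_M_TOTAL, seed_fraction, FIXTURE_SEED_LENGTH),
                modulator_ratio=ratio,
            )
        )
    factors = {
        f"{tag}/tro_{ratio:g}": f for ratio, f in FIXTURE_DOSE_FACTORS.items()
    }
    return GeneratorSpec(
        rates=FIXTURE_RATES,
        conditions=tuple(conds),
        perturbation=PerturbationHypothesis(target="k2_only", factors=factors),
        noise_sd=noise_sd,
        replicates=replicates,
        t_max=t_max,
        n_points=n_points,
        seed=seed,
    )


def dose_series_spec(
    seed_fraction: float,
    tag: str,
    t_max: float,
    seed: int = 0,
    noise_sd: float = 0.02,
    replicates: int = 3,
    n_points: int = 150,
) -> GeneratorSpec:
    """Generator spec for one modulator dose series at a given seed level.

    Conditions are a control plus the ratios {10:1, 5:1, 1:1} with the
    planted ``FIXTURE_DOSE_FACTORS`` on k2, labelled ``{tag}/control`` and
    ``{tag}/tro_<ratio>``.
    """
    return _series_spec(seed_fraction, tag, t_max, seed, noise_sd, replicates, n_points)


def make_reference_fixture(
    seed: int = 20,
    noise_sd: float = 0.02,
    replicates: int = 3,
    n_points: int = 150,
    n_fibrils: int = 100,
) -> FixtureBundle:
    """Build the canonical synthetic campaign.

    Unseeded, 5%- and 25%-seeded dose series at modulator ratios
    {10:1, 5:1, 1:1} with planted k2 fold-changes {1.5, 2.5, 5} (x5 at the
    equimolar condition), sigma = 0.02 noise, plus lognormal morphometry sets
    for control/treated lengths, heights and widths.
    """
    specs = {
        "unseeded": _series_spec(0.0, "unseeded", 3.0, seed, noise_sd, replicates, n_points),
        "seeded_5": _series_spec(0.05, "seeded_5", 2.0, seed + 1, noise_sd, replicates, n_points),
        "seeded_25": _series_spec(0.25, "seeded_25", 1.2, seed + 2, noise_sd, replicates, n_points),
    }
    series = {}
    truth = {"fixture_seed": seed, "series": {}}
    for name, sp in specs.items():
        data, t = generate_tht_traces(sp)
        series[name] = data
        truth["series"][name] = t
    morph = {}
    morph_truth = {}
    for i, name in enumerate(MORPHOMETRY_PRESETS):
        n = n_fibrils if "length" in name else 2 * n_fibrils
        morph[name] = fibril_preset(name, n=n, seed=seed + 10 + i)
        mean, log_sd, dimension, modality = MORPHOMETRY_PRESETS[name]
        morph_truth[name] = {
            "target_mean": mean, "log_sd": log_sd, "n": n,
            "dimension": dimension, "modality": modality, "seed": seed + 10 + i,
        }
    truth["morphometry"] = morph_truth
    truth["rng"] = RNG_ALGORITHM
    return FixtureBundle(
        unseeded=series["unseeded"],
        seeded_5=series["seeded_5"],
        seeded_25=series["seeded_25"],
        morphometry=morph,
        truth=truth,
    )
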