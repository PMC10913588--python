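"""Synthetic insured population with a linked, selectively responding health survey.

The generator emulates the statistical structure of administrative claims data
linked to a self-administered health survey:

* heavily right-skewed annual spending with a point mass at zero
  (zero-inflated lognormal);
* categorical risk-adjuster families (age-sex, region, a morbidity flag)
  that shift expected spending and are available for everyone;
* a single latent severity factor, *not* observable through the adjusters,
  that loads on both spending and the survey's self-reported chronic-condition
  flags — so the survey carries predictive signal for residual spending after
  risk equalization;
* health-dependent survey non-response (sicker people respond less), so the
  raw survey sample is unrepresentative and raking is exercised;
* a mortality proxy that inflates decedents' spending, used as a raking margin.

Every person carries ``true_group_effect``: the expected residual spending under
a correctly specified adjuster-only payment model.  It exists only so that tests
can recover known under/overcompensation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "AdjusterFamily",
    "SpendingParams",
    "GeneratorConfig",
    "ConfigurationError",
    "generate_population",
    "split_train_test",
    "condition_columns",
]


class ConfigurationError(ValueError):
    """Raised when a GeneratorConfig field is invalid; names the offending field."""


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class AdjusterFamily:
    """One categorical risk-adjuster family.

    ``class_probs`` are the population shares of each class (must sum to 1);
    ``class_effects`` are additive euro shifts of expected annual spending,
    one per class (the first class is the natural reference).
    """

    name: str
    class_probs: tuple[float, ...]
    class_effects: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.class_probs) != len(self.class_effects):
            raise ConfigurationError(
                f"adjuster_spec[{self.name}]: class_probs and class_effects lengths differ"
            )
        if len(self.class_probs) < 2:
            raise ConfigurationError(f"adjuster_spec[{self.name}]: needs >= 2 classes")
        if abs(sum(self.class_probs) - 1.0) > 1e-9 or min(self.class_probs) <= 0:
            raise ConfigurationError(
                f"adjuster_spec[{self.name}]: class_probs must be positive and sum to 1"
            )

    @property
    def labels(self) -> list[str]:
        return [f"{self.name}_{k}" for k in range(len(self.class_probs))]


def _default_adjusters() -> tuple[AdjusterFamily, ...]:
    # 10 age-sex cells, 4 regions, one pharmacy-like morbidity flag.
    agesex_probs = (0.12, 0.12, 0.11, 0.11, 0.10, 0.10, 0.10, 0.10, 0.07, 0.07)
    agesex_eff = (-900.0, -800.0, -600.0, -400.0, -100.0, 200.0, 700.0, 1200.0, 2200.0, 3500.0)
    return (
        AdjusterFamily("agesex", agesex_probs, agesex_eff),
        AdjusterFamily("region", (0.3, 0.3, 0.25, 0.15), (0.0, 50.0, -80.0, 120.0)),
        AdjusterFamily("morbidity", (0.85, 0.15), (0.0, 2500.0)),
    )


@dataclass(frozen=True)
class SpendingParams:
    """Zero-inflated lognormal spending: ``B * L`` with ``B ~ Bernoulli(1 - zero_mass)``
    and ``L`` lognormal with log-scale sd ``sigma``, location set per person so that
    the unconditional mean equals the person's expected spending."""

    base_mean: float = 2200.0  # euro, expected spending in all reference classes
    zero_mass: float = 0.20  # share with (near) zero annual spending
    sigma: float = 1.2  # lognormal log-scale sd
    floor: float = 50.0  # lower bound on expected spending before drawing
    mortality_multiplier: float = 5.0  # decedents' expected-spending multiplier


@dataclass(frozen=True)
class GeneratorConfig:
    n_population: int = 200_000
    survey_fraction: float = 0.30  # baseline response propensity
    seed: int = 0
    adjuster_spec: tuple[AdjusterFamily, ...] = field(default_factory=_default_adjusters)
    n_conditions: int = 23  # 19 "last 12 months" + 4 "ever" chronic conditions
    hidden_severity_sd: float = 750.0  # euro sd of latent severity missed by adjusters
    condition_loading: float | tuple[float, ...] = 0.9  # latent-factor loading on report logit
    condition_prevalence: float | tuple[float, ...] = 0.08
    condition_effects: float | tuple[float, ...] = 0.0  # direct euro effect of each flag
    spending_noise: SpendingParams = field(default_factory=SpendingParams)
    nonresponse_beta: float = 0.35  # response logit decrease per sd of latent severity
    mortality_rate: float = 0.01
    general_health_cut: float = 1.1  # latent-factor cutoff: above -> "fair_poor"

    def __post_init__(self) -> None:
        if self.n_population <= 0:
            raise ConfigurationError("n_population must be > 0")
        if not 0 < self.survey_fraction < 1:
            raise ConfigurationError("survey_fraction must be in (0, 1)")
        if self.hidden_severity_sd < 0:
            raise ConfigurationError("hidden_severity_sd must be >= 0")
        if not 0 <= self.mortality_rate <= 1:
            raise ConfigurationError("mortality_rate must be in [0, 1]")
        if self.n_conditions < 1:
            raise ConfigurationError("n_conditions must be >= 1")
        if not 0 <= self.spending_noise.zero_mass < 1:
            raise ConfigurationError("spending_noise.zero_mass must be in [0, 1)")
        for name in ("condition_loading", "condition_prevalence", "condition_effects"):
            val = getattr(self, name)
            if isinstance(val, tuple) and len(val) != self.n_conditions:
                raise ConfigurationError(f"{name}: length must equal n_conditions")
        prev = np.asarray(self._per_condition("condition_prevalence"))
        if np.any(prev <= 0) or np.any(prev >= 1):
            raise ConfigurationError("condition_prevalence must be in (0, 1)")

    def _per_condition(self, name: str) -> np.ndarray:
        val = getattr(self, name)
        if isinstance(val, tuple):
            return np.asarray(val, dtype=float)
        return np.full(self.n_conditions, float(val))

    def to_dict(self) -> dict:
        return asdict(self)


def condition_columns(n_conditions: int) -> list[str]:
    return [f"cond_{j:02d}" for j in range(n_conditions)]


def with_group_undercompensation(
    config: GeneratorConfig, j: int, delta: float, prevalence: float = 0.2
) -> GeneratorConfig:
    """Return a config where condition ``j`` carries a known expected residual.

    The flag is made independent of the latent factor (zero loading) with the
    given prevalence ``p`` and a direct spending effect ``delta / (1 - p)``, so
    that under a correctly specified adjuster-only payment model the flagged
    group's expected mean residual (its expected loss) is exactly ``delta``:
    the group's effect is ``delta/(1-p)`` while the population mean absorbs
    ``p * delta/(1-p)`` into the intercept.
    """
    import dataclasses

    load = list(config._per_condition("condition_loading"))
    prev = list(config._per_condition("condition_prevalence"))
    eff = list(config._per_condition("condition_effects"))
    load[j], prev[j], eff[j] = 0.0, prevalence, delta / (1.0 - prevalence)
    return dataclasses.replace(
        config,
        condition_loading=tuple(load),
        condition_prevalence=tuple(prev),
        condition_effects=tuple(eff),
    )


def expected_flag_gap(config: GeneratorConfig, j: int, n_mc: int = 400_000, seed: int = 12345) -> float:
    """Closed-form-by-quadrature expected spending gap (flag j carriers minus
    non-carriers), used as an oracle in tests.

    Carriers of flag j differ in expected spending through (a) the direct euro
    effect of the flag and (b) the latent factor, whose conditional mean given
    the flag is obtained by Monte-Carlo integration over the standard normal
    factor (independent of the seed used for the population itself).
    """
    rng = np.random.default_rng(seed)
    h = rng.standard_normal(n_mc)
    load = config._per_condition("condition_loading")[j]
    prev = config._per_condition("condition_prevalence")[j]
    eff = config._per_condition("condition_effects")[j]
    intercept = _condition_intercepts(np.array([load]), np.array([prev]))[0]
    p = _sigmoid(intercept + load * h)
    p_flag = p.mean()
    e_h_given_flag = (p * h).mean() / p_flag
    e_h_given_noflag = ((1 - p) * h).mean() / (1 - p_flag)
    return eff + config.hidden_severity_sd * (e_h_given_flag - e_h_given_noflag)


def _condition_intercepts(loadings: np.ndarray, prevalences: np.ndarray,
                          n_grid: int = 201) -> np.ndarray:
    """Logit intercepts so each condition's marginal prevalence matches the target,
    integrating the logistic over the standard-normal latent factor (Gauss-Hermite)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_grid)
    weights = weights / weights.sum()
    intercepts = np.empty_like(prevalences)
    for j, (b, p) in enumerate(zip(loadings, prevalences)):
        lo, hi = -20.0, 20.0
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            marg = float(np.dot(weights, _sigmoid(mid + b * nodes)))
            if marg < p:
                lo = mid
            else:
                hi = mid
        intercepts[j] = 0.5 * (lo + hi)
    return intercepts


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the person-level table. Deterministic given ``config.seed``.

    Columns: ``person_id``, one column per adjuster family, ``spending``,
    ``died``, ``survey_responded``, ``cond_XX`` flags and ``general_health``
    (non-null only for responders), ``weight`` (NaN until raking) and
    ``true_group_effect`` (generator-only ground truth).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_population

    df = pd.DataFrame({"person_id": np.arange(n, dtype=np.int64)})

    # Risk-adjuster classes and their additive euro effects.
    adjuster_effect = np.zeros(n)
    for fam in config.adjuster_spec:
        classes = rng.choice(len(fam.class_probs), size=n, p=np.asarray(fam.class_probs))
        df[fam.name] = pd.Categorical.from_codes(classes, categories=fam.labels)
        adjuster_effect += np.asarray(fam.class_effects)[classes]

    # Latent severity factor: standard normal, unobserved by the adjusters.
    h = rng.standard_normal(n)

    loadings = config._per_condition("condition_loading")
    prevalences = config._per_condition("condition_prevalence")
    effects = config._per_condition("condition_effects")
    intercepts = _condition_intercepts(loadings, prevalences)

    # Condition status exists for everyone; it is *observed* only via the survey.
    logits = intercepts[None, :] + h[:, None] * loadings[None, :]
    flags = rng.random((n, config.n_conditions)) < _sigmoid(logits)

    severity = config.hidden_severity_sd * h + flags @ effects
    df["true_group_effect"] = severity - severity.mean()

    died = rng.random(n) < config.mortality_rate
    df["died"] = died

    sp = config.spending_noise
    mean_spending = np.maximum(sp.base_mean + adjuster_effect + severity, sp.floor)
    mean_spending = np.where(died, mean_spending * sp.mortality_multiplier, mean_spending)
    p_use = 1.0 - sp.zero_mass
    any_use = rng.random(n) < p_use
    mu = np.log(mean_spending / p_use) - 0.5 * sp.sigma**2
    df["spending"] = np.where(any_use, np.exp(mu + sp.sigma * rng.standard_normal(n)), 0.0)

    # Health-dependent non-response: sicker (higher h) people respond less.
    base_logit = np.log(config.survey_fraction / (1 - config.survey_fraction))
    p_respond = _sigmoid(base_logit - config.nonresponse_beta * h)
    responded = rng.random(n) < p_respond
    df["survey_responded"] = responded

    fair_poor = (h + 0.35 * rng.standard_normal(n)) > config.general_health_cut
    gh = np.where(fair_poor, "fair_poor", "good")
    df["general_health"] = pd.Categorical(
        np.where(responded, gh, None), categories=["good", "fair_poor"]
    )
    for j, col in enumerate(condition_columns(config.n_conditions)):
        df[col] = pd.array(np.where(responded, flags[:, j], pd.NA), dtype="boolean")

    df["weight"] = np.nan
    return df


def split_train_test(
    survey: pd.DataFrame, train_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly split survey responders into disjoint, exhaustive train/test id sets.

    Returns ``(train_ids, test_ids)`` with ``len(train) = round(train_fraction * n)``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    responders = survey.loc[survey["survey_responded"], "person_id"].to_numpy()
    if responders.size == 0:
        raise ValueError("survey contains no responders")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(np.sort(responders))
    n_train = int(round(train_fraction * responders.size))
    n_train = min(max(n_train, 1), responders.size - 1)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
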