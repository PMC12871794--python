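"""Generative models for scale-dependence studies.

Two generators are provided:

* :func:`simulate_cohort` draws a cohort under the latent additive model

      Y' = G beta + E alpha + (G*E) gamma + eps,     eps ~ N(0, 1)

  where G is an n×m matrix of polygenic scores, and then maps the latent
  trait onto an observation scale (identity, exponential, or inverse-logit).
  The PGS and environment variance fractions (h², env_var) are exact by
  construction: with eps supplying the residual fraction, the total latent
  variance is 1/(1 - h² - env_var) and beta, alpha are scaled accordingly.

* :func:`simulate_genotype_cohort` draws an unlinked genotype panel
  (binomial dosages) with a phenotype built additively from known per-SNP
  effects, optionally group-specific (e.g. sex-specific architectures) and
  optionally exponentiated to produce a multiplicative, log-additive trait.

Both are deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.special

__all__ = [
    "OBSERVATION_SCALES",
    "SimulationConfig",
    "Cohort",
    "GenotypePanel",
    "apply_observation_scale",
    "simulate_cohort",
    "simulate_sign_flip_cohort",
    "filter_outliers",
    "simulate_genotype_cohort",
]

OBSERVATION_SCALES = ("identity", "exponential", "inverse_logit")

#: On the identity scale the latent Gaussian trait can be non-positive; the
#: default location shift places the sample minimum at least this many latent
#: standard deviations above zero so that power transforms are defined.
_IDENTITY_SHIFT_SDS = 6.0


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a PGS×E cohort.

    n_samples, n_pgs
        Cohort size N and number of polygenic score columns m.
    h2, env_var
        Fractions of the latent variance explained by the combined PGS term
        G·beta and by the environment term E·alpha.  Must satisfy
        ``h2 + env_var < 1``; the individual noise supplies the remainder.
    gamma
        Scalar interaction coefficient applied to every PGS column's
        product with E; 0 gives a purely additive latent trait.
    observation_scale
        Map from the latent to the observed trait: ``identity``,
        ``exponential`` (Y = exp(Y')), or ``inverse_logit``
        (Y = 1/(1+exp(-Y'))).
    env_dist, env_frequency
        Distribution of E: ``gaussian`` (standard normal, the default) or
        ``bernoulli`` with the given exposure frequency.  alpha is scaled by
        the theoretical variance of E so env_var is respected either way.
    location_shift
        Constant added to the latent trait before the observation map.
        ``None`` selects a default per scale: for ``identity`` a shift
        placing the minimum at ≥6 latent SD above zero (so Box-Cox is
        defined), and 0 otherwise.
    """

    n_samples: int
    n_pgs: int = 25
    h2: float = 0.3
    env_var: float = 0.2
    gamma: float = 0.0
    observation_scale: str = "identity"
    env_dist: str = "gaussian"
    env_frequency: float = 0.5
    location_shift: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_pgs < 1:
            raise ValueError("n_samples and n_pgs must be positive")
        if not (0 <= self.h2 < 1 and 0 <= self.env_var < 1):
            raise ValueError("h2 and env_var must lie in [0, 1)")
        if self.h2 + self.env_var >= 1:
            raise ValueError(
                f"h2 + env_var must be < 1, got {self.h2 + self.env_var}"
            )
        if self.observation_scale not in OBSERVATION_SCALES:
            raise ValueError(
                f"observation_scale must be one of {OBSERVATION_SCALES}, "
                f"got {self.observation_scale!r}"
            )
        if self.env_dist not in ("gaussian", "bernoulli"):
            raise ValueError("env_dist must be 'gaussian' or 'bernoulli'")
        if not 0 < self.env_frequency < 1:
            raise ValueError("env_frequency must lie in (0, 1)")
        if self.location_shift is not None and self.location_shift < 0:
            raise ValueError("location_shift must be nonnegative")

    @property
    def latent_total_var(self) -> float:
        """Total latent variance implied by var(eps)=1 supplying 1-h2-env_var."""
        return 1.0 / (1.0 - self.h2 - self.env_var)


@dataclass
class Cohort:
    """Sample-aligned data for one simulated cohort."""

    G: np.ndarray  # n × m PGS matrix
    E: np.ndarray  # length n environment
    y_latent: np.ndarray  # Y', the trait on the additive scale
    y_observed: np.ndarray  # Y = f(Y' + shift)
    true_beta: np.ndarray  # length m
    true_alpha: float
    true_gamma: float
    C: np.ndarray | None = None  # optional n × k covariates
    groups: np.ndarray | None = None  # optional group labels (e.g. sex)

    def __post_init__(self) -> None:
        n = len(self.y_latent)
        for name in ("G", "E", "y_observed", "C", "groups"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} is not sample-aligned (length {len(arr)} != {n})")

    @property
    def n_samples(self) -> int:
        return len(self.y_latent)

    @property
    def true_score(self) -> np.ndarray:
        """The oracle combined polygenic score G·beta."""
        return self.G @ self.true_beta


@dataclass
class GenotypePanel:
    """An unlinked dosage panel with its SNP map and true architecture.

    ``snp_map`` has columns snp, chr, bp, a1, a2, freq with 1-based,
    strictly increasing positions within each chromosome.  ``true_effects``
    maps a group label to its per-SNP effect vector; the label ``"all"`` is
    used when effects are shared.
    """

    dosages: np.ndarray  # n × p, entries in [0, 2]
    snp_map: pd.DataFrame
    true_effects: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        freqs = np.asarray(self.snp_map["freq"], dtype=float)
        if np.any((freqs <= 0) | (freqs >= 1)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        for _, sub in self.snp_map.groupby("chr"):
            bp = np.asarray(sub["bp"])
            if np.any(np.diff(bp) <= 0):
                raise ValueError("base-pair positions must be strictly increasing per chromosome")
        if self.dosages.shape[1] != len(self.snp_map):
            raise ValueError("dosage columns do not match the SNP map")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_map["snp"])


def apply_observation_scale(
    y_latent: np.ndarray,
    observation_scale: str,
    location_shift: float | None = None,
) -> tuple[np.ndarray, float]:
    """Map a latent trait onto an observation scale.

    Returns ``(y_observed, shift_used)``.  A ``location_shift`` of ``None``
    selects the per-scale default (see :class:`SimulationConfig`).  The
    result must be strictly positive (power transforms require Y > 0);
    otherwise a ``ValueError`` names the smallest offending value.
    """
    y_latent = np.asarray(y_latent, dtype=float)
    if observation_scale not in OBSERVATION_SCALES:
        raise ValueError(f"unknown observation scale {observation_scale!r}")
    if observation_scale == "inverse_logit":
        if location_shift not in (None, 0.0):
            raise ValueError("inverse_logit maps to (0,1); no location shift is applied")
        return scipy.special.expit(y_latent), 0.0
    if location_shift is None:
        if observation_scale == "identity":
            sd = float(np.std(y_latent))
            location_shift = max(0.0, _IDENTITY_SHIFT_SDS * sd - float(np.min(y_latent)))
        else:
            location_shift = 0.0
    shifted = y_latent + location_shift
    y_obs = shifted if observation_scale == "identity" else np.exp(shifted)
    if np.min(y_obs) <= 0:
        raise ValueError(
            "observed phenotype is not strictly positive after the location "
            f"shift (smallest value {np.min(y_obs):g}); Box-Cox requires Y > 0"
        )
    return y_obs, float(location_shift)


def _draw_environment(rng: np.random.Generator, config: SimulationConfig) -> tuple[np.ndarray, float]:
    """Draw E and return it with its theoretical variance."""
    if config.env_dist == "gaussian":
        return rng.standard_normal(config.n_samples), 1.0
    f = config.env_frequency
    e = rng.binomial(1, f, config.n_samples).astype(float)
    return e, f * (1.0 - f)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw one cohort under the latent PGS×E model.

    Columns of G and the noise are standard normal; beta is constant across
    columns with ``var(G beta) = h2 × total``, alpha satisfies
    ``var(E alpha) = env_var × total`` using the theoretical variance of E,
    and gamma multiplies every columnwise product G_j·E.  The observed trait
    is ``f(Y' + shift)`` per the configured observation scale.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_pgs
    total = config.latent_total_var

    G = rng.standard_normal((n, m))
    E, env_theoretical_var = _draw_environment(rng, config)
    eps = rng.standard_normal(n)

    beta = np.full(m, np.sqrt(config.h2 * total / m))
    alpha = float(np.sqrt(config.env_var * total / env_theoretical_var))

    y_latent = G @ beta + alpha * E + config.gamma * (G.sum(axis=1) * E) + eps
    y_observed, _ = apply_observation_scale(
        y_latent, config.observation_scale, config.location_shift
    )
    return Cohort(
        G=G,
        E=E,
        y_latent=y_latent,
        y_observed=y_observed,
        true_beta=beta,
        true_alpha=alpha,
        true_gamma=config.gamma,
    )


def simulate_sign_flip_cohort(
    n_samples: int,
    effect: float = 0.5,
    noise_sd: float = 1.0,
    observation_scale: str = "identity",
    seed: int = 0,
) -> Cohort:
    """A cohort whose PGS effect flips sign with a binary environment.

    The latent trait is ``Y' = effect × PGS × (2E - 1) + eps`` with
    E ~ Bernoulli(1/2): the score's effect is +effect when E=1 and -effect
    when E=0.  Because the effect's *sign* depends on E, the induced
    interaction survives every monotone rescaling of the trait — the
    canonical scale-independent (XOR-like) architecture.
    """
    rng = np.random.default_rng(seed)
    pgs = rng.standard_normal(n_samples)
    e = rng.binomial(1, 0.5, n_samples).astype(float)
    eps = noise_sd * rng.standard_normal(n_samples)
    y_latent = effect * pgs * (2.0 * e - 1.0) + eps
    y_observed, _ = apply_observation_scale(y_latent, observation_scale)
    return Cohort(
        G=pgs[:, None],
        E=e,
        y_latent=y_latent,
        y_observed=y_observed,
        true_beta=np.array([-effect]),
        true_alpha=0.0,
        true_gamma=2.0 * effect,
    )


def filter_outliers(y, tail_fraction: float) -> np.ndarray:
    """Indices of samples retained after symmetric quantile-tail exclusion.

    Excludes samples strictly below the ``tail_fraction`` empirical quantile
    or strictly above the ``1 - tail_fraction`` quantile (linear-interpolation
    quantiles).  ``tail_fraction=0`` retains everything; the operation is
    idempotent at a fixed fraction.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype must be finite")
    if not 0 <= tail_fraction < 0.5:
        raise ValueError("tail_fraction must lie in [0, 0.5)")
    lo, hi = np.quantile(y, [tail_fraction, 1.0 - tail_fraction])
    keep = np.flatnonzero((y >= lo) & (y <= hi))
    if keep.size == 0:
        raise ValueError("outlier filter retained no samples")
    return keep


def simulate_genotype_cohort(
    n_samples: int,
    n_snps: int,
    effects=None,
    freqs=None,
    freq_range: tuple[float, float] = (0.05, 0.95),
    group_fractions: Mapping[str, float] | None = None,
    noise_sd: float = 1.0,
    multiplicative: bool = False,
    intercept: float = 0.0,
    chrom: int = 1,
    spacing_bp: int = 50_000,
    seed: int = 0,
) -> tuple[GenotypePanel, Cohort]:
    """Draw an unlinked genotype panel and a phenotype with known architecture.

    Dosages are Binomial(2, freq) per SNP (frequencies given explicitly or
    drawn uniformly from ``freq_range``).  The latent trait is
    ``intercept + D·b + noise`` where ``b`` is either a shared effect vector
    or, when ``effects`` is a mapping of group label to vector, the effect
    vector of each sample's group (groups assigned by ``group_fractions``,
    default an even split).  With ``multiplicative=True`` the observed trait
    is ``exp(Y')`` — a log-additive phenotype; otherwise it is Y' itself.

    Returns the panel and a :class:`Cohort` sharing sample order (the
    cohort's G holds the n×1 oracle genetic score).
    """
    if n_samples < 1 or n_snps < 1:
        raise ValueError("n_samples and n_snps must be positive")
    rng = np.random.default_rng(seed)

    if freqs is None:
        lo, hi = freq_range
        if not 0 < lo <= hi < 1:
            raise ValueError("freq_range must lie strictly inside (0, 1)")
        freqs = rng.uniform(lo, hi, n_snps)
    else:
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (n_snps,):
            raise ValueError("freqs must have length n_snps")
        if np.any((freqs <= 0) | (freqs >= 1)):
            raise ValueError(
                "monomorphic SNP requested (frequency 0 or 1); frequencies must lie in (0, 1)"
            )

    dosages = rng.binomial(2, freqs, size=(n_samples, n_snps)).astype(float)
    snp_map = pd.DataFrame(
        {
            "snp": [f"snp{i + 1}" for i in range(n_snps)],
            "chr": chrom,
            "bp": np.arange(1, n_snps + 1, dtype=int) * int(spacing_bp),
            "a1": "A",
            "a2": "G",
            "freq": freqs,
        }
    )

    if effects is None:
        effects = np.zeros(n_snps)
    if isinstance(effects, Mapping):
        effect_map = {g: np.asarray(b, dtype=float) for g, b in effects.items()}
        labels = list(effect_map)
        if group_fractions is None:
            probs = np.full(len(labels), 1.0 / len(labels))
        else:
            probs = np.array([group_fractions[g] for g in labels], dtype=float)
            probs = probs / probs.sum()
        groups = rng.choice(labels, size=n_samples, p=probs)
        genetic = np.empty(n_samples)
        for g, b in effect_map.items():
            if b.shape != (n_snps,):
                raise ValueError(f"effect vector for group {g!r} must have length n_snps")
            mask = groups == g
            genetic[mask] = dosages[mask] @ b
    else:
        effect_map = {"all": np.asarray(effects, dtype=float)}
        if effect_map["all"].shape != (n_snps,):
            raise ValueError("effects must have length n_snps")
        groups = None
        genetic = dosages @ effect_map["all"]

    noise = noise_sd * rng.standard_normal(n_samples) if noise_sd > 0 else 0.0
    y_latent = intercept + genetic + noise
    y_observed = np.exp(y_latent) if multiplicative else y_latent.copy()

    panel = GenotypePanel(dosages=dosages, snp_map=snp_map, true_effects=effect_map)
    cohort = Cohort(
        G=genetic[:, None],
        E=np.zeros(n_samples),
        y_latent=y_latent,
        y_observed=y_observed,
        true_beta=np.array([1.0]),
        true_alpha=0.0,
        true_gamma=0.0,
        groups=groups,
    )
    return panel, cohort
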