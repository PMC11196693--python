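"""Hierarchical synthetic leaf-trait data with known ground truth.

The generator builds a species-by-site table from an explicit generative
model on the log scale:

    log x_ij = a_i + beta_i * m_j + f(E_j) + eps_ij

where ``m_j`` is a latent site gradient, ``a_i`` a species baseline
(optionally coupled to the species' niche position to emulate environmental
filtering), ``beta_i`` a species-specific plasticity slope, ``f(E_j)`` the
summed effects of named environmental covariates (linear or a threshold
interaction of two covariates) and ``eps_ij`` residual noise.  Concentrations
are exponentiated so all values are positive and the downstream log transform
recovers the linear structure exactly.

Species either occupy contiguous windows of the sorted gradient (niche
filtering) or a random subset of sites.  The returned :class:`GroundTruth`
records the realized slopes, within-species variance fractions, informative
covariates and the gradient itself, so every downstream statistic has a
parameter-recovery test.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._random import stream
from .dataset import Dataset


class ConfigError(ValueError):
    """The synthetic configuration is internally inconsistent."""


@dataclass
class TraitParams:
    """Generative parameters for one trait on the log scale.

    ``mu_log`` is the grand mean of log concentration, ``sigma_species`` the
    SD of species baselines (across-species variation), ``sigma_resid`` the
    residual SD (within-species noise), and ``slope_mean``/``slope_sd`` the
    normal distribution of true plasticity slopes beta_i (sd 0 = point mass).
    """

    mu_log: float = 3.0
    sigma_species: float = 0.3
    sigma_resid: float = 0.1
    slope_mean: float = 1.0
    slope_sd: float = 0.0


@dataclass
class CovariateSpec:
    """One named site-level covariate and its effect on the traits.

    ``source="independent"`` draws standard-normal site values; ``"gradient"``
    exposes the latent gradient itself as a measurable covariate.  Effects are
    additive on the log trait: ``form="linear"`` contributes ``effect * E_j``;
    ``form="threshold"`` contributes ``effect * sign(E_j * E_partner_j)``, a
    pure interaction with zero linear projection on either covariate.
    """

    name: str
    informative: bool = False
    effect_n: float = 0.0
    effect_p: float = 0.0
    form: str = "linear"
    partner: str | None = None
    source: str = "independent"


@dataclass
class SyntheticConfig:
    """Full specification of one synthetic dataset."""

    n_species: int = 40
    n_sites: int = 80
    occupancy: float | int = 1.0  # fraction -> niche-window width; int -> sites per species
    occupancy_mode: str = "window"  # "window" (contiguous in gradient) or "random"
    gradient_sd: float = 1.0
    baseline_coupling: float = 0.0  # species baseline tracks its niche centre this strongly
    leaf_n: TraitParams = field(default_factory=TraitParams)
    leaf_p: TraitParams = field(default_factory=lambda: TraitParams(mu_log=0.4, sigma_species=0.3, sigma_resid=0.1))
    covariates: list[CovariateSpec] = field(default_factory=list)
    seed: int = 0

    def sites_per_species(self) -> int:
        if isinstance(self.occupancy, (int, np.integer)) and not isinstance(self.occupancy, bool):
            return int(self.occupancy)
        return max(2, int(round(float(self.occupancy) * self.n_sites)))

    def validate(self) -> None:
        if self.n_species < 1 or self.n_sites < 1:
            raise ConfigError("n_species and n_sites must be >= 1")
        if self.leaf_n.sigma_species < 0 or self.leaf_n.sigma_resid < 0:
            raise ConfigError("standard deviations must be >= 0")
        k = self.sites_per_species()
        if k < 1 or k > self.n_sites:
            raise ConfigError(
                f"occupancy requires {k} sites per species but only {self.n_sites} sites exist"
            )
        if self.occupancy_mode not in ("window", "random"):
            raise ConfigError(f"unknown occupancy_mode {self.occupancy_mode!r}")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate covariate names")
        for c in self.covariates:
            if c.form == "threshold" and (c.partner is None or c.partner not in names):
                raise ConfigError(f"threshold covariate {c.name!r} needs a valid partner")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Realized generative quantities for parameter-recovery tests.

    ``true_within_fraction`` is the realized within-species share of the
    total log-trait sum of squares (computed from the sample, not from the
    asymptotic sigmas).
    """

    true_slopes: dict[str, dict[str, float]]  # trait -> species -> beta_i
    true_within_fraction: dict[str, float]  # trait -> fraction in [0, 1]
    true_informative_set: list[str]
    site_gradient: dict[str, float]  # site_id -> m_j

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _within_fraction(values: np.ndarray, species: np.ndarray) -> float:
    df = pd.DataFrame({"v": values, "s": species})
    total = ((df["v"] - df["v"].mean()) ** 2).sum()
    within = ((df["v"] - df.groupby("s")["v"].transform("mean")) ** 2).sum()
    return float(within / total) if total > 0 else 0.0


def generate(config: SyntheticConfig) -> tuple[Dataset, GroundTruth]:
    """Draw one dataset (and its ground truth) from the generative model."""
    config.validate()
    seed = config.seed
    n_sp, n_si = config.n_species, config.n_sites
    k = config.sites_per_species()

    site_ids = np.array([f"S{j:04d}" for j in range(n_si)])
    species_ids = np.array([f"sp{i:04d}" for i in range(n_sp)])
    m = stream(seed, "gradient").normal(0.0, config.gradient_sd, n_si)

    # occupancy: which sites each species is observed at
    occ_rng = stream(seed, "occupancy")
    order = np.argsort(m)
    occupied: list[np.ndarray] = []
    for i in range(n_sp):
        if config.occupancy_mode == "window":
            start = int(occ_rng.integers(0, n_si - k + 1))
            occupied.append(order[start : start + k])
        else:
            occupied.append(occ_rng.choice(n_si, size=k, replace=False))

    # site-level covariates
    cov_values: dict[str, np.ndarray] = {}
    for c in config.covariates:
        if c.source == "gradient":
            cov_values[c.name] = m.copy()
        else:
            cov_values[c.name] = stream(seed, f"cov_{c.name}").normal(0.0, 1.0, n_si)

    def env_effect(trait: str) -> np.ndarray:
        total = np.zeros(n_si)
        for c in config.covariates:
            eff = c.effect_n if trait == "leaf_n" else c.effect_p
            if eff == 0.0:
                continue
            if c.form == "linear":
                total += eff * cov_values[c.name]
            elif c.form == "threshold":
                total += eff * np.sign(cov_values[c.name] * cov_values[c.partner])
            else:
                raise ConfigError(f"unknown covariate form {c.form!r}")
        return total

    niche_centre = np.array([m[occ].mean() for occ in occupied])

    log_traits: dict[str, np.ndarray] = {}
    slopes: dict[str, np.ndarray] = {}
    rows_i = np.concatenate([np.full(len(occ), i) for i, occ in enumerate(occupied)])
    rows_j = np.concatenate(occupied)
    for trait, params in (("leaf_n", config.leaf_n), ("leaf_p", config.leaf_p)):
        a = (
            params.mu_log
            + config.baseline_coupling * niche_centre
            + params.sigma_species * stream(seed, f"baseline_{trait}").normal(size=n_sp)
        )
        beta = params.slope_mean + params.slope_sd * stream(seed, f"slope_{trait}").normal(size=n_sp)
        eps = params.sigma_resid * stream(seed, f"resid_{trait}").normal(size=len(rows_i))
        g = env_effect(trait)
        log_traits[trait] = a[rows_i] + beta[rows_i] * m[rows_j] + g[rows_j] + eps
        slopes[trait] = beta

    df = pd.DataFrame(
        {
            "record_id": [f"r{i:06d}" for i in range(len(rows_i))],
            "species": species_ids[rows_i],
            "genus": np.array([f"g{i // 4:03d}" for i in rows_i]),
            "family": np.array([f"f{i // 16:03d}" for i in rows_i]),
            "site_id": site_ids[rows_j],
            "leaf_n": np.exp(log_traits["leaf_n"]),
            "leaf_p": np.exp(log_traits["leaf_p"]),
        }
    )
    df["np_ratio"] = df["leaf_n"] / df["leaf_p"]
    for name, vals in cov_values.items():
        df[name] = vals[rows_j]

    truth = GroundTruth(
        true_slopes={
            t: {str(s): float(b) for s, b in zip(species_ids, slopes[t])} for t in slopes
        },
        true_within_fraction={
            t: _within_fraction(log_traits[t], rows_i) for t in log_traits
        },
        true_informative_set=[c.name for c in config.covariates if c.informative],
        site_gradient={str(s): float(v) for s, v in zip(site_ids, m)},
    )
    ds = Dataset(
        df,
        covariate_names=list(cov_values.keys()),
        provenance=[f"synthetic: {n_sp} species x {n_si} sites, seed {seed}"],
    )
    return ds, truth


def _noise_covariates(n: int, start: int = 1) -> list[CovariateSpec]:
    return [CovariateSpec(name=f"noise{start + i:02d}") for i in range(n)]


def make_scenario(name: str, seed: int = 0) -> SyntheticConfig:
    """Named study conditions used throughout the tests and examples.

    ``fig1a_niche``
        Flat species (slope 0) in narrow niche windows whose baselines track
        the gradient: all large-scale trait variation comes from species
        turnover (the fixed-stoichiometry / niche-filtering world).
    ``fig1b_plastic``
        Fully plastic species (slope 1) occupying all sites; the gradient is
        exposed as a measurable covariate, so site means are a linear
        function of it.
    ``rf_vs_lm_nonlinear``
        Within-species environmental signal is a threshold interaction of two
        covariates with zero linear projection: detectable by a random forest,
        invisible to a linear model.
    ``icc_recovery``
        Pure random-intercept structure (no gradient tracking, no covariate
        effects) with equal across/within variance for mixed-model recovery.
    ``rfe_signal``
        Three informative linear covariates hidden among nine pure-noise
        columns for feature-elimination tests.
    """
    if name == "fig1a_niche":
        return SyntheticConfig(
            n_species=60,
            n_sites=80,
            occupancy=0.15,
            occupancy_mode="window",
            baseline_coupling=1.0,
            leaf_n=TraitParams(mu_log=3.0, sigma_species=0.12, sigma_resid=0.08, slope_mean=0.0),
            leaf_p=TraitParams(mu_log=0.4, sigma_species=0.12, sigma_resid=0.08, slope_mean=0.0),
            covariates=[CovariateSpec("env1", informative=True, source="gradient")],
            seed=seed,
        )
    if name == "fig1b_plastic":
        return SyntheticConfig(
            n_species=40,
            n_sites=60,
            occupancy=1.0,
            leaf_n=TraitParams(mu_log=3.0, sigma_species=0.3, sigma_resid=0.05, slope_mean=1.0),
            leaf_p=TraitParams(mu_log=0.4, sigma_species=0.3, sigma_resid=0.05, slope_mean=1.0),
            covariates=[CovariateSpec("env1", informative=True, source="gradient")],
            seed=seed,
        )
    if name == "rf_vs_lm_nonlinear":
        return SyntheticConfig(
            n_species=50,
            n_sites=60,
            occupancy=1.0,
            leaf_n=TraitParams(mu_log=3.0, sigma_species=0.3, sigma_resid=0.15, slope_mean=0.0),
            leaf_p=TraitParams(mu_log=0.4, sigma_species=0.3, sigma_resid=0.15, slope_mean=0.0),
            covariates=[
                CovariateSpec("env_a", informative=True, effect_n=0.3, effect_p=0.3,
                              form="threshold", partner="env_b"),
                CovariateSpec("env_b", informative=True),
                *_noise_covariates(2),
            ],
            seed=seed,
        )
    if name == "icc_recovery":
        s = np.sqrt(0.5)
        return SyntheticConfig(
            n_species=200,
            n_sites=200,
            occupancy=10,
            occupancy_mode="random",
            leaf_n=TraitParams(mu_log=3.0, sigma_species=s, sigma_resid=s, slope_mean=0.0),
            leaf_p=TraitParams(mu_log=0.4, sigma_species=s, sigma_resid=s, slope_mean=0.0),
            seed=seed,
        )
    if name == "rfe_signal":
        return SyntheticConfig(
            n_species=40,
            n_sites=80,
            occupancy=1.0,
            leaf_n=TraitParams(mu_log=3.0, sigma_species=0.2, sigma_resid=0.15, slope_mean=0.0),
            leaf_p=TraitParams(mu_log=0.4, sigma_species=0.2, sigma_resid=0.15, slope_mean=0.0),
            covariates=[
                CovariateSpec("sig_a", informative=True, effect_n=0.40, effect_p=0.40),
                CovariateSpec("sig_b", informative=True, effect_n=0.30, effect_p=0.30),
                CovariateSpec("sig_c", informative=True, effect_n=0.20, effect_p=0.20),
                *_noise_covariates(9),
            ],
            seed=seed,
        )
    raise ValueError(f"unknown scenario {name!r}")
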