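"""Trait gradient analysis: species-level regressions against community means.

For each species i, the trait values x_ij observed at its sites are regressed
(OLS, on the natural-log scale) on the site-mean trait values x̄_j computed
across all species sampled at site j.  The slope b_i measures how much the
species tracks the community-level gradient: 0 means a fixed trait
(environmental filtering only), 1 means the species varies in lockstep with
the site mean (full plasticity), >1 an over-expressed response.

The module also computes each species' occurrence range R_i (the 1-99%
quantile spread of original-scale site means over its sites, normalized by
the overall 1-99% range so ranges are comparable across traits), the mode of
the slope density (Gaussian KDE, Silverman bandwidth), and the species
variation decomposition: R^2 between the observed values and each of two
modified datasets holding only across-species or only within-species
variation.  Those two R^2 values sum to one — they are the between- and
within-group shares of the total sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import (
    TRAITS,
    Dataset,
    filter_occurrence,
    log_transform,
    normalize_to_global_mean,
    replace_with_species_means,
)


def tga_site_means(ds: Dataset, trait: str) -> pd.Series:
    """Per-site arithmetic mean of the trait values (focal species included).

    Expects the dataset on the scale the regression will use (log scale for
    the standard analysis) and already occurrence-filtered.
    """
    return ds.df.groupby("site_id")[trait].mean()


@dataclass
class TGAFit:
    """OLS fit of one species' trait values against site means."""

    species: str
    trait: str
    slope: float
    intercept: float
    slope_se: float
    ci95: tuple[float, float]
    n_points: int


def fit_species_regressions(ds: Dataset, trait: str, min_points: int = 2) -> list[TGAFit]:
    """Per-species OLS of x_ij on the site mean x̄_j.

    Species with fewer than ``min_points`` records or with constant site
    means are skipped (their slope is undefined).  The dataset should already
    be occurrence-filtered and log-transformed.
    """
    site_means = tga_site_means(ds, trait)
    df = ds.df.assign(_xbar=ds.df["site_id"].map(site_means))
    fits: list[TGAFit] = []
    for species, grp in df.groupby("species", sort=True):
        x = grp["_xbar"].to_numpy(float)
        y = grp[trait].to_numpy(float)
        if len(x) < max(2, min_points) or np.ptp(x) < 1e-12:
            continue
        res = stats.linregress(x, y)
        n = len(x)
        if n > 2:
            tcrit = stats.t.ppf(0.975, n - 2)
            ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
        else:
            ci = (-np.inf, np.inf)
        fits.append(
            TGAFit(str(species), trait, float(res.slope), float(res.intercept),
                   float(res.stderr), (float(ci[0]), float(ci[1])), n)
        )
    return fits


def slope_distribution(slopes, grid_size: int = 512) -> tuple[float, pd.DataFrame]:
    """Mode and density curve of the slope distribution.

    Gaussian KDE with Silverman bandwidth evaluated on a ``grid_size``-point
    grid spanning [min - bw, max + bw]; the mode is the grid argmax.  A
    degenerate sample (all slopes equal) returns that value with a
    single-point density.
    """
    s = np.asarray(slopes, float)
    if len(s) == 0:
        raise ValueError("no slopes to summarize")
    if np.ptp(s) < 1e-12:
        return float(s[0]), pd.DataFrame({"slope": [s[0]], "density": [np.inf]})
    kde = stats.gaussian_kde(s, bw_method="silverman")
    bw = float(kde.factor * s.std(ddof=1))
    grid = np.linspace(s.min() - bw, s.max() + bw, grid_size)
    density = kde(grid)
    mode = float(grid[int(np.argmax(density))])
    return mode, pd.DataFrame({"slope": grid, "density": density})


def species_ranges(
    ds_raw: Dataset, trait: str, norm: str = "range"
) -> pd.DataFrame:
    """Occurrence ranges: 1-99% quantile spread of site means per species.

    Computed on the original (not log) scale.  ``range_norm`` divides by the
    overall 1-99% range of all site means (``norm="range"``); ``norm="mean"``
    divides by the overall mean of site means instead.  Quantiles use linear
    interpolation between order statistics.
    """
    if norm not in ("range", "mean"):
        raise ValueError(f"unknown normalization {norm!r}")
    site_means = tga_site_means(ds_raw, trait)
    all_means = site_means.to_numpy(float)
    overall = (
        float(np.quantile(all_means, 0.99) - np.quantile(all_means, 0.01))
        if norm == "range"
        else float(all_means.mean())
    )
    rows = []
    df = ds_raw.df.assign(_xbar=ds_raw.df["site_id"].map(site_means))
    for species, grp in df.groupby("species", sort=True):
        vals = grp.drop_duplicates("site_id")["_xbar"].to_numpy(float)
        raw = float(np.quantile(vals, 0.99) - np.quantile(vals, 0.01))
        rows.append(
            {"species": str(species), "trait": trait, "range_raw": raw,
             "range_norm": raw / overall if overall > 0 else np.nan}
        )
    return pd.DataFrame(rows)


def range_correlations(ranges_by_trait: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Pearson r between species' normalized ranges across traits."""
    rows = []
    traits = list(ranges_by_trait)
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            merged = ranges_by_trait[a].merge(ranges_by_trait[b], on="species", suffixes=("_a", "_b"))
            ra = merged["range_norm_a"].to_numpy(float)
            rb = merged["range_norm_b"].to_numpy(float)
            if len(merged) < 2 or np.ptp(ra) < 1e-12 or np.ptp(rb) < 1e-12:
                r, p = np.nan, np.nan  # degenerate: ranges constant across species
            else:
                r, p = stats.pearsonr(ra, rb)
            rows.append({"trait_a": a, "trait_b": b, "pearson_r": float(r),
                         "p_value": float(p), "n_species": len(merged)})
    return pd.DataFrame(rows)


@dataclass
class SpeciesVariationResult:
    """Across- vs within-species share of total trait variation.

    ``r2_across`` is the squared correlation of observed values with the
    species-mean-replaced series (= between-species SS / total SS);
    ``r2_within`` with the global-mean-recentered series (= within-species
    SS / total SS).  When both are defined they sum to one.
    """

    trait: str
    r2_across: float
    r2_within: float
    global_mean: float
    n_records: int
    n_species: int
    across_degenerate: bool = False
    within_degenerate: bool = False


def species_variation_decomposition(ds: Dataset, trait: str) -> SpeciesVariationResult:
    """Decompose total variation into across- and within-species shares.

    Expects the analysis-scale (log) dataset.  A modification with zero
    variance (e.g., no within-species variation at all) yields R^2 = 0 for
    that component with a degeneracy flag.  A single-species dataset has no
    across-species component and raises.
    """
    if ds.n_species < 2:
        raise ValueError("species variation decomposition needs >= 2 species")
    obs = ds.df[trait].to_numpy(float)
    across = replace_with_species_means(ds, traits=[trait]).df[trait].to_numpy(float)
    within = normalize_to_global_mean(ds, traits=[trait]).df[trait].to_numpy(float)

    def r2(modified: np.ndarray) -> tuple[float, bool]:
        if np.var(modified) < 1e-14 * max(1.0, np.var(obs)):
            return 0.0, True
        r, _ = stats.pearsonr(obs, modified)
        return float(r**2), False

    r2_across, deg_a = r2(across)
    r2_within, deg_w = r2(within)
    if deg_a and not deg_w:
        r2_within = 1.0
    if deg_w and not deg_a:
        r2_across = 1.0
    return SpeciesVariationResult(
        trait=trait,
        r2_across=r2_across,
        r2_within=r2_within,
        global_mean=float(obs.mean()),
        n_records=len(obs),
        n_species=ds.n_species,
        across_degenerate=deg_a,
        within_degenerate=deg_w,
    )


@dataclass
class TGAResult:
    """Full trait-gradient analysis for one or more traits."""

    fits: pd.DataFrame  # one row per species x trait
    slope_modes: dict[str, float]
    slope_densities: dict[str, pd.DataFrame]
    ranges: dict[str, pd.DataFrame]
    range_medians: dict[str, float]
    range_corr: pd.DataFrame
    decomposition: dict[str, SpeciesVariationResult]
    filter_report: object = None

    def slopes(self, trait: str) -> np.ndarray:
        sub = self.fits[self.fits["trait"] == trait]
        return sub["slope"].to_numpy(float)

    def summary(self) -> dict:
        return {
            "slope_modes": self.slope_modes,
            "range_medians": self.range_medians,
            "range_correlations": self.range_corr.to_dict(orient="records"),
            "decomposition": {
                t: {"r2_across": d.r2_across, "r2_within": d.r2_within,
                    "n_records": d.n_records, "n_species": d.n_species}
                for t, d in self.decomposition.items()
            },
            "n_fits": int(len(self.fits)),
        }


def run_tga(
    ds_raw: Dataset,
    traits=TRAITS,
    min_sites_per_species: int = 5,
    min_species_per_site: int = 5,
    iterate_filter: bool = False,
    norm: str = "range",
) -> TGAResult:
    """Occurrence-filter, log-transform and run the full trait gradient analysis.

    ``ds_raw`` is the original-scale dataset (already N:P-filtered upstream).
    Regressions and the species variation decomposition run on the log scale;
    occurrence ranges on the original scale, both on the filtered subset.
    """
    filtered, report = filter_occurrence(
        ds_raw, min_sites_per_species, min_species_per_site, iterate=iterate_filter
    )
    logged = log_transform(filtered, traits=traits)

    fit_rows = []
    modes, densities, ranges, medians, decomp = {}, {}, {}, {}, {}
    for trait in traits:
        fits = fit_species_regressions(logged, trait)
        for f in fits:
            fit_rows.append(
                {"species": f.species, "trait": trait, "slope": f.slope,
                 "intercept": f.intercept, "slope_se": f.slope_se,
                 "ci_low": f.ci95[0], "ci_high": f.ci95[1], "n_points": f.n_points}
            )
        modes[trait], densities[trait] = slope_distribution([f.slope for f in fits])
        ranges[trait] = species_ranges(filtered, trait, norm=norm)
        medians[trait] = float(ranges[trait]["range_norm"].median())
        decomp[trait] = species_variation_decomposition(logged, trait)

    return TGAResult(
        fits=pd.DataFrame(fit_rows),
        slope_modes=modes,
        slope_densities=densities,
        ranges=ranges,
        range_medians=medians,
        range_corr=range_correlations(ranges),
        decomposition=decomp,
        filter_report=report,
    )
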