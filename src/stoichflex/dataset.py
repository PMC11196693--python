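"""Species-by-site leaf trait tables: I/O, quality filters, transforms, aggregation.

The central container is :class:`Dataset`, a thin wrapper around a pandas
DataFrame with one row per leaf sample (one species observed at one site),
the three stoichiometric traits (leaf N, leaf P in mg g^-1 and the
dimensionless N:P ratio) and any number of named environmental covariate
columns.  Every filter and transform returns a new :class:`Dataset` and
appends a line to its provenance log, so an analysis dataset carries a
readable record of how it was produced.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

TRAITS = ("leaf_n", "leaf_p", "np_ratio")
MANDATORY_COLUMNS = ("species", "site_id", "leaf_n", "leaf_p")
STANDARD_COLUMNS = (
    "record_id",
    "species",
    "genus",
    "family",
    "site_id",
    "year",
    "leaf_n",
    "leaf_p",
    "np_ratio",
)


class SchemaError(ValueError):
    """The input table lacks a mandatory column or maps one incorrectly."""


class ParseError(ValueError):
    """A trait cell could not be interpreted as a number."""


class EmptyResultError(ValueError):
    """A filter removed every record."""


@dataclass
class FilterReport:
    """Outcome of one filtering rule applied to a dataset."""

    rule: str
    n_input: int
    n_removed: int
    removed_ids: list

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "rule": self.rule,
                "n_input": self.n_input,
                "n_removed": self.n_removed,
                "fraction_removed": self.fraction_removed,
                "removed_ids": [str(i) for i in self.removed_ids],
            }
        )


@dataclass
class TransformResult:
    """A fitted monotone transform of one value series."""

    name: str
    values: np.ndarray
    lmbda: float | None = None


@dataclass
class Dataset:
    """One row per leaf sample plus named environmental covariates.

    Parameters
    ----------
    df
        Table with the standard columns (``record_id, species, genus, family,
        site_id, year, leaf_n, leaf_p, np_ratio``; some optional) plus one
        numeric column per covariate.
    covariate_names
        Ordered names of the covariate columns.
    provenance
        Free-text log of the filters/transforms that produced this dataset.
    """

    df: pd.DataFrame
    covariate_names: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def n_species(self) -> int:
        return self.df["species"].nunique()

    @property
    def n_sites(self) -> int:
        return self.df["site_id"].nunique()

    def copy(self) -> "Dataset":
        return Dataset(self.df.copy(), list(self.covariate_names), list(self.provenance))

    def _derive(self, df: pd.DataFrame, note: str) -> "Dataset":
        return Dataset(df, list(self.covariate_names), self.provenance + [note])


def _ensure_record_ids(df: pd.DataFrame) -> pd.DataFrame:
    if "record_id" not in df.columns:
        df = df.copy()
        df.insert(0, "record_id", [f"r{i:06d}" for i in range(len(df))])
    return df


def read_dataset(path, schema: dict[str, str] | None = None) -> Dataset:
    """Read a leaf-trait CSV into a :class:`Dataset`.

    Parameters
    ----------
    path
        CSV file with a header row, UTF-8, "." decimal separator.
    schema
        Optional map from canonical column names (``species``, ``site_id``,
        ``leaf_n``, ``leaf_p``, ...) to the column names used in the file.

    Every numeric column not among the standard ones is treated as an
    environmental covariate.  ``np_ratio`` is computed as ``leaf_n/leaf_p``
    where absent.
    """
    raw = pd.read_csv(path)
    if schema:
        rename = {v: k for k, v in schema.items()}
        raw = raw.rename(columns=rename)
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")
    for col in ("leaf_n", "leaf_p", "np_ratio"):
        if col not in raw.columns:
            continue
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"non-numeric value {raw[col].iloc[idx]!r} in column {col!r} at row {idx}")
        raw[col] = coerced
    if (raw["leaf_n"] <= 0).any() or (raw["leaf_p"] <= 0).any():
        bad = raw.index[(raw["leaf_n"] <= 0) | (raw["leaf_p"] <= 0)][0]
        raise ValueError(f"non-positive leaf concentration at row {bad}; concentrations must be > 0")
    raw = _ensure_record_ids(raw)
    if "np_ratio" not in raw.columns:
        raw["np_ratio"] = raw["leaf_n"] / raw["leaf_p"]
    else:
        missing = raw["np_ratio"].isna()
        raw.loc[missing, "np_ratio"] = raw.loc[missing, "leaf_n"] / raw.loc[missing, "leaf_p"]
        expected = raw["leaf_n"] / raw["leaf_p"]
        rel = np.abs(raw["np_ratio"] - expected) / np.abs(expected)
        if (rel > 1e-6).any():
            warnings.warn(
                f"{int((rel > 1e-6).sum())} rows have np_ratio inconsistent with leaf_n/leaf_p "
                "(rel. tol. 1e-6); stated values kept",
                stacklevel=2,
            )
    covariates = [
        c
        for c in raw.columns
        if c not in STANDARD_COLUMNS and pd.api.types.is_numeric_dtype(raw[c])
    ]
    return Dataset(raw.reset_index(drop=True), covariates, [f"read {len(raw)} records from {path}"])


def write_dataset(ds: Dataset, path) -> None:
    """Write the dataset back to CSV (full float precision, round-trip safe)."""
    cols = [c for c in STANDARD_COLUMNS if c in ds.df.columns] + list(ds.covariate_names)
    ds.df[cols].to_csv(path, index=False)


def filter_np_outliers(ds: Dataset, threshold: float = 70.0) -> tuple[Dataset, FilterReport]:
    """Drop records with N:P strictly above ``threshold`` (default 70 g N / g P).

    Extreme ratios are almost always measurement or unit errors; the strict
    inequality keeps records exactly at the threshold.
    """
    keep = ds.df["np_ratio"] <= threshold
    removed = ds.df.loc[~keep, "record_id"].tolist()
    report = FilterReport("np_ratio_max", len(ds.df), len(removed), removed)
    if not keep.any():
        warnings.warn("N:P filter removed every record", stacklevel=2)
    out = ds._derive(
        ds.df.loc[keep].reset_index(drop=True),
        f"filter np_ratio <= {threshold}: removed {len(removed)}",
    )
    return out, report


def filter_occurrence(
    ds: Dataset,
    min_sites_per_species: int = 5,
    min_species_per_site: int = 5,
    iterate: bool = False,
) -> tuple[Dataset, FilterReport]:
    """Keep records of well-replicated species at well-sampled sites.

    A species must occur at >= ``min_sites_per_species`` distinct sites and a
    site must host >= ``min_species_per_site`` distinct species.  By default
    both criteria are evaluated once on the input and intersected; with
    ``iterate=True`` they are re-evaluated until a fixed point (removing a
    species can push a site below the threshold and vice versa).
    """
    df = ds.df
    n_input = len(df)

    def one_pass(frame: pd.DataFrame) -> pd.Series:
        sites_per_species = frame.groupby("species")["site_id"].nunique()
        species_per_site = frame.groupby("site_id")["species"].nunique()
        good_sp = sites_per_species[sites_per_species >= min_sites_per_species].index
        good_si = species_per_site[species_per_site >= min_species_per_site].index
        return frame["species"].isin(good_sp) & frame["site_id"].isin(good_si)

    keep = one_pass(df)
    if iterate:
        current = df.loc[keep]
        while True:
            mask = one_pass(current)
            if mask.all():
                break
            current = current.loc[mask]
        keep = df["record_id"].isin(current["record_id"])
    removed = df.loc[~keep, "record_id"].tolist()
    if not keep.any():
        raise EmptyResultError("no species-site pairs survive the occurrence filter")
    report = FilterReport("occurrence_min", n_input, len(removed), removed)
    mode = "iterated" if iterate else "single-pass"
    out = ds._derive(
        df.loc[keep].reset_index(drop=True),
        f"occurrence filter ({mode}, >= {min_sites_per_species} sites/species, "
        f">= {min_species_per_site} species/site): removed {len(removed)}",
    )
    return out, report


def aggregate_sites(ds: Dataset, weighting: str = "records") -> pd.DataFrame:
    """Aggregate to one row per site (community means).

    ``weighting="records"`` (default) averages with one vote per record; with
    no abundance information this is the community-weighted mean that the
    sampling design supports.  ``weighting="species_means"`` first averages
    within species at the site, then across species.

    Returns a DataFrame indexed by ``site_id`` with ``n_records``,
    ``n_species``, the trait means and the covariate means.
    """
    if weighting not in ("records", "species_means"):
        raise ValueError(f"unknown weighting {weighting!r}")
    df = ds.df
    value_cols = [t for t in TRAITS if t in df.columns] + list(ds.covariate_names)
    if weighting == "records":
        means = df.groupby("site_id")[value_cols].mean()
    else:
        means = (
            df.groupby(["site_id", "species"])[value_cols].mean().groupby("site_id").mean()
        )
    counts = df.groupby("site_id").agg(
        n_records=("record_id", "size"), n_species=("species", "nunique")
    )
    for col in value_cols:
        if means[col].isna().any():
            warnings.warn(f"all-missing covariate {col!r} at some site; mean reported missing", stacklevel=2)
    return counts.join(means)


def species_summaries(ds: Dataset) -> pd.DataFrame:
    """One row per species: record/site counts and trait means."""
    df = ds.df
    trait_cols = [t for t in TRAITS if t in df.columns]
    means = df.groupby("species")[trait_cols].mean()
    counts = df.groupby("species").agg(
        n_records=("record_id", "size"), n_sites=("site_id", "nunique")
    )
    return counts.join(means)


def _species_means(df: pd.DataFrame, traits) -> pd.DataFrame:
    return df.groupby("species")[list(traits)].transform("mean")


def center_within_species(ds: Dataset, traits=TRAITS) -> Dataset:
    """Subtract each species' mean from its trait values.

    The result contains only within-species variation; covariates are left
    unchanged.  Species means of the output are 0 by construction.
    """
    df = ds.df.copy()
    df[list(traits)] = df[list(traits)] - _species_means(ds.df, traits)
    return ds._derive(df, f"centered within species: {', '.join(traits)}")


def replace_with_species_means(ds: Dataset, traits=TRAITS) -> Dataset:
    """Replace every trait value by its species mean (across-species variation only)."""
    df = ds.df.copy()
    df[list(traits)] = _species_means(ds.df, traits)
    return ds._derive(df, f"replaced by species means: {', '.join(traits)}")


def normalize_to_global_mean(ds: Dataset, traits=TRAITS) -> Dataset:
    """Recenter every species on the grand mean: x' = x - species mean + grand mean.

    Keeps only within-species variation but on the original scale of the
    grand mean, so x' remains comparable to the raw values.
    """
    df = ds.df.copy()
    grand = ds.df[list(traits)].mean()
    df[list(traits)] = ds.df[list(traits)] - _species_means(ds.df, traits) + grand
    return ds._derive(df, f"normalized to global mean: {', '.join(traits)}")


def log_transform(ds: Dataset, traits=TRAITS) -> Dataset:
    """Natural log of the trait columns (concentrations must be positive)."""
    df = ds.df.copy()
    for t in traits:
        vals = df[t].to_numpy(float)
        if (vals <= 0).any():
            rid = df.loc[df[t] <= 0, "record_id"].iloc[0]
            raise ValueError(f"non-positive {t} for record {rid!r}; log transform undefined")
        df[t] = np.log(vals)
    return ds._derive(df, f"log-transformed: {', '.join(traits)}")


def yeo_johnson(values) -> TransformResult:
    """Yeo-Johnson power transform with lambda estimated by maximum likelihood.

    The transform is monotone for every lambda; it reduces to a shifted log
    for lambda = 0 on nonnegative data and to the identity for lambda = 1.
    """
    arr = np.asarray(values, dtype=float)
    transformed, lmbda = stats.yeojohnson(arr)
    return TransformResult("yeo-johnson", np.asarray(transformed, float), float(lmbda))


def yeo_johnson_inverse(values, lmbda: float) -> np.ndarray:
    """Invert the Yeo-Johnson transform for a known lambda."""
    y = np.asarray(values, dtype=float)
    x = np.empty_like(y)
    pos = y >= 0
    if abs(lmbda) < 1e-12:
        x[pos] = np.expm1(y[pos])
    else:
        x[pos] = np.power(lmbda * y[pos] + 1.0, 1.0 / lmbda) - 1.0
    if abs(lmbda - 2.0) < 1e-12:
        x[~pos] = -np.expm1(-y[~pos])
    else:
        x[~pos] = 1.0 - np.power(1.0 - (2.0 - lmbda) * y[~pos], 1.0 / (2.0 - lmbda))
    return x
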