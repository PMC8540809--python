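"""Class-abundance and degradation analytics for NAFC feature tables.

Inputs are tidy tables of Orbitrap-derived features with columns ``mf``
(molecular formula), ``sample_id`` and ``concentration`` (mg/L or relative
intensity).  The module computes per-class relative abundance profiles,
before/after concentration deltas (C_io − C_i) for heat-map aggregation,
completely-removed and newly-produced species sets, classic-NA summaries,
and percent removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .formula import _parse_cached, classify, dbe, is_classic_na, species_label

__all__ = [
    "annotate_features",
    "class_abundance",
    "classic_na_summary",
    "delta_concentration",
    "heatmap_matrix",
    "percent_removal",
    "read_ms_table",
    "removed_and_produced_classes",
]

REQUIRED_COLUMNS = ("mf", "sample_id", "concentration")


def read_ms_table(path) -> pd.DataFrame:
    """Read an MS feature CSV with columns mf, sample_id, concentration."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MS table {path} is missing columns {missing}")
    return df


def annotate_features(features: pd.DataFrame) -> pd.DataFrame:
    """Add species, nafc_class, carbon, dbe and classic-NA columns.

    Formulas are canonicalized through the parser, so equivalent strings with
    permuted element tokens collapse to the same compound.
    """
    df = features.copy()
    parsed = df["mf"].map(_parse_cached)
    df["mf"] = parsed.map(lambda ec: ec.formula)
    df["species"] = parsed.map(species_label)
    df["nafc_class"] = parsed.map(classify)
    df["carbon"] = parsed.map(lambda ec: ec.c)
    df["dbe"] = parsed.map(dbe)
    df["classic_na"] = parsed.map(is_classic_na)
    if (df["concentration"] < 0).any():
        raise ValueError("negative concentrations are not allowed")
    return df


def _one_sample(features: pd.DataFrame, sample_id: str | None) -> pd.DataFrame:
    if sample_id is not None:
        features = features[features["sample_id"] == sample_id]
    elif features["sample_id"].nunique() > 1:
        raise ValueError("table holds several samples; pass sample_id")
    return features


def class_abundance(features: pd.DataFrame, sample_id: str | None = None,
                    weight: str = "concentration", level: str = "species") -> pd.Series:
    """Relative abundance per species label (or coarse class) in one sample.

    weight="concentration" (default) weighs each compound by its measured
    concentration; weight="count" weighs compounds equally.  The result sums
    to 1 and is invariant to the row order of the input.
    """
    if level not in ("species", "nafc_class"):
        raise ValueError("level must be 'species' or 'nafc_class'")
    df = annotate_features(_one_sample(features, sample_id))
    df = df[df["concentration"] > 0]
    if df.empty:
        raise ValueError(f"no features with positive concentration in sample {sample_id!r}")
    if weight == "concentration":
        totals = df.groupby(level)["concentration"].sum()
    elif weight == "count":
        totals = df.groupby(level)["mf"].nunique().astype(float)
    else:
        raise ValueError("weight must be 'concentration' or 'count'")
    return (totals / totals.sum()).sort_index()


def delta_concentration(before: pd.DataFrame, after: pd.DataFrame) -> pd.DataFrame:
    """Per-compound concentration change C_io − C_i across a treatment.

    Every formula present in either table appears once; a compound absent
    from one table counts as concentration 0 there.  Negative deltas mark
    degradation products (species whose concentration rose).  Output carries
    species, class, carbon number and DBE for heat-map aggregation.
    """
    b = annotate_features(_one_sample(before, None)).groupby("mf")["concentration"].sum()
    a = annotate_features(_one_sample(after, None)).groupby("mf")["concentration"].sum()
    joined = pd.concat([b.rename("before"), a.rename("after")], axis=1).fillna(0.0)
    parsed = joined.index.to_series().map(_parse_cached)
    out = joined.reset_index()
    out["delta"] = out["before"] - out["after"]
    out["species"] = parsed.map(species_label).to_numpy()
    out["nafc_class"] = parsed.map(classify).to_numpy()
    out["carbon"] = parsed.map(lambda ec: ec.c).to_numpy()
    out["dbe"] = parsed.map(dbe).to_numpy()
    out["classic_na"] = parsed.map(is_classic_na).to_numpy()
    return out.sort_values("mf").reset_index(drop=True)


def removed_and_produced_classes(before: pd.DataFrame, after: pd.DataFrame) -> tuple[set, set]:
    """Species labels completely removed by treatment, and newly produced.

    removed = positive total concentration before and zero after;
    produced = zero before and positive after.  The two sets are disjoint by
    construction.
    """
    d = delta_concentration(before, after)
    per_species = d.groupby("species")[["before", "after"]].sum()
    removed = set(per_species.index[(per_species["before"] > 0) & (per_species["after"] == 0)])
    produced = set(per_species.index[(per_species["before"] == 0) & (per_species["after"] > 0)])
    return removed, produced


@dataclass
class ClassicNaSummary:
    """Classic-NA census of one sample: counts, total and shape histograms."""

    n_compounds: int
    total_concentration: float
    carbon_hist: dict = field(default_factory=dict)  # carbon number -> fraction of compounds
    dbe_hist: dict = field(default_factory=dict)     # DBE -> fraction of compounds


def classic_na_summary(features: pd.DataFrame, sample_id: str | None = None) -> ClassicNaSummary:
    """Count, cumulative concentration and carbon/DBE histograms of classic NAs."""
    df = annotate_features(_one_sample(features, sample_id))
    df = df[df["classic_na"] & (df["concentration"] > 0)]
    if df.empty:
        return ClassicNaSummary(0, 0.0, {}, {})
    n = df["mf"].nunique()
    carbon = df.drop_duplicates("mf")["carbon"].value_counts(normalize=True).sort_index()
    dbe_h = df.drop_duplicates("mf")["dbe"].value_counts(normalize=True).sort_index()
    return ClassicNaSummary(
        n_compounds=int(n),
        total_concentration=float(df["concentration"].sum()),
        carbon_hist={int(k): float(v) for k, v in carbon.items()},
        dbe_hist={float(k): float(v) for k, v in dbe_h.items()},
    )


def percent_removal(before: pd.DataFrame, after: pd.DataFrame,
                    restrict_to_classic: bool = False) -> float:
    """Percent of total concentration removed by treatment, optionally classic-NA only.

    100 × (total_before − total_after) / total_before over the selected
    compound set.  Negative values mean net production.
    """
    d = delta_concentration(before, after)
    if restrict_to_classic:
        d = d[d["classic_na"]]
    tb, ta = d["before"].sum(), d["after"].sum()
    if tb <= 0:
        raise ValueError("total concentration before treatment must be positive")
    return 100.0 * (tb - ta) / tb


def heatmap_matrix(delta: pd.DataFrame, nafc_class: str | None = None) -> pd.DataFrame:
    """Pivot a delta table into a carbon-number × DBE matrix of summed deltas."""
    d = delta if nafc_class is None else delta[delta["nafc_class"] == nafc_class]
    return d.pivot_table(index="carbon", columns="dbe", values="delta",
                         aggfunc="sum", fill_value=0.0)
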