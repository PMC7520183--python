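"""Diet proportion vectors from metabarcoding read counts.

A scat's diet profile is the vector of per-taxon read proportions
(reads of taxon j / total reads in the sample). Species-level profiles feed
the specialization index; order-level profiles (species lumped into
taxonomic orders, with salmonids optionally split into juvenile and adult
pseudo-orders via hard-part ratios) feed the prey correlations.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

CLOSURE_ATOL = 1e-9

JUVENILE_ORDER = "Juvenile Salmoniformes"
ADULT_ORDER = "Adult Salmoniformes"
SALMONIFORMES = "Salmoniformes"


def to_proportions(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize a samples x taxa count table to proportions."""
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total reads")
    return counts.div(totals, axis=0)


def _check_closure(props: pd.DataFrame) -> None:
    s = props.sum(axis=1)
    if not np.allclose(s, 1.0, atol=CLOSURE_ATOL, rtol=0):
        bad = s.index[~np.isclose(s, 1.0, atol=CLOSURE_ATOL, rtol=0)][0]
        raise ValueError(f"proportions for sample {bad!r} do not sum to 1")


def aggregate_orders(props: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Sum species proportions into taxonomic orders (closure preserved)."""
    _check_closure(props)
    present = props.columns[(props > 0).any(axis=0)]
    missing = [t for t in present if t not in annotation.index]
    if missing:
        raise ValueError(f"taxa without annotation: {missing}")
    orders = {t: annotation.loc[t, "order"] for t in props.columns
              if t in annotation.index}
    known = [t for t in props.columns if t in orders]
    out = props[known].T.groupby([orders[t] for t in known]).sum().T
    out.columns.name = "order"
    return out


def lookup_juvenile_ratio(sample_id: str, species: str, hard_parts: pd.DataFrame,
                          location, year, month: int, season: str
                          ) -> tuple[float, str]:
    """Juvenile fraction for one salmonid species with scope fallback.

    Resolution order: sample-level ratio, then month-level for the same
    location and year, then season-level (location+year first, then a
    global season row), else 0 (all adult). Returns (ratio, scope used).
    """
    if hard_parts is None or len(hard_parts) == 0:
        return 0.0, "default-adult"
    hp = hard_parts[hard_parts["species"] == species]
    row = hp[(hp["scope"] == "sample") & (hp["sample_id"] == sample_id)]
    if len(row):
        return float(row["juvenile_fraction"].iloc[0]), "sample"
    row = hp[(hp["scope"] == "month") & (hp["location"] == location)
             & (hp["year"] == year) & (hp["month"] == month)]
    if len(row):
        return float(row["juvenile_fraction"].iloc[0]), "month"
    sea = hp[hp["scope"] == "season"]
    row = sea[(sea["location"] == location) & (sea["year"] == year)
              & (sea["season"] == season)]
    if len(row):
        return float(row["juvenile_fraction"].iloc[0]), "season"
    row = sea[sea["location"].isna() & (sea["season"] == season)]
    if len(row):
        return float(row["juvenile_fraction"].iloc[0]), "season"
    return 0.0, "default-adult"


def split_salmonids(order_props: pd.DataFrame, species_props: pd.DataFrame,
                    annotation: pd.DataFrame, ratios: pd.DataFrame) -> pd.DataFrame:
    """Add juvenile/adult salmonid pseudo-orders to an order-level table.

    ``ratios`` holds one juvenile fraction per (sample_id, taxon); the
    per-species split is juvenile = p * ratio, adult = p * (1 - ratio),
    summed over salmonid species. The Salmoniformes column is kept, so the
    pseudo-orders are supplemental and the base order vector still closes
    to 1 without them.
    """
    if ((ratios["juvenile_fraction"] < 0) | (ratios["juvenile_fraction"] > 1)).any():
        raise ValueError("juvenile fraction outside [0, 1]")
    salmonids = [t for t in species_props.columns
                 if t in annotation.index and annotation.loc[t, "is_salmonid"]]
    out = order_props.copy()
    juv = pd.Series(0.0, index=out.index)
    adu = pd.Series(0.0, index=out.index)
    rmap = ratios.set_index(["sample_id", "taxon"])["juvenile_fraction"]
    for t in salmonids:
        p = species_props[t]
        r = pd.Series([rmap.get((s, t), 0.0) for s in out.index], index=out.index)
        juv += p * r
        adu += p * (1.0 - r)
    out[JUVENILE_ORDER] = juv
    out[ADULT_ORDER] = adu
    if SALMONIFORMES in out.columns:
        resid = (out[JUVENILE_ORDER] + out[ADULT_ORDER] - out[SALMONIFORMES]).abs()
        if (resid > 1e-12).any():
            raise ValueError("juvenile + adult does not conserve the "
                             "Salmoniformes total")
    return out


def benthic_fraction(props: pd.DataFrame, annotation: pd.DataFrame) -> pd.Series:
    """Per-sample summed proportion of benthic-habitat taxa.

    Taxa lacking a habitat annotation contribute zero; their count is
    surfaced as a warning rather than an error.
    """
    benthic = [t for t in props.columns
               if t in annotation.index and annotation.loc[t, "habitat"] == "benthic"]
    unknown = [t for t in props.columns
               if t not in annotation.index
               or annotation.loc[t, "habitat"] == "unknown"]
    if unknown:
        warnings.warn(f"{len(unknown)} taxa with unknown habitat contribute 0 "
                      "to the benthic fraction", stacklevel=2)
    if not benthic:
        return pd.Series(0.0, index=props.index, name="benthic_fraction")
    return props[benthic].sum(axis=1).rename("benthic_fraction")
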