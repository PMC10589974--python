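"""Choropleth data products: class assignment and export tables.

These functions produce the *data* behind univariate and bivariate
choropleth maps — class indices, bin edges and join-ready tables — so the
pipeline stays testable headless; rendering is left to the caller.

Classification conventions (documented because mapping packages differ):
classes are 1-based; the ``quantile`` scheme places bin edges at empirical
quantiles and resolves a value lying exactly on an edge to the *lower* bin;
``equal_interval`` splits the observed range evenly with the same tie rule.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Classification",
    "classify_univariate",
    "bivariate_choropleth_classes",
    "count_exceeding",
    "ExceedanceCount",
    "export_map_table",
]


@dataclass
class Classification:
    classes: np.ndarray  # 1-based bin index per district
    edges: np.ndarray  # interior bin edges (n_bins - 1 of them)
    scheme: str
    n_bins: int


def classify_univariate(values, n_bins: int = 3, scheme: str = "quantile") -> Classification:
    """Assign each district to one of ``n_bins`` classes (1-based)."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} districts, got {x.size}")
    if np.ptp(x) == 0:
        warnings.warn("all values equal; single class assigned")
        return Classification(np.ones(x.size, dtype=int), np.array([]), scheme, n_bins)
    if scheme == "quantile":
        edges = np.quantile(x, np.arange(1, n_bins) / n_bins)
    elif scheme == "equal_interval":
        edges = x.min() + np.arange(1, n_bins) * (x.max() - x.min()) / n_bins
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    # side='left': a value equal to an edge falls in the lower bin
    classes = np.searchsorted(edges, x, side="left") + 1
    return Classification(classes, edges, scheme, n_bins)


def bivariate_choropleth_classes(values_a: pd.Series, values_b: pd.Series,
                                 n_bins: int = 3, scheme: str = "quantile"):
    """Joint (tertile by default) classification of two district vectors.

    Both inputs are Series indexed by district label over the *same*
    district set. Returns ``(table, crosstab)``: a per-district table with
    ``class_a``/``class_b`` and the n_bins x n_bins cross-tabulation of
    class-pair counts.
    """
    a, b = pd.Series(values_a), pd.Series(values_b)
    if set(a.index) != set(b.index):
        only_a = sorted(set(a.index) - set(b.index))
        only_b = sorted(set(b.index) - set(a.index))
        raise ValueError(f"district sets differ: only in a={only_a}, only in b={only_b}")
    b = b.reindex(a.index)
    ca = classify_univariate(a.to_numpy(), n_bins, scheme)
    cb = classify_univariate(b.to_numpy(), n_bins, scheme)
    table = pd.DataFrame(
        {
            "district": a.index,
            "value_a": a.to_numpy(),
            "value_b": b.to_numpy(),
            "class_a": ca.classes,
            "class_b": cb.classes,
        }
    )
    crosstab = pd.crosstab(
        pd.Categorical(ca.classes, categories=range(1, n_bins + 1)),
        pd.Categorical(cb.classes, categories=range(1, n_bins + 1)),
        dropna=False,
    )
    crosstab.index.name, crosstab.columns.name = "class_a", "class_b"
    return table, crosstab


@dataclass
class ExceedanceCount:
    strictly_above: int
    at_or_above: int
    threshold: float
    comparison: str = "both conventions reported"


def count_exceeding(values, threshold: float) -> ExceedanceCount:
    """Count districts above a threshold, under both comparison conventions."""
    x = np.asarray(values, dtype=float).ravel()
    return ExceedanceCount(int((x > threshold).sum()), int((x >= threshold).sum()),
                           float(threshold))


def export_map_table(table: pd.DataFrame, path, format: str = "csv",
                     geometry_path=None, label_property: str = "district") -> None:
    """Write a per-district attribute table as CSV or attribute-joined GeoJSON.

    For GeoJSON a FeatureCollection keyed by ``label_property`` must be
    supplied; every district in the table must have a geometry (missing
    labels are an error naming them). Class columns are serialised as
    integers, values at full precision.
    """
    if "district" not in table.columns:
        raise ValueError("table must have a 'district' column")
    if format == "csv":
        table.to_csv(path, index=False)
        return
    if format != "geojson":
        raise ValueError(f"unknown format {format!r}")
    if geometry_path is None:
        raise ValueError("geojson export needs a geometry file")
    with open(geometry_path) as fh:
        geo = json.load(fh)
    feats = {str(f.get("properties", {}).get(label_property)): f
             for f in geo.get("features", [])}
    missing = sorted(set(table["district"].astype(str)) - set(feats))
    if missing:
        raise ValueError(f"no geometry for district(s): {missing}")
    out_feats = []
    for _, row in table.iterrows():
        f = json.loads(json.dumps(feats[str(row["district"])]))  # deep copy
        for col in table.columns:
            v = row[col]
            if isinstance(v, (np.integer,)):
                v = int(v)
            elif isinstance(v, (np.floating,)):
                v = float(v)
            f.setdefault("properties", {})[col] = v
        out_feats.append(f)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": out_feats}, fh)
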