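"""Site-level biodiversity responses.

Four responses per site, computed from effort-adjusted records:

* species richness — number of uniquely named species sampled at the site;
* Chao1 richness — richness corrected upward using singleton and doubleton
  counts (on raw, pre-adjustment integer counts, where F1/F2 are defined);
* total abundance — sum of effort-adjusted abundances (often non-integer);
* inverse Simpson diversity — 1 / Σ pᵢ², the effective number of equally
  abundant species.

Total abundance and Simpson diversity are modelled on the ln(x+1) scale;
the transform columns are emitted alongside.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "site_richness", "chao1", "total_abundance", "simpson_diversity",
    "transform_response", "compute_site_metrics",
]

log = logging.getLogger(__name__)


def site_richness(abundances) -> int:
    """Number of species with a positive measurement."""
    a = np.asarray(abundances, dtype=float)
    return int(np.sum(a > 0))


def chao1(raw_counts, bias_corrected: bool = True) -> float:
    """Chao1 estimated richness from integerised raw counts.

    The bias-corrected form S + F1(F1-1)/(2(F2+1)) is the default (defined
    even without doubletons); the classic form S + F1^2/(2 F2) is available
    for sensitivity. Counts are rounded half-up to integers first since
    singletons and doubletons are defined on counts.
    """
    c = np.asarray(raw_counts, dtype=float)
    c = np.floor(c + 0.5)           # round half up
    c = c[c > 0]
    s_obs = len(c)
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0      # classic fallback when F2 = 0


def total_abundance(abundances) -> float:
    """Sum of effort-adjusted abundances at a site."""
    return float(np.sum(np.asarray(abundances, dtype=float)))


def simpson_diversity(abundances) -> float:
    """Inverse Simpson index 1 / Σ pᵢ²; 0 for an empty site."""
    a = np.asarray(abundances, dtype=float)
    a = a[a > 0]
    tot = a.sum()
    if tot <= 0:
        return 0.0
    p = a / tot
    return float(1.0 / np.sum(p * p))


def transform_response(x):
    """ln(x + 1), the zero-safe log transform used for the gaussian models."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("transform_response requires non-negative input")
    out = np.log1p(x)
    return out if out.ndim else float(out)


_SITE_META = ["SS", "SSB", "Longitude", "Latitude", "Predominant_land_use",
              "Use_intensity", "LUI", "Continent", "Fertiliser", "zone"]


def compute_site_metrics(table: pd.DataFrame, by: tuple = ("SSBS",),
                         bias_corrected_chao: bool = True) -> pd.DataFrame:
    """Per-site metrics table (one row per ``by`` group).

    ``by`` defaults to the site; pass ("SSBS", "Order") for the taxonomic
    models, which treat each order's assemblage at a site as the unit.
    Species identity is the best-guess binomial; duplicated names within a
    site are merged (summing abundance) before computing any metric.
    """
    table = table[table["Measurement"] > 0]
    raw_col = "Raw_measurement" if "Raw_measurement" in table.columns \
        else "Measurement"
    by = list(by)
    merged = (table.groupby(by + ["Best_guess_binomial"], sort=False)
              .agg(adj=("Measurement", "sum"), raw=(raw_col, "sum"))
              .reset_index())

    rows = []
    for key, g in merged.groupby(by, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        adj = g["adj"].to_numpy()
        rows.append((*key, site_richness(adj),
                     chao1(g["raw"].to_numpy(), bias_corrected_chao),
                     total_abundance(adj), simpson_diversity(adj)))
    out = pd.DataFrame(rows, columns=by + ["richness", "chao1",
                                           "total_abundance", "simpson"])
    out["abundance_ln1p"] = transform_response(out["total_abundance"])
    out["simpson_ln1p"] = transform_response(out["simpson"])

    meta_cols = [c for c in _SITE_META if c in table.columns]
    if meta_cols:
        meta = table.groupby("SSBS", sort=False)[meta_cols].first()
        out = out.merge(meta, left_on="SSBS", right_index=True, how="left")
    return out
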