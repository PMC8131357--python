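"""Robustness battery: continental jack-knife, Moran's I residual screen,
balanced tropical/non-tropical resampling, forest-cover-stratified baselines.

These are the checks run on every significant model of the main analysis:
geographic sensitivity (drop each continent and refit), per-study spatial
autocorrelation of residuals (Moran's I with inverse great-circle-distance
weights and a permutation p-value), whether tropical/non-tropical interval
widths merely track sample size (resample 1000 sites per zone, 100 times),
and whether the primary-vegetation baseline's forest cover changes the
story (≥60% vs ≤40% cover baselines).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .effects import (EffectConfig, class_rows_for_factor, effects_as_percent,
                      effects_table)
from .models import ModelFit, ModelSpec, fit_mixed
from .mixed import ConvergenceError

__all__ = [
    "JackknifeResult", "MoranResult", "jackknife_continents", "morans_i",
    "morans_i_by_study", "balanced_resample_zone",
    "stratify_baseline_by_cover", "haversine_km",
]

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


@dataclass
class JackknifeResult:
    excluded: str
    n_sites_removed: int
    fit: ModelFit | None
    effects: pd.DataFrame
    dropped_classes: list = field(default_factory=list)
    converged: bool = True


@dataclass
class MoranResult:
    study: str
    n_sites: int
    moran_i: float
    p_value: float
    significant: bool


def jackknife_continents(data: pd.DataFrame, spec: ModelSpec,
                         factor: str, baseline_level: str,
                         config: EffectConfig,
                         random: tuple = ("SS", "SSB"), olre: bool = False
                         ) -> list:
    """Refit and recompute effects with each continent's sites excluded.

    Classes emptied by an exclusion are absent from that refit's effects
    table (the design builder drops their columns, logged). Non-convergent
    refits are recorded, not fatal.
    """
    out = []
    for continent in sorted(data["Continent"].dropna().unique()):
        sub = data[data["Continent"] != continent]
        removed = len(data) - len(sub)
        full_classes = set(data[factor].unique())
        dropped = sorted(full_classes - set(sub[factor].unique()))
        if dropped:
            log.info("jackknife %s: classes emptied: %s", continent, dropped)
        try:
            fit = fit_mixed(spec, sub, random=random, olre=olre)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            log.warning("jackknife %s: refit failed (%s)", continent, exc)
            out.append(JackknifeResult(continent, removed, None,
                                       pd.DataFrame(), dropped, False))
            continue
        cr, br, labels = class_rows_for_factor(fit, factor, baseline_level)
        eff = effects_table(effects_as_percent(fit, cr, br, labels, config))
        out.append(JackknifeResult(continent, removed, fit, eff, dropped,
                                   fit.converged))
    return out


def haversine_km(lat, lon) -> np.ndarray:
    """Pairwise great-circle distances (km) for point vectors."""
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def _moran_weights(lat, lon) -> np.ndarray | None:
    d = haversine_km(lat, lon)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    dup = ~np.isfinite(w)
    np.fill_diagonal(dup, False)
    if dup.any():
        log.warning("Moran weights: %d co-located pairs given weight 0",
                    int(dup.sum() / 2))
        w[dup] = 0.0
    rs = w.sum(axis=1, keepdims=True)
    if np.all(rs == 0):
        return None
    rs[rs == 0] = 1.0
    return w / rs


def morans_i(values, lat, lon, n_perm: int = 999,
             seed: int = 0) -> tuple[float, float]:
    """Moran's I with row-standardised inverse-distance weights.

    I = (n/ΣW)·(Σᵢⱼ wᵢⱼ eᵢeⱼ / Σᵢ eᵢ²) with e the mean-centred values. The
    p-value is a two-sided permutation test (values shuffled over
    locations), robust at the small per-study site counts typical of
    survey data.
    """
    e = np.asarray(values, dtype=float)
    e = e - e.mean()
    n = len(e)
    w = _moran_weights(lat, lon)
    if w is None:
        raise ValueError("all sites co-located; Moran's I undefined")
    s0 = w.sum()
    denom = float(e @ e)
    if denom == 0:
        return 0.0, 1.0
    i_obs = (n / s0) * float(e @ (w @ e)) / denom
    rng = np.random.default_rng(seed)
    perm = np.array([rng.permutation(n) for _ in range(n_perm)])
    E = e[perm]                              # (n_perm, n)
    i_perm = (n / s0) * np.einsum("ij,ij->i", E, E @ w.T) / denom
    centre = i_perm.mean()
    p = (1.0 + np.sum(np.abs(i_perm - centre) >= abs(i_obs - centre))) \
        / (n_perm + 1.0)
    return float(i_obs), float(p)


def morans_i_by_study(residuals: pd.Series, sites: pd.DataFrame,
                      n_perm: int = 999, alpha: float = 0.05,
                      min_sites: int = 4, seed: int = 0
                      ) -> tuple[pd.DataFrame, float]:
    """Per-study Moran's I over model residuals.

    ``sites`` must carry SS/Latitude/Longitude aligned with ``residuals``.
    Studies with fewer than ``min_sites`` distinct coordinates are excluded
    from the percentage denominator (logged). Returns the per-study table
    and the percentage of tested studies significant at ``alpha``.
    """
    rows = []
    skipped = 0
    df = sites[["SS", "Latitude", "Longitude"]].copy()
    df["resid"] = np.asarray(residuals, dtype=float)
    for k, (study, g) in enumerate(df.groupby("SS")):
        coords = g[["Latitude", "Longitude"]].drop_duplicates()
        if len(coords) < min_sites:
            skipped += 1
            continue
        try:
            i_obs, p = morans_i(g["resid"].to_numpy(), g["Latitude"],
                                g["Longitude"], n_perm=n_perm,
                                seed=seed + k)
        except ValueError:
            skipped += 1
            continue
        rows.append(MoranResult(study, len(g), i_obs, p, p < alpha))
    if skipped:
        log.info("morans_i_by_study: %d studies skipped (too few distinct "
                 "coordinates)", skipped)
    table = pd.DataFrame([(r.study, r.n_sites, r.moran_i, r.p_value,
                           r.significant) for r in rows],
                         columns=["SS", "n_sites", "moran_i", "p", "significant"])
    pct = 100.0 * table["significant"].mean() if len(table) else float("nan")
    return table, float(pct)


def balanced_resample_zone(data: pd.DataFrame, spec: ModelSpec,
                           factor: str, baseline_level: str,
                           config: EffectConfig, n_sites: int = 1000,
                           reps: int = 100, seed: int = 0,
                           random: tuple = ("SS", "SSB"),
                           stratum_col: str = "zone") -> pd.DataFrame:
    """Equal-size zone resampling to decouple interval width from n.

    Each rep draws ``n_sites`` sites without replacement from each zone,
    refits, and records the percentage-effect interval widths. If a zone
    has fewer sites than requested, n is lowered to the smaller zone size
    with a warning. Returns a long frame (rep, zone, class, width).
    """
    rng = np.random.default_rng(seed)
    zones = sorted(data[stratum_col].dropna().unique())
    avail = {z: data.index[data[stratum_col] == z] for z in zones}
    n_eff = min([n_sites] + [len(v) for v in avail.values()])
    if n_eff < n_sites:
        log.warning("balanced_resample_zone: lowering n_sites to %d", n_eff)
    rows = []
    for rep in range(reps):
        idx = np.concatenate([
            rng.choice(avail[z], size=n_eff, replace=False) for z in zones])
        sub = data.loc[idx]
        try:
            fit = fit_mixed(spec, sub, random=random)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            log.warning("balanced_resample_zone rep %d failed: %s", rep, exc)
            continue
        rep_cfg = EffectConfig(n_draws=config.n_draws,
                               percentiles=config.percentiles,
                               seed=config.seed + rep,
                               backtransform=config.backtransform)
        for z in zones:
            cr, br, labels = class_rows_for_factor(
                fit, factor, baseline_level, fill={stratum_col: z})
            for est in effects_as_percent(fit, cr, br, labels, rep_cfg):
                rows.append((rep, z, est.label,
                             est.upper_pct - est.lower_pct))
    return pd.DataFrame(rows, columns=["rep", "zone", "class", "width"])


def stratify_baseline_by_cover(sites: pd.DataFrame, cover: pd.Series,
                               hi: float = 0.60, lo: float = 0.40,
                               baseline_class: str = "Primary_Minimal"
                               ) -> dict:
    """Split baseline sites into high / low forest-cover subsets.

    Cover is a fraction in [0, 1]; the high subset is cover >= hi
    (boundary inclusive), the low subset cover <= lo, and the middle is
    excluded. Empty subsets are reported with a warning so the downstream
    comparison can be skipped.
    """
    c = np.asarray(cover, dtype=float)
    if np.nanmin(c) < 0 or np.nanmax(c) > 1:
        raise ValueError("cover values must lie in [0, 1]")
    is_base = sites["LUI"] == baseline_class
    out = {
        "high": sites[is_base & (c >= hi)],
        "low": sites[is_base & (c <= lo)],
    }
    for name, sub in out.items():
        if sub.empty:
            log.warning("stratify_baseline_by_cover: %s-cover baseline empty",
                        name)
    return out
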