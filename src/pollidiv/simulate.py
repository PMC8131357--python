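"""Synthetic PREDICTS-like inputs with known ground truth.

This module is the test-bed for the whole pipeline: it fabricates the three
kinds of input the analysis consumes — (1) a long-format site-by-taxon survey
table with nested study/block/site structure and planted land-use-intensity
effects, (2) an abstract corpus with planted pollination-evidence sentences
plus a reference taxonomy, and (3) smooth gridded covariate surfaces — so
that every downstream stage can be checked against a
:class:`TruthRecord` without downloading anything.

Generative model for the survey table
-------------------------------------
Sites are nested in spatial blocks nested in studies. Each study gets a
log-normal intercept (between-study heterogeneity in methods and locality),
each block a log-normal intercept within study. Each study samples a species
pool; species carry log-normal abundance effects. A site's land-use ×
intensity (LUI) class is drawn from configurable weights; the class
multiplies each species' expected count by the planted abundance effect and
each species' occupancy probability by the planted richness effect. Counts
are negative-binomial (not Poisson) so the observation-level-random-effect
machinery downstream has genuine overdispersion to absorb. Expected counts
scale with the site's sampling effort, which the ingest stage later adjusts
back out.

With occupancy effects at 1, the expected total abundance of a class
relative to the baseline equals the planted abundance multiplier exactly,
which is what :class:`TruthRecord` stores (as a percentage of baseline).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig", "TruthRecord", "ConfigError",
    "build_taxonomy", "generate_survey", "generate_corpus",
    "generate_covariate_grid", "SurfaceParams", "write_corpus",
]

from .grids import CovariateGrid


class ConfigError(ValueError):
    """Invalid simulation configuration."""


LAND_USES = ["Primary", "MSV", "ISV", "YSV",
             "Plantation", "Pasture", "Cropland", "Urban"]
INTENSITIES = ["Minimal", "Light", "Intense"]
BASELINE_CLASS = "Primary_Minimal"
TROPIC_LAT = 23.4368

ORDERS = {
    # order -> (taxonomic class, n_families)
    "Hymenoptera": ("Insecta", 4),
    "Lepidoptera": ("Insecta", 3),
    "Diptera": ("Insecta", 3),
    "Coleoptera": ("Insecta", 3),
    "Apodiformes": ("Aves", 2),
    "Passeriformes": ("Aves", 2),
}

CONTINENTS = ["Europe", "North America", "Africa",
              "South America", "Oceania", "Asia"]
CONTINENT_WEIGHTS = [0.262, 0.244, 0.20, 0.123, 0.086, 0.085]


def _default_weights() -> dict:
    classes = [f"{lu}_{i}" for lu in LAND_USES for i in INTENSITIES]
    w = {c: np.nan for c in classes}
    base_w = 0.16
    rest = (1.0 - base_w) / (len(classes) - 1)
    for c in classes:
        w[c] = base_w if c == BASELINE_CLASS else rest
    return w


def _default_abundance_effects() -> dict:
    eff = {f"{lu}_{i}": 1.0 for lu in LAND_USES for i in INTENSITIES}
    # low/intermediate intensity beneficial, high intensity harmful:
    # the pattern the study design is built to detect.
    eff.update({
        "Urban_Minimal": 1.55, "Urban_Light": 1.25, "Urban_Intense": 0.60,
        "Pasture_Minimal": 1.60, "Pasture_Light": 1.20, "Pasture_Intense": 0.40,
        "Plantation_Light": 1.10, "Plantation_Intense": 0.70,
        "Cropland_Light": 1.05, "Cropland_Intense": 0.85,
        "YSV_Intense": 0.90,
    })
    return eff


@dataclass
class SimConfig:
    """Study conditions for the synthetic survey/corpus/grid generators.

    Sizes default to roughly 1,500 sites over 25 studies, the scale at
    which the parameter-recovery battery operates.
    """

    n_studies: int = 25
    blocks_per_study: tuple = (2, 4)        # inclusive range
    sites_per_block: tuple = (15, 25)       # inclusive range
    species_pool_per_study: int = 30
    lui_class_weights: dict = field(default_factory=_default_weights)
    planted_effects: dict = field(default_factory=_default_abundance_effects)
    richness_effects: dict = field(default_factory=dict)  # default 1.0
    baseline_class: str = BASELINE_CLASS
    study_sd: float = 0.5                   # SD of study log-intercepts
    block_sd: float = 0.3                   # SD of block log-intercepts
    species_sd: float = 0.8                 # SD of species log-abundance
    overdispersion: float = 1.0             # NB size k; smaller = more dispersed
    base_occupancy: float = 0.4             # occupancy prob at baseline
    log_mu0: float = np.log(8.0)            # baseline per-species mean count
    effort_range: tuple = (0.5, 1.0)
    effort_missing_rate: float = 0.0        # missing-at-random effort option
    tropical_fraction: float = 0.4
    study_box_deg: float = 1.0              # spatial extent of a study
    spatial_resid_sd: float = 0.0           # optional spatially correlated field
    spatial_range_deg: float = 0.3
    fertiliser_slope_by_order: dict = field(default_factory=dict)
    # corpus settings
    n_evidence_genera: int = 40
    n_negative_genera: int = 5
    n_distractor_abstracts: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies <= 0:
            raise ConfigError("n_studies must be positive")
        if not self.lui_class_weights:
            raise ConfigError("lui_class_weights is empty")
        tot = sum(self.lui_class_weights.values())
        if not np.isclose(tot, 1.0, atol=1e-6):
            raise ConfigError(f"lui_class_weights sum to {tot}, expected 1")
        if self.planted_effects.get(self.baseline_class, 1.0) != 1.0:
            raise ConfigError("baseline class planted effect must equal 1.0")
        for name in ("study_sd", "block_sd", "species_sd", "spatial_resid_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.overdispersion <= 0:
            raise ConfigError("overdispersion (NB size) must be positive")
        lo, hi = self.effort_range
        if not (0 < lo <= hi):
            raise ConfigError("effort_range must be a positive interval")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TruthRecord:
    """Planted ground truth accompanying a generated dataset."""

    baseline_class: str = BASELINE_CLASS
    abundance_pct: dict = field(default_factory=dict)   # class -> % of baseline
    richness_pct: dict = field(default_factory=dict)    # occupancy ratio * 100
    slopes_by_order: dict = field(default_factory=dict)
    # roster truth (set by generate_corpus)
    direct_confidence: dict = field(default_factory=dict)   # genus -> 1..4
    blocklist: set = field(default_factory=set)
    group_entries: set = field(default_factory=set)         # (taxon, level)
    pollinator_genera: set = field(default_factory=set)     # all implied genera


# ---------------------------------------------------------------------------
# pseudo-Latin name generation
# ---------------------------------------------------------------------------

_SYL = ["an", "bo", "ca", "chi", "do", "eu", "fa", "glo", "hy", "il", "ja",
        "ko", "la", "me", "ni", "or", "pa", "que", "ro", "sa", "the", "ul",
        "ve", "xi", "yo", "zu", "bra", "cre", "dru", "fle"]


def _make_name(rng, n_syl, used: set, suffix="") -> str:
    while True:
        name = "".join(rng.choice(_SYL) for _ in range(n_syl)) + suffix
        if name not in used:
            used.add(name)
            return name


def build_taxonomy(config: SimConfig) -> pd.DataFrame:
    """Reference taxonomy: genus -> tribe? -> subfamily? -> family -> order -> class.

    Deterministic in ``config.seed`` so the survey and corpus generators,
    called separately, share one taxonomy.
    """
    rng = np.random.default_rng(_derive_seed(config.seed, "taxonomy"))
    used: set = set()
    rows = []
    for order, (cls, n_fam) in ORDERS.items():
        for _ in range(n_fam):
            family = _make_name(rng, 3, used, "idae").capitalize()
            n_sub = int(rng.integers(0, 4))        # 0 => genera sit under family
            subfams = [_make_name(rng, 3, used, "inae").capitalize()
                       for _ in range(n_sub)]
            branches = subfams if subfams else [None]
            for sub in branches:
                n_tribes = int(rng.integers(0, 3)) if sub is not None else 0
                tribes = [_make_name(rng, 3, used, "ini").capitalize()
                          for _ in range(n_tribes)]
                leaves = tribes if tribes else [None]
                for tribe in leaves:
                    for _ in range(int(rng.integers(2, 5))):
                        genus = _make_name(rng, 3, used).capitalize()
                        rows.append((genus, tribe, sub, family, order, cls))
    return pd.DataFrame(rows, columns=["genus", "tribe", "subfamily",
                                       "family", "order", "class"])


def _derive_seed(seed: int, tag: str) -> int:
    import hashlib
    h = hashlib.sha256(f"{seed}:{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# survey generator
# ---------------------------------------------------------------------------

def generate_survey(config: SimConfig, taxonomy: pd.DataFrame | None = None,
                    fert_grid: CovariateGrid | None = None
                    ) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate a long-format PREDICTS-style survey table with planted effects.

    Returns the table and the :class:`TruthRecord` of planted
    percentage-of-baseline effects. If ``fertiliser_slope_by_order`` is
    non-empty, sites additionally receive fertiliser application rates from
    ``fert_grid`` (generated internally when not supplied) and species
    counts respond log-linearly to log10(rate + 1).
    """
    config.validate()
    if taxonomy is None:
        taxonomy = build_taxonomy(config)
    rng = np.random.default_rng(_derive_seed(config.seed, "survey"))

    classes = list(config.lui_class_weights)
    weights = np.array([config.lui_class_weights[c] for c in classes])
    weights = weights / weights.sum()
    ab_eff = {c: config.planted_effects.get(c, 1.0) for c in classes}
    occ_eff = {c: config.richness_effects.get(c, 1.0) for c in classes}
    if config.baseline_class not in classes:
        raise ConfigError("baseline class missing from lui_class_weights")

    use_fert = bool(config.fertiliser_slope_by_order)
    if use_fert and fert_grid is None:
        fert_grid = generate_covariate_grid(
            extent=(-180.0, 180.0, -60.0, 60.0), resolution_arcmin=30.0,
            surface=SurfaceParams(constant=50.0, n_bumps=40,
                                  bump_amplitude=400.0, bump_width_deg=15.0),
            seed=_derive_seed(config.seed, "fertgrid"))

    eff_lo, eff_hi = config.effort_range
    k = config.overdispersion
    genus_order = dict(zip(taxonomy["genus"], taxonomy["order"]))
    genus_family = dict(zip(taxonomy["genus"], taxonomy["family"]))
    genus_class = dict(zip(taxonomy["genus"], taxonomy["class"]))
    all_genera = taxonomy["genus"].to_numpy()
    used_epithets: set = set()

    records = []
    for s in range(config.n_studies):
        ss = f"ST{s:03d}"
        tropical = rng.random() < config.tropical_fraction
        if tropical:
            lat0 = rng.uniform(-TROPIC_LAT + 1, TROPIC_LAT - 1)
        else:
            lat0 = rng.choice([-1, 1]) * rng.uniform(26.0, 60.0)
        lon0 = rng.uniform(-170.0, 170.0)
        continent = rng.choice(CONTINENTS, p=CONTINENT_WEIGHTS)
        u_study = rng.normal(0.0, config.study_sd)

        pool_idx = rng.choice(len(all_genera),
                              size=min(config.species_pool_per_study,
                                       len(all_genera)), replace=False)
        pool_genera = all_genera[pool_idx]
        pool_binoms = np.array([
            f"{g} {_make_name(rng, 2, used_epithets) + 'us'}"
            for g in pool_genera])
        sp_effect = rng.normal(0.0, config.species_sd, size=len(pool_genera))
        sp_slope = np.array([
            config.fertiliser_slope_by_order.get(genus_order[g], 0.0)
            for g in pool_genera])

        n_blocks = int(rng.integers(config.blocks_per_study[0],
                                    config.blocks_per_study[1] + 1))
        site_no = 0
        for b in range(n_blocks):
            ssb = f"{ss}_B{b:02d}"
            u_block = rng.normal(0.0, config.block_sd)
            n_sites = int(rng.integers(config.sites_per_block[0],
                                       config.sites_per_block[1] + 1))
            half = config.study_box_deg / 2
            lats = lat0 + rng.uniform(-half, half, n_sites)
            lons = lon0 + rng.uniform(-half, half, n_sites)
            if config.spatial_resid_sd > 0:
                sp_field = _gp_field(lats, lons, config.spatial_resid_sd,
                                     config.spatial_range_deg, rng)
            else:
                sp_field = np.zeros(n_sites)
            lui = rng.choice(classes, p=weights, size=n_sites)
            efforts = rng.uniform(eff_lo, eff_hi, n_sites)
            miss = rng.random(n_sites) < config.effort_missing_rate
            if use_fert:
                ferts = fert_grid.extract(lons, lats)
                ferts = np.where(np.isnan(ferts), 0.0, ferts)
            else:
                ferts = np.zeros(n_sites)

            for j in range(n_sites):
                site_no += 1
                ssbs = f"{ss}_S{site_no:04d}"
                c = lui[j]
                lu, inten = c.rsplit("_", 1)
                p_occ = min(config.base_occupancy * occ_eff[c], 1.0)
                present = rng.random(len(pool_genera)) < p_occ
                log_m = (config.log_mu0 + u_study + u_block + sp_field[j]
                         + np.log(ab_eff[c]) + sp_effect
                         + sp_slope * np.log10(ferts[j] + 1.0)
                         + np.log(efforts[j] / eff_hi))
                m = np.exp(log_m)
                counts = rng.negative_binomial(k, k / (k + m))
                keep = present & (counts > 0)
                for gi in np.nonzero(keep)[0]:
                    g = pool_genera[gi]
                    records.append((
                        ss, ssb, ssbs, round(lons[j], 6), round(lats[j], 6),
                        lu, inten, genus_class[g], genus_order[g],
                        genus_family[g], g, pool_binoms[gi],
                        float(counts[gi]),
                        np.nan if miss[j] else round(efforts[j], 6),
                        "abundance", continent,
                        round(float(ferts[j]), 6) if use_fert else np.nan,
                    ))

    table = pd.DataFrame(records, columns=[
        "SS", "SSB", "SSBS", "Longitude", "Latitude",
        "Predominant_land_use", "Use_intensity", "Class", "Order", "Family",
        "Genus", "Best_guess_binomial", "Measurement", "Sampling_effort",
        "Diversity_metric_type", "Continent", "Fertiliser"])

    truth = TruthRecord(
        baseline_class=config.baseline_class,
        abundance_pct={c: 100.0 * ab_eff[c] * occ_eff[c] for c in classes},
        richness_pct={c: 100.0 * occ_eff[c] for c in classes},
        slopes_by_order=dict(config.fertiliser_slope_by_order),
    )
    return table, truth


def _gp_field(lats, lons, sd, range_deg, rng):
    """Spatially correlated Gaussian field over site locations (per block)."""
    pts = np.column_stack([lats, lons])
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    cov = sd ** 2 * np.exp(-d / range_deg) + 1e-10 * np.eye(len(pts))
    return np.linalg.cholesky(cov) @ rng.normal(size=len(pts))


# ---------------------------------------------------------------------------
# abstract corpus generator
# ---------------------------------------------------------------------------

# evidence cue templates, one per confidence level; phrasing is what the
# roster scanner's cue lexicon keys on
_CUES = {
    1: "Pollinator-exclusion experiments demonstrated that fruit set depended on visitation by {b}.",
    2: "Individuals of {b} were found to carry substantial pollen loads between flowers.",
    3: "Adults of {b} were observed feeding on nectar and pollen throughout the season.",
    4: "{b} regularly visited flowers without damaging floral tissue.",
}
_NEGATIVE_CUES = [
    "{b} destructively robbed flowers, damaging ovules without transferring pollen.",
    "{b} preyed upon visiting insects at flowers and contributed nothing to pollination.",
]
_FILLER = ("We surveyed plant-animal interactions across the study region. "
           "Visitation networks were recorded over two field seasons. ")


def generate_corpus(config: SimConfig, taxonomy: pd.DataFrame | None = None
                    ) -> tuple[dict, pd.DataFrame, TruthRecord]:
    """Templated abstract corpus with planted pollination evidence.

    Returns (corpus, taxonomy, truth): ``corpus`` maps abstract id -> text.
    The truth roster (direct confidences, blocklist, extrapolated groups) is
    derived here by direct application of the evidence rules, independently
    of the roster module's implementation.
    """
    config.validate()
    if taxonomy is None:
        taxonomy = build_taxonomy(config)
    rng = np.random.default_rng(_derive_seed(config.seed, "corpus"))
    genera = taxonomy["genus"].to_numpy()
    n_ev = config.n_evidence_genera
    n_neg = config.n_negative_genera
    if n_ev + n_neg > len(genera):
        raise ConfigError("requested more evidence genera than taxonomy contains")

    chosen = rng.choice(len(genera), size=n_ev + n_neg, replace=False)
    pos_genera = genera[chosen[:n_ev]]
    neg_genera = genera[chosen[n_ev:]]

    used_ep: set = set()
    corpus: dict[str, str] = {}
    direct: dict[str, int] = {}
    abs_no = 0

    def binom(g):
        return f"{g} {_make_name(rng, 2, used_ep) + 'is'}"

    for g in pos_genera:
        levels = rng.integers(1, 5, size=int(rng.integers(1, 3)))
        direct[g] = int(levels.min())       # best evidence = lowest number
        for lv in levels:
            abs_no += 1
            corpus[f"A{abs_no:04d}"] = _FILLER + _CUES[int(lv)].format(b=binom(g))
    for g in neg_genera:
        abs_no += 1
        tmpl = _NEGATIVE_CUES[int(rng.integers(0, len(_NEGATIVE_CUES)))]
        corpus[f"A{abs_no:04d}"] = _FILLER + tmpl.format(b=binom(g))
    for _ in range(config.n_distractor_abstracts):
        abs_no += 1
        plant = _make_name(rng, 3, used_ep).capitalize()
        corpus[f"A{abs_no:04d}"] = (_FILLER +
            f"Flowering of {plant} {_make_name(rng, 2, used_ep)}a "
            "was recorded alongside unrelated soil measurements.")

    truth = TruthRecord(direct_confidence=direct, blocklist=set(neg_genera))
    truth.group_entries = _truth_groups(taxonomy, set(direct), truth.blocklist)
    covered = set(direct)
    for taxon, level in truth.group_entries:
        covered |= set(_genera_under(taxonomy, taxon, level))
    truth.pollinator_genera = covered
    return corpus, taxonomy, truth


def _genera_under(tax: pd.DataFrame, taxon: str, level: str) -> list:
    return tax.loc[tax[level] == taxon, "genus"].tolist()


def _truth_groups(tax: pd.DataFrame, confident: set, blocked: set) -> set:
    """Brute-force application of the multiple-branch extrapolation rule.

    A group (family, then subfamily, then tribe) is wholly pollinating when
    at least two of its immediate sub-lineages contain a genus with direct
    evidence and the group contains no genus with contrary evidence.
    Written as plain nested loops, separate from the roster module's
    recursive implementation, so the two can be checked against each other.
    """
    out = set()
    for family, fam in tax.groupby("family"):
        if set(fam["genus"]) & blocked:
            fam_ok = False
        else:
            branches = set()
            for _, r in fam.iterrows():
                if r["genus"] in confident:
                    branches.add(r["subfamily"] if pd.notna(r["subfamily"])
                                 else ("genus:" + r["genus"]))
            fam_ok = len(branches) >= 2
        if fam_ok:
            out.add((family, "family"))
            continue
        for sub, subdf in fam.dropna(subset=["subfamily"]).groupby("subfamily"):
            if set(subdf["genus"]) & blocked:
                sub_ok = False
            else:
                branches = set()
                for _, r in subdf.iterrows():
                    if r["genus"] in confident:
                        branches.add(r["tribe"] if pd.notna(r["tribe"])
                                     else ("genus:" + r["genus"]))
                sub_ok = len(branches) >= 2
            if sub_ok:
                out.add((sub, "subfamily"))
                continue
            for tribe, trdf in subdf.dropna(subset=["tribe"]).groupby("tribe"):
                if set(trdf["genus"]) & blocked:
                    continue
                if len(set(trdf["genus"]) & confident) >= 2:
                    out.add((tribe, "tribe"))
    return out


def write_corpus(corpus: dict, outdir) -> None:
    """One plain-text file per abstract."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for aid, text in corpus.items():
        (outdir / f"{aid}.txt").write_text(text)


# ---------------------------------------------------------------------------
# covariate surfaces
# ---------------------------------------------------------------------------

@dataclass
class SurfaceParams:
    """Smooth-field parameters: constant background plus Gaussian bumps."""
    constant: float = 0.0
    n_bumps: int = 0
    bump_amplitude: float = 1.0
    bump_width_deg: float = 5.0
    noise_sd: float = 0.0


def generate_covariate_grid(extent, resolution_arcmin: float,
                            surface: SurfaceParams, seed: int
                            ) -> CovariateGrid:
    """Non-negative smooth gridded surface over a lon/lat box.

    ``extent`` is (xmin, xmax, ymin, ymax) in decimal degrees; the
    resolution (arc-minutes) must divide the extent evenly.
    """
    if resolution_arcmin <= 0:
        raise ConfigError("resolution must be positive")
    xmin, xmax, ymin, ymax = extent
    cs = resolution_arcmin / 60.0
    ncols = (xmax - xmin) / cs
    nrows = (ymax - ymin) / cs
    if not (np.isclose(ncols, round(ncols)) and np.isclose(nrows, round(nrows))):
        raise ConfigError("resolution does not divide the extent evenly")
    ncols, nrows = int(round(ncols)), int(round(nrows))
    rng = np.random.default_rng(seed)
    xc = xmin + cs * (np.arange(ncols) + 0.5)
    yc = ymax - cs * (np.arange(nrows) + 0.5)       # row 0 = north
    XX, YY = np.meshgrid(xc, yc)
    vals = np.full((nrows, ncols), float(surface.constant))
    for _ in range(surface.n_bumps):
        bx = rng.uniform(xmin, xmax)
        by = rng.uniform(ymin, ymax)
        amp = rng.uniform(0, surface.bump_amplitude)
        w = surface.bump_width_deg
        vals += amp * np.exp(-((XX - bx) ** 2 + (YY - by) ** 2) / (2 * w ** 2))
    if surface.noise_sd > 0:
        vals += rng.normal(0, surface.noise_sd, vals.shape)
    vals = np.maximum(vals, 0.0)            # application rates cannot go negative
    return CovariateGrid(values=vals, xllcorner=xmin, yllcorner=ymin,
                         cellsize=cs)
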