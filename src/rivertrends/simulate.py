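"""Synthetic kick-sample surveys with known ground truth.

Counts follow the same generative hierarchy the trend models assume: for
group g at site s in year t (t = year - first year),

    log lambda = beta0_g + beta1_g * t + u0_s + u1_s * t + v_t + eps_obs,

with (u0, u1) bivariate normal site intercept/slope effects, v_t a shared
year shock, and eps_obs an independent per-record normal deviate (the
observation-level random effect producing overdispersed, Poisson-lognormal
counts).  Each site-year-season is sampled independently with probability
``p_season_sampled``, emulating the patchy site-year coverage of national
monitoring data.  Sites receive sediment proportions and altitudes
consistent with an intended river typology class drawn from
``typology_mix``.

Randomness comes from one seed; per-site sub-streams are spawned
deterministically, so identical configurations reproduce byte-identical
tables and raising ``p_season_sampled`` under the same seed never removes
a sampled site-season.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import typology as typ
from .errors import ConfigurationError
from .records import KICK_METHOD, SAMPLE_COLUMNS, WIDER_GROUPS
from .traits import DIET_COMPONENTS

#: Table of intended-class frequencies matching the six typology classes, from
#: the national site census (525, 3289, 72, 45, 525, 553 sites).
DEFAULT_TYPOLOGY_MIX = tuple(
    np.array([525, 3289, 72, 45, 525, 553], dtype=float) / 5009.0
)

#: Diet-score templates used to build a synthetic trait table per guild.
_GUILD_TEMPLATES = {
    "carnivore": {
        "living_macroinvertebrates": 5,
        "living_microinvertebrates": 4,
        "dead_animal_ge1mm": 2,
        "vertebrates": 1,
    },
    "herbivore": {
        "living_microphytes": 5,
        "living_macrophytes": 3,
        "detritus_lt1mm": 1,
    },
    "decomposer": {
        "detritus_lt1mm": 5,
        "dead_plant_ge1mm": 4,
        "microorganisms": 2,
    },
}


@dataclass(frozen=True)
class GroupSpec:
    """One simulated taxonomic group: members, baseline and trend.

    ``beta0`` is the baseline log abundance per kick sample in the first
    year; ``beta1`` the annual log-linear trend.  ``members`` lists
    (genus, family) pairs; one count record is generated per member per
    sample.  ``guild`` picks the diet-score template for the synthetic
    trait table so the group lands in a known trophic guild.
    """

    group: str
    members: tuple[tuple[str, str], ...]
    beta0: float
    beta1: float
    guild: str = "decomposer"


def default_taxa_spec() -> tuple[GroupSpec, ...]:
    """Three single-genus groups with one exemplar per trophic guild.

    Baselines and trends follow the national trophic-level estimates
    (carnivores +, herbivores +, decomposers -).
    """
    return (
        GroupSpec("Odonata", (("Coenagrion", "Coenagrionidae"),), 3.513, 0.010, "carnivore"),
        GroupSpec("Ephemeroptera", (("Baetis", "Baetidae"),), 5.053, 0.008, "herbivore"),
        GroupSpec("Diptera", (("Chironomus", "Chironomidae"),), 5.921, -0.014, "decomposer"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic survey.

    Variance defaults sit at the magnitudes typical of the national fits
    (site-intercept SD 1.0, site-slope SD 0.06, year SD 0.1, OLRE SD 0.9),
    and the default sampling probability 0.4 reproduces the observed
    density of roughly 0.75 samples per site-year over an 18-year series.
    """

    n_sites: int = 100
    year_range: tuple[int, int] = (2002, 2019)
    typology_mix: tuple[float, ...] = DEFAULT_TYPOLOGY_MIX
    taxa_spec: tuple[GroupSpec, ...] = field(default_factory=default_taxa_spec)
    sd_site_intercept: float = 1.0
    sd_site_slope: float = 0.06
    corr_site: float = 0.0
    sd_year: float = 0.1
    sd_olre: float = 0.9
    p_season_sampled: float = 0.4
    season_offset: float = 0.0
    include_zero_counts: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be a positive integer")
        y0, y1 = self.year_range
        if y1 < y0:
            raise ConfigurationError("year_range must be an increasing pair")
        mix = np.asarray(self.typology_mix, dtype=float)
        if mix.shape != (6,):
            raise ConfigurationError(
                "typology_mix must have 6 entries (one per typology class)"
            )
        if (mix < 0).any():
            raise ConfigurationError("typology_mix entries must be >= 0")
        if abs(mix.sum() - 1.0) > 5e-3:
            raise ConfigurationError(
                f"typology_mix sums to {mix.sum():.6f}, not 1"
            )
        object.__setattr__(self, "typology_mix", tuple(mix / mix.sum()))
        for name in ("sd_site_intercept", "sd_site_slope", "sd_year", "sd_olre"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not -1.0 <= self.corr_site <= 1.0:
            raise ConfigurationError("corr_site must lie in [-1, 1]")
        if not 0.0 <= self.p_season_sampled <= 1.0:
            raise ConfigurationError("p_season_sampled must lie in [0, 1]")
        if not self.taxa_spec:
            raise ConfigurationError("taxa_spec must not be empty")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_range[0], self.year_range[1] + 1)


@dataclass
class GroundTruth:
    """Realized latent quantities of one simulated survey.

    Indexed frames: site effects by site_id (u0, u1, typology), year shocks
    by year, and the fixed group parameters.  ``site_year(site_id, year)``
    returns the latent (u0 + u1*t + v_t) contribution for that cell.
    """

    site_effects: pd.DataFrame
    year_effects: pd.DataFrame
    group_params: pd.DataFrame
    year0: int

    def site_year(self, site_id, year) -> float:
        u = self.site_effects.loc[site_id]
        v = self.year_effects.loc[year, "v"]
        t = year - self.year0
        return float(u["u0"] + u["u1"] * t + v)

    def write(self, out_dir) -> None:
        self.site_effects.reset_index().to_csv(
            f"{out_dir}/truth_site_effects.csv", index=False
        )
        self.year_effects.reset_index().to_csv(
            f"{out_dir}/truth_year_effects.csv", index=False
        )
        self.group_params.to_csv(f"{out_dir}/truth_group_params.csv", index=False)


def _site_streams(config: SimulationConfig):
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_sites + 1)
    global_rng = np.random.default_rng(children[0])
    site_rngs = [np.random.default_rng(c) for c in children[1:]]
    return global_rng, site_rngs


_CLASS_SEDIMENTS = {
    "Calcareous": ("chalk", "limestone"),
    "Siliceous": ("clay", "hardrock"),
    "Organic": ("peat",),
}


def generate_sites(config: SimulationConfig) -> pd.DataFrame:
    """Draw ``n_sites`` sites whose sediments/altitude match an intended class.

    Each site's intended typology class is drawn from ``typology_mix``; its
    dominant sediment receives a strict-majority share (>= 0.55) so the
    per-sediment dominance rule recovers the intended geology, and altitude
    is drawn above/below the 200 m boundary accordingly.  The returned table
    carries the site CSV dialect columns plus the derived ``typology``.
    """
    if not config.taxa_spec:
        raise ConfigurationError("taxa_spec must not be empty")
    global_rng, _ = _site_streams(config)
    classes = global_rng.choice(
        len(typ.TYPOLOGY_CLASSES), size=config.n_sites, p=config.typology_mix
    )
    rows = []
    for i, ci in enumerate(classes):
        cls = typ.TYPOLOGY_CLASSES[ci]
        geology, band = cls.split("/")
        dominant = _CLASS_SEDIMENTS[geology][
            global_rng.integers(len(_CLASS_SEDIMENTS[geology]))
        ]
        share = global_rng.uniform(0.55, 0.9)
        others = [s for s in typ.SEDIMENTS if s != dominant]
        rest = global_rng.dirichlet(np.ones(len(others))) * (1.0 - share)
        props = dict(zip(others, rest))
        props[dominant] = share
        altitude = (
            global_rng.uniform(typ.HIGH_ALTITUDE_M, 700.0)
            if band == "High"
            else global_rng.uniform(5.0, typ.HIGH_ALTITUDE_M - 1.0)
        )
        rows.append(
            {
                "site_id": f"S{i:05d}",
                **{f"prop_{s}": props[s] for s in typ.SEDIMENTS},
                "mean_catchment_altitude_m": altitude,
            }
        )
    sites = pd.DataFrame(rows, columns=list(typ.SITE_COLUMNS))
    sites = typ.classify_sites(sites)
    intended = [typ.TYPOLOGY_CLASSES[c] for c in classes]
    if list(sites["typology"]) != intended:
        raise AssertionError("generated sites inconsistent with intended classes")
    return sites


def generate_survey(
    sites: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate count records for every sampled site-year-season.

    Returns the record table (sample CSV dialect plus derived year/season)
    and the realized :class:`GroundTruth`.
    """
    if sites.empty:
        raise ConfigurationError("sites table is empty")
    if not config.taxa_spec:
        raise ConfigurationError("taxa_spec must not be empty")

    # Fresh streams per call: survey draws do not depend on whether
    # generate_sites() consumed the global stream first.
    global_rng, site_rngs = _site_streams(config)
    years = config.years
    y0 = years[0]
    v = global_rng.normal(0.0, config.sd_year, size=len(years))

    cov = np.array(
        [
            [
                config.sd_site_intercept**2,
                config.corr_site * config.sd_site_intercept * config.sd_site_slope,
            ],
            [
                config.corr_site * config.sd_site_intercept * config.sd_site_slope,
                config.sd_site_slope**2,
            ],
        ]
    )

    season_months = {"spring": (3, 4, 5), "autumn": (9, 10, 11)}
    records: list[tuple] = []
    site_eff = []
    site_ids = list(sites["site_id"])
    for s_idx, site_id in enumerate(site_ids):
        rng = site_rngs[s_idx % len(site_rngs)]
        u0, u1 = rng.multivariate_normal(np.zeros(2), cov)
        site_eff.append((site_id, u0, u1))
        # All sampling uniforms drawn up front: the sampled-design indicator
        # is a monotone function of p_season_sampled under a fixed seed.
        uniforms = rng.random((len(years), 2))
        for t, year in enumerate(years):
            for k, season in enumerate(("spring", "autumn")):
                if uniforms[t, k] >= config.p_season_sampled:
                    continue
                months = season_months[season]
                month = months[rng.integers(3)]
                day = int(rng.integers(1, 29))
                date = f"{year:04d}-{month:02d}-{day:02d}"
                sample_id = f"{site_id}-{year}-{season}"
                offset = config.season_offset if season == "autumn" else 0.0
                for spec in config.taxa_spec:
                    for genus, _family in spec.members:
                        eps = rng.normal(0.0, config.sd_olre)
                        log_mu = (
                            spec.beta0
                            + spec.beta1 * t
                            + u0
                            + u1 * t
                            + v[t]
                            + offset
                            + eps
                        )
                        count = int(rng.poisson(np.exp(np.clip(log_mu, -30, 30))))
                        if count == 0 and not config.include_zero_counts:
                            continue
                        records.append(
                            (
                                site_id,
                                sample_id,
                                date,
                                KICK_METHOD,
                                genus,
                                "genus",
                                count,
                                year,
                                season,
                            )
                        )

    df = pd.DataFrame(
        records, columns=list(SAMPLE_COLUMNS) + ["year", "season"]
    )
    if not df.empty:
        df["date"] = pd.to_datetime(df["date"])

    truth = GroundTruth(
        site_effects=pd.DataFrame(
            site_eff, columns=["site_id", "u0", "u1"]
        ).set_index("site_id"),
        year_effects=pd.DataFrame({"year": years, "v": v}).set_index("year"),
        group_params=pd.DataFrame(
            [
                {"group": s.group, "beta0": s.beta0, "beta1": s.beta1}
                for s in config.taxa_spec
            ]
        ),
        year0=int(y0),
    )
    truth.site_effects = truth.site_effects.join(
        sites.set_index("site_id")["typology"], how="left"
    )
    return df, truth


def taxonomy_table(taxa_spec: tuple[GroupSpec, ...]) -> pd.DataFrame:
    """Taxonomy CSV rows (genus, family and higher-group entries) for a spec."""
    rows = []
    for spec in taxa_spec:
        if spec.group not in WIDER_GROUPS:
            raise ConfigurationError(
                f"group {spec.group!r} not in the wider-group vocabulary"
            )
        for genus, family in spec.members:
            rows.append((genus, "genus", family, spec.group))
            rows.append((family, "family", family, spec.group))
        rows.append((spec.group, "higher-group", "", spec.group))
    return pd.DataFrame(
        rows, columns=["taxon_name", "rank", "family", "group"]
    ).drop_duplicates(subset="taxon_name", ignore_index=True)


def trait_table(taxa_spec: tuple[GroupSpec, ...]) -> pd.DataFrame:
    """Synthetic genus-level fuzzy-coded trait table matching each group's guild.

    A stand-in for a published trait database: schema-compatible, with each
    genus given the integer 0-5 template of its configured guild.
    """
    rows = []
    for spec in taxa_spec:
        template = _GUILD_TEMPLATES.get(spec.guild)
        if template is None:
            raise ConfigurationError(f"unknown guild {spec.guild!r}")
        for genus, _family in spec.members:
            rows.append(
                {"genus": genus, **{c: template.get(c, 0) for c in DIET_COMPONENTS}}
            )
    return (
        pd.DataFrame(rows)
        .drop_duplicates(subset="genus", ignore_index=True)
        .set_index("genus")
    )


def write_survey(out_dir, config: SimulationConfig) -> dict:
    """Generate a full survey and write every CSV dialect to ``out_dir``.

    Writes samples.csv, sites.csv, taxonomy.csv, traits.csv and the ground
    truth tables; returns the in-memory objects.
    """
    sites = generate_sites(config)
    df, truth = generate_survey(sites, config)
    sites.to_csv(f"{out_dir}/sites.csv", index=False)
    out = df[list(SAMPLE_COLUMNS)].copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(f"{out_dir}/samples.csv", index=False)
    taxonomy_table(config.taxa_spec).to_csv(f"{out_dir}/taxonomy.csv", index=False)
    trait_table(config.taxa_spec).reset_index().to_csv(
        f"{out_dir}/traits.csv", index=False
    )
    truth.write(out_dir)
    return {"sites": sites, "records": df, "truth": truth}


def config_from_mapping(mapping: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML/JSON-style mapping."""
    mapping = dict(mapping)
    if "taxa_spec" in mapping:
        specs = []
        for item in mapping["taxa_spec"]:
            members = tuple((g, f) for g, f in item["members"])
            specs.append(
                GroupSpec(
                    item["group"],
                    members,
                    float(item["beta0"]),
                    float(item["beta1"]),
                    item.get("guild", "decomposer"),
                )
            )
        mapping["taxa_spec"] = tuple(specs)
    if "year_range" in mapping:
        mapping["year_range"] = tuple(mapping["year_range"])
    if "typology_mix" in mapping:
        mapping["typology_mix"] = tuple(mapping["typology_mix"])
    try:
        return SimulationConfig(**mapping)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
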