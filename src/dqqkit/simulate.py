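"""Synthetic multistage survey generator.

Emulates the structure of a Gallup-World-Poll-style diet-quality survey of
five Southeast Asian countries: roughly 1000 respondents aged 15+ per
country, in-person countries sampled as 100-125 clusters of 8-10 interviews
and telephone countries as independent respondents (single-respondent
clusters).  Food-group consumption is drawn per stratum (adolescents 15-19
vs adults 20+) with a beta-distributed cluster-level random effect, giving
exact marginal prevalences and a configurable within-cluster pairwise
correlation (ICC).  The cluster effect for a food group is shared by both
age strata in a cluster — a village's food environment affects everyone —
so between-stratum contrasts are less design-inflated than level estimates,
as in real multistage surveys.

Food groups are independent given the cluster effect by default; an optional
latent "diet healthfulness" factor (one standard-deviation parameter on the
logit scale, raising promote-group and lowering limit-group odds) induces
cross-group correlation at the cost of slightly perturbing marginal
prevalences.

Generation is deterministic given the seed: independent numpy substreams
are spawned per country, and within a country per purpose (demographics,
cluster effects, one stream per food group).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .indicators import Respondent
from .taxonomy import FoodGroupVector, food_group, food_group_codes

IN_PERSON = "in_person"
TELEPHONE = "telephone"

# Default per-group consumption prevalences (fraction, adolescent 15-19 /
# adult 20+) matching the published five-country pooled 24-h recall rates.
DEFAULT_PREVALENCE: dict[str, tuple[float, float]] = {
    "grain_based_staple_foods": (0.973, 0.974),
    "whole_grains": (0.221, 0.182),
    "roots_and_tubers": (0.328, 0.318),
    "pulses_legumes": (0.413, 0.413),
    "nuts_and_seeds": (0.182, 0.212),
    "vitamin_a_rich_orange_vegetables": (0.436, 0.444),
    "dark_green_leafy_vegetables": (0.645, 0.705),
    "other_vegetables": (0.714, 0.754),
    "vitamin_a_rich_fruits": (0.299, 0.298),
    "citrus_fruits": (0.236, 0.341),
    "other_fruits": (0.605, 0.590),
    "eggs": (0.641, 0.616),
    "cheese": (0.108, 0.082),
    "yogurt": (0.067, 0.097),
    "milk": (0.253, 0.232),
    "poultry": (0.484, 0.451),
    "fish_and_seafood": (0.603, 0.633),
    "unprocessed_red_meat_ruminants": (0.228, 0.244),
    "unprocessed_red_meat_non_ruminants": (0.340, 0.431),
    "processed_meats": (0.334, 0.222),
    "baked_grain_based_sweets": (0.418, 0.375),
    "other_sweets": (0.420, 0.266),
    "salty_snacks": (0.269, 0.140),
    "instant_noodles": (0.443, 0.352),
    "deep_fried_foods": (0.332, 0.287),
    "fast_foods": (0.046, 0.049),
    "sweet_tea_coffee_cocoa": (0.415, 0.437),
    "fruit_juice_fruit_flavoured_drinks": (0.259, 0.216),
    "soft_drinks_and_energy_sports_drinks": (0.294, 0.257),
}

DEFAULT_ADOLESCENT_SHARE = 0.095


@dataclass(frozen=True)
class CountryDesign:
    """Sampling design of one country.

    In-person countries are multistage: ``n_clusters`` (100-125) times
    ``interviews_per_cluster`` (8-10).  Telephone countries draw
    ``n_respondents`` independent respondents.
    """

    name: str
    mode: str  # "in_person" | "telephone"
    n_clusters: Optional[int] = None
    interviews_per_cluster: Optional[int] = None
    n_respondents: Optional[int] = None
    adolescent_share: Optional[float] = None  # falls back to config default

    def __post_init__(self) -> None:
        if self.mode == IN_PERSON:
            if self.n_clusters is None or self.interviews_per_cluster is None:
                raise ValueError("in-person design needs n_clusters and interviews_per_cluster")
            if not 100 <= self.n_clusters <= 125:
                raise ValueError("n_clusters must be within 100-125 for in-person designs")
            if not 8 <= self.interviews_per_cluster <= 10:
                raise ValueError("interviews_per_cluster must be within 8-10")
        elif self.mode == TELEPHONE:
            if self.n_respondents is None or self.n_respondents < 1:
                raise ValueError("telephone design needs n_respondents >= 1")
        else:
            raise ValueError(f"mode must be '{IN_PERSON}' or '{TELEPHONE}'")
        if self.adolescent_share is not None and not 0.0 <= self.adolescent_share <= 1.0:
            raise ValueError("adolescent_share must be in [0, 1]")

    @property
    def n_total(self) -> int:
        if self.mode == IN_PERSON:
            return self.n_clusters * self.interviews_per_cluster
        return self.n_respondents


@dataclass(frozen=True)
class DemographicMargins:
    """Marginal demographic distributions for one age group."""

    female: float
    rural: float
    primary_or_less: float
    education_unknown: float
    wealth: tuple[float, float, float, float, float]

    def __post_init__(self) -> None:
        for p in (self.female, self.rural, self.primary_or_less, self.education_unknown):
            if not 0.0 <= p <= 1.0:
                raise ValueError("demographic proportions must lie in [0, 1]")
        if self.primary_or_less + self.education_unknown > 1.0:
            raise ValueError("education margins exceed 1")
        if len(self.wealth) != 5 or abs(sum(self.wealth) - 1.0) > 1e-9:
            raise ValueError("wealth quintile probabilities must be 5 values summing to 1")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full generator configuration; deterministic given ``seed``."""

    countries: tuple[CountryDesign, ...]
    margins: dict[str, DemographicMargins]  # keys: "adolescent", "adult"
    prevalence: dict[str, dict[str, float]]  # code -> {"adolescent": p, "adult": p}
    adolescent_share: float = DEFAULT_ADOLESCENT_SHARE
    icc: float = 0.05
    healthfulness_sd: float = 0.0
    adult_age_shape: float = 2.0
    adult_age_scale: float = 11.0
    max_age: int = 95
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.countries:
            raise ValueError("at least one country is required")
        if set(self.margins) != {"adolescent", "adult"}:
            raise ValueError("margins must be given for 'adolescent' and 'adult'")
        if set(self.prevalence) != set(food_group_codes()):
            raise ValueError("prevalence table must cover all 29 food groups")
        for code, per_stratum in self.prevalence.items():
            for stratum in ("adolescent", "adult"):
                p = per_stratum[stratum]
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"prevalence out of [0,1] for {code}/{stratum}")
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must lie in [0, 1)")
        if not 0.0 <= self.adolescent_share <= 1.0:
            raise ValueError("adolescent_share must lie in [0, 1]")
        if self.healthfulness_sd < 0:
            raise ValueError("healthfulness_sd must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["countries"] = [asdict(c) for c in self.countries]
        d["margins"] = {k: asdict(v) for k, v in self.margins.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["countries"] = tuple(CountryDesign(**c) for c in d["countries"])
        d["margins"] = {
            k: DemographicMargins(**{**m, "wealth": tuple(m["wealth"])})
            for k, m in d["margins"].items()
        }
        return cls(**d)


def default_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """The five-country study scenario.

    Three in-person countries (multistage clusters) and two telephone
    countries, ~1000 respondents each; adolescent share per country chosen
    so the pooled share is ~9.5%; per-group prevalences from the published
    pooled adolescent/adult consumption rates.
    """
    countries = (
        CountryDesign("Cambodia", IN_PERSON, n_clusters=125, interviews_per_cluster=8,
                      adolescent_share=0.090),
        CountryDesign("Indonesia", IN_PERSON, n_clusters=118, interviews_per_cluster=9,
                      adolescent_share=0.108),
        CountryDesign("Laos", IN_PERSON, n_clusters=125, interviews_per_cluster=8,
                      adolescent_share=0.109),
        CountryDesign("Philippines", TELEPHONE, n_respondents=1000, adolescent_share=0.132),
        CountryDesign("Vietnam", TELEPHONE, n_respondents=1007, adolescent_share=0.033),
    )
    margins = {
        "adolescent": DemographicMargins(
            female=0.603, rural=0.639, primary_or_less=0.345, education_unknown=0.002,
            wealth=(0.213, 0.173, 0.219, 0.205, 0.190),
        ),
        "adult": DemographicMargins(
            female=0.578, rural=0.552, primary_or_less=0.408, education_unknown=0.004,
            wealth=(0.180, 0.175, 0.186, 0.203, 0.256),
        ),
    }
    prevalence = {
        code: {"adolescent": a, "adult": b} for code, (a, b) in DEFAULT_PREVALENCE.items()
    }
    return ScenarioConfig(
        countries=countries, margins=margins, prevalence=prevalence, seed=seed, **overrides
    )


# ---------------------------------------------------------------------------
# Consumption draws with a cluster-level random effect
# ---------------------------------------------------------------------------


def generate_consumption(
    prevalence: Union[float, Sequence[float]],
    icc: float,
    cluster_assignments: Sequence,
    rng: np.random.Generator,
    cluster_quantiles: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Binary consumption draws, exchangeable within clusters.

    A cluster-level probability is drawn from a beta distribution with mean
    equal to the marginal ``prevalence`` and variance ``icc * p(1-p)``
    (shape parameters ``a = p(1-icc)/icc``, ``b = (1-p)(1-icc)/icc``), then
    respondents draw independent Bernoulli given their cluster probability.
    This yields marginal mean exactly ``prevalence`` and pairwise
    within-cluster correlation ``icc``; ``icc = 0`` reduces to independent
    draws.

    ``prevalence`` may be per-respondent (e.g. by age stratum); cluster
    effects are then applied through a shared per-cluster uniform quantile so
    strata in one cluster move together.  ``cluster_quantiles`` (one uniform
    per distinct cluster, in order of first appearance) may be supplied to
    share cluster effects across calls; otherwise they are drawn from ``rng``.
    """
    codes, uniques = pd.factorize(pd.Series(list(cluster_assignments)))
    n = len(codes)
    p = np.broadcast_to(np.asarray(prevalence, dtype=float), (n,)).copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("prevalence must lie in [0, 1]")
    if not 0.0 <= icc < 1.0:
        raise ValueError("icc must lie in [0, 1)")
    K = len(uniques)
    if cluster_quantiles is None:
        u = rng.random(K)
    else:
        u = np.asarray(cluster_quantiles, dtype=float)
        if u.shape != (K,):
            raise ValueError("cluster_quantiles must have one value per distinct cluster")
    if icc == 0.0:
        q = p
    else:
        q = np.empty(n)
        interior = (p > 0.0) & (p < 1.0)
        a = p * (1.0 - icc) / icc
        b = (1.0 - p) * (1.0 - icc) / icc
        ui = u[codes]
        q[interior] = stats.beta.ppf(ui[interior], a[interior], b[interior])
        q[~interior] = p[~interior]  # degenerate prevalences stay degenerate
    return rng.random(n) < q


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratedDataset:
    """A generated respondent table plus provenance for reproducibility."""

    frame: pd.DataFrame
    config: ScenarioConfig
    provenance: dict

    def respondents(self) -> Iterator[Respondent]:
        codes = food_group_codes()
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            diet = FoodGroupVector({c: bool(d[c]) for c in codes})
            yield Respondent(
                respondent_id=d["respondent_id"],
                country=d["country"],
                cluster_id=d["cluster_id"],
                weight=float(d["weight"]),
                age_years=int(d["age_years"]),
                gender=d["gender"],
                education=d["education"],
                residence=d["residence"],
                wealth_quintile=int(d["wealth_quintile"]),
                diet=diet,
            )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def write(self, out_dir) -> None:
        """Write the respondent CSV plus the YAML config sidecar."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_csv(out / "respondents.csv")
        with open(out / "scenario.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {"config": self.config.to_dict(), "provenance": self.provenance}, fh
            )


def _config_hash(config: ScenarioConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _country_slug(name: str) -> str:
    return "".join(ch for ch in name.upper() if ch.isalpha())[:3]


def generate_population(config: ScenarioConfig) -> GeneratedDataset:
    """Generate the full multi-country respondent table.

    Deterministic given ``config.seed``: the root seed sequence spawns one
    child per country; each country spawns one stream for demographics, one
    for cluster effects and one per food group.
    """
    root = np.random.SeedSequence(config.seed)
    country_seeds = root.spawn(len(config.countries))
    frames = []
    for country, cseed in zip(config.countries, country_seeds):
        frames.append(_generate_country(config, country, cseed))
    frame = pd.concat(frames, ignore_index=True)
    if frame["respondent_id"].duplicated().any():
        raise RuntimeError("respondent ids must be unique")
    provenance = {"seed": config.seed, "config_hash": _config_hash(config)}
    return GeneratedDataset(frame=frame, config=config, provenance=provenance)


def _generate_country(
    config: ScenarioConfig, country: CountryDesign, cseed: np.random.SeedSequence
) -> pd.DataFrame:
    demo_seed, cluster_seed, *group_seeds = cseed.spawn(2 + 29)
    demo_rng = np.random.default_rng(demo_seed)
    cluster_rng = np.random.default_rng(cluster_seed)

    n = country.n_total
    slug = _country_slug(country.name)
    if country.mode == IN_PERSON:
        cluster_idx = np.repeat(np.arange(country.n_clusters), country.interviews_per_cluster)
    else:
        cluster_idx = np.arange(n)  # telephone: one respondent per "cluster"
    cluster_ids = np.array([f"{slug}-C{j + 1:04d}" for j in cluster_idx])

    share = (
        country.adolescent_share
        if country.adolescent_share is not None
        else config.adolescent_share
    )
    is_adol = demo_rng.random(n) < share
    ages = np.empty(n, dtype=int)
    ages[is_adol] = demo_rng.integers(15, 20, size=int(is_adol.sum()))
    n_adult = int((~is_adol).sum())
    adult_ages = 20 + demo_rng.gamma(config.adult_age_shape, config.adult_age_scale, n_adult)
    ages[~is_adol] = np.minimum(np.round(adult_ages), config.max_age).astype(int)

    gender = np.empty(n, dtype=object)
    education = np.empty(n, dtype=object)
    residence = np.empty(n, dtype=object)
    wealth = np.empty(n, dtype=int)
    for stratum, mask in (("adolescent", is_adol), ("adult", ~is_adol)):
        m = config.margins[stratum]
        k = int(mask.sum())
        if k == 0:
            continue
        gender[mask] = np.where(demo_rng.random(k) < m.female, "female", "male")
        residence[mask] = np.where(demo_rng.random(k) < m.rural, "rural", "urban")
        edu_u = demo_rng.random(k)
        edu = np.where(
            edu_u < m.primary_or_less,
            "completed_primary_or_less",
            np.where(edu_u < m.primary_or_less + m.education_unknown, "unknown",
                     "more_than_primary"),
        )
        education[mask] = edu
        wealth[mask] = demo_rng.choice(np.arange(1, 6), size=k, p=list(m.wealth))

    # latent healthfulness factor (optional cross-group correlation)
    z = demo_rng.standard_normal(n) if config.healthfulness_sd > 0 else None

    consumption: dict[str, np.ndarray] = {}
    n_clusters = len(np.unique(cluster_idx))
    for code, gseed in zip(food_group_codes(), group_seeds):
        grng = np.random.default_rng(gseed)
        p = np.where(
            is_adol,
            config.prevalence[code]["adolescent"],
            config.prevalence[code]["adult"],
        ).astype(float)
        if z is not None:
            sign = 1.0 if food_group(code).category == "promote" else -1.0
            pc = np.clip(p, 1e-9, 1 - 1e-9)
            logit = np.log(pc / (1 - pc)) + sign * config.healthfulness_sd * z
            shifted = 1.0 / (1.0 + np.exp(-logit))
            p = np.where((p > 0) & (p < 1), shifted, p)
        cluster_u = cluster_rng.random(n_clusters)
        consumption[code] = generate_consumption(
            p, config.icc, cluster_idx, grng, cluster_quantiles=cluster_u
        ).astype(int)

    df = pd.DataFrame(
        {
            "respondent_id": [f"{slug}-R{i + 1:05d}" for i in range(n)],
            "country": country.name,
            "cluster_id": cluster_ids,
            "weight": 1.0,
            "age_years": ages,
            "gender": gender,
            "education": education,
            "residence": residence,
            "wealth_quintile": wealth,
        }
    )
    for code in food_group_codes():
        df[code] = consumption[code]
    return df
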