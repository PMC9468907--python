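"""Seeded synthetic quadrat surveys with known ground truth.

The generator emulates the data structure the analysis assumes: multiple
sites along rainfall/soil gradients, ~30 quadrats per site, a species pool
drawn from four growth-form archetypes that differ in the latent means of
the four trait indices, species occurrence driven by a trait x environment
fourth-corner coefficient matrix ``B`` on the logit scale, Dirichlet cover
shares within quadrats, lognormal leaf-table heights (so the grazer use
index emerges from the height pipeline rather than being set directly),
Bernoulli dung presence driven by a site-level grazing pressure, and a
linear dung -> bare-ground effect.

Every random stage draws from its own stream spawned from the single
config seed, so stages can be regenerated independently and the whole
survey is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .survey import Survey, write_survey

TRAITS = ["culm_orientation_index", "lateral_index", "tuft_index", "grazer_use_index"]
ENV_VARS = ["map_mm", "sand_pct", "cec", "ph"]


@dataclass
class Archetype:
    """Latent trait distribution of one growth form.

    ``culm`` is the mean 1-5 culm code, ``lateral``/``tuft`` the mean
    per-record probabilities of lateral spread / a tufted base, and
    ``height_ratio`` the typical ratio of the species' leaf-table height to
    the site median sward height (near 1 for grazer-attractant forms, well
    below 1 for prostrate avoiders, well above 1 for tall resisters).
    """

    culm: float
    culm_sd: float
    lateral: float
    lateral_sd: float
    tuft: float
    tuft_sd: float
    height_ratio: float
    height_ratio_sd: float  # sd of log height ratio across species


#: Default archetypes, qualitatively mirroring the four field growth forms:
#: lateral attractors spread laterally with prostrate culms at sward height;
#: tufted attractors are tufted, near sward height; resisters are tufted,
#: upright and tall (low grazer use); avoiders are sparse and short.
DEFAULT_ARCHETYPES: dict[str, Archetype] = {
    "lateral_attractor": Archetype(1.8, 0.4, 0.85, 0.08, 0.15, 0.08, 1.0, 0.15),
    "avoider": Archetype(2.6, 0.5, 0.45, 0.15, 0.15, 0.08, 0.33, 0.20),
    "tufted_attractor": Archetype(3.2, 0.5, 0.15, 0.08, 0.80, 0.10, 1.0, 0.15),
    "resister": Archetype(4.4, 0.3, 0.10, 0.06, 0.90, 0.06, 2.8, 0.20),
}

#: Default fourth-corner matrix (traits x environment, standardized scales),
#: qualitatively mirroring the associations the field analysis targets:
#: tufted, lateral and upright-culmed species increase with rainfall,
#: prostrate culms with sand and CEC, tufted species on acid soils.
DEFAULT_B = pd.DataFrame(
    [
        # map_mm, sand_pct, cec,   ph
        [0.5, -0.6, -0.3, 0.3],   # culm_orientation_index
        [0.4, 0.2, 0.0, 0.0],     # lateral_index
        [0.5, 0.0, 0.0, -0.3],    # tuft_index
        [0.0, 0.0, 0.2, 0.0],     # grazer_use_index
    ],
    index=TRAITS,
    columns=ENV_VARS,
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic survey generator.

    Defaults reproduce the sampling design of a multi-site grazed-grassland
    survey: 33 sites of 30 quadrats (0.25 m^2), a pool of 48 species split
    evenly over the four archetypes, rainfall 336-987 mm/yr and sand
    44%-93% gradients, and a positive dung -> bare-ground slope.
    """

    seed: int = 0
    n_sites: int = 33
    quadrats_per_site: int = 30
    n_species: int = 48
    archetypes: dict[str, Archetype] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    env_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "map_mm": (336.0, 987.0),
            "sand_pct": (44.0, 93.0),
            "cec": (2.0, 25.0),
            "ph": (4.5, 8.5),
        }
    )
    B: pd.DataFrame = field(default_factory=lambda: DEFAULT_B.copy())
    occurrence_intercept_mean: float = -0.2
    occurrence_intercept_sd: float = 0.5
    quadrat_occupancy: float = 0.55  # P(site species appears in a quadrat)
    cover_concentration: float = 0.4  # Dirichlet parameter; < 1 = few dominants
    total_cover_range: tuple[float, float] = (50.0, 95.0)
    culm_record_sd: float = 0.6  # record-level jitter around the latent culm code
    site_height_mm: float = 60.0  # typical sward leaf-table height
    site_height_log_sd: float = 0.3
    record_height_log_sd: float = 0.25
    bareground_intercept: float = 20.0
    bareground_dung_slope: float = 15.0
    bareground_sd: float = 8.0  # quadrat-level noise
    grazing_pressure_range: tuple[float, float] = (0.2, 0.9)

    def validate(self) -> "SimulationConfig":
        if self.quadrats_per_site < 15:
            raise ValueError("quadrats_per_site must be >= 15 (survey design minimum)")
        if self.bareground_sd < 0 or self.site_height_log_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        return self


@dataclass
class GroundTruth:
    """The generative parameters behind one simulated survey."""

    species_archetype: pd.Series  # species -> archetype label
    species_latent: pd.DataFrame  # species x latent trait values
    B: pd.DataFrame
    bareground_coefficients: dict[str, float]
    site_grazing_pressure: pd.Series
    expected_form_occupancy: pd.DataFrame  # site x form mean presence prob.

    def to_json(self) -> str:
        return json.dumps(
            {
                "species_archetype": self.species_archetype.to_dict(),
                "species_latent": self.species_latent.round(6).to_dict(orient="index"),
                "B": self.B.to_dict(orient="index"),
                "bareground_coefficients": self.bareground_coefficients,
                "site_grazing_pressure": self.site_grazing_pressure.round(6).to_dict(),
                "expected_form_occupancy": self.expected_form_occupancy.round(6).to_dict(
                    orient="index"
                ),
            },
            indent=2,
            sort_keys=True,
        )


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from plain (e.g. YAML-loaded) data.

    Keys are exactly the SimulationConfig fields; ``archetypes`` maps labels
    to Archetype field dicts, ``B`` maps trait names to {env var: value},
    and the range fields accept 2-element lists.
    """
    d = dict(d)
    if "archetypes" in d:
        d["archetypes"] = {
            label: a if isinstance(a, Archetype) else Archetype(**a)
            for label, a in d["archetypes"].items()
        }
    if "B" in d and not isinstance(d["B"], pd.DataFrame):
        B = pd.DataFrame(d["B"]).T.reindex(index=TRAITS, columns=ENV_VARS)
        if B.isna().any().any():
            raise ValueError(
                f"B must cover every trait x environment pair: rows {TRAITS}, "
                f"columns {ENV_VARS}"
            )
        d["B"] = B
    if "env_ranges" in d:
        d["env_ranges"] = {k: tuple(v) for k, v in d["env_ranges"].items()}
    for key in ("total_cover_range", "grazing_pressure_range"):
        if key in d:
            d[key] = tuple(d[key])
    unknown = set(d) - {f.name for f in dataclasses.fields(SimulationConfig)}
    if unknown:
        raise ValueError(f"unknown simulation config key(s): {sorted(unknown)}")
    return SimulationConfig(**d).validate()


def config_from_yaml(path) -> SimulationConfig:
    """Load a simulation config from a YAML file of SimulationConfig keys."""
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi)) if size else float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_species_pool(config: SimulationConfig, rng=None) -> tuple[pd.Series, pd.DataFrame]:
    """Draw the species pool: archetype labels and latent trait parameters.

    Latent lateral/tuft values are truncated-normal draws in [0, 1], culm
    codes in [1, 5], and the log height ratio is normal around the
    archetype's.  An archetype whose mean/SD put more than half its mass
    outside the legal range is rejected as degenerate.
    """
    config.validate()
    if rng is None:
        rng = _streams(config.seed, 6)[0]
    names = sorted(config.archetypes)
    for label in names:
        a = config.archetypes[label]
        for mean, sd, lo, hi in (
            (a.lateral, a.lateral_sd, 0.0, 1.0),
            (a.tuft, a.tuft_sd, 0.0, 1.0),
            (a.culm, a.culm_sd, 1.0, 5.0),
        ):
            if sd > 0:
                inside = stats.norm.cdf(hi, mean, sd) - stats.norm.cdf(lo, mean, sd)
                if inside < 0.5:
                    raise ValueError(
                        f"archetype {label!r}: >50% of trait mass truncated "
                        f"(mean={mean}, sd={sd}, range=[{lo},{hi}])"
                    )
    per = config.n_species // len(names)
    extra = config.n_species - per * len(names)
    labels, rows, species = [], [], []
    i = 0
    for j, label in enumerate(names):
        a = config.archetypes[label]
        count = per + (1 if j < extra else 0)
        for _ in range(count):
            i += 1
            species.append(f"sp{i:03d}")
            labels.append(label)
            rows.append(
                {
                    "culm": _truncnorm(rng, a.culm, a.culm_sd, 1.0, 5.0),
                    "lateral": _truncnorm(rng, a.lateral, a.lateral_sd, 0.0, 1.0),
                    "tuft": _truncnorm(rng, a.tuft, a.tuft_sd, 0.0, 1.0),
                    "log_height_ratio": rng.normal(np.log(a.height_ratio), a.height_ratio_sd),
                }
            )
    latent = pd.DataFrame(rows, index=pd.Index(species, name="species"))
    return pd.Series(labels, index=latent.index, name="archetype"), latent


_CODE_TO_CATEGORY = {
    1: "lateral",
    2: "geniculate-lateral",
    4: "geniculate-upright",
    5: "upright",
}


def _culm_category(code: int, rng) -> str:
    # code 3 covers both geniculate and decumbent orientations
    if code == 3:
        return "geniculate" if rng.random() < 0.5 else "decumbent"
    return _CODE_TO_CATEGORY[code]


def _latent_standardized(latent: pd.DataFrame) -> pd.DataFrame:
    """Latent traits on the standardized scale the occurrence model uses."""
    # grazer use proxy: min(r, 1/r) of the typical height ratio
    ratio = np.exp(latent["log_height_ratio"])
    use = np.minimum(ratio, 1.0 / ratio)
    Z = pd.DataFrame(
        {
            "culm_orientation_index": latent["culm"],
            "lateral_index": latent["lateral"],
            "tuft_index": latent["tuft"],
            "grazer_use_index": use,
        }
    )
    sd = Z.std(ddof=0).replace(0.0, 1.0)  # constant traits carry no signal
    return (Z - Z.mean()) / sd


def simulate_survey(
    config: SimulationConfig, out_dir=None
) -> tuple[Survey, GroundTruth]:
    """Generate a full synthetic survey and its ground truth.

    Stage streams (all spawned from ``config.seed``): species pool,
    environment, occurrence, quadrat composition/cover, heights,
    dung & bare ground.  With ``out_dir`` set the survey CSVs and
    ``ground_truth.json`` are written there.
    """
    config.validate()
    rng_pool, rng_env, rng_occ, rng_quad, rng_height, rng_ground = _streams(config.seed, 6)

    archetype, latent = simulate_species_pool(config, rng_pool)
    species = list(latent.index)
    n_sp = len(species)

    # --- sites along environment gradients -------------------------------
    site_ids = [f"S{i + 1:02d}" for i in range(config.n_sites)]
    env = pd.DataFrame(
        {
            v: rng_env.uniform(lo, hi, config.n_sites)
            for v, (lo, hi) in config.env_ranges.items()
        },
        index=pd.Index(site_ids, name="site_id"),
    )
    env_z = (env - env.mean()) / env.std(ddof=0)

    # --- occurrence: logit P = alpha_s + traits' B env -------------------
    alpha = rng_occ.normal(
        config.occurrence_intercept_mean, config.occurrence_intercept_sd, n_sp
    )
    Tz = _latent_standardized(latent)
    eta = (
        alpha[None, :]
        + env_z[ENV_VARS].to_numpy() @ config.B.loc[TRAITS, ENV_VARS].to_numpy().T @ Tz[TRAITS].to_numpy().T
    )
    prob = 1.0 / (1.0 + np.exp(-eta))  # sites x species
    presence = np.zeros_like(prob, dtype=bool)
    for i in range(config.n_sites):
        for _attempt in range(100):
            draw = rng_occ.random(n_sp) < prob[i]
            if draw.sum() >= 2:
                presence[i] = draw
                break
        else:
            raise RuntimeError(f"site {site_ids[i]} drew no species after 100 attempts")

    form_names = sorted(config.archetypes)
    occupancy = pd.DataFrame(
        {f: prob[:, (archetype == f).to_numpy()].mean(axis=1) for f in form_names},
        index=env.index,
    )

    # --- quadrat composition, cover, heights ------------------------------
    site_height = config.site_height_mm * np.exp(
        rng_height.normal(0.0, config.site_height_log_sd, config.n_sites)
    )
    ratio = np.exp(latent["log_height_ratio"]).to_numpy()
    obs_rows = []
    for i, site in enumerate(site_ids):
        present_idx = np.where(presence[i])[0]
        # persistent site-level abundance: a few species dominate every quadrat
        weight = rng_quad.gamma(config.cover_concentration, 1.0, len(present_idx))
        weight = np.maximum(weight, 1e-6)
        p_occ = np.clip(
            config.quadrat_occupancy * np.sqrt(weight / weight.mean()), 0.05, 0.98
        )
        for q in range(config.quadrats_per_site):
            quad = f"Q{q + 1:02d}"
            pick = rng_quad.random(len(present_idx)) < p_occ
            if not pick.any():
                pick[rng_quad.integers(len(present_idx))] = True
            inq = present_idx[pick]
            shares = weight[pick] * np.exp(rng_quad.normal(0.0, 0.3, pick.sum()))
            shares = shares / shares.sum()
            total = rng_quad.uniform(*config.total_cover_range)
            covers = np.maximum(np.round(shares * total, 1), 0.1)
            heights = (
                site_height[i]
                * ratio[inq]
                * np.exp(rng_height.normal(0.0, config.record_height_log_sd, len(inq)))
            )
            heights = np.maximum(np.round(heights), 1.0)
            for j, s_idx in enumerate(inq):
                sp = species[s_idx]
                code = int(
                    np.clip(
                        np.round(
                            latent["culm"].iloc[s_idx]
                            + rng_quad.normal(0, config.culm_record_sd)
                        ),
                        1,
                        5,
                    )
                )
                spreads = rng_quad.random() < latent["lateral"].iloc[s_idx]
                tufted = rng_quad.random() < latent["tuft"].iloc[s_idx]
                if spreads:
                    stolons = rng_quad.random() < 0.7
                    rhizome = "long" if not stolons or rng_quad.random() < 0.3 else "none"
                else:
                    stolons = False
                    rhizome = "short" if tufted and rng_quad.random() < 0.5 else "none"
                obs_rows.append(
                    (
                        site, quad, sp, covers[j], heights[j],
                        _culm_category(code, rng_quad), stolons, rhizome, tufted,
                    )
                )
    observations = pd.DataFrame(
        obs_rows,
        columns=[
            "site_id", "quadrat_id", "species", "cover_pct", "leaf_table_height_mm",
            "culm_orientation", "stolons", "rhizome", "tufted_base",
        ],
    )

    # --- dung and bare ground ---------------------------------------------
    pressure = rng_ground.uniform(*config.grazing_pressure_range, config.n_sites)
    meta_rows = []
    for i, site in enumerate(site_ids):
        dung = rng_ground.random(config.quadrats_per_site) < pressure[i]
        dung_prop = dung.mean()
        bare = np.clip(
            config.bareground_intercept
            + config.bareground_dung_slope * dung_prop
            + rng_ground.normal(0.0, config.bareground_sd, config.quadrats_per_site),
            0.0,
            100.0,
        )
        for q in range(config.quadrats_per_site):
            meta_rows.append((site, f"Q{q + 1:02d}", round(float(bare[q]), 1), bool(dung[q])))
    meta = pd.DataFrame(
        meta_rows, columns=["site_id", "quadrat_id", "bare_ground_pct", "dung_present"]
    )

    sites = env.reset_index()
    survey = Survey(observations, meta, sites).validate()
    truth = GroundTruth(
        species_archetype=archetype,
        species_latent=latent,
        B=config.B.copy(),
        bareground_coefficients={
            "intercept": config.bareground_intercept,
            "dung_slope": config.bareground_dung_slope,
            "sd": config.bareground_sd,
        },
        site_grazing_pressure=pd.Series(pressure, index=env.index),
        expected_form_occupancy=occupancy,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_survey(survey, out_dir)
        (out_dir / "ground_truth.json").write_text(truth.to_json())
    return survey, truth


def simulate_triplet(
    n_sites: int,
    n_species: int,
    B: pd.DataFrame | np.ndarray | None = None,
    seed: int = 0,
    intercept_sd: float = 0.5,
):
    """Directly simulate a community triplet from the fourth-corner model.

    Environment and trait matrices are standard-normal; presence is drawn
    from ``logit P = alpha_s + traits' B env`` with ``B = 0`` by default
    (the null of no trait-environment association).  Used for calibration
    and power studies of the fourth-corner stage without the cost of a full
    quadrat survey.
    """
    from .fourthcorner import CommunityTriplet

    rng = np.random.default_rng(seed)
    Bm = np.zeros((4, 4)) if B is None else np.asarray(B, dtype=float)
    sites = [f"S{i + 1:02d}" for i in range(n_sites)]
    species = [f"sp{j + 1:03d}" for j in range(n_species)]
    R = pd.DataFrame(rng.standard_normal((n_sites, 4)), index=sites, columns=ENV_VARS)
    Q = pd.DataFrame(rng.standard_normal((n_species, 4)), index=species, columns=TRAITS)
    Rz = (R - R.mean()) / R.std(ddof=0)
    Qz = (Q - Q.mean()) / Q.std(ddof=0)
    alpha = rng.normal(0.0, intercept_sd, n_species)
    eta = alpha[None, :] + Rz.to_numpy() @ Bm.T @ Qz.to_numpy().T
    L = (rng.random(eta.shape) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    # guarantee variation in every species column (all-0/all-1 separates)
    for j in range(n_species):
        if L[:, j].sum() == 0:
            L[rng.integers(n_sites), j] = 1
        elif L[:, j].sum() == n_sites:
            L[rng.integers(n_sites), j] = 0
    scaler = pd.DataFrame(
        {"center": np.zeros(4), "scale": np.ones(4)}, index=ENV_VARS
    ).T
    return CommunityTriplet(
        L=pd.DataFrame(L, index=sites, columns=species),
        R=Rz,
        Q=Qz,
        R_scaler=scaler,
        Q_scaler=scaler.rename(columns=dict(zip(ENV_VARS, TRAITS))),
        site_cover=pd.DataFrame(L, index=sites, columns=species, dtype=float),
    )


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_configs() -> dict[str, SimulationConfig]:
    zero_B = DEFAULT_B * 0.0
    planted_B = DEFAULT_B * 0.0
    planted_B.loc["tuft_index", "map_mm"] = 1.0
    return {
        "tiny": SimulationConfig(
            seed=11, n_sites=2, quadrats_per_site=15, n_species=4, quadrat_occupancy=0.9
        ),
        "null": SimulationConfig(seed=12, n_sites=8, quadrats_per_site=20, B=zero_B),
        "planted_clusters": SimulationConfig(seed=13, n_sites=8, quadrats_per_site=30),
        "planted_fourthcorner": SimulationConfig(
            seed=14, n_sites=10, quadrats_per_site=20, B=planted_B
        ),
        "planted_bareground": SimulationConfig(
            seed=15, n_sites=10, quadrats_per_site=30,
            bareground_intercept=20.0, bareground_dung_slope=15.0, bareground_sd=8.0,
        ),
    }


FIXTURE_NAMES = tuple(sorted(_fixture_configs()))


def make_fixture(name: str, out_dir=None) -> tuple[Survey, GroundTruth]:
    """Generate one of the small packaged example surveys.

    ``tiny`` is a 2-site smoke-test survey; ``null`` has no
    trait-environment association (B = 0); ``planted_clusters`` carries
    four well-separated archetypes; ``planted_fourthcorner`` a single
    positive tuft x rainfall coefficient; ``planted_bareground`` a known
    dung -> bare-ground slope.
    """
    configs = _fixture_configs()
    if name not in configs:
        raise ValueError(f"unknown fixture {name!r}; presets: {sorted(configs)}")
    return simulate_survey(configs[name], out_dir=out_dir)
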