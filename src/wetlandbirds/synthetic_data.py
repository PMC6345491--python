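"""Synthetic winter wetland-bird studies with known parameters.

Emulates the design of a two-winter point-count survey of wetlands in an
agricultural landscape: 33 wetlands (20 conservation-easement "ACEP", 13
reference) of 0.28-32.4 ha, a variable number of point-count locations
per wetland (1-9, mean ~4), two survey years, and two replicate visits
per point per year. Occupancy states and detections are generated from
the same logistic-linear sub-models the estimator assumes, and wetland
richness from a Poisson log-linear model, so every pipeline stage can be
tested against known truth without field data.

Covariate generators reproduce the published envelopes of the source
study design (ranges of continuous covariates, level proportions of
categorical ones); empirical joint distributions are not emulated. The
default species effects are centred on the field study's reported
log-odds ratios (e.g. a negative size effect for dark-eyed junco, a
positive one for swamp sparrow).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_data import (
    DetectionTable, ModelSpec, SiteCovariates, SurveyCovariates,
    RichnessTable, build_design, global_spec, LEVELS, SPECIES,
)

__all__ = [
    "SimulationScenario", "SpeciesTruth", "SimulatedStudy",
    "simulate_covariates", "simulate_detections", "simulate_richness",
    "simulate_study", "write_study",
]

#: Level proportions for categorical covariates (same order as LEVELS).
CATEGORY_PROPORTIONS = {
    "herb": (0.22, 0.26, 0.52),
    "shrub1": (0.77, 0.23),
    "bareground": (0.73, 0.27),
    "shrub5": (0.41, 0.37, 0.22),
    "water": (0.85, 0.15),
    "woody": (0.87, 0.13),
    "sky": (0.56, 0.44),
}

#: Uniform ranges for continuous survey covariates.
SURVEY_RANGES = {
    "time": (6.85, 15.22),
    "wind": (0.0, 4.5),
    "temp": (-12.2, 17.8),
    "dist": (0.0, 67.0),
    "day": (1.0, 102.0),
}

SIZE_RANGE = (0.28, 32.4)


@dataclass
class SpeciesTruth:
    """Generating coefficients for one species, on the encoded scale.

    Effects are keyed by covariate name; a scalar applies to every dummy
    column of a categorical covariate, a sequence maps per non-reference
    level. Unlisted covariates have zero effect.
    """

    occ_intercept: float = 0.0
    occ_effects: dict = dc_field(default_factory=dict)
    det_intercept: float = 0.0
    det_effects: dict = dc_field(default_factory=dict)


def _default_truth() -> dict[str, SpeciesTruth]:
    # signs and magnitudes follow the field study's reported effects
    return {
        "sosp": SpeciesTruth(2.0, {"type": 1.1, "shrub1": -2.6},
                             0.5, {"day": -1.1}),
        "deju": SpeciesTruth(-1.5, {"size": -1.6}, 0.3, {"time": 0.8}),
        "swsp": SpeciesTruth(-2.2, {"size": 2.4}, 0.3, {"wind": -0.9}),
        "wtsp": SpeciesTruth(-0.5, {"water": 3.2}, 0.2, {}),
    }


@dataclass
class SimulationScenario:
    """Design envelope and generating parameters for one synthetic study."""

    n_acep: int = 20
    n_reference: int = 13
    n_years: int = 2
    n_visits: int = 2
    # points per wetland: 1 + Binomial(8, 3/8) -> support 1..9, mean 4
    points_binomial_n: int = 8
    points_binomial_p: float = 0.375
    species_truth: dict[str, SpeciesTruth] = dc_field(default_factory=_default_truth)
    # richness: log lambda = c0 + c_type*[reference] + c_size*size_z + c_year*[year 2]
    richness_coefficients: dict = dc_field(default_factory=lambda: {
        "intercept": np.log(15.0), "type": -0.05, "size": 0.2, "year": -0.08,
    })
    seed: int = 0


@dataclass
class SimulatedStudy:
    wetlands: pd.DataFrame
    site_covariates: SiteCovariates
    survey_covariates: SurveyCovariates
    detections: dict[str, DetectionTable]
    latent_z: dict[str, np.ndarray]      # white-box truth; never read by fits
    richness: RichnessTable
    scenario: SimulationScenario


def _rng(seed) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))


def simulate_covariates(scenario: SimulationScenario,
                        seed: int | None = None):
    """Draw wetlands, per-point-year site covariates and per-visit survey
    covariates. Returns ``(SiteCovariates, SurveyCovariates, wetlands)``."""
    rng = _rng(scenario.seed if seed is None else seed)
    n_w = scenario.n_acep + scenario.n_reference
    lo, hi = SIZE_RANGE
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), n_w))
    wetlands = pd.DataFrame({
        "wetland_id": [f"W{i + 1:02d}" for i in range(n_w)],
        "type": ["ACEP"] * scenario.n_acep + ["reference"] * scenario.n_reference,
        "size": np.round(sizes, 2),
        "n_points": 1 + rng.binomial(scenario.points_binomial_n,
                                     scenario.points_binomial_p, n_w),
    })

    site_rows, survey_rows = [], []
    for _, w in wetlands.iterrows():
        for pt in range(int(w["n_points"])):
            site_id = f"{w['wetland_id']}P{pt + 1}"
            for year in range(1, scenario.n_years + 1):
                row = {"site_id": site_id, "wetland_id": w["wetland_id"],
                       "year": str(year), "type": w["type"], "size": w["size"]}
                for name, props in CATEGORY_PROPORTIONS.items():
                    if name == "sky":
                        continue
                    levels = LEVELS[name]
                    row[name] = levels[rng.choice(len(levels), p=props)]
                site_rows.append(row)
                for visit in range(1, scenario.n_visits + 1):
                    srow = {"site_id": site_id, "year": str(year),
                            "visit": visit}
                    for name, (a, b) in SURVEY_RANGES.items():
                        srow[name] = round(float(rng.uniform(a, b)), 2)
                    srow["day"] = float(int(srow["day"]))
                    srow["sky"] = LEVELS["sky"][
                        rng.choice(2, p=CATEGORY_PROPORTIONS["sky"])]
                    survey_rows.append(srow)

    sc = SiteCovariates(pd.DataFrame(site_rows)[list(SiteCovariates.COLUMNS)])
    vc = SurveyCovariates(pd.DataFrame(survey_rows)[list(SurveyCovariates.COLUMNS)])
    sc.validate()
    vc.validate()
    return sc, vc, wetlands


def true_coefficient_vectors(truth: SpeciesTruth, design) -> tuple[np.ndarray, np.ndarray]:
    """Expand a :class:`SpeciesTruth` into (alpha, beta) aligned with the
    design-matrix columns."""
    def expand(intercept, effects, blocks, n_cols):
        vec = np.zeros(n_cols)
        vec[0] = intercept
        for name, val in effects.items():
            cols = blocks[name]
            vals = np.atleast_1d(np.asarray(val, dtype=float))
            if vals.size == 1:
                vals = np.repeat(vals, len(cols))
            if vals.size != len(cols):
                raise ValueError(
                    f"effect for {name!r} has {vals.size} values for "
                    f"{len(cols)} columns")
            vec[cols] = vals
        return vec

    alpha = expand(truth.occ_intercept, truth.occ_effects,
                   design.x_blocks, design.X.shape[1])
    beta = expand(truth.det_intercept, truth.det_effects,
                  design.w_blocks, design.W.shape[1])
    return alpha, beta


def simulate_detections(sc: SiteCovariates, vc: SurveyCovariates,
                        alpha, beta, seed: int,
                        spec: ModelSpec | None = None,
                        species: str = "sosp"):
    """Generate one species' detection histories from the occupancy model.

    z_i ~ Bernoulli(inv-logit(x_i . alpha)); y_ij ~ Bernoulli(z_i *
    inv-logit(w_ij . beta)). Returns ``(DetectionTable, z, design)`` with
    the latent states exposed for white-box testing only.
    """
    spec = spec or global_spec(species)
    skeleton = sc.data[["site_id", "wetland_id", "year"]].copy()
    for j in range(1, N_VISITS_DEFAULT + 1):
        skeleton[f"y{j}"] = 0.0
    det0 = DetectionTable(skeleton.reset_index(drop=True), species=species)
    design = build_design(det0, sc, vc, spec)

    rng = _rng(seed)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    psi = 1.0 / (1.0 + np.exp(-design.X @ alpha))
    p = 1.0 / (1.0 + np.exp(-design.W @ beta))
    z = (rng.random(design.n_sites) < psi).astype(float)
    y_flat = (rng.random(len(p)) < p).astype(float) * z[design.w_site_index]

    data = det0.data.copy()
    y = np.zeros((design.n_sites, N_VISITS_DEFAULT))
    y[design.w_site_index, design.w_visit - 1] = y_flat
    for j in range(N_VISITS_DEFAULT):
        data[f"y{j + 1}"] = y[:, j]
    table = DetectionTable(data, species=species)
    table.validate()
    design.y_w = y_flat  # design was built on an empty skeleton
    return table, z, design


N_VISITS_DEFAULT = 2


def design_skeleton(sc: SiteCovariates, vc: SurveyCovariates,
                    spec: ModelSpec, species: str = "sosp"):
    """Design matrices over all site-units, before any detections exist."""
    skeleton = sc.data[["site_id", "wetland_id", "year"]].copy()
    for j in range(1, N_VISITS_DEFAULT + 1):
        skeleton[f"y{j}"] = 0.0
    det0 = DetectionTable(skeleton.reset_index(drop=True), species=species)
    return build_design(det0, sc, vc, spec)


def simulate_species(sc: SiteCovariates, vc: SurveyCovariates,
                     truth: SpeciesTruth, seed: int,
                     spec: ModelSpec | None = None, species: str = "sosp"):
    """Detection histories for one species from its :class:`SpeciesTruth`."""
    spec = spec or global_spec(species)
    design = design_skeleton(sc, vc, spec, species)
    alpha, beta = true_coefficient_vectors(truth, design)
    return simulate_detections(sc, vc, alpha, beta, seed, spec=spec,
                               species=species)


def simulate_richness(wetlands: pd.DataFrame, coefficients: dict,
                      seed: int, n_years: int = 2) -> RichnessTable:
    """Per wetland-year Poisson richness counts from a log-linear model.

    log lambda = c0 + c_type*[reference] + c_size*size_z + c_year*[year 2],
    with size standardized over wetlands.
    """
    rng = _rng(seed)
    size = wetlands["size"].to_numpy(dtype=float)
    size_z = (size - size.mean()) / size.std(ddof=1)
    is_ref = (wetlands["type"] == "reference").to_numpy(dtype=float)
    rows = []
    for year in range(1, n_years + 1):
        eta = (coefficients["intercept"]
               + coefficients["type"] * is_ref
               + coefficients["size"] * size_z
               + coefficients["year"] * (1.0 if year == 2 else 0.0))
        counts = rng.poisson(np.exp(eta))
        for i, w in wetlands.iterrows():
            rows.append({"wetland_id": w["wetland_id"], "year": str(year),
                         "type": w["type"], "size": w["size"],
                         "richness": int(counts[i])})
    table = RichnessTable(pd.DataFrame(rows)[list(RichnessTable.COLUMNS)])
    table.validate()
    return table


def simulate_study(scenario: SimulationScenario | None = None) -> SimulatedStudy:
    """Generate a complete study: covariates, all four species' detection
    histories, and wetland richness, all reproducible from scenario.seed."""
    scenario = scenario or SimulationScenario()
    ss = np.random.SeedSequence(scenario.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    sc, vc, wetlands = simulate_covariates(scenario, seed=child_seeds[0])
    detections, latent = {}, {}
    for k, sp in enumerate(SPECIES):
        det, z, _ = simulate_species(sc, vc, scenario.species_truth[sp],
                                     seed=child_seeds[1 + k], species=sp)
        detections[sp] = det
        latent[sp] = z
    richness = simulate_richness(wetlands, scenario.richness_coefficients,
                                 seed=child_seeds[5], n_years=scenario.n_years)
    return SimulatedStudy(wetlands=wetlands, site_covariates=sc,
                          survey_covariates=vc, detections=detections,
                          latent_z=latent, richness=richness,
                          scenario=scenario)


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write the four survey CSV dialects (plus the latent-state side table)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    first = study.detections[SPECIES[0]].data
    det = first[["site_id", "wetland_id", "year"]].copy()
    for sp in SPECIES:
        d = study.detections[sp].data
        for j in range(1, study.scenario.n_visits + 1):
            det[f"{sp}{j}"] = d[f"y{j}"].map(
                lambda v: "" if pd.isna(v) else str(int(v)))
    paths = {
        "detections": outdir / "s1_detections.csv",
        "site_covariates": outdir / "s2_site_covariates.csv",
        "survey_covariates": outdir / "s3_survey_covariates.csv",
        "richness": outdir / "s4_richness.csv",
        "latent_z": outdir / "latent_z_synthetic.csv",
    }
    det.to_csv(paths["detections"], index=False)
    study.site_covariates.data.to_csv(paths["site_covariates"], index=False)
    study.survey_covariates.data.to_csv(paths["survey_covariates"], index=False)
    study.richness.data.to_csv(paths["richness"], index=False)
    z = pd.DataFrame({"site_id": first["site_id"], "year": first["year"]})
    for sp in SPECIES:
        z[f"z_{sp}"] = study.latent_z[sp].astype(int)
    z.to_csv(paths["latent_z"], index=False)
    return paths
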