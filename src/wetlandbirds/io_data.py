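"""Reading, validation and design-matrix construction for winter bird survey tables.

Four CSV dialects are supported, mirroring a field study's supplementary
data layout:

* **detections** — two replicate 0/1 surveys per point-count location per
  year, one pair of columns per species (``sosp1, sosp2, ...``);
* **site covariates** — vegetation and wetland attributes per point per
  year (occupancy sub-model);
* **survey covariates** — conditions recorded on each visit (detection
  sub-model);
* **richness** — apparent species counts per wetland per year.

The occupancy replication unit ("site-unit") is a point-count location in
one year, with two replicate visits; year re-enters the occupancy model as
a covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = ("sosp", "swsp", "deju", "wtsp")

#: Level sets for categorical covariates; the first level is the dummy
#: reference. Continuous covariates map to None.
LEVELS: dict[str, tuple[str, ...] | None] = {
    "type": ("ACEP", "reference"),
    "year": ("1", "2"),
    "herb": ("0-25", "26-75", "76-100"),
    "shrub1": ("0-50", "51-100"),
    "bareground": ("0-50", "51-100"),
    "woody": ("absent", "present"),
    "water": ("absent", "present"),
    "shrub5": ("0-25", "26-75", "76-100"),
    "sky": ("0-1", "2-3"),
    "size": None,
    "time": None,
    "wind": None,
    "temp": None,
    "dist": None,
    "day": None,
}

OCCUPANCY_COVARIATES = (
    "herb", "shrub1", "bareground", "shrub5", "water", "woody",
    "size", "type", "year",
)
DETECTION_COVARIATES = ("time", "sky", "wind", "temp", "dist", "day")

N_VISITS = 2


class SchemaError(ValueError):
    """A required column is absent from an input table."""


class ValidationError(ValueError):
    """A cell value violates the table's contract."""


@dataclass
class ModelSpec:
    """Which covariates enter the occupancy (psi) and detection (p) sub-models.

    Intercepts are always included implicitly.
    """

    occupancy_covariates: list[str]
    detection_covariates: list[str]
    species: str = ""

    def __post_init__(self) -> None:
        for name in self.occupancy_covariates:
            if name not in OCCUPANCY_COVARIATES:
                raise ValidationError(f"unknown occupancy covariate {name!r}")
        for name in self.detection_covariates:
            if name not in DETECTION_COVARIATES:
                raise ValidationError(f"unknown detection covariate {name!r}")


def global_spec(species: str = "") -> ModelSpec:
    """The all-covariate model every species' selection starts from."""
    return ModelSpec(
        occupancy_covariates=list(OCCUPANCY_COVARIATES),
        detection_covariates=list(DETECTION_COVARIATES),
        species=species,
    )


@dataclass
class DetectionTable:
    """Per site-unit detection histories.

    ``data`` has one row per point x year with columns ``site_id``,
    ``wetland_id``, ``year`` and visit columns ``y1 .. yJ`` holding
    0.0 / 1.0 / NaN (missing visit).
    """

    data: pd.DataFrame
    species: str = ""
    n_visits: int = N_VISITS

    @property
    def n_sites(self) -> int:
        return len(self.data)

    @property
    def y(self) -> np.ndarray:
        """(n_sites, J) float array with NaN for missing visits."""
        cols = [f"y{j + 1}" for j in range(self.n_visits)]
        return self.data[cols].to_numpy(dtype=float)

    @property
    def any_detection(self) -> np.ndarray:
        return np.nansum(self.y, axis=1) > 0

    def naive_occupancy(self) -> float:
        """Fraction of site-units with at least one detection."""
        return float(self.any_detection.mean())

    def validate(self) -> None:
        y = self.y
        bad = ~(np.isnan(y) | (y == 0) | (y == 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"detection value {y[i, j]!r} outside {{0,1,missing}} at "
                f"site {self.data['site_id'].iloc[i]!r} visit {j + 1}"
            )
        if np.isnan(y).all(axis=1).any():
            i = int(np.argwhere(np.isnan(y).all(axis=1))[0][0])
            raise ValidationError(
                f"site {self.data['site_id'].iloc[i]!r} has no non-missing visit"
            )
        per_site = self.data.groupby("site_id")["wetland_id"].nunique()
        if (per_site > 1).any():
            raise ValidationError(
                f"site {per_site[per_site > 1].index[0]!r} maps to multiple wetlands"
            )


@dataclass
class SiteCovariates:
    """Occupancy covariates, one row per site_id x year."""

    data: pd.DataFrame

    COLUMNS = ("site_id", "wetland_id", "year", "type", "size", "herb",
               "shrub1", "bareground", "woody", "water", "shrub5")

    def validate(self) -> None:
        if (self.data["size"].astype(float) <= 0).any():
            raise ValidationError("wetland size must be positive")
        for name in ("type", "herb", "shrub1", "bareground", "woody",
                     "water", "shrub5", "year"):
            levels = LEVELS[name]
            vals = set(self.data[name].astype(str))
            unknown = vals - set(levels)
            if unknown:
                raise ValidationError(
                    f"unknown level(s) {sorted(unknown)} for covariate {name!r}"
                )
        dup = self.data.duplicated(["site_id", "year"])
        if dup.any():
            raise ValidationError("duplicate site_id x year rows in site covariates")


@dataclass
class SurveyCovariates:
    """Detection covariates, one row per site_id x year x visit."""

    data: pd.DataFrame

    COLUMNS = ("site_id", "year", "visit", "time", "sky", "wind", "temp",
               "dist", "day")

    def validate(self) -> None:
        if (self.data["wind"].astype(float) < 0).any():
            raise ValidationError("wind speed must be nonnegative")
        t = self.data["time"].astype(float)
        if ((t < 0) | (t > 24)).any():
            raise ValidationError("time of day must lie in [0, 24]")
        vals = set(self.data["sky"].astype(str))
        unknown = vals - set(LEVELS["sky"])
        if unknown:
            raise ValidationError(f"unknown sky level(s) {sorted(unknown)}")
        dup = self.data.duplicated(["site_id", "year", "visit"])
        if dup.any():
            raise ValidationError("duplicate site_id x year x visit rows")


@dataclass
class RichnessTable:
    """Apparent species richness per wetland per year."""

    data: pd.DataFrame

    COLUMNS = ("wetland_id", "year", "type", "size", "richness")

    def validate(self) -> None:
        r = self.data["richness"]
        as_float = r.astype(float)
        if ((as_float % 1) != 0).any() or (as_float < 0).any():
            bad = self.data.loc[(as_float % 1 != 0) | (as_float < 0)].index[0]
            raise ValidationError(
                f"richness must be a nonnegative integer (row {bad})"
            )
        if self.data.duplicated(["wetland_id", "year"]).any():
            raise ValidationError("duplicate wetland x year rows in richness table")


@dataclass
class DesignMatrices:
    """Encoded design matrices for one occupancy model fit.

    ``X`` has one row per site-unit (intercept first); ``W`` has one row per
    non-missing site-unit visit. ``w_site_index`` maps each W row back to
    its X row, and ``y_w`` holds the corresponding 0/1 outcomes.
    ``encoding_record`` stores, per covariate, either the dummy reference
    level or the mean/SD/median used for standardization, so raw-scale
    values can be recovered.
    """

    X: np.ndarray
    W: np.ndarray
    x_columns: list[str]
    w_columns: list[str]
    w_site_index: np.ndarray
    w_visit: np.ndarray
    y_w: np.ndarray
    encoding_record: dict
    x_blocks: dict[str, list[int]] = field(default_factory=dict)
    w_blocks: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.X.shape[0]

    @property
    def any_detection(self) -> np.ndarray:
        return np.bincount(self.w_site_index, weights=self.y_w,
                           minlength=self.n_sites) > 0


def _read_csv(path, required: tuple[str, ...], known: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=True, skipinitialspace=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, extra)
    return df


def read_detection_table(path, species: str) -> DetectionTable:
    """Read the detection/non-detection CSV for one species.

    Expects columns ``site_id, wetland_id, year`` plus two replicate-survey
    columns per species (``sosp1, sosp2, ...``). Blank cells are missing
    visits.
    """
    if species not in SPECIES:
        raise ValidationError(f"species must be one of {SPECIES}, got {species!r}")
    visit_cols = [f"{species}{j + 1}" for j in range(N_VISITS)]
    known = ("site_id", "wetland_id", "year") + tuple(
        f"{s}{j + 1}" for s in SPECIES for j in range(N_VISITS)
    )
    df = _read_csv(path, ("site_id", "wetland_id", "year") + tuple(visit_cols), known)
    out = df[["site_id", "wetland_id", "year"]].copy()
    out["year"] = out["year"].astype(str)
    for j, col in enumerate(visit_cols):
        vals = df[col]
        ok = vals.isna() | vals.isin(["0", "1", "0.0", "1.0"])
        if not ok.all():
            row = int(np.argwhere(~ok.to_numpy())[0][0])
            raise ValidationError(
                f"{path}: detection value {vals.iloc[row]!r} outside "
                f"{{0,1,blank}} in column {col!r}, row {row}"
            )
        out[f"y{j + 1}"] = vals.astype(float)
    table = DetectionTable(out.reset_index(drop=True), species=species)
    table.validate()
    logger.info("read %d site-units for species %s from %s",
                table.n_sites, species, path)
    return table


def read_site_covariates(path) -> SiteCovariates:
    df = _read_csv(path, SiteCovariates.COLUMNS, SiteCovariates.COLUMNS)
    df = df[list(SiteCovariates.COLUMNS)].copy()
    df["size"] = df["size"].astype(float)
    df["year"] = df["year"].astype(str)
    table = SiteCovariates(df.reset_index(drop=True))
    table.validate()
    return table


def read_survey_covariates(path) -> SurveyCovariates:
    df = _read_csv(path, SurveyCovariates.COLUMNS, SurveyCovariates.COLUMNS)
    df = df[list(SurveyCovariates.COLUMNS)].copy()
    for c in ("time", "wind", "temp", "dist", "day"):
        df[c] = df[c].astype(float)
    df["visit"] = df["visit"].astype(int)
    df["year"] = df["year"].astype(str)
    table = SurveyCovariates(df.reset_index(drop=True))
    table.validate()
    return table


def read_richness_table(path) -> RichnessTable:
    """Read the apparent-richness CSV (one row per wetland per year)."""
    df = _read_csv(path, RichnessTable.COLUMNS, RichnessTable.COLUMNS)
    df = df[list(RichnessTable.COLUMNS)].copy()
    df["size"] = df["size"].astype(float)
    df["year"] = df["year"].astype(str)
    try:
        rich = df["richness"].astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric richness value") from exc
    df["richness"] = rich
    table = RichnessTable(df.reset_index(drop=True))
    table.validate()
    table.data["richness"] = table.data["richness"].astype(int)
    return table


def _encode_column(values: pd.Series, name: str, record: dict | None = None):
    """Encode one covariate -> (matrix block, column names, record entry).

    Categorical covariates become 0/1 dummies against the first listed
    level; continuous covariates are z-standardized. Passing a prior
    ``record`` entry reuses its mean/SD (for applying a frozen encoding).
    """
    levels = LEVELS[name]
    if levels is not None:
        vals = values.astype(str)
        unknown = set(vals) - set(levels)
        if unknown:
            raise ValidationError(
                f"unknown level(s) {sorted(unknown)} for covariate {name!r}"
            )
        cols = []
        names = []
        for lev in levels[1:]:
            cols.append((vals == lev).to_numpy(dtype=float))
            names.append(f"{name}[{lev}]")
        entry = {"kind": "categorical", "levels": list(levels),
                 "reference": levels[0]}
        return np.column_stack(cols), names, entry
    raw = values.to_numpy(dtype=float)
    if record is not None:
        mean, sd = record["mean"], record["sd"]
    else:
        mean = float(np.mean(raw))
        sd = float(np.std(raw, ddof=1))
        if sd == 0:
            raise ValidationError(f"covariate {name!r} has zero variance")
    entry = {"kind": "continuous", "mean": mean, "sd": sd,
             "median": float(np.median(raw))}
    return ((raw - mean) / sd)[:, None], [name], entry


def build_design(det: DetectionTable, sc: SiteCovariates,
                 vc: SurveyCovariates, spec: ModelSpec,
                 encoding_record: dict | None = None) -> DesignMatrices:
    """Assemble occupancy (X) and detection (W) design matrices.

    Rows of X follow the site-unit order of ``det``; rows of W cover the
    non-missing visits in site-unit-major, visit-minor order. Missing
    visits are dropped from W (and hence from the detection likelihood).
    Passing a previous ``encoding_record`` re-applies its standardization
    instead of recomputing means/SDs.
    """
    key = ["site_id", "year"]
    site_units = det.data[key]
    merged = site_units.merge(sc.data, on=key, how="left", validate="one_to_one")
    if merged["type"].isna().any():
        missing = merged.loc[merged["type"].isna(), "site_id"].iloc[0]
        raise ValidationError(f"site {missing!r} missing from site covariates")

    record = dict(encoding_record) if encoding_record else {}
    x_parts = [np.ones((len(merged), 1))]
    x_names = ["(Intercept)"]
    x_blocks: dict[str, list[int]] = {}
    for name in spec.occupancy_covariates:
        prior = record.get(name) if encoding_record else None
        block, names, entry = _encode_column(merged[name], name, prior)
        x_blocks[name] = list(range(len(x_names), len(x_names) + len(names)))
        x_parts.append(block)
        x_names.extend(names)
        record.setdefault(name, entry)
    X = np.hstack(x_parts)

    # flatten visits, dropping missing ones
    y = det.y
    site_idx, visit_idx = np.nonzero(~np.isnan(y))
    y_w = y[site_idx, visit_idx]
    flat = pd.DataFrame({
        "site_id": det.data["site_id"].to_numpy()[site_idx],
        "year": det.data["year"].to_numpy()[site_idx],
        "visit": visit_idx + 1,
    })
    vmerged = flat.merge(vc.data, on=["site_id", "year", "visit"],
                         how="left", validate="one_to_one")
    probe = spec.detection_covariates[0] if spec.detection_covariates else None
    if probe is not None and vmerged[probe].isna().any():
        missing = vmerged.loc[vmerged[probe].isna(), "site_id"].iloc[0]
        raise ValidationError(
            f"site {missing!r} missing rows in survey covariates"
        )

    w_parts = [np.ones((len(vmerged), 1))]
    w_names = ["(Intercept)"]
    w_blocks: dict[str, list[int]] = {}
    for name in spec.detection_covariates:
        rkey = f"det:{name}"
        prior = record.get(rkey) if encoding_record else None
        block, names, entry = _encode_column(vmerged[name], name, prior)
        w_blocks[name] = list(range(len(w_names), len(w_names) + len(names)))
        w_parts.append(block)
        w_names.extend(names)
        record.setdefault(rkey, entry)
    W = np.hstack(w_parts)

    n_dropped = int(np.isnan(y).sum())
    if n_dropped:
        logger.info("dropped %d missing visits from detection design", n_dropped)
    return DesignMatrices(
        X=X, W=W, x_columns=x_names, w_columns=w_names,
        w_site_index=site_idx.astype(np.intp), w_visit=visit_idx + 1,
        y_w=y_w, encoding_record=record,
        x_blocks=x_blocks, w_blocks=w_blocks,
    )


def check_collinearity(sc: SiteCovariates | pd.DataFrame,
                       threshold: float = 0.5) -> pd.DataFrame:
    """Pairwise absolute correlations among occupancy covariates.

    Categorical covariates enter through their integer level codes. Pairs
    with |r| >= ``threshold`` are flagged; a pair involving a constant
    column is reported with NaN correlation and never flagged. A plain
    numeric DataFrame may be passed instead of a :class:`SiteCovariates`.
    """
    numeric = {}
    if isinstance(sc, pd.DataFrame):
        n_rows = len(sc)
        for name in sc.columns:
            numeric[name] = sc[name].to_numpy(dtype=float)
    else:
        n_rows = len(sc.data)
        for name in OCCUPANCY_COVARIATES:
            levels = LEVELS[name]
            col = sc.data[name]
            if levels is not None:
                numeric[name] = col.astype(str).map(
                    {lev: i for i, lev in enumerate(levels)}).to_numpy(dtype=float)
            else:
                numeric[name] = col.to_numpy(dtype=float)
    names = list(numeric)
    if len(names) < 2:
        raise ValidationError("need at least 2 covariates for a correlation screen")
    if n_rows < 3:
        raise ValidationError("need at least 3 rows for a correlation screen")
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            xa, xb = numeric[names[a]], numeric[names[b]]
            if np.std(xa) == 0 or np.std(xb) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(xa, xb)[0, 1])
            rows.append({
                "covariate_a": names[a], "covariate_b": names[b],
                "abs_correlation": abs(r) if np.isfinite(r) else np.nan,
                "flagged": bool(np.isfinite(r) and abs(r) >= threshold),
            })
    return pd.DataFrame(rows)
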