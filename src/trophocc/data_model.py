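"""Survey data containers, validation, and delimited-text I/O.

The study design couples two survey streams collected at the same points in
burned conifer forest: repeated black-backed woodpecker point-count surveys
(up to three passive plus three broadcast 2-minute detection intervals per
visit, under a removal protocol) across post-fire years, and a single
final-year woodboring-beetle survey in which up to six snags per point are
scored 0-8 each for accumulated larval sign.  This module defines the typed
containers for those data, the derived covariates the occupancy model
consumes (snag-density index, years since fire), and plain-CSV readers and
writers so a full dataset round-trips through four delimited files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SNAG_CATEGORY_VALUES",
    "SNAG_SIZE_CLASSES",
    "MAX_SCORE_PER_TREE",
    "MAX_TREES_PER_POINT",
    "PASSIVE",
    "BROADCAST",
    "ValidationError",
    "Fire",
    "StudyDesign",
    "DetectionRecord",
    "BeetleSurvey",
    "PointCovariates",
    "SurveyDataset",
    "snag_index",
    "standardize_columns",
    "ModelInputs",
    "PointInputs",
    "build_model_inputs",
    "read_dataset",
    "write_dataset",
]

# Field categories for snag counts per diameter class, and the numeric
# quantities they map to when building the relative snag-density index.
SNAG_CATEGORY_VALUES: dict[str, float] = {
    "<=5": 1.0,
    "6-15": 6.0,
    "16-30": 16.0,
    "31-50": 31.0,
    "51-100": 51.0,
    ">100": 101.0,
}

#: Diameter-at-breast-height classes counted in the field (cm).
SNAG_SIZE_CLASSES: tuple[str, str, str] = ("dbh_10_30", "dbh_30_60", "dbh_gt60")

MAX_SCORE_PER_TREE = 8
MAX_TREES_PER_POINT = 6
MAX_INTERVALS_PER_TYPE = 3

PASSIVE = 0
BROADCAST = 1


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant.

    ``rows`` carries a short description of each offending record so the
    caller can locate the problem in the source files.
    """

    def __init__(self, message: str, rows: Sequence[str] = ()):
        self.rows = list(rows)
        if self.rows:
            message = message + "\n  " + "\n  ".join(self.rows)
        super().__init__(message)


def snag_index(categories: Iterable[str]) -> float:
    """Relative snag-density index from the three size-class categories.

    Each of the three diameter classes carries one of the categorical count
    labels ``<=5, 6-15, 16-30, 31-50, 51-100, >100``; these map to the
    numeric quantities 1, 6, 16, 31, 51 and 101 respectively, and the index
    is their sum across size classes (snags/ha, relative).

    >>> snag_index(["<=5", "<=5", "<=5"])
    3.0
    """
    cats = list(categories)
    if len(cats) != len(SNAG_SIZE_CLASSES):
        raise ValidationError(
            f"expected {len(SNAG_SIZE_CLASSES)} size-class categories, got {len(cats)}"
        )
    total = 0.0
    for c in cats:
        if c not in SNAG_CATEGORY_VALUES:
            raise ValidationError(
                f"unknown snag count category {c!r}; "
                f"expected one of {sorted(SNAG_CATEGORY_VALUES)}"
            )
        total += SNAG_CATEGORY_VALUES[c]
    return total


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fire:
    """One fire: identity, year burned, point count, and survey-year set."""

    fire_id: str
    year_burned: int
    n_points: int
    survey_years: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "survey_years", tuple(sorted(set(self.survey_years))))
        if self.n_points < 1:
            raise ValidationError(f"fire {self.fire_id}: n_points must be >= 1")
        if not self.survey_years:
            raise ValidationError(f"fire {self.fire_id}: no survey years")
        if self.year_burned >= min(self.survey_years):
            raise ValidationError(
                f"fire {self.fire_id}: year burned {self.year_burned} not before "
                f"first survey year {min(self.survey_years)}"
            )


@dataclass(frozen=True)
class StudyDesign:
    """Fire-level layout of the study.

    The latent occurrence series of every point is indexed by model year
    t = 1..T, where t = T corresponds to ``reference_year`` (the single year
    with beetle surveys) and t = 1 to the first post-fire year of the
    earliest-burning fire.
    """

    fires: tuple[Fire, ...]
    reference_year: int

    def __post_init__(self):
        object.__setattr__(self, "fires", tuple(self.fires))
        ids = [f.fire_id for f in self.fires]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate fire_id in design")
        bad = [f.fire_id for f in self.fires if self.reference_year not in f.survey_years]
        if bad:
            raise ValidationError(
                f"reference year {self.reference_year} missing from survey years",
                [f"fire {i}" for i in bad],
            )

    @property
    def n_points(self) -> int:
        return sum(f.n_points for f in self.fires)

    @property
    def first_model_year(self) -> int:
        """Calendar year carrying model index t = 1."""
        return min(f.year_burned for f in self.fires) + 1

    @property
    def T(self) -> int:
        """Number of model years; the reference year holds t = T."""
        return self.reference_year - self.first_model_year + 1

    def model_year(self, calendar_year: int) -> int:
        return calendar_year - self.first_model_year + 1

    def fire(self, fire_id: str) -> Fire:
        for f in self.fires:
            if f.fire_id == fire_id:
                return f
        raise KeyError(fire_id)


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionRecord:
    """One detection interval of one point-count visit.

    ``survey_type`` is 0 for passive listening and 1 for call broadcast.
    Under the removal protocol, intervals after the first detection within a
    point-year are ``censored`` (not conducted) and carry no detection value.
    """

    fire_id: str
    point_id: str
    year: int
    interval: int  # 1-based position within the visit
    survey_type: int
    detected: int | None
    censored: bool = False

    def __post_init__(self):
        if self.survey_type not in (PASSIVE, BROADCAST):
            raise ValidationError(f"survey_type must be 0 or 1, got {self.survey_type}")
        if self.censored:
            if self.detected is not None:
                raise ValidationError(
                    f"{self.point_id}/{self.year} interval {self.interval}: "
                    "censored interval carries a detection value"
                )
        elif self.detected not in (0, 1):
            raise ValidationError(
                f"{self.point_id}/{self.year} interval {self.interval}: "
                f"detected must be 0 or 1, got {self.detected}"
            )


@dataclass(frozen=True)
class BeetleSurvey:
    """Final-year beetle survey at one point: summed 0-8 sign scores."""

    point_id: str
    num_trees: int
    activity: int

    def __post_init__(self):
        if not 1 <= self.num_trees <= MAX_TREES_PER_POINT:
            raise ValidationError(
                f"{self.point_id}: num_trees must be in 1..{MAX_TREES_PER_POINT}, "
                f"got {self.num_trees}"
            )
        if not 0 <= self.activity <= self.num_trees * MAX_SCORE_PER_TREE:
            raise ValidationError(
                f"{self.point_id}: activity {self.activity} outside "
                f"[0, {self.num_trees * MAX_SCORE_PER_TREE}] "
                f"(num_trees={self.num_trees} x {MAX_SCORE_PER_TREE})"
            )

    @property
    def trials(self) -> int:
        return self.num_trees * MAX_SCORE_PER_TREE


@dataclass(frozen=True)
class PointCovariates:
    """Static and yearly covariates of one survey point.

    ``snag_categories`` maps a calendar survey year to the three categorical
    snag counts (one per diameter class, in ``SNAG_SIZE_CLASSES`` order).
    """

    point_id: str
    fire_id: str
    elevation_m: float
    latitude: float
    pine_prop: float
    snag_categories: Mapping[int, tuple[str, str, str]] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.pine_prop <= 1.0:
            raise ValidationError(
                f"{self.point_id}: pine_prop {self.pine_prop} outside [0, 1]"
            )
        for year, cats in self.snag_categories.items():
            snag_index(cats)  # raises on unknown category

    def snag_index_for(self, year: int) -> float:
        return snag_index(self.snag_categories[year])


@dataclass
class SurveyDataset:
    """All data for one fitting run, with explicit missingness.

    Point-years with no surveys simply carry no DetectionRecord rows; the
    likelihood treats them as emission-free years.  Beetle surveys exist
    only for the design's reference year.
    """

    design: StudyDesign
    detections: list[DetectionRecord]
    beetle: list[BeetleSurvey]
    covariates: dict[str, PointCovariates]
    scaling: dict[str, tuple[float, float]] | None = None

    def validate(self) -> "SurveyDataset":
        errs: list[str] = []
        fire_ids = {f.fire_id for f in self.design.fires}
        for pid, cov in self.covariates.items():
            if pid != cov.point_id:
                errs.append(f"covariate key {pid} != point_id {cov.point_id}")
            if cov.fire_id not in fire_ids:
                errs.append(f"point {pid}: unknown fire {cov.fire_id}")
        per_fire: dict[str, int] = {}
        for cov in self.covariates.values():
            per_fire[cov.fire_id] = per_fire.get(cov.fire_id, 0) + 1
        for f in self.design.fires:
            if per_fire.get(f.fire_id, 0) != f.n_points:
                errs.append(
                    f"fire {f.fire_id}: {per_fire.get(f.fire_id, 0)} covariate "
                    f"points, design says {f.n_points}"
                )
        for rec in self.detections:
            if rec.point_id not in self.covariates:
                errs.append(f"detection at unknown point {rec.point_id}")
                continue
            fire = self.design.fire(rec.fire_id)
            if rec.year not in fire.survey_years:
                errs.append(
                    f"point {rec.point_id}: detection in {rec.year}, not a "
                    f"survey year of fire {rec.fire_id}"
                )
        # interval ordering / limits within each point-year
        by_py: dict[tuple[str, int], list[DetectionRecord]] = {}
        for rec in self.detections:
            by_py.setdefault((rec.point_id, rec.year), []).append(rec)
        for (pid, year), recs in by_py.items():
            recs = sorted(recs, key=lambda r: r.interval)
            if [r.interval for r in recs] != list(range(1, len(recs) + 1)):
                errs.append(f"{pid}/{year}: intervals not consecutive from 1")
            for stype in (PASSIVE, BROADCAST):
                if sum(r.survey_type == stype for r in recs) > MAX_INTERVALS_PER_TYPE:
                    errs.append(f"{pid}/{year}: more than {MAX_INTERVALS_PER_TYPE} "
                                f"intervals of type {stype}")
            seen_det = False
            for r in recs:
                if seen_det and not r.censored:
                    errs.append(f"{pid}/{year}: uncensored interval {r.interval} "
                                "after first detection (removal design)")
                if not r.censored and r.detected == 1:
                    seen_det = True
        for b in self.beetle:
            if b.point_id not in self.covariates:
                errs.append(f"beetle survey at unknown point {b.point_id}")
        if errs:
            raise ValidationError("dataset failed validation", errs)
        return self

    def point_ids(self) -> list[str]:
        """Points in deterministic order: design fire order, then point id."""
        order = {f.fire_id: i for i, f in enumerate(self.design.fires)}
        return sorted(
            self.covariates,
            key=lambda pid: (order[self.covariates[pid].fire_id], pid),
        )

    def checksum(self) -> str:
        """Stable content digest used as fitting provenance."""
        h = hashlib.md5()
        for part in _dataset_frames(self).values():
            h.update(part.to_csv(index=False).encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _design_frame(design: StudyDesign) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fire_id": [f.fire_id for f in design.fires],
            "year_burned": [f.year_burned for f in design.fires],
            "n_points": [f.n_points for f in design.fires],
            "survey_years": [";".join(map(str, f.survey_years)) for f in design.fires],
            "reference_year": [design.reference_year] * len(design.fires),
        }
    )


def _detections_frame(detections: Sequence[DetectionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "fire_id": [r.fire_id for r in detections],
            "point_id": [r.point_id for r in detections],
            "year": [r.year for r in detections],
            "interval": [r.interval for r in detections],
            "type": [r.survey_type for r in detections],
            "detected": [r.detected for r in detections],
            "censored": [int(r.censored) for r in detections],
        }
    )


def _covariates_frame(dataset: SurveyDataset) -> pd.DataFrame:
    years = sorted({y for f in dataset.design.fires for y in f.survey_years})
    rows = []
    for pid in dataset.point_ids():
        cov = dataset.covariates[pid]
        row: dict[str, object] = {
            "point_id": pid,
            "fire_id": cov.fire_id,
            "elevation_m": cov.elevation_m,
            "latitude": cov.latitude,
            "pine_prop": cov.pine_prop,
        }
        for year in years:
            cats = cov.snag_categories.get(year)
            for i, cls in enumerate(SNAG_SIZE_CLASSES):
                row[f"snag_{cls}_{year}"] = cats[i] if cats is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)


def _dataset_frames(dataset: SurveyDataset) -> dict[str, pd.DataFrame]:
    beetle = pd.DataFrame(
        {
            "point_id": [b.point_id for b in dataset.beetle],
            "num_trees": [b.num_trees for b in dataset.beetle],
            "activity": [b.activity for b in dataset.beetle],
        }
    )
    return {
        "design": _design_frame(dataset.design),
        "detections": _detections_frame(dataset.detections),
        "beetle": beetle,
        "covariates": _covariates_frame(dataset),
    }


def write_dataset(dataset: SurveyDataset, directory: str | Path) -> dict[str, Path]:
    """Write the four CSV files (design, detections, beetle, covariates)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in _dataset_frames(dataset).items():
        path = directory / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


def _require_columns(df: pd.DataFrame, cols: Sequence[str], label: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{label}: missing column(s) {missing}")


def read_dataset(
    detections_path: str | Path,
    beetle_path: str | Path,
    covariates_path: str | Path,
    design_path: str | Path,
) -> SurveyDataset:
    """Read and validate a dataset from its four CSV files."""
    ddf = pd.read_csv(design_path, float_precision="round_trip")
    _require_columns(
        ddf, ["fire_id", "year_burned", "n_points", "survey_years", "reference_year"],
        "design.csv",
    )
    fires = tuple(
        Fire(
            fire_id=str(r.fire_id),
            year_burned=int(r.year_burned),
            n_points=int(r.n_points),
            survey_years=tuple(int(y) for y in str(r.survey_years).split(";")),
        )
        for r in ddf.itertuples()
    )
    design = StudyDesign(fires=fires, reference_year=int(ddf["reference_year"].iloc[0]))

    det_df = pd.read_csv(detections_path, float_precision="round_trip")
    _require_columns(
        det_df, ["fire_id", "point_id", "year", "interval", "type", "detected", "censored"],
        "detections.csv",
    )
    detections = [
        DetectionRecord(
            fire_id=str(r.fire_id),
            point_id=str(r.point_id),
            year=int(r.year),
            interval=int(r.interval),
            survey_type=int(r.type),
            detected=None if pd.isna(r.detected) else int(r.detected),
            censored=bool(int(r.censored)),
        )
        for r in det_df.itertuples()
    ]

    bdf = pd.read_csv(beetle_path, float_precision="round_trip")
    _require_columns(bdf, ["point_id", "num_trees", "activity"], "beetle.csv")
    beetle = [
        BeetleSurvey(point_id=str(r.point_id), num_trees=int(r.num_trees),
                     activity=int(r.activity))
        for r in bdf.itertuples()
    ]

    cdf = pd.read_csv(covariates_path, float_precision="round_trip")
    _require_columns(
        cdf, ["point_id", "fire_id", "elevation_m", "latitude", "pine_prop"],
        "covariates.csv",
    )
    snag_cols: dict[int, list[str]] = {}
    for col in cdf.columns:
        if col.startswith("snag_"):
            for cls in SNAG_SIZE_CLASSES:
                prefix = f"snag_{cls}_"
                if col.startswith(prefix):
                    snag_cols.setdefault(int(col[len(prefix):]), []).append(col)
    covariates: dict[str, PointCovariates] = {}
    for r in cdf.itertuples():
        cats: dict[int, tuple[str, str, str]] = {}
        for year in sorted(snag_cols):
            vals = [getattr(r, f"snag_{cls}_{year}", None) for cls in SNAG_SIZE_CLASSES]
            if all(isinstance(v, str) and v for v in vals):
                cats[year] = tuple(vals)  # type: ignore[assignment]
        covariates[str(r.point_id)] = PointCovariates(
            point_id=str(r.point_id),
            fire_id=str(r.fire_id),
            elevation_m=float(r.elevation_m),
            latitude=float(r.latitude),
            pine_prop=float(r.pine_prop),
            snag_categories=cats,
        )

    return SurveyDataset(
        design=design, detections=detections, beetle=beetle, covariates=covariates
    ).validate()


# ---------------------------------------------------------------------------
# Derived covariates and model inputs
# ---------------------------------------------------------------------------

def standardize_columns(
    df: pd.DataFrame,
    columns: Sequence[str],
    scaling: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Center/scale the named columns to mean 0, SD 1 (sample SD, ddof=1).

    If ``scaling`` is given, its stored (mean, sd) constants are applied
    instead of re-estimating, which makes the transform reusable and
    invertible.  Columns not named (e.g. pine proportion, on its natural
    [0, 1] scale) are left untouched.  A zero-variance column raises a
    ``ValidationError`` naming the column.
    """
    out = df.copy()
    used: dict[str, tuple[float, float]] = {}
    for col in columns:
        vals = out[col].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if scaling is not None and col in scaling:
            mean, sd = scaling[col]
        else:
            mean = float(np.mean(finite))
            sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
        if sd == 0.0 or not np.isfinite(sd):
            raise ValidationError(f"covariate {col!r} has zero variance; cannot standardize")
        out[col] = (vals - mean) / sd
        used[col] = (mean, sd)
    return out, used


@dataclass
class PointInputs:
    """Per-point slice of ModelInputs, for the scalar likelihood path."""

    point_id: str
    fire_index: int
    t_start: int  # first post-fire model year (1-based)
    T: int
    elev: float
    lat: float
    pine: float
    snag: np.ndarray      # (T,) standardized snag index
    age_s: np.ndarray     # (T,) standardized years since fire
    det_b: np.ndarray     # (T,) broadcast-interval detections
    nd_b: np.ndarray      # (T,) broadcast-interval non-detections
    det_p: np.ndarray     # (T,) passive-interval detections
    nd_p: np.ndarray      # (T,) passive-interval non-detections

    @property
    def any_det(self) -> np.ndarray:
        return (self.det_b + self.det_p) > 0

    @property
    def n_surveys(self) -> np.ndarray:
        return self.det_b + self.nd_b + self.det_p + self.nd_p


@dataclass
class ModelInputs:
    """Dense numeric arrays the likelihood and sampler operate on.

    All (n_points, T) matrices are aligned to the design's model-year grid;
    entries before a point's first post-fire year are invalid (masked by
    ``valid``).  Interval data are collapsed to per-type detection and
    non-detection counts, which is sufficient because the Bernoulli interval
    emissions depend on intervals only through those counts.
    """

    point_ids: list[str]
    fire_ids: list[str]
    fire_index: np.ndarray       # (n,) int, index into fire_ids
    T: int
    t_start: np.ndarray          # (n,) int, 1-based first post-fire model year
    valid: np.ndarray            # (n, T) bool
    elev: np.ndarray             # (n,) standardized
    lat: np.ndarray              # (n,) standardized
    pine: np.ndarray             # (n,) natural [0,1]
    age: np.ndarray              # (n, T) raw years since fire (nan where invalid)
    age_s: np.ndarray            # (n, T) standardized (0 where invalid)
    snag: np.ndarray             # (n, T) standardized snag index (0 where invalid)
    det_b: np.ndarray            # (n, T) int
    nd_b: np.ndarray
    det_p: np.ndarray
    nd_p: np.ndarray
    beetle_point: np.ndarray     # (m,) int index into points
    beetle_trials: np.ndarray    # (m,) int
    beetle_activity: np.ndarray  # (m,) int
    scaling: dict[str, tuple[float, float]]
    checksum: str = ""

    @property
    def n_points(self) -> int:
        return len(self.point_ids)

    @property
    def n_fires(self) -> int:
        return len(self.fire_ids)

    @property
    def any_det(self) -> np.ndarray:
        return (self.det_b + self.det_p) > 0

    def standardize_age(self, age_years: np.ndarray | float) -> np.ndarray | float:
        mean, sd = self.scaling["age"]
        return (np.asarray(age_years, dtype=float) - mean) / sd

    def point(self, j: int) -> PointInputs:
        return PointInputs(
            point_id=self.point_ids[j],
            fire_index=int(self.fire_index[j]),
            t_start=int(self.t_start[j]),
            T=self.T,
            elev=float(self.elev[j]),
            lat=float(self.lat[j]),
            pine=float(self.pine[j]),
            snag=self.snag[j],
            age_s=self.age_s[j],
            det_b=self.det_b[j],
            nd_b=self.nd_b[j],
            det_p=self.det_p[j],
            nd_p=self.nd_p[j],
        )


def _nearest_fill(values: dict[int, float], t_start: int, T: int) -> np.ndarray:
    """Fill model years t_start..T from sparsely observed years.

    Unobserved years take the nearest observed year's value; distance ties
    resolve to the earlier year.  Returns a (T,) array with zeros before
    t_start (masked later).
    """
    out = np.zeros(T)
    obs_years = sorted(values)
    for t in range(t_start, T + 1):
        best = min(obs_years, key=lambda y: (abs(y - t), y))
        out[t - 1] = values[best]
    return out


def build_model_inputs(dataset: SurveyDataset, standardize: bool = True) -> ModelInputs:
    """Assemble dense arrays (and covariate scaling) from a validated dataset.

    Elevation, latitude, snag index and years-since-fire are z-scored with
    sample SD over the modeled point-years; pine proportion keeps its
    natural scale.  With ``standardize=False`` raw values are kept and the
    stored scaling constants are identities.
    """
    design = dataset.design
    T = design.T
    point_ids = dataset.point_ids()
    fire_ids = [f.fire_id for f in design.fires]
    fire_pos = {fid: i for i, fid in enumerate(fire_ids)}
    n = len(point_ids)
    pidx = {pid: j for j, pid in enumerate(point_ids)}

    fire_index = np.zeros(n, dtype=np.int64)
    t_start = np.zeros(n, dtype=np.int64)
    elev = np.zeros(n)
    lat = np.zeros(n)
    pine = np.zeros(n)
    age = np.full((n, T), np.nan)
    snag_raw = np.zeros((n, T))
    for j, pid in enumerate(point_ids):
        cov = dataset.covariates[pid]
        fire = design.fire(cov.fire_id)
        fire_index[j] = fire_pos[cov.fire_id]
        ts = design.model_year(fire.year_burned + 1)
        t_start[j] = ts
        elev[j] = cov.elevation_m
        lat[j] = cov.latitude
        pine[j] = cov.pine_prop
        for t in range(ts, T + 1):
            age[j, t - 1] = t - ts + 1
        if cov.snag_categories:
            obs = {design.model_year(y): cov.snag_index_for(y)
                   for y in cov.snag_categories}
            snag_raw[j] = _nearest_fill(obs, ts, T)

    valid = np.zeros((n, T), dtype=bool)
    for j in range(n):
        valid[j, t_start[j] - 1:] = True

    det_b = np.zeros((n, T), dtype=np.int64)
    nd_b = np.zeros((n, T), dtype=np.int64)
    det_p = np.zeros((n, T), dtype=np.int64)
    nd_p = np.zeros((n, T), dtype=np.int64)
    for rec in dataset.detections:
        if rec.censored:
            continue  # removal design: censored intervals contribute nothing
        j = pidx[rec.point_id]
        t = design.model_year(rec.year) - 1
        if rec.survey_type == BROADCAST:
            (det_b if rec.detected else nd_b)[j, t] += 1
        else:
            (det_p if rec.detected else nd_p)[j, t] += 1

    beetle_point = np.array([pidx[b.point_id] for b in dataset.beetle], dtype=np.int64)
    beetle_trials = np.array([b.trials for b in dataset.beetle], dtype=np.int64)
    beetle_activity = np.array([b.activity for b in dataset.beetle], dtype=np.int64)

    scaling: dict[str, tuple[float, float]] = {
        "elevation": (0.0, 1.0), "latitude": (0.0, 1.0),
        "snag": (0.0, 1.0), "age": (0.0, 1.0),
    }
    age_s = np.where(valid, np.nan_to_num(age), 0.0)
    snag = snag_raw.copy()
    if standardize:
        frame = pd.DataFrame({"elevation": elev, "latitude": lat})
        frame, sc = standardize_columns(frame, ["elevation", "latitude"])
        elev = frame["elevation"].to_numpy()
        lat = frame["latitude"].to_numpy()
        scaling.update(sc)
        for name, mat in (("snag", snag), ("age", age_s)):
            vals = mat[valid]
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            if sd == 0.0:
                raise ValidationError(f"covariate {name!r} has zero variance; cannot standardize")
            mat[valid] = (vals - mean) / sd
            mat[~valid] = 0.0
            scaling[name] = (mean, sd)

    return ModelInputs(
        point_ids=point_ids,
        fire_ids=fire_ids,
        fire_index=fire_index,
        T=T,
        t_start=t_start,
        valid=valid,
        elev=elev,
        lat=lat,
        pine=pine,
        age=age,
        age_s=age_s,
        snag=snag,
        det_b=det_b,
        nd_b=nd_b,
        det_p=det_p,
        nd_p=nd_p,
        beetle_point=beetle_point,
        beetle_trials=beetle_trials,
        beetle_activity=beetle_activity,
        scaling=scaling,
        checksum=dataset.checksum(),
    )
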