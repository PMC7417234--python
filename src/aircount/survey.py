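"""Observation tables and distance-binned transect counts.

Every downstream model in this package starts from one of two data products
of a drone thermal-imaging survey with automated detection:

* an *observation table* — one row per object that was either flagged by the
  detection algorithm or known (from ground truthing) to have been missed,
  carrying a four-level fate label (``unique_detection``, ``duplicate``,
  ``false_positive``, ``missed``) and the covariates used by the detection /
  false-detection / duplicate-detection probability models;
* a *transect count array* — counts of detections per transect x visit x
  perpendicular-distance bin, with transect-level land-cover covariates and
  visit-level weather covariates, consumed by the N-mixture model.

Tables are plain :class:`pandas.DataFrame` objects with a fixed column
vocabulary; this module owns validation, CSV round-tripping, the
train/test-by-date split and distance binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "KLASSES",
    "DETECTED_KLASSES",
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "DEFAULT_BIN_EDGES",
    "STRIP_HALFWIDTH",
    "SchemaError",
    "ValidationError",
    "SplitResult",
    "TransectCounts",
    "make_survey_id",
    "validate_observations",
    "composition_counts",
    "read_observations",
    "write_observations",
    "split_by_date",
    "bin_counts",
]

#: The four observation fates. ``missed`` rows come from ground truthing and
#: never enter abundance estimation; the other three are algorithm output.
KLASSES = ("unique_detection", "duplicate", "false_positive", "missed")
DETECTED_KLASSES = ("unique_detection", "duplicate", "false_positive")

REQUIRED_COLUMNS = (
    "object_id",
    "survey_id",
    "site",
    "date",
    "klass",
    "temperature",
    "wind_speed",
    "dist_edge",
    "dist_nearest",
    "time_since_prev",
    "perp_distance",
)
OPTIONAL_COLUMNS = ("lon", "lat", "transect")

#: Perpendicular-distance bin edges in metres (five 15 m classes).
DEFAULT_BIN_EDGES = (0.0, 15.0, 30.0, 45.0, 60.0, 75.0)

#: Half-width of the surveyed strip in metres; perpendicular distances must
#: fall strictly inside it.
STRIP_HALFWIDTH = 75.0


class SchemaError(ValueError):
    """A required column is missing or the column map is unusable."""


class ValidationError(ValueError):
    """A row violates the observation-table invariants."""


def make_survey_id(site: str, date) -> str:
    """Survey key: ``<site>_<ISO date>``."""
    return f"{site}_{pd.Timestamp(date).date().isoformat()}"


def _normalize_klass(value: str) -> str:
    return str(value).strip().lower().replace("-", "_").replace(" ", "_")


def validate_observations(table: pd.DataFrame, *, strip_halfwidth: float = STRIP_HALFWIDTH) -> pd.DataFrame:
    """Validate an observation table against the schema invariants.

    Checks performed:

    * all required columns present (``SchemaError`` otherwise);
    * ``klass`` values in the four-level vocabulary (case-insensitively),
      reported with row positions;
    * ``temperature``, ``wind_speed``, ``dist_edge``, ``perp_distance``
      present and non-negative; ``perp_distance`` < *strip_halfwidth*;
    * ``dist_nearest`` and ``time_since_prev`` present whenever the row is
      not a miss;
    * ``object_id`` unique; each ``survey_id`` maps to exactly one
      (site, date) pair.

    Returns the table with ``klass`` normalized and ``date`` coerced to
    ``datetime.date``. Composition counts are *reported* by
    :func:`composition_counts`, never enforced.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    out = table.copy()
    out["klass"] = out["klass"].map(_normalize_klass)
    bad = ~out["klass"].isin(KLASSES)
    if bad.any():
        rows = [int(i) + 1 for i in np.flatnonzero(bad.to_numpy())[:5]]
        vals = sorted(out.loc[bad, "klass"].unique())
        raise ValidationError(
            f"invalid klass value(s) {vals} at row(s) {rows}; expected one of {list(KLASSES)}"
        )
    out["date"] = pd.to_datetime(out["date"]).dt.date

    for col in ("temperature", "wind_speed", "dist_edge", "perp_distance"):
        vals = pd.to_numeric(out[col], errors="coerce")
        if vals.isna().any():
            rows = [int(i) + 1 for i in np.flatnonzero(vals.isna().to_numpy())[:5]]
            raise ValidationError(f"column {col!r} missing or non-numeric at row(s) {rows}")
        if (vals < 0).any():
            rows = [int(i) + 1 for i in np.flatnonzero((vals < 0).to_numpy())[:5]]
            raise ValidationError(f"negative {col} at row(s) {rows}")
        out[col] = vals.astype(float)
    too_far = out["perp_distance"] >= strip_halfwidth
    if too_far.any():
        rows = [int(i) + 1 for i in np.flatnonzero(too_far.to_numpy())[:5]]
        raise ValidationError(
            f"perp_distance >= strip half-width ({strip_halfwidth} m) at row(s) {rows}"
        )

    detected = out["klass"] != "missed"
    for col in ("dist_nearest", "time_since_prev"):
        vals = pd.to_numeric(out[col], errors="coerce")
        absent = detected & vals.isna()
        if absent.any():
            rows = [int(i) + 1 for i in np.flatnonzero(absent.to_numpy())[:5]]
            raise ValidationError(f"{col} required for detected objects, missing at row(s) {rows}")
        out[col] = vals.astype(float)

    dup_ids = out["object_id"].duplicated()
    if dup_ids.any():
        raise ValidationError(f"duplicate object_id values: {sorted(out.loc[dup_ids, 'object_id'].unique())[:5]}")
    key = out["site"].astype(str) + "|" + out["date"].astype(str)
    mapping = pd.DataFrame({"survey_id": out["survey_id"], "key": key}).drop_duplicates()
    clashes = mapping["survey_id"][mapping["survey_id"].duplicated()]
    if len(clashes):
        raise ValidationError(f"survey_id maps to more than one (site, date): {sorted(set(clashes))}")
    return out


def composition_counts(table: pd.DataFrame) -> pd.Series:
    """Count rows per fate class (reported, never enforced)."""
    return table["klass"].value_counts().reindex(KLASSES, fill_value=0)


def read_observations(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate an observation table from delimited text.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional map from canonical column names (``REQUIRED_COLUMNS``) to
        the column names used in the file. Unmapped canonical names are
        assumed to appear verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    raw = pd.read_csv(path)
    if schema:
        rename = {v: k for k, v in schema.items()}
        missing_src = [v for v in schema.values() if v not in raw.columns]
        if missing_src:
            raise SchemaError(f"schema names column(s) not in file: {', '.join(missing_src)}")
        raw = raw.rename(columns=rename)
    return validate_observations(raw)


def write_observations(table: pd.DataFrame, path) -> None:
    """Write an observation table as UTF-8 CSV (stable column order).

    ``read_observations(write_observations(t)) == t`` up to dtype
    normalization; output is byte-stable across runs for equal input.
    """
    cols = [c for c in REQUIRED_COLUMNS if c in table.columns]
    cols += [c for c in OPTIONAL_COLUMNS if c in table.columns]
    out = table[cols].copy()
    if "date" in out.columns and len(out):
        out["date"] = pd.to_datetime(out["date"]).dt.date
    out.to_csv(path, index=False)


@dataclass
class SplitResult:
    """Train/test partition of an observation table by survey date."""

    train: pd.DataFrame
    test: pd.DataFrame
    cutoff_dates: tuple

    def __post_init__(self):
        assert len(self.train) + len(self.test) >= 0


def split_by_date(table: pd.DataFrame, test_dates) -> SplitResult:
    """Partition a table into train/test by survey date.

    Membership is determined solely by ``date``: rows whose date is in
    *test_dates* go to the test table, everything else to training. Dates
    absent from the table raise ``ValueError``.
    """
    dates = pd.to_datetime(pd.Series(sorted(set(pd.Timestamp(d).date() for d in test_dates)))).dt.date
    present = set(pd.to_datetime(table["date"]).dt.date)
    unknown = [d for d in dates if d not in present]
    if unknown:
        raise ValueError(f"test date(s) not present in table: {[d.isoformat() for d in unknown]}")
    row_dates = pd.to_datetime(table["date"]).dt.date
    mask = row_dates.isin(set(dates))
    return SplitResult(
        train=table.loc[~mask].copy(),
        test=table.loc[mask].copy(),
        cutoff_dates=tuple(d.isoformat() for d in dates),
    )


@dataclass
class TransectCounts:
    """Distance-binned counts per transect x visit, with covariates.

    ``counts[t, v, b]`` is the number of detections on transect *t*, visit
    *v*, in distance bin *b*. ``transect_covs`` holds per-transect land-cover
    percentages (columns such as ``forest``, ``grass``, ``road``, ``water``);
    ``visit_covs`` holds per-visit weather (``temperature``, ``wind_speed``).
    """

    counts: np.ndarray
    bin_edges: np.ndarray = field(default_factory=lambda: np.asarray(DEFAULT_BIN_EDGES))
    transect_ids: tuple = ()
    visit_ids: tuple = ()
    transect_covs: pd.DataFrame | None = None
    visit_covs: pd.DataFrame | None = None
    site: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.counts.ndim != 3:
            raise ValidationError("counts must be a (transects, visits, bins) array")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if self.bin_edges[0] != 0 or np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin_edges must start at 0 and strictly increase")
        if self.counts.shape[2] != len(self.bin_edges) - 1:
            raise ValidationError("counts bin dimension does not match bin_edges")
        if not self.transect_ids:
            self.transect_ids = tuple(f"t{i + 1}" for i in range(self.counts.shape[0]))
        if not self.visit_ids:
            self.visit_ids = tuple(f"v{i + 1}" for i in range(self.counts.shape[1]))
        if self.transect_covs is not None:
            if len(self.transect_covs) != self.counts.shape[0]:
                raise ValidationError("transect_covs row count must equal number of transects")
            pct = self.transect_covs.select_dtypes("number")
            if ((pct < 0) | (pct > 100)).any().any():
                raise ValidationError("land-cover percentages must lie in [0, 100]")
        if self.visit_covs is not None and len(self.visit_covs) != self.counts.shape[1]:
            raise ValidationError("visit_covs row count must equal number of visits")

    @property
    def n_transects(self) -> int:
        return self.counts.shape[0]

    @property
    def n_visits(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    def to_csv(self, path) -> None:
        """One row per transect x visit: bin1..binB plus covariate columns."""
        T, V, B = self.counts.shape
        rows = []
        for t in range(T):
            for v in range(V):
                row = {"site": self.site, "transect": self.transect_ids[t], "visit": self.visit_ids[v]}
                for b in range(B):
                    row[f"bin{b + 1}"] = int(self.counts[t, v, b])
                if self.transect_covs is not None:
                    for c in self.transect_covs.columns:
                        row[f"transect_{c}"] = self.transect_covs.iloc[t][c]
                if self.visit_covs is not None:
                    for c in self.visit_covs.columns:
                        row[f"visit_{c}"] = self.visit_covs.iloc[v][c]
                rows.append(row)
        header = ",".join(str(e) for e in self.bin_edges)
        df = pd.DataFrame(rows)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# bin_edges={header}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TransectCounts":
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            if first.startswith("# bin_edges="):
                edges = np.asarray([float(x) for x in first.split("=", 1)[1].split(",")])
                df = pd.read_csv(fh)
            else:
                edges = np.asarray(DEFAULT_BIN_EDGES)
                fh.seek(0)
                df = pd.read_csv(fh)
        tids = tuple(dict.fromkeys(df["transect"].astype(str)))
        vids = tuple(dict.fromkeys(df["visit"].astype(str)))
        bin_cols = sorted((c for c in df.columns if c.startswith("bin")), key=lambda c: int(c[3:]))
        counts = np.zeros((len(tids), len(vids), len(bin_cols)), dtype=int)
        for _, row in df.iterrows():
            t = tids.index(str(row["transect"]))
            v = vids.index(str(row["visit"]))
            counts[t, v, :] = [row[c] for c in bin_cols]
        tcov_cols = [c for c in df.columns if c.startswith("transect_")]
        vcov_cols = [c for c in df.columns if c.startswith("visit_")]
        tcov = None
        if tcov_cols:
            tcov = (
                df.drop_duplicates("transect").set_index("transect")[tcov_cols].loc[list(tids)]
            ).reset_index(drop=True)
            tcov.columns = [c.removeprefix("transect_") for c in tcov.columns]
        vcov = None
        if vcov_cols:
            vcov = (
                df.drop_duplicates("visit").set_index("visit")[vcov_cols].loc[list(vids)]
            ).reset_index(drop=True)
            vcov.columns = [c.removeprefix("visit_") for c in vcov.columns]
        site = str(df["site"].iloc[0]) if "site" in df.columns and len(df) else ""
        return cls(counts, edges, tids, vids, tcov, vcov, site)


def bin_counts(
    table: pd.DataFrame,
    bin_edges=DEFAULT_BIN_EDGES,
    keep=DETECTED_KLASSES,
) -> TransectCounts:
    """Bin kept observations into perpendicular-distance classes.

    Rows whose ``klass`` is in *keep* are tallied into half-open bins
    ``[lo, hi)`` defined by *bin_edges*; a perpendicular distance at or
    beyond the outermost edge is an error. Grouping is by transect (the
    ``transect`` column if present, else the site label) x survey date; the
    total count always equals the number of kept rows and is invariant to
    row order.
    """
    edges = np.asarray(bin_edges, dtype=float)
    keep = {keep} if isinstance(keep, str) else set(keep)
    sub = table[table["klass"].isin(keep)]
    group_col = "transect" if "transect" in table.columns else "site"
    if len(sub):
        d = sub["perp_distance"].to_numpy(dtype=float)
        over = d >= edges[-1]
        if over.any():
            ids = list(sub.loc[over, "object_id"].astype(str))[:10]
            raise ValidationError(
                f"perp_distance >= {edges[-1]} m for object(s) {ids}; cannot bin"
            )
        tids = tuple(dict.fromkeys(sub[group_col].astype(str)))
        vids = tuple(str(x) for x in dict.fromkeys(pd.to_datetime(sub["date"]).dt.date))
        counts = np.zeros((len(tids), len(vids), len(edges) - 1), dtype=int)
        bins = np.digitize(d, edges[1:-1], right=False)
        t_idx = sub[group_col].astype(str).map({t: i for i, t in enumerate(tids)}).to_numpy()
        v_idx = (
            pd.to_datetime(sub["date"]).dt.date.astype(str).map({v: i for i, v in enumerate(vids)}).to_numpy()
        )
        np.add.at(counts, (t_idx, v_idx, bins), 1)
    else:
        tids, vids = ("t1",), ("v1",)
        counts = np.zeros((1, 1, len(edges) - 1), dtype=int)
    site = str(table["site"].iloc[0]) if len(table) else ""
    return TransectCounts(counts, edges, tids, vids, site=site)
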