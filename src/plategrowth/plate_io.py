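"""Reading and writing plate-reader kinetic exports and analysis state.

Two text dialects are supported:

* **long** (canonical): one row per well x kinetic cycle with header
  ``well,sample,condition,time_s,od[,temp_c]`` (comma- or tab-separated).
* **matrix** (instrument-like): a ``key<TAB>value`` metadata block, a
  ``Well`` header row with plate coordinates, a ``Time[s]`` header row
  with the ``Sample_Condition`` labels, then one row per cycle holding
  the time stamp in seconds (optionally a ``Temp[C]`` value) and one OD
  per well.

All times are converted to hours elapsed since the first reading of the
plate.  Each well carries a ``Sample_Condition`` label; medium-only
background wells use a reserved sample label (default ``"blank"``) with
the condition naming their medium.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "StateError",
    "TimeSeries",
    "WellRecord",
    "PlateExperiment",
    "AnalysisState",
    "parse_plate_export",
    "parse_label",
    "write_plate_export",
    "write_results_table",
    "save_state",
    "load_state",
    "RESULT_COLUMNS",
]

STATE_SCHEMA_VERSION = 1

#: Fixed column order for per-well result tables.
RESULT_COLUMNS = [
    "well",
    "sample",
    "condition",
    "mu_max",
    "t_at_mu_max",
    "od0_fit",
    "lag_time",
    "doubling_time",
    "yield_biomass",
    "valid",
    "warnings",
]

#: Fixed column order for aggregated result tables.
AGGREGATE_COLUMNS = [
    "sample",
    "condition",
    "parameter",
    "n",
    "mean",
    "variance",
    "n_excluded",
    "wells",
]


class ParseError(ValueError):
    """Raised for malformed plate exports; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class StateError(ValueError):
    """Raised when an analysis-state document cannot be loaded."""


@dataclass(frozen=True)
class TimeSeries:
    """One well's optical-density trajectory over real time.

    Parameters
    ----------
    times
        Time points in hours, strictly increasing.
    values
        Optical densities (dimensionless), same length as ``times``.
    temperatures
        Optional per-time-point temperatures in deg C (provenance only).
    """

    times: np.ndarray
    values: np.ndarray
    temperatures: np.ndarray | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.temperatures is not None:
            temps = np.asarray(self.temperatures, dtype=float)
            object.__setattr__(self, "temperatures", temps)
            if temps.shape != times.shape:
                raise ValueError("temperatures length differs from times")
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if times.shape != values.shape:
            raise ValueError("times and values differ in length")
        if times.size and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("all OD values must be finite")

    def __len__(self) -> int:
        return self.times.size

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        """Return a copy on the same time grid with new OD values."""
        return TimeSeries(self.times, values, self.temperatures)


@dataclass
class WellRecord:
    """A single well: plate coordinate, label, raw and processed series."""

    well_id: str
    sample: str
    condition: str
    raw: TimeSeries
    processed: TimeSeries | None = None
    blacklisted: bool = False

    def __post_init__(self):
        if not self.sample:
            raise ValueError(f"well {self.well_id}: empty sample label")
        if not self.condition:
            raise ValueError(f"well {self.well_id}: empty condition label")
        if self.processed is not None and not np.array_equal(
            self.processed.times, self.raw.times
        ):
            raise ValueError(
                f"well {self.well_id}: processed series not on the raw time grid"
            )

    @property
    def series(self) -> TimeSeries:
        """The processed series when present, else the raw one."""
        return self.processed if self.processed is not None else self.raw


@dataclass
class PlateExperiment:
    """A labelled plate of wells, including medium-only blanks.

    Wells share one common time grid.  The replicate-grouping structure
    W(sample, condition) is derived from the well labels; medium-only
    wells carry ``blank_sample_label`` as their sample.
    """

    wells: list[WellRecord]
    plate_format: int = 384
    blank_sample_label: str = "blank"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate well ids: {', '.join(dupes)}")
        if self.wells:
            grid = self.wells[0].raw.times
            for w in self.wells[1:]:
                if not np.array_equal(w.raw.times, grid):
                    raise ValueError(
                        f"well {w.well_id} is not on the common time grid"
                    )

    @property
    def times(self) -> np.ndarray:
        return self.wells[0].raw.times

    def well(self, well_id: str) -> WellRecord:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)

    def is_blank(self, well: WellRecord) -> bool:
        return well.sample == self.blank_sample_label

    def blank_wells(self, condition: str) -> list[WellRecord]:
        """W(blank, condition): medium-only wells for one condition."""
        return [
            w
            for w in self.wells
            if self.is_blank(w) and w.condition == condition
        ]

    def sample_wells(self) -> list[WellRecord]:
        return [w for w in self.wells if not self.is_blank(w)]

    def conditions(self) -> list[str]:
        """Conditions present among non-blank wells, in plate order."""
        seen: dict[str, None] = {}
        for w in self.sample_wells():
            seen.setdefault(w.condition, None)
        return list(seen)

    def groups(self) -> dict[tuple[str, str], list[WellRecord]]:
        """W(sample, condition) for all non-blank wells, in plate order."""
        out: dict[tuple[str, str], list[WellRecord]] = {}
        for w in self.sample_wells():
            out.setdefault((w.sample, w.condition), []).append(w)
        return out


def parse_label(label: str, blank_label: str = "blank") -> tuple[str, str]:
    """Split a ``Sample_Condition`` label at the FIRST underscore.

    The sample may not contain underscores; the condition may (complex
    media names such as ``YPD_2%NaCl``).  A bare ``blank_label`` is
    accepted for unlabelled medium-only wells and mapped to an empty
    condition.
    """
    if not label:
        raise ValueError("empty well label")
    if "_" not in label:
        if label == blank_label:
            return (blank_label, "")
        raise ValueError(
            f"unlabelled well: {label!r} has no '_' separating sample and condition"
        )
    sample, condition = label.split("_", 1)
    if not sample or not condition:
        raise ValueError(f"malformed label {label!r}")
    return sample, condition


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def parse_plate_export(
    source,
    dialect: str = "matrix",
    blank_label: str = "blank",
    plate_format: int | None = None,
) -> PlateExperiment:
    """Parse a kinetic export into a :class:`PlateExperiment`.

    Parameters
    ----------
    source
        A text stream, a path, or the export text itself.
    dialect
        ``"long"`` or ``"matrix"`` (see module docstring).
    blank_label
        Reserved sample label designating medium-only wells.
    plate_format
        Declared well count; inferred from the number of wells if absent.
    """
    text = _read_text(source)
    if dialect == "long":
        exp = _parse_long(text, blank_label)
    elif dialect == "matrix":
        exp = _parse_matrix(text, blank_label)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if plate_format is not None:
        exp.plate_format = plate_format
    else:
        exp.plate_format = _infer_format(len(exp.wells))
    return exp


def _read_text(source) -> str:
    if hasattr(source, "read"):
        return source.read()
    s = str(source)
    if "\n" not in s and ("\t" not in s and "," not in s):
        with open(s, "r", encoding="utf-8") as fh:
            return fh.read()
    return s


def _infer_format(n_wells: int) -> int:
    for fmt in (96, 384):
        if n_wells <= fmt:
            return fmt
    return n_wells


def _parse_long(text: str, blank_label: str) -> PlateExperiment:
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty export")
    sep = _sniff_delimiter(lines[0])
    header = [h.strip() for h in lines[0].split(sep)]
    required = ["well", "sample", "condition", "time_s", "od"]
    if header[: len(required)] != required:
        raise ParseError(
            f"expected header starting with {','.join(required)}, got {lines[0]!r}",
            line=1,
        )
    has_temp = "temp_c" in header
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep, skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"unreadable export: {exc}") from None
    for col in ("time_s", "od"):
        bad = df.index[df[col].isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ParseError(f"missing {col} value", line=int(bad[0]) + 2)
    wells: list[WellRecord] = []
    t0: float | None = None
    for well_id, sub in df.groupby("well", sort=False):
        times_s = sub["time_s"].to_numpy(dtype=float)
        if t0 is None:
            t0 = float(times_s[0])
        times_h = (times_s - t0) / 3600.0
        if np.any(np.diff(times_h) <= 0):
            raise ParseError(f"non-monotone time stamps in well {well_id}")
        temps = (
            sub["temp_c"].to_numpy(dtype=float)
            if has_temp and sub["temp_c"].notna().all()
            else None
        )
        sample = str(sub["sample"].iloc[0])
        condition = str(sub["condition"].iloc[0])
        wells.append(
            WellRecord(
                well_id=str(well_id),
                sample=sample,
                condition=condition,
                raw=TimeSeries(times_h, sub["od"].to_numpy(dtype=float), temps),
            )
        )
    return PlateExperiment(wells=wells, blank_sample_label=blank_label)


def _parse_matrix(text: str, blank_label: str) -> PlateExperiment:
    lines = text.splitlines()
    metadata: dict[str, str] = {}
    well_ids: list[str] | None = None
    labels: list[str] | None = None
    has_temp = False
    data_start = None
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        cells = line.split("\t")
        key = cells[0].strip()
        if key == "Well":
            well_ids = [c.strip() for c in cells[1:] if c.strip()]
        elif key == "Time[s]":
            rest = [c.strip() for c in cells[1:]]
            if rest and rest[0] == "Temp[C]":
                has_temp = True
                rest = rest[1:]
            labels = [c for c in rest if c]
            data_start = i + 1
            break
        elif len(cells) == 2:
            metadata[key] = cells[1].strip()
        else:
            raise ParseError(f"unrecognized header line {line!r}", line=i + 1)
    if labels is None or data_start is None:
        raise ParseError("no 'Time[s]' header row found")
    if well_ids is None:
        raise ParseError("no 'Well' header row with plate coordinates found")
    if len(well_ids) != len(labels):
        raise ParseError(
            f"{len(well_ids)} well coordinates but {len(labels)} labels"
        )
    n_cols = 1 + (1 if has_temp else 0) + len(labels)
    times_s: list[float] = []
    temps: list[float] = []
    rows: list[list[float]] = []
    for i in range(data_start, len(lines)):
        line = lines[i]
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != n_cols:
            raise ParseError(
                f"expected {n_cols} cells, found {len(cells)}", line=i + 1
            )
        try:
            vals = [float(c) for c in cells]
        except ValueError:
            raise ParseError(f"non-numeric cell in {line!r}", line=i + 1) from None
        times_s.append(vals[0])
        if has_temp:
            temps.append(vals[1])
            rows.append(vals[2:])
        else:
            rows.append(vals[1:])
    if not rows:
        raise ParseError("export contains no kinetic cycles")
    t = np.asarray(times_s, dtype=float)
    times_h = (t - t[0]) / 3600.0
    if np.any(np.diff(times_h) <= 0):
        bad = int(np.nonzero(np.diff(times_h) <= 0)[0][0])
        raise ParseError("non-monotone time stamps", line=data_start + bad + 2)
    od = np.asarray(rows, dtype=float)
    temp_arr = np.asarray(temps, dtype=float) if has_temp else None
    wells = []
    for j, (well_id, label) in enumerate(zip(well_ids, labels)):
        sample, condition = parse_label(label, blank_label)
        if not condition:  # bare blank label: condition is the medium, unknown
            condition = "medium"
        wells.append(
            WellRecord(
                well_id=well_id,
                sample=sample,
                condition=condition,
                raw=TimeSeries(times_h, od[:, j], temp_arr),
            )
        )
    return PlateExperiment(
        wells=wells, blank_sample_label=blank_label, metadata=metadata
    )


def write_plate_export(experiment: PlateExperiment, sink=None, sep: str = ",") -> str:
    """Write an experiment in the canonical long dialect.

    Returns the text; also writes it to ``sink`` (stream or path) when given.
    Times are emitted in seconds at full precision so that a re-parse
    reproduces the experiment.
    """
    any_temp = any(w.raw.temperatures is not None for w in experiment.wells)
    cols = ["well", "sample", "condition", "time_s", "od"]
    if any_temp:
        cols.append("temp_c")
    buf = io.StringIO()
    buf.write(sep.join(cols) + "\n")
    for w in experiment.wells:
        ts = w.raw
        for k in range(len(ts)):
            row = [
                w.well_id,
                w.sample,
                w.condition,
                repr(float(ts.times[k]) * 3600.0),
                repr(float(ts.values[k])),
            ]
            if any_temp:
                row.append(
                    repr(float(ts.temperatures[k]))
                    if ts.temperatures is not None
                    else ""
                )
            buf.write(sep.join(row) + "\n")
    text = buf.getvalue()
    if sink is not None:
        _write_text(sink, text)
    return text


def _write_text(sink, text: str) -> None:
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            fh.write(text)


def _fmt(x) -> str:
    """Floating values at 6 significant digits; passthrough otherwise."""
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_results_table(summaries, mode: str, sink=None) -> str:
    """Write growth results as delimited text.

    ``mode="per_well"`` expects a mapping well_id -> (WellRecord,
    GrowthParameters) or an iterable of rows and emits one row per
    non-blacklisted well.  ``mode="aggregated"`` expects an iterable of
    :class:`~plategrowth.growth.ReplicateSummary` and emits one row per
    (sample, condition, parameter) with mean and variance.
    """
    if not summaries:
        raise ValueError("no results to write")
    if mode == "per_well":
        rows = []
        for well, params in summaries:
            if well.blacklisted:
                continue
            rows.append(
                {
                    "well": well.well_id,
                    "sample": well.sample,
                    "condition": well.condition,
                    "mu_max": params.mu_max,
                    "t_at_mu_max": params.t_at_mu_max,
                    "od0_fit": params.od0_fit,
                    "lag_time": params.lag_time,
                    "doubling_time": params.doubling_time,
                    "yield_biomass": params.yield_biomass,
                    "valid": params.valid,
                    "warnings": ";".join(params.warnings),
                }
            )
        df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    elif mode == "aggregated":
        rows = []
        for s in summaries:
            rows.append(
                {
                    "sample": s.sample,
                    "condition": s.condition,
                    "parameter": s.parameter,
                    "n": s.n,
                    "mean": s.mean,
                    "variance": s.variance,
                    "n_excluded": s.n_excluded,
                    "wells": ";".join(s.well_ids),
                }
            )
        df = pd.DataFrame(rows, columns=AGGREGATE_COLUMNS)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    text = df.to_csv(index=False, float_format="%.6g")
    if sink is not None:
        _write_text(sink, text)
    return text


@dataclass
class AnalysisState:
    """A saved analysis: config, calibration, blacklist, per-well results.

    Reloading a saved state reproduces identical results without
    recomputation; the stored config allows an identical re-run.
    """

    config: "ExtractionConfig"
    calibration: "CalibrationModel | None" = None
    blacklist: set = field(default_factory=set)
    results: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def digest_file(path) -> str:
    """SHA-256 digest of a file, for state provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def save_state(state: AnalysisState, sink) -> str:
    """Serialise an :class:`AnalysisState` to a JSON document."""
    from .growth import GrowthParameters  # noqa: F401  (type for loaders)

    doc = {
        "schema_version": STATE_SCHEMA_VERSION,
        "config": state.config.to_dict(),
        "calibration": state.calibration.to_dict() if state.calibration else None,
        "blacklist": sorted(state.blacklist),
        "results": {w: p.to_dict() for w, p in sorted(state.results.items())},
        "provenance": state.provenance,
    }
    text = json.dumps(doc, indent=1, sort_keys=True)
    if sink is not None:
        _write_text(sink, text)
    return text


def load_state(source) -> AnalysisState:
    """Load an :class:`AnalysisState` saved by :func:`save_state`."""
    from .growth import ExtractionConfig, GrowthParameters
    from .preprocess import CalibrationModel

    text = _read_text(source)
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise StateError(f"corrupted state document: {exc}") from None
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise StateError("not an analysis-state document")
    if doc["schema_version"] != STATE_SCHEMA_VERSION:
        raise StateError(
            f"unsupported schema version {doc['schema_version']!r} "
            f"(expected {STATE_SCHEMA_VERSION})"
        )
    try:
        config = ExtractionConfig.from_dict(doc["config"])
        calibration = (
            CalibrationModel.from_dict(doc["calibration"])
            if doc.get("calibration")
            else None
        )
        results = {
            w: GrowthParameters.from_dict(p) for w, p in doc["results"].items()
        }
    except (KeyError, TypeError) as exc:
        raise StateError(f"incomplete state document: {exc!r}") from None
    return AnalysisState(
        config=config,
        calibration=calibration,
        blacklist=set(doc.get("blacklist", [])),
        results=results,
        provenance=doc.get("provenance", {}),
    )
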