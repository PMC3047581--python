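"""Import templates, sorted exports, and the project store.

Template layout (CSV or XLSX, one logical layout): the first column holds
row labels, each further column is one replicate profile.

    well          A1        A2      ...
    run_id        run1      run1
    sample        COL1      COL1
    amplicon      12240     12240
    amplicon_size 150       150
    strandedness  single    single
    quantity_ng   (calibration templates only; blank otherwise)
    1             50123.0   49887.2
    2             50234.1   50011.8
    ...           ...       ...

Cycle numbers are 1-based and inferred from row order.  Import is
column-atomic: a malformed column is rejected with its row/column
coordinates while the remaining columns import, and nothing is dropped
silently — counts are reported on the result.

Exports (one worksheet or CSV file per group, sorted by run, sample or
amplicon) carry the analysis columns: No (molecules), C_1/2, E_max, dE,
F_max, avg F_0, window start/size and flags, at full precision.

The project store is a single versioned JSON file holding the three
collections — experiment (runs of replicate sets), calibration (reaction
setups with their OCF), and amplicons — chosen over an opaque object
database for transparency and diffability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .core import (
    FluorescenceProfile,
    LreFit,
    LreWindow,
    Strandedness,
    WindowParams,
)
from .diagnostics import Kinetics, KineticsReport
from .errors import ImportError_, ProjectLoadError, ProjectSchemaError
from .quantify import Ocf, ReplicateSet, Run
from .windows import AnalyzedProfile, CandidateRecord, WindowTrace

__all__ = [
    "SCHEMA_VERSION",
    "ImportIssue",
    "ImportResult",
    "Amplicon",
    "CalibrationSetup",
    "Project",
    "read_profile_table",
    "write_template",
    "write_export",
    "save_project",
    "load_project",
    "group_profiles",
]

SCHEMA_VERSION = 1

_HEADER_ROWS = ["well", "run_id", "sample", "amplicon", "amplicon_size", "strandedness"]
_QUANTITY_ROW = "quantity_ng"


@dataclass(frozen=True)
class ImportIssue:
    """A rejected column, with 1-based spreadsheet coordinates."""

    column: int
    row: int | None
    message: str

    def __str__(self) -> str:
        where = f"column {self.column}"
        if self.row is not None:
            where += f", row {self.row}"
        return f"{where}: {self.message}"


@dataclass
class ImportResult:
    """Profiles imported from one template, plus per-column diagnostics."""

    profiles: list[FluorescenceProfile]
    quantities_ng: dict[str, float]  # well label -> known ng (calibration)
    issues: list[ImportIssue]
    n_columns: int

    @property
    def ok(self) -> bool:
        return not self.issues


@dataclass
class Amplicon:
    """Amplicon-collection entry; supplies sizes during run import."""

    name: str
    size: int
    primers: tuple[str, str] | None = None
    notes: str = ""


@dataclass
class CalibrationSetup:
    """Calibration profiles for one reaction setup and their OCF."""

    name: str
    profiles: list[FluorescenceProfile] = field(default_factory=list)
    analyzed: list[AnalyzedProfile] | None = None
    known_ng: float | None = None
    ocf: Ocf | None = None


@dataclass
class Project:
    """The three collections of an LRE project."""

    runs: list[Run] = field(default_factory=list)
    calibrations: list[CalibrationSetup] = field(default_factory=list)
    amplicons: dict[str, Amplicon] = field(default_factory=dict)
    params: WindowParams = field(default_factory=WindowParams)
    schema_version: int = SCHEMA_VERSION


# ---------------------------------------------------------------------------
# template import / export


def _read_grid(path: str | Path) -> list[list[str]]:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        frame = pd.read_excel(path, header=None, dtype=object)
    else:
        frame = pd.read_csv(path, header=None, dtype=object, keep_default_na=False)
    grid: list[list[str]] = []
    for _, row in frame.iterrows():
        grid.append(["" if _is_blank(v) else str(v).strip() for v in row])
    return grid


def _is_blank(v: Any) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return str(v).strip() == ""


def read_profile_table(path: str | Path, kind: str = "sample") -> ImportResult:
    """Read a Fig-6-style import template (CSV or XLSX).

    ``kind="calibration"`` marks profiles as calibration profiles and
    reads the ``quantity_ng`` header row (known DNA mass per reaction).
    Malformed columns are rejected individually with coordinates; valid
    columns always import.
    """
    if kind not in ("sample", "calibration"):
        raise ValueError("kind must be 'sample' or 'calibration'")
    grid = _read_grid(path)
    labels = [row[0] if row else "" for row in grid]
    row_of: dict[str, int] = {}
    for i, lab in enumerate(labels):
        key = lab.strip().lower()
        if key and key not in row_of:
            row_of[key] = i
    missing = [h for h in _HEADER_ROWS if h not in row_of]
    if missing:
        raise ImportError_(f"template is missing header rows: {missing}")
    cycle_rows = [
        (i, int(lab)) for i, lab in enumerate(labels) if lab.strip().isdigit()
    ]
    if len(cycle_rows) < 10:
        raise ImportError_("template has fewer than 10 cycle rows")
    expected = list(range(1, len(cycle_rows) + 1))
    if [c for _, c in cycle_rows] != expected:
        raise ImportError_("cycle rows must be consecutive starting at 1")
    n_cols = max(len(r) for r in grid)

    def cell(i: int, j: int) -> str:
        row = grid[i]
        return row[j] if j < len(row) else ""

    profiles: list[FluorescenceProfile] = []
    quantities: dict[str, float] = {}
    issues: list[ImportIssue] = []
    for j in range(1, n_cols):
        if all(cell(i, j) == "" for i in range(len(grid))):
            continue  # fully blank column
        try:
            header = {h: cell(row_of[h], j) for h in _HEADER_ROWS}
            for h in ("sample", "amplicon", "amplicon_size", "strandedness"):
                if header[h] == "":
                    raise _ColumnError(row_of[h] + 1, f"missing {h}")
            try:
                size = int(float(header["amplicon_size"]))
            except ValueError:
                raise _ColumnError(
                    row_of["amplicon_size"] + 1,
                    f"bad amplicon size {header['amplicon_size']!r}",
                )
            try:
                strand = Strandedness.parse(header["strandedness"])
            except ValueError as exc:
                raise _ColumnError(row_of["strandedness"] + 1, str(exc))
            readings = []
            for i, cyc in cycle_rows:
                text = cell(i, j)
                try:
                    readings.append(float(text))
                except ValueError:
                    raise _ColumnError(
                        i + 1, f"non-numeric fluorescence {text!r} at cycle {cyc}"
                    )
            well = header["well"] or f"col{j + 1}"
            profile = FluorescenceProfile(
                well_label=well,
                sample_name=header["sample"],
                amplicon_name=header["amplicon"],
                amplicon_size=size,
                strandedness=strand,
                raw_fc=np.array(readings),
                is_calibration=(kind == "calibration"),
                run_id=header["run_id"],
            )
            if kind == "calibration":
                qrow = row_of.get(_QUANTITY_ROW)
                qtext = cell(qrow, j) if qrow is not None else ""
                if qtext == "":
                    raise _ColumnError(
                        (qrow or 0) + 1, "calibration column missing quantity_ng"
                    )
                try:
                    quantities[well] = float(qtext)
                except ValueError:
                    raise _ColumnError(qrow + 1, f"bad quantity_ng {qtext!r}")
            profiles.append(profile)
        except _ColumnError as exc:
            issues.append(ImportIssue(column=j + 1, row=exc.row, message=exc.msg))
        except ValueError as exc:  # profile invariant violations
            issues.append(ImportIssue(column=j + 1, row=None, message=str(exc)))
    return ImportResult(
        profiles=profiles,
        quantities_ng=quantities,
        issues=issues,
        n_columns=n_cols - 1,
    )


class _ColumnError(Exception):
    def __init__(self, row: int, msg: str) -> None:
        self.row, self.msg = row, msg


def write_template(
    profiles: list[FluorescenceProfile],
    path: str | Path,
    quantities_ng: dict[str, float] | None = None,
) -> Path:
    """Write profiles to the canonical import-template layout.

    Calibration templates (any profile with ``is_calibration``) include
    the ``quantity_ng`` row from ``quantities_ng`` (well label -> ng).
    """
    if not profiles:
        raise ValueError("no profiles to write")
    n = profiles[0].n_cycles
    if any(p.n_cycles != n for p in profiles):
        raise ValueError("profiles have mismatched cycle counts")
    calibration = any(p.is_calibration for p in profiles)
    rows: list[list[object]] = [
        ["well"] + [p.well_label for p in profiles],
        ["run_id"] + [p.run_id for p in profiles],
        ["sample"] + [p.sample_name for p in profiles],
        ["amplicon"] + [p.amplicon_name for p in profiles],
        ["amplicon_size"] + [p.amplicon_size for p in profiles],
        ["strandedness"] + [p.strandedness.value for p in profiles],
    ]
    if calibration:
        q = quantities_ng or {}
        rows.append(
            [_QUANTITY_ROW]
            + [repr(q[p.well_label]) if p.well_label in q else "" for p in profiles]
        )
    for c in range(1, n + 1):
        rows.append([c] + [repr(float(p.raw_fc[c - 1])) for p in profiles])
    path = Path(path)
    frame = pd.DataFrame(rows)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        frame.to_excel(path, header=False, index=False)
    else:
        frame.to_csv(path, header=False, index=False)
    return path


def group_profiles(profiles: list[FluorescenceProfile]) -> list[Run]:
    """Group imported profiles into runs of replicate sets.

    Profiles sharing a run id form a run; within it, profiles sharing
    (sample, amplicon) are technical replicates.  Order is preserved;
    counts are conserved.
    """
    runs: dict[str, dict[tuple[str, str], ReplicateSet]] = {}
    order: list[str] = []
    for p in profiles:
        rid = p.run_id or "run1"
        if rid not in runs:
            runs[rid] = {}
            order.append(rid)
        key = (p.sample_name, p.amplicon_name)
        if key not in runs[rid]:
            runs[rid][key] = ReplicateSet(
                sample_name=p.sample_name, amplicon_name=p.amplicon_name, profiles=[]
            )
        runs[rid][key].profiles.append(p)
    return [
        Run(run_id=rid, replicate_sets=list(runs[rid].values())) for rid in order
    ]


# ---------------------------------------------------------------------------
# analyzed-data export


_EXPORT_COLUMNS = [
    "run_id",
    "sample",
    "amplicon",
    "no_molecules",
    "c_half",
    "emax",
    "delta_e",
    "fmax",
    "avg_f0",
    "window_start",
    "window_size",
    "flags",
]


def _set_row(run: Run, rset: ReplicateSet) -> dict[str, object]:
    row: dict[str, object] = {
        "run_id": run.run_id,
        "sample": rset.sample_name,
        "amplicon": rset.amplicon_name,
        "no_molecules": rset.quantity if rset.quantity is not None else "",
        "c_half": "",
        "emax": "",
        "delta_e": "",
        "fmax": "",
        "avg_f0": "",
        "window_start": "",
        "window_size": "",
        "flags": ";".join(rset.flags),
    }
    ap = rset.average_analyzed
    if ap is not None and ap.fit is not None:
        row.update(
            c_half=ap.fit.c_half,
            emax=ap.fit.emax,
            delta_e=ap.fit.delta_e,
            fmax=ap.fit.fmax,
            avg_f0=ap.fit.avg_f0,
            window_start=ap.window.start_cycle,
            window_size=ap.window.size,
        )
        extra = ";".join(ap.flags)
        if extra:
            row["flags"] = ";".join(x for x in (str(row["flags"]), extra) if x)
    return row


def write_export(
    project: Project, sort_by: str, path: str | Path
) -> dict[str, Path]:
    """Export analyzed replicate sets, one sheet/CSV per group.

    ``sort_by`` is ``run``, ``sample`` or ``amplicon``.  An ``.xlsx``
    path gets one worksheet per group; any other path is treated as a
    directory receiving one CSV per group.  Returns group -> file (for
    XLSX, every group maps to the workbook path).
    """
    if sort_by not in ("run", "sample", "amplicon"):
        raise ValueError("sort_by must be run, sample or amplicon")
    groups: dict[str, list[dict[str, object]]] = {}
    for run in project.runs:
        for rset in run.replicate_sets:
            key = {
                "run": run.run_id,
                "sample": rset.sample_name,
                "amplicon": rset.amplicon_name,
            }[sort_by]
            groups.setdefault(key, []).append(_set_row(run, rset))
    if not groups:
        raise ValueError("project has no replicate sets to export")
    path = Path(path)
    written: dict[str, Path] = {}
    if path.suffix.lower() == ".xlsx":
        with pd.ExcelWriter(path) as writer:
            for key in sorted(groups):
                pd.DataFrame(groups[key], columns=_EXPORT_COLUMNS).to_excel(
                    writer, sheet_name=str(key)[:31], index=False
                )
                written[key] = path
    else:
        path.mkdir(parents=True, exist_ok=True)
        for key in sorted(groups):
            out = path / f"{sort_by}_{key}.csv"
            pd.DataFrame(groups[key], columns=_EXPORT_COLUMNS).to_csv(
                out, index=False
            )
            written[key] = out
    return written


# ---------------------------------------------------------------------------
# project store (versioned JSON)


def _arr(a: np.ndarray | None) -> list[float] | None:
    return None if a is None else [float(v) for v in a]


def _profile_to_dict(p: FluorescenceProfile) -> dict:
    return {
        "well_label": p.well_label,
        "sample_name": p.sample_name,
        "amplicon_name": p.amplicon_name,
        "amplicon_size": p.amplicon_size,
        "strandedness": p.strandedness.value,
        "raw_fc": _arr(p.raw_fc),
        "is_calibration": p.is_calibration,
        "run_id": p.run_id,
    }


def _profile_from_dict(d: dict) -> FluorescenceProfile:
    return FluorescenceProfile(
        well_label=d["well_label"],
        sample_name=d["sample_name"],
        amplicon_name=d["amplicon_name"],
        amplicon_size=d["amplicon_size"],
        strandedness=Strandedness(d["strandedness"]),
        raw_fc=np.array(d["raw_fc"], dtype=float),
        is_calibration=d["is_calibration"],
        run_id=d["run_id"],
    )


def _fit_to_dict(f: LreFit | None) -> dict | None:
    if f is None:
        return None
    return {
        "emax": f.emax,
        "delta_e": f.delta_e,
        "fmax": f.fmax,
        "r2": f.r2,
        "f0_per_cycle": _arr(f.f0_per_cycle),
        "avg_f0": f.avg_f0,
        "c_half": f.c_half,
    }


def _fit_from_dict(d: dict | None) -> LreFit | None:
    if d is None:
        return None
    return LreFit(
        emax=d["emax"],
        delta_e=d["delta_e"],
        fmax=d["fmax"],
        r2=d["r2"],
        f0_per_cycle=np.array(d["f0_per_cycle"], dtype=float),
        avg_f0=d["avg_f0"],
        c_half=d["c_half"],
    )


def _params_to_dict(p: WindowParams) -> dict:
    return {
        "min_fc": p.min_fc,
        "f0_threshold": p.f0_threshold,
        "initial_window_size": p.initial_window_size,
        "baseline_cycles": list(p.baseline_cycles) if p.baseline_cycles else None,
    }


def _params_from_dict(d: dict) -> WindowParams:
    bc = d["baseline_cycles"]
    return WindowParams(
        min_fc=d["min_fc"],
        f0_threshold=d["f0_threshold"],
        initial_window_size=d["initial_window_size"],
        baseline_cycles=tuple(bc) if bc else None,
    )


def _trace_to_dict(t: WindowTrace | None) -> dict | None:
    if t is None:
        return None
    return {
        "records": [
            {
                "cycle": r.cycle,
                "fc": r.fc,
                "ec": r.ec,
                "f0": r.f0,
                "pct_diff": r.pct_diff,
                "accepted": r.accepted,
            }
            for r in t.records
        ],
        "stop_reason": t.stop_reason,
        "window": [t.window.start_cycle, t.window.size],
    }


def _trace_from_dict(d: dict | None) -> WindowTrace | None:
    if d is None:
        return None
    return WindowTrace(
        records=[CandidateRecord(**r) for r in d["records"]],
        stop_reason=d["stop_reason"],
        window=LreWindow(start_cycle=d["window"][0], size=d["window"][1]),
    )


def _kinetics_to_dict(k: KineticsReport | None) -> dict | None:
    if k is None:
        return None
    return {
        "classification": k.classification.value,
        "drift_score": k.drift_score,
        "window_r2": k.window_r2,
        "below_window_mean": k.below_window_mean,
        "curvature_t_stat": k.curvature_t_stat,
        "notes": k.notes,
    }


def _kinetics_from_dict(d: dict | None) -> KineticsReport | None:
    if d is None:
        return None
    return KineticsReport(
        classification=Kinetics(d["classification"]),
        drift_score=d["drift_score"],
        window_r2=d["window_r2"],
        below_window_mean=d["below_window_mean"],
        curvature_t_stat=d["curvature_t_stat"],
        notes=d["notes"],
    )


def _analyzed_to_dict(a: AnalyzedProfile | None) -> dict | None:
    if a is None:
        return None
    return {
        "profile": _profile_to_dict(a.profile),
        "params": _params_to_dict(a.params),
        "baseline": None if a.baselined is None else a.baselined.baseline,
        "start_cycle": a.start_cycle,
        "window": None if a.window is None else [a.window.start_cycle, a.window.size],
        "fit": _fit_to_dict(a.fit),
        "trace": _trace_to_dict(a.trace),
        "kinetics": _kinetics_to_dict(a.kinetics),
        "flags": list(a.flags),
    }


def _analyzed_from_dict(d: dict | None) -> AnalyzedProfile | None:
    from .core import subtract_baseline

    if d is None:
        return None
    profile = _profile_from_dict(d["profile"])
    params = _params_from_dict(d["params"])
    out = AnalyzedProfile(profile=profile, params=params)
    if d["baseline"] is not None:
        out.baselined = subtract_baseline(profile, params.baseline_cycles)
    out.start_cycle = d["start_cycle"]
    if d["window"] is not None:
        out.window = LreWindow(start_cycle=d["window"][0], size=d["window"][1])
    out.fit = _fit_from_dict(d["fit"])
    out.trace = _trace_from_dict(d["trace"])
    out.kinetics = _kinetics_from_dict(d["kinetics"])
    out.flags = list(d["flags"])
    return out


def _ocf_to_dict(o: Ocf | None) -> dict | None:
    if o is None:
        return None
    return {
        "value": o.value,
        "sd": o.sd,
        "source_reaction_setup": o.source_reaction_setup,
        "calibration_profile_ids": list(o.calibration_profile_ids),
        "per_profile": list(o.per_profile),
    }


def _ocf_from_dict(d: dict | None) -> Ocf | None:
    return None if d is None else Ocf(**d)


def _rset_to_dict(s: ReplicateSet) -> dict:
    return {
        "sample_name": s.sample_name,
        "amplicon_name": s.amplicon_name,
        "profiles": [_profile_to_dict(p) for p in s.profiles],
        "analyzed": None
        if s.analyzed is None
        else [_analyzed_to_dict(a) for a in s.analyzed],
        "average_profile": None
        if s.average_profile is None
        else _profile_to_dict(s.average_profile),
        "average_analyzed": _analyzed_to_dict(s.average_analyzed),
        "quantity": s.quantity,
        "quantification_path": s.quantification_path,
        "f0_cv": s.f0_cv,
        "flags": list(s.flags),
    }


def _rset_from_dict(d: dict) -> ReplicateSet:
    return ReplicateSet(
        sample_name=d["sample_name"],
        amplicon_name=d["amplicon_name"],
        profiles=[_profile_from_dict(p) for p in d["profiles"]],
        analyzed=None
        if d["analyzed"] is None
        else [_analyzed_from_dict(a) for a in d["analyzed"]],
        average_profile=None
        if d["average_profile"] is None
        else _profile_from_dict(d["average_profile"]),
        average_analyzed=_analyzed_from_dict(d["average_analyzed"]),
        quantity=d["quantity"],
        quantification_path=d["quantification_path"],
        f0_cv=d["f0_cv"],
        flags=list(d["flags"]),
    )


def _run_to_dict(r: Run) -> dict:
    return {
        "run_id": r.run_id,
        "run_date": r.run_date,
        "replicate_sets": [_rset_to_dict(s) for s in r.replicate_sets],
        "ocf": _ocf_to_dict(r.ocf),
        "av_repl_f0_cv": r.av_repl_f0_cv,
    }


def _run_from_dict(d: dict) -> Run:
    return Run(
        run_id=d["run_id"],
        run_date=d["run_date"],
        replicate_sets=[_rset_from_dict(s) for s in d["replicate_sets"]],
        ocf=_ocf_from_dict(d["ocf"]),
        av_repl_f0_cv=d["av_repl_f0_cv"],
    )


def _calset_to_dict(c: CalibrationSetup) -> dict:
    return {
        "name": c.name,
        "profiles": [_profile_to_dict(p) for p in c.profiles],
        "analyzed": None
        if c.analyzed is None
        else [_analyzed_to_dict(a) for a in c.analyzed],
        "known_ng": c.known_ng,
        "ocf": _ocf_to_dict(c.ocf),
    }


def _calset_from_dict(d: dict) -> CalibrationSetup:
    return CalibrationSetup(
        name=d["name"],
        profiles=[_profile_from_dict(p) for p in d["profiles"]],
        analyzed=None
        if d["analyzed"] is None
        else [_analyzed_from_dict(a) for a in d["analyzed"]],
        known_ng=d["known_ng"],
        ocf=_ocf_from_dict(d["ocf"]),
    )


def project_to_dict(project: Project) -> dict:
    return {
        "schema_version": project.schema_version,
        "params": _params_to_dict(project.params),
        "runs": [_run_to_dict(r) for r in project.runs],
        "calibrations": [_calset_to_dict(c) for c in project.calibrations],
        "amplicons": {
            name: {
                "name": a.name,
                "size": a.size,
                "primers": list(a.primers) if a.primers else None,
                "notes": a.notes,
            }
            for name, a in project.amplicons.items()
        },
    }


def project_from_dict(data: dict) -> Project:
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ProjectSchemaError(
            f"project schema version {version!r} is not supported "
            f"(this build reads version {SCHEMA_VERSION}); migrate explicitly"
        )
    return Project(
        runs=[_run_from_dict(r) for r in data["runs"]],
        calibrations=[_calset_from_dict(c) for c in data["calibrations"]],
        amplicons={
            name: Amplicon(
                name=d["name"],
                size=d["size"],
                primers=tuple(d["primers"]) if d["primers"] else None,
                notes=d["notes"],
            )
            for name, d in data["amplicons"].items()
        },
        params=_params_from_dict(data["params"]),
        schema_version=version,
    )


def save_project(project: Project, path: str | Path) -> Path:
    """Write the project to a versioned JSON file (full precision)."""
    path = Path(path)
    path.write_text(json.dumps(project_to_dict(project), indent=1))
    return path


def load_project(path: str | Path) -> Project:
    """Read a project file; schema-version mismatches fail explicitly."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ProjectLoadError(f"cannot read {path}: {exc}") from exc
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ProjectLoadError(
            f"{path} is not valid project JSON (line {exc.lineno}, "
            f"column {exc.colno}: {exc.msg})"
        ) from exc
    if not isinstance(data, dict):
        raise ProjectLoadError(f"{path} does not contain a project object")
    try:
        return project_from_dict(data)
    except ProjectSchemaError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ProjectLoadError(f"{path} is structurally invalid: {exc!r}") from exc
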