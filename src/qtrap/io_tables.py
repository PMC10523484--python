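"""Tabular I/O for pulling-work traces, alchemical ΔU samples and distance series.

Three table families flow through the pipeline:

* work traces from steered (pulled) simulations — time, moving-restraint
  center, measured coordinate, accumulated external work;
* per-window alchemical energy-difference samples (ΔU = U(λ_to) − U(λ_from),
  sampled in either endpoint ensemble, one sign convention throughout);
* donor–acceptor distance time series.

Each family has a plain TSV representation (tab- or whitespace-separated,
``#``-prefixed comments, one header line) and, where an MD engine emits its
own log dialect, a whitelist line-grammar reader (``smd_log``, ``fepout``).
The grammars are documented in ``docs/formats.md``.  Internal units are
fixed: ns, Å, kcal/mol.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import TableParseError, TableSchemaError, QtrapError

__all__ = [
    "WorkTrace",
    "FepWindowSamples",
    "DistanceSeries",
    "read_work_traces",
    "write_work_traces",
    "read_fep_samples",
    "write_fep_samples",
    "read_distance_series",
    "write_distance_series",
    "write_results",
    "read_results",
]

_FS_PER_NS = 1.0e6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class WorkTrace:
    """One pulling trajectory.

    Attributes
    ----------
    traj_id : str
        Label of the trajectory.
    time : ndarray
        Simulation time in ns, strictly increasing.
    restraint_center : ndarray
        Position of the moving harmonic restraint center, Å, monotone
        non-decreasing within a pull.
    coordinate : ndarray
        The measured pulling coordinate, Å.
    accumulated_work : ndarray
        External work accumulated by the restraint, kcal/mol; starts at 0.
    """

    traj_id: str
    time: np.ndarray
    restraint_center: np.ndarray
    coordinate: np.ndarray
    accumulated_work: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.restraint_center = np.asarray(self.restraint_center, dtype=float)
        self.coordinate = np.asarray(self.coordinate, dtype=float)
        self.accumulated_work = np.asarray(self.accumulated_work, dtype=float)
        n = len(self.time)
        for name in ("restraint_center", "coordinate", "accumulated_work"):
            if len(getattr(self, name)) != n:
                raise TableSchemaError(
                    f"trace {self.traj_id!r}: column {name} has length "
                    f"{len(getattr(self, name))}, expected {n}"
                )
        if n < 2:
            raise TableSchemaError(f"trace {self.traj_id!r}: needs ≥ 2 rows, got {n}")
        if not np.all(np.diff(self.time) > 0):
            i = int(np.argmin(np.diff(self.time) > 0))
            raise TableParseError(
                f"trace {self.traj_id!r}: time not strictly increasing at row {i + 1}"
            )
        if not np.all(np.diff(self.restraint_center) >= 0):
            i = int(np.argmin(np.diff(self.restraint_center) >= 0))
            raise TableParseError(
                f"trace {self.traj_id!r}: restraint center decreases at row {i + 1}"
            )
        if abs(self.accumulated_work[0]) > 1e-9:
            raise TableSchemaError(
                f"trace {self.traj_id!r}: accumulated work starts at "
                f"{self.accumulated_work[0]!r}, expected 0"
            )

    def __len__(self) -> int:
        return len(self.time)

    def __eq__(self, other) -> bool:
        if not isinstance(other, WorkTrace):
            return NotImplemented
        return self.traj_id == other.traj_id and all(
            np.allclose(getattr(self, f), getattr(other, f), rtol=1e-9, atol=1e-12)
            for f in ("time", "restraint_center", "coordinate", "accumulated_work")
        )


@dataclass
class FepWindowSamples:
    """Energy-difference samples for one alchemical window λ_from → λ_to.

    ``forward_du`` holds ΔU = U(λ_to) − U(λ_from) sampled in the λ_from
    ensemble; ``reverse_du`` holds the same quantity sampled in the λ_to
    ensemble (one sign convention for both directions).  ``reverse_du`` may
    be empty when only a one-sided (exponential-averaging) estimate is
    possible.
    """

    lambda_from: float
    lambda_to: float
    forward_du: np.ndarray
    reverse_du: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.forward_du = np.asarray(self.forward_du, dtype=float)
        self.reverse_du = np.asarray(self.reverse_du, dtype=float)
        for lam in (self.lambda_from, self.lambda_to):
            if not 0.0 <= lam <= 1.0:
                raise QtrapError(f"λ value {lam} outside [0, 1]")
        if self.lambda_from == self.lambda_to:
            raise QtrapError(f"degenerate window: λ_from == λ_to == {self.lambda_from}")
        if self.forward_du.size == 0:
            raise TableSchemaError(
                f"window ({self.lambda_from}, {self.lambda_to}): forward_du is empty"
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, FepWindowSamples):
            return NotImplemented
        return (
            self.lambda_from == other.lambda_from
            and self.lambda_to == other.lambda_to
            and self.forward_du.shape == other.forward_du.shape
            and self.reverse_du.shape == other.reverse_du.shape
            and np.allclose(self.forward_du, other.forward_du, rtol=1e-9, atol=1e-12)
            and np.allclose(self.reverse_du, other.reverse_du, rtol=1e-9, atol=1e-12)
        )


@dataclass
class DistanceSeries:
    """A donor–acceptor distance time series (e.g. CoQ10 headgroup ↔ N2)."""

    time: np.ndarray
    distance: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        if len(self.time) != len(self.distance):
            raise TableSchemaError(
                f"series {self.label!r}: time ({len(self.time)}) and distance "
                f"({len(self.distance)}) lengths differ"
            )
        if np.any(self.distance <= 0):
            i = int(np.argmax(self.distance <= 0))
            raise TableParseError(
                f"series {self.label!r}: non-positive distance "
                f"{self.distance[i]} at row {i + 1}"
            )

    def __len__(self) -> int:
        return len(self.distance)


# ---------------------------------------------------------------------------
# low-level line handling
# ---------------------------------------------------------------------------

def _data_lines(path) -> list[tuple[int, list[str]]]:
    """All non-comment, non-blank lines of *path* as (1-based lineno, fields)."""
    out = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            out.append((lineno, line.split()))
    return out


def _floats(fields: Sequence[str], lineno: int, path) -> list[float]:
    try:
        return [float(f) for f in fields]
    except ValueError as exc:
        raise TableParseError(f"{path}: non-numeric field ({exc})", line=lineno) from None


def _require_columns(header: Sequence[str], required: Sequence[str], path):
    missing = [c for c in required if c not in header]
    if missing:
        raise TableSchemaError(f"{path}: missing column(s) {missing}; header is {list(header)}")


# ---------------------------------------------------------------------------
# work traces
# ---------------------------------------------------------------------------

_WORK_COLUMNS = ["traj_id", "time_ns", "restraint_center_A", "coordinate_A",
                 "work_kcal_per_mol"]


def read_work_traces(path, dialect: str = "tsv") -> list[WorkTrace]:
    """Read pulling work traces from *path*.

    Parameters
    ----------
    path : path-like
    dialect : {"tsv", "smd_log"}
        ``tsv`` — header + one row per sample with a ``traj_id`` column;
        ``smd_log`` — engine-style log: ``#SMDSTART <id>`` opens a block,
        ``SMD <time_fs> <center> <coord> <work>`` records samples, anything
        else is ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_work_tsv(path)
    if dialect == "smd_log":
        return _read_work_smdlog(path)
    raise ValueError(f"unsupported work-trace dialect {dialect!r}")


def _read_work_tsv(path) -> list[WorkTrace]:
    lines = _data_lines(path)
    if not lines:
        raise TableSchemaError(f"{path}: empty table")
    header_lineno, header = lines[0]
    _require_columns(header, _WORK_COLUMNS, path)
    idx = {c: header.index(c) for c in _WORK_COLUMNS}
    blocks: dict[str, list[tuple[int, list[float]]]] = {}
    order: list[str] = []
    for lineno, fields in lines[1:]:
        if len(fields) != len(header):
            raise TableParseError(
                f"{path}: row has {len(fields)} fields, header has {len(header)}",
                line=lineno,
            )
        tid = fields[idx["traj_id"]]
        vals = _floats(
            [fields[idx[c]] for c in _WORK_COLUMNS[1:]], lineno, path
        )
        if tid not in blocks:
            blocks[tid] = []
            order.append(tid)
        blocks[tid].append((lineno, vals))
    return [_trace_from_rows(tid, blocks[tid], path) for tid in order]


def _read_work_smdlog(path) -> list[WorkTrace]:
    blocks: dict[str, list[tuple[int, list[float]]]] = {}
    order: list[str] = []
    current: str | None = None
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            fields = raw.split()
            if not fields:
                continue
            if fields[0] == "#SMDSTART":
                if len(fields) < 2:
                    raise TableParseError(f"{path}: #SMDSTART without id", line=lineno)
                current = fields[1]
                if current not in blocks:
                    blocks[current] = []
                    order.append(current)
            elif fields[0] == "SMD":
                if current is None:
                    raise TableParseError(
                        f"{path}: SMD record before any #SMDSTART", line=lineno
                    )
                if len(fields) != 5:
                    raise TableParseError(
                        f"{path}: SMD record needs 4 numeric fields", line=lineno
                    )
                t_fs, c, x, w = _floats(fields[1:], lineno, path)
                blocks[current].append((lineno, [t_fs / _FS_PER_NS, c, x, w]))
            # any other line is engine noise: ignored by design
    if not order:
        raise TableSchemaError(f"{path}: no SMD records found")
    return [_trace_from_rows(tid, blocks[tid], path) for tid in order]


def _trace_from_rows(tid, rows, path) -> WorkTrace:
    arr = np.array([vals for _, vals in rows], dtype=float)
    dt = np.diff(arr[:, 0])
    if np.any(dt <= 0):
        bad = rows[int(np.argmax(dt <= 0)) + 1][0]
        raise TableParseError(
            f"{path}: trace {tid!r} time not strictly increasing", line=bad
        )
    dc = np.diff(arr[:, 1])
    if np.any(dc < 0):
        bad = rows[int(np.argmax(dc < 0)) + 1][0]
        raise TableParseError(
            f"{path}: trace {tid!r} restraint center decreases", line=bad
        )
    return WorkTrace(tid, arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


def write_work_traces(traces: Iterable[WorkTrace], path, dialect: str = "tsv") -> None:
    """Write traces in the ``tsv`` or ``smd_log`` dialect (10 sig. digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("# qtrap work traces\n")
            fh.write("\t".join(_WORK_COLUMNS) + "\n")
            for tr in traces:
                for row in zip(tr.time, tr.restraint_center, tr.coordinate,
                               tr.accumulated_work):
                    fh.write(tr.traj_id + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        elif dialect == "smd_log":
            for tr in traces:
                fh.write(f"#SMDSTART {tr.traj_id}\n")
                for row in zip(tr.time, tr.restraint_center, tr.coordinate,
                               tr.accumulated_work):
                    fh.write(
                        f"SMD {row[0] * _FS_PER_NS:.10g} {row[1]:.10g} "
                        f"{row[2]:.10g} {row[3]:.10g}\n"
                    )
        else:
            raise ValueError(f"unsupported work-trace dialect {dialect!r}")


# ---------------------------------------------------------------------------
# alchemical ΔU samples
# ---------------------------------------------------------------------------

_FEP_COLUMNS = ["lambda_from", "lambda_to", "direction", "du_kcal_per_mol"]


def read_fep_samples(path, dialect: str = "tsv") -> list[FepWindowSamples]:
    """Read per-window alchemical ΔU samples.

    Parameters
    ----------
    path : path-like
    dialect : {"tsv", "fepout"}
        ``tsv`` — header + one row per sample, ``direction`` ∈ {f, r};
        ``fepout`` — engine-style log: ``#FEPWINDOW <λ_from> <λ_to> <f|r>``
        opens a block, ``FepEnergy: <step> <ΔU>`` records samples, all other
        lines are ignored.

    Windows are returned sorted by ``lambda_from``; forward and reverse runs
    are matched by their (λ_from, λ_to) pair.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        pairs = _read_fep_tsv(path)
    elif dialect == "fepout":
        pairs = _read_fep_fepout(path)
    else:
        raise ValueError(f"unsupported FEP dialect {dialect!r}")

    windows = []
    for (lf, lt), (fwd, rev) in sorted(pairs.items()):
        if not fwd:
            raise TableSchemaError(
                f"{path}: window ({lf}, {lt}) has no forward samples"
            )
        windows.append(
            FepWindowSamples(lf, lt, np.array(fwd, float), np.array(rev, float))
        )
    return windows


def _check_lambda(lam: float, path, lineno: int) -> float:
    if not 0.0 <= lam <= 1.0:
        raise TableParseError(f"{path}: λ value {lam} outside [0, 1]", line=lineno)
    return lam


def _read_fep_tsv(path):
    lines = _data_lines(path)
    if not lines:
        raise TableSchemaError(f"{path}: empty table")
    _, header = lines[0]
    _require_columns(header, _FEP_COLUMNS, path)
    idx = {c: header.index(c) for c in _FEP_COLUMNS}
    pairs: dict[tuple[float, float], tuple[list, list]] = {}
    for lineno, fields in lines[1:]:
        lf = _check_lambda(float(fields[idx["lambda_from"]]), path, lineno)
        lt = _check_lambda(float(fields[idx["lambda_to"]]), path, lineno)
        direction = fields[idx["direction"]]
        if direction not in ("f", "r"):
            raise TableParseError(
                f"{path}: direction must be 'f' or 'r', got {direction!r}",
                line=lineno,
            )
        du = _floats([fields[idx["du_kcal_per_mol"]]], lineno, path)[0]
        fwd, rev = pairs.setdefault((lf, lt), ([], []))
        (fwd if direction == "f" else rev).append(du)
    return pairs


def _read_fep_fepout(path):
    pairs: dict[tuple[float, float], tuple[list, list]] = {}
    current: tuple[tuple[float, float], str] | None = None
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            fields = raw.split()
            if not fields:
                continue
            if fields[0] == "#FEPWINDOW":
                if len(fields) != 4 or fields[3] not in ("f", "r"):
                    raise TableParseError(
                        f"{path}: #FEPWINDOW needs 'λ_from λ_to f|r'", line=lineno
                    )
                lf = _check_lambda(float(fields[1]), path, lineno)
                lt = _check_lambda(float(fields[2]), path, lineno)
                current = ((lf, lt), fields[3])
                pairs.setdefault((lf, lt), ([], []))
            elif fields[0] == "FepEnergy:":
                if current is None:
                    raise TableParseError(
                        f"{path}: FepEnergy: record before any #FEPWINDOW", line=lineno
                    )
                if len(fields) != 3:
                    raise TableParseError(
                        f"{path}: FepEnergy: record needs step and ΔU", line=lineno
                    )
                du = _floats(fields[2:], lineno, path)[0]
                key, direction = current
                pairs[key][0 if direction == "f" else 1].append(du)
            # whitelist parsing: every other line is ignored
    if not pairs:
        raise TableSchemaError(f"{path}: no FEP windows found")
    return pairs


def write_fep_samples(windows: Iterable[FepWindowSamples], path,
                      dialect: str = "tsv") -> None:
    """Write window samples in the ``tsv`` or ``fepout`` dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("# qtrap alchemical ΔU samples\n")
            fh.write("\t".join(_FEP_COLUMNS) + "\n")
            for w in windows:
                for du in w.forward_du:
                    fh.write(f"{w.lambda_from:.10g}\t{w.lambda_to:.10g}\tf\t{du:.10g}\n")
                for du in w.reverse_du:
                    fh.write(f"{w.lambda_from:.10g}\t{w.lambda_to:.10g}\tr\t{du:.10g}\n")
        elif dialect == "fepout":
            for w in windows:
                fh.write(f"#FEPWINDOW {w.lambda_from:.10g} {w.lambda_to:.10g} f\n")
                for step, du in enumerate(w.forward_du):
                    fh.write(f"FepEnergy: {step} {du:.10g}\n")
                if w.reverse_du.size:
                    fh.write(f"#FEPWINDOW {w.lambda_from:.10g} {w.lambda_to:.10g} r\n")
                    for step, du in enumerate(w.reverse_du):
                        fh.write(f"FepEnergy: {step} {du:.10g}\n")
        else:
            raise ValueError(f"unsupported FEP dialect {dialect!r}")


# ---------------------------------------------------------------------------
# distance series
# ---------------------------------------------------------------------------

def read_distance_series(path, label: str = "") -> DistanceSeries:
    """Read a two-column (time_ns, distance_A) table and attach *label*."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = _data_lines(path)
    if not lines:
        raise TableSchemaError(f"{path}: empty table")
    start = 0
    try:  # optional header line
        float(lines[0][1][0])
    except ValueError:
        start = 1
    times, dists = [], []
    for lineno, fields in lines[start:]:
        if len(fields) < 2:
            raise TableParseError(f"{path}: need two columns", line=lineno)
        t, d = _floats(fields[:2], lineno, path)
        if d <= 0:
            raise TableParseError(f"{path}: non-positive distance {d}", line=lineno)
        times.append(t)
        dists.append(d)
    return DistanceSeries(np.array(times), np.array(dists), label=label)


def write_distance_series(series: DistanceSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# qtrap distance series label={series.label}\n")
        fh.write("time_ns\tdistance_A\n")
        for t, d in zip(series.time, series.distance):
            fh.write(f"{t:.10g}\t{d:.10g}\n")


# ---------------------------------------------------------------------------
# generic result records
# ---------------------------------------------------------------------------

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_to_plain(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _flatten(d: dict, prefix: str = "") -> dict:
    flat = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            flat.update(_flatten(v, key + "."))
        elif isinstance(v, list):
            for i, item in enumerate(v):
                if isinstance(item, dict):
                    flat.update(_flatten(item, f"{key}[{i}]."))
                else:
                    flat[f"{key}[{i}]"] = item
        else:
            flat[key] = v
    return flat


def write_results(record, path, format: str = "json") -> None:
    """Serialize an analysis result (dataclass or mapping) losslessly.

    JSON keys are sorted so identical records serialize byte-identically;
    TSV numeric fields are formatted to 10 significant digits.
    """
    plain = _to_plain(record)
    if not isinstance(plain, dict):
        raise TypeError("record must be a dataclass instance or a mapping")
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(plain, fh, sort_keys=True, indent=2)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            for k, v in sorted(_flatten(plain).items()):
                if isinstance(v, float):
                    fh.write(f"{k}\t{v:.10g}\n")
                else:
                    fh.write(f"{k}\t{v}\n")
    else:
        raise ValueError(f"unsupported result format {format!r}")


def read_results(path, format: str = "json") -> dict:
    """Read back a record written by :func:`write_results`."""
    path = Path(path)
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    if format == "tsv":
        out: dict = {}
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                k, _, v = line.rstrip("\n").partition("\t")
                try:
                    out[k] = float(v)
                except ValueError:
                    out[k] = v
        return out
    raise ValueError(f"unsupported result format {format!r}")
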