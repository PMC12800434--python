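"""Readers/writers for the interchange formats the pipeline touches.

TRC (marker trajectories) and MOT-style tab-delimited tables (force and
stage outputs) are the lingua franca of the motion-capture ecosystem; both
are written in a documented dialect that round-trips losslessly at 8
significant digits.  Trial bundles additionally carry a JSON sidecar with
metadata and (for synthetic trials) the generating ground truth.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .data import ForceRecord, GroundTruth, MarkerSet, TrialBundle, TrialMeta
from .errors import FileFormatError

__all__ = ["write_trc", "read_trc", "write_mot", "read_mot",
           "write_trial", "read_trial"]

_FMT = "%.8g"


def _fmt(x: float) -> str:
    return _FMT % x


# --------------------------------------------------------------------------
# TRC
# --------------------------------------------------------------------------
def write_trc(path, markers: MarkerSet, units: str = "m") -> None:
    """Write a MarkerSet as TRC (tab-delimited, X/Y/Z triplets per marker).

    The header declares DataRate/NumFrames/NumMarkers and the length units
    (``m`` or ``mm``); +Y is up, +X anterior.
    """
    path = Path(path)
    names = markers.names
    scale = 1000.0 if units == "mm" else 1.0
    n = markers.time.shape[0]
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{_fmt(markers.rate)}\t{_fmt(markers.rate)}\t{n}\t{len(names)}\t{units}\t"
        f"{_fmt(markers.rate)}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t",
        "\t\t" + "\t".join(f"X{i}\tY{i}\tZ{i}" for i in range(1, len(names) + 1)),
    ]
    for i in range(n):
        row = [str(i + 1), _fmt(markers.time[i])]
        for nm in names:
            row.extend(_fmt(v * scale) for v in markers.data[nm][i])
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_trc(path) -> MarkerSet:
    """Read a TRC file; mm units are converted to metres."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise FileFormatError(f"{path}: truncated TRC header")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    hdr = dict(zip(header_keys, header_vals))
    try:
        rate = float(hdr["DataRate"])
        n_frames = int(hdr["NumFrames"])
        n_markers = int(hdr["NumMarkers"])
        units = hdr["Units"]
    except (KeyError, ValueError) as e:
        raise FileFormatError(f"{path}: bad TRC header ({e})") from e
    names = [s for s in lines[3].split("\t")[2:] if s]
    if len(names) != n_markers:
        raise FileFormatError(
            f"{path}: header NumMarkers={n_markers} but {len(names)} labels")
    scale = 1e-3 if units.lower() == "mm" else 1.0
    time = np.empty(n_frames)
    data = {nm: np.empty((n_frames, 3)) for nm in names}
    body = [ln for ln in lines[5:] if ln.strip()]
    if len(body) != n_frames:
        raise FileFormatError(
            f"{path}: header NumFrames={n_frames} but {len(body)} data rows "
            f"(line {6 + len(body)})")
    for i, ln in enumerate(body):
        parts = ln.split("\t")
        if len(parts) != 2 + 3 * n_markers:
            raise FileFormatError(f"{path}: line {6 + i}: expected "
                                  f"{2 + 3 * n_markers} columns, got {len(parts)}")
        time[i] = float(parts[1])
        vals = np.array(parts[2:], dtype=float) * scale
        for k, nm in enumerate(names):
            data[nm][i] = vals[3 * k:3 * k + 3]
    return MarkerSet(time, rate, data)


# --------------------------------------------------------------------------
# MOT-style tables
# --------------------------------------------------------------------------
def write_mot(path, time: np.ndarray, columns: dict[str, np.ndarray],
              name: str = "liftsim") -> None:
    """Write a labeled time-series table (MOT-style text header + data)."""
    path = Path(path)
    cols = {k: np.asarray(v, dtype=float) for k, v in columns.items()}
    n = len(time)
    for k, v in cols.items():
        if v.shape != (n,):
            raise FileFormatError(f"column {k!r}: shape {v.shape} != ({n},)")
    lines = [name, "version=1", f"nRows={n}", f"nColumns={1 + len(cols)}",
             "inDegrees=no", "endheader",
             "time\t" + "\t".join(cols)]
    for i in range(n):
        lines.append("\t".join([_fmt(time[i])] + [_fmt(v[i]) for v in cols.values()]))
    path.write_text("\n".join(lines) + "\n")


def read_mot(path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Read a MOT-style table; returns (time, {column: values})."""
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        end = next(i for i, ln in enumerate(lines) if ln.strip() == "endheader")
    except StopIteration:
        raise FileFormatError(f"{path}: missing 'endheader'") from None
    header = lines[end + 1].split("\t")
    if header[0] != "time":
        raise FileFormatError(f"{path}: first column must be 'time', got {header[0]!r}")
    body = [ln for ln in lines[end + 2:] if ln.strip()]
    arr = np.empty((len(body), len(header)))
    for i, ln in enumerate(body):
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise FileFormatError(
                f"{path}: line {end + 3 + i}: expected {len(header)} columns, "
                f"got {len(parts)} (missing column?)")
        arr[i] = [float(p) for p in parts]
    declared = [ln for ln in lines[:end] if ln.startswith("nColumns=")]
    if declared and int(declared[0].split("=")[1]) != len(header):
        raise FileFormatError(f"{path}: header/body column count mismatch")
    return arr[:, 0], {h: arr[:, k + 1] for k, h in enumerate(header[1:])}


# --------------------------------------------------------------------------
# trial bundles
# --------------------------------------------------------------------------
def _force_columns(rec: ForceRecord) -> dict[str, np.ndarray]:
    out = {}
    for prefix, arr in (("force", rec.force), ("moment", rec.moment), ("cop", rec.cop)):
        for k, ax in enumerate("xyz"):
            out[f"{rec.name}_{prefix}_{ax}"] = arr[:, k]
    return out


def _record_from_columns(name: str, time: np.ndarray, cols: dict,
                         rate: float, frame: str) -> ForceRecord:
    def grab(prefix):
        try:
            return np.stack([cols[f"{name}_{prefix}_{ax}"] for ax in "xyz"], axis=1)
        except KeyError as e:
            raise FileFormatError(f"missing column {e.args[0]!r}") from None
    return ForceRecord(name, time, rate, grab("force"), grab("moment"),
                       grab("cop"), frame)


def write_trial(outdir, trial: TrialBundle) -> dict[str, Path]:
    """Write a trial bundle: markers.trc, forces.mot, meta.json.

    Synthetic ground truth, when present, goes into ground_truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"markers": outdir / "markers.trc", "forces": outdir / "forces.mot",
             "meta": outdir / "meta.json"}
    write_trc(paths["markers"], trial.markers)
    cols = _force_columns(trial.grf)
    for rec in trial.ehfm.values():
        cols.update(_force_columns(rec))
    write_mot(paths["forces"], trial.grf.time, cols, name="forces")
    from dataclasses import asdict
    meta = {
        "body_mass": trial.meta.body_mass, "stature": trial.meta.stature,
        "marker_rate": trial.meta.marker_rate, "force_rate": trial.meta.force_rate,
        "box": _jsonable(asdict(trial.meta.box)),
        "task": _jsonable(asdict(trial.meta.task)),
        "records": {rec.name: {"frame": rec.frame} for rec in
                    [trial.grf, *trial.ehfm.values()]},
        "axes": "+x anterior, +y up, +z left; SI units",
    }
    paths["meta"].write_text(json.dumps(meta, indent=1, sort_keys=True))
    if trial.ground_truth is not None:
        gt = trial.ground_truth
        payload = {k: _jsonable(getattr(gt, k)) for k in
                   ("grip_times", "phase_kinds", "ehf_global", "ehm_global",
                    "handle_pos", "q_marker", "q_force", "box_pose",
                    "grip_fraction")}
        p = outdir / "ground_truth.json"
        p.write_text(json.dumps(payload))
        paths["ground_truth"] = p
    return paths


def read_trial(outdir) -> TrialBundle:
    """Read a trial bundle written by :func:`write_trial`."""
    from .synthetic import BoxSpec, TaskConfig

    outdir = Path(outdir)
    meta_d = json.loads((outdir / "meta.json").read_text())
    markers = read_trc(outdir / "markers.trc")
    t, cols = read_mot(outdir / "forces.mot")
    rate = meta_d["force_rate"]
    records = {}
    for name, info in meta_d["records"].items():
        records[name] = _record_from_columns(name, t, cols, rate, info["frame"])
    box = BoxSpec(**{k: (v if k != "corner_marker_offsets"
                         else {kk: np.array(vv) for kk, vv in v.items()})
                     for k, v in meta_d["box"].items()})
    task = TaskConfig(**meta_d["task"])
    meta = TrialMeta(meta_d["body_mass"], meta_d["stature"], box, task,
                     meta_d["marker_rate"], meta_d["force_rate"])
    gt = None
    gt_path = outdir / "ground_truth.json"
    if gt_path.exists():
        d = json.loads(gt_path.read_text())
        gt = GroundTruth(**{k: (np.array(v) if k != "phase_kinds" else v)
                            for k, v in d.items()})
    ehfm = {name.replace("handle_", ""): rec for name, rec in records.items()
            if name.startswith("handle_")}
    return TrialBundle(markers=markers, grf=records["ground"], ehfm=ehfm,
                       meta=meta, ground_truth=gt)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
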