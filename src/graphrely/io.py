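"""Reading and writing recordings, connectivity stacks and outcome tables.

Recordings travel either as European Data Format (EDF) files or as a
delimited sample matrix with a JSON metadata sidecar.  The EDF path uses a
deliberately small built-in reader/writer for the classic 16-bit EDF
layout (one-second data records); values survive a round trip within the
format's quantization step.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import BandDefinition, ConnectivityStack, InputError, Recording
from .synthetic import TwoWayTable

__all__ = [
    "write_recording_matrix",
    "write_recording_edf",
    "read_recording",
    "write_stack",
    "read_stack",
    "write_two_way_table",
    "read_two_way_table",
]

logger = logging.getLogger("graphrely")


# ---------------------------------------------------------------------------
# matrix + sidecar


def write_recording_matrix(rec: Recording, path: str | Path) -> Path:
    """Write samples as TSV (rows = time, columns = channels) + JSON sidecar."""
    path = Path(path)
    if path.suffix != ".tsv":
        path = path.with_suffix(".tsv")
    header = "\t".join(rec.channel_labels)
    np.savetxt(path, rec.samples.T, fmt="%.17g", delimiter="\t",
               header=header, comments="")
    sidecar = {
        "channel_labels": list(rec.channel_labels),
        "sampling_rate": rec.sampling_rate,
        "participant_id": rec.participant_id,
        "session_id": rec.session_id,
        "condition": rec.condition,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def _read_matrix(path: Path) -> Recording:
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise InputError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for key in ("channel_labels", "sampling_rate"):
        if key not in meta:
            raise InputError(f"sidecar {sidecar_path} lacks required field {key!r}")
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    data = np.atleast_2d(data)
    return Recording(
        samples=data.T,
        sampling_rate=float(meta["sampling_rate"]),
        channel_labels=list(meta["channel_labels"]),
        participant_id=meta.get("participant_id", "P01"),
        session_id=meta.get("session_id", "S1"),
        condition=meta.get("condition", "PRE"),
    )


# ---------------------------------------------------------------------------
# EDF (classic, 16-bit, one-second records)


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _phys_field(v: float) -> str:
    """Shortest representation of a physical min/max that fits 8 chars.

    The writer must scale against the value the 8-character header field
    can actually carry, so the representable value is what gets used.
    """
    for prec in range(7, 0, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{v:.0e}"[:8]


def write_recording_edf(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as a classic EDF file.

    One-second data records are used, so the sampling rate must be a whole
    number; trailing samples beyond the last full second are dropped (with
    a log warning).  Amplitudes are scaled per channel onto the 16-bit
    digital range; the physical dimension is recorded as uV.
    """
    path = Path(path).with_suffix(".edf")
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise InputError("EDF writer needs an integer sampling rate")
    spr = int(round(fs))
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise InputError("recording shorter than one EDF record (1 s)")
    if n_records * spr < rec.n_samples:
        logger.warning(
            "EDF write drops %d trailing samples (partial record)",
            rec.n_samples - n_records * spr,
        )
    data = rec.samples[:, : n_records * spr]
    ns = rec.n_channels
    dmin, dmax = -32768, 32767
    pmins = data.min(axis=1)
    pmaxs = data.max(axis=1)
    flat = pmaxs == pmins
    pmaxs = np.where(flat, pmins + 1.0, pmaxs)
    # widen to the 8-char header representation so the stored extrema
    # still bracket the data and scaling round-trips exactly
    pmin_strs, pmax_strs = [], []
    for c in range(ns):
        lo_s, hi_s = _phys_field(pmins[c]), _phys_field(pmaxs[c])
        step = max(abs(pmins[c]) * 1e-7, 1e-9)
        while float(lo_s) > pmins[c]:
            lo_s = _phys_field(pmins[c] - step)
            step *= 10.0
        step = max(abs(pmaxs[c]) * 1e-7, 1e-9)
        while float(hi_s) < pmaxs[c]:
            hi_s = _phys_field(pmaxs[c] + step)
            step *= 10.0
        pmin_strs.append(lo_s)
        pmax_strs.append(hi_s)
    pmins = np.array([float(s) for s in pmin_strs])
    pmaxs = np.array([float(s) for s in pmax_strs])

    head = b"".join([
        _pad("0", 8),
        _pad(rec.participant_id, 80),
        _pad(f"{rec.session_id} {rec.condition}", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])

    def sig_field(values: list[str], width: int) -> bytes:
        return b"".join(_pad(v, width) for v in values)

    head += sig_field(list(rec.channel_labels), 16)
    head += sig_field([""] * ns, 80)
    head += sig_field(["uV"] * ns, 8)
    head += sig_field(pmin_strs, 8)
    head += sig_field(pmax_strs, 8)
    head += sig_field([str(dmin)] * ns, 8)
    head += sig_field([str(dmax)] * ns, 8)
    head += sig_field([""] * ns, 80)
    head += sig_field([str(spr)] * ns, 8)
    head += sig_field([""] * ns, 32)

    scale = (dmax - dmin) / (pmaxs - pmins)
    digital = np.round((data - pmins[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(head)
        for r in range(n_records):
            chunk = digital[:, r * spr : (r + 1) * spr]
            fh.write(chunk.tobytes())  # channel-major within record
    return path


def _read_edf(path: Path) -> Recording:
    raw = path.read_bytes()
    if len(raw) < 256:
        raise InputError(f"{path} is not an EDF file (truncated header)")

    def txt(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii", errors="replace").strip()

    patient = txt(8, 80)
    recording_field = txt(88, 80)
    n_records = int(txt(236, 8))
    record_dur = float(txt(244, 8))
    ns = int(txt(252, 4))
    off = 256

    def sig(width: int) -> list[str]:
        nonlocal off
        vals = [raw[off + s * width : off + (s + 1) * width]
                .decode("ascii", errors="replace").strip() for s in range(ns)]
        off += ns * width
        return vals

    labels = sig(16)
    sig(80)  # transducer
    sig(8)  # dimension
    pmins = np.array([float(v) for v in sig(8)])
    pmaxs = np.array([float(v) for v in sig(8)])
    dmins = np.array([float(v) for v in sig(8)])
    dmaxs = np.array([float(v) for v in sig(8)])
    sig(80)  # prefiltering
    sprs = [int(v) for v in sig(8)]
    sig(32)  # reserved
    if len(set(sprs)) != 1:
        raise InputError("mixed per-signal sampling rates are not supported")
    spr = sprs[0]
    if record_dur <= 0:
        raise InputError("missing/invalid record duration: sampling rate unknown")
    fs = spr / record_dur

    payload = np.frombuffer(raw, dtype="<i2", offset=256 * (ns + 1))
    expected = n_records * ns * spr
    if payload.size < expected:
        raise InputError("EDF payload shorter than header promises")
    payload = payload[:expected].reshape(n_records, ns, spr)
    digital = np.concatenate([payload[r] for r in range(n_records)], axis=1).astype(float)
    scale = (pmaxs - pmins) / (dmaxs - dmins)
    physical = (digital - dmins[:, None]) * scale[:, None] + pmins[:, None]

    parts = recording_field.split()
    session_id = parts[0] if parts else "S1"
    condition = parts[1] if len(parts) > 1 else "PRE"
    return Recording(
        samples=physical, sampling_rate=fs, channel_labels=labels,
        participant_id=patient or "P01", session_id=session_id,
        condition=condition,
    )


def read_recording(path: str | Path) -> Recording:
    """Read a Recording from EDF or from a delimited matrix + JSON sidecar."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such recording file: {path}")
    if path.suffix.lower() == ".edf":
        return _read_edf(path)
    return _read_matrix(path)


# ---------------------------------------------------------------------------
# connectivity stacks


def stack_filename(stack: ConnectivityStack) -> str:
    return (f"{stack.participant_id}_{stack.session_id}_{stack.condition}"
            f"__{stack.estimator}__{stack.band.name}.tsv")


def write_stack(stack: ConnectivityStack, out_dir: str | Path) -> Path:
    """Write a stack as long-format TSV (epoch, row, col, value; upper triangle)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = stack.matrices.shape[1]
    iu = np.triu_indices(n, k=1)
    rows = []
    for e in range(stack.n_epochs):
        vals = stack.matrices[e][iu]
        rows.append(np.column_stack([
            np.full(iu[0].size, e), iu[0], iu[1], vals,
        ]))
    table = np.concatenate(rows)
    path = out_dir / stack_filename(stack)
    np.savetxt(path, table, fmt=["%d", "%d", "%d", "%.10g"], delimiter="\t",
               header="epoch\trow\tcol\tvalue", comments="")
    meta = {
        "estimator": stack.estimator,
        "band": {"name": stack.band.name, "low": stack.band.low,
                 "high": stack.band.high},
        "channel_labels": list(stack.channel_labels),
        "n_epochs": int(stack.n_epochs),
        "participant_id": stack.participant_id,
        "session_id": stack.session_id,
        "condition": stack.condition,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path) -> ConnectivityStack:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    table = np.loadtxt(path, delimiter="\t", skiprows=1)
    table = np.atleast_2d(table)
    n_ch = len(meta["channel_labels"])
    n_ep = int(meta["n_epochs"])
    mats = np.zeros((n_ep, n_ch, n_ch))
    e = table[:, 0].astype(int)
    i = table[:, 1].astype(int)
    j = table[:, 2].astype(int)
    mats[e, i, j] = table[:, 3]
    mats[e, j, i] = table[:, 3]
    band = BandDefinition(**meta["band"])
    return ConnectivityStack(
        matrices=mats, estimator=meta["estimator"], band=band,
        channel_labels=list(meta["channel_labels"]),
        participant_id=meta["participant_id"],
        session_id=meta["session_id"], condition=meta["condition"],
    )


# ---------------------------------------------------------------------------
# two-way tables


def write_two_way_table(table: TwoWayTable, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(table.values, index=table.subject_ids,
                      columns=table.session_ids)
    df.index.name = "participant"
    df.to_csv(path)
    return path


def read_two_way_table(path: str | Path, outcome_label: str = "outcome",
                       condition: str = "") -> TwoWayTable:
    df = pd.read_csv(path, index_col=0)
    return TwoWayTable(
        values=df.to_numpy(dtype=float), outcome_label=outcome_label,
        condition=condition, subject_ids=[str(s) for s in df.index],
        session_ids=[str(c) for c in df.columns],
    )
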