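"""Tab-delimited dataset and parameter file formats.

Dataset table: one row per patient with columns ``patient_id``,
``sample_type`` (paired / pt_only / mt_only), ``obs_order`` (pt_first /
mt_first / unknown / na), ``seeding_evidence`` (0 / 1 / unknown / na), then
two columns ``P.<event>`` and ``M.<event>`` per event holding 0, 1, or an
empty cell when the corresponding tumor is unobserved.  The event column
order defines the event index order everywhere in the package.

Parameter file: tab-delimited matrix, first two rows the log observation
effects (``Obs.PT``, ``Obs.MT``), remaining rows the log interaction matrix
theta; columns (and theta rows) are labeled by the event names plus
``Seeding``.  Values are written with 12 significant digits so round trips
preserve parameters to beyond 10 digits.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    SEEDING_NAME,
    EventSystem,
    PairMHNError,
    ParameterSet,
    Sample,
)

_META_COLUMNS = ["patient_id", "sample_type", "obs_order", "seeding_evidence"]
_EVIDENCE_TO_FILE = {"absent": "0", "present": "1", "unknown": "unknown", None: "na"}
_FILE_TO_EVIDENCE = {v: k for k, v in _EVIDENCE_TO_FILE.items()}


def _row_error(pid: str, column: str, message: str) -> PairMHNError:
    return PairMHNError(f"patient {pid!r}, column {column!r}: {message}")


def write_dataset(samples: Sequence[Sample], sys: EventSystem, path) -> None:
    rows = []
    for s in samples:
        row = {
            "patient_id": s.patient_id,
            "sample_type": s.sample_type,
            "obs_order": s.obs_order if s.sample_type == "paired" else "na",
            "seeding_evidence": _EVIDENCE_TO_FILE[s.seeding_evidence],
        }
        for i, name in enumerate(sys.event_names):
            row[f"P.{name}"] = str(int(s.pt[i])) if s.pt is not None else ""
            row[f"M.{name}"] = str(int(s.mt[i])) if s.mt is not None else ""
        rows.append(row)
    columns = _META_COLUMNS + [
        f"{side}.{name}" for name in sys.event_names for side in ("P", "M")
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def _parse_genotype(pid: str, cells: list[str], names: Sequence[str], side: str):
    present = [c != "" for c in cells]
    if not any(present):
        return None
    if not all(present):
        col = f"{side}.{names[present.index(False)]}"
        raise _row_error(pid, col, "genotype must be fully observed or fully blank")
    geno = np.zeros(len(cells), dtype=np.int8)
    for i, c in enumerate(cells):
        if c not in ("0", "1"):
            raise _row_error(pid, f"{side}.{names[i]}", f"expected 0/1/empty, got {c!r}")
        geno[i] = int(c)
    return geno


def read_dataset(path) -> tuple[list[Sample], EventSystem]:
    """Parse a dataset table; the header defines the event system."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise PairMHNError(f"{path}: empty file") from None
        if header[: len(_META_COLUMNS)] != _META_COLUMNS:
            raise PairMHNError(
                f"{path}: header must start with {_META_COLUMNS}, got {header[:4]}"
            )
        event_cols = header[len(_META_COLUMNS) :]
        if len(event_cols) % 2:
            raise PairMHNError(f"{path}: event columns must come in P./M. pairs")
        names = []
        for k in range(0, len(event_cols), 2):
            pcol, mcol = event_cols[k], event_cols[k + 1]
            if not pcol.startswith("P.") or not mcol.startswith("M."):
                raise PairMHNError(f"{path}: expected P.<event>, M.<event>; got {pcol}, {mcol}")
            if pcol[2:] != mcol[2:]:
                raise PairMHNError(f"{path}: mismatched event pair {pcol} / {mcol}")
            names.append(pcol[2:])
        sys = EventSystem(len(names), tuple(names))
        samples = []
        seen = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or all(c == "" for c in row):
                continue
            if len(row) != len(header):
                raise PairMHNError(f"{path}:{lineno}: wrong number of columns")
            pid, stype, order, evidence = row[:4]
            if pid in seen:
                raise _row_error(pid, "patient_id", "duplicate patient id")
            seen.add(pid)
            if stype not in ("paired", "pt_only", "mt_only"):
                raise _row_error(pid, "sample_type", f"unknown sample_type {stype!r}")
            pt = _parse_genotype(pid, row[4::2], names, "P")
            mt = _parse_genotype(pid, row[5::2], names, "M")
            if stype == "paired" and (pt is None or mt is None):
                raise _row_error(pid, "sample_type", "paired row with a blank genotype")
            if stype == "pt_only" and mt is not None:
                raise _row_error(pid, "sample_type", "pt_only row carries M. values")
            if stype == "mt_only" and pt is not None:
                raise _row_error(pid, "sample_type", "mt_only row carries P. values")
            if stype == "paired":
                if order not in ("pt_first", "mt_first", "unknown"):
                    raise _row_error(pid, "obs_order", f"invalid obs_order {order!r}")
            elif order != "na":
                raise _row_error(pid, "obs_order", "obs_order must be 'na' for unpaired rows")
            if evidence not in _FILE_TO_EVIDENCE:
                raise _row_error(pid, "seeding_evidence", f"invalid value {evidence!r}")
            ev = _FILE_TO_EVIDENCE[evidence]
            if stype == "mt_only" and ev == "absent":
                raise _row_error(
                    pid, "seeding_evidence", "an observed metastasis implies seeding"
                )
            if stype != "pt_only" and ev in ("absent",):
                raise _row_error(pid, "seeding_evidence", "only pt_only rows carry evidence 0")
            try:
                samples.append(
                    Sample(
                        pid,
                        pt=pt,
                        mt=mt,
                        seeding_evidence=ev if stype == "pt_only" else (
                            "present" if stype == "mt_only" and ev == "present" else None
                        ),
                        obs_order=order if stype == "paired" else None,
                    )
                )
            except PairMHNError as exc:
                raise _row_error(pid, "sample_type", str(exc)) from exc
    return samples, sys


_OBS_ROWS = ["Obs.PT", "Obs.MT"]


def write_params(params: ParameterSet, sys: EventSystem, path) -> None:
    if params.n != sys.n:
        raise PairMHNError("parameter dimension does not match the event system")
    cols = list(sys.all_names)
    data = np.vstack([params.omega_pt, params.omega_mt, params.theta])
    df = pd.DataFrame(data, index=_OBS_ROWS + cols, columns=cols)
    df.to_csv(path, sep="\t", float_format="%.12g", index_label="row")


def read_params(path, sys: EventSystem | None = None) -> tuple[ParameterSet, EventSystem]:
    """Read a parameter matrix; validates names against ``sys`` when given."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = [str(c) for c in df.columns]
    if not cols or cols[-1] != SEEDING_NAME:
        raise PairMHNError(f"{path}: last column must be {SEEDING_NAME!r}")
    names = tuple(cols[:-1])
    file_sys = EventSystem(len(names), names)
    if sys is not None and tuple(sys.event_names) != names:
        raise PairMHNError(
            f"{path}: event names {list(names)} do not match the dataset's "
            f"{list(sys.event_names)}"
        )
    expected_rows = _OBS_ROWS + cols
    if [str(r) for r in df.index] != expected_rows:
        raise PairMHNError(f"{path}: rows must be {expected_rows}")
    values = df.to_numpy(dtype=float)
    params = ParameterSet(values[2:], values[0], values[1])
    return params, file_sys


def write_event_log(histories, sys: EventSystem, path) -> None:
    """Tidy event-log table (patient_id, event_label, time) for simulated runs."""
    rows = []
    for i, hist in enumerate(histories):
        pid = f"P{i + 1:05d}"
        for label, t in hist.event_log(sys):
            rows.append((pid, label, t))
    pd.DataFrame(rows, columns=["patient_id", "event_label", "time"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def write_trajectories(trees, path) -> None:
    """Tidy trajectory table (patient_id, branch, rank, event_label, ...)."""
    rows = []
    for tree in trees:
        segments = (
            ("shared", tree.shared_prefix),
            ("pt", tree.pt_branch),
            ("mt", tree.mt_branch),
        )
        for branch, labels in segments:
            L = sum(len(seg) for _, seg in segments)
            offset = 0 if branch == "shared" else len(tree.shared_prefix)
            for k, lab in enumerate(labels):
                rank = offset + k + 1
                denom = max(L - 1, 1)
                rows.append(
                    (
                        tree.patient_id,
                        branch,
                        rank,
                        lab,
                        (rank - 1) / denom if L > 1 else 0.0,
                        tree.log_probability,
                    )
                )
    pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "branch",
            "rank",
            "event_label",
            "relative_position",
            "log_probability",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
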