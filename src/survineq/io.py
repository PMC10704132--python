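"""Readers and writers for the pipeline's file formats.

Comma-separated text for curve coordinates (``time,survival``), risk tables
(``time,n_risk``) and pseudo-IPD (``time,event,weight,study,arm``); JSON for
fitted models, selection results and analysis bundles; YAML or JSON for
configuration. Writing then reading reproduces values to full precision,
and all JSON is emitted with sorted keys so repeated runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import InputError
from .pseudo_ipd import DigitizedCurve, PseudoIPD
from .survival_models import FittedModel

__all__ = [
    "read_curve",
    "write_curve",
    "read_ipd",
    "write_ipd",
    "read_model",
    "write_model",
    "read_config",
    "write_json",
    "file_sha256",
]


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _read_two_column(path, columns: tuple[str, str]) -> np.ndarray:
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise InputError(f"{path}: cannot parse as CSV ({exc})") from exc
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}; found {list(frame.columns)}")
    frame = frame[list(columns)]
    for col in columns:
        bad = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()]
        if len(bad):
            raise InputError(
                f"{path}: non-numeric value in column {col!r} at data row {int(bad[0])}"
            )
    return frame.astype(float).to_numpy()


def read_curve(coords_path, risk_path=None, meta=None) -> DigitizedCurve:
    """Read a digitized curve from coordinate and risk-table CSV files.

    ``meta`` may be a dict or the path of a YAML/JSON sidecar with keys
    ``study``, ``arm``, ``outcome`` and ``total_events``.
    """
    coords = _read_two_column(coords_path, ("time", "survival"))
    if risk_path is None:
        raise InputError(
            f"{coords_path}: no risk table given; pass --allow-no-risk/"
            "a single-entry table with the initial sample size to proceed"
        )
    risk = _read_two_column(risk_path, ("time", "n_risk"))
    if isinstance(meta, (str, Path)):
        meta = read_config(meta)
    meta = dict(meta or {})
    bad = coords[:, 1]
    out_of_range = np.where((bad < 0) | (bad > 1))[0]
    if len(out_of_range):
        row = int(out_of_range[0])
        raise InputError(
            f"{coords_path}: survival {bad[row]} out of [0, 1] at data row {row}"
        )
    try:
        return DigitizedCurve(
            coordinates=coords,
            risk_table=risk,
            total_events=None if meta.get("total_events") is None
            else int(meta["total_events"]),
            study_label=str(meta.get("study", "study")),
            arm_label=str(meta.get("arm", "intervention")),
            outcome_label=str(meta.get("outcome", "OS")),
        )
    except InputError as exc:
        raise InputError(f"{coords_path}: {exc}") from exc


def write_curve(curve: DigitizedCurve, coords_path, risk_path, meta_path=None):
    pd.DataFrame(curve.coordinates, columns=["time", "survival"]).to_csv(
        coords_path, index=False, float_format="%.17g"
    )
    pd.DataFrame(curve.risk_table, columns=["time", "n_risk"]).to_csv(
        risk_path, index=False, float_format="%.17g"
    )
    if meta_path is not None:
        meta = {
            "study": curve.study_label,
            "arm": curve.arm_label,
            "outcome": curve.outcome_label,
            "total_events": curve.total_events,
        }
        Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_ipd(path) -> PseudoIPD:
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise InputError(f"{path}: cannot parse as CSV ({exc})") from exc
    required = ["time", "event", "weight", "study", "arm"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    try:
        return PseudoIPD(
            time=frame["time"].to_numpy(dtype=float),
            event=frame["event"].to_numpy(dtype=int),
            weight=frame["weight"].to_numpy(dtype=float),
            study=frame["study"].astype(str).to_numpy(dtype=object),
            arm=frame["arm"].astype(str).to_numpy(dtype=object),
        )
    except (ValueError, InputError) as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_ipd(ipd: PseudoIPD, path):
    ipd.to_frame().to_csv(path, index=False, float_format="%.17g")


def write_model(model: FittedModel, path, provenance: dict | None = None):
    payload = model.to_dict()
    if provenance:
        payload["provenance"] = provenance
    write_json(payload, path)


def read_model(path) -> FittedModel:
    payload = json.loads(Path(path).read_text())
    return FittedModel.from_dict(payload)


def read_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    loaded = yaml.safe_load(text)
    if not isinstance(loaded, dict):
        raise InputError(f"{path}: configuration must be a mapping")
    return loaded


def write_json(payload, path):
    """Deterministic JSON: sorted keys, no timestamps, trailing newline."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     allow_nan=True) + "\n")
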