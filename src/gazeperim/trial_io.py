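"""On-disk formats: trial files, cohort manifests, field maps, normative
distributions and model checkpoints.

Trial files are tab-separated UTF-8 with a single '#'-prefixed JSON header
line holding all metadata (schema version, configs, seeds), followed by a
column-name row and one row per sample.  Maps are a row-major matrix text
file (NaN = unsampled) with a JSON sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import SchemaError
from .mapping import GridSpec, VisualFieldMap
from .observer import ObserverParams, TrackingRecord
from .scotoma import ScotomaSpec
from .tfce import NormativeDistribution, TfceParams
from .trajectory import TrialConfig

SCHEMA_VERSION = "1"
TRIAL_COLUMNS = ["t_s", "s_x_deg", "s_y_deg", "p_x_deg", "p_y_deg", "occluded"]


def _jsonable(obj) -> object:
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_trial(path: str | Path, record: TrackingRecord) -> None:
    path = Path(path)
    header = {
        "schema_version": SCHEMA_VERSION,
        "participant_id": record.participant_id,
        "trial_id": record.trial_id,
        "config": _jsonable(record.config),
        "scotoma": _jsonable(record.scotoma),
    }
    n = len(record)
    t = np.arange(n) * record.config.dt
    with path.open("w", encoding="utf-8") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        fh.write("\t".join(TRIAL_COLUMNS) + "\n")
        for i in range(n):
            fh.write(f"{t[i]:.6f}\t{record.s_x[i]:.6f}\t{record.s_y[i]:.6f}"
                     f"\t{record.p_x[i]:.6f}\t{record.p_y[i]:.6f}"
                     f"\t{int(record.occluded[i])}\n")


def read_trial(path: str | Path) -> TrackingRecord:
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise SchemaError(f"{path}: line 1: missing '#' JSON header")
    try:
        header = json.loads(first[1:])
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: line 1: invalid JSON header: {exc}") from exc
    version = header.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"{path}: unsupported schema version {version!r}, "
                          f"expected {SCHEMA_VERSION!r}")
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: line 2: missing columns {missing}")
    cfg = TrialConfig(**header["config"])
    if len(df) != cfg.n_samples:
        raise SchemaError(f"{path}: {len(df)} rows but config implies "
                          f"{cfg.n_samples} samples")
    for col in TRIAL_COLUMNS[:-1]:
        bad = np.flatnonzero(~np.isfinite(df[col].to_numpy()))
        if bad.size:
            raise SchemaError(f"{path}: line {int(bad[0]) + 3}: non-finite "
                              f"value in column {col}")
    return TrackingRecord(
        config=cfg,
        scotoma=ScotomaSpec(**header["scotoma"]),
        s_x=df["s_x_deg"].to_numpy(),
        s_y=df["s_y_deg"].to_numpy(),
        p_x=df["p_x_deg"].to_numpy(),
        p_y=df["p_y_deg"].to_numpy(),
        occluded=df["occluded"].to_numpy(dtype=np.uint8),
        participant_id=header["participant_id"],
        trial_id=header["trial_id"],
    )


def write_manifest(path: str | Path, manifest: Mapping) -> None:
    Path(path).write_text(json.dumps(_jsonable(manifest), indent=2) + "\n",
                          encoding="utf-8")


def read_manifest(path: str | Path) -> Dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))


def write_map(path: str | Path, vfmap: VisualFieldMap) -> None:
    """Matrix text (probabilities, NaN = unsampled) + .json sidecar + counts."""
    path = Path(path)
    np.savetxt(path, vfmap.grid, fmt="%.6f")
    np.savetxt(path.with_suffix(path.suffix + ".counts"), vfmap.counts, fmt="%d")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "grid_spec": _jsonable(vfmap.grid_spec),
        "dropped": vfmap.dropped,
        "counts_file": path.name + ".counts",
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n", encoding="utf-8")


def read_map(path: str | Path) -> VisualFieldMap:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json")
                         .read_text(encoding="utf-8"))
    if sidecar.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"{path}: unsupported map schema version")
    spec = GridSpec(**sidecar["grid_spec"])
    grid = np.loadtxt(path)
    counts = np.loadtxt(path.parent / sidecar["counts_file"]).astype(int)
    flagged = np.where(np.isnan(grid), 0.0, grid) * counts
    return VisualFieldMap(grid_spec=spec, flagged=np.rint(flagged).astype(int),
                          counts=counts, dropped=int(sidecar.get("dropped", 0)))


def write_norms(path: str | Path, norms: NormativeDistribution,
                params: TfceParams | None = None) -> None:
    """Flat values file + JSON metadata."""
    path = Path(path)
    np.savetxt(path, norms.values, fmt="%.9g")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "n_values": int(norms.values.size),
        "source_ids": list(norms.source_ids),
        "tfce_params": _jsonable(params) if params else None,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, indent=2) + "\n", encoding="utf-8")


def read_norms(path: str | Path) -> NormativeDistribution:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json")
                      .read_text(encoding="utf-8"))
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"{path}: unsupported norms schema version")
    return NormativeDistribution(values=np.loadtxt(path),
                                 source_ids=meta.get("source_ids", []))


def save_model(stem: str | Path, model) -> None:
    """Checkpoint as <stem>.npz (weights) + <stem>.json (config, version)."""
    stem = str(stem)
    np.savez(f"{stem}.npz", **model.params)
    Path(f"{stem}.json").write_text(
        json.dumps({"schema_version": SCHEMA_VERSION,
                    "config": _jsonable(model.cfg)}, indent=2) + "\n",
        encoding="utf-8")


def load_model(stem: str | Path):
    from .rnn.model import RnnConfig, TwoStreamRnn

    stem = str(stem)
    meta = json.loads(Path(f"{stem}.json").read_text(encoding="utf-8"))
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"{stem}: unsupported model schema version")
    model = TwoStreamRnn(RnnConfig(**meta["config"]))
    with np.load(f"{stem}.npz") as archive:
        params = model.params
        for k in params:
            params[k][...] = archive[k]
    return model
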