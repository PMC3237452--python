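"""File formats: long-format panel CSV, model serialization, study config.

The interchange format for perfusion data is a tidy CSV with one row per
measurement: ``batch_id, label, metabolite, time_hr, concentration``.  Long
format makes partial (online) batches natural and survives appends; the
pivot to the 3-D array happens here, with validation of duplicates, unknown
metabolites and ragged batches.  Empty concentration cells are allowed and
come back as NaN (to be repaired by ``preprocess.replace_invalid``).

Models serialize to a single versioned JSON file (text-based, portable).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import LABELS, BatchDataset
from .exceptions import ValidationError
from .mpca import MPCAModel
from .panel import MetabolitePanel, default_panel
from .plsda import MPLSDAModel
from .preprocess import ScalerParams

CSV_COLUMNS = ["batch_id", "label", "metabolite", "time_hr", "concentration"]
MODEL_FORMAT = "ischemix-model"
MODEL_VERSION = 1


# ---------------------------------------------------------------------------
# panel CSV
# ---------------------------------------------------------------------------

def write_panel_csv(dataset: BatchDataset, path: str | Path) -> None:
    """Write a dataset as long-format CSV (lossless round-trip)."""
    rows = []
    for i, bid in enumerate(dataset.batch_ids):
        for j, met in enumerate(dataset.panel.names):
            for k in range(dataset.n_time):
                rows.append((bid, dataset.labels[i], met, k + 1, dataset.values[i, j, k]))
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_panel_csv(path: str | Path, panel: MetabolitePanel | None = None) -> BatchDataset:
    """Read a long-format panel CSV into a :class:`BatchDataset`.

    Validates: required columns, labels, duplicate (batch, metabolite, hour)
    keys, metabolite names outside the panel, and ragged batches (a batch
    missing a (metabolite, hour) row entirely).  Empty concentrations are
    kept as NaN.
    """
    panel = panel or default_panel()
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"CSV is missing required columns: {missing}")
    df["batch_id"] = df["batch_id"].astype(str)

    unknown = sorted(set(df["metabolite"]) - set(panel.names))
    if unknown:
        raise ValidationError(f"unknown metabolite names not in panel: {unknown}")
    bad_labels = sorted(set(df["label"].astype(str)) - set(LABELS))
    if bad_labels:
        raise ValidationError(f"labels {bad_labels} not in {LABELS}")

    dup = df.duplicated(subset=["batch_id", "metabolite", "time_hr"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["batch_id", "metabolite", "time_hr"]].drop_duplicates()
        raise ValidationError(
            "duplicate (batch_id, metabolite, time_hr) rows: "
            + "; ".join(f"({r.batch_id}, {r.metabolite}, {r.time_hr})"
                        for r in keys.itertuples()))

    hours = sorted(df["time_hr"].unique())
    K = int(max(hours))
    if hours != list(range(1, K + 1)):
        raise ValidationError(f"time_hr values {hours} are not 1..{K}")

    batch_ids = list(dict.fromkeys(df["batch_id"]))  # first-appearance order
    labels = []
    for bid in batch_ids:
        labs = set(df.loc[df["batch_id"] == bid, "label"].astype(str))
        if len(labs) != 1:
            raise ValidationError(f"batch {bid!r} has inconsistent labels {sorted(labs)}")
        labels.append(labs.pop())

    expected = len(panel) * K
    pivot = df.set_index(["batch_id", "metabolite", "time_hr"])["concentration"]
    values = np.full((len(batch_ids), len(panel), K), np.nan)
    for i, bid in enumerate(batch_ids):
        sub = pivot.loc[bid]
        if len(sub) != expected:
            present = set(sub.index)
            gaps = [(m, k) for m in panel.names for k in range(1, K + 1)
                    if (m, k) not in present]
            raise ValidationError(
                f"batch {bid!r} is ragged: missing rows for {gaps[:5]}"
                + ("..." if len(gaps) > 5 else ""))
        for (met, k), v in sub.items():
            values[i, panel.index_of(met), int(k) - 1] = v
    return BatchDataset(panel, values, batch_ids, labels)


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def _encode(obj):
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, dict):
        return {str(k): _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _decode(obj):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=obj.get("dtype", "float64"))
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def save_model(model: MPCAModel | MPLSDAModel, path: str | Path) -> None:
    """Serialize a fitted model to versioned JSON."""
    if isinstance(model, MPCAModel):
        kind = "mpca"
    elif isinstance(model, MPLSDAModel):
        kind = "mplsda"
    else:
        raise ValidationError(f"cannot serialize object of type {type(model).__name__}")
    payload = {"format": MODEL_FORMAT, "version": MODEL_VERSION, "type": kind,
               "panel": list(model.panel.names),
               "fields": {}}
    for f in dataclasses.fields(model):
        if f.name == "panel":
            continue
        value = getattr(model, f.name)
        if isinstance(value, ScalerParams):
            value = {"means": value.means, "sds": value.sds, "degenerate": value.degenerate}
        payload["fields"][f.name] = _encode(value)
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> MPCAModel | MPLSDAModel:
    """Load a model serialized by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != MODEL_FORMAT:
        raise ValidationError(f"{path} is not an ischemix model file")
    if payload.get("version") != MODEL_VERSION:
        raise ValidationError(f"unsupported model file version {payload.get('version')}")
    panel = MetabolitePanel(tuple(payload["panel"]))
    fields = {k: _decode(v) for k, v in payload["fields"].items()}
    sc = fields["scaler"]
    fields["scaler"] = ScalerParams(sc["means"], sc["sds"], sc["degenerate"].astype(bool))
    cls = MPCAModel if payload["type"] == "mpca" else MPLSDAModel
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name == "panel":
            continue
        v = fields[f.name]
        if f.name in ("alphas", "class_order"):
            v = tuple(v)
        if f.name == "limits_offline":
            v = {float(a): float(np.asarray(l)) for a, l in v.items()}
        if f.name == "limits_online":
            v = {m: {float(a): np.asarray(l) for a, l in d.items()} for m, d in v.items()}
        kwargs[f.name] = v
    return cls(panel=panel, **kwargs)


# ---------------------------------------------------------------------------
# study configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Constants of a monitoring/classification study."""

    K: int = 6
    R_mpca: int = 3
    R_mpls: int = 3
    alphas: tuple[float, float] = (0.05, 0.01)
    index_log_base: float = 10.0
    index_threshold: float = 1.35
    online_spe_mode: str = "instantaneous"
    online_mpls_strategy: str = "truncated_refit"
    cv_runs: int = 100
    cv_per_class: int = 5
    cv_cap: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.index_threshold <= 0 or self.index_log_base <= 1:
            raise ValidationError("index threshold must be > 0 and log base > 1")
        for a in self.alphas:
            if not 0 < a < 1:
                raise ValidationError("alpha levels must lie in (0, 1)")


def save_config(config: StudyConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["alphas"] = list(d["alphas"])
    Path(path).write_text(yaml.safe_dump(d))


def load_config(path: str | Path) -> StudyConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    if "alphas" in d:
        d["alphas"] = tuple(d["alphas"])
    return StudyConfig(**d)
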