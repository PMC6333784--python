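"""CSV dialects, configuration schema and report writing.

Two table formats travel through the pipeline:

* **Kinetic traces** -- canonical *long* CSV with columns ``condition``,
  ``replicate``, ``time_h``, ``signal`` and per-condition metadata columns
  ``m_total_uM``, ``seed_fraction``, ``modulator_ratio`` (constant within a
  condition).  A *wide* plate-reader-export dialect is auto-detected: one
  ``time_h`` column plus one column per well named ``condition|replicate``,
  with the metadata supplied in ``#meta`` comment rows.
* **Morphometry** -- one measurement per row: ``condition``, ``modality``,
  ``dimension``, ``value``, ``unit`` (whitelist ``nm``/``um``) and an
  optional ``fibril_id`` (periodic TEM widths enter as two rows per fibril).

Run configuration is a single YAML file validated against a strict pydantic
schema (unknown keys rejected); reports are JSON with sorted keys and floats
rounded to six significant digits, so diffs are stable.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .fitting import ConditionData, ConditionSpec
from .kinetics import KineticTrace, ReactionConditions
from .morphometry import DIMENSIONS, MODALITIES, FibrilMeasurementSet

META_COLUMNS = ("m_total_uM", "seed_fraction", "modulator_ratio")

#: canonical units per dimension: lengths in um, cross-sections in nm
CANONICAL_UNITS = {"length": "um", "height": "nm", "width": "nm"}
_UNIT_FACTORS = {("um", "nm"): 1e3, ("nm", "um"): 1e-3}


class TraceValidationError(ValueError):
    """A trace CSV violates the dialect contract (message names file/rows)."""


@dataclass
class TraceTable:
    """Long-format kinetic traces plus per-condition metadata.

    ``frame`` has columns condition, replicate, time_h, signal;
    ``metadata`` is indexed by condition with columns ``META_COLUMNS``.
    """

    frame: pd.DataFrame
    metadata: pd.DataFrame

    def conditions(self) -> list[str]:
        return list(self.metadata.index)

    def to_condition_data(
        self, seed_length: float = 500.0, normalized: bool | None = None
    ) -> list[ConditionData]:
        """Convert to the fitting layer's containers.

        ``normalized=None`` flags traces whose values already lie in the
        noise-tolerant mass-fraction band [-0.1, 1.1] as normalized.
        """
        out = []
        for label, meta in self.metadata.iterrows():
            spec = ConditionSpec(
                label=str(label),
                conditions=ReactionConditions(
                    m_total=float(meta["m_total_uM"]),
                    seed_fraction=float(meta["seed_fraction"]),
                    seed_length=seed_length,
                ),
                modulator_ratio=float(meta["modulator_ratio"]),
            )
            traces = []
            sub = self.frame[self.frame["condition"] == label]
            for rep, grp in sub.groupby("replicate", sort=True):
                v = grp["signal"].to_numpy()
                if normalized is None:
                    is_norm = bool(v.min() >= -0.1 and v.max() <= 1.1)
                else:
                    is_norm = normalized
                traces.append(
                    KineticTrace(
                        grp["time_h"].to_numpy(),
                        v,
                        label=f"{label}/{rep}",
                        normalized=is_norm,
                    )
                )
            out.append(ConditionData(spec=spec, traces=traces))
        return out


def condition_data_to_table(data: list[ConditionData]) -> TraceTable:
    """Inverse of :meth:`TraceTable.to_condition_data` for generated bundles."""
    rows = []
    meta = {}
    for cd in data:
        meta[cd.spec.label] = {
            "m_total_uM": cd.spec.conditions.m_total,
            "seed_fraction": cd.spec.conditions.seed_fraction,
            "modulator_ratio": cd.spec.modulator_ratio,
        }
        for i, tr in enumerate(cd.traces):
            for t, v in zip(tr.times, tr.values):
                rows.append(
                    {
                        "condition": cd.spec.label,
                        "replicate": i,
                        "time_h": t,
                        "signal": v,
                    }
                )
    frame = pd.DataFrame(rows)
    metadata = pd.DataFrame.from_dict(meta, orient="index")
    metadata.index.name = "condition"
    return TraceTable(frame=frame, metadata=metadata)


# --------------------------------------------------------------------------
# trace CSV
# --------------------------------------------------------------------------


def _validate_table(table: TraceTable, origin: str) -> None:
    f = table.frame
    dup = f.duplicated(subset=["condition", "replicate", "time_h"])
    if dup.any():
        rows = (f.index[dup] + 2).tolist()[:5]
        raise TraceValidationError(
            f"{origin}: duplicate (condition, replicate, time_h) keys at data row(s) {rows}"
        )
    for (cond, rep), grp in f.groupby(["condition", "replicate"], sort=False):
        t = grp["time_h"].to_numpy()
        bad = np.nonzero(np.diff(t) <= 0)[0]
        if len(bad):
            row = int(grp.index[bad[0] + 1]) + 2
            raise TraceValidationError(
                f"{origin}: non-monotone time for condition {cond!r} replicate {rep} "
                f"at data row {row}"
            )
    missing = set(f["condition"].unique()) - set(table.metadata.index)
    if missing:
        raise TraceValidationError(f"{origin}: missing metadata for condition(s) {sorted(missing)}")


def _parse_meta_comments(lines: list[str], origin: str) -> pd.DataFrame:
    records = {}
    for ln in lines:
        body = ln.lstrip("#").strip()
        if not body.lower().startswith("meta,"):
            continue
        parts = [p.strip() for p in body.split(",")]
        if len(parts) != 2 + len(META_COLUMNS):
            raise TraceValidationError(
                f"{origin}: malformed #meta line (expected 'meta,<condition>,"
                + ",".join(META_COLUMNS)
                + f"'): {ln.strip()!r}"
            )
        try:
            records[parts[1]] = {
                c: float(v) for c, v in zip(META_COLUMNS, parts[2:])
            }
        except ValueError as exc:
            raise TraceValidationError(f"{origin}: non-numeric #meta value in {ln.strip()!r}") from exc
    md = pd.DataFrame.from_dict(records, orient="index")
    md.index.name = "condition"
    return md


def read_trace_csv(path: str | Path) -> TraceTable:
    """Read a trace CSV, auto-detecting the long or wide dialect."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    comments = [ln for ln in lines if ln.startswith("#")]
    body = "\n".join(ln for ln in lines if not ln.startswith("#"))
    try:
        raw = pd.read_csv(_io.StringIO(body))
    except Exception as exc:
        raise TraceValidationError(f"{path}: not parseable as CSV: {exc}") from exc
    cols = set(raw.columns)
    if "time_h" not in cols:
        raise TraceValidationError(f"{path}: required column 'time_h' is missing")
    if {"condition", "replicate", "signal"} <= cols:
        frame = raw[["condition", "replicate", "time_h", "signal"]].copy()
        frame["condition"] = frame["condition"].astype(str)
        if set(META_COLUMNS) <= cols:
            meta = raw[["condition", *META_COLUMNS]].drop_duplicates()
            counts = meta.groupby("condition").size()
            bad = counts[counts > 1]
            if len(bad):
                raise TraceValidationError(
                    f"{path}: inconsistent metadata within condition(s) {list(bad.index)}"
                )
            metadata = meta.set_index("condition")[list(META_COLUMNS)]
        else:
            metadata = _parse_meta_comments(comments, str(path))
    else:
        # wide dialect: every non-time column is one well, "condition|replicate"
        metadata = _parse_meta_comments(comments, str(path))
        rows = []
        for col in raw.columns:
            if col == "time_h":
                continue
            if "|" in col:
                cond, rep = col.rsplit("|", 1)
            else:
                cond, rep = col, "0"
            sub = raw[["time_h", col]].dropna()
            for t, v in zip(sub["time_h"], sub[col]):
                rows.append(
                    {"condition": cond, "replicate": rep, "time_h": t, "signal": v}
                )
        frame = pd.DataFrame(rows)
    table = TraceTable(frame=frame.reset_index(drop=True), metadata=metadata)
    _validate_table(table, str(path))
    return table


def write_trace_csv(table: TraceTable, path: str | Path) -> None:
    """Write the canonical long dialect (metadata inlined per row)."""
    path = Path(path)
    merged = table.frame.merge(
        table.metadata, left_on="condition", right_index=True, how="left"
    )
    merged = merged[["condition", "replicate", "time_h", "signal", *META_COLUMNS]]
    merged.to_csv(path, index=False)


# --------------------------------------------------------------------------
# morphometry CSV
# --------------------------------------------------------------------------


def read_morphometry_csv(path: str | Path) -> list[FibrilMeasurementSet]:
    """Read per-fibril measurements; returns one set per
    (condition, modality, dimension), values converted to canonical units."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"condition", "modality", "dimension", "value", "unit"}
    if not required <= set(df.columns):
        raise TraceValidationError(
            f"{path}: morphometry CSV needs columns {sorted(required)}"
        )
    bad_units = set(df["unit"].unique()) - {"nm", "um"}
    if bad_units:
        raise TraceValidationError(f"{path}: units outside whitelist {{nm, um}}: {sorted(bad_units)}")
    bad_dim = set(df["dimension"].unique()) - set(DIMENSIONS)
    if bad_dim:
        raise TraceValidationError(f"{path}: unknown dimension(s) {sorted(bad_dim)}")
    bad_mod = set(df["modality"].unique()) - set(MODALITIES)
    if bad_mod:
        raise TraceValidationError(f"{path}: unknown modality(ies) {sorted(bad_mod)}")
    nonpos = df.index[df["value"] <= 0]
    if len(nonpos):
        raise TraceValidationError(
            f"{path}: non-positive measurement at data row(s) {(nonpos + 2).tolist()[:5]}"
        )
    out = []
    for (cond, mod, dim), grp in df.groupby(["condition", "modality", "dimension"], sort=True):
        target = CANONICAL_UNITS[dim]
        values = np.array(
            [
                v * _UNIT_FACTORS.get((u, target), 1.0)
                for v, u in zip(grp["value"], grp["unit"])
            ]
        )
        out.append(
            FibrilMeasurementSet(
                values=values, dimension=dim, modality=mod, condition=str(cond)
            )
        )
    return out


def write_morphometry_csv(msets: list[FibrilMeasurementSet], path: str | Path) -> None:
    rows = []
    for ms in msets:
        unit = CANONICAL_UNITS[ms.dimension]
        for v in ms.values:
            rows.append(
                {
                    "condition": ms.condition,
                    "modality": ms.modality,
                    "dimension": ms.dimension,
                    "value": v,
                    "unit": unit,
                }
            )
    pd.DataFrame(rows).to_csv(Path(path), index=False)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------


class ModelOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_c: float = 2.0
    n_2: float = 2.0
    saturating_secondary: bool = False

    @field_validator("saturating_secondary")
    @classmethod
    def _no_saturation(cls, v: bool) -> bool:
        if v:
            raise ValueError("saturating secondary nucleation is not implemented")
        return v


class NormalizationOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    baseline_window: float = Field(0.1, gt=0, lt=0.5)
    plateau_window: float = Field(0.1, gt=0, lt=0.5)


class FitOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hypothesis: str = "secondary_product"
    n_basinhop: int = Field(50, ge=1)
    seed: int = 0
    bounds_decades: float = Field(3.0, gt=0)
    step_size: float = Field(0.7, gt=0)


class GeneratorOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    noise_sd: float = Field(0.02, ge=0)
    replicates: int = Field(3, ge=1)
    n_points: int = Field(150, ge=8)
    n_fibrils: int = Field(100, ge=2)
    seed: int = 20


class RunConfig(BaseModel):
    """Top-level configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    model: ModelOptions = Field(default_factory=ModelOptions)
    normalization: NormalizationOptions = Field(default_factory=NormalizationOptions)
    fit: FitOptions = Field(default_factory=FitOptions)
    generator: GeneratorOptions = Field(default_factory=GeneratorOptions)
    log_level: str = "INFO"


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(payload)


def config_hash(cfg: RunConfig) -> str:
    """Stable sha256 of the canonical JSON form (for reproducibility logs)."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _canonicalize(obj):
    if isinstance(obj, dict):
        return {str(k): _canonicalize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonicalize(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        return _round_sig(float(obj))
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_canonicalize(v) for v in obj.tolist()]
    return obj


def write_report(payload: dict, path: str | Path) -> None:
    """Diff-stable JSON report: sorted keys, 6-significant-digit floats."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_canonicalize(payload), fh, sort_keys=True, indent=2)
        fh.write("\n")
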