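"""Sensor CSV dialect, run configuration, and result writers.

The sensor stream is a plain comma-separated file with a mandatory header::

    timestamp,do_mg_l,temp_c,chl_ug_l,secchi_m,ph_surface,ph_bottom,source_id

``timestamp`` is ISO 8601 local pond time (day/night rules are clock-time
rules, so no offset arithmetic is applied).  ``do_mg_l`` and ``temp_c`` are
mandatory per record; the remaining channels are optional and left empty
when absent.  Timestamps must be strictly increasing per ``source_id``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SensorCSVError
from . import model as _model
from .model import EcosystemParams, TemperatureForcing

logger = logging.getLogger("pondwatch")

SCHEMA_VERSION = 1

SENSOR_COLUMNS = [
    "timestamp",
    "do_mg_l",
    "temp_c",
    "chl_ug_l",
    "secchi_m",
    "ph_surface",
    "ph_bottom",
    "source_id",
]


@dataclass(frozen=True)
class MeasurementRecord:
    """One timestamped sensor observation."""

    timestamp: datetime
    do_mg_l: Optional[float]
    temp_c: Optional[float]
    chl_ug_l: Optional[float] = None
    secchi_m: Optional[float] = None
    ph_surface: Optional[float] = None
    ph_bottom: Optional[float] = None
    source_id: str = "node-0"

    @property
    def has_do(self) -> bool:
        return self.do_mg_l is not None

    @property
    def has_chl(self) -> bool:
        return self.chl_ug_l is not None


def _parse_float(value, column, lineno, warnings, lenient):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None, True
    try:
        return float(value), True
    except (TypeError, ValueError):
        msg = f"line {lineno}: unparseable {column} value {value!r}"
        if lenient:
            warnings.append(msg)
            return None, False
        raise SensorCSVError(msg)


def read_sensor_csv(path, strict: bool = True):
    """Parse a sensor CSV into a list of :class:`MeasurementRecord`.

    In strict mode any malformed row or non-monotone timestamp aborts with
    :class:`SensorCSVError`; in lenient mode offending rows are skipped and
    returned as warning strings.

    Returns ``(records, warnings)``.
    """
    path = Path(path)
    if not path.exists():
        raise SensorCSVError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"timestamp", "do_mg_l", "temp_c"} - set(df.columns)
    if missing:
        raise SensorCSVError(f"missing mandatory columns: {sorted(missing)}")
    records: list[MeasurementRecord] = []
    warnings: list[str] = []
    last_ts: dict[str, datetime] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        raw = row._asdict()
        try:
            ts = datetime.fromisoformat(raw["timestamp"])
        except ValueError:
            msg = f"line {lineno}: unparseable timestamp {raw['timestamp']!r}"
            if strict:
                raise SensorCSVError(msg)
            warnings.append(msg)
            continue
        source = raw.get("source_id") or "node-0"
        prev = last_ts.get(source)
        if prev is not None and ts <= prev:
            msg = f"line {lineno}: non-monotone timestamp for {source}"
            if strict:
                raise SensorCSVError(msg)
            warnings.append(msg)
            continue
        vals = {}
        ok = True
        for col in ("do_mg_l", "temp_c", "chl_ug_l", "secchi_m", "ph_surface", "ph_bottom"):
            v, good = _parse_float(raw.get(col, ""), col, lineno, warnings, not strict)
            vals[col] = v
            ok = ok and good
        if not ok:
            continue
        if vals["do_mg_l"] is not None and vals["do_mg_l"] < 0:
            msg = f"line {lineno}: negative do_mg_l {vals['do_mg_l']}"
            if strict:
                raise SensorCSVError(msg)
            warnings.append(msg)
            continue
        last_ts[source] = ts
        records.append(MeasurementRecord(timestamp=ts, source_id=source, **vals))
    return records, warnings


def records_to_dataframe(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["timestamp"] = r.timestamp.isoformat()
        rows.append(d)
    return pd.DataFrame(rows, columns=SENSOR_COLUMNS)


def write_sensor_csv(records: Sequence[MeasurementRecord], path) -> None:
    df = records_to_dataframe(records)
    for col in df.columns:
        if col not in ("timestamp", "source_id"):
            df[col] = df[col].map(lambda v: "" if v is None or pd.isna(v) else f"{v:.6g}")
    df.to_csv(path, index=False)


def write_outputs(results, path, format: str = "csv") -> Path:
    """Write a result table (DataFrame) or mapping to ``path``.

    Floats are rendered with 6 significant digits; identical inputs produce
    byte-identical files.  JSON output is wrapped in a versioned envelope.
    """
    path = Path(path)
    if results is None or (hasattr(results, "__len__") and len(results) == 0):
        raise ConfigError("refusing to write empty results")
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        if not isinstance(results, pd.DataFrame):
            results = pd.DataFrame(results)
        results.to_csv(path, index=False, float_format="%.6g")
    elif format == "json":
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, datetime):
                return o.isoformat()
            raise TypeError(f"not JSON serialisable: {type(o)}")

        if isinstance(results, pd.DataFrame):
            payload = results.to_dict(orient="records")
        else:
            payload = results
        doc = {"schema_version": SCHEMA_VERSION, "results": payload}
        path.write_text(json.dumps(doc, indent=2, default=_default) + "\n")
    else:
        raise ConfigError(f"unknown output format {format!r}")
    return path


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_BLOCKS = {
    "ecosystem", "forcing", "noise", "filter", "indirect", "species",
    "schedule", "seed", "x0", "start_time",
}


@dataclass
class RunConfig:
    """Validated bundle of all configuration blocks for a run."""

    params: EcosystemParams = field(default_factory=EcosystemParams)
    forcing: TemperatureForcing = field(default_factory=TemperatureForcing)
    noise: "object" = None        # synth.NoiseSpec
    filter: "object" = None       # kalman.FilterConfig
    indirect: "object" = None     # indirect.IndirectCoeffs
    species: "object" = None      # trend.SpeciesLimits
    schedule: "object" = None     # synth.SamplingSchedule
    x0: np.ndarray = None
    start_time: datetime = None
    seed: int = 0

    def config_hash(self) -> str:
        blob = repr(self).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _build(cls, block: dict, name: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise ConfigError(f"unknown keys in '{name}' block: {sorted(unknown)}")
    try:
        return cls(**block)
    except TypeError as exc:
        raise ConfigError(f"invalid '{name}' block: {exc}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run-configuration file."""
    from .synth import NoiseSpec, SamplingSchedule
    from .kalman import FilterConfig
    from .indirect import IndirectCoeffs
    from .trend import SpeciesLimits

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _CONFIG_BLOCKS
    if unknown:
        raise ConfigError(f"unknown config blocks: {sorted(unknown)}")
    cfg = RunConfig()
    if "ecosystem" in raw:
        cfg.params = _build(EcosystemParams, raw["ecosystem"], "ecosystem")
    if "forcing" in raw:
        cfg.forcing = _build(TemperatureForcing, raw["forcing"], "forcing")
    cfg.noise = _build(NoiseSpec, raw.get("noise", {}), "noise")
    cfg.filter = _build(FilterConfig, raw.get("filter", {}), "filter")
    cfg.indirect = _build(IndirectCoeffs, raw.get("indirect", {}), "indirect")
    if "species" in raw:
        cfg.species = _build(SpeciesLimits, raw["species"], "species")
    cfg.schedule = _build(SamplingSchedule, raw.get("schedule", {}), "schedule")
    if "x0" in raw:
        cfg.x0 = _model.validate_state(raw["x0"])
    if "start_time" in raw:
        cfg.start_time = datetime.fromisoformat(str(raw["start_time"]))
    cfg.seed = int(raw.get("seed", 0))
    return cfg


def log_provenance(cfg: RunConfig, seed: int) -> None:
    from . import __version__

    logger.info(
        "run provenance: config_hash=%s seed=%d pondwatch=%s",
        cfg.config_hash(), seed, __version__,
    )
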