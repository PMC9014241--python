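"""Text-based interchange formats.

Plain comma-separated text with headers is the primary format: line
curves, photon tables and per-burst observables round-trip losslessly at
17 significant digits.  Each writer leaves a JSON metadata sidecar
(``<path>.meta.json``) with the resolved parameters so any output can be
reproduced from its sidecar alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .lines import CURVE_COLUMNS, LineCurve
from .simulate import BurstTable

__all__ = [
    "write_line_curve",
    "read_line_curve",
    "write_photons",
    "read_photons",
    "write_bursts",
    "read_burst_table",
    "write_observables",
]

PHOTON_SCHEMA = ["burst_id", "channel", "delay_ns", "macrotime_ms"]
PHOTON_SCHEMA_VERSION = 1
FLOAT_FMT = "%.17g"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _write_meta(path: Path, meta: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    _sidecar(path).write_text(json.dumps(meta, indent=2, default=default) + "\n")


def write_line_curve(curve: LineCurve, path: str | Path) -> Path:
    """Write a LineCurve to CSV plus a JSON metadata sidecar."""
    path = Path(path)
    curve.samples.to_csv(path, index=False, float_format=FLOAT_FMT)
    _write_meta(path, {"kind": curve.kind, "param_name": curve.param_name,
                       **curve.metadata})
    return path


def read_line_curve(path: str | Path) -> LineCurve:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    kind = meta.pop("kind")
    param_name = meta.pop("param_name")
    return LineCurve(kind=kind, param_name=param_name, samples=df, metadata=meta)


def write_photons(table: BurstTable, path: str | Path) -> Path:
    """Photon table: one row per photon (burst_id, channel, delay_ns,
    macrotime_ms); schema version recorded in the sidecar."""
    path = Path(path)
    table.photons[PHOTON_SCHEMA].to_csv(path, index=False, float_format=FLOAT_FMT)
    _write_meta(path, {"schema": PHOTON_SCHEMA, "version": PHOTON_SCHEMA_VERSION,
                       **table.metadata})
    return path


def read_photons(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in PHOTON_SCHEMA if c not in df.columns]
    if missing:
        raise ValueError(f"photon file {path} missing columns {missing}")
    bad = ~df["channel"].isin(["D", "A"])
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:10]  # +2: header + 1-based
        raise ValueError(f"malformed channel values at lines {lines} of {path}")
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return df, meta


def write_bursts(table: BurstTable, path: str | Path) -> Path:
    """Burst summary table (counts, duration, true occupancies)."""
    path = Path(path)
    table.bursts.to_csv(path, index=False, float_format=FLOAT_FMT)
    _write_meta(path, table.metadata)
    return path


def read_burst_table(photon_path: str | Path,
                     burst_path: str | Path | None = None) -> BurstTable:
    """Rebuild a BurstTable from a photon file (and optional burst summary).

    Without a summary file the per-burst counts are recomputed from the
    photons; true occupancies are then unavailable.
    """
    photons, meta = read_photons(photon_path)
    if burst_path is not None:
        bursts = pd.read_csv(burst_path)
    else:
        g = photons.groupby("burst_id", sort=True)
        bursts = pd.DataFrame(
            {
                "burst_id": list(g.groups),
                "n_donor": g.apply(lambda d: int((d["channel"] == "D").sum()),
                                   include_groups=False).to_numpy(),
                "n_acceptor": g.apply(lambda d: int((d["channel"] == "A").sum()),
                                      include_groups=False).to_numpy(),
            }
        )
    return BurstTable(bursts=bursts, photons=photons, metadata=meta)


def write_observables(obs: pd.DataFrame, path: str | Path,
                      metadata: dict | None = None) -> Path:
    path = Path(path)
    obs.to_csv(path, index=False, float_format=FLOAT_FMT)
    _write_meta(path, metadata or {})
    return path
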