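"""CSV/JSON readers and writers for the interchange formats.

Locations travel as RFC-4180 CSV with header ``animal_id,time,x,y``;
unit tables as CSV with ``unit_id,center_x,center_y,radius``, covariate
columns, and (once counted) ``count``.  Fit and bootstrap reports are JSON.
Floats are written to 12 significant digits so write-then-read round-trips.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .sampling import LOCATION_COLUMNS, UnitTable

__all__ = [
    "read_locations",
    "read_units",
    "write_units",
    "write_locations",
    "write_fit",
    "read_fit",
    "read_region",
]

_FLOAT_FMT = "%.12g"


def read_locations(path) -> pd.DataFrame:
    """Read and validate a GPS location table.

    Timestamps are validated for parseability only — the estimator never
    uses them.  Malformed rows are reported with their file line numbers.
    """
    try:
        raw = pd.read_csv(path, dtype=str, skip_blank_lines=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty location file: {path}") from None
    missing = [c for c in LOCATION_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing column: {', '.join(missing)}")
    if len(raw) == 0:
        raise ValueError(f"location file has a header but no rows: {path}")

    # a duplicated header row mid-file parses as a data row of column names
    dup = raw.apply(lambda r: list(r[list(LOCATION_COLUMNS)]) == list(LOCATION_COLUMNS), axis=1)
    if dup.any():
        lines = [int(i) + 2 for i in raw.index[dup]]  # +2: header + 1-based
        raise ValueError(f"duplicated header row at line(s): {lines}")

    out = pd.DataFrame({"animal_id": raw["animal_id"].astype(str)})
    time = pd.to_datetime(raw["time"], errors="coerce", format="ISO8601")
    bad = raw.index[time.isna() | raw["animal_id"].isna()]
    for col in ("x", "y"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = bad.union(raw.index[vals.isna() | ~np.isfinite(vals)])
        out[col] = vals
    if len(bad) > 0:
        lines = [int(i) + 2 for i in bad[:20]]
        raise ValueError(f"malformed location row(s) at line(s): {lines}")
    out.insert(1, "time", time)
    return out


def write_locations(path, locations: pd.DataFrame) -> None:
    loc = locations.copy()
    loc["time"] = pd.to_datetime(loc["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    loc.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_units(path) -> UnitTable:
    """Read a sampling-unit table; covariate columns must be numeric."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty unit file: {path}") from None
    missing = [c for c in ("unit_id", "center_x", "center_y", "radius") if c not in frame.columns]
    if missing:
        raise ValueError(f"missing column: {', '.join(missing)}")
    for col in frame.columns:
        if col == "unit_id":
            continue
        vals = pd.to_numeric(frame[col], errors="coerce")
        if vals.isna().any():
            raise ValueError(f"covariate column contains non-numeric values: {col}")
        frame[col] = vals
    return UnitTable(frame)


def write_units(path, units: UnitTable) -> None:
    units.frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _provenance(config: dict | None = None) -> dict:
    from importlib.metadata import version

    import scipy
    import shapely

    from . import __version__

    return {
        "package": {"nbrspf": __version__},
        "libraries": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "shapely": shapely.__version__,
            "click": version("click"),
        },
        "config": config or {},
    }


def write_fit(path, result, config: dict | None = None) -> None:
    """Serialize an RSPFResults or BootstrapResults (anything with to_dict)."""
    payload = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    payload["provenance"] = _provenance(config)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_fit(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def read_region(path):
    """Region JSON: {"xmin":..,"ymin":..,"xmax":..,"ymax":.., "polygon": [[x,y],..]?}."""
    from .sampling import Region

    with open(path) as fh:
        cfg = json.load(fh)
    missing = [k for k in ("xmin", "ymin", "xmax", "ymax") if k not in cfg]
    if missing:
        raise ValueError(f"region file missing key(s): {', '.join(missing)}")
    return Region(
        cfg["xmin"], cfg["ymin"], cfg["xmax"], cfg["ymax"], polygon=cfg.get("polygon")
    )
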