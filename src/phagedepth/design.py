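"""The depth x time sampling design and depth-bin vocabulary.

The study design is a water-column grid: seven depths spanning the
surface mixed layer to the upper mesopelagic, sampled on twelve occasions
over roughly a year and a half. Depths collapse into four persistent
habitat bins (surface, deep chlorophyll maximum, 200 m, mesopelagic);
contigs whose temporal behaviour is dominated by boom-and-bust spikes
form a fifth, "sporadic" group.
"""

from __future__ import annotations

import pandas as pd

from .exceptions import DataError

#: Sampling depths in meters, shallow to deep.
DEFAULT_DEPTHS = (25, 75, 125, 200, 500, 770, 1000)

#: Depths averaged to form the "surface ocean mean" reference.
SURFACE_DEPTHS = (25, 75)

#: Persistent depth bins, shallow to deep (adjacency follows this order).
BIN_ORDER = ("surface", "DCM", "two_hundred", "mesopelagic")

#: All assignable distribution groups.
GROUPS = BIN_ORDER + ("sporadic",)


def depth_bin(depth_m: float) -> str:
    """Map a sampling depth in meters onto its persistent habitat bin.

    25-75 m -> surface; ~125 m -> DCM; ~200 m -> two_hundred;
    500 m and deeper -> mesopelagic.
    """
    d = float(depth_m)
    if d <= 0:
        raise DataError(f"depth must be positive, got {depth_m}")
    if d < 100:
        return "surface"
    if d < 150:
        return "DCM"
    if d < 350:
        return "two_hundred"
    return "mesopelagic"


def bin_depths(bin_name: str, depths=DEFAULT_DEPTHS) -> tuple[int, ...]:
    """Sampling depths belonging to one habitat bin."""
    if bin_name not in BIN_ORDER:
        raise DataError(f"unknown depth bin {bin_name!r}")
    return tuple(d for d in depths if depth_bin(d) == bin_name)


def validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Check a sample table (sample_id, depth_m, date) and return it sorted.

    (depth, date) pairs must be unique; dates are parsed to Timestamps.
    """
    required = {"sample_id", "depth_m", "date"}
    missing = required - set(samples.columns)
    if missing:
        raise DataError(f"sample table missing columns: {sorted(missing)}")
    out = samples.copy()
    out["date"] = pd.to_datetime(out["date"])
    if out["sample_id"].duplicated().any():
        raise DataError("duplicate sample_id in sample table")
    if out.duplicated(subset=["depth_m", "date"]).any():
        raise DataError("duplicate (depth, date) pair in sample table")
    return out.sort_values(["depth_m", "date"], kind="stable").reset_index(drop=True)
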