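"""Sediment interstitial-space physics.

A submerged sediment layer of total volume ``V_T`` is partitioned into solid
particles (``V_s``), pore water (``V_w``) and gas-filled space (``V_a``).
Three derived descriptors characterise the interstitial space:

* volumetric water content ``Moi_v = V_w / V_T``,
* gas-space percent ``VP_a = 100 * (1 - Moi_v * rho_w / (Moi_m * rho_ws))``,
  where ``Moi_m`` is the mass water content (water mass over total wet mass),
  ``rho_w`` the pore-water density and ``rho_ws`` the density of the gas-free
  sediment-water mixture (wet mass over ``V_s + V_w``),
* total interstitial space ``TIS = Moi_v + VP_a`` (both in percent).

Under the readings above the gas-space formula is an identity: it returns
exactly ``100 * V_a / V_T`` for any consistent volume budget.  Particle
descriptors are the mean particle size and the particle evenness, the
coefficient of variation (Cv) of the size distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VolumeBudget",
    "LayerPhysics",
    "GasSpaceResult",
    "volumetric_water_content",
    "gas_space_percent",
    "total_interstitial_space",
    "particle_evenness",
    "replicate_average",
    "summarize_profiles",
    "round_half_up",
    "read_layer_table",
    "write_layer_table",
    "table1_path",
    "load_table1",
    "PHYSICS_VARIABLES",
]

#: canonical layer-physics variable names used in long-format tables
PHYSICS_VARIABLES = ("tis", "vwc", "gas_space", "p_size", "p_evenness")


class InvalidInputError(ValueError):
    """Raised when a physics operation receives inconsistent input."""


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties going away from zero (half-up), not banker's rounding."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class VolumeBudget:
    """Volume partition of one sediment layer sample.

    All volumes share one arbitrary unit; the total must equal the sum of
    the three phases.
    """

    v_solid: float
    v_water: float
    v_gas: float

    def __post_init__(self) -> None:
        for name in ("v_solid", "v_water", "v_gas"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")

    @property
    def v_total(self) -> float:
        return self.v_solid + self.v_water + self.v_gas


@dataclass
class LayerPhysics:
    """Measured interstitial-space record for one site x 5-cm layer.

    Percent quantities (``moi_v``, ``vp_a``, ``tis``) are stored on the 0-100
    scale; ``moi_m`` is a mass fraction; densities in g/cm^3.  ``None`` marks
    a measurement that could not be made; summaries skip missing values.
    """

    site_id: str
    depth_cm: float
    moi_v: float | None = None
    moi_m: float | None = None
    rho_w: float | None = None
    rho_ws: float | None = None
    vp_a: float | None = None
    tis: float | None = None
    p_size_um: float | None = None
    p_evenness: float | None = None
    n_replicates: int = 5


@dataclass(frozen=True)
class GasSpaceResult:
    """Gas-space percent with the pre-clamp value retained.

    Slightly negative raw values arise from measurement noise in gas-free
    layers; they are reported as 0 with ``clamped`` set.
    """

    percent: float
    raw_percent: float
    clamped: bool

    def __float__(self) -> float:
        return self.percent


def volumetric_water_content(budget: VolumeBudget) -> float:
    """Water volume as a fraction of total layer volume (Moi_v)."""
    if budget.v_total <= 0:
        raise InvalidInputError("total volume must be positive")
    return budget.v_water / budget.v_total


def gas_space_percent(
    moi_v: float, moi_m: float, rho_w: float, rho_ws: float
) -> GasSpaceResult:
    """Gas-space volume percent from water contents and densities.

    ``moi_v`` is the volumetric water content as a fraction, ``moi_m`` the
    mass water content as a fraction.  The raw value can dip below zero for
    gas-free layers measured with noise; the reported percent clamps at 0.
    """
    if moi_v < 0:
        raise InvalidInputError("moi_v must be non-negative")
    if not (0 < moi_m < 1):
        raise InvalidInputError("moi_m must lie in (0, 1)")
    if rho_w <= 0 or rho_ws <= 0:
        raise InvalidInputError("densities must be positive")
    denom = moi_m * rho_ws
    if denom == 0:
        raise InvalidInputError("moi_m * rho_ws must be nonzero")
    raw = 100.0 * (1.0 - (moi_v * rho_w) / denom)
    clamped = raw < 0
    return GasSpaceResult(percent=max(raw, 0.0), raw_percent=raw, clamped=clamped)


def total_interstitial_space(
    moi_v_pct: float, vp_a_pct: float, *, layer: str | None = None, tol: float = 0.5
) -> float:
    """Total interstitial space percent: water-filled plus gas-filled space."""
    for name, v in (("moi_v_pct", moi_v_pct), ("vp_a_pct", vp_a_pct)):
        if not (0 <= v <= 100):
            raise InvalidInputError(f"{name}={v} outside [0, 100]")
    total = moi_v_pct + vp_a_pct
    if total > 100 + tol:
        where = f" at layer {layer}" if layer else ""
        raise InvalidInputError(
            f"inconsistent layer{where}: VWC + gas space = {total:.2f}% > 100%"
        )
    return total


def particle_evenness(sizes: Sequence[float], *, ddof: int = 1) -> float:
    """Coefficient of variation (Cv) of a particle-size sample.

    Uses the sample (n-1) standard deviation by default; set ``ddof=0`` for
    the population form.  Higher Cv means a less even size distribution.
    """
    arr = np.asarray(sizes, dtype=float)
    if arr.size < 2:
        raise InvalidInputError("particle evenness needs at least 2 sizes")
    if np.any(arr <= 0):
        raise InvalidInputError("particle sizes must be positive")
    mean = arr.mean()
    if mean == 0:
        raise InvalidInputError("zero mean particle size")
    return float(arr.std(ddof=ddof) / mean)


def replicate_average(values: Iterable[float | None]) -> tuple[float | None, int]:
    """Mean over non-missing replicates; returns ``(mean, n_used)``.

    All-missing input yields ``(None, 0)`` rather than raising, so that a
    fully failed layer measurement propagates as a missing cell.
    """
    observed = [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))]
    if not observed:
        return None, 0
    return float(np.mean(observed)), len(observed)


def _trend_sign(values: pd.Series, depths: pd.Series) -> float | None:
    """Sign of the Spearman correlation of a variable with depth (one site)."""
    mask = values.notna() & depths.notna()
    if mask.sum() < 3 or values[mask].nunique() < 2:
        return None
    rho = stats.spearmanr(depths[mask], values[mask]).statistic
    return float(np.sign(rho))


def summarize_profiles(layers: pd.DataFrame) -> pd.DataFrame:
    """Range summary (min, max, n) per variable plus per-site depth trends.

    ``layers`` is a long-format frame with columns ``site_id``, ``depth_cm``,
    ``variable``, ``value``.  Returns one row per variable with columns
    ``min``, ``max``, ``n`` and one ``trend_<site>`` column per site holding
    the sign of the variable's Spearman correlation with depth at that site
    (missing values excluded pairwise).
    """
    if layers.empty:
        raise InvalidInputError("no layers to summarize")
    rows = {}
    sites = sorted(layers["site_id"].unique())
    for variable, grp in layers.groupby("variable"):
        vals = grp["value"].dropna()
        row: dict[str, float | None] = {
            "min": float(vals.min()) if len(vals) else None,
            "max": float(vals.max()) if len(vals) else None,
            "n": int(len(vals)),
        }
        for site in sites:
            sg = grp[grp["site_id"] == site]
            row[f"trend_{site}"] = _trend_sign(sg["value"], sg["depth_cm"])
        rows[variable] = row
    order = [v for v in PHYSICS_VARIABLES if v in rows] + [
        v for v in rows if v not in PHYSICS_VARIABLES
    ]
    out = pd.DataFrame.from_dict(rows, orient="index").loc[order]
    out.index.name = "variable"
    return out


# ---------------------------------------------------------------------------
# long-format layer-table I/O


def read_layer_table(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a long-format layer-physics TSV.

    Expected columns: ``site_id``, ``depth_cm``, ``variable``, ``value`` and
    optionally ``replicate``.  ``NA`` (or empty) marks missing measurements.
    Leading ``#`` lines are collected into a metadata dict when they look
    like ``# key: value`` (site water depths and temperatures ride along as
    metadata only).  Replicate-level rows are averaged per layer x variable.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, val = stripped.partition(":")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA", "- -", "/", ""])
    required = {"site_id", "depth_cm", "variable", "value"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"layer table missing columns: {sorted(missing)}")
    if "replicate" in df.columns and df["replicate"].notna().any():
        df = (
            df.groupby(["site_id", "depth_cm", "variable"], as_index=False)["value"]
            .mean()
        )
    else:
        df = df[["site_id", "depth_cm", "variable", "value"]].copy()
    df["depth_cm"] = df["depth_cm"].astype(float)
    return df, meta


def write_layer_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def table1_path() -> Path:
    """Path to the packaged Chaohu Lake layer-physics measurement table."""
    return Path(str(resources.files("porescreen").joinpath("data/table1.tsv")))


def load_table1() -> tuple[pd.DataFrame, dict[str, str]]:
    """Load the packaged measurement fixture (four sites x nine layers)."""
    return read_layer_table(table1_path())
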