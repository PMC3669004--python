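"""CSV schema and configuration loading.

Leaf table (one row per leaf): ``campaign_date`` (ISO 8601),
``delta_t_days``, ``shoot_id``, ``leaf_rank``, ``length_start_mm``,
``length_end_mm``, ``increment_mm``, ``increment_above_mark_mm``,
``dry_weight_end_g`` and optional ``dry_weight_start_g``.  Campaign
sidecar: ``campaign_date``, ``n_marked``, ``new_leaves`` and optional
``p_days``.  Headers carry unit suffixes on purpose; units are never
silently coerced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .simulate import SimulationConfig
from .types import Campaign, LeafObservation, ShootSample

__all__ = [
    "LEAF_COLUMNS",
    "SIDECAR_COLUMNS",
    "RunOptions",
    "read_leaf_table",
    "write_leaf_table",
    "load_config",
]

log = logging.getLogger("eelgrass_allometry")

LEAF_COLUMNS = (
    "campaign_date",
    "delta_t_days",
    "shoot_id",
    "leaf_rank",
    "length_start_mm",
    "length_end_mm",
    "increment_mm",
    "increment_above_mark_mm",
    "dry_weight_end_g",
)
OPTIONAL_LEAF_COLUMNS = ("dry_weight_start_g",)
SIDECAR_COLUMNS = ("campaign_date", "n_marked", "new_leaves")

_INCREMENT_TOL = 1e-9


@dataclass(frozen=True)
class RunOptions:
    """Pipeline-level options read from the config file."""

    params_source: str = "config"     # "config" (site-reference alpha/beta) | "fit"
    marking_mode: str = "auto"        # "auto" | "formal" | "field" | "subtraction"
    make_plot: bool = False

    def __post_init__(self) -> None:
        if self.params_source not in ("fit", "config"):
            raise ValidationError(
                f"run.params_source must be 'fit' or 'config', got {self.params_source!r}"
            )
        if self.marking_mode not in ("auto", "formal", "field", "subtraction"):
            raise ValidationError(f"unknown run.marking_mode {self.marking_mode!r}")


def write_leaf_table(campaigns: Sequence[Campaign], leaf_path, sidecar_path) -> None:
    """Serialize campaigns to the leaf table + campaign sidecar CSVs."""
    rows = []
    side = []
    for camp in campaigns:
        date = camp.date.isoformat()
        for shoot in camp.shoots:
            for leaf in shoot.leaves:
                rows.append(
                    {
                        "campaign_date": date,
                        "delta_t_days": camp.delta_t,
                        "shoot_id": shoot.shoot_id,
                        "leaf_rank": leaf.rank,
                        "length_start_mm": leaf.length_start,
                        "length_end_mm": leaf.length_end,
                        "increment_mm": leaf.increment,
                        "increment_above_mark_mm": leaf.increment_above_mark,
                        "dry_weight_end_g": leaf.dry_weight_end,
                        "dry_weight_start_g": (
                            "" if leaf.dry_weight_start is None else leaf.dry_weight_start
                        ),
                    }
                )
        side.append(
            {
                "campaign_date": date,
                "n_marked": camp.n_marked,
                "new_leaves": camp.new_leaves,
                "p_days": "" if camp.p is None else camp.p,
            }
        )
    cols = list(LEAF_COLUMNS) + list(OPTIONAL_LEAF_COLUMNS)
    pd.DataFrame(rows, columns=cols).to_csv(leaf_path, index=False, float_format="%.17g")
    pd.DataFrame(side, columns=list(SIDECAR_COLUMNS) + ["p_days"]).to_csv(
        sidecar_path, index=False, float_format="%.17g"
    )


def read_leaf_table(leaf_path, sidecar_path) -> list[Campaign]:
    """Parse and validate the CSV pair into Campaign objects.

    Violations (missing columns, duplicate keys, increments inconsistent
    with the two lengths) raise :class:`ValidationError` naming the rows
    involved (2-based, i.e. as displayed in a spreadsheet with header).
    """
    leaf_path, sidecar_path = Path(leaf_path), Path(sidecar_path)
    df = pd.read_csv(leaf_path)
    missing = [c for c in LEAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{leaf_path}: missing columns {missing}")
    side = pd.read_csv(sidecar_path)
    missing = [c for c in SIDECAR_COLUMNS if c not in side.columns]
    if missing:
        raise ValidationError(f"{sidecar_path}: missing columns {missing}")

    if df.empty:
        log.warning("%s: leaf table is empty", leaf_path)
        return []

    keys = df[["campaign_date", "shoot_id", "leaf_rank"]]
    dup_mask = keys.duplicated(keep=False)
    if dup_mask.any():
        rows = [str(i + 2) for i in df.index[dup_mask][:10]]
        raise ValidationError(
            f"{leaf_path}: duplicate (campaign_date, shoot_id, leaf_rank) "
            f"keys at rows {', '.join(rows)}"
        )
    derived = df["length_end_mm"] - df["length_start_mm"]
    bad = np.abs(df["increment_mm"] - derived) > _INCREMENT_TOL
    if bad.any():
        rows = [str(i + 2) for i in df.index[bad][:10]]
        raise ValidationError(
            f"{leaf_path}: increment_mm != length_end_mm - length_start_mm "
            f"at rows {', '.join(rows)}"
        )

    side_by_date = {}
    for _, r in side.iterrows():
        side_by_date[str(r["campaign_date"])] = r

    has_start = "dry_weight_start_g" in df.columns
    campaigns = []
    # preserve first-appearance order of campaigns and shoots for lossless
    # round-trips
    for date, cdf in df.groupby("campaign_date", sort=False):
        if date not in side_by_date:
            raise ValidationError(
                f"{sidecar_path}: no sidecar row for campaign {date}"
            )
        srow = side_by_date[date]
        delta_t = float(cdf["delta_t_days"].iloc[0])
        if not np.allclose(cdf["delta_t_days"], delta_t):
            raise ValidationError(
                f"{leaf_path}: campaign {date} has inconsistent delta_t_days"
            )
        shoots = []
        for shoot_id, sdf in cdf.groupby("shoot_id", sort=False):
            leaves = []
            for _, r in sdf.sort_values("leaf_rank").iterrows():
                w0 = r["dry_weight_start_g"] if has_start else np.nan
                leaves.append(
                    LeafObservation(
                        rank=int(r["leaf_rank"]),
                        length_start=float(r["length_start_mm"]),
                        length_end=float(r["length_end_mm"]),
                        increment=float(r["increment_mm"]),
                        increment_above_mark=float(r["increment_above_mark_mm"]),
                        dry_weight_end=float(r["dry_weight_end_g"]),
                        dry_weight_start=None if pd.isna(w0) else float(w0),
                    )
                )
            shoots.append(ShootSample(shoot_id=str(shoot_id), leaves=tuple(leaves)))
        p = srow.get("p_days", np.nan)
        campaigns.append(
            Campaign(
                date=date,
                delta_t=delta_t,
                shoots=tuple(shoots),
                n_marked=int(srow["n_marked"]),
                new_leaves=int(srow["new_leaves"]),
                p=None if pd.isna(p) else float(p),
            )
        )
    return campaigns


def load_config(path=None) -> tuple[SimulationConfig, RunOptions]:
    """Load the YAML config file.

    Two optional top-level sections: ``simulation`` (fields of
    :class:`SimulationConfig`) and ``run`` (fields of
    :class:`RunOptions`).  Missing entries take defaults; unknown keys
    are rejected by name.  ``path=None`` or an empty file yields all
    defaults.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
    unknown = set(raw) - {"simulation", "run"}
    if unknown:
        raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")

    sim_raw = raw.get("simulation") or {}
    bad = set(sim_raw) - set(SimulationConfig.field_names())
    if bad:
        raise ValidationError(f"unknown simulation config keys: {sorted(bad)}")
    try:
        config = SimulationConfig(**sim_raw)
    except TypeError as exc:  # wrong value types
        raise ValidationError(f"simulation config: {exc}") from exc

    run_raw = raw.get("run") or {}
    bad = set(run_raw) - {"params_source", "marking_mode", "make_plot"}
    if bad:
        raise ValidationError(f"unknown run config keys: {sorted(bad)}")
    options = RunOptions(**run_raw)
    return config, options
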