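"""Model file I/O and bundled data tables.

Model descriptions are YAML (or JSON) documents with sections:

* ``segments`` — name, ``origin_mm`` / ``rotation_deg`` placement at
  zero-pose, optional ``mesh`` and ``inertial``;
* ``joints`` — name, ``parent``/``child`` segment, ``center_mm`` rotation
  center (parent frame), ``dofs`` with unit ``axis`` and ``range_deg``;
* ``muscles`` — per muscle the Hill parameters (``f_max_N``, ``l_opt_mm``,
  ``l_slack_mm``, ``alpha_opt_deg``, optional ``v_max``) and the ``path``
  as an ordered list of ``{segment, xyz_mm, role}``;
* ``poses`` — optional named poses, DoF name -> angle in degrees.

Lengths are millimetres, angles degrees, forces newtons in files; angles
are radians inside the library.

The bundled tables transcribe the model's joint ranges and the 59 muscle
parameter sets (42 hindlimb + 17 forelimb) and are validated at load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .muscle import MuscleParams
from .paths import AttachmentPoint, MusclePath
from .skeleton import Pose, SkeletonModel, build_skeleton

__all__ = [
    "BundledTables",
    "DataIntegrityError",
    "load_bundled_tables",
    "bundled_muscle_params",
    "load_model",
    "save_model",
    "LoadedModel",
]

RATIO_TOL = 0.005  # printed 2-decimal rounding tolerance
RATIO_TOL_FLAGGED = 0.01  # rows the source table itself prints inconsistently
N_HINDLIMB = 42
N_FORELIMB = 17


class DataIntegrityError(RuntimeError):
    """Bundled table failed its load-time validation."""


@dataclass
class BundledTables:
    joints: pd.DataFrame
    muscles: pd.DataFrame


def _read_bundled_csv(name: str) -> pd.DataFrame:
    with resources.files("mousemsk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_bundled_tables() -> BundledTables:
    """Load and validate the bundled joint-range and muscle-parameter tables.

    Validation: 42 hindlimb + 17 forelimb muscle rows, and every printed
    lts/lmo ratio reproducible from the printed columns within the
    2-decimal rounding tolerance (0.005), except the six rows the source
    prints inconsistently, which are flagged ``ratio-mismatch`` in the CSV
    and allowed up to 0.01.
    """
    try:
        joints = _read_bundled_csv("joint_ranges.csv")
        muscles = _read_bundled_csv("muscle_params.csv")
    except Exception as exc:  # parse failure
        raise DataIntegrityError(f"cannot parse bundled tables: {exc}") from exc
    n_hind = int((muscles["section"] == "hindlimb").sum())
    n_fore = int((muscles["section"] == "forelimb").sum())
    if n_hind != N_HINDLIMB or n_fore != N_FORELIMB:
        raise DataIntegrityError(
            f"muscle table has {n_hind} hindlimb / {n_fore} forelimb rows, "
            f"expected {N_HINDLIMB} / {N_FORELIMB}"
        )
    dev = (muscles["ratio"] - muscles["l_slack_mm"] / muscles["l_opt_mm"]).abs()
    flagged = muscles["note"].fillna("") == "ratio-mismatch"
    bad = (dev > RATIO_TOL) & ~flagged
    bad_flagged = (dev > RATIO_TOL_FLAGGED) & flagged
    if bad.any() or bad_flagged.any():
        rows = muscles.loc[bad | bad_flagged, "abbreviation"].tolist()
        raise DataIntegrityError(f"ratio column inconsistent for rows {rows}")
    if (joints["range_min_deg"] >= joints["range_max_deg"]).any():
        raise DataIntegrityError("joint-range table has degenerate ranges")
    return BundledTables(joints=joints, muscles=muscles)


def bundled_muscle_params(name_or_abbrev: str) -> MuscleParams:
    """Hill parameter set for one bundled muscle, by full name or abbreviation."""
    t = load_bundled_tables().muscles
    row = t[(t["name"] == name_or_abbrev) | (t["abbreviation"] == name_or_abbrev)]
    if len(row) != 1:
        raise KeyError(f"muscle {name_or_abbrev!r} not found in bundled table")
    r = row.iloc[0]
    return MuscleParams(
        name=r["name"],
        f_max=float(r["f_max_N"]),
        l_opt=float(r["l_opt_mm"]),
        l_slack=float(r["l_slack_mm"]),
        alpha_opt=float(r["alpha_opt_deg"]),
        group=r["group"],
    )


@dataclass
class LoadedModel:
    skeleton: SkeletonModel
    muscles: dict[str, tuple[MusclePath, MuscleParams]]
    poses: dict[str, Pose]
    config: dict


def parse_model(config: dict) -> LoadedModel:
    """Build skeleton, muscles and named poses from a model-description dict."""
    skeleton = build_skeleton(config)
    muscles: dict[str, tuple[MusclePath, MuscleParams]] = {}
    for m in config.get("muscles", []):
        params = MuscleParams(
            name=m["name"],
            f_max=float(m["f_max_N"]),
            l_opt=float(m["l_opt_mm"]),
            l_slack=float(m["l_slack_mm"]),
            alpha_opt=float(m.get("alpha_opt_deg", 0.0)),
            v_max=float(m.get("v_max", 10.0)),
            group=m.get("group", ""),
        )
        pts = tuple(
            AttachmentPoint(
                segment=p["segment"],
                local_position=tuple(p["xyz_mm"]),
                role=p.get(
                    "role",
                    "origin" if i == 0 else
                    "insertion" if i == len(m["path"]) - 1 else "waypoint",
                ),
            )
            for i, p in enumerate(m["path"])
        )
        muscles[m["name"]] = (MusclePath(m["name"], pts), params)
    poses = {
        name: Pose({d: math.radians(a) for d, a in angles.items()})
        for name, angles in config.get("poses", {}).items()
    }
    return LoadedModel(skeleton, muscles, poses, config)


def load_model(path: str | Path) -> LoadedModel:
    """Load a model description from a YAML or JSON file."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    return parse_model(config)


def save_model(config: dict, path: str | Path) -> None:
    """Write a model-description dict to YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
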