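"""Bundled whole-body skeleton configuration (108 segments).

Builds the model-description dict for the full mouse skeleton: 50 vertebrae
(8 cervical, 13 thoracic, 6 lumbar, 3 coccygeal, 20 caudal; the 4 sacral
vertebrae are merged into the pelvis bone), the pelvis, the head (upper and
lower jaw counted as one bone), 15 bones per forelimb and 13 per hindlimb —
108 segments joined by 107 joints.

DoF ranges come from the bundled joint-range table.  Consecutive vertebrae
carry flexion-extension and lateral-bending DoFs; the hip and shoulder are
3-DoF ball joints, the knee a hinge, the ankle 3-DoF, the elbow split into
a humero-ulnar hinge and a radio-ulnar supination-pronation DoF, the wrist
2-DoF, and every digit joint a hinge.  The scapula is attached to the
fourth thoracic vertebra by a 3-DoF joint with nominal +/-20 deg ranges
(the printed table lists no scapulothoracic joint; the attachment is this
config's own convention, documented here).

Segment placements are nominal straight-chain offsets (mm) chosen to give
an anatomically plausible overall scale; the published bone geometry is
not part of this package.  Per-group DoF tally (this config's own count):
2 per vertebral joint (49 joints), 1 head, 2 tail-root-equivalent included
above, 3+1+3+10 per hindlimb, 3+3+1+1+2+10 per forelimb.

Axis convention: right-handed; x = sagittal, y = coronal, z = transversal.
Flexion-extension rotates about z, abduction-adduction about y,
internal-external rotation and lateral bending about x.
"""

from __future__ import annotations

__all__ = ["whole_body_config"]

AXIS_FLEX = (0.0, 0.0, 1.0)  # transversal
AXIS_ABD = (0.0, 1.0, 0.0)  # coronal
AXIS_ROT = (1.0, 0.0, 0.0)  # sagittal


def _dof(name, axis, lo, hi):
    return {"name": name, "axis": list(axis), "range_deg": [lo, hi]}


def _chain(cfg, names, parent, step_mm, dof_specs):
    """Append a serial chain of segments, each jointed to the previous."""
    for name in names:
        cfg["segments"].append({"name": name, "origin_mm": list(step_mm)})
        cfg["joints"].append(
            {
                "name": f"{name}_joint",
                "parent": parent,
                "child": name,
                "center_mm": list(step_mm),
                "dofs": [
                    _dof(f"{name}_{dn}", axis, lo, hi)
                    for dn, axis, lo, hi in dof_specs
                ],
            }
        )
        parent = name
    return parent


def whole_body_config() -> dict:
    """Model-description dict for the bundled 108-segment mouse skeleton."""
    cfg: dict = {"name": "mouse_whole_body", "segments": [], "joints": []}
    cfg["segments"].append({"name": "pelvis", "origin_mm": [0.0, 0.0, 0.0]})

    def vert_dofs(flex_range, lat_range):
        return [
            ("flexion", AXIS_FLEX, *flex_range),
            ("lateral", AXIS_ROT, *lat_range),
        ]

    # spine: pelvis -> lumbar (6) -> thoracic (13) -> cervical (8) -> head
    last = _chain(
        cfg, [f"lumbar_{i}" for i in range(1, 7)], "pelvis",
        (2.5, 0.0, 0.0), vert_dofs((-6.0, 6.0), (-5.0, 5.0)),
    )
    last = _chain(
        cfg, [f"thoracic_{i}" for i in range(1, 14)], last,
        (2.5, 0.0, 0.0), vert_dofs((-5.0, 5.0), (-5.0, 5.0)),
    )
    last = _chain(
        cfg, [f"cervical_{i}" for i in range(1, 9)], last,
        (2.0, 0.0, 0.0), vert_dofs((-9.0, 9.0), (-5.0, 5.0)),
    )
    _chain(
        cfg, ["head"], last, (8.0, 0.0, 0.0),
        [("flexion", AXIS_FLEX, -50.0, 50.0)],
    )

    # tail: pelvis -> coccygeal (3) -> caudal (20), 23 serial bones
    last = _chain(
        cfg, [f"coccygeal_{i}" for i in range(1, 4)], "pelvis",
        (-2.5, 0.0, 0.0), vert_dofs((-10.0, 10.0), (-10.0, 10.0)),
    )
    _chain(
        cfg, [f"caudal_{i}" for i in range(1, 21)], last,
        (-3.0, 0.0, 0.0), vert_dofs((-10.0, 10.0), (-10.0, 10.0)),
    )

    for side, sign in (("left", 1.0), ("right", -1.0)):
        # hindlimb: femur, tibia, tarsus, 5 metatarsus, 5 phalanges (13)
        hip = f"{side}_femur"
        _chain(
            cfg, [hip], "pelvis", (0.0, sign * 6.0, 0.0),
            [
                ("hip_flexion", AXIS_FLEX, -30.0, 50.0),
                ("hip_abduction", AXIS_ABD, -40.0, 20.0),
                ("hip_rotation", AXIS_ROT, -10.0, 30.0),
            ],
        )
        _chain(
            cfg, [f"{side}_tibia"], hip, (0.0, sign * 1.0, -15.0),
            [("knee_flexion", AXIS_FLEX, -145.0, -40.0)],
        )
        _chain(
            cfg, [f"{side}_tarsus"], f"{side}_tibia", (0.0, 0.0, -17.0),
            [
                ("ankle_flexion", AXIS_FLEX, -50.0, 50.0),
                ("ankle_inversion", AXIS_ROT, -30.0, 50.0),
                ("ankle_abduction", AXIS_ABD, -10.0, 30.0),
            ],
        )
        for d in range(1, 6):
            _chain(
                cfg, [f"{side}_metatarsus_{d}"], f"{side}_tarsus",
                (3.0, sign * (d - 3) * 0.8, -1.0),
                [("mtp_flexion", AXIS_FLEX, -5.0, 5.0)],
            )
            _chain(
                cfg, [f"{side}_hind_phalange_{d}"], f"{side}_metatarsus_{d}",
                (2.0, 0.0, 0.0),
                [("flexion", AXIS_FLEX, -5.0, 5.0)],
            )

        # forelimb: scapula, humerus, ulna, radius, carpus,
        # 5 metacarpus, 5 phalanges (15)
        _chain(
            cfg, [f"{side}_scapula"], "thoracic_4", (0.0, sign * 5.0, 2.0),
            [
                ("scap_elevation", AXIS_FLEX, -20.0, 20.0),
                ("scap_protraction", AXIS_ABD, -20.0, 20.0),
                ("scap_rotation", AXIS_ROT, -20.0, 20.0),
            ],
        )
        _chain(
            cfg, [f"{side}_humerus"], f"{side}_scapula", (0.0, sign * 2.0, -4.0),
            [
                ("shoulder_retraction", AXIS_FLEX, -45.0, 45.0),
                ("shoulder_abduction", AXIS_ABD, -36.0, 3.0),
                ("shoulder_rotation", AXIS_ROT, -40.0, 14.0),
            ],
        )
        _chain(
            cfg, [f"{side}_ulna"], f"{side}_humerus", (0.0, 0.0, -10.0),
            [("elbow_flexion", AXIS_FLEX, 60.0, 153.0)],
        )
        _chain(
            cfg, [f"{side}_radius"], f"{side}_ulna", (1.0, 0.0, -1.0),
            [("elbow_supination", AXIS_ROT, -5.0, 30.0)],
        )
        _chain(
            cfg, [f"{side}_carpus"], f"{side}_radius", (0.0, 0.0, -9.0),
            [
                ("wrist_flexion", AXIS_FLEX, -20.0, 50.0),
                ("wrist_abduction", AXIS_ABD, -10.0, 10.0),
            ],
        )
        for d in range(1, 6):
            _chain(
                cfg, [f"{side}_metacarpus_{d}"], f"{side}_carpus",
                (2.0, sign * (d - 3) * 0.6, -0.8),
                [("mtc_flexion", AXIS_FLEX, -5.0, 5.0)],
            )
            _chain(
                cfg, [f"{side}_fore_phalange_{d}"], f"{side}_metacarpus_{d}",
                (1.5, 0.0, 0.0),
                [("flexion", AXIS_FLEX, -5.0, 5.0)],
            )
    return cfg
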