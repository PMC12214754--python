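"""Articulated 22-keypoint macaque-like skeleton and its camera projection.

The skeleton is a kinematic tree rooted at the pelvis, posed by a small set of
named joint angles (degrees).  Nine behavioural classes (sitting, eating,
hanging, laying, standing, walking, reaching, crouching, climbing) define
class-specific joint-angle distributions; exemplars within a class are draws
from those distributions.  The keypoint labels are placeholders -- downstream
analyses depend only on the count (22) and the tree structure.

Body frame: x lateral (animal's right positive), y vertical up, z anterior
(facing direction).  The camera orbits the vertical axis (azimuth, degrees)
and can be elevated (default +45 deg, looking down); projection is
orthographic, aimed at the pelvis.  Image convention after projection:
x right, y *down* (raster order), z = signed distance from the frontal plane
through the pelvis.
"""

from __future__ import annotations

import numpy as np

KEYPOINT_LABELS: tuple[str, ...] = (
    "nose", "chin", "head_top", "neck",
    "l_shoulder", "r_shoulder", "l_elbow", "r_elbow", "l_hand", "r_hand",
    "mid_spine", "lower_back", "pelvis",
    "l_hip", "r_hip", "l_knee", "r_knee", "l_foot", "r_foot",
    "tail_base", "tail_mid", "tail_tip",
)

N_KEYPOINTS = len(KEYPOINT_LABELS)  # 22

#: left/right partner indices, used when comparing mirror views of a
#: bilaterally symmetric pose (identity for midline keypoints).
MIRROR_PAIRS: dict[str, str] = {
    "l_shoulder": "r_shoulder", "r_shoulder": "l_shoulder",
    "l_elbow": "r_elbow", "r_elbow": "l_elbow",
    "l_hand": "r_hand", "r_hand": "l_hand",
    "l_hip": "r_hip", "r_hip": "l_hip",
    "l_knee": "r_knee", "r_knee": "l_knee",
    "l_foot": "r_foot", "r_foot": "l_foot",
}

#: bones (parent, child) by label; used for silhouette rasterization.
BONES: tuple[tuple[str, str], ...] = (
    ("pelvis", "lower_back"), ("lower_back", "mid_spine"), ("mid_spine", "neck"),
    ("neck", "head_top"), ("head_top", "nose"), ("nose", "chin"),
    ("neck", "l_shoulder"), ("l_shoulder", "l_elbow"), ("l_elbow", "l_hand"),
    ("neck", "r_shoulder"), ("r_shoulder", "r_elbow"), ("r_elbow", "r_hand"),
    ("pelvis", "l_hip"), ("l_hip", "l_knee"), ("l_knee", "l_foot"),
    ("pelvis", "r_hip"), ("r_hip", "r_knee"), ("r_knee", "r_foot"),
    ("pelvis", "tail_base"), ("tail_base", "tail_mid"), ("tail_mid", "tail_tip"),
)

_IDX = {lab: i for i, lab in enumerate(KEYPOINT_LABELS)}

# segment lengths, model units
_L = {
    "lower_back": 0.40, "mid_spine": 0.40, "neck": 0.45,
    "head_top": 0.22, "nose": 0.20, "chin": 0.10,
    "upper_arm": 0.45, "forearm": 0.45,
    "thigh": 0.50, "shin": 0.50,
    "tail": (0.15, 0.25, 0.25),
    "shoulder_w": 0.22, "hip_w": 0.18,
}

#: the behavioural class whose cameras are displaced below the horizontal
#: plane (the animal hangs upside down from the ceiling).
HANGING_CLASS = 3

# class-mean joint angles (degrees); unlisted parameters default to 0
_CLASS_MEANS: dict[int, dict[str, float]] = {
    1: dict(spine_pitch=70, spine_curl=8, head_pitch=-20,
            l_arm_pitch=25, r_arm_pitch=25, l_elbow_bend=-40, r_elbow_bend=-40,
            l_leg_pitch=60, r_leg_pitch=60, l_knee_bend=-120, r_knee_bend=-120,
            tail_pitch=-35, tail_curl=-20),                       # sitting
    2: dict(spine_pitch=60, spine_curl=5, head_pitch=-45,
            l_arm_pitch=120, r_arm_pitch=25, l_elbow_bend=-110, r_elbow_bend=-30,
            l_leg_pitch=55, r_leg_pitch=55, l_knee_bend=-115, r_knee_bend=-115,
            tail_pitch=-30, tail_curl=-15),                       # eating
    3: dict(spine_pitch=75, spine_curl=-5, head_pitch=30, invert=1,
            l_arm_pitch=165, r_arm_pitch=165, l_elbow_bend=-20, r_elbow_bend=-20,
            l_leg_pitch=150, r_leg_pitch=150, l_knee_bend=-30, r_knee_bend=-30,
            arm_splay=18, leg_splay=18, tail_pitch=20, tail_curl=25),  # hanging
    4: dict(spine_pitch=5, spine_curl=2, head_pitch=25,
            l_arm_pitch=75, r_arm_pitch=75, l_elbow_bend=-35, r_elbow_bend=-35,
            l_leg_pitch=80, r_leg_pitch=80, l_knee_bend=-50, r_knee_bend=-50,
            tail_pitch=5, tail_curl=10),                          # laying
    5: dict(spine_pitch=12, spine_curl=3, head_pitch=10,
            l_arm_pitch=5, r_arm_pitch=5, l_elbow_bend=-10, r_elbow_bend=-10,
            l_leg_pitch=5, r_leg_pitch=5, l_knee_bend=-15, r_knee_bend=-15,
            tail_pitch=25, tail_curl=15),                         # standing
    6: dict(spine_pitch=12, spine_curl=3, head_pitch=12,
            l_arm_pitch=35, r_arm_pitch=-20, l_elbow_bend=-45, r_elbow_bend=-10,
            l_leg_pitch=-25, r_leg_pitch=30, l_knee_bend=-20, r_knee_bend=-55,
            tail_pitch=30, tail_curl=10),                         # walking
    7: dict(spine_pitch=48, spine_curl=6, head_pitch=22,
            l_arm_pitch=150, r_arm_pitch=55, l_elbow_bend=-15, r_elbow_bend=-55,
            l_leg_pitch=40, r_leg_pitch=40, l_knee_bend=-95, r_knee_bend=-95,
            tail_pitch=-15, tail_curl=-10),                       # reaching
    8: dict(spine_pitch=28, spine_curl=10, head_pitch=-10,
            l_arm_pitch=12, r_arm_pitch=12, l_elbow_bend=-100, r_elbow_bend=-100,
            l_leg_pitch=32, r_leg_pitch=32, l_knee_bend=-105, r_knee_bend=-105,
            tail_pitch=-40, tail_curl=-15),                       # crouching
    9: dict(spine_pitch=62, spine_curl=4, head_pitch=28,
            l_arm_pitch=140, r_arm_pitch=95, l_elbow_bend=-30, r_elbow_bend=-60,
            l_leg_pitch=60, r_leg_pitch=18, l_knee_bend=-75, r_knee_bend=-35,
            arm_splay=12, leg_splay=12, tail_pitch=40, tail_curl=15),  # climbing
}

#: angular parameters drawn with this within-class s.d. (degrees)
_CLASS_SD = 7.0

_PARAM_NAMES = (
    "spine_pitch", "spine_curl", "head_pitch", "head_yaw",
    "l_arm_pitch", "r_arm_pitch", "l_elbow_bend", "r_elbow_bend", "arm_splay",
    "l_leg_pitch", "r_leg_pitch", "l_knee_bend", "r_knee_bend", "leg_splay",
    "tail_pitch", "tail_curl",
)


def class_parameters(pose_class: int, rng: np.random.Generator | None = None) -> dict:
    """Joint-angle parameters for one exemplar of ``pose_class`` (1..9).

    With ``rng`` given, angles are drawn around the class means with an s.d.
    of 7 degrees (left and right limbs drawn independently, which yields the
    natural-pose asymmetries); otherwise the class means are returned.
    """
    if pose_class not in _CLASS_MEANS:
        raise ValueError(f"pose_class must be 1..9, got {pose_class}")
    means = _CLASS_MEANS[pose_class]
    params = {name: float(means.get(name, 0.0)) for name in _PARAM_NAMES}
    params["invert"] = bool(means.get("invert", 0))
    if rng is not None:
        for name in _PARAM_NAMES:
            params[name] += _CLASS_SD * rng.standard_normal()
    return params


def _dir(pitch_deg: float, yaw_deg: float) -> np.ndarray:
    """Unit vector at ``pitch`` above the horizontal, yawed from +z toward +x."""
    p = np.deg2rad(pitch_deg)
    a = np.deg2rad(yaw_deg)
    return np.array([np.sin(a) * np.cos(p), np.sin(p), np.cos(a) * np.cos(p)])


def build_skeleton(params: dict) -> np.ndarray:
    """Forward kinematics: joint angles -> (22, 3) body-frame coordinates.

    The pelvis sits at the origin.  Returns coordinates in model units.
    """
    g = params.get
    c = np.zeros((N_KEYPOINTS, 3))

    sp, cu = g("spine_pitch", 0.0), g("spine_curl", 0.0)
    c[_IDX["lower_back"]] = c[_IDX["pelvis"]] + _L["lower_back"] * _dir(sp, 0)
    c[_IDX["mid_spine"]] = c[_IDX["lower_back"]] + _L["mid_spine"] * _dir(sp + cu, 0)
    c[_IDX["neck"]] = c[_IDX["mid_spine"]] + _L["neck"] * _dir(sp + 2 * cu, 0)

    hp = sp + 2 * cu + g("head_pitch", 0.0)
    hy = g("head_yaw", 0.0)
    c[_IDX["head_top"]] = c[_IDX["neck"]] + _L["head_top"] * _dir(hp + 50, hy)
    c[_IDX["nose"]] = c[_IDX["head_top"]] + _L["nose"] * _dir(hp - 30, hy)
    c[_IDX["chin"]] = c[_IDX["nose"]] + _L["chin"] * _dir(hp - 90, hy)

    asp = g("arm_splay", 0.0)
    for side, sgn in (("l", -1.0), ("r", 1.0)):
        sh = c[_IDX["neck"]] + np.array([sgn * _L["shoulder_w"], -0.05, 0.0])
        c[_IDX[f"{side}_shoulder"]] = sh
        ap = g(f"{side}_arm_pitch", 0.0)
        eb = g(f"{side}_elbow_bend", 0.0)
        el = sh + _L["upper_arm"] * _dir(ap - 90, sgn * asp)
        c[_IDX[f"{side}_elbow"]] = el
        c[_IDX[f"{side}_hand"]] = el + _L["forearm"] * _dir(ap - 90 + eb, sgn * asp)

    lsp = g("leg_splay", 0.0)
    for side, sgn in (("l", -1.0), ("r", 1.0)):
        hip = c[_IDX["pelvis"]] + np.array([sgn * _L["hip_w"], -0.05, -0.05])
        c[_IDX[f"{side}_hip"]] = hip
        lp = g(f"{side}_leg_pitch", 0.0)
        kb = g(f"{side}_knee_bend", 0.0)
        kn = hip + _L["thigh"] * _dir(lp - 90, sgn * lsp)
        c[_IDX[f"{side}_knee"]] = kn
        c[_IDX[f"{side}_foot"]] = kn + _L["shin"] * _dir(lp - 90 + kb, sgn * lsp)

    tp, tc = g("tail_pitch", 0.0), g("tail_curl", 0.0)
    lens = _L["tail"]
    c[_IDX["tail_base"]] = c[_IDX["pelvis"]] + lens[0] * _dir(tp, 180)
    c[_IDX["tail_mid"]] = c[_IDX["tail_base"]] + lens[1] * _dir(tp + tc, 180)
    c[_IDX["tail_tip"]] = c[_IDX["tail_mid"]] + lens[2] * _dir(tp + 2 * tc, 180)

    if params.get("invert"):
        # hang upside down: 180 deg rotation about the anterior (z) axis
        c[:, 0] *= -1.0
        c[:, 1] *= -1.0
    return c


def _rot_y(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    return np.array([[np.cos(t), 0, np.sin(t)], [0, 1, 0], [-np.sin(t), 0, np.cos(t)]])


def _rot_x(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    return np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])


def project_skeleton(coords: np.ndarray, azimuth: float, elevation: float) -> np.ndarray:
    """Orthographic camera-aligned coordinates of a posed skeleton.

    The camera orbits the vertical axis by ``azimuth`` degrees, is tilted by
    ``elevation`` degrees (positive: above the horizontal plane, looking
    down), and is aimed at the pelvis.  Returns (22, 3): image-plane x
    (right), image-plane y (*up*, in model units; the raster flip happens at
    pixel-scaling time), and z, the signed distance from the frontal plane
    through the pelvis.
    """
    pelvis = coords[_IDX["pelvis"]]
    rot = _rot_x(elevation) @ _rot_y(-azimuth)
    return (coords - pelvis) @ rot.T


def pelvis_index() -> int:
    return _IDX["pelvis"]


def keypoint_index(label: str) -> int:
    return _IDX[label]
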