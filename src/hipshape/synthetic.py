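"""Parametric pelvis+femur surrogate cohorts with analytic ground-truth angles.

The generator emulates the statistical structure of a symptomatic hip-pain
cohort: 75 subjects (50 female) whose diagnostic-angle distributions follow
the study's summary table, sex-linked pubic-arch / bone-thickness / size
effects, a hip-dysplasia continuum (shallow steep roof, aspheric femoral
head, lateral subluxation coupled to the centre-edge deficit), and an
acetabular-version axis that is sampled independently of dysplasia. Every
surrogate is built on a fixed parametric grid, so point correspondence holds
by construction, and the acetabular rim geometry realises the requested
CE/AI/AcAV/AASA/PASA angles exactly relative to the anatomical frame and the
inter-head line.

Anatomy of one hip surrogate (canonical frame; right side, mirrored left):

* pelvis (1200 points): a two-layer acetabular cup cap around the femoral
  head centre whose rim passes exactly through the anterior-sector,
  lateral-rim and posterior-sector anchor directions; a rim ring; a medial
  acetabular-roof landmark realising AI; two vertical wall-edge lines whose
  chord realises AcAV; an iliac sheet carrying the ASIS; the pubic symphysis
  and an inferior pubic ramus meeting the midline at half the pubic-arch
  angle; an ischial plate; and an ischial-spine bump of configurable
  prominence.
* femur (800 points): a femoral head sphere (deformed by an aspherical
  cam-like bump that never touches the medial articulating region used for
  sphere fitting), a neck at the neck-shaft angle, and a shaft.

Pose jitter is subject-level rigid (whole pelvis+femur assembly) plus a
per-femur rotation about its own head centre, mimicking patient positioning
and leg rotation; isotropic Gaussian point noise is applied last.
Ground-truth angles are recorded before jitter and noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import ANGLE_NAMES, SIDES, AngleSet, Cohort, CorrespondedShape, Subject

__all__ = [
    "InfeasibleParameterError",
    "GenerationError",
    "HipParams",
    "SubjectParams",
    "GeneratorConfig",
    "default_config",
    "build_subject",
    "sample_subject_params",
    "generate_cohort",
    "angle_table",
    "PELVIS_N_POINTS",
    "FEMUR_N_POINTS",
]


class InfeasibleParameterError(ValueError):
    """Angle/shape parameters that cannot be realised as a surrogate."""


class GenerationError(RuntimeError):
    """Cohort generation failed after bounded resampling."""


# ---------------------------------------------------------------------------
# canonical geometry (mm, unscaled; local coords are (lateral, anterior, superior))

PELVIS_N_POINTS = 1200
FEMUR_N_POINTS = 800

_HALF_INTERHEAD = 85.0          # head-centre distance from midline
_ASIS_LOCAL = np.array([62.0, 40.0, 70.0])
_SYMPHYSIS_LOCAL = np.array([0.0, 40.0, -25.0])  # same anterior coord as ASIS
_CUP_CLEARANCE = 2.0            # cup radius = head radius + clearance
_INFERIOR_CAP_DEG = 55.0        # fixed inferior extent of the cup cap
_ROOF_CHORD_FRAC = 0.8          # medial-roof landmark distance / cup radius
_WALL_OFFSET_FRAC = 0.35        # wall-chord midpoint lateral offset / cup radius
_WALL_CHORD_FRAC = 1.7          # wall-edge chord length / cup radius
_WALL_HALF_SPAN_FRAC = 0.7      # vertical half-extent of wall-edge lines
_NECK_LENGTH_FRAC = 0.12        # femoral neck length / femur length
_SHAFT_LENGTH_FRAC = 0.26       # modelled shaft length / femur length
_HEAD_REGION_MEDIAL = 0.2       # head-region mask: medial component threshold
_CAM_AXIS = np.array([1.0, 0.5, 1.0]) / np.linalg.norm([1.0, 0.5, 1.0])
_CAM_COS_SUPPORT = np.cos(np.deg2rad(40.0))

_N_PSI = 24                     # cup azimuth samples (includes 0/90/180/270)
_N_T = 14                       # cup polar fractions per azimuth (rim separate)
_N_WALL = 9                     # points per wall-edge line


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, roughly uniform unit directions (golden-angle spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


_HEAD_DIRS = _fibonacci_sphere(360)
_HEAD_REGION_IDX = np.flatnonzero(_HEAD_DIRS[:, 0] < -_HEAD_REGION_MEDIAL)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class HipParams:
    """Per-hip surrogate parameters (angles in degrees, lengths in mm)."""

    ce: float = 28.0
    ai: float = 8.0
    acav: float = 20.1
    aasa: float = 49.3
    pasa: float = 90.1
    head_radius: float = 23.0
    head_asphericity: float = 0.0
    subluxation: float = 0.0
    ischial_spine_prominence: float = 0.0

    def __post_init__(self) -> None:
        if self.head_radius <= 0:
            raise InfeasibleParameterError(f"head_radius must be > 0, got {self.head_radius}")
        if self.head_asphericity < 0 or self.subluxation < 0:
            raise InfeasibleParameterError("asphericity and subluxation must be >= 0")
        if self.ischial_spine_prominence < 0:
            raise InfeasibleParameterError("ischial_spine_prominence must be >= 0")


@dataclass
class SubjectParams:
    """All parameters needed to build one subject deterministically."""

    subject_id: str = "S000"
    sex: str = "F"
    global_scale: float = 1.0
    bone_thickness: float = 4.5
    pubic_arch_angle: float = 95.0
    femur_length: float = 420.0
    neck_shaft_angle: float = 127.0
    left: HipParams = field(default_factory=HipParams)
    right: HipParams = field(default_factory=HipParams)
    subject_rotation_deg: tuple = (0.0, 0.0, 0.0)
    subject_translation_mm: tuple = (0.0, 0.0, 0.0)
    femur_rotation_deg: dict = field(default_factory=lambda: {"L": (0.0, 0.0, 0.0), "R": (0.0, 0.0, 0.0)})
    noise_sd: float = 0.0
    seed: int = 0

    def hip(self, side: str) -> HipParams:
        return self.left if side == "L" else self.right


@dataclass
class GeneratorConfig:
    """Synthetic-cohort parameters.

    Angle means/sds are the study's summary-table values: AcAV/AASA/PASA are
    split by sex; CE and AI by dysplasia stratum (the dysplastic stratum is
    truncated below the 25 deg diagnostic threshold, the normal stratum
    above it); sector angles get an additive dysplasia shift whose
    prevalence-weighted mean is zero so the per-sex marginals are preserved.
    ``side_icc`` is the fraction of each angle's variance shared between a
    subject's two hips.
    """

    n_subjects: int = 75
    n_female: int = 50
    frac_unilateral: float = 0.5
    frac_bilateral: float = 0.3

    ce_normal_mean: float = 28.0
    ce_normal_sd: float = 3.5
    ce_dysplastic_mean: float = 14.5
    ce_dysplastic_sd: float = 5.0
    ai_normal_mean: float = 8.0
    ai_normal_sd: float = 4.0
    ai_dysplastic_mean: float = 18.0
    ai_dysplastic_sd: float = 6.0
    acav_female_mean: float = 22.1
    acav_female_sd: float = 5.0
    acav_male_mean: float = 16.2
    acav_male_sd: float = 4.1
    aasa_female_mean: float = 47.7
    aasa_female_sd: float = 8.9
    aasa_male_mean: float = 52.7
    aasa_male_sd: float = 8.4
    pasa_female_mean: float = 92.1
    pasa_female_sd: float = 8.2
    pasa_male_mean: float = 86.0
    pasa_male_sd: float = 6.9
    aasa_shift_dysplastic: float = -4.0
    aasa_shift_normal: float = 4.9
    pasa_shift_dysplastic: float = -3.0
    pasa_shift_normal: float = 3.7
    side_icc: float = 0.3

    arch_angle_female: float = 95.0
    arch_angle_male: float = 72.0
    arch_angle_sd: float = 6.0
    thickness_female: float = 4.2
    thickness_male: float = 5.6
    thickness_sd: float = 0.5
    scale_female: float = 1.0
    scale_male: float = 1.06
    scale_sd: float = 0.035
    femur_length_female: float = 410.0
    femur_length_male: float = 450.0
    femur_length_sd: float = 15.0
    neck_shaft_mean: float = 127.0
    neck_shaft_sd: float = 5.0
    head_radius_mean: float = 23.0
    head_radius_sd: float = 1.3

    asphericity_per_deg: float = 0.006   # per degree of CE deficit below 25
    subluxation_per_deg: float = 0.15    # mm per degree of CE deficit below 25
    spine_kappa: float = 0.35            # mm per degree of anteversion deficit
    acav_reference: float = 20.1         # cohort-mean anteversion

    noise_sd: float = 0.4
    subject_rotation_max_deg: float = 5.0
    subject_translation_max_mm: float = 10.0
    femur_rotation_max_deg: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_female > self.n_subjects:
            raise ValueError("n_female cannot exceed n_subjects")
        if not 0 <= self.frac_unilateral + self.frac_bilateral <= 1:
            raise ValueError("dysplasia fractions must lie in [0, 1] and sum to <= 1")
        for f in dataclasses.fields(self):
            if f.name.endswith("_sd") and getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown GeneratorConfig keys: {sorted(unknown)}")
        return cls(**d)


def default_config() -> GeneratorConfig:
    """The default study conditions: 75 subjects, 50 female, table-based angles."""
    return GeneratorConfig()


# ---------------------------------------------------------------------------
# surrogate construction


def _euler_rotation(angles_deg) -> np.ndarray:
    """Rotation matrix from extrinsic x-y-z Euler angles in degrees."""
    ax, ay, az = np.deg2rad(np.asarray(angles_deg, dtype=float))
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _cup_polar_limit(psi_deg: np.ndarray, hp: HipParams) -> np.ndarray:
    """Cup-cap polar extent (deg from the medial axis) per azimuth.

    Anchors: anterior (psi=0) -> AASA, superior (90) -> 90+CE,
    posterior (180) -> PASA, inferior (270) -> fixed; linear-periodic
    interpolation in between, exact at the anchors.
    """
    xs = np.array([0.0, 90.0, 180.0, 270.0, 360.0])
    ys = np.array([hp.aasa, 90.0 + hp.ce, hp.pasa, _INFERIOR_CAP_DEG, hp.aasa])
    return np.interp(np.mod(psi_deg, 360.0), xs, ys)


def _validate_hip(hp: HipParams) -> None:
    if hp.aasa + hp.pasa >= 360.0:
        raise InfeasibleParameterError(
            f"empty rim cap: AASA + PASA = {hp.aasa + hp.pasa:.1f} >= 360"
        )
    anchors = {"aasa": hp.aasa, "lateral (90+ce)": 90.0 + hp.ce, "pasa": hp.pasa}
    for name, val in anchors.items():
        if not 3.0 < val < 177.0:
            raise InfeasibleParameterError(f"cup anchor {name} = {val:.1f} outside (3, 177) deg")
    if not -60.0 < hp.acav < 60.0:
        raise InfeasibleParameterError(f"acav = {hp.acav:.1f} outside (-60, 60) deg")


def _tube(start, direction, length, radius, n_rings, n_around, e1) -> np.ndarray:
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    e1 = np.asarray(e1, float)
    e1 = e1 - (e1 @ d) * d
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    fr = np.linspace(0.0, 1.0, n_rings)
    ang = 2 * np.pi * np.arange(n_around) / n_around
    centers = np.asarray(start, float) + np.outer(fr * length, d)
    ring = radius * (np.outer(np.cos(ang), e1) + np.outer(np.sin(ang), e2))
    return (centers[:, None, :] + ring[None, :, :]).reshape(-1, 3)


def _build_pelvis_local(hp: HipParams, sp: SubjectParams) -> tuple:
    """Pelvis point set in local (lateral, anterior, superior) coords + landmarks."""
    r = hp.head_radius + _CUP_CLEARANCE
    t_bone = sp.bone_thickness
    h = np.array([_HALF_INTERHEAD + hp.subluxation, 0.0, 0.0])  # actual head centre

    blocks, landmarks = [], {}
    offset = 0

    def add(pts):
        nonlocal offset
        pts = np.atleast_2d(np.asarray(pts, float))
        blocks.append(pts)
        start = offset
        offset += len(pts)
        return start

    # cup cap: directions from the head centre; medial axis is -lateral
    psi = np.arange(_N_PSI) * (360.0 / _N_PSI)
    phimax = _cup_polar_limit(psi, hp)
    tt = np.arange(1, _N_T + 1) / (_N_T + 1)
    phi = np.deg2rad(np.outer(tt, phimax))           # (_N_T, _N_PSI)
    psir = np.deg2rad(psi)[None, :]
    dirs = np.stack(
        [-np.cos(phi), np.sin(phi) * np.cos(psir), np.sin(phi) * np.sin(psir)], axis=-1
    ).reshape(-1, 3)
    add(h + r * dirs)                                # inner layer
    add(h + (r + t_bone) * dirs)                     # outer layer

    # rim ring at full polar extent (inner radius); anchor azimuths are exact
    phir = np.deg2rad(phimax)
    rim_dirs = np.column_stack(
        [-np.cos(phir), np.sin(phir) * np.cos(np.deg2rad(psi)), np.sin(phir) * np.sin(np.deg2rad(psi))]
    )
    rim0 = add(h + r * rim_dirs)
    landmarks["rim_circle"] = np.arange(rim0, rim0 + _N_PSI)
    landmarks["anterior_rim"] = rim0 + 0                    # psi = 0
    landmarks["lateral_rim"] = rim0 + _N_PSI // 4           # psi = 90
    landmarks["posterior_rim"] = rim0 + _N_PSI // 2         # psi = 180

    # medial acetabular-roof landmark: the roof chord makes the AI angle
    lat_rim = h + r * np.array(
        [np.sin(np.deg2rad(hp.ce)), 0.0, np.cos(np.deg2rad(hp.ce))]
    )
    ai_r = np.deg2rad(hp.ai)
    roof = lat_rim - _ROOF_CHORD_FRAC * r * np.array([np.cos(ai_r), 0.0, np.sin(ai_r)])
    landmarks["medial_roof"] = add(roof)

    # wall-edge lines: the anterior->posterior wall chord realises AcAV
    th = np.deg2rad(hp.acav)
    mid = h + np.array([_WALL_OFFSET_FRAC * r, 0.0, 0.0])
    chord_dir = np.array([-np.sin(th), np.cos(th), 0.0])  # medial comp = -lateral
    a_w = mid + 0.5 * _WALL_CHORD_FRAC * r * chord_dir
    p_w = mid - 0.5 * _WALL_CHORD_FRAC * r * chord_dir
    z_off = np.linspace(-_WALL_HALF_SPAN_FRAC * r, _WALL_HALF_SPAN_FRAC * r, _N_WALL)
    a_line = a_w + np.outer(z_off, [0.0, 0.0, 1.0])
    p_line = p_w + np.outer(z_off, [0.0, 0.0, 1.0])
    a0 = add(a_line)
    p0 = add(p_line)
    landmarks["anterior_wall"] = a0 + _N_WALL // 2
    landmarks["posterior_wall"] = p0 + _N_WALL // 2

    # pubic symphysis + inferior pubic ramus at half the pubic-arch angle
    landmarks["pubic_symphysis"] = add(_SYMPHYSIS_LOCAL)
    half = np.deg2rad(0.5 * sp.pubic_arch_angle)
    ramus_dir = np.array([np.sin(half), 0.0, -np.cos(half)])
    add(_tube(_SYMPHYSIS_LOCAL, ramus_dir, 55.0, 5.0, 12, 8, e1=[0.0, 1.0, 0.0]))

    # ischial plate (two layers offset by bone thickness)
    ci = h + r * np.array([-0.4, -0.9, -1.2])
    u = np.linspace(-15.0, 15.0, 8)
    gu, gv = np.meshgrid(u, u, indexing="ij")
    plate = ci + np.stack([np.zeros_like(gu), gu, gv], axis=-1).reshape(-1, 3)
    add(plate)
    add(plate + np.array([-t_bone, 0.0, 0.0]))

    # ischial-spine bump, prominence along the posteromedial direction
    p_sp = hp.ischial_spine_prominence
    base = h + r * np.array([-0.6, -0.9, -0.2])
    spine_dir = np.array([-1.0, -1.0, 0.0]) / np.sqrt(2.0)
    e1 = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(spine_dir, e1)
    pts = []
    for s in np.linspace(0.0, 0.9, 4):
        ring_r = 3.5 * (1.0 - s)
        for a in 2 * np.pi * np.arange(5) / 5:
            pts.append(base + s * p_sp * spine_dir + ring_r * (np.cos(a) * e1 + np.sin(a) * e2))
    for s in (0.3, 0.6, 0.9):
        pts.append(base + s * p_sp * spine_dir)
    add(np.asarray(pts))
    landmarks["ischial_spine"] = add(base + p_sp * spine_dir)

    # ASIS landmark, then the iliac sheet sized to complete the point budget
    landmarks["asis"] = add(_ASIS_LOCAL)
    n_fill = PELVIS_N_POINTS - offset
    if n_fill < 2:
        raise InfeasibleParameterError("pelvis point budget exceeded")
    sheet_base = h + np.array([0.0, 0.0, 1.05 * r])
    mid_ctrl = 0.5 * (sheet_base + _ASIS_LOCAL) + np.array([15.0, -10.0, 0.0])
    k_layer = (n_fill + 1) // 2
    g = int(np.ceil(np.sqrt(k_layer)))
    gu, gv = np.meshgrid(np.linspace(0, 1, g), np.linspace(0, 1, g), indexing="ij")
    uu = gu.ravel()[:k_layer]
    vv = gv.ravel()[:k_layer]
    bez = (
        np.outer((1 - uu) ** 2, sheet_base)
        + np.outer(2 * uu * (1 - uu), mid_ctrl)
        + np.outer(uu**2, _ASIS_LOCAL)
    )
    width = 35.0 * (1.0 - 0.3 * uu)
    sheet = bez + np.outer((vv - 0.5) * width, [0.0, 1.0, 0.0])
    add(sheet + np.array([0.5 * t_bone, 0.0, 0.0]))
    add((sheet - np.array([0.5 * t_bone, 0.0, 0.0]))[: n_fill - k_layer])

    points = np.concatenate(blocks, axis=0)
    assert points.shape == (PELVIS_N_POINTS, 3)
    return points, landmarks, h


def _build_femur_local(hp: HipParams, sp: SubjectParams) -> tuple:
    """Femur point set in local (lateral, anterior, superior) coords + landmarks."""
    h = np.array([_HALF_INTERHEAD + hp.subluxation, 0.0, 0.0])
    r = hp.head_radius

    # head: sphere with a cam-like bump that vanishes on the medial (articular)
    # region, so the head-region sphere fit is exact at any asphericity
    c = _HEAD_DIRS @ _CAM_AXIS
    bump = np.where(c > _CAM_COS_SUPPORT, ((c - _CAM_COS_SUPPORT) / (1 - _CAM_COS_SUPPORT)) ** 2, 0.0)
    radii = r * (1.0 + hp.head_asphericity * bump)
    head = h + radii[:, None] * _HEAD_DIRS

    delta = np.deg2rad(sp.neck_shaft_angle - 90.0)
    neck_dir = np.array([np.cos(delta), 0.0, -np.sin(delta)])
    neck_len = _NECK_LENGTH_FRAC * sp.femur_length
    neck = _tube(h + 0.7 * r * neck_dir, neck_dir, neck_len - 0.7 * r, 0.62 * r, 8, 10, e1=[0.0, 1.0, 0.0])

    troch = h + neck_len * neck_dir
    shaft_radius = 13.5 * sp.femur_length / 430.0
    shaft = _tube(troch, [0.0, 0.0, -1.0], _SHAFT_LENGTH_FRAC * sp.femur_length, shaft_radius, 18, 20, e1=[1.0, 0.0, 0.0])

    points = np.concatenate([head, neck, shaft], axis=0)
    assert points.shape == (FEMUR_N_POINTS, 3)
    landmarks = {
        "head": _HEAD_REGION_IDX.copy(),
        "neck": np.arange(len(head), len(head) + len(neck)),
        "shaft": np.arange(len(head) + len(neck), FEMUR_N_POINTS),
    }
    return points, landmarks, h


def _to_world(points_local: np.ndarray, side: str) -> np.ndarray:
    """Map local (lateral, anterior, superior) coords to the world frame."""
    out = points_local.copy()
    if side == "L":
        out[:, 0] = -out[:, 0]
    return out


def build_subject(params: SubjectParams) -> Subject:
    """Build one subject's four surrogate bones deterministically.

    Ground-truth angles are the requested per-hip angles (the construction
    realises them exactly); they are recorded before pose jitter and noise.
    """
    for side in SIDES:
        _validate_hip(params.hip(side))
    if params.global_scale <= 0:
        raise InfeasibleParameterError("global_scale must be > 0")
    if not 20.0 < params.pubic_arch_angle < 170.0:
        raise InfeasibleParameterError("pubic_arch_angle outside (20, 170) deg")

    shapes = {}
    head_centers = {}
    for side in SIDES:
        hp = params.hip(side)
        p_pts, p_lm, h_local = _build_pelvis_local(hp, params)
        f_pts, f_lm, _ = _build_femur_local(hp, params)
        shapes[f"pelvis_{side}"] = (_to_world(p_pts, side), p_lm)
        shapes[f"femur_{side}"] = (_to_world(f_pts, side), f_lm)
        head_centers[side] = _to_world(h_local[None, :], side)[0]

    s = params.global_scale
    R_subj = _euler_rotation(params.subject_rotation_deg)
    t_subj = np.asarray(params.subject_translation_mm, float)
    rng = np.random.default_rng(params.seed)

    out_shapes = {}
    for bone in ("pelvis_L", "pelvis_R", "femur_L", "femur_R"):
        pts, lm = shapes[bone]
        pts = s * pts
        if bone.startswith("femur"):
            side = bone[-1]
            hc = s * head_centers[side]
            R_f = _euler_rotation(params.femur_rotation_deg[side])
            pts = (pts - hc) @ R_f.T + hc
        pts = pts @ R_subj.T + t_subj
        if params.noise_sd > 0:
            pts = pts + rng.normal(0.0, params.noise_sd, pts.shape)
        out_shapes[bone] = CorrespondedShape(bone, pts, lm)

    true_angles = {
        side: AngleSet(
            ce=params.hip(side).ce,
            ai=params.hip(side).ai,
            acav=params.hip(side).acav,
            aasa=params.hip(side).aasa,
            pasa=params.hip(side).pasa,
        )
        for side in SIDES
    }
    dysplasia = {side: bool(true_angles[side].ce < 25.0) for side in SIDES}
    return Subject(
        subject_id=params.subject_id,
        sex=params.sex,
        shapes=out_shapes,
        true_angles=true_angles,
        dysplasia=dysplasia,
        params=params,
    )


# ---------------------------------------------------------------------------
# cohort sampling


def _draw_truncated(rng, mean, sd, lo, hi, shared, icc):
    """One correlated draw ``mean + sd*(sqrt(icc)*shared + sqrt(1-icc)*z)``
    with the side-level component ``z`` drawn from the exact truncated
    conditional (inverse-CDF sampling), so stratum bounds always hold."""
    from scipy.stats import norm

    if sd == 0.0:
        if not (lo <= mean < hi):
            raise GenerationError(f"degenerate draw: mean {mean} outside [{lo}, {hi})")
        return float(mean)
    mu_c = mean + sd * np.sqrt(icc) * shared
    s_c = sd * np.sqrt(1.0 - icc)
    if s_c == 0.0:
        if not (lo <= mu_c < hi):
            raise GenerationError(f"degenerate draw: conditional mean {mu_c} outside [{lo}, {hi})")
        return float(mu_c)
    a = norm.cdf((lo - mu_c) / s_c)
    b = norm.cdf((hi - mu_c) / s_c)
    if b - a < 1e-14:
        raise GenerationError(f"truncation interval [{lo}, {hi}) has no mass around {mu_c}")
    u = rng.uniform(a, b)
    return float(mu_c + s_c * norm.ppf(u))


def _sample_one(cfg: GeneratorConfig, i: int, rng: np.random.Generator) -> SubjectParams:
    sex = "F" if i < cfg.n_female else "M"
    u = rng.uniform()
    if u < cfg.frac_unilateral:
        dys_side = "L" if rng.uniform() < 0.5 else "R"
        dys = {s: (s == dys_side) for s in SIDES}
    elif u < cfg.frac_unilateral + cfg.frac_bilateral:
        dys = {"L": True, "R": True}
    else:
        dys = {"L": False, "R": False}

    icc = cfg.side_icc
    z_ce, z_ai, z_av, z_aa, z_pa = rng.standard_normal(5)

    hips = {}
    for side in SIDES:
        d = dys[side]
        ce = _draw_truncated(
            rng,
            cfg.ce_dysplastic_mean if d else cfg.ce_normal_mean,
            cfg.ce_dysplastic_sd if d else cfg.ce_normal_sd,
            -20.0 if d else 25.0,
            25.0 if d else 60.0,
            z_ce,
            icc,
        )
        ai = _draw_truncated(
            rng,
            cfg.ai_dysplastic_mean if d else cfg.ai_normal_mean,
            cfg.ai_dysplastic_sd if d else cfg.ai_normal_sd,
            -15.0,
            50.0,
            z_ai,
            icc,
        )
        acav = _draw_truncated(
            rng,
            cfg.acav_female_mean if sex == "F" else cfg.acav_male_mean,
            cfg.acav_female_sd if sex == "F" else cfg.acav_male_sd,
            -40.0,
            55.0,
            z_av,
            icc,
        )
        aasa = _draw_truncated(
            rng,
            (cfg.aasa_female_mean if sex == "F" else cfg.aasa_male_mean)
            + (cfg.aasa_shift_dysplastic if d else cfg.aasa_shift_normal),
            cfg.aasa_female_sd if sex == "F" else cfg.aasa_male_sd,
            10.0,
            120.0,
            z_aa,
            icc,
        )
        pasa = _draw_truncated(
            rng,
            (cfg.pasa_female_mean if sex == "F" else cfg.pasa_male_mean)
            + (cfg.pasa_shift_dysplastic if d else cfg.pasa_shift_normal),
            cfg.pasa_female_sd if sex == "F" else cfg.pasa_male_sd,
            30.0,
            160.0,
            z_pa,
            icc,
        )
        deficit = max(0.0, 25.0 - ce)
        hips[side] = HipParams(
            ce=ce,
            ai=ai,
            acav=acav,
            aasa=aasa,
            pasa=pasa,
            head_radius=max(15.0, rng.normal(cfg.head_radius_mean, cfg.head_radius_sd)),
            head_asphericity=cfg.asphericity_per_deg * deficit,
            subluxation=cfg.subluxation_per_deg * deficit,
            ischial_spine_prominence=max(0.0, cfg.spine_kappa * (cfg.acav_reference - acav)),
        )

    a = cfg.subject_rotation_max_deg
    t = cfg.subject_translation_max_mm
    f = cfg.femur_rotation_max_deg
    return SubjectParams(
        subject_id=f"S{i + 1:03d}",
        sex=sex,
        global_scale=max(0.8, rng.normal(cfg.scale_female if sex == "F" else cfg.scale_male, cfg.scale_sd)),
        bone_thickness=max(2.0, rng.normal(cfg.thickness_female if sex == "F" else cfg.thickness_male, cfg.thickness_sd)),
        pubic_arch_angle=float(
            np.clip(rng.normal(cfg.arch_angle_female if sex == "F" else cfg.arch_angle_male, cfg.arch_angle_sd), 25.0, 165.0)
        ),
        femur_length=max(300.0, rng.normal(cfg.femur_length_female if sex == "F" else cfg.femur_length_male, cfg.femur_length_sd)),
        neck_shaft_angle=float(np.clip(rng.normal(cfg.neck_shaft_mean, cfg.neck_shaft_sd), 110.0, 145.0)),
        left=hips["L"],
        right=hips["R"],
        subject_rotation_deg=tuple(rng.uniform(-a, a, 3)),
        subject_translation_mm=tuple(rng.uniform(-t, t, 3)),
        femur_rotation_deg={s: tuple(rng.uniform(-f, f, 3)) for s in SIDES},
        noise_sd=cfg.noise_sd,
        seed=int(rng.integers(2**31)),
    )


def sample_subject_params(config: GeneratorConfig) -> list:
    """Draw per-subject parameters; per-subject seeds come from a counter-based
    split of the master seed, so results do not depend on generation order."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    return [
        _sample_one(config, i, np.random.default_rng(children[i]))
        for i in range(config.n_subjects)
    ]


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a full synthetic cohort with ground truth retained.

    Infeasible parameter draws are resampled (at most 100 attempts per
    subject) before a :class:`GenerationError` is raised.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    subjects = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng(children[i])
        last_err = None
        for _ in range(100):
            try:
                subjects.append(build_subject(_sample_one(config, i, rng)))
                break
            except InfeasibleParameterError as err:  # pragma: no cover - rare
                last_err = err
        else:
            raise GenerationError(
                f"subject {i}: no feasible parameters after 100 attempts ({last_err})"
            )
    return Cohort(subjects=subjects, config=config)


def angle_table(source) -> "pandas.DataFrame":
    """Long-format ground-truth angle table (one row per hip).

    ``source`` may be a :class:`Cohort`, a list of :class:`SubjectParams`
    (fast path: no shapes are built), or a :class:`GeneratorConfig`.
    Columns: subject_id, side, sex, dysplasia, ce, ai, acav, aasa, pasa, hasa.
    """
    import pandas as pd

    if isinstance(source, GeneratorConfig):
        source = sample_subject_params(source)
    rows = []
    for item in source:
        if isinstance(item, Subject):
            sid, sex = item.subject_id, item.sex
            angle_of = {s: item.true_angles[s] for s in SIDES}
        else:
            sid, sex = item.subject_id, item.sex
            angle_of = {
                s: AngleSet(
                    ce=item.hip(s).ce, ai=item.hip(s).ai, acav=item.hip(s).acav,
                    aasa=item.hip(s).aasa, pasa=item.hip(s).pasa,
                )
                for s in SIDES
            }
        for side in SIDES:
            ang = angle_of[side]
            rows.append(
                {"subject_id": sid, "side": side, "sex": sex, "dysplasia": ang.ce < 25.0,
                 **{k: getattr(ang, k) for k in ANGLE_NAMES}}
            )
    return pd.DataFrame(rows)
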