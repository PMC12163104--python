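"""Computational analogs of the six diagnostic hip angles.

The manual radiographic measurements these functions emulate are defined on
standardised supine scans; here each subject carries its own anatomical frame
built from the anterior-pelvic-plane landmarks (ASIS, pubic symphysis) and
the inter-head line, which makes every angle exactly invariant to rigid
whole-subject pose and to global scale:

* lateral axis: own head centre -> away from the contralateral head centre;
* superior axis: symphysis -> ASIS direction, orthogonalised to lateral;
* anterior axis: symphysis direction off the inter-head midpoint,
  orthogonalised to both.

Definitions (all signs chosen so coverage and anteversion are positive for
normal anatomy on either side):

* CE: coronal-plane angle between the superior axis and the ray from the
  femoral head centre (sphere fit on the articular head region) to the
  lateral acetabular rim landmark.
* AI: coronal-plane inclination of the roof chord (medial roof landmark ->
  lateral rim landmark) relative to the transverse axis.
* AcAV: axial-plane angle between the posterior->anterior wall-edge chord
  and the sagittal axis; smaller values mean a more retroverted acetabulum.
* AASA / PASA: axial-plane angles at the head centre between the line
  toward the contralateral head centre and the ray to the anterior /
  posterior sector-rim landmark. HASA is their sum by definition.
"""

from __future__ import annotations

import numpy as np

from .core import AngleSet, CorrespondedShape
from .geometry import fit_sphere

__all__ = ["AngleSet", "DYSPLASIA_CE_THRESHOLD", "measure_angles", "classify_dysplasia", "head_center"]

DYSPLASIA_CE_THRESHOLD = 25.0

_REQUIRED_PELVIS_LANDMARKS = (
    "asis",
    "pubic_symphysis",
    "lateral_rim",
    "medial_roof",
    "anterior_rim",
    "posterior_rim",
    "anterior_wall",
    "posterior_wall",
)


def head_center(femur: CorrespondedShape) -> np.ndarray:
    """Femoral head centre: algebraic sphere fit on the head-region points."""
    if "head" not in femur.landmark_index_map:
        raise ValueError(f"{femur.bone_id}: missing 'head' region landmark")
    region = femur.region("head")
    if len(region) < 4:
        raise ValueError(f"{femur.bone_id}: head region has {len(region)} < 4 points")
    return fit_sphere(region).center


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("degenerate anatomical frame: zero-length axis")
    return v / n


def measure_angles(
    pelvis: CorrespondedShape,
    femur: CorrespondedShape,
    contralateral_head_center,
    side: str,
) -> AngleSet:
    """Measure CE, AI, AcAV, AASA, PASA (and hence HASA) for one hip.

    ``contralateral_head_center`` is required because the sector angles are
    defined off the inter-head line; a subject missing one femur is not
    measurable.
    """
    if side not in ("L", "R"):
        raise ValueError(f"side must be 'L' or 'R', got {side!r}")
    missing = [n for n in _REQUIRED_PELVIS_LANDMARKS if n not in pelvis.landmark_index_map]
    if missing:
        raise ValueError(f"{pelvis.bone_id}: missing landmarks {missing}")

    h = head_center(femur)
    h_contra = np.asarray(contralateral_head_center, dtype=float).reshape(3)

    # per-subject anatomical frame
    u_lat = _unit(h - h_contra)
    asis = pelvis.landmark("asis")
    sym = pelvis.landmark("pubic_symphysis")
    v_sa = asis - sym
    u_sup = _unit(v_sa - (v_sa @ u_lat) * u_lat)
    m = sym - 0.5 * (h + h_contra)
    u_ant = _unit(m - (m @ u_lat) * u_lat - (m @ u_sup) * u_sup)
    u_med = -u_lat

    # coronal-plane angles (project out the anterior component)
    d = pelvis.landmark("lateral_rim") - h
    ce = np.degrees(np.arctan2(d @ u_lat, d @ u_sup))
    e = pelvis.landmark("lateral_rim") - pelvis.landmark("medial_roof")
    ai = np.degrees(np.arctan2(e @ u_sup, e @ u_lat))

    # axial-plane angles (project out the superior component)
    a = pelvis.landmark("anterior_rim") - h
    aasa = np.degrees(np.arctan2(a @ u_ant, a @ u_med))
    p = pelvis.landmark("posterior_rim") - h
    pasa = np.degrees(np.arctan2(-(p @ u_ant), p @ u_med))
    w = pelvis.landmark("anterior_wall") - pelvis.landmark("posterior_wall")
    acav = np.degrees(np.arctan2(w @ u_med, w @ u_ant))

    return AngleSet(ce=ce, ai=ai, acav=acav, aasa=aasa, pasa=pasa)


def classify_dysplasia(angle_set: AngleSet) -> bool:
    """Hip dysplasia diagnosis: centre-edge angle strictly below 25 degrees."""
    return bool(angle_set.ce < DYSPLASIA_CE_THRESHOLD)


def measure_subject(shapes: dict) -> dict:
    """Measure both hips of one subject from its four bone shapes.

    ``shapes`` maps bone ids to :class:`CorrespondedShape`; returns
    ``{"L": AngleSet, "R": AngleSet}``.
    """
    centers = {side: head_center(shapes[f"femur_{side}"]) for side in ("L", "R")}
    return {
        side: measure_angles(
            shapes[f"pelvis_{side}"],
            shapes[f"femur_{side}"],
            centers["R" if side == "L" else "L"],
            side,
        )
        for side in ("L", "R")
    }
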