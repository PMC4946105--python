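"""Cross-round relocation via the snick fiducial and cytomorphological CTC calls.

The fluorescence round and the brightfield (or FISH) round of the same spot
are registered by fitting a rigid transform between the snick outlines
detected in each round.  Morphometrics are then computed on the brightfield
crops and two rule sets are applied:

* epithelial CTC — all five of: intact nucleus, CD45 negativity,
  epithelial-marker positivity, nucleus diameter strictly greater than
  1.5 pore diameters (12 um), visible cytoplasm;
* marker-negative CTC — nucleus diameter of at least two pore diameters
  (16 um, inclusive), nuclear irregularity and a high
  nuclear-to-cytoplasmic ratio.

Note the deliberately asymmetric boundaries: the 12-um rule is strict while
the 16-um marker-negative rule is inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import convex_hull_image

from ctcscan.phenotype import ClassificationThresholds, GalleryRecord


class FiducialError(ValueError):
    """Snick outline missing or unusable."""


class AmbiguousFiducialError(FiducialError):
    """The fiducial is symmetric: orientation cannot be resolved."""


class WrongRuleBranchError(ValueError):
    """Marker-negative rule applied to a marker-positive record."""


@dataclass
class RigidTransform:
    """Planar isometry ``p -> R(theta) p + t`` (optional mirror first)."""

    rotation_deg: float
    translation_um: np.ndarray
    mirror: bool = False

    def matrix(self) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        r = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        if self.mirror:
            r = r @ np.diag([1.0, -1.0])
        return r

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix().T + np.asarray(self.translation_um, dtype=float)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix()),
                                          -np.linalg.inv(self.matrix()) @ np.asarray(self.translation_um, dtype=float))

    @classmethod
    def from_matrix(cls, m: np.ndarray, t: np.ndarray) -> "RigidTransform":
        """Decompose an orthogonal 2x2 matrix (det +-1) plus translation."""
        mirror = bool(np.linalg.det(m) < 0)
        r = m @ np.diag([1.0, -1.0]) if mirror else m
        th = math.degrees(math.atan2(r[1, 0], r[0, 0]))
        return cls(rotation_deg=th, translation_um=np.asarray(t, dtype=float), mirror=mirror)


def _kabsch(a: np.ndarray, b: np.ndarray, allow_mirror: bool) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit mapping points ``a`` onto ``b`` (known order)."""
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    aa, bb = a - ca, b - cb
    h = aa.T @ bb
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d < 0 and not allow_mirror:
        s = np.diag([1.0, -1.0])
        r = vt.T @ s @ u.T
    else:
        r = vt.T @ u.T
    t = cb - r @ ca
    res = a @ r.T + t - b
    rms = float(np.sqrt((res**2).sum(axis=1).mean()))
    return r, t, rms


def register_rounds(
    snick_outline_a: np.ndarray | None,
    snick_outline_b: np.ndarray | None,
    allow_mirror: bool = False,
    ambiguity_ratio: float = 0.02,
) -> tuple[RigidTransform, float]:
    """Fit the rigid transform taking round-A coordinates to round-B.

    Outlines are corresponding polyline point sets (same sampling).  Returns
    the transform and the residual fiducial RMS distance in micrometres.
    A symmetric fiducial — one whose reversed outline also fits well — is
    rejected with :class:`AmbiguousFiducialError` since it cannot resolve
    orientation.
    """
    if snick_outline_a is None or snick_outline_b is None:
        raise FiducialError("snick outline not detected in one of the rounds")
    a = np.atleast_2d(np.asarray(snick_outline_a, dtype=float))
    b = np.atleast_2d(np.asarray(snick_outline_b, dtype=float))
    if a.shape != b.shape or a.shape[0] < 3:
        raise FiducialError(f"outlines must match and have >= 3 points, got {a.shape} vs {b.shape}")
    r, t, rms = _kabsch(a, b, allow_mirror)
    scale = float(np.linalg.norm(a - a.mean(axis=0), axis=1).max())
    # a self-congruent (symmetric) outline cannot resolve orientation
    _, _, rms_self = _kabsch(a[::-1], a, allow_mirror=True)
    if rms_self <= ambiguity_ratio * scale:
        raise AmbiguousFiducialError(
            f"fiducial is symmetric (self-congruence RMS {rms_self:.3g} um); cannot resolve orientation"
        )
    return RigidTransform.from_matrix(r, t), rms


# ---------------------------------------------------------------------------
# morphometrics


@dataclass
class Morphometrics:
    nucleus_diameter_um: float
    nc_ratio: float  # nuclear area / cytoplasmic area
    irregularity: float  # 1 - solidity, 0 = convex
    cytoplasm_present: bool
    nucleus_intact: bool

    def __post_init__(self) -> None:
        if self.nc_ratio < 0:
            raise ValueError("nc_ratio must be >= 0")
        if not (0.0 <= self.irregularity <= 1.0):
            raise ValueError("irregularity must be within [0, 1]")


def cytoplasm_mask_from_brightfield(brightfield: np.ndarray, nuclear_mask: np.ndarray) -> np.ndarray:
    """Whole-cell mask from a brightfield crop (stained cell darker than
    membrane); keeps the component overlapping the nucleus."""
    bf = np.asarray(brightfield, dtype=float)
    thr = threshold_otsu(bf)
    cell = bf < thr
    cell |= nuclear_mask
    labels, _ = ndi.label(cell)
    keep = np.unique(labels[nuclear_mask])
    keep = keep[keep > 0]
    if keep.size == 0:
        return nuclear_mask.copy()
    return np.isin(labels, keep)


def compute_morphometrics(
    nuclear_mask: np.ndarray,
    cell_mask: np.ndarray | None = None,
    brightfield: np.ndarray | None = None,
    pixel_size_um: float = 0.5,
    min_cytoplasm_fraction: float = 0.2,
    require_cytoplasm: bool = False,
) -> Morphometrics:
    """Morphometrics of one nucleus.

    ``nucleus_diameter_um`` is the equivalent-circle diameter;
    ``nc_ratio = nuclear area / cytoplasmic area`` with the cytoplasm being
    the cell mask minus the nucleus; ``irregularity = 1 - solidity``.
    A "well-defined cytoplasm" means cytoplasm area above
    ``min_cytoplasm_fraction`` of the nuclear area.  "Nucleus intact" is a
    heuristic: single connected component not truncated by the crop edge.
    """
    nuc = np.asarray(nuclear_mask, dtype=bool)
    if not nuc.any():
        raise ValueError("nuclear mask is empty")
    if cell_mask is None:
        cell_mask = cytoplasm_mask_from_brightfield(brightfield, nuc) if brightfield is not None else nuc
    cell = np.asarray(cell_mask, dtype=bool) | nuc

    nuc_area_px = int(nuc.sum())
    cyto_area_px = int(cell.sum()) - nuc_area_px
    area_um2 = nuc_area_px * pixel_size_um**2
    diameter = 2.0 * math.sqrt(area_um2 / math.pi)
    nc_ratio = float("inf") if cyto_area_px == 0 else nuc_area_px / cyto_area_px
    cytoplasm_present = cyto_area_px > min_cytoplasm_fraction * nuc_area_px
    if require_cytoplasm and cyto_area_px == 0:
        raise ValueError("cytoplasm requested but the cell mask adds no pixels beyond the nucleus")

    hull = convex_hull_image(nuc)
    irregularity = float(np.clip(1.0 - nuc_area_px / max(int(hull.sum()), 1), 0.0, 1.0))

    _, n_comp = ndi.label(nuc)
    edge_touch = nuc[0, :].any() or nuc[-1, :].any() or nuc[:, 0].any() or nuc[:, -1].any()
    nucleus_intact = n_comp == 1 and not edge_touch

    return Morphometrics(
        nucleus_diameter_um=diameter,
        nc_ratio=nc_ratio,
        irregularity=irregularity,
        cytoplasm_present=cytoplasm_present,
        nucleus_intact=nucleus_intact,
    )


# ---------------------------------------------------------------------------
# CTC calls


@dataclass
class CtcCall:
    is_ctc: bool
    breakdown: dict[str, bool] = field(default_factory=dict)


EPITHELIAL_MIN_DIAMETER_UM = 12.0  # 1.5 pore diameters, strict
MARKERNEG_MIN_DIAMETER_UM = 16.0  # two pore diameters, inclusive


def call_epithelial_ctc(
    record: GalleryRecord,
    morph: Morphometrics,
    thresholds: ClassificationThresholds,
    cd45_max: float,
    min_diameter_um: float = EPITHELIAL_MIN_DIAMETER_UM,
) -> CtcCall:
    """Five-criteria epithelial CTC call with a per-criterion breakdown."""
    if morph is None:
        raise ValueError("morphometrics are required for the epithelial CTC call")
    breakdown = {
        "i_nucleus_intact": bool(morph.nucleus_intact),
        "ii_cd45_negative": bool(record.sec_avg_int <= cd45_max),
        "iii_epithelial_positive": bool(record.ter_avg_int > thresholds.epithelial_min),
        "iv_diameter_gt_12um": bool(morph.nucleus_diameter_um > min_diameter_um),
        "v_cytoplasm_present": bool(morph.cytoplasm_present),
    }
    return CtcCall(is_ctc=all(breakdown.values()), breakdown=breakdown)


def call_markerneg_ctc(
    record: GalleryRecord,
    morph: Morphometrics,
    thresholds: ClassificationThresholds,
    irregularity_min: float = 0.05,
    nc_ratio_min: float = 2.0,
    min_diameter_um: float = MARKERNEG_MIN_DIAMETER_UM,
) -> CtcCall:
    """Three-criteria call for CTCs without epithelial/mesenchymal markers."""
    if morph is None:
        raise ValueError("morphometrics are required for the marker-negative CTC call")
    if record.ter_avg_int > thresholds.epithelial_min or record.quat_avg_int > thresholds.mesenchymal_min:
        raise WrongRuleBranchError(
            "marker-negative rule applied to a marker-positive record; use the epithelial rule"
        )
    breakdown = {
        "i_diameter_ge_16um": bool(morph.nucleus_diameter_um >= min_diameter_um),
        "ii_irregular_nucleus": bool(morph.irregularity >= irregularity_min),
        "iii_high_nc_ratio": bool(morph.nc_ratio >= nc_ratio_min),
    }
    return CtcCall(is_ctc=all(breakdown.values()), breakdown=breakdown)
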