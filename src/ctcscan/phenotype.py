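"""Eight-category phenotype classification and the reviewable image gallery.

Selected DAPI+/CD45- elements are binned by marker expression, nucleus size
and cluster composition:

* single cells: E+/M-, E+/M+, E-/M+, then marker-negative cells split on
  equivalent nucleus diameter strictly greater than 16 um (two pore
  diameters) into E-/M- >2pores and E-/M- <2pores;
* merged objects: CTC clusters (>= 4 CD45- constituents, none CD45+),
  mixed clusters (>= 4 constituents with both CD45- and CD45+ members) and
  microclusters (exactly 3 CD45- constituents).

Merged objects of exactly two CD45- constituents fall between the single
cell and the microcluster definitions; they are reported explicitly as
``uncategorized-pair`` instead of being silently binned.  Merged objects
failing every cluster definition (e.g. pure CD45+ clumps passing the
cluster area gate) fall back to the single-cell rules on their merged
measurements, keeping the partition exhaustive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from ctcscan.image import CD45, DAPI, EPITHELIAL, MESENCHYMAL, ChannelImage
from ctcscan.segment import (
    CLUSTER_CANDIDATE,
    BackgroundEstimate,
    CellCandidate,
    ClusterInfo,
)


class MissingConstituentsError(ValueError):
    """A cluster object was classified without constituent counts."""


class ReviewLockedError(RuntimeError):
    """Attempt to modify a gallery record already confirmed."""


class CellCategory(enum.Enum):
    E_POS_M_NEG = "E+/M-"
    E_POS_M_POS = "E+/M+"
    E_NEG_M_POS = "E-/M+"
    E_NEG_M_NEG_LARGE = "E-/M- >2pores"
    E_NEG_M_NEG_SMALL = "E-/M- <2pores"
    CTC_CLUSTER = "CTC-cluster"
    MIXED_CLUSTER = "mixed-cluster"
    MICROCLUSTER = "microcluster"
    # documented gap: two CD45- constituents fit none of the eight categories
    UNCATEGORIZED_PAIR = "uncategorized-pair"


#: the eight mutually exclusive, exhaustive categories
EIGHT_CATEGORIES = tuple(c for c in CellCategory if c is not CellCategory.UNCATEGORIZED_PAIR)


@dataclass
class ClassificationThresholds:
    """Marker positivity cutoffs and size/count rules for classification."""

    epithelial_min: float = 20.0
    mesenchymal_min: float = 20.0
    two_pore_diameter_um: float = 16.0
    cluster_min_cells: int = 4
    microcluster_cells: int = 3

    def __post_init__(self) -> None:
        if self.cluster_min_cells <= self.microcluster_cells:
            raise ValueError("cluster_min_cells must exceed microcluster_cells")

    @classmethod
    def from_background(
        cls,
        backgrounds: dict[str, BackgroundEstimate],
        sigmas: float = 3.0,
        **kwargs,
    ) -> "ClassificationThresholds":
        """Positivity = mean above background + ``sigmas`` * background sd."""
        return cls(
            epithelial_min=backgrounds[EPITHELIAL].mean + sigmas * backgrounds[EPITHELIAL].sd,
            mesenchymal_min=backgrounds[MESENCHYMAL].mean + sigmas * backgrounds[MESENCHYMAL].sd,
            **kwargs,
        )


def classify_candidate(
    candidate: CellCandidate,
    thresholds: ClassificationThresholds,
    cluster: ClusterInfo | None = None,
) -> CellCategory:
    """Assign exactly one category to a selected element.

    ``cluster`` must be provided for candidates flagged as cluster
    candidates; omitting it raises :class:`MissingConstituentsError`.
    """
    if candidate.flag == CLUSTER_CANDIDATE and cluster is None:
        raise MissingConstituentsError(
            f"candidate {candidate.id} is a cluster object but no constituent counts were given"
        )
    if cluster is not None:
        neg, pos = cluster.n_cd45_negative, cluster.n_cd45_positive
        if neg >= thresholds.cluster_min_cells and pos == 0:
            return CellCategory.CTC_CLUSTER
        if neg + pos >= thresholds.cluster_min_cells and neg >= 1 and pos >= 1:
            return CellCategory.MIXED_CLUSTER
        if neg == thresholds.microcluster_cells:
            return CellCategory.MICROCLUSTER
        if neg == 2:
            return CellCategory.UNCATEGORIZED_PAIR
        # degenerate cluster object: fall through to single-cell rules
    if not candidate.measured:
        raise ValueError(f"candidate {candidate.id} must be measured before classification")
    epi = candidate.epithelial_avg > thresholds.epithelial_min
    mes = candidate.mesenchymal_avg > thresholds.mesenchymal_min
    if epi and not mes:
        return CellCategory.E_POS_M_NEG
    if epi and mes:
        return CellCategory.E_POS_M_POS
    if mes:
        return CellCategory.E_NEG_M_POS
    # strict: a diameter of exactly 16 um goes to the "<2 pores" branch
    if candidate.equiv_diameter_um > thresholds.two_pore_diameter_um:
        return CellCategory.E_NEG_M_NEG_LARGE
    return CellCategory.E_NEG_M_NEG_SMALL


# ---------------------------------------------------------------------------
# gallery

PENDING = "pending"
CONFIRMED = "confirmed"
REJECTED = "rejected"
REVIEW_STATUSES = (PENDING, CONFIRMED, REJECTED)


@dataclass
class GalleryRecord:
    """One reviewable gallery row: crops plus the five characteristics."""

    candidate_id: int
    category: CellCategory
    crops: dict[str, np.ndarray]
    area_um2: float
    equiv_diameter_um: float
    centroid_um: tuple[float, float]
    avg_int: float  # DAPI
    avg_int_bg: float  # background
    sec_avg_int: float  # CD45
    ter_avg_int: float  # epithelial / AF488
    quat_avg_int: float  # mesenchymal / AF546
    review_status: str = PENDING

    def set_review(self, status: str) -> None:
        if status not in REVIEW_STATUSES:
            raise ValueError(f"unknown review status {status!r}")
        if self.review_status == CONFIRMED and status != CONFIRMED:
            raise ReviewLockedError(f"record {self.candidate_id} is confirmed and immutable")
        self.review_status = status


def build_gallery(
    classified: list[tuple[CellCandidate, CellCategory]],
    channels: dict[str, ChannelImage],
    margin_um: float = 5.0,
) -> list[GalleryRecord]:
    """One record per selected element, with per-channel crops.

    Crops cover the candidate bounding box plus a fixed margin, clipped to
    the image; a missing channel raises ``KeyError``.
    """
    for role in (DAPI, CD45, EPITHELIAL, MESENCHYMAL):
        if role not in channels:
            raise KeyError(f"channel {role!r} required for gallery crops")
    records: list[GalleryRecord] = []
    if not classified:
        return records
    ps = channels[DAPI].require_pixel_size()
    margin_px = int(round(margin_um / ps))
    ny, nx = channels[DAPI].shape
    for cand, category in classified:
        if not cand.measured:
            raise ValueError(f"candidate {cand.id} must be measured before gallery build")
        r0, c0, r1, c1 = cand.bbox
        r0, c0 = max(0, r0 - margin_px), max(0, c0 - margin_px)
        r1, c1 = min(ny, r1 + margin_px), min(nx, c1 + margin_px)
        crops = {role: np.array(channels[role].data[r0:r1, c0:c1]) for role in channels}
        records.append(
            GalleryRecord(
                candidate_id=cand.id,
                category=category,
                crops=crops,
                area_um2=cand.nucleus_area_um2,
                equiv_diameter_um=cand.equiv_diameter_um,
                centroid_um=cand.centroid_um,
                avg_int=cand.dapi_avg,
                avg_int_bg=cand.background_avg,
                sec_avg_int=cand.cd45_avg,
                ter_avg_int=cand.epithelial_avg,
                quat_avg_int=cand.mesenchymal_avg,
            )
        )
    return records
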