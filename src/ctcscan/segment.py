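"""DAPI+ nucleus segmentation, candidate measurement and CD45- selection.

The automated selection applies three criteria to each segmented object —
DAPI intensity, CD45 intensity, nuclear area strictly greater than 55 um^2
(one 8-um pore is ~50 um^2) — plus a fourth cluster criterion: objects with
nuclear area strictly greater than 150 um^2 (three pore-equivalents) are
kept regardless of CD45, so mixed clusters containing CD45+ members are not
lost.  Boundary semantics are strict: area exactly 55 (or 150) um^2 fails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from ctcscan.image import CD45, DAPI, EPITHELIAL, MESENCHYMAL, ChannelImage


class UnmeasuredCandidateError(ValueError):
    """Selection was applied to a candidate whose intensities are unmeasured."""


class EmptyBackgroundError(ValueError):
    """No background pixels remain after exclusion."""


def pore_equivalent_area_um2(pore_diameter_um: float = 8.0, rounded: bool = True) -> float:
    """Cross-sectional area of one circular pore; 8 um -> 50 um^2 (rounded).

    This is the area unit anchoring the nuclear-area gates: the single-cell
    gate is just above one pore-equivalent, the cluster gate equals three.
    """
    area = math.pi * (pore_diameter_um / 2.0) ** 2
    return float(round(area)) if rounded else area


@dataclass
class SelectionGates:
    """Tunable gates of the automated DAPI+/CD45- selection.

    ``dapi_min`` / ``cd45_max`` default to ``None`` and are resolved against
    measured background statistics (``background + 5 sd`` and
    ``background + 3 sd`` respectively) via :meth:`resolve`.
    """

    dapi_min: float | None = None
    cd45_max: float | None = None
    area_min_um2: float = 55.0
    cluster_area_min_um2: float = 3.0 * pore_equivalent_area_um2()
    pore_area_um2: float = pore_equivalent_area_um2()

    def __post_init__(self) -> None:
        if self.area_min_um2 <= 0 or self.cluster_area_min_um2 <= 0:
            raise ValueError("area gates must be positive")
        if self.cluster_area_min_um2 <= self.area_min_um2:
            raise ValueError("cluster_area_min_um2 must exceed area_min_um2")

    def resolve(self, backgrounds: dict[str, "BackgroundEstimate"]) -> "SelectionGates":
        """Fill intensity gates from background statistics where unset."""
        dapi_min = self.dapi_min
        cd45_max = self.cd45_max
        if dapi_min is None:
            bg = backgrounds[DAPI]
            dapi_min = bg.mean + 5.0 * bg.sd
        if cd45_max is None:
            bg = backgrounds[CD45]
            cd45_max = bg.mean + 3.0 * bg.sd
        return SelectionGates(
            dapi_min=dapi_min,
            cd45_max=cd45_max,
            area_min_um2=self.area_min_um2,
            cluster_area_min_um2=self.cluster_area_min_um2,
            pore_area_um2=self.pore_area_um2,
        )


SINGLE = "single"
CLUSTER_CANDIDATE = "cluster-candidate"


@dataclass
class CellCandidate:
    """A segmented DAPI+ object and its gallery characteristics.

    Intensity fields mirror the gallery columns: ``dapi_avg`` (Avg_Int),
    ``background_avg`` (Avg_Int_Bg), ``cd45_avg`` (Sec_Avg_Int),
    ``epithelial_avg`` (Ter_Avg_Int), ``mesenchymal_avg`` (Quat_Avg_Int).
    """

    id: int
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    mask: np.ndarray  # boolean patch of shape (row1-row0, col1-col0)
    centroid_um: tuple[float, float]  # (x, y)
    nucleus_area_um2: float
    equiv_diameter_um: float
    dapi_avg: float | None = None
    background_avg: float | None = None
    cd45_avg: float | None = None
    epithelial_avg: float | None = None
    mesenchymal_avg: float | None = None
    on_pore: bool | None = None
    flag: str | None = None  # set by select_cd45_negative

    def __post_init__(self) -> None:
        if self.nucleus_area_um2 <= 0:
            raise ValueError("nucleus_area_um2 must be positive")

    @property
    def measured(self) -> bool:
        return None not in (
            self.dapi_avg,
            self.background_avg,
            self.cd45_avg,
            self.epithelial_avg,
            self.mesenchymal_avg,
        )

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        r0, c0, _, _ = self.bbox
        rr, cc = np.nonzero(self.mask)
        return rr + r0, cc + c0


@dataclass
class SegmentationParams:
    """Knobs of the threshold-plus-watershed DAPI segmentation."""

    threshold: float | None = None  # absolute; default background + offset_sigmas * sd
    offset_sigmas: float = 4.0
    smooth_sigma_px: float = 0.0
    min_area_um2: float = 10.0
    split: bool = True
    min_peak_distance_um: float = 2.0
    #: refine each mask to pixels above this fraction of its own peak-over-
    #: background, making measured areas independent of absolute brightness
    refine_level_fraction: float = 0.5


@dataclass
class BackgroundEstimate:
    """Robust background level of one channel (median / MAD-based sd)."""

    mean: float
    sd: float
    n_pixels: int

    def __float__(self) -> float:
        return self.mean


def _robust_stats(values: np.ndarray) -> tuple[float, float]:
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, max(1.4826 * mad, 0.5)


def estimate_background(channel: ChannelImage, exclude_mask: np.ndarray | None = None) -> BackgroundEstimate:
    """Robust central tendency of pixels outside all masks.

    ``exclude_mask`` marks nuclei / pore-debris pixels to ignore; it is
    dilated slightly so halo pixels do not bias the estimate.
    """
    data = np.asarray(channel.data, dtype=float)
    if data.size == 0:
        raise EmptyBackgroundError("image is empty")
    if exclude_mask is not None:
        excl = ndi.binary_dilation(exclude_mask, iterations=2)
        values = data[~excl]
    else:
        values = data.ravel()
    if values.size == 0:
        raise EmptyBackgroundError("no background pixels outside the exclusion mask")
    mean, sd = _robust_stats(values)
    return BackgroundEstimate(mean=mean, sd=sd, n_pixels=int(values.size))


def segment_nuclei(dapi: ChannelImage, params: SegmentationParams | None = None) -> list[CellCandidate]:
    """Segment DAPI+ nuclei into disjoint 4-connected masks.

    In split mode touching nuclei are separated by a distance-transform
    watershed; with ``params.split=False`` touching nuclei stay merged into
    one object (the pass used by the cluster gate).  Masks whose mean DAPI
    does not exceed the estimated background are dropped.
    """
    params = params or SegmentationParams()
    ps = dapi.require_pixel_size()
    data = np.asarray(dapi.data, dtype=float)

    bg_mean, bg_sd = _robust_stats(data.ravel())
    thr = params.threshold if params.threshold is not None else bg_mean + params.offset_sigmas * bg_sd
    smoothed = ndi.gaussian_filter(data, params.smooth_sigma_px) if params.smooth_sigma_px > 0 else data
    binary = smoothed > thr
    if not binary.any():
        return []
    binary = ndi.binary_fill_holes(binary)

    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    if params.split:
        distance = ndi.distance_transform_edt(binary)
        min_dist_px = max(1, int(round(params.min_peak_distance_um / ps)))
        coords = peak_local_max(distance, min_distance=min_dist_px, labels=binary)
        markers = np.zeros(binary.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        markers, _ = ndi.label(markers > 0, structure=np.ones((3, 3)))
        labels = watershed(-distance, markers, mask=binary, connectivity=1)
    else:
        labels, _ = ndi.label(binary, structure=structure)

    min_area_px = params.min_area_um2 / (ps * ps)
    out: list[CellCandidate] = []
    objects = ndi.find_objects(labels)
    next_id = 0
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        patch = labels[sl] == lab
        if params.refine_level_fraction > 0:
            patch = _refine_mask(data[sl], patch, bg_mean, params.refine_level_fraction)
            if patch is None:
                continue
        area_px = int(patch.sum())
        if area_px < min_area_px:
            continue
        rr, cc = np.nonzero(patch)
        mean_dapi = float(data[sl][patch].mean())
        if mean_dapi <= bg_mean:
            continue
        r0, c0 = sl[0].start, sl[1].start
        cy = float((rr + r0).mean())
        cx = float((cc + c0).mean())
        area_um2 = area_px * ps * ps
        out.append(
            CellCandidate(
                id=next_id,
                bbox=(r0, c0, sl[0].stop, sl[1].stop),
                mask=patch,
                centroid_um=(cx * ps, cy * ps),
                nucleus_area_um2=area_um2,
                equiv_diameter_um=2.0 * math.sqrt(area_um2 / math.pi),
            )
        )
        next_id += 1
    return out


def _refine_mask(patch_data: np.ndarray, patch: np.ndarray, bg: float, fraction: float) -> np.ndarray | None:
    """Shrink a coarse mask to pixels above ``fraction`` of its own
    peak-over-background; keep the component holding the peak."""
    vals = patch_data[patch]
    peak = float(vals.max())
    level = bg + fraction * (peak - bg)
    refined = patch & (patch_data >= level)
    if not refined.any():
        return None
    labels, _ = ndi.label(refined)
    flat_idx = np.argmax(np.where(patch, patch_data, -np.inf))
    peak_rc = np.unravel_index(flat_idx, patch.shape)
    lab = labels[peak_rc]
    if lab == 0:
        return None
    return labels == lab


def candidates_mask(candidates: list[CellCandidate], shape: tuple[int, int]) -> np.ndarray:
    """Union boolean mask of all candidate pixels."""
    mask = np.zeros(shape, dtype=bool)
    for c in candidates:
        r0, c0, r1, c1 = c.bbox
        mask[r0:r1, c0:c1] |= c.mask
    return mask


def measure_candidate(
    candidate: CellCandidate,
    channels: dict[str, ChannelImage],
    backgrounds: dict[str, BackgroundEstimate],
    pore_centers_um: np.ndarray | None = None,
    pore_radius_um: float = 4.0,
) -> CellCandidate:
    """Populate the five gallery intensity fields (and the on-pore flag).

    ``channels`` must contain the four fluorescence roles with identical
    shapes and pixel sizes; mismatches raise ``ValueError``.
    """
    dapi = channels[DAPI]
    ps = dapi.require_pixel_size()
    for role in (CD45, EPITHELIAL, MESENCHYMAL):
        ch = channels[role]
        if ch.shape != dapi.shape:
            raise ValueError(f"channel {role!r} shape {ch.shape} != DAPI shape {dapi.shape}")
        if ch.require_pixel_size() != ps:
            raise ValueError(f"channel {role!r} pixel size mismatch")
    rr, cc = candidate.pixel_coords()
    candidate.dapi_avg = float(dapi.data[rr, cc].mean(dtype=np.float64))
    candidate.background_avg = float(backgrounds[DAPI].mean)
    candidate.cd45_avg = float(channels[CD45].data[rr, cc].mean(dtype=np.float64))
    candidate.epithelial_avg = float(channels[EPITHELIAL].data[rr, cc].mean(dtype=np.float64))
    candidate.mesenchymal_avg = float(channels[MESENCHYMAL].data[rr, cc].mean(dtype=np.float64))
    if pore_centers_um is not None and len(pore_centers_um):
        d2 = np.sum((pore_centers_um - np.asarray(candidate.centroid_um)) ** 2, axis=1)
        candidate.on_pore = bool(d2.min() <= pore_radius_um**2)
    else:
        candidate.on_pore = None
    return candidate


def select_cd45_negative(candidates: list[CellCandidate], gates: SelectionGates) -> list[CellCandidate]:
    """Apply the automated selection; output order follows the input.

    Single rule: ``dapi_avg >= dapi_min`` and ``cd45_avg <= cd45_max`` and
    ``area > area_min``.  Cluster rule: ``area > cluster_area_min`` and
    ``dapi_avg >= dapi_min`` — CD45 is not considered.  A candidate passing
    the single rule is flagged ``"single"`` (even when it also passes the
    cluster rule); one passing only the cluster rule is flagged
    ``"cluster-candidate"``.
    """
    if gates.dapi_min is None or gates.cd45_max is None:
        raise ValueError("gates must be resolved (dapi_min / cd45_max set) before selection")
    out: list[CellCandidate] = []
    for c in candidates:
        if not c.measured:
            raise UnmeasuredCandidateError(f"candidate {c.id} has unmeasured intensity fields")
        single = (
            c.dapi_avg >= gates.dapi_min
            and c.cd45_avg <= gates.cd45_max
            and c.nucleus_area_um2 > gates.area_min_um2
        )
        cluster = c.nucleus_area_um2 > gates.cluster_area_min_um2 and c.dapi_avg >= gates.dapi_min
        if single:
            c.flag = SINGLE
            out.append(c)
        elif cluster:
            c.flag = CLUSTER_CANDIDATE
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# whole-spot selection pipeline


@dataclass
class ClusterInfo:
    """Constituent composition of a merged (cluster-mode) object."""

    n_cd45_negative: int
    n_cd45_positive: int

    @property
    def total(self) -> int:
        return self.n_cd45_negative + self.n_cd45_positive


@dataclass
class SelectionResult:
    selected: list[CellCandidate]
    cluster_info: dict[int, ClusterInfo]  # candidate id -> composition (cluster candidates only)
    backgrounds: dict[str, BackgroundEstimate]
    gates: SelectionGates


def run_spot_selection(
    channels: dict[str, ChannelImage],
    gates: SelectionGates | None = None,
    params: SegmentationParams | None = None,
    pore_centers_um: np.ndarray | None = None,
    pore_radius_um: float = 4.0,
) -> SelectionResult:
    """Two-pass selection over a whole spot scan.

    Pass 1 segments with splitting and applies both rules per object.
    Pass 2 segments without splitting; merged components that exceed the
    cluster gate and contain at least two split-pass nuclei are added as
    cluster candidates (their constituents are counted and CD45-typed, which
    the phenotype stage needs).  Components already represented by a
    single-rule selection are not duplicated.
    """
    gates = gates or SelectionGates()
    params = params or SegmentationParams()
    dapi = channels[DAPI]

    split_cands = segment_nuclei(dapi, params)
    excl = candidates_mask(split_cands, dapi.shape)
    backgrounds = {role: estimate_background(channels[role], excl) for role in channels}
    resolved = gates.resolve(backgrounds)
    for c in split_cands:
        measure_candidate(c, channels, backgrounds, pore_centers_um, pore_radius_um)
    selected = select_cd45_negative(split_cands, resolved)
    selected_ids = {id(c) for c in selected}
    cluster_info: dict[int, ClusterInfo] = {}
    # a lone nucleus can pass only the cluster gate (big and CD45+): its
    # "composition" is itself, letting classification fall through cleanly
    for c in selected:
        if c.flag == CLUSTER_CANDIDATE:
            neg = 1 if c.cd45_avg <= resolved.cd45_max else 0
            cluster_info[c.id] = ClusterInfo(n_cd45_negative=neg, n_cd45_positive=1 - neg)

    # cluster pass: no splitting and no per-object refinement — a merged
    # clump must keep its dim members, so the full demarcated footprint is
    # gated instead of the half-max one
    merged_params = SegmentationParams(
        threshold=params.threshold,
        offset_sigmas=params.offset_sigmas,
        smooth_sigma_px=params.smooth_sigma_px,
        min_area_um2=params.min_area_um2,
        split=False,
        min_peak_distance_um=params.min_peak_distance_um,
        refine_level_fraction=0.0,
    )
    merged = segment_nuclei(dapi, merged_params)
    next_id = max((c.id for c in split_cands), default=-1) + 1
    ps = dapi.require_pixel_size()
    for m in merged:
        if m.nucleus_area_um2 <= resolved.cluster_area_min_um2:
            continue
        # constituents: split-pass nuclei whose centroid falls inside this component
        members = []
        r0, c0, r1, c1 = m.bbox
        for c in split_cands:
            col = int(round(c.centroid_um[0] / ps))
            row = int(round(c.centroid_um[1] / ps))
            if r0 <= row < r1 and c0 <= col < c1 and m.mask[row - r0, col - c0]:
                members.append(c)
        if len(members) < 2:
            continue  # a lone big nucleus is handled by the single rule
        if any(id(c) in selected_ids and c.flag == SINGLE and len(members) == 1 for c in members):
            continue
        measure_candidate(m, channels, backgrounds, pore_centers_um, pore_radius_um)
        if m.dapi_avg < resolved.dapi_min:
            continue
        m.id = next_id
        next_id += 1
        m.flag = CLUSTER_CANDIDATE
        n_neg = sum(1 for c in members if c.cd45_avg <= resolved.cd45_max)
        cluster_info[m.id] = ClusterInfo(n_cd45_negative=n_neg, n_cd45_positive=len(members) - n_neg)
        # drop member singles that were selected only via the cluster rule
        selected = [s for s in selected if not (s in members and s.flag == CLUSTER_CANDIDATE)]
        selected.append(m)
    return SelectionResult(selected=selected, cluster_info=cluster_info, backgrounds=backgrounds, gates=resolved)
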