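"""Synthetic filter-spot images and FISH z-stacks with known ground truth.

Everything downstream (segmentation, gating, phenotype classification,
relocation, FISH spot detection) is exercised against the truth lists
produced here.  All randomness flows from explicit seeds; two runs with the
same seed produce bit-identical images and truth.

Physical picture: a circular membrane "spot" perforated by an hexagonal
lattice of 8-um pores carries thousands of leukocyte-scale DAPI+/CD45+
nuclei, rare large DAPI+/CD45- cells with variable epithelial/mesenchymal
marker levels, and autofluorescent debris confined to pore interiors.  The
membrane is not flat: a smooth low-order polynomial surface gives the true
focus height at every position.  FISH spots are 3-D Gaussians inside thick
nuclei.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ctcscan.image import (
    CD45,
    DAPI,
    EPITHELIAL,
    FISH_GREEN,
    FISH_RED,
    MESENCHYMAL,
    ChannelImage,
    ZStackSeries,
)

LEUKOCYTE = "leukocyte"
CTC = "ctc"
DEBRIS = "debris"

EXPOSURE_MIN_MS = 5.0
EXPOSURE_MAX_MS = 100.0


class PackingError(ValueError):
    """Requested cell count cannot be packed onto the spot without overlap."""


class ExposureRangeError(ValueError):
    """Exposure time outside the supported 5-100 ms range."""


# ---------------------------------------------------------------------------
# geometry


@dataclass
class SnickSpec:
    """Asymmetric notch cut into the spot rim, used as relocation fiducial.

    The notch is a scalene triangle: two rim points at unequal arc offsets
    from ``angle_deg`` and an apex pulled inward and sideways.  The asymmetry
    makes the outline orientation-resolving.
    """

    angle_deg: float = 0.0
    depth_um: float = 120.0
    half_width_a_um: float = 60.0
    half_width_b_um: float = 100.0
    apex_skew_um: float = 35.0

    def __post_init__(self) -> None:
        if self.half_width_a_um == self.half_width_b_um and self.apex_skew_um == 0:
            raise ValueError("snick must be asymmetric (orientation-resolving)")


@dataclass
class FilterGeometry:
    """Pore lattice and spot outline of one 1-mL filter spot."""

    pore_diameter_um: float = 8.0
    pore_pitch_um: float = 20.0
    spot_diameter_mm: float = 1.0
    snick: SnickSpec = field(default_factory=SnickSpec)

    def __post_init__(self) -> None:
        if self.pore_diameter_um <= 0:
            raise ValueError("pore_diameter_um must be positive")
        if self.pore_pitch_um <= self.pore_diameter_um:
            raise ValueError("pore_pitch_um must exceed pore_diameter_um (pores must not overlap)")
        if self.spot_diameter_mm <= 0:
            raise ValueError("spot_diameter_mm must be positive")

    @property
    def spot_radius_um(self) -> float:
        return self.spot_diameter_mm * 1000.0 / 2.0

    @property
    def pore_radius_um(self) -> float:
        return self.pore_diameter_um / 2.0

    def pore_centers_um(self) -> np.ndarray:
        """Hexagonal lattice of pore centres, ``(n, 2)`` array of (x, y) um."""
        pitch = self.pore_pitch_um
        r_max = self.spot_radius_um - self.pore_diameter_um
        dy = pitch * math.sqrt(3.0) / 2.0
        rows = int(r_max // dy) + 1
        centers = []
        for iy in range(-rows, rows + 1):
            y = iy * dy
            x_off = (pitch / 2.0) if (iy % 2) else 0.0
            cols = int((r_max + pitch) // pitch) + 1
            for ix in range(-cols, cols + 1):
                x = ix * pitch + x_off
                if x * x + y * y <= r_max * r_max:
                    centers.append((x, y))
        return np.asarray(centers, dtype=float)

    def snick_outline_um(self, n_points: int = 60) -> np.ndarray:
        """Polyline of the snick notch in spot coordinates, ``(n, 2)`` um."""
        s = self.snick
        ang = math.radians(s.angle_deg)
        radial = np.array([math.cos(ang), math.sin(ang)])
        tangent = np.array([-math.sin(ang), math.cos(ang)])
        rim = self.spot_radius_um
        p_a = rim * radial - s.half_width_a_um * tangent
        apex = (rim - s.depth_um) * radial + s.apex_skew_um * tangent
        p_b = rim * radial + s.half_width_b_um * tangent
        n1 = n_points // 2
        n2 = n_points - n1
        seg1 = np.linspace(p_a, apex, n1, endpoint=False)
        seg2 = np.linspace(apex, p_b, n2)
        return np.vstack([seg1, seg2])


# ---------------------------------------------------------------------------
# focal surface


@dataclass
class FocalSurface:
    """Smooth true-focus height ``z0(x, y)`` over the spot, in micrometres.

    A low-order 2-D polynomial in coordinates normalised by ``extent_um``;
    ``refocus_sd_um`` models the residual error left by the scanner's
    per-frame DAPI refocus.
    """

    coeffs: np.ndarray  # (k, k) matrix, term c[i, j] * xn**i * yn**j
    extent_um: float
    refocus_sd_um: float = 0.5

    def evaluate(self, x_um, y_um):
        xn = np.asarray(x_um, dtype=float) / self.extent_um
        yn = np.asarray(y_um, dtype=float) / self.extent_um
        return np.polynomial.polynomial.polyval2d(xn, yn, self.coeffs)

    @classmethod
    def flat(cls, extent_um: float = 1000.0, refocus_sd_um: float = 0.0) -> "FocalSurface":
        return cls(coeffs=np.zeros((1, 1)), extent_um=extent_um, refocus_sd_um=refocus_sd_um)

    @classmethod
    def random(
        cls,
        seed: int,
        extent_um: float = 1000.0,
        peak_to_peak_um: float = 10.0,
        order: int = 3,
        refocus_sd_um: float = 0.5,
    ) -> "FocalSurface":
        """Random smooth surface rescaled to the requested peak-to-peak range."""
        rng = np.random.default_rng(seed)
        coeffs = rng.standard_normal((order + 1, order + 1))
        coeffs[0, 0] = 0.0
        surf = cls(coeffs=coeffs, extent_um=extent_um, refocus_sd_um=refocus_sd_um)
        g = np.linspace(-extent_um, extent_um, 41)
        zz = surf.evaluate(*np.meshgrid(g, g))
        ptp = float(zz.max() - zz.min())
        if ptp > 0:
            surf.coeffs = coeffs * (peak_to_peak_um / ptp)
        return surf


# ---------------------------------------------------------------------------
# exposure / detector model


@dataclass
class ExposureModel:
    """8-bit detector: ``I = clip(dark + k * rate * t + noise, 0, gain)``.

    Monotone non-decreasing in exposure time, saturating exactly at ``gain``
    (maximum 255).  ``read_noise_sd`` is Gaussian read noise in counts; pass
    ``rng=None`` to :meth:`apply` for a noiseless render.
    """

    gain: int = 255
    dark_level: float = 8.0
    k: float = 1.0
    read_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.gain <= 255):
            raise ValueError("gain must be in (0, 255]")
        if self.k < 0:
            raise ValueError("k must be non-negative (monotone response)")

    def apply(self, photon_rate: np.ndarray, exposure_ms: float, rng: np.random.Generator | None = None) -> np.ndarray:
        if not (EXPOSURE_MIN_MS <= exposure_ms <= EXPOSURE_MAX_MS):
            raise ExposureRangeError(
                f"exposure {exposure_ms} ms outside [{EXPOSURE_MIN_MS}, {EXPOSURE_MAX_MS}]"
            )
        counts = self.dark_level + self.k * np.asarray(photon_rate, dtype=float) * exposure_ms
        if rng is not None and self.read_noise_sd > 0:
            counts = counts + rng.normal(0.0, self.read_noise_sd, size=counts.shape)
        return np.clip(np.rint(counts), 0, self.gain).astype(np.uint8)


def apply_exposure(
    photon_rate: np.ndarray,
    exposure_ms: float,
    model: ExposureModel,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Expose a photon-rate image through the detector model."""
    return model.apply(photon_rate, exposure_ms, rng=rng)


# ---------------------------------------------------------------------------
# cells


@dataclass
class SimFishSpot:
    """Planted 3-D FISH spot, position relative to the nucleus centre (um)."""

    x_um: float
    y_um: float
    z_um: float
    channel: str = FISH_RED
    radius_um: float = 0.4
    amplitude: float = 3.0


@dataclass
class SimulatedCell:
    """Ground-truth cell on the filter."""

    center_um: tuple[float, float]
    nucleus_area_um2: float
    nucleus_thickness_um: float
    type_label: str
    marker_levels: dict[str, float]
    on_pore: bool = False
    fish_spots: list[SimFishSpot] = field(default_factory=list)
    cluster_id: int | None = None

    @property
    def nucleus_radius_um(self) -> float:
        return math.sqrt(self.nucleus_area_um2 / math.pi)

    @property
    def cell_radius_um(self) -> float:
        # cytoplasmic footprint: markers extend beyond the nucleus
        return 1.3 * self.nucleus_radius_um


@dataclass
class CellPopulation:
    """Counts and marker-level distributions for :func:`generate_filter_spot`."""

    n_leukocytes: int = 0
    n_ctcs: int = 0
    n_debris: int = 0
    n_leukocyte_clusters: int = 0
    cluster_size_range: tuple[int, int] = (4, 6)
    leukocyte_area_um2: tuple[float, float] = (30.0, 7.0)  # mean, sd; clipped < 55
    ctc_area_um2: tuple[float, float] = (110.0, 420.0)  # uniform range; up to >700 allowed
    ctc_epithelial_pos_fraction: float = 0.6
    ctc_mesenchymal_pos_fraction: float = 0.4
    # photon rates (counts per ms at k=1)
    dapi_rate: float = 3.0
    cd45_pos_rate: float = 2.5
    cd45_neg_rate: float = 0.02
    marker_pos_rate: float = 2.0
    marker_neg_rate: float = 0.02

    def total_cells(self) -> int:
        return (
            self.n_leukocytes
            + self.n_ctcs
            + self.n_debris
            + self.n_leukocyte_clusters * self.cluster_size_range[1]
        )


DEFAULT_EXPOSURES_MS = {DAPI: 50.0, CD45: 60.0, EPITHELIAL: 40.0, MESENCHYMAL: 40.0}


@dataclass
class SpotSimulation:
    """Output of :func:`generate_filter_spot`: rendered planes plus truth."""

    images: dict[str, ChannelImage]
    cells: list[SimulatedCell]
    pore_centers_um: np.ndarray
    geometry: FilterGeometry
    pixel_size_um: float
    model: ExposureModel
    seed: int

    @property
    def image_offset_um(self) -> float:
        """Offset mapping spot-centred truth coordinates to image ones."""
        npix = next(iter(self.images.values())).shape[0]
        return (npix - 1) / 2.0 * self.pixel_size_um

    def to_image_coords(self, xy_um: np.ndarray) -> np.ndarray:
        """Truth (spot-centred) -> image-frame coordinates, micrometres."""
        return np.asarray(xy_um, dtype=float) + self.image_offset_um


def _sample_positions(
    rng: np.random.Generator,
    radii_um: np.ndarray,
    spot_radius_um: float,
    margin_um: float = 2.0,
    max_attempts: int = 200,
) -> np.ndarray:
    """Non-overlapping uniform positions in a disc via an occupancy grid."""
    n = len(radii_um)
    if n == 0:
        return np.zeros((0, 2))
    r_max = float(radii_um.max())
    footprint = np.sum((2 * radii_um + margin_um) ** 2)
    if footprint > 0.55 * math.pi * spot_radius_um**2:
        raise PackingError(
            f"cannot pack {n} cells (footprint {footprint:.0f} um^2) onto spot of "
            f"radius {spot_radius_um:.0f} um"
        )
    cell = 2 * r_max + margin_um
    grid: dict[tuple[int, int], list[int]] = {}
    pos = np.zeros((n, 2))
    # place the largest cells first: a big nucleus cannot squeeze into the
    # gaps left by thousands of small ones
    order = np.argsort(-radii_um, kind="stable")
    for i in order:
        ri = radii_um[i]
        for _ in range(max_attempts):
            ang = rng.uniform(0, 2 * math.pi)
            rad = spot_radius_um * 0.97 * math.sqrt(rng.uniform())
            x, y = rad * math.cos(ang), rad * math.sin(ang)
            gx, gy = int(x // cell), int(y // cell)
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for j in grid.get((gx + dx, gy + dy), ()):
                        lim = ri + radii_um[j] + margin_um
                        if (x - pos[j, 0]) ** 2 + (y - pos[j, 1]) ** 2 < lim * lim:
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                pos[i] = (x, y)
                grid.setdefault((gx, gy), []).append(i)
                break
        else:
            raise PackingError(f"failed to place cell {i} of {n} after {max_attempts} attempts")
    return pos


def _nearest_pore(pore_centers: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Distance from each point to its nearest pore centre."""
    if len(pore_centers) == 0:
        return np.full(len(xy), np.inf)
    from scipy.spatial import cKDTree

    tree = cKDTree(pore_centers)
    d, _ = tree.query(xy)
    return d


def _stamp_soft_disk(rate: np.ndarray, cx_px: float, cy_px: float, r_px: float, amp: float) -> None:
    """Add a flat-topped disk whose half-maximum contour sits at ``r_px``.

    A steep super-Gaussian so an above-half-max footprint recovers the true
    area regardless of the absolute amplitude.
    """
    half = int(math.ceil(r_px * 1.5)) + 2
    x0, y0 = int(round(cx_px)), int(round(cy_px))
    ny, nx = rate.shape
    xs = slice(max(0, x0 - half), min(nx, x0 + half + 1))
    ys = slice(max(0, y0 - half), min(ny, y0 + half + 1))
    if xs.start >= xs.stop or ys.start >= ys.stop:
        return
    yy, xx = np.mgrid[ys, xs]
    d2 = ((xx - cx_px) ** 2 + (yy - cy_px) ** 2) / max(r_px, 0.5) ** 2
    rate[ys, xs] += amp * np.exp(-math.log(2.0) * d2**4)


def _render_pore_texture(rate: np.ndarray, pore_centers: np.ndarray, pore_r_px: float, px: float, amp: float) -> None:
    """Faint autofluorescent rims around every pore (vectorised ring stamp)."""
    if len(pore_centers) == 0:
        return
    half = int(math.ceil(pore_r_px)) + 2
    size = 2 * half + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    d = np.sqrt(xx**2 + yy**2)
    ring = amp * np.exp(-((d - pore_r_px) ** 2) / (2 * 0.8**2))
    ny, nx = rate.shape
    for x_um, y_um in pore_centers:
        cx, cy = int(round(x_um / px)), int(round(y_um / px))
        x0, x1 = cx - half, cx + half + 1
        y0, y1 = cy - half, cy + half + 1
        if x0 < 0 or y0 < 0 or x1 > nx or y1 > ny:
            continue
        rate[y0:y1, x0:x1] += ring


def generate_filter_spot(
    geometry: FilterGeometry,
    population: CellPopulation,
    seed: int,
    pixel_size_um: float = 0.5,
    model: ExposureModel | None = None,
    exposures_ms: dict[str, float] | None = None,
    noise: bool = True,
) -> SpotSimulation:
    """Render a four-channel filter-spot scan plus its ground-truth cell list.

    Channels: DAPI (nuclear), CD45 (leukocyte), epithelial (green),
    mesenchymal (red).  Debris is confined to pore interiors.  Raises
    :class:`PackingError` rather than silently truncating when the requested
    population does not fit.
    """
    model = model or ExposureModel()
    exposures = dict(DEFAULT_EXPOSURES_MS)
    if exposures_ms:
        exposures.update(exposures_ms)
    rng = np.random.default_rng(seed)
    pores = geometry.pore_centers_um()

    cells: list[SimulatedCell] = []

    # --- leukocytes (isolated) + CTCs share the packing pass
    mean_a, sd_a = population.leukocyte_area_um2
    leu_areas = np.clip(rng.normal(mean_a, sd_a, population.n_leukocytes), 12.0, 54.0)
    lo, hi = population.ctc_area_um2
    ctc_areas = rng.uniform(lo, hi, population.n_ctcs)
    areas = np.concatenate([leu_areas, ctc_areas])
    radii = 1.3 * np.sqrt(areas / math.pi)
    positions = _sample_positions(rng, radii, geometry.spot_radius_um)

    for i in range(population.n_leukocytes):
        cells.append(
            SimulatedCell(
                center_um=(positions[i, 0], positions[i, 1]),
                nucleus_area_um2=float(leu_areas[i]),
                nucleus_thickness_um=4.0,
                type_label=LEUKOCYTE,
                marker_levels={
                    DAPI: population.dapi_rate * rng.uniform(0.8, 1.2),
                    CD45: population.cd45_pos_rate * rng.uniform(0.7, 1.3),
                    EPITHELIAL: population.marker_neg_rate,
                    MESENCHYMAL: population.marker_neg_rate * rng.uniform(1, 5),
                },
            )
        )
    for j in range(population.n_ctcs):
        i = population.n_leukocytes + j
        epi = population.marker_pos_rate * rng.uniform(0.5, 1.5) if rng.uniform() < population.ctc_epithelial_pos_fraction else population.marker_neg_rate
        mes = population.marker_pos_rate * rng.uniform(0.5, 1.5) if rng.uniform() < population.ctc_mesenchymal_pos_fraction else population.marker_neg_rate
        cells.append(
            SimulatedCell(
                center_um=(positions[i, 0], positions[i, 1]),
                nucleus_area_um2=float(ctc_areas[j]),
                nucleus_thickness_um=rng.uniform(10.0, 16.0),
                type_label=CTC,
                marker_levels={
                    DAPI: population.dapi_rate * rng.uniform(0.9, 1.3),
                    CD45: population.cd45_neg_rate,
                    EPITHELIAL: epi,
                    MESENCHYMAL: mes,
                },
            )
        )

    # --- deliberate leukocyte clusters: chains of touching nuclei
    for c in range(population.n_leukocyte_clusters):
        size = int(rng.integers(population.cluster_size_range[0], population.cluster_size_range[1] + 1))
        ang = rng.uniform(0, 2 * math.pi)
        rad = geometry.spot_radius_um * 0.9 * math.sqrt(rng.uniform())
        cx, cy = rad * math.cos(ang), rad * math.sin(ang)
        placed: list[SimulatedCell] = []
        for _ in range(size):
            a = float(np.clip(rng.normal(mean_a, sd_a), 15.0, 54.0))
            r = math.sqrt(a / math.pi)
            if not placed:
                pos_xy = (cx, cy)
            else:
                # touch the previous member without burying earlier ones
                prev = placed[-1]
                d = prev.nucleus_radius_um + r + 0.1
                for _ in range(40):
                    step_ang = rng.uniform(0, 2 * math.pi)
                    pos_xy = (
                        prev.center_um[0] + d * math.cos(step_ang),
                        prev.center_um[1] + d * math.sin(step_ang),
                    )
                    if all(
                        math.hypot(pos_xy[0] - q.center_um[0], pos_xy[1] - q.center_um[1])
                        >= q.nucleus_radius_um + r
                        for q in placed[:-1]
                    ):
                        break
            cell = SimulatedCell(
                center_um=pos_xy,
                nucleus_area_um2=a,
                nucleus_thickness_um=4.0,
                type_label=LEUKOCYTE,
                marker_levels={
                    DAPI: population.dapi_rate * rng.uniform(0.8, 1.2),
                    CD45: population.cd45_pos_rate * rng.uniform(0.7, 1.3),
                    EPITHELIAL: population.marker_neg_rate,
                    MESENCHYMAL: population.marker_neg_rate * rng.uniform(1, 5),
                },
                cluster_id=c,
            )
            cells.append(cell)
            placed.append(cell)

    # --- debris: sub-nuclear DAPI blobs strictly inside pore interiors
    if population.n_debris and len(pores) == 0:
        raise ValueError("debris requested but geometry has no pores")
    if population.n_debris:
        idx = rng.choice(len(pores), size=population.n_debris, replace=population.n_debris > len(pores))
        for k in idx:
            jit = rng.uniform(-1.0, 1.0, 2) * (geometry.pore_radius_um - 2.0)
            cells.append(
                SimulatedCell(
                    center_um=(pores[k, 0] + jit[0], pores[k, 1] + jit[1]),
                    nucleus_area_um2=float(rng.uniform(4.0, 20.0)),
                    nucleus_thickness_um=2.0,
                    type_label=DEBRIS,
                    marker_levels={
                        DAPI: population.dapi_rate * rng.uniform(0.3, 0.8),
                        CD45: population.cd45_pos_rate * rng.uniform(0.0, 0.4),
                        EPITHELIAL: population.marker_neg_rate,
                        MESENCHYMAL: population.marker_neg_rate,
                    },
                )
            )

    # on-pore flags
    if cells:
        xy = np.array([c.center_um for c in cells])
        d = _nearest_pore(pores, xy)
        for c, di in zip(cells, d):
            c.on_pore = bool(di <= geometry.pore_radius_um)

    # --- render channels
    px = pixel_size_um
    npix = int(math.ceil(geometry.spot_radius_um * 2 / px)) + 1
    half_um = (npix - 1) / 2 * px  # image centre == spot centre

    images: dict[str, ChannelImage] = {}
    for role in (DAPI, CD45, EPITHELIAL, MESENCHYMAL):
        rate = np.zeros((npix, npix), dtype=np.float32)
        _render_pore_texture(rate, pores, geometry.pore_radius_um / px, px, amp=0.04)
        for c in cells:
            amp = c.marker_levels.get(role, 0.0)
            if amp <= 0:
                continue
            r_um = c.nucleus_radius_um if role == DAPI else c.cell_radius_um
            if c.type_label == DEBRIS and role != DAPI:
                r_um = c.nucleus_radius_um
            _stamp_soft_disk(
                rate,
                (c.center_um[0] + half_um) / px,
                (c.center_um[1] + half_um) / px,
                r_um / px,
                amp,
            )
        img = model.apply(rate, exposures[role], rng=rng if noise else None)
        images[role] = ChannelImage(img, pixel_size_um=px, role=role, exposure_ms=exposures[role])

    return SpotSimulation(
        images=images,
        cells=cells,
        pore_centers_um=pores,
        geometry=geometry,
        pixel_size_um=px,
        model=model,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# FISH z-stacks


#: lateral / axial PSF scale of a rendered FISH spot (no optics model intended)
FISH_LATERAL_SD_UM = 0.4
FISH_AXIAL_SD_UM = 0.8
#: spots contribute to a plane only within this many axial sigmas
AXIAL_SUPPORT_SIGMAS = 2.5


def make_fish_cell(
    rng: np.random.Generator,
    center_um: tuple[float, float] = (0.0, 0.0),
    nucleus_area_um2: float = 200.0,
    nucleus_thickness_um: float = 14.0,
    n_red: int = 4,
    n_green: int = 4,
    paired: bool = True,
    pair_separation_um: float = 0.3,
    amplitude: float = 3.0,
) -> SimulatedCell:
    """A CTC-like nucleus with FISH spots uniform in z through its thickness.

    With ``paired=True`` red/green spots are laid down as fused pairs
    (separation ``pair_separation_um``), the native break-apart pattern.
    """
    cell = SimulatedCell(
        center_um=center_um,
        nucleus_area_um2=nucleus_area_um2,
        nucleus_thickness_um=nucleus_thickness_um,
        type_label=CTC,
        marker_levels={DAPI: 3.0, CD45: 0.02},
    )
    r_lat = 0.7 * cell.nucleus_radius_um
    t2 = nucleus_thickness_um / 2.0
    if paired:
        n_pairs = min(n_red, n_green)
        for _ in range(n_pairs):
            ang = rng.uniform(0, 2 * math.pi)
            rad = r_lat * math.sqrt(rng.uniform())
            x, y = rad * math.cos(ang), rad * math.sin(ang)
            z = rng.uniform(-t2, t2)
            off = pair_separation_um / 2.0
            pang = rng.uniform(0, 2 * math.pi)
            dx, dy = off * math.cos(pang), off * math.sin(pang)
            cell.fish_spots.append(SimFishSpot(x - dx, y - dy, z, FISH_RED, amplitude=amplitude))
            cell.fish_spots.append(SimFishSpot(x + dx, y + dy, z, FISH_GREEN, amplitude=amplitude))
        n_red, n_green = n_red - n_pairs, n_green - n_pairs
    for channel, n in ((FISH_RED, n_red), (FISH_GREEN, n_green)):
        for _ in range(n):
            ang = rng.uniform(0, 2 * math.pi)
            rad = r_lat * math.sqrt(rng.uniform())
            cell.fish_spots.append(
                SimFishSpot(
                    rad * math.cos(ang), rad * math.sin(ang), rng.uniform(-t2, t2), channel, amplitude=amplitude
                )
            )
    return cell


def render_zstack(
    cells: list[SimulatedCell],
    surface: FocalSurface,
    n_stacks: int,
    step_um: float,
    channel: str,
    center_um: tuple[float, float] | None = None,
    fov_um: float = 24.0,
    pixel_size_um: float = 0.2,
    exposure_ms: float = 20.0,
    model: ExposureModel | None = None,
    rng: np.random.Generator | None = None,
    refocus_error_um: float | None = None,
) -> ZStackSeries:
    """Optical-section series of a field of view for one FISH/DAPI channel.

    Plane ``j`` sits at ``z_center + (j - (n - 1) / 2) * step_um`` where
    ``z_center`` is the focal-surface height at the FOV centre (the scanner
    refocuses on DAPI every frame) plus a residual refocus error.  FISH spots
    are 3-D Gaussians rendered only in planes within their axial support;
    the total comb span is ``(n_stacks - 1) * step_um``.
    """
    if n_stacks < 1:
        raise ValueError("n_stacks must be >= 1")
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    model = model or ExposureModel()
    if center_um is None:
        if not cells:
            center_um = (0.0, 0.0)
        else:
            xy = np.array([c.center_um for c in cells])
            center_um = (float(xy[:, 0].mean()), float(xy[:, 1].mean()))
    cx, cy = center_um
    z_surface = float(surface.evaluate(cx, cy))
    if refocus_error_um is None:
        refocus_error_um = (
            float(rng.normal(0.0, surface.refocus_sd_um)) if rng is not None and surface.refocus_sd_um > 0 else 0.0
        )
    # the scanner focuses on the DAPI-stained nucleus body, i.e. mid-thickness
    thickness = cells[0].nucleus_thickness_um if cells else 0.0
    z_center = z_surface + thickness / 2.0 + refocus_error_um

    px = pixel_size_um
    npx = int(round(fov_um / px))
    half_um = fov_um / 2.0
    planes = np.zeros((n_stacks, npx, npx), dtype=np.float32)
    zs = z_center + (np.arange(n_stacks) - (n_stacks - 1) / 2.0) * step_um

    sig_lat_px = FISH_LATERAL_SD_UM / px
    for cell in cells:
        nuc_z = float(surface.evaluate(*cell.center_um)) + cell.nucleus_thickness_um / 2.0
        if channel == DAPI:
            r_px = cell.nucleus_radius_um / px
            cx_px = (cell.center_um[0] - cx + half_um) / px
            cy_px = (cell.center_um[1] - cy + half_um) / px
            t2 = cell.nucleus_thickness_um / 2.0
            for j, zj in enumerate(zs):
                dz = abs(zj - nuc_z)
                amp_z = 1.0 if dz <= t2 else math.exp(-((dz - t2) ** 2) / (2 * FISH_AXIAL_SD_UM**2))
                if amp_z < 1e-3:
                    continue
                amp = cell.marker_levels.get(DAPI, 3.0) * amp_z
                _stamp_soft_disk(planes[j], cx_px, cy_px, r_px, amp)
            continue
        for spot in cell.fish_spots:
            if spot.channel != channel:
                continue
            sx = (cell.center_um[0] + spot.x_um - cx + half_um) / px
            sy = (cell.center_um[1] + spot.y_um - cy + half_um) / px
            sz = nuc_z + spot.z_um
            sig_z = FISH_AXIAL_SD_UM
            for j, zj in enumerate(zs):
                dz = abs(zj - sz)
                if dz > AXIAL_SUPPORT_SIGMAS * sig_z:
                    continue  # outside axial support
                amp = spot.amplitude * math.exp(-(dz**2) / (2 * sig_z**2))
                _stamp_gaussian(planes[j], sx, sy, sig_lat_px, amp)

    data = np.stack(
        [model.apply(planes[j], exposure_ms, rng=rng) for j in range(n_stacks)]
    )
    return ZStackSeries(
        data=data,
        pixel_size_um=px,
        step_um=step_um,
        role=channel,
        z_center_um=z_center,
        exposure_ms=exposure_ms,
    )


def _stamp_gaussian(plane: np.ndarray, cx_px: float, cy_px: float, sigma_px: float, amp: float) -> None:
    half = int(math.ceil(4 * sigma_px)) + 1
    x0, y0 = int(round(cx_px)), int(round(cy_px))
    ny, nx = plane.shape
    xs = slice(max(0, x0 - half), min(nx, x0 + half + 1))
    ys = slice(max(0, y0 - half), min(ny, y0 + half + 1))
    if xs.start >= xs.stop or ys.start >= ys.stop:
        return
    yy, xx = np.mgrid[ys, xs]
    plane[ys, xs] += amp * np.exp(-(((xx - cx_px) ** 2 + (yy - cy_px) ** 2) / (2 * sigma_px**2)))


def axial_capture_fraction(
    n_stacks: int,
    step_um: float,
    thickness_um: float,
    support_um: float = AXIAL_SUPPORT_SIGMAS * FISH_AXIAL_SD_UM,
) -> float:
    """Expected fraction of z-uniform spots whose centre lies within reach of
    the comb (half-span plus axial support), closed form."""
    if thickness_um <= 0:
        return 1.0
    half_span = (n_stacks - 1) * step_um / 2.0
    reach = 2.0 * (half_span + support_um)
    return min(1.0, reach / thickness_um)
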