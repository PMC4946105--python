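"""FISH z-stack spot detection, multi-exposure fusion and break-apart calls.

Spot detection is per-plane Laplacian-of-Gaussian blob finding followed by
cross-plane linking into 3-D spots.  Because FISH signal intensity varies
strongly across a filter, each channel is acquired at up to three exposure
times and the exposure maximising the number of countable spots is kept
(lowest exposure on ties — thick, bloomed signals can fake the distance
between two spots).  Per-cell verdicts follow break-apart convention:
fused red/green pairs are native, any split pair (or isolated single-colour
signal) is a rearrangement, and more than two fused pairs without a split
is a native-copy gain.

:func:`detection_rate` implements the per-setting table statistic: the
percentage of cells whose maximum observed spot count — ignoring
non-interpretable (n.i.) entries — is attained at that setting, ties
counting for every tying setting, rounded to the nearest integer percent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

from ctcscan.image import FISH_GREEN, FISH_RED, ZStackSeries
from ctcscan.simulate import (
    EXPOSURE_MAX_MS,
    EXPOSURE_MIN_MS,
    FISH_LATERAL_SD_UM,
    FocalSurface,
    SimulatedCell,
    make_fish_cell,
    render_zstack,
)

MAX_Z_STACKS = 30  # scanner tolerates at most 30

NON_INTERPRETABLE = "non-interpretable"
REARRANGED = "rearranged"
NATIVE = "native"
NATIVE_COPY_GAIN = "native-copy-gain"


class NonInterpretableError(RuntimeError):
    """FISH spots are uncountable for this acquisition (e.g. focus failure)."""

    def __init__(self, reason: str) -> None:
        super().__init__(reason)
        self.reason = reason


@dataclass
class ScanConfig:
    """Acquisition settings for FISH z-stack capture."""

    n_stacks: int = 30
    step_um: float = 0.6
    exposures_ms: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {FISH_RED: (20.0, 50.0, 100.0), FISH_GREEN: (20.0, 50.0, 100.0)}
    )
    gain: int = 255
    offset: float = 0.0
    n_focus_points: int = 9
    magnification: str = "63x"

    def __post_init__(self) -> None:
        if not (1 <= self.n_stacks <= MAX_Z_STACKS):
            raise ValueError(f"n_stacks must be within [1, {MAX_Z_STACKS}]")
        if self.step_um <= 0:
            raise ValueError("step_um must be positive")
        for channel, exposures in self.exposures_ms.items():
            if not (1 <= len(exposures) <= 3):
                raise ValueError(f"channel {channel!r} needs 1-3 exposures")
            for e in exposures:
                if not (EXPOSURE_MIN_MS <= e <= EXPOSURE_MAX_MS):
                    raise ValueError(
                        f"exposure {e} ms for {channel!r} outside [{EXPOSURE_MIN_MS}, {EXPOSURE_MAX_MS}]"
                    )

    @property
    def span_um(self) -> float:
        return (self.n_stacks - 1) * self.step_um

    @property
    def n_exposure_settings(self) -> int:
        """Size of the exposure search space (3 per channel -> 9 or 27)."""
        n = 1
        for exposures in self.exposures_ms.values():
            n *= len(exposures)
        return n


@dataclass
class FishSpot3D:
    x_um: float
    y_um: float
    z_um: float
    channel: str
    peak_intensity: float
    lateral_diameter_um: float
    z_extent: int
    may_be_merged: bool = False
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.z_extent < 1:
            raise ValueError("z_extent must be >= 1")
        if self.lateral_diameter_um <= 0:
            raise ValueError("lateral_diameter_um must be positive")


@dataclass
class SpotDetectionParams:
    lateral_sigma_um: float = FISH_LATERAL_SD_UM
    link_radius_um: float = 0.5
    response_sigmas: float = 6.0  # LoG response threshold in robust sds
    response_threshold: float | None = None  # absolute override
    merge_diameter_factor: float = 1.25  # footprint above this x FWHM -> merged flag
    #: a spot this much brighter than the cohort median is likely two fused
    #: signals below lateral resolution
    merge_intensity_factor: float = 1.7
    saturation_level: int = 255
    saturated_fraction_limit: float = 0.5


def _plane_peaks(
    plane: np.ndarray, sigma_px: float, response_sigmas: float, response_threshold: float | None
) -> list[tuple[int, int, float]]:
    resp = -ndi.gaussian_laplace(plane.astype(float), sigma=sigma_px) * sigma_px**2
    if response_threshold is None:
        med = np.median(resp)
        mad = np.median(np.abs(resp - med))
        thr = med + response_sigmas * max(1.4826 * mad, 0.25)
    else:
        thr = response_threshold
    coords = peak_local_max(resp, min_distance=max(1, int(round(sigma_px))), threshold_abs=thr)
    return [(int(r), int(c), float(resp[r, c])) for r, c in coords]


def _footprint_diameter_px(plane: np.ndarray, r: int, c: int, bg: float) -> float:
    """Equivalent diameter of the above-half-max footprint around a peak."""
    half = 8
    ny, nx = plane.shape
    r0, r1 = max(0, r - half), min(ny, r + half + 1)
    c0, c1 = max(0, c - half), min(nx, c + half + 1)
    win = plane[r0:r1, c0:c1].astype(float)
    level = bg + 0.5 * (float(plane[r, c]) - bg)
    above = win >= level
    labels, _ = ndi.label(above)
    lab = labels[r - r0, c - c0]
    if lab == 0:
        return 1.0
    area = int((labels == lab).sum())
    return 2.0 * math.sqrt(area / math.pi)


def detect_spots(zstack: ZStackSeries, params: SpotDetectionParams | None = None) -> list[FishSpot3D]:
    """Detect 3-D FISH spots: per-plane LoG blobs linked across planes.

    Raises :class:`NonInterpretableError` when the acquisition is saturated
    beyond use; an empty stack yields an empty list.
    """
    params = params or SpotDetectionParams()
    if zstack.data.size == 0 or zstack.n_planes == 0:
        return []
    px = zstack.require_pixel_size()
    data = zstack.data
    sat = float((data >= params.saturation_level).mean())
    if sat > params.saturated_fraction_limit:
        raise NonInterpretableError(f"{sat:.0%} of pixels saturated; spots uncountable")

    sigma_px = params.lateral_sigma_um / px
    link_px = params.link_radius_um / px
    bg = float(np.median(data))

    # collect per-plane peaks then link across consecutive planes
    tracks: list[dict] = []  # {last_z, points: [(z, r, c, I)]}
    for j in range(zstack.n_planes):
        peaks = _plane_peaks(data[j], sigma_px, params.response_sigmas, params.response_threshold)
        used = set()
        for r, c, resp in peaks:
            intensity = float(data[j, r, c]) - bg
            best, best_d = None, link_px
            for ti, tr in enumerate(tracks):
                if ti in used or tr["last_z"] != j - 1:
                    continue
                lz, lr, lc, _ = tr["points"][-1]
                d = math.hypot(r - lr, c - lc)
                if d <= best_d:
                    best, best_d = ti, d
            if best is None:
                tracks.append({"last_z": j, "points": [(j, r, c, intensity)]})
            else:
                tracks[best]["points"].append((j, r, c, intensity))
                tracks[best]["last_z"] = j
                used.add(best)

    spots: list[FishSpot3D] = []
    fwhm_px = 2.355 * sigma_px
    for tr in tracks:
        pts = tr["points"]
        w = np.array([max(p[3], 1e-6) for p in pts])
        zz = np.array([p[0] for p in pts], dtype=float)
        rr = np.array([p[1] for p in pts], dtype=float)
        cc = np.array([p[2] for p in pts], dtype=float)
        z_idx = float(np.average(zz, weights=w))
        peak_i = int(np.argmax(w))
        jb, rb, cb = pts[peak_i][0], pts[peak_i][1], pts[peak_i][2]
        diam_px = _footprint_diameter_px(data[jb], rb, cb, bg)
        saturated = bool(data[jb, rb, cb] >= params.saturation_level)
        spots.append(
            FishSpot3D(
                x_um=float(np.average(cc, weights=w)) * px,
                y_um=float(np.average(rr, weights=w)) * px,
                z_um=float(zstack.plane_z_um(z_idx)),
                channel=zstack.role,
                peak_intensity=float(w.max()),
                lateral_diameter_um=diam_px * px,
                z_extent=len(pts),
                may_be_merged=bool(diam_px > params.merge_diameter_factor * fwhm_px),
                saturated=saturated,
            )
        )
    # a second merge cue: a spot far brighter than its cohort is likely two
    # fused signals below lateral resolution
    if len(spots) >= 3:
        med_peak = float(np.median([s.peak_intensity for s in spots]))
        for s in spots:
            if s.peak_intensity > params.merge_intensity_factor * med_peak:
                s.may_be_merged = True
    return spots


# ---------------------------------------------------------------------------
# multi-exposure fusion


@dataclass
class FusionResult:
    exposure_ms: float
    spots: list[FishSpot3D]
    counts: dict[float, int | None]  # per-exposure countable-spot counts (None = n.i.)


def countable_spots(spots: "list[FishSpot3D]") -> "list[FishSpot3D]":
    """Spots that can be counted reliably: saturated blobs flagged as merged
    (two truth-distinct peaks bloomed together) are excluded."""
    return [s for s in spots if not (s.saturated and s.may_be_merged)]


def multi_exposure_fuse(
    detections: dict[float, "list[FishSpot3D] | NonInterpretableError"],
) -> FusionResult:
    """Pick the exposure maximising the countable-spot count for one channel.

    ``detections`` maps exposure time to either a spot list or a
    :class:`NonInterpretableError`.  Counting uses :func:`countable_spots`,
    so an exposure that saturate-merges a pair another exposure resolves is
    penalised.  Ties go to the lowest exposure (least bloom — thick signals
    can fake the distance between two spots).  All-n.i. input raises
    :class:`NonInterpretableError`.
    """
    if not detections:
        raise NonInterpretableError("no exposures acquired")
    counts: dict[float, int | None] = {}
    for exposure, result in detections.items():
        counts[exposure] = (
            None if isinstance(result, NonInterpretableError) else len(countable_spots(result))
        )
    valid = {e: c for e, c in counts.items() if c is not None}
    if not valid:
        raise NonInterpretableError("all exposures non-interpretable")
    best_count = max(valid.values())
    chosen = min(e for e, c in valid.items() if c == best_count)
    return FusionResult(exposure_ms=chosen, spots=countable_spots(detections[chosen]), counts=counts)


# ---------------------------------------------------------------------------
# break-apart calling


@dataclass
class BreakApartRules:
    """Pairing distances in units of the combined signal diameter."""

    signal_diameter_um: float = 1.0
    d_fuse_um: float | None = None  # default: 1 signal diameter
    d_split_um: float | None = None  # default: 2 signal diameters
    copy_gain_min_fused: int = 3  # fused pairs > 2 -> copy gain

    def __post_init__(self) -> None:
        if self.d_fuse_um is None:
            self.d_fuse_um = self.signal_diameter_um
        if self.d_split_um is None:
            self.d_split_um = 2.0 * self.signal_diameter_um
        if self.d_split_um <= self.d_fuse_um:
            raise ValueError("d_split_um must exceed d_fuse_um")


@dataclass
class FishCall:
    verdict: str
    red_count: int
    green_count: int
    fused_pairs: int
    split_pairs: int
    isolated: int = 0
    reason: str | None = None

    def __post_init__(self) -> None:
        if min(self.red_count, self.green_count, self.fused_pairs, self.split_pairs) < 0:
            raise ValueError("counts must be non-negative")
        if self.verdict == NON_INTERPRETABLE and not self.reason:
            raise ValueError("non-interpretable calls must carry a reason")


def _pair_mutual_nearest(red: list[FishSpot3D], green: list[FishSpot3D]) -> list[tuple[int, int, float]]:
    """Greedy globally-closest pairing (mutual nearest neighbours)."""
    if not red or not green:
        return []
    rp = np.array([[s.x_um, s.y_um, s.z_um] for s in red])
    gp = np.array([[s.x_um, s.y_um, s.z_um] for s in green])
    d = np.sqrt(((rp[:, None, :] - gp[None, :, :]) ** 2).sum(-1))
    pairs = []
    used_r: set[int] = set()
    used_g: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for i, j in order:
        if i in used_r or j in used_g:
            continue
        pairs.append((int(i), int(j), float(d[i, j])))
        used_r.add(int(i))
        used_g.add(int(j))
    return pairs


def call_break_apart(
    red: list[FishSpot3D],
    green: list[FishSpot3D],
    rules: BreakApartRules | None = None,
) -> FishCall:
    """Per-cell verdict from fused/split red-green pairing."""
    rules = rules or BreakApartRules()
    if not red and not green:
        return FishCall(
            verdict=NON_INTERPRETABLE,
            red_count=0,
            green_count=0,
            fused_pairs=0,
            split_pairs=0,
            reason="no signals in either channel",
        )
    pairs = _pair_mutual_nearest(red, green)
    fused = sum(1 for _, _, d in pairs if d <= rules.d_fuse_um)
    split = sum(1 for _, _, d in pairs if d >= rules.d_split_um)
    isolated = abs(len(red) - len(green))
    if split >= 1 or isolated >= 1:
        verdict = REARRANGED
    elif fused >= rules.copy_gain_min_fused:
        verdict = NATIVE_COPY_GAIN
    else:
        verdict = NATIVE
    return FishCall(
        verdict=verdict,
        red_count=len(red),
        green_count=len(green),
        fused_pairs=fused,
        split_pairs=split,
        isolated=isolated,
    )


# ---------------------------------------------------------------------------
# spot-count tables and the detection-rate statistic


class SpotCountTable:
    """Rectangular per-cell x per-setting spot counts; missing = n.i.

    Thin wrapper over a pandas ``DataFrame`` (rows: cell ids, columns:
    setting labels, ``NaN`` for non-interpretable entries).
    """

    def __init__(self, df: pd.DataFrame) -> None:
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise ValueError("duplicate cell ids or settings in spot-count table")
        self.df = df.astype(float)

    @classmethod
    def from_records(cls, records: "list[tuple[object, object, float | None]]") -> "SpotCountTable":
        """Build from ``(cell_id, setting, count-or-None)`` triples."""
        seen: dict[tuple, float | None] = {}
        for cell, setting, count in records:
            key = (cell, setting)
            if key in seen:
                raise ValueError(f"duplicate entry for cell {cell!r} at setting {setting!r}")
            seen[key] = count
        cells = list(dict.fromkeys(c for c, _, _ in records))
        settings = list(dict.fromkeys(s for _, s, _ in records))
        df = pd.DataFrame(np.nan, index=pd.Index(cells, name="cell_id"), columns=settings)
        for (cell, setting), count in seen.items():
            df.loc[cell, setting] = np.nan if count is None else float(count)
        return cls(df)

    @property
    def settings(self) -> list:
        return list(self.df.columns)

    @property
    def cells(self) -> list:
        return list(self.df.index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpotCountTable):
            return NotImplemented
        if list(self.df.index) != list(other.df.index) or list(self.df.columns) != list(other.df.columns):
            return False
        a, b = self.df.to_numpy(), other.df.to_numpy()
        return bool(((a == b) | (np.isnan(a) & np.isnan(b))).all())


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def detection_rate(table: SpotCountTable, setting) -> int:
    """Percentage of cells whose maximum observed count is attained at
    ``setting`` (ties count for every tying setting; n.i. entries are
    ignored when taking a row's maximum), rounded to the nearest integer.

    Rows with no observed entry at all are dropped with a warning.
    """
    df = table.df
    if setting not in df.columns:
        raise KeyError(f"setting {setting!r} not in table columns {list(df.columns)}")
    n = 0
    k = 0
    n_dropped = 0
    values = df.to_numpy()
    col = list(df.columns).index(setting)
    for row in values:
        observed = row[~np.isnan(row)]
        if observed.size == 0:
            n_dropped += 1
            continue
        n += 1
        if not np.isnan(row[col]) and row[col] == observed.max():
            k += 1
    if n_dropped:
        warnings.warn(f"{n_dropped} fully non-interpretable row(s) dropped from detection rate")
    if n == 0:
        raise ValueError("table has no interpretable rows")
    return _round_half_up(100.0 * k / n)


def build_spot_count_table(cells, settings, counter) -> SpotCountTable:
    """Evaluate ``counter(cell, setting) -> count | None`` over the grid."""
    if len(set(settings)) != len(list(settings)):
        raise ValueError("duplicate settings")
    records = []
    for ci, cell in enumerate(cells):
        for setting in settings:
            records.append((ci, setting, counter(cell, setting)))
    return SpotCountTable.from_records(records)


# ---------------------------------------------------------------------------
# simulated sweeps


@dataclass
class SweepResult:
    table: SpotCountTable
    rates: dict
    capture_fraction: dict


def _default_cohort(n_cells: int, seed: int, nucleus_thickness_um: float, spots_per_channel: int) -> list[SimulatedCell]:
    rng = np.random.default_rng(seed)
    return [
        make_fish_cell(
            rng,
            nucleus_thickness_um=nucleus_thickness_um,
            n_red=spots_per_channel,
            n_green=spots_per_channel,
        )
        for _ in range(n_cells)
    ]


def _scan_cell(
    cell: SimulatedCell,
    n_stacks: int,
    step_um: float,
    channel: str,
    surface: FocalSurface,
    rng: np.random.Generator,
    params: SpotDetectionParams,
) -> tuple[int | None, float]:
    """Count detected spots for one cell at one setting; returns
    (count-or-None, captured fraction of planted spots in this channel)."""
    planted = sum(1 for s in cell.fish_spots if s.channel == channel)
    stack = render_zstack(
        [cell],
        surface,
        n_stacks=n_stacks,
        step_um=step_um,
        channel=channel,
        center_um=cell.center_um,
        rng=rng,
    )
    try:
        spots = detect_spots(stack, params)
    except NonInterpretableError:
        return None, 0.0
    return len(spots), (len(spots) / planted if planted else 0.0)


def zstack_sweep(
    stacks: tuple[int, ...] = (5, 10, 15, 20, 25, 30),
    step_um: float = 0.6,
    n_cells: int = 12,
    spots_per_channel: int = 6,
    nucleus_thickness_um: float = 14.0,
    channel: str = FISH_RED,
    seed: int = 0,
    surface: FocalSurface | None = None,
    params: SpotDetectionParams | None = None,
) -> SweepResult:
    """Re-scan one simulated cohort at several z-stack counts.

    Returns the spot-count table, the per-setting detection rates and the
    mean captured-spot fraction per setting.
    """
    cohort = _default_cohort(n_cells, seed, nucleus_thickness_um, spots_per_channel)
    surface = surface or FocalSurface.flat(refocus_sd_um=0.3)
    params = params or SpotDetectionParams()
    capture: dict = {}
    records = []
    for n_stacks in stacks:
        fractions = []
        for ci, cell in enumerate(cohort):
            rng = np.random.default_rng((seed, n_stacks, ci))
            count, frac = _scan_cell(cell, n_stacks, step_um, channel, surface, rng, params)
            records.append((ci, n_stacks, count))
            fractions.append(frac)
        capture[n_stacks] = float(np.mean(fractions))
    table = SpotCountTable.from_records(records)
    rates = {s: detection_rate(table, s) for s in stacks}
    return SweepResult(table=table, rates=rates, capture_fraction=capture)


def step_sweep(
    steps: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8),
    n_stacks: int = 30,
    n_cells: int = 12,
    spots_per_channel: int = 6,
    nucleus_thickness_um: float = 14.0,
    channel: str = FISH_RED,
    seed: int = 0,
    surface: FocalSurface | None = None,
    params: SpotDetectionParams | None = None,
) -> SweepResult:
    """Re-scan one simulated cohort at several step sizes (fixed 30 stacks)."""
    cohort = _default_cohort(n_cells, seed, nucleus_thickness_um, spots_per_channel)
    surface = surface or FocalSurface.flat(refocus_sd_um=0.3)
    params = params or SpotDetectionParams()
    capture: dict = {}
    records = []
    for step in steps:
        fractions = []
        for ci, cell in enumerate(cohort):
            rng = np.random.default_rng((seed, int(step * 1000), ci))
            count, frac = _scan_cell(cell, n_stacks, step, channel, surface, rng, params)
            records.append((ci, step, count))
            fractions.append(frac)
        capture[step] = float(np.mean(fractions))
    table = SpotCountTable.from_records(records)
    rates = {s: detection_rate(table, s) for s in steps}
    return SweepResult(table=table, rates=rates, capture_fraction=capture)
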