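"""File formats: multi-page TIFF with calibration metadata, gallery and
spot-count CSVs, ground-truth JSON sidecars.

CSV dialect is UTF-8, comma-separated, ``.`` decimal; missing FISH counts
are written as the literal ``n.i.``.  Every writer has a matching reader and
round-trips losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from ctcscan.fafish import SpotCountTable
from ctcscan.image import ChannelImage, ZStackSeries
from ctcscan.phenotype import CellCategory, GalleryRecord
from ctcscan.simulate import SimFishSpot, SimulatedCell

NI_TOKEN = "n.i."

GALLERY_COLUMNS = [
    "id",
    "category",
    "area_um2",
    "Avg_Int",
    "Avg_Int_Bg",
    "Sec_Avg_Int",
    "Ter_Avg_Int",
    "Quat_Avg_Int",
    "review_status",
]


class FormatError(ValueError):
    """Unreadable file or missing required metadata."""


# ---------------------------------------------------------------------------
# TIFF


def write_spot_tiff(path, images: dict[str, ChannelImage]) -> None:
    """Multi-page TIFF, one page per channel, calibration in the page
    description JSON."""
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for role, img in images.items():
            meta = {
                "role": role,
                "pixel_size_um": img.pixel_size_um,
                "exposure_ms": img.exposure_ms,
                "kind": "channel",
            }
            tif.write(np.asarray(img.data), description=json.dumps(meta))


def write_zstack_tiff(path, stack: ZStackSeries) -> None:
    path = Path(path)
    with tifffile.TiffWriter(path) as tif:
        for j in range(stack.n_planes):
            meta = {
                "role": stack.role,
                "pixel_size_um": stack.pixel_size_um,
                "exposure_ms": stack.exposure_ms,
                "kind": "zplane",
                "step_um": stack.step_um,
                "z_center_um": stack.z_center_um,
                "plane": j,
                "n_planes": stack.n_planes,
            }
            tif.write(stack.data[j], description=json.dumps(meta))


def _page_meta(page) -> dict:
    desc = page.tags.get("ImageDescription")
    if desc is None:
        raise FormatError("TIFF page has no description metadata")
    try:
        meta = json.loads(desc.value)
    except (TypeError, json.JSONDecodeError) as exc:
        raise FormatError(f"TIFF page description is not valid JSON: {exc}") from exc
    if meta.get("pixel_size_um") is None:
        raise FormatError("TIFF metadata lacks pixel_size_um")
    return meta


def read_images(path) -> "dict[str, ChannelImage] | ZStackSeries":
    """Read a package-written TIFF back into channel images or a z-stack."""
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [(
                _page_meta(p),
                p.asarray(),
            ) for p in tif.pages]
    except FormatError:
        raise
    except Exception as exc:  # truncated / not a TIFF
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if not pages:
        raise FormatError(f"{path} contains no pages")
    kind = pages[0][0].get("kind")
    if kind == "channel":
        return {
            meta["role"]: ChannelImage(
                data,
                pixel_size_um=meta["pixel_size_um"],
                role=meta["role"],
                exposure_ms=meta.get("exposure_ms"),
            )
            for meta, data in pages
        }
    if kind == "zplane":
        meta0 = pages[0][0]
        if len(pages) != meta0.get("n_planes"):
            raise FormatError(
                f"z-stack {path} truncated: {len(pages)} pages, expected {meta0.get('n_planes')}"
            )
        data = np.stack([d for _, d in pages])
        return ZStackSeries(
            data,
            pixel_size_um=meta0["pixel_size_um"],
            step_um=meta0["step_um"],
            role=meta0["role"],
            z_center_um=meta0.get("z_center_um", 0.0),
            exposure_ms=meta0.get("exposure_ms"),
        )
    raise FormatError(f"unknown page kind {kind!r} in {path}")


# ---------------------------------------------------------------------------
# ground truth sidecar


def cells_to_json(cells: list[SimulatedCell], path) -> None:
    payload = []
    for c in cells:
        d = dataclasses.asdict(c)
        d["center_um"] = list(c.center_um)
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=1))


def cells_from_json(path) -> list[SimulatedCell]:
    payload = json.loads(Path(path).read_text())
    cells = []
    for d in payload:
        spots = [SimFishSpot(**s) for s in d.pop("fish_spots", [])]
        d["center_um"] = tuple(d["center_um"])
        cells.append(SimulatedCell(**d, fish_spots=spots))
    return cells


# ---------------------------------------------------------------------------
# gallery CSV / JSON


def write_gallery_csv(records: list[GalleryRecord], path) -> None:
    rows = [
        {
            "id": r.candidate_id,
            "category": r.category.value,
            "area_um2": r.area_um2,
            "Avg_Int": r.avg_int,
            "Avg_Int_Bg": r.avg_int_bg,
            "Sec_Avg_Int": r.sec_avg_int,
            "Ter_Avg_Int": r.ter_avg_int,
            "Quat_Avg_Int": r.quat_avg_int,
            "review_status": r.review_status,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=GALLERY_COLUMNS).to_csv(path, index=False)


def read_gallery_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(GALLERY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"gallery CSV missing columns {sorted(missing)}")
    return df


def gallery_to_json(records: list[GalleryRecord], path) -> None:
    payload = []
    for r in records:
        payload.append(
            {
                "candidate_id": r.candidate_id,
                "category": r.category.value,
                "area_um2": r.area_um2,
                "equiv_diameter_um": r.equiv_diameter_um,
                "centroid_um": list(r.centroid_um),
                "avg_int": r.avg_int,
                "avg_int_bg": r.avg_int_bg,
                "sec_avg_int": r.sec_avg_int,
                "ter_avg_int": r.ter_avg_int,
                "quat_avg_int": r.quat_avg_int,
                "review_status": r.review_status,
                "crops": {role: crop.tolist() for role, crop in r.crops.items()},
                "crop_dtype": {role: str(crop.dtype) for role, crop in r.crops.items()},
            }
        )
    Path(path).write_text(json.dumps(payload))


def gallery_from_json(path) -> list[GalleryRecord]:
    payload = json.loads(Path(path).read_text())
    records = []
    for d in payload:
        crops = {
            role: np.array(vals, dtype=d["crop_dtype"][role]) for role, vals in d["crops"].items()
        }
        records.append(
            GalleryRecord(
                candidate_id=d["candidate_id"],
                category=CellCategory(d["category"]),
                crops=crops,
                area_um2=d["area_um2"],
                equiv_diameter_um=d["equiv_diameter_um"],
                centroid_um=tuple(d["centroid_um"]),
                avg_int=d["avg_int"],
                avg_int_bg=d["avg_int_bg"],
                sec_avg_int=d["sec_avg_int"],
                ter_avg_int=d["ter_avg_int"],
                quat_avg_int=d["quat_avg_int"],
                review_status=d["review_status"],
            )
        )
    return records


# ---------------------------------------------------------------------------
# FISH spot-count table CSV


def write_fish_table_csv(table: SpotCountTable, path) -> None:
    df = table.df.copy()
    out = df.map(lambda v: NI_TOKEN if pd.isna(v) else (int(v) if float(v).is_integer() else v))
    out.index.name = "cell_id"
    out.to_csv(path)


def read_fish_table_csv(path) -> SpotCountTable:
    df = pd.read_csv(path, index_col=0, dtype=str)
    def parse(v):
        if pd.isna(v) or str(v).strip() in (NI_TOKEN, "n.i", "ni", ""):
            return np.nan
        return float(v)
    parsed = df.map(parse)
    # prefer numeric column labels where possible (z-stack counts, steps)
    cols = []
    for c in parsed.columns:
        try:
            f = float(c)
            cols.append(int(f) if f.is_integer() else f)
        except ValueError:
            cols.append(c)
    parsed.columns = cols
    return SpotCountTable(parsed)
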