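"""File formats: NIfTI volumes with CSV frame-timing sidecars, CSV TAC and
result tables, and raster section images."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .core import DynamicImage, FrameSchedule, LabelAtlas, TimeActivityCurve

__all__ = [
    "save_schedule", "load_schedule",
    "save_dynamic_image", "load_dynamic_image",
    "save_atlas", "load_atlas",
    "save_map", "load_map",
    "tacs_to_table", "table_to_tacs", "save_tacs", "load_tacs",
    "save_section_image", "load_section_image",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def save_schedule(schedule: FrameSchedule, path) -> None:
    pd.DataFrame({
        "frame_start_s": schedule.frame_start,
        "frame_dur_s": schedule.frame_duration,
    }).to_csv(path, index=False)


def load_schedule(path) -> FrameSchedule:
    tab = pd.read_csv(path)
    return FrameSchedule(tab.frame_start_s.to_numpy(), tab.frame_dur_s.to_numpy())


def save_dynamic_image(image: DynamicImage, path, timing_path) -> None:
    nib.save(nib.Nifti1Image(image.data.astype(np.float32), _affine(image.voxel_size_mm)),
             str(path))
    save_schedule(image.schedule, timing_path)


def load_dynamic_image(path, timing_path) -> DynamicImage:
    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    return DynamicImage(np.asarray(img.dataobj, dtype=np.float32),
                        load_schedule(timing_path), voxel)


def save_atlas(atlas: LabelAtlas, path, names_path=None, voxel_size_mm: float = 0.776) -> None:
    nib.save(nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(voxel_size_mm)), str(path))
    if names_path is not None:
        pd.DataFrame(
            {"label": list(atlas.names), "region": list(atlas.names.values())}
        ).to_csv(names_path, index=False)


def load_atlas(path, names_path=None) -> LabelAtlas:
    labels = np.asarray(nib.load(str(path)).dataobj).astype(np.int16)
    names = {}
    if names_path is not None:
        tab = pd.read_csv(names_path)
        names = dict(zip(tab.label.astype(int), tab.region.astype(str)))
    return LabelAtlas(labels, names)


def save_map(map3d: np.ndarray, path, voxel_size_mm: float = 0.776) -> None:
    nib.save(nib.Nifti1Image(np.asarray(map3d, dtype=np.float32), _affine(voxel_size_mm)),
             str(path))


def load_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float32)


def tacs_to_table(tacs: dict[str, TimeActivityCurve]) -> pd.DataFrame:
    rows = []
    for name, tac in tacs.items():
        rows.append(pd.DataFrame({
            "frame_start_s": tac.schedule.frame_start,
            "frame_dur_s": tac.schedule.frame_duration,
            "region": name,
            "activity_kBq_cc": tac.activity,
        }))
    return pd.concat(rows, ignore_index=True)


def table_to_tacs(table: pd.DataFrame) -> dict[str, TimeActivityCurve]:
    out = {}
    for region, sub in table.groupby("region", sort=False):
        sub = sub.sort_values("frame_start_s")
        schedule = FrameSchedule(sub.frame_start_s.to_numpy(), sub.frame_dur_s.to_numpy())
        out[str(region)] = TimeActivityCurve(schedule, sub.activity_kBq_cc.to_numpy(),
                                             str(region))
    return out


def save_tacs(tacs: dict[str, TimeActivityCurve], path) -> None:
    tacs_to_table(tacs).to_csv(path, index=False)


def load_tacs(path) -> dict[str, TimeActivityCurve]:
    return table_to_tacs(pd.read_csv(path))


def save_section_image(img: np.ndarray, path) -> None:
    iio.imwrite(Path(path), img)


def load_section_image(path) -> np.ndarray:
    return iio.imread(Path(path))
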