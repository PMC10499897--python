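"""File readers and writers for the pipeline's input/output formats.

Synthetic and real data travel through the same files: multi-page TIFF
for mask movies and two-channel stacks (via ``tifffile``), CSV point
and force tables (via ``pandas``), and a JSON ground-truth sidecar per
generated dataset. Analysis modules consume the objects returned by
the readers, so generated data can be round-tripped through disk and
analysed exactly like experimental exports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .buckle import BeadFrame
from .contour import ContourTrace
from .morphodynamics import MaskMovie
from .ruffles import RuffleField
from .synthgen import GroundTruth
from .zline import TwoChannelStack

__all__ = [
    "write_contours", "read_contours",
    "write_ruffle_field", "read_ruffle_field",
    "write_mask_movie", "read_mask_movie",
    "write_stack", "read_stack",
    "write_beads", "read_beads",
    "write_forces", "read_forces",
    "write_ground_truth", "read_ground_truth",
]


# ----------------------------------------------------------------- contours

def write_contours(traces: list[ContourTrace], contours_csv, fiducials_csv) -> None:
    """Write traces as (trace_id, point_index, x_px, y_px) + fiducial table."""
    rows, frows = [], []
    for tr in traces:
        for i, (x, y) in enumerate(tr.points):
            rows.append({"trace_id": tr.trace_id, "point_index": i,
                         "x_px": x, "y_px": y, "closed": tr.closed})
        frows.append({"trace_id": tr.trace_id,
                      "x_px": tr.fiducial[0], "y_px": tr.fiducial[1]})
    pd.DataFrame(rows).to_csv(contours_csv, index=False)
    pd.DataFrame(frows).to_csv(fiducials_csv, index=False)


def read_contours(contours_csv, fiducials_csv, pixel_size: float) -> list[ContourTrace]:
    pts = pd.read_csv(contours_csv)
    fids = pd.read_csv(fiducials_csv).set_index("trace_id")
    traces = []
    for tid, grp in pts.groupby("trace_id", sort=False):
        grp = grp.sort_values("point_index")
        closed = bool(grp["closed"].iloc[0]) if "closed" in grp else True
        traces.append(ContourTrace(
            points=grp[["x_px", "y_px"]].to_numpy(),
            pixel_size=pixel_size,
            fiducial=fids.loc[tid, ["x_px", "y_px"]].to_numpy(dtype=float),
            closed=closed, trace_id=str(tid)))
    return traces


# ------------------------------------------------------------ ridge textures

def write_ruffle_field(field: RuffleField, image_tiff, roi_tiff) -> None:
    tifffile.imwrite(image_tiff, field.image.astype(np.float32))
    tifffile.imwrite(roi_tiff, field.roi.astype(np.uint8))


def read_ruffle_field(image_tiff, roi_tiff, pixel_size: float,
                      image_id: str | None = None) -> RuffleField:
    return RuffleField(image=tifffile.imread(image_tiff).astype(float),
                       roi=tifffile.imread(roi_tiff).astype(bool),
                       pixel_size=pixel_size,
                       image_id=image_id or Path(str(image_tiff)).stem)


# --------------------------------------------------------------- mask movies

def write_mask_movie(movie: MaskMovie, masks_tiff, wave2_tiff=None) -> None:
    tifffile.imwrite(masks_tiff, movie.frames.astype(np.uint8))
    if wave2_tiff is not None and movie.wave2 is not None:
        tifffile.imwrite(wave2_tiff, movie.wave2.astype(np.uint8))


def read_mask_movie(masks_tiff, wave2_tiff=None, frame_interval: float = 5.0,
                    pixel_size: float = 0.1) -> MaskMovie:
    frames = tifffile.imread(masks_tiff)
    wave2 = tifffile.imread(wave2_tiff).astype(bool) if wave2_tiff else None
    return MaskMovie(frames=frames, wave2=wave2,
                     frame_interval=frame_interval, pixel_size=pixel_size)


# -------------------------------------------------------- two-channel stacks

def write_stack(stack: TwoChannelStack, path) -> None:
    """Two-channel stack as a (2, z, y, x) TIFF, channel axis tagged."""
    arr = np.stack([stack.mem, stack.prot]).astype(np.float32)
    tifffile.imwrite(path, arr, metadata={"axes": "CZYX"})


def read_stack(path, z_step: float, pixel_size: float = 0.1) -> TwoChannelStack:
    arr = tifffile.imread(path)
    if arr.ndim != 4 or arr.shape[0] != 2:
        raise ValueError("expected a (2, z, y, x) two-channel stack")
    return TwoChannelStack(mem=arr[0], prot=arr[1], z_step=z_step,
                           pixel_size=pixel_size)


# --------------------------------------------------------------- bead tables

def write_beads(frames: list[BeadFrame], path) -> None:
    """Bead + tracer table: frame, kind, x_nm, y_nm, z_nm."""
    rows = []
    for t, fr in enumerate(frames):
        for x, y, z in fr.beads:
            rows.append({"frame": t, "kind": "bead",
                         "x_nm": x, "y_nm": y, "z_nm": z})
        rows.append({"frame": t, "kind": "tracer",
                     "x_nm": fr.tracer_xy[0], "y_nm": fr.tracer_xy[1],
                     "z_nm": np.nan})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_beads(path, box: tuple[float, float]) -> list[BeadFrame]:
    df = pd.read_csv(path)
    frames = []
    for t, grp in df.groupby("frame", sort=True):
        beads = grp[grp["kind"] == "bead"][["x_nm", "y_nm", "z_nm"]].to_numpy()
        tracer = grp[grp["kind"] == "tracer"]
        if len(tracer) != 1:
            raise ValueError(f"frame {t}: expected exactly one tracer row")
        frames.append(BeadFrame(beads=beads,
                                tracer_xy=tracer[["x_nm", "y_nm"]].to_numpy()[0],
                                box=box, time_ns=float(t)))
    return frames


# -------------------------------------------------------------- force tables

def write_forces(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_forces(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"cell_id", "group", "force_pN"}
    if not required.issubset(df.columns):
        raise ValueError(f"force table must have columns {sorted(required)}")
    return df


# -------------------------------------------------------------- ground truth

class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return super().default(obj)


def write_ground_truth(gt: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(gt.as_dict(), cls=_NumpyEncoder, indent=1))


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(kind=d["kind"], seed=d["seed"], params=d["params"])
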