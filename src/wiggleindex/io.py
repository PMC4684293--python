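"""Frame ingestion, plate layout, assay metadata, and result export.

The canonical input is a folder of frames (JPEG or TIFF) from one
10-second, 4-well video; a 24-well plate filmed at one time point is six
such folders.  Frames are converted to grayscale on ingestion and kept on
the native 8-bit 0–255 scale as 64-bit floats, because the downstream
sigma_S threshold is calibrated to 8-bit magnitudes.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "DataError",
    "FrameStack",
    "WellBox",
    "PlateLayout",
    "AssayMetadata",
    "NamingTemplate",
    "load_frame_sequence",
    "crop_wells",
    "parse_metadata",
    "write_heatmap",
    "write_sigma_tiff",
    "write_results_table",
    "read_results_table",
    "RESULTS_COLUMNS",
]

# Grayscale conversion uses ITU-R BT.601 luma weights (0.299, 0.587, 0.114).
# The integer form keeps already-gray pixels (r = g = b = v) exactly at v.
_LUMA_NUM = np.array([299.0, 587.0, 114.0])

#: Column order of the results CSV (stable contract for downstream tools).
RESULTS_COLUMNS = [
    "well_id",
    "genotype",
    "insecticide",
    "dose_ppm",
    "time_min",
    "wi_value",
    "pixels_above_threshold",
]


class DataError(Exception):
    """Unreadable, inconsistent, or contract-violating input data."""


@dataclass
class FrameStack:
    """Ordered grayscale frames for one field of view.

    ``frames`` is a float64 array of shape (frame, row, column) with
    intensities in [0, 255].
    """

    frames: np.ndarray
    frame_rate: float = 25.0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise DataError(
                f"frames must be a non-empty (frame, row, col) array, "
                f"got shape {self.frames.shape}"
            )
        lo, hi = float(self.frames.min()), float(self.frames.max())
        if lo < 0.0 or hi > 255.0:
            raise DataError(f"intensities must lie in [0, 255], got [{lo}, {hi}]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class WellBox:
    """Axis-aligned well bounding box; 0-based, half-open pixel ranges."""

    well_id: str
    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self) -> None:
        if self.row_start >= self.row_stop or self.col_start >= self.col_stop:
            raise DataError(f"empty bounding box for well {self.well_id!r}")
        if min(self.row_start, self.col_start) < 0:
            raise DataError(f"negative bounding box for well {self.well_id!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.row_stop - self.row_start, self.col_stop - self.col_start


@dataclass
class PlateLayout:
    """Well positions within one video frame (default grid: 2 x 2 wells)."""

    wells: list[WellBox]
    grid_shape: tuple[int, int] = (2, 2)

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise DataError(f"duplicate well ids in layout: {sorted(ids)}")

    @classmethod
    def regular_grid(
        cls,
        frame_shape: tuple[int, int],
        grid_shape: tuple[int, int] = (2, 2),
        well_ids: Sequence[str] | None = None,
    ) -> "PlateLayout":
        """Evenly tile ``frame_shape`` into a rows x cols grid of wells."""
        nr, nc = grid_shape
        H, W = frame_shape
        if well_ids is None:
            well_ids = [
                f"{string.ascii_uppercase[r]}{c + 1}" for r in range(nr) for c in range(nc)
            ]
        if len(well_ids) != nr * nc:
            raise DataError(f"need {nr * nc} well ids, got {len(well_ids)}")
        boxes = []
        rows = np.linspace(0, H, nr + 1).astype(int)
        cols = np.linspace(0, W, nc + 1).astype(int)
        k = 0
        for r in range(nr):
            for c in range(nc):
                boxes.append(
                    WellBox(well_ids[k], rows[r], rows[r + 1], cols[c], cols[c + 1])
                )
                k += 1
        return cls(wells=boxes, grid_shape=grid_shape)


@dataclass(frozen=True)
class AssayMetadata:
    """What one well/time-point measurement is: genotype, treatment, when."""

    genotype: str = ""
    insecticide: str = ""
    dose_ppm: float = 0.0
    time_min: float = 0.0
    well_id: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.dose_ppm < 0:
            raise DataError(f"dose must be >= 0, got {self.dose_ppm}")

    @property
    def group(self) -> str:
        """Group label for statistics: genotype x insecticide x dose."""
        dose = f"{self.dose_ppm:g}"
        return f"{self.genotype}|{self.insecticide}|{dose}ppm"


_FIELD_PATTERNS = {
    "genotype": r"(?P<genotype>[A-Za-z0-9.+-]+)",
    "insecticide": r"(?P<insecticide>[A-Za-z0-9.+-]+)",
    "dose_ppm": r"(?P<dose_ppm>\d+(?:\.\d+)?)",
    "time_min": r"(?P<time_min>\d+(?:\.\d+)?)",
    "well_id": r"(?P<well_id>[A-Za-z0-9]+)",
    "replicate": r"(?P<replicate>[A-Za-z0-9]+)",
}


@dataclass(frozen=True)
class NamingTemplate:
    """File-name template with ``{field}`` placeholders and literal separators.

    Example: ``"{genotype}_{insecticide}_{dose_ppm}ppm_t{time_min}_v{replicate}.avi"``
    parses ``"ArmeniaI4_imi_48ppm_t30_v2.avi"``.  Parsing is strict — a
    missing or malformed field raises rather than silently defaulting —
    and ``format`` is its exact inverse on valid metadata.
    """

    template: str

    def _regex(self) -> re.Pattern[str]:
        parts: list[str] = []
        for literal, name, spec_, conv in string.Formatter().parse(self.template):
            parts.append(re.escape(literal))
            if name is not None:
                if name not in _FIELD_PATTERNS:
                    raise DataError(
                        f"unknown template field {name!r}; "
                        f"known: {sorted(_FIELD_PATTERNS)}"
                    )
                parts.append(_FIELD_PATTERNS[name])
        return re.compile("^" + "".join(parts) + "$")

    def parse(self, filename: str) -> AssayMetadata:
        m = self._regex().match(filename)
        if m is None:
            raise DataError(
                f"filename {filename!r} does not match template {self.template!r}"
            )
        kw: dict[str, object] = m.groupdict()
        for num in ("dose_ppm", "time_min"):
            if num in kw:
                kw[num] = float(kw[num])  # type: ignore[arg-type]
        return AssayMetadata(**kw)  # type: ignore[arg-type]

    def format(self, meta: AssayMetadata) -> str:
        values = {
            "genotype": meta.genotype,
            "insecticide": meta.insecticide,
            "dose_ppm": f"{meta.dose_ppm:g}",
            "time_min": f"{meta.time_min:g}",
            "well_id": meta.well_id,
            "replicate": meta.replicate,
        }
        return self.template.format(**values)


def parse_metadata(filename: str, template: str | NamingTemplate) -> AssayMetadata:
    """Parse assay metadata out of a (video or folder) name."""
    if not isinstance(template, NamingTemplate):
        template = NamingTemplate(template)
    return template.parse(filename)


_NUM_RE = re.compile(r"(\d+)")


def _natural_key(name: str) -> tuple:
    """Sort key treating digit runs numerically: frame_2 < frame_10."""
    return tuple(int(tok) if tok.isdigit() else tok for tok in _NUM_RE.split(name))


def _to_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3]
        return rgb @ _LUMA_NUM / 1000.0
    raise DataError(f"unsupported frame shape {arr.shape}")


def load_frame_sequence(
    directory: str | Path,
    pattern: str = "*",
    frame_rate: float = 25.0,
) -> FrameStack:
    """Load an image-sequence folder into a :class:`FrameStack`.

    Files matching ``pattern`` are ordered by natural-numeric sort of their
    names (so ``frame_10`` follows ``frame_2``), read, and converted to
    grayscale.  RGB input is converted with BT.601 luma weights before any
    computation.  A video container (AVI/MP4) may be passed instead of a
    folder; it is decoded through imageio behind the same interface.
    """
    path = Path(directory)
    if path.is_file():
        try:
            raw = iio.imread(path)
        except Exception as exc:  # pragma: no cover - codec availability
            raise DataError(f"cannot decode video {path}: {exc}") from exc
        frames = [_to_gray(fr) for fr in raw]
    else:
        if not path.is_dir():
            raise DataError(f"no such frame folder: {path}")
        files = sorted(
            (p for p in path.glob(pattern) if p.is_file()),
            key=lambda p: _natural_key(p.name),
        )
        if not files:
            raise DataError(f"no frames matching {pattern!r} in {path}")
        frames = []
        for p in files:
            try:
                frames.append(_to_gray(iio.imread(p)))
            except DataError:
                raise
            except Exception as exc:
                raise DataError(f"unreadable frame {p}: {exc}") from exc
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise DataError(f"inconsistent frame shapes: {sorted(shapes)}")
    return FrameStack(
        frames=np.stack(frames), frame_rate=frame_rate, source_id=path.name
    )


def crop_wells(
    stack: FrameStack, layout: PlateLayout
) -> list[tuple[str, FrameStack]]:
    """Cut one sub-stack per well out of a multi-well video.

    Each sub-stack keeps every frame of the input; pixels outside the
    well's bounding box are excluded.  The crop is the full rectangle; an
    optional circular mask is deliberately not applied by default.
    """
    H, W = stack.frame_shape
    out = []
    for box in layout.wells:
        if box.row_stop > H or box.col_stop > W:
            raise DataError(
                f"well {box.well_id!r} box exceeds frame bounds {H}x{W}"
            )
        sub = stack.frames[:, box.row_start : box.row_stop, box.col_start : box.col_stop]
        out.append(
            (
                box.well_id,
                FrameStack(
                    frames=sub.copy(),
                    frame_rate=stack.frame_rate,
                    source_id=f"{stack.source_id}/{box.well_id}",
                ),
            )
        )
    return out


def write_heatmap(
    field,
    path: str | Path,
    cmap: str = "inferno",
    vmin: float = 0.0,
    vmax: float | None = None,
) -> Path:
    """Write a sigma_S map as a PNG heat map plus a JSON color-scale sidecar.

    The colormap is applied directly to the array (no figure machinery), so
    the same field always produces byte-identical files.  The sidecar
    ``<path>.json`` documents the color scale (cmap, vmin, vmax).
    """
    import matplotlib

    sig = np.asarray(field.sigma_s if hasattr(field, "sigma_s") else field, float)
    if not np.all(np.isfinite(sig)):
        raise DataError("sigma_S field contains non-finite values")
    if vmax is None:
        vmax = float(sig.max())
    span = vmax - vmin
    norm = np.zeros_like(sig) if span <= 0 else np.clip((sig - vmin) / span, 0, 1)
    rgba = (matplotlib.colormaps[cmap](norm) * 255).astype(np.uint8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(rgba[..., :3]).save(path, format="PNG")
    sidecar = {"cmap": cmap, "vmin": vmin, "vmax": vmax, "units": "sigma_S (8-bit intensity SD)"}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def write_sigma_tiff(field, path: str | Path) -> Path:
    """Export the raw sigma_S map as a 32-bit float TIFF."""
    import tifffile

    sig = np.asarray(field.sigma_s if hasattr(field, "sigma_s") else field, np.float32)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, sig)
    return path


def _record_row(rec) -> dict:
    meta = rec.metadata or AssayMetadata()
    return {
        "well_id": meta.well_id,
        "genotype": meta.genotype,
        "insecticide": meta.insecticide,
        "dose_ppm": meta.dose_ppm,
        "time_min": meta.time_min,
        "wi_value": rec.wi_value,
        "pixels_above_threshold": rec.ta_count,
    }


def write_results_table(records: Iterable, path: str | Path) -> Path:
    """Write WI records (or pre-built row dicts) to a CSV with a fixed schema.

    Columns, in order: well_id, genotype, insecticide, dose_ppm, time_min,
    wi_value, pixels_above_threshold.  An empty record list still produces
    a header-only CSV.
    """
    rows = []
    for rec in records:
        if isinstance(rec, dict):
            if set(rec) != set(RESULTS_COLUMNS):
                raise DataError(
                    f"row schema {sorted(rec)} != expected {sorted(RESULTS_COLUMNS)}"
                )
            rows.append(rec)
        else:
            rows.append(_record_row(rec))
    df = pd.DataFrame(rows, columns=RESULTS_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results CSV back, validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"results table {path} missing columns {missing}")
    return df[RESULTS_COLUMNS + [c for c in df.columns if c not in RESULTS_COLUMNS]]
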