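"""Readers and writers for the pipeline's interchange formats.

Videos travel as multi-page grayscale TIFF with the frame rate in a
sidecar JSON (``<stem>.json`` next to the stack); longitudinal endpoint
tables as tidy CSV (subject, group, treatment, endpoint, day, value);
expression data as a TSV matrix (transcript ids in the first column)
plus a sample-metadata TSV.  Frequency maps are written as 32-bit float
TIFF with NaN marking inactive pixels.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cilia import FrequencyMap, SpectralConfig, VideoStack
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_video",
    "write_video",
    "read_expression",
    "write_expression",
    "read_endpoints",
    "write_endpoints",
    "write_frequency_map",
    "read_frequency_map",
]

ENDPOINT_COLUMNS = ["subject", "group", "treatment", "endpoint", "day", "value"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_video(path, fps: float | None = None) -> VideoStack:
    """Load a multi-page grayscale TIFF as a float video stack.

    The frame rate comes from the ``fps`` argument or, failing that, the
    ``fps`` key of the sidecar JSON written by :func:`write_video`.
    Non-uniform frame shapes and too-short stacks are rejected.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.dtype == object:
        raise ValueError(f"{path} is not a uniform 2D+time grayscale stack (shape {frames.shape})")
    if fps is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            fps = json.loads(sidecar.read_text()).get("fps")
        if fps is None:
            raise ValueError(
                f"no frame rate for {path}: pass fps= or provide a sidecar JSON "
                f"({sidecar.name}) with an 'fps' key"
            )
    stack = VideoStack(frames=np.asarray(frames, dtype=float), fps=float(fps))
    logger.info("read %s: %d frames of %dx%d at %g fps", path, stack.n_frames, *stack.shape, stack.fps)
    return stack


def write_video(stack: VideoStack, path) -> Path:
    """Write a stack as multi-page float32 TIFF + fps sidecar JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    _sidecar_path(path).write_text(json.dumps({"fps": stack.fps}) + "\n")
    return path


def read_expression(matrix_path, metadata_path) -> ExpressionMatrix:
    """Read a transcripts x samples TSV and its sample-metadata TSV.

    The metadata is keyed by sample id; samples without metadata are
    rejected by name, extra metadata rows are tolerated with a warning.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    metadata.index = metadata.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values=values, metadata=metadata)


def write_expression(matrix: ExpressionMatrix, matrix_path, metadata_path) -> None:
    Path(matrix_path).parent.mkdir(parents=True, exist_ok=True)
    matrix.values.to_csv(matrix_path, sep="\t", index_label="transcript")
    matrix.metadata.to_csv(metadata_path, sep="\t", index_label="sample")


def read_endpoints(path) -> pd.DataFrame:
    """Read a tidy endpoint CSV; all interchange columns are required."""
    table = pd.read_csv(path)
    missing = [c for c in ENDPOINT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"endpoint table {path} lacks columns {missing}")
    return table


def write_endpoints(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def write_frequency_map(fmap: FrequencyMap, path) -> Path:
    """Frequency map as 32-bit float TIFF (NaN = inactive) + config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, fmap.values.astype(np.float32))
    meta = {"fps": fmap.fps}
    if fmap.config is not None:
        meta["config"] = {
            "band_low": fmap.config.band_low,
            "band_high": fmap.config.band_high,
            "snr_threshold": fmap.config.snr_threshold,
            "detrend": fmap.config.detrend,
            "window": fmap.config.window,
        }
    _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True) + "\n")
    return path


def read_frequency_map(path) -> FrequencyMap:
    path = Path(path)
    values = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar_path(path).read_text())
    config = SpectralConfig(**meta["config"]) if "config" in meta else None
    return FrequencyMap(values=values, fps=meta["fps"], config=config)
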