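"""File formats: NIfTI volumes, BIDS-style events, motion traces, tables."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .design import TaskDesign


def save_events_tsv(design: TaskDesign, path: str | Path) -> None:
    design.to_events_frame().to_csv(path, sep="\t", index=False)


def load_events_tsv(path: str | Path, task_id: str, run_id: int,
                    repetition_time: float = 2.0) -> TaskDesign:
    frame = pd.read_csv(path, sep="\t")
    return TaskDesign.from_events_frame(frame, task_id=task_id, run_id=run_id,
                                        repetition_time=repetition_time)


def save_motion_txt(trace: np.ndarray, path: str | Path) -> None:
    """Six-column whitespace-delimited realignment parameters."""
    np.savetxt(path, np.asarray(trace, dtype=float), fmt="%.8f")


def load_motion_txt(path: str | Path) -> np.ndarray:
    trace = np.loadtxt(path)
    if trace.ndim == 1:
        trace = trace[None, :]
    if trace.shape[1] != 6:
        raise ValueError(f"motion file must have 6 columns, found {trace.shape[1]}")
    return trace


def save_series_nifti(data4d: np.ndarray, path: str | Path,
                      repetition_time: float = 2.0,
                      affine: np.ndarray | None = None) -> None:
    """(x, y, z, t) array to NIfTI-1 with the TR in the header."""
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data4d, dtype=np.float32), affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], repetition_time))
    nib.save(img, str(path))


def load_series_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    tr = float(img.header.get_zooms()[3]) if data.ndim == 4 else 0.0
    return data, tr


def save_map_nifti(data3d: np.ndarray, path: str | Path,
                   affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data3d, dtype=np.float32), affine), str(path))


def load_map_nifti(path: str | Path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj, dtype=float)


def series_to_matrix(data4d: np.ndarray) -> tuple[np.ndarray, tuple[int, int, int]]:
    """(x, y, z, t) NIfTI array to the (volumes, voxels) analysis layout."""
    shape3d = data4d.shape[:3]
    return data4d.reshape(-1, data4d.shape[3]).T, shape3d


def matrix_to_series(matrix: np.ndarray, shape3d: tuple[int, int, int]) -> np.ndarray:
    return matrix.T.reshape(*shape3d, matrix.shape[0])
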