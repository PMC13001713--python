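"""61-channel 10-10 EEG montage utilities.

The package ships an idealized spherical-head position table for the 61
scalp electrodes used throughout (a standard 10-10 layout including the
central auditory ROI FCz/FC1/FC2/Cz/C1/C2/CPz/CP1/CP2).  Positions are in
meters, head-centered, z up.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

#: Central scalp region of interest used for TRF time courses.
ROI_CHANNELS = ("FCz", "FC1", "FC2", "Cz", "C1", "C2", "CPz", "CP1", "CP2")


def load_montage() -> pd.DataFrame:
    """Return the bundled 61-channel montage as a DataFrame.

    Columns: ``name`` (str), ``x``, ``y``, ``z`` (float, meters).
    Row order is the canonical channel order used by the synthetic EEG
    generator and the epoch container.
    """
    ref = importlib.resources.files("speechtrace") / "data" / "montage_61ch.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return df


def read_positions(path) -> pd.DataFrame:
    """Read a whitespace-delimited electrode position file (name x y z)."""
    df = pd.read_csv(path, sep=r"\s+")
    expected = {"name", "x", "y", "z"}
    if not expected.issubset(df.columns):
        raise ValueError(f"position table must have columns {sorted(expected)}")
    return df


def channel_positions(names=None) -> tuple[list[str], np.ndarray]:
    """Names and (n, 3) position array for the bundled montage.

    Parameters
    ----------
    names : sequence of str, optional
        Subset (and ordering) of channels to return.  Default: all 61.
    """
    df = load_montage()
    if names is None:
        names = list(df["name"])
    df = df.set_index("name")
    missing = [n for n in names if n not in df.index]
    if missing:
        raise KeyError(f"channels not in montage: {missing}")
    pos = df.loc[list(names), ["x", "y", "z"]].to_numpy(float)
    return list(names), pos


def azimuthal_projection(pos3d: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant 2-D projection of 3-D scalp positions.

    The polar angle from the vertex (+z axis) becomes the radius, the
    azimuth is preserved; this is the standard scalp flattening used for
    topographic maps and for triangulating electrode neighborhoods.
    """
    pos3d = np.asarray(pos3d, float)
    if pos3d.ndim != 2 or pos3d.shape[1] != 3:
        raise ValueError("expected (n, 3) positions")
    r = np.linalg.norm(pos3d, axis=1)
    if np.any(r == 0):
        raise ValueError("electrode at head center cannot be projected")
    theta = np.arccos(np.clip(pos3d[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(pos3d[:, 1], pos3d[:, 0])
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])
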