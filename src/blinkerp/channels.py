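"""Default 34-channel EEG montage used throughout the package.

The channel set mirrors a 34-electrode 10-20/10-10 layout with a parietal
midline electrode (Pz) and two frontopolar electrodes (Fp1/Fp2), which are
respectively the analysis channel for stimulus/blink-locked potentials and
the channels on which the corneo-retinal blink artifact is maximal.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

#: Canonical channel order (front to back).
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "AFz",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
)

#: The two most frontal electrodes; blink-artifact energy concentrates here.
FRONTOPOLAR_CHANNELS: tuple[str, str] = ("Fp1", "Fp2")

#: Posterior electrodes used by the coarse "parietal-dominant" map test.
PARIETAL_CHANNELS: tuple[str, ...] = (
    "CP1", "CP2", "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
)


@lru_cache(maxsize=8)
def electrode_positions(channels: tuple[str, ...] = DEFAULT_CHANNELS,
                        radius_mm: float = 92.0) -> np.ndarray:
    """Electrode positions projected onto a sphere of ``radius_mm``.

    Positions come from the standard 10-20 template montage and are
    re-projected radially onto the scalp sphere of the spherical head model,
    so electrode geometry and forward model are mutually consistent.

    Returns an ``(n_channels, 3)`` array in millimetres.
    """
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    missing = [ch for ch in channels if ch not in pos]
    if missing:
        raise ValueError(f"channels absent from the 10-20 template: {missing}")
    xyz = np.asarray([pos[ch] for ch in channels], dtype=float)
    # template head frame origin is close to, but not exactly, the sphere
    # centre; recentre on the mean before projecting radially
    xyz = xyz - xyz.mean(axis=0)
    norms = np.linalg.norm(xyz, axis=1, keepdims=True)
    return radius_mm * xyz / norms


def channel_indices(channel_names, wanted) -> np.ndarray:
    """Indices of ``wanted`` labels within ``channel_names`` (all must exist)."""
    lookup = {name: i for i, name in enumerate(channel_names)}
    missing = [w for w in wanted if w not in lookup]
    if missing:
        raise KeyError(f"channels not present: {missing}")
    return np.asarray([lookup[w] for w in wanted], dtype=int)
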