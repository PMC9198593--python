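"""32-channel 10-20 montage used by the synthetic cohort.

Positions are approximate top-view scalp coordinates on a unit head
(x: left negative / right positive, y: anterior positive), sufficient for
building smooth spatial gain maps; no volume conduction is modelled.
"""

from __future__ import annotations

import numpy as np

#: Default 32-electrode montage (extended 10-20 labels).
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "PO3", "POz", "PO4",
    "O1", "O2",
)

#: Approximate 2-D scalp position per label.
POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.30, 0.90), "Fp2": (0.30, 0.90),
    "F7": (-0.75, 0.55), "F3": (-0.40, 0.60), "Fz": (0.0, 0.60),
    "F4": (0.40, 0.60), "F8": (0.75, 0.55),
    "FT7": (-0.85, 0.30), "FC3": (-0.40, 0.30), "FCz": (0.0, 0.30),
    "FC4": (0.40, 0.30), "FT8": (0.85, 0.30),
    "T7": (-0.90, 0.0), "C3": (-0.45, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.45, 0.0), "T8": (0.90, 0.0),
    "TP7": (-0.85, -0.30), "CP3": (-0.40, -0.30), "CPz": (0.0, -0.30),
    "CP4": (0.40, -0.30), "TP8": (0.85, -0.30),
    "P7": (-0.75, -0.55), "P3": (-0.40, -0.60), "Pz": (0.0, -0.60),
    "P4": (0.40, -0.60), "P8": (0.75, -0.55),
    "PO3": (-0.30, -0.75), "POz": (0.0, -0.75), "PO4": (0.30, -0.75),
    "O1": (-0.30, -0.90), "O2": (0.30, -0.90),
}


def default_topography(
    labels: tuple[str, ...] | list[str] = CHANNELS_32,
    center_labels: tuple[str, ...] = ("C3", "CP3", "CPz"),
    sigma: float = 0.40,
    baseline: float = 0.15,
) -> np.ndarray:
    """Smooth per-electrode gain map peaking at the left centro-parietal sites.

    The gain is a Gaussian bump (width ``sigma`` in head-radius units)
    centred on the centroid of ``center_labels``, lifted by a small
    ``baseline`` so every electrode carries some stimulus-driven signal,
    and normalised to a maximum of 1.

    Unknown labels (real montages can differ) get the baseline gain.
    """
    center = np.mean([POSITIONS[l] for l in center_labels], axis=0)
    gains = np.empty(len(labels))
    for i, lab in enumerate(labels):
        if lab in POSITIONS:
            d2 = float(np.sum((np.asarray(POSITIONS[lab]) - center) ** 2))
            gains[i] = baseline + (1.0 - baseline) * np.exp(-d2 / (2.0 * sigma**2))
        else:
            gains[i] = baseline
    return gains / gains.max()
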