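"""Figure-style visual output: axial overlays and the Bland–Altman plot."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .agreement import AgreementReport
from .volume import VoxelVolume

ROOT_RGB = (255, 0, 0)  # root surface: red
CROWN_RGB = (255, 255, 255)  # crown surface: white


def overlay_slice(volume: VoxelVolume, labels: np.ndarray, z: int) -> np.ndarray:
    """RGB render of one axial slice: grayscale anatomy, root edges red,
    crown edges white (label codes from :mod:`rsaseg.pipeline`)."""
    gray = volume.intensities[z]
    rgb = np.stack([gray] * 3, axis=-1).astype(np.uint8)
    rgb[labels[z] == 1] = ROOT_RGB
    rgb[labels[z] == 2] = CROWN_RGB
    return rgb


def save_overlays(
    volume: VoxelVolume, labels: np.ndarray, directory: str | Path, stride: int = 1
) -> list[Path]:
    """Write per-slice PNG overlays; ``stride`` thins the stack."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for z in range(0, volume.n_slices, stride):
        path = directory / f"overlay_z{z:04d}.png"
        Image.fromarray(overlay_slice(volume, labels, z)).save(path)
        paths.append(path)
    return paths


def save_bland_altman_plot(
    report: AgreementReport, scatter: pd.DataFrame, path: str | Path
) -> Path:
    """Difference-vs-mean plot with bias line and 1.96 SD limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(scatter["pair_mean_mm2"], scatter["difference_mm2"], color="k", s=25)
    ax.axhline(report.mean_diff_mm2, color="b", label=f"bias = {report.mean_diff_mm2:.2f}")
    for y, name in ((report.loa_low, "-1.96 SD"), (report.loa_high, "+1.96 SD")):
        ax.axhline(y, color="r", linestyle="--", label=f"{name} = {y:.2f}")
    ax.set_xlabel("pair mean RSA (mm$^2$)")
    ax.set_ylabel("difference (mm$^2$)")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
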