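"""Synthetic CBCT-like tooth phantoms with analytic ground truth.

A phantom is a simple solid (square prism, digitized cylinder, or a coaxial
root-below/wider-crown-above "two-part tooth") embedded in air, with the
root and crown regions given two separated intensity modes — mimicking the
bimodal cementum/enamel surface histogram of a real isolated-tooth scan.
Because the geometry is known before noise is added, the true root edge
count, the true RSA under the pixel-count rule, and the analytic valley of
the surface-intensity mixture are all computable exactly, giving every
pipeline stage an oracle without any scan data.

The two-part tooth deliberately marks the root/crown junction by intensity
only (no geometric step at the junction on the root side): like the real
cementoenamel junction, it must be found from the histogram, not the shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import InputError
from .volume import VoxelVolume

_SHAPES = ("square_prism", "cylinder", "two_part_tooth")
#: Extra half-width of the crown prism relative to the root, in pixels per side.
_CROWN_OVERHANG_PX = 2
_AIR_MARGIN = 2


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of one synthetic tooth.

    ``cross_section_px`` is the full width (side length, or cylinder
    diameter) of the root cross-section. Intensity modes must satisfy
    ``root_mean_intensity < crown_mean_intensity`` and be separated by at
    least 4 noise standard deviations so the phantom is solvable.
    """

    shape: str = "two_part_tooth"
    root_height_slices: int = 40
    crown_height_slices: int = 12
    cross_section_px: int = 20
    root_mean_intensity: int = 90
    crown_mean_intensity: int = 190
    noise_sd: float = 4.0
    air_mean_intensity: int = 0
    seed: int = 0
    pixel_size_mm: float = 0.3
    slice_spacing_mm: float = 0.3

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise InputError(f"unknown phantom shape {self.shape!r}; choose from {_SHAPES}")
        if self.root_height_slices < 1 or self.crown_height_slices < 0:
            raise InputError("root needs >=1 slice; crown height must be >=0")
        if self.cross_section_px < 2:
            raise InputError("cross-section must be at least 2 px")
        if not 0 <= self.root_mean_intensity < self.crown_mean_intensity <= 255:
            raise InputError("need 0 <= root mean < crown mean <= 255")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if self.noise_sd > 0 and (
            self.crown_mean_intensity - self.root_mean_intensity < 4 * self.noise_sd
            or self.root_mean_intensity - self.air_mean_intensity < 4 * self.noise_sd
        ):
            raise InputError("intensity modes must be separated by >= 4 * noise_sd")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth computed from the clean geometry before noise."""

    true_threshold_bin: int
    true_root_edge_pixels: int
    true_rsa_mm2: float
    label_grid: np.ndarray = field(repr=False)  # 0 air, 1 root, 2 crown


def _disk_mask(width: int) -> np.ndarray:
    """Digitized disk of diameter ``width`` on a width x width grid."""
    r = width / 2.0
    c = (width - 1) / 2.0
    yy, xx = np.mgrid[0:width, 0:width]
    return (yy - c) ** 2 + (xx - c) ** 2 <= r * r


def _place(canvas: np.ndarray, footprint: np.ndarray, z0: int, z1: int, label: int) -> None:
    ny, nx = canvas.shape[1:]
    fy, fx = footprint.shape
    y0 = (ny - fy) // 2
    x0 = (nx - fx) // 2
    canvas[z0:z1, y0 : y0 + fy, x0 : x0 + fx][:, footprint] = label


def build_labels(spec: PhantomSpec) -> np.ndarray:
    """Clean label grid (0 air, 1 root, 2 crown) for a spec, air margin included."""
    crown_w = spec.cross_section_px + (
        2 * _CROWN_OVERHANG_PX if spec.shape == "two_part_tooth" and spec.crown_height_slices else 0
    )
    side = max(spec.cross_section_px, crown_w) + 2 * _AIR_MARGIN
    nz = spec.root_height_slices + spec.crown_height_slices + 2 * _AIR_MARGIN
    labels = np.zeros((nz, side, side), dtype=np.uint8)

    if spec.shape == "cylinder":
        root_fp = _disk_mask(spec.cross_section_px)
        crown_fp = root_fp
    else:
        root_fp = np.ones((spec.cross_section_px, spec.cross_section_px), dtype=bool)
        crown_fp = np.ones((crown_w, crown_w), dtype=bool)

    z_root0 = _AIR_MARGIN
    z_root1 = z_root0 + spec.root_height_slices
    _place(labels, root_fp, z_root0, z_root1, 1)
    if spec.crown_height_slices:
        _place(labels, crown_fp, z_root1, z_root1 + spec.crown_height_slices, 2)
    return labels


def _inplane_edges(mask: np.ndarray) -> np.ndarray:
    struct = np.ones((1, 3, 3), dtype=bool)
    return mask & ~ndimage.binary_erosion(mask, structure=struct, border_value=0)


def analytic_valley(
    root_mean: float, crown_mean: float, noise_sd: float, w_root: float, w_crown: float
) -> int:
    """Valley bin of the two-Gaussian surface-intensity mixture.

    Minimises the log mixture density on the integer bins between the two
    means (log-space keeps the minimum well defined when the modes barely
    overlap). With ``noise_sd = 0`` the modes are deltas and the valley is
    the midpoint bin.
    """
    lo, hi = int(np.ceil(root_mean)), int(np.floor(crown_mean))
    if noise_sd == 0:
        return (lo + hi) // 2
    x = np.arange(lo, hi + 1, dtype=float)
    log_root = np.log(w_root) - 0.5 * ((x - root_mean) / noise_sd) ** 2
    log_crown = np.log(w_crown) - 0.5 * ((x - crown_mean) / noise_sd) ** 2
    mixture = np.logaddexp(log_root, log_crown)
    return lo + int(np.argmin(mixture))


def generate(spec: PhantomSpec) -> tuple[VoxelVolume, PhantomTruth]:
    """Render a phantom volume and its analytic truth.

    Deterministic given ``spec.seed``: voxel intensities are
    ``round(Normal(mean_of_region, noise_sd))`` clipped to [0, 255].
    """
    labels = build_labels(spec)
    edges = _inplane_edges(labels > 0)
    root_edges = int((edges & (labels == 1)).sum())
    crown_edges = int((edges & (labels == 2)).sum())

    truth = PhantomTruth(
        true_threshold_bin=analytic_valley(
            spec.root_mean_intensity,
            spec.crown_mean_intensity,
            spec.noise_sd,
            max(root_edges, 1),
            max(crown_edges, 1),
        ),
        true_root_edge_pixels=root_edges,
        true_rsa_mm2=root_edges * spec.pixel_size_mm * spec.slice_spacing_mm,
        label_grid=labels,
    )

    means = np.array(
        [spec.air_mean_intensity, spec.root_mean_intensity, spec.crown_mean_intensity],
        dtype=np.float64,
    )
    clean = means[labels]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        clean = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    intensities = np.clip(np.floor(clean + 0.5), 0, 255).astype(np.uint8)
    volume = VoxelVolume(
        intensities,
        pixel_size_mm=spec.pixel_size_mm,
        slice_spacing_mm=spec.slice_spacing_mm,
    )
    return volume, truth


def spec_to_config(spec: PhantomSpec) -> str:
    """Serialise a spec as flat ``key=value`` lines."""
    return "".join(f"{k}={v}\n" for k, v in vars(spec).items())


def spec_from_config(text: str) -> PhantomSpec:
    """Parse the flat ``key=value`` serialisation back into a spec."""
    base = PhantomSpec()
    kwargs = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise InputError(f"malformed phantom config line: {line!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if not hasattr(base, key):
            raise InputError(f"unknown phantom config key: {key!r}")
        current = getattr(base, key)
        kwargs[key] = value.strip() if isinstance(current, str) else type(current)(float(value)) if isinstance(current, int) else float(value)
    return replace(base, **kwargs)
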