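"""End-to-end per-tooth pipeline: volume in, per-tooth RSA report out."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import segmentation as seg
from .errors import InputError, RsaSegError
from .segmentation import (
    EdgeLabeling,
    EdgeMap,
    SurfaceHistogram,
    ThresholdResult,
    ToothComponent,
)
from .surface_area import RsaResult, compute_rsa
from .volume import VoxelVolume

#: Label-volume codes emitted by :func:`label_volume`.
LABEL_BACKGROUND, LABEL_ROOT_EDGE, LABEL_CROWN_EDGE, LABEL_INTERIOR = 0, 1, 2, 3


@dataclass(frozen=True)
class ToothReport:
    """Everything the pipeline derives for one connected tooth component."""

    component: ToothComponent
    edges: EdgeMap
    histogram: SurfaceHistogram
    threshold: ThresholdResult
    labeling: EdgeLabeling
    rsa: RsaResult


def segment_volume(
    volume: VoxelVolume,
    air_threshold: int | None = None,
    smoothing_window: int = 5,
    min_prominence_fraction: float = 0.10,
    plateau_tolerance_fraction: float = 0.02,
    min_component_voxels: int = seg.DEFAULT_MIN_COMPONENT_VOXELS,
    threshold_override: int | None = None,
) -> list[ToothReport]:
    """Run the full chain on a volume, one report per detected tooth.

    Each component gets its own personalised threshold; ``threshold_override``
    forces a fixed X (e.g. for root-only specimens with no enamel mode).

    Raises
    ------
    InputError
        No components survive binarization and size filtering.
    """
    mask = seg.binarize(volume, air_threshold=air_threshold)
    components = seg.connected_components(mask, min_voxels=min_component_voxels)
    if not components:
        raise InputError("no tooth components found in volume")
    reports = []
    for component in components:
        try:
            edges = seg.extract_edges(component)
            hist = seg.surface_histogram(volume, edges)
            if threshold_override is None:
                threshold = seg.find_threshold(
                    hist,
                    smoothing_window=smoothing_window,
                    min_prominence_fraction=min_prominence_fraction,
                    plateau_tolerance_fraction=plateau_tolerance_fraction,
                )
            else:
                threshold = threshold_override
            labeling = seg.classify_edges(volume, edges, threshold)
            rsa = compute_rsa(labeling, volume)
        except RsaSegError as exc:
            raise type(exc)(
                f"component {component.component_id}: {exc}"
            ) from exc
        if isinstance(threshold, int):
            threshold = ThresholdResult(
                P=0, X=threshold, smoothed_counts=hist.counts.astype(float)
            )
        reports.append(
            ToothReport(
                component=component,
                edges=edges,
                histogram=hist,
                threshold=threshold,
                labeling=labeling,
                rsa=rsa,
            )
        )
    return reports


def report_table(reports: list[ToothReport]) -> pd.DataFrame:
    """Per-tooth summary: one row per component."""
    return pd.DataFrame(
        {
            "component_id": [r.component.component_id for r in reports],
            "voxel_count": [r.component.voxel_count for r in reports],
            "edge_pixels": [r.edges.pixel_count for r in reports],
            "P": [r.threshold.P for r in reports],
            "X": [r.threshold.X for r in reports],
            "root_edge_pixels": [r.rsa.root_edge_pixels for r in reports],
            "rsa_mm2": [r.rsa.rsa_mm2 for r in reports],
        }
    )


def label_volume(volume: VoxelVolume, reports: list[ToothReport]) -> np.ndarray:
    """Merge reports into one uint8 label grid.

    0 background, 1 root edge, 2 crown edge, 3 interior tooth. Interior
    labelling is visualization-only; the RSA arithmetic uses edge pixels.
    """
    labels = np.zeros(volume.shape, dtype=np.uint8)
    for r in reports:
        labels[r.component.mask.values] = LABEL_INTERIOR
    for r in reports:
        labels[r.labeling.crown_edges.values] = LABEL_CROWN_EDGE
        labels[r.labeling.root_edges.values] = LABEL_ROOT_EDGE
    return labels
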