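"""Nucleus segmentation and nucleus-to-cell grouping.

The computational analogue of the manual ImageJ step: nuclei are identified
in the DAPI channel by a single threshold applied uniformly to every frame
of a study, their background-subtracted integrated intensity is measured,
and nuclei are grouped into cells via the lineage-marker mask (CD31 marks
endothelial cells).

Outputs are plain DataFrames:

``nuclei``
    one row per nucleus — ``nucleus_id, frame, row, col, area,
    integrated_intensity, flagged, cd31_positive, lineage_positive``.
``cells``
    one row per cell — ``cell_id, cell_type, nucleus_ids, n_nuclei,
    viable, qc`` (``qc`` is ``"ok"`` or ``"multi"`` for >=3 detected
    nuclei, which are excluded from the mono/binuclear calculus downstream).
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import expand_labels

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdPolicy",
    "assign_nuclei_to_cells",
    "pooled_threshold",
    "quantify_frames",
    "segment_nuclei",
]

ThresholdPolicy = "float | str"  # "otsu" or an absolute intensity value

#: Pixels to grow each nucleus mask by before integration, to capture PSF
#: tails; growth never crosses into a neighbouring nucleus's territory.
DEFAULT_DILATION_PX = 3
DEFAULT_MIN_AREA = 15


def pooled_threshold(dapi_frames: Sequence[np.ndarray], subsample: int = 4) -> float:
    """Otsu threshold on the pooled log-intensity histogram of all frames.

    Pooling enforces the one-threshold-for-all-samples contract; per-frame
    thresholds would let exposure drift leak into ploidy calls.  Otsu is
    computed on ``log1p`` intensities — with a sparse foreground (nuclei
    cover a few percent of pixels) linear-domain Otsu drifts into the dim
    end of the nucleus intensity range, clipping large dim nuclei, whereas
    in log space the background/foreground split is scale-stable.
    """
    pooled = np.concatenate(
        [np.asarray(f, dtype=np.float64).ravel()[::subsample] for f in dapi_frames]
    )
    return float(np.expm1(threshold_otsu(np.log1p(pooled))))


def _resolve_threshold(policy, dapi_frames: Sequence[np.ndarray]) -> float:
    if isinstance(policy, str):
        if policy.lower() == "otsu":
            return pooled_threshold(dapi_frames)
        return float(policy)
    return float(policy)


def segment_nuclei(
    dapi_frame: np.ndarray,
    threshold_policy,
    min_area: int = DEFAULT_MIN_AREA,
    dilation_px: int = DEFAULT_DILATION_PX,
) -> pd.DataFrame:
    """Find nuclei in a single DAPI frame and measure integrated intensity.

    Connected components at or above the threshold and of at least
    ``min_area`` pixels are kept.  The background is estimated as the median
    of sub-threshold pixels and subtracted;
    ``integrated_intensity = sum(pixel - background)`` over the (slightly
    dilated) component.  Records whose background subtraction overshoots
    into non-positive totals are flagged, never dropped.

    An all-zero frame yields an empty table; a near-saturated integer frame
    (>= 1% of pixels at the dtype maximum) logs a warning.
    """
    frame = np.asarray(dapi_frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("segment_nuclei expects a single-channel 2-D frame")
    if frame.min() < 0:
        raise ValueError("DAPI frame must be nonnegative")
    if np.issubdtype(np.asarray(dapi_frame).dtype, np.integer):
        dtype_max = np.iinfo(np.asarray(dapi_frame).dtype).max
        if (np.asarray(dapi_frame) >= dtype_max).mean() >= 0.01:
            logger.warning("frame appears saturated (>=1%% of pixels at dtype max)")

    thr = _resolve_threshold(threshold_policy, [frame])
    mask = frame >= thr
    columns = ["nucleus_id", "row", "col", "area", "integrated_intensity", "flagged"]
    if not mask.any():
        return pd.DataFrame(columns=columns)
    below = frame[~mask]
    background = float(np.median(below)) if below.size else 0.0

    labels = label(mask)
    props = regionprops(labels)
    keep = [p for p in props if p.area >= min_area]
    if not keep:
        return pd.DataFrame(columns=columns)
    grown = expand_labels(labels, distance=dilation_px) if dilation_px > 0 else labels
    keep_labels = np.array([p.label for p in keep])
    sums = ndimage.sum_labels(frame, grown, index=keep_labels)
    counts = ndimage.sum_labels(np.ones_like(frame), grown, index=keep_labels)
    integrated = sums - background * counts
    rows = [
        {
            "nucleus_id": i,
            "row": p.centroid[0],
            "col": p.centroid[1],
            "area": int(p.area),
            "integrated_intensity": float(v),
            "flagged": bool(v <= 0),
        }
        for i, (p, v) in enumerate(zip(keep, integrated))
    ]
    return pd.DataFrame(rows, columns=columns)


def _marker_labels(frame: np.ndarray, threshold_policy, min_area: int = 30) -> np.ndarray:
    """Label a marker channel; an empty (all-zero) channel yields no mask."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.max() <= 0:
        return np.zeros(frame.shape, dtype=int)
    if isinstance(threshold_policy, str) and threshold_policy.lower() == "otsu":
        thr = float(threshold_otsu(frame))
    else:
        thr = float(threshold_policy)
    labels = label(frame >= thr)
    # drop specks
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_area)
    if small.size:
        labels[np.isin(labels, small)] = 0
    return labels


def assign_nuclei_to_cells(
    nuclei: pd.DataFrame,
    lineage_frame: np.ndarray,
    cd31_frame: np.ndarray,
    threshold_policy="otsu",
    lineage_cell_type: str = "cardiomyocyte",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group nuclei into cells via the marker masks of one frame.

    Nuclei whose centroids fall inside one lineage-mask component form one
    cell of ``lineage_cell_type``; nuclei in CD31 components are endothelial;
    nuclei in neither mask become single-nucleus cells of type ``unknown``.
    A nucleus claimed by both masks is typed by the stronger marker at its
    centroid; collisions are counted and logged.

    Returns ``(cells, nuclei)`` where ``nuclei`` is the input annotated with
    ``cd31_positive`` / ``lineage_positive`` flags.
    """
    nuclei = nuclei.copy()
    lin_labels = _marker_labels(lineage_frame, threshold_policy)
    cd_labels = _marker_labels(cd31_frame, threshold_policy)
    lineage_frame = np.asarray(lineage_frame, dtype=np.float64)
    cd31_frame = np.asarray(cd31_frame, dtype=np.float64)

    groups: dict[tuple, list[int]] = {}
    cd31_pos, lin_pos = [], []
    collisions = 0
    for _, nuc in nuclei.iterrows():
        r = int(np.clip(round(nuc["row"]), 0, lin_labels.shape[0] - 1))
        c = int(np.clip(round(nuc["col"]), 0, lin_labels.shape[1] - 1))
        lin_id = int(lin_labels[r, c])
        cd_id = int(cd_labels[r, c])
        if lin_id and cd_id:
            collisions += 1
            if cd31_frame[r, c] >= lineage_frame[r, c]:
                lin_id = 0
            else:
                cd_id = 0
        cd31_pos.append(bool(cd_id))
        lin_pos.append(bool(lin_id))
        if lin_id:
            key = ("lineage", lin_id)
        elif cd_id:
            key = ("cd31", cd_id)
        else:
            key = ("none", int(nuc["nucleus_id"]))
        groups.setdefault(key, []).append(int(nuc["nucleus_id"]))
    if collisions:
        logger.info("%d nuclei fell in both lineage and CD31 masks", collisions)

    nuclei["cd31_positive"] = cd31_pos
    nuclei["lineage_positive"] = lin_pos
    cell_rows = []
    for i, (key, ids) in enumerate(sorted(groups.items(), key=lambda kv: kv[1][0])):
        kind = key[0]
        cell_type = {
            "lineage": lineage_cell_type,
            "cd31": "endothelial",
            "none": "unknown",
        }[kind]
        cell_rows.append(
            {
                "cell_id": i,
                "cell_type": cell_type,
                "nucleus_ids": tuple(ids),
                "n_nuclei": len(ids),
                "viable": True,
                "qc": "ok" if len(ids) <= 2 else "multi",
            }
        )
    cells = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "cell_type", "nucleus_ids", "n_nuclei", "viable", "qc"],
    )
    return cells, nuclei


def quantify_frames(
    frames: Sequence[np.ndarray],
    threshold_policy="otsu",
    min_area: int = DEFAULT_MIN_AREA,
    dilation_px: int = DEFAULT_DILATION_PX,
    lineage_cell_type: str = "cardiomyocyte",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run segmentation + assignment over a whole study's frames.

    The DAPI threshold is resolved once (pooled Otsu by default) and the
    same value applied to every frame, honouring the uniform-threshold
    contract.  Nucleus and cell ids are globally unique across frames.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames given")
    dapi_frames = [np.asarray(f)[0] for f in frames]
    thr = _resolve_threshold(threshold_policy, dapi_frames)

    all_nuclei, all_cells = [], []
    nucleus_offset = cell_offset = 0
    for fi, frame in enumerate(frames):
        frame = np.asarray(frame)
        nuclei = segment_nuclei(frame[0], thr, min_area=min_area, dilation_px=dilation_px)
        if nuclei.empty:
            continue
        cells, nuclei = assign_nuclei_to_cells(
            nuclei, frame[1], frame[2], lineage_cell_type=lineage_cell_type
        )
        nuclei["frame"] = fi
        nuclei["nucleus_id"] += nucleus_offset
        cells["cell_id"] += cell_offset
        cells["nucleus_ids"] = cells["nucleus_ids"].map(
            lambda ids: tuple(i + nucleus_offset for i in ids)
        )
        nucleus_offset += len(nuclei)
        cell_offset += len(cells)
        all_nuclei.append(nuclei)
        all_cells.append(cells)
    if not all_nuclei:
        warnings.warn("no nuclei detected in any frame")
        return (
            pd.DataFrame(
                columns=[
                    "nucleus_id", "row", "col", "area", "integrated_intensity",
                    "flagged", "cd31_positive", "lineage_positive", "frame",
                ]
            ),
            pd.DataFrame(
                columns=["cell_id", "cell_type", "nucleus_ids", "n_nuclei", "viable", "qc"]
            ),
        )
    return (
        pd.concat(all_nuclei, ignore_index=True),
        pd.concat(all_cells, ignore_index=True),
    )
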