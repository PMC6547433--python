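"""Nuclear/cytoplasmic localization scoring from two-channel images.

Nuclei are segmented from the RFP (histone-marker) channel by Otsu
thresholding; cell bodies are grown around each nucleus over GFP pixels
above a robust-background threshold, with contested pixels assigned to the
nearest nucleus. The per-cell score is

    score = (mean nuclear GFP / mean whole-cell GFP)
          / (mean cytoplasmic GFP / mean whole-cell GFP)
          = mean nuclear GFP / mean cytoplasmic GFP,

which is 1 for a uniformly distributed factor and invariant to multiplying
the GFP channel by any positive constant. It is *not* invariant to adding a
constant unless background subtraction is enabled (off by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops

log = logging.getLogger(__name__)

__all__ = [
    "segment_nuclei",
    "segment_cells",
    "CellMeasurement",
    "localization_score",
    "measure_frame",
    "aggregate_timecourse",
]


def robust_background_threshold(
    image: np.ndarray, dim_fraction: float = 0.75, n_sd: float = 2.0
) -> float:
    """mean + ``n_sd`` * SD of the dimmest ``dim_fraction`` of pixels."""
    flat = np.sort(np.asarray(image, dtype=float).ravel())
    dim = flat[: max(1, int(len(flat) * dim_fraction))]
    return float(dim.mean() + n_sd * dim.std())


def segment_nuclei(
    rfp: np.ndarray, min_area: int = 9, max_area: int | None = None
) -> np.ndarray:
    """Label nuclei in the RFP channel (Otsu threshold, size-filtered).

    Touching nuclei are not declumped: a merged pair yields one label.
    Returns a labeled int array; all-background labelings are valid and
    logged.
    """
    rfp = np.asarray(rfp, dtype=float)
    if rfp.max() <= rfp.min():
        log.info("segment_nuclei: blank frame, no nuclei")
        return np.zeros(rfp.shape, dtype=np.int32)
    mask = rfp > threshold_otsu(rfp)
    labels = sk_label(mask)
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for region in regionprops(labels):
        if region.area >= min_area and (max_area is None or region.area <= max_area):
            keep[region.label] = True
    labels[~keep[labels]] = 0
    out, _, _ = _relabel(labels)
    if out.max() == 0:
        log.info("segment_nuclei: no region passed the size filter")
    return out


def _relabel(labels: np.ndarray):
    ids = np.unique(labels)
    ids = ids[ids != 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    return remap[labels], ids, len(ids)


def segment_cells(
    gfp: np.ndarray,
    nuclei: np.ndarray,
    dim_fraction: float = 0.75,
    n_sd: float = 2.0,
) -> np.ndarray:
    """Grow one cell region per nucleus over above-background GFP pixels.

    The foreground is GFP strictly above the robust-background threshold
    (mean + ``n_sd``*SD of the dimmest ``dim_fraction`` of pixels); each
    foreground pixel is assigned to the nearest nucleus, so adjacent cells
    partition the foreground. Every cell contains its own nucleus. A nucleus
    with no surrounding foreground keeps only its own pixels and is flagged
    in the log.
    """
    gfp = np.asarray(gfp, dtype=float)
    if gfp.shape != nuclei.shape:
        raise ValueError("channel shapes differ")
    if nuclei.max() == 0:
        return np.zeros_like(nuclei)
    foreground = gfp > robust_background_threshold(gfp, dim_fraction, n_sd)
    # drop single-pixel noise speckle before growing cells
    foreground = ndimage.binary_opening(foreground, structure=np.ones((3, 3)))
    # propagation grows outward from the seeds: keep only foreground regions
    # connected to a nucleus, so isolated noise pixels never join a cell
    comp = sk_label(foreground | (nuclei > 0))
    seeded = np.zeros(comp.max() + 1, dtype=bool)
    seeded[np.unique(comp[nuclei > 0])] = True
    foreground &= seeded[comp]
    # nearest-seed propagation: index of the closest nucleus pixel
    _, (ii, jj) = ndimage.distance_transform_edt(nuclei == 0, return_indices=True)
    cells = nuclei[ii, jj]
    cells[~foreground] = 0
    cells[nuclei > 0] = nuclei[nuclei > 0]  # a cell always contains its nucleus
    for nid in np.unique(nuclei[nuclei > 0]):
        if (cells == nid).sum() <= (nuclei == nid).sum():
            log.info("segment_cells: nucleus %d has no cytoplasmic GFP; cell == nucleus", nid)
    return cells


@dataclass(frozen=True)
class CellMeasurement:
    cell_id: int
    frame: int
    nucleus_area: int
    cell_area: int
    mean_nuclear: float
    mean_cytoplasmic: float
    mean_cell: float
    normalized_nuclear: float
    normalized_cytoplasmic: float
    score: float


def localization_score(
    gfp: np.ndarray,
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    cell_id: int = 0,
    frame: int = 0,
    background: float = 0.0,
    cytoplasm_floor: float = 1e-12,
) -> CellMeasurement | None:
    """Score one cell; None (logged) when the score would be unstable.

    The cytoplasm is the cell minus the nucleus. ``background`` is
    subtracted from the GFP channel first when background subtraction is
    requested (default 0, i.e. off).
    """
    gfp = np.asarray(gfp, dtype=float) - background
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    if (nucleus_mask & ~cell_mask).any():
        raise ValueError("nucleus extends outside the cell mask")
    cyto_mask = cell_mask & ~nucleus_mask
    if not cyto_mask.any():
        log.info("cell %d: nucleus fills the whole cell; excluded", cell_id)
        return None
    mean_nuc = float(gfp[nucleus_mask].mean())
    mean_cyt = float(gfp[cyto_mask].mean())
    mean_cell = float(gfp[cell_mask].mean())
    if mean_cyt <= cytoplasm_floor or mean_cell <= 0:
        log.info("cell %d: cytoplasmic mean below floor; excluded", cell_id)
        return None
    return CellMeasurement(
        cell_id=cell_id,
        frame=frame,
        nucleus_area=int(nucleus_mask.sum()),
        cell_area=int(cell_mask.sum()),
        mean_nuclear=mean_nuc,
        mean_cytoplasmic=mean_cyt,
        mean_cell=mean_cell,
        normalized_nuclear=mean_nuc / mean_cell,
        normalized_cytoplasmic=mean_cyt / mean_cell,
        score=(mean_nuc / mean_cell) / (mean_cyt / mean_cell),
    )


def measure_frame(
    rfp: np.ndarray,
    gfp: np.ndarray,
    frame: int = 0,
    background_subtract: bool = False,
    **segment_kwargs,
) -> pd.DataFrame:
    """Segment a two-channel frame and score every cell."""
    nuclei = segment_nuclei(rfp, **{k: v for k, v in segment_kwargs.items() if k in ("min_area", "max_area")})
    cells = segment_cells(gfp, nuclei)
    background = robust_background_threshold(gfp) if background_subtract else 0.0
    rows = []
    for nid in np.unique(nuclei[nuclei > 0]):
        m = localization_score(
            gfp, nuclei == nid, cells == nid, cell_id=int(nid), frame=frame,
            background=background,
        )
        if m is not None:
            rows.append(m.__dict__)
    return pd.DataFrame(rows)


def aggregate_timecourse(
    measurements: pd.DataFrame, group_cols, min_cells: int = 200
) -> pd.DataFrame:
    """Per-group mean score with a normal-approximation 95% CI.

    CI = mean +/- 1.96 * SD / sqrt(n). Groups with fewer than ``min_cells``
    cells are kept but flagged; empty groups cannot occur under groupby and
    single-cell groups get a zero-width CI component of NaN SD logged.
    """
    if len(measurements) == 0:
        raise ValueError("no measurements to aggregate")
    out = []
    for key, sub in measurements.groupby(list(group_cols)):
        n = len(sub)
        mean = float(sub["score"].mean())
        sd = float(sub["score"].std(ddof=1)) if n > 1 else 0.0
        half = 1.96 * sd / np.sqrt(n)
        row = dict(zip(group_cols, key if isinstance(key, tuple) else (key,)))
        row.update(
            n=n, mean_score=mean, ci_lo=mean - half, ci_hi=mean + half,
            flagged=n < min_cells,
        )
        out.append(row)
    return pd.DataFrame(out)
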