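"""Closed-form vascular and histology quantifications.

Pressure-myography tone, hypoxic dilation expressed as percent of tone
reversed, percent-hemisphere-infarcted from slice-wise normal-tissue
areas, Z-axis fluorescence profile area under the curve, and per-cell
DHE (superoxide-sensitive dye) fluorescence time courses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DiameterTrace",
    "InfarctInput",
    "myogenic_tone",
    "dilation_percent",
    "infarct_percent",
    "zprofile_auc",
    "dhe_timecourse",
]


@dataclass
class DiameterTrace:
    """Lumen diameter vs time from edge-detection videomicroscopy."""

    timestamps_s: np.ndarray
    diameter_um: np.ndarray
    pressure_mmhg: float
    passive_diameter_um: float | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.diameter_um = np.asarray(self.diameter_um, dtype=float)
        if self.timestamps_s.shape != self.diameter_um.shape:
            raise ValueError("timestamps and diameters must align")
        if np.any(self.diameter_um <= 0):
            raise ValueError("lumen diameters must be positive")


@dataclass
class InfarctInput:
    """Per-slice normal-tissue areas for the two hemispheres.

    ``area_nonischemic`` (VC side) and ``area_ischemic`` (VL side) must
    have one entry per slice in consistent units; thickness may be a
    scalar (constant slabs -- it then cancels) or per-slice.
    """

    area_nonischemic: np.ndarray
    area_ischemic: np.ndarray
    thickness: float | np.ndarray = 1.0

    def __post_init__(self) -> None:
        self.area_nonischemic = np.atleast_1d(np.asarray(self.area_nonischemic, float))
        self.area_ischemic = np.atleast_1d(np.asarray(self.area_ischemic, float))
        if self.area_nonischemic.shape != self.area_ischemic.shape:
            raise ValueError("both hemispheres need the same slice count")
        if np.any(self.area_nonischemic < 0) or np.any(self.area_ischemic < 0):
            raise ValueError("areas must be non-negative")
        th = np.asarray(self.thickness, dtype=float)
        if th.ndim > 0 and th.shape != self.area_nonischemic.shape:
            raise ValueError("per-slice thickness must match the slice count")
        if np.any(th <= 0):
            raise ValueError("slice thickness must be positive")
        self.thickness = th


def myogenic_tone(active_um: float, passive_um: float) -> float:
    """Myogenic tone (%) = [1 - active/passive] x 100.

    Active diameters above passive yield negative tone; this is reported
    with a warning rather than clipped, since it flags a failed passive
    determination or active dilation beyond the passive state.
    """
    if passive_um <= 0:
        raise ValueError("passive diameter must be positive")
    if active_um < 0:
        raise ValueError("active diameter cannot be negative")
    tone = (1.0 - active_um / passive_um) * 100.0
    if active_um > passive_um:
        warnings.warn(
            f"active diameter {active_um} exceeds passive {passive_um}: negative tone",
            stacklevel=2,
        )
    return tone


def dilation_percent(baseline_um: float, response_um: float, passive_um: float) -> float:
    """Dilation as percent of resting tone reversed.

    100 x (response - baseline)/(passive - baseline): 0% means no change
    from the myogenic baseline, 100% full dilation to the passive
    diameter.  Normalising to the passive diameter keeps responses
    comparable across vessels of different calibre.
    """
    if passive_um <= baseline_um:
        raise ValueError("passive diameter must exceed the active baseline")
    return 100.0 * (response_um - baseline_um) / (passive_um - baseline_um)


def infarct_percent(infarct: InfarctInput) -> float:
    """Percent hemisphere infarcted, %HI = (VC - VL)/VC x 100.

    VC and VL are normal-tissue volumes of the non-ischemic and ischemic
    hemispheres, each the sum of slice area x thickness (a constant
    thickness cancels).  VL > VC gives a negative value with a warning
    (possible edema), not a clipped zero.
    """
    vc = float(np.sum(infarct.area_nonischemic * infarct.thickness))
    vl = float(np.sum(infarct.area_ischemic * infarct.thickness))
    if vc <= 0:
        raise ValueError("non-ischemic normal-tissue volume must be positive")
    if vl > vc:
        warnings.warn("ischemic-side volume exceeds control side (edema?)", stacklevel=2)
    return (vc - vl) / vc * 100.0


def zprofile_auc(z_positions, intensities) -> float:
    """Trapezoidal area under a Z-axis fluorescence intensity profile."""
    z = np.asarray(list(z_positions), dtype=float)
    f = np.asarray(list(intensities), dtype=float)
    if z.shape != f.shape:
        raise ValueError("z positions and intensities must align")
    if z.size < 2:
        raise ValueError("a Z profile needs at least two points")
    if not (np.all(np.diff(z) > 0) or np.all(np.diff(z) < 0)):
        raise ValueError("z positions must be strictly monotonic")
    return float(abs(np.trapezoid(f, z)))


def dhe_timecourse(frames: np.ndarray, cell_masks) -> pd.DataFrame:
    """Per-cell F/F0 time course from a slow (frames-per-minute) recording.

    ``cell_masks`` is either a labelled integer image (0 = background) or
    a sequence of boolean masks, one per cell.  Each cell's mean
    intensity is normalised to its own first frame.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must be a (t, y, x) stack")
    masks: list[np.ndarray]
    if isinstance(cell_masks, np.ndarray) and cell_masks.dtype != bool:
        ids = [i for i in np.unique(cell_masks) if i != 0]
        masks = [cell_masks == i for i in ids]
    else:
        masks = [np.asarray(m, dtype=bool) for m in cell_masks]
    if not masks:
        raise ValueError("no cell masks supplied")
    out = {}
    for i, mask in enumerate(masks, start=1):
        if mask.shape != frames.shape[1:]:
            raise ValueError("mask shape must match the frames")
        if not mask.any():
            raise ValueError(f"cell mask {i} is empty")
        trace = frames[:, mask].mean(axis=1)
        if trace[0] <= 0:
            raise ValueError(f"cell {i} has non-positive baseline intensity")
        out[f"cell_{i}"] = trace / trace[0]
    return pd.DataFrame(out, index=pd.RangeIndex(frames.shape[0], name="frame"))
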