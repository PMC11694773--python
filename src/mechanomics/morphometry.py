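"""Time-lapsed bone morphometrics.

Given two registered bone segmentations of the same fracture site, each
voxel is classified by set logic into *formation* (bone at the later time
only), *resorption* (bone at the earlier time only) or *quiescence* (bone at
both). From these classes and the VOI geometry the standard indices follow:

* BV/TV — bone volume fraction, normalised by the central VOIs:
  DC/DC, DP/DC, FC/FC and FP/FC (the defect center and fracture cortex
  volumes stand in for the total volume of intact bone);
* BFR / BRR — bone formation / resorption rate, the percentage of the
  reference volume formed (resorbed) per day over the scan interval, with
  BRR reported as a non-positive number;
* defect size ``h = 2 * DC / (CSA_P + CSA_D)`` from the week-0 defect
  volume and the adjacent proximal/distal cortical cross-sectional areas.

Internally all fractions are unit-free; the percent scale (x100) is applied
at the reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError, ParameterError, UndefinedRatioError
from .images import BoneMask, VOISet

#: Label codes in a remodeling map.
REMODELING_CODES = {"none": 0, "formation": 1, "quiescent": 2, "resorption": 3}


@dataclass
class RemodelingMap:
    """Per-voxel formation/quiescence/resorption labels between two frames."""

    labels: np.ndarray  # int8 volume with REMODELING_CODES
    interval_days: float
    counts: dict[str, int] = field(default_factory=dict)

    def class_mask(self, name: str) -> np.ndarray:
        return self.labels == REMODELING_CODES[name]


@dataclass
class MorphometryResult:
    """Per-VOI morphometric indices; any unset part is None.

    ``bvtv`` maps VOI name -> bone volume fraction (percent), ``bfr``/``brr``
    map VOI name -> rate (percent of reference volume per day; BRR <= 0),
    ``tv_reference`` maps VOI name -> the voxel count used as its normaliser
    (|DC| for DC and DP, |FC| for FC and FP).
    """

    bvtv: dict[str, float] | None = None
    bfr: dict[str, float] | None = None
    brr: dict[str, float] | None = None
    tv_reference: dict[str, int] | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-VOI table of whatever indices are present."""
        vois = sorted(
            set()
            | set(self.bvtv or {})
            | set(self.bfr or {})
            | set(self.brr or {})
        )
        rows = []
        for v in vois:
            rows.append(
                {
                    "voi": v,
                    "bvtv_pct": (self.bvtv or {}).get(v, np.nan),
                    "bfr_pct_per_day": (self.bfr or {}).get(v, np.nan),
                    "brr_pct_per_day": (self.brr or {}).get(v, np.nan),
                    "tv_reference_voxels": (self.tv_reference or {}).get(v, np.nan),
                }
            )
        return pd.DataFrame(rows)


#: Normalising VOI for each analysis VOI (central VOIs act as total volume).
TV_REFERENCE_VOI = {"DC": "DC", "DP": "DC", "FC": "FC", "FP": "FC"}


def classify_remodeling(
    mask_t1: BoneMask, mask_t2: BoneMask, interval_days: float
) -> RemodelingMap:
    """Classify voxels into formation / quiescence / resorption.

    formation = bone at t2 only, resorption = bone at t1 only, quiescent =
    bone at both; everything else is background. The three class counts sum
    to ``|mask_t1 | mask_t2|`` exactly.
    """
    if mask_t1.shape != mask_t2.shape:
        raise GeometryError(
            f"mask shapes differ: {mask_t1.shape} vs {mask_t2.shape}"
        )
    if not (interval_days > 0):
        raise ParameterError(f"interval_days must be > 0, got {interval_days}")
    m1, m2 = mask_t1.values, mask_t2.values
    labels = np.zeros(m1.shape, dtype=np.int8)
    labels[m2 & ~m1] = REMODELING_CODES["formation"]
    labels[m1 & m2] = REMODELING_CODES["quiescent"]
    labels[m1 & ~m2] = REMODELING_CODES["resorption"]
    counts = {
        name: int((labels == code).sum())
        for name, code in REMODELING_CODES.items()
        if name != "none"
    }
    return RemodelingMap(labels=labels, interval_days=float(interval_days), counts=counts)


def _tv_references(vois: VOISet) -> dict[str, int]:
    if not vois.volumes:
        from .images import validate_vois  # fill counts lazily

        counts = np.bincount(vois.labels.ravel().astype(np.int64), minlength=5)
        vois.volumes = {n: int(counts[c]) for n, c in
                        {"DC": 1, "DP": 2, "FC": 3, "FP": 4}.items()}
    return {v: vois.volumes[ref] for v, ref in TV_REFERENCE_VOI.items()}


def bone_volume_fractions(mask: BoneMask, vois: VOISet) -> MorphometryResult:
    """BV/TV per VOI (percent), normalised by the central VOIs.

    BV/TV(DC) = |bone ∩ DC| / |DC|, BV/TV(DP) = |bone ∩ DP| / |DC|,
    BV/TV(FC) = |bone ∩ FC| / |FC|, BV/TV(FP) = |bone ∩ FP| / |FC|.
    """
    if mask.shape != vois.labels.shape:
        raise GeometryError("bone mask and VOI label shapes differ")
    tv = _tv_references(vois)
    bvtv: dict[str, float] = {}
    for voi in TV_REFERENCE_VOI:
        bone_in_voi = int((mask.values & vois.mask(voi)).sum())
        if tv[voi] == 0:
            raise UndefinedRatioError(
                f"normalising VOI {TV_REFERENCE_VOI[voi]} is empty for {voi}"
            )
        bvtv[voi] = 100.0 * bone_in_voi / tv[voi]
    return MorphometryResult(bvtv=bvtv, tv_reference=tv)


def formation_resorption_rates(
    remodeling: RemodelingMap, vois: VOISet
) -> MorphometryResult:
    """BFR and BRR per VOI in percent of reference volume per day.

    BFR(VOI) = 100 * |formation ∩ VOI| / TV_ref / interval_days and
    BRR(VOI) = -100 * |resorption ∩ VOI| / TV_ref / interval_days, with
    TV_ref = |DC| for DC/DP and |FC| for FC/FP. BRR carries a negative sign
    by convention (bone loss).
    """
    if remodeling.labels.shape != vois.labels.shape:
        raise GeometryError("remodeling map and VOI label shapes differ")
    if not (remodeling.interval_days > 0):
        raise ParameterError("interval_days must be > 0")
    tv = _tv_references(vois)
    form = remodeling.class_mask("formation")
    reso = remodeling.class_mask("resorption")
    bfr: dict[str, float] = {}
    brr: dict[str, float] = {}
    for voi in TV_REFERENCE_VOI:
        if tv[voi] == 0:
            raise UndefinedRatioError(
                f"normalising VOI {TV_REFERENCE_VOI[voi]} is empty for {voi}"
            )
        in_voi = vois.mask(voi)
        bfr[voi] = 100.0 * int((form & in_voi).sum()) / tv[voi] / remodeling.interval_days
        brr[voi] = -100.0 * int((reso & in_voi).sum()) / tv[voi] / remodeling.interval_days
    return MorphometryResult(bfr=bfr, brr=brr, tv_reference=tv)


def defect_size(dc_volume: float, csa_p: float, csa_d: float) -> float:
    """Defect size h = 2 * DC / (CSA_P + CSA_D).

    Parameters
    ----------
    dc_volume
        Defect-center volume at week 0 (mm^3).
    csa_p, csa_d
        Proximal and distal cortical cross-sectional areas directly adjacent
        to the defect (mm^2).

    Returns
    -------
    float
        Defect size in mm.
    """
    if not (csa_p + csa_d > 0):
        raise UndefinedRatioError("CSA_P + CSA_D must be positive")
    return 2.0 * dc_volume / (csa_p + csa_d)
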