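"""Volumetry and the liver disruption involvement (LDI) percentage.

LDI is the fraction of liver parenchyma volume disrupted by trauma,

    LDI(%) = V(trauma) / V(liver) * 100,

where each volume is the mask's voxel count times the unit voxel volume from
the scan metadata.  The denominator is the whole segmented liver, normal and
affected parenchyma alike; a case without detected trauma has LDI 0 by
convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

from .core import BinaryMask, require_same_lattice, voxel_volume_mm3

__all__ = ["SeverityReport", "estimate_volume", "compute_ldi"]


@dataclass(frozen=True)
class SeverityReport:
    """Physical volumes and the LDI percentage for one case."""

    liver_volume_mm3: float
    trauma_volume_mm3: float
    ldi_pct: float
    case_id: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def estimate_volume(mask: BinaryMask) -> float:
    """Physical mask volume: voxel count x unit voxel volume (mm^3)."""
    return mask.count() * voxel_volume_mm3(mask)


def compute_ldi(liver: BinaryMask, trauma: BinaryMask, case_id: str = "") -> SeverityReport:
    """LDI percentage from liver and trauma masks on a common lattice.

    An empty trauma mask gives LDI 0.  An empty liver with non-empty trauma
    leaves the ratio undefined and raises.  Trauma voxels outside the liver
    (possible only when upstream clipping is disabled) still count toward
    the numerator but trigger a warning.
    """
    require_same_lattice(liver, trauma)
    n_liver = liver.count()
    n_trauma = trauma.count()
    if n_trauma == 0:
        ldi = 0.0
    else:
        if n_liver == 0:
            raise ValueError(
                "non-empty trauma mask with empty liver mask: LDI is undefined"
            )
        n_outside = int((trauma.data & ~liver.data).sum())
        if n_outside:
            warnings.warn(
                f"{n_outside} trauma voxels lie outside the liver mask; "
                "they are counted in the numerator",
                stacklevel=2,
            )
        ldi = 100.0 * n_trauma / n_liver
    return SeverityReport(
        liver_volume_mm3=estimate_volume(liver),
        trauma_volume_mm3=estimate_volume(trauma),
        ldi_pct=float(ldi),
        case_id=case_id,
    )
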