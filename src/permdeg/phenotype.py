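"""Body-composition metrics from micro-CT volumetry.

Lean body mass (LBM) is body weight minus fat mass, with fat mass obtained
from the segmented total adipose-tissue volume at the standard adipose
density of 0.9 g/cm^3:

    LBM (g) = body weight (g) − adipose volume (cm^3) × 0.9 (g/cm^3)
"""

from __future__ import annotations

import pandas as pd

from .errors import ValidationError

__all__ = ["FAT_DENSITY_G_PER_CM3", "lean_body_mass", "add_lean_body_mass"]

#: density of adipose tissue used to convert volume to mass
FAT_DENSITY_G_PER_CM3 = 0.9


def lean_body_mass(
    body_weight_g: float,
    adipose_volume_cm3: float,
    fat_density: float = FAT_DENSITY_G_PER_CM3,
) -> float:
    """Lean body mass in grams.

    Raises :class:`ValidationError` when inputs are out of range or the
    implied fat mass exceeds body weight (a segmentation inconsistency).
    """
    if not body_weight_g > 0:
        raise ValidationError("body weight must be positive")
    if adipose_volume_cm3 < 0:
        raise ValidationError("adipose volume must be >= 0")
    if not fat_density > 0:
        raise ValidationError("fat density must be positive")
    lbm = body_weight_g - adipose_volume_cm3 * fat_density
    if lbm < 0:
        raise ValidationError(
            f"fat mass {adipose_volume_cm3 * fat_density:.3g} g exceeds body "
            f"weight {body_weight_g:.3g} g: volume inconsistent with weight"
        )
    return lbm


def add_lean_body_mass(
    records: pd.DataFrame, fat_density: float = FAT_DENSITY_G_PER_CM3
) -> pd.DataFrame:
    """Append an ``lbm_g`` column to an (id, body_weight_g,
    adipose_volume_cm3) table; used by the CSV-in/CSV-out CLI path."""
    required = {"body_weight_g", "adipose_volume_cm3"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"missing column(s): {sorted(missing)}")
    out = records.copy()
    out["lbm_g"] = [
        lean_body_mass(w, v, fat_density=fat_density)
        for w, v in zip(out["body_weight_g"], out["adipose_volume_cm3"])
    ]
    return out
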