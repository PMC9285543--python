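"""Physiological cross-sectional areas (PCSA) of jaw adductor muscles.

Two routes to A_Phys are supported, mirroring how the quantity is obtained
for extant versus extinct archosaurs:

* from muscle architecture (wet mass, mean pennation angle, mean fibre
  length): ``A_Phys = M cos(theta) / (rho L)``;
* from a gross cross-section A_Gross measured perpendicular to the muscle
  body's long axis, corrected for pennation by division by sin(theta)
  (identity at theta = 0, the parallel-fibred case).

Muscles are pooled into three functional groups with fixed default fossil
pennation angles: temporal (mTemp, 45 deg), quadrate (mQuad, 0 deg) and
pterygoid (mPt, 30 deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DENSITY_G_PER_MM3",
    "MUSCLE_GROUPS",
    "GROUP_PENNATION_DEG",
    "MuscleArchitecture",
    "CrossSection",
    "aphys_from_architecture",
    "aphys_from_gross",
    "mean_bilateral_gross",
    "read_architecture_table",
    "read_gross_table",
]

#: Specific density of vertebrate skeletal muscle, g/mm^3.
DENSITY_G_PER_MM3 = 1.056e-3

#: The three functional jaw adductor groups.
MUSCLE_GROUPS = ("mTemp", "mQuad", "mPt")

#: Default pennation angle (degrees) applied to fossil A_Gross per group.
GROUP_PENNATION_DEG = {"mTemp": 45.0, "mQuad": 0.0, "mPt": 30.0}


@dataclass(frozen=True)
class MuscleArchitecture:
    """Architecture of one muscle body.

    Parameters
    ----------
    mass_g
        Wet weight of the muscle body, g.
    pennation_deg
        Mean pennation angle, degrees; 0 for parallel fibres.
    fibre_length_mm
        Mean fibre length, mm.
    density_g_mm3
        Specific density, g/mm^3.
    """

    mass_g: float
    pennation_deg: float
    fibre_length_mm: float
    density_g_mm3: float = DENSITY_G_PER_MM3

    def __post_init__(self) -> None:
        if not self.mass_g > 0:
            raise ValueError("muscle mass must be positive")
        if not self.fibre_length_mm > 0:
            raise ValueError("fibre length must be positive")
        if not self.density_g_mm3 > 0:
            raise ValueError("muscle density must be positive")
        if not 0 <= self.pennation_deg < 90:
            raise ValueError("pennation angle must lie in [0, 90) degrees")


@dataclass(frozen=True)
class CrossSection:
    """A muscle cross-sectional area in mm^2, physiological or gross."""

    area_mm2: float
    kind: str  # "physiological" | "gross"

    def __post_init__(self) -> None:
        if not self.area_mm2 > 0:
            raise ValueError("cross-sectional area must be positive")
        if self.kind not in ("physiological", "gross"):
            raise ValueError(f"unknown cross-section kind {self.kind!r}")


def aphys_from_architecture(arch: MuscleArchitecture) -> CrossSection:
    """A_Phys from muscle architecture: ``M cos(theta) / (rho L)`` in mm^2."""
    theta = math.radians(arch.pennation_deg)
    area = arch.mass_g * math.cos(theta) / (arch.density_g_mm3 * arch.fibre_length_mm)
    return CrossSection(area_mm2=area, kind="physiological")


def aphys_from_gross(gross: CrossSection, pennation_deg: float) -> CrossSection:
    """Approximate A_Phys from a gross cross-section.

    The pennation correction divides A_Gross by sin(theta); at theta = 0
    (parallel fibres, the quadrate group default) no correction is applied.
    """
    if gross.kind != "gross":
        raise ValueError("input cross-section must be gross")
    if not 0 <= pennation_deg < 90:
        raise ValueError("pennation angle must lie in [0, 90) degrees")
    if pennation_deg == 0:
        area = gross.area_mm2
    else:
        area = gross.area_mm2 / math.sin(math.radians(pennation_deg))
    return CrossSection(area_mm2=area, kind="physiological")


def mean_bilateral_gross(
    left_mm2: float | None, right_mm2: float | None
) -> CrossSection:
    """Mean of left/right gross areas; falls back to the single measurable
    side when one is absent (damaged or asymmetric specimens)."""
    sides = [s for s in (left_mm2, right_mm2) if s is not None and not pd.isna(s)]
    if not sides:
        raise ValueError("at least one side must be measured")
    for s in sides:
        if not s > 0:
            raise ValueError("gross areas must be positive")
    return CrossSection(area_mm2=sum(sides) / len(sides), kind="gross")


def read_architecture_table(path) -> pd.DataFrame:
    """Architecture CSV: ``taxon,muscle_group,mass_g,pennation_deg,fibre_length_mm``.

    Returns the table with an added ``aphys_mm2`` column.
    """
    df = pd.read_csv(path, comment="#")
    required = {"taxon", "muscle_group", "mass_g", "pennation_deg", "fibre_length_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"architecture table must have columns {sorted(required)}")
    df = df.copy()
    df["aphys_mm2"] = [
        aphys_from_architecture(
            MuscleArchitecture(r.mass_g, r.pennation_deg, r.fibre_length_mm)
        ).area_mm2
        for r in df.itertuples()
    ]
    return df


def read_gross_table(path, group_angles: dict | None = None) -> pd.DataFrame:
    """Gross-area CSV: ``taxon,muscle_group,area_left_mm2,area_right_mm2``.

    Bilateral means are taken per row and pennation-corrected with the group
    default angles (overridable), yielding an ``aphys_mm2`` column.
    """
    angles = dict(GROUP_PENNATION_DEG if group_angles is None else group_angles)
    df = pd.read_csv(path, comment="#")
    required = {"taxon", "muscle_group", "area_left_mm2", "area_right_mm2"}
    if not required.issubset(df.columns):
        raise ValueError(f"gross table must have columns {sorted(required)}")
    df = df.copy()
    aphys = []
    for r in df.itertuples():
        if r.muscle_group not in angles:
            raise ValueError(f"no pennation angle for muscle group {r.muscle_group!r}")
        gross = mean_bilateral_gross(r.area_left_mm2, r.area_right_mm2)
        aphys.append(aphys_from_gross(gross, angles[r.muscle_group]).area_mm2)
    df["aphys_mm2"] = aphys
    return df
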