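"""Static lever model: muscle cross-sectional areas to bilateral bite force.

Muscle force is tetanic stress times A_Phys (F = sigma * A, sigma 0.3 N/mm^2
by default).  Each muscle group's force acts on its moment arm about the jaw
joint; moments are summed, divided by the out-lever (jaw joint to bite
point) and doubled for bilateral biting:

    F_Bite = 2 * sum_i(F_i * r_i) / d

evaluated at the anterior-most and posterior-most bite positions.  The model
is two-dimensional and scalar: forces act perpendicular to their in-levers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .muscle import CrossSection
from .ppm import PredictiveDistribution

__all__ = [
    "TETANIC_STRESS_N_PER_MM2",
    "LeverGeometry",
    "BiteForceResult",
    "muscle_force",
    "bite_force",
    "bite_force_from_predictions",
    "read_geometry_table",
]

#: Tetanic (maximal isometric) muscle stress, N/mm^2 (= 300 kPa).
TETANIC_STRESS_N_PER_MM2 = 0.3


@dataclass(frozen=True)
class LeverGeometry:
    """Per-taxon jaw lever geometry (all distances mm).

    ``moment_arms_mm`` maps muscle group -> in-lever (moment arm about the
    jaw joint); the out-levers run from the jaw joint to the anterior-most
    and posterior-most bite points.
    """

    moment_arms_mm: Mapping[str, float]
    outlever_ant_mm: float
    outlever_post_mm: float

    def __post_init__(self) -> None:
        for group, arm in self.moment_arms_mm.items():
            if not arm > 0:
                raise ValueError(f"moment arm for {group!r} must be positive")
        if not (self.outlever_ant_mm > 0 and self.outlever_post_mm > 0):
            raise ValueError("out-lever distances must be positive")
        if self.outlever_ant_mm < self.outlever_post_mm:
            raise ValueError(
                "anterior out-lever must be at least the posterior out-lever "
                "(the anterior bite point is farther from the jaw joint)"
            )


@dataclass(frozen=True)
class BiteForceResult:
    """Bilateral bite forces (N) with the per-muscle breakdown."""

    f_bant_n: float
    f_bpost_n: float
    muscle_forces_n: dict[str, float]
    torques_nmm: dict[str, float]


def muscle_force(
    aphys: CrossSection | float, sigma: float = TETANIC_STRESS_N_PER_MM2
) -> float:
    """Maximal isometric force (N) of a muscle: sigma * A_Phys."""
    area = aphys.area_mm2 if isinstance(aphys, CrossSection) else float(aphys)
    if not area > 0:
        raise ValueError("A_Phys must be positive")
    if not sigma > 0:
        raise ValueError("tetanic stress must be positive")
    return sigma * area


def bite_force(
    forces_n: Mapping[str, float], geometry: LeverGeometry
) -> BiteForceResult:
    """Bilateral bite force at the anterior and posterior bite points."""
    torques = {}
    for group, force in forces_n.items():
        if group not in geometry.moment_arms_mm:
            raise ValueError(f"no moment arm supplied for muscle group {group!r}")
        if force < 0:
            raise ValueError(f"negative muscle force for {group!r}")
        torques[group] = force * geometry.moment_arms_mm[group]
    total = sum(torques.values())
    return BiteForceResult(
        f_bant_n=2.0 * total / geometry.outlever_ant_mm,
        f_bpost_n=2.0 * total / geometry.outlever_post_mm,
        muscle_forces_n=dict(forces_n),
        torques_nmm=torques,
    )


def bite_force_from_predictions(
    predictions: Mapping[str, PredictiveDistribution],
    geometry: LeverGeometry,
    sigma: float = TETANIC_STRESS_N_PER_MM2,
) -> BiteForceResult:
    """Bite force from posterior predictive A_Phys distributions.

    One distribution per muscle group, on the log10(mm^2) scale.  The
    predictive median is taken per group and back-transformed (equivalently,
    the median of the back-transformed draws: the median commutes with
    monotone maps), then fed through the lever model.
    """
    missing = sorted(set(geometry.moment_arms_mm) - set(predictions))
    if missing:
        raise ValueError(f"missing predictive distributions for groups: {missing}")
    forces = {
        group: muscle_force(10.0 ** pred.median, sigma)
        for group, pred in predictions.items()
    }
    return bite_force(forces, geometry)


def read_geometry_table(path) -> dict[str, LeverGeometry]:
    """Geometry CSV with header
    ``taxon,arm_mTemp_mm,arm_mQuad_mm,arm_mPt_mm,outlever_ant_mm,outlever_post_mm``.
    """
    df = pd.read_csv(path, comment="#")
    required = {
        "taxon", "arm_mTemp_mm", "arm_mQuad_mm", "arm_mPt_mm",
        "outlever_ant_mm", "outlever_post_mm",
    }
    if not required.issubset(df.columns):
        raise ValueError(f"geometry table must have columns {sorted(required)}")
    out = {}
    for r in df.itertuples():
        out[str(r.taxon)] = LeverGeometry(
            moment_arms_mm={
                "mTemp": float(r.arm_mTemp_mm),
                "mQuad": float(r.arm_mQuad_mm),
                "mPt": float(r.arm_mPt_mm),
            },
            outlever_ant_mm=float(r.outlever_ant_mm),
            outlever_post_mm=float(r.outlever_post_mm),
        )
    return out
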