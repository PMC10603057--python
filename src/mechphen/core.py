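"""Shared domain types for the morpho-mechanical phenotyping pipeline.

The pipeline studies how fibroblasts (vimentin wildtype vs knockout)
adapt to their mechanical microenvironment: polyacrylamide substrates of
two stiffnesses (12 and 27 kPa) coated with collagen I at two densities
(25 and 100 ug/ml), observed at 24 h and 48 h.  These types carry the
experimental design and the vector-field container used by the traction
force microscopy stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

# Young's moduli of the two polyacrylamide substrate formulations, Pa.
STIFFNESS_PA = {"E_P": 12_000.0, "E_H": 27_000.0}
# Collagen type I coating densities, ug/ml.
COATING_UG_ML = {"C_P": 25.0, "C_H": 100.0}
GENOTYPES = ("VimWT", "VimKO")
TIMEPOINTS_H = (24, 48)

PROPERTY_CATEGORIES = (
    "cellular morphology",
    "nuclear morphology",
    "cell mechanics",
    "cell migration",
    "cell-matrix interactions",
)


@dataclass(frozen=True)
class Condition:
    """One cell-culture condition of the 2 x 2 x 2 design at a timepoint.

    Attributes
    ----------
    stiffness_level : {"E_P", "E_H"}
        Physiological (12 kPa) or high (27 kPa) substrate stiffness.
    ecm_level : {"C_P", "C_H"}
        Physiological (25 ug/ml) or high (100 ug/ml) collagen coating.
    genotype : {"VimWT", "VimKO"}
        Vimentin wildtype or knockout fibroblasts.
    timepoint_h : int
        Culture duration in hours (24 or 48).
    """

    stiffness_level: str
    ecm_level: str
    genotype: str
    timepoint_h: int = 24

    def __post_init__(self) -> None:
        if self.stiffness_level not in STIFFNESS_PA:
            raise ValueError(f"unknown stiffness level {self.stiffness_level!r}")
        if self.ecm_level not in COATING_UG_ML:
            raise ValueError(f"unknown ECM density level {self.ecm_level!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.timepoint_h <= 0:
            raise ValueError("timepoint_h must be positive")

    @property
    def modulus_pa(self) -> float:
        return STIFFNESS_PA[self.stiffness_level]

    @property
    def coating_ug_ml(self) -> float:
        return COATING_UG_ML[self.ecm_level]

    @property
    def condition_id(self) -> str:
        return (
            f"{self.stiffness_level}-{self.ecm_level}-"
            f"{self.genotype}-{self.timepoint_h}h"
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.condition_id


def control_condition(timepoint_h: int = 24) -> Condition:
    """The reference culture condition E_P-C_P-VimWT."""
    return Condition("E_P", "C_P", "VimWT", timepoint_h)


def full_design(timepoint_h: int = 24) -> list[Condition]:
    """All 8 stiffness x density x genotype combinations at a timepoint."""
    return [
        Condition(s, c, g, timepoint_h)
        for s, c, g in product(STIFFNESS_PA, COATING_UG_ML, GENOTYPES)
    ]


@dataclass
class VectorField2D:
    """A 2D vector field sampled on a regular grid.

    Used both for bead displacement fields (components in um) and for
    traction fields (components in Pa).  ``u`` is the x-component and
    ``v`` the y-component; arrays are indexed [row, col] = [y, x].
    """

    u: np.ndarray
    v: np.ndarray
    spacing_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.ndim != 2 or self.u.shape != self.v.shape:
            raise ValueError("u and v must be 2D arrays of identical shape")
        if self.spacing_um <= 0:
            raise ValueError("grid spacing must be positive")
        if self.valid is None:
            self.valid = np.ones(self.u.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.u.shape:
                raise ValueError("validity mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def magnitude(self) -> np.ndarray:
        """Pointwise Euclidean norm of the vectors."""
        return np.hypot(self.u, self.v)

    def net_vector(self) -> np.ndarray:
        """Component-wise sum over the grid (e.g. net force check)."""
        return np.array([self.u.sum(), self.v.sum()])

    def copy(self) -> "VectorField2D":
        return VectorField2D(
            self.u.copy(), self.v.copy(), self.spacing_um,
            self.origin_um, self.valid.copy(),
        )


@dataclass(frozen=True)
class SubstrateModel:
    """Linear-elastic half-space substrate with imaging calibration.

    Parameters
    ----------
    young_modulus_pa : float
        Young's modulus E of the gel, Pa.
    poisson_ratio : float
        Poisson ratio nu; polyacrylamide is nearly incompressible, so
        the default is 0.5.
    pixel_size_um : float
        Lateral calibration of the bead images, um per pixel.
    """

    young_modulus_pa: float
    poisson_ratio: float = 0.5
    pixel_size_um: float = 0.2

    def __post_init__(self) -> None:
        if self.young_modulus_pa <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
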