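"""Orthotropic aortic-wall stiffness.

The aortic wall is stiffer longitudinally than circumferentially because
of collagen/elastin fiber orientation.  For an orthotropic lamina the
modulus seen at an angle ``theta`` from the longitudinal axis follows the
classical transformation

    1/E(theta) = cos^4(theta)/E_L + sin^4(theta)/E_C
                 + 1/4 * (1/G_LC - 2*v_LC/E_L) * sin^2(2*theta)

This package does not run a stress solver; the directional modulus is
exposed as a standalone utility and recorded in case reports as material
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class OrthotropicMaterial:
    """Orthotropic elastic constants of the wall.

    Attributes
    ----------
    E_L : longitudinal elastic modulus, MPa
    E_C : circumferential elastic modulus, MPa
    G_LC : in-plane shear modulus, MPa
    v_LC : major Poisson's ratio (dimensionless)
    """

    E_L: float
    E_C: float
    G_LC: float
    v_LC: float

    def __post_init__(self):
        if self.E_L <= 0 or self.E_C <= 0 or self.G_LC <= 0:
            raise ValueError("elastic and shear moduli must be positive")
        if not (0.0 <= self.v_LC < 0.5):
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")


#: Placeholder wall constants (MPa); order of magnitude only — patient or
#: literature values should be supplied in the case config.
DEFAULT_WALL = OrthotropicMaterial(E_L=3.0, E_C=1.5, G_LC=0.6, v_LC=0.27)


def elastic_modulus_at_angle(mat: OrthotropicMaterial, theta) -> np.ndarray | float:
    """Directional elastic modulus E(theta), MPa.

    ``theta`` is measured from the longitudinal direction; the result is
    periodic with period pi, with E(0) = E_L and E(pi/2) = E_C.  Accepts
    scalars or arrays.
    """
    theta = np.asarray(theta, dtype=float)
    c, s = np.cos(theta), np.sin(theta)
    compliance = (
        c**4 / mat.E_L
        + s**4 / mat.E_C
        + 0.25 * (1.0 / mat.G_LC - 2.0 * mat.v_LC / mat.E_L) * np.sin(2.0 * theta) ** 2
    )
    E = 1.0 / compliance
    return float(E) if E.ndim == 0 else E
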