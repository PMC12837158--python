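"""Physics-informed risk features from the apposition field.

Three normalized, dimensionless features summarize the sealing geometry:

* **AC** (aortic conicity): relative change in mean lumen radius between
  the proximal and distal boundaries of the sealing region; symmetric
  for taper vs widening.
* **SGS2** (stent-graft shape): mean per-slice non-circularity of the
  deployed graft section, (rG,max - rG,min)/rG,max.
* **SGM2** (malapposition extent): longest contiguous longitudinal run
  of wall-graft gap above a threshold ``epsilon``, at any angle, as a
  fraction of the region length.

Each lies in [0, 1] by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .apposition import AppositionField

#: Default apposition threshold (mm): the mesh-noise floor of the slicing
#: pipeline on synthetic fixtures; gaps below this are indistinguishable
#: from discretization error.
DEFAULT_EPSILON = 0.1


@dataclass(frozen=True)
class RiskFeatures:
    """The three ERI inputs plus diagnostics carried into reports."""

    ac: float
    sgs2: float
    sgm2: float
    oversizing_mean: float
    max_gap_depth: float  # mm; diagnostic, not an ERI input
    epsilon: float

    def __post_init__(self):
        for name in ("ac", "sgs2", "sgm2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    def as_dict(self) -> dict:
        return {
            "ac": self.ac,
            "sgs2": self.sgs2,
            "sgm2": self.sgm2,
            "oversizing_mean": self.oversizing_mean,
            "max_gap_depth_mm": self.max_gap_depth,
            "epsilon_mm": self.epsilon,
        }


def aortic_conicity(field_: AppositionField) -> float:
    """AC = |mean rA(first) - mean rA(last)| / max of the two."""
    if field_.n_slices < 2:
        raise ValueError("conicity needs at least 2 slices")
    r_first = field_.r_aorta[0].mean()
    r_last = field_.r_aorta[-1].mean()
    denom = max(r_first, r_last)
    if denom <= 0:
        raise ValueError("degenerate zero mean radius")
    return float(abs(r_first - r_last) / denom)


def graft_shape_score(field_: AppositionField, mode: str = "mean") -> float:
    """Per-slice non-circularity (rG,max - rG,min)/rG,max aggregated over slices.

    ``mode="mean"`` (default) keeps the score in [0, 1]; ``mode="sum"``
    returns the raw sum over slices (can exceed 1 and is provided only as
    a diagnostic alternative).
    """
    rg_max = field_.rg_max
    if np.any(rg_max <= 0):
        raise ValueError("degenerate slice with rG,max = 0")
    d = (rg_max - field_.rg_min) / rg_max
    if mode == "mean":
        return float(d.mean())
    if mode == "sum":
        return float(d.sum())
    raise ValueError(f"unknown SGS2 mode {mode!r}")


def malapposition_extent(
    field_: AppositionField, epsilon: float = DEFAULT_EPSILON, mode: str = "extent"
) -> float:
    """SGM2: longest longitudinal malapposition run / region length.

    A sample is malapposed when gap > epsilon.  For each angle the
    longest contiguous run of malapposed slices is converted to mm
    (run count x slice spacing); the maximum over angles, divided by the
    region length, is the score.  ``mode="depth"`` instead returns the
    peak gap depth normalized by the initial graft radius (diagnostic
    alternative interpretation).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if field_.n_slices == 0 or field_.n_angles == 0:
        raise ValueError("empty apposition field")
    gap = np.clip(field_.gap, 0.0, None)
    if mode == "depth":
        return float(min(1.0, gap.max() / field_.r_g0))
    if mode != "extent":
        raise ValueError(f"unknown SGM2 mode {mode!r}")
    mal = gap > epsilon  # (n_slices, n_angles)
    max_run = _longest_run_per_column(mal).max() if mal.any() else 0
    length_mm = max_run * field_.region.slice_spacing
    return float(min(1.0, length_mm / field_.region.length))


def _longest_run_per_column(mask: np.ndarray) -> np.ndarray:
    """Longest run of True down each column of a 2-D boolean array."""
    ns, na = mask.shape
    runs = np.zeros(na, dtype=int)
    best = np.zeros(na, dtype=int)
    for i in range(ns):
        runs = np.where(mask[i], runs + 1, 0)
        best = np.maximum(best, runs)
    return best


def extract_features(
    field_: AppositionField,
    epsilon: float = DEFAULT_EPSILON,
    sgs_mode: str = "mean",
    sgm_mode: str = "extent",
) -> RiskFeatures:
    """All risk features of one case, with oversizing and gap diagnostics."""
    from .apposition import oversizing_profile

    ac = aortic_conicity(field_)
    sgs2 = graft_shape_score(field_, mode=sgs_mode)
    sgm2 = malapposition_extent(field_, epsilon=epsilon, mode=sgm_mode)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        over = float(oversizing_profile(field_).mean())
    return RiskFeatures(
        ac=min(1.0, ac),
        sgs2=min(1.0, sgs2),
        sgm2=sgm2,
        oversizing_mean=over,
        max_gap_depth=float(np.clip(field_.gap, 0, None).max()),
        epsilon=epsilon,
    )
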