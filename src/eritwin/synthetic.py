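"""Parametric synthetic anatomies and cohorts.

Real deployed EVAR geometries come out of an image-based finite-element
deployment simulation; none are publicly deposited.  This module builds
the *deployed state* directly: a tubular aortic neck with controllable
taper (conicity), angulation and aneurysm bulge, plus a graft surface
apposed to the wall except inside declared, cosine-tapered gap defects
and optional cross-section ovalization.  Because every defect is declared
in the :class:`SyntheticCaseSpec`, downstream feature extraction can be
tested against known ground truth.

A cohort generator draws per-case specs and clinical covariates, assigns
the ground-truth endoleak label by an explicit, declared rule on the
geometry (never hidden inside the sampler), and induces confounding
between planning group and covariates for propensity-matching tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional

import numpy as np
import pandas as pd

from .geometry import CenterlinePath, GeometryError, SurfaceMesh, loft_closed_tube, resample_centerline


@dataclass(frozen=True)
class GapDefect:
    """Localized wall-graft separation.

    The graft radius is depressed by ``depth * sin^2(pi * x)`` longitudinally
    over ``[start_s, start_s + length]`` (x the normalized position) and by a
    matching cosine taper across ``angular_span_deg`` centered on
    ``angular_center_deg``; the peak separation equals ``depth``.
    """

    start_s: float  # mm from the graft's proximal edge
    length: float  # longitudinal extent, mm
    angular_center_deg: float
    angular_span_deg: float
    depth: float  # peak gap, mm


@dataclass
class SyntheticCaseSpec:
    """Full parameterization of one synthetic aorta + deployed graft."""

    neck_radius_proximal: float = 10.6  # mm
    neck_radius_distal: float = 10.6  # mm; differs from proximal => conical neck
    neck_length: float = 30.0  # mm
    angulation_deg: float = 0.0  # total centerline direction change
    sac_max_radius: float = 25.0  # mm
    sac_length: float = 40.0  # mm
    tail_length: float = 8.0  # straight distal segment, mm
    graft_start: float = 0.0  # mm from proximal end
    graft_length: float = 25.0  # mm
    graft_nominal_radius: Optional[float] = None  # R_G0-generating parameter
    ovalization: float = 0.0  # (r_max - r_min)/r_max of graft sections
    gap_defects: List[GapDefect] = field(default_factory=list)
    ring_spacing: float = 0.4  # mesh resolution along the axis, mm
    n_circumferential: int = 128
    seed: int = 0

    def __post_init__(self):
        if min(self.neck_radius_proximal, self.neck_radius_distal) <= 0:
            raise ValueError("neck radii must be positive")
        if self.sac_max_radius < self.neck_radius_distal:
            raise ValueError(
                "sac radius below distal neck radius would self-intersect the bulge"
            )
        if not (0.0 <= self.ovalization < 1.0):
            raise ValueError("ovalization must lie in [0, 1)")
        for d in self.gap_defects:
            if d.start_s < 0 or d.start_s + d.length > self.graft_length:
                raise ValueError("gap defect extends beyond the graft")
            if d.depth <= 0:
                raise ValueError("gap defect depth must be positive")
        if self.graft_nominal_radius is None:
            self.graft_nominal_radius = round(1.15 * self.neck_radius_proximal, 3)

    @property
    def total_length(self) -> float:
        return self.neck_length + self.sac_length + self.tail_length

    @property
    def conicity(self) -> float:
        a, b = self.neck_radius_proximal, self.neck_radius_distal
        return abs(a - b) / max(a, b)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticCaseSpec":
        d = dict(d)
        d["gap_defects"] = [
            g if isinstance(g, GapDefect) else GapDefect(**g) for g in d.get("gap_defects", [])
        ]
        return cls(**d)


def _wall_radius(spec: SyntheticCaseSpec, s: np.ndarray) -> np.ndarray:
    """Aortic lumen radius profile along arclength (mm)."""
    s = np.asarray(s, dtype=float)
    r = np.empty_like(s)
    rp, rd = spec.neck_radius_proximal, spec.neck_radius_distal
    neck = s <= spec.neck_length
    r[neck] = rp + (rd - rp) * s[neck] / spec.neck_length
    sac = (s > spec.neck_length) & (s <= spec.neck_length + spec.sac_length)
    x = (s[sac] - spec.neck_length) / spec.sac_length
    r[sac] = rd + (spec.sac_max_radius - rd) * np.sin(np.pi * x) ** 2
    tail = s > spec.neck_length + spec.sac_length
    r[tail] = rd
    return r


def _centerline_points(spec: SyntheticCaseSpec, ds: float = 0.25) -> np.ndarray:
    """Centerline with the requested total angulation, bent smoothly in x-z."""
    L = spec.total_length
    n = int(round(L / ds)) + 1
    s = np.linspace(0.0, L, n)
    alpha = math.radians(spec.angulation_deg)
    # direction angle ramps smoothly (smoothstep) from 0 to alpha
    x = s / L
    theta = alpha * (3 * x**2 - 2 * x**3)
    dirs = np.column_stack([np.sin(theta), np.zeros_like(theta), np.cos(theta)])
    pts = np.zeros((n, 3))
    pts[1:] = np.cumsum(0.5 * (dirs[1:] + dirs[:-1]) * np.diff(s)[:, None], axis=0)
    return pts


def generate_aorta(spec: SyntheticCaseSpec) -> tuple[SurfaceMesh, CenterlinePath]:
    """Watertight aortic surface plus its generating centerline.

    The cross-section radius interpolates linearly between the proximal
    and distal neck radii, bulges to ``sac_max_radius`` over the sac and
    returns to the distal radius.  Deterministic given the spec.
    """
    path = resample_centerline(_centerline_points(spec), spec.ring_spacing)
    svals = path.s
    radii = _wall_radius(spec, svals)
    U, V = path.frames()
    phi = 2.0 * np.pi * np.arange(spec.n_circumferential) / spec.n_circumferential
    cosphi, sinphi = np.cos(phi), np.sin(phi)
    rings = (
        path.points[:, None, :]
        + radii[:, None, None]
        * (cosphi[None, :, None] * U[:, None, :] + sinphi[None, :, None] * V[:, None, :])
    )
    return loft_closed_tube(rings), path


def _graft_radius_field(
    spec: SyntheticCaseSpec, s_local: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Deployed graft radius at local arclength x angle (mm).

    Starts from the wall radius (perfect apposition), applies ovalization
    as an inward minor-axis deviation and subtracts declared gap-defect
    depressions.  Raises when a depression exceeds the local radius.
    """
    s_local = np.asarray(s_local, dtype=float)
    phi = np.asarray(phi, dtype=float)
    wall = _wall_radius(spec, s_local + spec.graft_start)
    r = np.repeat(wall[:, None], len(phi), axis=1)
    if spec.ovalization > 0:
        # (r_max - r_min)/r_max = ovalization, major axis at phi = 0
        r = r * (1.0 - spec.ovalization * np.sin(phi) ** 2)[None, :]
    for d in spec.gap_defects:
        xin = (s_local - d.start_s) / d.length
        f_s = np.where((xin >= 0) & (xin <= 1), np.sin(np.pi * np.clip(xin, 0, 1)) ** 2, 0.0)
        half = math.radians(d.angular_span_deg) / 2.0
        dphi = np.angle(np.exp(1j * (phi - math.radians(d.angular_center_deg))))
        f_phi = np.where(np.abs(dphi) <= half, np.cos(np.pi * dphi / (2 * half)) ** 2, 0.0)
        r = r - d.depth * f_s[:, None] * f_phi[None, :]
    if np.any(r <= 0.05):
        raise GeometryError("gap depth reaches or exceeds the local graft radius")
    return r


def generate_deployed_graft(
    spec: SyntheticCaseSpec, path: Optional[CenterlinePath] = None
) -> SurfaceMesh:
    """Deployed graft surface apposed to the aortic wall except at defects."""
    if path is None:
        path = resample_centerline(_centerline_points(spec), spec.ring_spacing)
    s0, s1 = spec.graft_start, spec.graft_start + spec.graft_length
    n = max(2, int(round((s1 - s0) / spec.ring_spacing)) + 1)
    svals = np.linspace(s0, s1, n)
    phi = 2.0 * np.pi * np.arange(spec.n_circumferential) / spec.n_circumferential
    r = _graft_radius_field(spec, svals - s0, phi)
    U, V = path.frames()
    cosphi, sinphi = np.cos(phi), np.sin(phi)
    centers = np.array([path.point_at(s) for s in svals])
    # frames interpolated from the path samples
    idx = np.clip(np.searchsorted(path.s, svals), 0, len(path.s) - 1)
    rings = (
        centers[:, None, :]
        + r[:, :, None] * (cosphi[None, :, None] * U[idx][:, None, :]
                           + sinphi[None, :, None] * V[idx][:, None, :])
    )
    return loft_closed_tube(rings)


def generate_case(spec: SyntheticCaseSpec):
    """Convenience: (aorta mesh, graft mesh, centerline) for one spec."""
    aorta, path = generate_aorta(spec)
    graft = generate_deployed_graft(spec, path)
    return aorta, graft, path


# --------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class LabelRule:
    """Declared ground-truth endoleak rule applied to the case geometry.

    A case leaks when a wall gap deeper than ``depth_mm`` persists at
    least ``extent_mm`` longitudinally (declared defects, or an
    ovalization-induced minor-axis gap amp*r which persists over the whole
    graft), or when neck conicity exceeds ``conicity_threshold``.  Labels
    are then flipped at ``noise_rate`` to emulate diagnostic noise.
    """

    depth_mm: float = 1.0
    extent_mm: float = 5.0
    conicity_threshold: float = 0.25
    noise_rate: float = 0.03

    def applies(self, spec: SyntheticCaseSpec) -> bool:
        for d in spec.gap_defects:
            if d.depth > self.depth_mm and d.length >= self.extent_mm:
                return True
        if spec.ovalization * spec.neck_radius_proximal > self.depth_mm:
            return True
        return spec.conicity > self.conicity_threshold


#: Covariates entering the propensity model, mirroring standard EVAR
#: baseline tables (demographics, comorbidity flags, neck anatomy).
COVARIATE_COLUMNS = [
    "age", "male", "bmi", "hypertension", "diabetes", "cad", "copd", "ckd",
    "crf_hd", "cerebrovascular", "hyperlipidemia", "hostile_neck",
    "neck_length", "neck_angle", "neck_diameter",
]

BINARY_COVARIATES = {
    "male", "hypertension", "diabetes", "cad", "copd", "ckd", "crf_hd",
    "cerebrovascular", "hyperlipidemia", "hostile_neck",
}


@dataclass
class CohortRecord:
    """One synthetic patient: covariates, planning group, features, label."""

    case_id: str
    age: float
    male: int
    bmi: float
    hypertension: int
    diabetes: int
    cad: int
    copd: int
    ckd: int
    crf_hd: int
    cerebrovascular: int
    hyperlipidemia: int
    smoking: int
    hostile_neck: int
    neck_length: float
    neck_angle: float
    neck_diameter: float
    group: int  # 1 = digital-twin planning arm
    ac: float
    sgs2: float
    sgm2: float
    leak: int  # ground-truth (noisy) endoleak label


def _analytic_features(
    spec: SyntheticCaseSpec,
    region_length: float = 20.0,
    epsilon: float = 0.1,
) -> tuple[float, float, float]:
    """Closed-form expected features over a proximal region of the graft.

    Mirrors what the mesh pipeline measures: conicity over the region,
    mean cross-section non-circularity, and the longest longitudinal run
    of gap > epsilon as a fraction of the region length.
    """
    L = min(region_length, spec.graft_length)
    r0 = _wall_radius(spec, np.array([spec.graft_start]))[0]
    r1 = _wall_radius(spec, np.array([min(spec.graft_start + L, spec.neck_length)]))[0]
    ac = abs(r0 - r1) / max(r0, r1)
    sgs2 = spec.ovalization
    runs = [0.0]
    if spec.ovalization * min(r0, r1) > epsilon:
        # minor-axis separation persists over the graft's full coverage
        runs.append(L)
    for d in spec.gap_defects:
        if d.depth <= epsilon:
            continue
        # width of the sin^2 longitudinal profile above epsilon
        frac = 1.0 - (2.0 / math.pi) * math.asin(math.sqrt(epsilon / d.depth))
        lo = max(d.start_s, 0.0)
        hi = min(d.start_s + d.length, L)
        runs.append(max(0.0, (hi - lo)) * frac)
    sgm2 = min(1.0, max(runs) / L)
    return float(np.clip(ac, 0, 1)), float(np.clip(sgs2, 0, 1)), float(sgm2)


def _draw_case_spec(rng: np.random.Generator, risky: bool) -> SyntheticCaseSpec:
    """One anatomy draw; ``risky`` selects leak-prone deployment geometry."""
    rp = float(np.clip(rng.normal(10.6, 1.25), 7.5, 15.0))
    angle = float(np.clip(rng.gamma(2.0, 18.0), 0.0, 85.0))
    neck_len = float(np.clip(rng.normal(30.0, 6.0), 16.0, 45.0))
    if risky:
        mech = rng.choice(["defect", "taper", "oval"], p=[0.6, 0.25, 0.15])
    else:
        mech = "benign"
    taper = float(np.clip(rng.normal(0.06, 0.04), 0.0, 0.18))
    # well-deployed grafts are near-circular: residual non-circularity < 1%
    oval = float(np.clip(abs(rng.normal(0.0, 0.003)), 0.0, 0.008))
    defects: list[GapDefect] = []
    if mech == "taper":
        taper = float(rng.uniform(0.28, 0.45))
    elif mech == "oval":
        oval = float(rng.uniform(1.15, 1.8)) / rp  # amp*r > 1 mm
    elif mech == "defect":
        depth = float(rng.uniform(1.3, 3.0))
        length = float(rng.uniform(6.0, 14.0))
        defects.append(
            GapDefect(
                start_s=float(rng.uniform(0.5, 4.0)),
                length=length,
                angular_center_deg=float(rng.uniform(0, 360)),
                angular_span_deg=float(rng.uniform(60, 150)),
                depth=depth,
            )
        )
    else:
        # benign cases may carry shallow, sub-threshold irregularities
        if rng.random() < 0.35:
            defects.append(
                GapDefect(
                    start_s=float(rng.uniform(0.5, 6.0)),
                    length=float(rng.uniform(2.0, 4.5)),
                    angular_center_deg=float(rng.uniform(0, 360)),
                    angular_span_deg=float(rng.uniform(40, 100)),
                    depth=float(rng.uniform(0.15, 0.85)),
                )
            )
    rd = rp * (1.0 - taper)
    return SyntheticCaseSpec(
        neck_radius_proximal=rp,
        neck_radius_distal=rd,
        neck_length=neck_len,
        angulation_deg=angle,
        sac_max_radius=float(np.clip(rng.normal(25.0, 4.0), rd + 2.0, 40.0)),
        ovalization=oval,
        gap_defects=defects,
        graft_length=25.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_cohort(
    n: int,
    leak_fraction: float = 0.3,
    confounding: float = 0.0,
    seed: int = 0,
    rule: LabelRule = LabelRule(),
    feature_noise_sd: float = 0.01,
    treated_fraction: float = 0.25,
) -> tuple[list[CohortRecord], list[SyntheticCaseSpec]]:
    """Labeled synthetic cohort with per-case deployment specs.

    ``leak_fraction`` sets the share of anatomies drawn from the
    leak-prone parameter regime; the *label* itself always comes from the
    declared :class:`LabelRule` on the drawn geometry plus its stated
    noise rate.  ``confounding`` scales how strongly the planning-group
    flag depends on age, smoking and hostile neck anatomy (0 gives a
    randomized group and near-zero standardized mean differences).
    """
    if n < 10:
        raise ValueError("cohort size must be at least 10")
    if not (0.0 < leak_fraction < 1.0):
        raise ValueError("leak_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    specs: list[SyntheticCaseSpec] = []
    logit_base = math.log(treated_fraction / (1.0 - treated_fraction))
    for i in range(n):
        risky = bool(rng.random() < leak_fraction)
        spec = _draw_case_spec(rng, risky)
        specs.append(spec)
        ac, sgs2, sgm2 = _analytic_features(spec)
        ac = float(np.clip(ac + rng.normal(0, feature_noise_sd), 0, 1))
        sgs2 = float(np.clip(sgs2 + rng.normal(0, feature_noise_sd), 0, 1))
        sgm2 = float(np.clip(sgm2 + rng.normal(0, feature_noise_sd), 0, 1))
        leak = rule.applies(spec)
        if rng.random() < rule.noise_rate:
            leak = not leak
        age = float(np.clip(rng.normal(78.6, 8.7), 50, 95))
        smoking = int(rng.random() < 0.5)
        hostile = int(
            spec.angulation_deg > 60.0 or spec.neck_length < 18.0 or spec.conicity > 0.15
        )
        lin = confounding * (
            0.8 * (age - 78.6) / 8.7 + 1.2 * smoking + 1.0 * hostile
        )
        group = int(rng.random() < 1.0 / (1.0 + math.exp(-(logit_base + lin))))
        records.append(
            CohortRecord(
                case_id=f"case{i:04d}",
                age=age,
                male=int(rng.random() < 0.733),
                bmi=float(np.clip(rng.normal(22.7, 4.7), 14, 40)),
                hypertension=int(rng.random() < 0.80),
                diabetes=int(rng.random() < 0.18),
                cad=int(rng.random() < 0.18),
                copd=int(rng.random() < 0.08),
                ckd=int(rng.random() < 0.08),
                crf_hd=int(rng.random() < 0.05),
                cerebrovascular=int(rng.random() < 0.21),
                hyperlipidemia=int(rng.random() < 0.14),
                smoking=smoking,
                hostile_neck=hostile,
                neck_length=spec.neck_length,
                neck_angle=spec.angulation_deg,
                neck_diameter=2.0 * spec.neck_radius_proximal,
                group=group,
                ac=ac,
                sgs2=sgs2,
                sgm2=sgm2,
                leak=int(leak),
            )
        )
    return records, specs


def cohort_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records]).set_index("case_id")
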