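"""Phantom cohorts with known ground truth.

Generates demographics plus six-class probability volumes (and simple
deformation fields) that emulate the statistical structure of a real
multi-site lifespan cohort without any anatomy: a spherically layered "head"
(white-matter core, gray-matter shell, CSF, bone and soft-tissue shells,
background outside) whose gray/white balance follows a smooth age
trajectory, with a small global sex offset, a field-strength effect
localised to the gray/white tissue boundary, and voxel noise whose standard
deviation decreases with the subject's combined data-quality score.

The six expected class probabilities sum to 1 before noise by construction;
noise is added independently per class and clipped to [0, 1], leaving the
kind of per-voxel inconsistency that real segmentations exhibit (and that
prior assembly must repair).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable, SubjectRecord, quality_indicator
from .voxelwise import TISSUE_CLASSES, TissueStack

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "DeformationField",
    "generate_cohort",
    "generate_deformation",
]


@dataclass
class PhantomSpec:
    """Study conditions of the phantom cohort.

    Ages are uniform over ``age_range`` months; the gray-matter trajectory is
    a gamma-shaped pulse peaking at ``gm_peak_age`` months (childhood peak
    followed by a slow decline), exchanged against white matter so tissue
    mass is conserved.  Maturation timing varies regionally, as in real
    development: the local peak age is modulated by
    ``1 + peak_age_gradient * sin(2 pi peak_age_cycles * z)`` for normalized
    coordinate z in [0, 1] along the third axis, so no single global curve
    fits every voxel and neighbouring regions mature on different schedules.
    ``sex_effect`` and ``field_effect`` are probability offsets (male >
    female on GM; 3T vs 1.5T at the GM/WM interface).
    ``sigma0`` is the noise SD at average quality; per-subject noise is
    ``sigma0 * exp(-quality_noise_scale * q)`` for combined quality score q.
    """

    grid_size: int = 16
    n_subjects: int = 200
    age_range: tuple[float, float] = (13.0, 900.0)
    gm_peak_age: float = 120.0
    peak_age_gradient: float = 0.5
    peak_age_cycles: float = 1.5
    gm_amplitude: float = 0.12
    sex_effect: float = 0.03
    field_effect: float = 0.05
    sigma0: float = 0.03
    quality_noise_scale: float = 0.15
    p_male: float = 0.46
    p_3t: float = 0.70
    voxel_size_mm: float = 8.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.rng_seed is None:
            raise ValueError("phantom generation requires an explicit rng_seed")
        if self.grid_size < 4:
            raise ValueError("grid_size must be at least 4")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not (0 < self.age_range[0] < self.age_range[1]):
            raise ValueError("invalid age range")
        if 4.0 * (self.gm_amplitude + 0.5 * self.sex_effect
                  + self.field_effect) >= 1.0:
            raise ValueError("combined effects too large; probabilities would leave [0,1]")


@dataclass
class PhantomTruth:
    """Ground truth behind a generated cohort, for recovery tests.

    The age and sex effects move probability mass into gray matter from all
    other classes in proportion to their local mass; the field-strength
    effect exchanges mass between gray and white matter at their interface.
    Both mechanisms conserve the per-voxel probability simplex exactly.
    ``gm_weight`` is the spatial weight of the age-effect GM increment,
    4 m_GM (1 - m_GM); ``boundary_weight`` is 4 m_GM m_WM.
    """

    base_maps: dict[str, np.ndarray]       # expected class maps at traj = 0
    gm_weight: np.ndarray                  # spatial weight of the age effect
    boundary_weight: np.ndarray            # spatial weight of the field effect
    sex_weight: np.ndarray                 # spatial weight of the sex effect
    peak_age_map: np.ndarray               # regional maturation peak (months)
    sigma_per_subject: np.ndarray
    spec: PhantomSpec

    def trajectory(self, age_months, peak_age=None) -> np.ndarray:
        """Unit-peak gamma pulse: (a/tau) * exp(1 - a/tau), peak at tau."""
        tau = self.spec.gm_peak_age if peak_age is None else peak_age
        a = np.asarray(age_months, dtype=float) / tau
        return a * np.exp(1.0 - a)

    def expected_map(self, class_label: str, age_months: float,
                     male: float, is_3t: float) -> np.ndarray:
        """Noise-free expected probability map for one demographic setting."""
        s = self.spec
        m_gm = self.base_maps["GM"]
        traj = self.trajectory(float(age_months), self.peak_age_map)
        # fraction of each non-GM class handed over to GM at this setting
        shrink = (s.gm_amplitude * traj
                  + 0.5 * s.sex_effect * male) * 4.0 * m_gm
        field_d = s.field_effect * is_3t * self.boundary_weight
        if class_label == "GM":
            return m_gm + (1.0 - m_gm) * shrink + field_d
        if class_label == "WM":
            return self.base_maps["WM"] * (1.0 - shrink) - field_d
        return self.base_maps[class_label] * (1.0 - shrink)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _radial_memberships(g: int) -> dict[str, np.ndarray]:
    """Six soft spherical shells summing to 1 everywhere."""
    ax = (np.arange(g) + 0.5) / g * 2.0 - 1.0
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(xx ** 2 + yy ** 2 + zz ** 2)
    # soft step up at each boundary radius; the transition width emulates
    # partial-volume blur spanning a few voxels of a coarse grid
    edges = {"WM": 0.32, "GM": 0.55, "CSF": 0.66, "bone": 0.76, "soft": 0.86}
    w = 0.20
    steps = {k: _smoothstep((r - e) / w + 0.5) for k, e in edges.items()}
    m = {}
    m["WM"] = 1.0 - steps["WM"]
    m["GM"] = steps["WM"] - steps["GM"]
    m["CSF"] = steps["GM"] - steps["CSF"]
    m["bone"] = steps["CSF"] - steps["bone"]
    m["soft"] = steps["bone"] - steps["soft"]
    m["background"] = steps["soft"]
    return m


def generate_cohort(spec: PhantomSpec
                    ) -> tuple[CohortTable, dict[str, TissueStack], PhantomTruth]:
    """Draw demographics and six-class probability stacks described by ``spec``.

    Returns the cohort table (with the combined quality score already
    computed), one :class:`TissueStack` per class in canonical order, and the
    :class:`PhantomTruth` record.  Deterministic given ``spec.rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n, g = spec.n_subjects, spec.grid_size

    ages = rng.uniform(*spec.age_range, size=n)
    male = (rng.random(n) < spec.p_male).astype(float)
    is_3t = (rng.random(n) < spec.p_3t).astype(float)
    resolution = np.clip(rng.normal(1.07, 0.12, n), 0.9, None)
    cnr = rng.normal(0.0, 1.0, n)
    inr = rng.normal(0.0, 1.0, n)

    records = [SubjectRecord(
        subject_id=f"phantom{i:04d}",
        age_months=float(ages[i]),
        sex="M" if male[i] else "F",
        field_strength=3.0 if is_3t[i] else 1.5,
        resolution=float(resolution[i]),
        cnr=float(cnr[i]),
        inr=float(inr[i]),
    ) for i in range(n)]
    table = CohortTable(records)
    q = quality_indicator(table)
    sigma = spec.sigma0 * np.exp(-spec.quality_noise_scale * q)

    base = _radial_memberships(g)
    # age and sex effects draw mass into GM from every other class in
    # proportion to its local share (weight 4 m_GM (1 - m_GM), peaking at
    # mixed voxels and vanishing where GM is pure or absent); the
    # field-strength effect exchanges GM and WM mass at their interface.
    # Both conserve the per-voxel simplex exactly, pre-noise.
    boundary_w = 4.0 * base["GM"] * base["WM"]
    gm_w = 4.0 * base["GM"] * (1.0 - base["GM"])
    sex_w = 0.5 * gm_w
    # regional maturation timing: peak age oscillates along the third axis
    z01 = ((np.arange(g) + 0.5) / g)[None, None, :]
    mod = np.sin(2.0 * np.pi * spec.peak_age_cycles * z01)
    peak_map = spec.gm_peak_age * (1.0 + spec.peak_age_gradient
                                   * np.broadcast_to(mod, (g, g, g)))

    truth = PhantomTruth(base_maps={k: v.copy() for k, v in base.items()},
                         gm_weight=gm_w, boundary_weight=boundary_w,
                         sex_weight=sex_w, peak_age_map=peak_map.copy(),
                         sigma_per_subject=sigma, spec=spec)

    m_gm = base["GM"]
    traj = truth.trajectory(ages[:, None, None, None], peak_map[None])
    shrink = (spec.gm_amplitude * traj
              + 0.5 * spec.sex_effect * male[:, None, None, None]) \
        * 4.0 * m_gm[None]
    field_d = spec.field_effect * is_3t[:, None, None, None] * boundary_w[None]

    affine = np.diag([spec.voxel_size_mm] * 3 + [1.0])
    stacks: dict[str, TissueStack] = {}
    for label in TISSUE_CLASSES:
        if label == "GM":
            expected = m_gm[None] + (1.0 - m_gm[None]) * shrink + field_d
        elif label == "WM":
            expected = base["WM"][None] * (1.0 - shrink) - field_d
        else:
            expected = base[label][None] * (1.0 - shrink)
        noisy = expected + rng.normal(0.0, 1.0, expected.shape) \
            * sigma[:, None, None, None]
        stacks[label] = TissueStack(label, np.clip(noisy, 0.0, 1.0), affine)
    return table, stacks, truth


# ---------------------------------------------------------------------------
# Deformation fields with known Jacobians
# ---------------------------------------------------------------------------

@dataclass
class DeformationField:
    """Voxel displacement field (mm) plus the global affine of the mapping."""

    displacement: np.ndarray               # (nx, ny, nz, 3)
    affine: np.ndarray                     # 4x4, the linear part of the map
    voxel_size_mm: float = 1.0
    analytic_jacobian: np.ndarray | None = None  # det(I + grad u), closed form

    def __post_init__(self) -> None:
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise ValueError("displacement must be (nx, ny, nz, 3)")
        if not np.isfinite(self.displacement).all():
            raise ValueError("displacement must be finite")
        if abs(np.linalg.det(np.asarray(self.affine)[:3, :3])) < 1e-12:
            raise ValueError("affine matrix is singular")


def generate_deformation(grid_size: int, kind: str = "identity",
                         scale: float = 1.2, amplitude: float = 0.05,
                         cycles: float = 1.0,
                         voxel_size_mm: float = 1.0) -> DeformationField:
    """Construct a deformation field with an analytically known Jacobian.

    kinds: "identity" (det J = 1 everywhere), "uniform_scale" (pure affine
    scaling, nonlinear det J = 1), "sinusoidal" (displacement
    u_x = A sin(k x) along the first axis, det J = 1 + A k cos(k x)).
    """
    g = grid_size
    u = np.zeros((g, g, g, 3))
    affine = np.eye(4)
    if kind == "identity":
        jac = np.ones((g, g, g))
    elif kind == "uniform_scale":
        affine = np.diag([scale, scale, scale, 1.0])
        jac = np.ones((g, g, g))
    elif kind == "sinusoidal":
        L = g * voxel_size_mm
        k = 2.0 * np.pi * cycles / L
        x = (np.arange(g) + 0.5) * voxel_size_mm
        ux = amplitude * np.sin(k * x)
        u[..., 0] = ux[:, None, None]
        jac = np.broadcast_to(
            (1.0 + amplitude * k * np.cos(k * x))[:, None, None], (g, g, g)).copy()
    else:
        raise ValueError(f"unknown deformation kind {kind!r}")
    return DeformationField(u, affine, voxel_size_mm, analytic_jacobian=jac)
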