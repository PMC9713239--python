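"""Parametric knee model: geometry, ligament mechanics, and a quasi-static solver.

The model is a deliberately small stand-in for a full rigid-body musculoskeletal
knee: ten ligament bundles act as tension-only line elements between femur and
tibia, the femoral condyles are spheres seated in shallow tibial dishes,
and at each fixed flexion angle the five secondary tibiofemoral degrees of
freedom (M/L, A/P, P/D translation in mm; V/V, I/E rotation in deg) settle into
the configuration minimizing total elastic energy.  This mirrors the structure
of force-dependent kinematics: a quasi-static equilibrium of the passive
structures at prescribed flexion.

Frames
------
Tibia frame: origin at the joint centre, x lateral, y anterior, z proximal.
Femur frame coincides with the tibia frame in the reference configuration
(full extension, zero secondary DOFs); flexion rotates the femur about the
x axis through the condylar centres.  Implant component placement transforms
only the articular surfaces relative to their bone; ligament attachments stay
with the bone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "BUNDLES",
    "GROUPS",
    "RETAINED_BUNDLES",
    "CRUCIATE_BUNDLES",
    "PARAM_NAMES",
    "TABLE_BOUNDS",
    "POSE_NAMES",
    "PropertyLayout",
    "LigamentPropertyVector",
    "KneeGeometry",
    "ImplantPose",
    "FlexionSchedule",
    "KneeState",
    "SolverSettings",
    "ligament_force",
    "ligament_energy_density",
    "strain_from_length",
    "solve_equilibrium",
    "simulate_squat",
    "squat_batch",
    "evaluate_points",
    "total_energy",
    "make_synthetic_subject",
    "audit_subject",
    "count_property_parameters",
    "load_model_config",
    "save_subject",
    "load_subject",
]

# ---------------------------------------------------------------------------
# Parameterization
# ---------------------------------------------------------------------------

#: Ligament bundle names.  ACL/PCL carry two bundles each (anteromedial /
#: posterolateral and anterolateral / posteromedial respectively); PC is the
#: posterior capsule.
BUNDLES = (
    "deepMCL", "supMCL", "LCL", "ALL", "PFL",
    "ACL0", "ACL1", "PCL0", "PCL1", "PC",
)

GROUPS = {
    "medial": ("deepMCL", "supMCL"),
    "lateral": ("LCL", "ALL", "PFL"),
    "central": ("ACL0", "ACL1", "PCL0", "PCL1"),
    "capsule": ("PC",),
}

#: Bundles retained after a posterior-stabilized TKA (cruciates sacrificed).
RETAINED_BUNDLES = ("deepMCL", "supMCL", "LCL", "ALL", "PFL", "PC")
CRUCIATE_BUNDLES = ("ACL0", "ACL1", "PCL0", "PCL1")

#: Sampling bounds for the subject parameters: per bundle the reference strain
#: eps_r (dimensionless) and linear stiffness k (N), plus the perturbable
#: attachment-site offsets (mm) in the bone's local x/y axes.  Missing offset
#: entries mean the coordinate is fixed.
TABLE_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "deepMCL": {"eps_r": (-0.2, 0.3), "k": (2000, 9000),
                "fem_x": (-10, 10), "fem_y": (-8, 8), "tib_x": (-10, 10)},
    "supMCL": {"eps_r": (-0.2, 0.2), "k": (2000, 9000),
               "fem_x": (-10, 10), "fem_y": (-8, 8), "tib_x": (-10, 10)},
    "LCL": {"eps_r": (-0.2, 0.2), "k": (2000, 9000),
            "fem_x": (-8, 8), "fem_y": (-8, 8), "tib_x": (-5, 5)},
    "ALL": {"eps_r": (-0.3, 0.2), "k": (2000, 9000),
            "fem_x": (-8, 8), "fem_y": (-8, 8), "tib_x": (-10, 10)},
    "PFL": {"eps_r": (-0.3, 0.2), "k": (2000, 9000),
            "fem_x": (-10, 10), "fem_y": (-6, 6)},
    "ACL0": {"eps_r": (-0.2, 0.4), "k": (4000, 10000),
             "fem_x": (-6, 6), "fem_y": (-6, 6), "tib_x": (-8, 8), "tib_y": (-8, 8)},
    "ACL1": {"eps_r": (-0.2, 0.4), "k": (4000, 10000),
             "fem_x": (-6, 6), "fem_y": (-6, 6), "tib_x": (-8, 8), "tib_y": (-8, 8)},
    "PCL0": {"eps_r": (-0.5, 0.4), "k": (4000, 12000),
             "fem_x": (-6, 6), "fem_y": (-6, 6), "tib_x": (-8, 8), "tib_y": (-8, 8)},
    "PCL1": {"eps_r": (-0.5, 0.4), "k": (4000, 12000),
             "fem_x": (-6, 6), "fem_y": (-6, 6), "tib_x": (-8, 8), "tib_y": (-8, 8)},
    "PC": {"eps_r": (0.05, 0.2), "k": (5000, 10000)},
}

_OFFSET_KEYS = ("fem_x", "fem_y", "tib_x", "tib_y")


def _build_param_names() -> list[str]:
    names = []
    for b in BUNDLES:
        names.append(f"{b}.eps_r")
        names.append(f"{b}.k")
        for key in _OFFSET_KEYS:
            if key in TABLE_BOUNDS[b]:
                names.append(f"{b}.{key}")
    return names


#: Canonical ordering of the 50 scalar subject parameters.
PARAM_NAMES: tuple[str, ...] = tuple(_build_param_names())

POSE_NAMES = (
    "fem_ml", "fem_ap", "fem_pd", "fem_fe", "fem_vv", "fem_ie",
    "tib_ml", "tib_ap", "tib_pd", "tib_slope", "tib_vv", "tib_ie",
)


def count_property_parameters(bounds_config: dict) -> int:
    """Number of scalar ligament parameters with declared sampling bounds.

    ``bounds_config`` maps bundle name -> {parameter name -> (lo, hi)}.
    """
    if not isinstance(bounds_config, dict):
        raise TypeError("bounds_config must be a mapping of bundles")
    n = 0
    for bundle, entries in bounds_config.items():
        if not isinstance(entries, dict):
            raise ValueError(f"malformed bounds for bundle {bundle!r}")
        for key, bound in entries.items():
            lo, hi = bound  # raises if malformed
            if not (float(lo) <= float(hi)):
                raise ValueError(f"empty bound for {bundle}.{key}")
            n += 1
    return n


class PropertyLayout:
    """Index maps between the flat 50-vector and per-bundle mechanics arrays."""

    def __init__(self, bounds: dict[str, dict[str, tuple[float, float]]] | None = None):
        self.bounds_config = bounds or TABLE_BOUNDS
        self.names: list[str] = []
        lo, hi = [], []
        self._eps_idx = np.full(len(BUNDLES), -1, dtype=int)
        self._k_idx = np.full(len(BUNDLES), -1, dtype=int)
        # offset index per bundle per (fem_x, fem_y, tib_x, tib_y); -1 = fixed
        self._off_idx = np.full((len(BUNDLES), 4), -1, dtype=int)
        for bi, b in enumerate(BUNDLES):
            entries = self.bounds_config.get(b, {})
            for key, bound in entries.items():
                idx = len(self.names)
                self.names.append(f"{b}.{key}")
                lo.append(bound[0])
                hi.append(bound[1])
                if key == "eps_r":
                    self._eps_idx[bi] = idx
                elif key == "k":
                    self._k_idx[bi] = idx
                else:
                    self._off_idx[bi, _OFFSET_KEYS.index(key)] = idx
        self.lower = np.asarray(lo, float)
        self.upper = np.asarray(hi, float)
        self.n_params = len(self.names)

    def unpack(self, props: np.ndarray):
        """(N, n_params) -> eps_r (N,10), k (N,10), fem_off (N,10,2), tib_off (N,10,2)."""
        props = np.atleast_2d(np.asarray(props, float))
        n = props.shape[0]
        nb = len(BUNDLES)
        eps_r = np.zeros((n, nb))
        k = np.zeros((n, nb))
        off = np.zeros((n, nb, 4))
        for bi in range(nb):
            if self._eps_idx[bi] >= 0:
                eps_r[:, bi] = props[:, self._eps_idx[bi]]
            if self._k_idx[bi] >= 0:
                k[:, bi] = props[:, self._k_idx[bi]]
            for j in range(4):
                if self._off_idx[bi, j] >= 0:
                    off[:, bi, j] = props[:, self._off_idx[bi, j]]
        return eps_r, k, off[:, :, :2], off[:, :, 2:]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def in_bounds(self, props: np.ndarray) -> np.ndarray:
        props = np.atleast_2d(props)
        return np.all((props >= self.lower - 1e-12) & (props <= self.upper + 1e-12), axis=1)


#: Default layout for the Table-2 parameterization (50 parameters).
LAYOUT = PropertyLayout()


@dataclass
class LigamentPropertyVector:
    """The 50 scalar subject parameters in canonical order.

    Twenty material entries (reference strain and linear stiffness per
    bundle) and thirty attachment-site offsets where the sampling table
    declares bounds.  ``strict`` validates every entry against its bound.
    """

    values: np.ndarray
    layout: PropertyLayout = field(default_factory=lambda: LAYOUT)

    def __post_init__(self):
        self.values = np.asarray(self.values, float).reshape(-1)
        if self.values.shape != (self.layout.n_params,):
            raise ValueError(
                f"expected {self.layout.n_params} parameters, got {self.values.shape[0]}")

    def validate_bounds(self) -> None:
        if not bool(self.layout.in_bounds(self.values)[0]):
            bad = np.flatnonzero((self.values < self.layout.lower)
                                 | (self.values > self.layout.upper))
            names = [self.layout.names[i] for i in bad]
            raise ValueError(f"parameters out of bounds: {names}")

    def as_dict(self) -> dict:
        return dict(zip(self.layout.names, map(float, self.values)))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.layout.index(name)])


# ---------------------------------------------------------------------------
# Ligament material law
# ---------------------------------------------------------------------------

def ligament_force(eps, k, eps_l=0.03):
    """Tension-only piecewise force-strain law with a quadratic toe region.

    f = 0 for eps <= 0; f = k * eps^2 / (4 eps_l) for 0 < eps <= 2 eps_l;
    f = k * (eps - eps_l) above.  Continuous and C1 at the toe/linear
    transition.  ``k`` is the linear stiffness in N (force per unit strain),
    ``eps_l`` the toe-region half-width.
    """
    k = np.asarray(k, float)
    eps_l_a = np.asarray(eps_l, float)
    if np.any(k <= 0):
        raise ValueError("stiffness k must be positive")
    if np.any(eps_l_a <= 0):
        raise ValueError("toe half-width eps_l must be positive")
    eps = np.asarray(eps, float)
    toe = k * eps ** 2 / (4.0 * eps_l_a)
    lin = k * (eps - eps_l_a)
    out = np.where(eps <= 0, 0.0, np.where(eps <= 2 * eps_l_a, toe, lin))
    if out.ndim == 0:
        return float(out)
    return out


def _force_and_slope(eps, k, eps_l):
    """Vectorized force and d(force)/d(strain) without input validation."""
    toe = eps <= 2 * eps_l
    f = np.where(eps <= 0, 0.0, np.where(toe, k * eps ** 2 / (4 * eps_l), k * (eps - eps_l)))
    fp = np.where(eps <= 0, 0.0, np.where(toe, k * eps / (2 * eps_l), k))
    return f, fp


def ligament_energy_density(eps, k, eps_l=0.03):
    """Elastic energy per unit slack length, the strain integral of the force law."""
    eps = np.asarray(eps, float)
    toe = k * eps ** 3 / (12.0 * eps_l)
    cap = 2.0 / 3.0 * k * eps_l ** 2
    lin = cap + 0.5 * k * ((eps - eps_l) ** 2 - eps_l ** 2)
    return np.where(eps <= 0, 0.0, np.where(eps <= 2 * eps_l, toe, lin))


def strain_from_length(current_length, reference_length, eps_r):
    """Engineering strain given the current length and the reference strain.

    The slack length l0 is defined so the strain at the reference pose equals
    ``eps_r``: l0 = reference_length / (1 + eps_r).
    """
    current_length = np.asarray(current_length, float)
    reference_length = np.asarray(reference_length, float)
    if np.any(current_length <= 0) or np.any(reference_length <= 0):
        raise ValueError("lengths must be positive")
    if np.any(np.asarray(eps_r) <= -1):
        raise ValueError("reference strain must exceed -1")
    l0 = reference_length / (1.0 + np.asarray(eps_r, float))
    out = (current_length - l0) / l0
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class KneeGeometry:
    """Rigid geometry of the synthetic subject (mm, bone frames)."""

    fem_attach: np.ndarray          # (10, 3) femur frame
    tib_attach: np.ndarray          # (10, 3) tibia frame
    condyle_centers: np.ndarray     # (2, 3) femur frame: [medial, lateral]
    condyle_radii: np.ndarray       # (2,)
    dish_centers: np.ndarray        # (2, 3) tibia frame curvature centers of the
                                    # medial/lateral tibial dishes
    dish_radii: np.ndarray = field(default=None)   # (2,), > condyle radii
    ref_lengths: np.ndarray = field(default=None)  # (10,) captured at reference pose
    theta_ref: float = 20.0         # deg, flexion of the reference pose
    bundles: tuple = BUNDLES
    groups: dict = field(default_factory=lambda: dict(GROUPS))

    def __post_init__(self):
        self.fem_attach = np.asarray(self.fem_attach, float)
        self.tib_attach = np.asarray(self.tib_attach, float)
        self.condyle_centers = np.asarray(self.condyle_centers, float)
        self.condyle_radii = np.asarray(self.condyle_radii, float)
        self.dish_centers = np.asarray(self.dish_centers, float)
        if self.dish_radii is None:
            self.dish_radii = self.condyle_radii + np.array([8.0, 15.0])
        self.dish_radii = np.asarray(self.dish_radii, float)
        if np.any(self.dish_radii <= self.condyle_radii):
            raise ValueError("dish radii must exceed condyle radii")
        nb = len(self.bundles)
        if self.fem_attach.shape != (nb, 3) or self.tib_attach.shape != (nb, 3):
            raise ValueError("one femoral and one tibial attachment per bundle required")
        labelled = [b for grp in self.groups.values() for b in grp]
        if sorted(labelled) != sorted(self.bundles):
            raise ValueError("groups must partition the bundle set")
        if self.ref_lengths is None:
            self.ref_lengths = self._lengths_at_reference()
        else:
            self.ref_lengths = np.asarray(self.ref_lengths, float)
        if np.any(self.ref_lengths <= 0):
            raise ValueError("reference lengths must be strictly positive")

    def _lengths_at_reference(self) -> np.ndarray:
        rot = _rot_x(np.deg2rad(self.theta_ref))
        world = self.fem_attach @ rot.T
        return np.linalg.norm(world - self.tib_attach, axis=1)

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([self.bundles.index(b) for b in self.groups[group]], dtype=int)

    def mirrored(self) -> "KneeGeometry":
        """Reflection about the sagittal (x = 0) plane; used for symmetry audits."""
        flip = np.array([-1.0, 1.0, 1.0])
        return replace(
            self,
            fem_attach=self.fem_attach * flip,
            tib_attach=self.tib_attach * flip,
            condyle_centers=self.condyle_centers[::-1] * flip,
            condyle_radii=self.condyle_radii[::-1].copy(),
            dish_centers=self.dish_centers[::-1] * flip,
            dish_radii=self.dish_radii[::-1].copy(),
            ref_lengths=self.ref_lengths.copy(),
        )


@dataclass
class ImplantPose:
    """12-DOF implant component placement relative to mechanical alignment.

    Ordering: femur M/L, A/P, P/D (mm), F/E, V/V, I/E (deg);
    tibia M/L, A/P, P/D (mm), slope, V/V, I/E (deg).
    The zero vector is the mechanically aligned reference position.
    """

    values: np.ndarray = field(default_factory=lambda: np.zeros(12))

    def __post_init__(self):
        self.values = np.asarray(self.values, float).reshape(-1)
        if self.values.shape != (12,):
            raise ValueError("implant pose requires exactly 12 DOFs")

    @classmethod
    def zero(cls) -> "ImplantPose":
        return cls(np.zeros(12))

    def as_dict(self) -> dict:
        return dict(zip(POSE_NAMES, map(float, self.values)))


@dataclass
class FlexionSchedule:
    """Ordered flexion angles (deg) at which the squat is evaluated."""

    angles: np.ndarray = field(default_factory=lambda: np.linspace(20.0, 120.0, 7))

    def __post_init__(self):
        self.angles = np.asarray(self.angles, float).reshape(-1)
        if len(self.angles) == 0 or np.any(np.diff(self.angles) <= 0):
            raise ValueError("flexion schedule must be strictly increasing")

    def __len__(self):
        return len(self.angles)


@dataclass
class KneeState:
    """Secondary kinematics and ligament state at one flexion angle."""

    theta: float
    dofs: np.ndarray          # (5,) M/L, A/P, P/D (mm), V/V, I/E (deg)
    strains: np.ndarray       # per bundle, dimensionless
    forces: np.ndarray        # per bundle, N
    energy: float
    converged: bool
    message: str = ""


@dataclass
class SolverSettings:
    """Numerical settings of the quasi-static equilibrium solver."""

    contact_stiffness: float = 1.0e4   # N/mm, quadratic penalty on penetration
    preload: float = 100.0             # N compressive load along P/D
    tether_trans: float = 1.0          # N/mm soft-tissue envelope on translations
    tether_rot: float = 2.0            # N*mm/deg^2 envelope on V/V, I/E
    eps_l: float = 0.03                # toe-region half-width, all bundles
    tol: float = 1.0e-4                # mm / deg convergence tolerance on DOFs
    max_iter: int = 80


DEFAULT_SOLVER = SolverSettings()

_DOF_NAMES = ("ml", "ap", "pd", "vv", "ie")
_DEG = np.pi / 180.0


def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], float)


def _rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], float)


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], float)


def _rot_xyz_batch(a, b, c):
    """Vectorized R_x(a) @ R_y(b) @ R_z(c) for angle arrays (radians)."""
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    r = np.empty((a.shape[0], 3, 3))
    r[:, 0, 0] = cb * cc
    r[:, 0, 1] = -cb * sc
    r[:, 0, 2] = sb
    r[:, 1, 0] = ca * sc + sa * sb * cc
    r[:, 1, 1] = ca * cc - sa * sb * sc
    r[:, 1, 2] = -sa * cb
    r[:, 2, 0] = sa * sc - ca * sb * cc
    r[:, 2, 1] = sa * cc + ca * sb * sc
    r[:, 2, 2] = ca * cb
    return r


def _component_transforms(poses: np.ndarray):
    """Per-row femoral/tibial component rotations and translations.

    poses: (N, 12).  Intrinsic rotation order F/E -> V/V -> I/E for the femoral
    component and slope -> V/V -> I/E for the tibial component.
    """
    r_f = _rot_xyz_batch(poses[:, 3] * _DEG, poses[:, 4] * _DEG, poses[:, 5] * _DEG)
    r_t = _rot_xyz_batch(poses[:, 9] * _DEG, poses[:, 10] * _DEG, poses[:, 11] * _DEG)
    return r_f, poses[:, 0:3], r_t, poses[:, 6:9]


class _BatchProblem:
    """Precomputed per-row quantities for the batched equilibrium solve."""

    def __init__(self, geometry: KneeGeometry, props: np.ndarray,
                 poses: np.ndarray | None, thetas: np.ndarray,
                 bundle_idx: np.ndarray, settings: SolverSettings,
                 layout: PropertyLayout = None):
        layout = layout or LAYOUT
        props = np.atleast_2d(np.asarray(props, float))
        n = max(props.shape[0], len(np.atleast_1d(thetas)))
        if props.shape[0] == 1:
            props = np.broadcast_to(props, (n, props.shape[1]))
        thetas = np.broadcast_to(np.atleast_1d(np.asarray(thetas, float)), (n,))
        eps_r, k, fem_off, tib_off = layout.unpack(props)
        bi = bundle_idx
        self.n, self.nb = n, len(bi)
        self.k = k[:, bi]
        self.eps_l = settings.eps_l
        self.l0 = (geometry.ref_lengths[bi] / (1.0 + eps_r[:, bi]))
        # attachment sites with local-frame offsets applied on x/y
        fa = np.broadcast_to(geometry.fem_attach[bi], (n, self.nb, 3)).copy()
        ta = np.broadcast_to(geometry.tib_attach[bi], (n, self.nb, 3)).copy()
        fa[:, :, :2] += fem_off[:, bi]
        ta[:, :, :2] += tib_off[:, bi]
        self.tib_att = ta
        self.settings = settings
        #: radial clearance of each conforming tibial dish (mm)
        self.clearance = geometry.dish_radii - geometry.condyle_radii

        if poses is None:
            poses = np.zeros((n, 12))
        else:
            poses = np.atleast_2d(np.asarray(poses, float))
            if poses.shape[0] == 1:
                poses = np.broadcast_to(poses, (n, 12))
        r_f, t_f, r_t, t_t = _component_transforms(poses)
        centers = np.einsum("nij,cj->nci", r_f, geometry.condyle_centers) + t_f[:, None, :]
        self.dish_w = (np.einsum("nij,cj->nci", r_t, geometry.dish_centers)
                       + t_t[:, None, :])                            # (n, 2, 3)
        # pre-rotate femur-frame points by flexion
        c, s = np.cos(thetas * _DEG), np.sin(thetas * _DEG)
        rfe = np.zeros((n, 3, 3))
        rfe[:, 0, 0] = 1.0
        rfe[:, 1, 1] = c
        rfe[:, 1, 2] = -s
        rfe[:, 2, 1] = s
        rfe[:, 2, 2] = c
        self.fem_att_fe = np.einsum("nij,nbj->nbi", rfe, fa)         # (n, nb, 3)
        self.centers_fe = np.einsum("nij,ncj->nci", rfe, centers)    # (n, 2, 3)
        self.fem_att_fe_T = np.ascontiguousarray(self.fem_att_fe.transpose(0, 2, 1))
        self.centers_fe_T = np.ascontiguousarray(self.centers_fe.transpose(0, 2, 1))

    def _world_points(self, q):
        """Femoral points in the tibia frame for secondary DOFs q (n, 5)."""
        vv, ie = q[:, 3] * _DEG, q[:, 4] * _DEG
        cv, sv = np.cos(vv), np.sin(vv)
        ci, si = np.cos(ie), np.sin(ie)
        nq = q.shape[0]
        # R = Rz(ie) @ Ry(vv)
        r = np.zeros((nq, 3, 3))
        r[:, 0, 0] = ci * cv
        r[:, 0, 1] = -si
        r[:, 0, 2] = ci * sv
        r[:, 1, 0] = si * cv
        r[:, 1, 1] = ci
        r[:, 1, 2] = si * sv
        r[:, 2, 0] = -sv
        r[:, 2, 2] = cv
        # derivatives wrt vv and ie (radians)
        dv = np.zeros((nq, 3, 3))
        dv[:, 0, 0] = -ci * sv
        dv[:, 0, 2] = ci * cv
        dv[:, 1, 0] = -si * sv
        dv[:, 1, 2] = si * cv
        dv[:, 2, 0] = -cv
        dv[:, 2, 2] = -sv
        di = np.zeros((nq, 3, 3))
        di[:, 0, 0] = -si * cv
        di[:, 0, 1] = -ci
        di[:, 0, 2] = -si * sv
        di[:, 1, 0] = ci * cv
        di[:, 1, 1] = -si
        di[:, 1, 2] = ci * sv
        return r, dv, di

    def _subset(self, arr, rows):
        return arr if rows is None else arr[rows]

    def strains_at(self, q, rows=None):
        r, _, _ = self._world_points(q)
        fa_t = self._subset(self.fem_att_fe_T, rows)
        w = np.matmul(r, fa_t).transpose(0, 2, 1) + q[:, None, 0:3]
        lens = np.linalg.norm(w - self._subset(self.tib_att, rows), axis=2)
        l0 = self._subset(self.l0, rows)
        return (lens - l0) / l0

    def energy(self, q, rows=None):
        """Total elastic energy (N*mm) per row."""
        st = self.settings
        r, _, _ = self._world_points(q)
        fa_t = self._subset(self.fem_att_fe_T, rows)
        l0 = self._subset(self.l0, rows)
        k = self._subset(self.k, rows)
        w = np.matmul(r, fa_t).transpose(0, 2, 1) + q[:, None, 0:3]
        lens = np.linalg.norm(w - self._subset(self.tib_att, rows), axis=2)
        eps = (lens - l0) / l0
        e = np.sum(l0 * ligament_energy_density(eps, k, self.eps_l), axis=1)
        cw = (np.matmul(r, self._subset(self.centers_fe_T, rows)).transpose(0, 2, 1)
              + q[:, None, 0:3])
        dist = np.linalg.norm(cw - self._subset(self.dish_w, rows), axis=2)
        gap = self.clearance[None, :] - dist
        pen = np.minimum(gap, 0.0)
        e = e + 0.5 * st.contact_stiffness * np.sum(pen ** 2, axis=1)
        e = e + st.preload * q[:, 2]
        kt = np.array([st.tether_trans] * 3 + [st.tether_rot] * 2)
        e = e + 0.5 * np.sum(kt * q ** 2, axis=1)
        return e

    def grad_hess(self, q, rows=None):
        """Analytic gradient and Gauss-Newton Hessian of the energy."""
        st = self.settings
        fa_t = self._subset(self.fem_att_fe_T, rows)
        l0 = self._subset(self.l0, rows)
        kk = self._subset(self.k, rows)
        r, dv, di = self._world_points(q)
        w = np.matmul(r, fa_t).transpose(0, 2, 1) + q[:, None, 0:3]
        d = w - self._subset(self.tib_att, rows)
        lens = np.linalg.norm(d, axis=2)
        u = d / lens[:, :, None]
        eps = (lens - l0) / l0
        f, fp = _force_and_slope(eps, kk, self.eps_l)
        # dw/dq columns: identity for translations, a_vv/a_ie for rotations
        nq = q.shape[0]
        a_vv = np.matmul(dv, fa_t).transpose(0, 2, 1) * _DEG  # (nq, nb, 3)
        a_ie = np.matmul(di, fa_t).transpose(0, 2, 1) * _DEG
        jac = np.empty((nq, self.nb, 5))
        jac[:, :, 0:3] = u
        jac[:, :, 3] = np.einsum("nbi,nbi->nb", u, a_vv)
        jac[:, :, 4] = np.einsum("nbi,nbi->nb", u, a_ie)
        grad = np.einsum("nb,nbq->nq", f, jac)
        # geometric (string-swing) curvature: f/len * (J3^T J3 - jac jac^T); PSD.
        # J3^T J3 has closed-form blocks: I3, A = [a_vv a_ie], G = A^T A.
        w_geo = f / lens                                      # (nq, nb)
        s_geo = w_geo.sum(axis=1)
        geo = np.zeros((nq, 5, 5))
        geo[:, 0, 0] = s_geo
        geo[:, 1, 1] = s_geo
        geo[:, 2, 2] = s_geo
        geo[:, 0:3, 3] = np.einsum("nb,nbi->ni", w_geo, a_vv)
        geo[:, 0:3, 4] = np.einsum("nb,nbi->ni", w_geo, a_ie)
        geo[:, 3, 0:3] = geo[:, 0:3, 3]
        geo[:, 4, 0:3] = geo[:, 0:3, 4]
        geo[:, 3, 3] = np.einsum("nb,nbi,nbi->n", w_geo, a_vv, a_vv)
        geo[:, 3, 4] = np.einsum("nb,nbi,nbi->n", w_geo, a_vv, a_ie)
        geo[:, 4, 3] = geo[:, 3, 4]
        geo[:, 4, 4] = np.einsum("nb,nbi,nbi->n", w_geo, a_ie, a_ie)
        wgt = fp / l0 - w_geo
        hess = np.matmul((jac * wgt[:, :, None]).transpose(0, 2, 1), jac) + geo
        # dished condylar contact: gap = clearance - |c_world - dish_center|
        cf_t = self._subset(self.centers_fe_T, rows)
        cw = np.matmul(r, cf_t).transpose(0, 2, 1) + q[:, None, 0:3]
        dvec = cw - self._subset(self.dish_w, rows)
        dist = np.linalg.norm(dvec, axis=2)
        uhat = dvec / np.maximum(dist, 1e-9)[:, :, None]
        gap = self.clearance[None, :] - dist
        cjac = np.empty((nq, 2, 5))              # d(dist)/dq
        cjac[:, :, 0:3] = uhat
        cjac[:, :, 3] = np.einsum("nci,nci->nc",
                                  uhat,
                                  np.matmul(dv, cf_t).transpose(0, 2, 1)) * _DEG
        cjac[:, :, 4] = np.einsum("nci,nci->nc",
                                  uhat,
                                  np.matmul(di, cf_t).transpose(0, 2, 1)) * _DEG
        active = gap < 0.0
        gpen = np.where(active, gap, 0.0)
        grad += st.contact_stiffness * np.einsum("nc,ncq->nq", -gpen, cjac)
        hess += st.contact_stiffness * np.einsum("nc,ncq,ncp->nqp",
                                                 active.astype(float), cjac, cjac)
        # preload + tether
        grad[:, 2] += st.preload
        kt = np.array([st.tether_trans] * 3 + [st.tether_rot] * 2)
        grad += kt * q
        hess += np.diag(kt)
        return grad, hess


def _solve_batch(problem, q0: np.ndarray, settings: SolverSettings):
    """Damped (Levenberg) Gauss-Newton minimization of the batch energies.

    Rows that reach the step tolerance drop out of subsequent iterations, so
    the cost tracks the hardest rows only.
    """
    q = np.array(q0, float, copy=True)
    n = q.shape[0]
    mu = np.full(n, 1e-3)
    done = np.zeros(n, bool)
    stall = np.zeros(n, np.int8)
    energy = problem.energy(q)
    eye = np.eye(5)
    for _ in range(settings.max_iter):
        act = np.flatnonzero(~done)
        if act.size == 0:
            break
        qa = q[act]
        ea = energy[act]
        mua = mu[act]
        grad, hess = problem.grad_hess(qa, rows=act)
        h = hess + mua[:, None, None] * eye
        try:
            step = np.linalg.solve(h, -grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            h = hess + (mua[:, None, None] + 1e-2) * eye
            step = np.stack([np.linalg.lstsq(h[i], -grad[i], rcond=None)[0]
                             for i in range(h.shape[0])])
        norm = np.max(np.abs(step), axis=1, keepdims=True)
        step *= np.where(norm > 10.0, 10.0 / np.maximum(norm, 1e-300), 1.0)
        improved = np.zeros(act.size, bool)
        for _ in range(10):
            todo = np.flatnonzero(~improved)
            if todo.size == 0:
                break
            trial = qa[todo] + step[todo]
            e_trial = problem.energy(trial, rows=act[todo])
            good = e_trial <= ea[todo] + 1e-10 * (1 + np.abs(ea[todo]))
            gi = todo[good]
            qa[gi] = trial[good]
            ea[gi] = e_trial[good]
            improved[gi] = True
            bi = todo[~good]
            mua[bi] *= 8.0
            step[bi] *= 0.5
        mua[improved] = np.maximum(mua[improved] / 4.0, 1e-6)
        small = np.max(np.abs(step), axis=1) < settings.tol
        # rows cycling at the energy noise floor also terminate: acceptance
        # tolerates O(1e-10 |E|) increases, so near a minimum the energy
        # oscillates instead of decreasing; several consecutive iterations
        # without a meaningful decrease mean the row is converged
        decreased = improved & (energy[act] - ea > 1e-8 * (1.0 + np.abs(ea)))
        stall_a = stall[act]
        stall_a = np.where(decreased, 0, np.minimum(stall_a + 1, 100)).astype(np.int8)
        finished = (improved & small) | (stall_a >= 5) | (~improved & (mua > 1e8))
        q[act] = qa
        energy[act] = ea
        mu[act] = mua
        stall[act] = stall_a
        done[act[finished]] = True
        if np.all(done):
            break
    converged = done
    return q, energy, converged


def total_energy(geometry: KneeGeometry, props, pose, theta, dofs,
                 bundles: Sequence[str] | None = None,
                 settings: SolverSettings = DEFAULT_SOLVER) -> float:
    """Total elastic energy at prescribed secondary DOFs (oracle/audit hook)."""
    bidx = _bundle_indices(geometry, bundles)
    poses = None if pose is None else np.atleast_2d(_pose_values(pose))
    dofs = np.atleast_2d(np.asarray(dofs, float))
    prob = _BatchProblem(geometry, np.atleast_2d(props), poses,
                         np.full(dofs.shape[0], float(theta)), bidx, settings)
    e = prob.energy(np.broadcast_to(dofs, (prob.n, 5)).copy())
    return float(e[0]) if e.shape[0] == 1 and np.ndim(dofs) <= 2 and dofs.shape[0] == 1 else e


def _pose_values(pose) -> np.ndarray:
    if pose is None:
        return np.zeros(12)
    if isinstance(pose, ImplantPose):
        return pose.values
    return np.asarray(pose, float).reshape(-1)


def _bundle_indices(geometry: KneeGeometry, bundles: Sequence[str] | None) -> np.ndarray:
    names = bundles if bundles is not None else geometry.bundles
    return np.array([geometry.bundles.index(b) for b in names], dtype=int)


def solve_equilibrium(geometry: KneeGeometry, props, pose, theta: float,
                      bundles: Sequence[str] | None = None,
                      settings: SolverSettings = DEFAULT_SOLVER,
                      q0=None, free_dofs=None) -> KneeState:
    """Quasi-static equilibrium of the five secondary DOFs at fixed flexion.

    ``pose=None`` evaluates the native joint; an :class:`ImplantPose` (or
    12-vector) evaluates the replaced joint with component surfaces displaced.
    ``free_dofs`` restricts the minimization to a subset of DOF names
    (from ``ml, ap, pd, vv, ie``); the rest stay at ``q0``.
    """
    bidx = _bundle_indices(geometry, bundles)
    poses = None if pose is None else np.atleast_2d(_pose_values(pose))
    prob = _BatchProblem(geometry, np.atleast_2d(props), poses,
                         np.array([float(theta)]), bidx, settings)
    q_init = np.zeros((1, 5)) if q0 is None else np.atleast_2d(np.asarray(q0, float)).copy()
    if free_dofs is not None:
        mask = np.array([name in free_dofs for name in _DOF_NAMES])
        q, energy, conv = _solve_masked(prob, q_init, settings, mask)
    else:
        q, energy, conv = _solve_batch(prob, q_init, settings)
    eps = prob.strains_at(q)[0]
    forces = np.asarray(ligament_force(eps, prob.k[0], settings.eps_l), float)
    msg = "" if conv[0] else "equilibrium solver did not reach tolerance"
    return KneeState(theta=float(theta), dofs=q[0], strains=eps, forces=forces,
                     energy=float(energy[0]), converged=bool(conv[0]), message=msg)


def _solve_masked(problem, q0, settings, mask):
    """Coordinate-restricted solve: fixed DOFs pinned by a very stiff tether."""
    q = np.array(q0, float, copy=True)
    big = 1e12
    kt = np.where(mask, 0.0, big)

    class _Pinned:
        def __init__(self, base, q_fix):
            self.base = base
            self.n = base.n
            self.q_fix = q_fix

        def _fix(self, rows):
            return self.q_fix if rows is None else self.q_fix[rows]

        def energy(self, q, rows=None):
            return (self.base.energy(q, rows=rows)
                    + 0.5 * np.sum(kt * (q - self._fix(rows)) ** 2, axis=1))

        def grad_hess(self, q, rows=None):
            g, h = self.base.grad_hess(q, rows=rows)
            g = g + kt * (q - self._fix(rows))
            h = h + np.diag(kt)
            return g, h

        def strains_at(self, q, rows=None):
            return self.base.strains_at(q, rows=rows)

    pinned = _Pinned(problem, q)
    qs, e, conv = _solve_batch(pinned, q, settings)
    qs[:, ~mask] = q0[:, ~mask]
    e = problem.energy(qs)
    return qs, e, conv


def simulate_squat(geometry: KneeGeometry, props, pose,
                   schedule: FlexionSchedule | None = None,
                   bundles: Sequence[str] | None = None,
                   settings: SolverSettings = DEFAULT_SOLVER) -> list[KneeState]:
    """Simulate the squat: one equilibrium per scheduled flexion angle.

    Each angle is warm-started from the previous solution.  Deterministic for
    fixed inputs.  Raises ``RuntimeError`` naming the angle if an equilibrium
    fails to converge.
    """
    schedule = schedule or FlexionSchedule()
    states: list[KneeState] = []
    q0 = None
    for theta in schedule.angles:
        state = solve_equilibrium(geometry, props, pose, theta,
                                  bundles=bundles, settings=settings, q0=q0)
        if not state.converged:
            raise RuntimeError(f"equilibrium failed at flexion {theta:.1f} deg")
        states.append(state)
        q0 = state.dofs[None, :]
    return states


def squat_batch(geometry: KneeGeometry, props, poses, schedule=None,
                bundles: Sequence[str] | None = None,
                settings: SolverSettings = DEFAULT_SOLVER):
    """Vectorized squat over N property/pose rows.

    Returns ``strains (N, nb, T)``, ``dofs (N, 5, T)``, ``converged (N,)``.
    ``poses`` may be None (native), a single pose, or (N, 12).
    """
    schedule = schedule or FlexionSchedule()
    bidx = _bundle_indices(geometry, bundles)
    props = np.atleast_2d(np.asarray(props, float))
    pose_arr = None if poses is None else np.atleast_2d(_pose_values(poses) if np.ndim(poses) == 1 or isinstance(poses, ImplantPose) else np.asarray(poses, float))
    n = props.shape[0] if pose_arr is None else max(props.shape[0], pose_arr.shape[0])
    t = len(schedule)
    strains = np.empty((n, len(bidx), t))
    dofs = np.empty((n, 5, t))
    conv = np.ones(n, bool)
    q0 = np.zeros((n, 5))
    for j, theta in enumerate(schedule.angles):
        prob = _BatchProblem(geometry, props, pose_arr, np.full(n, theta), bidx, settings)
        q, _, c = _solve_batch(prob, q0, settings)
        strains[:, :, j] = prob.strains_at(q)
        dofs[:, :, j] = q
        conv &= c
        q0 = q
    return strains, dofs, conv


def rigid_strains(geometry: KneeGeometry, props, poses, thetas,
                  bundles: Sequence[str] | None = None,
                  settings: SolverSettings = DEFAULT_SOLVER) -> np.ndarray:
    """Closed-form bundle strains at the contact-following configuration.

    No iterative equilibrium solve: M/L, A/P and I/E stay at the tether rest
    (zero) while P/D and V/V are set by a linearized solve of the two condylar
    gap equations, i.e. the femur simply follows the articular surfaces.
    Used as a physics feature by the surrogate (the network then only learns
    the ligament-driven correction) and handy for quick screening.
    """
    bidx = _bundle_indices(geometry, bundles)
    thetas = np.atleast_1d(np.asarray(thetas, float))
    pose_arr = None if poses is None else np.atleast_2d(np.asarray(poses, float))
    prob = _BatchProblem(geometry, props, pose_arr, thetas, bidx, settings)
    q = np.zeros((prob.n, 5))
    # seat both condyles: dist_s(pd, vv) = clearance_s, linearized around q = 0
    r, dv, _ = prob._world_points(q)
    cw = np.einsum("nij,ncj->nci", r, prob.centers_fe)
    dvec = cw - prob.dish_w
    dist = np.linalg.norm(dvec, axis=2)
    uhat = dvec / np.maximum(dist, 1e-9)[:, :, None]
    gap0 = prob.clearance[None, :] - dist
    d_pd = uhat[:, :, 2]
    d_vv = np.einsum("nci,nci->nc", uhat,
                     np.einsum("nij,ncj->nci", dv, prob.centers_fe)) * _DEG
    a = np.stack([np.stack([d_pd[:, 0], d_vv[:, 0]], axis=1),
                  np.stack([d_pd[:, 1], d_vv[:, 1]], axis=1)], axis=1)
    det = np.linalg.det(a)
    ok = np.abs(det) > 1e-8
    sol = np.zeros((prob.n, 2))
    if np.any(ok):
        sol[ok] = np.linalg.solve(a[ok], gap0[ok][:, :, None])[:, :, 0]
    q[:, 2] = sol[:, 0]
    q[:, 3] = sol[:, 1]
    return prob.strains_at(q)


def evaluate_points(geometry: KneeGeometry, props, poses, thetas,
                    bundles: Sequence[str] | None = None,
                    settings: SolverSettings = DEFAULT_SOLVER):
    """Cold-start equilibrium at per-row flexion angles (surrogate labeling).

    Returns ``strains (N, nb)``, ``dofs (N, 5)``, ``converged (N,)``.
    """
    bidx = _bundle_indices(geometry, bundles)
    thetas = np.atleast_1d(np.asarray(thetas, float))
    pose_arr = None if poses is None else np.atleast_2d(np.asarray(poses, float))
    prob = _BatchProblem(geometry, props, pose_arr, thetas, bidx, settings)
    q, _, conv = _solve_batch(prob, np.zeros((prob.n, 5)), settings)
    return prob.strains_at(q), q, conv


# ---------------------------------------------------------------------------
# Synthetic subject generator
# ---------------------------------------------------------------------------

#: Baseline attachment sites (mm).  Femoral sites sit close to the flexion
#: axis (small y/z) so nominal bundles are near-isometric through flexion, as
#: in the native knee; tibial sites set plausible lever arms.
_BASE_FEM = {
    "deepMCL": (-41.0, 1.0, 1.0),
    "supMCL": (-43.0, 0.5, 1.5),
    "LCL": (43.0, 0.5, 1.0),
    "ALL": (42.0, 1.5, -1.0),
    "PFL": (42.0, -1.5, 0.5),
    "ACL0": (8.0, -1.5, -1.0),
    "ACL1": (10.0, -2.0, 0.5),
    "PCL0": (-9.0, 1.5, -0.5),
    "PCL1": (-7.0, 2.0, 1.0),
    "PC": (0.0, 0.0, 1.5),
}
_BASE_TIB = {
    "deepMCL": (-38.0, 2.0, -20.0),
    "supMCL": (-36.0, 3.0, -75.0),
    "LCL": (44.0, -4.0, -48.0),
    "ALL": (36.0, 14.0, -25.0),
    "PFL": (45.0, -12.0, -42.0),
    "ACL0": (-4.0, 14.0, -22.0),
    "ACL1": (1.0, 12.0, -22.0),
    "PCL0": (-1.0, -16.0, -26.0),
    "PCL1": (-5.0, -18.0, -28.0),
    "PC": (0.0, -24.0, -35.0),
}


def _nominal_props(geometry: KneeGeometry, eps_r: np.ndarray, k: np.ndarray,
                   layout: PropertyLayout = None) -> np.ndarray:
    layout = layout or LAYOUT
    props = np.zeros(layout.n_params)
    for bi, b in enumerate(BUNDLES):
        props[layout.index(f"{b}.eps_r")] = eps_r[bi]
        props[layout.index(f"{b}.k")] = k[bi]
    return props


def make_synthetic_subject(seed: int, max_retries: int = 10,
                           settings: SolverSettings = DEFAULT_SOLVER):
    """Generate a reproducible synthetic knee subject.

    Returns ``(geometry, nominal_properties)`` where the nominal native squat
    keeps every bundle's peak strain inside the physiological (-2%, 6%) band
    and the medial, lateral and central groups all engage.  The reference
    strains are calibrated by fixed-point iteration on the simulated squat.
    Raises ``RuntimeError`` if no admissible subject is found.
    """
    rng = np.random.default_rng(seed)
    schedule = FlexionSchedule()
    for _ in range(max_retries):
        fem = np.array([_BASE_FEM[b] for b in BUNDLES])
        tib = np.array([_BASE_TIB[b] for b in BUNDLES])
        fem[:, 0] += rng.uniform(-1.5, 1.5, len(BUNDLES))
        fem[:, 1:] += rng.uniform(-0.5, 0.5, (len(BUNDLES), 2))
        tib += rng.uniform(-1.5, 1.5, (len(BUNDLES), 3))
        half = 22.0 + rng.uniform(-1.5, 1.5)
        radius = 24.0 + rng.uniform(-1.5, 1.5)
        geometry = KneeGeometry(
            fem_attach=fem,
            tib_attach=tib,
            condyle_centers=np.array([[-half, 0.0, 0.0], [half, 0.0, 0.0]]),
            condyle_radii=np.array([radius, radius]),
            dish_centers=np.array([[-half, 0.0, 8.0], [half, 0.0, 15.0]]),
            dish_radii=np.array([radius + 8.0, radius + 15.0]),
        )
        k_lo = np.array([TABLE_BOUNDS[b]["k"][0] for b in BUNDLES])
        k_hi = np.array([TABLE_BOUNDS[b]["k"][1] for b in BUNDLES])
        k = k_lo + (0.35 + 0.3 * rng.random(len(BUNDLES))) * (k_hi - k_lo)
        target = rng.uniform(0.012, 0.025, len(BUNDLES))
        target[BUNDLES.index("PC")] = rng.uniform(0.052, 0.058)
        eps_lo = np.array([TABLE_BOUNDS[b]["eps_r"][0] for b in BUNDLES]) + 1e-3
        eps_hi = np.array([TABLE_BOUNDS[b]["eps_r"][1] for b in BUNDLES]) - 1e-3
        eps_r = target.copy()
        ok = True
        for _ in range(8):
            props = _nominal_props(geometry, eps_r, k)
            strains, _, conv = squat_batch(geometry, props, None,
                                           schedule, settings=settings)
            if not conv[0]:
                ok = False
                break
            peak = strains[0].max(axis=1)
            # damped fixed-point update: equilibrium feedback is mild
            eps_r = np.clip(eps_r + 0.8 * (target - peak), eps_lo, eps_hi)
        if not ok:
            continue
        props = _nominal_props(geometry, eps_r, k)
        report = audit_subject(geometry, props, schedule, settings)
        if report["ok"]:
            return geometry, props
    raise RuntimeError(f"could not generate an admissible subject for seed {seed}")


def audit_subject(geometry: KneeGeometry, props, schedule=None,
                  settings: SolverSettings = DEFAULT_SOLVER) -> dict:
    """Check the generator postcondition on a subject's nominal native squat."""
    schedule = schedule or FlexionSchedule()
    strains, dofs, conv = squat_batch(geometry, props, None, schedule, settings=settings)
    strains = strains[0]
    peak = strains.max(axis=1)
    in_band = bool(np.all(peak > -0.02) and np.all(peak < 0.06))
    engaged = {}
    per_angle = {}
    for grp in ("medial", "lateral", "central"):
        gi = geometry.group_indices(grp)
        gmax = strains[gi].max(axis=0)
        engaged[grp] = bool(np.any(gmax > 0))
        per_angle[grp] = bool(np.all(gmax > 0))
    return {
        "ok": bool(conv[0] and in_band and all(engaged.values())
                   and all(per_angle.values())),
        "converged": bool(conv[0]),
        "strains_in_band": in_band,
        "peak_strains": dict(zip(BUNDLES, map(float, peak))),
        "groups_engaged": engaged,
        "groups_engaged_every_angle": per_angle,
    }


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def load_model_config(path):
    """Read a model configuration YAML with bounds/schedule/solver sections.

    Returns ``(layout, schedule, settings)``; missing sections fall back to
    the package defaults.  ``bounds`` entries mirror the sampling table
    (bundle -> {parameter: [lo, hi]}), ``schedule`` takes an ``angles`` list,
    and ``solver`` any :class:`SolverSettings` field.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - {"bounds", "schedule", "solver"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    layout = LAYOUT
    if "bounds" in raw:
        bounds = {b: {k: tuple(v) for k, v in entries.items()}
                  for b, entries in raw["bounds"].items()}
        count_property_parameters(bounds)   # validates shape
        layout = PropertyLayout(bounds)
    schedule = FlexionSchedule()
    if "schedule" in raw:
        schedule = FlexionSchedule(np.asarray(raw["schedule"]["angles"], float))
    settings = DEFAULT_SOLVER
    if "solver" in raw:
        fields = set(SolverSettings.__dataclass_fields__)
        bad = set(raw["solver"]) - fields
        if bad:
            raise ValueError(f"unknown solver settings: {sorted(bad)}")
        settings = SolverSettings(**raw["solver"])
    return layout, schedule, settings


def save_subject(path, geometry: KneeGeometry, props) -> None:
    """Write a subject (geometry + nominal 50-vector) to JSON."""
    payload = {
        "bundles": list(geometry.bundles),
        "fem_attach": geometry.fem_attach.tolist(),
        "tib_attach": geometry.tib_attach.tolist(),
        "condyle_centers": geometry.condyle_centers.tolist(),
        "condyle_radii": geometry.condyle_radii.tolist(),
        "dish_centers": geometry.dish_centers.tolist(),
        "dish_radii": geometry.dish_radii.tolist(),
        "ref_lengths": geometry.ref_lengths.tolist(),
        "theta_ref": geometry.theta_ref,
        "groups": {k: list(v) for k, v in geometry.groups.items()},
        "nominal_properties": dict(zip(PARAM_NAMES, map(float, np.asarray(props)))),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_subject(path):
    with open(path) as fh:
        payload = json.load(fh)
    geometry = KneeGeometry(
        fem_attach=payload["fem_attach"],
        tib_attach=payload["tib_attach"],
        condyle_centers=payload["condyle_centers"],
        condyle_radii=payload["condyle_radii"],
        dish_centers=payload["dish_centers"],
        dish_radii=payload["dish_radii"],
        ref_lengths=payload["ref_lengths"],
        theta_ref=payload["theta_ref"],
        bundles=tuple(payload["bundles"]),
        groups={k: tuple(v) for k, v in payload["groups"].items()},
    )
    props = np.array([payload["nominal_properties"][n] for n in PARAM_NAMES])
    return geometry, props
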