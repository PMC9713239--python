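"""Native safe zones and the post-TKA balanced-outcome predicate.

Three native safe zones constrain which ligament-property sets are considered
physiologically plausible for the intact knee:

* ``SZ_D`` (damage): every bundle's peak strain over the squat lies in the
  physiological band (-2%, 6%).
* ``SZ_D&S`` (damage & stability): additionally the medial, lateral and
  central ligament groups each carry tension (group-max strain > 0) at every
  flexion angle.
* ``SZ_D&K`` (damage & kinematics): the damage indicator combined with a
  Gaussian likelihood of measured secondary kinematics.

After TKA the outcome is "balanced" when medial and lateral ligaments engage
throughout the squat and no retained ligament exceeds 6% strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .knee_core import FlexionSchedule, KneeState

__all__ = [
    "STRAIN_LOWER",
    "STRAIN_UPPER",
    "SafeZoneSpec",
    "KinematicsTarget",
    "BalanceOutcome",
    "sz_damage_ok",
    "sz_stability_ok",
    "sz_kinematics_loglik",
    "post_tka_balanced",
    "damage_violation",
    "stability_violation",
    "kinematics_loglik_array",
    "balanced_mask",
]

STRAIN_LOWER = -0.02
STRAIN_UPPER = 0.06

#: Per-DOF standard deviations of the kinematics likelihood (mm or deg):
#: 0.5 for M/L, A/P and I/E; 1.0 for P/D and V/V.
KINEMATICS_SIGMA = np.array([0.5, 0.5, 1.0, 1.0, 0.5])

_DOF_ORDER = ("ml", "ap", "pd", "vv", "ie")


@dataclass
class SafeZoneSpec:
    """Declarative description of a native safe zone."""

    kind: str  # "damage" | "damage_stability" | "damage_kinematics"
    strain_lower: float = STRAIN_LOWER
    strain_upper: float = STRAIN_UPPER
    engaged_groups: tuple = ("medial", "lateral", "central")
    kinematics_target: "KinematicsTarget | None" = None

    _KINDS = ("damage", "damage_stability", "damage_kinematics")
    _ALIASES = {"d": "damage", "ds": "damage_stability", "dk": "damage_kinematics"}

    def __post_init__(self):
        self.kind = self._ALIASES.get(self.kind, self.kind)
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown safe zone kind {self.kind!r}")
        if self.strain_lower >= self.strain_upper:
            raise ValueError("strain bounds out of order")
        if self.kind == "damage_kinematics" and self.kinematics_target is None:
            raise ValueError("damage_kinematics requires a kinematics target")


@dataclass
class KinematicsTarget:
    """Reference secondary-kinematics trajectory with per-DOF spread."""

    angles: np.ndarray            # (T,) deg
    trajectory: np.ndarray        # (5, T): M/L, A/P, P/D (mm), V/V, I/E (deg)
    sigma: np.ndarray = field(default_factory=lambda: KINEMATICS_SIGMA.copy())

    def __post_init__(self):
        self.angles = np.asarray(self.angles, float).reshape(-1)
        self.trajectory = np.asarray(self.trajectory, float)
        self.sigma = np.asarray(self.sigma, float).reshape(-1)
        if self.trajectory.shape != (5, len(self.angles)):
            raise ValueError("trajectory must be (5, n_angles)")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")

    @classmethod
    def from_states(cls, states: "list[KneeState]") -> "KinematicsTarget":
        angles = np.array([s.theta for s in states])
        traj = np.stack([s.dofs for s in states], axis=1)
        return cls(angles=angles, trajectory=traj)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"angle": self.angles})
        for i, name in enumerate(_DOF_ORDER):
            df[name] = self.trajectory[i]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "KinematicsTarget":
        df = pd.read_csv(path)
        traj = np.stack([df[name].to_numpy() for name in _DOF_ORDER])
        return cls(angles=df["angle"].to_numpy(), trajectory=traj)


@dataclass
class BalanceOutcome:
    balanced: bool
    max_medial: np.ndarray        # per angle
    max_lateral: np.ndarray       # per angle
    max_strain: float
    violations: list


def _strain_matrix(states: "list[KneeState]") -> np.ndarray:
    if not states:
        raise ValueError("empty state list")
    return np.stack([s.strains for s in states], axis=1)  # (nb, T)


def sz_damage_ok(states, lower: float = STRAIN_LOWER, upper: float = STRAIN_UPPER) -> bool:
    """True iff every bundle's peak strain over the squat lies in (lower, upper)."""
    peaks = _strain_matrix(states).max(axis=1)
    return bool(np.all(peaks > lower) and np.all(peaks < upper))


def sz_stability_ok(states, geometry,
                    groups=("medial", "lateral", "central")) -> bool:
    """Damage plus per-angle engagement of the medial/lateral/central groups."""
    if not sz_damage_ok(states):
        return False
    strains = _strain_matrix(states)
    for grp in groups:
        gi = geometry.group_indices(grp)
        if not np.all(strains[gi].max(axis=0) > 0.0):
            return False
    return True


def sz_kinematics_loglik(states, target: KinematicsTarget,
                         check_damage: bool = True) -> float:
    """Gaussian log-density of the simulated kinematics under the target.

    Independent normals per DOF and angle; the damage constraint is applied as
    a hard indicator alongside (``-inf`` only through that indicator when
    ``check_damage`` is set).
    """
    angles = np.array([s.theta for s in states])
    if len(angles) != len(target.angles) or not np.allclose(angles, target.angles):
        raise ValueError("state angles do not match the kinematics target schedule")
    sim = np.stack([s.dofs for s in states], axis=1)
    ll = _gauss_loglik(sim[None], target)[0]
    if check_damage and not sz_damage_ok(states):
        return -np.inf
    return float(ll)


def _gauss_loglik(dofs: np.ndarray, target: KinematicsTarget) -> np.ndarray:
    """(N, 5, T) simulated trajectories -> (N,) log-densities."""
    resid = (dofs - target.trajectory[None]) / target.sigma[None, :, None]
    t = dofs.shape[2]
    const = -t * np.sum(np.log(target.sigma * np.sqrt(2 * np.pi)))
    return const - 0.5 * np.sum(resid ** 2, axis=(1, 2))


def post_tka_balanced(states, geometry, upper: float = STRAIN_UPPER) -> BalanceOutcome:
    """Balanced iff medial and lateral groups engage at every angle and no
    bundle strain exceeds the damage bound anywhere in the squat."""
    strains = _strain_matrix(states)
    bundles = states[0].strains.shape[0]
    names = geometry.bundles[:bundles] if bundles == len(geometry.bundles) else None
    med = [i for i, b in enumerate(_state_bundles(states, geometry)) if b in geometry.groups["medial"]]
    lat = [i for i, b in enumerate(_state_bundles(states, geometry)) if b in geometry.groups["lateral"]]
    max_med = strains[med].max(axis=0)
    max_lat = strains[lat].max(axis=0)
    max_strain = float(strains.max())
    violations = []
    angles = [s.theta for s in states]
    if max_strain > upper:
        bi, ti = np.unravel_index(np.argmax(strains), strains.shape)
        label = _state_bundles(states, geometry)[bi]
        violations.append(("overstrain", label, angles[ti]))
    for t, a in enumerate(angles):
        if max_med[t] <= 0:
            violations.append(("medial_slack", None, a))
        if max_lat[t] <= 0:
            violations.append(("lateral_slack", None, a))
    balanced = (max_strain <= upper and np.all(max_med > 0) and np.all(max_lat > 0))
    return BalanceOutcome(balanced=bool(balanced), max_medial=max_med,
                          max_lateral=max_lat, max_strain=max_strain,
                          violations=violations)


def _state_bundles(states, geometry):
    nb = states[0].strains.shape[0]
    if nb == len(geometry.bundles):
        return geometry.bundles
    from .knee_core import RETAINED_BUNDLES
    if nb == len(RETAINED_BUNDLES):
        return RETAINED_BUNDLES
    raise ValueError("cannot infer bundle labels from state dimension")


# ---------------------------------------------------------------------------
# Vectorized forms used by the samplers and planners
# ---------------------------------------------------------------------------

def damage_violation(strains: np.ndarray,
                     lower: float = STRAIN_LOWER,
                     upper: float = STRAIN_UPPER) -> np.ndarray:
    """Squared constraint violation of the damage zone.

    ``strains``: (N, nb, T).  The bound applies to each bundle's peak strain
    over the squat.  Returns (N,) sums of squared excursions (strain^2 units).
    """
    peaks = strains.max(axis=2)
    over = np.maximum(peaks - upper, 0.0)
    under = np.maximum(lower - peaks, 0.0)
    return np.sum(over ** 2 + under ** 2, axis=1)


def stability_violation(strains: np.ndarray, geometry,
                        groups=("medial", "lateral", "central")) -> np.ndarray:
    """Squared per-angle engagement shortfall of the ligament groups."""
    out = np.zeros(strains.shape[0])
    for grp in groups:
        gi = geometry.group_indices(grp)
        gmax = strains[:, gi, :].max(axis=1)
        out += np.sum(np.maximum(-gmax, 0.0) ** 2, axis=1)
    return out


def kinematics_loglik_array(dofs: np.ndarray, target: KinematicsTarget) -> np.ndarray:
    """(N, 5, T) -> (N,) Gaussian log-densities (no damage indicator)."""
    return _gauss_loglik(dofs, target)


def balanced_mask(strains: np.ndarray, medial_idx, lateral_idx,
                  upper: float = STRAIN_UPPER) -> np.ndarray:
    """(N, nb, T) retained-bundle strains -> (N,) balanced flags."""
    ok = strains.max(axis=(1, 2)) <= upper
    ok &= np.all(strains[:, medial_idx, :].max(axis=1) > 0.0, axis=1)
    ok &= np.all(strains[:, lateral_idx, :].max(axis=1) > 0.0, axis=1)
    return ok
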