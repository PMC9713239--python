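"""Bayesian estimation of subject-specific ligament properties.

A transitional MCMC (TMCMC) sampler tempers from the uniform prior on the
sampling-bound box to the safe-zone posterior.  Safe zones defined purely by
constraints (damage, stability) have indicator posteriors that cannot be
tempered directly; stages therefore use a soft penalized log-target
``loglik - lambda * violation^2`` whose effective penalty weight escalates
with the tempering exponent, followed by an exact accept/reject against the
indicator.  The result is a "set family": a matrix of property vectors that
all reproduce physiologically plausible native squats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import safe_zones as sz
from .knee_core import LAYOUT, FlexionSchedule, squat_batch

__all__ = ["TmcmcConfig", "SetFamily", "tmcmc_sample", "build_family", "audit_family"]


@dataclass
class TmcmcConfig:
    """TMCMC sampler settings."""

    chain_size: int = 2000       # use >= ~6x the parameter count (300 for 50-d)
    cov_target: float = 0.5      # target coefficient of variation of weights
    scaling: float = 0.2         # proposal scale factor (beta in Ching & Chen)
    max_stages: int = 40
    n_mh_steps: int = 5          # Metropolis moves per chain per stage
    penalty_weight: float = 1.0e6  # lambda at full tempering, per strain^2
    seed: int = 0

    def __post_init__(self):
        if self.chain_size < 100:
            raise ValueError("chain size must be at least 100")
        if not (0.0 < self.scaling <= 1.0):
            raise ValueError("proposal scaling must lie in (0, 1]")


@dataclass
class SetFamily:
    """Family of property vectors consistent with one native safe zone."""

    props: np.ndarray                 # (n_sets, n_params)
    safe_zone_kind: str
    names: tuple = tuple(LAYOUT.names)
    metadata: dict = field(default_factory=dict)

    def __len__(self):
        return self.props.shape[0]

    def to_csv(self, path, sidecar=None) -> None:
        pd.DataFrame(self.props, columns=list(self.names)).to_csv(path, index=False)
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump({"safe_zone_kind": self.safe_zone_kind,
                           "metadata": self.metadata}, fh, indent=1, sort_keys=True)
                fh.write("\n")

    @classmethod
    def from_csv(cls, path, sidecar=None) -> "SetFamily":
        df = pd.read_csv(path, float_precision="round_trip")
        kind, meta = "damage", {}
        if sidecar is not None:
            with open(sidecar) as fh:
                payload = json.load(fh)
            kind = payload.get("safe_zone_kind", kind)
            meta = payload.get("metadata", {})
        return cls(props=df.to_numpy(float), safe_zone_kind=kind,
                   names=tuple(df.columns), metadata=meta)

    def column(self, name: str) -> np.ndarray:
        return self.props[:, self.names.index(name)]


def _safe_cholesky(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor of a possibly rank-deficient sample covariance."""
    d = cov.shape[0]
    jitter = 1e-10 * (np.trace(cov) / d + 1.0)
    try:
        return np.linalg.cholesky(cov + jitter * np.eye(d))
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        floor = max(1e-12, 1e-8 * float(vals.max()))
        return vecs * np.sqrt(np.maximum(vals, floor))


def _weight_cov(log_w: np.ndarray) -> float:
    w = np.exp(log_w - log_w.max())
    return float(np.std(w) / np.mean(w))


def _next_beta(beta: float, log_target: np.ndarray, cov_target: float) -> float:
    """Largest tempering increment keeping the weight CoV at the target."""
    lo, hi = 0.0, 1.0 - beta
    if hi <= 0:
        return 1.0
    if _weight_cov(hi * log_target) <= cov_target:
        return 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _weight_cov(mid * log_target) > cov_target:
            hi = mid
        else:
            lo = mid
    inc = 0.5 * (lo + hi)
    if inc < 1e-9:
        # pure-indicator targets give a weight CoV independent of the
        # increment, so bisection collapses to zero; step anyway
        inc = max(1e-3 * (1.0 - beta), 1e-9)
    return min(1.0, beta + inc)


def tmcmc_sample(log_target, bounds, config: TmcmcConfig):
    """Transitional MCMC from the uniform prior on a box to ``log_target``.

    ``log_target(x)`` maps an (N, d) batch to (N,) log-densities (may be
    ``-inf``).  ``bounds`` is (lower, upper) arrays of length d.  Returns
    ``(samples, info)`` where ``info`` records the stage history.
    """
    lower, upper = (np.asarray(b, float) for b in bounds)
    d = lower.size
    rng = np.random.default_rng(config.seed)
    n = config.chain_size
    x = lower + rng.random((n, d)) * (upper - lower)
    lt = np.asarray(log_target(x), float)
    if not np.any(np.isfinite(lt)):
        raise RuntimeError(
            "degenerate TMCMC start: log-target is -inf for every prior sample")
    beta = 0.0
    info = {"betas": [], "acceptance": [], "stages": 0, "seed": config.seed}
    for _ in range(config.max_stages):
        finite = np.isfinite(lt)
        lt_f = np.where(finite, lt, -1e300)
        beta_new = _next_beta(beta, lt_f, config.cov_target)
        dbeta = beta_new - beta
        log_w = dbeta * lt_f
        log_w -= log_w.max()
        w = np.exp(log_w)
        w /= w.sum()
        mean = np.einsum("n,nd->d", w, x)
        xc = x - mean
        cov = np.einsum("n,nd,ne->de", w, xc, xc)
        chol = _safe_cholesky(config.scaling ** 2 * cov)
        idx = rng.choice(n, size=n, p=w)
        x = x[idx]
        lt = lt[idx]
        acc = 0
        for _ in range(config.n_mh_steps):
            prop = x + rng.standard_normal((n, d)) @ chol.T
            inside = np.all((prop >= lower) & (prop <= upper), axis=1)
            lt_prop = np.full(n, -np.inf)
            if np.any(inside):
                lt_prop[inside] = np.asarray(log_target(prop[inside]), float)
            log_alpha = beta_new * (lt_prop - lt)
            accept = np.log(rng.random(n)) < log_alpha
            accept &= np.isfinite(lt_prop)
            x[accept] = prop[accept]
            lt[accept] = lt_prop[accept]
            acc += accept.mean() / config.n_mh_steps
        info["betas"].append(beta_new)
        info["acceptance"].append(float(acc))
        info["stages"] += 1
        beta = beta_new
        if beta >= 1.0:
            break
    return x, info


# ---------------------------------------------------------------------------
# Safe-zone families
# ---------------------------------------------------------------------------

def _zone_evaluator(geometry, spec: sz.SafeZoneSpec, schedule, settings):
    """Batched knee-model evaluation of a safe zone.

    Returns ``evaluate(props) -> (loglik, violation, converged)`` where
    ``loglik`` is the Gaussian kinematics term (zero for indicator zones) and
    ``violation`` the squared constraint excursion.
    """

    def evaluate(props):
        strains, dofs, conv = squat_batch(geometry, props, None, schedule,
                                          settings=settings)
        viol = sz.damage_violation(strains, spec.strain_lower, spec.strain_upper)
        if spec.kind == "damage_stability":
            viol = viol + sz.stability_violation(strains, geometry, spec.engaged_groups)
        ll = np.zeros(viol.shape)
        if spec.kind == "damage_kinematics":
            ll = sz.kinematics_loglik_array(dofs, spec.kinematics_target)
        return ll, viol, conv

    return evaluate


def _polish_to_indicator(x, evaluate, lower, upper, config: TmcmcConfig,
                         rng, lam0: float, max_rounds: int = 10,
                         target_valid: float = 0.9):
    """MH rounds under a geometrically escalating penalty weight.

    In high dimension the soft posterior concentrates in a thin shell of
    slightly violating samples; escalating lambda anneals the chains into the
    exact indicator region (violation == 0).
    """
    n, d = x.shape
    lam = lam0
    ll, viol, conv = evaluate(x)
    viol = np.where(conv, viol, np.inf)
    for _ in range(max_rounds):
        if np.mean(viol <= 0.0) >= target_valid:
            break
        # largest penalty increment keeping the weight CoV near the target,
        # searched on a geometric ladder
        dlam = lam
        for _ in range(40):
            if _weight_cov(-dlam * np.where(np.isfinite(viol), viol, 1e30)) \
                    >= config.cov_target or np.all(viol[np.isfinite(viol)] <= 0):
                break
            dlam *= 4.0
        lam = lam + dlam
        log_w = -dlam * np.where(np.isfinite(viol), viol, 1e300)
        log_w -= log_w.max()
        w = np.exp(log_w)
        w /= w.sum()
        mean = np.einsum("n,nd->d", w, x)
        xc = x - mean
        cov = np.einsum("n,nd,ne->de", w, xc, xc)
        chol = _safe_cholesky(config.scaling ** 2 * cov)
        idx = rng.choice(n, size=n, p=w)
        x, ll, viol = x[idx].copy(), ll[idx].copy(), viol[idx].copy()
        for _ in range(config.n_mh_steps):
            prop = x + rng.standard_normal((n, d)) @ chol.T
            inside = np.all((prop >= lower) & (prop <= upper), axis=1)
            lt_prop = np.full(n, -np.inf)
            ll_p = np.zeros(n)
            viol_p = np.full(n, np.inf)
            if np.any(inside):
                ll_i, viol_i, conv_i = evaluate(prop[inside])
                viol_i = np.where(conv_i, viol_i, np.inf)
                ll_p[inside], viol_p[inside] = ll_i, viol_i
                lt_prop[inside] = np.where(np.isfinite(viol_i),
                                           ll_i - lam * viol_i, -np.inf)
            lt = np.where(np.isfinite(viol), ll - lam * viol, -np.inf)
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.random(n)) < (lt_prop - lt)
            accept &= np.isfinite(lt_prop)
            x[accept] = prop[accept]
            ll[accept] = ll_p[accept]
            viol[accept] = viol_p[accept]
    return x, viol, np.isfinite(viol)


def _indicator(geometry, spec: sz.SafeZoneSpec, strains, dofs) -> np.ndarray:
    ok = sz.damage_violation(strains, spec.strain_lower, spec.strain_upper) <= 0.0
    if spec.kind == "damage_stability":
        ok &= sz.stability_violation(strains, geometry, spec.engaged_groups) <= 0.0
    return ok


def build_family(geometry, safe_zone: sz.SafeZoneSpec, n_sets: int,
                 config: TmcmcConfig | None = None, schedule=None,
                 settings=None, audit_size: int = 200,
                 min_pass: float = 0.95) -> SetFamily:
    """Collect a set family of ligament properties for one native safe zone.

    Runs TMCMC on the soft-penalized target, applies the exact indicator to
    the final-stage samples (topping up from the valid pool if a few chains
    remain slightly outside), then audits a subsample through the full knee
    model, rejecting the family if membership falls below ``min_pass``.
    """
    from .knee_core import DEFAULT_SOLVER

    schedule = schedule or FlexionSchedule()
    settings = settings or DEFAULT_SOLVER
    config = config or TmcmcConfig(chain_size=max(n_sets, 100))
    if config.chain_size < n_sets:
        raise ValueError("chain size must be at least the requested family size")
    evaluate = _zone_evaluator(geometry, safe_zone, schedule, settings)

    def log_target(props):
        ll, viol, conv = evaluate(props)
        out = ll - config.penalty_weight * viol
        out[~conv] = -np.inf
        return out

    samples, info = tmcmc_sample(log_target, (LAYOUT.lower, LAYOUT.upper), config)
    rng = np.random.default_rng(config.seed + 3)
    samples, viol, conv = _polish_to_indicator(
        samples, evaluate, LAYOUT.lower, LAYOUT.upper, config, rng,
        lam0=config.penalty_weight)
    ok = (viol <= 0.0) & conv
    n_valid = int(ok.sum())
    if n_valid < max(1, int(0.5 * n_sets)):
        raise RuntimeError(
            "TMCMC family rejected: only "
            f"{n_valid}/{config.chain_size} samples satisfy the safe zone "
            f"({safe_zone.kind}); residual mean violation "
            f"{float(np.mean(viol[np.isfinite(viol)])):.2e} strain^2, "
            f"{int((~conv).sum())} non-converged chains")
    rng = np.random.default_rng(config.seed + 1)
    valid_idx = np.flatnonzero(ok)
    if n_valid >= n_sets:
        chosen = valid_idx[rng.permutation(n_valid)[:n_sets]]
    else:
        chosen = np.concatenate([valid_idx,
                                 rng.choice(valid_idx, n_sets - n_valid)])
    family = SetFamily(
        props=samples[chosen],
        safe_zone_kind=safe_zone.kind,
        metadata={**info, "n_valid_final": n_valid,
                  "requested": int(n_sets), "penalty_weight": config.penalty_weight},
    )
    report = audit_family(geometry, family, safe_zone, schedule, settings,
                          audit_size=audit_size, seed=config.seed + 2)
    family.metadata["audit"] = report
    if report["pass_fraction"] < min_pass:
        raise RuntimeError(
            f"family audit failed: {report['pass_fraction']:.2%} membership "
            f"(required {min_pass:.0%}); diagnostics: {report}")
    return family


def audit_family(geometry, family: SetFamily, safe_zone: sz.SafeZoneSpec,
                 schedule=None, settings=None, audit_size: int = 200,
                 seed: int = 0) -> dict:
    """Re-evaluate a family subsample through the full knee model."""
    from .knee_core import DEFAULT_SOLVER

    schedule = schedule or FlexionSchedule()
    settings = settings or DEFAULT_SOLVER
    rng = np.random.default_rng(seed)
    n = len(family)
    take = min(n, max(audit_size, 1))
    idx = rng.permutation(n)[:take]
    strains, dofs, conv = squat_batch(geometry, family.props[idx], None,
                                      schedule, settings=settings)
    ok = _indicator(geometry, safe_zone, strains, dofs) & conv
    out = {"n_audited": int(take), "pass_fraction": float(ok.mean()),
           "n_converged": int(conv.sum())}
    if safe_zone.kind == "damage_kinematics":
        ll = sz.kinematics_loglik_array(dofs, safe_zone.kinematics_target)
        out["loglik_range"] = [float(ll.min()), float(ll.max())]
    return out
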