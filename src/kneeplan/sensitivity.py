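"""Critical-ligament-property identification.

For each property set of an SZ_D&S family, the implant-pose optimization is
repeated with the ligament properties held fixed, propagating surgical
imprecision alone by quasi-Monte Carlo (Sobol) sampling.  The resulting
per-set outputs (optimized mean pose DOFs and success probability) feed the
delta moment-independent sensitivity measure: for input i,

    delta_i = 1/2 * E_{X_i} integral |f_Y(y) - f_{Y|X_i}(y)| dy

estimated by slicing the input into quantile classes and comparing Gaussian
kernel density estimates of the conditional and marginal output.  A rank
penalty (p = 10/r for a missed ground-truth member of rank r) scores the
stability of the top-10 critical set under subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde, qmc, norm

from . import planning as pl
from .knee_core import FlexionSchedule

__all__ = [
    "SensitivitySample",
    "DeltaResult",
    "ConvergenceScore",
    "qmc_pose_samples",
    "collect_sa_samples",
    "delta_measure",
    "convergence_penalty",
    "sa_convergence_curve",
]


@dataclass
class SensitivitySample:
    """Responses of one per-set optimization (fixed ligament properties)."""

    props: np.ndarray          # the property vector (inputs)
    pose: np.ndarray           # optimized mean pose (12,)
    gsp: float


@dataclass
class DeltaResult:
    """Delta estimates with the Table-style criticality classification."""

    delta: np.ndarray                      # per input, in [0, 1]
    names: tuple = ()
    n_classes: int = 0

    @property
    def ranking(self) -> np.ndarray:
        """Input indices from most to least critical."""
        return np.argsort(-self.delta, kind="stable")

    def top(self, k: int = 10) -> list:
        idx = self.ranking[:k]
        return [self.names[i] if self.names else int(i) for i in idx]

    def classification(self) -> dict:
        """Top-10 split into 3 most / 3 mid / 4 least critical."""
        top10 = self.top(10)
        return {"most": top10[:3], "mid": top10[3:6], "least": top10[6:10]}


@dataclass
class ConvergenceScore:
    evaluated: list
    truth: list
    penalty: float
    missing: list = field(default_factory=list)


def qmc_pose_samples(preset: pl.PrecisionPreset, n: int = 256,
                     seed: int = 0) -> np.ndarray:
    """Sobol pose perturbations mapped through the per-DOF normal inverse CDF.

    The unscrambled Sobol sequence is fast-forwarded past its origin point,
    so the first sample is the distribution median (zero perturbation).
    ``seed`` selects how far the sequence is additionally advanced, keeping
    the deterministic low-discrepancy structure.
    """
    if not preset.complete:
        raise ValueError(f"preset {preset.name!r} has unreported sigmas")
    sob = qmc.Sobol(12, scramble=False)
    sob.fast_forward(1 + n * (seed % 64))
    u = sob.random(n)
    z = norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
    return z * preset.sigma


def collect_sa_samples(family, model_factory, preset: pl.PrecisionPreset,
                       n_sets: int = 750, n_qmc: int = 256,
                       ga: pl.GAConfig | None = None,
                       schedule: FlexionSchedule | None = None,
                       seed: int = 0, optimize: bool = True,
                       progress=None) -> list[SensitivitySample]:
    """One pose optimization per property set, pose uncertainty via QMCS.

    ``model_factory(props_row)`` must return a strain-table model whose
    family is the single given property set (the same optimization contract
    as the planning module, with constant ligament properties).  With
    ``optimize=False`` the mechanically aligned pose is kept and only the
    success probability is propagated (cheap screening variant).
    Failed optimizations are recorded and excluded.
    """
    schedule = schedule or FlexionSchedule()
    ga = ga or pl.GAConfig(generations=30, offspring=16, seed=seed)
    props_mat = family.props if hasattr(family, "props") else np.atleast_2d(family)
    if n_sets > props_mat.shape[0]:
        raise ValueError("n_sets exceeds the family size")
    perturb = qmc_pose_samples(preset, n_qmc, seed=seed)
    out: list[SensitivitySample] = []
    n_failed = 0
    for i in range(n_sets):
        props = props_mat[i]
        model = model_factory(props)
        samples = pl.MCSampleSet(perturbations=perturb,
                                 property_rows=np.zeros(n_qmc, dtype=int),
                                 seed=seed, preset_name=preset.name)
        try:
            if optimize:
                ga_i = pl.GAConfig(generations=ga.generations,
                                   offspring=ga.offspring,
                                   eta_crossover=ga.eta_crossover,
                                   eta_mutation=ga.eta_mutation,
                                   mutation_rate=ga.mutation_rate,
                                   seed=ga.seed, bound=ga.bound)
                res = pl.optimize_plan(samples, model, ga_i, schedule)
                out.append(SensitivitySample(props=props, pose=res.pose.values,
                                             gsp=res.gsp))
            else:
                gsp = pl.success_probability(np.zeros(12), samples, model, schedule)
                out.append(SensitivitySample(props=props, pose=np.zeros(12),
                                             gsp=gsp))
        except RuntimeError:
            n_failed += 1
        if progress is not None:
            progress(i + 1, n_sets)
    if n_failed:
        import warnings
        warnings.warn(f"{n_failed}/{n_sets} per-set optimizations failed and "
                      "were excluded")
    return out


# ---------------------------------------------------------------------------
# Delta moment-independent measure
# ---------------------------------------------------------------------------

def _delta_single(x: np.ndarray, y: np.ndarray, n_classes: int,
                  grid: np.ndarray, f_marg: np.ndarray) -> float:
    """Delta estimate for one input against precomputed marginal density."""
    order = np.argsort(x, kind="stable")
    splits = np.array_split(order, n_classes)
    total = 0.0
    n = len(y)
    for cls in splits:
        if len(cls) < 3:
            continue
        yc = y[cls]
        if np.std(yc) < 1e-12:
            # degenerate slice: narrow normal stands in for the point mass
            f_cond = norm.pdf(grid, loc=yc[0],
                              scale=max(1e-3 * np.std(y), 1e-12))
        else:
            f_cond = gaussian_kde(yc)(grid)
        total += len(cls) / n * np.trapezoid(np.abs(f_marg - f_cond), grid)
    return 0.5 * total


def delta_measure(inputs: np.ndarray, output: np.ndarray,
                  n_classes: int | None = None, seed: int = 0,
                  names=(), bias_correction: bool = True,
                  grid_size: int = 512, min_rows: int = 100) -> DeltaResult:
    """Borgonovo delta moment-independent sensitivity per input column.

    Inputs are partitioned into ``n_classes`` equal-count quantile classes
    (default ``max(8, floor(sqrt(n)))``); densities use Gaussian KDE with
    Scott's rule on a common grid.  With ``bias_correction`` the estimate for
    a permuted (independent) copy of each input is subtracted and the result
    clipped to [0, 1], removing the finite-sample bias that otherwise makes
    independent inputs score above zero.  A constant output yields all-zero
    deltas with a warning.
    """
    inputs = np.atleast_2d(np.asarray(inputs, float))
    output = np.asarray(output, float).reshape(-1)
    n, d = inputs.shape
    if n < min_rows:
        raise ValueError(f"delta measure requires at least {min_rows} rows")
    if output.shape[0] != n:
        raise ValueError("inputs and output length mismatch")
    if np.std(output) < 1e-12:
        import warnings
        warnings.warn("constant output: all delta estimates reported as 0")
        return DeltaResult(delta=np.zeros(d), names=tuple(names),
                           n_classes=0)
    n_classes = n_classes or max(8, int(np.sqrt(n)))
    span = output.max() - output.min()
    grid = np.linspace(output.min() - 0.25 * span, output.max() + 0.25 * span,
                       grid_size)
    f_marg = gaussian_kde(output)(grid)
    rng = np.random.default_rng(seed)
    delta = np.empty(d)
    for j in range(d):
        est = _delta_single(inputs[:, j], output, n_classes, grid, f_marg)
        if bias_correction:
            null = _delta_single(rng.permutation(inputs[:, j]), output,
                                 n_classes, grid, f_marg)
            est = est - null
        delta[j] = min(max(est, 0.0), 1.0)
    return DeltaResult(delta=delta, names=tuple(names), n_classes=n_classes)


def convergence_penalty(evaluated_top, truth_top_ranked) -> ConvergenceScore:
    """Rank penalty of an evaluated critical set against the ground truth.

    Each ground-truth member of rank r (1 = most critical) missing from the
    evaluated set adds 10/r.  Zero iff the sets agree as sets.
    """
    evaluated = list(evaluated_top)
    truth = list(truth_top_ranked)
    if len(set(evaluated)) != len(evaluated) or len(set(truth)) != len(truth):
        raise ValueError("duplicate entries in a critical set")
    if len(evaluated) != len(truth):
        raise ValueError("evaluated and truth sets must have equal size")
    ev = set(evaluated)
    missing = [(m, r + 1) for r, m in enumerate(truth) if m not in ev]
    penalty = sum(10.0 / r for _, r in missing)
    return ConvergenceScore(evaluated=evaluated, truth=truth,
                            penalty=float(penalty),
                            missing=[m for m, _ in missing])


def sa_convergence_curve(inputs: np.ndarray, output: np.ndarray,
                         subset_sizes, n_repeats: int = 50, seed: int = 0,
                         top_k: int = 10, names=()) -> dict:
    """Penalty of subsample rankings versus the full-sample ground truth.

    For each subset size, ``n_repeats`` random subsamples are drawn, the
    delta ranking recomputed, and the rank penalty against the full-sample
    top-``top_k`` recorded.  Returns mean and spread per size.
    """
    inputs = np.atleast_2d(np.asarray(inputs, float))
    output = np.asarray(output, float).reshape(-1)
    n = inputs.shape[0]
    truth = delta_measure(inputs, output, seed=seed, names=names).top(top_k)
    rng = np.random.default_rng(seed)
    sizes, means, spreads, all_pen = [], [], [], []
    for size in subset_sizes:
        if size > n:
            raise ValueError(f"subset size {size} exceeds sample count {n}")
        pens = []
        for _ in range(n_repeats):
            if size == n:
                idx = np.arange(n)
            else:
                idx = rng.choice(n, size=size, replace=False)
            sub = delta_measure(inputs[idx], output[idx], seed=seed,
                                names=names).top(top_k)
            pens.append(convergence_penalty(sub, truth).penalty)
        sizes.append(int(size))
        means.append(float(np.mean(pens)))
        spreads.append(float(np.std(pens)))
        all_pen.append(pens)
    return {"sizes": sizes, "mean_penalty": means, "std_penalty": spreads,
            "penalties": all_pen, "truth": truth}
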