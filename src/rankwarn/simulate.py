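"""Ground-truthed synthetic studies for end-to-end testing of the method.

Three generators produce (normal pool, time course, truth) triples:

* ``simulate_factor_study`` — the primary test surface. Genes carry
  i.i.d. Gaussian noise around fixed base levels; from the planted
  transition onward a small module (the "DNB" genes) picks up a shared
  latent factor whose loading grows linearly per time step. That raises
  the module's standard deviation, its intra-module correlation and its
  mean displacement while leaving the rest of the genome stationary —
  exactly the signature dynamic-network-biomarker theory predicts near
  a critical transition.
* ``simulate_network_study`` — secondary realism: a small
  Michaelis-Menten-form stochastic regulatory network driven
  quasi-statically through a fold bifurcation by a control parameter q,
  with the critical point placed exactly at q = 0. This is a stand-in
  system of the same model class as published tipping-point benchmark
  networks, not a reproduction of any specific one.
* ``simulate_null_study`` — stationary noise throughout, for
  false-positive calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .containers import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_factor_study",
    "simulate_network_study",
    "simulate_null_study",
    "simulate_cohort",
]

#: mean displacement of the shared factor, in units of its loading
MEAN_SHIFT_GAIN = 1.0
#: range of per-gene base expression levels (log2-like scale)
BASE_LEVEL_RANGE = (4.0, 12.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the desk-scale study: 200 genes observed at 16 time
    points with the transition planted at index 10, a 20-gene DNB
    module, an 8-sample normal pool, unit observation noise on a
    log2-like scale, and a factor-loading ramp of 0.9 noise-SD units per
    post-transition step (which doubles the module SD by the second
    post-transition time point). ``noise_sd`` doubles as the diffusion
    coefficient in network mode, where states are O(1) and a much
    smaller value (e.g. 0.05) is appropriate.
    """

    n_genes: int = 200
    dnb_size: int = 20
    n_timepoints: int = 16
    transition_index: int = 10
    n_normal_samples: int = 8
    noise_sd: float = 1.0
    dnb_variance_ramp: float = 0.9
    seed: int = 0
    mode: str = "factor_model"

    def __post_init__(self):
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if not 0 <= self.dnb_size < self.n_genes:
            raise ValueError("dnb_size must satisfy 0 <= dnb_size < n_genes")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be >= 1")
        if not 0 < self.transition_index < self.n_timepoints:
            raise ValueError("transition_index must lie strictly inside "
                             "(0, n_timepoints)")
        if self.n_normal_samples < 1:
            raise ValueError("n_normal_samples must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dnb_variance_ramp < 0:
            raise ValueError("dnb_variance_ramp must be >= 0")
        if self.mode not in ("factor_model", "network_sde"):
            raise ValueError(f"unknown mode: {self.mode!r}")


@dataclass(frozen=True)
class SimulatedStudy:
    """A generated study with its ground truth."""

    normal_matrix: ExpressionMatrix
    course: ExpressionMatrix
    truth_transition_index: int | None
    dnb_gene_ids: frozenset
    config: SimulationConfig
    q_values: tuple | None = None  # network mode only

    @property
    def time_labels(self) -> tuple:
        return tuple(self.course.sample_ids)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def _time_labels(n: int) -> list[str]:
    # zero-padded decimal strings sort identically as text and as numbers
    width = max(2, len(str(n)))
    return [f"{j:0{width}d}" for j in range(n)]


def _base_levels(rng: np.random.Generator, n: int) -> np.ndarray:
    lo, hi = BASE_LEVEL_RANGE
    return rng.uniform(lo, hi, size=n)


def simulate_factor_study(config: SimulationConfig) -> SimulatedStudy:
    """Plant a DNB module via a growing shared latent factor.

    Before the transition every gene g at every time point is
    ``base_g + eps`` with eps ~ N(0, noise_sd^2). From the transition
    index onward, at the k-th post-transition step (k = 1, 2, ...) the
    DNB genes receive an additional ``lambda_k * (f_t + 1)`` where
    ``lambda_k = dnb_variance_ramp * k * noise_sd`` and f_t ~ N(0, 1) is
    shared by the module at that time point. Module SD grows as
    ``noise_sd * sqrt(1 + (ramp*k)^2)``; intra-module correlation grows
    toward 1; the module mean drifts upward by lambda_k.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    base = _base_levels(rng, config.n_genes)

    normal = base[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, config.n_normal_samples))
    normal_ids = [f"normal{j:02d}" for j in range(config.n_normal_samples)]

    dnb_idx = rng.choice(config.n_genes, size=config.dnb_size, replace=False)
    course = base[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, config.n_timepoints))
    for t in range(config.transition_index, config.n_timepoints):
        k = t - config.transition_index + 1
        lam = config.dnb_variance_ramp * k * config.noise_sd
        shared = rng.normal()
        course[dnb_idx, t] += lam * (shared + MEAN_SHIFT_GAIN)

    dnb_ids = frozenset(genes[i] for i in dnb_idx)
    return SimulatedStudy(
        normal_matrix=ExpressionMatrix(normal, gene_ids=genes,
                                       sample_ids=normal_ids),
        course=ExpressionMatrix(course, gene_ids=genes,
                                sample_ids=_time_labels(config.n_timepoints)),
        truth_transition_index=config.transition_index,
        dnb_gene_ids=dnb_ids,
        config=config,
    )


def simulate_cohort(config: SimulationConfig, n_case_subjects: int = 3,
                    n_null_subjects: int = 5):
    """A multi-subject study sharing one gene universe, as one matrix.

    Emulates the challenge-study layout: every subject contributes its
    own baseline samples plus a time course; case subjects carry the
    planted DNB transition (one common DNB module, subject-specific
    factor realizations), null subjects are stationary and serve as the
    normal pool for threshold calibration.

    Returns
    -------
    (ExpressionMatrix, pandas.DataFrame, dict)
        The combined matrix, a metadata table with columns
        ``sample_id, subject_id, time, group``, and a ground-truth dict
        (transition index/label, DNB gene ids, subject lists).
    """
    if n_case_subjects < 1 or n_null_subjects < 0:
        raise ValueError("need >= 1 case subject and >= 0 null subjects")
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    base = _base_levels(rng, config.n_genes)
    dnb_idx = rng.choice(config.n_genes, size=config.dnb_size, replace=False)
    tlabels = _time_labels(config.n_timepoints)

    columns: dict[str, np.ndarray] = {}
    rows = []
    subjects = ([(f"case{i:02d}", True) for i in range(n_case_subjects)]
                + [(f"null{i:02d}", False) for i in range(n_null_subjects)])
    for subject, planted in subjects:
        for j in range(config.n_normal_samples):
            sid = f"{subject}_b{j:02d}"
            columns[sid] = base + rng.normal(0.0, config.noise_sd,
                                             config.n_genes)
            rows.append((sid, subject, "baseline", "baseline"))
        course = base[:, None] + rng.normal(
            0.0, config.noise_sd, size=(config.n_genes, config.n_timepoints))
        if planted and config.dnb_variance_ramp > 0:
            for t in range(config.transition_index, config.n_timepoints):
                k = t - config.transition_index + 1
                lam = config.dnb_variance_ramp * k * config.noise_sd
                course[dnb_idx, t] += lam * (rng.normal() + MEAN_SHIFT_GAIN)
        for t, label in enumerate(tlabels):
            sid = f"{subject}_{label}"
            columns[sid] = course[:, t]
            rows.append((sid, subject, label, "case" if planted else "normal"))

    matrix = ExpressionMatrix(pd.DataFrame(columns, index=genes))
    metadata = pd.DataFrame(rows, columns=["sample_id", "subject_id",
                                           "time", "group"])
    truth = {
        "transition_index": config.transition_index,
        "transition_time": tlabels[config.transition_index],
        "dnb_gene_ids": sorted(genes[i] for i in dnb_idx),
        "case_subjects": [s for s, p in subjects if p],
        "null_subjects": [s for s, p in subjects if not p],
    }
    return matrix, metadata, truth


def simulate_null_study(config: SimulationConfig) -> SimulatedStudy:
    """Stationary noise throughout; no planted structure."""
    null_cfg = replace(config, dnb_variance_ramp=0.0)
    study = simulate_factor_study(null_cfg)
    return SimulatedStudy(
        normal_matrix=study.normal_matrix,
        course=study.course,
        truth_transition_index=None,
        dnb_gene_ids=frozenset(),
        config=null_cfg,
    )


# ---------------------------------------------------------------------------
# Michaelis-Menten-form network with a fold bifurcation at q = 0
# ---------------------------------------------------------------------------

_BETA = 2.0  # maximal activation rate of the core self-activating node


def _fold_constants() -> tuple[float, float]:
    """Basal input a and fold-point state x* of the core node.

    The core node obeys dx/dt = a + q + beta*x^2/(1+x^2) - x. Writing
    g(x) = x - beta*x^2/(1+x^2), steady states satisfy a + q = g(x) and
    the low branch annihilates where g'(x) = 0, i.e. (1+x^2)^2 = 4x
    (for beta = 2). Choosing a = g(x*) at the smaller root places that
    saddle-node exactly at q = 0.
    """
    x_star = brentq(lambda x: (1 + x * x) ** 2 - 4 * x, 0.05, 0.95)
    a = x_star - _BETA * x_star ** 2 / (1 + x_star ** 2)
    return a, x_star


def _q_grid(n_timepoints: int, transition_index: int,
            q_min: float = -0.4, q_max: float = 0.2) -> np.ndarray:
    """Control-parameter grid with q = 0 exactly at transition_index."""
    neg = np.linspace(q_min, 0.0, transition_index, endpoint=False)
    pos = np.linspace(0.0, q_max, n_timepoints - transition_index)
    return np.concatenate([neg, pos])


def _drift(x: np.ndarray, q: float, a: float) -> np.ndarray:
    """Michaelis-Menten-form drift of the n-node cascade.

    Node 0 self-activates with Hill coefficient 2 and feels the control
    parameter q additively; node j > 0 is driven by node j-1, odd nodes
    by activation x^2/(1+x^2) and even nodes by repression 1/(1+x^2),
    each with basal production 0.1 and unit degradation.
    """
    dx = np.empty_like(x)
    dx[0] = a + q + _BETA * x[0] ** 2 / (1 + x[0] ** 2) - x[0]
    up = x[:-1]
    hill_act = up ** 2 / (1 + up ** 2)
    hill_rep = 1.0 / (1 + up ** 2)
    odd = (np.arange(1, x.size) % 2) == 1
    dx[1:] = 0.1 + np.where(odd, hill_act, hill_rep) - x[1:]
    return dx


def _euler_maruyama(x0, q, a, rng, *, n_steps, dt, noise_sd):
    x = np.array(x0, dtype=float)
    sqdt = np.sqrt(dt)
    for _ in range(n_steps):
        x = x + _drift(x, q, a) * dt
        if noise_sd > 0:
            x = x + noise_sd * sqdt * rng.standard_normal(x.size)
        np.maximum(x, 0.0, out=x)  # concentrations stay non-negative
        if not np.all(np.isfinite(x)) or np.any(x > 1e6):
            raise RuntimeError(
                "SDE integration blew up; reduce dt or noise_sd")
    return x


def simulate_network_study(config: SimulationConfig, *, dt: float = 0.01,
                           burn_in: int = 1000,
                           q_min: float = -0.4,
                           q_max: float = 0.2) -> SimulatedStudy:
    """Quasi-static sweep of a stochastic regulatory network through a fold.

    ``config.n_genes`` nodes (at least 6) form a cascade headed by a
    bistable self-activating node whose low steady state disappears in a
    saddle-node bifurcation exactly at q = 0. The control parameter is
    swept over ``n_timepoints`` values from ``q_min`` to ``q_max`` with
    q = 0 at ``config.transition_index``; at each q the system is
    relaxed for ``burn_in`` Euler-Maruyama steps from its previous state
    and the final state is recorded as that time point's single sample.
    The normal pool is sampled at ``q_min`` with decorrelation gaps.
    Approaching q = 0 from below the core node's restoring force
    vanishes, so its variance and displacement grow — critical slowing
    down, the signal the scoring statistic is built to amplify.
    """
    if config.n_genes < 6:
        raise ValueError("network mode needs at least 6 nodes")
    if dt <= 0 or burn_in < 1:
        raise ValueError("dt must be > 0 and burn_in >= 1")
    if dt >= 2.0:
        # unit degradation makes the explicit step unstable for dt >= 2
        raise ValueError(f"dt={dt} is unstable for this system; reduce dt")
    a, x_star = _fold_constants()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"n{i:02d}" for i in range(n)]
    qs = _q_grid(config.n_timepoints, config.transition_index, q_min, q_max)

    # equilibrate on the low branch at q_min
    x = np.full(n, 0.2)
    x = _euler_maruyama(x, qs[0], a, rng, n_steps=2 * burn_in, dt=dt,
                        noise_sd=config.noise_sd)

    normal = np.empty((n, config.n_normal_samples))
    for j in range(config.n_normal_samples):
        x = _euler_maruyama(x, qs[0], a, rng, n_steps=max(burn_in // 5, 1),
                            dt=dt, noise_sd=config.noise_sd)
        normal[:, j] = x

    course = np.empty((n, config.n_timepoints))
    for t, q in enumerate(qs):
        x = _euler_maruyama(x, q, a, rng, n_steps=burn_in, dt=dt,
                            noise_sd=config.noise_sd)
        course[:, t] = x

    # the bifurcating subsystem: the core node and its first two targets
    dnb_ids = frozenset(genes[:3])
    return SimulatedStudy(
        normal_matrix=ExpressionMatrix(
            normal, gene_ids=genes,
            sample_ids=[f"normal{j:02d}" for j in range(config.n_normal_samples)]),
        course=ExpressionMatrix(course, gene_ids=genes,
                                sample_ids=_time_labels(config.n_timepoints)),
        truth_transition_index=int(np.flatnonzero(qs >= 0)[0]),
        dnb_gene_ids=dnb_ids,
        config=config,
        q_values=tuple(float(q) for q in qs),
    )
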