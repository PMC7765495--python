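"""Synthetic inhibitor time-course RNA-seq experiments with known ground truth.

Emulates the study design downstream stages expect: a treated arm in
triplicate at 3/6/9 h, time-matched DMSO solvent controls, untreated anchor
samples at 0 h and 9 h, negative-binomial counts with gene-wise dispersion,
and treatment effects that follow impulse-shaped (transient) or monotone
trajectories on the fold-change scale.

Baseline transcript abundances are lognormal and normalized to relative
abundance, so the configured library size sets the expected depth per
sample; per-sample library sizes are jittered lognormally (10% CV by
default) to exercise normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .impulse import evaluate_impulse
from .preprocess import CountMatrix, SampleSheet

__all__ = [
    "SimConfig",
    "sample_nb_counts",
    "simulate_experiment",
    "simulate_dual_experiment",
    "simulate_edge_table",
]

_SHAPES = ("up", "down", "transient")


@dataclass
class SimConfig:
    """Parameters of one synthetic inhibitor experiment.

    Defaults follow the emulated design: triplicates, timepoints 0/3/6/9 h,
    ~1e6 expected counts per library (a scaled-down depth convenient for
    testing), lognormal baselines, lognormal dispersions centered near 0.05
    (a typical bulk RNA-seq tagwise value), and true effect sizes expressed
    as the maximum |log2 fold change| attained at an observed timepoint.
    """

    n_genes: int = 2000
    frac_de: float = 0.1
    timepoints_h: tuple[int, ...] = (0, 3, 6, 9)
    n_reps: int = 3
    lib_size: float = 1e6
    #: (mu, sigma) of the natural-log baseline abundance weight
    log_mean_baseline: tuple[float, float] = (2.0, 1.5)
    #: ("lognormal", mu_of_log, sigma_of_log) or ("fixed", value)
    dispersion_dist: tuple = ("lognormal", math.log(0.05), 0.3)
    #: ("uniform", lo, hi) or ("fixed", value) for true max |LFC| of DE genes
    effect_lfc_dist: tuple = ("uniform", 0.5, 3.0)
    #: mixture over monotone-up / monotone-down / transient trajectories
    trajectory_mix: dict = field(default_factory=lambda: {"up": 0.4, "down": 0.4, "transient": 0.2})
    #: lognormal sd of per-sample library-size jitter
    lib_size_cv: float = 0.1
    #: optional log2 shift applied to the DMSO arm (solvent effect); 0 = none
    solvent_shift: float = 0.0
    treatment_label: str = "SB"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_de <= 1.0):
            raise ValueError(f"frac_de must be in [0,1], got {self.frac_de}")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if self.lib_size <= 0:
            raise ValueError("lib_size must be > 0")
        self.timepoints_h = tuple(sorted(int(t) for t in self.timepoints_h))
        for pair in (self.log_mean_baseline,):
            if not all(np.isfinite(pair)):
                raise ValueError("non-finite distribution parameters")
        for dist in (self.dispersion_dist, self.effect_lfc_dist):
            if not all(np.isfinite(v) for v in dist[1:]):
                raise ValueError("non-finite distribution parameters")
        tot = sum(self.trajectory_mix.get(k, 0.0) for k in _SHAPES)
        if not math.isclose(tot, 1.0, rel_tol=1e-6):
            raise ValueError("trajectory_mix fractions must sum to 1")


def _draw(dist: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "fixed":
        return np.full(size, float(dist[1]))
    if kind == "lognormal":
        return rng.lognormal(dist[1], dist[2], size)
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size)
    raise ValueError(f"unknown distribution kind {kind!r}")


def sample_nb_counts(mean, dispersion, size: int | None = None, rng=None) -> np.ndarray:
    """Negative-binomial counts with Var = mean + dispersion·mean².

    ``dispersion`` = 0 degenerates to Poisson. ``rng`` may be a Generator or
    an integer seed.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mean = np.asarray(mean, dtype=float)
    phi = np.asarray(dispersion, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("mean must be > 0")
    if np.any(phi < 0):
        raise ValueError("dispersion must be >= 0")
    if size is not None:
        mean = np.broadcast_to(mean, (size,) if np.ndim(mean) == 0 else mean.shape)
        phi = np.broadcast_to(phi, mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = phi < 1e-12
    out[pois] = rng.poisson(mean[pois])
    if np.any(~pois):
        r = 1.0 / phi[~pois]
        p = r / (r + mean[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def _draw_trajectory(shape: str, effect: float, sign: float, obs_times: np.ndarray,
                     rng: np.random.Generator) -> tuple[dict, np.ndarray]:
    """Impulse parameters on the fold-change scale, scaled so that
    max |log2 fc| over the observed nonzero timepoints equals ``effect``."""
    beta = rng.uniform(0.5, 2.0)
    if shape == "up":
        params = dict(h0=1.0, h1=2.0, h2=2.0, t1=rng.uniform(1.0, 6.0), t2=30.0, beta=beta)
    elif shape == "down":
        params = dict(h0=1.0, h1=0.5, h2=0.5, t1=rng.uniform(1.0, 6.0), t2=30.0, beta=beta)
    else:  # transient: returns toward baseline inside the window
        peak = 2.0 if sign > 0 else 0.5
        params = dict(h0=1.0, h1=peak, h2=1.0, t1=rng.uniform(1.0, 4.0), t2=rng.uniform(5.0, 8.0), beta=beta)
    raw = np.log2(evaluate_impulse(params, obs_times))
    scale = effect / np.max(np.abs(raw))
    lfc = raw * scale
    # exponent scaling keeps the curve in the impulse family on the log scale
    params = dict(params, _log2_scale=scale)
    return params, lfc


def _simulate_arms(cfg: SimConfig, rng: np.random.Generator, arms: Sequence[str],
                   de_masks: dict[str, np.ndarray]):
    """Shared engine: given DE masks per treated arm, draw trajectories and counts."""
    n = cfg.n_genes
    genes = [f"g{i:05d}" for i in range(n)]
    obs = np.array([t for t in cfg.timepoints_h if t != 0], dtype=float)

    weights = rng.lognormal(cfg.log_mean_baseline[0], cfg.log_mean_baseline[1], n)
    base_cpm = weights / weights.sum() * 1e6
    phi = _draw(cfg.dispersion_dist, n, rng)

    truth_rows = []
    fc = {}  # (arm) -> genes x obs fold-change matrix
    for arm in arms:
        mask = de_masks[arm]
        shapes = rng.choice(_SHAPES, size=n, p=[cfg.trajectory_mix.get(k, 0.0) for k in _SHAPES])
        effects = _draw(cfg.effect_lfc_dist, n, rng)
        signs = rng.choice([-1.0, 1.0], size=n)
        mat = np.zeros((n, obs.size))
        for i in range(n):
            if not mask[i]:
                truth_rows.append(dict(gene_id=genes[i], arm=arm, is_de=False, shape="flat",
                                       true_max_lfc=0.0,
                                       **{f"true_lfc_{int(t)}h": 0.0 for t in obs}))
                continue
            params, lfc = _draw_trajectory(shapes[i], effects[i], signs[i], obs, rng)
            mat[i] = lfc
            truth_rows.append(dict(gene_id=genes[i], arm=arm, is_de=True, shape=shapes[i],
                                   true_max_lfc=float(np.max(np.abs(lfc))),
                                   **{f"true_lfc_{int(t)}h": float(v) for t, v in zip(obs, lfc)}))
        fc[arm] = 2.0 ** mat

    # sample layout
    layout = []  # (sample_id, treatment, timepoint, replicate)
    for arm in arms:
        for t in obs.astype(int):
            for r in range(1, cfg.n_reps + 1):
                layout.append((f"{arm}_{t}h_r{r}", arm, int(t), r))
    for t in obs.astype(int):
        for r in range(1, cfg.n_reps + 1):
            layout.append((f"DMSO_{t}h_r{r}", "DMSO", int(t), r))
    anchor_times = [t for t in (0, max(cfg.timepoints_h)) if t in cfg.timepoints_h]
    for t in anchor_times:
        for r in range(1, cfg.n_reps + 1):
            layout.append((f"untreated_{t}h_r{r}", "untreated", int(t), r))

    cols = {}
    for sid, trt, t, r in layout:
        lib = cfg.lib_size * rng.lognormal(0.0, cfg.lib_size_cv)
        mu = base_cpm * lib / 1e6
        if trt in arms and t != 0:
            j = int(np.where(obs == t)[0][0])
            mu = mu * fc[trt][:, j]
        elif trt == "DMSO" and cfg.solvent_shift != 0.0:
            mu = mu * 2.0 ** cfg.solvent_shift
        cols[sid] = sample_nb_counts(np.maximum(mu, 1e-8), phi, rng=rng)

    counts = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    sheet = SampleSheet(pd.DataFrame(layout, columns=["sample", "treatment", "timepoint_h", "replicate"]))
    truth = pd.DataFrame(truth_rows)
    return CountMatrix(counts), sheet, truth


def _de_mask(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n_de = int(round(cfg.frac_de * cfg.n_genes))
    mask = np.zeros(cfg.n_genes, dtype=bool)
    mask[rng.choice(cfg.n_genes, size=n_de, replace=False)] = True
    return mask


def simulate_experiment(config: SimConfig, seed: int | None = None):
    """Simulate one inhibitor experiment.

    Returns ``(CountMatrix, SampleSheet, truth)`` where ``truth`` is a
    DataFrame with one row per gene (columns: gene_id, arm, is_de, shape,
    true_max_lfc, true_lfc_<t>h). Identical (config, seed) gives identical
    output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    arm = config.treatment_label
    return _simulate_arms(config, rng, [arm], {arm: _de_mask(config, rng)})


def simulate_dual_experiment(config: SimConfig, seed: int | None = None,
                             shared_de_frac: float = 0.25):
    """Simulate two inhibitor arms (SB and SU) over a shared baseline and a
    shared DMSO control arm, with a controllable overlap between the two DE
    gene sets (trajectories and signs drawn independently per arm, so common
    targets split into concordantly and discordantly regulated genes)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_genes
    n_de = int(round(config.frac_de * n))
    n_shared = int(round(shared_de_frac * n_de))
    order = rng.permutation(n)
    shared = order[:n_shared]
    only_a = order[n_shared:n_de]
    only_b = order[n_de:2 * n_de - n_shared]
    mask_a = np.zeros(n, bool); mask_a[shared] = True; mask_a[only_a] = True
    mask_b = np.zeros(n, bool); mask_b[shared] = True; mask_b[only_b] = True
    return _simulate_arms(config, rng, ["SB", "SU"], {"SB": mask_a, "SU": mask_b})


def simulate_edge_table(gene_ids: Sequence[str], n_edges: int, rng=None,
                        score_range: tuple[int, int] = (150, 999)) -> pd.DataFrame:
    """Random undirected interaction edges in STRING export dialect
    (columns node1, node2, combined_score in 0–1000)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    genes = list(gene_ids)
    seen = set()
    rows = []
    attempts = 0
    while len(rows) < n_edges and attempts < 50 * n_edges:
        attempts += 1
        i, j = rng.choice(len(genes), size=2, replace=False)
        a, b = sorted((genes[i], genes[j]))
        if (a, b) in seen:
            continue
        seen.add((a, b))
        rows.append((a, b, int(rng.integers(score_range[0], score_range[1] + 1))))
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
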