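"""Budget-constrained screening loop.

The screen walks the pipeline: cluster the embedding space and draw a
seed sample spread across clusters, evaluate the expensive property oracles
on it, then iterate — fit one exact GP per objective on everything
evaluated so far, compute each objective's expected improvement over the
unevaluated pool, combine them by product, evaluate the top-scoring batch —
until the oracle-call budget (a fixed fraction of the library, 6% by
default) is spent. The budget counts every successful oracle evaluation,
seed sample included.

All randomness flows from a single master seed through a documented split
(clustering, per-cluster sampling), so runs are exactly reproducible and a
checkpointed run resumes bit-identically.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .acquisition import score_candidates, select_batch
from .library_io import ScreeningLibrary
from .surrogate import GPModel, fit_gp, predict
from .transforms import TransformSpec, apply_transform

logger = logging.getLogger("moscreen")

CHECKPOINT_SCHEMA_VERSION = 1

#: an oracle maps an array of molecule indices to raw property values;
#: NaN marks a failed evaluation (molecule excluded, budget not charged)
Oracle = Callable[[np.ndarray], np.ndarray]


class PrecomputedOracle:
    """Oracle backed by a full per-molecule value vector (table mode)."""

    def __init__(self, values: np.ndarray):
        self.values = np.asarray(values, dtype=float)

    def __call__(self, indices: np.ndarray) -> np.ndarray:
        return self.values[np.asarray(indices, dtype=int)]


@dataclass(frozen=True)
class ObjectiveSpec:
    """One property to screen for: oracle, transform, desirability rule.

    ``desirable_range`` is an inclusive (low, high) interval on the raw
    property scale used only for reporting (e.g. binding affinity below -8
    kcal/mol is (-inf, -8)); the optimizer itself sees only the transformed
    score.
    """

    name: str
    oracle: Oracle
    transform: TransformSpec
    desirable_range: tuple[float, float] | None = None


@dataclass(frozen=True)
class ScreenConfig:
    """Run parameters for one screen; every field has a usable default."""

    budget_fraction: float = 0.06
    init_fraction_of_budget: float = 0.25
    n_clusters: int = 20
    batch_size: int | None = None  # None: (budget - seed) / 20 iterations
    seed: int = 0
    kernel_family: str = "rbf"
    zeta: float = 0.01
    log_space: bool = True
    gp_max_iter: int = 200
    pool_chunk: int | None = None
    checkpoint_path: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.budget_fraction <= 1:
            raise ValueError("budget_fraction must be in (0, 1]")
        if not 0 < self.init_fraction_of_budget <= 1:
            raise ValueError("init_fraction_of_budget must be in (0, 1]")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class BOState:
    """Mutable loop state: evaluated set, observations, remaining budget."""

    budget_total: int
    evaluated: list[int] = field(default_factory=list)
    iteration_acquired: list[int] = field(default_factory=list)
    raw: dict[str, list[float]] = field(default_factory=dict)
    transformed: dict[str, list[float]] = field(default_factory=dict)
    failures: set[int] = field(default_factory=set)
    iteration: int = 0

    @property
    def budget_remaining(self) -> int:
        return self.budget_total - len(self.evaluated)

    def f_star(self, name: str) -> float:
        return max(self.transformed[name])


@dataclass(frozen=True)
class ScreenResult:
    """Everything a screen produced, in acquisition order."""

    evaluated_indices: np.ndarray
    iteration_acquired: np.ndarray
    observations: dict[str, dict[str, np.ndarray]]  # name -> raw/transformed
    trace: list[dict]
    budget_total: int
    n: int
    config: ScreenConfig

    def write_csv(self, path: str | os.PathLike,
                  library: ScreeningLibrary) -> None:
        import pandas as pd

        data: dict[str, list] = {
            "id": [library.records[i].id for i in self.evaluated_indices],
            "rank": list(range(len(self.evaluated_indices))),
            "iteration": list(self.iteration_acquired),
        }
        for name, obs in self.observations.items():
            data[f"{name}_raw"] = list(obs["raw"])
            data[f"{name}_transformed"] = list(obs["transformed"])
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def _allocate_proportional(sizes: np.ndarray, n_init: int) -> np.ndarray:
    """Largest-remainder allocation of ``n_init`` draws across clusters.

    Proportional to cluster size; every nonempty cluster gets at least one
    draw when the budget allows; allocations never exceed cluster size.
    """
    sizes = np.asarray(sizes, dtype=int)
    total = int(sizes.sum())
    if n_init > total:
        raise ValueError("n_init exceeds library size")
    nonempty = np.nonzero(sizes > 0)[0]
    alloc = np.zeros_like(sizes)
    if n_init < nonempty.size:
        # too few draws to cover every cluster: favour the largest
        order = nonempty[np.argsort(-sizes[nonempty], kind="stable")]
        alloc[order[:n_init]] = 1
        return alloc
    alloc[nonempty] = 1
    remaining = n_init - nonempty.size
    while remaining > 0:
        room = sizes - alloc
        quota = remaining * sizes / total
        quota[room <= 0] = 0
        base = np.minimum(np.floor(quota).astype(int), room)
        if base.sum() == 0:
            # hand out singly by largest fractional remainder
            frac = np.where(room > 0, quota - np.floor(quota), -1.0)
            order = np.argsort(-frac, kind="stable")
            for idx in order[:remaining]:
                if room[idx] > 0:
                    alloc[idx] += 1
                    remaining -= 1
                if remaining == 0:
                    break
            continue
        take = np.minimum(base, room)
        alloc += take
        remaining -= int(take.sum())
    return alloc


def cluster_initialize(library: ScreeningLibrary, n_clusters: int,
                       n_init: int, seed: int) -> np.ndarray:
    """Seed sample spread over a k-means partition of the embedding space.

    Draws are allocated to clusters proportionally to cluster size (each
    nonempty cluster gets at least one when the budget allows) and taken
    uniformly without replacement within each cluster. Deterministic given
    ``seed``.
    """
    if n_init > len(library):
        raise ValueError("n_init exceeds library size")
    if n_init == len(library):
        return np.arange(len(library))
    emb = library.embeddings
    if emb is None:
        raise ValueError("library has no embeddings to cluster")
    ss = np.random.SeedSequence(seed)
    km_seed, draw_seed = (int(s) & 0x7FFFFFFF for s in ss.generate_state(2))
    n_clusters = min(n_clusters, len(library))
    if n_clusters == 1:
        labels = np.zeros(len(library), dtype=int)
    else:
        km = KMeans(n_clusters=n_clusters, random_state=km_seed, n_init=10)
        labels = km.fit_predict(emb)
    sizes = np.bincount(labels, minlength=n_clusters)
    alloc = _allocate_proportional(sizes, n_init)
    rng = np.random.default_rng(draw_seed)
    chosen: list[np.ndarray] = []
    for c in range(n_clusters):
        if alloc[c] == 0:
            continue
        members = np.nonzero(labels == c)[0]
        chosen.append(rng.choice(members, size=int(alloc[c]), replace=False))
    out = np.concatenate(chosen)
    return np.sort(out)


def _evaluate(state: BOState, objectives: Sequence[ObjectiveSpec],
              indices: np.ndarray) -> None:
    """Call every oracle on ``indices``; record successes, flag failures."""
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        return
    raw_cols = {}
    ok = np.ones(indices.size, dtype=bool)
    for spec in objectives:
        vals = np.asarray(spec.oracle(indices), dtype=float)
        raw_cols[spec.name] = vals
        ok &= np.isfinite(vals)
    n_fail = int((~ok).sum())
    if n_fail:
        state.failures.update(int(i) for i in indices[~ok])
        logger.warning("iteration %d: %d oracle failures (not charged)",
                       state.iteration, n_fail)
    for spec in objectives:
        good = raw_cols[spec.name][ok]
        state.raw[spec.name].extend(float(v) for v in good)
        state.transformed[spec.name].extend(
            float(v) for v in apply_transform(spec.transform, good))
    state.evaluated.extend(int(i) for i in indices[ok])
    state.iteration_acquired.extend([state.iteration] * int(ok.sum()))


def save_checkpoint(path: str | os.PathLike, state: BOState,
                    seed: int) -> None:
    payload = {
        "schema_version": CHECKPOINT_SCHEMA_VERSION,
        "seed": seed,
        "budget_total": state.budget_total,
        "iteration": state.iteration,
        "evaluated": state.evaluated,
        "iteration_acquired": state.iteration_acquired,
        "failures": sorted(state.failures),
        "raw": state.raw,
        "transformed": state.transformed,
    }
    tmp = f"{os.fspath(path)}.tmp"
    with open(tmp, "w") as fh:
        json.dump(payload, fh)
    os.replace(tmp, path)


def load_checkpoint(path: str | os.PathLike, expected_seed: int) -> BOState:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != CHECKPOINT_SCHEMA_VERSION:
        raise ValueError("unsupported checkpoint schema version")
    if payload["seed"] != expected_seed:
        raise ValueError(
            f"checkpoint seed {payload['seed']} != configured seed "
            f"{expected_seed}"
        )
    return BOState(
        budget_total=payload["budget_total"],
        evaluated=list(payload["evaluated"]),
        iteration_acquired=list(payload["iteration_acquired"]),
        raw={k: list(v) for k, v in payload["raw"].items()},
        transformed={k: list(v) for k, v in payload["transformed"].items()},
        failures=set(payload["failures"]),
        iteration=payload["iteration"],
    )


def run_screen(library: ScreeningLibrary, config: ScreenConfig,
               objectives: Sequence[ObjectiveSpec],
               resume_from: str | os.PathLike | None = None) -> ScreenResult:
    """Run the full screen and return the evaluated set with its trace.

    Stops exactly when the budget ``ceil(budget_fraction * n)`` is spent
    (the final batch is truncated to fit); no molecule's oracle is ever
    called twice. Fully reproducible given ``config.seed``; passing
    ``resume_from`` continues an interrupted run bit-identically because
    the only random draw (the seed sample) is already in the checkpoint.
    """
    if library.embeddings is None:
        raise ValueError("library has no embeddings")
    if not objectives:
        raise ValueError("at least one objective required")
    n = len(library)
    budget_total = math.ceil(config.budget_fraction * n)
    if budget_total < len(objectives) + 2:
        raise ValueError(
            f"budget {budget_total} too small to fit {len(objectives)} GPs"
        )

    n_init = min(budget_total, max(2, round(config.init_fraction_of_budget
                                            * budget_total)))
    batch_size = config.batch_size or max(
        1, round((budget_total - n_init) / 20))

    if resume_from is not None:
        state = load_checkpoint(resume_from, config.seed)
        logger.info("resumed at iteration %d with %d evaluated",
                    state.iteration, len(state.evaluated))
    else:
        state = BOState(budget_total=budget_total,
                        raw={o.name: [] for o in objectives},
                        transformed={o.name: [] for o in objectives})
        seed_idx = cluster_initialize(library,
                                      min(config.n_clusters, n_init),
                                      n_init, config.seed)
        _evaluate(state, objectives, seed_idx)
        state.iteration = 1
        if config.checkpoint_path:
            save_checkpoint(config.checkpoint_path, state, config.seed)

    trace: list[dict] = []
    unavailable = np.zeros(n, dtype=bool)
    unavailable[list(state.failures)] = True

    while state.budget_remaining > 0:
        mask = np.ones(n, dtype=bool)
        mask[state.evaluated] = False
        mask &= ~unavailable
        if not mask.any():
            logger.warning("candidate pool exhausted before budget")
            break
        train_x = library.embeddings[state.evaluated]
        models: dict[str, GPModel] = {}
        means = np.empty((n, len(objectives)))
        stdevs = np.empty((n, len(objectives)))
        zetas = np.empty(len(objectives))
        for j, spec in enumerate(objectives):
            model = fit_gp(train_x, np.asarray(state.transformed[spec.name]),
                           kernel_family=config.kernel_family,
                           seed=config.seed, max_iter=config.gp_max_iter)
            post = predict(model, library.embeddings,
                           chunk_size=config.pool_chunk)
            means[:, j] = post.mean
            stdevs[:, j] = np.sqrt(post.variance)
            # zeta lives on the standardized scale; rescale per objective
            zetas[j] = config.zeta * model.y_scale
            models[spec.name] = model
        incumbents = np.array([state.f_star(o.name) for o in objectives])
        scores = score_candidates(means, stdevs, incumbents, zetas,
                                  config.log_space)
        take = min(batch_size, state.budget_remaining)
        # rank on the log product: same ordering, immune to underflow
        batch = select_batch(scores.log_combined, mask, take)
        trace.append({
            "iteration": state.iteration,
            "batch": [int(i) for i in batch],
            "f_star": {o.name: float(f)
                       for o, f in zip(objectives, incumbents)},
            "hyperparameters": {
                name: {"lengthscale": m.kernel.lengthscale,
                       "signal_variance": m.kernel.signal_variance,
                       "noise_variance": m.kernel.noise_variance}
                for name, m in models.items()},
            "acq_max": float(scores.combined[mask].max()),
            "acq_log_max": float(scores.log_combined[mask].max()),
        })
        logger.info("iteration %d: batch of %d, best log-acq %.3g",
                    state.iteration, len(batch), trace[-1]["acq_log_max"])
        _evaluate(state, objectives, batch)
        unavailable[list(state.failures)] = True
        state.iteration += 1
        if config.checkpoint_path:
            save_checkpoint(config.checkpoint_path, state, config.seed)
        if batch.size == 0:
            break

    return ScreenResult(
        evaluated_indices=np.asarray(state.evaluated, dtype=int),
        iteration_acquired=np.asarray(state.iteration_acquired, dtype=int),
        observations={
            o.name: {"raw": np.asarray(state.raw[o.name]),
                     "transformed": np.asarray(state.transformed[o.name])}
            for o in objectives},
        trace=trace,
        budget_total=budget_total,
        n=n,
        config=config,
    )
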