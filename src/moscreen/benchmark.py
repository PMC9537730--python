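"""Synthetic screening libraries with known ground truth.

The generator emulates the statistical shape of a docking-based screen
without any chemistry: embeddings are drawn from a mixture of Gaussian
blobs (so clustering the descriptor space is meaningful), and each raw
objective is a smooth random function of the embedding — a random
Fourier-feature (RFF) expansion with a chosen lengthscale, which lies in
the RBF function class the GP surrogate assumes — affinely rescaled into a
realistic value range and observed with independent Gaussian noise. The
default three objectives mimic a binding-affinity-like score (-12..-4,
lower is better), a LogP-like partition coefficient (-2..7, best near 2.5)
and a synthetic-accessibility-like score (1..6, lower is better).

Ground-truth desirability uses quantile-calibrated analogues of the
absolute rules used for real screens (affinity below a cutoff, LogP inside
a band around 2.5, SAS below a cutoff): a single quantile parameter is
bisected until the jointly-desirable set is a controlled 1-3% of the
library, so recovery statistics are comparable across seeds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .engine import ObjectiveSpec, PrecomputedOracle
from .library_io import ScreeningLibrary, library_from_arrays
from .transforms import TransformSpec

logger = logging.getLogger("moscreen")

#: default per-objective raw value ranges (low, high)
DEFAULT_RANGES = {
    "affinity": (-12.0, -4.0),
    "logp": (-2.0, 7.0),
    "sas": (1.0, 6.0),
}
_OBJECTIVE_ORDER = ("affinity", "logp", "sas")

#: number of random Fourier features per latent objective function
_N_FEATURES = 256


@dataclass(frozen=True)
class SyntheticLibrarySpec:
    """Knobs of the generator; defaults define the standard benchmark.

    ``smoothness`` is the RFF lengthscale per objective in embedding units
    (embeddings spread over a region of radius ~6, so the default 4.0 gives
    functions that vary over a handful of large-scale regions — smooth
    enough for a GP to learn from a few hundred points, structured enough
    that the desirable set is localized but not a single blob).
    ``noise_sd`` defaults to ~2% of each objective's span, the order of
    run-to-run scatter of a deterministic-but-seeded docking pipeline.
    """

    n_molecules: int = 5000
    d: int = 32
    n_objectives: int = 3
    smoothness: tuple[float, ...] = (100.0, 100.0, 100.0)
    noise_sd: tuple[float, ...] = (0.15, 0.18, 0.1)
    value_ranges: tuple[tuple[float, float], ...] = tuple(
        DEFAULT_RANGES[k] for k in _OBJECTIVE_ORDER)
    n_blobs: int = 20
    desirable_target: float = 0.0105  # aim of the joint-desirability calibration
    desirable_band: tuple[float, float] = (0.01, 0.03)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_molecules < 100:
            raise ValueError("n_molecules must be >= 100")
        if self.d < 2:
            raise ValueError("embedding dimension must be >= 2")
        if self.n_objectives not in (2, 3):
            raise ValueError("n_objectives must be 2 or 3")
        if any(s <= 0 for s in self.smoothness[: self.n_objectives]):
            raise ValueError("smoothness must be > 0")
        if any(s < 0 for s in self.noise_sd[: self.n_objectives]):
            raise ValueError("noise_sd must be >= 0")

    @property
    def objective_names(self) -> tuple[str, ...]:
        return _OBJECTIVE_ORDER[: self.n_objectives]


@dataclass(frozen=True)
class SyntheticBenchmark:
    """A generated library, its oracles, and the ground truth behind them."""

    library: ScreeningLibrary
    objectives: tuple[ObjectiveSpec, ...]
    desirable: np.ndarray  # sorted indices passing all desirability rules
    values: dict[str, np.ndarray] = field(default_factory=dict)
    thresholds: dict[str, tuple[float, float]] = field(default_factory=dict)
    spec: SyntheticLibrarySpec | None = None


def _rff_function(rng: np.random.Generator, x: np.ndarray,
                  lengthscale: float) -> np.ndarray:
    """Smooth random function of ``x``: cos features with RBF spectrum."""
    d = x.shape[1]
    w = rng.normal(size=(_N_FEATURES, d)) / lengthscale
    b = rng.uniform(0.0, 2.0 * math.pi, size=_N_FEATURES)
    theta = rng.normal(size=_N_FEATURES)
    return math.sqrt(2.0 / _N_FEATURES) * np.cos(x @ w.T + b) @ theta


def _rescale(values: np.ndarray, low: float, high: float) -> np.ndarray:
    vmin, vmax = values.min(), values.max()
    return low + (values - vmin) * (high - low) / (vmax - vmin)


def _shape_marginal(name: str, latent: np.ndarray) -> np.ndarray:
    """Monotone marginal shaping so each property's distribution looks like
    its real-world counterpart rather than the raw near-Gaussian latent.

    LogP: screening libraries are assembled under drug-likeness filters, so
    the LogP bulk is concentrated well inside the drug-like window with
    thin tails reaching the range ends; a signed-power stretch of the tails
    (bulk compressed toward the center after rescaling) reproduces that.
    Affinity / SAS: both saturate at their favorable end (binding free
    energy bottoms out; easily-made molecules bunch at the easy end of the
    scale), so the favorable tail is mildly compressed. Monotone maps keep
    the functions smooth and GP-learnable.
    """
    z = latent / latent.std()
    if name == "logp":
        return np.sign(z) * np.abs(z) ** 1.5
    return np.where(z < 0, -np.abs(z) ** 0.85, z)


#: absolute desirability rules on the raw scales: strong binding, drug-like
#: LogP window, easily synthesizable
ABSOLUTE_RULES = {
    "affinity": (-np.inf, -8.0),
    "logp": (0.0, 5.0),
    "sas": (-np.inf, 2.0),
}

#: base pass fractions of the quantile-analogue rules: binding affinity is
#: moderately selective, SAS selective, and together with the broad LogP
#: window the joint fraction is ~2% when the objectives are independent
BASE_QUANTILES = {"affinity": 0.20, "sas": 0.15}


def desirable_set(values: dict[str, np.ndarray],
                  rules: dict[str, tuple[float, float]]) -> np.ndarray:
    """Indices passing every per-objective rule (inclusive intervals)."""
    n = len(next(iter(values.values())))
    keep = np.ones(n, dtype=bool)
    for name, (low, high) in rules.items():
        keep &= (values[name] >= low) & (values[name] <= high)
    return np.nonzero(keep)[0]


def _rules_at(values: dict[str, np.ndarray], gamma: float
              ) -> dict[str, tuple[float, float]]:
    """Quantile-analogue rules with pass fractions scaled by ``gamma``.

    The LogP band is held at its absolute analogue; the "lower is better"
    cutoffs sit at their base quantiles scaled by a common factor, so the
    rules keep the shape of the real screen's (a broad LogP feasibility
    window, selectivity driven by the scored objectives) with the same
    relative stringency on every generated library.
    """
    rules: dict[str, tuple[float, float]] = {}
    for name in values:
        if name == "logp":
            rules[name] = ABSOLUTE_RULES["logp"]
        else:
            q = min(max(BASE_QUANTILES[name] * gamma, 1e-4), 1.0)
            rules[name] = (-np.inf, float(np.quantile(values[name], q)))
    return rules


def _calibrate_thresholds(values: dict[str, np.ndarray],
                          target: float, band: tuple[float, float]
                          ) -> dict[str, tuple[float, float]]:
    """Scale the quantile-analogue cutoffs by a single shared factor until
    the joint-desirable fraction lands in ``band`` (bisected toward
    ``target``)."""
    n = len(next(iter(values.values())))

    def joint_fraction(gamma: float) -> float:
        return desirable_set(values, _rules_at(values, gamma)).size / n

    lo, hi = 1e-3, 1.0 / max(BASE_QUANTILES.values())
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if joint_fraction(mid) < target:
            lo = mid
        else:
            hi = mid
    gamma = 0.5 * (lo + hi)
    frac = joint_fraction(gamma)
    if not band[0] <= frac <= band[1]:
        raise RuntimeError(
            f"desirability calibration failed: joint fraction {frac:.4f} "
            f"outside [{band[0]}, {band[1]}]"
        )
    return _rules_at(values, gamma)


def default_transforms() -> dict[str, TransformSpec]:
    """Affinity and SAS negated; LogP through the unit-width bell at 2.5."""
    return {
        "affinity": TransformSpec("negate"),
        "logp": TransformSpec("gaussian_peak", center=2.5, width=1.0),
        "sas": TransformSpec("negate"),
    }


def generate_library(spec: SyntheticLibrarySpec) -> SyntheticBenchmark:
    """Generate a benchmark library, oracles and ground truth, deterministically.

    Embeddings come from ``n_blobs`` Gaussian blobs; each objective is an
    RFF function of the embedding rescaled into its value range plus noise.
    The returned desirable set is exactly the set of indices passing all
    calibrated per-objective rules on the (noisy) oracle values.
    """
    # independent child streams: embeddings, one per latent function, one
    # per noise draw — so e.g. changing noise_sd never changes the latents
    ss = np.random.SeedSequence(spec.seed)
    emb_ss, *obj_ss = ss.spawn(1 + 2 * spec.n_objectives)
    rng = np.random.default_rng(emb_ss)
    n, d = spec.n_molecules, spec.d
    centers = rng.normal(scale=3.0, size=(spec.n_blobs, d))
    weights = rng.dirichlet(np.full(spec.n_blobs, 5.0))
    assignment = rng.choice(spec.n_blobs, size=n, p=weights)
    emb = centers[assignment] + rng.normal(size=(n, d))

    values: dict[str, np.ndarray] = {}
    latents: list[np.ndarray] = []
    for j, name in enumerate(spec.objective_names):
        latent_rng = np.random.default_rng(obj_ss[2 * j])
        latent = _rff_function(latent_rng, emb, spec.smoothness[j])
        # residualize against earlier objectives: very smooth functions on a
        # clustered library are close to low-rank, so independent draws can
        # come out strongly correlated by chance; orthogonalizing keeps the
        # objectives genuinely non-redundant (a real trade-off) every seed
        latent = latent - latent.mean()
        for prev in latents:
            latent = latent - (latent @ prev) / (prev @ prev) * prev
        latents.append(latent)
        latent = _shape_marginal(name, latent)
        low, high = spec.value_ranges[j]
        raw = _rescale(latent, low, high)
        if spec.noise_sd[j] > 0:
            noise_rng = np.random.default_rng(obj_ss[2 * j + 1])
            raw = raw + noise_rng.normal(scale=spec.noise_sd[j], size=n)
        values[name] = raw

    thresholds = _calibrate_thresholds(values, spec.desirable_target,
                                       spec.desirable_band)
    desirable = desirable_set(values, thresholds)
    logger.info("benchmark seed %d: %d/%d desirable (%.2f%%)",
                spec.seed, desirable.size, n, 100.0 * desirable.size / n)

    ids = [f"syn{idx:06d}" for idx in range(n)]
    library = library_from_arrays(ids, emb, embedding_name="synthetic")
    transforms = default_transforms()
    objectives = tuple(
        ObjectiveSpec(name=name,
                      oracle=PrecomputedOracle(values[name]),
                      transform=transforms[name],
                      desirable_range=thresholds[name])
        for name in spec.objective_names
    )
    return SyntheticBenchmark(library=library, objectives=objectives,
                              desirable=desirable, values=dict(values),
                              thresholds=dict(thresholds), spec=spec)


def smoothness_check(library: ScreeningLibrary, oracle_values: np.ndarray,
                     probe_pairs: int = 2000, seed: int = 0) -> float:
    """Spearman correlation between embedding distance and |value difference|
    over random molecule pairs.

    A learnable objective gives a clearly positive statistic (nearby
    molecules have similar values); unstructured values give ~0.
    """
    rng = np.random.default_rng(seed)
    n = len(library)
    i = rng.integers(0, n, size=probe_pairs)
    j = rng.integers(0, n, size=probe_pairs)
    keep = i != j
    i, j = i[keep], j[keep]
    emb = library.embeddings
    dist = np.linalg.norm(emb[i] - emb[j], axis=1)
    dval = np.abs(oracle_values[i] - oracle_values[j])
    rho = spearmanr(dist, dval).statistic
    return float(rho)


def write_benchmark(benchmark: SyntheticBenchmark, out_dir: str) -> None:
    """Dump a benchmark as plain files (embeddings, properties, truth)."""
    import os

    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    np.save(os.path.join(out_dir, "embeddings.npy"),
            benchmark.library.embeddings)
    data = {"id": benchmark.library.ids}
    data.update({name: vals for name, vals in benchmark.values.items()})
    pd.DataFrame(data).to_csv(os.path.join(out_dir, "properties.csv"),
                              index=False, float_format="%.17g")
    np.savetxt(os.path.join(out_dir, "desirable.txt"),
               benchmark.desirable, fmt="%d")
    with open(os.path.join(out_dir, "thresholds.json"), "w") as fh:
        import json

        json.dump({k: list(v) for k, v in benchmark.thresholds.items()}, fh,
                  indent=2)
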