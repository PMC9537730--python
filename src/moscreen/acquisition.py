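"""Expected improvement and its multi-objective product.

For a single objective with posterior mean mu and standard deviation sigma
at a candidate and per-objective incumbent f* (best transformed value
observed so far), the expected improvement E[max(0, f - f*)] has the closed
form

    EI = sigma * (Z * Phi(Z) + phi(Z)),   Z = (mu - f* - zeta) / sigma

with Phi/phi the standard normal CDF/PDF and zeta >= 0 an exploration
offset. With several objectives, each modelled by its own GP with its own
incumbent, the per-objective EIs are multiplied; a candidate scores highly
only if it promises improvement on every objective at once, which steers
acquisition toward the Pareto-desirable region. The product is evaluated in
log space by default because individual EIs routinely underflow with three
or more objectives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass(frozen=True)
class AcquisitionConfig:
    """Exploration weight, batch size, and product evaluation mode.

    ``zeta`` is applied on the standardized objective scale used for GP
    fitting, so one default suits objectives of any raw magnitude.
    """

    zeta: float = 0.01
    batch_size: int = 1
    log_space: bool = True

    def __post_init__(self) -> None:
        if self.zeta < 0:
            raise ValueError("zeta must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass(frozen=True)
class AcquisitionScores:
    """Per-objective EI matrix, combined product scores, and incumbents.

    ``log_combined`` is the sum of per-objective log EIs — the same ranking
    as ``combined`` but immune to underflow, which is what batch selection
    uses (the product of three small EIs is routinely below 1e-308).
    """

    per_objective_ei: np.ndarray  # n_candidates x n_objectives
    combined: np.ndarray
    log_combined: np.ndarray
    best_so_far: np.ndarray


def expected_improvement(mean: np.ndarray, stdev: np.ndarray, f_star: float,
                         zeta: float = 0.0) -> np.ndarray:
    """Closed-form EI per candidate; zero wherever ``stdev`` is zero.

    A fully determined candidate offers no expected improvement, so the
    sigma = 0 limit is defined as 0 — this also keeps already-evaluated
    molecules unattractive independent of masking.
    """
    mean = np.asarray(mean, dtype=float)
    stdev = np.asarray(stdev, dtype=float)
    if np.any(stdev < 0):
        raise ValueError("stdev must be >= 0")
    out = np.zeros_like(mean)
    pos = stdev > 0
    z = (mean[pos] - f_star - zeta) / stdev[pos]
    out[pos] = stdev[pos] * (z * norm.cdf(z) + norm.pdf(z))
    np.clip(out, 0.0, None, out=out)
    return out


def log_expected_improvement(mean: np.ndarray, stdev: np.ndarray,
                             f_star: float, zeta: float = 0.0) -> np.ndarray:
    """log EI, finite far into the hopeless tail where EI itself underflows.

    Identical to ``log(expected_improvement(...))`` wherever the closed form
    is representable. For negative Z the term Z Phi(Z) + phi(Z) is factored
    as exp(-Z^2/2) (1/sqrt(2 pi) - |Z| erfcx(|Z|/sqrt 2) / 2) using the
    scaled complementary error function, which stays accurate and finite
    arbitrarily deep in the hopeless tail where EI itself underflows — so
    candidates keep a meaningful ranking there. Returns -inf where stdev
    is zero.
    """
    from scipy.special import erfcx

    mean = np.asarray(mean, dtype=float)
    stdev = np.asarray(stdev, dtype=float)
    if np.any(stdev < 0):
        raise ValueError("stdev must be >= 0")
    out = np.full(np.shape(mean), -np.inf)
    pos = stdev > 0
    z = (mean[pos] - f_star - zeta) / stdev[pos]
    h = np.empty_like(z)
    neg = z < 0
    zs = z[~neg]
    h[~neg] = np.log(zs * norm.cdf(zs) + norm.pdf(zs))
    za = -z[neg]  # |Z|
    bracket = (1.0 / math.sqrt(2.0 * math.pi)
               - 0.5 * za * erfcx(za / math.sqrt(2.0)))
    h[neg] = -0.5 * za * za + np.log(np.maximum(bracket, 1e-320))
    out[pos] = np.log(stdev[pos]) + h
    return out


def product_acquisition(per_objective_ei: np.ndarray,
                        log_space: bool = True) -> np.ndarray:
    """Row-wise product of per-objective EIs.

    In log space the product is exp(sum of logs), with any zero EI
    short-circuiting the row to exactly 0.
    """
    ei = np.asarray(per_objective_ei, dtype=float)
    if ei.ndim == 1:
        ei = ei[:, None]
    if np.any(ei < 0):
        raise ValueError("EI entries must be >= 0")
    if not log_space:
        return np.prod(ei, axis=1)
    combined = np.zeros(ei.shape[0])
    alive = np.all(ei > 0, axis=1)
    if alive.any():
        combined[alive] = np.exp(np.log(ei[alive]).sum(axis=1))
    return combined


def select_batch(combined: np.ndarray, candidate_mask: np.ndarray,
                 batch_size: int) -> np.ndarray:
    """Indices of the ``batch_size`` highest-scoring unmasked candidates.

    Ties break toward the lower index; masked (already evaluated or
    unavailable) molecules are never selected. When fewer than
    ``batch_size`` candidates remain, all of them are returned.
    """
    combined = np.asarray(combined, dtype=float)
    candidate_mask = np.asarray(candidate_mask, dtype=bool)
    if combined.shape != candidate_mask.shape:
        raise ValueError("combined and candidate_mask must align")
    candidates = np.nonzero(candidate_mask)[0]
    if candidates.size <= batch_size:
        return candidates
    # stable sort on negated scores: equal scores keep ascending index order
    order = np.argsort(-combined[candidates], kind="stable")
    return candidates[order[:batch_size]]


def score_candidates(means: np.ndarray, stdevs: np.ndarray,
                     incumbents: np.ndarray,
                     zetas: np.ndarray | float = 0.0,
                     log_space: bool = True) -> AcquisitionScores:
    """Assemble per-objective EIs and their product for a candidate pool.

    ``means``/``stdevs`` are n_candidates x n_objectives; ``zetas`` may be a
    scalar or a per-objective vector (the engine passes zeta rescaled by
    each objective's standardization factor).
    """
    means = np.atleast_2d(np.asarray(means, dtype=float))
    stdevs = np.atleast_2d(np.asarray(stdevs, dtype=float))
    incumbents = np.asarray(incumbents, dtype=float)
    n_obj = means.shape[1]
    zetas = np.broadcast_to(np.asarray(zetas, dtype=float), (n_obj,))
    ei = np.column_stack([
        expected_improvement(means[:, j], stdevs[:, j], incumbents[j], zetas[j])
        for j in range(n_obj)
    ])
    log_ei = np.column_stack([
        log_expected_improvement(means[:, j], stdevs[:, j], incumbents[j],
                                 zetas[j])
        for j in range(n_obj)
    ])
    return AcquisitionScores(per_objective_ei=ei,
                             combined=product_acquisition(ei, log_space),
                             log_combined=log_ei.sum(axis=1),
                             best_so_far=incumbents)
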