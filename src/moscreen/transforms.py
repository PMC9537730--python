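"""Map raw property values onto a common "larger is better" scale.

Screening objectives pull in different directions: binding affinity and
synthetic-accessibility score should be as low as possible, while LogP
should sit near a drug-like sweet spot. Before the optimizer sees them,
each raw property is transformed so that every objective is maximized:

* ``negate`` — multiply by -1 (binding affinity, SAS);
* ``gaussian_peak`` — ``exp(-(raw - center)^2 / (2 width^2))``, a unit-height
  bell peaked at ``center`` (LogP, peaked at 2.5);
* ``identity`` — pass through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_KINDS = ("negate", "gaussian_peak", "identity")


@dataclass(frozen=True)
class TransformSpec:
    """Which transform to apply and, for ``gaussian_peak``, its shape.

    ``center`` and ``width`` are in the raw property's units; ``width`` is
    the standard deviation of the bell. The default width of 1.0 on the LogP
    scale keeps the drug-like band dominant: LogP 0 and 5 both map to
    ~0.044 while 2.5 maps to the maximum of 1.
    """

    kind: str
    center: float = 2.5
    width: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}; "
                             f"expected one of {_KINDS}")
        if self.kind == "gaussian_peak" and not self.width > 0:
            raise ValueError("gaussian_peak width must be > 0")


def apply_transform(spec: TransformSpec, raw):
    """Apply ``spec`` to a scalar or array of raw values, preserving shape.

    Raises on non-finite input; the transformed score of a ``gaussian_peak``
    is in (0, 1] with the maximum attained exactly at ``center``.
    """
    arr = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite raw property value")
    if spec.kind == "negate":
        out = -arr
    elif spec.kind == "gaussian_peak":
        out = np.exp(-((arr - spec.center) ** 2) / (2.0 * spec.width**2))
    else:
        out = arr.copy()
    if np.isscalar(raw) or np.ndim(raw) == 0:
        return float(out)
    return out
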