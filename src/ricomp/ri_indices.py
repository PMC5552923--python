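"""Reproductive-isolation indices from barrier-component data.

A cross is scored at a sequence of reproductive barriers (e.g.
fertilization rate, hatching rate, tadpoles produced, metamorphosis
rate).  Each barrier yields a strength ``RI_k = 1 - het/hom`` comparing
heterospecific to homospecific success.  Two ways of combining barrier
strengths into a single index are provided:

* the composite index: the unweighted mean of the component strengths,
  which on k equally scored components takes values on a 1/k grid;
* the sequential index: ``RI_total = 1 - prod_k(1 - RI_k)``, which
  accounts for the barriers acting in biological order — each barrier
  only removes gene flow that survived the earlier ones — and yields a
  more continuous response.  The absolute contribution of barrier n is
  ``AC_n = RI_n * prod_{i<n}(1 - RI_i)`` and the contributions sum to
  the total exactly.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["barrier_strength", "composite_index", "sequential_index"]


def barrier_strength(
    heterospecific_success: float,
    homospecific_success: float,
    clamp: bool = False,
) -> float:
    """Strength of one barrier: ``1 - het/hom``.

    0 means heterospecific crosses do as well as homospecific ones (no
    isolation); 1 means heterospecific crosses fail completely.  When
    heterospecific success exceeds homospecific success the index is
    negative (heterospecific advantage); it is kept with a warning
    unless ``clamp=True`` floors it at 0.
    """
    if not (0.0 <= heterospecific_success <= 1.0):
        raise ValueError("heterospecific success must be in [0, 1]")
    if not (0.0 <= homospecific_success <= 1.0):
        raise ValueError("homospecific success must be in [0, 1]")
    if homospecific_success == 0.0:
        raise ValueError("undefined index: homospecific success is zero")
    ri = 1.0 - heterospecific_success / homospecific_success
    if ri < 0.0:
        if clamp:
            return 0.0
        warnings.warn(
            "heterospecific success exceeds homospecific success; "
            "barrier strength is negative",
            stacklevel=2,
        )
    return ri


def composite_index(strengths) -> float:
    """Unweighted mean of the component barrier strengths."""
    arr = np.asarray(list(strengths), dtype=float)
    if arr.size == 0:
        raise ValueError("no barrier components supplied")
    if not np.all(np.isfinite(arr)):
        raise ValueError("barrier strengths must be finite")
    return float(arr.mean())


def sequential_index(strengths) -> tuple[float, np.ndarray]:
    """Total RI and per-barrier absolute contributions, barriers in order.

    Returns ``(total, contributions)`` with
    ``total = 1 - prod(1 - RI_k)`` and
    ``contributions[n] = RI_n * prod_{i<n}(1 - RI_i)``; the
    contributions sum to the total.  Strengths must lie in [0, 1]: the
    multiplicative form has no meaning for negative components.
    """
    arr = np.asarray(list(strengths), dtype=float)
    if arr.size == 0:
        raise ValueError("no barrier components supplied")
    if np.any(arr < 0.0) or np.any(arr > 1.0) or not np.all(np.isfinite(arr)):
        raise ValueError("sequential index requires strengths in [0, 1]")
    surviving = np.concatenate([[1.0], np.cumprod(1.0 - arr)[:-1]])
    contributions = arr * surviving
    total = 1.0 - float(np.prod(1.0 - arr))
    return total, contributions
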