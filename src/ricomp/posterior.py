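"""Posterior summaries, HPD hypothesis tests, and convergence checks.

Hypotheses about the crossing model are tested directly on the
posterior: a coefficient is called significant when its 95% highest
posterior density (HPD) interval excludes zero.  Derived quantities
follow the same rule — e.g. the total genetic-distance slope for
sympatric pairs is the per-draw sum of the allopatric slope and the
interaction coefficient, and the sympatric mean is the per-draw sum of
the intercept and the sympatry offset; both are summarized from the
derived sample, not from point estimates.

Convergence is assessed with the Gelman-Rubin potential scale reduction
factor (PSRF) comparing within- and between-chain variance; chains are
treated as converged when every univariate PSRF is <= 1.1.  The
classic estimator with the (1 + 1/m) inflation is used, without the
Brooks-Gelman degrees-of-freedom correction; the multivariate PSRF is
the largest-eigenvalue form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from ricomp.gibbs import PosteriorChains, VARIANCE_NAMES

__all__ = [
    "HPDInterval",
    "Summary",
    "SummaryRow",
    "contrast",
    "hpd",
    "psrf",
    "summarize",
]


@dataclass(frozen=True)
class HPDInterval:
    """Shortest credible interval at the given coverage."""

    lower: float
    upper: float
    prob: float = 0.95

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("HPD lower bound exceeds upper bound")

    @property
    def excludes_zero(self) -> bool:
        return self.lower > 0.0 or self.upper < 0.0


@dataclass
class SummaryRow:
    """Posterior summary of one parameter or derived contrast."""

    name: str
    kind: str  # "fixed" | "variance" | "contrast"
    mean: float
    mode: float
    hpd: HPDInterval
    psrf: float | None
    excludes_zero: bool


@dataclass
class Summary:
    """Per-parameter posterior summaries plus global diagnostics."""

    rows: list[SummaryRow]
    multivariate_psrf: float | None = None
    meta: dict = field(default_factory=dict)

    def row(self, name: str) -> SummaryRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(f"no summary row named {name!r}")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rows]


def hpd(samples: np.ndarray, prob: float = 0.95) -> HPDInterval:
    """Shortest window containing ``ceil(prob * n)`` order statistics.

    Ties between equally narrow windows are broken toward the leftmost
    window, so the result is deterministic.
    """
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < math.ceil(1.0 / (1.0 - prob)):
        raise ValueError(
            f"need at least {math.ceil(1.0 / (1.0 - prob))} samples for "
            f"prob={prob}, got {n}"
        )
    k = math.ceil(prob * n)
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin returns the first (leftmost) minimum
    return HPDInterval(lower=float(x[i]), upper=float(x[i + k - 1]), prob=prob)


def _kde_mode(samples: np.ndarray) -> float:
    """Posterior mode via Gaussian KDE with Silverman bandwidth."""
    x = np.asarray(samples, dtype=float).ravel()
    if np.ptp(x) == 0.0:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def _psrf_univariate(draws: np.ndarray) -> float:
    """PSRF from an (m, n) array of draws; m chains of length n."""
    m, n = draws.shape
    within = draws.var(axis=1, ddof=1)
    W = float(within.mean())
    means = draws.mean(axis=1)
    B_over_n = float(means.var(ddof=1))
    if W <= 0.0:
        if B_over_n <= 0.0:
            return 1.0  # constant draws: trivially converged
        warnings.warn(
            "chains are each constant but disagree; PSRF is infinite",
            stacklevel=3,
        )
        return float("inf")
    return math.sqrt(((n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n) / W)


def psrf(chains: PosteriorChains) -> tuple[dict[str, float], float]:
    """Univariate PSRF per parameter and the multivariate PSRF.

    Requires >= 2 chains of equal retained length.  Parameters with zero
    within-chain variance are reported as 1.0 (degenerate, trivially
    converged) and excluded from the multivariate statistic.
    """
    if len(chains.chains) < 2:
        raise ValueError("PSRF requires at least two chains")
    n = chains.n_retained
    if n < 10:
        raise ValueError("PSRF requires at least 10 retained draws per chain")
    uni: dict[str, float] = {}
    usable: list[str] = []
    for name in chains.parameters:
        draws = chains.array(name)
        uni[name] = _psrf_univariate(draws)
        if draws.var(axis=1, ddof=1).min() > 0.0:
            usable.append(name)

    if not usable:
        return uni, 1.0
    stacked = np.stack([chains.array(p) for p in usable], axis=-1)  # (m, n, k)
    m = stacked.shape[0]
    W = np.mean([np.cov(chain, rowvar=False, ddof=1) for chain in stacked], axis=0)
    means = stacked.mean(axis=1)  # (m, k)
    B_over_n = np.atleast_2d(np.cov(means, rowvar=False, ddof=1))
    W = np.atleast_2d(W)
    try:
        lam = float(np.max(np.real(np.linalg.eigvals(np.linalg.solve(W, B_over_n)))))
    except np.linalg.LinAlgError:
        lam = float("inf")
    multi = math.sqrt((n - 1) / n + (1.0 + 1.0 / m) * lam)
    return uni, multi


def contrast(
    chains: PosteriorChains,
    weights: dict[str, float],
    name: str | None = None,
    prob: float = 0.95,
) -> tuple[np.ndarray, SummaryRow]:
    """Per-draw linear combination of parameters and its summary.

    ``weights`` maps parameter names to coefficients; e.g.
    ``{"gendist": 1, "gendist:sympatry[sym]": 1}`` yields the total
    genetic-distance slope in sympatric crosses.  The derived sample is
    pooled across chains; HPD and the excludes-zero call are computed
    on it directly.
    """
    unknown = [k for k in weights if k not in chains.chains[0]]
    if unknown:
        raise KeyError(f"unknown parameters in contrast: {unknown}")
    if name is None:
        name = " + ".join(
            (f"{w:g}*{p}" if w != 1 else p) for p, w in weights.items()
        )
    per_chain = [
        sum(w * chain[p] for p, w in weights.items()) for chain in chains.chains
    ]
    derived = np.concatenate(per_chain)
    if np.ptp(derived) == 0.0:
        interval = HPDInterval(float(derived[0]), float(derived[0]), prob)
    else:
        interval = hpd(derived, prob)
    rhat = (
        _psrf_univariate(np.stack(per_chain)) if len(per_chain) >= 2 else None
    )
    row = SummaryRow(
        name=name,
        kind="contrast",
        mean=float(derived.mean()),
        mode=_kde_mode(derived),
        hpd=interval,
        psrf=rhat,
        excludes_zero=interval.excludes_zero,
    )
    return derived, row


def summarize(
    chains: PosteriorChains,
    contrasts: dict[str, dict[str, float]] | None = None,
    prob: float = 0.95,
) -> Summary:
    """Pooled posterior mean, KDE mode, HPD, PSRF per parameter.

    ``contrasts`` maps a display name to a weight dictionary; each
    contrast gets its own summary row.  If any univariate PSRF exceeds
    1.1 a warning is emitted before pooling, since pooled summaries are
    only meaningful for converged chains.
    """
    multi: float | None = None
    uni: dict[str, float] = {}
    if len(chains.chains) >= 2:
        uni, multi = psrf(chains)
        worst = max(uni.values())
        if worst > 1.1:
            warnings.warn(
                f"pooling chains with max PSRF {worst:.3f} > 1.1; summaries "
                "may be unreliable",
                stacklevel=2,
            )
    rows: list[SummaryRow] = []
    for pname in chains.parameters:
        pooled = chains.pooled(pname)
        if np.ptp(pooled) == 0.0:
            interval = HPDInterval(float(pooled[0]), float(pooled[0]), prob)
        else:
            interval = hpd(pooled, prob)
        rows.append(
            SummaryRow(
                name=pname,
                kind="variance" if pname in VARIANCE_NAMES else "fixed",
                mean=float(pooled.mean()),
                mode=_kde_mode(pooled),
                hpd=interval,
                psrf=uni.get(pname),
                excludes_zero=interval.excludes_zero,
            )
        )
    for cname, weights in (contrasts or {}).items():
        _, row = contrast(chains, weights, name=cname, prob=prob)
        rows.append(row)
    return Summary(rows=rows, multivariate_psrf=multi, meta=dict(chains.meta))
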