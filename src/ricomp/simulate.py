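"""Synthetic phylogenies and crossing datasets with known truth.

The generator draws data from exactly the model the sampler fits, so
parameter recovery and calibration can be checked end to end:

* :func:`simulate_yule` grows a pure-birth tree (unit depth, tips
  ``sp1..spN``) standing in for an empirical phylogeny;
* :func:`simulate_crossing_data` samples ordered species pairs with
  replacement — each species typically appears in several crosses,
  which is precisely why the phylogenetic random effects are needed —
  and generates responses
  ``y = X beta + Z_f u_f + Z_m u_m + e`` with
  ``u ~ N(0, sigma2 * A)``.

The genetic-distance predictor is the patristic distance scaled by
twice the tree depth, so it lies in [0, 1]; on an ultrametric tree this
equals ``1 - A_ij``.  Optional further continuous predictors
(geographic distance, floral trait distance) are drawn jointly with
genetic distance through a Gaussian copula at a configured correlation,
to exercise the correlated-predictor prior.  Responses are left
untruncated by default: the fitted model is Gaussian and clipping to
[0, 1] would bias recovery checks (a ``clip`` flag exists for realism
experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from ricomp.model_build import CrossingDataset
from ricomp.relatedness import Phylogeny, RelatednessMatrix, tree_to_relatedness

__all__ = ["SimulationTruth", "simulate_crossing_data", "simulate_yule"]


def _default_fixed() -> dict[str, float]:
    # moderate-signal regime: clear but not overwhelming effects on an
    # RI-like response scale
    return {
        "mu": 0.2,
        "gendist": 0.5,
        "sympatry[sympatric]": 0.25,
        "gendist:sympatry[sympatric]": 0.4,
    }


@dataclass
class SimulationTruth:
    """Generative parameters for a synthetic crossing dataset.

    ``fixed`` is keyed by design-column name (``mu`` intercept,
    ``gendist`` slope, ``sympatry[sympatric]`` sympatry offset,
    ``gendist:sympatry[sympatric]`` slope change in sympatry, plus any
    extra continuous predictors).  Variance components are variances;
    the defaults correspond to maternal/paternal species standard
    deviations of 0.05 and a residual standard deviation of 0.1 on the
    RI scale.
    """

    fixed: dict[str, float] = field(default_factory=_default_fixed)
    sigma2_f: float = 0.0025
    sigma2_m: float = 0.0025
    sigma2_e: float = 0.01
    sympatry_prob: float = 0.5
    extra_predictors: list[str] = field(default_factory=list)
    predictor_corr: np.ndarray | None = None  # (1+k)x(1+k), gendist first
    sympatry_depth_bias: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.sigma2_f, self.sigma2_m, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")
        if not 0.0 <= self.sympatry_prob <= 1.0:
            raise ValueError("sympatry probability must be in [0, 1]")
        if self.extra_predictors:
            k = 1 + len(self.extra_predictors)
            if self.predictor_corr is None:
                self.predictor_corr = np.eye(k)
            self.predictor_corr = np.asarray(self.predictor_corr, dtype=float)
            if self.predictor_corr.shape != (k, k):
                raise ValueError(
                    f"predictor correlation matrix must be {k}x{k} "
                    "(genetic distance first)"
                )
            if not np.allclose(np.diag(self.predictor_corr), 1.0):
                raise ValueError("correlation matrix must have unit diagonal")
            if np.min(np.linalg.eigvalsh(self.predictor_corr)) < -1e-10:
                raise ValueError("predictor correlation matrix is not PSD")

    @property
    def formula(self) -> str:
        rhs = "gendist * sympatry"
        for name in self.extra_predictors:
            rhs += f" + {name}"
        return f"RI ~ {rhs}"


def simulate_yule(n_tips: int, seed: int | None = None) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_tips`` tips, scaled to unit depth.

    Lineages split at rate 1 per lineage; after the last split the tree
    is extended by one more exponential waiting time and every branch
    is divided by the total depth, giving an ultrametric tree of depth
    exactly 1.  Tips are labelled ``sp1..spN``.  Deterministic given
    ``seed``.
    """
    if n_tips < 2:
        raise ValueError("a Yule tree needs at least 2 tips")
    rng = np.random.default_rng(seed)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    root = tree.seed_node
    active: list[tuple[dendropy.Node, float]] = []
    t = 0.0
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, t))
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        node, birth = active.pop(idx)
        node.edge.length = t - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    T = t + rng.exponential(1.0 / len(active))
    for node, birth in active:
        node.edge.length = T - birth

    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= T
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = tns.require_taxon(label=f"sp{i}")
    return tree


def _copula_extras(
    gendist: np.ndarray,
    names: list[str],
    corr: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Extra predictors correlated with genetic distance.

    Genetic distance is mapped to normal scores through its ranks; the
    remaining coordinates are drawn from the conditional Gaussian given
    those scores and mapped back through the normal CDF, so each extra
    predictor is marginally ~ Uniform(0, 1) with roughly the configured
    correlation to genetic distance.
    """
    n = gendist.size
    z1 = norm.ppf((rankdata(gendist) - 0.5) / n)
    C11 = corr[:1, :1]
    C12 = corr[:1, 1:]
    C22 = corr[1:, 1:]
    slope = np.linalg.solve(C11, C12)  # (1, k)
    cond_cov = C22 - C12.T @ slope
    eigval, eigvec = np.linalg.eigh(cond_cov)
    L = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    w = rng.standard_normal((n, len(names)))
    z_rest = np.outer(z1, slope.ravel()) + w @ L.T
    return {name: norm.cdf(z_rest[:, j]) for j, name in enumerate(names)}


def simulate_crossing_data(
    tree_or_A: Phylogeny | RelatednessMatrix,
    truth: SimulationTruth | None = None,
    n_crosses: int = 150,
    seed: int | None = None,
    clip: bool = False,
) -> tuple[CrossingDataset, SimulationTruth]:
    """Simulate a crossing dataset under the mixed model.

    Parameters
    ----------
    tree_or_A
        Ultrametric phylogeny or pre-built relatedness matrix covering
        the taxon pool.
    truth
        Generative parameters; defaults to the moderate-signal regime.
    n_crosses
        Number of crosses (ordered distinct species pairs, sampled with
        replacement).
    seed
        Seed for all randomness in pair sampling, predictors, random
        effects and residuals.
    clip
        Clamp responses to [0, 1] (off by default; see module notes).

    Returns the dataset together with the truth actually used.
    """
    truth = truth or SimulationTruth()
    if isinstance(tree_or_A, RelatednessMatrix):
        relate = tree_or_A
    else:
        relate = tree_to_relatedness(tree_or_A)
    labels = relate.labels
    q = len(labels)
    if q < 4:
        raise ValueError("need at least 4 taxa to form interesting crosses")
    n_params = len(truth.fixed)
    if n_crosses < n_params + 3:
        raise ValueError(
            f"need at least {n_params + 3} crosses for {n_params} parameters"
        )
    rng = np.random.default_rng(seed)

    mi = rng.integers(q, size=n_crosses)
    pi = rng.integers(q - 1, size=n_crosses)
    pi = np.where(pi >= mi, pi + 1, pi)  # distinct ordered pairs

    # on an ultrametric unit-depth tree, patristic/(2*depth) = 1 - A_ij
    gendist = 1.0 - relate.A[mi, pi]

    if truth.sympatry_depth_bias != 0.0:
        base = np.log(truth.sympatry_prob / (1.0 - truth.sympatry_prob))
        logit = base - truth.sympatry_depth_bias * (gendist - gendist.mean())
        p_sym = 1.0 / (1.0 + np.exp(-logit))
    else:
        p_sym = np.full(n_crosses, truth.sympatry_prob)
    sym = rng.random(n_crosses) < p_sym
    sym_dummy = sym.astype(float)

    columns: dict[str, np.ndarray] = {"gendist": gendist}
    if truth.extra_predictors:
        columns.update(
            _copula_extras(gendist, truth.extra_predictors, truth.predictor_corr, rng)
        )

    design_cols = {
        "mu": np.ones(n_crosses),
        "gendist": gendist,
        "sympatry[sympatric]": sym_dummy,
        "gendist:sympatry[sympatric]": gendist * sym_dummy,
    }
    for name in truth.extra_predictors:
        design_cols[name] = columns[name]
    unknown = [k for k in truth.fixed if k not in design_cols]
    if unknown:
        raise KeyError(f"truth names without a design column: {unknown}")
    xb = sum(truth.fixed[k] * design_cols[k] for k in truth.fixed)

    eigval, eigvec = np.linalg.eigh(relate.A)
    L = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    u_f = np.sqrt(truth.sigma2_f) * (L @ rng.standard_normal(q))
    u_m = np.sqrt(truth.sigma2_m) * (L @ rng.standard_normal(q))
    e = np.sqrt(truth.sigma2_e) * rng.standard_normal(n_crosses)
    y = xb + u_f[mi] + u_m[pi] + e
    if clip:
        y = np.clip(y, 0.0, 1.0)

    taxa = np.asarray(labels)
    table = pd.DataFrame(
        {
            "maternal": taxa[mi],
            "paternal": taxa[pi],
            "RI": y,
            "gendist": gendist,
            "sympatry": np.where(sym, "sympatric", "allopatric"),
        }
    )
    for name in truth.extra_predictors:
        table[name] = columns[name]

    dataset = CrossingDataset(
        table=table,
        maternal_col="maternal",
        paternal_col="paternal",
        response_cols=["RI"],
        continuous_cols=["gendist", *truth.extra_predictors],
        categorical_cols=["sympatry"],
    )
    return dataset, truth
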