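"""Design matrices and priors for the crossing mixed model.

The fitted model is

    y = X beta + Z_f u_f + Z_m u_m + e

where each row of the crossing table contributes one observation of a
reproductive-isolation response ``y``; ``X`` holds an intercept plus
continuous predictors (genetic distance, geographic distance, trait
distances), dummy-coded categorical predictors (sympatry, flower
colour) and their interactions; and ``Z_f``/``Z_m`` are incidence
matrices of the maternal and paternal species of each cross.  Separate
maternal and paternal effects are used because not every species
appears in both parental roles; restricting each Z to the taxa actually
observed in that role keeps the matrices dense and the variance
estimates precise.

Formula mini-language: ``RI ~ gendist * sympatry`` expands ``a*b`` to
``a + b + a:b``; ``a:b`` is the interaction alone; categorical terms
are declared by the table schema and the reference level can be forced
with ``C(term, ref=LEVEL)``.  Dummy coding is k-1 against the
reference, which is "allopatric" when such a level exists (so the
intercept is the allopatric baseline) and otherwise the first level in
sorted order.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ricomp.relatedness import RelatednessMatrix

__all__ = [
    "CrossRecord",
    "CrossingDataset",
    "DesignMatrices",
    "ModelFormula",
    "PriorSpec",
    "build_design",
    "build_prior",
]

logger = logging.getLogger(__name__)

_PREFERRED_REFERENCES = ("allopatric", "allopatry")


@dataclass
class CrossRecord:
    """One interspecific cross: parents, responses, predictors."""

    maternal_taxon: str
    paternal_taxon: str
    responses: dict[str, float]
    continuous: dict[str, float]
    categorical: dict[str, str]


class CrossingDataset:
    """A table of interspecific crosses plus its column roles.

    Parameters
    ----------
    table
        One row per cross.
    maternal_col, paternal_col
        Columns holding the parent taxon labels.
    response_cols, continuous_cols, categorical_cols
        Column roles; every declared column must exist in ``table``.

    Taxon labels are stripped of surrounding whitespace and internal
    spaces are replaced with underscores, matching the Newick
    convention, so crossing tables join to trees by exact label.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        maternal_col: str,
        paternal_col: str,
        response_cols: list[str],
        continuous_cols: list[str] | None = None,
        categorical_cols: list[str] | None = None,
    ) -> None:
        if maternal_col == paternal_col:
            raise ValueError("maternal and paternal columns must differ")
        continuous_cols = list(continuous_cols or [])
        categorical_cols = list(categorical_cols or [])
        declared = [maternal_col, paternal_col, *response_cols, *continuous_cols, *categorical_cols]
        missing = [c for c in declared if c not in table.columns]
        if missing:
            raise KeyError(f"declared columns absent from table: {missing}")
        table = table.copy()
        for col in (maternal_col, paternal_col):
            table[col] = (
                table[col].astype(str).str.strip().str.replace(r"\s+", "_", regex=True)
            )
        self.table = table.reset_index(drop=True)
        self.maternal_col = maternal_col
        self.paternal_col = paternal_col
        self.response_cols = list(response_cols)
        self.continuous_cols = continuous_cols
        self.categorical_cols = categorical_cols

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def taxa(self) -> list[str]:
        """Union of maternal and paternal taxon labels, sorted."""
        return sorted(
            set(self.table[self.maternal_col]) | set(self.table[self.paternal_col])
        )

    @property
    def records(self) -> list[CrossRecord]:
        out = []
        for _, row in self.table.iterrows():
            out.append(
                CrossRecord(
                    maternal_taxon=row[self.maternal_col],
                    paternal_taxon=row[self.paternal_col],
                    responses={c: row[c] for c in self.response_cols},
                    continuous={c: row[c] for c in self.continuous_cols},
                    categorical={c: str(row[c]) for c in self.categorical_cols},
                )
            )
        return out


@dataclass
class ModelFormula:
    """Parsed model formula: a response and an ordered list of terms.

    Terms are tuples: ``("continuous", name)``,
    ``("categorical", name, ref_or_None)`` or
    ``("interaction", (factor, factor))`` where each factor is itself a
    continuous/categorical tuple.
    """

    response: str
    terms: list[tuple]
    intercept: bool = True

    _C_RE = re.compile(r"^C\(\s*(\w+)\s*(?:,\s*ref\s*=\s*([^)]+?)\s*)?\)$")

    @classmethod
    def parse(cls, text: str, categorical_cols: list[str] | None = None) -> "ModelFormula":
        categorical = set(categorical_cols or [])
        if "~" not in text:
            raise ValueError("formula must contain '~'")
        lhs, rhs = (part.strip() for part in text.split("~", 1))
        if not lhs:
            raise ValueError("formula lacks a response")

        def parse_factor(tok: str) -> tuple:
            tok = tok.strip()
            m = cls._C_RE.match(tok)
            if m:
                name, ref = m.group(1), m.group(2)
                return ("categorical", name, ref.strip() if ref else None)
            if tok in categorical:
                return ("categorical", tok, None)
            return ("continuous", tok)

        terms: list[tuple] = []
        for tok in (t.strip() for t in rhs.split("+")):
            if not tok or tok == "1":
                continue
            if "*" in tok:
                a, b = (parse_factor(p) for p in tok.split("*", 1))
                terms.extend([a, b, ("interaction", (a, b))])
            elif ":" in tok:
                a, b = (parse_factor(p) for p in tok.split(":", 1))
                terms.append(("interaction", (a, b)))
            else:
                terms.append(parse_factor(tok))
        if not terms:
            raise ValueError("formula has no predictor terms")
        return cls(response=lhs, terms=terms)


@dataclass
class DesignMatrices:
    """Realized model matrices for one crossing dataset and formula."""

    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    f_labels: list[str]           # taxa observed in the maternal role
    m_labels: list[str]           # taxa observed in the paternal role
    f_index: np.ndarray           # row -> maternal column, len n
    m_index: np.ndarray
    A_f: np.ndarray               # relatedness sub-matrix, maternal order
    A_m: np.ndarray
    continuous_idx: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q_f(self) -> int:
        return len(self.f_labels)

    @property
    def q_m(self) -> int:
        return len(self.m_labels)

    @property
    def Z_f(self) -> np.ndarray:
        Z = np.zeros((self.n, self.q_f))
        Z[np.arange(self.n), self.f_index] = 1.0
        return Z

    @property
    def Z_m(self) -> np.ndarray:
        Z = np.zeros((self.n, self.q_m))
        Z[np.arange(self.n), self.m_index] = 1.0
        return Z


@dataclass
class PriorSpec:
    """Priors for the Gibbs sampler.

    ``b0``/``B0`` parameterize the Gaussian prior on the fixed effects;
    ``V`` and ``nu`` hold the scale and belief of the scaled
    inverse-gamma priors on the maternal, paternal and residual variance
    components.  The scale is one third of the response variance —
    splitting the total variance evenly across the three covariance
    components of the model.
    """

    b0: np.ndarray
    B0: np.ndarray
    V: dict[str, float]
    nu: dict[str, float]

    def __post_init__(self) -> None:
        if not np.allclose(self.B0, self.B0.T, atol=1e-10):
            raise ValueError("B0 must be symmetric")
        if any(v <= 0 for v in self.V.values()):
            raise ValueError("variance prior scales must be positive")
        if any(v <= 0 for v in self.nu.values()):
            raise ValueError("variance prior beliefs must be positive")


def _factor_columns(
    factor: tuple, table: pd.DataFrame, standardize: bool
) -> tuple[np.ndarray, list[str]]:
    """Columns for one factor: (n x k) array plus names."""
    kind = factor[0]
    name = factor[1]
    if kind == "continuous":
        vals = pd.to_numeric(table[name], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValueError(f"non-numeric values in continuous predictor {name!r}")
        if standardize:
            sd = vals.std(ddof=1)
            vals = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        return vals[:, None], [name]
    # categorical: k-1 dummies against the reference
    ref = factor[2]
    levels = sorted(table[name].astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"categorical term {name!r} is constant (single level)")
    if ref is None:
        preferred = [lv for lv in levels if lv.lower() in _PREFERRED_REFERENCES]
        ref = preferred[0] if preferred else levels[0]
    if ref not in levels:
        raise ValueError(f"reference level {ref!r} not observed for {name!r}")
    keep = [lv for lv in levels if lv != ref]
    cols = np.column_stack(
        [(table[name].astype(str) == lv).to_numpy(dtype=float) for lv in keep]
    )
    return cols, [f"{name}[{lv}]" for lv in keep]


def build_design(
    dataset: CrossingDataset,
    formula: ModelFormula | str,
    relate: RelatednessMatrix,
    standardize: bool = False,
) -> DesignMatrices:
    """Realize y, X, Z_f, Z_m and the per-role relatedness sub-matrices.

    Rows with a missing response or missing value in any predictor used
    by the formula are dropped (the count is logged).  Every taxon in
    the retained rows must appear in ``relate``; orphans raise with the
    full list so the user can fix label mismatches in one pass.
    """
    if isinstance(formula, str):
        formula = ModelFormula.parse(formula, dataset.categorical_cols)
    table = dataset.table

    used_cols = {formula.response}
    for term in formula.terms:
        if term[0] == "interaction":
            used_cols.update(f[1] for f in term[1])
        else:
            used_cols.add(term[1])
    missing_cols = [c for c in used_cols if c not in table.columns]
    if missing_cols:
        raise KeyError(f"formula references absent columns: {missing_cols}")

    numeric = {formula.response} | set(dataset.continuous_cols)
    mask = np.ones(len(table), dtype=bool)
    for col in used_cols:
        if col in numeric:
            mask &= pd.to_numeric(table[col], errors="coerce").notna().to_numpy()
        else:
            mask &= table[col].notna().to_numpy()
    dropped = int((~mask).sum())
    if dropped:
        logger.info("dropped %d rows with missing response or predictor", dropped)
    table = table.loc[mask].reset_index(drop=True)
    if len(table) == 0:
        raise ValueError("no complete rows left after dropping missing data")

    taxa = set(table[dataset.maternal_col]) | set(table[dataset.paternal_col])
    orphans = sorted(taxa - set(relate.labels))
    if orphans:
        raise KeyError(f"taxa absent from relatedness matrix: {orphans}")

    y = pd.to_numeric(table[formula.response]).to_numpy(dtype=float)

    blocks: list[np.ndarray] = []
    names: list[str] = []
    continuous_idx: list[int] = []
    if formula.intercept:
        blocks.append(np.ones((len(table), 1)))
        names.append("mu")
    for term in formula.terms:
        if term[0] == "interaction":
            (ca, na), (cb, nb) = (
                _factor_columns(f, table, standardize) for f in term[1]
            )
            cols = ca[:, :, None] * cb[:, None, :]
            cols = cols.reshape(len(table), -1)
            new_names = [f"{a}:{b}" for a in na for b in nb]
        else:
            cols, new_names = _factor_columns(term, table, standardize)
            if term[0] == "continuous":
                continuous_idx.extend(
                    range(sum(b.shape[1] for b in blocks), sum(b.shape[1] for b in blocks) + 1)
                )
        blocks.append(cols)
        names.extend(new_names)
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate design columns: {names}")
    X = np.hstack(blocks)

    f_labels = sorted(table[dataset.maternal_col].unique())
    m_labels = sorted(table[dataset.paternal_col].unique())
    f_pos = {lab: i for i, lab in enumerate(f_labels)}
    m_pos = {lab: i for i, lab in enumerate(m_labels)}
    f_index = table[dataset.maternal_col].map(f_pos).to_numpy(dtype=int)
    m_index = table[dataset.paternal_col].map(m_pos).to_numpy(dtype=int)

    return DesignMatrices(
        y=y,
        X=X,
        x_names=names,
        f_labels=f_labels,
        m_labels=m_labels,
        f_index=f_index,
        m_index=m_index,
        A_f=relate.submatrix(f_labels),
        A_m=relate.submatrix(m_labels),
        continuous_idx=continuous_idx,
    )


def build_prior(
    design: DesignMatrices,
    mode: str = "independent",
    beta_scale: float = 1e8,
    nu: float = 1.0,
) -> PriorSpec:
    """Prior specification for a design.

    Each variance component (maternal, paternal, residual) gets a scaled
    inverse-gamma prior with scale ``var(y) / 3`` — one third of the
    total response variance per covariance component — and belief
    ``nu``.  The fixed-effect prior is N(0, B0):

    * ``mode="independent"``: ``B0 = beta_scale * I`` (diagonal;
      effectively flat at the default scale);
    * ``mode="correlated"``: off-diagonal entries for pairs of
      non-intercept continuous columns are ``beta_scale * r_jk`` with
      ``r_jk`` the empirical correlation of those design columns, so
      the prior acknowledges the multicollinearity among the
      predictors.  The result is projected to the nearest PSD matrix
      (eigenvalue clipping at 0, with a warning) if needed.
    """
    if beta_scale <= 0:
        raise ValueError("beta_scale must be positive")
    if mode not in ("independent", "correlated"):
        raise ValueError("mode must be 'independent' or 'correlated'")
    var_y = float(np.var(design.y, ddof=1)) if design.n > 1 else 0.0
    if var_y <= 0:
        raise ValueError("degenerate response: variance of y is zero")
    V = var_y / 3.0

    p = design.p
    B0 = beta_scale * np.eye(p)
    if mode == "correlated" and len(design.continuous_idx) > 1:
        idx = design.continuous_idx
        sub = design.X[:, idx]
        r = np.corrcoef(sub, rowvar=False)
        for a, j in enumerate(idx):
            for b, k in enumerate(idx):
                if j != k:
                    B0[j, k] = beta_scale * r[a, b]
        eigval, eigvec = np.linalg.eigh(B0)
        if np.min(eigval) < 0:
            warnings.warn(
                "correlated beta prior was not positive semi-definite; "
                "negative eigenvalues clipped to zero",
                stacklevel=2,
            )
            B0 = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
            B0 = (B0 + B0.T) / 2.0

    return PriorSpec(
        b0=np.zeros(p),
        B0=B0,
        V={"maternal": V, "paternal": V, "residual": V},
        nu={"maternal": nu, "paternal": nu, "residual": nu},
    )
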