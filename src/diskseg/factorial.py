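"""Three-level fractional factorial robustness design and effect analysis.

The robustness study asks which of four three-level factors (curve severity,
disk position relative to the apex, MR acquisition sequence, segmenting user)
and one uncontrollable blocking factor (inter-patient variability) influence
the DSC response.  The design is an M^(k−p) fractional factorial — with the
defaults M=3 levels, k=4 factors and p=2 eliminated higher-order
interactions, replicated over 3 blocks: 3^(4−2) × 3 = 27 runs.

Effects are estimated by OLS with orthogonal-polynomial contrasts per factor
(linear term L = x on the −1/0/+1 coding; quadratic term Q = 3x²−2, denoted
with a trailing ``*``), block as a categorical term, and whatever two-factor
interaction contrasts are estimable given the aliasing; aliased interaction
contrasts are reported rather than silently fitted.  The standardized effect
(estimate / standard error) drives the Pareto ranking.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_FACTORS = ("cobb", "position", "mri", "user")


@dataclass
class DesignMatrix:
    """Run layout with block and factor modalities in {−1, 0, 1}."""

    df: pd.DataFrame  # columns: run, block, <factors...>[, response]
    factor_names: Tuple[str, ...]
    M: int = 3
    k: int = 4
    p: int = 2
    blocks: int = 3

    @property
    def n_runs(self) -> int:
        return len(self.df)

    def with_response(self, response: Sequence[float]) -> "DesignMatrix":
        df = self.df.copy()
        df["response"] = np.asarray(response, dtype=float)
        return DesignMatrix(df, self.factor_names, self.M, self.k, self.p, self.blocks)

    def check_balance(self) -> None:
        per_level = self.n_runs // self.M
        for f in self.factor_names:
            counts = self.df[f].value_counts()
            if sorted(counts.index) != [-1, 0, 1] or not (counts == per_level).all():
                raise ValueError(f"factor {f!r} is not balanced")
        bc = self.df["block"].value_counts()
        if not (bc == self.n_runs // self.blocks).all():
            raise ValueError("blocks are not of equal size")


def _generator_vectors(m: int, p: int) -> List[Tuple[int, ...]]:
    """Canonical non-unit GF(3) coefficient vectors for the aliased factors."""
    gens = []
    for v in itertools.product(range(3), repeat=m):
        if sum(v) == 0:
            continue
        nz = [x for x in v if x != 0]
        if nz[0] != 1:  # canonical representative (first nonzero = 1)
            continue
        if sum(x != 0 for x in v) < 2:  # skip unit vectors (the base factors)
            continue
        gens.append(v)
    if len(gens) < p:
        raise ValueError(f"cannot build {p} generators from {m} base factors")
    return gens[:p]


def generate_design(
    M: int = 3,
    k: int = 4,
    p: int = 2,
    blocks: int = 3,
    seed: int = 0,
    factor_names: Optional[Sequence[str]] = None,
) -> DesignMatrix:
    """Build the blocked 3-level fractional factorial (M^(k−p) runs × blocks).

    The base full factorial spans the first ``k−p`` factors; each remaining
    factor is a modular (GF(3)) linear combination of the base columns —
    standard three-level aliasing.  The same fraction is replicated in every
    block and the run order within each block is randomized by ``seed``.
    """
    if M != 3:
        raise ValueError("only 3-level designs are supported (M=3)")
    if k < p + 1:
        raise ValueError("need k >= p + 1")
    if blocks < 1:
        raise ValueError("blocks must be >= 1")
    if factor_names is None:
        factor_names = DEFAULT_FACTORS[:k] if k <= 4 else tuple(f"f{i+1}" for i in range(k))
    factor_names = tuple(factor_names)
    if len(factor_names) != k:
        raise ValueError("factor_names length must equal k")

    m = k - p
    base = np.array(list(itertools.product(range(3), repeat=m)), dtype=int)
    cols = [base[:, i] for i in range(m)]
    if p > 0:
        for gen in _generator_vectors(m, p):
            cols.append(np.mod(base @ np.asarray(gen), 3))
    levels = np.stack(cols, axis=1) - 1  # {0,1,2} -> {−1,0,1}

    rng = np.random.default_rng(seed)
    rows = []
    run = 1
    for b in range(1, blocks + 1):
        order = rng.permutation(len(levels))
        for idx in order:
            rows.append((run, b, *levels[idx]))
            run += 1
    df = pd.DataFrame(rows, columns=["run", "block", *factor_names])
    design = DesignMatrix(df, factor_names, M, k, p, blocks)
    design.check_balance()
    return design


@dataclass
class EffectTable:
    """Per-term effect estimates with standardized effects and p-values."""

    table: pd.DataFrame  # columns: term, estimate, std_err, standardized, p_value
    aliased: List[str] = field(default_factory=list)
    residual_df: int = 0

    def sorted_by_magnitude(self) -> pd.DataFrame:
        return self.table.reindex(
            self.table["standardized"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)


def _term_columns(design: DesignMatrix) -> Dict[str, np.ndarray]:
    """Orthogonal-polynomial main effects, block dummies, and candidate
    two-factor interaction contrasts (as products of L/Q codings)."""
    df = design.df
    cols: Dict[str, np.ndarray] = {}
    if design.blocks > 1:
        for b in sorted(df["block"].unique())[1:]:
            cols[f"block[{b}]"] = (df["block"] == b).to_numpy(dtype=float)
    coded: Dict[str, np.ndarray] = {}
    for f in design.factor_names:
        x = df[f].to_numpy(dtype=float)
        coded[f] = x
        coded[f + "*"] = 3.0 * x**2 - 2.0  # orthogonal quadratic on {−1,0,1}
        cols[f] = coded[f]
        cols[f + "*"] = coded[f + "*"]
    for a, b in itertools.combinations(design.factor_names, 2):
        for sa in ("", "*"):
            for sb in ("", "*"):
                cols[f"{a}{sa}x{b}{sb}"] = coded[a + sa] * coded[b + sb]
    return cols


def estimate_effects(design: DesignMatrix) -> EffectTable:
    """Fit the effect model by OLS and return estimates with uncertainty.

    Interaction contrasts that are aliased with already-included terms (rank
    deficiency) are excluded from the fit and listed in ``aliased``.  Raises
    when the model would saturate (zero residual degrees of freedom).
    """
    if "response" not in design.df.columns:
        raise ValueError("design has no response column")
    y = design.df["response"].to_numpy(dtype=float)
    n = len(y)
    candidates = _term_columns(design)
    X = np.ones((n, 1))
    names = ["Intercept"]
    aliased: List[str] = []
    main_terms = {f for f in design.factor_names} | {f + "*" for f in design.factor_names}
    for name, col in candidates.items():
        Xtry = np.column_stack([X, col])
        is_interaction = name not in main_terms and not name.startswith("block[")
        if np.linalg.matrix_rank(Xtry) > np.linalg.matrix_rank(X):
            if is_interaction and n - Xtry.shape[1] < 1:
                aliased.append(name)  # no df left for this interaction
                continue
            X = Xtry
            names.append(name)
        elif is_interaction:
            aliased.append(name)
        else:
            raise ValueError(f"term {name!r} is not estimable in this design")
    residual_df = n - X.shape[1]
    if residual_df < 1:
        raise ValueError(
            f"saturated model: {X.shape[1]} parameters for {n} runs leaves "
            f"{residual_df} residual degrees of freedom"
        )
    fit = sm.OLS(y, X).fit()
    rows = []
    for i, name in enumerate(names):
        if name == "Intercept":
            continue
        rows.append(
            {
                "term": name,
                "estimate": float(fit.params[i]),
                "std_err": float(fit.bse[i]),
                "standardized": float(fit.tvalues[i]),
                "p_value": float(fit.pvalues[i]),
            }
        )
    return EffectTable(table=pd.DataFrame(rows), aliased=aliased, residual_df=residual_df)


def pareto_ranking(effects: EffectTable, alpha: float = 0.05) -> pd.DataFrame:
    """Terms sorted by |standardized effect|, flagged significant at ``alpha``."""
    out = effects.sorted_by_magnitude().copy()
    out["significant"] = out["p_value"] < alpha
    return out


def load_design_csv(path, factor_names: Sequence[str] = DEFAULT_FACTORS) -> DesignMatrix:
    """Load an externally supplied design (e.g. a published run table).

    Expects columns ``run, block, <factors...>`` and optionally ``response``.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    factor_names = tuple(f.lower() for f in factor_names)
    missing = [c for c in ("run", "block", *factor_names) if c not in df.columns]
    if missing:
        raise ValueError(f"design CSV missing columns: {missing}")
    blocks = df["block"].nunique()
    return DesignMatrix(df, factor_names, M=3, k=len(factor_names), p=0, blocks=blocks)
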