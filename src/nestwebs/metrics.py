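"""Composition and evenness statistics for nest communities.

Implements the compositional side of the analysis: Pielou evenness per nest,
Bray–Curtis dissimilarities on raw functional-group counts, a
distance-based permutational MANOVA with sequential (type-I) term entry,
a dispersion-homogeneity test (PERMDISP), beta regression of evenness on
nest predictors, and rank-abundance summaries per age class.

The PERMANOVA is implemented from the Gower-centred inner-product matrix
(McArdle & Anderson partitioning) rather than delegated, because the study
design needs sequential multi-term partitioning (age + connectivity +
age:connectivity) with free row permutation; single-factor results agree with
scikit-bio's one-way PERMANOVA.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permdisp as _skbio_permdisp
from statsmodels.othermod.betareg import BetaModel

from .catalog import StudyDataset

__all__ = [
    "EvennessRecord",
    "PermanovaResult",
    "pielou_evenness",
    "evenness_table",
    "bray_curtis",
    "permanova",
    "permdisp",
    "beta_regression",
    "BetaRegressionResult",
    "rank_abundance",
]


@dataclass(frozen=True)
class EvennessRecord:
    """Richness S, Shannon entropy H (nats) and Pielou evenness J = H/ln S.

    J is undefined when fewer than two groups are present (ln S = 0); the
    ``defined`` flag carries that state explicitly instead of a silent NaN.
    """

    nest_id: str
    S: int
    H: float
    J: float | None

    @property
    def defined(self) -> bool:
        return self.J is not None


def pielou_evenness(counts: dict[str, int] | np.ndarray, nest_id: str = "") -> EvennessRecord:
    """Pielou evenness of one abundance vector.

    H is computed over the positive counts with natural log; J = H / ln S.
    Raises on an all-zero vector.
    """
    values = np.asarray(
        list(counts.values()) if isinstance(counts, dict) else counts, dtype=float
    )
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError(f"nest {nest_id!r}: all counts are zero, evenness undefined")
    p = positive / positive.sum()
    h = float(-(p * np.log(p)).sum())
    s = int(positive.size)
    j = h / math.log(s) if s >= 2 else None
    return EvennessRecord(nest_id=nest_id, S=s, H=h, J=j)


def evenness_table(ds: StudyDataset) -> pd.DataFrame:
    """Per-nest evenness records joined with age class and connectivity."""
    rows = []
    for nest in ds.nests:
        rec = pielou_evenness(nest.abundance, nest.nest_id)
        rows.append(
            {
                "nest_id": rec.nest_id,
                "S": rec.S,
                "H": rec.H,
                "J": rec.J,
                "age_class": nest.age_class,
                "connectivity": nest.connectivity,
            }
        )
    return pd.DataFrame(rows).set_index("nest_id")


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray–Curtis dissimilarities between nests from a nest × group table.

    d(a, b) = Σ|x_a − x_b| / Σ(x_a + x_b), on raw counts (no transform).
    """
    if len(table) < 2:
        raise ValueError("need at least 2 nests")
    totals = table.sum(axis=1)
    empty = totals[totals == 0]
    if not empty.empty:
        raise ValueError(f"all-zero nest(s): {list(empty.index)}")
    d = squareform(pdist(table.to_numpy(dtype=float), metric="braycurtis"))
    return DistanceMatrix(d, ids=[str(i) for i in table.index])


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    """Sequential distance-based ANOVA table.

    ``terms`` maps term name to (df, SS, R2, pseudo-F, p); residual/total
    rows carry df and SS; R² fractions of all terms plus residual sum to 1.
    """

    terms: dict[str, dict[str, float]]
    residual: dict[str, float]
    total: dict[str, float]
    n_permutations: int
    seed: int | None

    def term(self, name: str, key: str) -> float:
        return self.terms[name][key]


def _design_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    """Numeric column(s) for one term; ':' denotes an interaction product."""
    parts = term.split(":")
    cols = np.ones(len(design))
    for part in parts:
        v = design[part]
        if v.dtype == object or str(v.dtype) == "category" or v.dtype == bool:
            codes, uniques = pd.factorize(v, sort=True)
            if len(uniques) < 2:
                raise ValueError(f"constant predictor {part!r}")
            if len(uniques) != 2:
                raise ValueError(f"factor {part!r} must have exactly 2 levels for this design")
            col = codes.astype(float)
        else:
            col = v.to_numpy(dtype=float)
        if np.ptp(col) == 0:
            raise ValueError(f"constant predictor {part!r}")
        cols = cols * col
    return cols.reshape(-1, 1)


def _hat(x: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    return q @ q.T


def permanova(
    d: DistanceMatrix,
    design: pd.DataFrame,
    terms: tuple[str, ...] = ("age_class", "connectivity", "age_class:connectivity"),
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational MANOVA on a distance matrix with sequential term entry.

    Partitions the total sum of squares tr(G), where G is the Gower-centred
    matrix of −d²/2, over the terms entered in order (type-I, mirroring
    adonis2 defaults), with free permutation of rows.  Permutation p-values
    use the add-one rule, p = (1 + #{F* ≥ F}) / (1 + n_perm), so they are
    never zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids = list(d.ids)
    if set(ids) != set(map(str, design.index)) or len(ids) != len(design):
        raise ValueError("design rows do not match distance-matrix ids")
    design = design.loc[[type(design.index[0])(i) for i in ids]]
    n = len(ids)

    a = -0.5 * np.asarray(d.data) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    ss_total = float(np.trace(g))

    # cumulative hat matrices: intercept, then one per added term
    x = np.ones((n, 1))
    hats = [_hat(x)]
    dfs = []
    for term in terms:
        cols = _design_columns(design, term)
        x = np.hstack([x, cols])
        hats.append(_hat(x))
        dfs.append(cols.shape[1])
    df_res = n - x.shape[1]

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        traces = np.array([float(np.trace(h @ gmat)) for h in hats])
        ss_terms = np.diff(traces)
        ss_res = float(np.trace(gmat)) - traces[-1]
        return ss_terms, ss_res

    ss_terms, ss_res = term_stats(g)
    ms_res = ss_res / df_res
    f_obs = (ss_terms / np.array(dfs)) / ms_res

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_t, ss_r = term_stats(gp)
        f_perm = (ss_t / np.array(dfs)) / (ss_r / df_res)
        # tolerance so permutations tying the observed labeling count as >=
        exceed += f_perm >= f_obs - 1e-12 * np.abs(f_obs)
    p = (1.0 + exceed) / (1.0 + n_perm)

    term_table = {
        term: {
            "df": dfs[k],
            "SS": float(ss_terms[k]),
            "R2": float(ss_terms[k] / ss_total),
            "F": float(f_obs[k]),
            "p": float(p[k]),
        }
        for k, term in enumerate(terms)
    }
    return PermanovaResult(
        terms=term_table,
        residual={"df": df_res, "SS": ss_res, "R2": ss_res / ss_total},
        total={"df": n - 1, "SS": ss_total, "R2": 1.0},
        n_permutations=n_perm,
        seed=seed,
    )


def permanova_exhaustive_f(d: DistanceMatrix, labels: pd.Series) -> tuple[float, float]:
    """Exact one-way PERMANOVA by full enumeration of label permutations.

    Brute-force reference for small n: returns (observed pseudo-F, exact p).
    Intended for tests; factorially slow.
    """
    design = pd.DataFrame({"g": labels})
    base = permanova(d, design, terms=("g",), n_perm=1, seed=0)
    f_obs = base.term("g", "F")
    values = list(labels)
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(values))):
        permuted = pd.Series([values[i] for i in perm], index=labels.index)
        f = permanova(d, pd.DataFrame({"g": permuted}), terms=("g",), n_perm=1, seed=0).term(
            "g", "F"
        )
        total += 1
        if f >= f_obs - 1e-12:
            count += 1
    return f_obs, count / total


def permdisp(
    d: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict[str, float]:
    """Homogeneity of multivariate dispersions (distance to spatial medians).

    Each nest's distance to its group's spatial median in principal-coordinate
    space feeds a one-way F test whose p-value comes from permutation.
    Delegates to scikit-bio's PERMDISP (median-based, with the usual
    negative-eigenvalue handling of the PCoA embedding).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    singles = counts[counts < 2]
    if not singles.empty:
        raise ValueError(f"singleton group(s): {list(singles.index)}")
    aligned = groups.loc[[type(groups.index[0])(i) for i in d.ids]]
    res = _skbio_permdisp(d, aligned.to_numpy(), permutations=n_perm, seed=seed)
    return {"F": float(res["test statistic"]), "p": float(res["p-value"]), "n_perm": n_perm}


# ---------------------------------------------------------------------------
# Beta regression of evenness


@dataclass(frozen=True)
class BetaRegressionResult:
    params: pd.Series
    bse: pd.Series
    wald_chi2: pd.Series
    wald_p: pd.Series
    converged: bool
    n: int
    shrunk: bool

    def coef(self, name: str) -> float:
        return float(self.params[name])


def beta_regression(
    j: pd.Series,
    design: pd.DataFrame,
    formula_terms: tuple[str, ...] = ("age_class", "connectivity", "age_class:connectivity"),
) -> BetaRegressionResult:
    """Beta regression of evenness on nest predictors (logit mean link).

    Responses must lie in (0, 1); exact boundary values are shrunk with the
    standard (y·(n−1) + 0.5)/n transform and the result is flagged.  Precision
    is a single constant.  Per-coefficient Wald χ² = (β̂/se)² with 1 df —
    with a two-level factor and single-df terms these are also the per-term
    statistics.
    """
    y = j.astype(float).copy()
    if ((y < 0) | (y > 1)).any():
        raise ValueError("responses must lie in [0, 1]")
    shrunk = bool(((y == 0) | (y == 1)).any())
    if shrunk:
        n = len(y)
        y = (y * (n - 1) + 0.5) / n
    df = design.loc[y.index].copy()
    df["J"] = y
    formula = "J ~ " + " + ".join(formula_terms).replace(":", ":")
    model = BetaModel.from_formula(formula, df)
    fit = model.fit(disp=False)
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError(f"beta regression did not converge: {fit.mle_retvals}")
    mean_names = [p for p in fit.params.index if p != "precision"]
    params = fit.params[mean_names]
    bse = fit.bse[mean_names]
    chi2 = (params / bse) ** 2
    pvals = pd.Series(stats.chi2.sf(chi2, df=1), index=chi2.index)
    return BetaRegressionResult(
        params=params,
        bse=bse,
        wald_chi2=chi2,
        wald_p=pvals,
        converged=True,
        n=len(y),
        shrunk=shrunk,
    )


def rank_abundance(ds: StudyDataset, by_age: bool = True) -> pd.DataFrame:
    """Mean relative abundance ± SE per functional group, per age class.

    Per nest, relative abundance = count / nest total; the class mean and
    standard error are taken across nests.  Groups are sorted by their pooled
    mean relative abundance (descending), ties broken by group id; the SE of
    a single-nest class is reported as NaN.
    """
    table = ds.abundance_table()
    meta = ds.metadata_table()
    rel = table.div(table.sum(axis=1), axis=0)
    classes = meta["age_class"] if by_age else pd.Series("all", index=meta.index)
    present = set(classes.unique())
    if by_age and present != {"new", "old"} and len(ds.nests) > 1:
        missing = {"new", "old"} - present
        if missing:
            raise ValueError(f"empty age class(es): {sorted(missing)}")
    pooled = rel.mean(axis=0)
    order = sorted(table.columns, key=lambda g: (-pooled[g], g))
    rows = []
    for cls in sorted(present):
        sub = rel.loc[classes[classes == cls].index]
        for rank, gid in enumerate(order, start=1):
            vals = sub[gid]
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
            rows.append(
                {
                    "age_class": cls,
                    "group": gid,
                    "rank": rank,
                    "mean_rel_abundance": float(vals.mean()),
                    "se": se,
                    "n_nests": len(vals),
                }
            )
    return pd.DataFrame(rows)


def association_totals(ds: StudyDataset) -> dict[str, int]:
    """Total individuals collected per association type across all nests."""
    table = ds.abundance_table()
    totals = {"obligate": 0, "facultative": 0}
    for g in ds.catalog:
        totals[g.association.value] += int(table[g.id].sum())
    return totals
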