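"""Community-matrix stability of nest food webs.

For every nest web a signed interaction matrix A* is sampled: each trophic
link contributes a negative effect of the consumer on its resource and a
positive effect of the resource on its consumer, each competition pair
contributes a negative effect in both directions, all drawn from N(mu, sigma)
(defaults mu = -0.1 for consumption and competition, +0.1 for the benefit,
sigma = 0.05).  Where a directed cell carries both a trophic and a
competitive effect — a taxon preying on its competitor — the two independent
draws are summed.  Self-regulation fixes the diagonal at -1.

Assuming Lotka-Volterra dynamics near equilibrium, the community matrix is
M = D A* with D the diagonal of equilibrium relative abundances; relative
(not absolute) abundances keep eigenvalues comparable across nests of very
different total abundance, since scaling a matrix scales all its eigenvalues.
Local asymptotic stability is read off the leading eigenvalue real part
Re(lambda_1): negative means return to equilibrium, more negative means a
faster return.  Each nest is summarised by the mean Re(lambda_1) over 50
replicate draws and the response log|mean|.

Four scenarios cross the abundance structure (observed vs perfectly even,
d_i = 1/n) with the topology (observed vs randomized by shuffling all
off-diagonal elements of the sampled matrix), isolating whether stability
differences between nest age classes come from the abundance distribution or
from the arrangement of the interactions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .foodweb import LocalFoodWeb

__all__ = [
    "StrengthParams",
    "ScenarioSpec",
    "StabilityResult",
    "SCENARIOS",
    "sample_interaction_matrix",
    "community_matrix",
    "leading_eigen_real",
    "rewire",
    "nest_stability",
    "run_scenarios",
]


@dataclass(frozen=True)
class StrengthParams:
    """Interaction-strength distribution parameters.

    mu_consumption: mean effect of a consumer on its resource (default -0.1).
    mu_benefit: mean effect of a resource on its consumer (default +0.1).
    mu_competition: mean effect between basal-resource competitors (-0.1).
    sigma: SD of every draw (default 0.05).  diagonal: self-regulation (-1).
    """

    mu_consumption: float = -0.1
    mu_benefit: float = 0.1
    mu_competition: float = -0.1
    sigma: float = 0.05
    diagonal: float = -1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.diagonal >= 0:
            raise ValueError("diagonal self-regulation must be negative")


@dataclass(frozen=True)
class ScenarioSpec:
    """One abundance x topology scenario."""

    abundance_mode: str  # "observed" | "even"
    topology_mode: str  # "observed" | "randomized"
    params: StrengthParams = StrengthParams()
    n_reps: int = 50

    def __post_init__(self) -> None:
        if self.abundance_mode not in ("observed", "even"):
            raise ValueError(f"unknown abundance_mode {self.abundance_mode!r}")
        if self.topology_mode not in ("observed", "randomized"):
            raise ValueError(f"unknown topology_mode {self.topology_mode!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    @property
    def scenario_id(self) -> str:
        return f"{self.abundance_mode}/{self.topology_mode}"


#: The four study scenarios in presentation order.
SCENARIOS: tuple[tuple[str, str], ...] = (
    ("observed", "observed"),
    ("observed", "randomized"),
    ("even", "observed"),
    ("even", "randomized"),
)


@dataclass(frozen=True)
class StabilityResult:
    """Replicate leading-eigenvalue real parts for one nest x scenario."""

    nest_id: str
    scenario_id: str
    replicate_re_lambda1: tuple[float, ...]
    mean_re_lambda1: float
    response: float | None  # log(|mean|); None when the mean is >= 0
    community_size: int
    stable: bool


def sample_interaction_matrix(
    web: LocalFoodWeb, params: StrengthParams, rng: np.random.Generator
) -> np.ndarray:
    """One draw of the signed interaction matrix A* for a web.

    Convention: entry (i, j) is the effect of member j on member i.  Cells
    that carry both a trophic and a competitive effect receive the sum of two
    independent draws; all other off-diagonals are exactly zero.
    """
    if not web.members:
        raise ValueError("empty web")
    idx = {m: k for k, m in enumerate(web.members)}
    n = len(web.members)
    a = np.zeros((n, n))
    for consumer, resource in sorted(web.links):
        c, r = idx[consumer], idx[resource]
        a[r, c] += rng.normal(params.mu_consumption, params.sigma)  # consumer harms resource
        a[c, r] += rng.normal(params.mu_benefit, params.sigma)  # resource feeds consumer
    for pair in sorted(web.competition, key=sorted):
        i, j = (idx[m] for m in sorted(pair))
        a[i, j] += rng.normal(params.mu_competition, params.sigma)
        a[j, i] += rng.normal(params.mu_competition, params.sigma)
    np.fill_diagonal(a, params.diagonal)
    return a


def community_matrix(rel_abund: np.ndarray, a: np.ndarray) -> np.ndarray:
    """M = D A*: row i of A* scaled by the relative abundance d_i."""
    d = np.asarray(rel_abund, dtype=float)
    if d.shape[0] != a.shape[0] or a.shape[0] != a.shape[1]:
        raise ValueError("dimension mismatch between abundances and matrix")
    return d[:, None] * a


def leading_eigen_real(m: np.ndarray) -> float:
    """Max real part over all (possibly complex) eigenvalues of M."""
    return float(np.linalg.eigvals(m).real.max())


def rewire(a: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle all off-diagonal elements (zeros included); diagonal untouched."""
    n = a.shape[0]
    out = a.copy()
    mask = ~np.eye(n, dtype=bool)
    vals = out[mask]
    rng.shuffle(vals)
    out[mask] = vals
    return out


def _even_abund(n: int) -> np.ndarray:
    return np.full(n, 1.0 / n)


def nest_stability(
    web: LocalFoodWeb,
    spec: ScenarioSpec,
    seed_seq: np.random.SeedSequence | int | None = None,
) -> StabilityResult:
    """Replicate-averaged stability of one nest under one scenario.

    Each replicate draws a fresh A* from its own substream (so any subset of
    replicates is reproducible in isolation), optionally rewires it, scales
    by observed or even relative abundances, and records Re(lambda_1).
    Unstable replicates are retained; the log response is only defined when
    the replicate mean is negative.
    """
    if not isinstance(seed_seq, np.random.SeedSequence):
        seed_seq = np.random.SeedSequence(seed_seq)
    n = len(web.members)
    d = (
        np.array([web.rel_abund[m] for m in web.members])
        if spec.abundance_mode == "observed"
        else _even_abund(n)
    )
    values = []
    for child in seed_seq.spawn(spec.n_reps):
        rng = np.random.default_rng(child)
        a = sample_interaction_matrix(web, spec.params, rng)
        if spec.topology_mode == "randomized":
            a = rewire(a, rng)
        values.append(leading_eigen_real(community_matrix(d, a)))
    mean = float(np.mean(values))
    if mean == 0.0:
        raise ValueError(f"nest {web.nest_id!r}: mean Re(lambda1) is exactly 0, log response undefined")
    return StabilityResult(
        nest_id=web.nest_id,
        scenario_id=spec.scenario_id,
        replicate_re_lambda1=tuple(values),
        mean_re_lambda1=mean,
        response=float(np.log(abs(mean))) if mean < 0 else None,
        community_size=n,
        stable=mean < 0,
    )


def _nest_scenario_seed(root_seed: int, nest_id: str, scenario_id: str, mu_key: float) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [
            int(root_seed) % (2**31),
            zlib.crc32(nest_id.encode()),
            zlib.crc32(scenario_id.encode()),
            zlib.crc32(repr(round(mu_key, 10)).encode()),
        ]
    )


def run_scenarios(
    webs: dict[str, LocalFoodWeb],
    params_grid: tuple[StrengthParams, ...] = (StrengthParams(),),
    n_reps: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Full cross of the four scenarios x parameter grid x nests.

    Deterministic given ``seed``.  Per-nest failures (a web whose replicate
    mean is nonnegative) are flagged rows, not aborts.  Long-format columns:
    nest_id, scenario, abundance_mode, topology_mode, mu, sigma, n,
    mean_re_lambda1, response, stable, error.
    """
    if not webs:
        raise ValueError("no webs supplied")
    rows = []
    for params in params_grid:
        for abundance_mode, topology_mode in SCENARIOS:
            spec = ScenarioSpec(abundance_mode, topology_mode, params=params, n_reps=n_reps)
            for nest_id in sorted(webs):
                ss = _nest_scenario_seed(seed, nest_id, spec.scenario_id, params.mu_consumption)
                row = {
                    "nest_id": nest_id,
                    "scenario": spec.scenario_id,
                    "abundance_mode": abundance_mode,
                    "topology_mode": topology_mode,
                    "mu": params.mu_consumption,
                    "sigma": params.sigma,
                    "n": len(webs[nest_id].members),
                }
                try:
                    res = nest_stability(webs[nest_id], spec, ss)
                    row.update(
                        mean_re_lambda1=res.mean_re_lambda1,
                        response=res.response,
                        stable=res.stable,
                        error="",
                    )
                except ValueError as exc:
                    row.update(mean_re_lambda1=np.nan, response=np.nan, stable=False, error=str(exc))
                rows.append(row)
    return pd.DataFrame(rows)
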