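"""Descriptor-subset selection: stepwise, Lasso/LARS, GA, and GreedGene.

Four algorithms each return exactly k descriptor names (default k = 5,
the subset size used throughout the S2R QSAR models). The default
fitness is leave-one-out Q-squared of the k-descriptor ordinary
least-squares model, which rewards predictive rather than merely
descriptive fits.

GreedGene is the hybrid selector: several independent GA runs vote on a
consensus descriptor core, the core is completed to size k by exhaustive
enumeration over the remaining columns, and a final correlated-swap
refinement tries each selected descriptor's correlation-group partners.
The exhaustive stage costs C(p - |core|, k - |core|) model fits — e.g.
completing a 2-descriptor core out of 160 columns takes C(158, 3) =
644,956 fits instead of the C(160, 5) = 820,384,032 a full enumeration
would need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .descriptors import DescriptorMatrix

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "SelectionError",
    "count_combinations",
    "forward_stepwise",
    "lasso_path_select",
    "ga_select",
    "greedgene",
    "FitnessCache",
]


class SelectionError(ValueError):
    pass


def count_combinations(n: int, k: int) -> int:
    """Exact binomial coefficient C(n, k); plans exhaustive-search budgets."""
    if n < 0 or k < 0:
        raise SelectionError(f"C(n, k) needs non-negative arguments; got n={n}, k={k}")
    if k > n:
        raise SelectionError(f"C(n, k) undefined for k > n; got n={n}, k={k}")
    return math.comb(n, k)


@dataclass
class SelectionConfig:
    """Tunable parameters shared by the selection algorithms.

    ``fitness``: "q2_loo" (default; leave-one-out Q2 of the OLS refit) or
    "r2_train". GA parameters follow common practice for subset-selection
    GAs; ``ga_mutation_rate`` of None means 1/p, set per matrix.
    ``core_consensus_fraction`` is the fraction of GA repeats a descriptor
    must appear in to join the GreedGene core. ``exhaustive_budget`` caps
    the number of model fits the exhaustive completion may require.
    """

    k: int = 5
    fitness: str = "q2_loo"
    ga_population: int = 100
    ga_generations: int = 50
    ga_mutation_rate: float | None = None
    ga_crossover_rate: float = 0.8
    ga_repeats: int = 5
    core_consensus_fraction: float = 0.8
    lasso_lambda_path: Sequence[float] | None = None
    exhaustive_budget: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise SelectionError("k must be >= 1")
        if not (0.0 < self.core_consensus_fraction <= 1.0):
            raise SelectionError("core_consensus_fraction must be in (0, 1]")
        if self.fitness not in ("q2_loo", "r2_train"):
            raise SelectionError(f"unknown fitness {self.fitness!r}")


@dataclass
class SelectionResult:
    """A chosen descriptor subset with provenance of the search."""

    algorithm: str
    descriptor_names: list[str]
    fitness_value: float
    core_names: list[str] = field(default_factory=list)
    exhaustive_evaluations: int = 0
    trace: list[float] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "descriptor_names": self.descriptor_names,
            "fitness_value": self.fitness_value,
            "core_names": self.core_names,
            "exhaustive_evaluations": self.exhaustive_evaluations,
            "trace": self.trace,
        }


class FitnessCache:
    """Memoized subset fitness on a fixed (X, y).

    Fitness of a subset is the chosen statistic of the OLS model on those
    columns; rank-deficient subsets score -inf. The LOO Q2 uses the
    hat-matrix identity (one QR factorization per subset).
    """

    def __init__(self, matrix: DescriptorMatrix, y: np.ndarray, fitness: str = "q2_loo"):
        self.names = list(matrix.descriptor_names)
        self.X = np.asarray(matrix.values, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.fitness = fitness
        n = len(self.y)
        self._ones = np.ones((n, 1))
        self._ss_tot = float(((self.y - self.y.mean()) ** 2).sum())
        if self._ss_tot == 0.0:
            raise SelectionError("response has zero variance; fitness undefined")
        self._cache: dict[frozenset[int], float] = {}
        self.evaluations = 0

    def __call__(self, idx: Sequence[int]) -> float:
        key = frozenset(idx)
        if key in self._cache:
            return self._cache[key]
        self.evaluations += 1
        D = np.hstack([self._ones, self.X[:, sorted(key)]])
        n, p = D.shape
        val = -math.inf
        if n > p + 1:
            Q, R = np.linalg.qr(D)
            diag = np.abs(np.diag(R))
            if diag.min() > 1e-10 * max(diag.max(), 1.0):
                beta = np.linalg.solve(R, Q.T @ self.y)
                resid = self.y - D @ beta
                if self.fitness == "r2_train":
                    val = 1.0 - float((resid**2).sum()) / self._ss_tot
                else:
                    h = (Q**2).sum(axis=1)
                    if h.max() < 1.0 - 1e-12:
                        press = float(((resid / (1.0 - h)) ** 2).sum())
                        val = 1.0 - press / self._ss_tot
        self._cache[key] = val
        return val

    def name_tuple(self, idx: Sequence[int]) -> tuple[str, ...]:
        return tuple(sorted(self.names[i] for i in idx))


def _argbest(candidates: list[tuple[int, ...]], cache: FitnessCache) -> tuple[float, tuple[int, ...]]:
    best_fit = -math.inf
    best: tuple[int, ...] | None = None
    best_names: tuple[str, ...] | None = None
    for c in candidates:
        f = cache(c)
        names = cache.name_tuple(c)
        if f > best_fit or (f == best_fit and best_names is not None and names < best_names):
            best_fit, best, best_names = f, c, names
    if best is None:
        raise SelectionError("no evaluable candidate subsets")
    return best_fit, best


def forward_stepwise(
    matrix: DescriptorMatrix,
    y: np.ndarray,
    k: int = 5,
    fitness: str = "q2_loo",
    classic: bool = False,
) -> SelectionResult:
    """Greedy forward selection of k descriptors.

    At each step the descriptor whose addition maximizes the refit
    model's fitness is added (ties broken by name). With
    ``classic=True`` entry is instead driven by correlation: the first
    descriptor is the one most correlated with the response and each
    subsequent entry maximizes absolute correlation with the current
    residual (partial-correlation entry), as in traditional forward
    stepwise regression; the fitness of the final subset is still
    reported on the common scale.
    """
    y = np.asarray(y, dtype=float)
    p = matrix.n_descriptors
    if not (1 <= k <= p):
        raise SelectionError(f"k must be in [1, {p}]; got {k}")
    if len(y) <= k + 1:
        raise SelectionError("need n > k + 1 observations")
    cache = FitnessCache(matrix, y, fitness)
    selected: list[int] = []
    trace: list[float] = []
    if classic:
        X = cache.X
        resid = y - y.mean()
        for _ in range(k):
            best_j, best_c = None, -1.0
            for j in range(p):
                if j in selected:
                    continue
                col = X[:, j] - X[:, j].mean()
                denom = math.sqrt(float((col**2).sum()) * float((resid**2).sum()))
                c = abs(float(col @ resid) / denom) if denom > 0 else 0.0
                if c > best_c or (c == best_c and best_j is not None and cache.names[j] < cache.names[best_j]):
                    best_j, best_c = j, c
            selected.append(best_j)
            # refit and update residual
            D = np.hstack([np.ones((len(y), 1)), X[:, selected]])
            beta, *_ = np.linalg.lstsq(D, y, rcond=None)
            resid = y - D @ beta
            trace.append(cache(tuple(selected)))
    else:
        for _ in range(k):
            cands = [tuple(selected + [j]) for j in range(p) if j not in selected]
            evaluable = [c for c in cands if cache(c) > -math.inf]
            if not evaluable:
                raise SelectionError("every candidate addition produced a singular design")
            fit, best = _argbest(evaluable, cache)
            selected = list(best)
            # keep entry order: append the newly added index
            trace.append(fit)
    # preserve entry order in names
    order = selected
    final_fit = cache(tuple(order))
    return SelectionResult(
        algorithm="stepwise_classic" if classic else "stepwise",
        descriptor_names=[cache.names[j] for j in order],
        fitness_value=final_fit,
        trace=trace,
    )

def lasso_path_select(
    matrix: DescriptorMatrix,
    y: np.ndarray,
    k: int = 5,
    lambda_path: Sequence[float] | None = None,
    fitness: str = "q2_loo",
) -> SelectionResult:
    """First k variables to enter the LARS/Lasso regularization path.

    Columns are standardized internally (zero mean, unit variance); the
    path is traversed from large to small penalty and the first k
    distinct variables to activate are selected. The reported model is an
    unpenalized OLS refit on those k descriptors. ``lambda_path``, when
    given, restricts the path to those penalty values (descending).
    """
    from sklearn.linear_model import lars_path

    y = np.asarray(y, dtype=float)
    p = matrix.n_descriptors
    if not (1 <= k <= p):
        raise SelectionError(f"k must be in [1, {p}]; got {k}")
    X = matrix.values
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Xs = (X - mu) / sd
    if lambda_path is not None:
        alphas_arg = np.sort(np.asarray(lambda_path, dtype=float))[::-1]
        if np.any(alphas_arg <= 0):
            raise SelectionError("lambda path values must be positive")
        _, active, coefs = lars_path(Xs, y - y.mean(), method="lasso", alpha_min=float(alphas_arg.min()))
    else:
        _, active, coefs = lars_path(Xs, y - y.mean(), method="lasso")
    entry_order: list[int] = []
    for j in active:
        j = int(j)
        if j not in entry_order:
            entry_order.append(j)
        if len(entry_order) == k:
            break
    if len(entry_order) < k:
        raise SelectionError(
            f"only {len(entry_order)} variables entered the Lasso/LARS path; cannot select k={k}"
        )
    cache = FitnessCache(matrix, y, fitness)
    fit = cache(tuple(entry_order))
    return SelectionResult(
        algorithm="lasso_lars",
        descriptor_names=[cache.names[j] for j in entry_order],
        fitness_value=fit,
    )


# ---------------------------------------------------------------------------
# Genetic algorithm

def _repair(subset: set[int], k: int, p: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Force a candidate gene set to exactly k distinct indices."""
    subset = set(subset)
    while len(subset) > k:
        subset.remove(int(rng.choice(sorted(subset))))
    while len(subset) < k:
        j = int(rng.integers(p))
        subset.add(j)
    return tuple(sorted(subset))


def ga_select(
    matrix: DescriptorMatrix,
    y: np.ndarray,
    config: SelectionConfig | None = None,
    cache: "FitnessCache | None" = None,
) -> SelectionResult:
    """Genetic-algorithm subset selection with an exactly-k representation.

    Each descriptor is a gene that is present or absent; individuals are
    repaired to exactly k present genes after crossover and mutation
    (the modeled QSAR protocol always builds exactly-k-descriptor
    models). Tournament selection (size 3), uniform crossover drawing
    from the union of the parents' genes, and swap mutation (an included
    gene trades places with an excluded one). Elitist: the best-ever
    individual is preserved and returned. Deterministic given
    ``config.seed``.
    """
    config = config or SelectionConfig()
    y = np.asarray(y, dtype=float)
    p = matrix.n_descriptors
    k = config.k
    if not (1 <= k <= p):
        raise SelectionError(f"k must be in [1, {p}]; got {k}")
    if config.ga_population < 2:
        raise SelectionError("GA population must be >= 2")
    cache = cache or FitnessCache(matrix, y, config.fitness)
    rng = np.random.default_rng(config.seed)
    mut_rate = config.ga_mutation_rate if config.ga_mutation_rate is not None else 1.0 / p

    if p == k:
        only = tuple(range(p))
        return SelectionResult(
            algorithm="ga",
            descriptor_names=[cache.names[j] for j in only],
            fitness_value=cache(only),
            trace=[cache(only)],
        )

    pop = [tuple(sorted(rng.choice(p, size=k, replace=False))) for _ in range(config.ga_population)]
    fits = [cache(ind) for ind in pop]
    best_fit, best = _argbest(pop, cache)
    trace = [best_fit]

    def tournament() -> tuple[int, ...]:
        idx = rng.integers(len(pop), size=3)
        return pop[max(idx, key=lambda i: fits[i])]

    for _ in range(config.ga_generations):
        nxt: list[tuple[int, ...]] = [best]  # elitism
        while len(nxt) < config.ga_population:
            a, b = tournament(), tournament()
            if rng.random() < config.ga_crossover_rate:
                union = sorted(set(a) | set(b))
                child = set()
                for g in union:
                    if g in a and g in b:
                        child.add(g)
                    elif rng.random() < 0.5:
                        child.add(g)
                child_t = _repair(child, k, p, rng)
            else:
                child_t = a
            # swap mutation per included gene
            child_set = set(child_t)
            for g in sorted(child_set):
                if rng.random() < mut_rate:
                    pool = [j for j in range(p) if j not in child_set]
                    if pool:
                        child_set.remove(g)
                        child_set.add(int(rng.choice(pool)))
            nxt.append(tuple(sorted(child_set)))
        pop = nxt
        fits = [cache(ind) for ind in pop]
        gen_fit, gen_best = _argbest(pop, cache)
        if gen_fit > best_fit or (
            gen_fit == best_fit and cache.name_tuple(gen_best) < cache.name_tuple(best)
        ):
            best_fit, best = gen_fit, gen_best
        trace.append(best_fit)

    return SelectionResult(
        algorithm="ga",
        descriptor_names=sorted(cache.names[j] for j in best),
        fitness_value=best_fit,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# GreedGene

def greedgene(
    matrix: DescriptorMatrix,
    y: np.ndarray,
    config: SelectionConfig | None = None,
    correlation_groups: Mapping[str, Sequence[str]] | None = None,
    swap_candidates: DescriptorMatrix | None = None,
) -> SelectionResult:
    """GA consensus core + exhaustive completion + correlated-swap check.

    1. Run the GA ``ga_repeats`` times with derived seeds
       (``seed + repeat``); each run votes for its best subset.
    2. The core is every descriptor appearing in at least
       ``core_consensus_fraction`` of the repeats' results; if the core
       already has k or more members it is truncated to the k most
       frequent (frequency, then name).
    3. Every completion of the core to size k over the remaining columns
       is evaluated exhaustively — C(p - |core|, k - |core|) model fits,
       refused if above ``exhaustive_budget``. The GA repeats' own best
       subsets are also kept as candidates, so the result can never fall
       below the best GA repeat.
    4. Correlated-swap refinement: each selected descriptor is tentatively
       replaced by each member of its correlation group (descriptors
       pruned earlier at |r| > 0.9); strict improvements are kept and the
       sweep repeats until no swap improves the fitness. Group members
       that were pruned out of ``matrix`` are reachable when
       ``swap_candidates`` (e.g. the pre-pruning screened matrix) supplies
       their columns; the GA and exhaustive stages still search only the
       pruned columns.
    """
    config = config or SelectionConfig()
    y = np.asarray(y, dtype=float)
    p = matrix.n_descriptors
    k = config.k
    if not (1 <= k <= p):
        raise SelectionError(f"k must be in [1, {p}]; got {k}")

    search_matrix = matrix
    if swap_candidates is not None and correlation_groups:
        have = set(matrix.descriptor_names)
        pool = set(swap_candidates.descriptor_names)
        extra: list[str] = []
        for rep, members in correlation_groups.items():
            if rep == "__degenerate__":
                continue
            for m in members:
                if m not in have and m in pool and m not in extra:
                    extra.append(m)
        if extra:
            extra_vals = swap_candidates.to_frame().loc[matrix.molecule_ids, extra].to_numpy(float)
            search_matrix = DescriptorMatrix(
                matrix.molecule_ids,
                matrix.descriptor_names + extra,
                np.column_stack([matrix.values, extra_vals]),
                matrix.provider,
            )

    cache = FitnessCache(search_matrix, y, config.fitness)
    name_to_idx = {n: j for j, n in enumerate(cache.names)}

    # 1. repeated GA
    repeat_results: list[SelectionResult] = []
    for r in range(config.ga_repeats):
        cfg = SelectionConfig(
            k=k,
            fitness=config.fitness,
            ga_population=config.ga_population,
            ga_generations=config.ga_generations,
            ga_mutation_rate=config.ga_mutation_rate,
            ga_crossover_rate=config.ga_crossover_rate,
            seed=config.seed + r,
        )
        repeat_results.append(ga_select(matrix, y, cfg, cache=cache))

    # 2. consensus core
    counts: dict[str, int] = {}
    for res in repeat_results:
        for n in res.descriptor_names:
            counts[n] = counts.get(n, 0) + 1
    need = config.core_consensus_fraction * config.ga_repeats
    core = sorted(n for n, c in counts.items() if c >= need)
    if len(core) >= k:
        core = sorted(sorted(core, key=lambda n: (-counts[n], n))[:k])
    core_idx = tuple(name_to_idx[n] for n in core)

    # 3. exhaustive completion
    n_eval = count_combinations(p - len(core), k - len(core))
    if n_eval > config.exhaustive_budget:
        raise SelectionError(
            f"exhaustive completion needs C({p - len(core)}, {k - len(core)}) = {n_eval} "
            f"model fits, above the budget of {config.exhaustive_budget}"
        )
    remaining = [j for j in range(p) if j not in core_idx]
    best_fit, best = -math.inf, None
    best_names: tuple[str, ...] | None = None
    for extra in combinations(remaining, k - len(core)):
        cand = tuple(sorted(core_idx + extra))
        f = cache(cand)
        names = cache.name_tuple(cand)
        if f > best_fit or (f == best_fit and best_names is not None and names < best_names):
            best_fit, best, best_names = f, cand, names
    # GA repeats' own winners stay in the candidate pool
    for res in repeat_results:
        cand = tuple(sorted(name_to_idx[n] for n in res.descriptor_names))
        f = cache(cand)
        names = cache.name_tuple(cand)
        if f > best_fit or (f == best_fit and names < best_names):
            best_fit, best, best_names = f, cand, names
    if best is None:
        raise SelectionError("no evaluable completion of the consensus core")

    # 4. correlated-swap refinement
    groups = {str(kk): list(v) for kk, v in (correlation_groups or {}).items()}
    member_of: dict[str, list[str]] = {}
    for rep, members in groups.items():
        if rep == "__degenerate__":
            continue
        for m in members:
            member_of[m] = [x for x in members if x != m] + ([rep] if rep != m and rep not in members else [])
    improved = True
    current = set(best)
    while improved:
        improved = False
        for j in sorted(current):
            partners = member_of.get(cache.names[j], [])
            for pname in partners:
                pj = name_to_idx.get(pname)
                if pj is None or pj in current:
                    continue
                trial = tuple(sorted((current - {j}) | {pj}))
                if cache(trial) > best_fit:
                    best_fit, current = cache(trial), set(trial)
                    improved = True
                    break
            if improved:
                break

    return SelectionResult(
        algorithm="greedgene",
        descriptor_names=sorted(cache.names[j] for j in current),
        fitness_value=best_fit,
        core_names=core,
        exhaustive_evaluations=n_eval,
        trace=[r.fitness_value for r in repeat_results],
    )
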