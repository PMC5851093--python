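"""Likelihood-based assignment of MHC alleles to duplicated loci.

When several near-identical loci are co-amplified by one primer pair, each
individual yields a pooled, locus-unresolved set of alleles (2–4 distinct
sequences for a two-locus system). This module partitions the allele panel
into loci by maximizing a Hardy–Weinberg genotype likelihood over the
partition, scoring candidate partitions ("allele configurations") with AIC
or BIC and searching the partition space with simulated annealing; an
exhaustive enumerator over set partitions serves as an oracle for small
panels.

For a candidate partition, an individual's observed set decomposes into
per-locus genotypes: a locus holding two of the individual's alleles is a
heterozygote, one allele a homozygote (or, optionally, a heterozygote with a
null allele), zero alleles is only possible as a null homozygote. The
likelihood of the individual is the sum over all compatible decompositions of
the product of per-locus HWE genotype probabilities; locus allele frequencies
are maximum-likelihood estimates obtained by EM over the latent
decompositions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_model import MISSING, GenotypeDataset, ObservedAlleleSet

NULL_ALLELE = "<null>"

INFEASIBLE = float("inf")


@dataclass
class SAOptions:
    """Simulated-annealing schedule and model options."""

    t0: float = 10.0
    cool: float = 0.99
    steps_per_temp: int = 20
    t_min: float = 1e-3
    cycles: int = 5
    criterion: str = "AIC"
    seed: int = 0
    allow_null: bool = False

    def __post_init__(self) -> None:
        if self.t0 <= 0:
            raise ValueError("t0 must be > 0")
        if not 0 < self.cool < 1:
            raise ValueError("cool must be in (0, 1)")
        if self.steps_per_temp < 1:
            raise ValueError("steps_per_temp must be >= 1")
        if self.t_min <= 0 or self.t_min >= self.t0:
            raise ValueError("t_min must be in (0, t0)")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.criterion not in ("AIC", "BIC"):
            raise ValueError("criterion must be AIC or BIC")


@dataclass
class AlleleConfiguration:
    """A partition of alleles into loci with its fitted HWE likelihood."""

    partition: dict[str, int]  # allele name -> locus index 1..m
    m: int
    freqs: list[dict[str, float]]  # per locus: allele -> frequency
    loglik: float
    n_params: int
    aic: float
    bic: float
    n_individuals: int
    criterion: str = "AIC"

    @property
    def score(self) -> float:
        return self.aic if self.criterion == "AIC" else self.bic

    def canonical_partition(self) -> tuple[tuple[str, ...], ...]:
        """Locus-label-free canonical form: blocks sorted by allele names."""
        blocks: dict[int, list[str]] = {}
        for a, l in self.partition.items():
            blocks.setdefault(l, []).append(a)
        return tuple(sorted(tuple(sorted(b)) for b in blocks.values()))


Decomposition = tuple[tuple[str, str], ...]  # per locus, unordered genotype


def enumerate_decompositions(
    obs: ObservedAlleleSet | frozenset[str],
    partition: dict[str, int],
    m: int,
    allow_null: bool = False,
) -> list[Decomposition]:
    """All per-locus genotype decompositions compatible with an observed set.

    Returns the empty list when some locus receives three or more of the
    individual's alleles (or zero without ``allow_null``): the configuration
    cannot explain the observation.
    """
    alleles = obs.alleles if isinstance(obs, ObservedAlleleSet) else obs
    per_locus: list[list[str]] = [[] for _ in range(m)]
    for a in sorted(alleles):
        if a not in partition:
            raise KeyError(f"allele {a!r} not covered by partition")
        per_locus[partition[a] - 1].append(a)
    locus_options: list[list[tuple[str, str]]] = []
    for held in per_locus:
        if len(held) > 2:
            return []
        if len(held) == 2:
            locus_options.append([(held[0], held[1])])
        elif len(held) == 1:
            opts = [(held[0], held[0])]
            if allow_null:
                opts.append((held[0], NULL_ALLELE))
            locus_options.append(opts)
        else:
            if not allow_null:
                return []
            locus_options.append([(NULL_ALLELE, NULL_ALLELE)])
    return [tuple(combo) for combo in itertools.product(*locus_options)]


def _locus_alleles(partition: dict[str, int], m: int, allow_null: bool) -> list[list[str]]:
    held: list[list[str]] = [[] for _ in range(m)]
    for a in sorted(partition):
        held[partition[a] - 1].append(a)
    if allow_null:
        for h in held:
            h.append(NULL_ALLELE)
    return held


@dataclass
class EMResult:
    freqs: list[dict[str, float]]
    loglik: float
    n_iter: int
    loglik_history: list[float] = field(default_factory=list)
    feasible: bool = True


def em_allele_frequencies(
    observations: list[ObservedAlleleSet],
    partition: dict[str, int],
    m: int,
    tol: float = 1e-8,
    max_iter: int = 1000,
    allow_null: bool = False,
) -> EMResult:
    """ML allele frequencies under HWE by EM over latent decompositions.

    The log-likelihood is guaranteed non-decreasing across iterations; the
    trajectory is recorded in ``loglik_history`` so callers can assert
    monotonicity. An individual with no compatible decomposition makes the
    configuration infeasible (``feasible=False``, ``loglik=-inf``).
    """
    held = _locus_alleles(partition, m, allow_null)

    # group identical observed sets
    groups: dict[frozenset[str], int] = {}
    for o in observations:
        groups[o.alleles] = groups.get(o.alleles, 0) + 1
    decomps: dict[frozenset[str], list[Decomposition]] = {}
    for key in groups:
        d = enumerate_decompositions(key, partition, m, allow_null)
        if not d:
            return EMResult(freqs=[], loglik=-math.inf, n_iter=0, feasible=False)
        decomps[key] = d

    n = len(observations)
    freqs = [{a: 1.0 / len(h) for a in h} for h in held]

    def geno_prob(locus: int, g: tuple[str, str]) -> float:
        pa = freqs[locus][g[0]]
        pb = freqs[locus][g[1]]
        return pa * pa if g[0] == g[1] else 2.0 * pa * pb

    history: list[float] = []
    loglik = -math.inf
    it = 0
    for it in range(1, max_iter + 1):
        counts = [dict.fromkeys(h, 0.0) for h in held]
        new_loglik = 0.0
        for key, weight in groups.items():
            probs = []
            for d in decomps[key]:
                p = 1.0
                for locus, g in enumerate(d):
                    p *= geno_prob(locus, g)
                probs.append(p)
            total = sum(probs)
            if total <= 0.0:
                return EMResult(
                    freqs=freqs, loglik=-math.inf, n_iter=it, feasible=False
                )
            new_loglik += weight * math.log(total)
            for d, p in zip(decomps[key], probs):
                w = weight * p / total
                for locus, g in enumerate(d):
                    counts[locus][g[0]] += w
                    counts[locus][g[1]] += w
        history.append(new_loglik)
        if new_loglik - loglik < tol and it > 1:
            loglik = new_loglik
            break
        loglik = new_loglik
        freqs = [
            {a: c / (2.0 * n) for a, c in locus_counts.items()}
            for locus_counts in counts
        ]
    return EMResult(
        freqs=freqs, loglik=loglik, n_iter=it, loglik_history=history, feasible=True
    )


def score_configuration(
    observations: list[ObservedAlleleSet],
    partition: dict[str, int],
    m: int,
    criterion: str = "AIC",
    allow_null: bool = False,
    tol: float = 1e-8,
) -> AlleleConfiguration:
    """Fit and score one allele configuration by AIC or BIC.

    The parameter count is ``k = sum_l (k_l - 1)`` over per-locus allele
    counts (a null allele, when enabled, counts as one extra allele at its
    locus). Infeasible configurations score ``+inf``.
    """
    held = _locus_alleles(partition, m, allow_null)
    if any(len(h) == 0 for h in held):
        raise ValueError("every locus must hold at least one allele")
    n = len(observations)
    em = em_allele_frequencies(
        observations, partition, m, tol=tol, allow_null=allow_null
    )
    k = sum(len(h) - 1 for h in held)
    if not em.feasible:
        return AlleleConfiguration(
            partition=dict(partition),
            m=m,
            freqs=[],
            loglik=-math.inf,
            n_params=k,
            aic=INFEASIBLE,
            bic=INFEASIBLE,
            n_individuals=n,
            criterion=criterion,
        )
    aic = 2.0 * k - 2.0 * em.loglik
    bic = k * math.log(n) - 2.0 * em.loglik
    return AlleleConfiguration(
        partition=dict(partition),
        m=m,
        freqs=em.freqs,
        loglik=em.loglik,
        n_params=k,
        aic=aic,
        bic=bic,
        n_individuals=n,
        criterion=criterion,
    )


# ---------------------------------------------------------------------------
# Search


def _partition_key(assign: tuple[int, ...]) -> tuple[int, ...]:
    """Canonical restricted-growth relabeling of a locus assignment vector."""
    relabel: dict[int, int] = {}
    out = []
    for x in assign:
        if x not in relabel:
            relabel[x] = len(relabel)
        out.append(relabel[x])
    return tuple(out)


class _ConfigCache:
    """Memoizes configuration scores per canonical partition."""

    def __init__(self, observations, allele_names, m, criterion, allow_null):
        self.observations = observations
        self.allele_names = allele_names
        self.index = {a: i for i, a in enumerate(allele_names)}
        self.m = m
        self.criterion = criterion
        self.allow_null = allow_null
        self.cache: dict[tuple[int, ...], AlleleConfiguration] = {}
        # unique observed sets as index lists, with multiplicities
        groups: dict[frozenset[str], int] = {}
        for o in observations:
            groups[o.alleles] = groups.get(o.alleles, 0) + 1
        self.groups = [
            ([self.index[a] for a in key], w) for key, w in groups.items()
        ]

    def violations(self, assign: tuple[int, ...]) -> int:
        """Structural incompatibility count: per individual, observed
        alleles beyond two on one locus, plus (without null alleles) loci
        left without any observed allele. Zero iff the likelihood is
        computable."""
        total = 0
        for idx, w in self.groups:
            per_locus = [0] * self.m
            for i in idx:
                per_locus[assign[i] - 1] += 1
            bad = sum(max(0, c - 2) for c in per_locus)
            if not self.allow_null:
                bad += sum(1 for c in per_locus if c == 0)
            total += w * bad
        return total

    def score(self, assign: tuple[int, ...]) -> AlleleConfiguration:
        key = _partition_key(assign)
        if key not in self.cache:
            partition = {
                a: l + 1 for a, l in zip(self.allele_names, key)
            }
            self.cache[key] = score_configuration(
                self.observations,
                partition,
                self.m,
                criterion=self.criterion,
                allow_null=self.allow_null,
            )
        return self.cache[key]


def _greedy_initial(
    observations: list[ObservedAlleleSet],
    allele_names: list[str],
    m: int,
    cache: _ConfigCache,
) -> tuple[int, ...] | None:
    """Greedy feasible seed: place high-count alleles on distinct loci, then
    each remaining allele on the feasible locus with the best interim score.

    Interim feasibility uses the hard cap of two observed alleles per locus
    per individual; the interim score counts, per individual, loci receiving
    more than two alleles (fewer violations preferred), tie-broken by the
    full criterion once complete.
    """
    marginal = {a: 0 for a in allele_names}
    for o in observations:
        for a in o.alleles:
            marginal[a] += 1
    ranked = sorted(allele_names, key=lambda a: (-marginal[a], a))
    assign = {a: None for a in allele_names}
    for locus, a in enumerate(ranked[:m]):
        assign[a] = locus
    for a in ranked[m:]:
        best = None
        for locus in range(m):
            violations = 0
            for o in observations:
                per_locus = [0] * m
                for b in o.alleles:
                    if assign[b] is not None:
                        per_locus[assign[b]] += 1
                    elif b == a:
                        per_locus[locus] += 1
                violations += sum(max(0, c - 2) for c in per_locus)
            if best is None or violations < best[0]:
                best = (violations, locus)
        assign[a] = best[1]
    vec = tuple(assign[a] + 1 for a in allele_names)
    return vec


def _repair_feasibility(
    assign: tuple[int, ...], cache: _ConfigCache, rng, restarts: int = 50
) -> tuple[int, ...]:
    """Drive the structural violation count to zero by hill-climbing over
    single-allele moves and pair swaps, with random restarts; returns the
    best assignment found (violations 0 where a feasible one is reachable)."""
    m = cache.m
    n = len(assign)

    def descend(vec: list[int]) -> tuple[int, list[int]]:
        v = cache.violations(tuple(vec))
        improved = True
        while v > 0 and improved:
            improved = False
            order = rng.permutation(n)
            for i in order:
                for l in range(1, m + 1):
                    if l == vec[i]:
                        continue
                    old = vec[i]
                    vec[i] = l
                    if len(set(vec)) == m:
                        nv = cache.violations(tuple(vec))
                        if nv < v:
                            v = nv
                            improved = True
                            break
                    vec[i] = old
                else:
                    continue
                break
        return v, vec

    best_v, best_vec = descend(list(assign))
    tries = 0
    while best_v > 0 and tries < restarts:
        tries += 1
        cand = list(rng.integers(1, m + 1, size=n))
        if len(set(cand)) < m:
            continue
        v, vec = descend(cand)
        if v < best_v:
            best_v, best_vec = v, vec
    return tuple(best_vec)


def sa_search(
    observations: list[ObservedAlleleSet],
    m: int,
    options: SAOptions | None = None,
) -> AlleleConfiguration:
    """Find the minimum-AIC/BIC allele configuration by simulated annealing.

    Metropolis acceptance with energy E = AIC or BIC: always accept a
    non-worse proposal, accept a worse one with probability exp(-dE/T); the
    temperature is multiplied by ``cool`` after every ``steps_per_temp``
    proposals until it falls below ``t_min``, and the whole cycle restarts
    (from the incumbent best) ``cycles`` times. Fully reproducible for a
    given seed.
    """
    options = options or SAOptions()
    allele_names = sorted({a for o in observations for a in o.alleles})
    n_alleles = len(allele_names)
    if m < 1:
        raise ValueError("m must be >= 1")
    if n_alleles < m:
        raise ValueError(f"m={m} incompatible with observations: only {n_alleles} alleles")
    cache = _ConfigCache(observations, allele_names, m, options.criterion, options.allow_null)
    if m == 1:
        return cache.score(tuple([1] * n_alleles))

    rng = np.random.default_rng(options.seed)
    current = _greedy_initial(observations, allele_names, m, cache)
    current = _repair_feasibility(current, cache, rng)
    if cache.violations(current) > 0:
        raise ValueError(
            f"m={m} incompatible with observations: no feasible configuration"
        )
    best_cfg = cache.score(current)
    cur_cfg = best_cfg

    for _ in range(options.cycles):
        t = options.t0
        while t >= options.t_min:
            for _ in range(options.steps_per_temp):
                vec = list(current)
                if m > 1 and rng.random() < 0.2 and n_alleles >= 2:
                    # swap move: exchange loci of two alleles on different loci
                    i, j = rng.integers(0, n_alleles, size=2)
                    if vec[i] != vec[j]:
                        vec[i], vec[j] = vec[j], vec[i]
                else:
                    i = int(rng.integers(0, n_alleles))
                    choices = [l for l in range(1, m + 1) if l != vec[i]]
                    vec[i] = int(choices[int(rng.integers(0, len(choices)))])
                proposal = tuple(vec)
                if len(set(proposal)) < m:
                    continue  # empty locus: reject
                new_cfg = cache.score(proposal)
                de = new_cfg.score - cur_cfg.score
                accept = de <= 0 or (
                    math.isfinite(de) and rng.random() < math.exp(-de / t)
                )
                if accept:
                    current, cur_cfg = proposal, new_cfg
                    if (new_cfg.score, new_cfg.canonical_partition()) < (
                        best_cfg.score,
                        best_cfg.canonical_partition(),
                    ):
                        best_cfg = new_cfg
            t *= options.cool
        # next cycle restarts from the incumbent optimum
        current = tuple(
            best_cfg.partition[a] for a in allele_names
        )
        cur_cfg = best_cfg
    if not math.isfinite(best_cfg.score):
        raise ValueError(f"m={m} incompatible with observations: no feasible configuration")
    return best_cfg


def _set_partitions(items: list[str], m: int):
    """All set partitions of ``items`` into exactly m non-empty blocks."""

    def rec(i, blocks):
        if i == len(items):
            if len(blocks) == m:
                yield [list(b) for b in blocks]
            return
        # prune: remaining items must be able to fill up to m blocks
        if len(blocks) + (len(items) - i) < m:
            return
        for b in blocks:
            b.append(items[i])
            yield from rec(i + 1, blocks)
            b.pop()
        if len(blocks) < m:
            blocks.append([items[i]])
            yield from rec(i + 1, blocks)
            blocks.pop()

    yield from rec(0, [])


def exhaustive_search(
    observations: list[ObservedAlleleSet],
    m: int,
    criterion: str = "AIC",
    allow_null: bool = False,
    max_alleles: int = 12,
) -> AlleleConfiguration:
    """Enumerate every partition into m loci and return the best-scoring one.

    Guarded to panels of at most ``max_alleles`` alleles (Bell-number
    growth). Ties are broken lexicographically on the canonical partition.
    """
    allele_names = sorted({a for o in observations for a in o.alleles})
    if len(allele_names) > max_alleles:
        raise ValueError(
            f"{len(allele_names)} alleles exceeds the exhaustive-search guard "
            f"({max_alleles}); use sa_search"
        )
    best: AlleleConfiguration | None = None
    for blocks in _set_partitions(allele_names, m):
        partition = {a: i + 1 for i, b in enumerate(blocks) for a in b}
        cfg = score_configuration(
            observations, partition, m, criterion=criterion, allow_null=allow_null
        )
        if best is None or (cfg.score, cfg.canonical_partition()) < (
            best.score,
            best.canonical_partition(),
        ):
            best = cfg
    if best is None:
        raise ValueError("no partition enumerated")
    return best


def select_locus_number(
    observations: list[ObservedAlleleSet],
    m_range: list[int],
    criterion: str = "AIC",
    options: SAOptions | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of loci by minimizing AIC/BIC over ``m_range``."""
    if not m_range:
        raise ValueError("m_range must be non-empty")
    options = options or SAOptions()
    options = replace(options, criterion=criterion)
    max_obs = max(len(o.alleles) for o in observations)
    min_obs = min(len(o.alleles) for o in observations)
    rows = []
    results: dict[int, AlleleConfiguration] = {}
    for m in sorted(m_range):
        feasible_bound = max_obs <= 2 * m and (options.allow_null or m <= min_obs)
        if not feasible_bound:
            rows.append({"m": m, "score": INFEASIBLE, "loglik": -math.inf, "k": None})
            continue
        try:
            cfg = sa_search(observations, m, options)
        except ValueError:
            rows.append({"m": m, "score": INFEASIBLE, "loglik": -math.inf, "k": None})
            continue
        results[m] = cfg
        rows.append({"m": m, "score": cfg.score, "loglik": cfg.loglik, "k": cfg.n_params})
    table = pd.DataFrame(rows)
    if not results:
        raise ValueError("no feasible locus number in m_range")
    m_best = min(results, key=lambda m: (results[m].score, m))
    return m_best, table


def call_genotypes(
    observations: list[ObservedAlleleSet],
    configuration: AlleleConfiguration,
    allow_null: bool = False,
    min_posterior: float = 0.95,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Materialize per-locus genotypes as the maximum-posterior decomposition.

    Returns the genotype table plus a per-individual call summary with the
    posterior of the chosen decomposition; calls below ``min_posterior`` are
    flagged ambiguous. Individuals incompatible with the configuration get
    missing-coded genotypes.
    """
    freqs = configuration.freqs
    m = configuration.m
    rows = []
    summary = []
    for o in observations:
        decomps = enumerate_decompositions(o, configuration.partition, m, allow_null)
        if not decomps:
            for locus in range(1, m + 1):
                rows.append(
                    {
                        "individual_id": o.individual_id,
                        "population": o.population,
                        "locus": f"locus{locus}",
                        "allele_a": MISSING,
                        "allele_b": MISSING,
                    }
                )
            summary.append(
                {
                    "individual_id": o.individual_id,
                    "posterior": np.nan,
                    "ambiguous": True,
                    "infeasible": True,
                }
            )
            continue
        probs = []
        for d in decomps:
            p = 1.0
            for locus, g in enumerate(d):
                pa = freqs[locus].get(g[0], 0.0)
                pb = freqs[locus].get(g[1], 0.0)
                p *= pa * pa if g[0] == g[1] else 2 * pa * pb
            probs.append(p)
        total = sum(probs)
        if total <= 0:
            order = sorted(range(len(decomps)), key=lambda i: decomps[i])
            best_i, post = order[0], np.nan
        else:
            # max posterior, ties broken lexicographically on the decomposition
            best_i = min(
                range(len(decomps)), key=lambda i: (-probs[i], decomps[i])
            )
            post = probs[best_i] / total
        chosen = decomps[best_i]
        for locus, g in enumerate(chosen, start=1):
            # real allele first; null (missing-coded) last
            a, b = sorted(g, key=lambda x: (x == NULL_ALLELE, x))
            rows.append(
                {
                    "individual_id": o.individual_id,
                    "population": o.population,
                    "locus": f"locus{locus}",
                    "allele_a": MISSING if a == NULL_ALLELE else a,
                    "allele_b": MISSING if b == NULL_ALLELE else b,
                }
            )
        summary.append(
            {
                "individual_id": o.individual_id,
                "posterior": post,
                "ambiguous": not (post == post and post >= min_posterior),
                "infeasible": False,
            }
        )
    return GenotypeDataset(pd.DataFrame(rows)), pd.DataFrame(summary)
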