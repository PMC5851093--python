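"""Diversity and differentiation statistics over genotype and count tables.

Conventions follow the mixed toolchain standard in wildlife MHC surveys:

* gene diversity H_E uses Nei's unbiased small-sample correction
  ``2n/(2n-1) * (1 - sum p_i^2)``;
* PIC is Botstein's polymorphism information content;
* A_E is the effective number of alleles ``1 / sum p_i^2``;
* A_R is hypergeometric rarefaction of allele counts to a reference number
  of gene copies g;
* F-statistics are the Weir & Cockerham (1984) variance-component
  estimators theta (F_ST), f (F_IS) and F (F_IT), with Nei's G_ST available
  as an alternative;
* the HWE test is the Guo & Thompson exact conditional test, by full
  enumeration for small tables or a Markov chain with switch proposals;
* null-allele frequency uses the Chakraborty or Brookfield-1 estimator.

Summary rows over populations are statistic-dependent: H_E and PIC pool all
individuals, while A_E averages across populations (matching the distinct
programs those statistics are conventionally computed with).
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io_model import MISSING, GenotypeDataset


@dataclass
class AlleleCountTable:
    """Integer allele counts for one population at one locus."""

    population: str
    locus: str
    n_individuals: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative allele count")
        if sum(self.counts.values()) != 2 * self.n_individuals:
            raise ValueError(
                f"{self.population}/{self.locus}: counts sum to "
                f"{sum(self.counts.values())}, expected {2 * self.n_individuals}"
            )
        if not any(self.counts.values()):
            raise ValueError("all-zero count table")

    @property
    def gene_count(self) -> int:
        return 2 * self.n_individuals

    @property
    def k(self) -> int:
        return sum(1 for c in self.counts.values() if c > 0)

    def frequencies(self) -> dict[str, float]:
        g = self.gene_count
        return {a: c / g for a, c in self.counts.items() if c > 0}


@dataclass
class DiversityStats:
    population: str
    locus: str
    n: int
    k: int
    h_obs: float | None
    h_exp: float
    pic: float
    a_e: float
    a_r: float | None
    f_is: float | None
    p_null: float | None


# ---------------------------------------------------------------------------
# Counts


def allele_counts(genotypes: GenotypeDataset) -> list[AlleleCountTable]:
    """Tally allele counts per population x locus over called genotypes."""
    out = []
    called = genotypes.called()
    for (pop, locus), grp in called.groupby(["population", "locus"], sort=True):
        counts: Counter = Counter()
        for row in grp.itertuples(index=False):
            counts[row.allele_a] += 1
            counts[row.allele_b] += 1
        if not counts:
            continue
        out.append(
            AlleleCountTable(
                population=pop,
                locus=locus,
                n_individuals=len(grp),
                counts=dict(sorted(counts.items())),
            )
        )
    return out


def counts_from_frequencies(
    freqs: dict[str, float],
    n: int,
    population: str = "pop",
    locus: str = "locus",
) -> AlleleCountTable:
    """Reconstruct integer allele counts from rounded printed frequencies.

    Uses largest-remainder rounding: start from ``round(p_i * 2n)`` and move
    the alleles with the largest rounding residue by one until the counts
    sum to 2n. Refuses adjustments beyond one copy per allele, which would
    mean the frequencies are inconsistent with the stated sample size.
    """
    total = sum(freqs.values())
    if any(p < 0 for p in freqs.values()):
        raise ValueError("negative frequency")
    if abs(total - 1.0) > 0.011:
        raise ValueError(f"frequencies sum to {total:.3f}, not 1")
    g = 2 * n
    names = list(freqs)
    raw = {a: freqs[a] * g for a in names}
    counts = {a: int(round(raw[a])) for a in names}
    diff = g - sum(counts.values())
    step = 1 if diff > 0 else -1
    moved: Counter = Counter()
    while diff != 0:
        # residue in the direction we still need to move
        cand = sorted(
            names,
            key=lambda a: (-(step * (raw[a] - counts[a])), a),
        )
        a = cand[0]
        if moved[a] >= 1:
            raise ValueError(
                "frequencies inconsistent with sample size: "
                "largest-remainder adjustment exceeds +/-1 per allele"
            )
        counts[a] += step
        moved[a] += 1
        diff -= step
    counts = {a: c for a, c in sorted(counts.items()) if c > 0}
    return AlleleCountTable(
        population=population, locus=locus, n_individuals=n, counts=counts
    )


def pool_counts(tables: list[AlleleCountTable], population: str = "All") -> AlleleCountTable:
    """Sum count tables (same locus) over populations."""
    loci = {t.locus for t in tables}
    if len(loci) != 1:
        raise ValueError("pool_counts expects tables for a single locus")
    counts: Counter = Counter()
    n = 0
    for t in tables:
        counts.update(t.counts)
        n += t.n_individuals
    return AlleleCountTable(
        population=population,
        locus=loci.pop(),
        n_individuals=n,
        counts=dict(sorted(counts.items())),
    )


# ---------------------------------------------------------------------------
# Per-locus diversity statistics


def observed_heterozygosity(genotypes: GenotypeDataset, population: str, locus: str) -> float:
    """Fraction of called genotypes with two different alleles."""
    df = genotypes.called()
    df = df[(df["population"] == population) & (df["locus"] == locus)]
    if df.empty:
        raise ValueError(f"no called genotypes for {population}/{locus}")
    return float((df["allele_a"] != df["allele_b"]).mean())


def unbiased_expected_heterozygosity(counts: AlleleCountTable) -> float:
    """Nei's unbiased gene diversity ``2n/(2n-1) * (1 - sum p^2)``."""
    g = counts.gene_count
    if g < 2:
        raise ValueError("need at least 2 gene copies")
    sum_p2 = sum(p * p for p in counts.frequencies().values())
    return g / (g - 1) * (1.0 - sum_p2)


def pic(counts: AlleleCountTable) -> float:
    """Botstein's polymorphism information content.

    ``PIC = 1 - sum p_i^2 - [(sum p_i^2)^2 - sum p_i^4]``.
    """
    ps = list(counts.frequencies().values())
    s2 = sum(p * p for p in ps)
    s4 = sum(p**4 for p in ps)
    return 1.0 - s2 - (s2 * s2 - s4)


def effective_allele_number(counts: AlleleCountTable) -> float:
    """Effective number of alleles ``A_E = 1 / sum p^2``."""
    s2 = sum(p * p for p in counts.frequencies().values())
    return 1.0 / s2


def allelic_richness(counts: AlleleCountTable, g: int) -> float:
    """Rarefied allele count at g gene copies (hypergeometric expectation).

    ``A_R = sum_i [1 - C(2n - N_i, g) / C(2n, g)]``, computed in log space.
    """
    G = counts.gene_count
    if not 1 <= g <= G:
        raise ValueError(f"rarefaction size g={g} outside [1, {G}]")

    def log_comb(a: int, b: int) -> float:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    denom = log_comb(G, g)
    total = 0.0
    for N in counts.counts.values():
        if N <= 0:
            continue
        if G - N < g:
            total += 1.0
        else:
            total += 1.0 - math.exp(log_comb(G - N, g) - denom)
    return total


def null_allele_frequency(
    h_exp: float, h_obs: float, method: str = "chakraborty"
) -> float:
    """Null-allele frequency from the heterozygote deficit.

    ``chakraborty``: (H_E - H_O)/(H_E + H_O); ``brookfield1``:
    (H_E - H_O)/(1 + H_E). Negative estimates are returned as computed.
    """
    if method == "chakraborty":
        denom = h_exp + h_obs
        if denom == 0:
            raise ValueError("H_E + H_O = 0: estimator undefined")
        return (h_exp - h_obs) / denom
    if method == "brookfield1":
        return (h_exp - h_obs) / (1.0 + h_exp)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Weir & Cockerham F-statistics


@dataclass
class FStatsResult:
    f_st: float | None
    f_is: float | None
    f_it: float | None
    per_locus: pd.DataFrame
    g_st: float | None = None


def _wc_components(genotypes: GenotypeDataset, locus: str):
    """Per-allele variance components a (among pops), b (among individuals
    within pops), c (within individuals) for one locus; Weir & Cockerham
    (1984)."""
    df = genotypes.called()
    df = df[df["locus"] == locus]
    pops = sorted(df["population"].unique())
    r = len(pops)
    if r < 2:
        raise ValueError("need >= 2 populations for theta")
    n_i = np.array(
        [len(df[df["population"] == p]) for p in pops], dtype=float
    )
    if (n_i == 0).any():
        raise ValueError(f"population with no called genotypes at {locus}")
    nbar = n_i.mean()
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    alleles = sorted(set(df["allele_a"]) | set(df["allele_b"]))
    rows = []
    for allele in alleles:
        p_i = np.zeros(r)
        h_i = np.zeros(r)
        for j, pop in enumerate(pops):
            sub = df[df["population"] == pop]
            p_i[j] = (
                (sub["allele_a"] == allele).sum() + (sub["allele_b"] == allele).sum()
            ) / (2 * n_i[j])
            h_i[j] = (
                ((sub["allele_a"] == allele) ^ (sub["allele_b"] == allele)).sum()
                / n_i[j]
            )
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (
            nbar
            / nc
            * (
                s2
                - 1.0
                / (nbar - 1)
                * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
            )
        )
        b = (
            nbar
            / (nbar - 1)
            * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
        )
        c = hbar / 2.0
        rows.append((allele, a, b, c))
    return rows


def wc_f_statistics(genotypes: GenotypeDataset) -> FStatsResult:
    """Weir-Cockerham theta (F_ST), f (F_IS) and F (F_IT).

    Components are summed over alleles within a locus and over loci for the
    multilocus estimates. A locus monomorphic across all populations has
    undefined estimates and is reported as missing. Nei's
    ``G_ST = (H_T - H_S)/H_T`` over the same data is included as an
    alternative differentiation estimator.
    """
    per_locus_rows = []
    A = B = C = 0.0
    for locus in genotypes.loci:
        comps = _wc_components(genotypes, locus)
        a = sum(x[1] for x in comps)
        b = sum(x[2] for x in comps)
        c = sum(x[3] for x in comps)
        denom = a + b + c
        if denom == 0:
            per_locus_rows.append(
                {"locus": locus, "theta": np.nan, "f": np.nan, "F": np.nan}
            )
            continue
        A += a
        B += b
        C += c
        per_locus_rows.append(
            {
                "locus": locus,
                "theta": a / denom,
                "f": 1 - c / (b + c) if (b + c) != 0 else np.nan,
                "F": 1 - c / denom,
            }
        )
    per_locus = pd.DataFrame(per_locus_rows)
    denom = A + B + C
    if denom == 0:
        return FStatsResult(
            f_st=None, f_is=None, f_it=None, per_locus=per_locus, g_st=None
        )
    return FStatsResult(
        f_st=A / denom,
        f_is=1 - C / (B + C) if (B + C) != 0 else None,
        f_it=1 - C / denom,
        per_locus=per_locus,
        g_st=nei_gst(genotypes),
    )


def nei_gst(genotypes: GenotypeDataset) -> float | None:
    """Nei's G_ST = (H_T - H_S)/H_T over loci, from allele counts."""
    tables = allele_counts(genotypes)
    by_locus: dict[str, list[AlleleCountTable]] = defaultdict(list)
    for t in tables:
        by_locus[t.locus].append(t)
    ht_sum = hs_sum = 0.0
    for locus, tl in by_locus.items():
        if len(tl) < 2:
            continue
        alleles = sorted({a for t in tl for a in t.counts})
        freq_mat = np.array(
            [[t.frequencies().get(a, 0.0) for a in alleles] for t in tl]
        )
        pbar = freq_mat.mean(axis=0)
        ht = 1 - (pbar**2).sum()
        hs = float(np.mean([1 - (row**2).sum() for row in freq_mat]))
        ht_sum += ht
        hs_sum += hs
    if ht_sum == 0:
        return None
    return (ht_sum - hs_sum) / ht_sum


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Guo & Thompson)


def _log_table_prob(geno: dict[tuple[str, str], int], allele_counts_: dict[str, int], n: int):
    """Log conditional probability of a genotype array given allele counts."""
    h = sum(c for (a, b), c in geno.items() if a != b)
    lg = (
        gammaln(n + 1)
        + h * math.log(2.0)
        + sum(gammaln(c + 1) for c in allele_counts_.values())
        - sum(gammaln(c + 1) for c in geno.values())
        - gammaln(2 * n + 1)
    )
    return lg


def genotype_counts(genotypes: GenotypeDataset, population: str, locus: str) -> dict[tuple[str, str], int]:
    df = genotypes.called()
    df = df[(df["population"] == population) & (df["locus"] == locus)]
    out: Counter = Counter()
    for row in df.itertuples(index=False):
        a, b = sorted((row.allele_a, row.allele_b))
        out[(a, b)] += 1
    return dict(out)


@dataclass
class HWETestResult:
    p_value: float
    method: str
    se: float | None = None


def hwe_exact_test(
    geno_counts: dict[tuple[str, str], int],
    method: str = "enumeration",
    steps: int = 100_000,
    dememorization: int = 10_000,
    seed: int | None = None,
) -> HWETestResult:
    """Exact conditional HWE test (Guo & Thompson 1992).

    The p-value is the total conditional probability of genotype arrays (with
    the observed allele counts) no more probable than the observed array.
    ``enumeration`` visits every array; ``mcmc`` estimates the p-value with a
    Markov chain of switch proposals after a dememorization burn-in and
    reports a Monte-Carlo standard error. A monomorphic sample returns p=1.
    """
    geno_counts = {tuple(sorted(k)): v for k, v in geno_counts.items()}
    alleles = sorted({a for g in geno_counts for a in g})
    n = sum(geno_counts.values())
    if n < 2 or len(alleles) < 2:
        return HWETestResult(p_value=1.0, method=method)
    ac: Counter = Counter()
    for (a, b), c in geno_counts.items():
        ac[a] += c
        ac[b] += c
    ac = dict(ac)
    obs_lp = _log_table_prob(geno_counts, ac, n)
    eps = 1e-9

    if method == "enumeration":
        pairs = [
            (alleles[i], alleles[j])
            for i in range(len(alleles))
            for j in range(i, len(alleles))
        ]
        total_p = 0.0
        tail_p = 0.0

        def rec(idx: int, remaining: dict[str, int], geno: dict):
            nonlocal total_p, tail_p
            if idx == len(pairs):
                if all(v == 0 for v in remaining.values()):
                    lp = _log_table_prob(geno, ac, n)
                    p = math.exp(lp)
                    total_p += p
                    if lp <= obs_lp + eps:
                        tail_p += p
                return
            a, b = pairs[idx]
            if a == b:
                cap = remaining[a] // 2
            else:
                cap = min(remaining[a], remaining[b])
            for c in range(cap + 1):
                geno[(a, b)] = c
                if a == b:
                    remaining[a] -= 2 * c
                else:
                    remaining[a] -= c
                    remaining[b] -= c
                rec(idx + 1, remaining, geno)
                if a == b:
                    remaining[a] += 2 * c
                else:
                    remaining[a] += c
                    remaining[b] += c
            del geno[(a, b)]

        rec(0, dict(ac), {})
        return HWETestResult(p_value=tail_p / total_p, method="enumeration")

    if method == "mcmc":
        rng = np.random.default_rng(seed)
        cur = Counter(geno_counts)
        cur_lp = obs_lp

        def pair_sel_prob(state: Counter, g1, g2) -> float:
            """Probability of drawing the unordered individual pair (g1, g2)
            when two distinct individuals are chosen uniformly."""
            if g1 == g2:
                ways = state[g1] * (state[g1] - 1) / 2.0
            else:
                ways = state[g1] * state[g2]
            return ways / (n * (n - 1) / 2.0)

        genos = list(cur.elements())  # per-individual genotypes, O(1) updates
        draws = []
        pair_idx = rng.integers(0, n, size=2 * (dememorization + steps))
        repair_u = rng.random(dememorization + steps)
        accept_u = rng.random(dememorization + steps)
        for step in range(dememorization + steps):
            # switch move: re-pair the alleles of two random individuals
            i, j = pair_idx[2 * step], pair_idx[2 * step + 1]
            if i != j:
                g1, g2 = genos[i], genos[j]
                a, b = g1
                c, d = g2
                if repair_u[step] < 0.5:
                    ng1, ng2 = tuple(sorted((a, c))), tuple(sorted((b, d)))
                else:
                    ng1, ng2 = tuple(sorted((a, d))), tuple(sorted((b, c)))
                if Counter((ng1, ng2)) != Counter((g1, g2)):
                    new = Counter(cur)
                    new[g1] -= 1
                    new[g2] -= 1
                    new[ng1] += 1
                    new[ng2] += 1
                    new = Counter({k: v for k, v in new.items() if v > 0})
                    lp = _log_table_prob(new, ac, n)

                    def n_repairings(p1, p2, t1, t2):
                        """How many of the two re-pairings of (p1, p2) yield
                        the unordered genotype pair (t1, t2)."""
                        a_, b_ = p1
                        c_, d_ = p2
                        target = Counter((t1, t2))
                        opts = [
                            (tuple(sorted((a_, c_))), tuple(sorted((b_, d_)))),
                            (tuple(sorted((a_, d_))), tuple(sorted((b_, c_)))),
                        ]
                        return sum(1 for o in opts if Counter(o) == target)

                    # Hastings ratio: pair-selection odds and re-pairing
                    # multiplicity both differ between the two states
                    log_q_fwd = math.log(
                        pair_sel_prob(cur, g1, g2) * n_repairings(g1, g2, ng1, ng2)
                    )
                    log_q_rev = math.log(
                        pair_sel_prob(new, ng1, ng2) * n_repairings(ng1, ng2, g1, g2)
                    )
                    log_alpha = (lp - cur_lp) + (log_q_rev - log_q_fwd)
                    if math.log(accept_u[step] + 1e-300) < log_alpha:
                        cur = new
                        cur_lp = lp
                        genos[i], genos[j] = ng1, ng2
            if step >= dememorization:
                draws.append(1.0 if cur_lp <= obs_lp + eps else 0.0)
        arr = np.asarray(draws)
        p = float(arr.mean())
        # batch-means standard error to absorb chain autocorrelation
        n_batches = 100
        bs = len(arr) // n_batches
        if bs >= 1:
            batches = arr[: n_batches * bs].reshape(n_batches, bs).mean(axis=1)
            se = float(batches.std(ddof=1) / math.sqrt(n_batches))
        else:
            se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else None
        return HWETestResult(p_value=p, method="mcmc", se=se)

    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Rank test and multiple-testing helpers


def mann_whitney_u(
    x, y, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U via rank sums; exact p for small untied samples,
    tie-corrected normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BonferroniResult:
    threshold: float
    flags: list[bool]


def bonferroni(p_values, alpha: float = 0.05) -> BonferroniResult:
    """Per-test Bonferroni threshold alpha/m and significance flags."""
    p_values = list(p_values)
    if not p_values:
        raise ValueError("need at least one p-value")
    thr = alpha / len(p_values)
    return BonferroniResult(threshold=thr, flags=[p < thr for p in p_values])


# ---------------------------------------------------------------------------
# Summary convenience


def diversity_table(
    genotypes: GenotypeDataset,
    rarefaction_g: int | None = None,
    null_method: str = "chakraborty",
) -> pd.DataFrame:
    """Per population x locus diversity statistics from a genotype table.

    ``rarefaction_g`` defaults to the minimum gene count over all
    population x locus samples.
    """
    tables = allele_counts(genotypes)
    if rarefaction_g is None:
        rarefaction_g = min(t.gene_count for t in tables)
    rows = []
    for t in tables:
        he = unbiased_expected_heterozygosity(t)
        ho = observed_heterozygosity(genotypes, t.population, t.locus)
        rows.append(
            {
                "population": t.population,
                "locus": t.locus,
                "n": t.n_individuals,
                "k": t.k,
                "h_obs": ho,
                "h_exp": he,
                "pic": pic(t),
                "a_e": effective_allele_number(t),
                "a_r": allelic_richness(t, rarefaction_g)
                if rarefaction_g <= t.gene_count
                else np.nan,
                "p_null": null_allele_frequency(he, ho, null_method)
                if (he + ho) > 0
                else np.nan,
            }
        )
    return pd.DataFrame(rows)
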