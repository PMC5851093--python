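"""Sequence-level polymorphism and selection statistics.

Implements the classic toolkit for exon-level selection scans on MHC
alignments: variable and parsimony-informative site counts, pairwise
p-distances with site-bootstrap standard errors, the Nei-Gojobori (1986)
proportion method for synonymous/nonsynonymous substitution rates with the
Jukes-Cantor correction and codon-bootstrap standard errors (optionally
restricted to a codon mask such as the antigen-binding sites of the DR beta
chain), the associated one-sided Z-test for selection, and Tajima's D on
population samples of gene copies reconstructed from allele counts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_model import AlleleSet, SiteMask
from .popgen import AlleleCountTable

_STANDARD_CODE = {
    "".join(c): aa
    for c, aa in zip(
        itertools.product("TCAG", repeat=3),
        "FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR" "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG",
    )
}

STOP_CODONS = {c for c, aa in _STANDARD_CODE.items() if aa == "*"}
BASES = "ACGT"


def translate_codon(codon: str) -> str | None:
    return _STANDARD_CODE.get(codon)


@dataclass
class CodonAlignment:
    """Equal-length in-frame nucleotide rows; gaps allowed."""

    names: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("need at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("rows must be equal length")
        (self.length,) = lengths
        if self.length % 3 != 0:
            raise ValueError("alignment length must be divisible by 3 (trim frame first)")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def codon_count(self) -> int:
        return self.length // 3

    def codon(self, row: int, index: int) -> str:
        """1-based codon index."""
        return self.sequences[row][3 * (index - 1) : 3 * index]

    @classmethod
    def from_alleles(
        cls, alleles: AlleleSet, frame_offset: int = 0, use_exon: bool = True
    ) -> "CodonAlignment":
        """Build an in-frame alignment from an allele panel.

        Skips ``frame_offset`` leading bases of the (exon) region and trims
        the trailing partial codon.
        """
        names, seqs = [], []
        for a in alleles:
            s = a.exon_seq if use_exon else a.nt_seq
            s = s[frame_offset:]
            s = s[: len(s) - len(s) % 3]
            names.append(a.name)
            seqs.append(s)
        return cls(names=names, sequences=seqs)


# ---------------------------------------------------------------------------
# Site statistics


def variable_and_informative_sites(
    rows: list[str], gap_policy: str = "missing"
) -> tuple[int, int, list[int]]:
    """Count variable and parsimony-informative columns.

    A column is variable if it holds >= 2 distinct states, and
    parsimony-informative if >= 2 states each occur in >= 2 rows. Under
    ``gap_policy="missing"`` gaps are ignored; under ``"fifth-state"`` a gap
    is an ordinary state. Returns (n_variable, n_informative, 1-based
    variable positions).
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 rows")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("rows must be equal length")
    n_var = 0
    n_pis = 0
    positions = []
    for i in range(len(rows[0])):
        col = [r[i] for r in rows]
        if gap_policy == "missing":
            col = [c for c in col if c not in "-N"]
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        if len(counts) >= 2:
            n_var += 1
            positions.append(i + 1)
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                n_pis += 1
    return n_var, n_pis, positions


def p_distance_matrix(
    rows: list[str], gap_policy: str = "pairwise_deletion"
) -> np.ndarray:
    """Pairwise p-distance (mismatch proportion); gapped sites are skipped
    pairwise (or globally under ``complete_deletion``)."""
    n = len(rows)
    L = len(rows[0])
    keep_all = None
    if gap_policy == "complete_deletion":
        keep_all = [
            i for i in range(L) if all(r[i] not in "-N" for r in rows)
        ]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if keep_all is not None:
                sites = keep_all
            else:
                sites = [
                    k
                    for k in range(L)
                    if rows[i][k] not in "-N" and rows[j][k] not in "-N"
                ]
            if not sites:
                D[i, j] = D[j, i] = np.nan
                continue
            mism = sum(1 for k in sites if rows[i][k] != rows[j][k])
            D[i, j] = D[j, i] = mism / len(sites)
    return D


def overall_mean_distance(
    rows: list[str],
    bootstrap: int = 1000,
    seed: int | None = None,
    gap_policy: str = "pairwise_deletion",
) -> tuple[float, float]:
    """Mean pairwise p-distance with a site-bootstrap standard error."""
    D = p_distance_matrix(rows, gap_policy)
    iu = np.triu_indices(len(rows), k=1)
    mean = float(np.nanmean(D[iu]))
    if bootstrap <= 0:
        return mean, 0.0
    rng = np.random.default_rng(seed)
    L = len(rows[0])
    reps = np.empty(bootstrap)
    for b in range(bootstrap):
        cols = rng.integers(0, L, size=L)
        rs = ["".join(r[c] for c in cols) for r in rows]
        Db = p_distance_matrix(rs, gap_policy)
        reps[b] = np.nanmean(Db[iu])
    return mean, float(reps.std(ddof=1))


# ---------------------------------------------------------------------------
# Nei-Gojobori


def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three single-base changes
    that are synonymous; changes to stop codons count as nonsynonymous.
    Returns (0, 0) for codons containing gaps/ambiguity or stops.
    """
    aa = translate_codon(codon)
    if aa is None or aa == "*":
        return 0.0, 0.0
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if translate_codon(mut) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averages over all shortest substitution pathways, skipping pathways that
    pass through a stop codon (if every pathway hits a stop, all pathways
    are used). Unweighted pathway counting per the original proportion
    method.
    """
    if translate_codon(c1) is None or translate_codon(c2) is None:
        return 0.0, 0.0
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order) -> tuple[float, float, bool]:
        sd = nd = 0.0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                return 0.0, 0.0, False
            if translate_codon(cur) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd, True

    paths = []
    blocked = []
    for order in itertools.permutations(diff_pos):
        sd, nd, ok = walk(order)
        if ok:
            paths.append((sd, nd))
        else:
            blocked.append(order)
    if not paths:
        # all pathways blocked by stops: fall back to counting through them
        for order in itertools.permutations(diff_pos):
            sd = nd = 0.0
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                a1, a2 = translate_codon(cur), translate_codon(nxt)
                if a1 == a2:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC-corrected distance ``-(3/4) ln(1 - 4p/3)``; undefined for p >= 3/4."""
    if p >= 0.75:
        raise ValueError(f"proportion {p:.3f} >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class DnDsResult:
    d_n: float
    d_s: float
    se_n: float
    se_s: float
    omega: float | None
    z: float | None
    p: float | None
    site_class: str
    n_codons_used: int


_SITES_CACHE: dict[str, tuple[float, float]] = {}
_DIFF_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _cached_sites(codon: str) -> tuple[float, float]:
    r = _SITES_CACHE.get(codon)
    if r is None:
        r = _SITES_CACHE[codon] = codon_sites(codon)
    return r


def _cached_diffs(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2) if c1 <= c2 else (c2, c1)
    r = _DIFF_CACHE.get(key)
    if r is None:
        r = _DIFF_CACHE[key] = codon_differences(*key)
    return r


def _pair_counts(codons1, codons2):
    """Site and difference counts for one sequence pair over shared ungapped
    codons; returns (S, N, Sd, Nd)."""
    S = N = Sd = Nd = 0.0
    for a, b in zip(codons1, codons2):
        if translate_codon(a) is None or translate_codon(b) is None:
            continue
        s1, n1 = _cached_sites(a)
        s2, n2 = _cached_sites(b)
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = _cached_diffs(a, b)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def _per_codon_arrays(seq_codons: list[list[str]]):
    """Per-pair, per-codon (S, N, Sd, Nd) arrays; invalid codons are zero."""
    n = len(seq_codons)
    K = len(seq_codons[0])
    pairs = list(itertools.combinations(range(n), 2))
    S = np.zeros((len(pairs), K))
    N = np.zeros((len(pairs), K))
    Sd = np.zeros((len(pairs), K))
    Nd = np.zeros((len(pairs), K))
    for pi, (i, j) in enumerate(pairs):
        for k in range(K):
            a, b = seq_codons[i][k], seq_codons[j][k]
            if translate_codon(a) is None or translate_codon(b) is None:
                continue
            s1, n1 = _cached_sites(a)
            s2, n2 = _cached_sites(b)
            S[pi, k] = (s1 + s2) / 2.0
            N[pi, k] = (n1 + n2) / 2.0
            Sd[pi, k], Nd[pi, k] = _cached_diffs(a, b)
    return S, N, Sd, Nd


def _jc_vec(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, np.nan)
    ok = p < 0.75
    out[ok] = -0.75 * np.log1p(-4.0 * p[ok] / 3.0)
    return out


def _mean_dn_ds_arrays(S, N, Sd, Nd, idx, strict: bool = False):
    """Mean pairwise (d_N, d_S) over codon indices ``idx``.

    With ``strict`` a saturated pair (p >= 3/4) raises; otherwise it yields
    NaN and the pair is dropped from the mean (bootstrap semantics).
    """
    idx = np.asarray(idx)
    Ssel = S[:, idx].sum(axis=1)
    Nsel = N[:, idx].sum(axis=1)
    ok = (Ssel > 0) & (Nsel > 0)
    if not ok.any():
        raise ValueError("no comparable codon pairs")
    ps = Sd[:, idx].sum(axis=1)[ok] / Ssel[ok]
    pn = Nd[:, idx].sum(axis=1)[ok] / Nsel[ok]
    if strict and ((ps >= 0.75).any() or (pn >= 0.75).any()):
        bad = int(np.argmax((ps >= 0.75) | (pn >= 0.75)))
        raise ValueError(
            f"sequence pair {bad}: substitution proportion >= 3/4, "
            "Jukes-Cantor correction undefined"
        )
    ds = _jc_vec(ps)
    dn = _jc_vec(pn)
    return float(np.nanmean(dn)), float(np.nanmean(ds))


def nei_gojobori(
    alignment: CodonAlignment,
    mask: SiteMask | None = None,
    site_class: str = "all",
    bootstrap: int = 1000,
    seed: int | None = None,
) -> DnDsResult:
    """Nei-Gojobori d_N and d_S with Jukes-Cantor correction.

    ``site_class`` restricts the computation to the codons of that class in
    ``mask`` ("ABS"/"non-ABS"); ``"all"`` uses every codon. Standard errors
    come from ``bootstrap`` codon resamples; omega is d_N/d_S (missing when
    d_S = 0) and the Z-test for positive selection (d_N > d_S) uses the
    bootstrap variances.
    """
    seq_codons = [
        [alignment.codon(r, k) for k in range(1, alignment.codon_count + 1)]
        for r in range(len(alignment.sequences))
    ]
    if site_class == "all" or mask is None:
        codon_idx = list(range(alignment.codon_count))
    else:
        mask.validate_against(alignment.codon_count)
        codon_idx = [i - 1 for i in mask.indices(site_class)]
    if not codon_idx:
        raise ValueError(f"no codons in class {site_class!r}")
    S, N, Sd, Nd = _per_codon_arrays(seq_codons)
    d_n, d_s = _mean_dn_ds_arrays(S, N, Sd, Nd, codon_idx, strict=True)
    rng = np.random.default_rng(seed)
    reps_n = np.empty(bootstrap)
    reps_s = np.empty(bootstrap)
    k = len(codon_idx)
    codon_idx_arr = np.asarray(codon_idx)
    for b in range(bootstrap):
        resample = codon_idx_arr[rng.integers(0, k, k)]
        try:
            reps_n[b], reps_s[b] = _mean_dn_ds_arrays(S, N, Sd, Nd, resample)
        except ValueError:
            reps_n[b], reps_s[b] = np.nan, np.nan
    se_n = float(np.nanstd(reps_n, ddof=1)) if bootstrap > 1 else 0.0
    se_s = float(np.nanstd(reps_s, ddof=1)) if bootstrap > 1 else 0.0
    omega = d_n / d_s if d_s > 0 else None
    z = p = None
    if se_n > 0 or se_s > 0:
        z, p = codon_z_test(d_n, d_s, se_n**2, se_s**2)
    return DnDsResult(
        d_n=d_n,
        d_s=d_s,
        se_n=se_n,
        se_s=se_s,
        omega=omega,
        z=z,
        p=p,
        site_class=site_class,
        n_codons_used=len(codon_idx),
    )


def codon_z_test(
    d_n: float,
    d_s: float,
    var_n: float,
    var_s: float,
    alternative: str = "positive",
) -> tuple[float, float]:
    """One-sided Z-test for selection: Z = (d_N - d_S)/sqrt(var_N + var_S).

    ``alternative="positive"`` tests d_N > d_S; ``"purifying"`` tests
    d_N < d_S.
    """
    if var_n < 0 or var_s < 0:
        raise ValueError("variances must be >= 0")
    pooled = var_n + var_s
    if pooled == 0:
        raise ValueError("zero pooled variance")
    z = (d_n - d_s) / math.sqrt(pooled)
    if alternative == "positive":
        p = float(stats.norm.sf(z))
    elif alternative == "purifying":
        p = float(stats.norm.cdf(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return z, p


# ---------------------------------------------------------------------------
# Tajima's D


@dataclass
class TajimaResult:
    d: float | None
    s: int
    pi: float
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> dict[str, float]:
    """The standard sample-size constants of Tajima's (1989) D."""
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajima_d(rows: list[str]) -> TajimaResult:
    """Tajima's D from a sample alignment of gene copies.

    Columns containing a gap or ambiguous base in any row are excluded. D is
    missing (None) when there are no segregating sites.
    """
    n = len(rows)
    if n < 2:
        raise ValueError("need >= 2 rows")
    L = len(rows[0])
    keep = [i for i in range(L) if all(r[i] in BASES for r in rows)]
    S = 0
    pairwise_total = 0.0
    n_pairs = n * (n - 1) / 2.0
    for i in keep:
        col = [r[i] for r in rows]
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        if len(counts) >= 2:
            S += 1
            het_pairs = (n * n - sum(v * v for v in counts.values())) / 2.0
            pairwise_total += het_pairs
    pi = pairwise_total / n_pairs
    k = tajima_constants(n)
    if S == 0:
        return TajimaResult(d=None, s=0, pi=pi, n=n, **k)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    d = (pi - S / k["a1"]) / math.sqrt(var)
    return TajimaResult(d=d, s=S, pi=pi, n=n, **k)


def expand_to_sample(alleles: AlleleSet, counts: AlleleCountTable) -> list[str]:
    """The 2n gene copies of a population sample as alignment rows.

    Each allele's sequence is repeated by its count; rows ordered by allele
    name then copy index.
    """
    rows = []
    for name in sorted(counts.counts):
        c = counts.counts[name]
        if c == 0:
            continue
        if name not in alleles:
            raise KeyError(f"counted allele {name!r} has no sequence")
        rows.extend([alleles[name].nt_seq] * c)
    if len(rows) != counts.gene_count:
        raise ValueError("row count does not match gene count")
    return rows
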