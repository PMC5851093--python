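"""Site statistics, NG86 dN/dS, the selection Z-test and Tajima's D."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from mhcpopgen.io_model import AlleleSequence, AlleleSet, SiteMask, read_site_mask
from mhcpopgen.popgen import AlleleCountTable
from mhcpopgen.selection import (
    BASES,
    STOP_CODONS,
    CodonAlignment,
    codon_differences,
    codon_sites,
    codon_z_test,
    expand_to_sample,
    jukes_cantor,
    nei_gojobori,
    overall_mean_distance,
    p_distance_matrix,
    tajima_constants,
    tajima_d,
    translate_codon,
    variable_and_informative_sites,
)
from mhcpopgen.summaries import bundled_path
from mhcpopgen.synthetic import simulate_codon_alignment, synthetic_drb_panel


class TestSiteStatistics:
    def test_identical_rows(self):
        assert variable_and_informative_sites(["ACGT"] * 3) == (0, 0, [])

    def test_hand_counted_columns(self):
        rows = ["ACGT", "ACGA", "ACGA", "ACCA"]
        n_var, n_pis, pos = variable_and_informative_sites(rows)
        assert (n_var, n_pis) == (2, 0)
        assert pos == [3, 4]

    def test_informative_needs_two_states_twice(self):
        rows = ["AA", "AA", "AT", "AT"]
        assert variable_and_informative_sites(rows)[:2] == (1, 1)

    def test_gap_policies(self):
        rows = ["A-", "AT", "AT", "AA"]
        missing = variable_and_informative_sites(rows, gap_policy="missing")
        fifth = variable_and_informative_sites(rows, gap_policy="fifth-state")
        assert missing[0] == 1 and fifth[0] == 1
        assert missing[1] == 0 and fifth[1] == 0


class TestPDistance:
    def test_identical(self):
        mean, se = overall_mean_distance(["ACGT" * 10] * 3, bootstrap=50, seed=1)
        assert mean == 0.0 and se == 0.0

    def test_direct_ratio(self):
        a = "A" * 50
        b = "A" * 45 + "C" * 5
        D = p_distance_matrix([a, b])
        assert D[0, 1] == pytest.approx(0.1)

    def test_matches_bruteforce_pair_count(self):
        rng = np.random.default_rng(2)
        rows = ["".join(rng.choice(list("ACGT-"), size=30)) for _ in range(4)]
        D = p_distance_matrix(rows)
        for i, j in itertools.combinations(range(4), 2):
            sites = [
                k
                for k in range(30)
                if rows[i][k] in "ACGT" and rows[j][k] in "ACGT"
            ]
            mism = sum(rows[i][k] != rows[j][k] for k in sites)
            assert D[i, j] == pytest.approx(mism / len(sites))


def brute_force_codon_pair(c1, c2):
    """Independent pathway enumerator for Sd/Nd between two codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_codon(cur) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestNeiGojobori:
    def test_site_counts_sum_to_three(self):
        for codon in map("".join, itertools.product(BASES, repeat=3)):
            s, n = codon_sites(codon)
            if translate_codon(codon) != "*":
                assert s + n == pytest.approx(3.0)

    def test_single_third_position_change(self):
        # TTT (Phe) -> TTA (Leu): nonsynonymous single-step
        assert codon_differences("TTT", "TTA") == (0.0, 1.0)
        assert codon_sites("TTT") == pytest.approx((1 / 3, 8 / 3))
        assert codon_sites("TTA") == pytest.approx((2 / 3, 7 / 3))

    def test_pathway_averaging_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        sense = sorted(set(map("".join, itertools.product(BASES, repeat=3))) - STOP_CODONS)
        for _ in range(200):
            c1, c2 = rng.choice(sense, size=2)
            expected = brute_force_codon_pair(c1, c2)
            if expected is None:
                continue
            assert codon_differences(c1, c2) == pytest.approx(expected)

    def test_identical_sequences_zero(self):
        aln = CodonAlignment(names=["a", "b"], sequences=["ATGGCT", "ATGGCT"])
        r = nei_gojobori(aln, bootstrap=10, seed=0)
        assert r.d_n == 0.0 and r.d_s == 0.0

    def test_pairwise_matches_biopython(self):
        from Bio import Align
        from Bio.Align.analysis import calculate_dn_ds

        for seed in range(5):
            aln = simulate_codon_alignment(2, 40, None, {"all": 1.0}, 15, seed=seed)
            r = nei_gojobori(aln, bootstrap=0, seed=0)
            bio = Align.Alignment(aln.sequences)
            dn_bio, ds_bio = calculate_dn_ds(bio, method="NG86")
            assert r.d_n == pytest.approx(dn_bio, abs=1e-9)
            assert r.d_s == pytest.approx(ds_bio, abs=1e-9)

    def test_row_order_invariance(self):
        aln = simulate_codon_alignment(6, 30, None, {"all": 1.0}, 10, seed=3)
        r1 = nei_gojobori(aln, bootstrap=0)
        rev = CodonAlignment(names=aln.names[::-1], sequences=aln.sequences[::-1])
        r2 = nei_gojobori(rev, bootstrap=0)
        assert r1.d_n == pytest.approx(r2.d_n) and r1.d_s == pytest.approx(r2.d_s)

    def test_masked_classes_partition_difference_counts(self):
        # per-pair Sd/Nd over all codons equals the sum over the two classes
        mask = read_site_mask(bundled_path("abs_mask_drb_exon2.csv"))
        aln = simulate_codon_alignment(
            4, 81, mask.codon_class, {"ABS": 2.0, "non-ABS": 0.5}, 25, seed=9
        )
        from mhcpopgen.selection import _pair_counts

        def counts(idx):
            c1 = [aln.codon(0, k + 1) for k in idx]
            c2 = [aln.codon(1, k + 1) for k in idx]
            return np.array(_pair_counts(c1, c2))

        all_idx = list(range(81))
        abs_idx = [i - 1 for i in mask.indices("ABS")]
        non_idx = [i - 1 for i in mask.indices("non-ABS")]
        assert counts(all_idx) == pytest.approx(counts(abs_idx) + counts(non_idx))

    def test_jc_correction_domain(self):
        with pytest.raises(ValueError, match="3/4"):
            jukes_cantor(0.8)


class TestZTest:
    def test_equal_rates(self):
        z, p = codon_z_test(0.1, 0.1, 0.01, 0.01)
        assert z == 0.0 and p == 0.5

    def test_published_style_values(self):
        z, p = codon_z_test(0.388, 0.057, 0.071**2, 0.038**2)
        assert z == pytest.approx(0.331 / math.sqrt(0.071**2 + 0.038**2), rel=1e-9)
        assert z == pytest.approx(4.11, abs=0.01)
        assert p < 0.001

    def test_antisymmetry(self):
        z1, _ = codon_z_test(0.3, 0.1, 0.01, 0.01)
        z2, _ = codon_z_test(0.1, 0.3, 0.01, 0.01)
        assert z1 == pytest.approx(-z2)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            codon_z_test(0.1, 0.2, 0.0, 0.0)


def reference_tajima(rows):
    """Independent textbook-formula implementation for cross-checking."""
    n = len(rows)
    L = len(rows[0])
    pi = 0.0
    npairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pi += sum(rows[i][k] != rows[j][k] for k in range(L))
            npairs += 1
    pi /= npairs
    S = sum(1 for k in range(L) if len({r[k] for r in rows}) > 1)
    if S == 0:
        return None
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajima:
    def test_no_segregating_sites(self):
        r = tajima_d(["ACGT"] * 4)
        assert r.s == 0 and r.d is None

    def test_zero_numerator_by_construction(self):
        # 4 sequences, one singleton-variant column: pi = 3/6*2... choose a
        # column pattern where pi == S/a1: with n=4, a1=11/6; S=1 needs
        # pi=6/11 which no single column gives, so build from the identity
        # directly: any rows where pi*a1 == S give D == 0
        rows = ["AAAA", "AAAT", "AATA", "ATAA", "TAAA"]  # n=5, 4 singleton cols
        r = tajima_d(rows)
        # pi = 4 * (2*4)/2 / 10 ... verify against the reference script sign
        ref = reference_tajima(rows)
        assert r.d == pytest.approx(ref, abs=1e-10)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(13)
        base = "".join(rng.choice(list(BASES), size=40))
        rows = []
        for _ in range(10):
            s = list(base)
            for _ in range(rng.integers(0, 6)):
                s[rng.integers(0, 40)] = BASES[rng.integers(0, 4)]
            rows.append("".join(s))
        ref = reference_tajima(rows)
        mine = tajima_d(rows)
        if ref is None:
            assert mine.d is None
        else:
            assert mine.d == pytest.approx(ref, abs=1e-10)

    def test_constants_match_closed_forms(self):
        for n in (4, 10, 50, 250):
            k = tajima_constants(n)
            assert k["a1"] == pytest.approx(sum(1 / i for i in range(1, n)))
            assert k["e1"] == pytest.approx(k["c1"] / k["a1"])
            assert k["e2"] == pytest.approx(k["c2"] / (k["a1"] ** 2 + k["a2"]))


class TestExpandToSample:
    def panel(self):
        return AlleleSet(
            [AlleleSequence("a", "ACGTAC"), AlleleSequence("b", "ACGTAA")]
        )

    def test_repeat_counts(self):
        t = AlleleCountTable("P", "L", 2, {"a": 3, "b": 1})
        rows = expand_to_sample(self.panel(), t)
        assert len(rows) == 4 and rows.count("ACGTAC") == 3

    def test_missing_sequence_error(self):
        t = AlleleCountTable("P", "L", 1, {"a": 1, "c": 1})
        with pytest.raises(KeyError):
            expand_to_sample(self.panel(), t)

    def test_pi_equals_frequency_weighted_distance(self):
        t = AlleleCountTable("P", "L", 3, {"a": 4, "b": 2})
        rows = expand_to_sample(self.panel(), t)
        r = tajima_d(rows)
        # algebraic identity: pi = sum_{i<j} N_i N_j d_ij / C(2n, 2)
        d_ab = 1  # sequences differ at one site
        expect = 4 * 2 * d_ab / (6 * 5 / 2)
        assert r.pi == pytest.approx(expect)


class TestSimulationRecovery:
    def test_selected_class_elevated_omega(self):
        mask = read_site_mask(bundled_path("abs_mask_drb_exon2.csv"))
        hits = 0
        for seed in range(20):
            aln = simulate_codon_alignment(
                10, 81, mask.codon_class, {"ABS": 5.0, "non-ABS": 0.3}, 30, seed=seed
            )
            r_abs = nei_gojobori(aln, mask, "ABS", bootstrap=0)
            r_non = nei_gojobori(aln, mask, "non-ABS", bootstrap=0)
            w_abs = r_abs.d_n / r_abs.d_s if r_abs.d_s > 0 else math.inf
            w_non = r_non.d_n / r_non.d_s if r_non.d_s > 0 else math.inf
            hits += w_abs > w_non
        assert hits >= 19

    def test_synthetic_panel_pipeline(self):
        panel = synthetic_drb_panel()
        aln = CodonAlignment.from_alleles(panel, frame_offset=2)
        assert aln.codon_count == 81
        n_var, n_pis, _ = variable_and_informative_sites(
            [a.exon_seq for a in panel]
        )
        assert n_var > 0 and n_pis >= 0
        mask = read_site_mask(bundled_path("abs_mask_drb_exon2.csv"))
        r = nei_gojobori(aln, mask, "ABS", bootstrap=50, seed=1)
        assert r.d_n >= 0 and r.se_n >= 0
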