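"""QC filters: missingness, MAF/HWE, LD pruning, relatedness."""

import math

import numpy as np
import pandas as pd
import pytest

from sweepscan.qc import (
    GenotypeTable,
    QcThresholds,
    MISSING,
    hwe_exact_p,
    filter_individuals_missing,
    filter_snps,
    snp_maf,
    ld_prune,
    pihat_matrix,
    remove_related,
    run_qc,
)

from conftest import make_snp_map


def make_table(geno, positions=None):
    geno = np.asarray(geno, dtype=np.int8)
    if positions is None:
        positions = [1000 * (j + 1) for j in range(geno.shape[1])]
    return GenotypeTable(
        geno, make_snp_map(positions), [f"s{i}" for i in range(geno.shape[0])]
    )


def hwe_enumeration_oracle(n_aa, n_ab, n_bb):
    """Exact HWE P by direct factorial enumeration (Fractions-free,
    small n only)."""
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab
    nb = 2 * n_bb + n_ab
    rare, com = min(na, nb), max(na, nb)

    def prob(h):
        return (
            2**h
            * math.factorial(n)
            / (
                math.factorial(h)
                * math.factorial((rare - h) // 2)
                * math.factorial((com - h) // 2)
            )
        )

    hets = list(range(rare % 2, rare + 1, 2))
    probs = {h: prob(h) for h in hets}
    total = sum(probs.values())
    obs = probs[n_ab]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12)) / total


class TestHweExact:
    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (40, 20, 40), (5, 90, 5), (30, 30, 40), (0, 10, 90)],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), rel=1e-9
        )

    def test_equilibrium_counts_retained_at_1e6(self):
        # (AA=25, Aa=50, aa=25) is the HWE expectation itself
        assert hwe_exact_p(25, 50, 25) > 1e-6


class TestMissingnessFilter:
    def test_no_missing_is_identity(self):
        t = make_table(np.ones((4, 10)))
        out, removed = filter_individuals_missing(t, 0.05)
        assert removed == []
        np.testing.assert_array_equal(out.geno, t.geno)

    def test_six_percent_missing_removed_at_five(self):
        geno = np.zeros((3, 100), dtype=np.int8)
        geno[1, :6] = MISSING  # 0.06 > 0.05
        out, removed = filter_individuals_missing(make_table(geno), 0.05)
        assert removed == ["s1"]
        assert out.sample_ids == ["s0", "s2"]

    def test_matches_brute_force_on_random_pattern(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, size=(30, 200)).astype(np.int8)
        geno[rng.random((30, 200)) < 0.04] = MISSING
        t = make_table(geno)
        _, removed = filter_individuals_missing(t, 0.05)
        expected = [
            f"s{i}" for i in range(30)
            if sum(geno[i, j] == MISSING for j in range(200)) / 200 > 0.05
        ]
        assert removed == expected

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        geno = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        geno[rng.random((10, 50)) < 0.1] = MISSING
        once, _ = filter_individuals_missing(make_table(geno), 0.05)
        twice, removed2 = filter_individuals_missing(once, 0.05)
        assert removed2 == []
        np.testing.assert_array_equal(once.geno, twice.geno)


class TestSnpFilters:
    def test_maf_threshold_logic(self):
        # MAF 0.04 in 50 individuals: 4 hets of 50 -> 4/100
        geno = np.zeros((50, 1), dtype=np.int8)
        geno[:4, 0] = 1
        t = make_table(geno)
        with_filter, _ = filter_snps(t, min_maf=0.05, hwe_alpha=1e-300)
        assert with_filter.n_snps == 0
        keep_low, _ = filter_snps(t, min_maf=0.05, hwe_alpha=1e-300, apply_maf=False)
        assert keep_low.n_snps == 1

    def test_monomorphic_reference_removed(self):
        t = make_table(np.zeros((20, 1)))
        out, log = filter_snps(t, min_maf=0.05, hwe_alpha=1e-300)
        assert out.n_snps == 0
        assert log["reason"].tolist() == ["maf"]

    def test_hwe_violation_removed(self):
        # all heterozygous: extreme HWE violation at any reasonable n
        t = make_table(np.ones((100, 1)))
        out, log = filter_snps(t, min_maf=0.0, hwe_alpha=1e-6, apply_maf=False)
        assert out.n_snps == 0
        assert log["reason"].tolist() == ["hwe"]


class TestLdPrune:
    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(5)
        col = rng.integers(0, 3, size=30).astype(np.int8)
        geno = np.column_stack([col, col, rng.integers(0, 3, 30)]).astype(np.int8)
        kept = ld_prune(make_table(geno), 50, 5, 0.2)
        assert 0 in kept and 1 not in kept  # earlier duplicate retained

    def test_independent_columns_all_retained(self):
        rng = np.random.default_rng(6)
        geno = rng.binomial(2, 0.5, size=(500, 20)).astype(np.int8)
        kept = ld_prune(make_table(geno), 50, 5, 0.5)
        assert list(kept) == list(range(20))

    def test_post_hoc_no_surviving_pair_exceeds_threshold(self):
        # constructed 60-SNP panel with blocks of correlated SNPs
        rng = np.random.default_rng(7)
        base = rng.binomial(2, 0.5, size=(80, 12)).astype(np.int8)
        cols = []
        for j in range(60):
            src = base[:, j % 12].copy()
            flip = rng.random(80) < 0.05  # near-copies -> high r2
            src[flip] = rng.integers(0, 3, flip.sum())
            cols.append(src)
        t = make_table(np.column_stack(cols).astype(np.int8))
        kept = set(ld_prune(t, prune_window=50, prune_step=5, prune_r2=0.2))
        geno = t.geno.astype(float)
        # re-scan every evaluated window: no surviving pair above r2 0.2
        for start in range(0, 60, 5):
            idx = [j for j in range(start, min(start + 50, 60)) if j in kept]
            for a_i, a in enumerate(idx):
                for b in idx[a_i + 1 :]:
                    r = np.corrcoef(geno[:, a], geno[:, b])[0, 1]
                    assert r * r <= 0.2 + 1e-12, (a, b, r * r)
        assert 0 < len(kept) < 60


class TestPihat:
    def test_duplicated_individual_near_one(self):
        rng = np.random.default_rng(8)
        freqs = rng.uniform(0.2, 0.8, 500)
        geno = rng.binomial(2, freqs, size=(6, 500)).astype(np.int8)
        geno[5] = geno[0]  # duplicate sample
        ph = pihat_matrix(make_table(geno))
        assert ph[0, 5] > 0.9
        retained = remove_related(ph, [f"s{i}" for i in range(6)], 0.2)
        assert len(retained) == 5 and ("s0" in retained) != ("s5" in retained)

    def test_unrelated_individuals_near_zero(self):
        rng = np.random.default_rng(9)
        freqs = rng.uniform(0.1, 0.9, 5000)
        geno = rng.binomial(2, freqs, size=(10, 5000)).astype(np.int8)
        ph = pihat_matrix(make_table(geno))
        off = ph[np.triu_indices(10, 1)]
        assert abs(off.mean()) < 0.05

    def test_parent_offspring_near_half(self):
        rng = np.random.default_rng(10)
        freqs = rng.uniform(0.2, 0.8, 5000)
        n_pairs = 5
        genos = []
        for _ in range(n_pairs):
            pa = (rng.random((2, 5000)) < freqs).astype(np.int8)  # parent haplotypes
            ma = (rng.random((2, 5000)) < freqs).astype(np.int8)
            child = pa[rng.integers(0, 2, 5000), np.arange(5000)] + ma[
                rng.integers(0, 2, 5000), np.arange(5000)
            ]
            genos.append(pa.sum(0))
            genos.append(child)
        ph = pihat_matrix(make_table(np.array(genos, dtype=np.int8)))
        po = [ph[2 * i, 2 * i + 1] for i in range(n_pairs)]
        assert np.mean(po) == pytest.approx(0.5, abs=0.1)

    def test_fewer_than_two_individuals(self):
        t = make_table(np.zeros((1, 10)))
        assert pihat_matrix(t).shape == (1, 1)


class TestFilterOrder:
    def test_individual_filter_first_changes_snp_outcome(self):
        """The chain filters individuals before SNPs; a SNP whose minor
        alleles sit in a to-be-removed individual can pass or fail the
        MAF filter depending on the order, so the order is contractual."""
        geno = np.zeros((10, 40), dtype=np.int8)
        geno[0, :3] = MISSING            # individual 0: 7.5% missing
        # SNP 10: minor alleles only in individual 0 -> MAF 2/20 = 0.1
        # with them, 0/18 without
        geno[0, 10] = 2
        t = make_table(geno)
        # contractual order: individual filter first, SNP 10 then fails MAF
        t1, removed = filter_individuals_missing(t, 0.05)
        assert removed == ["s0"]
        _, log_after = filter_snps(t1, 0.05, 1e-300)
        assert "snp10" in log_after["id"].tolist()
        # swapped order: SNP 10 passes MAF while individual 0 is present
        _, log_before = filter_snps(t, 0.05, 1e-300)
        assert "snp10" not in log_before["id"].tolist()


class TestFullChain:
    def test_planted_violations_removed_exactly(self):
        """One high-missingness individual, one low-MAF SNP, one
        HWE-violating SNP and one duplicated individual are each caught
        by their dedicated filter and nothing else is removed."""
        rng = np.random.default_rng(12)
        n, m = 30, 1500
        freqs = rng.uniform(0.2, 0.8, m)
        geno = rng.binomial(2, freqs, size=(n, m)).astype(np.int8)
        geno[7] = geno[3]                      # duplicated individual
        geno[5, : int(0.08 * m)] = MISSING     # 8% missing
        low = np.zeros(n, dtype=np.int8)       # MAF 2/80 = 0.025
        low[:2] = 1
        geno[:, 40] = low
        geno[:, 80] = 1                        # all-het: HWE violation
        t = make_table(geno)
        out, log = run_qc(t, QcThresholds())
        assert log["removed_missing"] == ["s5"]
        assert sorted(log["removed_snps"]["id"]) == ["snp40", "snp80"]
        assert sorted(log["removed_snps"]["reason"]) == ["hwe", "maf"]
        assert log["removed_related"] in (["s3"], ["s7"])
        assert out.n_samples == n - 2
        assert out.n_snps == m - 2
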