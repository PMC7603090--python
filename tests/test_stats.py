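"""Fst and EHH/XP-EHH against closed forms and brute-force oracles."""

from math import comb

import numpy as np
import pytest

from sweepscan.simulate import SimConfig, simulate_panel
from sweepscan.stats import (
    ehh_curve,
    fst_per_snp,
    fst_scan,
    xpehh_at,
    xpehh_scan,
)
from sweepscan.types import MISSING
from conftest import make_haps, make_variants


def fst_anova_oracle(m1, p1, m2, p2):
    """Independent allele-level ANOVA: lay out the alleles explicitly and
    compute mean squares from first principles."""
    alleles = [np.concatenate([np.ones(round(m * p)), np.zeros(m - round(m * p))])
               for m, p in ((m1, p1), (m2, p2))]
    means = [a.mean() for a in alleles]
    grand = np.concatenate(alleles).mean()
    msp = sum(len(a) * (mu - grand) ** 2 for a, mu in zip(alleles, means)) / (2 - 1)
    msg = sum(((a - mu) ** 2).sum() for a, mu in zip(alleles, means)) / (m1 - 1 + m2 - 1)
    total = m1 + m2
    n_c = total - (m1 ** 2 + m2 ** 2) / total
    denom = msp + (n_c - 1) * msg
    return (msp - msg) / denom if denom else float("nan")


class TestFstPerSnp:
    def test_fixed_difference_is_one(self):
        assert fst_per_snp(20, 1.0, 20, 0.0).fst == 1.0

    def test_equal_frequencies_forced_negative(self):
        res = fst_per_snp(20, 0.5, 20, 0.5)
        assert res.msp == 0.0
        assert res.fst == pytest.approx(-1 / (res.n_c - 1))
        assert res.fst == pytest.approx(-1 / 19)

    def test_worked_example_against_anova_oracle(self):
        res = fst_per_snp(20, 0.8, 20, 0.2)
        assert res.msp == pytest.approx(3.6)
        assert res.msg == pytest.approx(6.4 / 38)
        assert res.n_c == pytest.approx(20)
        assert res.fst == pytest.approx(0.50464, abs=5e-6)
        assert res.fst == pytest.approx(fst_anova_oracle(20, 0.8, 20, 0.2), abs=1e-12)

    def test_random_configurations_match_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            m1, m2 = rng.integers(2, 60, size=2)
            # frequencies realizable as allele counts so the oracle is exact
            p1 = rng.integers(0, m1 + 1) / m1
            p2 = rng.integers(0, m2 + 1) / m2
            got = fst_per_snp(int(m1), p1, int(m2), p2).fst
            want = fst_anova_oracle(int(m1), p1, int(m2), p2)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_monomorphic_same_allele_undefined(self):
        assert np.isnan(fst_per_snp(10, 0.0, 10, 0.0).fst)


class TestFstScan:
    def test_fixed_difference_panel(self):
        haps = make_haps([[1, 1]] * 8 + [[0, 0]] * 8)
        from sweepscan.types import PopulationMap
        pops = PopulationMap({f"S{i + 1}": ("A" if i < 4 else "B") for i in range(8)})
        fst = fst_scan(haps.to_genotypes(), pops, "A", "B")
        np.testing.assert_allclose(fst, 1.0)

    def test_sample_permutation_invariance(self, small_panel):
        v, h, p = small_panel
        g = h.to_genotypes()
        f1 = fst_scan(g, p, "OBJ", "REF")
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(g.sample_ids))
        f2 = fst_scan(g.subset_samples(perm), p, "OBJ", "REF")
        np.testing.assert_allclose(f1, f2)

    def test_matches_per_snp_composition(self, small_panel):
        v, h, p = small_panel
        g = h.to_genotypes()
        fst = fst_scan(g, p, "OBJ", "REF")
        idx = {s: k for k, s in enumerate(g.sample_ids)}
        rows_a = [idx[s] for s in p.samples_in("OBJ")]
        rows_b = [idx[s] for s in p.samples_in("REF")]
        for j in range(0, v.n_variants, 7):
            col_a = g.entries[rows_a, j]
            col_b = g.entries[rows_b, j]
            m1, m2 = 2 * len(col_a), 2 * len(col_b)
            want = fst_per_snp(m1, col_a.sum() / m1, m2, col_b.sum() / m2).fst
            if np.isnan(want):
                assert np.isnan(fst[j])
            else:
                assert fst[j] == pytest.approx(want, abs=1e-12)

    def test_unknown_population_errors(self, small_panel):
        _, h, p = small_panel
        with pytest.raises(KeyError):
            fst_scan(h.to_genotypes(), p, "OBJ", "NOPE")


# ---------------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------------

def ehh_brute_force(entries, core, x):
    """Exhaustive partition counting of EHH over the closed interval [core..x]
    (pooled denominator, missing haplotypes dropped from the numerator)."""
    lo, hi = min(core, x), max(core, x)
    n0 = int((entries[:, core] == 0).sum())
    n1 = int((entries[:, core] == 1).sum())
    denom = comb(n0, 2) + comb(n1, 2)
    if denom == 0:
        return None
    groups: dict[tuple, int] = {}
    for row in entries:
        if np.any(row[lo:hi + 1] == MISSING) or row[core] == MISSING:
            continue
        key = tuple(row[lo:hi + 1])
        groups[key] = groups.get(key, 0) + 1
    return sum(comb(c, 2) for c in groups.values()) / denom


class TestEhhCurve:
    def test_perfect_homozygosity(self):
        # two classes of two identical haplotypes out to every marker
        entries = np.array([[1, 0, 1], [1, 0, 1], [0, 1, 1], [0, 1, 1]], dtype=np.int8)
        haps = make_haps(entries)
        curve = ehh_curve(haps, make_variants([10, 20, 30]), core=1, epsilon=0.0)
        np.testing.assert_allclose(curve.values, 1.0)

    def test_complete_breakdown(self):
        # all four haplotypes distinct once the neighbor is included
        entries = np.array([[1, 0], [1, 1], [0, 0], [0, 1]], dtype=np.int8)
        haps = make_haps(entries)
        curve = ehh_curve(haps, make_variants([10, 20]), core=0, epsilon=0.0)
        assert curve.values[list(curve.positions).index(0)] == 1.0
        assert curve.values[-1] == 0.0

    def test_matches_brute_force_on_random_panels(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n_h = int(rng.integers(4, 13)) // 2 * 2
            n_m = int(rng.integers(5, 21))
            entries = rng.integers(0, 2, size=(n_h, n_m)).astype(np.int8)
            entries[rng.random(entries.shape) < 0.05] = MISSING
            haps = make_haps(entries)
            variants = make_variants(np.arange(n_m) * 100 + 1)
            core = int(rng.integers(0, n_m))
            curve = ehh_curve(haps, variants, core, epsilon=0.0)
            if curve is None:
                assert ehh_brute_force(entries, core, core) is None
                continue
            for off, val in zip(curve.positions, curve.values):
                x = list(variants.pos).index(variants.pos[core] + off)
                assert val == pytest.approx(ehh_brute_force(entries, core, x),
                                            abs=1e-12)

    def test_curves_non_increasing_outward(self, small_panel):
        v, h, p = small_panel
        sub = h.subset_samples(p.samples_in("OBJ"))
        for core in range(0, v.n_variants, 11):
            curve = ehh_curve(sub, v, core, epsilon=0.0)
            if curve is None:
                continue
            left = curve.values[curve.positions <= 0][::-1]
            right = curve.values[curve.positions >= 0]
            assert np.all(np.diff(left) <= 1e-12)
            assert np.all(np.diff(right) <= 1e-12)
            assert curve.values[list(curve.positions).index(0)] == 1.0


class TestXpehh:
    def test_identical_panels_give_unit_ratio(self, small_panel):
        v, h, p = small_panel
        sub = h.subset_samples(p.samples_in("OBJ"))
        for core in (5, 50, 150):
            res = xpehh_at(core, sub, sub, v)
            if res is None:
                continue
            assert res.ratio == pytest.approx(1.0)
            assert res.ln_ratio == pytest.approx(0.0)
            assert res.domain[0] <= v.pos[core] <= res.domain[1]

    def test_swept_object_population_exceeds_one(self):
        rng = np.random.default_rng(1)
        n_m = 41
        ref = rng.integers(0, 2, size=(12, n_m)).astype(np.int8)
        obj = np.tile(rng.integers(0, 2, size=n_m).astype(np.int8), (12, 1))
        obj[:, 20] = ref[:, 20] = np.array([0, 1] * 6, dtype=np.int8)  # shared core
        variants = make_variants(np.arange(n_m) * 1000 + 1)
        res = xpehh_at(20, make_haps(obj), make_haps(ref), variants)
        assert res.ratio > 1.0

    def test_population_swap_negates_ln_ratio(self, small_panel):
        v, h, p = small_panel
        ho = h.subset_samples(p.samples_in("OBJ"))
        hr = h.subset_samples(p.samples_in("REF"))
        r1, l1 = xpehh_scan(ho, hr, v)
        r2, l2 = xpehh_scan(hr, ho, v)
        ok = ~np.isnan(l1) & ~np.isnan(l2)
        np.testing.assert_allclose(l1[ok], -l2[ok], atol=1e-12)

    def test_integration_against_rectangle_rule_oracle(self):
        """Trapezoid iEHH ratio agrees with an independent rectangle-rule
        computation built on the brute-force EHH values, to 2%, once marker
        spacing is halved (dense panel)."""
        rng = np.random.default_rng(5)
        n_m = 81
        pos = np.arange(n_m) * 50 + 1  # dense, uniform spacing
        variants = make_variants(pos)
        obj = rng.integers(0, 2, size=(10, n_m)).astype(np.int8)
        obj[:6] = obj[0]  # partial homozygosity tract
        ref = rng.integers(0, 2, size=(10, n_m)).astype(np.int8)
        core = 40
        res = xpehh_at(core, make_haps(obj), make_haps(ref), variants, epsilon=0.05)
        assert res is not None

        def rect_iehh(entries, lo_idx, hi_idx):
            total = 0.0
            for j in range(lo_idx, hi_idx + 1):
                v = ehh_brute_force(entries, core, j)
                total += v * 50  # uniform spacing → rectangle rule
            return total

        lo_idx = list(pos).index(res.domain[0])
        hi_idx = list(pos).index(res.domain[1])
        oracle = rect_iehh(obj, lo_idx, hi_idx) / rect_iehh(ref, lo_idx, hi_idx)
        assert res.ratio == pytest.approx(oracle, rel=0.02)

    def test_no_sweep_median_ln_ratio_near_zero(self):
        cfg = SimConfig(n_pops=2, samples_per_pop=(20, 20), pop_labels=("A", "B"),
                        n_snps=2000, chrom_length=20_000_000, divergence_F=0.1, seed=21)
        v, h, p = simulate_panel(cfg)
        ho = h.subset_samples(p.samples_in("A"))
        hr = h.subset_samples(p.samples_in("B"))
        _, ln = xpehh_scan(ho, hr, v)
        assert abs(np.nanmedian(ln)) <= 0.1
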