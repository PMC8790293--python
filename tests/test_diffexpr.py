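"""Normalization, dispersion estimation, the NB exact test and DEG calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pathmarker.diffexpr import (
    CountMatrix,
    call_degs,
    cpm,
    de_table,
    estimate_dispersion,
    exact_test,
    normalize,
)
from pathmarker.synthetic_data import simulate_counts


def make_counts(matrix, n_tumor, n_normal):
    matrix = np.asarray(matrix)
    samples = [f"T{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_normal)]
    counts = pd.DataFrame(matrix, columns=samples,
                          index=[f"g{i}" for i in range(matrix.shape[0])])
    labels = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=samples)
    return CountMatrix(counts=counts, labels=labels)


class TestNormalize:
    def test_equal_libraries_unit_factors(self, toy_counts):
        assert np.allclose(normalize(toy_counts, "libsize"), 1.0)

    def test_doubled_library_doubles_factor(self):
        base = np.array([[10, 10, 20], [20, 20, 40], [30, 30, 60]])
        cm = make_counts(base, 2, 1)
        f = normalize(cm, "libsize")
        assert np.isclose(f["N0"] / f["T0"], 2.0)
        assert np.isclose(np.exp(np.mean(np.log(f))), 1.0)

    def test_tmm_matches_bruteforce_trimmed_mean(self):
        rng = np.random.default_rng(0)
        ref = rng.poisson(100, size=400)
        obs = rng.poisson(100, size=400)
        obs[:40] *= 5  # a block of genes shifted up in the observed sample
        cm = make_counts(np.column_stack([obs, ref]), 1, 1)
        f = normalize(cm, "tmm")

        # independent recomputation: doubly trimmed mean of gene-wise M values
        lib_o, lib_r = obs.sum(), ref.sum()
        ok = (obs > 0) & (ref > 0)
        m = np.log2((obs[ok] / lib_o) / (ref[ok] / lib_r))
        a = 0.5 * np.log2((obs[ok] / lib_o) * (ref[ok] / lib_r))
        keep = np.ones(m.size, bool)
        for v, t in ((m, 0.30), (a, 0.05)):
            lo, hi = np.quantile(v, [t, 1 - t])
            keep &= (v >= lo) & (v <= hi)
        raw = 2.0 ** np.mean(m[keep])
        expected = np.array([raw, 1.0])
        expected /= np.exp(np.mean(np.log(expected)))
        # reference column choice may swap the pair; compare the ratio
        assert np.isclose(f["T0"] / f["N0"], expected[0] / expected[1], rtol=1e-9)

    def test_all_zero_rejected(self):
        cm = make_counts(np.zeros((3, 4), dtype=int), 2, 2)
        with pytest.raises(ValueError):
            normalize(cm)


class TestDispersion:
    def test_poisson_common_near_zero(self):
        cm, _ = simulate_counts(2000, 25, 25, frac_de=0.0, dispersion=0.0,
                                seed=12, sample_factor_sd=0.0)
        est = estimate_dispersion(cm)
        assert est.common < 0.05

    def test_parameter_recovery(self):
        cm, _ = simulate_counts(2000, 25, 25, frac_de=0.0, dispersion=0.4,
                                seed=12)
        est = estimate_dispersion(cm)
        assert 0.3 <= est.common <= 0.5

    def test_constant_gene_clamped_to_zero(self):
        mat = np.full((1, 8), 7)
        cm = make_counts(mat, 4, 4)
        est = estimate_dispersion(cm, shrink_weight=0.0)
        assert est.per_gene.iloc[0] == 0.0

    def test_single_sample_group_falls_back_with_warning(self):
        mat = np.array([[5, 6], [7, 8]])
        cm = make_counts(mat, 1, 1)
        with pytest.warns(UserWarning):
            est = estimate_dispersion(cm)
        assert est.common == 0.0


class TestExactTest:
    def test_identical_totals_p_one(self):
        for phi in (0.0, 0.1, 1.0):
            assert exact_test([5, 5], [5, 5], phi) == 1.0

    def test_all_zero_p_one(self):
        assert exact_test([0, 0, 0], [0, 0], 0.3) == 1.0

    def test_matches_bruteforce_enumeration(self):
        # independent oracle: explicit linear-scale enumeration of the
        # conditional distribution of the group-A total
        def oracle(sa, sb, na, nb, phi):
            t = sa + sb

            def pmf(k, n):
                mu = n * t / (na + nb)
                if phi == 0:
                    return stats.poisson.pmf(k, mu)
                r = n / phi
                return stats.nbinom.pmf(k, r, r / (r + mu))

            probs = np.array([pmf(k, na) * pmf(t - k, nb) for k in range(t + 1)])
            probs = probs / probs.sum()
            return probs[probs <= probs[sa] * (1 + 1e-12)].sum()

        rng = np.random.default_rng(7)
        for _ in range(40):
            na, nb = rng.integers(1, 5, size=2)
            sa, sb = rng.integers(0, 15, size=2)
            phi = float(rng.choice([0.0, 0.1, 0.5, 2.0]))
            a = np.zeros(na, int)
            a[0] = sa
            b = np.zeros(nb, int)
            b[0] = sb
            assert exact_test(a, b, phi) == pytest.approx(
                oracle(int(sa), int(sb), int(na), int(nb), phi), abs=1e-10
            )

    def test_poisson_limit_matches_conditional_binomial(self):
        # phi = 0: split of the total is Binomial(t, nA/(nA+nB))
        for sa, sb, na, nb in [(8, 3, 2, 2), (10, 10, 3, 1), (0, 7, 1, 4)]:
            t = sa + sb
            probs = stats.binom.pmf(np.arange(t + 1), t, na / (na + nb))
            expected = probs[probs <= probs[sa] * (1 + 1e-12)].sum()
            a = np.zeros(na, int); a[0] = sa
            b = np.zeros(nb, int); b[0] = sb
            assert exact_test(a, b, 0.0) == pytest.approx(expected, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        sa=st.integers(0, 25),
        sb=st.integers(0, 25),
        phi=st.sampled_from([0.0, 0.2, 1.0]),
    )
    def test_label_swap_symmetry(self, sa, sb, phi):
        a = [sa, 0]
        b = [0, sb]
        assert exact_test(a, b, phi) == pytest.approx(
            exact_test(b, a, phi), abs=1e-12
        )

    def test_monotone_in_group_difference(self):
        # at fixed total, pushing the split further from balance never
        # increases the p-value
        t = 40
        last = 1.1
        for sa in range(20, 41):
            p = exact_test([sa], [t - sa], 0.1)
            assert p <= last + 1e-12
            last = p

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            exact_test([-1, 2], [3], 0.1)


class TestDEGCalling:
    def test_filter_rule_and_boundaries(self):
        tab = pd.DataFrame(
            {
                "gene": ["a", "b", "c", "d"],
                "FC": [2.5, 2.0, 0.4, 0.4],
                "PValue": [0.01, 0.001, 0.2, 0.01],
            }
        )
        call = call_degs(tab)
        kept = dict(zip(call.table["gene"], call.table["direction"]))
        assert kept == {"a": "up", "d": "down"}  # FC exactly 2.0 excluded
        assert call.n_up == 1 and call.n_down == 1

    def test_planted_de_recovery(self):
        cm, truth = simulate_counts(
            500, 50, 50, frac_de=0.1, lfc_magnitude=2.0, dispersion=0.1, seed=21
        )
        call = call_degs(de_table(cm))
        found = set(call.genes)
        recovered = len(truth.de_genes & found) / len(truth.de_genes)
        nulls = set(cm.genes) - truth.de_genes
        false_rate = len(found & nulls) / len(nulls)
        assert recovered >= 0.90
        assert false_rate <= 0.07

    def test_cpm_pseudocount_keeps_fc_finite(self):
        # one gene silent in the normal group entirely
        mat = np.vstack([[50, 50, 50, 0, 0, 0], [10] * 6])
        cm = make_counts(mat, 3, 3)
        tab = de_table(cm)
        assert np.isfinite(tab["FC"]).all()
        assert (tab["FC"] > 0).all()
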