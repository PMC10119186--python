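"""Burden/variance-component tests: identities, oracles, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, hypergeom, kstest

from ajburden import assoc, skat, synth
from ajburden.containers import GenotypeMatrix


class TestMixtureTail:
    def test_single_eigenvalue_is_exact_chi_square(self):
        for lam in (0.5, 1.0, 7.3):
            for q in (0.3, 2.0, 9.0):
                assert skat.mixture_sf(q, [lam]) == pytest.approx(
                    chi2.sf(q / lam, 1), rel=1e-9
                )

    def test_equal_eigenvalues_are_scaled_chi_square_k(self):
        lam = np.ones(5) * 2.0
        for q in (4.0, 10.0, 25.0):
            # sum of 5 chi2_1 scaled by 2 is 2 * chi2_5
            exact = chi2.sf(q / 2.0, 5)
            assert skat.mixture_sf(q, lam) == pytest.approx(exact, rel=1e-6)
            assert skat.mixture_sf(q, lam, method="saddle") == pytest.approx(
                exact, rel=0.02
            )

    def test_saddlepoint_matches_monte_carlo(self, rng):
        lam = np.array([3.0, 1.0, 0.5, 0.1])
        draws = (lam * rng.chisquare(1, size=(200_000, 4))).sum(axis=1)
        for q in (8.0, 15.0, 20.0):
            mc = (draws > q).mean()
            tol = max(3.5 * np.sqrt(mc * (1 - mc) / 2e5), 0.05 * mc)
            assert skat.mixture_sf(q, lam, method="saddle") == pytest.approx(
                mc, abs=tol
            )


class TestCarrierBurden:
    def test_reconstructed_carrier_counts_recover_reference_or(self):
        # carrier frequencies 15.74% of 1734 cases, 9.26% of 2719 controls
        n_case, n_ctrl = 1734, 2719
        c_case = round(0.1574 * n_case)
        c_ctrl = round(0.0926 * n_ctrl)
        carriers = np.zeros(n_case + n_ctrl, dtype=bool)
        carriers[:c_case] = True
        carriers[n_case:n_case + c_ctrl] = True
        y = np.concatenate([np.ones(n_case), np.zeros(n_ctrl)]).astype(int)
        res = assoc.carrier_burden_test(carriers, y)
        assert res["or_carrier"] == pytest.approx(1.83, abs=0.005)
        assert res["p"] < 1e-9

    def test_equal_frequencies_give_unit_or(self):
        carriers = np.tile([True] * 10 + [False] * 90, 2)
        y = np.repeat([1, 0], 100)
        res = assoc.carrier_burden_test(carriers, y)
        assert res["or_carrier"] == pytest.approx(1.0)
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_p_direction_consistent_with_exact_enumeration(self):
        # table (a=10, b=90, c=10, d=90): OR = 1; Fisher's exact p = 1
        carriers = np.tile([True] * 10 + [False] * 90, 2)
        y = np.repeat([1, 0], 100)
        res = assoc.carrier_burden_test(carriers, y)
        n, K, N = 200, 20, 100  # hypergeometric margins
        exact = sum(
            hypergeom.pmf(k, n, K, N)
            for k in range(K + 1)
            if hypergeom.pmf(k, n, K, N) <= hypergeom.pmf(10, n, K, N) + 1e-12
        )
        assert res["p"] == pytest.approx(1.0)
        assert exact == pytest.approx(1.0, abs=1e-9)

    def test_label_swap_inverts_or(self, rng):
        carriers = rng.random(300) < 0.2
        y = (rng.random(300) < 0.5).astype(int)
        a = assoc.carrier_burden_test(carriers, y)
        b = assoc.carrier_burden_test(carriers, 1 - y)
        assert a["or_carrier"] == pytest.approx(1.0 / b["or_carrier"])
        assert a["p"] == pytest.approx(b["p"], rel=1e-9)

    def test_all_carriers_degenerate(self):
        y = np.repeat([1, 0], 10)
        res = assoc.carrier_burden_test(np.ones(20, dtype=bool), y)
        assert res["degenerate"] and np.isnan(res["p"])

    def test_zero_cell_uses_haldane(self):
        carriers = np.array([True] * 5 + [False] * 95 + [False] * 100)
        y = np.repeat([1, 0], 100)
        res = assoc.carrier_burden_test(carriers, y)
        assert res["haldane"]
        assert np.isfinite(res["or_carrier"])


def _sim_block(rng, n=800, m=5, maf=None):
    if maf is None:
        maf = rng.uniform(0.005, 0.03, m)
    dose = rng.binomial(2, maf, size=(n, m)).astype(float)
    return dose, maf


class TestSkatO:
    def test_rho_identities(self, rng):
        dose, maf = _sim_block(rng)
        y = (rng.random(800) < 0.5).astype(float)
        res = assoc.skat_o_test(dose, y, maf=maf)
        i0 = res["rho_grid"].index(0.0)
        i1 = res["rho_grid"].index(1.0)
        assert res["q_rho"][i0] == pytest.approx(res["q_skat"], rel=1e-9)
        # rho=1 endpoint is evaluated at 0.999 by design
        assert res["q_rho"][i1] == pytest.approx(
            0.001 * res["q_skat"] + 0.999 * res["q_burden"], rel=1e-9
        )

    def test_single_variant_reduces_to_score_test(self, rng):
        dose, maf = _sim_block(rng, m=1, maf=np.array([0.05]))
        y = (rng.random(800) < 0.5).astype(float)
        res = assoc.skat_o_test(dose, y, maf=maf)
        assert res["p_skato"] == pytest.approx(res["p_rho"][0], abs=1e-6)
        assert np.allclose(res["p_rho"], res["p_rho"][0])

    def test_invariant_to_variant_and_sample_order(self, rng):
        dose, maf = _sim_block(rng, n=400)
        y = (rng.random(400) < 0.4).astype(float)
        res1 = assoc.skat_o_test(dose, y, maf=maf)
        perm_v = rng.permutation(dose.shape[1])
        res2 = assoc.skat_o_test(dose[:, perm_v], y, maf=maf[perm_v])
        assert res1["p_skato"] == pytest.approx(res2["p_skato"], rel=1e-6)
        perm_s = rng.permutation(400)
        res3 = assoc.skat_o_test(dose[perm_s], y[perm_s], maf=maf)
        assert res1["p_skato"] == pytest.approx(res3["p_skato"], rel=1e-6)

    def test_monomorphic_only_block_rejected(self):
        with pytest.raises(ValueError):
            assoc.skat_o_test(np.zeros((100, 3)), np.repeat([0.0, 1.0], 50))

    def test_null_calibration_permuted_phenotype(self, rng):
        # many genes, permuted phenotype: p uniform at the tested levels
        n, genes = 500, 300
        y = np.repeat([0.0, 1.0], n // 2)
        null = assoc.fit_null_model(y)
        ps = []
        for _ in range(genes):
            dose, maf = _sim_block(rng, n=n, m=4)
            res = assoc.skat_o_test(dose, null=null, maf=maf)
            ps.append(res["p_skato"])
        ps = np.asarray(ps)
        for alpha in (0.05, 0.01):
            frac = (ps < alpha).mean()
            ci = 3 * np.sqrt(alpha * (1 - alpha) / genes)
            assert abs(frac - alpha) <= ci

    def test_spiked_gene_beats_null_median(self, rng):
        n = 1000
        med_alt, med_null = [], []
        for _ in range(10):
            dose, maf = _sim_block(rng, n=n, m=5,
                                   maf=np.full(5, 0.01))
            carrier = (dose > 0).any(axis=1)
            logit = -1.0 + np.log(3.0) * carrier
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
            med_alt.append(assoc.skat_o_test(dose, y, maf=maf)["p_skato"])
            y0 = rng.permutation(y)
            med_null.append(assoc.skat_o_test(dose, y0, maf=maf)["p_skato"])
        assert np.median(med_alt) < np.median(med_null)


class TestVariantLogistic:
    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(200):
            dose = rng.binomial(2, 0.3, 500).astype(float)
            y = (rng.random(500) < 0.5).astype(float)
            res = assoc.variant_logistic(dose, y)
            ps.append(res["p"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_collinear_covariate_flagged(self, rng):
        dose = rng.binomial(2, 0.3, 200).astype(float)
        y = (rng.random(200) < 0.5).astype(float)
        res = assoc.variant_logistic(dose, y, covariates=dose[:, None])
        assert res["collinear"]

    def test_monomorphic_skipped(self):
        res = assoc.variant_logistic(np.zeros(100), np.repeat([0.0, 1.0], 50))
        assert res["skipped"]

    def test_strong_effect_detected(self, rng):
        hits = 0
        for _ in range(10):
            dose = rng.binomial(2, 0.05, 3000).astype(float)
            logit = -0.5 + np.log(3.0) * dose
            y = (rng.random(3000) < 1 / (1 + np.exp(-logit))).astype(float)
            res = assoc.variant_logistic(dose, y)
            hits += res["p"] < 1e-4
        assert hits >= 9


class TestInflation:
    def test_uniform_p_values_give_unit_lambda(self):
        p = np.linspace(1e-6, 1 - 1e-6, 10_001)
        assert assoc.inflation_check(p) == pytest.approx(1.0, abs=0.05)

    def test_squared_p_values_inflate(self):
        p = np.linspace(1e-6, 1 - 1e-6, 10_001) ** 2
        assert assoc.inflation_check(p) > 1.0

    def test_too_few_p_values_rejected(self):
        with pytest.raises(ValueError):
            assoc.inflation_check(np.linspace(0.1, 0.9, 50))

    def test_synonymous_and_split_control_modes_calibrated(self, null_study):
        study = null_study
        y = study.phenotype
        syn = assoc.synonymous_scan(study.annotation_full, study.genotypes, y)
        assert len(syn) > 50
        assert 0.2 < np.median(syn["p_skato"]) < 0.8
        qual = study.annotation_full[
            study.annotation_full["variant_id"].isin(study.qualifying)]
        blocks, _ = assoc.collapse_by_gene(qual, study.genotypes)
        cvc = assoc.controls_split_scan(blocks, y == 0, seed=1)
        assert len(cvc) > 50
        assert 0.2 < np.median(cvc["p_skato"]) < 0.8


class TestBonferroni:
    @pytest.mark.parametrize(
        "n,expected", [(13_268, 3.76e-6), (1, 0.05), (20, 0.0025)]
    )
    def test_threshold_values(self, n, expected):
        assert assoc.bonferroni_threshold(n) == pytest.approx(expected, rel=5e-3)

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            assoc.bonferroni_threshold(0)


class TestCollapse:
    def test_carrier_counts_match_brute_force(self, small_study):
        study = small_study
        qual = study.annotation_full[
            study.annotation_full["variant_id"].isin(study.qualifying)
        ]
        blocks, _ = assoc.collapse_by_gene(qual, study.genotypes)
        g = study.genotypes
        for gene, blk in list(blocks.items())[:20]:
            idx = g.variant_index(blk.variant_ids)
            brute = (g.dosages[:, idx] > 0).any(axis=1)
            np.testing.assert_array_equal(blk.carriers, brute)

    def test_single_het_gives_single_carrier(self):
        g = GenotypeMatrix(
            np.array([[0], [1], [0]], dtype=np.int8), ["a", "b", "c"], ["v1"]
        )
        qual = pd.DataFrame({"variant_id": ["v1"], "gene": ["G1"]})
        blocks, _ = assoc.collapse_by_gene(qual, g, maf_max=0.5)
        assert blocks["G1"].carriers.tolist() == [False, True, False]

    def test_sample_in_two_genes_counted_in_each(self):
        g = GenotypeMatrix(
            np.array([[1, 1], [0, 0]], dtype=np.int8), ["a", "b"], ["v1", "v2"]
        )
        qual = pd.DataFrame({"variant_id": ["v1", "v2"], "gene": ["G1", "G2"]})
        blocks, _ = assoc.collapse_by_gene(qual, g, maf_max=0.5)
        assert blocks["G1"].carriers[0] and blocks["G2"].carriers[0]


class TestPhewas:
    def test_min_case_threshold_and_null_positive_contrast(self, rng):
        n = 3000
        dose = rng.binomial(2, 0.01, size=(n, 6)).astype(float)
        maf = np.full(6, 0.01)
        block = assoc.GeneBlock("G1", np.array([f"v{i}" for i in range(6)],
                                               dtype=object),
                                dose, (dose > 0).any(axis=1), maf)
        sample_ids = [f"s{i}" for i in range(n)]
        pcs = rng.normal(size=(n, 2))
        carrier = block.carriers
        # linked phenotype: carriers at strongly elevated odds
        logit = -3.5 + 2.0 * carrier
        linked = np.asarray(rng.random(n) < 1 / (1 + np.exp(-logit)))
        codes = []
        for i in range(n):
            if linked[i]:
                codes.append((sample_ids[i], "LINKED"))
            if rng.random() < 0.05:
                codes.append((sample_ids[i], "RANDOM"))
            if rng.random() < 0.02:
                codes.append((sample_ids[i], "RARE99"))
        phen = pd.DataFrame(codes, columns=["sample_id", "code"])
        # force RARE99 below the case threshold
        rare_ids = phen[phen.code == "RARE99"]["sample_id"].iloc[:50]
        phen = phen[(phen.code != "RARE99")
                    | phen.sample_id.isin(rare_ids)]
        res = assoc.phewas_scan(block, phen, sample_ids, sample_ids, pcs,
                                seed=3)
        assert "RARE99" not in set(res["code"])  # < 100 cases
        got = res.set_index("code")
        assert got.loc["LINKED", "p_skato"] < got.loc["RANDOM", "p_skato"]
        assert (got["n_controls"] == 10 * got["n_cases"]).all()
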