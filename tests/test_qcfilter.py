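"""QC rules, exact HWE, kinship, and the six-rule deleteriousness filter."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from ajburden import qcfilter, synth
from ajburden.containers import GenotypeMatrix


def make_geno(dosages, **kw):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    kw.setdefault("sample_ids", [f"s{i}" for i in range(n)])
    kw.setdefault("variant_ids", [f"v{j}" for j in range(m)])
    return GenotypeMatrix(dosages=dosages, **kw)


class TestSplitMultiallelic:
    HEADER = ["##fileformat=VCFv4.2",
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2"]

    def test_biallelic_passes_through_with_normalized_id(self):
        rec = "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1"
        out = qcfilter.split_multiallelic(self.HEADER + [rec])
        assert out[-1] == "1\t100\t1:100:A:G\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1"

    def test_triallelic_gives_two_records(self):
        rec = "1\t200\t.\tA\tG,T\t.\tPASS\t.\tGT\t1/2\t0/2"
        out = qcfilter.split_multiallelic(self.HEADER + [rec])
        body = [l for l in out if not l.startswith("#")]
        assert len(body) == 2
        # allele 1 (G): sample1 het (1/2 -> 1/0), sample2 hom-ref
        assert body[0].split("\t")[9] == "1/0"
        assert body[0].split("\t")[10] == "0/0"
        # allele 2 (T): sample1 0/1, sample2 0/1
        assert body[1].split("\t")[9] == "0/1"
        assert body[1].split("\t")[10] == "0/1"

    def test_hand_expanded_fixture_with_ad_matches_byte_for_byte(self):
        recs = [
            "1\t10\t.\tC\tA,G\t50\tPASS\t.\tGT:AD\t0/1:5,3,2\t2/2:1,0,9",
            "2\t20\t.\tT\tC\t60\tPASS\t.\tGT:AD\t0/0:8,0\t0/1:4,4",
            "2\t30\t.\tG\tA,C,T\t70\tPASS\t.\tGT:AD\t1/3:2,3,0,4\t./.:.",
        ]
        expected = [
            "1\t10\t1:10:C:A\tC\tA\t50\tPASS\t.\tGT:AD\t0/1:7,3\t0/0:10,0",
            "1\t10\t1:10:C:G\tC\tG\t50\tPASS\t.\tGT:AD\t0/0:8,2\t1/1:1,9",
            "2\t20\t2:20:T:C\tT\tC\t60\tPASS\t.\tGT:AD\t0/0:8,0\t0/1:4,4",
            "2\t30\t2:30:G:A\tG\tA\t70\tPASS\t.\tGT:AD\t1/0:6,3\t./.:.",
            "2\t30\t2:30:G:C\tG\tC\t70\tPASS\t.\tGT:AD\t0/0:9,0\t./.:.",
            "2\t30\t2:30:G:T\tG\tT\t70\tPASS\t.\tGT:AD\t0/1:5,4\t./.:.",
        ]
        out = qcfilter.split_multiallelic(self.HEADER + recs)
        assert out[len(self.HEADER):] == expected


class TestHweExact:
    def test_matches_full_enumeration(self):
        # oracle: enumerate the conditional distribution of het counts
        from math import comb

        def oracle(n_het, n_hom1, n_hom2):
            n = n_het + n_hom1 + n_hom2
            rare = 2 * min(n_hom1, n_hom2) + n_het
            probs = {}
            for h in range(rare % 2, rare + 1, 2):
                r = (rare - h) // 2
                c = n - h - r
                if c < 0:
                    continue
                # P(h het | n, rare) proportional to multinomial weight
                from math import factorial as f
                probs[h] = (
                    f(n) / (f(r) * f(h) * f(c)) * 2**h
                )
            tot = sum(probs.values())
            target = probs[n_het] / tot
            return sum(v / tot for v in probs.values() if v / tot <= target + 1e-12)

        cases = [(10, 45, 45), (0, 90, 10), (20, 30, 50), (1, 1, 1), (50, 25, 25)]
        for het, h1, h2 in cases:
            assert qcfilter.hwe_exact_p(het, h1, h2) == pytest.approx(
                oracle(het, h1, h2), rel=1e-9
            )

    def test_extreme_het_deficit_is_significant(self):
        # AA=90, Aa=0, aa=10 wildly violates equilibrium
        p = qcfilter.hwe_exact_p(0, 90, 10)
        assert p < 1e-6

    def test_equilibrium_counts_not_significant(self):
        assert qcfilter.hwe_exact_p(50, 25, 25) > 0.5


class TestQcVariants:
    def test_clean_variant_retained_and_low_call_rate_removed(self, rng):
        n = 100
        clean = np.concatenate([np.zeros(25), np.ones(50), np.full(25, 2)])
        rng.shuffle(clean)
        low_cr = clean.copy()
        low_cr[:10] = -1  # 90% call rate
        g = make_geno(np.column_stack([clean, low_cr]))
        y = np.repeat([0, 1], 50)
        passing, report = qcfilter.qc_variants(g, y)
        assert 0 in passing
        assert 1 not in passing
        assert report.loc[1, "fail_call_rate"]

    def test_hwe_violating_variant_removed(self, rng):
        n = 100
        bad = np.concatenate([np.zeros(90), np.full(10, 2)])  # no hets
        good = np.concatenate([np.zeros(25), np.ones(50), np.full(25, 2)])
        g = make_geno(np.column_stack([good, bad]))
        passing, report = qcfilter.qc_variants(g, None)
        assert 0 in passing and 1 not in passing
        assert report.loc[1, "hwe_p"] < 1e-6

    def test_differential_missingness_removed(self):
        n = 200
        y = np.repeat([1, 0], 100)
        diff = np.ones(n, dtype=np.int8)
        diff[:60] = -1  # missing only in cases
        even = np.ones(n, dtype=np.int8)
        g = make_geno(np.column_stack([even, diff]))
        passing, report = qcfilter.qc_variants(g, y, min_call_rate=0.5)
        assert report.loc[1, "fail_diff_missingness"]
        assert not report.loc[0, "fail_diff_missingness"]


class TestKinship:
    def test_self_pair_via_duplicate_is_half(self, rng):
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 400), size=(10, 400)).astype(np.int8)
        d[1] = d[0]  # duplicate sample
        g = make_geno(d)
        k = qcfilter.kinship(g)
        pair = k[(k.sample_i == "s0") & (k.sample_j == "s1")]
        assert pair.phi.iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_unrelated_pairs_near_zero(self, rng):
        p = rng.uniform(0.2, 0.8, 5000)
        d = rng.binomial(2, p, size=(20, 5000)).astype(np.int8)
        k = qcfilter.kinship(make_geno(d))
        assert np.abs(k.phi).max() < 0.05

    def test_parent_offspring_near_quarter(self, rng):
        m = 4000
        p = rng.uniform(0.3, 0.7, m)
        parents = rng.binomial(1, p, size=(2, 2, m))  # 2 parents x 2 alleles
        child = np.empty((1, m), dtype=np.int8)
        pick = rng.integers(0, 2, size=(2, m))
        child[0] = parents[0, pick[0], np.arange(m)] + parents[1, pick[1], np.arange(m)]
        dos = np.vstack([parents.sum(axis=1).astype(np.int8), child])
        k = qcfilter.kinship(make_geno(dos))
        po = k[(k.sample_i == "s0") & (k.sample_j == "s2")].phi.iloc[0]
        assert abs(po - 0.25) < 0.05

    def test_too_few_markers_rejected(self, rng):
        d = rng.binomial(2, 0.5, size=(5, 100)).astype(np.int8)
        with pytest.raises(ValueError):
            qcfilter.kinship(make_geno(d))


class TestQcSamples:
    def _metrics(self, n, rng):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "het_hom_ratio": rng.normal(1.5, 0.02, n),
                "titv_ratio": rng.normal(2.1, 0.02, n),
                "insdel_ratio": rng.normal(1.0, 0.02, n),
                "missing_rate": np.full(n, 0.01),
            }
        )

    def test_identical_metrics_none_removed(self):
        n = 20
        m = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "het_hom_ratio": 1.5,
                "titv_ratio": 2.1,
                "insdel_ratio": 1.0,
                "missing_rate": 0.0,
            }
        )
        retained, _ = qcfilter.qc_samples(m)
        assert len(retained) == n

    def test_extreme_het_hom_outlier_removed(self, rng):
        m = self._metrics(30, rng)
        m.loc[3, "het_hom_ratio"] = 15.0
        retained, report = qcfilter.qc_samples(m)
        assert "s3" not in retained
        assert report.set_index("sample_id").loc["s3", "reason"] == "mad_het_hom_ratio"

    def test_high_missingness_removed(self, rng):
        m = self._metrics(30, rng)
        m.loc[5, "missing_rate"] = 0.05
        retained, _ = qcfilter.qc_samples(m)
        assert "s5" not in retained

    def test_duplicate_sample_drops_exactly_one(self, rng):
        d = rng.binomial(2, rng.uniform(0.2, 0.8, 500), size=(12, 500)).astype(np.int8)
        d[1] = d[0]
        d[1, :5] = -1  # duplicate has higher missingness
        g = make_geno(d)
        metrics = qcfilter.sample_qc_metrics(g)
        retained, report = qcfilter.qc_samples(metrics, g)
        assert ("s0" in retained) and ("s1" not in retained)


class TestHighImpactFilter:
    def _ann(self):
        return pd.DataFrame(
            {
                "variant_id": ["v1", "v2", "v3"],
                "gene": ["G1", "G1", "G2"],
                "consequence": ["synonymous", "missense", "missense"],
                "ref_maf": [0.001, np.nan, 0.001],
                "cadd": [30.0, 25.0, 25.0],
                "msc_cadd": [20.0, 20.0, 20.0],
                "gdi": [5.0, 5.0, 5.0],
                "blacklisted": [False, False, False],
            }
        )

    def test_synonymous_excluded_despite_perfect_scores(self):
        survivors, _ = qcfilter.high_impact_filter(self._ann(), None)
        assert "v1" not in set(survivors)

    def test_cohort_af_fallback_path_retains(self):
        cohort_af = pd.Series({"v1": 0.004, "v2": 0.004, "v3": 0.004})
        survivors, _ = qcfilter.high_impact_filter(self._ann(), cohort_af)
        assert "v2" in set(survivors)

    def test_maf_boundary_inclusive(self):
        ann = self._ann()
        ann.loc[2, "ref_maf"] = 0.01  # exactly at the bound: retained
        survivors, _ = qcfilter.high_impact_filter(ann, None)
        assert "v3" in set(survivors)
        ann.loc[2, "ref_maf"] = 0.0101
        survivors, _ = qcfilter.high_impact_filter(ann, None)
        assert "v3" not in set(survivors)

    def test_matches_brute_force_oracle_on_10k_variants(self):
        spec = synth.SimSpec(n_cases=50, n_controls=50, n_markers_rare=10_000,
                             n_genes=500, risk_genes=("G0001",), seed=17)
        study = synth.generate_study(spec)
        full = study.annotation_full
        af = pd.Series(study.genotypes.allele_freq(),
                       index=study.genotypes.variant_ids)

        wl = qcfilter.WHITELIST
        keep = []
        for _, r in full.iterrows():
            maf = r.ref_maf if np.isfinite(r.ref_maf) else af[r.variant_id]
            ok = (
                r.consequence in wl
                and maf <= 0.01
                and r.cadd >= (r.msc_cadd if np.isfinite(r.msc_cadd) else 15.0)
                and (not np.isfinite(r.gdi) or r.gdi < 13.34)
                and not r.blacklisted
            )
            if ok:
                keep.append(r.variant_id)
        survivors, attrition = qcfilter.high_impact_filter(full, af)
        assert set(survivors) == set(keep)
        # sequential attrition accounting sums to the input count
        removed = attrition.loc[attrition.rule != "survivors", "removed"].sum()
        final = attrition.loc[attrition.rule == "survivors", "entering"].iloc[0]
        assert removed + final == len(full)

    def test_order_independence_and_monotonicity(self):
        spec = synth.SimSpec(n_cases=40, n_controls=40, n_markers_rare=2000,
                             n_genes=100, risk_genes=(), risk_carrier_or=1.0,
                             seed=18)
        study = synth.generate_study(spec)
        full = study.annotation_full
        af = pd.Series(study.genotypes.allele_freq(),
                       index=study.genotypes.variant_ids)
        base, _ = qcfilter.high_impact_filter(full, af)
        # monotone: relaxing the GDI threshold can only grow the survivor set
        relaxed, _ = qcfilter.high_impact_filter(full, af, gdi_max=1e9)
        assert set(base) <= set(relaxed)
        # rules are pure predicates: shuffling the table rows leaves the set
        shuffled = full.sample(frac=1.0, random_state=0)
        again, _ = qcfilter.high_impact_filter(shuffled, af)
        assert set(again) == set(base)

    def test_variant_without_gene_counted_separately(self):
        ann = self._ann()
        ann.loc[1, "gene"] = np.nan
        survivors, attrition = qcfilter.high_impact_filter(ann, None)
        assert attrition.loc[attrition.rule == "input", "removed"].iloc[0] == 1
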