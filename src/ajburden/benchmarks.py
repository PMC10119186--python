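"""End-to-end benchmark experiments at fixed study conditions.

Each function runs one self-contained experiment through the public
pipeline — worked examples with stated inputs, null-calibration and power
suites on synthetic cohorts, distance-statistic oracle checks, ancestry
recovery, and the PRS population-transfer contrast — and returns the
measured quantities.  The calibration suite and the acceptance script are
both thin wrappers over these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import kstest

from . import ancestry, assoc, hgc, prs, qcfilter, synth
from ._seeds import child_rng, child_seed
from .containers import DistanceMatrix

__all__ = [
    "carrier_set_worked_example",
    "bonferroni_worked_example",
    "scan_study",
    "null_calibration",
    "power_recovery",
    "hgc_oracle_and_calibration",
    "filter_oracle_check",
    "ancestry_recovery",
    "prs_benchmark",
]


def carrier_set_worked_example() -> dict:
    """Carrier-set burden worked example from reported carrier frequencies.

    Reconstructs carrier counts by rounding frequency x cohort size
    (15.74% of 1734 cases, 9.26% of 2719 controls) and runs the 2x2
    carrier burden test.
    """
    n_case, n_ctrl = 1734, 2719
    c_case = round(0.1574 * n_case)
    c_ctrl = round(0.0926 * n_ctrl)
    carriers = np.zeros(n_case + n_ctrl, dtype=bool)
    carriers[:c_case] = True
    carriers[n_case:n_case + c_ctrl] = True
    y = np.concatenate([np.ones(n_case), np.zeros(n_ctrl)]).astype(int)
    res = assoc.carrier_burden_test(carriers, y)
    return {
        "n": n_case + n_ctrl,
        "carriers_case": c_case,
        "carriers_control": c_ctrl,
        "or_carrier": res["or_carrier"],
        "chi2": res["chi2"],
        "p": res["p"],
    }


def bonferroni_worked_example() -> dict:
    """Family-wise threshold worked example (0.05 / 13,268 tested genes)."""
    n_genes = 13_268
    return {"n": n_genes, "threshold": assoc.bonferroni_threshold(n_genes)}


def scan_study(spec: synth.SimSpec) -> pd.DataFrame:
    """Generate a study and run the full gene-level scan."""
    study = synth.generate_study(spec)
    qual = study.annotation_full[
        study.annotation_full["variant_id"].isin(study.qualifying)
    ]
    blocks, _ = assoc.collapse_by_gene(qual, study.genotypes)
    return assoc.gene_scan(blocks, study.phenotype)


def null_calibration(
    seed: int,
    *,
    n_reps: int = 8,
    n_cases: int = 1500,
    n_controls: int = 1500,
    n_markers: int = 8000,
    n_genes: int = 880,
) -> dict:
    """Type-I error and genomic inflation on pooled null cohorts.

    Runs ``n_reps`` independent null studies (carrier odds ratio 1) through
    generation, filtering, collapsing, and the gene-level scan, pooling the
    SKAT-O p-values across replicates to reach the target gene count.
    """
    ps = []
    for rep in range(n_reps):
        spec = synth.SimSpec(
            n_cases=n_cases, n_controls=n_controls, n_markers_rare=n_markers,
            n_genes=n_genes, risk_genes=(), risk_carrier_or=1.0,
            seed=child_seed(seed, f"nullrep{rep}"),
        )
        res = scan_study(spec)
        ps.append(res["p_skato"].to_numpy())
    p = np.concatenate(ps)
    p = p[np.isfinite(p)]
    return {
        "n": int(len(p)),
        "type_i_05": float(np.mean(p < 0.05)),
        "type_i_01": float(np.mean(p < 0.01)),
        "lambda_gc": assoc.inflation_check(p),
    }


def power_recovery(
    seed: int,
    *,
    n_seeds: int = 20,
    n_cases: int = 1500,
    n_controls: int = 1500,
    n_markers: int = 10_000,
    n_genes: int = 1000,
    risk_carrier_or: float = 3.0,
    risk_carrier_freq: float = 0.10,
) -> dict:
    """Fraction of replicates where every spiked gene ranks in the top 1%."""
    n_all_top = 0
    gene_hits = 0
    for rep in range(n_seeds):
        spec = synth.SimSpec(
            n_cases=n_cases, n_controls=n_controls, n_markers_rare=n_markers,
            n_genes=n_genes, risk_carrier_or=risk_carrier_or,
            risk_carrier_freq=risk_carrier_freq,
            seed=child_seed(seed, f"powrep{rep}"),
        )
        res = scan_study(spec)
        thresh = np.quantile(res["p_skato"], 0.01)
        hits = sum(
            res.loc[res["gene"] == g, "p_skato"].iloc[0] <= thresh
            for g in spec.risk_genes
            if (res["gene"] == g).any()
        )
        gene_hits += hits
        n_all_top += hits == len(spec.risk_genes)
    return {
        "n": n_seeds,
        "all_top1pct_fraction": n_all_top / n_seeds,
        "gene_top1pct_fraction": gene_hits / (n_seeds * 5),
    }


def hgc_oracle_and_calibration(
    seed: int,
    *,
    n_genes: int = 50,
    meta_reps: int = 200,
    iters: int = 500,
) -> dict:
    """Distance statistics vs brute-force double loops; resampling null.

    The oracle check compares the per-candidate mean distance, the nested
    set-to-set mean, and the within-set baseline against naive double loops
    on a random matrix.  The calibration check draws candidate sets from an
    exchangeable pool and tests the empirical P for uniformity.
    """
    rng = child_rng(seed, "hgc_oracle")
    genes = [f"g{i}" for i in range(n_genes)]
    upper = np.triu(rng.uniform(1, 20, size=(n_genes, n_genes)), k=1)
    d = DistanceMatrix(genes, upper + upper.T)
    b = genes[30:45]
    a = genes[:12]
    max_diff = 0.0
    for g in genes:
        brute = np.mean([
            d.values[d.index([g])[0], d.index([x])[0]] for x in b if x != g
        ])
        max_diff = max(max_diff, abs(hgc.candidate_avg_distance(g, b, d) - brute))
    brute_s2s = np.mean([
        np.mean([d.values[d.index([x])[0], d.index([y])[0]] for y in b])
        for x in a
    ])
    max_diff = max(max_diff, abs(hgc.set_to_set_distance(a, b, d) - brute_s2s))
    bi = d.index(b)
    sub = d.values[np.ix_(bi, bi)]
    brute_base = sub[~np.eye(len(b), dtype=bool)].mean()
    max_diff = max(max_diff, abs(hgc.within_set_baseline(b, d) - brute_base))

    pool = genes[:30]
    ps = []
    for rep in range(meta_reps):
        a_rand = list(rng.choice(pool, size=8, replace=False))
        res = hgc.resample_empirical_p(
            a_rand, b, pool, d, iters=iters,
            seed=child_seed(seed, f"hgc_cal{rep}"),
        )
        ps.append(res.empirical_p)
    ks_p = float(kstest(ps, "uniform").pvalue)
    return {"n": meta_reps, "oracle_max_abs_diff": float(max_diff),
            "null_ks_p": ks_p}


def filter_oracle_check(seed: int, *, n_variants: int = 10_000) -> dict:
    """Six-rule survivor set vs an independent row-wise predicate oracle."""
    spec = synth.SimSpec(
        n_cases=50, n_controls=50, n_markers_rare=n_variants,
        n_genes=max(2, n_variants // 20), risk_genes=("G0001",),
        seed=child_seed(seed, "filter_oracle"),
    )
    study = synth.generate_study(spec)
    full = study.annotation_full
    af = pd.Series(study.genotypes.allele_freq(),
                   index=study.genotypes.variant_ids)
    keep = set()
    for _, r in full.iterrows():
        maf = r.ref_maf if np.isfinite(r.ref_maf) else af[r.variant_id]
        if (
            r.consequence in qcfilter.WHITELIST
            and maf <= 0.01
            and r.cadd >= (r.msc_cadd if np.isfinite(r.msc_cadd) else 15.0)
            and (not np.isfinite(r.gdi) or r.gdi < qcfilter.GDI_CUTOFF)
            and not r.blacklisted
        ):
            keep.add(r.variant_id)
    survivors, attrition = qcfilter.high_impact_filter(full, af)
    removed = int(attrition.loc[attrition["rule"] != "survivors",
                                "removed"].sum())
    final = int(attrition.loc[attrition["rule"] == "survivors",
                              "entering"].iloc[0])
    return {
        "n": n_variants,
        "n_survivors": len(survivors),
        "set_mismatches": len(set(survivors) ^ keep),
        "attrition_sums_to_input": int(removed + final == len(full)),
    }


def ancestry_recovery(
    seed: int,
    *,
    n_markers: int = 5000,
    fst: float = 0.1,
    n_samples: int = 300,
) -> dict:
    """Admixture-fraction RMSE and two-round assignment accuracy.

    Recovery: q ~ Uniform(0,1) cohort, supervised estimates against the
    generating panel.  Assignment: a 0.9 cluster and a 0.3 cluster with a
    reference panel spanning the target cluster's range.
    """
    panel = synth.simulate_reference_panels(n_markers, fst, seed)
    g, tab = synth.simulate_cohort(panel, n_samples, child_seed(seed, "anc1"),
                                   admixture_mix=("uniform", 0.0, 1.0))
    est = ancestry.estimate_fractions(g, panel)
    rmse = float(np.sqrt(np.mean((est["q"].to_numpy()
                                  - tab["true_q"].to_numpy()) ** 2)))
    slope = float(np.polyfit(est["q"], tab["true_q"], 1)[0])

    n_ref, n_a, n_b = 30, 150, 150
    rng = child_rng(seed, "anc2")
    q = np.concatenate([
        rng.uniform(0.8, 1.0, n_ref),
        np.full(n_a, 0.9), np.full(n_b, 0.3),
    ])
    g2, _ = synth.simulate_cohort(panel, len(q), child_seed(seed, "anc2c"),
                                  admixture_mix=q)
    refs = list(g2.sample_ids[:n_ref])
    assigned, trace, _ = ancestry.two_round_assign(g2, panel, refs)
    a_ids = set(g2.sample_ids[n_ref:n_ref + n_a])
    b_ids = set(g2.sample_ids[n_ref + n_a:])
    return {
        "n": n_samples,
        "q_rmse": rmse,
        "q_regression_slope": slope,
        "sensitivity": len(assigned & a_ids) / n_a,
        "specificity": len(b_ids - assigned) / n_b,
        "round_cutoffs": list(trace["cutoff"]),
    }


def _prs_cohort(panel, meta, beta_true, pop_q, n, seed, rng):
    g, _ = synth.simulate_cohort(panel, n, seed,
                                 admixture_mix=("point", pop_q),
                                 variant_meta=meta)
    d = g.dosage_float(impute_af=True)
    logit = d @ beta_true
    logit -= logit.mean()
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(int)
    return g, y


def prs_benchmark(
    seed: int,
    *,
    n_seeds: int = 10,
    n_markers: int = 400,
    fst: float = 0.3,
    n_train: int = 1000,
    n_eval: int = 800,
    h2: float = 0.3,
    iters: int = 80,
) -> dict:
    """Closed-form shrinkage check and the population-transfer contrast.

    For each replicate, common-variant phenotypes are simulated from a
    shared per-allele causal model in two diverged populations; summary
    statistics from the matched population's training split and from the
    mismatched population feed the full grid-PRS + random-forest pipeline
    on the same held-out evaluation set.
    """
    # closed-form check at p = 1 with no LD
    rng = child_rng(seed, "prs_cf")
    panel0 = synth.simulate_reference_panels(200, 0.0, child_seed(seed, "cfp"))
    meta0 = synth.variant_positions(200)
    meta0["ref"], meta0["alt"] = "A", "G"
    g0, _ = synth.simulate_cohort(panel0, 500, child_seed(seed, "cfg"),
                                  variant_meta=meta0)
    summary0 = pd.DataFrame(
        {
            "variant_id": g0.variant_ids,
            "effect_allele": g0.alt,
            "other_allele": g0.ref,
            "beta": rng.normal(0, 0.2, 200),
            "se": 0.02,
            "n": 20_000,
        }
    )
    closed = prs.shrink_effects(summary0, g0, 1.0, h2=0.5, method="closed",
                                window=1)
    m0, n0 = 200, 20_000
    shrink = 0.5 * n0 / (0.5 * n0 + m0)
    expected = summary0["beta"].to_numpy() * shrink
    rel_err = float(np.max(np.abs(closed["posterior_mean"].to_numpy()
                                  - expected)
                           / np.maximum(np.abs(expected), 1e-6)))

    matched_aucs, mismatched_aucs = [], []
    for rep in range(n_seeds):
        rs = child_seed(seed, f"prsrep{rep}")
        rng = child_rng(seed, f"prsmodel{rep}")
        panel = synth.simulate_reference_panels(n_markers, fst,
                                                child_seed(seed, f"pp{rep}"))
        meta = synth.variant_positions(n_markers)
        meta["ref"], meta["alt"] = "A", "G"
        causal = rng.random(n_markers) < 0.10
        beta_true = np.where(causal, rng.normal(0, 0.25, n_markers), 0.0)
        g_tr, y_tr = _prs_cohort(panel, meta, beta_true, 1.0, n_train,
                                 child_seed(seed, f"tr{rep}"), rng)
        g_ev, y_ev = _prs_cohort(panel, meta, beta_true, 1.0, n_eval,
                                 child_seed(seed, f"ev{rep}"), rng)
        g_b, y_b = _prs_cohort(panel, meta, beta_true, 0.0, n_train,
                               child_seed(seed, f"pb{rep}"), rng)
        for name, (gt, yt) in (("matched", (g_tr, y_tr)),
                               ("mismatched", (g_b, y_b))):
            summ = synth.simulate_summary_stats(gt, yt)
            prof = prs.prs_profiles(g_ev, summ, g_ev, h2=h2, iters=iters,
                                    seed=rs, window=20)
            auc = prs.classify(prof, y_ev, folds=10, seed=rs)["mean_auc"]
            (matched_aucs if name == "matched" else mismatched_aucs).append(auc)
    return {
        "n": n_seeds,
        "closed_form_max_rel_err": rel_err,
        "auc_matched": float(np.mean(matched_aucs)),
        "auc_mismatched": float(np.mean(mismatched_aucs)),
        "matched_wins": int(np.sum(np.array(matched_aucs)
                                   > np.array(mismatched_aucs))),
    }
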