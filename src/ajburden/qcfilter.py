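"""Variant- and sample-level quality control and the six-step
high-impact rare-variant filter.

Variant QC enforces depth/quality means, an alternate-carrier quality rule,
call rate, Hardy-Weinberg equilibrium (exact test, computed in controls),
and case/control differential missingness (Fisher exact).  Sample QC uses
4-MAD outlier rules on het/hom, Ti/Tv, and ins/del ratios, a missingness
ceiling, and a within-pair robust kinship estimator for duplicates and
close relatives.  The deleteriousness filter retains a variant only if its
consequence is whitelisted, its effective MAF (reference-population MAF,
falling back to the cohort frequency) is at most 0.01, its CADD score
reaches its gene's mutation significance cutoff, its gene's damage index is
below 13.34, and it is not blacklisted.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .containers import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "split_multiallelic",
    "hwe_exact_p",
    "qc_variants",
    "sample_qc_metrics",
    "kinship",
    "qc_samples",
    "high_impact_filter",
    "WHITELIST",
    "GDI_CUTOFF",
]

WHITELIST = frozenset(
    {
        "missense",
        "start_lost",
        "stop_lost",
        "stop_gained",
        "splice_acceptor",
        "splice_donor",
        "inframe_insertion",
        "inframe_deletion",
        "protein_altering",
        "start_retained",
        "stop_retained",
        "frameshift",
    }
)
GDI_CUTOFF = 13.34  # gene damage index bound for disease-gene plausibility


# ---------------------------------------------------------------------------
# Multiallelic splitting
# ---------------------------------------------------------------------------

def _recode_gt(gt: str, allele: int) -> str:
    """Recode a GT string against one alternate allele (others become ref)."""
    sep = "|" if "|" in gt else "/"
    out = []
    for a in gt.replace("|", "/").split("/"):
        if a == ".":
            out.append(".")
        else:
            out.append("1" if int(a) == allele else "0")
    return sep.join(out)


def split_multiallelic(lines: Sequence[str]) -> list[str]:
    """Split multiallelic VCF body lines into one record per alternate allele.

    Genotypes are recoded against each split allele (other alternates count
    as reference); AD fields are redistributed with the dropped alternates'
    depths folded into the reference depth; IDs are regenerated as
    chrom:pos:ref:alt.  Header lines pass through; records with malformed
    genotype fields are skipped with a logged warning.
    """
    out: list[str] = []
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            out.append(line)
            continue
        f = line.split("\t")
        if len(f) < 10:
            out.append(line)
            continue
        chrom, pos, _, ref, alts = f[0], f[1], f[2], f[3], f[4].split(",")
        fmt = f[8].split(":")
        try:
            gt_i = fmt.index("GT")
        except ValueError:
            logger.warning("record %s:%s has no GT field; skipped", chrom, pos)
            continue
        ad_i = fmt.index("AD") if "AD" in fmt else None
        for k, alt in enumerate(alts, start=1):
            new_id = f"{chrom}:{pos}:{ref}:{alt}"
            cells = []
            bad = False
            for cell in f[9:]:
                parts = cell.split(":")
                try:
                    parts[gt_i] = _recode_gt(parts[gt_i], k)
                except (ValueError, IndexError):
                    bad = True
                    break
                if ad_i is not None and len(parts) > ad_i and parts[ad_i] != ".":
                    ads = [int(x) for x in parts[ad_i].split(",")]
                    alt_ad = ads[k] if len(ads) > k else 0
                    ref_ad = sum(ads) - alt_ad
                    parts[ad_i] = f"{ref_ad},{alt_ad}"
                cells.append(":".join(parts))
            if bad:
                logger.warning("malformed genotype at %s:%s; record skipped",
                               chrom, pos)
                continue
            out.append(
                "\t".join([chrom, pos, new_id, ref, alt] + f[5:9] + cells)
            )
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Wigginton-style enumeration)
# ---------------------------------------------------------------------------

def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value from genotype counts.

    Sums the probabilities of all heterozygote counts (given the observed
    allele counts) no more likely than the observed one, enumerating the
    conditional distribution by the standard recurrence.
    """
    n_het, n_hom1, n_hom2 = int(n_het), int(n_hom1), int(n_hom2)
    if min(n_het, n_hom1, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    rare = 2 * min(n_hom1, n_hom2) + n_het
    n = n_het + n_hom1 + n_hom2
    if n == 0 or rare == 0:
        return 1.0
    probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if (mid % 2) != (rare % 2):
        mid += 1
    probs[mid] = 1.0
    # downward recurrence: het -> het - 2
    het = mid
    while het > 1:
        probs[het - 2] = (
            probs[het] * het * (het - 1.0)
            / ((rare - het + 2.0) * (2.0 * n - rare - het + 2.0))
        )
        het -= 2
    # upward recurrence: het -> het + 2
    het = mid
    while het <= rare - 2:
        hom_r = (rare - het) / 2.0
        hom_c = n - het - hom_r
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        het += 2
    probs /= probs.sum()
    target = probs[n_het]
    return float(min(1.0, probs[probs <= target + 1e-12].sum()))


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

def qc_variants(
    g: GenotypeMatrix,
    phenotype: np.ndarray | None = None,
    *,
    min_mean_dp: float = 10.0,
    min_mean_gq: float = 20.0,
    min_call_rate: float = 0.95,
    hwe_p_cut: float = 1e-6,
    diff_miss_p_cut: float = 1e-5,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-variant QC; returns passing indices and a per-rule report.

    Rules: mean DP >= 10 and mean GQ >= 20; at least one alternate carrier
    with DP >= 10 and GQ >= 20; call rate >= 95%; HWE exact p >= 1e-6
    (computed in controls when a phenotype is given, otherwise all samples);
    case/control missingness difference Fisher p >= 1e-5.  Sub-rules whose
    inputs (DP/GQ, phenotype) are absent are skipped with a logged notice.
    """
    n, m = g.n_samples, g.n_variants
    report = pd.DataFrame({"variant_id": g.variant_ids})
    fail = np.zeros(m, dtype=bool)

    if g.dp is not None and g.gq is not None:
        mean_dp = np.nanmean(g.dp, axis=0)
        mean_gq = np.nanmean(g.gq, axis=0)
        report["fail_depth_quality"] = (mean_dp < min_mean_dp) | (mean_gq < min_mean_gq)
        carrier = g.dosages > 0
        good = carrier & (g.dp >= min_mean_dp) & (g.gq >= min_mean_gq)
        has_carrier = carrier.any(axis=0)
        report["fail_carrier_quality"] = has_carrier & ~good.any(axis=0)
    else:
        logger.info("DP/GQ absent; depth-quality rules skipped")
        report["fail_depth_quality"] = False
        report["fail_carrier_quality"] = False

    report["fail_call_rate"] = g.call_rate() < min_call_rate

    d = g.dosages
    if phenotype is not None:
        phenotype = np.asarray(phenotype)
        hwe_rows = phenotype == 0
    else:
        hwe_rows = np.ones(n, dtype=bool)
    sub = d[hwe_rows]
    n_het = (sub == 1).sum(axis=0)
    n_hom_ref = (sub == 0).sum(axis=0)
    n_hom_alt = (sub == 2).sum(axis=0)
    hwe_p = np.array(
        [hwe_exact_p(n_het[j], n_hom_ref[j], n_hom_alt[j]) for j in range(m)]
    )
    report["hwe_p"] = hwe_p
    report["fail_hwe"] = hwe_p < hwe_p_cut

    if phenotype is not None:
        miss = d == MISSING
        cases = phenotype == 1
        p_dm = np.ones(m)
        any_miss = miss.any(axis=0)
        n_case, n_ctrl = int(cases.sum()), int((~cases).sum())
        miss_case = miss[cases].sum(axis=0)
        miss_ctrl = miss[~cases].sum(axis=0)
        for j in np.flatnonzero(any_miss):
            table = [
                [n_case - miss_case[j], miss_case[j]],
                [n_ctrl - miss_ctrl[j], miss_ctrl[j]],
            ]
            p_dm[j] = fisher_exact(table)[1]
        report["diff_miss_p"] = p_dm
        report["fail_diff_missingness"] = p_dm < diff_miss_p_cut
    else:
        logger.info("phenotype absent; differential-missingness rule skipped")
        report["fail_diff_missingness"] = False

    for col in report.columns:
        if col.startswith("fail_"):
            fail |= report[col].to_numpy()
    report["pass"] = ~fail
    return np.flatnonzero(~fail), report


# ---------------------------------------------------------------------------
# Sample QC
# ---------------------------------------------------------------------------

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def sample_qc_metrics(g: GenotypeMatrix) -> pd.DataFrame:
    """Het/hom, Ti/Tv, ins/del ratios and missing rate per sample."""
    d = g.dosages
    het = d == 1
    hom_alt = d == 2
    carrier = d > 0
    is_snp = np.zeros(g.n_variants, dtype=bool)
    is_ti = np.zeros(g.n_variants, dtype=bool)
    is_ins = np.zeros(g.n_variants, dtype=bool)
    is_del = np.zeros(g.n_variants, dtype=bool)
    if g.ref is not None and g.alt is not None:
        for j, (r, a) in enumerate(zip(g.ref, g.alt)):
            if len(r) == 1 and len(a) == 1:
                is_snp[j] = True
                is_ti[j] = (r, a) in _TRANSITIONS
            elif len(a) > len(r):
                is_ins[j] = True
            elif len(r) > len(a):
                is_del[j] = True

    def ratio(num, den):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den > 0, num / den, np.nan)

    het_hom = ratio(het.sum(axis=1), hom_alt.sum(axis=1))
    titv = ratio((carrier & is_snp & is_ti).sum(axis=1),
                 (carrier & is_snp & ~is_ti).sum(axis=1))
    insdel = ratio((carrier & is_ins).sum(axis=1), (carrier & is_del).sum(axis=1))
    return pd.DataFrame(
        {
            "sample_id": g.sample_ids,
            "het_hom_ratio": het_hom,
            "titv_ratio": titv,
            "insdel_ratio": insdel,
            "missing_rate": (d == MISSING).mean(axis=1),
        }
    )


def kinship(g: GenotypeMatrix, *, min_informative: int = 200,
            min_joint: int = 50) -> pd.DataFrame:
    """Pairwise robust kinship from shared-heterozygosity counts.

    phi = (N_AaAa - 2 N_AA,aa) / (N_Aa,i + N_Aa,j), with heterozygote counts
    restricted to markers jointly called in the pair (the standard
    within-pair robust form; ~0.5 for duplicates, ~0.25 parent-offspring,
    ~0 for unrelated).  Pairs sharing fewer than ``min_joint`` called
    markers are flagged.
    """
    if g.n_variants < min_informative:
        raise ValueError(
            f"kinship requires >= {min_informative} informative markers"
        )
    d = g.dosages
    called = (d != MISSING).astype(np.float32)
    het = (d == 1).astype(np.float32)
    hom_ref = (d == 0).astype(np.float32)
    hom_alt = (d == 2).astype(np.float32)
    n_het_het = het @ het.T
    n_opp = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    het_joint = het @ called.T  # het in i over markers called in j
    denom = het_joint + het_joint.T
    joint = called @ called.T
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(denom > 0, (n_het_het - 2.0 * n_opp) / denom, np.nan)
    iu, ju = np.triu_indices(g.n_samples, k=1)
    return pd.DataFrame(
        {
            "sample_i": g.sample_ids[iu],
            "sample_j": g.sample_ids[ju],
            "phi": phi[iu, ju],
            "n_joint": joint[iu, ju].astype(int),
            "flagged": joint[iu, ju] < min_joint,
        }
    )


def qc_samples(
    metrics: pd.DataFrame,
    g: GenotypeMatrix | None = None,
    *,
    kinship_pairs: pd.DataFrame | None = None,
    mad_k: float = 4.0,
    max_missing: float = 0.03,
    kin_threshold: float = 0.185,
) -> tuple[set[str], pd.DataFrame]:
    """Sample-level QC; returns retained sample ids and a report.

    Removes samples outside ``mad_k`` median absolute deviations for any of
    het/hom, Ti/Tv, ins/del (a zero-MAD metric is skipped; cohorts under 10
    samples skip the MAD rules entirely); samples with missing rate above
    ``max_missing``; and, for every pair with kinship-derived IBD proportion
    above ``kin_threshold``, the member with the higher missing rate.
    """
    metrics = metrics.set_index("sample_id")
    n = len(metrics)
    removed: dict[str, str] = {}

    mad_cols = [c for c in ("het_hom_ratio", "titv_ratio", "insdel_ratio")
                if c in metrics.columns]
    if n < 10:
        warnings.warn("fewer than 10 samples; MAD outlier rules skipped")
    else:
        for col in mad_cols:
            x = metrics[col].to_numpy(float)
            if np.all(np.isnan(x)):
                logger.info("metric %s undefined for all samples; skipped", col)
                continue
            med = np.nanmedian(x)
            mad = np.nanmedian(np.abs(x - med))
            if mad == 0 or np.isnan(mad):
                logger.info("metric %s has zero MAD; outlier rule skipped", col)
                continue
            out = np.abs(x - med) > mad_k * mad
            for s in metrics.index[out]:
                removed.setdefault(s, f"mad_{col}")

    high_miss = metrics["missing_rate"] > max_missing
    for s in metrics.index[high_miss]:
        removed.setdefault(s, "missingness")

    if kinship_pairs is None and g is not None:
        kinship_pairs = kinship(g)
    if kinship_pairs is not None:
        close = kinship_pairs[kinship_pairs["phi"] > kin_threshold]
        for _, row in close.iterrows():
            i, j = row["sample_i"], row["sample_j"]
            if i in removed or j in removed:
                continue
            mi = metrics.loc[i, "missing_rate"]
            mj = metrics.loc[j, "missing_rate"]
            drop = j if (mj >= mi) else i
            removed.setdefault(drop, "kinship")

    report = pd.DataFrame(
        {
            "sample_id": metrics.index,
            "removed": [s in removed for s in metrics.index],
            "reason": [removed.get(s, "") for s in metrics.index],
        }
    )
    retained = set(metrics.index) - set(removed)
    return retained, report


# ---------------------------------------------------------------------------
# Six-step high-impact rare-variant filter
# ---------------------------------------------------------------------------

def high_impact_filter(
    ann: pd.DataFrame,
    cohort_af: pd.Series | dict | None = None,
    *,
    maf_max: float = 0.01,
    gdi_max: float = GDI_CUTOFF,
    msc_fallback: float = 15.0,
    whitelist: frozenset[str] = WHITELIST,
    min_site_dp: float = 10.0,
    min_site_mq: float = 40.0,
) -> tuple[pd.Index, pd.DataFrame]:
    """Apply the six deleteriousness rules; return survivors and attrition.

    Rules, applied sequentially with per-rule attrition counts (the survivor
    set is order-independent — each rule is a pure predicate):

    1. site quality: mean DP > ``min_site_dp`` and MQ > ``min_site_mq``
       (only when ``site_dp``/``site_mq`` columns are present);
    2. consequence in the high-impact whitelist;
    3. effective MAF <= ``maf_max`` where effective MAF is the reference-
       population MAF, falling back to the cohort frequency when missing;
    4. CADD >= the gene's MSC cutoff (missing MSC: CADD >= ``msc_fallback``);
    5. gene GDI < ``gdi_max`` (missing GDI treated as passing);
    6. not blacklisted.

    Variants with no gene assignment are excluded and counted separately.
    """
    ann = ann.copy()
    total = len(ann)
    no_gene = ann["gene"].isna() | (ann["gene"].astype(str) == "")
    ann = ann[~no_gene]

    if cohort_af is not None:
        cohort_af = pd.Series(cohort_af)
        fallback = ann["variant_id"].map(cohort_af)
    else:
        fallback = pd.Series(np.nan, index=ann.index)
    eff_maf = ann["ref_maf"].astype(float)
    used_fallback = eff_maf.isna()
    eff_maf = eff_maf.fillna(fallback)

    msc = ann["msc_cadd"].astype(float) if "msc_cadd" in ann else pd.Series(np.nan, index=ann.index)
    msc_missing = msc.isna()
    if msc_missing.any():
        logger.info("%d variants in genes lacking an MSC cutoff; fallback CADD >= %.3g",
                    int(msc_missing.sum()), msc_fallback)
    msc_eff = msc.fillna(msc_fallback)

    gdi = ann["gdi"].astype(float) if "gdi" in ann else pd.Series(np.nan, index=ann.index)
    if gdi.isna().any():
        logger.info("%d variants in genes lacking GDI; treated as passing",
                    int(gdi.isna().sum()))

    rules = {
        "site_quality": (
            (ann["site_dp"] > min_site_dp) & (ann["site_mq"] > min_site_mq)
            if {"site_dp", "site_mq"} <= set(ann.columns)
            else pd.Series(True, index=ann.index)
        ),
        "consequence": ann["consequence"].isin(whitelist),
        "maf": eff_maf.fillna(0.0) <= maf_max,
        "msc": ann["cadd"].astype(float) >= msc_eff,
        "gdi": gdi.isna() | (gdi < gdi_max),
        "blacklist": ~ann["blacklisted"].astype(bool)
        if "blacklisted" in ann
        else pd.Series(True, index=ann.index),
    }

    surviving = pd.Series(True, index=ann.index)
    rows = [{"rule": "input", "entering": total, "removed": int(no_gene.sum()),
             "note": "variants with no gene assignment removed"}]
    for name, ok in rules.items():
        entering = int(surviving.sum())
        removed = int((surviving & ~ok).sum())
        surviving &= ok
        rows.append({"rule": name, "entering": entering, "removed": removed,
                     "note": ""})
    rows.append({"rule": "survivors", "entering": int(surviving.sum()),
                 "removed": 0, "note": ""})
    attrition = pd.DataFrame(rows)
    survivors = pd.Index(ann.loc[surviving, "variant_id"])
    logger.info("high-impact filter: %d / %d variants retained (%d used cohort AF fallback)",
                len(survivors), total, int(used_fallback.sum()))
    return survivors, attrition
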