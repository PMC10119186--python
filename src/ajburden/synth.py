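"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: two
ancestral populations under a Balding-Nichols model with admixed samples,
rare variants carrying the attributes the deleteriousness filter consumes
(consequence class, reference-population MAF with gaps, CADD, per-gene MSC
cutoff and GDI, a blacklist), case/control phenotypes driven by spiked rare
risk alleles in designated genes, a gene x gene distance matrix in which a
core gene set is mutually proximate, and single-variant GWAS summary
statistics from an independent training split.

One global integer seed expands into per-stage child seeds through
:mod:`ajburden._seeds`; fixing the seed fixes every emitted artifact.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ._seeds import child_rng
from .containers import MISSING, AncestralFreqs, DistanceMatrix, GenotypeMatrix

__all__ = [
    "SimSpec",
    "simulate_reference_panels",
    "simulate_rare_panels",
    "draw_admixture",
    "simulate_cohort",
    "assign_genes",
    "boost_risk_frequencies",
    "simulate_annotations",
    "join_gene_metrics",
    "spike_phenotypes",
    "simulate_distance_matrix",
    "simulate_summary_stats",
    "StudyData",
    "generate_study",
]

# Consequence classes the high-impact filter whitelists, plus the neutral
# classes the generator mixes in to exercise the exclusion path.
WHITELIST_CONSEQUENCES = (
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
)
NEUTRAL_CONSEQUENCES = ("synonymous", "intron", "upstream")


@dataclasses.dataclass
class SimSpec:
    """Study-condition parameters for one synthetic cohort.

    Defaults mirror the analysed study's scale of effect: a founder-level
    divergence (FST 0.1) between the target and background populations,
    rare-variant MAFs log-uniform over [1e-4, 5e-3] so the MAF <= 0.01 rule
    is exercised on both sides, and a dominant carrier-level logistic
    disease model.
    """

    n_cases: int = 500
    n_controls: int = 500
    n_markers_common: int = 2000
    n_markers_rare: int = 2000
    n_genes: int = 400
    risk_genes: tuple[str, ...] = ("G0001", "G0002", "G0003", "G0004", "G0005")
    risk_carrier_or: float = 3.0
    risk_carrier_freq: float = 0.10
    fst: float = 0.1
    admixture_mix: object = ("point", 1.0)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cases", "n_controls", "n_markers_common",
                     "n_markers_rare", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.risk_carrier_or <= 0:
            raise ValueError("risk_carrier_or must be positive")
        gene_universe = {f"G{i + 1:04d}" for i in range(self.n_genes)}
        if not set(self.risk_genes) <= gene_universe:
            raise ValueError("risk_genes must be a subset of generated genes")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def genes(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    @property
    def prevalence(self) -> float:
        return self.n_cases / self.n_samples


# ---------------------------------------------------------------------------
# Reference panels
# ---------------------------------------------------------------------------

def _balding_nichols(rng, p_anc: np.ndarray, fst: float) -> np.ndarray:
    if fst == 0.0:
        return p_anc.copy()
    a = p_anc * (1.0 - fst) / fst
    b = (1.0 - p_anc) * (1.0 - fst) / fst
    return rng.beta(a, b)


def simulate_reference_panels(
    n_markers: int,
    fst: float,
    seed: int,
    *,
    prefix: str = "M",
) -> AncestralFreqs:
    """Common-marker two-population frequencies under Balding-Nichols.

    Ancestral frequencies are Uniform(0.05, 0.95); each population draws
    from Beta(p(1-fst)/fst, (1-p)(1-fst)/fst) around them (equal to p when
    fst = 0), clipped to [0.01, 0.99].
    """
    if not (0.0 <= fst < 1.0):
        raise ValueError("fst must be in [0, 1)")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = child_rng(seed, "panels")
    p_anc = rng.uniform(0.05, 0.95, size=n_markers)
    pa = np.clip(_balding_nichols(rng, p_anc, fst), 0.01, 0.99)
    pb = np.clip(_balding_nichols(rng, p_anc, fst), 0.01, 0.99)
    ids = np.array([f"{prefix}{i + 1:06d}" for i in range(n_markers)], dtype=object)
    return AncestralFreqs(ids, pa, pb, fst)


def simulate_rare_panels(
    n_markers: int,
    fst: float,
    seed: int,
    *,
    maf_range: tuple[float, float] = (1e-4, 5e-3),
    straddle_frac: float = 0.01,
    prefix: str = "R",
) -> AncestralFreqs:
    """Rare-site frequencies: log-uniform ancestral MAF, mild divergence.

    Ancestral minor allele frequencies are log-uniform over ``maf_range``;
    each population's frequency is a log-normal perturbation around them
    with scale sqrt(fst), preserving the rare spectrum (a Beta divergence
    draw at these frequencies would send nearly every site monomorphic).
    A ``straddle_frac`` share of sites is deliberately placed around the
    0.01 rarity cutoff (uniform on [0.008, 0.02]) so the MAF rule is
    exercised on both sides.
    """
    if not (0.0 <= fst < 1.0):
        raise ValueError("fst must be in [0, 1)")
    rng = child_rng(seed, "rare_panels")
    lo, hi = maf_range
    p_anc = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_markers))
    straddle = rng.random(n_markers) < straddle_frac
    p_anc[straddle] = rng.uniform(0.008, 0.02, size=int(straddle.sum()))
    sigma = np.sqrt(fst)
    pa = np.clip(p_anc * np.exp(rng.normal(0.0, sigma, n_markers)), 1e-6, 0.05)
    pb = np.clip(p_anc * np.exp(rng.normal(0.0, sigma, n_markers)), 1e-6, 0.05)
    ids = np.array([f"{prefix}{i + 1:06d}" for i in range(n_markers)], dtype=object)
    return AncestralFreqs(ids, pa, pb, fst)


# ---------------------------------------------------------------------------
# Cohort genotypes
# ---------------------------------------------------------------------------

def draw_admixture(n: int, mix, rng: np.random.Generator) -> np.ndarray:
    """Draw per-sample target-population fractions q from a mixture spec.

    ``mix`` may be an array of length n, a callable ``f(n, rng)``, or a tuple:
    ("point", q0), ("uniform", a, b), or
    ("two_cluster", (a1, b1), (a2, b2), frac_cluster1) with uniform clusters.
    """
    if callable(mix):
        q = np.asarray(mix(n, rng), dtype=float)
    elif isinstance(mix, (list, np.ndarray)) and not isinstance(mix[0], str):
        q = np.asarray(mix, dtype=float)
    else:
        kind = mix[0]
        if kind == "point":
            q = np.full(n, float(mix[1]))
        elif kind == "uniform":
            q = rng.uniform(mix[1], mix[2], size=n)
        elif kind == "two_cluster":
            (a1, b1), (a2, b2), frac = mix[1], mix[2], mix[3]
            in1 = rng.random(n) < frac
            q = np.where(in1, rng.uniform(a1, b1, n), rng.uniform(a2, b2, n))
        else:
            raise ValueError(f"unknown admixture mix {mix!r}")
    if len(q) != n:
        raise ValueError("admixture fractions must match sample count")
    return np.clip(q, 0.0, 1.0)


def simulate_cohort(
    panel: AncestralFreqs,
    n_samples: int,
    seed: int,
    *,
    admixture_mix=("point", 1.0),
    missing_rate: float = 0.0,
    sample_prefix: str = "S",
    with_quality: bool = False,
    variant_meta: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Admixed genotypes: dosage ~ Binomial(2, q*pA + (1-q)*pB).

    Returns the genotype matrix and a sample table recording each sample's
    true admixture fraction and a population label (popA if q >= 0.5).
    ``variant_meta`` may carry chrom/pos/ref/alt columns aligned to the panel.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = child_rng(seed, "cohort")
    q = draw_admixture(n_samples, admixture_mix, rng)
    m = panel.n_markers
    dosages = np.empty((n_samples, m), dtype=np.int8)
    chunk = max(1, int(2e6 // max(m, 1)))
    for start in range(0, n_samples, chunk):
        stop = min(start + chunk, n_samples)
        f = q[start:stop, None] * panel.freq_popA + (1 - q[start:stop, None]) * panel.freq_popB
        dosages[start:stop] = rng.binomial(2, f).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random((n_samples, m)) < missing_rate
        dosages[miss] = MISSING
    sample_ids = [f"{sample_prefix}{i + 1:05d}" for i in range(n_samples)]
    meta = {}
    if variant_meta is not None:
        meta = {k: variant_meta[k].to_numpy() for k in ("chrom", "pos", "ref", "alt")
                if k in variant_meta}
    dp = gq = None
    if with_quality:
        dp = rng.poisson(30, size=(n_samples, m)).clip(min=1).astype(float)
        gq = np.clip(rng.normal(60, 15, size=(n_samples, m)), 1, 99).round()
    g = GenotypeMatrix(
        dosages=dosages, sample_ids=sample_ids, variant_ids=panel.marker_id,
        dp=dp, gq=gq, **meta,
    )
    table = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "true_q": q,
            "population": np.where(q >= 0.5, "popA", "popB"),
        }
    )
    return g, table


_NUC = np.array(list("ACGT"))
_AMBIG = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _draw_alleles(rng, n, ambiguous_frac=0.1, indel_frac=0.05):
    """Ref/alt pairs: mostly SNVs, a controlled share strand-ambiguous/indel."""
    ref = rng.choice(_NUC, size=n)
    alt = np.empty(n, dtype=object)
    u = rng.random(n)
    for i in range(n):
        if u[i] < indel_frac:
            alt[i] = ref[i] + "".join(rng.choice(_NUC, size=2))  # insertion
        elif u[i] < indel_frac + ambiguous_frac:
            alt[i] = {"A": "T", "T": "A", "C": "G", "G": "C"}[ref[i]]
        else:
            choices = [b for b in "ACGT" if b != ref[i]
                       and (ref[i], b) not in _AMBIG]
            alt[i] = choices[int(rng.integers(len(choices)))]
    return ref.astype(object), alt


def variant_positions(n: int, chrom: str = "1", start: int = 10_000,
                      spacing: int = 997) -> pd.DataFrame:
    pos = start + spacing * np.arange(n)
    return pd.DataFrame({"chrom": chrom, "pos": pos})


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def assign_genes(n_variants: int, genes: Sequence[str]) -> np.ndarray:
    """Deal variants to genes in contiguous, balanced blocks."""
    genes = np.asarray(list(genes), dtype=object)
    ng = len(genes)
    return genes[np.minimum((np.arange(n_variants) * ng) // n_variants, ng - 1)]


def boost_risk_frequencies(
    panel: AncestralFreqs,
    gene_of: np.ndarray,
    risk_genes: Sequence[str],
    target_carrier_freq: float,
) -> AncestralFreqs:
    """Set risk-gene variant frequencies so each risk gene's expected
    aggregate carrier fraction matches ``target_carrier_freq``.

    With k qualifying variants per gene each at frequency f, the chance of
    carrying none is (1-f)^(2k); f solves 1-(1-f)^(2k) = target.  The
    resulting per-variant frequencies stay below the 0.01 rarity cutoff for
    realistic k and targets (k=10, target 0.10 gives f ~ 0.0053).
    """
    pa = panel.freq_popA.copy()
    pb = panel.freq_popB.copy()
    for rg in risk_genes:
        idx = np.flatnonzero(gene_of == rg)
        k = len(idx)
        if k == 0:
            continue
        f = 1.0 - (1.0 - target_carrier_freq) ** (1.0 / (2 * k))
        pa[idx] = f
        pb[idx] = f
    return AncestralFreqs(panel.marker_id, pa, pb, panel.fst)


def simulate_annotations(
    variant_ids: Sequence[str],
    genes: Sequence[str],
    seed: int,
    *,
    generating_maf: np.ndarray | None = None,
    risk_genes: Sequence[str] = (),
    whitelist_frac: float = 0.6,
    ref_maf_missing_frac: float = 0.10,
    blacklist_frac: float = 0.02,
    msc_missing_frac: float = 0.05,
    gdi_high_frac: float = 0.15,
    gdi_cutoff: float = 13.34,
    variant_meta: pd.DataFrame | None = None,
    gene_of: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str]]:
    """Per-variant annotation table, per-gene metric table, and blacklist.

    Variants are dealt to genes in contiguous blocks (every variant gets
    exactly one gene).  Consequences mix whitelisted high-impact classes
    with neutral ones; reference MAFs reproduce the generating frequencies
    but a configurable fraction is dropped to exercise the cohort-frequency
    fallback; CADD scores straddle each gene's MSC cutoff.  Variants in
    ``risk_genes`` are forced onto the qualifying path (whitelisted
    consequence, CADD above MSC, low-GDI gene, not blacklisted) so spiked
    signals survive filtration.
    """
    rng = child_rng(seed, "annotations")
    variant_ids = np.asarray(variant_ids, dtype=object)
    genes = list(genes)
    n, ng = len(variant_ids), len(genes)
    if gene_of is None:
        gene_of = assign_genes(n, genes)
    else:
        gene_of = np.asarray(gene_of, dtype=object)

    n_wl = len(WHITELIST_CONSEQUENCES)
    cons_pool = np.array(WHITELIST_CONSEQUENCES + NEUTRAL_CONSEQUENCES, dtype=object)
    probs = np.concatenate(
        [np.full(n_wl, whitelist_frac / n_wl),
         np.full(len(NEUTRAL_CONSEQUENCES), (1 - whitelist_frac) / len(NEUTRAL_CONSEQUENCES))]
    )
    consequence = rng.choice(cons_pool, size=n, p=probs)

    if generating_maf is None:
        generating_maf = np.exp(rng.uniform(np.log(1e-4), np.log(5e-3), size=n))
    ref_maf = np.asarray(generating_maf, dtype=float).copy()
    ref_maf[rng.random(n) < ref_maf_missing_frac] = np.nan

    cadd = rng.gamma(shape=4.0, scale=5.0, size=n)  # mean 20, long right tail

    # per-gene metrics
    msc = rng.uniform(5.0, 25.0, size=ng)
    msc[rng.random(ng) < msc_missing_frac] = np.nan
    gdi = rng.lognormal(mean=1.5, sigma=0.8, size=ng)
    high = rng.random(ng) < gdi_high_frac
    gdi[high] = gdi_cutoff + rng.lognormal(1.0, 0.5, size=high.sum())
    gdi[~high] = np.minimum(gdi[~high], gdi_cutoff * 0.95)

    blacklisted = rng.random(n) < blacklist_frac

    # force qualifying annotations inside risk genes
    risk = np.isin(gene_of, list(risk_genes))
    if risk.any():
        consequence[risk] = rng.choice(
            np.array(WHITELIST_CONSEQUENCES, dtype=object), size=int(risk.sum())
        )
        blacklisted[risk] = False
        gidx = {g: k for k, g in enumerate(genes)}
        for rg in risk_genes:
            k = gidx[rg]
            if np.isnan(msc[k]):
                msc[k] = 15.0
            gdi[k] = min(gdi[k], gdi_cutoff * 0.5)
            vr = gene_of == rg
            cadd[vr] = msc[k] + rng.uniform(1.0, 15.0, size=int(vr.sum()))

    ann = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "gene": gene_of,
            "consequence": consequence,
            "ref_maf": ref_maf,
            "cadd": cadd,
        }
    )
    if variant_meta is not None:
        ann = pd.concat(
            [ann[["variant_id"]],
             variant_meta[[c for c in ("chrom", "pos", "ref", "alt") if c in variant_meta]].reset_index(drop=True),
             ann.drop(columns=["variant_id"])],
            axis=1,
        )
    metrics = pd.DataFrame({"gene": genes, "msc_cadd": msc, "gdi": gdi})
    blacklist = set(variant_ids[blacklisted])
    return ann, metrics, blacklist


def join_gene_metrics(
    ann: pd.DataFrame, metrics: pd.DataFrame, blacklist: set[str]
) -> pd.DataFrame:
    """Join per-gene MSC/GDI and the blacklist flag onto the variant table."""
    out = ann.merge(metrics, on="gene", how="left")
    out["blacklisted"] = out["variant_id"].isin(blacklist)
    return out


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def risk_carrier_vector(
    g: GenotypeMatrix, qualifying_ann: pd.DataFrame, risk_genes: Sequence[str]
) -> np.ndarray:
    """True where a sample carries >=1 qualifying alternate allele in a risk gene."""
    vids = qualifying_ann.loc[
        qualifying_ann["gene"].isin(list(risk_genes)), "variant_id"
    ]
    present = [v for v in vids if v in set(g.variant_ids)]
    if not present:
        return np.zeros(g.n_samples, dtype=bool)
    idx = g.variant_index(present)
    return (g.dosages[:, idx] > 0).any(axis=1)


def spike_phenotypes(
    g: GenotypeMatrix,
    qualifying_ann: pd.DataFrame,
    spec: SimSpec,
    *,
    mode: str = "carrier",
) -> tuple[np.ndarray, dict]:
    """Case/control labels from a carrier-level (dominant) logistic model.

    Carrying >=1 qualifying allele in any risk gene multiplies disease odds
    by ``spec.risk_carrier_or``; the intercept is solved so the expected
    prevalence matches ``spec.prevalence``.  ``risk_carrier_or = 1`` yields
    a null cohort.  ``mode="per_allele"`` uses the summed qualifying risk
    dosage instead of the carrier indicator.
    """
    prevalence = spec.prevalence
    if not (0.0 < prevalence < 1.0):
        raise ValueError("target prevalence must be in (0, 1)")
    rng = child_rng(spec.seed, "phenotypes")
    if mode == "carrier":
        exposure = risk_carrier_vector(g, qualifying_ann, spec.risk_genes).astype(float)
    elif mode == "per_allele":
        vids = qualifying_ann.loc[
            qualifying_ann["gene"].isin(list(spec.risk_genes)), "variant_id"
        ]
        present = [v for v in vids if v in set(g.variant_ids)]
        idx = g.variant_index(present) if present else []
        exposure = (
            np.clip(g.dosages[:, idx], 0, 2).sum(axis=1).astype(float)
            if len(idx)
            else np.zeros(g.n_samples)
        )
    else:
        raise ValueError("mode must be 'carrier' or 'per_allele'")
    beta = np.log(spec.risk_carrier_or)

    def mean_prev(b0):
        return expit(b0 + beta * exposure).mean() - prevalence

    if mean_prev(-30.0) > 0 or mean_prev(30.0) < 0:  # pragma: no cover
        raise ValueError("target prevalence unattainable under this model")
    b0 = brentq(mean_prev, -30.0, 30.0, xtol=1e-10)
    y = (rng.random(g.n_samples) < expit(b0 + beta * exposure)).astype(np.int8)
    degenerate = bool(exposure.astype(bool).all() or not exposure.astype(bool).any())
    info = {
        "intercept": b0,
        "carrier_freq": float(exposure.astype(bool).mean()),
        "degenerate_carriage": degenerate and spec.risk_carrier_or != 1.0,
    }
    return y, info


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

def simulate_distance_matrix(
    genes: Sequence[str],
    core_set: Sequence[str],
    seed: int,
    *,
    core_mean: float = 5.0,
    background_mean: float = 15.0,
    sd: float = 2.0,
) -> DistanceMatrix:
    """Symmetric positive distances; pairs within ``core_set`` are closer.

    Within-core pairs draw from a low-mean truncated normal and every other
    pair from a higher-mean one; ``core_mean == background_mean`` gives an
    exchangeable null.
    """
    genes = list(genes)
    if not set(core_set) <= set(genes):
        raise ValueError("core_set must be a subset of genes")
    rng = child_rng(seed, "distance")
    n = len(genes)
    in_core = np.isin(np.array(genes, dtype=object), list(core_set))
    mean = np.where(in_core[:, None] & in_core[None, :], core_mean, background_mean)
    upper = np.triu(rng.normal(mean, sd), k=1)
    values = upper + upper.T
    values = np.abs(values)  # keep strictly positive off-diagonal
    np.fill_diagonal(values, 0.0)
    zero_off = (values == 0.0) & ~np.eye(n, dtype=bool)
    values[zero_off] = 1e-6
    return DistanceMatrix(genes, values)


# ---------------------------------------------------------------------------
# GWAS summary statistics (training split)
# ---------------------------------------------------------------------------

def simulate_summary_stats(
    g_train: GenotypeMatrix, y_train: np.ndarray
) -> pd.DataFrame:
    """Single-variant score-regression summary statistics on a training split.

    For each variant, beta = U/V and se = V^-1/2 with U the score
    sum((x - xbar)(y - ybar)) over called genotypes and V = ybar(1-ybar) *
    sum((x - xbar)^2), the one-step logistic score estimator.  Monomorphic
    variants get beta 0, infinite se, and a flag; perfect genotype-phenotype
    correlation is flagged as separation.
    """
    y = np.asarray(y_train, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    d = g_train.dosage_float()
    called = ~np.isnan(d)
    n_called = called.sum(axis=0)
    x = np.where(called, d, 0.0)
    sx = x.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = sx / n_called
        ybar = (np.where(called, y[:, None], 0.0).sum(axis=0)) / n_called
        xc = np.where(called, d - xbar, 0.0)
        u = (xc * (y[:, None] - ybar)).sum(axis=0)
        sxx = (xc**2).sum(axis=0)
        v = ybar * (1.0 - ybar) * sxx
        beta = np.where(v > 0, u / v, 0.0)
        se = np.where(v > 0, 1.0 / np.sqrt(v), np.inf)
        syy = ybar * (1 - ybar) * n_called
        denom = np.sqrt(sxx * syy)
        corr = np.where(denom > 0, u / denom, 0.0)
    monomorphic = sxx == 0
    separated = (~monomorphic) & (np.abs(corr) > 0.999)
    out = pd.DataFrame(
        {
            "variant_id": g_train.variant_ids,
            "effect_allele": (g_train.alt if g_train.alt is not None
                              else np.repeat("G", g_train.n_variants)),
            "other_allele": (g_train.ref if g_train.ref is not None
                             else np.repeat("A", g_train.n_variants)),
            "beta": beta,
            "se": se,
            "n": n_called.astype(int),
            "monomorphic": monomorphic,
            "separated": separated,
        }
    )
    return out


# ---------------------------------------------------------------------------
# Full-study orchestration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StudyData:
    """Bundle of every artifact one synthetic study emits."""

    spec: SimSpec
    panel: AncestralFreqs
    genotypes: GenotypeMatrix
    samples: pd.DataFrame
    annotation: pd.DataFrame
    gene_metrics: pd.DataFrame
    blacklist: set[str]
    annotation_full: pd.DataFrame  # annotation joined with metrics + blacklist
    qualifying: pd.Index
    attrition: pd.DataFrame
    phenotype: np.ndarray
    phenotype_info: dict


def generate_study(spec: SimSpec, *, with_quality: bool = False) -> StudyData:
    """Generate a complete rare-variant case-control study from one spec.

    Wires the stages together with consistent variant-to-gene assignment:
    rare-site panels, risk-gene frequency boosting to the target carrier
    fraction, cohort genotypes, annotation/metric/blacklist tables, the
    six-rule deleteriousness filter (to define qualifying variants), and
    carrier-model phenotypes.  Everything derives from ``spec.seed``.
    """
    from . import qcfilter  # local import; qcfilter does not import synth

    rare = simulate_rare_panels(spec.n_markers_rare, spec.fst, spec.seed)
    gene_of = assign_genes(spec.n_markers_rare, spec.genes)
    rare = boost_risk_frequencies(rare, gene_of, spec.risk_genes,
                                  spec.risk_carrier_freq)
    meta = variant_positions(spec.n_markers_rare)
    rng = child_rng(spec.seed, "alleles")
    ref, alt = _draw_alleles(rng, spec.n_markers_rare)
    meta["ref"], meta["alt"] = ref, alt
    g, samples = simulate_cohort(
        rare, spec.n_samples, spec.seed, admixture_mix=spec.admixture_mix,
        missing_rate=spec.missing_rate, with_quality=with_quality,
        variant_meta=meta,
    )
    ann, metrics, blacklist = simulate_annotations(
        g.variant_ids, spec.genes, spec.seed,
        generating_maf=np.minimum(rare.freq_popA, 1.0 - rare.freq_popA),
        risk_genes=spec.risk_genes, gene_of=gene_of, variant_meta=meta,
    )
    full = join_gene_metrics(ann, metrics, blacklist)
    cohort_af = pd.Series(g.allele_freq(), index=g.variant_ids)
    qualifying, attrition = qcfilter.high_impact_filter(full, cohort_af)
    y, info = spike_phenotypes(
        g, full[full["variant_id"].isin(qualifying)], spec
    )
    samples = samples.copy()
    samples["phenotype"] = y
    return StudyData(
        spec=spec, panel=rare, genotypes=g, samples=samples, annotation=ann,
        gene_metrics=metrics, blacklist=blacklist, annotation_full=full,
        qualifying=qualifying, attrition=attrition, phenotype=y,
        phenotype_info=info,
    )
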