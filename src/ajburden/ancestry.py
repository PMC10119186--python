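"""Genetic identification of the target-population subset.

Implements the cohort-definition stage: marker pre-masking (MAF, call rate,
strand-ambiguous exclusion), sliding-window LD pruning, a supervised
two-population admixture-fraction estimator (the reference panels fix the
ancestral allele frequencies, so each sample's target-population fraction q
maximizes an explicit binomial likelihood), minimum-reference-fraction
assignment with a second refinement round, and PCA projection for
validation and covariate construction.
"""

from __future__ import annotations

import warnings
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .containers import AncestralFreqs, GenotypeMatrix

__all__ = [
    "premask_markers",
    "ld_prune",
    "estimate_fractions",
    "assign_population",
    "two_round_assign",
    "pca_project",
]

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def premask_markers(
    g: GenotypeMatrix,
    maf_min: float = 0.02,
    call_rate_min: float = 0.95,
    drop_ambiguous_strand: bool = True,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Marker indices passing the structure-analysis pre-mask.

    Retains markers with MAF strictly greater than ``maf_min`` and call rate
    strictly greater than ``call_rate_min``; A/T and C/G pairs are removed
    when ``drop_ambiguous_strand`` is set.  ``exclude`` is an optional
    boolean per-variant mask (e.g. known high-LD regions from a BED file).
    """
    af = g.allele_freq()
    maf = np.minimum(af, 1.0 - af)
    keep = (maf > maf_min) & (g.call_rate() > call_rate_min)
    keep &= ~np.isnan(maf)
    if drop_ambiguous_strand and g.ref is not None and g.alt is not None:
        amb = np.array(
            [(r, a) in _AMBIGUOUS for r, a in zip(g.ref, g.alt)], dtype=bool
        )
        keep &= ~amb
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    return np.flatnonzero(keep)


def _window_r2(d: np.ndarray) -> np.ndarray:
    """Pairwise squared correlation on dosages with pairwise-complete obs."""
    if np.isnan(d).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c = np.ma.corrcoef(np.ma.masked_invalid(d.T))
        r = np.asarray(c.filled(0.0))
    else:
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(d.T)
        r = np.nan_to_num(r)
    return r**2


def ld_prune(
    g: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy sliding-window LD pruning (window/step/r2 as in --indep-pairwise).

    Markers are assumed ordered by genomic position.  Within each window the
    earlier member of any pair with r^2 > ``r2_max`` is kept and the later
    one removed; monomorphic markers are excluded up front (r^2 undefined).
    Deterministic given input order and independent of sample labels.
    """
    d = g.dosage_float()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        var = np.nanvar(d, axis=0)
    keep = np.ones(g.n_variants, dtype=bool)
    keep[~(var > 0)] = False
    for start in range(0, g.n_variants, step):
        idx = np.flatnonzero(keep[start : start + window]) + start
        if len(idx) < 2:
            continue
        r2 = _window_r2(d[:, idx])
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if keep[idx[b]] and r2[a, b] > r2_max:
                    keep[idx[b]] = False
        if start + window >= g.n_variants:
            break
    return np.flatnonzero(keep)


def estimate_fractions(
    g: GenotypeMatrix,
    panel: AncestralFreqs,
    *,
    min_markers: int = 50,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Supervised K=2 maximum-likelihood admixture fractions.

    Per sample, q maximizes sum_m log Binomial(g_m; 2, q*pA_m + (1-q)*pB_m)
    over q in [0, 1]; the log-likelihood is concave in q, solved by a
    safeguarded vectorized Newton iteration to ``tol``.  Missing genotypes
    are skipped.  Samples with fewer than ``min_markers`` called markers are
    flagged unreliable; a flat likelihood (pA == pB everywhere) returns
    q = 0.5 with a flag.
    """
    if g.n_variants != panel.n_markers:
        raise ValueError("genotype matrix and panel marker counts differ")
    d = g.dosage_float()
    called = ~np.isnan(d)
    n_used = called.sum(axis=1)
    gm = np.where(called, d, 0.0)
    two_minus = np.where(called, 2.0 - d, 0.0)
    pa, pb = panel.freq_popA, panel.freq_popB
    delta = pa - pb
    flat = bool(np.max(np.abs(delta)) < 1e-12)

    n = g.n_samples
    q = np.full(n, 0.5)
    lo = np.zeros(n)
    hi = np.ones(n)
    if not flat:
        for _ in range(max_iter):
            f = q[:, None] * pa + (1 - q)[:, None] * pb
            inv_f = np.where(called, 1.0 / f, 0.0)
            inv_1f = np.where(called, 1.0 / (1.0 - f), 0.0)
            grad = (gm * inv_f - two_minus * inv_1f) @ delta
            hess = -(gm * inv_f**2 + two_minus * inv_1f**2) @ (delta**2)
            # maintain a bracket around the concave maximum
            lo = np.where(grad > 0, np.maximum(lo, q), lo)
            hi = np.where(grad < 0, np.minimum(hi, q), hi)
            with np.errstate(divide="ignore", invalid="ignore"):
                step = np.where(hess < 0, -grad / hess, 0.0)
            q_new = q + step
            outside = (q_new <= lo) | (q_new >= hi) | ~np.isfinite(q_new)
            q_new = np.where(outside, 0.5 * (lo + hi), q_new)
            if np.max(np.abs(q_new - q)) < tol and _ > 2:
                q = q_new
                break
            q = q_new
        q = np.clip(q, 0.0, 1.0)

    f = np.clip(q[:, None] * pa + (1 - q)[:, None] * pb, 1e-12, 1 - 1e-12)
    loglik = (gm * np.log(f) + two_minus * np.log(1 - f)).sum(axis=1)
    return pd.DataFrame(
        {
            "sample_id": g.sample_ids,
            "q": 0.5 if flat else q,
            "loglik": loglik,
            "n_markers": n_used.astype(int),
            "flat_likelihood": flat,
            "unreliable": n_used < min_markers,
        }
    )


def assign_population(
    estimates: pd.DataFrame,
    reference_ids: Iterable[str],
    rounds: int = 2,
    reestimate: Callable[[list[str]], pd.DataFrame] | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Minimum-reference-fraction assignment with optional refinement rounds.

    Round 1: the cutoff is the minimum q among reference samples; candidates
    with q >= cutoff (boundary inclusive) are assigned.  Subsequent rounds
    call ``reestimate(retained_and_reference_ids)`` for updated estimates
    and re-apply the updated minimum-reference cutoff.  The trace records
    each round's cutoff and removal count.
    """
    reference_ids = set(reference_ids)
    if not reference_ids:
        raise ValueError("reference set must be non-empty")
    if not reference_ids <= set(estimates["sample_id"]):
        raise ValueError("reference_ids missing from estimates")
    current = estimates.set_index("sample_id")
    candidates = [s for s in estimates["sample_id"] if s not in reference_ids]
    assigned = set(candidates)
    trace = []
    for r in range(1, rounds + 1):
        cutoff = float(current.loc[sorted(reference_ids), "q"].min())
        pool = [s for s in candidates if s in current.index and s in assigned]
        newly = {s for s in pool if current.loc[s, "q"] >= cutoff}
        removed = len(pool) - len(newly)
        assigned = newly
        trace.append(
            {"round": r, "cutoff": cutoff, "n_assigned": len(assigned),
             "n_removed": removed}
        )
        if r < rounds and reestimate is not None:
            current = (
                reestimate(sorted(assigned | reference_ids))
                .set_index("sample_id")
            )
        elif r < rounds and reestimate is None:
            # fixed estimates cannot change the cutoff; later rounds no-op
            break
    return assigned, pd.DataFrame(trace)


def two_round_assign(
    g: GenotypeMatrix,
    panel: AncestralFreqs,
    reference_ids: Iterable[str],
    rounds: int = 2,
) -> tuple[set[str], pd.DataFrame, pd.DataFrame]:
    """Estimate fractions, then run the multi-round cutoff assignment.

    Refinement rounds re-estimate the target-population allele frequencies
    empirically from the reference plus currently retained samples (the
    analogue of re-running the structure analysis on the retained subset)
    and recompute q for those samples against the updated panel.
    """
    reference_ids = set(reference_ids)
    est = estimate_fractions(g, panel)

    def reestimate(ids: list[str]) -> pd.DataFrame:
        sub = g.take_samples(g.sample_index(ids))
        af = sub.allele_freq()
        pa = np.clip(np.where(np.isnan(af), panel.freq_popA, af), 0.01, 0.99)
        new_panel = AncestralFreqs(panel.marker_id, pa, panel.freq_popB, panel.fst)
        new_est = estimate_fractions(g, new_panel)
        return new_est[new_est["sample_id"].isin(ids)]

    assigned, trace = assign_population(
        est, reference_ids, rounds=rounds, reestimate=reestimate
    )
    return assigned, trace, est


def pca_project(
    g: GenotypeMatrix, k: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal component coordinates of standardized genotypes.

    Markers are mean-centered and scaled by sqrt(2p(1-p)); missing genotypes
    are imputed to the marker mean.  Returns (coordinates shape (n, k),
    explained-variance fractions).  The sign convention makes each
    component's largest-magnitude sample loading positive.  k above the
    matrix rank is truncated with a warning.
    """
    d = g.dosage_float()
    p = g.allele_freq()
    keep = (p > 0) & (p < 1) & ~np.isnan(p)
    d = d[:, keep]
    p = p[keep]
    mean = 2.0 * p
    scale = np.sqrt(2.0 * p * (1.0 - p))
    x = (np.where(np.isnan(d), mean, d) - mean) / scale
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > s[0] * 1e-9).sum()) if len(s) else 0
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}; truncating")
        k = rank
    coords = u[:, :k] * s[:k]
    # fix sign: largest-magnitude coordinate positive
    for j in range(k):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    explained = (s[:k] ** 2) / (s**2).sum() if len(s) else np.array([])
    return coords, explained
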