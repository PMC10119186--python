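"""Core in-memory containers shared by every pipeline stage."""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # dosage sentinel for a no-call genotype

__all__ = ["MISSING", "GenotypeMatrix", "AncestralFreqs", "DistanceMatrix"]


def _as_str_array(x) -> np.ndarray:
    return np.asarray(list(x), dtype=object)


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples x variants alternate-allele dosage matrix.

    ``dosages`` is int8 with values in {0, 1, 2} and ``MISSING`` (-1) for
    no-calls.  Optional per-variant metadata (chrom/pos 1-based VCF
    convention, ref/alt alleles) and per-genotype quality arrays (``dp``,
    ``gq``) ride along when the source provides them.
    """

    dosages: np.ndarray
    sample_ids: np.ndarray
    variant_ids: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    dp: np.ndarray | None = None
    gq: np.ndarray | None = None

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.sample_ids = _as_str_array(self.sample_ids)
        self.variant_ids = _as_str_array(self.variant_ids)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.variant_ids) != m:
            raise ValueError("variant_ids length does not match dosage columns")
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        for name in ("chrom", "pos", "ref", "alt"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if len(v) != m:
                    raise ValueError(f"{name} length does not match variants")
                setattr(self, name, v)
        for name in ("dp", "gq"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (n, m):
                    raise ValueError(f"{name} shape does not match dosages")
                setattr(self, name, v)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (samples x variants), True where genotype is missing."""
        return self.dosages == MISSING

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of called genotypes."""
        return 1.0 - self.missing_mask.mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-variant alternate allele frequency among called genotypes."""
        d = self.dosages.astype(float)
        called = d >= 0
        alt = np.where(called, d, 0.0).sum(axis=0)
        denom = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(denom > 0, alt / denom, np.nan)

    def dosage_float(self, impute_af: bool = False) -> np.ndarray:
        """Float dosages with missing as NaN, or mean-imputed to 2*AF."""
        d = self.dosages.astype(float)
        d[self.dosages == MISSING] = np.nan
        if impute_af:
            fill = 2.0 * self.allele_freq()
            idx = np.where(np.isnan(d))
            d[idx] = fill[idx[1]]
        return d

    def _take(self, rows, cols) -> "GenotypeMatrix":
        def sub2(a):
            return None if a is None else a[np.ix_(rows, cols)]

        def subc(a):
            return None if a is None else a[cols]

        return GenotypeMatrix(
            dosages=self.dosages[np.ix_(rows, cols)],
            sample_ids=self.sample_ids[rows],
            variant_ids=self.variant_ids[cols],
            chrom=subc(self.chrom),
            pos=subc(self.pos),
            ref=subc(self.ref),
            alt=subc(self.alt),
            dp=sub2(self.dp),
            gq=sub2(self.gq),
        )

    def take_variants(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return self._take(np.arange(self.n_samples), idx)

    def take_samples(self, idx: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return self._take(idx, np.arange(self.n_variants))

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=int)

    def variant_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        return np.array([lookup[v] for v in ids], dtype=int)


@dataclasses.dataclass
class AncestralFreqs:
    """Reference-panel allele frequencies for two ancestral populations.

    Stands in for the two reference panels of a supervised two-way admixture
    model.  Frequencies are kept strictly inside (0, 1) so per-genotype
    binomial log-likelihoods are finite.
    """

    marker_id: np.ndarray
    freq_popA: np.ndarray
    freq_popB: np.ndarray
    fst: float

    def __post_init__(self):
        self.marker_id = _as_str_array(self.marker_id)
        self.freq_popA = np.asarray(self.freq_popA, dtype=float)
        self.freq_popB = np.asarray(self.freq_popB, dtype=float)
        if not (len(self.marker_id) == len(self.freq_popA) == len(self.freq_popB)):
            raise ValueError("marker/frequency arrays must have equal length")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        for f in (self.freq_popA, self.freq_popB):
            if np.any(f <= 0.0) or np.any(f >= 1.0):
                raise ValueError("panel frequencies must lie strictly in (0,1)")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def take(self, idx) -> "AncestralFreqs":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return AncestralFreqs(
            self.marker_id[idx], self.freq_popA[idx], self.freq_popB[idx], self.fst
        )


class DistanceMatrix:
    """Symmetric gene x gene biological distance matrix.

    Houses the pairwise distances D_ij used by the connectome-style
    prioritization: exact symmetry, zero diagonal, finite non-negative values
    wherever the optional missing-pair mask is False.
    """

    def __init__(self, genes, values, mask=None):
        self.genes = _as_str_array(genes)
        self.values = np.asarray(values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match genes")
        if mask is None:
            mask = np.zeros((n, n), dtype=bool)
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.shape != (n, n):
            raise ValueError("mask must match values shape")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("distance matrix must be exactly symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        ok = self.values[~self.mask]
        if not np.all(np.isfinite(ok)) or np.any(ok < 0):
            raise ValueError("unmasked distances must be finite and non-negative")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def index(self, genes: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._index[g] for g in genes], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise KeyError(f"gene {e.args[0]!r} not in distance matrix") from None

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)
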