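"""Readers and writers for the plain-text formats the pipeline exchanges.

All coordinates are 1-based VCF convention; BED inputs are 0-based half-open
and converted at this boundary.  Genotypes travel either as VCF v4.2 with
GT:DP:GQ fields or as a variants x samples dosage TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, AncestralFreqs, DistanceMatrix, GenotypeMatrix

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write biallelic records with GT (and DP/GQ when present)."""
    has_q = g.dp is not None and g.gq is not None
    fmt = "GT:DP:GQ" if has_q else "GT"
    chrom = g.chrom if g.chrom is not None else np.repeat("1", g.n_variants)
    pos = g.pos if g.pos is not None else np.arange(1, g.n_variants + 1) * 1000
    ref = g.ref if g.ref is not None else np.repeat("A", g.n_variants)
    alt = g.alt if g.alt is not None else np.repeat("G", g.n_variants)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j in range(g.n_variants):
            cells = []
            for i in range(g.n_samples):
                gt = _GT_CODE[int(g.dosages[i, j])]
                if has_q:
                    cells.append(f"{gt}:{int(g.dp[i, j])}:{int(g.gq[i, j])}")
                else:
                    cells.append(gt)
            fh.write(
                f"{chrom[j]}\t{pos[j]}\t{g.variant_ids[j]}\t{ref[j]}\t{alt[j]}"
                f"\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def _parse_gt(field: str) -> int:
    gt = field.split(":", 1)[0].replace("|", "/")
    if "." in gt:
        return MISSING
    alleles = gt.split("/")
    return sum(1 for a in alleles if a != "0")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic GT[:DP:GQ] VCF into a GenotypeMatrix."""
    sample_ids: list[str] = []
    vid, chrom, pos, ref, alt = [], [], [], [], []
    rows, dp_rows, gq_rows = [], [], []
    have_dp = have_gq = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.split("\t")[9:]
                continue
            f = line.split("\t")
            if "," in f[4]:
                raise ValueError(
                    f"multiallelic record at {f[0]}:{f[1]}; split first"
                )
            chrom.append(f[0])
            pos.append(int(f[1]))
            vid.append(f[2] if f[2] != "." else f"{f[0]}:{f[1]}:{f[3]}:{f[4]}")
            ref.append(f[3])
            alt.append(f[4])
            keys = f[8].split(":")
            gt_i = keys.index("GT")
            dp_i = keys.index("DP") if "DP" in keys else None
            gq_i = keys.index("GQ") if "GQ" in keys else None
            have_dp |= dp_i is not None
            have_gq |= gq_i is not None
            row, dps, gqs = [], [], []
            for cell in f[9:]:
                parts = cell.split(":")
                row.append(_parse_gt(parts[gt_i]))
                if dp_i is not None and len(parts) > dp_i:
                    dps.append(float(parts[dp_i]) if parts[dp_i] != "." else np.nan)
                if gq_i is not None and len(parts) > gq_i:
                    gqs.append(float(parts[gq_i]) if parts[gq_i] != "." else np.nan)
            rows.append(row)
            dp_rows.append(dps)
            gq_rows.append(gqs)
    dosages = np.asarray(rows, dtype=np.int8).T if rows else np.zeros((len(sample_ids), 0), np.int8)
    dp = np.asarray(dp_rows, float).T if have_dp and dp_rows and dp_rows[0] else None
    gq = np.asarray(gq_rows, float).T if have_gq and gq_rows and gq_rows[0] else None
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=sample_ids,
        variant_ids=vid,
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=int),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        dp=dp,
        gq=gq,
    )


# ---------------------------------------------------------------------------
# Dosage TSV (variants as rows, samples as columns)
# ---------------------------------------------------------------------------

_META_COLS = ["variant_id", "chrom", "pos", "ref", "alt"]


def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    meta = {
        "variant_id": g.variant_ids,
        "chrom": g.chrom if g.chrom is not None else "1",
        "pos": g.pos if g.pos is not None else np.arange(1, g.n_variants + 1),
        "ref": g.ref if g.ref is not None else "A",
        "alt": g.alt if g.alt is not None else "G",
    }
    df = pd.DataFrame(meta)
    dose = pd.DataFrame(g.dosages.T, columns=g.sample_ids)
    pd.concat([df, dose], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    samples = [c for c in df.columns if c not in _META_COLS]
    return GenotypeMatrix(
        dosages=df[samples].to_numpy(dtype=np.int8).T,
        sample_ids=samples,
        variant_ids=df["variant_id"].to_numpy(dtype=object),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=int),
        ref=df["ref"].to_numpy(dtype=object),
        alt=df["alt"].to_numpy(dtype=object),
    )


# ---------------------------------------------------------------------------
# Annotation / gene metric / blacklist tables
# ---------------------------------------------------------------------------

def write_annotation_tsv(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_gene_metrics_tsv(metrics: pd.DataFrame, path: str | Path) -> None:
    metrics.to_csv(path, sep="\t", index=False)


def read_gene_metrics_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


# one variant_id per line
write_blacklist = write_gene_list
read_blacklist = read_gene_list


# ---------------------------------------------------------------------------
# Distance matrix / panels / summary stats
# ---------------------------------------------------------------------------

def write_distance_tsv(d: DistanceMatrix, path: str | Path) -> None:
    d.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.index.to_numpy(dtype=object), df.to_numpy(float))


def write_panel_tsv(panel: AncestralFreqs, path: str | Path) -> None:
    pd.DataFrame(
        {
            "marker_id": panel.marker_id,
            "freq_popA": panel.freq_popA,
            "freq_popB": panel.freq_popB,
        }
    ).to_csv(path, sep="\t", index=False)
    # fst recorded in a sidecar comment is overkill; kept in SimSpec/config


def read_panel_tsv(path: str | Path, fst: float = 0.0) -> AncestralFreqs:
    df = pd.read_csv(path, sep="\t")
    return AncestralFreqs(
        df["marker_id"].to_numpy(dtype=object),
        df["freq_popA"].to_numpy(float),
        df["freq_popB"].to_numpy(float),
        fst,
    )


def write_summary_tsv(summary: pd.DataFrame, path: str | Path) -> None:
    summary.to_csv(path, sep="\t", index=False)


def read_summary_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# BED mask (0-based half-open -> 1-based inclusive at this boundary)
# ---------------------------------------------------------------------------

def read_bed_mask(path: str | Path) -> list[tuple[str, int, int]]:
    """Return (chrom, start_1based, end_1based_inclusive) intervals."""
    out = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        c, s, e = ln.split("\t")[:3]
        out.append((c, int(s) + 1, int(e)))
    return out


def bed_mask_variants(g: GenotypeMatrix, intervals) -> np.ndarray:
    """Boolean per-variant array, True where the variant falls in a mask interval."""
    if g.chrom is None or g.pos is None:
        raise ValueError("genotype matrix lacks chrom/pos metadata")
    hit = np.zeros(g.n_variants, dtype=bool)
    for c, s, e in intervals:
        hit |= (g.chrom == c) & (g.pos >= s) & (g.pos <= e)
    return hit
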