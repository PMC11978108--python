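"""Plain-text interchange: TSV (primary) and a minimal allele-depth VCF.

All tables are tab-separated with a header row. Read-count tables are sparse
(zero-depth sample/site combinations are omitted) and are expanded against a
site panel when loaded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ancestry import CALL_LABELS, MISSING
from .genome import SitePanel
from .simulate import ReadCounts

_CALL_CODES = {v: k for k, v in CALL_LABELS.items()}


def write_read_counts(counts: ReadCounts, path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index=False)


def read_read_counts(path, panel: SitePanel,
                     samples: list[str] | None = None) -> ReadCounts:
    """Load a sparse (sample, chrom, pos, count_a, count_b) table."""
    df = pd.read_csv(path, sep="\t")
    if samples is None:
        samples = list(dict.fromkeys(df["sample"]))
    sidx = {s: i for i, s in enumerate(samples)}
    key = pd.MultiIndex.from_frame(panel.sites[["chrom", "pos"]])
    vidx = pd.Series(np.arange(len(panel)), index=key)
    rows = df["sample"].map(sidx).to_numpy()
    cols = vidx.loc[pd.MultiIndex.from_frame(df[["chrom", "pos"]])].to_numpy()
    count_a = np.zeros((len(samples), len(panel)), dtype=np.int32)
    count_b = np.zeros_like(count_a)
    count_a[rows, cols] = df["count_a"].to_numpy()
    count_b[rows, cols] = df["count_b"].to_numpy()
    return ReadCounts(samples, panel, count_a, count_b)


def write_vcf(counts: ReadCounts, path) -> None:
    """Minimal VCFv4.2 with per-sample allele depths (FORMAT AD)."""
    sites = counts.panel.sites
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        for chrom in counts.panel.chromosomes:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(counts.samples) + "\n")
        for j in range(len(sites)):
            row = sites.iloc[j]
            ads = "\t".join(f"{a},{b}" for a, b in
                            zip(counts.count_a[:, j], counts.count_b[:, j]))
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.allele_a}\t"
                     f"{row.allele_b}\t.\t.\t.\tAD\t{ads}\n")


def read_vcf(path, panel: SitePanel) -> ReadCounts:
    """Allele depths from a VCF with a FORMAT/AD field (needs cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    key = pd.MultiIndex.from_frame(panel.sites[["chrom", "pos"]])
    vidx = pd.Series(np.arange(len(panel)), index=key)
    count_a = np.zeros((len(samples), len(panel)), dtype=np.int32)
    count_b = np.zeros_like(count_a)
    for var in vcf:
        try:
            j = int(vidx.loc[(var.CHROM, var.POS)])
        except KeyError:
            continue
        ad = var.format("AD")
        count_a[:, j] = np.maximum(ad[:, 0], 0)
        count_b[:, j] = np.maximum(ad[:, 1], 0)
    return ReadCounts(samples, panel, count_a, count_b)


def write_calls(calls: np.ndarray, samples: list[str], panel: SitePanel,
                path) -> None:
    s_idx, v_idx = np.nonzero(calls != MISSING)
    pd.DataFrame({
        "sample": np.asarray(samples, dtype=object)[s_idx],
        "chrom": panel.sites["chrom"].to_numpy()[v_idx],
        "pos": panel.sites["pos"].to_numpy()[v_idx],
        "call": [CALL_LABELS[c] for c in calls[s_idx, v_idx]],
    }).to_csv(path, sep="\t", index=False)


def read_calls(path, panel: SitePanel,
               samples: list[str] | None = None) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    if samples is None:
        samples = list(dict.fromkeys(df["sample"]))
    sidx = {s: i for i, s in enumerate(samples)}
    key = pd.MultiIndex.from_frame(panel.sites[["chrom", "pos"]])
    vidx = pd.Series(np.arange(len(panel)), index=key)
    calls = np.full((len(samples), len(panel)), MISSING, dtype=np.int8)
    rows = df["sample"].map(sidx).to_numpy()
    cols = vidx.loc[pd.MultiIndex.from_frame(df[["chrom", "pos"]])].to_numpy()
    calls[rows, cols] = df["call"].map(_CALL_CODES).to_numpy(dtype=np.int8)
    return samples, calls


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
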