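"""Plain-text interchange formats between pipeline stages.

Everything is tab-separated UTF-8 with ``.`` for missing values: dosage
matrices (samples x variants), count matrices (genes x samples),
phenotype/covariate tables, GWAS-style summary statistics, and an optional
minimal VCF carrying dosages in the DS FORMAT field.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "write_tsv", "read_tsv",
    "write_dosages", "read_dosages",
    "write_counts", "read_counts",
    "write_phenotypes", "read_phenotypes",
    "write_summary_stats", "read_summary_stats",
    "write_vcf_dosages",
]

_NA = "."


def write_tsv(df: pd.DataFrame, path, index_label=None):
    df.to_csv(path, sep="\t", na_rep=_NA, index=index_label is not None,
              index_label=index_label)


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[_NA], index_col=index_col)


def write_dosages(dosages: pd.DataFrame, path):
    """Samples x variants dosage TSV; header row holds variant IDs."""
    write_tsv(dosages, path, index_label="sample")


def read_dosages(path) -> pd.DataFrame:
    return read_tsv(path, index_col="sample")


def write_counts(counts: pd.DataFrame, path):
    """Genes x samples integer count TSV."""
    write_tsv(counts, path, index_label="gene")


def read_counts(path) -> pd.DataFrame:
    return read_tsv(path, index_col="gene")


def write_phenotypes(lipids: pd.DataFrame, covariates: pd.DataFrame, path):
    write_tsv(lipids.join(covariates), path, index_label="sample")


def read_phenotypes(path) -> pd.DataFrame:
    return read_tsv(path, index_col="sample")


_SUMSTAT_COLS = {"chrom": "CHR", "pos": "POS", "id": "ID", "ea": "EA",
                 "oa": "OA", "eaf": "EAF", "beta": "BETA", "se": "SE",
                 "p": "P", "n": "N", "trait": "TRAIT", "gene": "GENE"}


def write_summary_stats(stats: pd.DataFrame, path):
    """GWAS summary-stats TSV with CHR, POS, ID, EA, OA, BETA, SE, P, N columns."""
    out = stats.rename(columns={k: v for k, v in _SUMSTAT_COLS.items()
                                if k in stats.columns})
    write_tsv(out, path)


def read_summary_stats(path) -> pd.DataFrame:
    df = read_tsv(path)
    inv = {v: k for k, v in _SUMSTAT_COLS.items()}
    return df.rename(columns={c: inv.get(c, c) for c in df.columns})


def write_vcf_dosages(dosages: pd.DataFrame, path, positions=None,
                      alleles=None):
    """Minimal VCF 4.2 with per-sample DS (dosage) FORMAT values."""
    samples = list(dosages.index)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, vid in enumerate(dosages.columns):
            chrom, pos = (positions or {}).get(vid, ("1", 2_000_000 * (j + 1)))
            ref, alt = (alleles or {}).get(vid, ("G", "A"))
            ds = "\t".join(f"{v:.3f}" for v in dosages[vid].to_numpy(float))
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tDS\t{ds}\n")
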