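"""Positional annotation of significant SNPs against a local gene interval file.

Gene intervals come from a user-supplied BED file (half-open, 0-based) and
are converted to 1-based closed coordinates to match SNP bp positions.  A
SNP inside a gene is reported as "within" (distance 0); otherwise the
nearest gene edge within ``max_distance`` is reported with a non-negative
distance and a side indicator (upstream = gene before the SNP, downstream
= gene after).  Equidistant genes are all reported.  Every input SNP keeps
at least one output row.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["read_bed_genes", "annotate_snps"]


def read_bed_genes(path) -> pd.DataFrame:
    """Gene intervals from BED (chrom, start, end, name[, score, strand]).

    Half-open 0-based BED coordinates are converted to 1-based closed
    (start+1 .. end) for comparison with SNP positions.
    """
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 4:
        raise ValueError("BED file needs at least chrom, start, end, name columns")
    genes = pd.DataFrame({
        "chrom": bed[0].astype(str),
        "start": bed[1].astype(int) + 1,
        "end": bed[2].astype(int),
        "gene_name": bed[3].astype(str),
        "strand": bed[5].astype(str) if bed.shape[1] > 5 else "+",
    })
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene interval with start > end after BED conversion")
    return genes


def annotate_snps(significant: pd.DataFrame, genes: pd.DataFrame,
                  max_distance: int = 1_000_000) -> pd.DataFrame:
    """Nearest-gene table for significant association rows.

    ``significant`` needs columns snp_id, chrom, pos (and optionally p);
    the output mirrors a per-SNP candidate-gene table: snp_id, chrom, pos,
    distance, relation ("within"/"nearby"/"none"), side, gene, p.
    """
    snp_chroms = set(significant["chrom"].astype(str))
    gene_chroms = set(genes["chrom"].astype(str))
    orphan = sorted(snp_chroms - gene_chroms)
    if orphan and not snp_chroms & gene_chroms:
        raise ValueError(f"chromosome labels do not match the gene file: {orphan}")

    rows = []
    for _, snp in significant.iterrows():
        sub = genes[genes["chrom"].astype(str) == str(snp["chrom"])]
        pos = int(snp["pos"])
        base = {"snp_id": snp["snp_id"], "chrom": snp["chrom"], "pos": pos,
                "p": snp.get("p", float("nan"))}
        if len(sub):
            inside = sub[(sub["start"] <= pos) & (pos <= sub["end"])]
        else:
            inside = sub
        if len(inside):
            for _, g in inside.iterrows():
                rows.append({**base, "distance": 0, "relation": "within",
                             "side": ".", "gene": g["gene_name"]})
            continue
        if len(sub):
            # distance to the nearest interval edge on either side
            dist = pd.concat([(sub["start"] - pos), (pos - sub["end"])], axis=1).max(axis=1)
            best = int(dist.min())
        else:
            best = max_distance + 1
        if best <= max_distance:
            for _, g in sub[dist == best].iterrows():
                side = "upstream" if g["end"] < pos else "downstream"
                rows.append({**base, "distance": best, "relation": "nearby",
                             "side": side, "gene": g["gene_name"]})
        else:
            rows.append({**base, "distance": pd.NA, "relation": "none",
                         "side": ".", "gene": pd.NA})
    return pd.DataFrame(rows)
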