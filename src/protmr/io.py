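"""Plain-text readers/writers for genotypes and summary statistics.

Genotypes go out as VCFv4.2 with a DS (dosage) FORMAT field or as a TSV
matrix; summary statistics use the screen's column vocabulary (snpid, rsid,
chr, pos, a1, a0, n, freq1, beta1, se, p, info, r2) with a ``# seed=`` header
comment so every artifact records the randomness that produced it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["write_dosage_vcf", "read_dosage_vcf", "write_summary_tsv", "read_summary_tsv"]


def write_dosage_vcf(dosages: np.ndarray, variants: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write an individuals-by-variants dosage matrix as a text VCF (DS field)."""
    n, m = dosages.shape
    samples = [f"S{i + 1}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if seed is not None:
            fh.write(f"##simulation_seed={seed}\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, (_, v) in enumerate(variants.iterrows()):
            ds = "\t".join(f"{x:g}" for x in dosages[:, j])
            # a1 is the effect (ALT) allele, a0 the reference
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['rsid']}\t{v['a0']}\t{v['a1']}\t.\t.\t"
                f"INFO={v.get('info', 1.0):g}\tDS\t{ds}\n"
            )


def read_dosage_vcf(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a DS-format dosage VCF back into (dosages, variants)."""
    rows, dosage_rows = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, rsid, ref, alt = f[0], int(f[1]), f[2], f[3], f[4]
            info = 1.0
            if f[7].startswith("INFO="):
                info = float(f[7][5:])
            rows.append({"chrom": int(chrom) if chrom.isdigit() else chrom,
                         "pos": pos, "rsid": rsid, "a1": alt, "a0": ref, "info": info})
            dosage_rows.append([float(x) for x in f[9:]])
    variants = pd.DataFrame(rows)
    return np.asarray(dosage_rows).T, variants


def write_summary_tsv(stats: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        stats.to_csv(fh, sep="\t", index=False)


def read_summary_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
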