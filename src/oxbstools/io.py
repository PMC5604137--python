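"""Plain-text readers and writers for the pipeline's file formats.

Matrices travel as TSV (probe rows, sample-id header); the probe manifest
is a BED-like TSV (0-based half-open on disk, 1-based positions in
memory); genotypes are read from a minimal VCF (GT field) or a 012 TSV;
regions are written as BED with a -log10 Sidak-p score.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class ParseError(ValueError):
    pass


def read_beta_tsv(path) -> pd.DataFrame:
    """Read a beta matrix; values must parse to [0, 1] (NA allowed)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    mat = df.apply(pd.to_numeric, errors="coerce")
    bad_token = mat.isna() & df.notna() & (df.astype(str) != "NA")
    if bad_token.any().any():
        r, c = np.argwhere(bad_token.to_numpy())[0]
        raise ParseError(f"non-numeric value at probe {df.index[r]}, "
                         f"sample {df.columns[c]} (line {r + 2})")
    out_of_range = (mat < 0) | (mat > 1)
    if out_of_range.any().any():
        r, c = np.argwhere(out_of_range.to_numpy())[0]
        raise ParseError(f"beta value {mat.iat[r, c]} outside [0, 1] at "
                         f"probe {mat.index[r]}, sample {mat.columns[c]} "
                         f"(line {r + 2})")
    return mat


def write_beta_tsv(matrix: pd.DataFrame, path, header: str | None = None):
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        matrix.to_csv(fh, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "dpc", "sex"}
    if not required <= set(df.columns):
        raise ParseError(f"sample sheet needs columns {sorted(required)}")
    return df


def read_manifest_bed(path) -> pd.DataFrame:
    """BED-like manifest -> in-memory manifest with 1-based positions."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "start" in df.columns:
        df["pos"] = df["start"].astype(int) + 1
    required = {"probe", "chrom", "pos"}
    if not required <= set(df.columns):
        raise ParseError(f"manifest needs columns {sorted(required)}")
    for col in ("strand", "feature", "cgi", "genes"):
        if col not in df.columns:
            df[col] = ""
    df["genes"] = df["genes"].fillna("")
    return df[["probe", "chrom", "pos", "strand", "feature", "cgi", "genes"]]


def read_genotypes_012(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.apply(pd.to_numeric, errors="coerce")


def read_genotypes_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Minimal VCF reader: returns (snps frame, dosage frame) from GT."""
    rows, dosages = [], []
    samples = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            if samples is None:
                raise ParseError("VCF header line missing")
            chrom, pos, snp = fields[0], int(fields[1]), fields[2]
            fmt = fields[8].split(":")
            gt_i = fmt.index("GT")
            row = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_i].replace("|", "/")
                if "." in gt:
                    row.append(np.nan)
                else:
                    row.append(float(sum(int(a) for a in gt.split("/"))))
            rows.append((snp, chrom, pos))
            dosages.append(row)
    snps = pd.DataFrame(rows, columns=["snp", "chrom", "pos"])
    dose = pd.DataFrame(dosages, index=snps["snp"], columns=samples)
    return snps, dose


def write_regions_bed(regions, path, parameters: dict | None = None):
    """Write regions as BED (0-based half-open), score = -log10(sidak_p)."""
    with open(path, "w") as fh:
        if parameters:
            params = " ".join(f"{k}={v}" for k, v in parameters.items())
            fh.write(f"# region calling: {params}\n")
        fh.write("# chrom\tstart\tend\tn_probes\tcombined_p\tsidak_p\t"
                 "score\tprobes\n")
        for r in regions:
            score = 300.0 if r.sidak_p <= 0 else min(
                -np.log10(r.sidak_p), 300.0)
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.n_probes}\t"
                     f"{r.combined_p:.6g}\t{r.sidak_p:.6g}\t{score:.3f}\t"
                     f"{','.join(r.probes)}\n")


def read_regions_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "n_probes",
                            "combined_p", "sidak_p", "score", "probes"])
    df["start"] = df["start"].astype(int) + 1  # back to 1-based inclusive
    return df


def read_blacklist(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines()
            if line.strip()}


def read_gmt(path) -> dict[str, set[str]]:
    """GMT pathway file -> gene -> pathway-set mapping."""
    gene_to_pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pw = parts[0]
            for g in parts[2:]:
                if g:
                    gene_to_pathways.setdefault(g, set()).add(pw)
    return gene_to_pathways
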