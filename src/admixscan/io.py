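"""Readers and writers for the pipeline's text formats.

Formats: panel TSV (snp_id, chrom, pos_bp, pos_cM, freq_A, freq_E, n_A,
n_E), sample x SNP dosage TSV, PLINK-style .ped/.map, phenotype TSV, and a
truth TSV of simulated European-allele counts. Coordinates are 1-based;
genetic positions are stored in cM. In .ped files the synthetic reference
allele is written as A and the variant allele as G for every marker, with
"0 0" for a missing call; allele codes outside the expected pair are an
error (no strand flipping is attempted).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MISSING
from .panel import PANEL_COLUMNS, AncestralPanel

REF_ALLELE = "A"
VAR_ALLELE = "G"


def write_panel(panel: AncestralPanel, path) -> None:
    panel.table.to_csv(path, sep="\t", index=False)


def read_panel(path) -> AncestralPanel:
    t = pd.read_csv(path, sep="\t")
    return AncestralPanel(t[PANEL_COLUMNS])


def write_dosage(genotypes: np.ndarray, sample_id, snp_id, path) -> None:
    df = pd.DataFrame(genotypes, columns=snp_id)
    df = df.astype(object).where(df >= 0, "NA")
    df.insert(0, "sample_id", sample_id)
    df.to_csv(path, sep="\t", index=False)


def read_dosage(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (genotypes int8 with -1 missing, sample ids, snp ids)."""
    df = pd.read_csv(path, sep="\t", na_values="NA")
    sample_id = df["sample_id"].to_numpy()
    snp_id = np.array(df.columns[1:])
    vals = df.iloc[:, 1:].to_numpy(float)
    bad = np.isfinite(vals) & ~np.isin(vals, (0, 1, 2))
    if bad.any():
        offenders = snp_id[bad.any(axis=0)].tolist()
        raise ValueError(f"dosage entries outside {{0,1,2,NA}} at SNPs: {offenders[:5]}")
    geno = np.where(np.isfinite(vals), vals, MISSING).astype(np.int8)
    return geno, sample_id, snp_id


def write_ped_map(genotypes: np.ndarray, sample_id, panel: AncestralPanel, prefix) -> None:
    """PLINK-style text output: <prefix>.ped and <prefix>.map."""
    prefix = Path(prefix)
    with open(f"{prefix}.map", "w") as fh:
        for c, sid, cm, bp in zip(panel.chrom, panel.snp_id, panel.pos_cM, panel.pos_bp):
            fh.write(f"{c}\t{sid}\t{cm:.6f}\t{bp}\n")
    allele_strings = {
        0: f"{REF_ALLELE} {REF_ALLELE}",
        1: f"{REF_ALLELE} {VAR_ALLELE}",
        2: f"{VAR_ALLELE} {VAR_ALLELE}",
        MISSING: "0 0",
    }
    with open(f"{prefix}.ped", "w") as fh:
        for i, sid in enumerate(sample_id):
            fields = [str(sid), str(sid), "0", "0", "0", "-9"]
            fields += [allele_strings[int(g)] for g in genotypes[i]]
            fh.write("\t".join(fields) + "\n")


def read_ped_map(prefix) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Returns (genotypes, sample ids, marker table with chrom/snp_id/pos_cM/pos_bp)."""
    prefix = Path(prefix)
    markers = pd.read_csv(
        f"{prefix}.map",
        sep="\t",
        header=None,
        names=["chrom", "snp_id", "pos_cM", "pos_bp"],
    )
    samples = []
    rows = []
    expected = {REF_ALLELE, VAR_ALLELE, "0"}
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            samples.append(parts[1])
            geno_fields = parts[6:]
            if len(geno_fields) != len(markers):
                raise ValueError(
                    f"sample {parts[1]}: {len(geno_fields)} genotypes for {len(markers)} markers"
                )
            row = np.empty(len(markers), dtype=np.int8)
            bad_snps = []
            for j, fieldpair in enumerate(geno_fields):
                a = fieldpair.split()
                if not set(a) <= expected:
                    bad_snps.append(markers["snp_id"].iloc[j])
                    continue
                if "0" in a:
                    row[j] = MISSING
                else:
                    row[j] = sum(x == VAR_ALLELE for x in a)
            if bad_snps:
                raise ValueError(f"allele codes inconsistent with panel at SNPs: {bad_snps[:5]}")
            rows.append(row)
    geno = np.vstack(rows) if rows else np.zeros((0, len(markers)), dtype=np.int8)
    return geno, np.array(samples), markers


def read_genotypes(path, format: str = "dosage_tsv"):
    """Dispatch reader: ``format`` in {"ped_map", "dosage_tsv"}.

    For ped_map, ``path`` is the file prefix. Markers keep file order; callers
    should align to the panel by snp_id.
    """
    if format == "dosage_tsv":
        geno, sample_id, snp_id = read_dosage(path)
        return geno, sample_id, pd.DataFrame({"snp_id": snp_id})
    if format == "ped_map":
        return read_ped_map(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(true_ancestry: np.ndarray, sample_id, snp_id, path) -> None:
    df = pd.DataFrame(true_ancestry, columns=snp_id)
    df.insert(0, "sample_id", sample_id)
    df.to_csv(path, sep="\t", index=False)


def read_truth(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return (
        df.iloc[:, 1:].to_numpy(np.int8),
        df["sample_id"].to_numpy(),
        np.array(df.columns[1:]),
    )
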