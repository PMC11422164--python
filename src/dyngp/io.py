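"""Readers, writers and sample alignment for the mapping tool.

Genotypes come from VCF (DS dosage field preferred over GT) or a TSV dosage
matrix (samples x variants, header of variant ids, first column sample ids).
Phenotypes, donor maps and state matrices are TSV keyed by sample id; counts
may also be MatrixMarket MTX with side-car gene/sample id files.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sparse_gp import DonorDesign

logger = logging.getLogger("dyngp")
if not logger.handlers:
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(h)
    logger.setLevel(logging.INFO)


@dataclass
class GenotypeSet:
    dosages: np.ndarray          # N x V in [0, 2]
    variant_ids: list
    sample_ids: list
    allele_freqs: np.ndarray

    @property
    def monomorphic(self) -> np.ndarray:
        return np.var(self.dosages, axis=0) == 0.0


def _finalize_genotypes(dos, variant_ids, sample_ids) -> GenotypeSet:
    dos = np.asarray(dos, dtype=float)
    # mean-impute missing dosages per variant; drop all-missing variants
    keep = []
    for j in range(dos.shape[1]):
        col = dos[:, j]
        miss = ~np.isfinite(col)
        if miss.all():
            logger.warning("variant %s has no called genotypes; dropped", variant_ids[j])
            continue
        if miss.any():
            col[miss] = col[~miss].mean()
        keep.append(j)
    dos = dos[:, keep]
    vids = [variant_ids[j] for j in keep]
    af = dos.mean(axis=0) / 2.0
    return GenotypeSet(dos, vids, list(sample_ids), af)


def read_genotypes_tsv(path) -> GenotypeSet:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return _finalize_genotypes(df.to_numpy(dtype=float), list(df.columns),
                               list(df.index.astype(str)))


def read_genotypes_vcf(path) -> GenotypeSet:
    """Read biallelic sites from a VCF; DS preferred, else GT (0/1 coding)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, vids = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic site %s:%s", var.CHROM, var.POS)
            continue
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        ds = None
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            col = np.where((gts < 0).any(axis=1), np.nan,
                           np.clip(gts, 0, 1).sum(axis=1)).astype(float)
        cols.append(col)
        vids.append(vid)
    if not cols:
        raise ValueError("no usable variants in VCF")
    return _finalize_genotypes(np.column_stack(cols), vids, samples)


def read_genotypes(path, fmt: str | None = None) -> GenotypeSet:
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    return read_genotypes_vcf(path) if fmt == "vcf" else read_genotypes_tsv(path)


def read_table(path, key: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if key is not None:
        df = df.set_index(key)
    else:
        df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df


def read_counts_mtx(mtx_path, sample_path, gene_path):
    """Counts from MatrixMarket (genes x cells or cells x genes + id files)."""
    from scipy.io import mmread

    M = np.asarray(mmread(str(mtx_path)).todense() if hasattr(mmread(str(mtx_path)), "todense") else mmread(str(mtx_path)))
    samples = [line.strip() for line in open(sample_path) if line.strip()]
    genes = [line.strip() for line in open(gene_path) if line.strip()]
    if M.shape == (len(genes), len(samples)):
        M = M.T
    if M.shape != (len(samples), len(genes)):
        raise ValueError("MTX shape does not match id files")
    return pd.DataFrame(M, index=samples, columns=genes)


@dataclass
class AlignedStudy:
    sample_ids: list
    phenotype: pd.DataFrame
    genotypes: GenotypeSet | None
    donor: DonorDesign | None
    states: np.ndarray | None
    dropped: dict


def align_study(pheno: pd.DataFrame, geno: GenotypeSet | None = None,
                donor_map: pd.Series | None = None,
                states: pd.DataFrame | None = None) -> AlignedStudy:
    """Intersect sample ids across inputs in deterministic sorted order."""
    sets = [set(map(str, pheno.index))]
    if geno is not None:
        sets.append(set(map(str, geno.sample_ids)))
    if donor_map is not None:
        sets.append(set(map(str, donor_map.index)))
    if states is not None:
        sets.append(set(map(str, states.index)))
    for ids in sets:
        pass
    if len(pheno.index) != len(set(pheno.index)):
        raise ValueError("duplicated sample ids in phenotype table")
    common = sorted(set.intersection(*sets))
    if not common:
        raise ValueError("no overlapping samples across inputs")
    dropped = {"phenotype": sorted(sets[0] - set(common))}
    for name, ids in zip(["genotypes", "donor", "states"], sets[1:]):
        dropped[name] = sorted(ids - set(common))
    for name, lost in dropped.items():
        if lost:
            logger.info("dropped %d sample(s) absent elsewhere from %s", len(lost), name)
    pheno_a = pheno.loc[common]
    geno_a = None
    if geno is not None:
        order = [geno.sample_ids.index(s) for s in common]
        geno_a = GenotypeSet(geno.dosages[order], geno.variant_ids, common,
                             geno.dosages[order].mean(axis=0) / 2.0)
    donor_a = None
    if donor_map is not None:
        donor_a = DonorDesign.from_assignment(donor_map.loc[common].to_numpy())
    states_a = states.loc[common].to_numpy(dtype=float) if states is not None else None
    return AlignedStudy(common, pheno_a, geno_a, donor_a, states_a, dropped)


def write_tsv(df: pd.DataFrame, path, index: bool = True):
    df.to_csv(path, sep="\t", index=index, float_format="%.15g")
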