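"""File handling and the per-SNP association workflow on real data.

Phenotypes and covariates are delimited tables (TSV or CSV) with a header
row whose first column holds individual IDs.  Genotypes come either from a
VCF (dosage taken from the GT field, oriented to count the minor allele) or
from a delimited 0/1/2 matrix with individuals as rows and SNPs as columns.
All statistics are pure functions of in-memory arrays; this module only
reads, aligns and writes.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .stats import permutation_pvalue, score_statistic
from .transforms import apply_method, residualize

__all__ = [
    "read_table",
    "read_genotype_matrix",
    "iter_vcf_genotypes",
    "iter_genotypes",
    "write_dataset",
    "test_snps",
]

logger = logging.getLogger("atemp")


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_table(path) -> pd.DataFrame:
    """Read a phenotype or covariate table; first column is individual ID."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no data columns after the ID column")
    return df


def read_genotype_matrix(path) -> pd.DataFrame:
    """Read a delimited genotype matrix (rows: individuals, columns: SNPs).

    Entries are minor-allele counts 0/1/2; blanks or NA are treated as
    missing genotypes.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def iter_vcf_genotypes(path) -> Iterator[tuple[str, pd.Series]]:
    """Yield (snp_id, dosage series) per variant of a VCF.

    Dosage counts the minor allele: per variant the less frequent observed
    allele is counted, with a tie at frequency 0.5 resolved toward ALT.
    Missing genotypes become NaN.  Multi-allelic sites are skipped with a
    warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = [str(s) for s in vcf.samples]
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        if len(variant.ALT) != 1:
            logger.warning("skipping multi-allelic variant %s", vid)
            continue
        dosage = np.asarray(variant.gt_types, dtype=float)  # 0/1/2, 3=missing
        dosage[dosage == 3] = np.nan
        alt_freq = np.nanmean(dosage) / 2.0 if np.isfinite(dosage).any() else 0.0
        if alt_freq > 0.5:  # ALT is the major allele: count REF instead
            dosage = 2.0 - dosage
        yield vid, pd.Series(dosage, index=samples)


def iter_genotypes(source) -> Iterator[tuple[str, pd.Series]]:
    """Yield (snp_id, dosage series) from a VCF or a genotype matrix file."""
    if str(source).endswith((".vcf", ".vcf.gz")):
        yield from iter_vcf_genotypes(source)
    else:
        geno = read_genotype_matrix(source)
        for snp in geno.columns:
            yield str(snp), geno[snp]


def write_dataset(genotype, phenotypes, prefix,
                  phenotype_names=None, snp_name: str = "snp1") -> tuple[Path, Path]:
    """Write a simulated cohort as paired phenotype + genotype TSV files.

    Returns the (phenotype_path, genotype_path) pair, named
    ``{prefix}.phen.tsv`` and ``{prefix}.geno.tsv``.
    """
    prefix = Path(prefix)
    y = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    if y.shape[0] == 1 and np.asarray(genotype).size != 1:
        y = y.T
    ids = [f"ind{i + 1}" for i in range(y.shape[0])]
    names = (list(phenotype_names) if phenotype_names is not None
             else [f"pheno{k + 1}" for k in range(y.shape[1])])
    phen_path = prefix.with_suffix(".phen.tsv")
    geno_path = prefix.with_suffix(".geno.tsv")
    pd.DataFrame(y, index=pd.Index(ids, name="iid"), columns=names) \
        .to_csv(phen_path, sep="\t")
    pd.DataFrame({snp_name: np.asarray(genotype, dtype=int)},
                 index=pd.Index(ids, name="iid")).to_csv(geno_path, sep="\t")
    return phen_path, geno_path


def test_snps(phenotype_file, genotype_source, covariate_file=None,
              method: str = "multiphen", permutations: Optional[int] = None,
              seed: int = 0, out_file=None) -> pd.DataFrame:
    """Test every SNP in ``genotype_source`` against all phenotypes jointly.

    Per SNP the workflow is: align individuals by ID across files, drop
    individuals with a missing genotype or any missing phenotype/covariate
    (listwise, independently per SNP), residualize phenotypes on covariates,
    apply the chosen transform, compute the score statistic, and report the
    asymptotic chi-square p-value.  A Bonferroni-adjusted p-value over the m
    SNPs actually tested is appended.  Monomorphic SNPs are skipped with a
    warning.

    Returns
    -------
    pandas.DataFrame
        One row per tested SNP with columns snp, maf, n_used, statistic,
        df, p_value, (p_permutation,) p_bonferroni; also written to
        ``out_file`` as TSV if given.
    """
    phen = read_table(phenotype_file)
    covar = read_table(covariate_file) if covariate_file is not None else None

    rows = []
    for snp, dosage in iter_genotypes(genotype_source):
        dosage = dosage.dropna()
        ids = phen.index.intersection(dosage.index)
        if covar is not None:
            ids = ids.intersection(covar.index)
        if len(ids) == 0:
            raise ValueError(
                f"{snp}: no overlapping individual IDs between genotype "
                "and phenotype/covariate files"
            )
        y = phen.loc[ids]
        keep = y.notna().all(axis=1)
        x = None
        if covar is not None:
            x = covar.loc[ids]
            keep &= x.notna().all(axis=1)
        ids = ids[keep.to_numpy()]
        if len(ids) < 2:
            logger.warning("skipping %s: fewer than 2 complete individuals", snp)
            continue
        g = dosage.loc[ids].to_numpy()
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError(f"{snp}: genotype values outside 0/1/2")
        g = g.astype(int)
        if np.unique(g).size < 2:
            logger.warning("skipping %s: monomorphic in the analysed sample", snp)
            continue

        values = phen.loc[ids].to_numpy(dtype=float)
        if x is not None:
            values = residualize(values, covar.loc[ids].to_numpy(dtype=float))
        values = apply_method(values, method)

        if permutations:
            res = permutation_pvalue(values, g, n_permutations=permutations,
                                     seed=seed, method=method)
        else:
            res = score_statistic(values, g, method=method)
        maf = float(g.mean() / 2.0)
        rows.append({
            "snp": snp,
            "maf": min(maf, 1.0 - maf),
            "n_used": res.n_used,
            "statistic": res.statistic,
            "df": res.df,
            "p_value": res.p_asymptotic,
            **({"p_permutation": res.p_permutation} if permutations else {}),
        })

    result = pd.DataFrame(rows)
    if len(result):
        m = len(result)
        result["p_bonferroni"] = np.minimum(1.0, result["p_value"] * m)
    if out_file is not None:
        result.to_csv(out_file, sep="\t", index=False)
    return result
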