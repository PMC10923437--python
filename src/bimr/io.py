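"""Cohort file ingestion and export.

On disk a cohort is a tab-delimited phenotype table (sample id column first,
then ``y1``/``y2`` and any covariates) plus one dosage table per instrument
set (sample id column first, instruments as columns with header IDs).
Dosages may also be pulled from a VCF (GT allele counts, or the DS dosage
field when present).
"""

from __future__ import annotations

import pathlib
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import Dataset, ValidationError, validate_dataset

__all__ = ["write_cohort", "read_cohort", "read_vcf_dosages"]

SAMPLE_COL = "sample_id"


def write_cohort(data: Dataset, directory, prefix: str = "cohort") -> Dict[str, pathlib.Path]:
    """Write a Dataset as TSV tables; returns the written paths.

    Produces ``<prefix>.phenotypes.tsv`` (y1, y2, covariates, confounder when
    present) and ``<prefix>.dosages1.tsv`` / ``<prefix>.dosages2.tsv``.
    """
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = data.n
    samples = list(data.sample_ids) if data.sample_ids is not None else [
        f"S{i:06d}" for i in range(n)
    ]
    pheno = pd.DataFrame({SAMPLE_COL: samples, "y1": data.y1, "y2": data.y2})
    if data.covariates is not None:
        cov = np.atleast_2d(data.covariates)
        for j in range(cov.shape[1]):
            pheno[f"cov{j + 1}"] = cov[:, j]
    if data.confounder is not None:
        pheno["confounder"] = data.confounder
    paths = {"phenotypes": directory / f"{prefix}.phenotypes.tsv"}
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False)
    for tag, X, ids in (
        ("dosages1", data.X1, data.instrument_ids_1),
        ("dosages2", data.X2, data.instrument_ids_2),
    ):
        k = X.shape[1]
        names = list(ids) if ids is not None else [
            f"snp{tag[-1]}_{j + 1}" for j in range(k)
        ]
        table = pd.DataFrame(X, columns=names)
        table.insert(0, SAMPLE_COL, samples)
        paths[tag] = directory / f"{prefix}.{tag}.tsv"
        table.to_csv(paths[tag], sep="\t", index=False)
    return paths


def _read_indexed(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    if table.shape[1] < 2:
        raise ValidationError(f"{path}: expected a sample-id column plus data columns")
    return table.set_index(table.columns[0])


def read_cohort(
    phenotype_path,
    dosage_paths: Sequence,
    instruments_1: Sequence[str],
    instruments_2: Sequence[str],
    covariate_columns: Optional[Sequence[str]] = None,
) -> Dataset:
    """Load and align a cohort from delimited tables.

    Instrument columns found across the dosage files are partitioned into the
    trait-1 and trait-2 sets by the two id lists; every dosage column must be
    assigned to exactly one set.  Sample rows are realigned by identifier; a
    sample present in one file but not another is an error.
    """
    overlap = set(instruments_1) & set(instruments_2)
    if overlap:
        raise ValidationError(
            f"instruments assigned to both traits: {sorted(overlap)} "
            "(violates the exclusion restriction by construction)"
        )
    pheno = _read_indexed(phenotype_path)
    for col in ("y1", "y2"):
        if col not in pheno.columns:
            raise ValidationError(f"phenotype table missing column {col!r}")
    dosages = [_read_indexed(p) for p in dosage_paths]
    all_dosage = pd.concat(dosages, axis=1, join="outer")
    ref = set(pheno.index)
    for path, table in zip(dosage_paths, dosages):
        missing = ref - set(table.index)
        extra = set(table.index) - ref
        if missing or extra:
            raise ValidationError(
                f"{path}: sample mismatch; missing={sorted(missing)[:5]} "
                f"extra={sorted(extra)[:5]}"
            )
    all_dosage = all_dosage.loc[pheno.index]
    known = set(instruments_1) | set(instruments_2)
    unassigned = [c for c in all_dosage.columns if c not in known]
    if unassigned:
        raise ValidationError(f"unassigned instrument columns: {unassigned[:10]}")
    absent = [c for c in known if c not in all_dosage.columns]
    if absent:
        raise ValidationError(f"assigned instruments absent from dosage files: {absent[:10]}")
    covariates = None
    if covariate_columns:
        bad = [c for c in covariate_columns if c not in pheno.columns]
        if bad:
            raise ValidationError(f"covariate columns not in phenotype table: {bad}")
        covariates = pheno[list(covariate_columns)].to_numpy(dtype=float)
    confounder = (
        pheno["confounder"].to_numpy(dtype=float)
        if "confounder" in pheno.columns
        else None
    )
    data = Dataset(
        y1=pheno["y1"].to_numpy(dtype=float),
        y2=pheno["y2"].to_numpy(dtype=float),
        X1=all_dosage[list(instruments_1)].to_numpy(dtype=float),
        X2=all_dosage[list(instruments_2)].to_numpy(dtype=float),
        covariates=covariates,
        confounder=confounder,
        instrument_ids_1=list(instruments_1),
        instrument_ids_2=list(instruments_2),
        sample_ids=list(pheno.index.astype(str)),
    )
    return validate_dataset(data)


def read_vcf_dosages(
    vcf_path,
    variant_ids: Sequence[str],
    impute_missing: bool = False,
) -> Tuple[np.ndarray, List[str]]:
    """Dosage matrix for the requested variant IDs from a VCF.

    Uses the DS FORMAT field when a record carries one, otherwise counts
    alternate alleles from GT.  Missing genotypes raise an error naming the
    site unless ``impute_missing`` is set, in which case they are replaced by
    the variant's mean dosage.  Columns follow the order of ``variant_ids``.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    wanted = {vid: j for j, vid in enumerate(variant_ids)}
    if len(wanted) != len(variant_ids):
        raise ValidationError("duplicate variant ids requested")
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    cols: Dict[str, np.ndarray] = {}
    for variant in vcf:
        vid = variant.ID
        if vid not in wanted or vid in cols:
            continue
        ds = variant.format("DS") if "DS" in (variant.FORMAT or []) else None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(len(samples), -1)[:, 0]
            miss = ~np.isfinite(dose)
        else:
            gts = np.array([g[:2] for g in variant.genotypes], dtype=float)
            miss = np.any(gts < 0, axis=1)
            dose = np.where(gts > 0, 1.0, 0.0).sum(axis=1)
        if miss.any():
            if not impute_missing:
                raise ValidationError(
                    f"missing genotypes at {vid} ({variant.CHROM}:{variant.POS}) "
                    f"for samples {[samples[i] for i in np.where(miss)[0][:5]]}"
                )
            dose = dose.astype(float)
            dose[miss] = dose[~miss].mean() if (~miss).any() else 0.0
        cols[vid] = dose
    absent = [v for v in variant_ids if v not in cols]
    if absent:
        raise ValidationError(f"variant ids not found in VCF: {absent[:10]}")
    matrix = np.column_stack([cols[v] for v in variant_ids])
    return matrix, samples
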