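"""Weighted-allele genetic risk score (GRS) for LDL cholesterol.

The score for a patient is the sum over SNPs of effect-allele dosage
(0, 1 or 2) times the per-allele effect size beta (mg/dL).  Missing
dosages are mean-imputed as 2 x maf (the Hardy-Weinberg expectation);
SNPs present in the weight table but absent from the genotypes are skipped
with a warning.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError

log = logging.getLogger(__name__)

WEIGHT_COLUMNS = ("rsid", "effect_allele", "beta", "maf")


def read_weights(path: str | Path) -> pd.DataFrame:
    """Read a SNP weight CSV with columns rsid, effect_allele, beta, maf."""
    w = pd.read_csv(path)
    missing = [c for c in WEIGHT_COLUMNS if c not in w.columns]
    if missing:
        raise ParameterError(f"weight table missing columns {missing}")
    if w["rsid"].duplicated().any():
        raise ParameterError("weight table has duplicate rsids")
    if not np.isfinite(w["beta"]).all():
        raise ParameterError("weight table has non-finite betas")
    if ((w["maf"] <= 0) | (w["maf"] > 0.5)).any():
        raise ParameterError("maf must lie in (0, 0.5]")
    return w


def compute_grs(genotypes: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Per-patient weighted allele score.

    ``genotypes``: patient x SNP dosage matrix (index patient_id, columns
    rsids, values in [0, 2] or NaN).  Returns a DataFrame with columns
    patient_id, grs, n_snps_used (count of non-missing SNPs entering the
    raw sum).
    """
    present = weights["rsid"].isin(genotypes.columns)
    skipped = weights.loc[~present, "rsid"].tolist()
    if skipped:
        warnings.warn(
            f"{len(skipped)} weight-table SNP(s) absent from genotypes, "
            f"skipped: {skipped[:5]}...",
            stacklevel=2,
        )
    used = weights[present]
    if not len(used):
        raise ParameterError("no weight-table SNP present in the genotypes")

    dosage = genotypes[used["rsid"].tolist()].to_numpy(float)
    if np.nanmin(dosage, initial=0) < 0 or np.nanmax(dosage, initial=0) > 2:
        raise ParameterError("dosages must lie in [0, 2]")
    beta = used["beta"].to_numpy(float)
    maf = used["maf"].to_numpy(float)
    missing = np.isnan(dosage)
    imputed = np.where(missing, 2.0 * maf, dosage)
    grs = imputed @ beta
    n_used = (~missing).sum(axis=1)
    return pd.DataFrame(
        {
            "patient_id": genotypes.index.to_numpy(),
            "grs": grs,
            "n_snps_used": n_used,
        }
    )


def read_genotypes_vcf(path: str | Path, weights: pd.DataFrame) -> pd.DataFrame:
    """Read effect-allele dosages from a VCF (GT field) for the weight SNPs.

    Dosage counts the weight table's effect allele: when the effect allele
    is the VCF REF allele the ALT count is flipped (2 - d).  Missing
    genotypes become NaN.  Requires cyvcf2.
    """
    from cyvcf2 import VCF

    by_id = weights.set_index("rsid")
    rows: dict[str, np.ndarray] = {}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for variant in vcf:
        rsid = variant.ID
        if rsid not in by_id.index:
            continue
        effect = str(by_id.loc[rsid, "effect_allele"]).upper()
        gts = np.asarray(variant.gt_types, dtype=float)  # 0 hom-ref,1 het,3 hom-alt
        dosage = np.select([gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], np.nan)
        if effect == str(variant.REF).upper():
            dosage = 2.0 - dosage
        elif variant.ALT and effect != str(variant.ALT[0]).upper():
            log.warning("rsid %s: effect allele %s matches neither REF nor ALT",
                        rsid, effect)
            continue
        rows[rsid] = dosage
    geno = pd.DataFrame(rows, index=pd.Index(samples, name="patient_id"))
    return geno


def validate_grs(scores: pd.DataFrame, measured_ldl: pd.Series) -> dict:
    """Correlate the GRS with measured baseline LDL on the patient overlap.

    Returns ``{"r": Pearson r, "r2": r^2, "p": two-sided p, "n": overlap}``.
    Raises :class:`ValidationError` with fewer than 3 overlapping patients.
    """
    s = scores.set_index("patient_id")["grs"]
    overlap = s.index.intersection(measured_ldl.index)
    if len(overlap) < 3:
        raise ValidationError(
            f"need >= 3 overlapping patients to validate, got {len(overlap)}"
        )
    x = s.loc[overlap].to_numpy(float)
    y = measured_ldl.loc[overlap].to_numpy(float)
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return {"r": r, "r2": r * r, "p": float(res.pvalue), "n": int(len(overlap))}
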