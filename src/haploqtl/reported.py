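"""Published QTL summaries for the soybean reflectance-trait panel.

The package bundles the reported per-locus QTL tables for NDVI and CHL in
the 341-accession Chinese soybean germplasm panel (38 NDVI loci with 89
alleles; 32 CHL loci with 82 alleles), together with the reported trait
heritabilities.  They serve as reference inputs for arithmetic consistency
checks: per-locus contributions are additive under the sequential R^2
decomposition, so the printed columns must reproduce the printed totals, and
heritability minus the summed QTL R^2 gives the undetected share of the
genetic variance.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: reported broad heritability of the accession means, percent
HERITABILITY_PCT = {"NDVI": 78.3, "CHL": 69.2}

#: reported panel composition
SUBPOP_SIZES = {"WA": 76, "LR": 83, "RC": 182}

#: threshold separating large- from small-contribution loci (percent PV)
LARGE_R2_PCT = 1.0


def qtl_summary(trait: str) -> pd.DataFrame:
    """Reported per-locus table for ``trait`` ("NDVI" or "CHL"): locus name,
    allele count, -lg P and R^2 (percent of phenotypic variance)."""
    trait = trait.upper()
    if trait not in ("NDVI", "CHL"):
        raise ValueError(f"unknown trait {trait!r}")
    name = f"qtl_summary_{trait.lower()}.tsv"
    with resources.files("haploqtl.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def r2_breakdown(table: pd.DataFrame) -> dict[str, float]:
    """Additivity summary of a per-locus QTL table.

    Returns the total R^2, the totals over large (R^2 >= 1%) and small
    contributors, their locus counts, and the allele-count sum — the
    quantities whose additivity the sequential decomposition guarantees.
    """
    r2 = table["r2_pct"]
    large = r2 >= LARGE_R2_PCT
    return {
        "total_r2_pct": round(float(r2.sum()), 2),
        "large_r2_pct": round(float(r2[large].sum()), 2),
        "small_r2_pct": round(float(r2[~large].sum()), 2),
        "n_loci": int(len(table)),
        "n_large": int(large.sum()),
        "n_small": int((~large).sum()),
        "n_alleles": int(table["n_alleles"].sum()),
    }


def undetected_variance_pct(trait: str) -> float:
    """Heritability minus total detected QTL R^2 (percent): the share of
    genetic variance attributable to unmapped loci."""
    table = qtl_summary(trait)
    return round(HERITABILITY_PCT[trait.upper()] - float(table["r2_pct"].sum()), 2)
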