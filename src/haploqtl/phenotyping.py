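"""Spectral-index computation, block adjustment, heritability, summaries.

The two traits handled here are canopy-level spectral reflectance indices:

* NDVI, the normalized difference vegetation index,
  ``(R_NIR - R_red) / (R_NIR + R_red)``, a unitless greenness proxy strictly
  inside (-1, 1) for positive reflectances;
* CHL, a red-edge chlorophyll index computed from reciprocal reflectances,
  ``1/R_700 - 1/R_NIR``.  The reciprocal-difference form is the member of the
  red-edge chlorophyll index family consistent with the observed CHL scale
  (roughly 1.2-4.8 for soybean canopies).

Phenotypes come from a randomized incomplete block design with two
replicates.  Plot values are adjusted under the equal-block-mean assumption
(each block's mean is shifted onto the grand mean), after which the design is
analysed as completely randomized: ``y_i = mu + g_i + eps_i``.  Variance
components use balanced one-way ANOVA moments, which coincide with REML for
the balanced nonnegative case, and heritability is
``h2 = sigma_g^2 / (sigma_g^2 + sigma^2 / r)`` with ``r`` replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd


class PhenotypeError(ValueError):
    """Raised for degenerate phenotype layouts (empty blocks, r = 1, ...)."""


@dataclass(frozen=True)
class ReflectanceRecord:
    """Per-plot band reflectances, each strictly positive (and at most 1)."""

    r_nir: float
    r_red: float
    r_700: float


@dataclass
class VarianceModel:
    """One-way random-effects fit of accession means: y_i = mu + g_i + eps_i."""

    mu: float
    g: pd.Series            # per-accession genotypic effect (BLUE deviations)
    sigma2_g: float
    sigma2_e: float
    r: int

    @property
    def h2(self) -> float:
        denom = self.sigma2_g + self.sigma2_e / self.r
        return 0.0 if denom == 0 else self.sigma2_g / denom


# ---------------------------------------------------------------------------
# spectral indices
# ---------------------------------------------------------------------------

def compute_ndvi(rec: ReflectanceRecord) -> float:
    """NDVI = (R_NIR - R_red) / (R_NIR + R_red)."""
    denom = rec.r_nir + rec.r_red
    if denom <= 0:
        raise PhenotypeError("NDVI undefined: R_NIR + R_red must be positive")
    return (rec.r_nir - rec.r_red) / denom


def compute_chl(rec: ReflectanceRecord) -> float:
    """CHL = 1/R_700 - 1/R_NIR (reciprocal red-edge chlorophyll index)."""
    if rec.r_700 <= 0 or rec.r_nir <= 0:
        raise PhenotypeError("CHL undefined: reflectances must be positive")
    return 1.0 / rec.r_700 - 1.0 / rec.r_nir


# ---------------------------------------------------------------------------
# block adjustment and variance components
# ---------------------------------------------------------------------------

def adjust_block_means(table: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Adjust plot values under the equal-block-mean assumption.

    Each observation is shifted by (its block mean - grand mean), so every
    block mean of the adjusted data equals the grand mean and the experiment
    can be analysed as completely randomized.  The adjustment is global
    (blocks from both replicates and both experiment groups are centred to the
    same grand mean), which also removes any group-environment shift.
    """
    if "block" not in table.columns:
        raise PhenotypeError("phenotype table must have a 'block' column")
    sizes = table.groupby("block", observed=True)[value_col].size()
    if (sizes == 0).any():
        raise PhenotypeError("every block must contain at least one plot")
    out = table.copy()
    grand = out[value_col].mean()
    block_means = out.groupby("block", observed=True)[value_col].transform("mean")
    out[value_col] = out[value_col] - (block_means - grand)
    return out


def estimate_components(
    table: pd.DataFrame,
    value_col: str = "value",
    min_replicates: int | None = None,
) -> VarianceModel:
    """Estimate (sigma_g^2, sigma^2) by balanced one-way ANOVA moments.

    ``sigma^2 = MS_error`` and ``sigma_g^2 = max(0, (MS_accession -
    MS_error)/r)``; for the balanced design with nonnegative components this
    is identical to the REML solution.  Accessions observed in fewer than
    ``min_replicates`` replicates (default: the panel's modal replicate
    count) are dropped, mirroring how incomplete entries are handled in
    replicated germplasm trials.
    """
    wide = table.pivot_table(index="accession_id", columns="replicate",
                             values=value_col, aggfunc="mean", observed=True)
    r_full = wide.shape[1]
    if r_full < 2:
        raise PhenotypeError(
            "variance components need r >= 2 replicates; got r = 1"
        )
    if min_replicates is None:
        min_replicates = r_full
    wide = wide.dropna(thresh=min_replicates).dropna(axis=0)
    n_acc = wide.shape[0]
    if n_acc < 2:
        raise PhenotypeError("variance components need at least 2 accessions")
    values = wide.to_numpy()
    r = values.shape[1]
    acc_means = values.mean(axis=1)
    grand = values.mean()
    ss_acc = r * ((acc_means - grand) ** 2).sum()
    ms_acc = ss_acc / (n_acc - 1)
    ss_err = ((values - acc_means[:, None]) ** 2).sum()
    ms_err = ss_err / (n_acc * (r - 1))
    sigma2_g = max(0.0, (ms_acc - ms_err) / r)
    g = pd.Series(acc_means - grand, index=wide.index, name="g")
    return VarianceModel(mu=float(grand), g=g, sigma2_g=float(sigma2_g),
                         sigma2_e=float(ms_err), r=r)


def heritability_by_timepoint(
    table: pd.DataFrame, value_col: str = "value", adjust: bool = True
) -> list[float]:
    """Per-time-point heritability estimates (block-adjusted by default)."""
    out = []
    for t in sorted(table["timepoint"].unique()):
        sub = table[table["timepoint"] == t]
        if adjust:
            sub = adjust_block_means(sub, value_col)
        out.append(estimate_components(sub, value_col).h2)
    return out


def select_best_measurement(per_timepoint_h2: Sequence[float]) -> int:
    """Index of the measurement with the highest heritability (earliest wins
    ties) — that single measurement represents the trait downstream."""
    h2 = list(per_timepoint_h2)
    if not h2:
        raise PhenotypeError("need at least one time point")
    return int(np.argmax(h2))


def accession_means(
    table: pd.DataFrame, timepoint: int, value_col: str = "value"
) -> pd.Series:
    """Block-adjusted accession means at one time point: the balanced-design
    sufficient statistic handed to the association scan."""
    sub = table[table["timepoint"] == timepoint]
    adj = adjust_block_means(sub, value_col)
    return adj.groupby("accession_id", observed=True)[value_col].mean()


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def distribution_summary(
    values: pd.Series,
    labels: pd.Series,
    midpoints: Sequence[float],
) -> pd.DataFrame:
    """Frequency table over bins centred on ``midpoints``.

    The first and last bins are open-ended (everything at or below the first
    midpoint's upper edge, everything at or above the last midpoint's lower
    edge), so the bins always cover the data.  Rows are the entire population
    followed by each group; columns are per-bin counts plus N, mean and range.
    """
    midpoints = np.asarray(midpoints, dtype=float)
    if len(midpoints) < 2 or (np.diff(midpoints) <= 0).any():
        raise PhenotypeError("midpoints must be increasing and at least two")
    inner = (midpoints[:-1] + midpoints[1:]) / 2
    edges = np.concatenate([[-np.inf], inner, [np.inf]])
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if np.isnan(values).any():
        raise PhenotypeError("values contain NaN, which falls in no bin")

    def row(name, v):
        counts = np.histogram(v, bins=edges)[0]
        return {
            "group": name,
            **{f"bin_{m:g}": int(c) for m, c in zip(midpoints, counts)},
            "N": len(v),
            "mean": float(np.mean(v)) if len(v) else np.nan,
            "min": float(np.min(v)) if len(v) else np.nan,
            "max": float(np.max(v)) if len(v) else np.nan,
        }

    rows = [row("Entire", values)]
    for grp in pd.unique(labels):
        rows.append(row(grp, values[labels == grp]))
    return pd.DataFrame(rows)


def compare_subpopulations(
    values: pd.Series,
    labels: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group means with compact significance letters.

    One-way ANOVA across groups followed by all-pairs Tukey HSD at ``alpha``;
    groups that share no letter differ significantly.  Letters are assigned by
    the usual insert-and-absorb display: groups are processed in order of
    ascending mean and join an existing letter class only if not significantly
    different from every member.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    labels = pd.Series(np.asarray(labels))
    groups = labels.unique().tolist()
    if len(groups) < 2:
        raise PhenotypeError("need at least two groups to compare")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        raise PhenotypeError("every group needs at least two members")

    tukey = pairwise_tukeyhsd(values.to_numpy(), labels.to_numpy(), alpha=alpha)
    res = pd.DataFrame(tukey.summary().data[1:], columns=tukey.summary().data[0])
    differ = {}
    for _, r in res.iterrows():
        pair = frozenset((str(r["group1"]), str(r["group2"])))
        differ[pair] = bool(r["reject"])

    means = values.groupby(labels.to_numpy()).mean()
    ordered = means.sort_values().index.tolist()
    classes: list[set] = []
    for g in ordered:
        placed = False
        for cls in classes:
            if all(not differ[frozenset((g, other))] for other in cls):
                cls.add(g)
                placed = True
        if not placed:
            classes.append({g})
    letters = {g: "" for g in ordered}
    for i, cls in enumerate(classes):
        for g in cls:
            letters[g] += chr(ord("a") + i)
    return pd.DataFrame({
        "group": ordered,
        "mean": [float(means[g]) for g in ordered],
        "n": [int(sizes[g]) for g in ordered],
        "letters": [letters[g] for g in ordered],
    })
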