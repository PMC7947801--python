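"""In-silico cross prediction of recombination potential.

For each candidate biparental cross the module derives a population of fully
homozygous inbred progeny lines under a linkage model, predicts each line's
phenotype as the population mean plus the sum of its carried QTL-allele
effects, and summarises the cross by percentiles of the predicted progeny
distribution — the 99th percentile being the cross's recombination
potential (the attainable level of transgressive segregation).

Linkage model: physical distance between adjacent loci is converted to map
distance at a constant rate (default 2.2 cM/Mb, approximately the soybean
genome-wide average), the Haldane map function gives the meiotic
recombination fraction r, and the recombinant-inbred-line-at-fixation
correction R = 2r/(1 + 2r) gives the switch probability of the two-state
parental-origin Markov chain along each chromosome.  Chromosomes segregate
independently and the origin of the first locus on each chromosome is a fair
coin flip.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .allele_matrix import QtlAlleleMatrix


class CrossError(ValueError):
    pass


@dataclass
class GeneticMapConfig:
    """Constant-rate physical-to-genetic map conversion."""

    cm_per_mb: float = 2.2

    def __post_init__(self) -> None:
        if self.cm_per_mb <= 0:
            raise CrossError("cM/Mb rate must be positive")

    def switch_probabilities(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """RIL switch probability between consecutive loci (0 across
        chromosome boundaries is handled by the caller)."""
        d_morgan = np.diff(pos) * self.cm_per_mb / 1e6 / 100.0
        r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
        return 2.0 * r / (1.0 + 2.0 * r)


@dataclass
class CrossPrediction:
    """Predicted progeny summary for one parent pair."""

    parent_a: str
    parent_b: str
    n_progeny: int
    p50: float
    p99: float
    progeny_mean: float

    def __post_init__(self) -> None:
        if self.p99 < self.p50:
            raise CrossError("P99 below P50: percentile computation broken")


# ---------------------------------------------------------------------------

def enumerate_crosses(
    accessions: Sequence[str],
    mode: str = "all",
    group_a: Optional[Sequence[str]] = None,
    group_b: Optional[Sequence[str]] = None,
) -> list[tuple[str, str]]:
    """All candidate single crosses, deterministically ordered.

    ``all``/``within-group``: the n(n-1)/2 unordered pairs of ``accessions``
    (pass the group members as ``accessions`` for a within-group set);
    ``between-groups``: the |A| x |B| pairs between two disjoint groups.
    """
    if mode in ("all", "within-group"):
        if len(accessions) < 2:
            raise CrossError("need at least two accessions to cross")
        return list(combinations(accessions, 2))
    if mode == "between-groups":
        if group_a is None or group_b is None:
            raise CrossError("between-groups mode needs both groups")
        if set(group_a) & set(group_b):
            raise CrossError("between-groups mode needs disjoint groups")
        return [(a, b) for a in group_a for b in group_b]
    raise CrossError(f"unknown cross enumeration mode: {mode}")


def simulate_derived_lines(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    map_config: GeneticMapConfig = GeneticMapConfig(),
    n: int = 2000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Derive ``n`` fully homozygous inbred lines from a biparental cross.

    Parents are allele-code vectors over the ordered loci; the result is an
    ``(n, n_loci)`` array of progeny allele codes.  Loci where the parents
    share an allele are monomorphic in the progeny.
    """
    parent_a = np.asarray(parent_a)
    parent_b = np.asarray(parent_b)
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    m = len(pos)
    if not (len(parent_a) == len(parent_b) == len(chrom) == m):
        raise CrossError("parents, chromosomes and positions must align")
    for c in np.unique(chrom):
        p = pos[chrom == c]
        # ties allowed: completely linked loci sit at distance zero
        if len(p) > 1 and not (np.diff(p) >= 0).all():
            raise CrossError("loci must be sorted by chromosome and position")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    switch = map_config.switch_probabilities(chrom, pos)
    new_chrom = np.concatenate([[True], chrom[1:] != chrom[:-1]])
    # at a chromosome boundary the next locus re-randomises (R = 1/2)
    prob = np.empty(m)
    prob[0] = 0.5
    prob[1:] = np.where(new_chrom[1:], 0.5, switch)
    flips = rng.random((n, m)) < prob[None, :]
    origin = np.logical_xor.accumulate(flips, axis=1)
    # reset accumulation at chromosome starts: XOR-accumulate within segments
    # by re-randomising the start (already Bernoulli(1/2)) — because the start
    # flip is uniform the accumulated parity remains uniform, and within-
    # segment transitions still occur with the intended probabilities.
    return np.where(origin, parent_b[None, :], parent_a[None, :])


def predict_progeny_phenotype(
    progeny: np.ndarray,
    matrix: QtlAlleleMatrix,
    mu_hat: float,
    locus_ids: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Predicted phenotype per line: mu_hat + sum of carried-allele effects.

    ``progeny`` holds allele indices into each locus's catalogue (columns in
    matrix locus order unless ``locus_ids`` says otherwise).
    """
    if locus_ids is None:
        locus_ids = matrix.locus_ids
    if progeny.shape[1] != len(locus_ids):
        raise CrossError("progeny columns do not match loci")
    values = np.full(progeny.shape[0], float(mu_hat))
    for j, lid in enumerate(locus_ids):
        eff = np.asarray([matrix.effects[lid][a] for a in matrix.alleles[lid]])
        codes = progeny[:, j]
        if (codes < 0).any() or codes.max(initial=0) >= len(eff):
            raise CrossError(f"progeny carry an allele with no effect at {lid}")
        values += eff[codes]
    return values


def cross_potential(
    values: np.ndarray,
    percentiles: Sequence[int] = (50, 99),
    parent_a: str = "A",
    parent_b: str = "B",
) -> CrossPrediction:
    """Nearest-rank percentiles of the predicted progeny distribution."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    if n == 0:
        raise CrossError("no progeny values")

    def nearest_rank(p: float) -> float:
        rank = int(np.ceil(p / 100.0 * n))
        return float(values[max(rank, 1) - 1])

    pcts = {p: nearest_rank(p) for p in percentiles}
    return CrossPrediction(
        parent_a=parent_a,
        parent_b=parent_b,
        n_progeny=n,
        p50=pcts.get(50, nearest_rank(50)),
        p99=pcts.get(99, nearest_rank(99)),
        progeny_mean=float(values.mean()),
    )


def predict_cross(
    matrix: QtlAlleleMatrix,
    parent_a: str,
    parent_b: str,
    chrom: np.ndarray,
    pos: np.ndarray,
    mu_hat: float,
    map_config: GeneticMapConfig = GeneticMapConfig(),
    n_progeny: int = 2000,
    seed: int | np.random.Generator = 0,
    percentiles: Sequence[int] = (50, 99),
) -> CrossPrediction:
    """Convenience wrapper: simulate one cross's progeny and summarise it."""
    ia = matrix.accession_ids.index(parent_a)
    ib = matrix.accession_ids.index(parent_b)
    ga = matrix.carried[:, ia]
    gb = matrix.carried[:, ib]
    if (ga < 0).any() or (gb < 0).any():
        raise CrossError("parents must be genotyped at every locus")
    progeny = simulate_derived_lines(ga, gb, chrom, pos, map_config,
                                     n=n_progeny, seed=seed)
    values = predict_progeny_phenotype(progeny, matrix, mu_hat)
    return cross_potential(values, percentiles, parent_a, parent_b)


def summarize_groups(
    predictions: Sequence[CrossPrediction],
    grouping: Mapping[tuple[str, str], str],
    parental_values: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Per-group cross counts with mean and max recombination potential.

    ``grouping`` maps (parent_a, parent_b) to a group label (e.g. "WA",
    "LR x RC", "Entire").  When per-accession predicted values are supplied,
    the extreme parental phenotype range of each group's parents is reported
    alongside.
    """
    rows: dict[str, dict] = {}
    for pred in predictions:
        grp = grouping.get((pred.parent_a, pred.parent_b))
        if grp is None:
            continue
        entry = rows.setdefault(grp, {"group": grp, "n_crosses": 0,
                                      "p99_sum": 0.0, "p99_max": -np.inf,
                                      "parents": set()})
        entry["n_crosses"] += 1
        entry["p99_sum"] += pred.p99
        entry["p99_max"] = max(entry["p99_max"], pred.p99)
        entry["parents"].update((pred.parent_a, pred.parent_b))
    out = []
    for grp, entry in rows.items():
        row = {
            "group": grp,
            "n_crosses": entry["n_crosses"],
            "mean_p99": entry["p99_sum"] / entry["n_crosses"],
            "max_p99": entry["p99_max"],
        }
        if parental_values is not None:
            vals = [parental_values[p] for p in entry["parents"]
                    if p in parental_values]
            row["parent_min"] = min(vals) if vals else np.nan
            row["parent_max"] = max(vals) if vals else np.nan
        out.append(row)
    return pd.DataFrame(out)
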