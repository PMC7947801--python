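"""QTL-allele matrix construction and allele-evolution accounting.

The QTL-allele matrix is the compact genetic summary produced by the
multi-locus scan: a locus x accession table in which each cell holds the
estimated effect of the allele that accession carries.  Splitting the matrix
by subpopulation (wild accessions WA -> landraces LR -> released cultivars
RC) lets allele-level evolutionary change be tallied:

* inherited — present in both the donor and the derived subpopulation;
* emerged   — present in the derived subpopulation but absent from both the
  donor and the ancestral (WA) subpopulation;
* recovered — absent from the donor but restored from the ancestor;
* excluded  — present in the donor, lost in the derived subpopulation;
* changed   — emerged + recovered + excluded.

These satisfy the set-partition identity
``total(derived) = inherited + emerged + recovered`` at every locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


class MatrixError(ValueError):
    pass


SUBPOPS = ("WA", "LR", "RC")


@dataclass
class QtlAlleleMatrix:
    """Locus x accession table of carried-allele effects."""

    locus_ids: list[str]
    alleles: dict[str, list[str]]          # locus -> allele catalogue
    effects: dict[str, dict[str, float]]   # locus -> allele -> effect
    accession_ids: list[str]
    subpop: np.ndarray
    carried: np.ndarray                    # locus x accession allele index, -1 missing

    @property
    def cells(self) -> np.ndarray:
        """Effect values carried by each accession (NaN where missing)."""
        out = np.full(self.carried.shape, np.nan)
        for i, lid in enumerate(self.locus_ids):
            eff = np.array([self.effects[lid][a] for a in self.alleles[lid]])
            ok = self.carried[i] >= 0
            out[i, ok] = eff[self.carried[i, ok]]
        return out

    def allele_of(self, locus_idx: int, acc_idx: int) -> Optional[str]:
        code = self.carried[locus_idx, acc_idx]
        if code < 0:
            return None
        return self.alleles[self.locus_ids[locus_idx]][code]


@dataclass
class ChangeLedger:
    """Allele-change tallies for one derived-vs-donor comparison."""

    label: str
    total_from: list[tuple[str, str]]
    total_to: list[tuple[str, str]]
    inherited: list[tuple[str, str]]
    emerged: list[tuple[str, str]]
    recovered: list[tuple[str, str]]
    excluded: list[tuple[str, str]]

    @property
    def changed(self) -> list[tuple[str, str]]:
        return sorted(self.emerged + self.recovered + self.excluded)

    def allele_counts(self) -> dict[str, int]:
        return {
            "total_from": len(self.total_from),
            "total_to": len(self.total_to),
            "inherited": len(self.inherited),
            "emerged": len(self.emerged),
            "recovered": len(self.recovered),
            "excluded": len(self.excluded),
            "changed": len(self.changed),
        }

    def locus_counts(self) -> dict[str, int]:
        return {cat: len({lid for lid, _ in getattr(self, cat)})
                for cat in ("total_from", "total_to", "inherited", "emerged",
                            "recovered", "excluded")} | {
                "changed": len({lid for lid, _ in self.changed})}

    def to_frame(self) -> pd.DataFrame:
        alleles = self.allele_counts()
        loci = self.locus_counts()
        rows = [{"comparison": self.label, "category": cat,
                 "n_loci": loci[cat], "n_alleles": alleles[cat]}
                for cat in ("total_to", "inherited", "emerged", "recovered",
                            "excluded", "changed")]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------

def build_matrix(
    qtls: Sequence,
    marker_codes: Mapping[str, np.ndarray],
    accession_ids: Sequence[str],
    subpop: Sequence[str],
) -> QtlAlleleMatrix:
    """Assemble the locus x accession matrix from detected loci.

    ``qtls`` is a sequence of records with ``marker_id``/``locus_id``,
    an allele catalogue and an effects map (both :class:`~haploqtl.association.QtlRecord`
    and :class:`~haploqtl.simulate.TruthLocus` qualify); ``marker_codes`` maps
    each locus id to the per-accession allele indices (-1 missing).
    """
    locus_ids, alleles, effects = [], {}, {}
    n_acc = len(accession_ids)
    carried = np.full((len(qtls), n_acc), -1, dtype=np.int32)
    for i, q in enumerate(qtls):
        lid = getattr(q, "marker_id", None) or getattr(q, "locus_id")
        catalogue = (list(getattr(q, "haplotypes", []))
                     or list(getattr(q, "alleles", [])))
        if not catalogue:
            # the effects map preserves the marker's allele-code order
            catalogue = list(q.effects)
        missing = set(catalogue) - set(q.effects)
        if missing:
            raise MatrixError(f"alleles {missing} at {lid} have no effect")
        codes = np.asarray(marker_codes[lid])
        if codes.shape != (n_acc,):
            raise MatrixError(f"allele codes for {lid} have wrong length")
        if codes.max(initial=-1) >= len(catalogue):
            raise MatrixError(f"allele code out of catalogue at {lid}")
        locus_ids.append(lid)
        alleles[lid] = catalogue
        effects[lid] = dict(q.effects)
        carried[i] = codes
    return QtlAlleleMatrix(
        locus_ids=locus_ids,
        alleles=alleles,
        effects=effects,
        accession_ids=list(accession_ids),
        subpop=np.asarray(subpop),
        carried=carried,
    )


def presence_sets(
    matrix: QtlAlleleMatrix,
    min_carriers: int = 1,
    subpops: Sequence[str] = SUBPOPS,
) -> dict:
    """Per-locus, per-subpopulation allele presence.

    An allele is present in a subpopulation when at least ``min_carriers``
    non-missing accessions of that subpopulation carry it.  No frequency
    floor is applied beyond the carrier threshold: detected marker alleles
    already passed the population-level MAF floor.
    """
    presence: dict = {}
    for pop in subpops:
        if (matrix.subpop == pop).sum() == 0:
            raise MatrixError(f"subpopulation {pop} is empty")
    for i, lid in enumerate(matrix.locus_ids):
        presence[lid] = {}
        for pop in subpops:
            codes = matrix.carried[i, matrix.subpop == pop]
            codes = codes[codes >= 0]
            counts = np.bincount(codes, minlength=len(matrix.alleles[lid]))
            presence[lid][pop] = {
                matrix.alleles[lid][j]
                for j in np.flatnonzero(counts >= min_carriers)
            }
    return presence


def _union(presence_at_locus: Mapping[str, set], pops: Sequence[str]) -> set:
    out: set = set()
    for p in pops:
        out |= presence_at_locus[p]
    return out


def change_accounting(
    presence: Mapping[str, Mapping[str, set]],
    from_pops: Sequence[str],
    to_pops: Sequence[str],
    ancestral: str = "WA",
    label: Optional[str] = None,
) -> ChangeLedger:
    """Tally inherited/emerged/recovered/excluded alleles, ``to`` vs ``from``.

    Both sides may be unions of subpopulations (e.g. LR+RC pooled against
    WA).  Recovery — present in the derived side, absent from the donor but
    present in the ancestor — is structurally empty whenever the donor side
    is the ancestor itself.
    """
    from_pops = tuple(from_pops)
    to_pops = tuple(to_pops)
    if set(from_pops) & set(to_pops):
        raise MatrixError("donor and derived subpopulation sets overlap")
    if label is None:
        label = f"{'+'.join(to_pops)} vs {'+'.join(from_pops)}"
    total_from, total_to = [], []
    inherited, emerged, recovered, excluded = [], [], [], []
    for lid in presence:
        at = presence[lid]
        src = _union(at, from_pops)
        dst = _union(at, to_pops)
        anc = at[ancestral]
        for a in sorted(src):
            total_from.append((lid, a))
            if a not in dst:
                excluded.append((lid, a))
        for a in sorted(dst):
            total_to.append((lid, a))
            if a in src:
                inherited.append((lid, a))
            elif a in anc:
                recovered.append((lid, a))
            else:
                emerged.append((lid, a))
    return ChangeLedger(
        label=label,
        total_from=total_from,
        total_to=total_to,
        inherited=inherited,
        emerged=emerged,
        recovered=recovered,
        excluded=excluded,
    )


def venn_summary(
    presence: Mapping[str, Mapping[str, set]],
    subpops: Sequence[str] = SUBPOPS,
) -> dict[str, int]:
    """Counts of (locus, allele) pairs in each region of the three-set Venn
    partition of allele presence; region counts sum to the union size."""
    if len(subpops) != 3:
        raise MatrixError("venn summary is defined for three subpopulations")
    regions = {}
    for r in range(1, 8):
        members = tuple(p for i, p in enumerate(subpops) if r >> i & 1)
        regions["&".join(members)] = 0
    for lid in presence:
        at = presence[lid]
        union = _union(at, subpops)
        for a in union:
            members = tuple(p for p in subpops if a in at[p])
            regions["&".join(members)] += 1
    return regions


def new_locus_detection(
    presence: Mapping[str, Mapping[str, set]],
    order: Sequence[str] = SUBPOPS,
) -> list[tuple[str, str]]:
    """Loci that became polymorphic only in a derived subpopulation.

    A locus is flagged "emerged in P" when every subpopulation ancestral to P
    carries exactly one allele there while P carries two or more.
    """
    flagged = []
    for lid in presence:
        at = presence[lid]
        for i in range(1, len(order)):
            derived = order[i]
            ancestors = order[:i]
            if all(len(at[p]) == 1 for p in ancestors) and len(at[derived]) >= 2:
                flagged.append((lid, derived))
                break
    return flagged
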