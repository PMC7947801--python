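"""SNP filtering, LD-block partition and multi-allelic SNPLDB marker assembly.

The unit of association testing in this package is not the single SNP but the
SNPLDB marker: a run of adjacent, tightly linked SNPs whose distinct
haplotypes form the alleles of one multi-allelic marker.  Blocks are defined
by the Gabriel-style confidence-interval rule on the normalised LD
coefficient |D'|, with the confidence interval obtained from a
Wall-Pritchard-style likelihood grid.  SNPs that fall in no block are carried
forward as ordinary biallelic (singleton) markers.

All genotypes are haploid-coded: the panel consists of fully homozygous
inbred lines, so each accession carries a single allele code per SNP
(0 = reference, 1 = alternate, -1 = missing).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np


class PanelError(ValueError):
    """Raised for malformed or degenerate genotype panels."""


MISSING = -1


@dataclass
class SnpPanel:
    """Accession x SNP genotype matrix for a panel of inbred accessions.

    ``genotypes`` is an ``(n_accessions, n_snps)`` int8 array with codes
    0 (reference), 1 (alternate), -1 (missing).  Positions are 1-based and
    strictly increasing within each chromosome.
    """

    accession_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    subpop: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.subpop is not None:
            self.subpop = np.asarray(self.subpop)

    @property
    def n_accessions(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        if self.genotypes.shape != (len(self.accession_ids), len(self.pos)):
            raise PanelError("genotype matrix shape does not match ids/positions")
        codes = np.unique(self.genotypes)
        if not np.isin(codes, [MISSING, 0, 1]).all():
            raise PanelError(f"allele codes must be in {{-1, 0, 1}}, got {codes}")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise PanelError(f"positions not strictly increasing on chromosome {c}")

    def is_sorted(self) -> bool:
        order = np.lexsort((self.pos, self.chrom))
        return bool((order == np.arange(self.n_snps)).all())

    def take_snps(self, index: np.ndarray) -> "SnpPanel":
        return SnpPanel(
            accession_ids=list(self.accession_ids),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            genotypes=self.genotypes[:, index],
            subpop=None if self.subpop is None else self.subpop.copy(),
        )


@dataclass
class LdBlock:
    """A contiguous run of SNPs in strong LD (or a singleton)."""

    chrom: object
    snp_indices: np.ndarray  # global SNP indices, ascending
    start: int               # bp, 1-based inclusive
    end: int

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


@dataclass
class SnpldbMarker:
    """A multi-allelic haplotype-block marker.

    ``haplotypes`` holds the allele catalogue as strings of per-SNP codes,
    ordered by descending frequency; ``codes`` maps each accession to an index
    into the catalogue (-1 = missing).
    """

    marker_id: str
    chrom: object
    start: int
    end: int
    snp_indices: np.ndarray
    haplotypes: list[str]
    frequencies: np.ndarray
    codes: np.ndarray

    @property
    def n_alleles(self) -> int:
        return len(self.haplotypes)


@dataclass
class StructureCovariates:
    """Genetic-similarity eigenstructure used as fixed model covariates."""

    similarity: np.ndarray
    eigenvalues: np.ndarray  # descending
    W: np.ndarray            # accession x m selected eigenvectors
    m: int


# ---------------------------------------------------------------------------
# MAF filtering
# ---------------------------------------------------------------------------

def filter_maf(panel: SnpPanel, floor: float = 0.02) -> tuple[SnpPanel, int]:
    """Drop SNPs whose minor allele is too rare.

    A SNP is retained when its minor-allele carrier count is at least
    ``max(1, floor(maf_floor * n_nonmissing))`` — with the canonical 2% floor
    in a 341-accession panel this keeps alleles carried by six or more
    accessions.  Returns the filtered panel and the number of SNPs removed.
    """
    if not (0.0 < floor < 0.5):
        raise PanelError(f"maf floor must be in (0, 0.5), got {floor}")
    if panel.n_snps == 0 or panel.n_accessions == 0:
        raise PanelError("cannot filter an empty panel")
    geno = panel.genotypes
    nonmiss = (geno != MISSING).sum(axis=0)
    alt = (geno == 1).sum(axis=0)
    minor = np.minimum(alt, nonmiss - alt)
    threshold = np.maximum(1, np.floor(floor * nonmiss)).astype(int)
    keep = (minor >= threshold) & (nonmiss > 0)
    removed = int((~keep).sum())
    return panel.take_snps(np.flatnonzero(keep)), removed


# ---------------------------------------------------------------------------
# |D'| confidence intervals and block partition
# ---------------------------------------------------------------------------

_DPRIME_GRID = np.arange(0.0, 1.0 + 1e-12, 0.001)


def dprime_ci(
    a: np.ndarray,
    b: np.ndarray,
    tail: float = 0.05,
) -> Optional[tuple[float, float]]:
    """Likelihood-grid confidence interval for |D'| between two haploid SNPs.

    The likelihood of the four haplotype counts is evaluated on a |D'| grid
    (step 0.001) with allele frequencies fixed at their MLEs and the sign of D
    fixed at its MLE; the central 90% of the normalised likelihood mass gives
    the (5%, 95%) interval.  Returns ``None`` for uninformative pairs (either
    SNP monomorphic among jointly called accessions).
    """
    ok = (a != MISSING) & (b != MISSING)
    a = a[ok].astype(np.float64)
    b = b[ok].astype(np.float64)
    n = len(a)
    if n == 0:
        return None
    pa = a.mean()
    pb = b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return None
    n11 = float(np.sum((a == 1) & (b == 1)))
    n10 = float(np.sum((a == 1) & (b == 0)))
    n01 = float(np.sum((a == 0) & (b == 1)))
    n00 = float(np.sum((a == 0) & (b == 0)))
    d_mle = n11 / n - pa * pb
    if d_mle >= 0:
        d_max = min(pa * (1 - pb), (1 - pa) * pb)
        sign = 1.0
    else:
        d_max = min(pa * pb, (1 - pa) * (1 - pb))
        sign = -1.0
    if d_max <= 0:
        return None
    d = sign * _DPRIME_GRID * d_max
    p11 = np.clip(pa * pb + d, 1e-12, None)
    p10 = np.clip(pa * (1 - pb) - d, 1e-12, None)
    p01 = np.clip((1 - pa) * pb - d, 1e-12, None)
    p00 = np.clip((1 - pa) * (1 - pb) + d, 1e-12, None)
    loglik = (n11 * np.log(p11) + n10 * np.log(p10)
              + n01 * np.log(p01) + n00 * np.log(p00))
    lik = np.exp(loglik - loglik.max())
    cum = np.cumsum(lik)
    cum /= cum[-1]
    low = float(_DPRIME_GRID[np.searchsorted(cum, tail)])
    high = float(_DPRIME_GRID[np.searchsorted(cum, 1.0 - tail)])
    return low, high


STRONG, RECOMB, UNINFORMATIVE = 1, -1, 0


def _classify_pair(
    ci: Optional[tuple[float, float]],
    strong_low: float,
    strong_high: float,
    recomb_high: float,
) -> int:
    if ci is None:
        return UNINFORMATIVE
    low, high = ci
    if low >= strong_low and high >= strong_high:
        return STRONG
    if high < recomb_high:
        return RECOMB
    return UNINFORMATIVE


def partition_blocks(
    panel: SnpPanel,
    max_span_bp: int = 100_000,
    strong_ci_low: float = 0.70,
    strong_ci_high: float = 0.98,
    recomb_ci_high: float = 0.90,
    strong_fraction: float = 0.95,
    max_block_snps: int = 25,
) -> list[LdBlock]:
    """Partition each chromosome into non-overlapping strong-LD blocks.

    A candidate interval of SNPs forms a block when its outermost pair is in
    strong LD (|D'| CI lower bound >= ``strong_ci_low`` and upper bound >=
    ``strong_ci_high``), at least 95% of its informative pairs are strong
    (pairs with CI upper bound < ``recomb_ci_high`` count as recombination
    evidence), and its bp span does not exceed ``max_span_bp``.  Candidates
    are accepted greedily from largest to smallest; SNPs in no accepted block
    become singleton blocks.
    """
    if not panel.is_sorted():
        raise PanelError("panel must be sorted by chromosome and position")
    blocks: list[LdBlock] = []
    geno = panel.genotypes
    for c in _chrom_order(panel.chrom):
        idx = np.flatnonzero(panel.chrom == c)
        pos = panel.pos[idx]
        n = len(idx)
        cls_cache: dict[tuple[int, int], int] = {}

        def pair_class(i: int, j: int) -> int:
            key = (i, j)
            if key not in cls_cache:
                ci = dprime_ci(geno[:, idx[i]], geno[:, idx[j]])
                cls_cache[key] = _classify_pair(
                    ci, strong_ci_low, strong_ci_high, recomb_ci_high
                )
            return cls_cache[key]

        candidates = []
        for i in range(n):
            jmax = i
            while (jmax + 1 < n and pos[jmax + 1] - pos[i] <= max_span_bp
                   and jmax + 1 - i < max_block_snps):
                jmax += 1
            for j in range(i + 1, jmax + 1):
                if pair_class(i, j) != STRONG:
                    continue
                n_strong = n_recomb = 0
                for u in range(i, j + 1):
                    for v in range(u + 1, j + 1):
                        k = pair_class(u, v)
                        if k == STRONG:
                            n_strong += 1
                        elif k == RECOMB:
                            n_recomb += 1
                informative = n_strong + n_recomb
                if informative == 0:
                    continue
                if n_strong / informative >= strong_fraction:
                    candidates.append((j - i + 1, i, j))
        candidates.sort(key=lambda t: (-t[0], t[1]))
        taken = np.zeros(n, dtype=bool)
        accepted = []
        for _, i, j in candidates:
            if taken[i:j + 1].any():
                continue
            taken[i:j + 1] = True
            accepted.append((i, j))
        for i in range(n):
            if not taken[i]:
                accepted.append((i, i))
        accepted.sort()
        for i, j in accepted:
            blocks.append(LdBlock(
                chrom=c,
                snp_indices=idx[i:j + 1],
                start=int(pos[i]),
                end=int(pos[j]),
            ))
    return blocks


def _chrom_order(chrom: np.ndarray) -> list:
    seen: list = []
    for c in chrom:
        if len(seen) == 0 or seen[-1] != c:
            if c in seen:
                raise PanelError("chromosome runs are not contiguous; sort the panel")
            seen.append(c)
    return seen


# ---------------------------------------------------------------------------
# SNPLDB marker assembly
# ---------------------------------------------------------------------------

def assemble_snpldb(
    panel: SnpPanel,
    blocks: Sequence[LdBlock],
    maf_floor: float = 0.02,
    max_missing_fraction: float = 0.2,
) -> list[SnpldbMarker]:
    """Turn LD blocks into multi-allelic haplotype markers.

    Within a block every distinct haplotype string is an allele.  Rare
    haplotypes (frequency < ``maf_floor``) are merged into the common
    haplotype at smallest Hamming distance (ties broken towards the more
    frequent haplotype, then lexicographically).  An accession with more than
    ``max_missing_fraction`` of the member SNPs missing is coded missing at
    the marker; below that threshold missing SNPs are imputed to the
    block-major allele.  Markers left with fewer than two alleles are dropped.
    """
    markers: list[SnpldbMarker] = []
    serial: dict = {}
    for block in blocks:
        sub = panel.genotypes[:, block.snp_indices].astype(np.int16)
        n_acc, k = sub.shape
        miss = sub == MISSING
        marker_missing = miss.mean(axis=1) > max_missing_fraction
        major = np.zeros(k, dtype=np.int16)
        for s in range(k):
            col = sub[:, s]
            called = col[col != MISSING]
            if len(called) == 0:
                major[s] = 0
            else:
                major[s] = 1 if (called == 1).sum() * 2 > len(called) else 0
        filled = np.where(miss, major[None, :], sub)
        hap_strings = np.array(["".join(map(str, row)) for row in filled])
        hap_strings[marker_missing] = ""

        valid = ~marker_missing
        n_valid = int(valid.sum())
        if n_valid == 0:
            continue
        uniq, counts = np.unique(hap_strings[valid], return_counts=True)
        tally = dict(zip(uniq.tolist(), counts.tolist()))
        tally = _merge_rare(tally, maf_floor, n_valid)
        if len(tally) < 2:
            continue

        # catalogue ordered by descending frequency, then lexicographically
        catalogue = sorted(tally, key=lambda h: (-tally[h], h))
        index = {h: i for i, h in enumerate(catalogue)}
        codes = np.full(n_acc, MISSING, dtype=np.int32)
        for i in np.flatnonzero(valid):
            h = hap_strings[i]
            if h not in index:
                h = _nearest(h, tally)
            codes[i] = index[h]
        freqs = np.bincount(codes[codes >= 0], minlength=len(catalogue)).astype(float)
        freqs /= freqs.sum()
        serial[block.chrom] = serial.get(block.chrom, 0) + 1
        markers.append(SnpldbMarker(
            marker_id=f"ldb{block.chrom}-{serial[block.chrom]}",
            chrom=block.chrom,
            start=block.start,
            end=block.end,
            snp_indices=np.asarray(block.snp_indices),
            haplotypes=[str(h) for h in catalogue],
            frequencies=freqs,
            codes=codes,
        ))
    return markers


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _nearest(h: str, tally: dict) -> str:
    return min(tally, key=lambda t: (_hamming(h, t), -tally[t], t))


def _merge_rare(tally: dict, maf_floor: float, n_valid: int) -> dict:
    """Fold haplotypes below the frequency floor into their nearest common one."""
    tally = dict(tally)
    while len(tally) > 1:
        freqs = {h: c / n_valid for h, c in tally.items()}
        rare = [h for h, f in freqs.items() if f < maf_floor]
        if not rare:
            break
        # rarest first; deterministic tie-break on the string
        h = min(rare, key=lambda x: (tally[x], x))
        common = {t: c for t, c in tally.items()
                  if t != h and c / n_valid >= maf_floor}
        pool = common if common else {t: c for t, c in tally.items() if t != h}
        target = min(pool, key=lambda t: (_hamming(h, t), -tally[t], t))
        tally[target] += tally.pop(h)
    return tally


# ---------------------------------------------------------------------------
# Genetic similarity and eigenvector covariates
# ---------------------------------------------------------------------------

def similarity_matrix(markers: Sequence[SnpldbMarker]) -> np.ndarray:
    """Allele-sharing similarity: the proportion of jointly called markers at
    which two accessions carry the same haplotype allele.  Diagonal is 1."""
    if len(markers) == 0:
        raise PanelError("similarity requires at least one marker")
    n = len(markers[0].codes)
    eq = np.zeros((n, n), dtype=np.int64)
    cnt = np.zeros((n, n), dtype=np.int64)
    for m in markers:
        c = m.codes
        valid = c != MISSING
        joint = valid[:, None] & valid[None, :]
        eq += joint & (c[:, None] == c[None, :])
        cnt += joint
    if (cnt == 0).any():
        raise PanelError("some accession pair shares no jointly called marker")
    sim = eq / cnt
    np.fill_diagonal(sim, 1.0)
    return sim


def eigen_covariates(
    similarity: np.ndarray,
    share: float = 0.5,
    max_covariates: Optional[int] = 10,
) -> StructureCovariates:
    """Eigendecompose the similarity matrix and select the leading
    eigenvectors whose cumulative share of the positive spectrum reaches
    ``share``.  The selected matrix W enters the association model as fixed
    population-structure covariates.

    The matrix is double-centred (Gower, as in principal-coordinate
    analysis) before decomposition: the raw similarity matrix of a germplasm
    panel is dominated by a near-constant leading eigenvector (mean
    relatedness), which is collinear with the model intercept and carries no
    structure information; centring makes the leading eigenvectors separate
    the subpopulations.

    ``max_covariates`` caps the selection (default 10, the usual number of
    structure axes fitted in eigenvector-based GWAS correction): when the
    centred spectrum is nearly flat the cumulative-share rule would otherwise
    select a large noise subspace that absorbs genuine marker signal.  Pass
    ``None`` to disable the cap."""
    similarity = np.asarray(similarity, dtype=float)
    if similarity.ndim != 2 or similarity.shape[0] != similarity.shape[1]:
        raise PanelError("similarity must be a square matrix")
    if not np.allclose(similarity, similarity.T, atol=1e-8):
        raise PanelError("similarity matrix must be symmetric")
    n = similarity.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    centred = j @ similarity @ j
    centred = (centred + centred.T) / 2
    vals, vecs = np.linalg.eigh(centred)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    positive = vals[vals > 0]
    total = positive.sum()
    if total <= 0:
        raise PanelError("similarity matrix has no positive eigenvalues")
    cum = np.cumsum(positive) / total
    m = int(np.searchsorted(cum, share) + 1)
    m = max(1, min(m, len(positive)))
    if max_covariates is not None:
        m = min(m, max_covariates)
    return StructureCovariates(
        similarity=similarity,
        eigenvalues=vals,
        W=vecs[:, :m],
        m=m,
    )
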