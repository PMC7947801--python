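"""Ground-truth simulation of a structured inbred germplasm panel.

The generator emulates the population used throughout the package: three
evolutionary subpopulations of fully homozygous accessions — wild accessions
(WA), farmer landraces (LR) derived from WA, and released cultivars (RC)
derived from LR.  Genotypes are organised in LD blocks: each block carries a
small pool of haplotypes built by sequential single-SNP mutation (a perfect
phylogeny), so adjacent SNPs within a block are in complete LD while blocks
segregate independently.  Landraces and cultivars are derived by per-block
haplotype-frequency resampling (drift), with explicitly *planted* allele
changes — novel haplotypes that emerge, haplotypes that are excluded, and
wild haplotypes lost in LR but recovered in RC — recorded in a ledger so the
downstream allele-evolution accounting can be verified against known truth.

Quantitative trait values are additive over a set of QTL blocks with
multi-allelic, sum-to-zero effects, plus a polygenic residual and per-plot
error, laid out in a replicated randomized incomplete block design over nine
measurement time points whose error variances are scheduled so that exactly
one time point attains the maximum heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from .phenotyping import ReflectanceRecord, compute_chl, compute_ndvi
from .snpldb import MISSING, SnpPanel

SUBPOPS = ("WA", "LR", "RC")


@dataclass
class TruthLocus:
    """One simulated QTL: a haplotype block with known allele effects."""

    locus_id: str
    block_index: int
    chrom: int
    start: int
    end: int
    snp_indices: np.ndarray
    alleles: list[str]            # full catalogue, incl. planted novel alleles
    effects: dict[str, float]     # per-allele effect, sums to zero
    codes: np.ndarray             # accession -> index into `alleles`


@dataclass
class GroundTruth:
    """Everything the recovery tests need to know about a simulation."""

    loci: list[TruthLocus]
    presence: dict                # locus_id -> {subpop: set of allele strings}
    planted: dict                 # comparison -> category -> [(locus_id, allele)]
    population_mean: float = 0.0
    realized_h2: Optional[float] = None
    best_timepoint: Optional[int] = None
    variances: dict = field(default_factory=dict)

    def validate(self) -> None:
        for locus in self.loci:
            total = sum(locus.effects.values())
            if abs(total) > 1e-9:
                raise ConfigError(
                    f"effects at {locus.locus_id} sum to {total}, expected 0"
                )

    def to_dict(self) -> dict:
        return {
            "population_mean": self.population_mean,
            "realized_h2": self.realized_h2,
            "best_timepoint": self.best_timepoint,
            "variances": self.variances,
            "planted": {
                comp: {cat: [[lid, a] for lid, a in pairs]
                       for cat, pairs in cats.items()}
                for comp, cats in self.planted.items()
            },
            "loci": [
                {
                    "locus_id": t.locus_id,
                    "chrom": int(t.chrom),
                    "start": int(t.start),
                    "end": int(t.end),
                    "alleles": t.alleles,
                    "effects": t.effects,
                    "presence": {p: sorted(self.presence[t.locus_id][p])
                                 for p in SUBPOPS},
                }
                for t in self.loci
            ],
        }


# ---------------------------------------------------------------------------
# genome layout
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    chrom: int
    snp_lo: int                 # global index of first member SNP
    k: int                      # number of member SNPs
    positions: np.ndarray
    haps: list[np.ndarray]      # catalogue of 0/1 vectors, grows when planting
    base_freqs: np.ndarray      # founder-pool frequencies (WA target)
    free_snps: list[int]        # local SNP indices not yet used by a mutation

    @property
    def snp_indices(self) -> np.ndarray:
        return np.arange(self.snp_lo, self.snp_lo + self.k)

    def hap_str(self, h: int) -> str:
        return "".join(map(str, self.haps[h]))

    @property
    def spare(self) -> int:
        return len(self.free_snps)


def _layout_genome(config: SimConfig, rng: np.random.Generator) -> list[_Block]:
    blocks: list[_Block] = []
    per_chrom = np.full(config.n_chromosomes, config.snp_count // config.n_chromosomes)
    per_chrom[: config.snp_count % config.n_chromosomes] += 1
    snp_cursor = 0
    for c in range(config.n_chromosomes):
        remaining = int(per_chrom[c])
        sizes = []
        while remaining > 0:
            if remaining == 1 or rng.random() < config.singleton_fraction:
                k = 1
            else:
                k = int(min(remaining, 2 + rng.poisson(2.0), 12))
            sizes.append(k)
            remaining -= k
        n_blocks = len(sizes)
        spans = []
        for k in sizes:
            if k == 1:
                spans.append(0)
            else:
                span = int(rng.exponential(config.block_mean_span_bp))
                spans.append(int(np.clip(span, 50 * (k - 1), 80_000)))
        slack = config.chrom_length_bp - sum(spans)
        min_gap = min(150_000, max(1, slack // (2 * n_blocks + 2)))
        free = slack - min_gap * (n_blocks + 1)
        if free < 0:
            raise ConfigError("chromosome too short for the requested blocks")
        gap_weights = rng.dirichlet(np.ones(n_blocks + 1))
        gaps = (min_gap + gap_weights * free).astype(np.int64)
        cursor = 1
        for b, (k, span) in enumerate(zip(sizes, spans)):
            cursor += int(gaps[b])
            start = cursor
            if k == 1:
                positions = np.array([start], dtype=np.int64)
            else:
                offs = rng.choice(np.arange(1, span + 1), size=k - 1, replace=False)
                positions = np.concatenate([[0], np.sort(offs)]) + start
            cursor = int(positions[-1]) + 1
            h_cap = min(config.haplotypes_per_block, k + 1)
            n_hap = 2 if k == 1 else int(np.clip(2 + rng.poisson(1.1), 2, h_cap))
            haps, free_snps = _phylogeny_pool(k, n_hap, rng)
            freqs = rng.dirichlet(np.full(n_hap, 1.0))
            freqs = np.clip(freqs, 0.04, None)
            freqs /= freqs.sum()
            blocks.append(_Block(
                chrom=c + 1,
                snp_lo=snp_cursor,
                k=k,
                positions=positions,
                haps=haps,
                base_freqs=freqs,
                free_snps=free_snps,
            ))
            snp_cursor += k
    return blocks


def _phylogeny_pool(
    k: int, n_hap: int, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[int]]:
    """Build ``n_hap`` distinct haplotypes over ``k`` SNPs by sequential
    single-SNP mutation, so every within-block SNP pair passes the
    four-gamete test (|D'| = 1)."""
    order = rng.permutation(k).tolist()
    haps = [np.zeros(k, dtype=np.int8)]
    for _ in range(n_hap - 1):
        parent = haps[int(rng.integers(len(haps)))].copy()
        snp = order.pop()
        parent[snp] ^= 1
        haps.append(parent)
    return haps, order


def _mutate_novel(block: _Block, rng: np.random.Generator) -> int:
    """Append a novel haplotype to the block catalogue (planted emergence)."""
    if not block.free_snps:
        raise ConfigError(
            "more planted haplotypes than block capacity "
            f"(block on chromosome {block.chrom} has no free SNPs)"
        )
    snp = block.free_snps.pop()
    parent = block.haps[0].copy()
    parent[snp] ^= 1
    block.haps.append(parent)
    return len(block.haps) - 1


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

def simulate_population(config: SimConfig) -> tuple[SnpPanel, GroundTruth]:
    """Simulate the three-subpopulation panel and its ground truth.

    Returns a fully homozygous :class:`SnpPanel` (subpopulation labels
    attached) and a :class:`GroundTruth` carrying the QTL architecture, the
    realised per-subpopulation allele presence sets, and the planted
    allele-change ledger.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    blocks = _layout_genome(config, rng)

    # ---- choose QTL blocks -------------------------------------------------
    lo, hi = config.alleles_per_qtl
    candidates = [i for i, b in enumerate(blocks)
                  if b.k >= 2 and lo <= len(b.haps) <= hi]
    if len(candidates) < config.n_qtl:
        raise ConfigError(
            f"only {len(candidates)} candidate blocks for {config.n_qtl} QTLs; "
            "increase snp_count or relax alleles_per_qtl"
        )
    qtl_idx = _select_qtl_blocks(config, blocks, candidates, rng)
    qtl_set = set(qtl_idx)

    # ---- assign planted events to QTL loci ---------------------------------
    events = _plan_events(config, blocks, qtl_idx, rng)

    # restrict new-locus blocks to a single founder haplotype
    for bi in events["new_locus_lr"] + events["new_locus_rc"]:
        block = blocks[bi]
        block.haps = [block.haps[0]]
        block.base_freqs = np.array([1.0])

    n_wa, n_lr, n_rc = config.n_wa, config.n_lr, config.n_rc
    n_acc = config.n_accessions
    subpop = np.array(["WA"] * n_wa + ["LR"] * n_lr + ["RC"] * n_rc)
    slices = {"WA": slice(0, n_wa), "LR": slice(n_wa, n_wa + n_lr),
              "RC": slice(n_wa + n_lr, n_acc)}

    assignments: dict[int, np.ndarray] = {}
    counts_by_pop: dict[int, dict[str, np.ndarray]] = {}
    for bi, block in enumerate(blocks):
        is_qtl = bi in qtl_set
        ev = {k: events[k].get(bi) for k in
              ("emerged_lr", "excluded_lr", "emerged_rc", "excluded_rc",
               "recovered_rc")}

        # WA: founder pool frequencies
        n_hap0 = len(block.haps)
        wa_counts = rng.multinomial(n_wa, block.base_freqs)
        if is_qtl:
            wa_counts = _enforce_presence(
                wa_counts, required=set(range(n_hap0)), banned=set(),
                min_carriers=config.min_carriers)

        # plant novel haplotypes now so count vectors share one catalogue
        novel_lr = _mutate_novel(block, rng) if ev["emerged_lr"] is not None else None
        novel_rc = _mutate_novel(block, rng) if ev["emerged_rc"] is not None else None
        n_hap = len(block.haps)
        wa_counts = _pad(wa_counts, n_hap)

        # LR: drift from realised WA frequencies, then planted edits
        lr_required = set(np.flatnonzero(wa_counts > 0).tolist())
        lr_banned: set[int] = set()
        if ev["excluded_lr"] is not None:
            lr_banned.add(ev["excluded_lr"])
            lr_required.discard(ev["excluded_lr"])
        if novel_lr is not None:
            lr_required.add(novel_lr)
        lr_counts = _drift_counts(
            wa_counts, n_lr, config, rng,
            add={novel_lr: config.emerged_freq} if novel_lr is not None else {},
            drop=lr_banned)
        if is_qtl:
            lr_counts = _enforce_presence(lr_counts, lr_required, lr_banned,
                                          config.min_carriers)

        # RC: drift from realised LR frequencies, then planted edits
        rc_required = set(np.flatnonzero(lr_counts > 0).tolist())
        rc_banned: set[int] = set()
        add_rc: dict[int, float] = {}
        if ev["excluded_rc"] is not None:
            rc_banned.add(ev["excluded_rc"])
            rc_required.discard(ev["excluded_rc"])
        if novel_rc is not None:
            rc_required.add(novel_rc)
            add_rc[novel_rc] = config.emerged_freq
        if ev["recovered_rc"] is not None:
            rc_required.add(ev["recovered_rc"])
            add_rc[ev["recovered_rc"]] = config.emerged_freq
        rc_counts = _drift_counts(lr_counts, n_rc, config, rng,
                                  add=add_rc, drop=rc_banned)
        if is_qtl:
            rc_counts = _enforce_presence(rc_counts, rc_required, rc_banned,
                                          config.min_carriers)

        assign = np.empty(n_acc, dtype=np.int32)
        for pop, cnts in (("WA", wa_counts), ("LR", lr_counts), ("RC", rc_counts)):
            vec = np.repeat(np.arange(n_hap), cnts)
            rng.shuffle(vec)
            assign[slices[pop]] = vec
        assignments[bi] = assign
        counts_by_pop[bi] = {"WA": wa_counts, "LR": lr_counts, "RC": rc_counts}

    # ---- genotype matrix ---------------------------------------------------
    n_snps = sum(b.k for b in blocks)
    geno = np.empty((n_acc, n_snps), dtype=np.int8)
    chrom = np.empty(n_snps, dtype=np.int64)
    pos = np.empty(n_snps, dtype=np.int64)
    for bi, block in enumerate(blocks):
        hap_matrix = np.stack(block.haps)
        geno[:, block.snp_lo:block.snp_lo + block.k] = hap_matrix[assignments[bi]]
        chrom[block.snp_lo:block.snp_lo + block.k] = block.chrom
        pos[block.snp_lo:block.snp_lo + block.k] = block.positions

    panel = SnpPanel(
        accession_ids=[f"acc{i:04d}" for i in range(n_acc)],
        chrom=chrom,
        pos=pos,
        ref=np.full(n_snps, "A"),
        alt=np.full(n_snps, "T"),
        genotypes=geno,
        subpop=subpop,
    )
    panel.validate()

    # ---- ground truth ------------------------------------------------------
    loci: list[TruthLocus] = []
    presence: dict = {}
    serial: dict[int, int] = {}
    locus_id_of_block: dict[int, str] = {}
    raw_effects = []
    for bi in qtl_idx:
        block = blocks[bi]
        serial[block.chrom] = serial.get(block.chrom, 0) + 1
        locus_id = f"q{config.trait}-{block.chrom:02d}-{serial[block.chrom]}"
        locus_id_of_block[bi] = locus_id
        alleles = [block.hap_str(h) for h in range(len(block.haps))]
        eff = rng.normal(size=len(alleles))
        eff -= eff.mean()
        raw_effects.append(eff)
        loci.append(TruthLocus(
            locus_id=locus_id,
            block_index=bi,
            chrom=block.chrom,
            start=int(block.positions[0]),
            end=int(block.positions[-1]),
            snp_indices=block.snp_indices,
            alleles=alleles,
            effects={},
            codes=assignments[bi].copy(),
        ))
        presence[locus_id] = {
            pop: {block.hap_str(h)
                  for h in np.flatnonzero(counts_by_pop[bi][pop] > 0)}
            for pop in SUBPOPS
        }

    # scale effects per locus so every QTL contributes the same share of the
    # genetic variance (each locus individually detectable), then rescale
    # jointly so the realised variance of the summed QTL values is qtl_sd^2
    per_locus_var = config.qtl_sd ** 2 / config.n_qtl
    for locus, eff in zip(loci, raw_effects):
        v = eff[locus.codes].var()
        if v <= 0:
            raise ConfigError(
                f"QTL {locus.locus_id} is monomorphic in the panel"
            )
        eff *= np.sqrt(per_locus_var / v)
    g_raw = np.zeros(n_acc)
    for locus, eff in zip(loci, raw_effects):
        g_raw += eff[locus.codes]
    sd = g_raw.std()
    if sd <= 0:
        raise ConfigError("degenerate QTL architecture: zero genetic variance")
    scale = config.qtl_sd / sd
    for locus, eff in zip(loci, raw_effects):
        scaled = eff * scale
        scaled -= scaled.mean()
        locus.effects = {a: float(e) for a, e in zip(locus.alleles, scaled)}

    planted = _planted_ledger(events, blocks, locus_id_of_block)
    truth = GroundTruth(loci=loci, presence=presence, planted=planted)
    truth.validate()
    return panel, truth


def _pad(counts: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros(n, dtype=np.int64)
    out[: len(counts)] = counts
    return out


def _drift_counts(
    parent_counts: np.ndarray,
    n_child: int,
    config: SimConfig,
    rng: np.random.Generator,
    add: dict[int, float],
    drop: set[int],
) -> np.ndarray:
    """Resample haplotype counts for a derived subpopulation.

    Frequencies drift around the parent's realised frequencies via a Dirichlet
    draw with concentration ``drift``; planted additions get the configured
    emergence frequency and planted drops are removed before sampling.
    """
    n_hap = len(parent_counts)
    base = parent_counts.astype(float)
    for h in drop:
        base[h] = 0.0
    present = np.flatnonzero(base > 0)
    if len(present) == 0:
        raise ConfigError("a block lost all haplotypes during derivation")
    alpha = base[present] / base[present].sum() * config.drift
    freqs = np.zeros(n_hap)
    freqs[present] = rng.dirichlet(alpha)
    for h, f in add.items():
        freqs *= (1.0 - f)
        freqs[h] += f
    freqs /= freqs.sum()
    return rng.multinomial(n_child, freqs)


def _enforce_presence(
    counts: np.ndarray,
    required: set[int],
    banned: set[int],
    min_carriers: int,
) -> np.ndarray:
    """Deterministically adjust sampled counts so the realised presence sets
    on QTL blocks match the planted intent exactly."""
    counts = counts.astype(np.int64).copy()
    for h in banned:
        if counts[h] > 0:
            counts[int(np.argmax(np.where(np.isin(np.arange(len(counts)),
                                                  list(banned)), -1, counts)))] += counts[h]
            counts[h] = 0
    if required and counts.sum() < min_carriers * len(required):
        raise ConfigError("subpopulation too small to carry all required alleles")
    for h in sorted(required):
        while counts[h] < min_carriers:
            eligible = [i for i in range(len(counts))
                        if i != h and counts[i] > (min_carriers if i in required else 0)]
            if not eligible:
                raise ConfigError("cannot enforce allele presence: no donor carriers")
            donor = max(eligible, key=lambda i: counts[i])
            counts[donor] -= 1
            counts[h] += 1
    return counts


def _select_qtl_blocks(
    config: SimConfig,
    blocks: list[_Block],
    candidates: list[int],
    rng: np.random.Generator,
) -> list[int]:
    """Pick QTL blocks so the planted events fit.

    Each planted event occupies its own locus, so the selection must include
    enough blocks with >= 3 founder haplotypes (exclusions keep the donor
    polymorphic) and enough with spare mutation capacity (emergences append a
    novel haplotype).
    """
    shuffled = list(candidates)
    rng.shuffle(shuffled)
    need_excl = config.n_excluded_lr + config.n_excluded_rc
    need_emerge = config.n_emerged_lr + config.n_emerged_rc
    chosen: list[int] = []

    def claim(predicate, need, label):
        taken = 0
        for bi in list(shuffled):
            if taken == need:
                break
            if predicate(blocks[bi]):
                chosen.append(bi)
                shuffled.remove(bi)
                taken += 1
        if taken < need:
            raise ConfigError(
                f"cannot place planted events: only {taken} of {need} blocks "
                f"suitable for '{label}'; increase snp_count"
            )

    claim(lambda b: len(b.haps) >= 3, need_excl, "exclusion")
    claim(lambda b: b.spare >= 1, need_emerge, "emergence")
    n_fill = config.n_qtl - len(chosen)
    if n_fill < 0:
        raise ConfigError("more planted events than QTLs; raise n_qtl")
    chosen.extend(shuffled[:n_fill])
    if len(chosen) < config.n_qtl:
        raise ConfigError("not enough candidate blocks for the requested QTLs")
    return sorted(chosen)


def _plan_events(
    config: SimConfig,
    blocks: list[_Block],
    qtl_idx: list[int],
    rng: np.random.Generator,
) -> dict:
    """Assign planted emergence/exclusion/recovery events to distinct QTL loci."""
    events: dict = {k: {} for k in ("emerged_lr", "excluded_lr", "emerged_rc",
                                    "excluded_rc", "recovered_rc")}
    events["new_locus_lr"] = []
    events["new_locus_rc"] = []

    shuffled = list(qtl_idx)
    rng.shuffle(shuffled)
    pool = list(shuffled)

    def take(predicate, label, prefer=None):
        # prefer blocks that cannot serve the other event kind, so scarce
        # dual-capability blocks stay available
        if prefer is not None:
            for i, bi in enumerate(pool):
                if predicate(blocks[bi]) and prefer(blocks[bi]):
                    return pool.pop(i)
        for i, bi in enumerate(pool):
            if predicate(blocks[bi]):
                return pool.pop(i)
        raise ConfigError(f"no QTL block available for planted event '{label}'")

    # emergences need spare mutation capacity
    for i in range(config.n_emerged_lr):
        bi = take(lambda b: b.spare >= 1, "emerged_lr",
                  prefer=lambda b: len(b.haps) < 3)
        events["emerged_lr"][bi] = True
        if i < config.n_new_loci_lr:
            events["new_locus_lr"].append(bi)
    for i in range(config.n_emerged_rc):
        bi = take(lambda b: b.spare >= 1, "emerged_rc",
                  prefer=lambda b: len(b.haps) < 3)
        events["emerged_rc"][bi] = True
        if i < config.n_new_loci_rc:
            events["new_locus_rc"].append(bi)
    # exclusions need >= 3 founder haplotypes so the subpopulation stays
    # polymorphic after the loss
    for i in range(config.n_excluded_lr):
        bi = take(lambda b: len(b.haps) >= 3, "excluded_lr",
                  prefer=lambda b: b.spare == 0)
        # drop the least-frequent founder haplotype
        events["excluded_lr"][bi] = int(np.argmin(blocks[bi].base_freqs))
        if i < config.n_recovered_rc:
            events["recovered_rc"][bi] = events["excluded_lr"][bi]
    for i in range(config.n_excluded_rc):
        bi = take(lambda b: len(b.haps) >= 3, "excluded_rc",
                  prefer=lambda b: b.spare == 0)
        events["excluded_rc"][bi] = int(np.argmin(blocks[bi].base_freqs))
    return events


def _planted_ledger(
    events: dict, blocks: list[_Block], locus_id_of_block: dict[int, str]
) -> dict:
    """Express the planted events as (locus, allele-string) pairs per
    comparison, in the shape the allele-evolution accounting reports."""
    def pairs(mapping, allele_of):
        out = []
        for bi in sorted(mapping):
            out.append((locus_id_of_block[bi], allele_of(bi)))
        return out

    novel_lr = {bi: len(blocks[bi].haps) - (2 if bi in events["emerged_rc"] else 1)
                for bi in events["emerged_lr"]}
    novel_rc = {bi: len(blocks[bi].haps) - 1 for bi in events["emerged_rc"]}

    lr_vs_wa = {
        "emerged": pairs(events["emerged_lr"],
                         lambda bi: blocks[bi].hap_str(novel_lr[bi])),
        "excluded": pairs(events["excluded_lr"],
                          lambda bi: blocks[bi].hap_str(events["excluded_lr"][bi])),
        "recovered": [],
    }
    rc_vs_lr = {
        "emerged": pairs(events["emerged_rc"],
                         lambda bi: blocks[bi].hap_str(novel_rc[bi])),
        "excluded": pairs(events["excluded_rc"],
                          lambda bi: blocks[bi].hap_str(events["excluded_rc"][bi])),
        "recovered": pairs(events["recovered_rc"],
                           lambda bi: blocks[bi].hap_str(events["recovered_rc"][bi])),
    }
    # union comparison: everything novel survives into LR+RC; a WA allele is
    # absent from the union only if excluded in LR and never recovered
    union_excluded = [p for p in lr_vs_wa["excluded"]
                      if p not in rc_vs_lr["recovered"]]
    lrrc_vs_wa = {
        "emerged": sorted(lr_vs_wa["emerged"] + rc_vs_lr["emerged"]),
        "excluded": union_excluded,
        "recovered": [],
    }
    return {"LR_vs_WA": lr_vs_wa, "RC_vs_LR": rc_vs_lr, "LRRC_vs_WA": lrrc_vs_wa}


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    panel: SnpPanel,
    truth: GroundTruth,
    config: SimConfig,
) -> pd.DataFrame:
    """Simulate replicated incomplete-block trait records.

    Each accession's genetic value is the sum of its carried QTL-allele
    effects plus a polygenic residual scaled so the genotypic variance and
    the best-time-point error variance hit ``target_h2`` and ``qtl_pv_share``
    exactly; observations add a per-block Gaussian effect, an optional
    group-environment shift, and per-time-point Gaussian error following the
    U-shaped error schedule.  Returns a long-format table with columns
    accession_id, subpop, group, replicate, block, timepoint, trait, value,
    and records the realised variance components on ``truth``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    n = panel.n_accessions

    g_qtl = np.zeros(n)
    for locus in truth.loci:
        eff = np.array([locus.effects[a] for a in locus.alleles])
        g_qtl += eff[locus.codes]

    var_qtl = float(g_qtl.var())
    pv = var_qtl / config.qtl_pv_share
    sigma_g2 = config.target_h2 * pv
    sigma_poly2 = sigma_g2 - var_qtl
    sigma_e2_best = config.n_replicates * (pv - sigma_g2)

    poly = rng.normal(size=n)
    # orthogonalise against the QTL values and rescale so the realised
    # genotypic variance equals sigma_g2 exactly
    poly -= poly.mean()
    gq = g_qtl - g_qtl.mean()
    if gq.std() > 0:
        poly -= (poly @ gq) / (gq @ gq) * gq
    if sigma_poly2 > 0 and poly.std() > 0:
        poly *= np.sqrt(sigma_poly2) / poly.std()
    else:
        poly = np.zeros(n)
    g = g_qtl + poly

    schedule = np.array(config.schedule())
    best = int(np.argmin(schedule))
    sigma_e2 = sigma_e2_best * schedule

    # randomized incomplete block design: two experiment groups, each with
    # n_replicates replicates split into incomplete blocks
    order = rng.permutation(n)
    half = n // 2
    group = np.empty(n, dtype=np.int64)
    group[order[:half]] = 1
    group[order[half:]] = 2
    group_shift = rng.normal(0.0, config.group_shift_sd, size=2)

    records = []
    for grp in (1, 2):
        members = np.flatnonzero(group == grp)
        for rep in range(1, config.n_replicates + 1):
            perm = rng.permutation(members)
            block_ids = np.arange(len(perm)) % config.n_blocks_per_replicate
            block_eff = rng.normal(0.0, config.block_sd,
                                   size=config.n_blocks_per_replicate)
            eps = rng.normal(
                0.0, 1.0, size=(len(perm), config.n_timepoints)
            ) * np.sqrt(sigma_e2)[None, :]
            for j, acc in enumerate(perm):
                base = (config.trait_mean + g[acc] + group_shift[grp - 1]
                        + block_eff[block_ids[j]])
                for t in range(config.n_timepoints):
                    records.append((
                        panel.accession_ids[acc],
                        panel.subpop[acc] if panel.subpop is not None else "",
                        grp, rep, f"g{grp}r{rep}b{block_ids[j] + 1}",
                        t, config.trait, base + eps[j, t],
                    ))

    realized_g2 = float(g.var())
    truth.population_mean = config.trait_mean
    truth.best_timepoint = best
    truth.realized_h2 = realized_g2 / (realized_g2 + sigma_e2_best / config.n_replicates) \
        if (realized_g2 + sigma_e2_best) > 0 else 1.0
    truth.variances = {
        "var_qtl": var_qtl,
        "sigma_g2": sigma_g2,
        "sigma_poly2": sigma_poly2,
        "sigma_e2_best": sigma_e2_best,
        "phenotypic_variance": pv,
    }
    return pd.DataFrame.from_records(
        records,
        columns=["accession_id", "subpop", "group", "replicate", "block",
                 "timepoint", "trait", "value"],
    )


# ---------------------------------------------------------------------------
# reflectance
# ---------------------------------------------------------------------------

def simulate_reflectance(
    target_ndvi: float,
    target_chl: float,
    r_nir: Optional[float] = None,
) -> ReflectanceRecord:
    """Invert the spectral-index formulas: return band reflectances whose
    NDVI and CHL equal the targets exactly.

    NDVI = (R_NIR - R_red)/(R_NIR + R_red) gives
    R_red = R_NIR (1 - v)/(1 + v); CHL = 1/R_700 - 1/R_NIR gives
    R_700 = 1/(CHL + 1/R_NIR).  When ``r_nir`` is not given it is chosen so
    R_red stays within (0, 1] for negative NDVI targets.  Raises for target
    combinations that need a reflectance outside (0, 1].
    """
    if not (-1.0 < target_ndvi < 1.0):
        raise ValueError(f"target NDVI must be in (-1, 1), got {target_ndvi}")
    if r_nir is None:
        # R_red = R_NIR (1-v)/(1+v) <= 1 requires R_NIR <= (1+v)/(1-v)
        r_nir = min(0.5, 0.5 * (1.0 + target_ndvi) / (1.0 - target_ndvi))
    if not (0.0 < r_nir <= 1.0):
        raise ValueError(f"R_NIR must be in (0, 1], got {r_nir}")
    r_red = r_nir * (1.0 - target_ndvi) / (1.0 + target_ndvi)
    if not (0.0 < r_red <= 1.0):
        raise ValueError(
            f"target NDVI {target_ndvi} needs R_red={r_red:.4f} outside (0, 1]"
        )
    denom = target_chl + 1.0 / r_nir
    if denom < 1.0:
        raise ValueError(
            f"target CHL {target_chl} unattainable with R_NIR={r_nir}"
        )
    r_700 = 1.0 / denom
    rec = ReflectanceRecord(r_nir=r_nir, r_red=r_red, r_700=r_700)
    assert abs(compute_ndvi(rec) - target_ndvi) < 1e-9
    assert abs(compute_chl(rec) - target_chl) < 1e-9
    return rec
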