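"""MAF filtering, D' block partition, SNPLDB assembly, similarity, eigenvectors."""

import numpy as np
import pytest

from haploqtl.snpldb import (MISSING, LdBlock, PanelError, SnpPanel,
                             assemble_snpldb, dprime_ci, eigen_covariates,
                             filter_maf, partition_blocks, similarity_matrix)


def make_panel(geno, pos=None, chrom=None):
    geno = np.asarray(geno, dtype=np.int8)
    n_acc, n_snp = geno.shape
    return SnpPanel(
        accession_ids=[f"a{i}" for i in range(n_acc)],
        chrom=np.asarray(chrom) if chrom is not None else np.ones(n_snp, dtype=int),
        pos=np.asarray(pos) if pos is not None else np.arange(1, n_snp + 1) * 100,
        ref=np.full(n_snp, "A"),
        alt=np.full(n_snp, "T"),
        genotypes=geno,
    )


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------

def test_maf_filter_six_carrier_rule():
    """At the 2% floor in a 341-accession panel, an allele carried by five
    accessions is dropped and one carried by six is kept."""
    n = 341
    five = np.zeros(n); five[:5] = 1
    six = np.zeros(n); six[:6] = 1
    mono = np.zeros(n)
    common = np.zeros(n); common[:170] = 1
    panel = make_panel(np.column_stack([five, six, mono, common]))
    kept, removed = filter_maf(panel, 0.02)
    assert removed == 2
    assert kept.n_snps == 2
    np.testing.assert_array_equal(kept.pos, [200, 400])


def test_maf_filter_rejects_bad_inputs():
    panel = make_panel(np.zeros((4, 0)))
    with pytest.raises(PanelError):
        filter_maf(panel)
    with pytest.raises(PanelError):
        filter_maf(make_panel(np.zeros((4, 2))), floor=0.7)


# ---------------------------------------------------------------------------
# D' confidence intervals and block partition
# ---------------------------------------------------------------------------

def _dprime_ci_oracle(a, b, step=0.001, tail=0.05):
    """Independent scalar-loop reimplementation of the likelihood-grid CI."""
    import math

    pairs = [(x, y) for x, y in zip(a, b) if x >= 0 and y >= 0]
    n = len(pairs)
    pa = sum(x for x, _ in pairs) / n
    pb = sum(y for _, y in pairs) / n
    if pa in (0, 1) or pb in (0, 1):
        return None
    n11 = sum(1 for x, y in pairs if x == 1 and y == 1)
    n10 = sum(1 for x, y in pairs if x == 1 and y == 0)
    n01 = sum(1 for x, y in pairs if x == 0 and y == 1)
    n00 = n - n11 - n10 - n01
    d_mle = n11 / n - pa * pb
    sign = 1.0 if d_mle >= 0 else -1.0
    d_max = (min(pa * (1 - pb), (1 - pa) * pb) if sign > 0
             else min(pa * pb, (1 - pa) * (1 - pb)))
    grid, liks = [], []
    g = 0.0
    while g <= 1.0 + 1e-12:
        d = sign * g * d_max
        ps = [pa * pb + d, pa * (1 - pb) - d, (1 - pa) * pb - d,
              (1 - pa) * (1 - pb) + d]
        ps = [max(p, 1e-12) for p in ps]
        ll = (n11 * math.log(ps[0]) + n10 * math.log(ps[1])
              + n01 * math.log(ps[2]) + n00 * math.log(ps[3]))
        grid.append(g)
        liks.append(ll)
        g += step
    peak = max(liks)
    weights = [math.exp(v - peak) for v in liks]
    total = sum(weights)
    cum, low, high = 0.0, None, None
    for g, w in zip(grid, weights):
        cum += w / total
        if low is None and cum >= tail:
            low = g
        if high is None and cum >= 1 - tail:
            high = g
    return low, high


def test_dprime_ci_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    for _ in range(10):
        a = rng.integers(0, 2, size=80)
        b = np.where(rng.random(80) < 0.8, a, rng.integers(0, 2, size=80))
        got = dprime_ci(a, b)
        want = _dprime_ci_oracle(a.tolist(), b.tolist())
        assert got == pytest.approx(want, abs=1e-9)


def test_identical_columns_form_one_block():
    col = np.array([0, 1] * 20)
    panel = make_panel(np.column_stack([col, col]), pos=[100, 200])
    blocks = partition_blocks(panel)
    assert len(blocks) == 1
    assert blocks[0].n_snps == 2


def test_equilibrium_pair_stays_split():
    # all four haplotypes at equal frequency: D' = 0
    a = np.repeat([0, 0, 1, 1], 25)
    b = np.tile([0, 1], 50)
    panel = make_panel(np.column_stack([a, b]), pos=[100, 200])
    blocks = partition_blocks(panel)
    assert [b.n_snps for b in blocks] == [1, 1]


def _planted_block_panel(rng, n_acc=250):
    """Ten SNPs: a 4-SNP perfect-phylogeny block flanked by independent SNPs."""
    haps = np.array([
        [0, 0, 0, 0],
        [1, 0, 0, 0],
        [1, 1, 0, 0],
        [0, 0, 1, 0],
        [0, 0, 1, 1],
    ])
    assign = rng.choice(5, size=n_acc, p=[0.24, 0.19, 0.19, 0.19, 0.19])
    block = haps[assign]
    outside = (rng.random((n_acc, 6)) < 0.4).astype(np.int8)
    geno = np.column_stack([outside[:, :3], block, outside[:, 3:]])
    pos = [1_000, 60_000, 130_000,
           200_000, 201_000, 202_500, 204_000,
           300_000, 380_000, 460_000]
    return make_panel(geno, pos=pos)


def test_partition_recovers_planted_block():
    rng = np.random.default_rng(1)
    panel = _planted_block_panel(rng)
    blocks = partition_blocks(panel)
    multi = [b for b in blocks if b.n_snps > 1]
    assert len(multi) == 1
    assert multi[0].start == 200_000 and multi[0].end == 204_000
    assert multi[0].n_snps == 4
    assert len(blocks) == 7  # 6 singletons around the block


def test_partition_invariant_to_accession_order():
    rng = np.random.default_rng(2)
    panel = _planted_block_panel(rng)
    perm = rng.permutation(panel.n_accessions)
    shuffled = SnpPanel(
        accession_ids=[panel.accession_ids[i] for i in perm],
        chrom=panel.chrom, pos=panel.pos, ref=panel.ref, alt=panel.alt,
        genotypes=panel.genotypes[perm],
    )
    spans_a = [(b.start, b.end) for b in partition_blocks(panel)]
    spans_b = [(b.start, b.end) for b in partition_blocks(shuffled)]
    assert spans_a == spans_b


def test_partition_requires_sorted_panel():
    panel = make_panel(np.zeros((4, 3)), pos=[300, 100, 200])
    with pytest.raises(PanelError):
        partition_blocks(panel)


# ---------------------------------------------------------------------------
# SNPLDB assembly
# ---------------------------------------------------------------------------

def _one_block(geno):
    n_snp = np.asarray(geno).shape[1]
    panel = make_panel(geno)
    block = LdBlock(chrom=1, snp_indices=np.arange(n_snp), start=100,
                    end=int(panel.pos[-1]))
    return panel, [block]


def test_singleton_snp_becomes_biallelic_marker():
    col = np.array([0] * 30 + [1] * 10)
    panel, blocks = _one_block(col[:, None])
    markers = assemble_snpldb(panel, blocks)
    assert len(markers) == 1
    assert markers[0].n_alleles == 2
    np.testing.assert_allclose(sorted(markers[0].frequencies), [0.25, 0.75])


def test_haplotype_frequencies_counted_exactly():
    haps = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
    assign = np.repeat([0, 1, 2, 3], [40, 30, 20, 10])
    panel, blocks = _one_block(haps[assign])
    markers = assemble_snpldb(panel, blocks, maf_floor=0.02)
    assert markers[0].n_alleles == 4
    np.testing.assert_allclose(markers[0].frequencies, [0.4, 0.3, 0.2, 0.1])
    assert markers[0].haplotypes == ["00", "01", "10", "11"]


def test_rare_haplotype_merges_to_nearest_common():
    haps = np.array([[0, 0, 0], [1, 1, 1], [1, 1, 0]])
    # "110" is a single carrier (1%): merged to "111" (Hamming 1), not "000"
    assign = np.repeat([0, 1, 2], [50, 49, 1])
    panel, blocks = _one_block(haps[assign])
    markers = assemble_snpldb(panel, blocks, maf_floor=0.02)
    m = markers[0]
    assert m.n_alleles == 2
    assert set(m.haplotypes) == {"000", "111"}
    np.testing.assert_allclose(sorted(m.frequencies), [0.5, 0.5])
    assert (m.frequencies >= 0.02).all()
    assert m.frequencies.sum() == pytest.approx(1.0)


def test_eleven_haplotype_block_caps_at_eleven_alleles():
    rng = np.random.default_rng(3)
    k = 10
    haps = np.zeros((11, k), dtype=np.int8)
    for h in range(1, 11):
        haps[h] = haps[rng.integers(h)]
        haps[h, h - 1] ^= 1
    assign = np.repeat(np.arange(11), 20)
    panel, blocks = _one_block(haps[assign])
    markers = assemble_snpldb(panel, blocks, maf_floor=0.02)
    assert markers[0].n_alleles == 11


def test_missing_policy_within_block():
    haps = np.array([[0, 0, 0, 0, 0], [1, 1, 1, 1, 1]])
    geno = haps[np.repeat([0, 1], [30, 10])].copy()
    geno[0, 0] = MISSING                  # 20% missing: imputed to major
    geno[1, :2] = MISSING                 # 40% missing: accession missing
    panel, blocks = _one_block(geno)
    markers = assemble_snpldb(panel, blocks)
    m = markers[0]
    assert m.codes[1] == MISSING
    assert m.codes[0] >= 0
    assert m.haplotypes[m.codes[0]] == "00000"


# ---------------------------------------------------------------------------
# similarity and eigenvector covariates
# ---------------------------------------------------------------------------

def _markers_from_codes(code_matrix):
    markers = []
    for j, codes in enumerate(np.asarray(code_matrix).T):
        k = int(codes[codes >= 0].max()) + 1
        freqs = np.bincount(codes[codes >= 0], minlength=k).astype(float)
        freqs /= freqs.sum()
        markers.append(type("M", (), {})())
        m = markers[-1]
        m.marker_id, m.chrom, m.start, m.end = f"m{j}", 1, j * 1000 + 1, j * 1000 + 10
        m.haplotypes = [str(i) for i in range(k)]
        m.frequencies = freqs
        m.codes = codes
        m.n_alleles = k
    return markers


def test_similarity_hand_tally():
    codes = np.array([
        [0, 1, 0, 2],
        [0, 1, 1, 2],
        [1, 0, 1, 0],
    ])
    sim = similarity_matrix(_markers_from_codes(codes))
    assert sim[0, 1] == pytest.approx(3 / 4)
    assert sim[0, 2] == pytest.approx(0.0)
    assert sim[1, 2] == pytest.approx(1 / 4)
    np.testing.assert_allclose(np.diag(sim), 1.0)
    # duplicate accessions have similarity one
    dup = np.vstack([codes, codes[0]])
    sim2 = similarity_matrix(_markers_from_codes(dup))
    assert sim2[0, 3] == pytest.approx(1.0)


def test_similarity_positive_semidefinite_after_shift():
    rng = np.random.default_rng(4)
    codes = rng.integers(0, 3, size=(20, 40))
    sim = similarity_matrix(_markers_from_codes(codes))
    vals = np.linalg.eigvalsh(sim)
    assert vals.min() > -1e-8


def test_eigen_covariates_separate_two_clusters():
    block = np.ones((10, 10)) * 0.9
    sim = np.kron(np.eye(2), block) + 0.1
    np.fill_diagonal(sim, 1.0)
    cov = eigen_covariates(sim, share=0.5)
    v1 = cov.W[:, 0]
    assert (np.sign(v1[:10]) != np.sign(v1[10:])).all()
    # columns orthonormal
    gram = cov.W.T @ cov.W
    np.testing.assert_allclose(gram, np.eye(cov.m), atol=1e-10)


def test_flat_spectrum_m_grows_with_share():
    n = 30
    sim = np.full((n, n), 0.2)
    np.fill_diagonal(sim, 1.0)
    m_small = eigen_covariates(sim, share=0.2, max_covariates=None).m
    m_large = eigen_covariates(sim, share=0.9, max_covariates=None).m
    assert m_large > m_small


def test_eigen_rejects_asymmetric_input():
    bad = np.array([[1.0, 0.5], [0.2, 1.0]])
    with pytest.raises(PanelError):
        eigen_covariates(bad)
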