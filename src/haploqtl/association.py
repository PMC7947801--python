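"""Restricted two-stage multi-locus multi-allele association scan.

The model is ``y = 1*mu + W a + X b + e``: accession trait means ``y``,
eigenvector structure covariates ``W``, and a multi-marker design ``X`` in
which a k-allele SNPLDB marker contributes k-1 indicator columns against its
most frequent (reference) allele.

Stage 1 fits every marker alone against the covariate-only baseline and
pre-selects markers whose partial-F p-value is at most ``alpha1``.  Stage 2
runs forward selection with backward elimination over the pre-selected set
under the joint multi-locus model at significance ``alpha``; because the
multi-locus model controls the experiment-wise error rate internally, an
ordinary 0.05 threshold is used rather than a genome-wide correction.

Reported per-locus statistics: the partial-F -lg(P) of the marker in the
final joint model, sum-to-zero allele effects, and a sequential (entry-order)
R^2 decomposition whose per-locus values add up exactly to the joint marker
R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .snpldb import MISSING, SnpldbMarker

_RANK_TOL = 1e-8


class AssociationError(ValueError):
    pass


@dataclass
class QtlRecord:
    """One detected locus in the final multi-locus model."""

    marker_id: str
    chrom: object
    start: int
    end: int
    n_alleles: int
    neg_lg_p: float
    r2_pct: float
    effects: dict[str, float]    # allele -> effect, frequency-weighted sum 0


@dataclass
class ScanHit:
    marker: SnpldbMarker
    p_value: float
    f_stat: float


@dataclass
class AssociationResult:
    records: list[QtlRecord]
    markers: list[SnpldbMarker]          # selected, in final entry order
    mu_hat: float
    model_r2_pct: float                  # joint marker R^2 (percent)
    n_preselected: int
    trace: list[str] = field(default_factory=list)


def marker_design(marker: SnpldbMarker) -> np.ndarray:
    """k-1 indicator columns against the most frequent (reference) allele.

    The allele catalogue is frequency-ordered, so the reference is index 0.
    Missing calls are coded as the reference (all-zero row).
    """
    n = len(marker.codes)
    k = marker.n_alleles
    x = np.zeros((n, k - 1))
    for j in range(1, k):
        x[marker.codes == j, j - 1] = 1.0
    return x


def _basis(a: np.ndarray) -> np.ndarray:
    """Orthonormal basis for the column space of ``a`` (rank-revealing)."""
    if a.size == 0:
        return np.zeros((a.shape[0], 0))
    u, s, _ = np.linalg.svd(a, full_matrices=False)
    rank = int((s > _RANK_TOL * max(a.shape) * (s[0] if len(s) else 1.0)).sum())
    return u[:, :rank]


def _rss(design: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of an OLS fit."""
    q = _basis(design)
    resid = y - q @ (q.T @ y)
    return float(resid @ resid), q.shape[1]


def _partial_f(
    rss_reduced: float, rss_full: float, q: int, df2: int
) -> tuple[float, float]:
    if df2 <= 0 or rss_full <= 0:
        return np.inf, 0.0
    f = ((rss_reduced - rss_full) / q) / (rss_full / df2)
    f = max(f, 0.0)
    return f, float(stats.f.sf(f, q, df2))


def _genome_key(m: SnpldbMarker) -> tuple:
    return (str(m.chrom), m.start, m.marker_id)


# ---------------------------------------------------------------------------
# stage 1: single-marker pre-selection
# ---------------------------------------------------------------------------

def stage1_scan(
    y: np.ndarray,
    W: Optional[np.ndarray],
    markers: Sequence[SnpldbMarker],
    alpha1: float = 0.05,
) -> list[ScanHit]:
    """Single-marker partial-F pre-selection against the covariate baseline.

    Returns hits with p <= ``alpha1`` ordered by ascending p (genome order on
    ties).  Markers collinear with the covariates (or monomorphic) are skipped
    with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    base = np.ones((n, 1)) if W is None else np.column_stack([np.ones(n), W])
    qb = _basis(base)
    p0 = qb.shape[1]
    y_r = y - qb @ (qb.T @ y)
    rss0 = float(y_r @ y_r)
    hits = []
    for m in markers:
        x = marker_design(m)
        x_r = x - qb @ (qb.T @ x)
        qx = _basis(x_r)
        q = qx.shape[1]
        if q == 0:
            warnings.warn(
                f"marker {m.marker_id} is collinear with covariates; skipped"
            )
            continue
        resid = y_r - qx @ (qx.T @ y_r)
        rss1 = float(resid @ resid)
        f, p = _partial_f(rss0, rss1, q, n - p0 - q)
        if p <= alpha1:
            hits.append(ScanHit(marker=m, p_value=p, f_stat=f))
    hits.sort(key=lambda h: (h.p_value, _genome_key(h.marker)))
    return hits


# ---------------------------------------------------------------------------
# stage 2: stepwise multi-locus model
# ---------------------------------------------------------------------------

def stage2_stepwise(
    y: np.ndarray,
    W: Optional[np.ndarray],
    preselected: Sequence[SnpldbMarker],
    alpha: float = 0.05,
    max_steps: int = 200,
) -> tuple[list[SnpldbMarker], list[str]]:
    """Forward selection with backward elimination over pre-selected markers.

    Forward: add the candidate with the smallest partial-F p-value given the
    current model if p <= ``alpha`` (ties -> larger F, then ascending genome
    order).  After each addition, backward elimination repeatedly removes the
    worst included marker whose partial-F p-value exceeds ``alpha``.
    Candidates whose columns add no rank to the design are skipped.  Returns
    the selected markers in final entry order plus a step trace.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    base = np.ones((n, 1)) if W is None else np.column_stack([np.ones(n), W])
    designs = {m.marker_id: marker_design(m) for m in preselected}
    by_id = {m.marker_id: m for m in preselected}

    selected: list[str] = []
    trace: list[str] = []

    def model_matrix(ids: Sequence[str]) -> np.ndarray:
        parts = [base] + [designs[i] for i in ids]
        return np.column_stack(parts)

    rss_cur, rank_cur = _rss(base, y)
    for _ in range(max_steps):
        # ---- forward step ----
        best = None
        for m in preselected:
            if m.marker_id in selected:
                continue
            rss_new, rank_new = _rss(model_matrix(selected + [m.marker_id]), y)
            q = rank_new - rank_cur
            if q == 0:
                continue
            f, p = _partial_f(rss_cur, rss_new, q, n - rank_new)
            key = (p, -f, _genome_key(m))
            if best is None or key < best[0]:
                best = (key, m, rss_new, rank_new, p, f)
        if best is None or best[4] > alpha:
            break
        _, m_add, rss_cur, rank_cur, p_add, _ = best
        selected.append(m_add.marker_id)
        trace.append(f"add {m_add.marker_id} p={p_add:.3g}")

        # ---- backward elimination ----
        while len(selected) > 1:
            worst = None
            for mid in selected:
                rest = [s for s in selected if s != mid]
                rss_minus, rank_minus = _rss(model_matrix(rest), y)
                q = rank_cur - rank_minus
                if q == 0:
                    # marker contributes no rank; treat as removable (p = 1)
                    f, p = 0.0, 1.0
                else:
                    f, p = _partial_f(rss_minus, rss_cur, q, n - rank_cur)
                key = (p, f)
                if worst is None or key > worst[0]:
                    worst = (key, mid, rss_minus, rank_minus, p)
            if worst is None or worst[4] <= alpha:
                break
            _, mid, rss_cur, rank_cur, p_rm = worst
            selected.remove(mid)
            trace.append(f"drop {mid} p={p_rm:.3g}")
    return [by_id[i] for i in selected], trace


# ---------------------------------------------------------------------------
# final-model statistics
# ---------------------------------------------------------------------------

def neg_lg_p(
    y: np.ndarray,
    W: Optional[np.ndarray],
    selected: Sequence[SnpldbMarker],
    marker: SnpldbMarker,
) -> float:
    """-log10 of the marker's partial-F p-value in the final joint model."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    base = np.ones((n, 1)) if W is None else np.column_stack([np.ones(n), W])
    full = np.column_stack([base] + [marker_design(m) for m in selected])
    rest = np.column_stack(
        [base] + [marker_design(m) for m in selected if m.marker_id != marker.marker_id]
    )
    rss_full, rank_full = _rss(full, y)
    rss_rest, rank_rest = _rss(rest, y)
    q = rank_full - rank_rest
    if q == 0:
        return 0.0
    _, p = _partial_f(rss_rest, rss_full, q, n - rank_full)
    p = max(p, np.finfo(float).tiny)
    return float(-np.log10(p))


def allele_effects(
    y: np.ndarray,
    W: Optional[np.ndarray],
    selected: Sequence[SnpldbMarker],
    marker: SnpldbMarker,
) -> dict[str, float]:
    """Sum-to-zero allele effects of one marker in the final joint model.

    Least-squares allele coefficients (reference allele at zero) are
    re-expressed as deviations whose frequency-weighted sum is zero, so the
    effects are comparable across loci regardless of reference choice.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    base = np.ones((n, 1)) if W is None else np.column_stack([np.ones(n), W])
    parts = [base]
    spans: dict[str, slice] = {}
    col = base.shape[1]
    for m in selected:
        x = marker_design(m)
        spans[m.marker_id] = slice(col, col + x.shape[1])
        parts.append(x)
        col += x.shape[1]
    design = np.column_stack(parts)
    beta = np.linalg.lstsq(design, y, rcond=None)[0]
    raw = np.concatenate([[0.0], beta[spans[marker.marker_id]]])
    freqs = marker.frequencies
    centred = raw - float(freqs @ raw)
    return {a: float(e) for a, e in zip(marker.haplotypes, centred)}


def locus_r2(
    y: np.ndarray,
    W: Optional[np.ndarray],
    selected: Sequence[SnpldbMarker],
) -> dict[str, float]:
    """Sequential (entry-order) R^2 percentage per selected marker.

    Each marker's contribution is its incremental explained sum of squares
    after the intercept, covariates and all earlier entries, divided by the
    total corrected SS.  The per-locus values therefore sum exactly to the
    joint marker R^2, matching how additive per-locus contributions are
    tabulated.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    tss = float(((y - y.mean()) ** 2).sum())
    base = np.ones((n, 1)) if W is None else np.column_stack([np.ones(n), W])
    rss_prev, _ = _rss(base, y)
    out: dict[str, float] = {}
    design = base
    for m in selected:
        design = np.column_stack([design, marker_design(m)])
        rss_next, _ = _rss(design, y)
        out[m.marker_id] = 100.0 * (rss_prev - rss_next) / tss
        rss_prev = rss_next
    return out


def run_scan(
    y: np.ndarray,
    W: Optional[np.ndarray],
    markers: Sequence[SnpldbMarker],
    alpha1: float = 0.05,
    alpha: float = 0.05,
) -> AssociationResult:
    """Full two-stage scan: pre-selection, stepwise fit, per-locus statistics."""
    hits = stage1_scan(y, W, markers, alpha1=alpha1)
    pre = [h.marker for h in hits]
    if pre:
        selected, trace = stage2_stepwise(y, W, pre, alpha=alpha)
    else:
        selected, trace = [], []
    r2 = locus_r2(y, W, selected)
    records = []
    for m in selected:
        records.append(QtlRecord(
            marker_id=m.marker_id,
            chrom=m.chrom,
            start=m.start,
            end=m.end,
            n_alleles=m.n_alleles,
            neg_lg_p=neg_lg_p(y, W, selected, m),
            r2_pct=r2[m.marker_id],
            effects=allele_effects(y, W, selected, m),
        ))
    return AssociationResult(
        records=records,
        markers=list(selected),
        mu_hat=float(np.mean(y)),
        model_r2_pct=float(sum(r2.values())),
        n_preselected=len(pre),
        trace=trace,
    )
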