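"""Significance testing of TAD–TAD contacts.

For each eligible (linearly non-contiguous, intra-chromosomal) TAD pair
the observed aggregate contact count ``x`` is tested against Fisher's
non-central hypergeometric (NCHG) null

    P(X = y) ∝ C(n_a, y) · C(N - n_a, n_b - y) · ω**y

where ``n_a`` and ``n_b`` are the total contacts each TAD engages in,
``N`` the total contacts on the chromosome, and the odds parameter

    ω = E(a, b) · N / (n_a · n_b)

centers the null on the pair's distance-decay expectation
``E(a, b) = ω_d · n_a · n_b / N`` (with ω_d the size-normalized mean
enrichment of the pair's distance stratum) — so the test asks whether
two TADs touch more often than expected at their genomic separation
given how much contact each engages in overall.
P-values (upper tail, computed in log space) are corrected with
Benjamini–Hochberg FDR pooled over all tested pairs, and significant
pairs must additionally show at least ``min_fold`` observed/expected
enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .core import TadContactMatrix, TadPairTest, TadSegmentation

logger = logging.getLogger(__name__)

_OMEGA_TINY = 1e-12


def eligible_pairs(seg: TadSegmentation, include_gaps: bool = False) -> list[tuple[int, int]]:
    """Index pairs (into the segmentation) of testable TAD pairs.

    Pairs must be linearly non-contiguous: at least one other tested
    segment lies between them. Gap-filler segments are excluded unless
    ``include_gaps`` (and do not break the adjacency of flanking TADs).
    """
    idx = [i for i, s in enumerate(seg)
           if include_gaps or s.is_called_domain]
    pairs = []
    for a in range(len(idx)):
        for b in range(a + 2, len(idx)):  # rank difference >= 2
            pairs.append((idx[a], idx[b]))
    return pairs


@dataclass
class DistanceExpectationModel:
    """Distance-decay expectation for TAD-pair contacts.

    Pairs are assigned to log-spaced strata of midpoint-separation bp.
    Each stratum carries two statistics over its observed pairs:

    * ``mean_count`` — the raw mean observed count E_d (reported as the
      stratum-level expectation);
    * ``mean_ratio`` — the mean of x · N / (n_a · n_b), i.e. the
      distance-specific enrichment over the size-product baseline.

    The pair-level expectation E(a, b) = mean_ratio_d · n_a · n_b / N
    conditions on both TADs' contact totals, so two TADs of very
    different coverage at the same separation are not held to the same
    raw count. Empty strata inherit the nearest non-empty stratum's
    values.
    """

    edges: np.ndarray        # len n_strata + 1, increasing
    mean_count: np.ndarray   # len n_strata
    mean_ratio: np.ndarray   # len n_strata
    global_mean: float

    def _stratum(self, distance_bp: float) -> int:
        k = int(np.searchsorted(self.edges, distance_bp, side="right")) - 1
        return min(max(k, 0), len(self.mean_count) - 1)

    def expected_count(self, distance_bp: float) -> float:
        """Raw mean observed count E_d in the stratum of this distance."""
        return float(self.mean_count[self._stratum(distance_bp)])

    def odds(self, distance_bp: float) -> float:
        """Distance-specific odds (size-normalized enrichment) omega_d."""
        return float(self.mean_ratio[self._stratum(distance_bp)])

    def expected_pair(self, distance_bp: float, n_a: int, n_b: int,
                      total: int) -> float:
        return self.odds(distance_bp) * n_a * n_b / total


def _fill_empty(values: np.ndarray) -> np.ndarray:
    filled = np.flatnonzero(~np.isnan(values))
    for k in np.flatnonzero(np.isnan(values)):
        values[k] = values[filled[np.argmin(np.abs(filled - k))]]
    return values


def fit_distance_expectation(tad_matrix: TadContactMatrix, n_strata: int = 30,
                             include_gaps: bool = False) -> DistanceExpectationModel:
    """Fit the distance-decay expectation over eligible TAD pairs."""
    seg = tad_matrix.segmentation
    pairs = eligible_pairs(seg, include_gaps=include_gaps)
    if not pairs:
        raise ValueError("no eligible (non-adjacent) TAD pairs to fit on")
    mids = np.array([s.interval.midpoint for s in seg])
    dist = np.array([abs(mids[j] - mids[i]) for i, j in pairs], dtype=float)
    obs = np.array([tad_matrix.matrix[i, j] for i, j in pairs])
    row_tot = tad_matrix.matrix.sum(axis=1)
    total = tad_matrix.matrix.sum()
    size_prod = np.array([row_tot[i] * row_tot[j] for i, j in pairs])
    ok = size_prod > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ok, obs * total / np.where(ok, size_prod, 1.0), np.nan)

    lo, hi = dist.min(), dist.max()
    if lo == hi:
        edges = np.array([lo, hi + 1.0])
    else:
        edges = np.geomspace(lo, hi, n_strata + 1)
        edges[-1] *= 1.0 + 1e-9  # include the max distance
    n = len(edges) - 1
    which = np.clip(np.searchsorted(edges, dist, side="right") - 1, 0, n - 1)
    mean_count = np.full(n, np.nan)
    mean_ratio = np.full(n, np.nan)
    for k in range(n):
        sel = which == k
        if sel.any():
            mean_count[k] = obs[sel].mean()
            mean_ratio[k] = np.nanmean(ratio[sel])
    return DistanceExpectationModel(edges, _fill_empty(mean_count),
                                    _fill_empty(mean_ratio), float(obs.mean()))


def nchg_logpmf(support: np.ndarray, n_a: int, n_b: int, total: int,
                omega: float, lgamma: np.ndarray | None = None) -> np.ndarray:
    """Normalized log-pmf of Fisher's NCHG over the given support.

    ``lgamma``, when given, is a precomputed table of gammaln(0..total+1)
    used to avoid repeated gammaln evaluation in genome-wide scans.
    """
    y = support
    lg = (lambda v: lgamma[v]) if lgamma is not None else (lambda v: gammaln(np.asarray(v, dtype=float)))
    log_unnorm = (
        lg(n_a + 1) - lg(y + 1) - lg(n_a - y + 1)
        + lg(total - n_a + 1) - lg(n_b - y + 1)
        - lg(total - n_a - n_b + y + 1)
        + y * np.log(omega)
    )
    return log_unnorm - logsumexp(log_unnorm)


def nchg_support(n_a: int, n_b: int, total: int) -> np.ndarray:
    lo = max(0, n_a + n_b - total)
    hi = min(n_a, n_b)
    if lo > hi:
        raise ValueError(f"empty NCHG support for n_a={n_a}, n_b={n_b}, N={total}")
    return np.arange(lo, hi + 1)


def nchg_pvalue(x: int, n_a: int, n_b: int, total: int, omega: float,
                lgamma: np.ndarray | None = None) -> float:
    """Upper-tail probability P(X >= x) under Fisher's NCHG."""
    if omega <= 0:
        raise ValueError("odds parameter must be > 0")
    support = nchg_support(n_a, n_b, total)
    if x < support[0] or x > support[-1]:
        raise ValueError(f"x={x} outside NCHG support [{support[0]}, {support[-1]}]")
    logpmf = nchg_logpmf(support, n_a, n_b, total, omega, lgamma=lgamma)
    p = float(np.exp(logsumexp(logpmf[support >= x])))
    return min(p, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def test_pairs(tad_matrix: TadContactMatrix,
               model: DistanceExpectationModel | None = None,
               n_strata: int = 30,
               include_gaps: bool = False) -> list[TadPairTest]:
    """NCHG p-values for all eligible pairs of one chromosome (no FDR yet)."""
    if model is None:
        model = fit_distance_expectation(tad_matrix, n_strata=n_strata,
                                         include_gaps=include_gaps)
    seg = tad_matrix.segmentation
    mat = tad_matrix.matrix
    row_tot = mat.sum(axis=1)
    total = int(mat.sum())
    lgamma = gammaln(np.arange(total + 2, dtype=float))
    mids = np.array([s.interval.midpoint for s in seg])
    out = []
    for i, j in eligible_pairs(seg, include_gaps=include_gaps):
        n_a, n_b = int(row_tot[i]), int(row_tot[j])
        if n_a == 0 or n_b == 0:
            logger.info("skipping zero-contact pair %s-%s",
                        seg.segments[i].id, seg.segments[j].id)
            continue
        x = int(round(mat[i, j]))
        dist = int(abs(mids[j] - mids[i]))
        # p-value: null centered on the size-aware pair expectation
        # omega_d * n_a * n_b / N; fold filter: distance-only expectation
        omega = max(model.odds(dist), _OMEGA_TINY)
        p = nchg_pvalue(x, n_a, n_b, total, omega, lgamma=lgamma)
        out.append(TadPairTest(
            tad_a=seg.segments[i].id, tad_b=seg.segments[j].id,
            distance_bp=dist, observed=x, n_a=n_a, n_b=n_b, total_n=total,
            expected=model.expected_count(dist), odds=omega, p_value=p))
    return out


def call_significant_interactions(
    tad_matrices: TadContactMatrix | list[TadContactMatrix],
    fdr: float = 0.01,
    min_fold: float = 5.0,
    n_strata: int = 30,
    include_gaps: bool = False,
) -> list[TadPairTest]:
    """Run the NCHG test and flag significant pairs.

    FDR correction is pooled over all chromosomes supplied. A pair is
    significant iff its q-value is below ``fdr`` and its observed count
    is at least ``min_fold`` times the distance expectation.
    """
    if isinstance(tad_matrices, TadContactMatrix):
        tad_matrices = [tad_matrices]
    pairs: list[TadPairTest] = []
    for tm in tad_matrices:
        pairs.extend(test_pairs(tm, n_strata=n_strata, include_gaps=include_gaps))
    if not pairs:
        return pairs
    q = bh_fdr([t.p_value for t in pairs])
    for t, qv in zip(pairs, q):
        t.q_value = float(qv)
        t.significant = bool(qv < fdr and t.fold >= min_fold)
    return pairs


def pairs_to_dataframe(pairs: list[TadPairTest]):
    import pandas as pd

    return pd.DataFrame({
        "tad_a": [t.tad_a for t in pairs],
        "tad_b": [t.tad_b for t in pairs],
        "distance_bp": [t.distance_bp for t in pairs],
        "observed": [t.observed for t in pairs],
        "expected": [t.expected for t in pairs],
        "odds": [t.odds for t in pairs],
        "p": [t.p_value for t in pairs],
        "q": [t.q_value for t in pairs],
        "fold": [t.fold for t in pairs],
        "significant": [t.significant for t in pairs],
    })
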