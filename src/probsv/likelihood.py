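"""Poisson likelihoods for candidate structural variants.

Fragment starts are modelled as a uniform Poisson process with rate ``lam``
(fragments per base, Lander-Waterman). Consequences used throughout:

* point coverage by concordant fragments ~ Poisson(lam_c), lam_c = lam * Lavg;
* the number of discordant fragments straddling a breakend
  ~ Poisson(lam_d), lam_d = (Lavg - 2*readlength) * lam;
* concordant fragments overlapping a deleted interval I = [amax, bmin]
  ~ Poisson(lam_I), lam_I = lam * (bmin - amax + Lavg).

A candidate variant V = (F, B) with k supporting discordant fragments is scored
under copy number c in {0, 1, 2} of the novel adjacency (0 = no variant,
1 = heterozygous, 2 = homozygous). For the generic breakend model the
copy-conditional probability is maximized over candidate breakend pairs
(a, b) in B; for deletions the read-depth over the whole implied interval is
used instead. The call statistic is the log likelihood ratio

    log Lambda(V) = max(log P(V|c=2), log P(V|c=1)) - log P(V|c=0).

Concordant counts over an interval are scaled by local mapability,
``n_hat = n / (alpha + beta * R)``; scaled counts are non-integral, so Poisson
terms use the gamma-function extension of log k!. Regions whose concordant
coverage is in the extreme upper tail of the Poisson model (above the
``cap_quantile`` quantile) are forced to c = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .fragments import ConcordantIndex, MapabilityTrack
from .geometry import BreakendPolygon, CandidateVariant, TrapezoidRegion

__all__ = [
    "ModelParams",
    "VariantScore",
    "poisson_log_pmf",
    "copy_conditional_logprob",
    "scale_concordant_count",
    "coverage_cap",
    "candidate_breakend_pairs",
    "score_breakend_variant",
    "score_deletion_variant",
    "ColumnModel",
    "column_model",
]

_NEG_INF = float("-inf")
_log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelParams:
    """Global parameters of the probabilistic model.

    lam          fragments per base (Poisson process rate); 0.3 corresponds
                 to ~60x fragment coverage with 200 bp fragments.
    lavg         mean fragment length (bases).
    readlength   read length (bases).
    p_err        probability that a fragment's mapping is erroneous.
    eta          rate of the exponential prior on the number of variants.
    alpha_map, beta_map
                 mapability scaling weights of n_hat = n/(alpha + beta R).
    cap_quantile coverage above this Poisson quantile forces c = 0.
    """

    lam: float
    lavg: float
    readlength: int
    p_err: float = 0.01
    eta: float = 1e-3
    alpha_map: float = 0.3
    beta_map: float = 0.7
    cap_quantile: float = 0.9999

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not 0 < self.p_err < 1:
            raise ValueError("p_err must lie in (0, 1)")
        if self.lavg <= 2 * self.readlength:
            raise ValueError("Lavg must exceed twice the read length "
                             "(otherwise lam_d would be negative)")
        if abs(self.alpha_map + self.beta_map - 1.0) > 1e-9:
            raise ValueError("alpha_map + beta_map must equal 1")

    @property
    def lam_c(self) -> float:
        """Poisson mean of point coverage by concordant fragments."""
        return self.lam * self.lavg

    @property
    def lam_d(self) -> float:
        """Poisson mean of breakend-straddling discordant fragments."""
        return (self.lavg - 2 * self.readlength) * self.lam

    @property
    def log_perr(self) -> float:
        return float(np.log(self.p_err))

    def lam_interval(self, length: int) -> float:
        """Poisson mean of concordant fragments overlapping an interval of the
        given (closed) length: lam * (length - 1 + Lavg)."""
        return self.lam * (length - 1 + self.lavg)


@dataclass
class VariantScore:
    """Likelihood-ratio score of one candidate variant."""

    log_lambda: float
    best_pair: tuple[int, int]
    copy_call: int
    logp: dict[int, float]
    model: str  # 'breakend' or 'deletion'
    k: int
    capped: bool = False
    n_a: int | None = None
    n_b: int | None = None
    n_interval: int | None = None
    n_hat: float | None = None
    r_map: float | None = None


def poisson_log_pmf(mean, k):
    """log Pois(mean; k) with Pois(0; 0) = 1 and the gamma-function extension
    of log k! for non-integer k (used for mapability-scaled counts)."""
    mean_arr = np.asarray(mean, dtype=float)
    k_arr = np.asarray(k, dtype=float)
    if np.any(mean_arr < 0):
        raise ValueError("mean must be non-negative")
    if np.any(k_arr < 0):
        raise ValueError("k must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            mean_arr > 0,
            k_arr * np.log(np.where(mean_arr > 0, mean_arr, 1.0)) - mean_arr
            - gammaln(k_arr + 1),
            np.where(k_arr == 0, 0.0, _NEG_INF),
        )
    if out.ndim == 0:
        return float(out)
    return out


def copy_conditional_logprob(c: int, k, n_a, n_b, params: ModelParams) -> float:
    """log P(V | C(a,b) = c) for the generic breakend model."""
    if c == 2:
        return (n_a + n_b) * params.log_perr + poisson_log_pmf(params.lam_d, k)
    if c == 1:
        return (poisson_log_pmf(params.lam_c / 2, n_a)
                + poisson_log_pmf(params.lam_c / 2, n_b)
                + poisson_log_pmf(params.lam_d / 2, k))
    if c == 0:
        return (poisson_log_pmf(params.lam_c, n_a)
                + poisson_log_pmf(params.lam_c, n_b)
                + k * params.log_perr)
    raise ValueError("copy number must be 0, 1 or 2")


def scale_concordant_count(n, r, params: ModelParams | None = None,
                           alpha: float = 0.3, beta: float = 0.7):
    """Mapability-scaled concordant count n_hat = n / (alpha + beta * R)."""
    if params is not None:
        alpha, beta = params.alpha_map, params.beta_map
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr > 1):
        raise ValueError("mapability fraction R must lie in [0, 1]")
    if np.any(np.asarray(n) < 0):
        raise ValueError("count must be non-negative")
    out = np.asarray(n, dtype=float) / (alpha + beta * r_arr)
    return float(out) if out.ndim == 0 else out


def coverage_cap(n, mean: float, cap_quantile: float = 0.9999) -> bool:
    """True when coverage n is in the extreme upper tail of Poisson(mean)
    (strictly above the cap_quantile quantile); such regions are forced to
    c = 0 without evaluating the variant hypotheses."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    return bool(n > sps.poisson.ppf(cap_quantile, mean))


# ---------------------------------------------------------------------------
# breakend-pair maximization over coverage cells


def _axis_cells(coverage: ConcordantIndex, chrom: str, lo: int, hi: int):
    """Constant-coverage cells [starts[i], ends[i]] covering [lo, hi]."""
    edges, values = coverage.step_profile(chrom, lo, hi)
    starts = edges
    ends = np.append(edges[1:] - 1, hi)
    return starts, ends, values.astype(float)


def _cell_mask(region: TrapezoidRegion, a1, a2, b1, b2):
    """Which (a-cell, b-cell) rectangles contain a point of the region.

    Cells already lie inside the region's a/b boxes, so only the diagonal band
    needs checking; with integer cell and band bounds, a feasible rectangle
    always contains an integer point of the region.
    """
    if region.q > 0:
        smin = a1[:, None] + b1[None, :]
        smax = a2[:, None] + b2[None, :]
    else:
        smin = a1[:, None] - b2[None, :]
        smax = a2[:, None] - b1[None, :]
    return (smin <= region.s_hi) & (smax >= region.s_lo)


def _cell_point(region: TrapezoidRegion, a1: int, a2: int, b1: int, b2: int
                ) -> tuple[int, int]:
    """An integer point of the region inside the cell rectangle."""
    if region.q > 0:
        s = max(region.s_lo, a1 + b1)
        a = max(a1, s - b2)
        return int(a), int(s - a)
    d = max(region.s_lo, a1 - b2)
    a = max(a1, b1 + d)
    return int(a), int(a - d)


def candidate_breakend_pairs(polygon: BreakendPolygon,
                             coverage: ConcordantIndex) -> list[tuple[int, int]]:
    """A finite candidate set of breakend pairs containing a maximizer of every
    copy-conditional probability: one integer representative per
    constant-coverage cell intersected with the polygon, plus the polygon's
    integral vertices."""
    if polygon.is_empty:
        raise ValueError("empty breakend polygon")
    region = polygon.region()
    a1, a2, _ = _axis_cells(coverage, polygon.chrom_a, region.a_lo, region.a_hi)
    b1, b2, _ = _axis_cells(coverage, polygon.chrom_b, region.b_lo, region.b_hi)
    mask = _cell_mask(region, a1, a2, b1, b2)
    pairs = set()
    for i, j in zip(*np.nonzero(mask)):
        pairs.add(_cell_point(region, int(a1[i]), int(a2[i]),
                              int(b1[j]), int(b2[j])))
    for va, vb in polygon.vertices:
        if va.denominator == 1 and vb.denominator == 1:
            pairs.add((int(va), int(vb)))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# variant scoring


@dataclass
class ColumnModel:
    """Per-candidate likelihood terms that do not depend on the support count.

    ``score(k)`` evaluates the three copy-number hypotheses at support k;
    the k-dependence enters only through Pois(lam_d; k), Pois(lam_d/2; k) and
    p_err^k, so the coverage maximization over breakend pairs is done once.
    """

    model: str
    base2: float
    base1: float
    base0: float
    capped: bool
    params: ModelParams
    best2: tuple[int, int]
    best1: tuple[int, int]
    best0: tuple[int, int]
    homozygous_only: bool = False
    n_a: int | None = None
    n_b: int | None = None
    n_interval: int | None = None
    n_hat: float | None = None
    r_map: float | None = None

    def score(self, k: int) -> tuple[float, float, float]:
        p = self.params
        logp2 = self.base2 + poisson_log_pmf(p.lam_d, k)
        logp1 = self.base1 + poisson_log_pmf(p.lam_d / 2, k)
        logp0 = self.base0 + k * p.log_perr
        if self.capped:
            logp2 = logp1 = _NEG_INF
        if self.homozygous_only:
            logp1 = _NEG_INF
        return logp2, logp1, logp0

    def log_lambda(self, k: int) -> float:
        logp2, logp1, logp0 = self.score(k)
        return max(logp2, logp1) - logp0

    def log_target_term(self, k: int) -> float:
        """Column contribution to the mapping-matrix target at support k > 0:
        the best copy-number hypothesis restricted to c > 0, or the null
        likelihood when the region's coverage is capped."""
        logp2, logp1, logp0 = self.score(k)
        if self.capped:
            return logp0
        return max(logp2, logp1)

    def variant_score(self, k: int) -> VariantScore:
        logp2, logp1, logp0 = self.score(k)
        log_lambda = max(logp2, logp1) - logp0
        if self.capped or logp0 >= max(logp2, logp1):
            if logp0 >= logp2 and logp0 >= logp1:
                copy_call, best = 0, self.best0
            else:
                copy_call, best = (2, self.best2) if logp2 >= logp1 else (1, self.best1)
        else:
            copy_call, best = (2, self.best2) if logp2 >= logp1 else (1, self.best1)
        if self.capped:
            copy_call, best = 0, self.best0
        return VariantScore(
            log_lambda=log_lambda, best_pair=best, copy_call=copy_call,
            logp={0: logp0, 1: logp1, 2: logp2}, model=self.model, k=k,
            capped=self.capped, n_a=self.n_a, n_b=self.n_b,
            n_interval=self.n_interval, n_hat=self.n_hat, r_map=self.r_map,
        )


def _breakend_column(polygon: BreakendPolygon, coverage: ConcordantIndex,
                     params: ModelParams, homozygous_only: bool) -> ColumnModel:
    region = polygon.region()
    a1, a2, na = _axis_cells(coverage, polygon.chrom_a, region.a_lo, region.a_hi)
    b1, b2, nb = _axis_cells(coverage, polygon.chrom_b, region.b_lo, region.b_hi)
    mask = _cell_mask(region, a1, a2, b1, b2)
    thr = sps.poisson.ppf(params.cap_quantile, params.lam_c)
    mask_sv = mask & (na[:, None] <= thr) & (nb[None, :] <= thr)

    def best_cell(values: np.ndarray, m: np.ndarray) -> tuple[float, tuple[int, int]]:
        masked = np.where(m, values, _NEG_INF)
        flat = int(np.argmax(masked))
        i, j = np.unravel_index(flat, masked.shape)
        pt = _cell_point(region, int(a1[i]), int(a2[i]), int(b1[j]), int(b2[j]))
        return float(masked[i, j]), pt

    f0 = (poisson_log_pmf(params.lam_c, na)[:, None]
          + poisson_log_pmf(params.lam_c, nb)[None, :])
    base0, best0 = best_cell(f0, mask)

    if mask_sv.any():
        capped = False
        sum_nab = na[:, None] + nb[None, :]
        base2, best2 = best_cell(sum_nab * params.log_perr, mask_sv)
        f1 = (poisson_log_pmf(params.lam_c / 2, na)[:, None]
              + poisson_log_pmf(params.lam_c / 2, nb)[None, :])
        base1, best1 = best_cell(f1, mask_sv)
    else:
        capped = True
        base2 = base1 = _NEG_INF
        best2 = best1 = best0

    ia = int(np.searchsorted(a1, best2[0], "right") - 1)
    ib = int(np.searchsorted(b1, best2[1], "right") - 1)
    return ColumnModel(
        model="breakend", base2=base2, base1=base1, base0=base0, capped=capped,
        params=params, best2=best2, best1=best1, best0=best0,
        homozygous_only=homozygous_only,
        n_a=int(na[ia]), n_b=int(nb[ib]),
    )


def _deletion_column(variant: CandidateVariant, coverage: ConcordantIndex,
                     mapability: MapabilityTrack, params: ModelParams,
                     homozygous_only: bool) -> ColumnModel:
    amax, bmin = variant.amax, variant.bmin
    n_int = coverage.n_interval(variant.chrom_a, amax, bmin)
    r = mapability.fraction(variant.chrom_a, amax, bmin)
    n_hat = scale_concordant_count(n_int, r, params)
    lam_i = params.lam_interval(bmin - amax + 1)
    capped = coverage_cap(n_hat, lam_i, params.cap_quantile)
    base2 = n_hat * params.log_perr
    base1 = poisson_log_pmf(lam_i / 2, n_hat)
    base0 = poisson_log_pmf(lam_i, n_hat)
    if capped:
        base2 = base1 = _NEG_INF
    pair = (amax, bmin)
    return ColumnModel(
        model="deletion", base2=base2, base1=base1, base0=base0, capped=capped,
        params=params, best2=pair, best1=pair, best0=pair,
        homozygous_only=homozygous_only,
        n_interval=int(n_int), n_hat=float(n_hat), r_map=float(r),
    )


def column_model(variant: CandidateVariant, coverage: ConcordantIndex,
                 mapability: MapabilityTrack | None, params: ModelParams,
                 breakend_only: bool = False,
                 homozygous_only: bool = False) -> ColumnModel:
    """Likelihood model for one candidate: the read-depth (interval) model for
    deletion-type candidates with a well-formed implied interval, the generic
    breakend model otherwise. Discordant counts are never mapability-scaled."""
    if variant.is_deletion and not breakend_only:
        if variant.amax <= variant.bmin:
            return _deletion_column(variant, coverage,
                                    mapability or MapabilityTrack.uniform(),
                                    params, homozygous_only)
        _log.debug(
            "candidate %s: implied interval inverted (amax=%d > bmin=%d); "
            "using the generic breakend model",
            variant.id, variant.amax, variant.bmin)
    return _breakend_column(variant.polygon, coverage, params, homozygous_only)


def score_breakend_variant(variant: CandidateVariant, coverage: ConcordantIndex,
                           params: ModelParams,
                           homozygous_only: bool = False) -> VariantScore:
    """Generic breakend (beRD) score: coverage drop at the two breakends."""
    col = _breakend_column(variant.polygon, coverage, params, homozygous_only)
    return col.variant_score(variant.k)


def score_deletion_variant(variant: CandidateVariant, coverage: ConcordantIndex,
                           mapability: MapabilityTrack | None,
                           params: ModelParams,
                           homozygous_only: bool = False) -> VariantScore:
    """Deletion score: read depth across the implied deleted interval
    I(B) = [amax, bmin], mapability-scaled."""
    col = column_model(variant, coverage, mapability, params,
                       homozygous_only=homozygous_only)
    return col.variant_score(variant.k)
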