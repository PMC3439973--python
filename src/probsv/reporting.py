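"""From chain output to a final call set.

The sampler yields per-fragment marginal supports ``m_bar[i, j]``. The default
reporting path builds the consensus mapping matrix M(tau), keeping a fragment's
assignment only when its marginal meets the threshold tau >= 0.5 (so at most
one assignment per fragment can qualify), rescores every supported candidate
under that matrix, filters by log-likelihood ratio and minimum support, and
removes redundant predictions. The chain-averaged likelihood ratio
Lambda(V) = (1/N) sum_i Lambda(V, M_i) is carried along as an auxiliary score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import BreakendPolygon, CandidateVariant
from .likelihood import ColumnModel, VariantScore
from .mcmc import ChainSummary

__all__ = [
    "FinalCall",
    "chain_lambda",
    "consensus_assignments",
    "consensus_matrix",
    "project_interval",
    "prune",
    "finalize",
    "calls_to_frame",
]


@dataclass
class FinalCall:
    """One reported structural variant."""

    candidate_id: int
    chrom: str
    chrom_b: str
    svtype: str
    signature: str
    start: int              # interval [start, end] = ordered [amax, bmin]
    end: int
    flipped: bool           # amax > bmin (possible for non-deletion types)
    best_pair: tuple[int, int]
    support: int            # fragments assigned under the consensus matrix
    copy_call: int
    log_lambda: float
    chain_log_lambda: float
    model: str
    score: VariantScore | None = None

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def chain_lambda(chain: ChainSummary, candidate_id: int, log: bool = True) -> float:
    """Chain-averaged likelihood ratio of a variant, (1/N) sum Lambda(V, M_i).

    Returned on the log scale by default (the average itself can overflow)."""
    try:
        j = chain.col_ids.index(candidate_id)
    except ValueError:
        raise KeyError(f"candidate {candidate_id} not in this chain") from None
    val = chain.chain_log_lambda[j]
    return val if log else math.exp(val)


def consensus_assignments(chains: list[ChainSummary], tau: float = 0.5
                          ) -> dict[int, int]:
    """Fragment -> candidate assignments of the consensus matrix M(tau).

    tau must lie in [0.5, 1); with tau >= 0.5 at most one cell per fragment can
    reach the threshold, so the result is a valid mapping matrix. The
    comparison is inclusive (m_bar >= tau).
    """
    if not 0.5 <= tau < 1.0:
        raise ValueError("tau must lie in [0.5, 1)")
    out: dict[int, int] = {}
    for chain in chains:
        best: dict[int, tuple[float, int]] = {}
        for (fid, cid), m in chain.m_bar.items():
            if m >= tau and m >= best.get(fid, (0.0, -1))[0]:
                best[fid] = (m, cid)
        for fid, (_, cid) in best.items():
            out[fid] = cid
    return out


def consensus_matrix(chains, matrix, tau: float = 0.5):
    """Consensus :class:`~probsv.mcmc.MappingMatrix` over a full alignment
    matrix (fragment ids are mapped back to row/column indices)."""
    from .mcmc import UNASSIGNED, MappingMatrix

    if isinstance(chains, ChainSummary):
        chains = [chains]
    assign = consensus_assignments(chains, tau)
    col_pos = {cid: p for p, cid in enumerate(matrix.col_ids)}
    gamma = np.full(matrix.n_rows, UNASSIGNED, dtype=np.int64)
    for i, fid in enumerate(matrix.row_ids):
        cid = assign.get(fid)
        if cid is not None:
            gamma[i] = col_pos[cid]
    return MappingMatrix(gamma=gamma, matrix=matrix)


def project_interval(variant: CandidateVariant | BreakendPolygon
                     ) -> tuple[int, int, bool]:
    """[amax, bmin] of a breakend polygon, ordered, with a flag when the raw
    pair was inverted (amax > bmin, possible for non-deletion signatures)."""
    poly = variant.polygon if isinstance(variant, CandidateVariant) else variant
    if poly.is_empty:
        raise ValueError("empty polygon has no interval")
    amax = int(poly.a_max)
    bmin = int(poly.b_min)
    if amax <= bmin:
        return amax, bmin, False
    return bmin, amax, True


def _redundant(i1: tuple[int, int], i2: tuple[int, int]) -> bool:
    lo = max(i1[0], i2[0])
    hi = min(i1[1], i2[1])
    inter = max(0, hi - lo + 1)
    if inter == 0:
        return False
    len1 = i1[1] - i1[0] + 1
    len2 = i2[1] - i2[0] + 1
    union = len1 + len2 - inter
    if inter >= 0.5 * union:
        return True
    # containment either way
    return inter == len1 or inter == len2


def prune(calls: list[FinalCall], score_key=None) -> list[FinalCall]:
    """Greedy redundancy pruning, best score first.

    Two calls on the same chromosome pair and variant type are redundant when
    their intervals overlap by at least half of their union or one contains
    the other; the higher-scoring call is kept. Idempotent.
    """
    if score_key is None:
        score_key = lambda c: c.log_lambda
    order = sorted(calls, key=lambda c: (-score_key(c), c.chrom, c.chrom_b,
                                         c.start, c.end, c.candidate_id))
    kept: list[FinalCall] = []
    for call in order:
        dup = any(
            k.chrom == call.chrom and k.chrom_b == call.chrom_b
            and k.svtype == call.svtype
            and _redundant(k.interval, call.interval)
            for k in kept
        )
        if not dup:
            kept.append(call)
    return kept


def finalize(chains: list[ChainSummary], candidates: list[CandidateVariant],
             column_models: dict[int, ColumnModel],
             fixed_assignments: dict[int, int] | None = None,
             tau: float = 0.5, threshold: float = 0.0,
             min_support: int = 1, do_prune: bool = True) -> list[FinalCall]:
    """Build the final call set from the sampled chains.

    The consensus matrix combines the fixed (unique-mapping) assignments with
    the chain marginals at threshold tau; each supported candidate is rescored
    at its consensus support count, filtered by ``log_lambda > threshold`` and
    ``support >= min_support``, ordered by score and pruned.
    """
    assign = dict(fixed_assignments or {})
    assign.update(consensus_assignments(chains, tau))
    support: dict[int, int] = {}
    for cid in assign.values():
        support[cid] = support.get(cid, 0) + 1

    chain_ll: dict[int, float] = {}
    for chain in chains:
        for j, cid in enumerate(chain.col_ids):
            chain_ll[cid] = chain.chain_log_lambda[j]

    calls: list[FinalCall] = []
    for cand in candidates:
        k = support.get(cand.id, 0)
        if k < max(min_support, 1):
            continue
        score = column_models[cand.id].variant_score(k)
        if not (score.log_lambda > threshold):
            continue
        lo, hi, flipped = project_interval(cand)
        calls.append(FinalCall(
            candidate_id=cand.id, chrom=cand.chrom_a, chrom_b=cand.chrom_b,
            svtype=cand.svtype, signature=cand.signature.name,
            start=lo, end=hi, flipped=flipped, best_pair=score.best_pair,
            support=k, copy_call=score.copy_call,
            log_lambda=score.log_lambda,
            chain_log_lambda=chain_ll.get(
                cand.id, column_models[cand.id].log_lambda(k)),
            model=score.model, score=score,
        ))
    calls.sort(key=lambda c: (-c.log_lambda, c.chrom, c.chrom_b,
                              c.start, c.end, c.candidate_id))
    if do_prune:
        calls = prune(calls)
    return calls


def calls_to_frame(calls: list[FinalCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({
            "candidate_id": c.candidate_id, "chrom": c.chrom,
            "chrom_b": c.chrom_b, "svtype": c.svtype,
            "signature": c.signature, "start": c.start, "end": c.end,
            "best_a": c.best_pair[0], "best_b": c.best_pair[1],
            "support": c.support, "copy_call": c.copy_call,
            "log_lambda": c.log_lambda,
            "chain_log_lambda": c.chain_log_lambda, "model": c.model,
        })
    cols = ["candidate_id", "chrom", "chrom_b", "svtype", "signature",
            "start", "end", "best_a", "best_b", "support", "copy_call",
            "log_lambda", "chain_log_lambda", "model"]
    return pd.DataFrame(rows, columns=cols)
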