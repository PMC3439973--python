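"""Metropolis-Hastings sampling over mapping matrices.

Each discordant fragment (a row) may support several candidate variants (the
columns it has an alignment in); the binary *alignment matrix* A records which.
A *mapping matrix* M assigns every fragment to at most one variant (or to
"mapping error"). The target distribution is

    P(M | A)  proportional to  eta * exp(-eta * V(M))
              * prod_{j : S_j(M) > 0} max_{c > 0} P(V_j(M) | C_j = c)
              * prod_{i unassigned} p_err

where S_j is the support of column j, V(M) the number of supported columns and
the per-column likelihood comes from :mod:`probsv.likelihood`.

Four move classes explore the space: N (reassign one row), Z (empty one
column, re-scattering its rows), Zbar (revive an empty column by pulling rows
in with probability 1/2 each, conditioned on pulling at least one) and S (swap
entries between two columns sharing rows, each with probability 1/2,
conditioned on at least one swap). Each iteration stays put with probability
1/2 (aperiodicity), then picks uniformly among the move classes currently
possible. Proposal probabilities sum the contribution of every class that can
produce the transition, so the Metropolis-Hastings ratio is exact and the
chain satisfies detailed balance for the target above.

Rows with a single possible column are fixed (not sampled) by default, the
standard heuristic for unique mappings; pass ``fix_unique=False`` to sample
them too. Independent connected components of the bipartite fragment-variant
graph are sampled separately; the product of per-component targets equals the
full target, so merging per-component marginals is exact.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import logsumexp

__all__ = [
    "AlignmentMatrix",
    "MappingMatrix",
    "MoveProposal",
    "ChainSummary",
    "Component",
    "build_alignment_matrix",
    "connected_components",
    "log_target",
    "propose",
    "proposal_probability",
    "acceptance",
    "run_chain",
    "enumerate_states",
    "exact_log_probs",
    "transition_matrix",
    "sample_kernel_counts",
    "detailed_balance_gap",
    "unique_only_summary",
]

UNASSIGNED = -1
_CLASSES = ("N", "Z", "Zbar", "S")


@dataclass
class AlignmentMatrix:
    """Sparse binary fragment x variant support matrix.

    ``rows[i]`` is the sorted tuple of column indices fragment i could support
    (every row is non-empty); ``row_ids``/``col_ids`` map local indices back to
    fragment and candidate identifiers.
    """

    rows: list[tuple[int, ...]]
    n_cols: int
    row_ids: list[int]
    col_ids: list[int]

    def __post_init__(self):
        for r in self.rows:
            if len(r) == 0:
                raise ValueError("every row must support at least one column")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def col_rows(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_cols)]
        for i, r in enumerate(self.rows):
            for j in r:
                out[j].append(i)
        return out

    @property
    def n_edges(self) -> int:
        return sum(len(r) for r in self.rows)


def build_alignment_matrix(candidates, fragment_ids=None) -> AlignmentMatrix:
    """Alignment matrix from clustered candidates (columns) and the discordant
    fragments appearing in them (rows)."""
    support: dict[int, set[int]] = {}
    col_ids = [c.id for c in candidates]
    col_pos = {cid: p for p, cid in enumerate(col_ids)}
    for c in candidates:
        for fid in c.fragment_ids:
            support.setdefault(fid, set()).add(col_pos[c.id])
    if fragment_ids is None:
        fragment_ids = sorted(support)
    rows = [tuple(sorted(support[fid])) for fid in fragment_ids]
    return AlignmentMatrix(rows=rows, n_cols=len(col_ids),
                           row_ids=list(fragment_ids), col_ids=col_ids)


@dataclass
class MappingMatrix:
    """Row assignment gamma_i in {-1, 0..n-1}; -1 marks a mapping error."""

    gamma: np.ndarray
    matrix: AlignmentMatrix

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=np.int64)
        for i, g in enumerate(self.gamma):
            if g != UNASSIGNED and g not in self.matrix.rows[i]:
                raise ValueError(f"row {i} assigned to unsupported column {g}")

    def support(self) -> np.ndarray:
        s = np.zeros(self.matrix.n_cols, dtype=np.int64)
        for g in self.gamma:
            if g != UNASSIGNED:
                s[g] += 1
        return s

    @property
    def n_variants(self) -> int:
        return int((self.support() > 0).sum())


@dataclass
class MoveProposal:
    move_class: str
    gamma: np.ndarray
    q_forward: float
    q_backward: float


@dataclass
class ChainSummary:
    """Posterior summaries accumulated over the sampled states."""

    row_ids: list[int]
    col_ids: list[int]
    m_bar: dict[tuple[int, int], float]   # (fragment id, candidate id) -> mean
    support_counts: list[dict[int, int]]  # per column: {total support: samples}
    chain_log_lambda: list[float]         # log of the chain-averaged Lambda(V)
    n_samples: int
    seed: int | None
    acceptance: dict[str, tuple[int, int]] = field(default_factory=dict)
    fixed_assignments: dict[int, int] = field(default_factory=dict)

    def marginal(self, fragment_id: int, candidate_id: int) -> float:
        return self.m_bar.get((fragment_id, candidate_id), 0.0)


# ---------------------------------------------------------------------------
# components


@dataclass
class Component:
    """One independent sub-problem: sampled rows, their columns, fixed support
    folded in, and the per-column likelihood tables of the target."""

    matrix: AlignmentMatrix           # sampled rows only, local column indices
    fixed_support: np.ndarray         # per local column
    col_log_target: list[np.ndarray]  # [j][k_total] -> target term, k=0 -> 0
    col_log_lambda: list[np.ndarray]  # [j][k_total] -> log Lambda at that k
    log_perr: float
    eta: float
    fixed_rows: list[tuple[int, int]] = field(default_factory=list)
    # (fragment id, local column) pairs fixed outside the sampler

    def _perr(self) -> float:
        return math.exp(self.log_perr)

    def __post_init__(self):
        self._col_rows = self.matrix.col_rows()
        pairs = {}
        for i, r in enumerate(self.matrix.rows):
            for j, k in itertools.combinations(r, 2):
                pairs.setdefault((j, k), []).append(i)
        self._pair_rows = pairs  # R_jk over sampled rows

    @property
    def n_rows(self):
        return self.matrix.n_rows

    @property
    def n_cols(self):
        return self.matrix.n_cols


def connected_components(matrix: AlignmentMatrix) -> list[AlignmentMatrix]:
    """Decompose the bipartite fragment-variant graph into independent
    sub-matrices; their union recovers the input exactly."""
    g = nx.Graph()
    for i, r in enumerate(matrix.rows):
        g.add_node(("r", i))
        for j in r:
            g.add_edge(("r", i), ("c", j))
    for j in range(matrix.n_cols):
        g.add_node(("c", j))
    out = []
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        rows = sorted(i for kind, i in comp if kind == "r")
        cols = sorted(j for kind, j in comp if kind == "c")
        col_map = {j: p for p, j in enumerate(cols)}
        sub_rows = [tuple(col_map[j] for j in matrix.rows[i]) for i in rows]
        out.append(AlignmentMatrix(
            rows=sub_rows, n_cols=len(cols),
            row_ids=[matrix.row_ids[i] for i in rows],
            col_ids=[matrix.col_ids[j] for j in cols],
        ))
    return out


def build_components(matrix: AlignmentMatrix, column_models: dict,
                     params, fix_unique: bool = True
                     ) -> tuple[list[Component], dict[int, int]]:
    """Split the full alignment matrix into samplable components.

    Rows with a single possible column are fixed to it when ``fix_unique`` is
    set (their support is folded into the per-column constant ``fixed_support``)
    and only the remaining rows are sampled. Returns the components and the
    map fragment id -> candidate id of the fixed assignments.

    ``column_models`` maps candidate id to the :class:`~probsv.likelihood.ColumnModel`
    providing ``log_target_term(k)`` and ``log_lambda(k)``.
    """
    fixed_assign: dict[int, int] = {}
    fixed_support = np.zeros(matrix.n_cols, dtype=np.int64)
    sampled_rows, sampled_ids = [], []
    for i, r in enumerate(matrix.rows):
        if fix_unique and len(r) == 1:
            fixed_support[r[0]] += 1
            fixed_assign[matrix.row_ids[i]] = matrix.col_ids[r[0]]
        else:
            sampled_rows.append(r)
            sampled_ids.append(matrix.row_ids[i])
    sub = AlignmentMatrix(rows=sampled_rows, n_cols=matrix.n_cols,
                          row_ids=sampled_ids, col_ids=list(matrix.col_ids)) \
        if sampled_rows else None

    components: list[Component] = []
    if sub is not None:
        # restrict to columns actually reachable from sampled rows
        used = sorted({j for r in sub.rows for j in r})
        col_map = {j: p for p, j in enumerate(used)}
        sub = AlignmentMatrix(
            rows=[tuple(col_map[j] for j in r) for r in sub.rows],
            n_cols=len(used), row_ids=sub.row_ids,
            col_ids=[matrix.col_ids[j] for j in used])
        fs = fixed_support[used]
        for piece in connected_components(sub):
            local_fs = np.array([fs[sub.col_ids.index(cid)]
                                 for cid in piece.col_ids], dtype=np.int64)
            col_rows = piece.col_rows()
            tgt_tables, lam_tables = [], []
            for lj, cid in enumerate(piece.col_ids):
                cm = column_models[cid]
                kmax = int(local_fs[lj]) + len(col_rows[lj])
                tgt = np.zeros(kmax + 1)
                lam = np.zeros(kmax + 1)
                for k in range(kmax + 1):
                    lam[k] = cm.log_lambda(k)
                    if k > 0:
                        tgt[k] = cm.log_target_term(k)
                tgt_tables.append(tgt)
                lam_tables.append(lam)
            components.append(Component(
                matrix=piece, fixed_support=local_fs,
                col_log_target=tgt_tables, col_log_lambda=lam_tables,
                log_perr=params.log_perr, eta=params.eta,
            ))
    return components, fixed_assign


# ---------------------------------------------------------------------------
# target


def log_target(comp: Component, gamma: np.ndarray) -> float:
    """log P(M, C* | A) up to the global normalizing constant."""
    s = comp.fixed_support.copy()
    unassigned = 0
    for i, g in enumerate(gamma):
        if g == UNASSIGNED:
            unassigned += 1
        else:
            s[g] += 1
    v = int((s > 0).sum())
    total = math.log(comp.eta) - comp.eta * v + unassigned * comp.log_perr
    for j in range(comp.n_cols):
        if s[j] > 0:
            total += float(comp.col_log_target[j][s[j]])
    return total


def _support(comp: Component, gamma: np.ndarray) -> np.ndarray:
    s = np.zeros(comp.n_cols, dtype=np.int64)
    for g in gamma:
        if g != UNASSIGNED:
            s[g] += 1
    return s


def _possible_classes(comp: Component, gamma: np.ndarray,
                      s: np.ndarray | None = None) -> list[str]:
    if s is None:
        s = _support(comp, gamma)
    classes = ["N"]  # a component always has >= 1 sampled row
    if (s > 0).any():
        classes.append("Z")
    if ((s == 0) & (comp.fixed_support == 0)).any():
        classes.append("Zbar")
    for (j, k), rows in comp._pair_rows.items():
        if any(gamma[i] in (j, k) for i in rows):
            classes.append("S")
            break
    return classes


# ---------------------------------------------------------------------------
# proposal distribution


def _qn(comp: Component, g1: np.ndarray, g2: np.ndarray,
        diff: list[int]) -> float:
    if len(diff) != 1:
        return 0.0
    i = diff[0]
    f, t = int(g1[i]), int(g2[i])
    big_f = comp.n_rows
    r = len(comp.matrix.rows[i])
    if f != UNASSIGNED and t == UNASSIGNED:
        # forced drop when no alternative column exists
        return (1.0 / big_f) if r == 1 else (comp._perr() / big_f)
    if f != UNASSIGNED and t != UNASSIGNED:
        return (1.0 / big_f) * (1.0 - comp._perr()) / (r - 1)
    if f == UNASSIGNED and t != UNASSIGNED:
        return 1.0 / (big_f * r)
    return 0.0


def _qz(comp: Component, g1: np.ndarray, g2: np.ndarray,
        diff: list[int], s1: np.ndarray, s2: np.ndarray) -> float:
    if not diff:
        return 0.0
    j = int(g1[diff[0]])
    if j == UNASSIGNED:
        return 0.0
    if any(int(g1[i]) != j for i in diff):
        return 0.0
    if s2[j] != 0 or s1[j] == 0:
        return 0.0
    # every row assigned to j in g1 must have moved (s2[j] == 0 ensures it)
    v = int((s1 > 0).sum())
    q = 1.0 / v
    for i in diff:
        t = int(g2[i])
        r = len(comp.matrix.rows[i])
        if t == UNASSIGNED:
            q *= comp._perr() if r >= 2 else 1.0
        else:
            if t == j:
                return 0.0
            q *= (1.0 - comp._perr()) / (r - 1)
    return q


def _qzbar(comp: Component, g1: np.ndarray, g2: np.ndarray,
           diff: list[int], s1: np.ndarray) -> float:
    if not diff:
        return 0.0
    j = int(g2[diff[0]])
    if j == UNASSIGNED:
        return 0.0
    if any(int(g2[i]) != j for i in diff):
        return 0.0
    if s1[j] != 0 or comp.fixed_support[j] != 0:
        return 0.0
    rows_j = comp._col_rows[j]
    if any(i not in rows_j for i in diff):
        return 0.0
    n_zero = int(((s1 == 0) & (comp.fixed_support == 0)).sum())
    r = len(rows_j)
    return (1.0 / n_zero) * (0.5 ** r) / (1.0 - 0.5 ** r)


def _qs(comp: Component, g1: np.ndarray, g2: np.ndarray,
        diff: list[int]) -> float:
    if not diff:
        return 0.0
    cols = set()
    for i in diff:
        f, t = int(g1[i]), int(g2[i])
        if f == UNASSIGNED or t == UNASSIGNED:
            return 0.0
        cols.update((f, t))
    if len(cols) != 2:
        return 0.0
    j, k = sorted(cols)
    rows_jk = comp._pair_rows.get((j, k))
    if not rows_jk:
        return 0.0
    for i in diff:
        if i not in rows_jk:
            return 0.0
        if {int(g1[i]), int(g2[i])} != {j, k}:
            return 0.0
    # total pair-selection weight over currently eligible pairs
    w_total = 0
    w_jk = 0
    for (a, b), rows in comp._pair_rows.items():
        if any(int(g1[i]) in (a, b) for i in rows):
            w_total += len(rows)
            if (a, b) == (j, k):
                w_jk = len(rows)
    if w_jk == 0:
        return 0.0
    r = sum(1 for i in rows_jk if int(g1[i]) in (j, k))
    return (w_jk / w_total) * (0.5 ** r) / (1.0 - 0.5 ** r)


def proposal_probability(comp: Component, g1: np.ndarray, g2: np.ndarray
                         ) -> float:
    """q(M, M'): total probability of proposing g2 from g1.

    Returns the self-loop probability 1/2 when the states are equal; otherwise
    sums the contribution of every move class able to produce the transition,
    weighted by the uniform choice among classes possible from g1 (and by the
    1/2 non-self-loop probability).
    """
    if np.array_equal(g1, g2):
        return 0.5
    diff = [i for i in range(len(g1)) if g1[i] != g2[i]]
    s1 = _support(comp, g1)
    s2 = _support(comp, g2)
    classes = _possible_classes(comp, g1, s1)
    total = _qn(comp, g1, g2, diff)
    if "Z" in classes:
        total += _qz(comp, g1, g2, diff, s1, s2)
    if "Zbar" in classes:
        total += _qzbar(comp, g1, g2, diff, s1)
    if "S" in classes:
        total += _qs(comp, g1, g2, diff)
    return 0.5 * total / len(classes)


# ---------------------------------------------------------------------------
# move sampling


def propose(comp: Component, gamma: np.ndarray, rng: np.random.Generator
            ) -> MoveProposal | None:
    """Draw one proposal; ``None`` is the 1/2-probability self-loop."""
    if rng.random() < 0.5:
        return None
    s = _support(comp, gamma)
    classes = _possible_classes(comp, gamma, s)
    move = classes[rng.integers(len(classes))]
    g2 = gamma.copy()
    perr = comp._perr()

    if move == "N":
        i = int(rng.integers(comp.n_rows))
        r = comp.matrix.rows[i]
        if gamma[i] != UNASSIGNED:
            alts = [c for c in r if c != gamma[i]]
            if alts and rng.random() >= perr:
                g2[i] = alts[int(rng.integers(len(alts)))]
            else:
                g2[i] = UNASSIGNED
        else:
            g2[i] = r[int(rng.integers(len(r)))]
    elif move == "Z":
        nz = np.flatnonzero(s > 0)
        j = int(nz[rng.integers(len(nz))])
        for i in comp._col_rows[j]:
            if gamma[i] != j:
                continue
            alts = [c for c in comp.matrix.rows[i] if c != j]
            if alts and rng.random() >= perr:
                g2[i] = alts[int(rng.integers(len(alts)))]
            else:
                g2[i] = UNASSIGNED
    elif move == "Zbar":
        zero = np.flatnonzero((s == 0) & (comp.fixed_support == 0))
        j = int(zero[rng.integers(len(zero))])
        rows_j = comp._col_rows[j]
        while True:
            bits = rng.random(len(rows_j)) < 0.5
            if bits.any():
                break
        for i, pulled in zip(rows_j, bits):
            if pulled:
                g2[i] = j
    else:  # S
        pairs, weights = [], []
        for (a, b), rows in comp._pair_rows.items():
            if any(gamma[i] in (a, b) for i in rows):
                pairs.append((a, b))
                weights.append(len(rows))
        w = np.asarray(weights, dtype=float)
        j, k = pairs[int(rng.choice(len(pairs), p=w / w.sum()))]
        elig = [i for i in comp._pair_rows[(j, k)] if gamma[i] in (j, k)]
        while True:
            bits = rng.random(len(elig)) < 0.5
            if bits.any():
                break
        for i, swap in zip(elig, bits):
            if swap:
                g2[i] = k if gamma[i] == j else j

    qf = proposal_probability(comp, gamma, g2)
    qb = proposal_probability(comp, g2, gamma)
    return MoveProposal(move, g2, qf, qb)


def acceptance(comp: Component, g1: np.ndarray, g2: np.ndarray,
               q_forward: float, q_backward: float) -> float:
    """Metropolis-Hastings acceptance probability alpha(M, M')."""
    if np.array_equal(g1, g2):
        return 1.0
    if q_forward <= 0:
        raise ValueError("proposal has zero forward probability")
    if q_backward <= 0:
        return 0.0
    delta = _log_target_delta(comp, g1, g2)
    log_alpha = math.log(q_backward) - math.log(q_forward) + delta
    return min(1.0, math.exp(min(0.0, log_alpha)))


def _log_target_delta(comp: Component, g1: np.ndarray, g2: np.ndarray) -> float:
    """log P(M'|A) - log P(M|A) from the rows and columns that differ."""
    d_un = 0
    ds: dict[int, int] = {}
    for i in range(len(g1)):
        a, b = int(g1[i]), int(g2[i])
        if a == b:
            continue
        if a == UNASSIGNED:
            d_un -= 1
        else:
            ds[a] = ds.get(a, 0) - 1
        if b == UNASSIGNED:
            d_un += 1
        else:
            ds[b] = ds.get(b, 0) + 1
    if not ds and d_un == 0:
        return 0.0
    s1 = _support(comp, g1)
    delta = d_un * comp.log_perr
    for j, dj in ds.items():
        if dj == 0:
            continue
        k1 = int(s1[j] + comp.fixed_support[j])
        k2 = k1 + dj
        t1 = float(comp.col_log_target[j][k1]) if k1 > 0 else 0.0
        t2 = float(comp.col_log_target[j][k2]) if k2 > 0 else 0.0
        delta += t2 - t1
        delta -= comp.eta * ((k2 > 0) - (k1 > 0))
    return delta


# ---------------------------------------------------------------------------
# running the chain


def _initial_gamma(comp: Component) -> np.ndarray:
    return np.array([r[0] for r in comp.matrix.rows], dtype=np.int64)


def run_chain(comp: Component, burn_in: int = 100_000,
              n_samples: int = 900_000, seed: int | None = 0,
              initial: np.ndarray | None = None) -> ChainSummary:
    """Sample the mapping-matrix posterior of one component.

    Deterministic given the seed. Accumulates the per-cell marginals m_bar,
    the per-column distribution of support counts and the chain average of
    Lambda(V, M) (stored as its log).
    """
    rng = np.random.default_rng(seed)
    gamma = _initial_gamma(comp) if initial is None else initial.copy()
    s = _support(comp, gamma)
    n_rows, n_cols = comp.n_rows, comp.n_cols

    # sojourn accounting: flush a row/column when its state changes
    cell_time = np.zeros((n_rows, n_cols), dtype=np.int64)
    row_since = np.zeros(n_rows, dtype=np.int64)
    col_counts = [dict() for _ in range(n_cols)]
    col_since = np.zeros(n_cols, dtype=np.int64)
    attempts = {c: 0 for c in _CLASSES}
    accepts = {c: 0 for c in _CLASSES}

    def flush(t: int, rows, cols):
        # credit the current state for samples [max(since, burn_in), t)
        for i in rows:
            since = row_since[i] if row_since[i] > burn_in else burn_in
            if gamma[i] != UNASSIGNED and t > since:
                cell_time[i, gamma[i]] += t - since
            row_since[i] = t
        for j in cols:
            since = col_since[j] if col_since[j] > burn_in else burn_in
            if t > since:
                k = int(s[j] + comp.fixed_support[j])
                col_counts[j][k] = col_counts[j].get(k, 0) + (t - since)
            col_since[j] = t

    total = burn_in + n_samples
    for t in range(total):
        prop = propose(comp, gamma, rng)
        if prop is None:
            continue
        attempts[prop.move_class] += 1
        alpha = acceptance(comp, gamma, prop.gamma, prop.q_forward,
                           prop.q_backward)
        if rng.random() < alpha:
            accepts[prop.move_class] += 1
            changed = [i for i in range(n_rows) if gamma[i] != prop.gamma[i]]
            cols = set()
            for i in changed:
                if gamma[i] != UNASSIGNED:
                    cols.add(int(gamma[i]))
                if prop.gamma[i] != UNASSIGNED:
                    cols.add(int(prop.gamma[i]))
            flush(t, changed, cols)
            for i in changed:
                if gamma[i] != UNASSIGNED:
                    s[gamma[i]] -= 1
                if prop.gamma[i] != UNASSIGNED:
                    s[prop.gamma[i]] += 1
                gamma[i] = prop.gamma[i]
    flush(total, range(n_rows), range(n_cols))

    m_bar = {}
    for i in range(n_rows):
        for j in range(n_cols):
            if cell_time[i, j]:
                m_bar[(comp.matrix.row_ids[i], comp.matrix.col_ids[j])] = (
                    cell_time[i, j] / n_samples)
    chain_ll = []
    for j in range(n_cols):
        ks = np.array(sorted(col_counts[j]), dtype=np.int64)
        cnt = np.array([col_counts[j][k] for k in ks], dtype=float)
        vals = comp.col_log_lambda[j][ks]
        chain_ll.append(float(logsumexp(vals, b=cnt) - math.log(n_samples)))
    acc = {c: (accepts[c], attempts[c]) for c in _CLASSES}
    fixed = {fid: comp.matrix.col_ids[j] if j < n_cols else j
             for fid, j in comp.fixed_rows}
    return ChainSummary(
        row_ids=list(comp.matrix.row_ids), col_ids=list(comp.matrix.col_ids),
        m_bar=m_bar, support_counts=col_counts, chain_log_lambda=chain_ll,
        n_samples=n_samples, seed=seed, acceptance=acc,
        fixed_assignments=fixed,
    )


def unique_only_summary(comp: Component) -> ChainSummary:
    """Degenerate summary assigning only rows with a unique possible column
    (the fallback for components too large to sample)."""
    m_bar = {}
    col_counts = [dict() for _ in range(comp.n_cols)]
    s = comp.fixed_support.copy()
    for i, r in enumerate(comp.matrix.rows):
        if len(r) == 1:
            m_bar[(comp.matrix.row_ids[i], comp.matrix.col_ids[r[0]])] = 1.0
            s[r[0]] += 1
    chain_ll = []
    for j in range(comp.n_cols):
        col_counts[j][int(s[j])] = 1
        chain_ll.append(float(comp.col_log_lambda[j][int(s[j])]))
    return ChainSummary(
        row_ids=list(comp.matrix.row_ids), col_ids=list(comp.matrix.col_ids),
        m_bar=m_bar, support_counts=col_counts, chain_log_lambda=chain_ll,
        n_samples=1, seed=None,
    )


# ---------------------------------------------------------------------------
# exact enumeration and kernel utilities (validation & small instances)


def enumerate_states(comp: Component) -> list[tuple[int, ...]]:
    """All valid mapping matrices of a component (gamma tuples)."""
    options = [(UNASSIGNED,) + r for r in comp.matrix.rows]
    return [tuple(g) for g in itertools.product(*options)]


def exact_log_probs(comp: Component,
                    states: list[tuple[int, ...]] | None = None
                    ) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """Exhaustively enumerated log P(M | A), normalized."""
    if states is None:
        states = enumerate_states(comp)
    logs = np.array([log_target(comp, np.array(g)) for g in states])
    return states, logs - logsumexp(logs)


def transition_matrix(comp: Component,
                      states: list[tuple[int, ...]] | None = None
                      ) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """Dense one-step transition kernel p(M, M') = q(M, M') alpha(M, M')
    assembled from the implemented proposal and acceptance probabilities."""
    if states is None:
        states = enumerate_states(comp)
    arrs = [np.array(g, dtype=np.int64) for g in states]
    n = len(states)
    p = np.zeros((n, n))
    logpi = np.array([log_target(comp, g) for g in arrs])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            qf = proposal_probability(comp, arrs[i], arrs[j])
            if qf <= 0:
                continue
            qb = proposal_probability(comp, arrs[j], arrs[i])
            if qb <= 0:
                continue
            log_alpha = min(0.0, math.log(qb) - math.log(qf)
                            + logpi[j] - logpi[i])
            p[i, j] = qf * math.exp(log_alpha)
        p[i, i] = 1.0 - p[i].sum()
    return states, p


def detailed_balance_gap(comp: Component) -> float:
    """max |pi(M) p(M,M') - pi(M') p(M',M)| over all state pairs."""
    states, p = transition_matrix(comp)
    _, logpi = exact_log_probs(comp, states)
    pi = np.exp(logpi)
    flow = pi[:, None] * p
    return float(np.abs(flow - flow.T).max())


def _kernel_counts_py(cum: np.ndarray, start: int, burn: int, n: int,
                      u: np.ndarray) -> np.ndarray:
    counts = np.zeros(cum.shape[0], dtype=np.int64)
    s = start
    for t in range(burn + n):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        if s >= cum.shape[0]:
            s = cum.shape[0] - 1
        if t >= burn:
            counts[s] += 1
    return counts


_kernel_counts_fast = None


def _get_kernel_counts():
    global _kernel_counts_fast
    if _kernel_counts_fast is None:
        try:
            import numba

            _kernel_counts_fast = numba.njit(cache=False)(_kernel_counts_py)
        except Exception:  # pragma: no cover - numba is an optional speed-up
            _kernel_counts_fast = _kernel_counts_py
    return _kernel_counts_fast


def sample_kernel_counts(p: np.ndarray, burn: int, n_samples: int,
                         seed: int, start: int = 0) -> np.ndarray:
    """Simulate the Markov chain with kernel ``p`` and count state visits
    after burn-in (used to compare the chain's empirical distribution against
    the enumerated target on small instances)."""
    rng = np.random.default_rng(seed)
    cum = np.cumsum(p, axis=1)
    u = rng.random(burn + n_samples)
    fn = _get_kernel_counts()
    return fn(cum, start, burn, n_samples, u)
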