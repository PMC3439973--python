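"""Breakend polygons and geometric clustering of discordant fragments.

A discordant fragment alignment with breakpoint-proximal coordinates ``x < y``
and strand signs ``sign(x), sign(y)`` constrains the mated breakends ``(a, b)``
of the rearrangement it supports to the trapezoid

    Gmin <= sign(x)(a - x) + sign(y)(b - y) <= Gmax,
    sign(x)(a - x) >= 0,   sign(y)(b - y) >= 0,

where ``Gmin = Lmin - 2*readlength`` and ``Gmax = Lmax - 2*readlength`` bound
the unsequenced inner gap of the fragment (the left-hand side is the gap length
the breakend pair implies). Fragments supporting the same variant have
overlapping trapezoids; the common intersection localizes the breakends.

All polygon arithmetic is exact: vertices are ``fractions.Fraction`` pairs and
half-plane clipping never introduces floating point, so degenerate
(zero-area) regions and boundary contacts are decided correctly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .fragments import FragmentAlignment, LibraryStats, Signature

__all__ = [
    "BreakendPolygon",
    "CandidateVariant",
    "TrapezoidRegion",
    "fragment_trapezoid",
    "trapezoid_region",
    "intersect_polygons",
    "cluster_discordants",
]

Point = tuple[Fraction, Fraction]
Halfplane = tuple[int, int, int]  # (p, r, c): p*a + r*b <= c


def _clip(vertices: list[Point], hp: Halfplane) -> list[Point]:
    """Sutherland-Hodgman clip of a convex polygon by one half-plane (exact)."""
    p, r, c = hp
    n = len(vertices)
    if n == 0:
        return []
    if n == 1:
        a, b = vertices[0]
        return vertices if p * a + r * b <= c else []
    out: list[Point] = []
    d = [p * a + r * b - c for a, b in vertices]
    for i in range(n):
        j = (i + 1) % n
        if d[i] <= 0:
            out.append(vertices[i])
        if (d[i] < 0 < d[j]) or (d[j] < 0 < d[i]):
            t = Fraction(d[i], d[i] - d[j])
            ax, ay = vertices[i]
            bx, by = vertices[j]
            out.append((ax + t * (bx - ax), ay + t * (by - ay)))
    # drop consecutive duplicates (including wrap-around)
    dedup: list[Point] = []
    for v in out:
        if not dedup or v != dedup[-1]:
            dedup.append(v)
    if len(dedup) > 1 and dedup[0] == dedup[-1]:
        dedup.pop()
    return dedup


def _convex_hull_area2(vertices: list[Point]) -> Fraction:
    """Twice the signed shoelace area."""
    s = Fraction(0)
    n = len(vertices)
    for i in range(n):
        ax, ay = vertices[i]
        bx, by = vertices[(i + 1) % n]
        s += ax * by - bx * ay
    return s


@dataclass(frozen=True)
class TrapezoidRegion:
    """Interval form of a (possibly intersected) breakend trapezoid.

    The region is ``{a in [a_lo, a_hi], b in [b_lo, b_hi],
    a + q*b in [s_lo, s_hi]}`` with ``q = sign(x) * sign(y)``. Every polygon in
    a single (chromosome pair, signature) stratum has this form, and the form
    is closed under intersection, which makes pairwise and subset feasibility
    tests exact integer-interval arithmetic.
    """

    a_lo: int
    a_hi: int
    b_lo: int
    b_hi: int
    q: int
    s_lo: int
    s_hi: int

    def intersect(self, other: "TrapezoidRegion") -> "TrapezoidRegion":
        if self.q != other.q:
            raise ValueError("cannot intersect trapezoids of different band type")
        return TrapezoidRegion(
            max(self.a_lo, other.a_lo), min(self.a_hi, other.a_hi),
            max(self.b_lo, other.b_lo), min(self.b_hi, other.b_hi),
            self.q,
            max(self.s_lo, other.s_lo), min(self.s_hi, other.s_hi),
        )

    @property
    def is_empty(self) -> bool:
        if self.a_lo > self.a_hi or self.b_lo > self.b_hi:
            return True
        if self.q > 0:
            smin, smax = self.a_lo + self.b_lo, self.a_hi + self.b_hi
        else:
            smin, smax = self.a_lo - self.b_hi, self.a_hi - self.b_lo
        return max(smin, self.s_lo) > min(smax, self.s_hi)

    def halfplanes(self) -> list[Halfplane]:
        return [
            (1, 0, self.a_hi), (-1, 0, -self.a_lo),
            (0, 1, self.b_hi), (0, -1, -self.b_lo),
            (1, self.q, self.s_hi), (-1, -self.q, -self.s_lo),
        ]

    def contains(self, a, b) -> bool:
        return (self.a_lo <= a <= self.a_hi and self.b_lo <= b <= self.b_hi
                and self.s_lo <= a + self.q * b <= self.s_hi)


class BreakendPolygon:
    """Convex region of candidate mated breakends (a, b).

    ``a`` lives on the left (smaller-coordinate) chromosome axis, ``b`` on the
    right. The polygon is stored both as an exact vertex list and as its
    defining half-planes; an empty vertex list marks an empty region.
    """

    def __init__(self, vertices: list[Point], halfplanes: list[Halfplane],
                 signature: Signature, chrom_a: str, chrom_b: str,
                 region: TrapezoidRegion | None = None):
        self.vertices = [(Fraction(a), Fraction(b)) for a, b in vertices]
        self.halfplanes = list(halfplanes)
        self.signature = signature
        self.chrom_a = chrom_a
        self.chrom_b = chrom_b
        self._region = region

    # -- construction ------------------------------------------------------

    @classmethod
    def from_region(cls, region: TrapezoidRegion, signature: Signature,
                    chrom_a: str, chrom_b: str) -> "BreakendPolygon":
        if region.is_empty:
            return cls([], region.halfplanes(), signature, chrom_a, chrom_b, region)
        box = [
            (Fraction(region.a_lo), Fraction(region.b_lo)),
            (Fraction(region.a_hi), Fraction(region.b_lo)),
            (Fraction(region.a_hi), Fraction(region.b_hi)),
            (Fraction(region.a_lo), Fraction(region.b_hi)),
        ]
        verts = box
        for hp in ((1, region.q, region.s_hi), (-1, -region.q, -region.s_lo)):
            verts = _clip(verts, hp)
        if _convex_hull_area2(verts) < 0:
            verts = verts[::-1]
        return cls(verts, region.halfplanes(), signature, chrom_a, chrom_b, region)

    # -- basic queries -----------------------------------------------------

    @property
    def is_empty(self) -> bool:
        return len(self.vertices) == 0

    @property
    def is_degenerate(self) -> bool:
        return self.area == 0

    @property
    def area(self) -> Fraction:
        if len(self.vertices) < 3:
            return Fraction(0)
        return abs(_convex_hull_area2(self.vertices)) / 2

    def contains(self, a, b) -> bool:
        """Exact membership test (closed region)."""
        return all(p * a + r * b <= c for p, r, c in self.halfplanes)

    @property
    def a_min(self):
        return min(v[0] for v in self.vertices)

    @property
    def a_max(self):
        """amax: the largest left breakend consistent with every supporter."""
        return max(v[0] for v in self.vertices)

    @property
    def b_min(self):
        """bmin: the smallest right breakend consistent with every supporter."""
        return min(v[1] for v in self.vertices)

    @property
    def b_max(self):
        return max(v[1] for v in self.vertices)

    def region(self) -> TrapezoidRegion:
        """Tight interval form (valid within one signature stratum)."""
        if self._region is not None and not self._region.is_empty:
            q = self._region.q
            s_vals = [a + q * b for a, b in self.vertices] or [0]
            return TrapezoidRegion(
                int(self.a_min), int(self.a_max),
                int(self.b_min), int(self.b_max), q,
                int(min(s_vals)), int(max(s_vals)),
            )
        if self._region is not None:
            return self._region
        raise ValueError("polygon was not built from a trapezoid region")

    def __repr__(self):
        if self.is_empty:
            return f"<BreakendPolygon empty {self.signature.name}>"
        return (f"<BreakendPolygon {self.signature.name} "
                f"a:[{self.a_min},{self.a_max}] b:[{self.b_min},{self.b_max}] "
                f"area={float(self.area):.1f}>")


def trapezoid_region(x: int, y: int, sign_x: int, sign_y: int,
                     stats: LibraryStats) -> TrapezoidRegion:
    """Interval form of the breakend trapezoid of one discordant alignment.

    The fragment-length range [Lmin, Lmax] bounds the inner gap
    ``sign(x)(a-x) + sign(y)(b-y)`` to [Lmin - 2*readlength,
    Lmax - 2*readlength]; the breakends lie on the breakpoint-proximal side of
    each read (``sign(x)(a-x) >= 0`` and likewise for b).
    """
    if stats.lmax < stats.lmin:
        raise ValueError("Lmax < Lmin")
    g_hi = stats.lmax - 2 * stats.readlength
    g_lo = stats.lmin - 2 * stats.readlength
    if g_hi < 0:
        raise ValueError("Lmax must exceed twice the read length")
    a_lo, a_hi = (x, x + g_hi) if sign_x > 0 else (x - g_hi, x)
    b_lo, b_hi = (y, y + g_hi) if sign_y > 0 else (y - g_hi, y)
    q = sign_x * sign_y
    t0 = g_lo + sign_x * x + sign_y * y
    t1 = g_hi + sign_x * x + sign_y * y
    s_lo, s_hi = sorted((sign_x * t0, sign_x * t1))
    return TrapezoidRegion(a_lo, a_hi, b_lo, b_hi, q, s_lo, s_hi)


def fragment_trapezoid(aln: FragmentAlignment, stats: LibraryStats
                       ) -> BreakendPolygon:
    """Breakend polygon of a single discordant fragment alignment."""
    if aln.signature is None:
        raise ValueError("concordant alignments have no breakend polygon")
    region = trapezoid_region(aln.x, aln.y, aln.sign_x, aln.sign_y, stats)
    return BreakendPolygon.from_region(region, aln.signature,
                                       aln.chrom_x, aln.chrom_y)


def intersect_polygons(p1: BreakendPolygon, p2: BreakendPolygon
                       ) -> BreakendPolygon:
    """Exact convex intersection of two breakend polygons.

    Polygons from different signatures or chromosome pairs never describe the
    same novel adjacency; intersecting them is an error.
    """
    if p1.signature != p2.signature:
        raise ValueError("cannot intersect polygons of different signatures")
    if (p1.chrom_a, p1.chrom_b) != (p2.chrom_a, p2.chrom_b):
        raise ValueError("cannot intersect polygons on different chromosome pairs")
    verts = p1.vertices
    for hp in p2.halfplanes:
        verts = _clip(verts, hp)
        if not verts:
            break
    region = None
    if p1._region is not None and p2._region is not None:
        region = p1._region.intersect(p2._region)
    if verts and _convex_hull_area2(verts) < 0:
        verts = verts[::-1]
    return BreakendPolygon(verts, p1.halfplanes + p2.halfplanes,
                           p1.signature, p1.chrom_a, p1.chrom_b, region)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class CandidateVariant:
    """A candidate SV: supporting fragments plus their common breakend polygon."""

    id: int
    chrom_a: str
    chrom_b: str
    signature: Signature
    fragment_ids: tuple[int, ...]
    alignment_rows: tuple[int, ...]
    polygon: BreakendPolygon

    @property
    def k(self) -> int:
        return len(set(self.fragment_ids))

    @property
    def amax(self) -> int:
        return int(self.polygon.a_max)

    @property
    def bmin(self) -> int:
        return int(self.polygon.b_min)

    @property
    def svtype(self) -> str:
        if self.signature == Signature.DELETION:
            return "DEL"
        if self.signature in (Signature.INV_PP, Signature.INV_MM):
            return "INV"
        return "BND"

    @property
    def is_deletion(self) -> bool:
        return self.signature == Signature.DELETION

    def __repr__(self):
        return (f"<CandidateVariant {self.id} {self.svtype} {self.chrom_a} "
                f"k={self.k} I=[{self.amax},{self.bmin}]>")


_CLUSTERABLE = (Signature.DELETION, Signature.INV_PP, Signature.INV_MM,
                Signature.TRANSLOCATION)


def _maximal_feasible_subsets(regions: list[TrapezoidRegion],
                              max_exact: int = 12
                              ) -> list[tuple[tuple[int, ...], TrapezoidRegion]]:
    """Maximal index subsets whose regions have a non-empty common intersection.

    Exact subset-tree enumeration up to ``max_exact`` members; beyond that a
    deterministic greedy grow-from-each-seed heuristic (complete whenever the
    whole component shares a common point, the typical case for a real SV).
    """
    n = len(regions)
    if n == 1:
        return [((0,), regions[0])]
    results: dict[frozenset, TrapezoidRegion] = {}

    def feasible(reg: TrapezoidRegion, k: int) -> TrapezoidRegion | None:
        out = reg.intersect(regions[k])
        return None if out.is_empty else out

    if n <= max_exact:
        def rec(members: tuple[int, ...], reg: TrapezoidRegion, start: int):
            maximal = not any(
                k not in members and feasible(reg, k) is not None
                for k in range(n))
            if maximal:
                results.setdefault(frozenset(members), reg)
                return
            for k in range(start, n):
                if k in members:
                    continue
                nxt = feasible(reg, k)
                if nxt is not None:
                    rec(members + (k,), nxt, k + 1)

        for i in range(n):
            rec((i,), regions[i], i + 1)
    else:
        for seed in range(n):
            members = [seed]
            reg = regions[seed]
            for k in range(n):
                if k == seed:
                    continue
                nxt = feasible(reg, k)
                if nxt is not None:
                    members.append(k)
                    reg = nxt
            results.setdefault(frozenset(members), reg)

    out = [(tuple(sorted(m)), reg) for m, reg in results.items()]
    # drop non-maximal leftovers (greedy path can produce subsets)
    keep = []
    sets = [frozenset(m) for m, _ in out]
    for i, (m, reg) in enumerate(out):
        if any(i != j and sets[i] < sets[j] for j in range(len(out))):
            continue
        keep.append((m, reg))
    keep.sort()
    return keep


def cluster_discordants(table: pd.DataFrame, stats: LibraryStats,
                        max_exact: int = 12) -> list[CandidateVariant]:
    """Cluster discordant fragment alignments into candidate variants.

    Within each (chromosome pair, signature, strand pattern) stratum, connected
    components of the pairwise trapezoid-overlap graph are refined into maximal
    fragment sets whose trapezoids share a common intersection; that common
    intersection becomes the candidate's breakend polygon. An alignment may
    appear in several candidates when its trapezoid bridges groups with no
    common point (the mapping-matrix sampler resolves such ties later).

    ``table`` is a classified alignment table restricted to discordant rows
    (columns ``fragment_id, chrom_x, chrom_y, sig, x, y, sign_x, sign_y``);
    the frame's index labels the alignment rows. Optional per-row
    ``lmin``/``lmax`` columns (mixed-library input) override ``stats``.
    """
    if "lmin" in table.columns and "lmax" in table.columns:
        lmin_all = table["lmin"].to_numpy(np.int64)
        lmax_all = table["lmax"].to_numpy(np.int64)
    else:
        lmin_all = np.full(len(table), stats.lmin, dtype=np.int64)
        lmax_all = np.full(len(table), stats.lmax, dtype=np.int64)
    if len(table) and (lmax_all - 2 * stats.readlength).min() < 0:
        raise ValueError("Lmax must exceed twice the read length")
    pos = {label: i for i, label in enumerate(table.index)}

    candidates: list[CandidateVariant] = []
    mask = table["sig"].isin([int(s) for s in _CLUSTERABLE])
    sub_all = table[mask]
    for key, grp in sub_all.groupby(
            ["chrom_x", "chrom_y", "sig", "sign_x", "sign_y"], observed=True):
        chrom_a, chrom_b, sig_code, sx, sy = key
        sig = Signature(int(sig_code))
        x = grp["x"].to_numpy(np.int64)
        y = grp["y"].to_numpy(np.int64)
        rows = grp.index.to_numpy()
        frag_ids = grp["fragment_id"].to_numpy(np.int64)
        loc = np.array([pos[label] for label in grp.index])
        g_hi = lmax_all[loc] - 2 * stats.readlength
        g_lo = lmin_all[loc] - 2 * stats.readlength
        q = int(sx) * int(sy)
        a_lo = np.where(sx > 0, x, x - g_hi)
        a_hi = np.where(sx > 0, x + g_hi, x)
        b_lo = np.where(sy > 0, y, y - g_hi)
        b_hi = np.where(sy > 0, y + g_hi, y)
        t0 = g_lo + sx * x + sy * y
        t1 = g_hi + sx * x + sy * y
        s_lo = np.minimum(sx * t0, sx * t1)
        s_hi = np.maximum(sx * t0, sx * t1)

        order = np.lexsort((frag_ids, y, x))
        n = len(order)
        regions = [TrapezoidRegion(int(a_lo[i]), int(a_hi[i]), int(b_lo[i]),
                                   int(b_hi[i]), q, int(s_lo[i]), int(s_hi[i]))
                   for i in order]
        rows = rows[order]
        frag_ids = frag_ids[order]

        # sweep over a-intervals to find overlapping pairs, then union-find
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        starts = np.array([r.a_lo for r in regions])
        idx = np.argsort(starts, kind="stable")
        active: list[int] = []
        for ii in idx:
            ri = regions[ii]
            active = [jj for jj in active if regions[jj].a_hi >= ri.a_lo]
            for jj in active:
                if not ri.intersect(regions[jj]).is_empty:
                    union(ii, jj)
            active.append(ii)

        comps: dict[int, list[int]] = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(i)

        for members in comps.values():
            local = [regions[i] for i in members]
            for subset, reg in _maximal_feasible_subsets(local, max_exact):
                sel = [members[i] for i in subset]
                poly = BreakendPolygon.from_region(reg, sig, str(chrom_a),
                                                   str(chrom_b))
                candidates.append(CandidateVariant(
                    id=-1, chrom_a=str(chrom_a), chrom_b=str(chrom_b),
                    signature=sig,
                    fragment_ids=tuple(int(frag_ids[i]) for i in sel),
                    alignment_rows=tuple(int(rows[i]) for i in sel),
                    polygon=poly,
                ))

    candidates.sort(key=lambda c: (c.chrom_a, c.chrom_b, int(c.signature),
                                   c.polygon.region().a_lo,
                                   c.polygon.region().b_lo,
                                   c.fragment_ids))
    for i, c in enumerate(candidates):
        c.id = i
    return candidates


def alignments_to_table(alignments: list[FragmentAlignment]) -> pd.DataFrame:
    """Build the clustering input table from FragmentAlignment objects."""
    rows = []
    for a in alignments:
        rows.append({
            "fragment_id": a.fragment_id,
            "chrom_x": a.chrom_x, "chrom_y": a.chrom_y,
            "sig": int(a.signature) if a.signature is not None else -1,
            "x": a.x, "y": a.y, "sign_x": a.sign_x, "sign_y": a.sign_y,
        })
    return pd.DataFrame(rows)
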