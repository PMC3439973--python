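"""Paired-end fragment alignments: pairing, concordance classification and coverage.

A sequenced fragment yields two reads. Each candidate placement of the pair on
the reference is a :class:`FragmentAlignment`; a fragment with several candidate
placements carries them all (the set ``A(f)``). A placement is *concordant* when
the reads have convergent orientation for the sequencing technology and the
mapped fragment length (outer span) lies inside the library's fragment-length
range ``[Lmin, Lmax]``; every other placement is *discordant* and carries a
signature naming the rearrangement it would support.

Coordinates are 1-based and fully closed (SAM convention). The
breakpoint-proximal coordinate of a read is its rightmost aligned base on the
forward strand and its leftmost aligned base on the reverse strand; ``sign`` is
+1 for a forward-strand read and -1 otherwise. These are the coordinates the
breakend-polygon geometry consumes.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Status",
    "Signature",
    "Technology",
    "ReadAlignment",
    "FragmentAlignment",
    "Fragment",
    "LibraryStats",
    "FilterStats",
    "classify_fragment",
    "classify_pair",
    "classify_table",
    "estimate_length_bounds",
    "filter_alignments",
    "filter_alignment_table",
    "partition_table",
    "ConcordantIndex",
    "MapabilityTrack",
    "concordant_coverage",
]


class Status(enum.Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"


class Signature(enum.IntEnum):
    """Rearrangement signature of a discordant placement.

    DELETION        convergent pair whose span exceeds Lmax.
    INV_PP / INV_MM same-chromosome pair with both reads on + / - strand.
    DIVERGENT       non-convergent opposite-strand pair, or a convergent pair
                    shorter than Lmin (insertion/duplication-like evidence;
                    not clustered here).
    TRANSLOCATION   reads on different chromosomes.
    """

    DELETION = 0
    INV_PP = 1
    INV_MM = 2
    DIVERGENT = 3
    TRANSLOCATION = 4


class Technology(enum.Enum):
    """Strand convention defining 'convergent orientation'.

    ILLUMINA: reads come from opposite strands; convergent means the left read
    is forward and the right read is reverse (+/-).
    SOLID: reads come from the same strand; convergent means +/+ with the
    first-sequenced read leftmost, or -/- with the first-sequenced read
    rightmost.
    """

    ILLUMINA = "illumina"
    SOLID = "solid"


@dataclass(frozen=True)
class ReadAlignment:
    """One aligned read: 1-based leftmost position, strand, length, quality."""

    chrom: str
    pos: int
    strand: str  # '+' or '-'
    read_len: int
    mapq: int = 255
    read_id: str = ""
    mate: int = 1  # 1 = first sequenced read of the pair

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based coordinates)")
        if self.read_len < 1:
            raise ValueError("read_len must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def end(self) -> int:
        """Rightmost aligned base (closed)."""
        return self.pos + self.read_len - 1

    @property
    def proximal(self) -> int:
        """Breakpoint-proximal coordinate: end on '+', start on '-'."""
        return self.end if self.strand == "+" else self.pos

    @property
    def sign(self) -> int:
        return 1 if self.strand == "+" else -1


@dataclass(frozen=True)
class FragmentAlignment:
    """One candidate placement of a fragment (a pair of read alignments).

    ``x < y`` are the breakpoint-proximal coordinates (ordered by chromosome
    then coordinate); ``sign_x``/``sign_y`` travel with them.  ``span`` is the
    outer mapped extent (rightmost base of the right read minus leftmost base
    of the left read, plus one) and is only meaningful on one chromosome.
    """

    fragment_id: int
    left: ReadAlignment
    right: ReadAlignment
    x: int
    y: int
    sign_x: int
    sign_y: int
    span: int
    status: Status
    signature: Signature | None  # None when concordant

    @property
    def chrom_x(self) -> str:
        return self.left.chrom

    @property
    def chrom_y(self) -> str:
        return self.right.chrom

    @property
    def mapq(self) -> int:
        return min(self.left.mapq, self.right.mapq)

    @property
    def extent(self) -> tuple[int, int]:
        """Full mapped extent [start, end] (same-chromosome placements)."""
        return (min(self.left.pos, self.right.pos),
                max(self.left.end, self.right.end))


@dataclass
class Fragment:
    """A sequenced fragment with its full candidate-placement set A(f)."""

    fragment_id: int
    alignments: list[FragmentAlignment]

    def __post_init__(self):
        if not self.alignments:
            raise ValueError("a fragment needs at least one alignment")

    @property
    def is_unique(self) -> bool:
        return len(self.alignments) == 1

    @property
    def all_discordant(self) -> bool:
        return all(a.status is Status.DISCORDANT for a in self.alignments)

    @property
    def any_concordant(self) -> bool:
        return any(a.status is Status.CONCORDANT for a in self.alignments)


@dataclass(frozen=True)
class LibraryStats:
    """Fragment-length range and read length of a sequencing library."""

    lmin: int
    lmax: int
    lavg: float
    readlength: int
    technology: Technology = Technology.ILLUMINA

    def __post_init__(self):
        if not (self.lmin <= self.lavg <= self.lmax):
            raise ValueError(
                f"require Lmin <= Lavg <= Lmax, got {self.lmin}, {self.lavg}, {self.lmax}"
            )


@dataclass
class FilterStats:
    n_input_alignments: int = 0
    n_low_mapq: int = 0
    n_long_span: int = 0
    n_overmapped_fragments: int = 0
    n_rejected_records: int = 0


# ---------------------------------------------------------------------------
# classification


def _is_convergent(left: ReadAlignment, right: ReadAlignment,
                   technology: Technology) -> bool:
    if technology is Technology.ILLUMINA:
        return left.strand == "+" and right.strand == "-"
    # SOLiD: same strand; '+' pairs read in genome order, '-' pairs reversed.
    if left.strand != right.strand:
        return False
    first_is_left = left.mate == 1
    return (left.strand == "+" and first_is_left) or (
        left.strand == "-" and not first_is_left
    )


def classify_pair(r1: ReadAlignment, r2: ReadAlignment, stats: LibraryStats,
                  fragment_id: int = 0) -> FragmentAlignment:
    """Pair two read alignments into a classified :class:`FragmentAlignment`."""
    # order by (chromosome, position): 'left' is the genomically first read
    if (r1.chrom, r1.pos, r1.end) <= (r2.chrom, r2.pos, r2.end):
        left, right = r1, r2
    else:
        left, right = r2, r1

    same = left.chrom == right.chrom
    span = right.end - left.pos + 1 if same else 0

    if not same:
        status, sig = Status.DISCORDANT, Signature.TRANSLOCATION
    elif left.strand == "+" and right.strand == "+":
        status, sig = Status.DISCORDANT, Signature.INV_PP
    elif left.strand == "-" and right.strand == "-":
        status, sig = Status.DISCORDANT, Signature.INV_MM
    elif _is_convergent(left, right, stats.technology):
        if stats.lmin <= span <= stats.lmax:
            status, sig = Status.CONCORDANT, None
        elif span > stats.lmax:
            status, sig = Status.DISCORDANT, Signature.DELETION
        else:
            status, sig = Status.DISCORDANT, Signature.DIVERGENT
    else:
        status, sig = Status.DISCORDANT, Signature.DIVERGENT

    px, py = left.proximal, right.proximal
    sx, sy = left.sign, right.sign
    if same and px > py:
        # proximal coordinates may invert the read order for short fragments
        px, py, sx, sy = py, px, sy, sx
    return FragmentAlignment(
        fragment_id=fragment_id, left=left, right=right,
        x=px, y=py, sign_x=sx, sign_y=sy, span=span,
        status=status, signature=sig,
    )


def classify_fragment(alignment: FragmentAlignment, stats: LibraryStats
                      ) -> tuple[Status, Signature | None]:
    """Re-classify a fragment alignment against a library's length bounds."""
    out = classify_pair(alignment.left, alignment.right, stats,
                        alignment.fragment_id)
    return out.status, out.signature


# vectorised table classification --------------------------------------------

_TABLE_COLUMNS = [
    "fragment_id", "chrom1", "pos1", "strand1", "len1",
    "chrom2", "pos2", "strand2", "len2", "mapq",
]


def classify_table(df: pd.DataFrame,
                   stats: "LibraryStats | dict[str, LibraryStats]"
                   ) -> pd.DataFrame:
    """Vectorised :func:`classify_pair` over an alignment table.

    ``df`` has one row per fragment alignment with columns
    ``fragment_id, chrom1, pos1, strand1, len1, chrom2, pos2, strand2, len2,
    mapq`` where ``strand*`` is boolean (True = forward) and read 1 is the
    first-sequenced read. Adds columns ``x, y, sign_x, sign_y, span,
    concordant, sig`` (``sig`` = :class:`Signature` code, -1 when concordant)
    plus per-row ``lmin``/``lmax``.

    Mixed-library input: pass a mapping read-group -> :class:`LibraryStats`
    and a ``library`` column; each alignment is classified against its own
    library's fragment-length bounds (the technology must be shared).
    """
    if isinstance(stats, dict):
        if "library" not in df.columns:
            raise ValueError("per-library stats require a 'library' column")
        libs = df["library"]
        lmin = libs.map({k: v.lmin for k, v in stats.items()}).to_numpy(float)
        lmax = libs.map({k: v.lmax for k, v in stats.items()}).to_numpy(float)
        if np.isnan(lmin).any():
            raise ValueError("alignment references an unknown library")
        stats = next(iter(stats.values()))
    else:
        lmin = np.full(len(df), stats.lmin, dtype=float)
        lmax = np.full(len(df), stats.lmax, dtype=float)
    out = df.copy()
    c1 = df["chrom1"].to_numpy()
    c2 = df["chrom2"].to_numpy()
    p1 = df["pos1"].to_numpy(np.int64)
    p2 = df["pos2"].to_numpy(np.int64)
    s1 = df["strand1"].to_numpy(bool)
    s2 = df["strand2"].to_numpy(bool)
    l1 = df["len1"].to_numpy(np.int64)
    l2 = df["len2"].to_numpy(np.int64)
    e1 = p1 + l1 - 1
    e2 = p2 + l2 - 1

    same = c1 == c2
    # genomic order within a chromosome; cross-chromosome pairs keep read order
    # unless chrom2 sorts first.
    swap = np.where(same, (p1 > p2) | ((p1 == p2) & (e1 > e2)),
                    c1 > c2)
    lpos = np.where(swap, p2, p1)
    lend = np.where(swap, e2, e1)
    lstr = np.where(swap, s2, s1)
    rpos = np.where(swap, p1, p2)
    rend = np.where(swap, e1, e2)
    rstr = np.where(swap, s1, s2)
    first_is_left = ~swap  # read 1 is the first sequenced

    span = np.where(same, rend - lpos + 1, 0)

    if stats.technology is Technology.ILLUMINA:
        convergent = lstr & ~rstr
    else:
        convergent = (lstr == rstr) & (lstr == first_is_left)

    sig = np.full(len(df), Signature.DIVERGENT, dtype=np.int8)
    sig[~same] = Signature.TRANSLOCATION
    sig[same & lstr & rstr] = Signature.INV_PP
    sig[same & ~lstr & ~rstr] = Signature.INV_MM
    sig[same & convergent & (span > lmax)] = Signature.DELETION
    concordant = same & convergent & (span >= lmin) & (span <= lmax)
    sig[concordant] = -1

    px = np.where(lstr, lend, lpos)
    py = np.where(rstr, rend, rpos)
    sx = np.where(lstr, 1, -1).astype(np.int8)
    sy = np.where(rstr, 1, -1).astype(np.int8)
    flip = same & (px > py)
    x = np.where(flip, py, px)
    y = np.where(flip, px, py)
    sflip_x = np.where(flip, sy, sx)
    sflip_y = np.where(flip, sx, sy)

    out["x"] = x
    out["y"] = y
    out["sign_x"] = sflip_x
    out["sign_y"] = sflip_y
    out["span"] = span
    out["concordant"] = concordant
    out["sig"] = sig
    out["chrom_x"] = np.where(swap, c2, c1)
    out["chrom_y"] = np.where(swap, c1, c2)
    out["start"] = lpos
    out["end"] = rend
    out["lmin"] = lmin.astype(np.int64)
    out["lmax"] = lmax.astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# library statistics


def estimate_length_bounds(
    spans,
    readlength: int,
    method: str = "quantile",
    level: float = 0.001,
    k_sd: float = 3.0,
    technology: Technology = Technology.ILLUMINA,
    override: LibraryStats | None = None,
) -> LibraryStats:
    """Estimate [Lmin, Lmax] from the empirical concordant-span distribution.

    The default rule takes the ``level`` and ``1 - level`` quantiles (0.1% and
    99.9%); ``method='sd'`` uses ``mean +/- k_sd * sd`` instead. An explicit
    ``override`` is returned unchanged.
    """
    if override is not None:
        return override
    spans = np.asarray(spans, dtype=float)
    if spans.size < 100:
        raise ValueError(
            f"only {spans.size} spans; supply explicit Lmin/Lmax bounds "
            "(need >= 100 concordant spans to estimate them)"
        )
    lavg = float(spans.mean())
    if method == "quantile":
        lo, hi = np.quantile(spans, [level, 1.0 - level])
    elif method == "sd":
        sd = float(spans.std())
        lo, hi = lavg - k_sd * sd, lavg + k_sd * sd
    else:
        raise ValueError(f"unknown method {method!r}")
    return LibraryStats(
        lmin=int(np.floor(lo)), lmax=int(np.ceil(hi)), lavg=lavg,
        readlength=int(readlength), technology=technology,
    )


# ---------------------------------------------------------------------------
# filters


def filter_alignments(
    fragments: list[Fragment],
    min_mapq: int = 10,
    max_span: int = 500_000,
    max_alignments: int = 100,
) -> tuple[list[Fragment], FilterStats]:
    """Mapping filters: mapq strictly above ``min_mapq``, same-chromosome span
    at most ``max_span``, and whole fragments dropped when they carry more than
    ``max_alignments`` placements genome-wide."""
    stats = FilterStats()
    kept: list[Fragment] = []
    for frag in fragments:
        stats.n_input_alignments += len(frag.alignments)
        if len(frag.alignments) > max_alignments:
            stats.n_overmapped_fragments += 1
            continue
        alns = []
        for a in frag.alignments:
            if a.mapq <= min_mapq:
                stats.n_low_mapq += 1
                continue
            if a.chrom_x == a.chrom_y and a.span > max_span:
                stats.n_long_span += 1
                continue
            alns.append(a)
        if alns:
            kept.append(Fragment(frag.fragment_id, alns))
    return kept, stats


def filter_alignment_table(
    df: pd.DataFrame,
    min_mapq: int = 10,
    max_span: int = 500_000,
    max_alignments: int = 100,
) -> tuple[pd.DataFrame, FilterStats]:
    """Table version of :func:`filter_alignments` (requires classify_table columns)."""
    stats = FilterStats(n_input_alignments=len(df))
    counts = df["fragment_id"].value_counts()
    overmapped = counts[counts > max_alignments].index
    stats.n_overmapped_fragments = len(overmapped)
    keep = ~df["fragment_id"].isin(overmapped)
    low = df["mapq"] <= min_mapq
    stats.n_low_mapq = int((keep & low).sum())
    keep &= ~low
    long_span = (df["chrom1"] == df["chrom2"]) & (df["span"] > max_span)
    stats.n_long_span = int((keep & long_span).sum())
    keep &= ~long_span
    return df[keep].copy(), stats


def partition_table(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split a classified table into (concordant, discordant, excluded).

    A fragment is *concordant* when its single placement is concordant;
    *discordant* when every placement is discordant; and *excluded* when it has
    several placements at least one of which is concordant (such fragments are
    ignored by the variant model).
    """
    grp = df.groupby("fragment_id")["concordant"]
    n_aln = grp.transform("size")
    any_conc = grp.transform("any")
    conc_mask = (n_aln == 1) & df["concordant"]
    disc_mask = ~any_conc
    excl_mask = any_conc & (n_aln > 1)
    return df[conc_mask], df[disc_mask], df[excl_mask]


# ---------------------------------------------------------------------------
# concordant coverage


class ConcordantIndex:
    """Position index over concordant fragment extents.

    ``n_point(chrom, p)`` is the number of concordant fragments whose full
    mapped extent [start, end] contains p; ``n_interval`` counts fragments
    whose extent intersects a closed interval.
    """

    def __init__(self, extents_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
                 chrom_lengths: dict[str, int] | None = None):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self.chrom_lengths = chrom_lengths or {}
        for chrom, (starts, ends) in extents_by_chrom.items():
            self._starts[chrom] = np.sort(np.asarray(starts, dtype=np.int64))
            self._ends[chrom] = np.sort(np.asarray(ends, dtype=np.int64))

    @classmethod
    def from_table(cls, concordant: pd.DataFrame,
                   chrom_lengths: dict[str, int] | None = None) -> "ConcordantIndex":
        by = {}
        for chrom, sub in concordant.groupby("chrom1", observed=True):
            by[str(chrom)] = (sub["start"].to_numpy(np.int64),
                              sub["end"].to_numpy(np.int64))
        return cls(by, chrom_lengths)

    @classmethod
    def from_fragments(cls, fragments: list[Fragment],
                       chrom_lengths: dict[str, int] | None = None) -> "ConcordantIndex":
        by: dict[str, list[tuple[int, int]]] = {}
        for f in fragments:
            a = f.alignments[0]
            by.setdefault(a.chrom_x, []).append(a.extent)
        arrs = {
            c: (np.array([e[0] for e in v]), np.array([e[1] for e in v]))
            for c, v in by.items()
        }
        return cls(arrs, chrom_lengths)

    def _check(self, chrom: str, pos: int) -> bool:
        length = self.chrom_lengths.get(chrom)
        if chrom not in self._starts and chrom not in (self.chrom_lengths or {}):
            warnings.warn(f"query on unindexed chromosome {chrom!r}")
            return False
        if pos < 1 or (length is not None and pos > length):
            warnings.warn(f"query position {chrom}:{pos} outside reference bounds")
            return False
        return True

    def n_point(self, chrom: str, p: int) -> int:
        if not self._check(chrom, p):
            return 0
        starts = self._starts.get(chrom)
        if starts is None:
            return 0
        ends = self._ends[chrom]
        return int(np.searchsorted(starts, p, "right")
                   - np.searchsorted(ends, p, "left"))

    def n_interval(self, chrom: str, lo: int, hi: int) -> int:
        if lo > hi:
            lo, hi = hi, lo
        starts = self._starts.get(chrom)
        if starts is None:
            self._check(chrom, lo)
            return 0
        ends = self._ends[chrom]
        n = starts.size
        return int(n - (n - np.searchsorted(starts, hi, "right"))
                   - np.searchsorted(ends, lo, "left"))

    def step_profile(self, chrom: str, lo: int, hi: int
                     ) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-constant coverage over [lo, hi].

        Returns ``(edges, values)``: coverage equals ``values[i]`` on
        ``[edges[i], edges[i+1] - 1]`` with a final implicit edge ``hi + 1``.
        """
        starts = self._starts.get(chrom)
        if starts is None:
            return np.array([lo], dtype=np.int64), np.array([0], dtype=np.int64)
        ends = self._ends[chrom]
        cps = np.concatenate([
            starts[(starts > lo) & (starts <= hi)],
            ends[(ends >= lo) & (ends < hi)] + 1,
        ])
        edges = np.unique(np.concatenate([[lo], cps]))
        values = (np.searchsorted(starts, edges, "right")
                  - np.searchsorted(ends, edges, "left"))
        return edges, values.astype(np.int64)


def concordant_coverage(index: ConcordantIndex, chrom: str, query) -> int:
    """n(p) for an integer query, n(I) for an ``(lo, hi)`` interval query."""
    if np.isscalar(query):
        return index.n_point(chrom, int(query))
    lo, hi = query
    return index.n_interval(chrom, int(lo), int(hi))


# ---------------------------------------------------------------------------
# mapability


class MapabilityTrack:
    """Per-base uniqueness track; ``fraction`` averages it over an interval.

    Stored as sorted, non-overlapping closed intervals with a value in [0, 1];
    positions not covered by any interval take ``default`` (fully mapable).
    """

    def __init__(self, intervals_by_chrom: dict[str, np.ndarray] | None = None,
                 default: float = 1.0):
        # each row of the per-chrom array: (start, end, value) with closed coords
        self._by_chrom: dict[str, np.ndarray] = {}
        self.default = float(default)
        for chrom, arr in (intervals_by_chrom or {}).items():
            arr = np.asarray(arr, dtype=float)
            if arr.size:
                arr = arr[np.argsort(arr[:, 0])]
            self._by_chrom[chrom] = arr

    @classmethod
    def uniform(cls, value: float = 1.0) -> "MapabilityTrack":
        return cls({}, default=value)

    @classmethod
    def from_bedgraph(cls, path, default: float = 1.0) -> "MapabilityTrack":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "value"])
        by = {}
        for chrom, sub in df.groupby("chrom"):
            # BED-graph is 0-based half-open; convert to 1-based closed
            by[str(chrom)] = np.column_stack([
                sub["start"].to_numpy() + 1,
                sub["end"].to_numpy(),
                sub["value"].to_numpy(),
            ])
        return cls(by, default=default)

    def fraction(self, chrom: str, lo: int, hi: int) -> float:
        """Mean per-base mapability R(I) over the closed interval [lo, hi]."""
        if lo > hi:
            lo, hi = hi, lo
        length = hi - lo + 1
        arr = self._by_chrom.get(chrom)
        if arr is None or not arr.size:
            return self.default
        total = 0.0
        covered = 0
        starts = arr[:, 0]
        i = max(0, int(np.searchsorted(starts, lo, "right")) - 1)
        for s, e, v in arr[i:]:
            if s > hi:
                break
            olo, ohi = max(lo, s), min(hi, e)
            if olo <= ohi:
                n = int(ohi - olo + 1)
                total += v * n
                covered += n
        total += self.default * (length - covered)
        return total / length

    def to_bedgraph(self, path) -> None:
        rows = []
        for chrom, arr in self._by_chrom.items():
            for s, e, v in arr:
                rows.append((chrom, int(s) - 1, int(e), v))
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)
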