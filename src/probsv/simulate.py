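"""Synthetic diploid test genomes and paired-end alignments.

The generator produces data with exactly the statistical structure the caller
assumes: a reference chromosome, a diploid test genome carrying deletions and
inversions of known genotype, fragments whose left ends follow a uniform
Poisson process (Lander-Waterman) split evenly across the two haplotypes, and
fragment lengths drawn from Normal(Lavg, sd) truncated below at twice the read
length. Reads are projected back to reference coordinates through the
haplotype coordinate maps: fragments straddling a rearrangement junction
become discordant, reads overlapping a junction fail to map and their fragment
is lost (the local coverage drop at breakends), a fraction ``p_err`` of
fragments receive a random erroneous placement, and reads falling inside
configured repeat blocks acquire the homologous alternative placements
(ambiguous fragments for the mapping-matrix sampler).

Defaults mirror the simulation conditions used to validate the model: 50 bp
reads, 200 bp mean fragment length with 20 bp standard deviation, fragment
rate lam = 0.3 per base (about 60x fragment coverage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import LibraryStats, MapabilityTrack, Technology

__all__ = [
    "SVSpec",
    "SimConfig",
    "HaplotypeMap",
    "SimResult",
    "build_test_genome",
    "sample_fragments",
    "project_alignments",
    "simulate_dataset",
    "default_sv_panel",
]


@dataclass(frozen=True)
class SVSpec:
    """One planted variant: the novel-adjacency breakends (a, b) on the
    reference (the affected segment is [a+1, b-1]) and its genotype
    (1 = heterozygous, 2 = homozygous)."""

    svtype: str  # 'deletion' or 'inversion'
    a: int
    b: int
    genotype: int
    id: int = 0

    def __post_init__(self):
        if self.svtype not in ("deletion", "inversion"):
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if not self.a + 1 < self.b:
            raise ValueError("require a + 1 < b (non-empty affected segment)")
        if self.genotype not in (1, 2):
            raise ValueError("genotype must be 1 or 2")

    @property
    def length(self) -> int:
        return self.b - self.a - 1


@dataclass(frozen=True)
class SimConfig:
    seed: int
    ref_length: int = 5_000_000
    chrom: str = "chr1"
    lam: float = 0.3          # fragments per base, whole genome (diploid)
    lavg: float = 200.0
    sd_l: float = 20.0
    readlength: int = 50
    p_err: float = 0.01
    repeats: tuple = ()       # (pos_a, pos_b, length) duplicated blocks
    technology: Technology = Technology.ILLUMINA

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.lavg <= 2 * self.readlength:
            raise ValueError("Lavg must exceed twice the read length")


@dataclass
class Junction:
    """A novel adjacency of the test genome in reference coordinates."""

    sv_id: int
    a: int
    b: int
    signature: str  # 'deletion', 'inv_pp', 'inv_mm'


class HaplotypeMap:
    """Piecewise-linear test <-> reference coordinate map of one haplotype.

    Blocks are contiguous reference segments in test order; ``orient`` is -1
    for inverted segments. Reads are mapped block-wise; a read spanning a
    block boundary has no clean alignment.
    """

    def __init__(self, blocks: list[tuple[int, int, int]],
                 junctions: list[Junction]):
        self.ref_start = np.array([b[0] for b in blocks], dtype=np.int64)
        self.ref_end = np.array([b[1] for b in blocks], dtype=np.int64)
        self.orient = np.array([b[2] for b in blocks], dtype=np.int64)
        lengths = self.ref_end - self.ref_start + 1
        self.test_start = np.concatenate([[1], 1 + np.cumsum(lengths)[:-1]])
        self.test_end = self.test_start + lengths - 1
        self.test_length = int(self.test_end[-1])
        self.junctions = junctions

    def map_reads(self, t1: np.ndarray, t2: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                             np.ndarray]:
        """Map test read intervals [t1, t2] to reference coordinates.

        Returns (ref_lo, ref_hi, inverted, block_index, ok); ``ok`` is False
        when a read crosses a block boundary (no clean alignment).
        """
        b1 = np.searchsorted(self.test_start, t1, "right") - 1
        b2 = np.searchsorted(self.test_start, t2, "right") - 1
        ok = (b1 == b2) & (t2 <= self.test_end[np.clip(b1, 0, None)])
        b = np.clip(b1, 0, len(self.test_start) - 1)
        off1 = t1 - self.test_start[b]
        off2 = t2 - self.test_start[b]
        fwd = self.orient[b] > 0
        lo = np.where(fwd, self.ref_start[b] + off1, self.ref_end[b] - off2)
        hi = np.where(fwd, self.ref_start[b] + off2, self.ref_end[b] - off1)
        return lo, hi, ~fwd, b, ok


def build_test_genome(ref_length: int, svs: list[SVSpec]
                      ) -> tuple[HaplotypeMap, HaplotypeMap]:
    """Apply the variant panel to both haplotypes of a diploid test genome.

    Homozygous variants go on both haplotypes, heterozygous ones on the first.
    A deletion of (a, b) removes [a+1, b-1] and creates the adjacency (a, b);
    an inversion reverses [a+1, b-1] and creates adjacencies (a, b-1)
    (inversion-type +/+) and (a+1, b) (inversion-type -/-).
    """
    svs = sorted(svs, key=lambda s: s.a)
    for prev, nxt in zip(svs, svs[1:]):
        if nxt.a <= prev.b:
            raise ValueError(
                f"overlapping variants: {prev.id} ([{prev.a},{prev.b}]) and "
                f"{nxt.id} ([{nxt.a},{nxt.b}])")
    if svs and (svs[0].a < 1 or svs[-1].b > ref_length):
        raise ValueError("variant outside the reference")

    def build(select) -> HaplotypeMap:
        blocks: list[tuple[int, int, int]] = []
        junctions: list[Junction] = []
        cursor = 1
        for sv in svs:
            if not select(sv):
                continue
            blocks.append((cursor, sv.a, 1))
            j_idx = len(blocks) - 1
            if sv.svtype == "deletion":
                junctions.append(Junction(sv.id, sv.a, sv.b, "deletion"))
            else:
                blocks.append((sv.a + 1, sv.b - 1, -1))
                junctions.append(Junction(sv.id, sv.a, sv.b - 1, "inv_pp"))
                junctions.append(Junction(sv.id, sv.a + 1, sv.b, "inv_mm"))
            cursor = sv.b
        blocks.append((cursor, ref_length, 1))
        return HaplotypeMap(blocks, junctions)

    hap1 = build(lambda sv: True)
    hap2 = build(lambda sv: sv.genotype == 2)
    return hap1, hap2


def sample_fragments(hap: HaplotypeMap, rate: float, config: SimConfig,
                     rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Poisson-process fragment sampling on one haplotype: left ends uniform
    at the given per-base rate, lengths Normal(Lavg, sd) truncated at twice the
    read length; fragments running off the end are discarded."""
    n = rng.poisson(rate * hap.test_length)
    starts = rng.integers(1, hap.test_length + 1, size=n)
    lengths = np.rint(rng.normal(config.lavg, config.sd_l, size=n)).astype(np.int64)
    lengths = np.maximum(lengths, 2 * config.readlength)
    keep = starts + lengths - 1 <= hap.test_length
    return starts[keep], lengths[keep]


def _junction_of(hap: HaplotypeMap, b_left: np.ndarray, b_right: np.ndarray
                 ) -> np.ndarray:
    """sv id of the junction between the blocks holding the two reads
    (-1 when both reads are in the same block)."""
    out = np.full(len(b_left), -1, dtype=np.int64)
    cross = b_left != b_right
    jmap = {}
    for idx, j in enumerate(hap.junctions):
        jmap[idx] = j.sv_id
    # junction after block i has index i in test order
    out[cross] = [jmap.get(int(bl), -1) for bl in b_left[cross]]
    return out


def project_alignments(starts: np.ndarray, lengths: np.ndarray,
                       hap: HaplotypeMap, hap_index: int, config: SimConfig,
                       rng: np.random.Generator, id_offset: int = 0
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project one haplotype's fragments to reference alignments.

    Returns an alignment table (one row per fragment alignment, the input
    format of :func:`probsv.fragments.classify_table`) and a per-fragment
    truth table (haplotype, straddled sv id, error flag, placement count).
    """
    rl = config.readlength
    l1, l2 = starts, starts + rl - 1
    r1, r2 = starts + lengths - rl, starts + lengths - 1
    lo1, hi1, inv1, b1, ok1 = hap.map_reads(l1, l2)
    lo2, hi2, inv2, b2, ok2 = hap.map_reads(r1, r2)
    ok = ok1 & ok2
    n_lost = int((~ok).sum())

    lo1, hi1, inv1, b1 = lo1[ok], hi1[ok], inv1[ok], b1[ok]
    lo2, hi2, inv2, b2 = lo2[ok], hi2[ok], inv2[ok], b2[ok]
    n = int(ok.sum())
    frag_ids = id_offset + np.arange(n, dtype=np.int64)
    sv_id = _junction_of(hap, np.minimum(b1, b2), np.maximum(b1, b2))

    # read 1 is sequenced forward on the test genome, read 2 reverse;
    # inversion blocks flip the reference strand
    strand1 = ~inv1
    strand2 = inv2

    # erroneous mappings: replace the placement with a random discordant one
    err = rng.random(n) < config.p_err
    n_err = int(err.sum())
    if n_err:
        max_pos = config.ref_length - rl + 1
        e_pos1 = rng.integers(1, max_pos + 1, size=n_err)
        e_pos2 = rng.integers(1, max_pos + 1, size=n_err)
        e_s1 = rng.random(n_err) < 0.5
        e_s2 = rng.random(n_err) < 0.5
        lo1[err], strand1[err] = e_pos1, e_s1
        lo2[err], strand2[err] = e_pos2, e_s2
        hi1[err] = e_pos1 + rl - 1
        hi2[err] = e_pos2 + rl - 1

    # repeat blocks: reads fully inside one copy also align to the other
    alt1 = np.full(n, -1, dtype=np.int64)
    alt2 = np.full(n, -1, dtype=np.int64)
    for pa, pb, length in config.repeats:
        for (lo, hi, alt) in ((lo1, hi1, alt1), (lo2, hi2, alt2)):
            in_a = (lo >= pa) & (hi <= pa + length - 1)
            in_b = (lo >= pb) & (hi <= pb + length - 1)
            alt[in_a] = lo[in_a] - pa + pb
            alt[in_b] = lo[in_b] - pb + pa

    rows = {
        "fragment_id": frag_ids, "chrom1": config.chrom, "pos1": lo1,
        "strand1": strand1, "len1": np.full(n, rl),
        "chrom2": config.chrom, "pos2": lo2, "strand2": strand2,
        "len2": np.full(n, rl), "mapq": np.full(n, 60),
    }
    base = pd.DataFrame(rows)
    frames = [base]
    has1 = alt1 >= 0
    has2 = alt2 >= 0
    for m1, m2 in ((True, False), (False, True), (True, True)):
        sel = (has1 == m1) & (has2 == m2) & (m1 | m2)
        if not sel.any():
            continue
        extra = base[sel].copy()
        if m1:
            extra["pos1"] = alt1[sel]
        if m2:
            extra["pos2"] = alt2[sel]
        frames.append(extra)
        if m1 and m2:
            # single-read alternatives of doubly repetitive fragments
            for col, alt in (("pos1", alt1), ("pos2", alt2)):
                e2 = base[sel].copy()
                e2[col] = alt[sel]
                frames.append(e2)
    aln = pd.concat(frames, ignore_index=True)
    # ambiguous fragments get degraded mapping quality on every placement
    multi = pd.Series(has1 | has2, index=base.index)
    multi_ids = frag_ids[multi.to_numpy()]
    aln.loc[aln["fragment_id"].isin(multi_ids), "mapq"] = 20

    truth = pd.DataFrame({
        "fragment_id": frag_ids,
        "haplotype": hap_index,
        "sv_id": np.where(err, -1, sv_id),
        "is_error": err,
        "n_alignments": aln.groupby("fragment_id").size().reindex(
            frag_ids, fill_value=1).to_numpy(),
        "test_start": starts[ok],
        "length": lengths[ok],
    })
    truth.attrs["n_lost_junction_reads"] = n_lost
    return aln, truth


@dataclass
class SimResult:
    """Bundle of one simulated data set."""

    config: SimConfig
    svs: list[SVSpec]
    haplotypes: tuple[HaplotypeMap, HaplotypeMap]
    alignments: pd.DataFrame
    truth: pd.DataFrame
    mapability: MapabilityTrack
    n_lost_junction_reads: int

    @property
    def library_stats(self) -> LibraryStats:
        """Idealized library stats from the generating Normal distribution
        (0.1% / 99.9% quantiles)."""
        from scipy import stats as sps

        z = sps.norm.ppf(0.999)
        return LibraryStats(
            lmin=int(np.floor(self.config.lavg - z * self.config.sd_l)),
            lmax=int(np.ceil(self.config.lavg + z * self.config.sd_l)),
            lavg=self.config.lavg, readlength=self.config.readlength,
            technology=self.config.technology,
        )

    def known_variants(self, delta: float = 0.0):
        from .evaluation import KnownVariant

        return [
            KnownVariant(chrom=self.config.chrom, a=sv.a, b=sv.b, delta=delta,
                         svtype="DEL" if sv.svtype == "deletion" else "INV",
                         genotype=sv.genotype, id=str(sv.id))
            for sv in self.svs
        ]


def simulate_dataset(config: SimConfig, svs: list[SVSpec]) -> SimResult:
    """Simulate a full data set: genome, fragments, projected alignments."""
    rng = np.random.default_rng(config.seed)
    hap1, hap2 = build_test_genome(config.ref_length, svs)
    frames, truths = [], []
    offset = 0
    lost = 0
    for idx, hap in enumerate((hap1, hap2)):
        starts, lengths = sample_fragments(hap, config.lam / 2, config, rng)
        aln, truth = project_alignments(starts, lengths, hap, idx, config,
                                        rng, id_offset=offset)
        offset += len(truth) + 1
        lost += truth.attrs["n_lost_junction_reads"]
        frames.append(aln)
        truths.append(truth)
    aln = pd.concat(frames, ignore_index=True)
    truth = pd.concat(truths, ignore_index=True)

    zero = []
    for pa, pb, length in config.repeats:
        zero.append((pa, pa + length - 1, 0.0))
        zero.append((pb, pb + length - 1, 0.0))
    track = MapabilityTrack(
        {config.chrom: np.array(sorted(zero), dtype=float)} if zero else {},
        default=1.0)
    return SimResult(config=config, svs=list(svs), haplotypes=(hap1, hap2),
                     alignments=aln, truth=truth, mapability=track,
                     n_lost_junction_reads=lost)


def default_sv_panel(ref_length: int = 5_000_000, n_del: int = 50,
                     n_inv: int = 10, seed: int = 0,
                     del_length: tuple[int, int] = (150, 2500),
                     inv_length: tuple[int, int] = (500, 5000),
                     margin: int = 20_000) -> list[SVSpec]:
    """A non-overlapping panel of deletions and inversions, genotypes split
    half homozygous / half heterozygous within each type."""
    rng = np.random.default_rng(seed)
    n = n_del + n_inv
    slot = (ref_length - 2 * margin) // n
    max_len = max(del_length[1], inv_length[1])
    if slot <= max_len + 4 * margin // n + 2:
        raise ValueError("reference too short for the requested panel")
    types = ["deletion"] * n_del + ["inversion"] * n_inv
    rng.shuffle(types)
    # genotypes: half homozygous / half heterozygous within each type
    counters = {"deletion": 0, "inversion": 0}
    svs = []
    for i, svtype in enumerate(types):
        lo, hi = del_length if svtype == "deletion" else inv_length
        length = int(rng.integers(lo, hi + 1))
        a0 = margin + i * slot
        a = int(a0 + rng.integers(0, slot - length - 2))
        genotype = 2 if counters[svtype] % 2 == 0 else 1
        counters[svtype] += 1
        svs.append(SVSpec(svtype=svtype, a=a, b=a + length + 1,
                          genotype=genotype, id=i))
    return svs
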