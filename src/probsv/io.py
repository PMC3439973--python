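"""Readers and writers for the standard formats around the caller.

Alignments come in as SAM/BAM (via pysam) or as a plain TSV with the same
fields; calls go out as BEDPE and VCF 4.1 (SVTYPE=DEL/INV with CIPOS/CIEND
from the breakend-polygon extent); truth sets are BED or BEDPE.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .evaluation import KnownVariant
from .fragments import LibraryStats
from .reporting import FinalCall

__all__ = [
    "read_sam",
    "write_sam",
    "read_alignment_table",
    "write_alignment_table",
    "write_candidates",
    "write_discordants_bedpe",
    "write_calls_bedpe",
    "write_vcf",
    "read_truth",
    "write_library_stats",
]

TABLE_COLUMNS = ["fragment_id", "chrom1", "pos1", "strand1", "len1",
                 "chrom2", "pos2", "strand2", "len2", "mapq"]


def read_alignment_table(path) -> pd.DataFrame:
    """Read the documented alignment TSV (one row per fragment alignment)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alignment table missing columns: {missing}")
    for col in ("strand1", "strand2"):
        if df[col].dtype == object:
            df[col] = df[col].map({"+": True, "-": False, "True": True,
                                   "False": False}).astype(bool)
    return df


def write_alignment_table(df: pd.DataFrame, path) -> None:
    out = df[TABLE_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False)


def read_sam(path) -> pd.DataFrame:
    """Pair SAM/BAM records into the alignment table.

    All mapped placements of each mate are collected per query name (primary
    and secondary) and combined pairwise into candidate fragment alignments.
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    mates: dict[str, tuple[list, list]] = {}
    with pysam.AlignmentFile(str(path), mode) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            entry = (rec.reference_name, rec.reference_start + 1,
                     not rec.is_reverse, rec.query_alignment_length
                     or rec.infer_read_length() or len(rec.query_sequence or ""),
                     rec.mapping_quality)
            slot = mates.setdefault(rec.query_name, ([], []))
            slot[1 if rec.is_read2 else 0].append(entry)
    rows = []
    for fid, name in enumerate(sorted(mates)):
        r1s, r2s = mates[name]
        if not r1s or not r2s:
            continue
        for a1, a2 in itertools.product(r1s, r2s):
            rows.append((fid, a1[0], a1[1], a1[2], a1[3],
                         a2[0], a2[1], a2[2], a2[3], min(a1[4], a2[4])))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_sam(df: pd.DataFrame, path, chrom_lengths: dict[str, int]) -> None:
    """Write the alignment table as SAM (two records per fragment alignment)."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": c, "LN": int(l)} for c, l in chrom_lengths.items()]}
    ref_ids = {c: i for i, c in enumerate(chrom_lengths)}
    seen: set[int] = set()
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for row in df.itertuples(index=False):
            secondary = row.fragment_id in seen
            seen.add(row.fragment_id)
            for mate, (chrom, pos, strand, rlen) in enumerate((
                    (row.chrom1, row.pos1, row.strand1, row.len1),
                    (row.chrom2, row.pos2, row.strand2, row.len2))):
                rec = pysam.AlignedSegment()
                rec.query_name = f"frag{row.fragment_id}"
                rec.reference_id = ref_ids[chrom]
                rec.reference_start = int(pos) - 1
                rec.mapping_quality = int(row.mapq)
                rec.cigarstring = f"{int(rlen)}M"
                rec.query_sequence = "N" * int(rlen)
                flag = 0x1 | (0x40 if mate == 0 else 0x80)
                if not strand:
                    flag |= 0x10
                if secondary:
                    flag |= 0x100
                rec.flag = flag
                fh.write(rec)


def write_library_stats(stats: LibraryStats, path) -> None:
    pd.DataFrame([{
        "lmin": stats.lmin, "lmax": stats.lmax, "lavg": stats.lavg,
        "readlength": stats.readlength,
        "technology": stats.technology.value,
    }]).to_csv(path, sep="\t", index=False)


def write_discordants_bedpe(table: pd.DataFrame, path) -> None:
    """Discordant fragment alignments as BEDPE (0-based half-open)."""
    out = pd.DataFrame({
        "chrom1": table["chrom_x"], "start1": table["x"] - 1,
        "end1": table["x"], "chrom2": table["chrom_y"],
        "start2": table["y"] - 1, "end2": table["y"],
        "name": table["fragment_id"], "score": table["mapq"],
        "strand1": np.where(table["sign_x"] > 0, "+", "-"),
        "strand2": np.where(table["sign_y"] > 0, "+", "-"),
        "signature": table["sig"],
    })
    out.to_csv(path, sep="\t", index=False, header=False)


def write_candidates(candidates, path) -> None:
    """Clustered candidates as a TSV (id, chrom pair, signature,
    support, fragment ids, polygon vertices)."""
    rows = []
    for c in candidates:
        verts = ";".join(f"{float(a):g},{float(b):g}"
                         for a, b in c.polygon.vertices)
        rows.append({
            "id": c.id, "chrom_a": c.chrom_a, "chrom_b": c.chrom_b,
            "signature": c.signature.name, "k": c.k,
            "fragments": ",".join(map(str, c.fragment_ids)),
            "amax": c.amax, "bmin": c.bmin, "polygon": verts,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_calls_bedpe(calls: list[FinalCall], path) -> None:
    rows = []
    for c in calls:
        rows.append((c.chrom, c.start - 1, c.start, c.chrom_b, c.end - 1,
                     c.end, f"cand{c.candidate_id}", f"{c.log_lambda:.4f}",
                     c.svtype, c.support, c.copy_call,
                     f"{c.chain_log_lambda:.4f}"))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def write_vcf(calls: list[FinalCall], path, chrom_lengths: dict[str, int],
              params_echo: str = "") -> None:
    """Final calls as VCF 4.1 with SVTYPE and confidence intervals from the
    breakend-polygon extent."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.1')
    if params_echo:
        header.add_line(f"##probsv_params={params_echo}")
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,'
                    'Description="Type of structural variant">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,'
                    'Description="End position of the variant">')
    header.add_line('##INFO=<ID=CIPOS,Number=2,Type=Integer,'
                    'Description="Confidence interval around POS">')
    header.add_line('##INFO=<ID=CIEND,Number=2,Type=Integer,'
                    'Description="Confidence interval around END">')
    header.add_line('##INFO=<ID=SUPPORT,Number=1,Type=Integer,'
                    'Description="Supporting discordant fragments">')
    header.add_line('##INFO=<ID=LOGLR,Number=1,Type=Float,'
                    'Description="Log likelihood ratio">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,'
                    'Description="Genotype">')
    for chrom, length in chrom_lengths.items():
        header.add_line(f"##contig=<ID={chrom},length={int(length)}>")
    header.add_sample("sample")
    with pysam.VariantFile(str(path), "w", header=header) as fh:
        for c in calls:
            rec = fh.new_record()
            rec.contig = c.chrom
            rec.start = c.start - 1  # 0-based
            rec.stop = c.end
            rec.id = f"cand{c.candidate_id}"
            rec.alleles = ("N", f"<{c.svtype}>")
            rec.info["SVTYPE"] = c.svtype
            rec.info["SUPPORT"] = c.support
            rec.info["LOGLR"] = float(c.log_lambda)
            rec.samples["sample"]["GT"] = ((0, 1) if c.copy_call == 1
                                           else (1, 1) if c.copy_call == 2
                                           else (0, 0))
            fh.write(rec)


def read_truth(path, delta: float = 0.0, svtype: str = "") -> list[KnownVariant]:
    """Known variants from BED (chrom, start, end [, type, genotype]) or
    BEDPE; coordinates are converted from 0-based half-open to breakends."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    if df.shape[1] >= 6 and df.dtypes[3] != object:
        # BEDPE: chrom1 start1 end1 chrom2 start2 end2 ...
        for i, row in df.iterrows():
            out.append(KnownVariant(
                chrom=str(row[0]), a=int(row[2]), b=int(row[4]) + 1,
                delta=delta, svtype=str(row[6]) if df.shape[1] > 6 else svtype,
                id=str(i)))
    else:
        for i, row in df.iterrows():
            out.append(KnownVariant(
                chrom=str(row[0]), a=int(row[1]), b=int(row[2]) + 1,
                delta=delta,
                svtype=str(row[3]) if df.shape[1] > 3 else svtype,
                genotype=int(row[4]) if df.shape[1] > 4 else None,
                id=str(i)))
    return out
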