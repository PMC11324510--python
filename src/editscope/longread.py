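"""Single-cell long-read genotyping over sgRNA target windows.

Cell barcodes and UMIs live in the 5' soft-clipped portion of each aligned
read; window base calls are read off the CIGAR; per-(cell, UMI) consensus
haplotypes are called by plurality and rolled up into one genotype per cell
with strict heterozygote exclusion.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
import pysam

from .refmodel import (
    GenomeSlice,
    TranscriptModel,
    ValidationError,
    WindowInterval,
    call_aa_changes,
    genotype_label,
    revcomp,
)

DELETION = "deletion"
UNCOVERED = "uncovered"

# 10x read1 sequencing primer; the CB+UMI follow it in the soft clip.
DEFAULT_ADAPTER = "CTACACGACGCTCTTCCGATCT"


@dataclass(frozen=True)
class AdapterSpec:
    """5' read structure: adapter, then cell barcode, then UMI."""

    adapter: str = DEFAULT_ADAPTER
    cb_len: int = 16
    umi_len: int = 10


@dataclass
class ReadTag:
    """One read's barcode/UMI assignment plus its window base calls."""

    cb: str
    umi: str
    read_id: str
    window_calls: Optional[List[str]] = None


@dataclass(frozen=True)
class Rejected:
    """A read (or UMI group) removed from analysis, with a reason code."""

    reason: str


@dataclass
class UmiConsensus:
    cb: str
    umi: str
    read_count: int
    consensus_hap: Optional[str]
    genotype_label: Optional[str]


@dataclass
class CellGenotype:
    cb: str
    genotype_label: Optional[str]
    n_umis: int
    n_umis_total: int
    zygosity: str  # homozygous | heterozygous | unresolved


@dataclass
class GenotypeParams:
    min_umi_reads: int = 10
    max_umi_dist: int = 2
    majority_frac: float = 1.0
    min_umis: int = 1


def load_whitelist(path) -> set:
    """One barcode per line; a trailing ``-1`` suffix is stripped."""
    out = set()
    for line in open(path):
        bc = line.strip()
        if bc:
            out.add(bc.split("-")[0])
    return out


def load_windows_tsv(path) -> Dict[str, WindowInterval]:
    """Windows TSV: guide_id, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t")
    wins = {}
    for r in df.itertuples(index=False):
        wins[str(r.guide_id)] = WindowInterval(r.chrom, int(r.start) - 1, int(r.end))
    return wins


def levenshtein(a: str, b: str, limit: Optional[int] = None) -> int:
    """Plain Levenshtein distance with an optional early-exit bound."""
    if a == b:
        return 0
    if limit is not None and abs(len(a) - len(b)) > limit:
        return limit + 1
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        if limit is not None and min(cur) > limit:
            return limit + 1
        prev = cur
    return prev[-1]


def extract_cb_umi(
    read: pysam.AlignedSegment,
    whitelist: set,
    adapter: AdapterSpec = AdapterSpec(),
) -> Union[ReadTag, Rejected]:
    """Pull the cell barcode and UMI out of the 5' soft clip.

    The read's original orientation is recovered from the alignment strand;
    the barcode must match the whitelist exactly (zero mismatches).
    """
    cigar = read.cigartuples
    seq = read.query_sequence
    if cigar is None or seq is None:
        raise ValidationError(f"malformed alignment record {read.query_name!r}")
    if not read.is_reverse:
        clip_len = cigar[0][1] if cigar[0][0] == 4 else 0
        clip_seq = seq[:clip_len]
    else:
        clip_len = cigar[-1][1] if cigar[-1][0] == 4 else 0
        clip_seq = revcomp(seq[len(seq) - clip_len :]) if clip_len else ""
    if not clip_seq:
        return Rejected("no_softclip")
    idx = clip_seq.rfind(adapter.adapter)
    if idx < 0:
        return Rejected("truncated")
    start = idx + len(adapter.adapter)
    need = adapter.cb_len + adapter.umi_len
    if start + need > len(clip_seq):
        return Rejected("truncated")
    cb = clip_seq[start : start + adapter.cb_len]
    umi = clip_seq[start + adapter.cb_len : start + need]
    if cb not in whitelist:
        return Rejected("cb_unmatched")
    return ReadTag(cb=cb, umi=umi, read_id=read.query_name)


def extract_window_calls(
    read: pysam.AlignedSegment, win: WindowInterval
) -> List[str]:
    """Per-window-position base calls from the alignment.

    Substituted bases are reported as-is, deleted positions as ``deletion``
    and positions outside the aligned span as ``uncovered``.  Insertions
    between window positions are ignored.
    """
    calls = [UNCOVERED] * win.width
    if read.reference_name != win.chrom:
        return calls
    seq = read.query_sequence
    for qpos, rpos in read.get_aligned_pairs():
        if rpos is None or not (win.start <= rpos < win.end):
            continue
        off = rpos - win.start
        if qpos is None:
            calls[off] = DELETION
        else:
            base = seq[qpos].upper()
            calls[off] = base if base in "ACGT" else UNCOVERED
    return calls


def consolidate_umis(
    umi_read_counts: Dict[str, int], max_dist: int = 2
) -> Dict[str, str]:
    """Single-linkage UMI merging with count-ordered representatives.

    UMIs whose pairwise edit distance chains at ``max_dist`` or below form one
    cluster (transitive closure over all pairs); every member maps to the
    cluster's highest-count UMI (ties broken lexicographically).  Read counts
    of merged UMIs accumulate on the representative, so totals are conserved.
    """
    for u, c in umi_read_counts.items():
        if c <= 0:
            raise ValidationError(f"non-positive read count for UMI {u}")
    order = sorted(umi_read_counts, key=lambda u: (-umi_read_counts[u], u))
    parent = {u: u for u in order}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for i, u in enumerate(order):
        for v in order[i + 1 :]:
            if find(u) != find(v) and levenshtein(u, v, max_dist) <= max_dist:
                parent[find(v)] = find(u)
    clusters: Dict[str, List[str]] = defaultdict(list)
    for u in order:
        clusters[find(u)].append(u)
    mapping: Dict[str, str] = {}
    for members in clusters.values():
        rep = min(members, key=lambda u: (-umi_read_counts[u], u))
        for u in members:
            mapping[u] = rep
    return mapping


def consensus_haplotype(call_matrix: Sequence[Sequence[str]]) -> Optional[str]:
    """Per-position plurality over A/C/G/T; any tie or a deletion/uncovered
    plurality yields ``None``."""
    width = len(call_matrix[0])
    out = []
    for j in range(width):
        counts = Counter(row[j] for row in call_matrix)
        top = max(counts.values())
        winners = [c for c, n in counts.items() if n == top]
        if len(winners) != 1 or winners[0] not in ("A", "C", "G", "T"):
            return None
        out.append(winners[0])
    return "".join(out)


def umi_consensus(
    group: Sequence[ReadTag],
    min_reads: int,
    labeler=None,
) -> Union[UmiConsensus, Rejected]:
    """Consensus window haplotype for one (cell, UMI) read group."""
    if not group:
        raise ValidationError("empty UMI group")
    if len(group) < min_reads:
        return Rejected("low_support")
    hap = consensus_haplotype([t.window_calls for t in group])
    if hap is None:
        return Rejected("no_consensus")
    label = labeler(hap) if labeler is not None else None
    return UmiConsensus(
        cb=group[0].cb,
        umi=group[0].umi,
        read_count=len(group),
        consensus_hap=hap,
        genotype_label=label,
    )


def cell_genotype(
    consensus_list: Sequence[UmiConsensus],
    majority_frac: float = 1.0,
    min_umis: int = 1,
) -> CellGenotype:
    """Roll per-UMI labels up to one per-cell genotype.

    A cell is homozygous when the top label's UMI share reaches
    ``majority_frac`` (default: unanimity), heterozygous otherwise, and
    unresolved below ``min_umis`` supporting UMIs.
    """
    cb = consensus_list[0].cb if consensus_list else None
    n_total = len(consensus_list)
    if n_total < min_umis or n_total == 0:
        return CellGenotype(cb, None, 0, n_total, "unresolved")
    counts = Counter(c.genotype_label for c in consensus_list)
    top_label, top_n = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n / n_total >= majority_frac:
        return CellGenotype(cb, top_label, top_n, n_total, "homozygous")
    return CellGenotype(cb, top_label, top_n, n_total, "heterozygous")


def make_labeler(win: WindowInterval, tx: TranscriptModel, ref: GenomeSlice):
    """Cache haplotype -> canonical genotype label for one window."""
    ref_hap = ref.fetch_window(win)
    cache: Dict[str, str] = {}

    def label(hap: str) -> str:
        if hap not in cache:
            cache[hap] = genotype_label(call_aa_changes(win, ref_hap, hap, tx, ref))
        return cache[hap]

    return label


def genotype_pipeline(
    alignment_path,
    ref: GenomeSlice,
    tx: TranscriptModel,
    whitelist: set,
    windows: Dict[str, WindowInterval],
    params: GenotypeParams = GenotypeParams(),
    adapter: AdapterSpec = AdapterSpec(),
):
    """Run barcode extraction -> window calls -> UMI consensus -> cell
    genotypes over every window.

    Returns ``(umi_table, cell_table, report)``; both tables are sorted by
    (cell barcode, window).
    """
    for wid, win in windows.items():
        if not ref.covers(win.chrom, win.start, win.end):
            raise ValidationError(f"window {wid} at {win.region()} outside reference")
        if not tx.single_exon_containing(win.start, win.end):
            raise ValidationError(f"window {wid} not within a single exon")

    labelers = {wid: make_labeler(win, tx, ref) for wid, win in windows.items()}
    groups: Dict[Tuple[str, str], Dict[str, List[ReadTag]]] = defaultdict(
        lambda: defaultdict(list)
    )
    report = {
        "reads_in": 0,
        "reads_rejected": Counter(),
        "reads_assigned": 0,
        "reads_no_window": 0,
        "umis_raw": 0,
        "umis_after_consolidation": 0,
        "umis_dropped": Counter(),
        "umis_kept": 0,
        "cells_genotyped": 0,
        "cells_heterozygous": 0,
        "cells_unresolved": 0,
    }

    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            report["reads_in"] += 1
            tag = extract_cb_umi(read, whitelist, adapter)
            if isinstance(tag, Rejected):
                report["reads_rejected"][tag.reason] += 1
                continue
            report["reads_assigned"] += 1
            hit = False
            for wid, win in windows.items():
                if (
                    read.reference_name == win.chrom
                    and read.reference_start < win.end
                    and read.reference_end > win.start
                ):
                    hit = True
                    calls = extract_window_calls(read, win)
                    groups[(wid, tag.cb)][tag.umi].append(
                        ReadTag(tag.cb, tag.umi, tag.read_id, calls)
                    )
            if not hit:
                report["reads_no_window"] += 1

    umi_rows = []
    cell_rows = []
    for (wid, cb) in sorted(groups, key=lambda k: (k[1], k[0])):
        by_umi = groups[(wid, cb)]
        counts = {u: len(tags) for u, tags in by_umi.items()}
        report["umis_raw"] += len(counts)
        mapping = consolidate_umis(counts, params.max_umi_dist)
        merged: Dict[str, List[ReadTag]] = defaultdict(list)
        for u, tags in by_umi.items():
            merged[mapping[u]].extend(tags)
        report["umis_after_consolidation"] += len(merged)
        consensus: List[UmiConsensus] = []
        for u in sorted(merged):
            res = umi_consensus(merged[u], params.min_umi_reads, labelers[wid])
            if isinstance(res, Rejected):
                report["umis_dropped"][res.reason] += 1
                continue
            report["umis_kept"] += 1
            consensus.append(res)
            umi_rows.append(
                {
                    "cb": cb,
                    "umi": u,
                    "window": wid,
                    "read_count": res.read_count,
                    "consensus_hap": res.consensus_hap,
                    "genotype_label": res.genotype_label,
                }
            )
        cg = cell_genotype(consensus, params.majority_frac, params.min_umis)
        if cg.zygosity == "homozygous":
            report["cells_genotyped"] += 1
        elif cg.zygosity == "heterozygous":
            report["cells_heterozygous"] += 1
        else:
            report["cells_unresolved"] += 1
        cell_rows.append(
            {
                "cb": cb,
                "window": wid,
                "genotype_label": cg.genotype_label,
                "n_umis": cg.n_umis,
                "n_umis_total": cg.n_umis_total,
                "zygosity": cg.zygosity,
            }
        )

    umi_cols = ["cb", "umi", "window", "read_count", "consensus_hap", "genotype_label"]
    cell_cols = ["cb", "window", "genotype_label", "n_umis", "n_umis_total", "zygosity"]
    umi_df = pd.DataFrame(umi_rows, columns=umi_cols)
    cell_df = pd.DataFrame(cell_rows, columns=cell_cols)
    report["reads_rejected"] = dict(report["reads_rejected"])
    report["umis_dropped"] = dict(report["umis_dropped"])
    return umi_df, cell_df, report
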