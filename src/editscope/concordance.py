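"""Cross-platform validation of window genotypes.

Per-UMI identity between long- and short-read calls, window variant
frequencies, and squared Pearson correlation between frequency tables
(e.g. genomic DNA vs single-cell cDNA).
"""

from __future__ import annotations

import gzip
from collections import defaultdict
from typing import Dict, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .longread import Rejected, consensus_haplotype
from .refmodel import GenomeSlice, ValidationError, WindowInterval, revcomp

LOG_PSEUDOCOUNT = 1e-4


class EmptyOverlapError(ValueError):
    """The two UMI tables share no (cb, umi, window) keys."""


class UndefinedCorrelationError(ValueError):
    """Zero variance in one of the frequency vectors."""


def _open_maybe_gz(path):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p)


def parse_amplicon_pairs(
    r1_path,
    r2_path,
    whitelist: set,
    win: WindowInterval,
    ref: GenomeSlice,
    window_id: str = "amplicon",
    min_reads: int = 3,
    anchor_len: int = 12,
) -> Tuple[pd.DataFrame, dict]:
    """Short-read amplicon pairs -> per-UMI window haplotype table.

    Read1 carries CB (16 nt) + UMI (10 nt); read2 carries the amplicon.  The
    window is located in read2 by exact matching of the ``anchor_len``
    reference bases immediately 5' of the window (reverse complement tried
    as a fallback), avoiding a full aligner.  Per-(cb, umi) haplotypes are
    called by plurality with ``min_reads`` support.
    """
    anchor = ref.fetch(win.chrom, win.start - anchor_len, win.start)
    report = {"reads_in": 0, "reads_rejected": defaultdict(int), "umis_dropped": defaultdict(int)}
    groups: Dict[Tuple[str, str], list] = defaultdict(list)
    with _open_maybe_gz(r1_path) as fh1, _open_maybe_gz(r2_path) as fh2:
        for rec1, rec2 in zip(SeqIO.parse(fh1, "fastq"), SeqIO.parse(fh2, "fastq")):
            report["reads_in"] += 1
            s1 = str(rec1.seq)
            if len(s1) < 26:
                report["reads_rejected"]["truncated"] += 1
                continue
            cb, umi = s1[:16], s1[16:26]
            if cb not in whitelist:
                report["reads_rejected"]["cb_unmatched"] += 1
                continue
            s2 = str(rec2.seq).upper()
            i = s2.find(anchor)
            if i < 0:
                s2 = revcomp(s2)
                i = s2.find(anchor)
            if i < 0:
                report["reads_rejected"]["no_anchor"] += 1
                continue
            hap = s2[i + anchor_len : i + anchor_len + win.width]
            if len(hap) < win.width:
                report["reads_rejected"]["truncated"] += 1
                continue
            groups[(cb, umi)].append(list(hap))

    rows = []
    for (cb, umi) in sorted(groups):
        calls = groups[(cb, umi)]
        if len(calls) < min_reads:
            report["umis_dropped"]["low_support"] += 1
            continue
        hap = consensus_haplotype(calls)
        if hap is None:
            report["umis_dropped"]["no_consensus"] += 1
            continue
        rows.append({"cb": cb, "umi": umi, "window": window_id, "genotype": hap})
    report["reads_rejected"] = dict(report["reads_rejected"])
    report["umis_dropped"] = dict(report["umis_dropped"])
    return pd.DataFrame(rows, columns=["cb", "umi", "window", "genotype"]), report


def umi_concordance(a: pd.DataFrame, b: pd.DataFrame):
    """Fraction of shared (cb, umi, window) keys with identical genotypes.

    Returns ``(fraction_identical, n_shared, per_window)``.
    """
    keys = ["cb", "umi", "window"]
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    if merged.empty:
        raise EmptyOverlapError("no shared (cb, umi, window) keys between tables")
    same = merged["genotype_a"] == merged["genotype_b"]
    per_window = (
        same.groupby(merged["window"])
        .agg(["mean", "size"])
        .rename(columns={"mean": "fraction_identical", "size": "n_shared"})
    )
    return float(same.mean()), int(len(merged)), per_window


def variant_frequencies(table: pd.DataFrame) -> pd.DataFrame:
    """Per-window genotype frequencies (supporting / total molecules)."""
    if table.empty:
        raise ValidationError("empty UMI genotype table")
    col = "genotype" if "genotype" in table.columns else "genotype_label"
    out = []
    for window, sub in table.groupby("window"):
        total = len(sub)
        for genotype, n in sub[col].value_counts().sort_index().items():
            out.append(
                {
                    "window": window,
                    "genotype": genotype,
                    "count": int(n),
                    "total": total,
                    "frequency": n / total,
                }
            )
    return pd.DataFrame(out)


def frequency_r2(
    x: pd.DataFrame, y: pd.DataFrame, log_scale: bool = False
) -> float:
    """Squared Pearson correlation of matched variant frequencies.

    Variants missing from one table are counted as frequency zero there.
    With ``log_scale`` the correlation is computed on
    ``log10(f + 1e-4)``, matching the usual log-log dot plot.
    """
    keys = [k for k in ("window", "genotype") if k in x.columns and k in y.columns]
    merged = x.merge(y, on=keys, how="outer", suffixes=("_x", "_y"))
    fx = merged["frequency_x"].fillna(0.0).to_numpy(float)
    fy = merged["frequency_y"].fillna(0.0).to_numpy(float)
    if len(merged) < 3:
        raise ValidationError("need at least 3 variants to compute R^2")
    if log_scale:
        fx = np.log10(fx + LOG_PSEUDOCOUNT)
        fy = np.log10(fy + LOG_PSEUDOCOUNT)
    if np.std(fx) == 0 or np.std(fy) == 0:
        raise UndefinedCorrelationError("zero variance in a frequency vector")
    r = np.corrcoef(fx, fy)[0, 1]
    return float(r * r)
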