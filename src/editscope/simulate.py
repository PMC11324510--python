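"""Synthetic truth-annotated data generation.

Emits a toy target locus, errored aligned long reads carrying soft-clipped
adapter+CB+UMI prefixes, and a negative-binomial expression matrix with a
genotype-dependent pathway shift -- everything the other modules consume,
with complete truth tables and no downloads.

Error injection is i.i.d. per base (substitutions and 1-bp indels); this is
a deliberate simplification of nanopore error structure that is sufficient
to exercise consensus logic.
"""

from __future__ import annotations

import itertools
import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .longread import DEFAULT_ADAPTER, AdapterSpec
from .phenotype import ExpressionMatrix
from .refmodel import (
    STOP,
    GenomeSlice,
    TranscriptModel,
    ValidationError,
    WindowInterval,
    call_aa_changes,
    genotype_label,
    revcomp,
)

BASES = "ACGT"
_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class VariantSim:
    """One simulated genotype: window haplotype + phenotype knobs."""

    fraction: float
    name: Optional[str] = None        # derived from the haplotype when None
    hap: Optional[str] = None         # None = auto-pick; "ref" = wild type
    effect: float = 1.0               # multiplier on pathway gene means
    capture: float = 1.0              # cDNA capture factor (NMD emulation)
    stop_gain: bool = False           # auto-pick a stop-gain haplotype


@dataclass
class SimConfig:
    seed: int
    n_cells: int = 200
    variants: Tuple[VariantSim, ...] = (
        VariantSim(fraction=0.5, hap="ref", name="WT"),
        VariantSim(fraction=0.5),
    )
    umis_per_cell: Tuple[int, int] = (3, 6)
    reads_per_umi: Tuple[int, int] = (10, 20)
    sub_rate: float = 0.02
    indel_rate: float = 0.01
    umi_error_rate: float = 0.005
    whitelist_size: int = 2000
    n_genes: int = 300
    pathway_size: int = 50
    nb_log_mean: float = 1.0
    nb_log_sd: float = 0.5
    nb_log_mean_pathway: Optional[float] = None  # default: same as nb_log_mean
    nb_dispersion: float = 10.0
    # Threshold proliferation program: genotypes with any pathway effect
    # (effect != 1) de-repress these genes uniformly, emulating switch-like
    # loss of checkpoint arrest on top of the graded pathway shift.
    arrest_size: int = 50
    arrest_factor: float = 3.0
    strand: str = "+"
    n_exons: int = 1
    n_codons: int = 40
    reverse_read_frac: float = 0.5
    chrom: str = "chrSim"

    def __post_init__(self):
        total = sum(v.fraction for v in self.variants)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"variant fractions sum to {total}, not 1")
        for r in (self.sub_rate, self.indel_rate, self.umi_error_rate):
            if not 0 <= r <= 1:
                raise ValidationError("error rates must lie in [0, 1]")
        if self.strand not in "+-":
            raise ValidationError("strand must be '+' or '-'")
        if not 1 <= self.n_exons <= 3:
            raise ValidationError("n_exons must be 1..3")


@dataclass
class Locus:
    genome: GenomeSlice
    tx: TranscriptModel
    window: WindowInterval
    window_id: str
    ref_hap: str
    variant_haps: Dict[str, str]      # genotype label -> plus-strand haplotype


def _random_codon(rng) -> str:
    while True:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in _STOP_CODONS:
            return codon


def _mirror(interval: Tuple[int, int], length: int) -> Tuple[int, int]:
    s, e = interval
    return length - e, length - s


def simulate_locus(cfg: SimConfig) -> Locus:
    """Toy gene with an in-CDS editing window; deterministic per seed.

    The two window codons are forced to ``CGA`` (arginine, one substitution
    from a stop) plus a random codon, so stop-gain and missense haplotypes
    are always available.  The window is reported on the plus strand
    regardless of gene orientation.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    win_codon = 10  # 0-based codon number of the first forced window codon
    codons = [_random_codon(rng) for _ in range(cfg.n_codons)]
    codons[0] = "ATG"
    codons[win_codon] = "CGA"
    codons[win_codon + 1] = _random_codon(rng)
    cds = "".join(codons) + "TAA"

    utr5, utr3, flank, intron_len = 6, 6, 60, 30
    # split the CDS into exon chunks, keeping the window inside chunk 1
    min_chunk1 = (win_codon + 2) * 3 + 3
    if cfg.n_exons == 1:
        chunks = [cds]
    else:
        c1 = max(min_chunk1, len(cds) // cfg.n_exons)
        rest = len(cds) - c1
        cuts = [0, c1] + [
            c1 + rest * i // (cfg.n_exons - 1) for i in range(1, cfg.n_exons)
        ]
        chunks = [cds[cuts[i] : cuts[i + 1]] for i in range(cfg.n_exons)]
        assert all(chunks) and "".join(chunks) == cds

    def rand_seq(n):
        return "".join(rng.choice(list(BASES), size=n))

    parts = [rand_seq(flank)]
    cursor = flank
    exons = []
    cds_start = cds_end = None
    for i, chunk in enumerate(chunks):
        ex_start = cursor
        if i == 0:
            parts.append(rand_seq(utr5))
            cursor += utr5
            cds_start = cursor
        parts.append(chunk)
        cursor += len(chunk)
        if i == len(chunks) - 1:
            cds_end = cursor
            parts.append(rand_seq(utr3))
            cursor += utr3
        exons.append((ex_start, cursor))
        if i < len(chunks) - 1:
            parts.append(rand_seq(intron_len))
            cursor += intron_len
    parts.append(rand_seq(flank))
    cursor += flank
    seq = "".join(parts)
    assert len(seq) == cursor

    win_fwd = (cds_start + 3 * win_codon, cds_start + 3 * win_codon + 6)

    if cfg.strand == "-":
        length = len(seq)
        seq = revcomp(seq)
        exons = sorted(_mirror(x, length) for x in exons)
        cds_start, cds_end = _mirror((cds_start, cds_end), length)
        win_fwd = _mirror(win_fwd, length)

    genome = GenomeSlice(cfg.chrom, seq, start=0)
    tx = TranscriptModel(
        name="simTx",
        chrom=cfg.chrom,
        strand=cfg.strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )
    tx.validate_cds(genome)
    window = WindowInterval(cfg.chrom, win_fwd[0], win_fwd[1])
    ref_hap = genome.fetch_window(window)

    variant_haps = _assign_haps(cfg, window, ref_hap, tx, genome)
    return Locus(genome, tx, window, "g1", ref_hap, variant_haps)


def _candidate_haps(window, ref_hap, tx, genome):
    """Alternate window haplotypes in deterministic order: all single
    substitutions, then all double substitutions."""
    singles, doubles = [], []
    for i in range(len(ref_hap)):
        for b in BASES:
            if b != ref_hap[i]:
                singles.append(ref_hap[:i] + b + ref_hap[i + 1 :])
    for i, j in itertools.combinations(range(len(ref_hap)), 2):
        for b1 in BASES:
            for b2 in BASES:
                if b1 != ref_hap[i] and b2 != ref_hap[j]:
                    h = list(ref_hap)
                    h[i], h[j] = b1, b2
                    doubles.append("".join(h))
    for hap in singles + doubles:
        changes = call_aa_changes(window, ref_hap, hap, tx, genome)
        if changes:
            yield hap, genotype_label(changes)


def _assign_haps(cfg, window, ref_hap, tx, genome) -> Dict[str, str]:
    used_labels = {"WT"}
    haps: Dict[str, str] = {}
    candidates = list(_candidate_haps(window, ref_hap, tx, genome))
    stop_first = [c for c in candidates if STOP in c[1]]
    plain = [c for c in candidates if STOP not in c[1]]
    resolved = []
    for v in cfg.variants:
        if v.hap == "ref" or (v.name == "WT" and v.hap is None and not v.stop_gain):
            resolved.append((v, "WT", ref_hap))
            continue
        if v.hap is not None:
            label = v.name or genotype_label(
                call_aa_changes(window, ref_hap, v.hap, tx, genome)
            )
            resolved.append((v, label, v.hap))
            used_labels.add(label)
            continue
        pool = stop_first if v.stop_gain else plain
        for hap, label in pool:
            if label not in used_labels:
                used_labels.add(label)
                resolved.append((v, label, hap))
                break
        else:
            raise ValidationError("ran out of distinct window haplotypes")
    for v, label, hap in resolved:
        haps[label] = hap
    if len(haps) != len(cfg.variants):
        raise ValidationError("variant labels are not distinct")
    return haps


def _resolved_variants(cfg: SimConfig, locus: Locus):
    """(label, hap, VariantSim) in config order."""
    labels = list(locus.variant_haps)
    return [
        (label, locus.variant_haps[label], v)
        for label, v in zip(labels, cfg.variants)
    ]


@dataclass
class LongReadSim:
    sam_lines: List[str]
    whitelist: List[str]
    cell_truth: pd.DataFrame          # cb, genotype_label, hap, n_umis
    umi_truth: pd.DataFrame           # cb, umi, hap

    def write(self, out_dir, window: WindowInterval, window_id: str) -> dict:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "sam": os.path.join(out_dir, "reads.sam"),
            "whitelist": os.path.join(out_dir, "whitelist.txt"),
            "windows": os.path.join(out_dir, "windows.tsv"),
            "cell_truth": os.path.join(out_dir, "truth_cells.tsv"),
            "umi_truth": os.path.join(out_dir, "truth_umis.tsv"),
        }
        with open(paths["sam"], "w") as fh:
            fh.write("\n".join(self.sam_lines) + "\n")
        with open(paths["whitelist"], "w") as fh:
            fh.write("\n".join(self.whitelist) + "\n")
        with open(paths["windows"], "w") as fh:
            fh.write("guide_id\tchrom\tstart\tend\n")
            fh.write(
                f"{window_id}\t{window.chrom}\t{window.start + 1}\t{window.end}\n"
            )
        self.cell_truth.to_csv(paths["cell_truth"], sep="\t", index=False)
        self.umi_truth.to_csv(paths["umi_truth"], sep="\t", index=False)
        return paths


def _random_barcodes(rng, n, length) -> List[str]:
    out = set()
    while len(out) < n:
        out.add("".join(rng.choice(list(BASES), size=length)))
    return sorted(out)


def _corrupt(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = rng.choice([b for b in BASES if b != chars[i]])
    return "".join(chars)


def _simulate_alignment(rng, genome, win, hap, sub_rate, indel_rate):
    """One errored aligned segment covering the window.

    Returns (aln_start, cigar_ops, seq); indels are kept away from the
    segment ends so the CIGAR stays well formed.
    """
    flank_l = int(rng.integers(20, 41))
    flank_r = int(rng.integers(20, 41))
    aln_start = max(genome.start, win.start - flank_l)
    aln_end = min(genome.end, win.end + flank_r)
    template = list(genome.fetch(win.chrom, aln_start, aln_end))
    for i, b in enumerate(hap):
        template[win.start - aln_start + i] = b
    seq: List[str] = []
    ops: List[List] = []  # [op_char, length]

    def push(op):
        if ops and ops[-1][0] == op:
            ops[-1][1] += 1
        else:
            ops.append([op, 1])

    n = len(template)
    for i, base in enumerate(template):
        interior = 5 <= i < n - 5
        r = rng.random()
        if interior and r < indel_rate / 2:
            push("D")
            continue
        if interior and r < indel_rate:
            seq.append(rng.choice(list(BASES)))
            push("I")
        b = base
        if rng.random() < sub_rate:
            b = rng.choice([x for x in BASES if x != base])
        seq.append(b)
        push("M")
    cigar = "".join(f"{ln}{op}" for op, ln in ops)
    return aln_start, cigar, "".join(seq)


def simulate_long_reads(
    cfg: SimConfig, locus: Locus, adapter: AdapterSpec = AdapterSpec()
) -> LongReadSim:
    """Aligned long reads (SAM text) + whitelist + truth tables.

    Soft-clipped prefixes carry adapter+CB+UMI; window bases come from each
    cell's genotype haplotype and are then corrupted at the configured error
    rates; stop-gain genotypes are thinned at the molecule level by their
    cDNA capture factor.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    whitelist = _random_barcodes(rng, cfg.whitelist_size, 16)
    cells = whitelist[: cfg.n_cells]
    variants = _resolved_variants(cfg, locus)
    fractions = np.array([v.fraction for _, _, v in variants])
    assignment = rng.choice(len(variants), size=cfg.n_cells, p=fractions)

    cell_rows, umi_rows, records = [], [], []
    read_no = 0
    for ci, cb in enumerate(cells):
        label, hap, vspec = variants[assignment[ci]]
        lo, hi = cfg.umis_per_cell
        n_umis = int(rng.integers(lo, hi + 1))
        n_kept = (
            int(rng.binomial(n_umis, vspec.capture))
            if vspec.capture < 1.0
            else n_umis
        )
        cell_rows.append(
            {
                "cb": cb,
                "genotype_label": label,
                "hap": hap,
                "n_umis": n_kept,
                "effect": vspec.effect,
                "capture": vspec.capture,
            }
        )
        umis = _random_barcodes(rng, n_kept, 10) if n_kept else []
        for umi in umis:
            umi_rows.append({"cb": cb, "umi": umi, "hap": hap})
            rlo, rhi = cfg.reads_per_umi
            n_reads = int(rng.integers(rlo, rhi + 1))
            for _ in range(n_reads):
                aln_start, cigar, aseq = _simulate_alignment(
                    rng, locus.genome, locus.window, hap, cfg.sub_rate, cfg.indel_rate
                )
                umi_obs = _corrupt(rng, umi, cfg.umi_error_rate)
                clip = adapter.adapter + cb + umi_obs
                if rng.random() < cfg.reverse_read_frac:
                    flag = 16
                    seq = aseq + revcomp(clip)
                    full_cigar = cigar + f"{len(clip)}S"
                else:
                    flag = 0
                    seq = clip + aseq
                    full_cigar = f"{len(clip)}S" + cigar
                records.append(
                    (
                        aln_start,
                        f"r{read_no:07d}\t{flag}\t{locus.genome.chrom}\t"
                        f"{aln_start + 1}\t60\t{full_cigar}\t*\t0\t0\t{seq}\t"
                        f"{'I' * len(seq)}",
                    )
                )
                read_no += 1

    records.sort(key=lambda r: (r[0], r[1]))
    header = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{locus.genome.chrom}\tLN:{locus.genome.end}",
    ]
    sam_lines = header + [r[1] for r in records]
    return LongReadSim(
        sam_lines=sam_lines,
        whitelist=whitelist,
        cell_truth=pd.DataFrame(
            cell_rows,
            columns=["cb", "genotype_label", "hap", "n_umis", "effect", "capture"],
        ),
        umi_truth=pd.DataFrame(umi_rows, columns=["cb", "umi", "hap"]),
    )


def dna_frequencies(cell_truth: pd.DataFrame, window_id: str = "g1") -> pd.DataFrame:
    """Genomic-DNA variant frequencies implied by the cell genotype truth
    (each homozygous cell contributes equally)."""
    total = len(cell_truth)
    rows = []
    for label, n in cell_truth["genotype_label"].value_counts().sort_index().items():
        rows.append(
            {
                "window": window_id,
                "genotype": label,
                "count": int(n),
                "total": total,
                "frequency": n / total,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ExpressionSim:
    matrix: ExpressionMatrix
    gene_set: List[str]
    truth_classes: pd.DataFrame       # genotype_label, effect, class

    def write(self, out_dir) -> dict:
        os.makedirs(out_dir, exist_ok=True)
        mtx_dir = os.path.join(out_dir, "mtx")
        self.matrix.write_mtx_dir(mtx_dir)
        paths = {
            "mtx_dir": mtx_dir,
            "gene_set": os.path.join(out_dir, "pathway_genes.txt"),
            "truth_classes": os.path.join(out_dir, "truth_classes.tsv"),
        }
        with open(paths["gene_set"], "w") as fh:
            fh.write("\n".join(self.gene_set) + "\n")
        self.truth_classes.to_csv(paths["truth_classes"], sep="\t", index=False)
        return paths


def simulate_expression(cfg: SimConfig, cell_truth: pd.DataFrame) -> ExpressionSim:
    """Negative-binomial counts with a multiplicative pathway shift per
    genotype; barcodes match the long-read cell truth (with ``-1`` suffix).

    ``cell_truth`` needs columns ``cb``, ``genotype_label`` and ``effect``
    (the per-genotype multiplier on pathway gene means).
    """
    rng = np.random.default_rng([cfg.seed, 2])
    n_path = min(cfg.pathway_size, cfg.n_genes)
    genes = [f"PW{i:03d}" for i in range(n_path)] + [
        f"G{i:04d}" for i in range(cfg.n_genes - n_path)
    ]
    base_means = np.exp(rng.normal(cfg.nb_log_mean, cfg.nb_log_sd, size=cfg.n_genes))
    if cfg.nb_log_mean_pathway is not None:
        base_means[:n_path] = np.exp(
            rng.normal(cfg.nb_log_mean_pathway, cfg.nb_log_sd, size=n_path)
        )
    r = cfg.nb_dispersion

    n_arrest = min(cfg.arrest_size, cfg.n_genes - n_path)
    barcodes = cell_truth["cb"].tolist()
    counts = np.zeros((cfg.n_genes, len(barcodes)), dtype=np.int64)
    for j, effect in enumerate(cell_truth["effect"]):
        means = base_means.copy()
        means[:n_path] *= effect
        if effect != 1.0 and n_arrest:
            means[n_path : n_path + n_arrest] *= cfg.arrest_factor
        p = r / (r + means)
        counts[:, j] = rng.negative_binomial(r, p)
    matrix = ExpressionMatrix(
        np.array(genes, dtype=object),
        np.array([f"{b}-1" for b in barcodes], dtype=object),
        counts,
    )
    truth = (
        cell_truth.groupby("genotype_label", sort=True)["effect"]
        .first()
        .reset_index()
    )
    truth["class"] = np.where(
        truth["effect"] == 1.0, "wild-type-like", "functionally-significant"
    )
    return ExpressionSim(matrix, genes[:n_path], truth)


def simulate_platform_pair(
    n_shared: int,
    disagree_rate: float,
    seed: int,
    labels: Sequence[str] = ("WT", "R11Q", "V12M"),
    window_id: str = "g1",
) -> Tuple[pd.DataFrame, pd.DataFrame, int]:
    """Two per-UMI genotype tables sharing ``n_shared`` keys with a planted
    per-UMI disagreement rate; returns (table_a, table_b, n_disagree)."""
    rng = np.random.default_rng(seed)
    cbs = _random_barcodes(rng, min(n_shared, 500), 16)
    rows_a, rows_b = [], []
    n_disagree = 0
    seen = set()
    labels = list(labels)
    while len(seen) < n_shared:
        cb = cbs[int(rng.integers(len(cbs)))]
        umi = "".join(rng.choice(list(BASES), size=10))
        if (cb, umi) in seen:
            continue
        seen.add((cb, umi))
        g = labels[int(rng.integers(len(labels)))]
        rows_a.append({"cb": cb, "umi": umi, "window": window_id, "genotype": g})
        if rng.random() < disagree_rate:
            n_disagree += 1
            others = [l for l in labels if l != g]
            g_b = others[int(rng.integers(len(others)))]
        else:
            g_b = g
        rows_b.append({"cb": cb, "umi": umi, "window": window_id, "genotype": g_b})
    return pd.DataFrame(rows_a), pd.DataFrame(rows_b), n_disagree


def simulate_bundle(cfg: SimConfig, out_dir: Optional[str] = None):
    """Full bundle: locus + long reads + expression (and files when
    ``out_dir`` is given)."""
    locus = simulate_locus(cfg)
    reads = simulate_long_reads(cfg, locus)
    expr = simulate_expression(cfg, reads.cell_truth)
    paths = {}
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        locus.genome.write_fasta(os.path.join(out_dir, "ref.fa"))
        locus.tx.to_json(os.path.join(out_dir, "transcript.json"))
        paths.update(reads.write(out_dir, locus.window, locus.window_id))
        paths.update(expr.write(out_dir))
        paths["fasta"] = os.path.join(out_dir, "ref.fa")
        paths["transcript"] = os.path.join(out_dir, "transcript.json")
    return locus, reads, expr, paths
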