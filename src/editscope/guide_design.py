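"""Base-editor sgRNA design and exhaustive edit-outcome enumeration.

A guide is a 20-nt protospacer with the PAM immediately 3' on the guide
strand and an editable window (default protospacer positions 3..8, numbered
1..20 from the PAM-distal 5' end).  Every subset of editable window bases can
be converted simultaneously, so a guide with k editable bases has 2^k
achievable window haplotypes (3^k when C->G byproducts are enabled for a
cytosine editor).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .refmodel import (
    AAChange,
    AnnotationError,
    GenomeSlice,
    TranscriptModel,
    ValidationError,
    WindowInterval,
    call_aa_changes,
    comp,
    revcomp,
    translate,
)

PROTOSPACER_LEN = 20

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class CombinatorialCapError(ValueError):
    """Too many editable bases to enumerate outcomes."""


def matches_iupac(seq: str, pattern: str) -> bool:
    return len(seq) == len(pattern) and all(
        b in IUPAC[p] for b, p in zip(seq.upper(), pattern.upper())
    )


@dataclass(frozen=True)
class BaseEditorSpec:
    """A base-editor chemistry: conversion, PAM pattern and window.

    ``window`` is the inclusive protospacer position range (1..20 from the
    PAM-distal end) in which conversion occurs.  ``conversion`` acts on the
    protospacer (guide) strand: C->T for a CBE, A->G for an ABE.
    """

    name: str
    from_base: str
    to_base: str
    pam: str
    window: Tuple[int, int] = (3, 8)
    include_byproduct: bool = False
    byproduct_base: str = "G"  # guide-strand C->G byproduct for CBEs

    def __post_init__(self):
        lo, hi = self.window
        if not (1 <= lo <= hi <= PROTOSPACER_LEN):
            raise ValidationError(f"window {self.window} outside 1..{PROTOSPACER_LEN}")
        if self.from_base == self.to_base:
            raise ValidationError("conversion bases must differ")
        if not self.pam:
            raise ValidationError("PAM pattern must be non-empty")


EDITOR_PRESETS = {
    "ngg-cbe": BaseEditorSpec("NGG-CBE", "C", "T", "NGG"),
    "ng-cbe": BaseEditorSpec("NG-CBE", "C", "T", "NG"),
    "ngg-abe": BaseEditorSpec("NGG-ABE", "A", "G", "NGG"),
    "ng-abe": BaseEditorSpec("NG-ABE", "A", "G", "NG"),
}


@dataclass(frozen=True)
class GuideDesign:
    """One protospacer placement realizing an intended substitution."""

    protospacer: str          # guide-strand sequence, 5'->3'
    guide_strand: str
    pam_seq: str              # observed PAM bases on the guide strand
    window: WindowInterval    # genomic plus-strand window interval
    editable_offsets: frozenset  # plus-strand window offsets with the editable base
    intended: AAChange
    intended_offset: int      # plus-strand window offset of the intended edit
    intended_position: int    # protospacer position (1..20) of the intended edit
    proto_start: int          # genomic span of the protospacer
    proto_end: int

    @property
    def n_bystanders(self) -> int:
        return len(self.editable_offsets) - 1


@dataclass(frozen=True)
class EditOutcome:
    """One achievable window haplotype for a guide."""

    edited_offsets: Tuple[int, ...]
    alt_hap: str              # plus-strand window haplotype
    aa_changes: Tuple[AAChange, ...]
    is_intended: bool
    is_reference: bool

    @property
    def label(self) -> str:
        if not self.aa_changes:
            return "WT"
        return ",".join(ch.label for ch in self.aa_changes)


def _guide_strand_conversion(spec: BaseEditorSpec, guide_strand: str) -> Tuple[str, str]:
    """Plus-strand (from, to) bases realized by the conversion on a strand."""
    if guide_strand == "+":
        return spec.from_base, spec.to_base
    return comp(spec.from_base), comp(spec.to_base)


def find_guides(
    intended: AAChange,
    tx: TranscriptModel,
    ref_seq: GenomeSlice,
    spec: BaseEditorSpec,
) -> List[GuideDesign]:
    """Enumerate every protospacer placement that can realize ``intended``.

    The single-nucleotide codon changes producing the substitution are
    intersected with the editor's conversion on each genome strand; for each
    achievable change, every placement putting the edited base at an
    in-window protospacer position with a matching PAM immediately 3' is
    emitted.  Unachievable substitutions yield an empty list.
    """
    cds_pos = tx.cds_positions()
    ci = intended.codon_index
    if 3 * ci > len(cds_pos):
        raise ValidationError(
            f"codon {ci} beyond CDS of {tx.name} ({len(cds_pos) // 3} codons)"
        )
    triplet = cds_pos[3 * (ci - 1) : 3 * ci]
    ref_codon = "".join(
        comp(ref_seq.fetch(tx.chrom, p, p + 1)) if tx.strand == "-"
        else ref_seq.fetch(tx.chrom, p, p + 1)
        for p in triplet
    )
    if translate(ref_codon) != intended.ref_aa:
        raise ValidationError(
            f"reference codon {ref_codon} encodes {translate(ref_codon)}, "
            f"not {intended.ref_aa} as stated by {intended.label}"
        )

    plen = len(spec.pam)
    wlo, whi = spec.window
    guides = []
    seen = set()
    for j, base in itertools.product(range(3), "ACGT"):
        if base == ref_codon[j]:
            continue
        alt_codon = ref_codon[:j] + base + ref_codon[j + 1 :]
        if translate(alt_codon) != intended.alt_aa:
            continue
        p = triplet[j]  # genomic position of the edited base
        if tx.strand == "+":
            plus_from, plus_to = ref_codon[j], base
        else:
            plus_from, plus_to = comp(ref_codon[j]), comp(base)
        for gstrand in "+-":
            need_from, need_to = _guide_strand_conversion(spec, gstrand)
            if (plus_from, plus_to) != (need_from, need_to):
                continue
            for w in range(wlo, whi + 1):
                placement = _placement(
                    p, w, gstrand, spec, tx, ref_seq, intended, plen, wlo, whi
                )
                if placement is None:
                    continue
                key = (placement.proto_start, placement.guide_strand)
                if key not in seen:
                    seen.add(key)
                    guides.append(placement)
    guides.sort(key=lambda g: (g.proto_start, g.guide_strand))
    return guides


def _placement(
    p: int,
    w: int,
    gstrand: str,
    spec: BaseEditorSpec,
    tx: TranscriptModel,
    ref_seq: GenomeSlice,
    intended: AAChange,
    plen: int,
    wlo: int,
    whi: int,
) -> Optional[GuideDesign]:
    """Build the guide placing edited base ``p`` at protospacer position ``w``."""
    if gstrand == "+":
        s = p - (w - 1)
        proto_span = (s, s + PROTOSPACER_LEN)
        pam_span = (s + PROTOSPACER_LEN, s + PROTOSPACER_LEN + plen)
        win_span = (s + wlo - 1, s + whi)
    else:
        s_end = p + w
        proto_span = (s_end - PROTOSPACER_LEN, s_end)
        pam_span = (s_end - PROTOSPACER_LEN - plen, s_end - PROTOSPACER_LEN)
        win_span = (s_end - whi, s_end - wlo + 1)
    lo = min(proto_span[0], pam_span[0])
    hi = max(proto_span[1], pam_span[1])
    if not ref_seq.covers(tx.chrom, lo, hi):
        return None
    proto_plus = ref_seq.fetch(tx.chrom, *proto_span)
    pam_plus = ref_seq.fetch(tx.chrom, *pam_span)
    if gstrand == "+":
        protospacer, pam_seq = proto_plus, pam_plus
    else:
        protospacer, pam_seq = revcomp(proto_plus), revcomp(pam_plus)
    if not matches_iupac(pam_seq, spec.pam):
        return None
    if not tx.single_exon_containing(*win_span):
        return None
    win = WindowInterval(tx.chrom, win_span[0], win_span[1], guide_strand=gstrand)
    win_ref = ref_seq.fetch_window(win)
    editable_plus = spec.from_base if gstrand == "+" else comp(spec.from_base)
    editable = frozenset(
        i for i in range(win.width) if win_ref[i] == editable_plus
    )
    intended_offset = p - win.start
    if intended_offset not in editable:
        return None
    return GuideDesign(
        protospacer=protospacer,
        guide_strand=gstrand,
        pam_seq=pam_seq,
        window=win,
        editable_offsets=editable,
        intended=intended,
        intended_offset=intended_offset,
        intended_position=w,
        proto_start=proto_span[0],
        proto_end=proto_span[1],
    )


def enumerate_outcomes(
    guide: GuideDesign,
    spec: BaseEditorSpec,
    tx: TranscriptModel,
    ref_seq: GenomeSlice,
    cap: int = 8,
) -> List[EditOutcome]:
    """All achievable window haplotypes for ``guide``: one per subset of
    editable offsets (or per {ref, to, byproduct} assignment when C->G
    byproducts are enabled).  The empty subset is the unique reference
    outcome."""
    win = guide.window
    ref_hap = ref_seq.fetch_window(win)
    offsets = sorted(guide.editable_offsets)
    if len(offsets) > cap:
        raise CombinatorialCapError(
            f"{len(offsets)} editable bases exceed the enumeration cap ({cap})"
        )
    _, plus_to = _guide_strand_conversion(spec, guide.guide_strand)
    choice_sets = []
    for off in offsets:
        choices = [ref_hap[off], plus_to]
        if spec.include_byproduct and spec.from_base == "C":
            by = spec.byproduct_base if guide.guide_strand == "+" else comp(
                spec.byproduct_base
            )
            choices.append(by)
        choice_sets.append(choices)

    outcomes = []
    for combo in itertools.product(*choice_sets):
        alt = list(ref_hap)
        edited = []
        for off, b in zip(offsets, combo):
            if b != ref_hap[off]:
                alt[off] = b
                edited.append(off)
        alt_hap = "".join(alt)
        changes = tuple(call_aa_changes(win, ref_hap, alt_hap, tx, ref_seq))
        outcomes.append(
            EditOutcome(
                edited_offsets=tuple(edited),
                alt_hap=alt_hap,
                aa_changes=changes,
                is_intended=any(ch == guide.intended for ch in changes),
                is_reference=alt_hap == ref_hap,
            )
        )
    return outcomes


def design_library(
    mutations: Sequence[AAChange],
    tx: TranscriptModel,
    ref_seq: GenomeSlice,
    specs: Sequence[BaseEditorSpec],
    select: str = "best",
    cap: int = 8,
):
    """Design guides for a mutation list across editor chemistries.

    ``select='best'`` keeps one guide per (mutation, editor) chosen by fewest
    editable bystanders, then smallest protospacer position of the intended
    base, then genomic coordinate; ``select='all'`` keeps every placement.

    Returns ``(table, summary)`` where the summary counts targetable
    mutations, guides per editor and achievable amino-acid changes both as a
    deduplicated union and summed per guide.
    """
    if not len(mutations):
        raise ValidationError("mutation list is empty")
    unique: List[AAChange] = []
    seen = set()
    for m in mutations:
        if m.label not in seen:
            seen.add(m.label)
            unique.append(m)

    rows = []
    guides_per_spec: Counter = Counter()
    union_labels = set()
    per_guide_total = 0
    for mut in unique:
        chosen = []
        for sp in specs:
            try:
                found = find_guides(mut, tx, ref_seq, sp)
            except ValidationError:
                found = []
            if select == "best" and found:
                found = [
                    min(
                        found,
                        key=lambda g: (
                            g.n_bystanders,
                            g.intended_position,
                            g.proto_start,
                        ),
                    )
                ]
            guides_per_spec[sp.name] += len(found)
            chosen.extend((sp, g) for g in found)
        mut_labels = set()
        for sp, g in chosen:
            labels = {
                ch.label
                for o in enumerate_outcomes(g, sp, tx, ref_seq, cap=cap)
                for ch in o.aa_changes
            }
            per_guide_total += len(labels)
            mut_labels |= labels
        union_labels |= mut_labels
        rows.append(
            {
                "mutation": mut.label,
                "targetable": bool(chosen),
                "n_guides": len(chosen),
                "achievable_changes": ",".join(sorted(mut_labels)),
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "n_mutations": len(unique),
        "n_targetable": int(table["targetable"].sum()),
        "guides_per_spec": dict(guides_per_spec),
        "n_guides": int(table["n_guides"].sum()),
        "n_achievable_changes_union": len(union_labels),
        "n_achievable_changes_per_guide_total": per_guide_total,
    }
    return table, summary


def guides_to_frame(
    entries: Sequence[Tuple[BaseEditorSpec, GuideDesign, int]]
) -> pd.DataFrame:
    """Tabulate guides as (editor, protospacer, strand, PAM, window, ...)."""
    rows = []
    for spec, g, n_outcomes in entries:
        rows.append(
            {
                "editor": spec.name,
                "intended": g.intended.label,
                "protospacer": g.protospacer,
                "strand": g.guide_strand,
                "pam": g.pam_seq,
                "chrom": g.window.chrom,
                "window_start": g.window.start + 1,  # 1-based inclusive out
                "window_end": g.window.end,
                "editable_offsets": ",".join(map(str, sorted(g.editable_offsets))),
                "n_outcomes": n_outcomes,
            }
        )
    return pd.DataFrame(rows)


def read_mutations_tsv(path) -> List[AAChange]:
    """Read a mutation table (gene, ref_aa, codon_index, alt_aa) or a single
    ``mutation`` column of labels like ``V197M``."""
    df = pd.read_csv(path, sep="\t")
    if "mutation" in df.columns:
        return [AAChange.parse(x) for x in df["mutation"]]
    required = {"ref_aa", "codon_index", "alt_aa"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"mutation TSV needs columns {sorted(required)} or 'mutation'"
        )
    return [
        AAChange(r.ref_aa, int(r.codon_index), r.alt_aa)
        for r in df.itertuples(index=False)
    ]
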