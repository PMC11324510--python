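"""Reference locus model.

Holds the target-locus sequence, the transcript/CDS structure, the
genomic<->codon coordinate maps and the amino-acid-change calling used by
both guide design and genotyping.

Conventions
-----------
* All coordinates are 0-based half-open internally.  File output and log
  messages use 1-based inclusive coordinates (``format_region``).
* Window haplotypes are always expressed on the genomic plus strand; the
  amino-acid caller complements internally for minus-strand transcripts.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable


class CoordinateError(ValueError):
    """A genomic position falls outside the expected interval set."""


class AnnotationError(ValueError):
    """The transcript annotation is inconsistent or unsupported."""


class ValidationError(ValueError):
    """An input sequence disagrees with the reference or is malformed."""


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_BASES = frozenset("ACGT")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
CODON_TO_AA.update({codon: "Ter" for codon in _TABLE.stop_codons})

STOP = "Ter"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMP)[::-1]


def comp(base: str) -> str:
    """Complement of a single base or string, without reversing."""
    return base.translate(_COMP)


def translate(codon: str) -> str:
    """Translate one codon with the standard genetic code.

    Returns the single-letter amino acid, or ``"Ter"`` for a stop codon.
    Ambiguous or non-ACGT bases raise :class:`ValidationError`.
    """
    if len(codon) != 3:
        raise ValidationError(f"codon must have 3 bases, got {codon!r}")
    codon = codon.upper()
    if not _VALID_BASES.issuperset(codon):
        raise ValidationError(f"codon contains non-ACGT base: {codon!r}")
    return CODON_TO_AA[codon]


def format_region(chrom: str, start: int, end: int) -> str:
    """Render a 0-based half-open interval as 1-based inclusive text."""
    return f"{chrom}:{start + 1}-{end}"


_AA_CHANGE_RE = re.compile(r"^([A-Z]|Ter)(\d+)([A-Z]|Ter)$")


@dataclass(frozen=True, order=True)
class AAChange:
    """A single amino-acid substitution, e.g. ``V197M`` or ``W146Ter``.

    Ordering is by protein position then by the replacement amino acid, so
    multi-change haplotype labels sort deterministically.
    """

    codon_index: int
    alt_aa: str
    ref_aa: str

    def __init__(self, ref_aa: str, codon_index: int, alt_aa: str):
        if codon_index < 1:
            raise ValidationError("codon_index must be >= 1")
        object.__setattr__(self, "ref_aa", ref_aa)
        object.__setattr__(self, "codon_index", int(codon_index))
        object.__setattr__(self, "alt_aa", alt_aa)

    @property
    def label(self) -> str:
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label

    @classmethod
    def parse(cls, label: str) -> "AAChange":
        m = _AA_CHANGE_RE.match(label.strip())
        if not m:
            raise ValidationError(f"cannot parse amino-acid change {label!r}")
        return cls(m.group(1), int(m.group(2)), m.group(3))


@dataclass(frozen=True)
class WindowInterval:
    """Genomic interval of an sgRNA editing window (plus-strand bounds)."""

    chrom: str
    start: int
    end: int
    guide_strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError("window end must exceed start")
        if self.guide_strand not in "+-":
            raise ValidationError("guide_strand must be '+' or '-'")

    @property
    def width(self) -> int:
        return self.end - self.start

    def region(self) -> str:
        return format_region(self.chrom, self.start, self.end)


class GenomeSlice:
    """A contiguous slice of one reference chromosome.

    Stores ``seq`` beginning at genomic coordinate ``start`` on ``chrom`` so
    that small target-locus FASTAs can carry full-chromosome coordinates.
    """

    def __init__(self, chrom: str, seq: str, start: int = 0):
        self.chrom = chrom
        self.seq = seq.upper()
        self.start = int(start)

    @property
    def end(self) -> int:
        return self.start + len(self.seq)

    def covers(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and self.start <= start and end <= self.end

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if not self.covers(chrom, start, end):
            raise CoordinateError(
                f"{format_region(chrom, start, end)} outside reference slice "
                f"{format_region(self.chrom, self.start, self.end)}"
            )
        return self.seq[start - self.start : end - self.start]

    def fetch_window(self, win: WindowInterval) -> str:
        return self.fetch(win.chrom, win.start, win.end)

    @classmethod
    def from_fasta(cls, path, chrom: Optional[str] = None, start: int = 0) -> "GenomeSlice":
        for rec in SeqIO.parse(str(path), "fasta"):
            if chrom is None or rec.id == chrom:
                # allow "name offset=<n>" in the description to restore coords
                m = re.search(r"offset=(\d+)", rec.description)
                off = int(m.group(1)) if m else start
                return cls(rec.id, str(rec.seq), off)
        raise ValidationError(f"no record {chrom!r} in {path}")

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.chrom} offset={self.start}\n")
            for i in range(0, len(self.seq), 80):
                fh.write(self.seq[i : i + 80] + "\n")


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript on the genome.

    ``exons`` are ascending, disjoint, 0-based half-open genomic intervals;
    ``cds_start``/``cds_end`` bound the coding region on the genome and must
    fall inside the exon union.  The spliced CDS (including the stop codon)
    must have length divisible by three.
    """

    name: str
    chrom: str
    strand: str
    exons: Sequence[tuple]
    cds_start: int
    cds_end: int
    _cds_positions: list = field(default=None, repr=False, compare=False)
    _cds_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if self.strand not in "+-":
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise AnnotationError(f"empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise AnnotationError("exons must be sorted and disjoint")
            prev_end = e
        if not self.exons:
            raise AnnotationError("transcript has no exons")
        if not (self.contains(self.cds_start) and self.contains(self.cds_end - 1)):
            raise AnnotationError("CDS bounds must lie inside the exon union")
        if len(self.cds_positions()) % 3 != 0:
            raise AnnotationError("spliced CDS length not divisible by 3")

    # -- coordinate plumbing -------------------------------------------------

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def spliced_index(self, pos: int) -> int:
        """Index of ``pos`` along the concatenated exons (genomic order)."""
        total = 0
        for s, e in self.exons:
            if s <= pos < e:
                return total + (pos - s)
            total += e - s
        raise CoordinateError(
            f"position {self.chrom}:{pos + 1} is not exonic in {self.name}"
        )

    def cds_positions(self) -> list:
        """Genomic positions of the CDS in transcript 5'->3' order."""
        if self._cds_positions is None:
            pos = [
                p
                for s, e in self.exons
                for p in range(max(s, self.cds_start), min(e, self.cds_end))
            ]
            if self.strand == "-":
                pos.reverse()
            self._cds_positions = pos
            self._cds_index = {p: i for i, p in enumerate(pos)}
        return self._cds_positions

    def cds_index_of(self, pos: int) -> Optional[int]:
        self.cds_positions()
        return self._cds_index.get(pos)

    def cds_sequence(self, ref: GenomeSlice) -> str:
        """Transcript-strand CDS sequence."""
        bases = [ref.fetch(self.chrom, p, p + 1) for p in self.cds_positions()]
        seq = "".join(bases)
        return comp(seq) if self.strand == "-" else seq

    def single_exon_containing(self, start: int, end: int) -> bool:
        return any(s <= start and end <= e for s, e in self.exons)

    def validate_cds(self, ref: GenomeSlice) -> None:
        """Check that the spliced CDS starts with ATG and ends with a stop."""
        cds = self.cds_sequence(ref)
        if cds[:3] != "ATG":
            raise AnnotationError(f"CDS of {self.name} does not begin with ATG")
        if translate(cds[-3:]) != STOP:
            raise AnnotationError(f"CDS of {self.name} does not end with a stop codon")
        for i in range(3, len(cds) - 3, 3):
            if translate(cds[i : i + 3]) == STOP:
                raise AnnotationError(f"internal stop codon at codon {i // 3 + 1}")

    # -- serialization -------------------------------------------------------

    def to_json(self, path) -> None:
        doc = {
            "name": self.name,
            "chrom": self.chrom,
            "strand": self.strand,
            "exons": [list(x) for x in self.exons],
            "cds_start": self.cds_start,
            "cds_end": self.cds_end,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "TranscriptModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            name=doc["name"],
            chrom=doc["chrom"],
            strand=doc["strand"],
            exons=[tuple(x) for x in doc["exons"]],
            cds_start=doc["cds_start"],
            cds_end=doc["cds_end"],
        )

    @classmethod
    def from_gtf(cls, path, transcript_id: Optional[str] = None) -> "TranscriptModel":
        """Load from a minimal GTF (exon + CDS features, 1-based inclusive).

        The CDS features are expected to include the stop codon; annotations
        that exclude it fail the frame check on load.
        """
        exons, cds = [], []
        chrom = strand = name = None
        for line in open(path):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise AnnotationError(f"malformed GTF line: {line!r}")
            attrs = f[8] if len(f) > 8 else ""
            m = re.search(r'transcript_id "([^"]+)"', attrs)
            tid = m.group(1) if m else None
            if transcript_id is not None and tid not in (None, transcript_id):
                continue
            if f[2] == "exon":
                exons.append((int(f[3]) - 1, int(f[4])))
                chrom, strand = f[0], f[6]
                name = tid or name
            elif f[2] == "CDS":
                cds.append((int(f[3]) - 1, int(f[4])))
        if not exons or not cds:
            raise AnnotationError(f"no exon/CDS features found in {path}")
        exons.sort()
        return cls(
            name=name or "tx",
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds_start=min(s for s, _ in cds),
            cds_end=max(e for _, e in cds),
        )


def load_transcript(path, transcript_id: Optional[str] = None) -> TranscriptModel:
    """Dispatch on extension: ``.json`` dialect or minimal GTF/GFF."""
    p = str(path)
    if p.endswith(".json"):
        return TranscriptModel.from_json(p)
    return TranscriptModel.from_gtf(p, transcript_id)


def genomic_to_codon(pos: int, tx: TranscriptModel):
    """Map a genomic position to (1-based codon index, offset in {0,1,2}).

    Returns ``None`` for exonic positions outside the CDS.  Non-exonic
    positions raise :class:`CoordinateError`.
    """
    spliced = tx.spliced_index(pos)
    if not (tx.cds_start <= pos < tx.cds_end):
        return None
    if tx.strand == "+":
        off = spliced - tx.spliced_index(tx.cds_start)
    else:
        off = tx.spliced_index(tx.cds_end - 1) - spliced
    return off // 3 + 1, off % 3


def call_aa_changes(
    win: WindowInterval,
    ref_hap: str,
    alt_hap: str,
    tx: TranscriptModel,
    ref_seq: GenomeSlice,
) -> list:
    """Amino-acid changes induced by replacing the window with ``alt_hap``.

    Both haplotypes are plus-strand strings of window width.  All window
    substitutions are applied to the affected codons simultaneously, the
    codons are translated (complementing for minus-strand transcripts), and a
    change is emitted only where the amino acid differs.  Synonymous edits
    emit nothing.  Output is sorted by codon index then replacement residue.
    """
    ref_hap = ref_hap.upper()
    alt_hap = alt_hap.upper()
    if len(ref_hap) != win.width or len(alt_hap) != win.width:
        raise ValidationError(
            f"haplotype length must equal window width {win.width}"
        )
    for hap in (ref_hap, alt_hap):
        if not _VALID_BASES.issuperset(hap):
            raise ValidationError(f"haplotype contains non-ACGT base: {hap!r}")
    observed = ref_seq.fetch_window(win)
    if observed != ref_hap:
        raise ValidationError(
            f"ref haplotype {ref_hap} does not match reference {observed} at "
            f"{win.region()} (stale annotation?)"
        )
    if win.chrom != tx.chrom:
        raise ValidationError("window and transcript are on different chromosomes")
    if not tx.single_exon_containing(win.start, win.end):
        raise AnnotationError(
            f"window {win.region()} does not lie within a single exon of {tx.name}"
        )

    diffs = [i for i in range(win.width) if ref_hap[i] != alt_hap[i]]
    if not diffs:
        return []

    cds_pos = tx.cds_positions()
    codons = set()
    for i in diffs:
        idx = tx.cds_index_of(win.start + i)
        if idx is not None:
            codons.add(idx // 3)

    changes = []
    for c in sorted(codons):
        triplet = cds_pos[3 * c : 3 * c + 3]
        ref_codon, alt_codon = [], []
        for p in triplet:
            r = ref_seq.fetch(win.chrom, p, p + 1)
            a = alt_hap[p - win.start] if win.start <= p < win.end else r
            if tx.strand == "-":
                r, a = comp(r), comp(a)
            ref_codon.append(r)
            alt_codon.append(a)
        ref_aa = translate("".join(ref_codon))
        alt_aa = translate("".join(alt_codon))
        if ref_aa != alt_aa:
            changes.append(AAChange(ref_aa, c + 1, alt_aa))
    changes.sort(key=lambda ch: (ch.codon_index, ch.alt_aa))
    return changes


def genotype_label(changes: Sequence[AAChange]) -> str:
    """Canonical per-haplotype genotype label: sorted labels or ``WT``."""
    if not changes:
        return "WT"
    ordered = sorted(changes, key=lambda ch: (ch.codon_index, ch.alt_aa))
    return ",".join(ch.label for ch in ordered)
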