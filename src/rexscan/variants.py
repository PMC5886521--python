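"""Resequencing evidence filters and coding-effect nomenclature.

Implements the post-calling stages of a bacterial resequencing
analysis: subtraction of variants shared with the wild-type control
(reference-sequence errors), thresholding of structural-variant
breakpoints on read support and imperfect-match fraction, greedy
pairing of left/right breakpoints that share unaligned sequence, and
protein-level naming of small variants (Thr597Lys missense, Glu454*
nonsense, Lys290fs frameshift, in-frame ins/del).

Variant calling itself (read mapping, realignment, the probabilistic
caller) is upstream of this module and out of scope; inputs are the
tabular evidence such callers export.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .regulon import GeneFeature
from .scan import reverse_complement

__all__ = [
    "VariantRecord",
    "BreakpointRecord",
    "SVCall",
    "CodingEffect",
    "subtract_background",
    "filter_breakpoints",
    "pair_breakpoints",
    "annotate_coding_effect",
    "parse_effect_description",
    "read_variants_tsv",
    "read_variants_vcf",
    "read_breakpoints_tsv",
    "write_breakpoints_tsv",
    "write_svcalls_tsv",
]

MAX_BREAKPOINT_SEQ = 75  # bp of unaligned sequence retained per breakpoint

#: Bacterial/archaeal genetic code (NCBI translation table 11).
CODON_TABLE_ID = 11


@dataclass(frozen=True)
class VariantRecord:
    """A small variant call. ``'-'`` in ref/alt marks a pure ins/del."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    type: str  # SNV | INS | DEL
    supporting_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if not 0.0 <= self.supporting_fraction <= 1.0:
            raise ValueError("supporting_fraction must be in [0,1]")
        if self.type not in {"SNV", "INS", "DEL"}:
            raise ValueError(f"unknown variant type {self.type!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class BreakpointRecord:
    """One side of a putative structural-variant breakpoint."""

    contig: str
    pos: int  # 1-based
    side: str  # left | right
    read_count: int
    frac_not_perfectly_matched: float
    unaligned_seq: str = ""

    def __post_init__(self) -> None:
        if self.side not in {"left", "right"}:
            raise ValueError(f"breakpoint side must be left/right, got {self.side!r}")
        if self.read_count < 0:
            raise ValueError("read_count must be >= 0")
        if not 0.0 <= self.frac_not_perfectly_matched <= 1.0:
            raise ValueError("frac_not_perfectly_matched must be in [0,1]")
        if len(self.unaligned_seq) > MAX_BREAKPOINT_SEQ:
            raise ValueError(
                f"unaligned_seq exceeds {MAX_BREAKPOINT_SEQ} bp"
            )


@dataclass(frozen=True)
class SVCall:
    """A matched left/right breakpoint pair supporting one SV event."""

    left: BreakpointRecord
    right: BreakpointRecord
    evidence_seq: str
    span: int

    def __post_init__(self) -> None:
        if self.left.pos > self.right.pos:
            raise ValueError("left breakpoint must not lie beyond the right one")


@dataclass(frozen=True)
class CodingEffect:
    """Protein-level description of a variant in conventional style."""

    locus_tag: str
    description: str
    kind: str  # missense|synonymous|nonsense|frameshift|inframe_ins|inframe_del|upstream


def subtract_background(
    sample: list[VariantRecord], control: list[VariantRecord]
) -> list[VariantRecord]:
    """Drop sample variants whose (contig,pos,ref,alt) key occurs in the
    control; stable order. Matching is exact — no indel normalisation."""
    control_keys = {v.key for v in control}
    return [v for v in sample if v.key not in control_keys]


def filter_breakpoints(
    records: list[BreakpointRecord],
    min_reads: int = 10,
    min_frac: float = 0.20,
) -> list[BreakpointRecord]:
    """Keep breakpoints with read_count >= min_reads and imperfect-match
    fraction >= min_frac (records *below* either threshold are
    eliminated, so exact-boundary records survive)."""
    if min_reads < 0 or min_frac < 0:
        raise ValueError("thresholds must be non-negative")
    return [
        r
        for r in records
        if r.read_count >= min_reads and r.frac_not_perfectly_matched >= min_frac
    ]


def _longest_common_substring(a: str, b: str) -> str:
    """Longest exact shared substring (dynamic programming; inputs <=75 bp)."""
    if not a or not b:
        return ""
    best_len, best_end = 0, 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best_len:
                    best_len, best_end = cur[j], i
        prev = cur
    return a[best_end - best_len : best_end]


def shared_evidence(a: str, b: str) -> str:
    """Longest substring shared by two breakpoint sequences, testing the
    second sequence in both orientations."""
    direct = _longest_common_substring(a.upper(), b.upper())
    try:
        flipped = _longest_common_substring(a.upper(), reverse_complement(b))
    except ValueError:  # non-ACGT in b; direct comparison only
        flipped = ""
    return direct if len(direct) >= len(flipped) else flipped


def pair_breakpoints(
    lefts: list[BreakpointRecord],
    rights: list[BreakpointRecord],
    max_span: int = 10_000,
    min_overlap: int = 15,
) -> tuple[list[SVCall], list[BreakpointRecord]]:
    """Greedy nearest-first pairing of left and right breakpoints.

    A candidate pair must lie within ``max_span`` bp on the same contig
    and share an exact substring of at least ``min_overlap`` bp between
    their unaligned sequences (either orientation). Candidates are taken
    closest-first; ties broken toward the lower-coordinate partner. Each
    breakpoint is used at most once. Returns (calls, unpaired).
    """
    candidates: list[tuple[int, int, int, int, int, str]] = []
    for i, lb in enumerate(lefts):
        for j, rb in enumerate(rights):
            if lb.contig != rb.contig or lb.pos > rb.pos:
                continue
            span = rb.pos - lb.pos
            if span > max_span:
                continue
            ev = shared_evidence(lb.unaligned_seq, rb.unaligned_seq)
            if len(ev) < min_overlap:
                continue
            candidates.append((span, lb.pos, rb.pos, i, j, ev))
    candidates.sort(key=lambda c: c[:3])
    used_l: set[int] = set()
    used_r: set[int] = set()
    calls: list[SVCall] = []
    for span, _lp, _rp, i, j, ev in candidates:
        if i in used_l or j in used_r:
            continue
        used_l.add(i)
        used_r.add(j)
        calls.append(SVCall(left=lefts[i], right=rights[j], evidence_seq=ev, span=span))
    unpaired = [lb for i, lb in enumerate(lefts) if i not in used_l]
    unpaired += [rb for j, rb in enumerate(rights) if j not in used_r]
    return calls, unpaired


# --- coding-effect nomenclature -------------------------------------------

_EFFECT_RE = re.compile(
    r"^(?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)(?P<alt>(?:[A-Z][a-z]{2})|fs|\*|(?:del))$"
)
_UPSTREAM_RE = re.compile(r"^(?P<off>\d+) bp upstream$")
_INS_RE = re.compile(
    r"^(?P<l>[A-Z][a-z]{2})(?P<lp>\d+)_(?P<r>[A-Z][a-z]{2})(?P<rp>\d+)ins(?P<aas>(?:[A-Z][a-z]{2})+)$"
)


def parse_effect_description(description: str) -> dict:
    """Parse a description back to its components (round-trip check)."""
    m = _EFFECT_RE.match(description)
    if m:
        return {"ref_aa": m.group("ref"), "position": int(m.group("pos")),
                "alt": m.group("alt")}
    m = _INS_RE.match(description)
    if m:
        return {"ref_aa": m.group("l"), "position": int(m.group("lp")),
                "alt": "ins" + m.group("aas")}
    m = _UPSTREAM_RE.match(description)
    if m:
        return {"ref_aa": None, "position": -int(m.group("off")), "alt": "upstream"}
    raise ValueError(f"unparseable effect description {description!r}")


def _translate(seq: str) -> str:
    return str(Seq(seq).translate(table=CODON_TABLE_ID))


def _cds_offset(variant: VariantRecord, gene: GeneFeature) -> int:
    """Strand-aware offset of the variant's first base within the CDS
    (negative = upstream of the translational start)."""
    g0 = variant.pos - 1  # 0-based genomic
    if gene.strand == "+":
        return g0 - gene.start
    return gene.end - 1 - g0


def annotate_coding_effect(
    variant: VariantRecord, gene: GeneFeature, cds_seq: str
) -> CodingEffect:
    """Name a variant's protein-level effect in conventional style.

    ``cds_seq`` is the coding sequence read 5'->3' on the gene's own
    strand; its length must be divisible by 3. SNVs translate the ref
    and alt codons with the bacterial code (alternative start codons
    translated as written); indels whose net length is not a multiple
    of 3 are frameshifts named at the first affected residue; variants
    up to 300 bp upstream of the start are kind ``upstream``.
    """
    cds = cds_seq.upper()
    if len(cds) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    ref = "" if variant.ref == "-" else variant.ref.upper()
    alt = "" if variant.alt == "-" else variant.alt.upper()
    if gene.strand == "-":
        ref = reverse_complement(ref) if ref else ""
        alt = reverse_complement(alt) if alt else ""
    off = _cds_offset(variant, gene)
    if off < 0:
        if off < -300:
            raise ValueError(
                f"variant {variant.pos} is {-off} bp upstream of {gene.locus_tag}; "
                "beyond the 300 bp promoter window"
            )
        return CodingEffect(gene.locus_tag, f"{-off} bp upstream", "upstream")
    if off >= len(cds):
        raise ValueError(
            f"variant {variant.pos} lies beyond the CDS of {gene.locus_tag}"
        )
    protein = _translate(cds)
    codon_idx = off // 3  # 0-based residue index of first affected base
    if "*" in protein[:codon_idx]:
        raise ValueError(
            f"annotation mismatch: internal stop before residue {codon_idx + 1} "
            f"of {gene.locus_tag}"
        )
    net = len(alt) - len(ref)
    if variant.type == "SNV":
        if len(ref) != 1 or len(alt) != 1:
            raise ValueError("SNV must have single-base ref and alt")
        if cds[off] != ref:
            raise ValueError(
                f"annotation mismatch: CDS base {cds[off]} != ref allele {ref} "
                f"at offset {off} in {gene.locus_tag}"
            )
        codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        mut_codon = "".join(
            alt if k == off - codon_idx * 3 else b for k, b in enumerate(codon)
        )
        ref_aa = _translate(codon)
        alt_aa = _translate(mut_codon)
        num = codon_idx + 1
        if alt_aa == ref_aa:
            return CodingEffect(
                gene.locus_tag, f"{seq3(ref_aa)}{num}{seq3(alt_aa)}", "synonymous"
            )
        if alt_aa == "*":
            return CodingEffect(gene.locus_tag, f"{seq3(ref_aa)}{num}*", "nonsense")
        return CodingEffect(
            gene.locus_tag, f"{seq3(ref_aa)}{num}{seq3(alt_aa)}", "missense"
        )
    # insertion or deletion
    num = codon_idx + 1
    ref_aa = protein[codon_idx]
    if net % 3 != 0:
        return CodingEffect(gene.locus_tag, f"{seq3(ref_aa)}{num}fs", "frameshift")
    if variant.type == "DEL":
        return CodingEffect(gene.locus_tag, f"{seq3(ref_aa)}{num}del", "inframe_del")
    # in-frame insertion between residue num-1 and num when it lands on a
    # codon boundary; named by the flanking residues
    ins_aas = _translate(alt) if off % 3 == 0 else ""
    left_num = num - 1 if off % 3 == 0 else num
    right_num = left_num + 1
    if off % 3 == 0 and left_num >= 1 and ins_aas and "*" not in ins_aas:
        left_aa = seq3(protein[left_num - 1])
        right_aa = seq3(protein[right_num - 1])
        return CodingEffect(
            gene.locus_tag,
            f"{left_aa}{left_num}_{right_aa}{right_num}ins"
            + "".join(seq3(a) for a in ins_aas),
            "inframe_ins",
        )
    return CodingEffect(gene.locus_tag, f"{seq3(ref_aa)}{num}{seq3(ref_aa)}", "inframe_ins")


# --- tabular I/O -----------------------------------------------------------

VARIANT_TSV_COLUMNS = ("contig", "pos", "ref", "alt", "type", "supporting_fraction")
BREAKPOINT_TSV_COLUMNS = (
    "contig",
    "pos",
    "side",
    "read_count",
    "frac_not_perfectly_matched",
    "unaligned_seq",
)


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if tuple(df.columns) != VARIANT_TSV_COLUMNS:
        raise ValueError(f"variant TSV must have columns {VARIANT_TSV_COLUMNS}")
    return [
        VariantRecord(r.contig, int(r.pos), r.ref, r.alt, r.type,
                      float(r.supporting_fraction))
        for r in df.itertuples()
    ]


def read_variants_vcf(path: str | Path, af_tag: str = "AF") -> list[VariantRecord]:
    """Minimal VCF reader: CHROM POS REF ALT plus an AF-style INFO tag.

    Pure-text parse of the mandatory columns; multi-allelic rows are
    split. Type is inferred from allele lengths (VCF-anchored indels).
    """
    out: list[VariantRecord] = []
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"VCF not found: {p}")
    with p.open() as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ValueError(f"truncated VCF row: {line!r}")
            chrom, pos, _id, ref, alts, _qual, _filt, info = fields[:8]
            af = 1.0
            for kv in info.split(";"):
                if kv.startswith(af_tag + "="):
                    af = float(kv.split("=", 1)[1].split(",")[0])
            for alt in alts.split(","):
                if len(ref) == len(alt) == 1:
                    vtype = "SNV"
                elif len(alt) > len(ref):
                    vtype = "INS"
                else:
                    vtype = "DEL"
                out.append(VariantRecord(chrom, int(pos), ref, alt, vtype, af))
    return out


def read_breakpoints_tsv(path: str | Path) -> list[BreakpointRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if tuple(df.columns) != BREAKPOINT_TSV_COLUMNS:
        raise ValueError(f"breakpoint TSV must have columns {BREAKPOINT_TSV_COLUMNS}")
    return [
        BreakpointRecord(r.contig, int(r.pos), r.side, int(r.read_count),
                         float(r.frac_not_perfectly_matched), r.unaligned_seq)
        for r in df.itertuples()
    ]


def write_breakpoints_tsv(records: list[BreakpointRecord], path: str | Path) -> int:
    rows = [
        {
            "contig": r.contig, "pos": r.pos, "side": r.side,
            "read_count": r.read_count,
            "frac_not_perfectly_matched": r.frac_not_perfectly_matched,
            "unaligned_seq": r.unaligned_seq,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(BREAKPOINT_TSV_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
    return len(rows)


def write_svcalls_tsv(calls: list[SVCall], path: str | Path) -> int:
    rows = [
        {
            "contig": c.left.contig,
            "left_pos": c.left.pos,
            "right_pos": c.right.pos,
            "span": c.span,
            "evidence_seq": c.evidence_seq,
            "left_reads": c.left.read_count,
            "right_reads": c.right.read_count,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=["contig", "left_pos", "right_pos", "span", "evidence_seq",
                 "left_reads", "right_reads"],
    ).to_csv(path, sep="\t", index=False)
    return len(rows)
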