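"""Genome scanning for palindromic operator sites.

Slides a compiled :class:`~rexscan.pattern.PalindromePattern` across
every contig of a genome, testing each 18-bp window in both
orientations, and emits de-duplicated hits in forward-strand genome
coordinates (0-based, half-open). A window matching in both
orientations is reported once with strand ``"both"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .pattern import PalindromePattern, match_window

__all__ = [
    "SiteHit",
    "ScanLog",
    "reverse_complement",
    "scan_sequence",
    "scan_genome",
    "write_sites_tsv",
    "read_sites_tsv",
    "write_sites_bed",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SITE_TSV_COLUMNS = (
    "contig",
    "start",
    "end",
    "strand",
    "forward_seq",
    "arm_mismatch_position",
    "spacer_gc_count",
)


@dataclass(frozen=True)
class SiteHit:
    """One matched window in genome coordinates.

    ``forward_seq`` is always the slice of the forward genome strand;
    ``strand`` records which orientation(s) passed the pattern;
    ``arm_mismatch_position`` and ``spacer_gc_count`` describe the
    matching orientation (the forward one when strand is ``"both"``).
    """

    contig: str
    start: int
    end: int
    strand: str  # "+", "-", or "both"
    forward_seq: str
    arm_mismatch_position: int = 0
    spacer_gc_count: int = 0

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.forward_seq):
            raise ValueError("site coordinates disagree with sequence length")
        if self.strand not in {"+", "-", "both"}:
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class ScanLog:
    """Per-scan bookkeeping: windows skipped for ambiguity codes."""

    windows_tested: int = 0
    windows_skipped_ambiguous: int = 0
    contigs: list[str] = field(default_factory=list)


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T string (involution; '' -> '')."""
    s = seq.upper()
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"cannot reverse-complement character(s) {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


def scan_sequence(
    seq: str,
    p: PalindromePattern,
    contig: str = "seq",
    log: ScanLog | None = None,
    circular: bool = False,
) -> list[SiteHit]:
    """Scan one contig on both strands; hits sorted by start offset.

    Windows containing ambiguity codes are skipped and counted in the
    log. With ``circular`` the scan wraps across the origin, reporting
    wrapped hits at their (mod length) start offset.
    """
    s = seq.upper()
    k = p.window_len
    n = len(s)
    if log is None:
        log = ScanLog()
    log.contigs.append(contig)
    hits: list[SiteHit] = []
    if n < k:
        return hits
    scan_s = s + s[: k - 1] if circular and n >= k else s
    last = (n if circular and n >= k else n - k + 1)
    for i in range(last):
        w = scan_s[i : i + k]
        log.windows_tested += 1
        if set(w) - set("ACGT"):
            log.windows_skipped_ambiguous += 1
            continue
        fwd = match_window(w, p)
        rev = match_window(reverse_complement(w), p)
        if not (fwd.matched or rev.matched):
            continue
        if fwd.matched and rev.matched:
            strand = "both"
        elif fwd.matched:
            strand = "+"
        else:
            strand = "-"
        rep = fwd if fwd.matched else rev
        hits.append(
            SiteHit(
                contig=contig,
                start=i,
                end=i + k,
                strand=strand,
                forward_seq=w,
                arm_mismatch_position=rep.arm_mismatch_position,
                spacer_gc_count=rep.spacer_gc_count,
            )
        )
    return hits


def scan_genome(
    fasta_path: str | Path,
    p: PalindromePattern,
    log: ScanLog | None = None,
    circular: bool = False,
) -> list[SiteHit]:
    """Scan every record of a (multi-)FASTA file.

    Contig ids are the first whitespace-delimited header token.
    Raises on a missing/empty file or duplicate contig ids.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate contig id(s) in {path}: {dupes}")
    if log is None:
        log = ScanLog()
    hits: list[SiteHit] = []
    for rec in records:
        rec_hits = scan_sequence(str(rec.seq), p, contig=rec.id, log=log, circular=circular)
        logger.info("contig %s: %d hit(s)", rec.id, len(rec_hits))
        hits.extend(rec_hits)
    if log.windows_skipped_ambiguous:
        logger.info(
            "%d window(s) skipped for ambiguity codes", log.windows_skipped_ambiguous
        )
    return hits


def write_sites_tsv(hits: list[SiteHit], out_path: str | Path) -> int:
    """Write hits as TSV; returns the number of rows written."""
    path = Path(out_path)
    with path.open("w") as fh:
        fh.write("\t".join(SITE_TSV_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.contig}\t{h.start}\t{h.end}\t{h.strand}\t{h.forward_seq}"
                f"\t{h.arm_mismatch_position}\t{h.spacer_gc_count}\n"
            )
    return len(hits)


def read_sites_tsv(path: str | Path) -> list[SiteHit]:
    hits: list[SiteHit] = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != SITE_TSV_COLUMNS:
            raise ValueError(f"unexpected site TSV header in {path}: {header}")
        for line in fh:
            if not line.strip():
                continue
            contig, start, end, strand, seq, mmpos, gc = line.rstrip("\n").split("\t")
            hits.append(
                SiteHit(contig, int(start), int(end), strand, seq, int(mmpos), int(gc))
            )
    return hits


def write_sites_bed(hits: list[SiteHit], out_path: str | Path) -> int:
    """BED6 export (score 0, name = forward sequence; 'both' written '+')."""
    path = Path(out_path)
    with path.open("w") as fh:
        for h in hits:
            strand = "+" if h.strand == "both" else h.strand
            fh.write(f"{h.contig}\t{h.start}\t{h.end}\t{h.forward_seq}\t0\t{strand}\n")
    return len(hits)
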