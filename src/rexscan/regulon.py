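"""Regulon annotation: site-to-gene assignment, filtering, consensus.

Each operator hit is attached to its nearest downstream gene — the gene
whose translational start the site sits upstream of, on the gene's own
strand, without overlapping any gene body. Distances follow the
convention of published operator tables: negative (upstream), measured
from the site boundary *farthest* from the gene so that the site length
is included (an 18-bp site immediately abutting a start codon is at
distance -18).

Sites surviving the distance and annotation filters are strand-
corrected into their matching orientation and stacked into a simple
threshold consensus (column base if its frequency reaches the
threshold, else N).
"""

from __future__ import annotations

import tempfile
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .scan import SiteHit, reverse_complement

__all__ = [
    "GeneFeature",
    "AnnotatedSite",
    "ConsensusResult",
    "DEFAULT_PRODUCT_DENYLIST",
    "load_features_gff",
    "load_features_tsv",
    "nearest_downstream_gene",
    "annotate_sites",
    "filter_sites",
    "orient_site",
    "build_consensus",
    "write_regulon_report",
    "read_regulon_report",
]

#: Products treated as "function not annotated" by default.
DEFAULT_PRODUCT_DENYLIST = frozenset({"hypothetical protein", ""})

REPORT_COLUMNS = (
    "locus_tag",
    "gene_name",
    "product",
    "sequence",
    "distance",
    "strand",
    "start",
    "end",
)


@dataclass(frozen=True)
class GeneFeature:
    """A gene (or CDS) feature in 0-based half-open coordinates."""

    contig: str
    start: int
    end: int
    strand: str
    locus_tag: str
    gene_name: str | None = None
    product: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.locus_tag}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.locus_tag}: strand must be + or -")


@dataclass(frozen=True)
class AnnotatedSite:
    """A site joined to its nearest downstream gene.

    ``distance`` is the signed upstream offset (always negative for a
    retained site); its magnitude is never below the site length.
    """

    site: SiteHit
    locus_tag: str
    gene_name: str | None
    product: str | None
    distance: int


@dataclass(frozen=True)
class ConsensusResult:
    oriented_seqs: tuple[str, ...]
    consensus: str
    threshold: float
    counts: pd.DataFrame  # rows A,C,G,T; one column per position (1-based)


def load_features_gff(gff_path: str | Path) -> list[GeneFeature]:
    """Load gene features from GFF3 (gene records, CDS as fallback).

    ``locus_tag`` and ``product`` are read from the attribute column;
    GFF3 1-based inclusive coordinates are converted to 0-based
    half-open.
    """
    import gffutils

    path = Path(gff_path)
    if not path.exists():
        raise FileNotFoundError(f"GFF3 file not found: {path}")
    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(path),
            dbfn=tmp.name,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        feats: list[GeneFeature] = []
        ftypes = ["gene"] if any(True for _ in db.features_of_type("gene")) else ["CDS"]
        for f in db.features_of_type(ftypes, order_by="start"):
            locus = f.attributes.get("locus_tag", [f.id])[0]
            gene_name = f.attributes.get("gene", [None])[0]
            product = f.attributes.get("product", [None])[0]
            feats.append(
                GeneFeature(
                    contig=f.seqid,
                    start=f.start - 1,
                    end=f.end,
                    strand=f.strand,
                    locus_tag=locus,
                    gene_name=gene_name,
                    product=product,
                )
            )
    _check_unique_loci(feats)
    return feats


def load_features_tsv(path: str | Path) -> list[GeneFeature]:
    """7-column TSV fallback: contig start end strand locus_tag gene_name product."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["contig", "start", "end", "strand", "locus_tag", "gene_name", "product"]
    if list(df.columns) != required:
        raise ValueError(f"feature TSV must have columns {required}, got {list(df.columns)}")
    feats = [
        GeneFeature(
            contig=r.contig,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            locus_tag=r.locus_tag,
            gene_name=r.gene_name or None,
            product=r.product or None,
        )
        for r in df.itertuples()
    ]
    _check_unique_loci(feats)
    return feats


def _check_unique_loci(feats: list[GeneFeature]) -> None:
    tags = [f.locus_tag for f in feats]
    if len(set(tags)) != len(tags):
        dupes = sorted({t for t in tags if tags.count(t) > 1})
        raise ValueError(f"duplicate locus_tag(s): {dupes}")


def nearest_downstream_gene(
    site: SiteHit, features: list[GeneFeature]
) -> tuple[GeneFeature, int] | None:
    """Nearest gene having the site in its upstream intergenic region.

    Returns ``(gene, distance)`` with distance negative, or None when
    the site overlaps any gene body or no gene lies downstream of it on
    either strand. For a + gene, |distance| = gene.start - site.start;
    for a - gene, |distance| = site.end - gene.end (the site boundary
    farthest from the gene, so the site length is included).
    """
    same = [f for f in features if f.contig == site.contig]
    if not same and features:
        raise ValueError(
            f"no features on contig {site.contig!r}; contig mismatch with annotation"
        )
    for f in same:  # overlap with any gene body disqualifies the site
        if site.start < f.end and f.start < site.end:
            return None
    best: tuple[int, int, GeneFeature] | None = None
    for f in same:
        if f.strand == "+" and site.end <= f.start:
            dist = f.start - site.start
        elif f.strand == "-" and site.start >= f.end:
            dist = site.end - f.end
        else:
            continue
        key = (dist, f.start)
        if best is None or key < best[:2]:
            best = (dist, f.start, f)
    if best is None:
        return None
    return best[2], -best[0]


def annotate_sites(
    hits: list[SiteHit], features: list[GeneFeature]
) -> list[AnnotatedSite]:
    """Assign every hit to a downstream gene, dropping unassignable hits."""
    out: list[AnnotatedSite] = []
    for h in hits:
        res = nearest_downstream_gene(h, features)
        if res is None:
            continue
        gene, dist = res
        out.append(
            AnnotatedSite(
                site=h,
                locus_tag=gene.locus_tag,
                gene_name=gene.gene_name,
                product=gene.product,
                distance=dist,
            )
        )
    return out


def filter_sites(
    annotated: list[AnnotatedSite],
    max_upstream: int = 200,
    require_annotation: bool = False,
    product_denylist: frozenset[str] = DEFAULT_PRODUCT_DENYLIST,
) -> list[AnnotatedSite]:
    """Apply the distance and annotation filters, preserving order.

    Sites more than ``max_upstream`` bp upstream are removed ("more
    than" is strict: |distance| == max_upstream is retained). With
    ``require_annotation``, sites whose gene product is missing or
    deny-listed are removed.
    """
    if max_upstream < 0:
        raise ValueError("max_upstream must be non-negative")
    kept = [a for a in annotated if abs(a.distance) <= max_upstream]
    if require_annotation:
        kept = [
            a
            for a in kept
            if a.product is not None and a.product.strip().lower() not in product_denylist
        ]
    return kept


def orient_site(site: SiteHit) -> str:
    """The site sequence in its matching orientation (+ preferred)."""
    if site.strand in {"+", "both"}:
        return site.forward_seq
    return reverse_complement(site.forward_seq)


def build_consensus(oriented_seqs: list[str], threshold: float = 1.0) -> ConsensusResult:
    """Threshold consensus over strand-corrected site sequences.

    Column i reports a concrete base iff its frequency among the input
    sequences is at least ``threshold`` (a fraction in (0.5, 1]); any
    more ambiguous column is written N.
    """
    if not oriented_seqs:
        raise ValueError("need at least one sequence")
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must be in (0.5, 1]")
    length = len(oriented_seqs[0])
    if any(len(s) != length for s in oriented_seqs):
        raise ValueError("all sequences must have equal length")
    seqs = [s.upper() for s in oriented_seqs]
    n = len(seqs)
    counts = {b: [0] * length for b in "ACGT"}
    letters: list[str] = []
    for i in range(length):
        col = Counter(s[i] for s in seqs)
        for b in "ACGT":
            counts[b][i] = col.get(b, 0)
        base, k = col.most_common(1)[0]
        letters.append(base if k / n >= threshold else "N")
    counts_df = pd.DataFrame(counts, index=range(1, length + 1)).T
    return ConsensusResult(
        oriented_seqs=tuple(seqs),
        consensus="".join(letters),
        threshold=threshold,
        counts=counts_df,
    )


def write_regulon_report(sites: list[AnnotatedSite], out_path: str | Path) -> int:
    """Write the annotated-site table as TSV; returns rows written."""
    path = Path(out_path)
    rows = [
        {
            "locus_tag": a.locus_tag,
            "gene_name": a.gene_name or "",
            "product": a.product or "",
            "sequence": a.site.forward_seq,
            "distance": a.distance,
            "strand": a.site.strand,
            "start": a.site.start,
            "end": a.site.end,
        }
        for a in sites
    ]
    df = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    df.to_csv(path, sep="\t", index=False)
    return len(rows)


def read_regulon_report(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"distance": int, "start": int, "end": int},
                     keep_default_na=False)
    if list(df.columns) != list(REPORT_COLUMNS):
        raise ValueError(f"unexpected report columns in {path}: {list(df.columns)}")
    return df
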