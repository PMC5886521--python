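"""Seeded synthetic data for every pipeline stage.

Generators emulate the study's inputs with known ground truth: an
AT-rich bacterial genome background with palindromic operator sites
planted at recorded loci and strands, gene features placed downstream
of a configurable fraction of sites, logistic OD600 growth curves,
breakpoint evidence tables straddling the filtering thresholds,
fermentation end-product tables built from chosen percent-theoretical
yields, and qPCR plates with planted copy ratios.

Each generator is deterministic under (seed, config): one global seed
fans out to fixed per-stage substreams. Generators derive their truth
labels from the stated rules and their own construction geometry, not
from the pipeline implementations — the one documented exception is
the final re-scan in :func:`gen_genome`, which uses the scanner to
append accidental background matches so the truth list is complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pattern import PalindromePattern, match_window
from .physiology import (
    FermentationRecord,
    QpcrSample,
    StandardCurve,
    logistic_od,
    theoretical_yield_coeff,
)
from .regulon import DEFAULT_PRODUCT_DENYLIST, GeneFeature
from .scan import reverse_complement, scan_sequence
from .variants import BreakpointRecord, MAX_BREAKPOINT_SEQ

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "sample_accepted_site",
    "gen_genome",
    "gen_gff",
    "write_fasta",
    "gen_od_curves",
    "gen_breakpoint_table",
    "gen_fermentation_table",
    "gen_qpcr",
]

# fixed substream indices for per-stage seed fan-out
_STREAM_GENOME = 0
_STREAM_OD = 1
_STREAM_BREAKPOINTS = 2
_STREAM_FERMENTATION = 3
_STREAM_QPCR = 4

_PRODUCT_VOCAB = (
    "alcohol dehydrogenase",
    "iron-containing alcohol dehydrogenase",
    "energy-conserving hydrogenase subunit",
    "hydrogenase maturation protein",
    "ABC-type sugar transporter",
    "lactate dehydrogenase",
    "phosphotransacetylase",
    "ferredoxin oxidoreductase subunit",
    "transcriptional regulator",
    "sporulation protein",
)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass
class GeneratorConfig:
    """Knobs for the genome/annotation generator.

    ``at_fraction`` sets the background A+T content (default 0.65,
    a Thermoanaerobacterium-like genome); ``annotated_fraction`` is the
    fraction of planted sites given a gene within 200 bp downstream;
    ``far_fraction`` of the annotated sites are instead placed 201-400
    bp upstream to exercise the distance filter; ``deny_fraction`` of
    downstream genes carry a deny-listed product.
    """

    seed: int = 0
    genome_length: int = 100_000
    at_fraction: float = 0.65
    n_sites: int = 20
    annotated_fraction: float = 1.0
    far_fraction: float = 0.0
    deny_fraction: float = 0.0
    contig: str = "synth_contig_1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.at_fraction <= 1.0:
            raise ValueError("at_fraction must be in [0,1]")
        if self.genome_length < self.n_sites * 50:
            raise ValueError(
                "infeasible packing: genome_length must be >= 50 bp per site"
            )


@dataclass
class SyntheticTruth:
    """Planted ground truth against which every stage is scored."""

    planted_sites: list[tuple[str, int, str, str]] = field(default_factory=list)
    genes: list[GeneFeature] = field(default_factory=list)
    expected_regulon: list[tuple[str, int]] = field(default_factory=list)
    breakpoint_pass_labels: list[bool] = field(default_factory=list)
    true_yields: dict[str, float] = field(default_factory=dict)
    true_mu: dict[str, float] = field(default_factory=dict)
    true_copy_ratios: dict[str, float] = field(default_factory=dict)


def sample_accepted_site(p: PalindromePattern, rng: np.random.Generator) -> str:
    """Uniform draw from the pattern's accepted window set.

    Constructive sampling: arm 1 uniformly over the template expansion,
    spacer uniformly over the admissible (<= max GC) strings, arm 2
    uniformly over the exact reverse complement plus every allowed
    single substitution. Every draw passes :func:`match_window`.
    """
    if p.max_spacer_gc not in (0, 1):
        raise ValueError("constructive sampling supports spacer GC budget 0 or 1")
    arms = sorted(p.arm_template.expand())
    arm1 = arms[int(rng.integers(len(arms)))]
    m = p.spacer_len
    n_pure = 2**m
    n_one_gc = m * 2 * 2 ** (m - 1) if p.max_spacer_gc == 1 else 0
    idx = int(rng.integers(n_pure + n_one_gc))
    if idx < n_pure:
        spacer = "".join("AT"[(idx >> k) & 1] for k in range(m))
    else:
        rem = idx - n_pure
        per_pos = 2 * 2 ** (m - 1)
        pos = rem // per_pos
        rem %= per_pos
        gc_base = "CG"[rem % 2]
        bits = rem // 2
        rest = ["AT"[(bits >> k) & 1] for k in range(m - 1)]
        spacer = "".join(rest[:pos] + [gc_base] + rest[pos:])
    exact = reverse_complement(arm1)
    variants = [exact]
    if p.max_arm_mismatches:
        for vp in sorted(p.allowed_arm2_mismatch_positions):
            for alt in "ACGT":
                if alt != exact[vp - 1]:
                    variants.append(exact[: vp - 1] + alt + exact[vp:])
    arm2 = variants[int(rng.integers(len(variants)))]
    window = arm1 + spacer + arm2
    assert match_window(window, p).matched
    return window


def _nearest_downstream_arithmetic(
    start: int, end: int, genes: list[GeneFeature]
) -> tuple[GeneFeature, int] | None:
    """Generator-side nearest-downstream-gene rule (independent of the
    annotation module): upstream-of-start on the gene's strand, no
    overlap with any gene body, distance from the far site boundary."""
    for g in genes:
        if start < g.end and g.start < end:
            return None
    best = None
    for g in genes:
        if g.strand == "+" and end <= g.start:
            d = g.start - start
        elif g.strand == "-" and start >= g.end:
            d = end - g.end
        else:
            continue
        if best is None or (d, g.start) < (best[1], best[0].start):
            best = (g, d)
    return (best[0], -best[1]) if best else None


def gen_genome(
    cfg: GeneratorConfig, p: PalindromePattern
) -> tuple[dict[str, str], SyntheticTruth]:
    """Generate a genome with planted operator sites and gene features.

    Sites are planted at non-overlapping block positions, half on each
    strand; genes are placed downstream per the config fractions. After
    planting, the genome is re-scanned and any accidental background
    matches are appended to the truth so planted-site recall/precision
    can be scored exactly.
    """
    rng = _rng(cfg.seed, _STREAM_GENOME)
    L = cfg.genome_length
    n = cfg.n_sites
    at = cfg.at_fraction
    probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]  # A C G T
    genome = list(rng.choice(list("ACGT"), size=L, p=probs))

    block = L // max(n, 1)
    gene_len_lo, gene_len_hi = 300, 900
    truth = SyntheticTruth()
    planted_starts: set[int] = set()
    site_records: list[tuple[int, str, str, int]] = []  # start, strand, seq, block idx
    for i in range(n):
        b = i * block
        site_strand = "+" if i < (n + 1) // 2 else "-"
        seq = sample_accepted_site(p, rng)
        annotated = rng.random() < cfg.annotated_fraction
        far = annotated and rng.random() < cfg.far_fraction
        d = int(rng.integers(201, 401)) if far else int(rng.integers(18, 201))
        gene_strand = "+" if i % 2 == 0 else "-"
        gene_len = int(rng.integers(gene_len_lo, gene_len_hi + 1))
        if annotated and gene_strand == "-":
            if b + 10 + gene_len + d + 40 >= b + block:
                raise ValueError("infeasible packing: block too small for gene + site")
            g_start = b + 10
            g_end = g_start + gene_len
            s = g_end + d - 18
        else:
            s = b + 10 + int(rng.integers(0, max(1, min(40, block - 10 - 18))))
            if annotated:
                g_start = s + d
                g_end = g_start + gene_len
                if g_end >= b + block:
                    g_end = b + block - 10
                    if g_end - g_start < 60:
                        raise ValueError("infeasible packing: gene does not fit block")
        if s + 18 > L:
            raise ValueError("infeasible packing: site beyond genome end")
        planted = seq if site_strand == "+" else reverse_complement(seq)
        genome[s : s + 18] = list(planted)
        planted_starts.add(s)
        site_records.append((s, site_strand, seq, i))
        if annotated:
            deny = rng.random() < cfg.deny_fraction
            product = (
                "hypothetical protein"
                if deny
                else _PRODUCT_VOCAB[int(rng.integers(len(_PRODUCT_VOCAB)))]
            )
            truth.genes.append(
                GeneFeature(
                    contig=cfg.contig,
                    start=g_start,
                    end=g_end,
                    strand=gene_strand,
                    locus_tag=f"SYN_{i:04d}",
                    gene_name=None,
                    product=product,
                )
            )

    seq_str = "".join(genome)
    for s, strand, seq, _ in site_records:
        truth.planted_sites.append((cfg.contig, s, strand, seq))

    # documented leakage: complete the truth by re-scanning with the
    # pipeline scanner so accidental background matches are recorded
    for hit in scan_sequence(seq_str, p, contig=cfg.contig):
        if hit.start not in planted_starts:
            oriented = (
                hit.forward_seq
                if hit.strand in {"+", "both"}
                else reverse_complement(hit.forward_seq)
            )
            truth.planted_sites.append((cfg.contig, hit.start, hit.strand, oriented))
            planted_starts.add(hit.start)

    # expected regulon from generator-side arithmetic over all truth sites
    for contig, s, _strand, _seq in sorted(truth.planted_sites, key=lambda x: x[1]):
        res = _nearest_downstream_arithmetic(s, s + 18, truth.genes)
        if res is None:
            continue
        gene, dist = res
        if abs(dist) > 200:
            continue
        if gene.product is None or gene.product.strip().lower() in DEFAULT_PRODUCT_DENYLIST:
            continue
        truth.expected_regulon.append((gene.locus_tag, dist))

    return {cfg.contig: seq_str}, truth


def write_fasta(seqs: dict[str, str], out_path: str | Path, width: int = 70) -> None:
    with Path(out_path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def gen_gff(truth: SyntheticTruth, out_path: str | Path) -> None:
    """Write truth genes as GFF3 (1-based inclusive coordinates)."""
    tags = [g.locus_tag for g in truth.genes]
    if len(set(tags)) != len(tags):
        raise ValueError("duplicate locus_tags in truth genes")
    with Path(out_path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(truth.genes, key=lambda g: (g.contig, g.start)):
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
            if g.gene_name:
                attrs += f";gene={g.gene_name}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.contig}\tsynth\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def gen_od_curves(
    true_mu: dict[str, float],
    k: float = 0.43,
    od0: float = 0.05,
    dt: float = 0.05,
    t_max: float = 24.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Logistic OD600 curves per strain with multiplicative lognormal
    noise, in long format (strain, time_h, od600)."""
    if k <= 0:
        raise ValueError("carrying capacity K must be positive")
    rng = _rng(seed, _STREAM_OD)
    t = np.arange(0.0, t_max + dt / 2, dt)
    rows = []
    for strain, mu in true_mu.items():
        od = logistic_od(t, mu, k, od0)
        if noise_sd > 0:
            od = od * rng.lognormal(mean=0.0, sigma=noise_sd, size=len(t))
        for ti, oi in zip(t, od):
            rows.append({"strain": strain, "time_h": float(ti), "od600": float(oi)})
    return pd.DataFrame(rows), dict(true_mu)


def gen_breakpoint_table(
    n: int = 500,
    pass_fraction: float = 0.5,
    seed: int = 0,
    contig: str = "synth_contig_1",
) -> tuple[list[BreakpointRecord], list[bool]]:
    """Breakpoint evidence rows straddling the 10-read / 0.20 thresholds.

    Values are drawn around both boundaries (including exact-boundary
    rows: the first intended-pass row is exactly (10 reads, 0.20), the
    first intended-fail row (9, 0.19)); the returned labels are then
    recomputed from the values by the strict retention rule
    (read_count >= 10 and fraction >= 0.20).
    """
    rng = _rng(seed, _STREAM_BREAKPOINTS)
    records: list[BreakpointRecord] = []
    intended = rng.random(n) < pass_fraction
    first_pass = True
    first_fail = True
    for i in range(n):
        side = "left" if i % 2 == 0 else "right"
        pos = int(rng.integers(1, 2_500_000))
        seq_len = int(rng.integers(20, MAX_BREAKPOINT_SEQ + 1))
        seq = "".join(rng.choice(list("ACGT"), size=seq_len))
        if intended[i]:
            if first_pass:
                reads, frac = 10, 0.20
                first_pass = False
            else:
                reads = int(rng.integers(10, 100))
                frac = float(np.round(0.20 + 0.80 * rng.random(), 4))
        else:
            if first_fail:
                reads, frac = 9, 0.19
                first_fail = False
            else:
                mode = int(rng.integers(3))
                if mode == 0:  # too few reads
                    reads = int(rng.integers(0, 10))
                    frac = float(np.round(rng.random(), 4))
                elif mode == 1:  # fraction too low
                    reads = int(rng.integers(10, 100))
                    frac = float(np.round(0.1999 * rng.random(), 4))
                else:  # both low
                    reads = int(rng.integers(0, 10))
                    frac = float(np.round(0.1999 * rng.random(), 4))
        records.append(
            BreakpointRecord(
                contig=contig,
                pos=pos,
                side=side,
                read_count=reads,
                frac_not_perfectly_matched=frac,
                unaligned_seq=seq,
            )
        )
    labels = [
        r.read_count >= 10 and r.frac_not_perfectly_matched >= 0.20 for r in records
    ]
    return records, labels


def gen_fermentation_table(
    true_yields: dict[str, float],
    substrate: str = "cellobiose",
    consumed: float = 5.0,
    seed: int = 0,
) -> tuple[list[FermentationRecord], dict[str, float]]:
    """Fermentation end-product rows built by inverting the yield model:
    ethanol = percent/100 * consumed * stoichiometric coefficient, with
    plausible acetate/lactate residuals filling the balance."""
    rng = _rng(seed, _STREAM_FERMENTATION)
    coeff = theoretical_yield_coeff(substrate)
    records = []
    for strain, pct in true_yields.items():
        if pct > 150:
            raise ValueError(f"implausible target yield {pct}% for {strain}")
        ethanol = pct / 100.0 * consumed * coeff
        slack = max(0.0, (100.0 - pct) / 100.0)
        acetate = float(np.round(slack * consumed * 0.3 * rng.random(), 4))
        lactate = float(np.round(slack * consumed * 0.2 * rng.random(), 4))
        records.append(
            FermentationRecord(
                strain=strain,
                substrate=substrate,
                substrate_initial=consumed,
                substrate_final=0.0,
                ethanol=ethanol,
                acetate=acetate,
                lactate=lactate,
            )
        )
    return records, dict(true_yields)


def gen_qpcr(
    true_copy_ratios: dict[str, float],
    curve: StandardCurve | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    reference_target: str = "recA",
    reference_copies: float = 1e5,
    replicates: int = 6,  # biological duplicates x technical triplicates
) -> tuple[list[QpcrSample], list[tuple[float, float]], dict[str, float]]:
    """qPCR wells with planted copy ratios plus a clean dilution series.

    Cq values follow the given standard curve (default: perfect
    efficiency, Cq = 40 - 3.32193*log10(copies)) with Gaussian Cq noise.
    Returns (sample wells, standards points, truth ratios including the
    reference at 1.0).
    """
    if curve is None:
        curve = StandardCurve(slope=-np.log2(10.0), intercept=40.0)
    rng = _rng(seed, _STREAM_QPCR)
    ratios = dict(true_copy_ratios)
    ratios.setdefault(reference_target, 1.0)
    samples: list[QpcrSample] = []
    for target, ratio in ratios.items():
        copies = reference_copies * ratio
        for rep in range(replicates):
            cq = curve.intercept + curve.slope * np.log10(copies)
            if noise_sd > 0:
                cq += rng.normal(0.0, noise_sd)
            samples.append(QpcrSample(sample=f"rep{rep + 1}", target=target, cq=float(cq)))
    standards = [
        (10.0**e, float(curve.intercept + curve.slope * e)) for e in range(3, 9)
    ]
    return samples, standards, ratios
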