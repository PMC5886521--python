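# Methods

## Operator model and matching semantics

A Rex operator is modelled as an 18-bp degenerate palindrome: a 5-bp
arm matching the template `WTGWW` (`W` = A or T), an 8-bp AT-rich
spacer, and a second arm equal to the reverse complement of the first.
The matcher applies three clauses to a window:

1. **arm 1** satisfies the template exactly — all tolerance lives in
   arm 2, which reproduces every published *T. saccharolyticum* site on
   at least one strand;
2. **spacer** contains at most one G or C (`max_spacer_gc = 1`);
3. **arm 2** equals the reverse complement of arm 1 except for at most
   one mismatch (`max_arm_mismatches ∈ {0, 1}`), confined to arm-2
   positions 4–5.

Conventions worth stating because they are not forced by the model:

* A template `N` position counts as a match, never as a mismatch.
* A tolerated arm-2 mismatch may be any of the three alternative bases,
  including G or C; the spacer G/C budget is independent of arm
  mismatches.
* Input is case-insensitive DNA; `U` and IUPAC ambiguity codes are
  rejected by the predicate (the scanner skips and counts ambiguous
  windows instead of failing).
* The three single-variant pattern specs and the reserved
  `"paper-union"` spec compile to the same dataclass; a stray bracketed
  citation token after the spacer (an artefact of how the syntax is
  sometimes typeset) is ignored by the parser.

The accepted set is small enough to enumerate exactly — 8 arm-1 strings
× 2304 admissible spacers × 7 arm-2 variants = 129 024 windows for the
union pattern (18 432 for the strict palindrome) — which the tests use
as an oracle against the window predicate.

## Genome scanning

Coordinates are 0-based half-open internally; GFF3's 1-based inclusive
convention is converted at the boundary. Every offset of every contig
is tested in both orientations; a window matching both ways is a single
hit with strand `both`, and `forward_seq` always reports the forward
genome strand regardless of which orientation matched. Overlapping hits
at different offsets are all kept (no greedy de-duplication), so counts
can exceed those of tools that merge adjacent matches. Windows are not
wrapped across contig ends unless circular mode is requested.

## Gene assignment, filtering, consensus

The distance of a site to a gene is signed and negative (upstream),
measured **from the site boundary farthest from the gene** to the
translational start: for a + gene `|d| = gene.start − site.start`, for
a − gene `|d| = site.end − gene.end`. The site length is therefore
included and `|d| ≥ 18` always. A site overlapping any gene body is
discarded before assignment; among eligible genes the smallest `|d|`
wins, ties broken toward the lower-coordinate gene. The upstream filter
is strict ("more than 200 bp" excluded): `|d| = 200` survives.
"Function not annotated" is operationalised as a missing product or
membership in a configurable deny-list (default: `hypothetical
protein`, empty string). Published category labels (carbon metabolism,
membrane, …) are manual curation and only supported as a user-supplied
locus→category map.

The consensus is a per-column threshold rule over strand-corrected
sites: a column reports its modal base if the base's frequency reaches
the threshold (default 1.0; valid range (0.5, 1] so the mode is
unique), else `N`. The full A/C/G/T count matrix is emitted alongside.

## Breakpoint evidence and variant nomenclature

Breakpoint records carry read support, the caller's "not perfectly
matched" read fraction (taken as given, never recomputed from reads)
and up to 75 bp of unaligned sequence. Retention requires
`read_count ≥ 10` **and** `fraction ≥ 0.20` — the published rule
eliminates records *below* either threshold, so exact-boundary records
survive. Left/right pairing is greedy nearest-first: candidate pairs on
the same contig within `max_span` (default 10 kb) sharing an exact
substring of ≥ `min_overlap` (default 15 bp, either orientation,
longest-common-substring by dynamic programming) are taken
closest-first, ties toward the lower coordinate, each breakpoint used
once. Identification of the shared sequence against external elements
(transposons, plasmids) is out of scope; the pairing criterion replaces
it with internal sequence agreement.

Background subtraction removes sample variants whose exact
(contig, pos, ref, alt) key occurs in the wild-type control; there is
deliberately no fuzzy indel normalisation.

Protein-level naming uses the bacterial genetic code (translation table
11; alternative start codons translated as written): `Thr597Lys`
missense, `Glu454*` nonsense, `Ala100Ala` synonymous, `Lys290fs` for
frame-disrupting indels (named at the first affected residue),
`Lys290del` / `Lys290_Ala291insAsnThr` for in-frame events, and
`184 bp upstream` for promoter-region variants (window: ≤ 300 bp). All
descriptions parse back to their components, and the tests re-apply
each mutation to the synthetic CDS and re-translate to confirm the
claimed residue.

## Physiology calculators

**Theoretical yield.** `coeff(substrate) = mol_ethanol_max × 46.069 /
formula_mass`, with cellobiose (342.297 g/mol) → 4 ethanol, glucose
(180.156) → 2, xylose (150.130) → 5/3; full precision internally, 2 dp
at the interface (cellobiose prints 0.54 g/g). Percent theoretical
yield = 100 × ethanol / (substrate consumed × coeff); consumption must
be positive; values above 100 % are flagged, not clipped. Initial
product concentrations are assumed baseline-subtracted upstream.

**Growth rate (μ_max, h⁻¹).** Two stages. Sliding 5-point log-linear
windows give the classical estimate: the steepest ln(OD) slope among
windows with r² ≥ 0.98 (a flat window counts r² = 1; windows containing
zero OD are skipped). That estimate — rescued by a whole-series
log-slope when short noisy windows leave nothing usable — seeds a
parametric logistic least-squares refinement on the log scale,
`OD(t) = K·od0·e^(μt) / (K + od0·(e^(μt) − 1))`, with K bounded far
above the observed maximum so non-saturating curves degenerate to an
exponential. The refinement exists because at a typical inoculation
density (OD ~0.05 against a plateau of ~0.43) the culture is never in
pure exponential growth: the best window slope underestimates μ by a
factor ≈ (1 − od0/K) ≈ 0.88, while the logistic fit recovers the
planted rate exactly on noise-free curves and within ~1 % under 2 %
multiplicative noise. If the optimiser fails the window estimate is
reported. Max OD is the maximum of a 3-point running-median smoothed
series (robust to single-well read spikes); rates below 10⁻⁸ h⁻¹ are
reported as 0.

**ADH specific activity.** Beer–Lambert inversion of the A340 slope:
rate (µmol/min) = slope × reaction volume (mL) / (ε × path length);
specific activity = rate / protein mass (mg). ε defaults to
6.22 mM⁻¹cm⁻¹ (NAD(P)H at 340 nm) with a 1-cm path; both are explicit
parameters since assay hardware varies. Cofactor oxidation enters as a
positive slope magnitude.

**qPCR.** Absolute quantification: least-squares line of Cq on
log₁₀(copies) from the dilution series; efficiency = 10^(−1/slope) − 1;
copies = 10^((Cq − intercept)/slope); replicate wells averaged on the
copy scale; expression reported as the ratio to the *recA* reference.
There is intentionally no ΔΔCq mode.

## Synthetic data

Generators are deterministic under (seed, config); a single integer
seed fans out to fixed per-stage substreams via `SeedSequence([seed,
stream])`. Defaults encode the study conditions: AT fraction 0.65
(Thermoanaerobacterium-like background), 100-kb genome with 20 planted
sites, 5 g/L cellobiose fully consumed, OD curves from od0 = 0.05
toward K = 0.43 sampled every 0.05 h for 24 h, per-well Cq noise drawn
as Gaussian and OD noise as multiplicative lognormal, qPCR plates of
biological duplicates × technical triplicates (6 wells per target).

Planted operator sites are sampled **uniformly from the accepted set**
(constructively: arm 1 × admissible spacer × arm-2 variant), so
mismatch handling is exercised — under the union pattern 6/7 of planted
sites carry an arm-2 mismatch. Sites are placed in disjoint genome
blocks, half on each strand; genes are placed downstream of a
configurable fraction of sites with distances drawn in [18, 200] (or
(200, 400] for the fraction meant to exercise the distance filter).
After planting, the genome is re-scanned and chance background matches
are appended to the truth so recall/precision can be scored exactly —
this is the one place a generator calls pipeline code; expected-regulon
distances are recomputed by independent generator-side arithmetic.
Breakpoint tables straddle both thresholds and always include exact
boundary rows (10 reads / 0.20) and near-miss rows (9 / 0.19); labels
are recomputed from the drawn values by the strict rule. Fermentation
tables invert the yield model; qPCR plates invert the standard curve.

What the generators do **not** emulate — and hence what passing tests
do not show about real data: read-level sequencing (no FASTQ, no
coverage or mapping artefacts), operon structure and overlapping genes,
compositional heterogeneity along real genomes (planted sites sit in
disjoint blocks), real HPLC/plate-reader error structure beyond simple
multiplicative or Gaussian noise, and inter-strain biological
variability.

## Verification experiment sizes

The test suite and the acceptance script use: 10⁵ random windows for
the matcher-vs-oracle comparison; full enumeration of both accepted
sets; a 100-kb genome with 20 planted sites for scan recovery; 500
breakpoint rows; noise-free OD curves at five rates spanning 0.06–0.38
h⁻¹; yield round-trips at 40/91/56 %; and a qPCR recovery experiment of
8 independently seeded plates whose per-plate ratio estimates are
combined by geometric mean. The plate count is a power choice: per-well
Cq noise of 0.1 leaves a single 6-well plate's ratio estimate with ~4 %
standard error, so one plate cannot support a 5 % recovery check
robustly; 8 plates bring the standard error to ~1.4 %, making the check
a >3σ bound while leaving the noise model and per-plate analysis
untouched.

## Known limitations

* The matcher is rule-based; there is no position-weight-matrix
  scoring, information content or E-value — a window either satisfies
  the three clauses or it does not.
* Scan counts may differ from pattern-locator web tools that de-duplicate
  overlapping or dyad-symmetric matches.
* Breakpoint pairing is a heuristic stand-in for manual inspection plus
  database search; it identifies *that* two breakpoints share sequence,
  not *what* the shared sequence is.
* The logistic refinement assumes a single growth phase; diauxic or
  lag-dominated curves will be summarised by their best overall
  logistic, and μ_max should then be read with care.
* Indel effect naming assumes the variant is wholly contained in the
  CDS (or its 300-bp promoter window) and does not re-normalise
  ambiguous indel placements.
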