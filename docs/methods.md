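# Methods

This note documents the models, statistics and design choices behind
`regmap`, the parameters that matter, and what the synthetic locus bundle
does and does not emulate.

## Coordinates and the gene model

All internal coordinates are 0-based half-open ascending (BED convention);
`length = end − start` holds exactly. Browser-style printed pairs may be
descending — the convention for minus-strand loci — and are normalised on
input to `(start=min, end=max, strand='-')`; printing a minus-strand
interval re-emits the descending form (a lossless round trip).

The gene model is deliberately minimal: two exons, one intron, 5′/3′ UTRs,
a TSS, a stop-codon junction, an optional 59-bp core promoter and an
optional poly(A) signal, with ~0.5 kb analysis flanks. Point context labels
(`upstream`, `core_promoter`, `utr5`, `exon`, `intron`, `utr3`,
`downstream`) partition the axis — `exon` means the coding part of an exon,
and the core promoter takes precedence where it overlaps the TSS
neighbourhood. An interval whose bases carry more than one label classifies
as `boundary`. Labels are strand-aware: for a minus-strand gene, upstream
lies at higher coordinates. Positions outside the modelled span classify as
upstream/downstream, never as errors.

## CpG island detection

A segment qualifies when **all three** hold strictly: GC fraction > 0.5,
length > 200 bp, observed/expected CpG > 0.6 with
obs/exp = (#CG · L)/(#C · #G). N bases are excluded from every count, so no
CG spans an N. Detection semantics are exhaustive: a base is *covered* iff
it lies in at least one qualifying segment of any length, computed exactly
in O(n²) via the identity that for fixed start *s* the union of all
qualifying `[s, e)` equals `[s, max_e(s))`. Islands are maximal covered
runs.

One subtlety is intrinsic to threshold-based segment criteria: a maximal
covered run is a union of qualifying segments but need not itself qualify
(qualifying segments can reach one-sidedly far into AT flanks, and the
merged run is diluted from both sides). Requiring non-overlapping output,
full oracle coverage, *and* per-island thresholds simultaneously is not
generally satisfiable. `regmap` therefore reports, per island, the
statistics of its **core** — the longest single qualifying segment inside
the run — which pass the thresholds by construction, while the island
interval is the full covered run, so the covered-base set equals the
exhaustive enumeration for every input. The BED export scores islands by
`round(1000 · obs/exp)` of the core, capped at 1000.

This detector intentionally does not replicate any specific published tool
(each uses a different heuristic); it implements the printed criteria with
a documented, deterministic search.

## Methylation depletion test

The question is whether CpG methylation sites are under-represented in a
candidate intronic segment. Unit of observation: the base pair; success: a
CpG-site start. The 2×2 table (sites / non-site bp × segment / rest of
intron) is tested with Pearson's χ² on 1 df; the Yates continuity
correction is off by default ("chi-square test" in its most common reading)
but exposed. "Rest of the intron" is the intron minus the candidate
segment; segment and background must be disjoint, and a zero marginal is an
error rather than a silent 0/0. An alternative construction (sites vs CpG
dinucleotide count) can be assembled from `cpg_site_positions` directly.
Under a simulated uniform null the test's type-I error at α = 0.05 stays
within 5 % ± 2 points (verified over 2000 replicates in the suite; Yates is
conservative, as expected).

In the integration stage, methylation contributes to region calling as a
*depletion-flagged segment* (only when significant at the configured α,
default 0.01) — never as raw per-CpG rows, which would otherwise overlap
every window.

## Alignment and variant calling

Line haplotypes are homologous end-to-end Sanger-style assemblies, so
variants are called from an optimal **global** alignment, linear gap
penalty (match +1, mismatch −1, gap −2 per base). Traceback ties break
diagonal > up > left, making indel placement deterministic; called indels
are then left-aligned (VCF normalisation) and encoded with one anchor base.
Adjacent mismatch columns stay separate SNPs (no MNP merging), matching
per-variant accounting. For long inputs the DP runs in a band around the
diagonal corridor, auto-sized to `max(64, 32 + |Δlen|)`; this is exact
whenever the optimal path stays inside the band — always the case for the
sparse variation this package targets — and the band is configurable for
diverged inputs. The in-row dependency of the linear-gap recurrence is
vectorised with a running-maximum ladder, so an 11 kb × 11 kb comparison
takes well under a second.

Variant density is reported as span/variant-count (bp per variant), next to
the genome-wide expectation of 39.4 bp per variant, which is shipped as a
documented reference constant (it summarises an external whole-genome
comparison and is not recomputable from a single locus).

## miRNA seed analysis

The seed is miRNA nucleotides 2–8 (a 7-mer; the 2–7 hexamer variant is a
parameter, since conventions differ). A target site is an mRNA-sense window
whose sequence is the reverse complement of the seed; mismatches are
Hamming counts over the seed window, and G:U wobble is *not* a match —
"complete complementarity" is taken literally. Per-tool predictions (TSV
rows of miRNA × tool × mRNA interval) are merged per miRNA, and the best
(minimum-mismatch, then leftmost) seed window within each predicted site is
recorded. A variant inside a seed window is evaluated per allele by
substituting the allele and recounting; differing counts ⇒ seed-disruptive.
Only single-base substitutions are evaluated (an indel in a seed window
would disrupt pairing trivially but changes the window frame; the package
flags it no further).

Site context records distance from the stop codon, distance to the 3′UTR
end, and AU fraction over the site ± 30 nt clipped to the UTR — the
positional/compositional correlates of effective sites. Secondary-structure
accessibility is deliberately out of scope; AU richness is the only context
proxy. Clustering merges predicted target intervals within 10 nt (default;
the synthetic bundle's cluster counts are insensitive to any gap in
[0, 25]), labels clusters by region context, and reports per-cluster miRNA
and tool counts as the multi-tool consensus measure.

## Region calling and variant tiers

For each constrained element the candidate window is the element ± `window`
(default 500 bp — the study-style feature clusters sit within a few hundred
bp of their constrained anchors; configurable). Criterion (b) needs ≥ 2
*distinct feature types* (instances do not accumulate). Qualifying windows
merge within `merge_gap` (default 200 bp) and each merged region re-verifies
both criteria on its final interval. Ordering is 5′→3′ and fully
deterministic; there is no p-value machinery because the rule is
deterministic set logic.

A note on monotonicity: the qualifying-anchor *set* is monotone
non-decreasing in `window`, and the region *count* is monotone
non-increasing in `merge_gap`; the region count is **not** monotone in
`window` (a smaller window can split one merged region into two). The test
suite asserts the forms that actually hold.

Tiers: 1 — constrained overlap or seed-disruptive; 2 — inside a called
region; 3 — overlaps any single feature; 4 — none. Indel overlap uses the
affected reference span (deletion: anchor + deleted bases; insertion:
anchor + following base). The tier is a total function; output sorts by
(tier, position).

## Strain haplotypes

Allele concordance is string-exact after normalisation (trim/upper;
indels compare as anchored, left-aligned ref/alt strings, so representation
cannot break a match). Missing entries are errors naming variant × strain —
the allele table is expected complete. The origin call is the class of the
exact-match strain set when homogeneous (`wild-derived` / `classical`),
`ambiguous` when mixed, `unresolved` when empty; nothing finer (local
ancestry, subspecies mosaics) is attempted.

## The synthetic locus bundle

`regmap.synth` generates an 11 kb plus-strand surrogate contig whose
*annotation topology* matches the study locus: 12 constrained elements
(2 exon-covering, 8 intronic, 1 upstream, 1 spanning the exon-1/intron
boundary — the context of the twelfth element is not pinned down by the
source counts, and the boundary placement is this package's choice), 2 open
chromatin sites, promoter TFBS/histone/RNA-pol clusters, an intronic
feature cluster over a methylation-depleted 400 bp segment, two detectable
promoter-region CpG islands, a 59 bp core promoter overlapping the TSS, a
poly(A) hexamer in the 3′UTR, five planted F/L variants (3 SNPs, 2 indels,
≥ 50 bp apart; the L haplotype is identical to the reference, following the
line-vs-line figure of the source study over its internally inconsistent
line-vs-reference counts), a 14-SNP cross-strain promoter set (1 in a
constrained element, 1 in the core promoter), miRNA predictions clustering
into 4 3′UTR + 1 CDS regions with one synthetic miRNA seed perfectly
complementary to the L allele and mismatching F, and a 17-strain allele
table (Lean ≡ 13 classical strains incl. C57BL/6J; Fat ≡ WSB/EiJ only,
with CAST/EiJ, PWK/PhJ and SPRET/EiJ at 4 of 5).

Sequence composition is engineered for the detectors, not for realism:
background is CpG-free DNA at GC ≈ 0.30 with CpG dinucleotides planted at
controlled densities (≈ 1/28 bp in the non-depleted intron, 2 sites in the
depleted segment — the χ² margin is large by construction), islands are
GC ≈ 0.85 blocks flanked by pure-AT spacers sized so island coverage cannot
bridge between them under the exhaustive segment semantics, and indel
contexts are locally non-repetitive so alignment recovers planted variants
at exactly their planted coordinates. Real-data features the bundle does
**not** emulate: base-level conservation scores, realistic methylation
level distributions, real miRNA sequences or the study's specific miRNA
identities, dbSNP identities (surrogate variants carry `-like` ids), and
genome-scale coordinates (the manifest records an affine map for
paper-style descending display). Passing tests on this bundle therefore
demonstrate correctness of the *integration logic and detectors under the
stated topology*, not performance on raw experimental tracks.

Every topology count is re-derived by the analysis modules at generation
time before files are written; generation is byte-reproducible from its
seed, and the randomised case generators (planted-variant and random-track
cases) carry exact ground truth by construction.

## Numerical and degenerate-input choices

Strict inequalities everywhere thresholds are printed as `>`; empty
intervals are legal (length 0) and classify as their point; all-N
sequences make GC content undefined (error), and a zero chi-square marginal
is an error; merging with negative gap is an error; readers reject
malformed rows with file and line rather than repairing them; methylation
values auto-detect percent vs fraction by `max > 1`. Problem sizes used
throughout the suite (11 kb locus, ≤ 700 bp random alignment cases, ≤ 2 kb
oracle comparisons, 2000-replicate χ² null) were chosen so each check is
exact or statistically well-powered at desk scale.
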