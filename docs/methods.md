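# Methods

## Duplex model

A binding site is modelled as a gapless, antiparallel duplex covering
the full miRNA length: window position *i* (mRNA 5′→3′) opposes the
miRNA base at position *L−i* (5′→3′), with no bulges or internal
loops. Four opposing pairs are scored — G-C (3 hydrogen bonds), A-U
(2), and the non-canonical G-U and A-C (1 each); every other
combination contributes nothing and counts as unpaired. The
inter-nucleotide distances attached to the paired steps (1.02–1.04 nm)
are carried as annotations only; they do not enter the energetics.

Free energy is linear in the bond count, ΔG = −k·Σbonds. The bond
counts are a defined part of the model, but the bonds→kJ/mole
conversion is this package's own calibration: **k = 2.4 kJ/mole per
bond** (configurable via `EnergyModel(k_e=...)`), chosen so that fully
complementary mixed-composition duplexes of 23–25 nt land in the
−140…−155 kJ/mole range typical of the strongest sites in published
MirTarget-style tables (e.g. a perfect 24-mer with 14 G/C scores
−148.8). Nothing threshold-related depends on k: the site filter uses
the ratio ΔG/ΔGm, where ΔGm = −k·(3·n_GC + 2·n_AU) is the energy of
the miRNA against its exact complement, and the k cancels. This is
property-tested across random energy scales.

Two ratio conventions exist because both appear in how such site
tables are described: `bonds` (default) is the energy ratio
100·ΔG/ΔGm; `paired` is the fraction of positions forming any scored
pair, which renders 20 paired positions of a 22-nt miRNA as 91 %. A-C
and G-U count as paired in both modes.

Known limitation: no nearest-neighbour stacking, folding,
target-site accessibility or seed-position weighting. The model is
deliberately the bond-count one; its percentages are not comparable to
RNAhybrid/RNAduplex energies.

## Scanning and coordinates

Every window of miRNA length is scored (vectorised over window starts
with a 4×4 bond lookup; an independent naive per-window loop serves as
the test oracle). Windows with ratio ≥ threshold (default 90 %,
inclusive) are sites. All passing starts are kept — runs of adjacent
starts are real structure (periodic sites produce them) and are only
collapsed for display, where runs of starts closer than the site
length print as "first ÷ last (n)".

Coordinates are 1-based inclusive from the first 5′UTR nucleotide; BED
output converts to 0-based half-open. Region assignment uses the
site's start position only: starts ≤ utr5_len are 5UTR, ≤ utr5_len +
cds_len are CDS, else 3UTR. Start-based assignment is deterministic
for sites that straddle a boundary, at the cost of crediting such a
site entirely to the upstream region.

The maximum start gap used when collapsing same-miRNA runs is not
externally defined; the default (< site length, i.e. the sites
overlap) is a configuration choice exposed as `max_gap`.

## Clusters and compaction

Clusters are connected components of the interval-overlap graph,
computed by a sorted sweep (provably identical for intervals, and
cross-checked against a networkx connected-components oracle).
Touching-but-disjoint intervals do not connect. Span is inclusive
(max end − min start + 1); summed length counts every reported start
once, which is what reproduces the published 272-nt ARID1A 5′UTR sum;
compaction = sum/span ≥ 1, with equality iff members tile the span
without overlap.

Clusters are computed per gene across the whole transcript and
labelled by the region of their span start, so a cluster crossing the
5′UTR/CDS boundary is reported once.

### Consistency audit of published figures

The printed per-site rows for eight published clusters are bundled in
`reference_tables` and re-derived: summed lengths are compared exactly,
spans within ±1 nt (the printed spans themselves disagree with their
own rows by 1 nt in places, e.g. E2F1 35 vs a derived 34), and
compaction within 0.15 allowing the ±1-nt span. Two published
compaction figures — ODC1 5′UTR "10.6×" and MAPK1 CDS "2.9×" — cannot
be derived from their own rows under any counting (the rows give
≈12.5× over 463 nt of sites and ≈3.5× over 94 nt respectively); the
audit flags them and reports the derived values without guessing a
correction. Rows whose starts are printed only as run endpoints
("17 ÷ 23 (3)") cannot be expanded into individual intervals and are
audited from counts alone.

## Associations and suppression

Effective sites satisfy region cutoffs of dG ≤ −130 kJ/mole (5′UTR,
CDS) and dG ≤ −115 kJ/mole (3′UTR); "−130 and higher" is read as
*stronger binding*, i.e. more negative, matching which example sites
pass. A miRNA with effective sites in ≥ 2 genes yields an
alternative-genes record; a gene with ≥ 2 such miRNAs an
alternative-miRNAs record; both deterministically sorted.

Suppression of protein synthesis from the miRNA:mRNA concentration
ratio R uses the occupancy form s(R) = 100·R/(1+R). A literal
proportional reading (s = 100·min(R,1)) would put 10:1 at 100 %, not
the stated ~90 %; the occupancy form reproduces both quoted regimes
(1:10 → 9.1 %, 10:1 → 90.9 %) and satisfies s(R) + s(1/R) = 100
exactly.

Competition inside a cluster combines the two stated advantage factors
— binding strength and concentration — as score = rel_expression ·
|dG| (missing expression = 1, ties by miRNA id). The functional form
is a documented heuristic: only the ranking direction is
substantiated, not any quantitative trade-off.

## Conservation

Ortholog comparison takes pre-aligned regions (equal lengths, `-`
gaps); alignment is an input, not a feature, since the regions
compared are short and nearly identical. Flank identity is
column-wise over configurable 5′/3′ windows (published examples use
10–13 nt; no single default is endorsed). Substitutions are classified
transition/transversion/indel; with a miRNA context, ddG = k·(bonds_ref
− bonds_alt) at the opposing position, and a substitution is
wobble-preserving if the new base still forms a scored pair. The
qualitative claim that such substitutions "practically do not affect"
binding is operationalised and tested as: a wobble-preserving
substitution moves a ≥ 20-nt site's bonds ratio by < 5 percentage
points. Species-specific inserts are runs of columns where exactly one
species has bases and all others gaps.

## Synthetic data

The generator emulates the *shapes* of the real analysis — planted
sites of controlled duplex quality, overlapping-site clusters,
dinucleotide-repeat sites, hub miRNAs with several target genes, and
an inverse trend between expression (NX) and clustering — over uniform
random background. It does not model real transcriptome composition,
codon structure, or conservation beyond substitution injection, so
passing recovery tests demonstrates correctness of the machinery, not
real-world predictive validity.

Site quality is controlled in paired-mode: a plant at target ratio r
embeds the miRNA's reverse complement with k = round(L·(1−r/100))
interior positions (≥ 2 from each end) replaced by bases forming no
scored pair, making the realized paired fraction exactly (L−k)/L.
Overlapping plants overwrite in order — overlap being the object of
study — and every plant's realized paired- and bonds-mode ratios are
recomputed from the final sequence into the truth ledger, so recovery
assertions always test against realized, not requested, quality.

Clusters of overlapping sites of *different* miRNAs are created via
miRNA families: variants derived from a planted miRNA by 1–2
substitutions share its site, the same mechanism by which real family
members (differing by 1–3 nt, ratio 91–95 %) co-occupy sites. A
single substitution costs ≤ 3 bonds, so one-substitution variants
always stay above the 90 % threshold; two-substitution variants may
drop below it, which adds realistic marginal sites. The family bases
and the hub miRNA are sampled with a G+C floor (13–14 of 23–24) so
their near-perfect sites clear the −130/−115 kJ/mole cutoffs
regardless of sampling noise.

The `gastric-like` scenario is a fixed cosmos of 10 genes (each 200 nt
5′UTR + 900 nt CDS + 400 nt 3′UTR) and 39 miRNAs: a ten-plant tiling
cluster in one 5′UTR, 8- and 6-member family clusters, GU- and
CA-dinucleotide-repeat sites (via repeat miRNAs whose complements are
the repeats), a hub miRNA (rel. expression 4.8) planted in six genes,
singleton sites on highly expressed genes (NX 25.2–963.7), and two
80 %-quality decoy plants for negative recovery. Everything is
deterministic under the seed, byte-identical on regeneration.

## Problem sizes and numerics

The randomized verification suites use 1000 random miRNA/transcript
pairs (transcripts ≤ 160 nt — ample for window-level agreement
checks), 20 random energy scales, and 200 random interval sets of up
to 60 intervals; the synthetic scenario is the fixed 10-gene cosmos.
These sizes make the whole suite run in seconds while exercising every
code path at scales where the brute-force oracles are themselves
trivially correct.

Rounding: TSV output rounds ΔG and the ratio to integers (Python
banker's rounding); compaction is reported to one decimal; BED scores
are round(ratio×10). Degenerate inputs: transcripts shorter than a
miRNA scan to an empty result with a warning; a zero-length 5′UTR puts
start 1 in the CDS; empty site lists yield header-only tables.
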