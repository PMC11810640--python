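# Methods

This note documents the models, algorithms, defaults and design choices
behind `dupmode`, and what the synthetic test conditions do and do not
demonstrate.

## Rank space and the classification contract

All positional reasoning happens in *gene-rank space*: on each chromosome,
genes are numbered 0..n−1 by start coordinate (ties broken by end, then
id), over **all** annotated genes, not only paralogs. "Adjacent" means
rank distance exactly 1; "separated by a few genes" means rank distance
2..`proximal_max` (default 10, i.e. at most 9 intervening genes). Strand
is stored but ignored: none of the classification criteria are
strand-sensitive. Coordinates are 1-based inclusive (GFF3 convention);
ranks are 0-based.

Classification is stepwise and exhaustive: every paranome pair receives
exactly one label, tested in the order SD → TD → PD → TRD → DD, so a pair
that is both a collinear anchor and rank-adjacent is segmental. The
schemes nest exactly: binary SSD = standard TD+PD+DD; standard DD =
extended TRD+DD; extended TRD = full rTRD+dTRD. These identities are
asserted in the test suite on identical inputs.

Paranome construction treats the filtered similarity table as the
authority: hits with E-value > 1e-10 (configurable) and self hits are
dropped, reciprocal duplicates collapse to one canonical pair keeping the
best evidence, and optional identity/coverage thresholds are available but
off by default. Top-hit limiting is the similarity searcher's concern and
is not re-applied.

## Collinearity by chaining in rank space

Collinear blocks are found by a longest-chain dynamic program over anchor
points (q_rank, s_rank), per chromosome pair and orientation:

* chains must be strictly monotone on both axes (increasing/increasing for
  parallel, increasing/decreasing for antiparallel);
* consecutive anchors may be at most `max_gap` ranks apart on either axis
  (default 25, measured as rank difference);
* scoring is anchor count only — no distance penalties;
* the best chain (longest; ties: smallest starting (q_rank, s_rank), then
  lexicographically smallest coordinate sequence, parallel before
  antiparallel) is extracted, its points removed, and the search repeats
  until the best chain falls below `min_anchors` (default 5).

The fully specified tie-break makes the algorithm deterministic and lets
the test suite compare it against exhaustive enumeration of every monotone
chain on small instances — the two agree exactly on 200 random instances
of up to 12 points.

Intragenomic runs mirror each unordered pair into both (a,b) and (b,a)
points and exclude a band of half-width `diag_band` (default 1) around the
self-diagonal on a chromosome against itself; without this, tandem arrays
would self-chain into spurious "blocks". Tandem arrays are deliberately
not collapsed before chaining — the band is the simpler mechanism and is
configurable. A pair is segmental if it is an anchor in *any* block.
Interspecies (query vs outgroup) synteny uses the same parameters by
default; a query gene is an *ancestral locus* if it appears as the query
member of at least one anchor in at least one interspecies block.

Open point, decided here: the 70% multi-outgroup rule counts outgroups for
which the exactly-one-ancestral test holds, divided by the **total**
number of outgroups supplied (not only those with usable synteny), and
compares with ≥. A pair with both or neither copy ancestral is not
transposed with respect to that outgroup — transposition requires
directional evidence. "Intronless" is `exon_count == 1` for the
primary (first-listed) transcript, the only annotation-level signal
available. Genes with no paralogs are omitted from gene-level output;
a separate singleton report is available.

## NG86 substitution rates

Only the Nei–Gojobori (1986) codon model is implemented; the API accepts
a model name so other codon models can be added. NG86 was chosen because
it is closed-form and exhaustively checkable: the complete 61×61
sense-codon difference table is compared against an independent
brute-force pathway enumerator in the tests.

Conventions (documented because implementations differ):

* **Sites.** Per codon position, the synonymous fraction is computed over
  the single-base changes that do not create a stop codon (denominator
  renormalized). N = 3·(codons) − S exactly.
* **Differences.** For codons differing at k positions, synonymous and
  nonsynonymous step counts are averaged over all k! orderings;
  orderings passing through a stop codon are excluded and the average is
  renormalized over survivors. If every ordering is blocked, all are
  counted with stop steps treated as nonsynonymous.
* **Correction.** Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is a
  saturation condition — the rate is reported as undefined and the pair
  retained and flagged.
* **Alignment.** Global protein alignment (BLOSUM62, gap open 10 /
  extend 1 — explicit configurable defaults, not claims about any
  reference tool), back-translated to codons; columns containing a gap,
  ambiguous base, or stop in either sequence are removed. Fewer than 10
  alignable codons is an error.

Per-pair computation is pure and results are merged in input order, so
output is bitwise-identical for any worker count.

## Ks mixture modeling

Ks values are filtered to (0.01, 2.0] by default — dropping near-identical
pairs (alleles, assembly artifacts) and saturated distances; both bounds
are configurable and tests that simulate components with mass above 2 use
a wider bound. Mixtures are fitted by EM (tolerance 1e-8 on the
log-likelihood, at most 1000 iterations, 10 restarts from k-means-style
seeds under a fixed default RNG seed of 2024 so published fits reproduce).
The lognormal family is normal EM on log values; component peaks are
reported at the lognormal **mode** exp(μ − σ²), since a peak in a Ks plot
is a density maximum.

Model order is chosen by BIC over a user-supplied candidate list, never
beyond it — mixture models on Ks data overcluster easily, so no automatic
order search is offered. A candidate k whose EM collapses a component or
fails to reach tolerance in every restart is dropped with a warning
(an error is raised only if every candidate fails); over-specified k on
well-separated data typically fails this way, which is the conservative
outcome. The per-iteration log-likelihood trajectory of the winning run is
kept on the model and asserted non-decreasing.

Age boundaries: the intersection of adjacent weighted densities is solved
in closed form (a quadratic on the fitting scale — for lognormals the 1/x
Jacobian cancels, so the same quadratic applies in log space); if no root
lies between the peaks (nested components), the peak midpoint is used with
a warning flag. The mean ± N·SD method (default N = 2) takes one
component's interval on the fitting scale; with k > 2 overlapping
components the interval is per-component with everything else labeled
"outside". Boundary values go to the lower group. Splitting SD pairs by
age group is the supported route to asking which segmental duplicates are
WGD-derived; no automatic WGD verdict is issued because no principled
decision rule exists at this level.

## Synthetic study conditions

The generator defaults define the test conditions: 4 chromosomes × 300
genes, 3 events per mode, 3 outgroup species, segmental blocks of 8 genes,
proximal copies 5 ranks downstream, dispersed copies 15 ranks downstream
(safely past the proximal limit of 10), ancestral exon counts drawn from
2..8 (so the intronless test is unambiguous), and per-pair divergence of
8 synonymous + 2 nonsynonymous changes over 100 codons — a young-duplicate
regime (Ks ≈ 0.1) far from saturation. Outgroups mirror the ancestral
order; the last chromosome carries no outgroup orthologs and hosts the
dispersed events, making "no ancestral locus" true by construction.

Events are placed in disjoint windows separated by a margin of 30 ranks —
deliberately wider than the chaining `max_gap` of 25 — so points from
different events can never join one chain. This is what makes 100%
planted-label recovery a *correctness* assertion rather than a benchmark:
the fixtures are adversarially clean. Consequently, passing tests show the
machinery implements its definitions exactly; they do not estimate
accuracy on real genomes, where tandem arrays, nested events, gene loss,
fractionation and alignment noise all degrade classification. The
generator also has no indel process, no rate heterogeneity across sites
or pairs, and does not simulate WGD-scale genomes.

The codon simulator plants exact change counts (each mutated codon gets a
single base change verified synonymous or nonsynonymous, never creating a
stop), so NG86 counts are recovered exactly (Sd and Nd equal the planted
counts) — used both for oracle tests and for the monotone-divergence
property (mean Ks strictly increases across 2/8/16/24 planted synonymous
changes over 100 replicates).

Mixture-recovery conditions fix component modes 0.2 and 1.5 with weights
0.6/0.4 and log-scale SDs 0.3/0.2 (realistic Ks-peak widths), n = 2000;
the 2-SD age-group coverage check uses a single component (mode 0.6,
log-SD 0.25, n = 2000) where the expected capture is the normal 2-SD mass,
95.45%.

## Numerical and degenerate-input choices

* EM variance floor 1e-10 (absolute) with collapse detection; component
  weights below 1e-8·n abort the restart.
* `jukes_cantor(0) = 0` exactly; Ka/Ks is undefined (None) when Ks = 0.
* Empty inputs: empty hit lists give empty paranomes; empty point sets
  give no blocks; empty frequency tables report zero counts with zero
  fractions.
* GFF3 genes lacking exon records get `exon_count = 1`; both
  exon→mRNA→gene and exon→gene dialects are accepted.
* All TSV/JSON outputs are written deterministically (sorted keys, no
  timestamps), so identical inputs give byte-identical outputs — asserted
  end-to-end in the CLI tests.

## Known limitations

* Similarity-based paranomes cannot distinguish paralogs from xenologs;
  in lineages with frequent horizontal transfer, pre-filter the input
  table with a xenolog-aware tool before classification.
* Collinearity scoring ignores substitution distances; very old, heavily
  fractionated blocks below `min_anchors` anchors are invisible, so some
  true segmental pairs will fall through to the dispersed category.
* Only NG86 ships; for deep divergences (Ks ≳ 2) NG86 underestimates
  rates and the Jukes–Cantor correction saturates.
* The 70%-of-outgroups rule counts all supplied outgroups, including ones
  whose synteny against the query is too weak to be informative; with few
  or distant outgroups the TRD class is conservative.
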