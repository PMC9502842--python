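# Methods

This note documents the models and procedures implemented in `vinascan`, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data validation does and does not demonstrate.

## Profile search and E-values

Homology detection uses position-specific scoring matrices rather than
profile HMMs. A profile is built from a seed alignment: columns with >50%
gaps are dropped and each column scores residue *a* as
`log2((f_a + α·bg_a) / ((1+α)·bg_a))` with observed frequency `f_a`, uniform
background `bg` and pseudocount weight `α = 1` by default. Scores of absent
residues are floored at −10 bits. Proteins are aligned to a profile by
Smith–Waterman with affine gaps (open 11, extend 1, bit-scaled).

Each profile is calibrated by aligning it to i.i.d. uniform-background decoys
(default 500 decoys of 300 aa) and fitting a Gumbel law to the max-scores by
the method of moments (`λ = π/(σ√6)`, `μ = mean − γ/λ`). The E-value of a hit
of score *S* from a query of length *n* is `(n/n₀)·exp(−λ(S−μ))`, i.e. the
Karlin–Altschul form `K·m·n·exp(−λS)` with `K` fixed by the calibration. This
E-value is **per search**: by construction roughly 5% of random proteins
reach E ≤ 0.05 against any one profile. Screens that visit many proteins
therefore additionally require the aligned block to cover a minimum fraction
of the profile (default 0.5): a genuine capsid-protein hit spans most of the
profile, while chance local hits cover ~10–20%. The acceptance rule for a
screen is: E ≤ 0.05, or 0.05 < E ≤ 1 with ≥70% of the profile's ten
highest-information columns carrying a query residue of the consensus
residue's physicochemical class (the mechanical counterpart of manual
curation of borderline candidates), and coverage above the floor. Proteins
whose best hit to a non-capsid conserved-family profile outscores the capsid
hit are rejected as other-domain matches.

Greedy centroid clustering joins a protein (longest first) to the first
centroid with global-alignment identity ≥ 0.5, identity counted as
matches / alignment columns with gap columns in the denominator. Cluster
merging aligns profile pairs locally, scoring a column pair by the dot
product of their rectified (negative entries clipped at zero) log-odds
vectors, background-corrected by subtracting the all-pairs mean + 1 sd of the
score matrix so chance pairings score negative on average; a pair merges when
the aligned footprint covers ≥ 0.5 of the shorter profile and the pair score
is ≥ 0.05 of the smaller self-score, iterated to a fixpoint with re-alignment
after each merge. The interpretation of the clustering threshold as alignment
identity and of "relative similarity" as a self-score ratio were open
choices; both are exposed as parameters.

## Gene calling

A transparent ORF caller stands in for a statistical gene finder: on both
strands, within every stop-bounded frame segment, the longest start(ATG/GTG/
TTG)-to-stop ORF of ≥ 30 codons is reported (translation table 11; alternative
starts translated as Met). Edge segments lacking a start and/or stop yield
flagged partial calls, which by default do count as "genes outside the
boundaries" in prophage classification. ORFs containing N are dropped. The
default minimum of 30 aa keeps the smallest conserved cassette protein
(P7, 40–50 aa) callable while bounding random-ORF noise. External gene maps
can be imported from GFF3 instead.

## Prophage boundaries and classification

±15 kb around the capsid gene is annotated (the window is clipped, not
shifted, at contig ends and flagged). The left boundary is the P16-family
gene nearest the MCP; the right boundary is the nearest P15 — or TR_Z1, the
distinct regulator that occupies the P15 locus in clade A — on the opposite
side. With ≥1 called gene wholly outside the boundary span the record is a
*prophage*, otherwise a *phage*; with neither boundary gene it is
*unclassified*. *Complete* requires both boundary genes (TR_Z1 satisfies the
right boundary and is flagged). Whole-genome comparison of related
(pro)phages chains exact 16-mer seeds along diagonals; blocks ≥ 300 nt with
>90% ungapped identity are shared, and the gaps between consecutive shared
blocks are reported as divergent loci annotated with the gene families they
overlap — the signature of replication-module replacement.

## Host inference

Flank voting: each protein on an MCP contig (genes inside known boundaries
excluded) is searched against a taxon-labeled reference protein set
(BLOSUM62 local alignment, score floor 50; ties to the longer alignment then
the smaller reference id). A hit counts for its taxon and all ancestors; the
assignment is the deepest taxonomy node with ≥ ⌈n/2⌉ of the n hit-bearing
proteins, equally deep qualifying nodes resolving to their lowest common
ancestor. Hitless proteins are excluded from the denominator because they
carry no taxon signal.

CRISPR arrays are detected on contigs > 10 kb by 8-mer recurrence with
periods compatible with repeat 23–47 nt and spacer 26–50 nt, greedy extension
of repeat copies tolerating ≤1 mismatch per copy, then trimming of
non-identical boundary columns (so exactly planted arrays are recovered at
exact coordinates). Spacers are matched to ±8 kb around each MCP on both
strands by 7-mer seeding and ungapped extension under +1/−3 scoring; a match
requires identity ≥ 95% and `E = K·(2·region length)·exp(−λS) ≤ 1e-15` with
λ solved exactly from the Karlin–Altschul identity at uniform background
(λ ≈ 1.374) and K = 0.1 as a conservative prefactor. Under these stated
constants the shortest exact match clearing the threshold against a 16-kb
window is 32 nt. The two host routes are reported side by side with an
agreement flag, never merged.

## Clades and trees

MCPs are dereplicated by greedy centroid clustering at 80% identity
(longest member represents). Alignment is guide-tree progressive: a 3-mer
distance UPGMA guide, pairwise/profile merges scored by expected BLOSUM62
column score with affine gaps. Trees are neighbor joining on Kimura-corrected
p-distances `d = −ln(1 − p − p²/5)` capped at 5.0, with bootstrap support
from column resampling. Distance NJ replaces maximum likelihood deliberately:
the quantity the pipeline needs is clade membership, and NJ is exact on
additive distances and deterministic. Clades A–E are defined by labeled
anchor sequences; a query takes the clade of its nearest anchor by corrected
pairwise distance, exact ties reported as "ambiguous" rather than resolved.
Anchor-nearest assignment can disagree with tree inspection near clade
boundaries; such cases surface as ambiguity, not silent choices.

## Core genome

The presence/absence matrix is binary per genome × family, with all
replication-protein families merged to "replication" and all endolysin
families to "lysin" (these modules undergo non-orthologous displacement, so
family-level absence does not mean functional absence). A family is core iff
strictly more than 50% of the genomes of at least 3 of the 5 clades carry it;
prevalence of exactly one half never qualifies. Highly divergent
(Verrucomicrobia-style) prophages can be excluded by id; short families
(P7, P17, P18) are flagged low-confidence. Multi-copy families count once per
genome.

## Abundance

Reads are classified by exact canonical k-mer (default k = 31) lookup against
flat labeled gene sets; a read takes the label with the most matching k-mers,
with zero-match and tied reads left unclassified, and k-mers shared between
labels removed at indexing. Derived statistics (fold ratios, within-set
percentages, dataset prevalence) are exact rationals, with display rounding
of percentages to integers and of fold ratios ≥1000 to the nearest hundred.
Where a published count table is internally inconsistent (two percentages
printed with swapped denominators), both ratios are reported explicitly.

## Synthetic data: what it emulates and what it does not

The generator plants, per contig: host proteins drawn from a 39-node
reference taxonomy's protein set (species differ by ~3% from genus bases;
flank copies diverge 5% more), an optional integrated cassette in the
canonical gene order (P16, rep, ORF-h, ATPase, P7, MCP, P3, P8, GNAT, P10,
spike, lysin, P17, P18, P15/TR_Z1) with clade-coupled biology (clade A:
alphaproteobacterial hosts, SleB-type hydrolase, TR_Z1; B/C/E:
gammaproteobacterial, P5-type lysin; D: betaproteobacterial, T4lyz-type),
CRISPR arrays on long host-only contigs whose spacers copy protospacers from
±8 kb around a planted MCP, and uniform substitution-error reads. Protein
divergence is substitution-only under a BLOSUM62-exchangeability kernel; a
12-nt palindromic insulator with stops in all six frames brackets every
planted gene so the ORF caller recovers planted intervals exactly. Default
study conditions: 200 contigs, 60% cassette-bearing, divergence 0.1, 4 flank
genes per side, CRISPR probability 0.3 per host contig; the
Verrucomicrobia-style degenerate cassette (no boundary genes, no lysin) is
off by default and opt-in for matrix/exclusion experiments. Clade consensi
sit at 0.25 substitutions/site from the base MCP and human-gut groups at
0.10 from clade A, giving clear but non-trivial clade structure.

Not emulated: indels within genes, realistic gut community composition, GC
skew and codon bias (codons are uniform), assembly artifacts, or HMM-grade
remote homology. Passing tests therefore demonstrate the correctness of the
rules and algorithms under controlled divergence, not sensitivity to real
highly divergent capsid proteins — on real data the profile engine is the
component one would tighten first (or substitute externally computed
searches via the module interfaces).

## Numerical and scale choices

All internal coordinates are 0-based half-open, converted only at I/O
(GFF3 1-based inclusive). Determinism: all reference material derives from
fixed per-name seeds; per-run randomness flows from one config seed;
equal-score ties resolve by smaller E-value, then coverage, then
lexicographic name. Degenerate cases raise (single-sequence profile, zero
decoy score variance) or return empty results (no boundary genes, zero
reads) as contracts specify. Validation problem sizes — 200-contig
simulations, 1,000-decoy calibration checks, 10,000-read abundance runs,
50–100 bootstrap replicates — are chosen so the whole suite runs on a
laptop-class single core in minutes while keeping binomial error bars well
inside the asserted margins.
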