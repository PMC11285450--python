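# Methods

This note records the models, conventions and numerical choices behind
genesieve, and what the synthetic benchmark does and does not demonstrate.

## Translated search

Queries are proteins; targets are raw reads. Each read is translated in all
six frames (frame *f* on strand '−' counts from the 5' end of the reverse
complement, the transeq convention; codons containing N render 'X' so
peptide and nucleotide coordinates stay aligned). The best local alignment
over the six frames is kept as one hit per (query, read) — multi-HSP
reporting is deliberately out of scope, matching a "best-matched read"
analysis style.

Alignment uses BLOSUM62 with affine gap cost 11 + k for a length-k gap,
computed by `Bio.Align.PairwiseAligner` in local mode. Tie-breaking between
co-optimal alignments follows the aligner's deterministic enumeration
order; frame ties break toward lower E-value, then '+' strand, then lower
frame. Percent identity uses the BLAST-tabular convention
(identities / alignment columns incl. gaps), because the downstream 40%/30%
tier cutoffs are defined on that scale.

Significance uses the Karlin–Altschul form `E = K·m·n·exp(−λS)` with
gapped-BLOSUM62 constants K = 0.041, λ = 0.267. The search space is raw
m·n (total query residues × total translated target residues over the whole
read library) with no finite-size edge correction; `search_all` freezes m
and n from the full input before aligning, so serial and threaded runs are
bit-identical. Reporting ceiling E ≤ 10 (BLAST-family default); the tiers
filter far more strictly later. Numeric parity with any external aligner is
a non-goal; `outfmt 6` interface parity is, and externally produced tables
are accepted interchangeably.

## Position profiles, coverage and loss

Per query position the profile keeps the best covering hit's identity
(primary key; ties → lower E-value, longer alignment, lexicographic read
id), that hit's mismatch and gap-open counts, and — tracked independently —
the minimum E-value over all covering hits.

**Coverage definition.** A position counts as covered only where a hit
aligns a residue across it. Columns inside a query gap (a read bridging a
genomic deletion with one affine gap) contribute *no* coverage: a residue
deleted from the genome must not count as recovered, and with span-based
coverage a single junction-spanning read would erase the loss signal of a
large deletion entirely. Hits parsed from external 12-column tables carry
no alignment detail, so their full span counts as covered — the faithful
reading of what a tabular-only pipeline can know.

The summary reports the median best identity over covered positions and the
position-loss percentage separately (imputing identity 0 at uncovered
positions would conflate the two axes); `loss_as_zero` reproduces the
alternative pooled reading. A fully uncovered profile has an undefined
(NaN) median and loss 100.

## Tiers and normalized peptide lengths

Tolerable tier: E < 1e-4 **and** identity > 40. Low tier: 30 < identity
≤ 40 with *no* E-value condition — the asymmetry is intentional and
surprising, so it is encoded exactly (identity exactly 40 falls to low;
exactly 30 is rejected; E exactly 1e-4 fails tolerable). Only the tolerable
tier feeds reconstruction; the low tier is archived.

The matched read region (not the whole read) is extracted, strand-corrected,
translated with stops kept, and scored as
`normalized_len = max stop-free run × identity/100`. Scope is the hit
region because whole-read ORFs would reward off-target sequence; the
`orf_scope="whole_read"` flag tests the other reading. The exact
Mann–Whitney U test (scipy backend; exact whenever both n ≤ 20 and the
pooled sample is tie-free, otherwise normal approximation with continuity
and tie corrections) compares normalized lengths between gene sets,
one-sided ("less") by default since the scientific claim is directional.

## Reconstruction

"Intersection of best hits" is implemented as a union tiling with
per-position best-hit consensus: highest identity, then lowest E-value,
then majority vote over all residue evidence at the position, then the
alphabetically first residue — a declared rule, deterministic and
order-independent. Uncovered positions emit '-' (absence of evidence), not
'X' (unknown residue). `depth` counts hits contributing a residue at the
position, so `residues[p] == '-' ⇔ depth[p] == 0` holds even where a hit's
only evidence is a deletion gap. On gapless hit sets the reconstruction
report's loss equals the profile's loss by construction.

## Presence calls

Four cutoffs place an explicit gray band on the evidence axes: present iff
median ≥ 70 and loss ≤ 20; likely_lost iff median < 60 or loss > 30;
ambiguous between. An undefined median (zero coverage) collapses to
likely_lost. The call is monotone in both axes by construction.

## Region identity and neighbor joining

Region windows (α1/α2 helices, β-sheets of the antigen-presenting part) are
extracted on reference coordinates from equal-length, column-aligned
sequences; full progressive MSA is out of scope and externally aligned
FASTA is accepted. Shipped region coordinate files are placeholders to be
edited per query — the exact helix/sheet boundaries are a user input, not a
package constant. Pairwise identity excludes columns where either sequence
has '-' (a comparison with no gap-free shared columns is an error);
distance is 100 − identity with no evolutionary-model correction, matching
the descriptive use of the trees.

Neighbor joining is the standard Saitou–Nei agglomeration with two fixed
conventions: equally minimal Q pairs join in lexicographic label order
(internal nodes inherit the smaller child label), and a negative limb
length is clamped to zero with the deficit shifted to the sister branch.
On additive matrices NJ recovers topology and branch lengths exactly
(verified to 1e-9 against patristic distances recomputed with dendropy).

## Structure confidence

pLDDT is read from the CA atom's B-factor per residue (mean of the
residue's atoms, with a warning, when CA is absent); PAE from the published
AlphaFold JSON layouts. A region is unreliable iff its aggregate pLDDT is
strictly below 70 — boundary 70.0 counts reliable; the aggregator is the
mean by default with minimum available, since a visual "yellow or orange
region" rule does not pin down the aggregation. PAE is summarized as the
mean over both orientations per region pair.

## Synthetic data

The generator emulates exactly the signal the pipeline searches for: a CDS
back-translated from the query (uniform synonymous codon choice — codon
usage bias would add realism without touching any tested property),
amino-acid divergence applied as nonsynonymous swaps at the stated rate
(controlling directly the identity the thresholds act on), pseudogenization
events (stop gains, ±1–2-base frameshifts, segmental deletions; coordinates
on the undisturbed CDS, events disjoint, structural edits applied 3'→5'),
random flanks, and uniformly placed substitution-error reads on both
strands with a Poisson read count of mean coverage·L/read_length. All
randomness derives from the scenario seed; outputs are byte-identical
across regenerations.

Default study conditions: 120-residue query, 150-nt flanks, coverage 20×,
read length 100 nt, base error 0.2%. The benchmark suite pairs ten intact
scenarios (divergence 0–0.10) with ten pseudogenized ones (segmental
deletions of 40–100% of the CDS, several compounded with premature stops or
frameshifts). These sizes keep a full benchmark run in seconds while giving
every statistic enough reads (~120–140 per scenario) to be stable.

What the simulator does **not** model: real genome background (flanks are
random DNA), paired ends, long reads, indel sequencing errors (available
behind the event machinery but off by default), intron/exon structure, and
codon usage. Passing the benchmark therefore demonstrates correctness of
the machinery under controlled conditions, not performance on real
libraries with repetitive backgrounds or cross-matching paralogs.

## Known limitations

* Reads spanning a deletion junction can extend their local alignment a few
  residues into the deleted segment as mismatches (cheaper than opening a
  gap), occasionally inflating coverage there; at the default conditions
  this keeps deletion-loss estimates within a few percentage points of
  truth but can exceed 5 points for unlucky read layouts.
* The E-value model uses raw m·n with literature constants rather than
  per-matrix estimated parameters; E-values are comparable within a run,
  not calibrated against any external tool.
* External `outfmt 6` hits lack frame and alignment detail; their spans are
  trusted as residue evidence and their frame recorded as 1.
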