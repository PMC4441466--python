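# Methods

## The inference problem

A pooled RNA-seq library from a phloem-feeding insect contains transcripts
from two genomes: the host insect and its obligate bacterial endosymbiont.
Given (i) the assembled transcripts, (ii) the symbiont reference sequences
and (iii) EC-number annotations, the package infers, for each amino-acid
biosynthesis pathway, which partner expresses each enzymatic step. The key
biological signal is *complementation*: the symbiont encodes most essential
amino-acid pathways but lacks the terminal aminotransferases EC 2.6.1.1
(phenylalanine) and EC 2.6.1.42 (valine/leucine/isoleucine), which the host
supplies, implying transport of the immediate precursor across the
host–symbiont boundary ("hand-off").

## Origin binning

A transcript is called **symbiont** iff its best local alignment against the
symbiont reference set has percent identity strictly above a threshold
(default 90, the blastn-style rule for symbiont unitig identification) *and*
an aligned query span of at least `min_alignment_span_bp` (default 50 bp).
Everything else — including transcripts matching nothing — is called
**host**. The span guard is our addition: without it a 10 bp perfect hit
would misattribute a host transcript; it is configurable because the
underlying rule is stated without one.

"Similarity" is implemented as percent identity over aligned columns
(gap columns included, N never counted as a match) of the optimal local
alignment, the natural reading of a blastn identity threshold for
nucleotide data.

### Alignment engine

Alignment is optimal Smith–Waterman with affine gaps (default +1/−2 match /
mismatch, −5 open, −2 extend; a gap of length k scores `open+(k−1)·extend`),
computed by Biopython's `PairwiseAligner` in local mode with a custom ACGTN
matrix in which N mismatches everything. Both query strands are tried; ties
prefer plus. Ties across reference sequences break by higher query coverage,
then lexicographically smallest subject id, so calls are deterministic.
Scores are computed without traceback first and the traceback is run only
for top-scoring subjects. The test suite verifies score equality against an
exhaustive Gotoh dynamic-programming oracle on hundreds of random pairs.

### E-values

Hit significance uses the Karlin–Altschul expectation
`E = K·m·n·exp(−λS)`. λ is solved exactly from
`Σᵢⱼ pᵢpⱼ·exp(λ·sᵢⱼ) = 1` by Brent root-finding at the configured base
frequencies (uniform by default); for +1/−2 this gives λ ≈ 1.3327, matching
the closed form `−ln((√21−3)/6)`. The prefactor K is a configurable constant
(default 0.1) rather than the evaluated ungapped series: every use of E here
(a ≤10⁻⁶ screen on near-identical hits, linearity and monotonicity
properties) is insensitive to K's exact value, and gapped corrections are
out of scope at desk scale.

## Expression

Reads are assigned to the best-aligning transcript when at least 95% of the
read bases match in the best local alignment; reads tying across several
transcripts are split equally (fractions tracked as exact rationals, so
assigned + unassigned mass equals the read count exactly). Exact substring
occurrences (either strand) short-circuit the aligner; otherwise candidate
transcripts are pre-selected by exact occurrence of one of three read
chunks (a read with fewer substitution errors than chunks always has an
error-free chunk, so its source is always a candidate), falling back to a
full scan when no chunk matches.

RPKM uses the pooled library as denominator — host and symbiont reads
together — because the emulated experiment sequences one pooled mRNA sample
and states no per-organism normalization; `denominator="per_origin"` is
available for the alternative. Percentage reporting rounds half-up (to 0 or
1 decimals) to reproduce printed summary figures deterministically. The
high-expression flag is strict: RPKM > 50.

qPCR relative expression is plain ΔΔCt
(`fold = 2^−((Ct_t,s − Ct_r,s) − (Ct_t,c − Ct_r,c))`) with no
amplification-efficiency correction.

## Pathway model and status classes

Pathways are **linearized**: the steps of each amino-acid group are the
printed enzyme rows of the packaged pathway table in order, the last row
being the terminal step; the true KEGG topology (branches, cycles) is
deliberately collapsed, because the inference consumes only per-EC
presence/absence and the identity of the last step. The three branched-chain
amino acids form one group (one KEGG map, one shared terminal step).
A step may carry an EC set (isofunctional enzymes, e.g. the two homocysteine
methyltransferases of methionine); it is satisfied by any member, and a step
satisfied by different partners via different ECs has provider **both**.

Provider of a step = the set of partners owning at least one annotated
transcript with RPKM above `detection_floor_rpkm` (default 0: any expressed
transcript counts, mirroring presence-based transcriptome evidence).
Status classes:

* `incomplete` — some step has provider `none`;
* `host_complete` — every step in {host, both}, at least one host;
* `symbiont_complete` — symmetric;
* `chimeric_complete` — otherwise (including all-`both`).

Hand-offs are emitted for every adjacent step pair whose providers are
single and different; `both` and `none` break no hand-off. The classifier is
verified exhaustively against a brute-force restatement of the rule over all
4^k provider vectors for k ≤ 4.

## Synthetic communities

The generator emulates the two-organism structure the analysis assumes:

* symbiont transcripts are copies of reference segments substituted at
  `symbiont_divergence` (default 0.02 — within-species blastn-detectable
  similarity); host transcripts are substituted at `host_divergence`
  (default 0.30 — deep divergence, below any 90% identity call);
* substitutions always change the base, so expected column identity to the
  template is exactly `1 − rate`; indels are off by default to keep identity
  analytically predictable;
* EC annotations follow the expected partner split by default:
  non-essential-pathway ECs on host transcripts, essential-pathway ECs on
  symbiont transcripts except EC 2.6.1.1 and 2.6.1.42 (host);
* abundance weights default to uniform in [0.5, 2]: moderate dispersion with
  no undetectably expressed gene, as in the expression table being emulated
  (every listed enzyme is detected in exactly one partner);
* reads of 100 bp (the emulated platform's read length) are drawn with
  probability ∝ weight × length, uniform start, per-base substitution errors
  (default 0.01), forward strand, single-ended; paired data would be counted
  as two independent reads anyway.

Default community size is 25 host + 25 symbiont transcripts of 300–900 bp;
validation runs use 10 seeds × 4000 reads, sizes at which the optimal
aligner is exact and fast and binomial sampling error is small relative to
the planted effects. What passing these tests shows: the chain recovers
planted origins, abundances and pathway structure under substitution-only
divergence and error. What it does not show: robustness to indels, chimeric
assemblies, paralogy, uneven coverage, or real annotation noise.

## Numerical choices and degenerate inputs

* Identity/coverage are 0 when the best local score is 0 (no alignment).
* `-` cells in the packaged expression table mean *not detected in that
  partner* and are parsed as missing, never zero — zero would corrupt the
  provider logic.
* Report row order is deterministic (non-essential first, then amino-acid
  name); transcript input order never affects any status or hand-off.
* Empty FASTA → empty collection; empty pathway list → empty report;
  zero requested reads → empty read set. Malformed files raise parse errors
  naming the line number.

## Known limitations

* The E-value K prefactor is nominal (see above).
* Pathway completeness is relative to the packaged step lists; pathways
  whose full KEGG step set is longer than the printed evidence can classify
  as complete here while being biologically unresolved.
* The ≥95% read-identity assignment is exact for substitution-only reads;
  the chunk-seeded candidate search can in principle miss a best-scoring
  transcript that shares no exact ~33-mer with the read, a case not reachable
  at the simulated error rates.
* No detection-limit model for stage-specific (e.g. egg) non-detection; no
  quality-score error model, PCR duplicates or coverage bias.
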