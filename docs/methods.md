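# Methods

This note documents the models and procedures implemented in `ampliphase`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the simulation-based tests do and do not show.

## Alignment contract

All sequence comparison goes through `ampliphase.alignment`. Two modes are
exposed: *local* (Smith–Waterman) and *semi-global* (the query is consumed
end to end, both target ends are clipped for free). Scoring is an affine
scheme where a gap of length L costs `gap_open + L·gap_extend`; the default
is match +1, mismatch −2, gap open −2, gap extend −1 — deliberately
edit-distance-like, because nanopore errors are indel-dominated and a mild
mismatch/gap asymmetry keeps local alignments compact without fragmenting
them. The unit-cost scheme (match 0, mismatch −1, gap −1), under which
score maximisation is exactly Levenshtein-distance minimisation, has a
bit-parallel backend (edlib) for semi-global mode; it is the default in the
two throughput-critical loops (template-grid scoring and barcode-probe
matching), which would otherwise dominate runtime by two orders of
magnitude. Every alignment is attempted on both query strands and the
better orientation reported; ambiguous bases (N) mismatch everything,
including another N. Both modes and both schemes are property-tested
against an independent quadratic-time Gotoh implementation on hundreds of
random string pairs.

Mapping quality is `min(60, round(60·(best − second)/best))` over the
candidate scores, 0 on ties or non-positive best, with a lone candidate
competing against an implicit 0. This keeps the three properties the
pipeline relies on — Phred-like scale, monotonicity in the score gap,
and 0 on total ambiguity — without reproducing any particular mapper's
estimator.

## Barcode design

Candidates are rejection-sampled uniformly and kept when they contain no
homopolymer longer than 2 bp, no tandem repeat, and 40–60% GC. "Tandem
repeat" is operationalised as: a unit of length 1–8 repeated at least three
consecutive times spanning at least 9 bp. This forbids the PCR-slippage-
prone structures the rule exists for while leaving the 16-bp sequence space
usable. Reference screening removes any candidate whose best local
alignment to either strand of the reference reaches 80% identical bases
(`n_matches / barcode_length ≥ 0.80`), so every retained barcode has
strictly fewer than 80% identical bases anywhere in the reference; with
threshold 1.0 the screen removes exactly the (reverse-complement-)verbatim
substrings.

Pairwise compatibility replaces a blastn all-vs-all with a deterministic
seed-and-extend predicate: two barcodes "align" when they share an exact
word of the configured size (default 6, both strands) that extends to a
positive-scoring local alignment. Under a positive match score this reduces
to shared-word existence, which is what the word-size parameter of the
original heuristic controls; the extension step is kept for non-default
schemes. The compatibility graph connects non-aligning pairs, and a barcode
set is a clique: exact maximal-clique enumeration up to 200 nodes, a greedy
high-degree heuristic above that (flagged non-exact in the result). Clique
results are verified pairwise against the graph before being returned and
are tested against exhaustive subset enumeration on random graphs of ≤ 15
nodes.

## Demultiplexing

A read of a dual-barcoded amplicon is assigned by matching, at each read
end, every candidate probe `barcode + 256-bp anchor` semi-globally within a
window of probe length + 100 bp. Because all probes of one side share the
anchor, raw probe scores differ only marginally between candidates; the
score fed to the MAPQ formula is therefore the barcode's *marginal*
contribution — probe score minus the anchor-only baseline in the same
window, clamped at zero. An exact barcode thus scores its full length,
competitors designed to be non-aligning score ≈ 0, and the MAPQ formula
saturates; a 1-bp-different competitor produces a small gap and a MAPQ far
below threshold, which is the desired behaviour for ambiguous pairs.
Candidates whose marginal score falls below 75% of the barcode length are
dropped outright: with the default error model the true barcode loses only
1–2 edit units (expected marginal ≈ 14/16 or 30/32), while an unrelated
sequence scores near the random-alignment floor, so the cut cleanly rejects
reads whose barcode region is junk without touching genuine matches.

An assignment requires both sides to pass MAPQ ≥ 30 in the *same* read
orientation (forward barcode at the 5′ end of that orientation) and the
(forward, backward) pair to exist in the sample manifest; everything else
lands in `unassigned` with the failure reason tallied. Equal-score
candidate ties give MAPQ 0 and are discarded. Read conservation (every
input read in exactly one output bin) and threshold monotonicity are
tested, as is a < 1% cross-sample misassignment bound on a simulated noisy
pool with 32-bp barcodes.

## Joint repeat quantification

Per read and per motif, bounds are estimated first. The *upper* bound is
`ceil(aligned decoy span / motif length)` from the best local alignment of
the read against a decoy of 1,000 tandem motif copies — alignment
tolerance lets flanking sequence bleed into the decoy footprint, which can
only inflate this bound. The decoy is truncated to twice the read length
(in units) when shorter than 1,000 units; a local alignment cannot cover
more decoy than that, so the result is unchanged while the quadratic cost
drops. The *lower* bound is the longest run of exact consecutive motif
copies anywhere in the read (all phases scanned; tested against a
brute-force scanner). Before grid refinement the bounds get a safety
margin, L ← max(0, L−1) and U ← U+3: basecall deletions can deflate the
alignment-derived upper bound, and a few extra grid rows are cheap
insurance that the argmax lies inside the searched box.

Refinement scores the full template `left_flank + motif1^m + interstitial +
motif2^n + right_flank` for every (m, n) in the bounds box against the read
(unit-cost semi-global; template consumed, read ends free) and returns the
argmax with deterministic tie-breaking (smallest m, then smallest n — ties
occur only in degenerate loci). Read orientation is resolved once per read
from flank alignments instead of per template; templates are cached across
the reads of a sample. The argmax is property-tested against exhaustive
DP-oracle re-scoring of the whole grid on a small synthetic locus, and the
generative identity (error-free reads return their true (m, n) exactly)
holds by construction.

Reads whose bounds are (0, 0) for both motifs — i.e. nothing in the read
aligns to either decoy in either orientation — are reported as
unquantified and excluded from phasing. Alignable junk still receives a
(typically extreme) profile and is removed downstream by the outlier and
equi-probability filters.

## Allele phasing

Profiles pass a single per-dimension 3-standard-deviation outlier filter
(population SD; a zero-spread dimension removes nothing). The number of
mixture components N ∈ {1, 2} — a diploid has at most two alleles — is
selected by BIC after adding uniform U(−0.5, 0.5) jitter independently to
every m and n: repeat counts are integers, and on rounded data the
2-component fit can reach unbounded likelihood, which the jitter prevents.
One jittered dataset is shared by both candidate fits. With fewer than 11
profiles (the parameter count of the 2-component full-covariance mixture)
N = 1 is returned with a warning.

The final mixture is fitted on the original integer profiles
(full covariance, EM with k-means initialisation, 10 restarts, covariance
regularised at 1e−6). Reads go to their maximum-responsibility component;
a read whose squared Mahalanobis distance to its component exceeds the
χ² 0.95 quantile with 2 df (≈ 5.991) lies outside the component's 95%
equi-probability surface and is discarded. Two safeguards collapse a
2-component fit back to one: fitted means closer than one repeat unit in
both dimensions (integer counts cannot distinguish such alleles; this is
what protects deep homozygous samples, where BIC otherwise happily splits
the jitter/rounding noise itself because the likelihood gain grows with
read count while the penalty grows only logarithmically), and a component
that captures no reads. QC fails when one allele is detected or an allele
keeps fewer than `min_reads` (default 50) reads.

Each group's reported genotype is the mode of its assigned integer (m, n)
pairs — estimates must be integers, and the mode is robust to the skewed
±1 noise of the per-read estimates — with lexicographic tie-breaking. With
two groups, the one with the larger motif1 estimate is labelled *expanded*
when it reaches the expansion threshold (default 36 units; 34/43 therefore
phases as intermediate-normal/expanded, and 20/30 as normal/normal).

## SNP calling, PAM effects, haplotypes

Allele read pools are optionally down-sampled to 200× (seeded shuffle,
maximal subset under the coverage cap) and piled up against the allele's
template via the unit-cost semi-global path; columns opposite read gaps
contribute nothing and read insertions are skipped. A substitution is
called where depth ≥ 50 and the modal non-reference base reaches 70% of
aligned bases — within a phased haploid pool a true variant is essentially
homozygous, while random errors stay near the per-base error rate, so the
0.7 fraction separates them by a wide margin at ≥ 50×. Indels are not
called: long-read indel errors concentrate in homopolymers and amplicon-
scale indel calling would need a dedicated error model. Calls are written
as minimal VCF v4.2 with ALLELE/DP/AF in INFO.

PAM gain/loss classification evaluates every candidate motif placement
(strand, start, length) overlapping the SNP independently for each enzyme:
a placement is a *gain* when the alternative sequence matches a
high-efficiency PAM there while the reference sequence matches none of
that enzyme's PAMs (high or low efficiency) at the same placement, and a
*loss* symmetrically. Placement-level evaluation is what makes an SNP
inside a run of overlapping PAMs (e.g. a G-rich patch with several NGG
frames, or a poly-T stretch under TTTN) report each affected frame rather
than vetoing itself. Gain and loss are antisymmetric under swapping the
alleles (property-tested). The shipped enzyme table — SpCas9 {NGG, NAG},
SpCas9_VQR {NGAN, NGNG}, SpCas9_EQR {NGAG, TGCG}, SpCas9_VRER {GGCG},
SaCas9 {NNGRRT}, AsCpf1 {TTTN}, all high-efficiency — is calibrated to a
curated 19-SNP classification table used as a regression fixture.
Depletion-screen efficiency measurements are per literal sequence, so
entries are IUPAC-generalised only where the screen supports the family
and literal otherwise; users with their own depletion data can supply a
replacement TSV, including low-efficiency motifs, which participate in the
exclusivity clause but never qualify a gain or loss themselves.

Haplotypes are indicator vectors over a fixed SNP panel, one per chromosome
class (normal/expanded) per QC-passed individual; frequencies are
normalised within each class and the all-reference vector is named Hap1.
Editability follows directly from phased genotypes: an individual is
editable via an SNP iff heterozygous with the intact (loss-type) or created
(gain-type) high-efficiency PAM exclusively on the expanded chromosome;
the report carries per-SNP and any-SNP fractions plus the four-way
alt-allele distribution (both / expanded only / normal only / neither).

## Simulator

`simulate_pool` emits reads of the form `forward barcode + forward anchor +
allele sequence + revcomp(backward barcode + backward anchor)`, where the
allele sequence is the locus template with planted substitutions
(restricted to the non-repeat regions, where real targetable SNPs lie).
The error process is one left-to-right pass of independent per-base events:
substitution to a uniform different base, insertion of a uniform base after
the position, deletion of the position. Defaults are 1% substitution, 3%
insertion, 3% deletion — a plausible residual error profile for
super-accuracy-basecalled nanopore amplicon reads, and deliberately
indel-heavy to stress the quantifier — with 100 reads per allele (the QC
floor is 50; real runs typically exceed 200×) and a 0.5 strand-flip
probability. Qualities are a constant Phred symbol consistent with the
total error rate; no stage consumes them. Everything is seeded and
byte-reproducible, and a ground-truth manifest accompanies every pool.

What the simulator does *not* emulate: homopolymer-length-dependent error
rates, signal-level artefacts, chimeric/truncated reads, PCR stutter
(somatic-style repeat-length mosaicism), or coverage imbalance beyond the
configured per-allele counts. Passing the recovery tests therefore shows
the pipeline is correct under a fair independent-error model of the right
magnitude, not that real-data accuracy will match the simulated figures;
PCR stutter in particular would widen the per-read (m, n) distribution in
ways only real amplicon data can calibrate.

## Accuracy study and problem sizes

`scripts/acceptance.py` simulates 60 diploid samples (normal CAG uniform in
15–30, expanded uniform in 40–60, CCG in {7, 10}, 100 reads per allele,
1%/3%/3% errors), runs quantification and phasing per sample, and reports
the percentage of samples with the expanded allele within ±1 unit and the
normal allele exactly recovered. Samples failing QC count as misses — an
accuracy claim should not get credit for refusing to answer. Per-sample
seeds are spawned from the master seed, so any sample can be reproduced in
isolation. The synthetic locus uses 100-bp flanks (the template factory
enforces ≥ 50 bp for reliable anchoring); the full study runs in a few
minutes on one CPU, with per-read cost dominated by the decoy alignments
and the ~100–400-cell template grid.

## Known limitations

- Deep homozygous samples are phased as one allele (QC fail) by the
  separation-collapse rule; true alleles differing by a single repeat unit
  at similar CCG are likewise not separable by design.
- The mixture is capped at N = 2; somatic repeat instability or mosaicism
  would need larger N and a different selection rule.
- The SNP caller handles substitutions only, and its positions are
  template-relative; lifting to genomic coordinates is the caller's
  responsibility via the locus coordinate field.
- The barcode clique search is exact only up to 200 candidates; above
  that the greedy result may be sub-optimal (flagged in the output).
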