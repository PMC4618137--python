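# Methods

## Problem and model

A sequenced small-RNA library is a mixture of mature miRNA reads drawn
from a reference set of hairpin precursors, each read possibly modified
relative to the canonical (miRBase-style) mature sequence by four
mechanisms: templated end variation (isomiRs — alternative Drosha/Dicer
cleavage shifts the 5′ and/or 3′ end by a few bases), 3′ non-templated
additions (NTA — mostly adenylation and uridylation by nucleotidyl
transferases), A-to-I editing (adenosine deamination, read as G by the
sequencer) and sequencing error. Identical reads are collapsed to *tags*
(sequence + count) before mapping; all statistics that speak about
"reads" are count-weighted tag statistics.

The mapping model is substitution-only: there are no indels, no 5′
additions and no 5′ trimming (a 5′ difference counts as an inner
mismatch). These restrictions mirror the biology being modelled — NTA is
a 3′ phenomenon — and keep the search exactly enumerable.

## The stratified search, precisely

For a tag of length L and ladder (m₀=0 < m₁ < … ), steps are tried in
order; within step s, trim iterations i = 0, 1, … up to
min(L − min_length, max_trim). The query is the tag minus its last i
bases. A placement with ≤ mₛ substitutions is *admissible* when it lies
on the mature's sense strand and both its 5′ and 3′ ends are within
±window of some canonical mature's ends. The first (step, iteration)
producing an admissible hit decides the tag:

* among admissible hits, those with the fewest actual mismatches are
  preferred (a local extension of the global perfect-match preference;
  ties at equal mismatch count proceed to the ambiguity rule);
* if all surviving hits belong to one multi-locus group the tag is
  assigned to it; otherwise it is discarded as ambiguous. In genome mode
  the rule is stricter: every minimal-mismatch hit anywhere in the
  genome must correspond to a locus of that same miRNA, so a tag that
  also matches a non-miRNA locus equally well is discarded. In precursor
  mode, hits outside every canonical window are ignored rather than
  counted against the tag.
* a tag admissible for two different matures on the same precursor is
  ambiguous by the same rule (distinct matures never share a group).

Unmapped tags carry a reason code reflecting the best evidence seen
across the whole search: `ambiguous` > `out_of_window` >
`antisense_only` > `no_hit`.

Defaults: precursor mode ladder (0,1,2), min_length 18 nt, window 5 nt,
no trim cap; genome mode ladder (0,1) with a 2-base trim cap. Offsets are
always expressed in the mature 5′→3′ frame, so isomiR classes are
strand-invariant for minus-strand genomic loci.

The matcher itself is a vectorised sliding-window Hamming scan (numpy)
with an exact substring fast path for the zero-mismatch step; references
(precursor sets or the small genomes used here) are tiny, so exhaustive
placement enumeration is affordable and is verified against an
independent pure-Python brute-force oracle in the test suite.

### One consequence worth knowing

Because perfect matches are preferred across trim iterations *within* a
step before the next mismatch allowance is tried, a read whose only error
sits in its last few templated bases is mapped at step 0 with those bases
trimmed (appearing as a short spurious NTA and a 3′-shortened isomiR)
rather than at step 1 full-length. At the default 0.1 % error rate this
reroutes roughly 0.4 % of reads and is the dominant residual bias in
isomiR/NTA estimates; it is well inside the binomial tolerances the
recovery tests use.

## Quantification

Counts are tallied per multi-locus group (one row per mature, however
many loci it has), and CPM uses library sizes from the ingest totals —
the number of individual clean reads per sample — never column sums. The
`per_locus_rows` switch reproduces per-locus double counting for
comparison with pipelines that have that defect. The expression filter
keeps miRNAs at ≥ 1 CPM in ≥ 3 samples (both configurable; with fewer
than 3 samples the threshold clamps to the sample count). Optional TMM
normalisation factors (30 % M-trim, 5 % A-trim, reference = sample whose
upper CPM quartile is closest to the mean, precision weights) rescale
effective library sizes and are cross-checked against edgeR's
`calcNormFactors` in the tests. Paired log2 fold changes use a 0.5 CPM
pseudocount and average per-patient log-ratios; formal
negative-binomial DE testing is delegated to external tools via the
exported count + design tables.

## Isoform analytics

* **isomiR identity** is the (offset5, offset3) pair; the NTA suffix is
  deliberately excluded (reads differing only in their 3′ tail are one
  isomiR; `include_nta` restores suffix-inclusive accounting for
  cross-tool comparison).
* **Presence** requires ≥ 1 % of the mature's mapped reads in a sample
  (boundary inclusive); distribution statistics require ≥ 100 mapped
  reads per mature per sample. Per-sample isomiR counts are averaged per
  tissue type, binned, and compared across tissues with a chi-squared
  independence test (skipped for a single tissue).
* **Classes**: canonical / 3′ end-site / 5′ start-site / both-sites from
  the offset signs. In `normal_dominant` mode the canonical is redefined
  per mature as the isomiR with the highest mean contribution across
  normal samples (ties break toward the annotated canonical, then the
  smallest |offset5| + |offset3|) and offsets are re-expressed against it
  before classing. For cohort summaries, "selected" matures are those
  with ≥ 100 reads in **every** sample; the quantifier is configurable
  since either reading of the coverage floor is defensible.
* **NTA**: suffix classes are adenylated (A-only), uridylated (T-only,
  i.e. U in RNA space), other-single and mixed — exhaustive and mutually
  exclusive over non-empty suffixes. Global per-addition contributions
  are averaged over mature × sample observations with ≥ 100 mapped
  reads; additions averaging below 1 % pool into "other". Screens report
  matures above a 30 % adenylation/uridylation level, the overlap of the
  top-adenylated and top-uridylated lists, and tissue-mean shifts
  ≥ 20 percentage points.
* **Arm ratios** (precursors annotated with both arms only): 5p/3p CPM
  ratio per tissue from tissue-mean CPMs, in two modes — all isoforms,
  or canonical-only reads ((0,0) offsets; NTA does not disqualify).
  Between-tissue ratio folds > 1.5 or < 0.66 are screen hits; a change
  of dominant arm among hits is an inversion. The ratio-of-means (rather
  than mean-of-ratios) aggregation was chosen for stability at low
  counts and is configurable at the call site by passing per-sample
  frames.

## Editing calls

The pileup runs over canonical mature coordinates only, built from the
aligner's inner-mismatch records, so trimmed NTA bases can never enter it
by construction. A read covers position p iff offset5 ≤ p < L + offset3.
Sites are called per (mature, position, alt) when any sample reaches
coverage ≥ 100, frequency ≥ 5 % and alt count ≥ 10, with the last 2 nt
before the mature 3′ end excluded as residual trimming territory. These
thresholds are this package's own defaults — chosen to be conservative
against error-rate backgrounds an order of magnitude higher than typical
— and all are configurable. A→G calls on the sense strand are flagged as
candidate A-to-I events; seed-region positions (2–8, 1-based) are marked
because editing there can retarget the miRNA. Cross-tissue comparison
pools counts per tissue and reports deltas with a descriptive
two-proportion z-test. Known-SNP positions can be excluded via an
optional list; resolving SNP vs editing properly requires matched
genomic DNA, which is out of scope.

## The simulator

The generator emulates a matched-cohort collapsed-tag study: 36 precursor
loci (including 2 two-locus multi-locus families and 2 near-paralog
pairs at Hamming distance 2), 9 samples (3 patients × normal / tumor /
metastasis), 200k reads per sample, per-mature log-normal expression
(σ = 1 natural-log units) shared across samples, 6 matures with ±1.5
log2 tumor/metastasis effects, a 9-component isomiR offset distribution
(68 % canonical, 3′ variation dominant, small 5′ and both-sites
components — all four classes occur, as they do in real data), A/U-
composed NTA rates totalling 15 %, one planted A→G editing site at 30 %
frequency, and a 0.1 % uniform substitution error applied last. Reads
are generated cell-wise (mature × offsets × editing × suffix) with
multinomial draws, so the emitted libraries and the truth tables agree
exactly by construction; only errored reads are materialised
individually. Everything is a function of one seed.

Two identifiability devices make truth exact rather than approximate:
mature 3′ tails and the following template bases are drawn from {C, G}
while NTA suffixes are {A, T}-composed, so an addition can never mimic a
templated extension; and non-family matures are kept at Hamming
distance ≥ 4 so cross-mapping occurs only where planted. Real data offer
no such guarantees — templated A/U runs downstream of a mature make
NTA/isomiR attribution genuinely ambiguous there — so passing recovery
tests demonstrate correctness of the machinery, not that real-data NTA
fractions are unbiased. Other simplifications: no hairpin
thermodynamics, no indel errors, no ligation bias, no non-miRNA RNA
background (on real libraries the mapped fraction is accordingly much
lower than the simulator's ~100 %).

`expected_mapping_fractions` gives a closed-form per-step expectation:
after maximal admissible trimming a read's unavoidable mismatch count is
a constant (untrimmable suffix bases + covered editing) plus a
Binomial(L_prefix, e) error count, and the read maps at the first step
whose allowance covers it. The form is exact under the C/G-guard design
except that it ignores errors creating better hits elsewhere (negligible
at the distances enforced).

## Numerical and procedural choices

* Coordinates are 0-based half-open internally; GFF3 I/O is 1-based
  inclusive. U→T normalisation at load; one DNA alphabet throughout.
* Ties among equally good admissible hits resolve deterministically
  (smallest |offset5| + |offset3|, then mature id); all outputs are
  sorted, so identical inputs give byte-identical outputs.
* Threshold comparisons at stated boundaries are inclusive (≥ 1 CPM,
  ≥ 1 % presence, ≥ 5 % frequency, ≥ 20 % shifts).
* Degenerate inputs: empty libraries produce empty tables, not errors;
  a reference without a single mature annotation is rejected; ambiguous
  arm annotations (no 5p/3p designation) are rejected rather than
  guessed; patients missing a contrast tissue are dropped from that
  contrast with a log notice.
* Test problem sizes: unit tests simulate at 5k–20k reads per sample;
  the end-to-end recovery tests use the full 200k × 9 design, chosen so
  binomial 3σ tolerances are decisive for every well-expressed mature.

## Known limitations

* Substitution-only alignment: an indel-bearing read is unmapped.
* 5′ NTA, 5′ trimming and internal (non-3′) tailing are not modelled.
* The editing caller reports candidate sites; without genomic DNA it
  cannot distinguish high-frequency SNPs from editing.
* TMM factors assume most miRNAs are not differentially expressed, as
  the method requires; with only dozens of simulated matures the factors
  are noisier than on genome-scale references.
* Genome mode expects the reference genome to fit comfortably in memory
  with a quadratic-ish scan; it is intended for precursor-locus-scale
  genomes and spot checks, not a drop-in replacement for an indexed
  aligner on a full mammalian genome.
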