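# Methods

`pollenid` implements molecular identification of mixed pollen samples by DNA
barcoding: each pollen mixture yields a clone library of ~100 individually
sequenced barcode amplicons per plastid marker (the coding *rbcL* gene and the
non-coding *trnH-psbA* spacer); reads are dereplicated into MOTUs, each MOTU
is assigned a taxon by percent identity against a curated local reference
database, the two markers are reconciled into one taxon list per sample, and
per-site sequencing depth is assessed with individual-based rarefaction.

## Alignment and percent identity

Every query/reference comparison is a full semi-global alignment
(Needleman–Wunsch with free end gaps) under match +1, mismatch −1, gap open
−2, gap extend −2. The engine is Biopython's `PairwiseAligner` with a custom
substitution matrix over the IUPAC alphabet: two symbols match when their base
sets intersect (`N` matches everything); a gap never matches. Percent identity
is

    identity = matches / (alignment columns − end-gap columns)

so an exact but end-trimmed clone still scores 100%, while internal gap
columns count against identity. Traceback is deterministic (the aligner's
first optimal alignment); the suite checks the optimal *score* against an
independent plain dynamic program and a full enumeration of alignments on
short sequences, and checks that the reported column statistics describe a
valid optimal alignment — tie-breaking among co-optimal alignments is the
library's and is not asserted.

**A caveat that shapes the design**: with free end gaps, the optimal alignment
of two *unrelated* sequences is essentially their best-scoring overlap
segment, whose identity can approach 100% over a dozen positions. Overlap
identity is therefore meaningless as a divergence measure for distant pairs.
`match_reference` consequently computes the exact alignment identity only for
references whose cheap full-length screen (position-by-position identity for
equal lengths, a global edit-distance bound otherwise) reaches within 5
percentage points of the best screen *and* at least 94%; all other references
report their screening identity, which is the identity of a valid full-length
alignment. This keeps distant hits on the full-length scale, guards the 99%
rule against spurious short-overlap identities, and reduces the per-query
cost from ~700 full dynamic programs to a handful. References below 94% can
never influence a call made at a 99% threshold.

## MOTU clustering

Reads of one (site, date, marker) library are grouped by single-linkage
clustering: two reads link when their optimal alignment has at most
`max_mismatches` (default 2) mismatch columns and no internal gap run longer
than `max_mismatches`. The 2-mismatch radius matches the observed error
footprint of cloning + Sanger sequencing of single inserts — one or two
substitutions per clone. Single linkage admits chains beyond the radius; that
is accepted, documented behaviour. The pair order is canonicalized before
aligning because co-optimal tracebacks can differ between (a, b) and (b, a)
and the linkage relation must be symmetric.

Equal-length reads of ≥ 100 nt are linked by Hamming distance directly: for
length-conserved, substitution-only amplicons the optimal alignment cannot
pay the internal-gap cost, so the ungapped mismatch count is the alignment
mismatch count. Short or unequal-length reads always take the full
alignment-based test (the path the brute-force clustering oracle exercises).

The representative of a MOTU is its most frequent exact sequence
(lexicographically smallest on ties); the consensus is a column-wise majority
vote, with ties broken toward the representative's base so the result is
independent of member order. Unequal-length members are aligned to the
representative and voted per representative position; insertions relative to
the representative, and columns where a deletion wins the vote, are dropped.

## Taxonomic assignment and the 99% rule

Each MOTU consensus receives one hit per (species, marker) reference, sorted
by identity (descending) then species name. Calls, at a configurable
threshold of 99% compared on *unrounded* identities (the one-decimal
rendering is display only):

* no qualifying hit → **unidentifiable** (and flagged for escalation to an
  external sequence collection — the escalation itself is out of scope);
* qualifying hits name one species → **species** call;
* several species, one genus → **genus** call (`"Genus sp."`);
* several genera → **ambiguous**, full hit list retained.

The default species rule requires uniqueness among *all* qualifying hits: a
congener at 99.6% beside a 100% hit demotes the call to genus level, which is
exactly how *rbcL* behaves for closely related species. An alternative
`top_hit` rule (species call whenever the top identity stratum is a single
species) is available behind a flag because the stricter convention is a
choice, not a law.

`reconcile_markers` combines the two markers' calls for one putative taxon:
the more specific call wins (species > genus > ambiguous > unidentifiable);
at equal specificity the precedence marker wins (default *trnH-psbA*, the
more variable spacer, which in practice resolves the *rbcL* congeneric ties).
Species-level disagreement between markers is flagged as a conflict, never
silently merged. At the pipeline level, single-marker calls are paired across
markers by genus compatibility (identical call names preferred), unpaired
calls pass through, and rows resolving to the same name are merged with clone
counts summed per marker.

## Community tables

Per-sample taxon lists become a long-format clone-count table and a
taxa × (site, sampling) presence/absence matrix: a taxon is present in a cell
when either marker detected it there; unidentifiable MOTUs are excluded from
community tables (but not from rarefaction, below). Summary statistics —
per-site richness, shared taxa between site pairs, persistence classes
(detected in exactly 1/2/3 samplings), status counts and distinct-genus
counts (with `"Genus sp."` collapsing to its genus) — are recomputed from the
matrix, never stored. The package ships a transcription of the published
52-taxon exemplar matrix (3 sites × 3 samplings, with per-taxon flowering
period, pollination mode and common/rare/alien status) as a plain TSV
fixture; the suite pins all its headline statistics. Where the source's
running text and its matrix disagree (three counts), the matrix is treated as
the record: the fixture preserves it bit-for-bit and the disagreeing prose
numbers are not asserted anywhere.

## Rarefaction

Species-accumulation curves are individual-based (x-axis: clones sequenced),
pooling a site's three collection dates per marker. The permutation estimator
averages the running distinct-taxon count over 1,000 (configurable) uniform
random orderings; the analytic estimator is the exact hypergeometric
expectation

    E[S_n] = Σ_i (1 − C(N−N_i, n) / C(N, n)),   N = Σ N_i,

with binomial coefficients in log space (depths of several hundred clones
must not overflow). The permutation mean converges to the closed form; at
1,000 iterations its per-depth Monte-Carlo standard error is ≈ 0.03 taxa on
a 300-clone pool, so the maximum deviation over all depths is typically
0.03–0.07. Unidentifiable MOTUs count as distinct pseudo-taxa by default
(their clones are real sequences of real, unnamed taxa; dropping them biases
the curve downward); a flag disables this.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, so the
whole pipeline is testable without any sequence download:

* **Reference database** — per-genus ancestor sequences are independent
  uniform random DNA (inter-genus divergence ≈ 0.75 substitutions/site, far
  above any congener); the first species of each genus *is* the ancestor and
  each further congener mutates it at a per-species divergence drawn
  uniformly from 0.002–0.01 substitutions/site. Two congeners therefore sit
  in the 99–100% identity band, reproducing the congeneric ties the
  assignment rule must handle. Marker lengths default to 627 nt (*rbcL*) and
  634 nt (*trnH-psbA*), the maximum aligned lengths of the emulated study.
  Status labels are drawn as common 0.80 / rare 0.17 / alien 0.03, the
  approximate proportions among the 52 identified taxa of the exemplar
  matrix.
* **Clone libraries** — clone species are a multinomial draw from the mixture
  composition; each clone copies its template with *exactly* k substitutions,
  k uniform on 1–2, positions uniform without replacement, substituted base
  always different. Both markers of a sample share one composition (both are
  amplified from the same pooled DNA).
* **Contaminants** — an optional per-clone probability replaces the clone
  with a random sequence accepted only if its best identity against the
  entire database is below 99%; by construction these MOTUs must come out
  unidentifiable, which makes the threshold itself the tested surface.
* **Study scenario** — the default scenario mirrors the emulated sampling
  design: a 693-species database over 450 genera (so roughly a third of
  species have a ≥99% congener), three sites whose 260-species floras overlap
  by ~80 species, three dates, per-sample mixtures of 12–18 species with
  flat-Dirichlet abundances (giving the skewed clone counts real mixtures
  show), 100 clones per library.

What the generator does **not** emulate — and what passing tests therefore do
not show about real data: PCR amplification bias between taxa, chimera
formation, indel sequencing errors, pseudogene capture, and error *hotspots*.
Real clone errors recur at shared positions, so real libraries dereplicate to
roughly one MOTU per taxon; with uniform error positions, two 2-error clones
of one template are usually 3–4 mismatches apart, so simulated libraries
split a taxon across several MOTUs. Downstream results are unaffected —
split MOTUs receive the same call and are merged at reconciliation — but
simulated MOTU counts exceed real ones. The multinomial clone model also
means clone counts track mixture proportions only in expectation; nothing is
claimed about the (unknown) mapping from true pollen abundance to clone
abundance.

## Determinism, sizes, degenerate inputs

All randomness flows through explicitly seeded NumPy generators (library
seeds are drawn from the scenario generator's own stream); identical
configuration and seeds give byte-identical outputs, which the CLI tests
assert. Every run logs the tool version, a configuration hash and per-stage
record counts. Degenerate inputs are hard validation errors: empty sequences,
non-IUPAC characters (reported with position), mixed (site, date, marker)
libraries, unsorted hit lists, duplicate (species, marker) references, empty
MOTUs, empty label lists. The *rbcL* pseudogene screen takes the reading
frame as an explicit parameter (the amplicon's frame depends on the primer
pair and is not knowable from the sequence alone) and checks frame-shift
before internal stops; it is undefined for the non-coding spacer.

Problem sizes used by the test suite and acceptance script: the full
recovery scenario runs at the emulated study's own scale (693 species ×
2 markers, 18 libraries × 100 clones); oracle-equivalence checks use 200
random pairs of ≤ 12 nt and 50 read sets of ≤ 30 reads; the rarefaction
agreement check uses a fixed 10-species/300-clone profile, and the asymptote
check uses three simulated sites with ≤ 15-species floras (~300 pooled clones
each), the regime in which near-complete coverage by 80% depth is the
expected behaviour.

## Known limitations

* Identity of distant references is reported on the full-length screening
  scale, not as optimal-alignment overlap identity (deliberate; see above).
* Genus-level pairing across markers is a heuristic; a pathological sample
  with two MOTUs of the same genus per marker can pair them arbitrarily
  (counts still conserved, names still correct).
* No abundance-aware denoising, chimera detection, or probabilistic taxonomy;
  the method is a faithful implementation of threshold-based best-match
  identification, with its known sensitivity to reference completeness.
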