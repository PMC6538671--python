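# Methods

This note documents the models and procedures implemented in `edmark`, the
choices made where the design was genuinely open, and what the synthetic
fixtures do and do not demonstrate.

## The marker model

The toolkit targets the standard architecture of group-specific
metabarcoding assays on degraded environmental DNA: a short variable core
(< 200 bp, because eDNA fragments are short) flanked by two conserved
20–30 bp primer-binding regions shared by every member of the target group.
A usable marker therefore has to satisfy three requirements at once — a
short amplicon, enough interspecific differences in the core, and
near-perfect conservation of both flanks across all target templates.

### Conservation profiling and window search

`conservation_profile` counts A/C/G/T/gap/ambiguous per alignment column;
the columnwise consensus is the majority base, with count ties broken
toward the base giving fewer total mismatches and then alphabetically
(for equal counts these coincide, so the rule is deterministic).

`find_conserved_windows` reports every *maximal* gap-free window of width
20–30 whose consensus differs from each template by at most
`max_mm_per_template` (default 1, i.e. one real-world primer–template
mismatch is tolerated per template). Because any sub-window of a passing
window also passes, non-maximal windows carry no information and are
suppressed; this keeps the candidate list finite and makes planted-fixture
recovery a sharp, exact test. Windows containing any gap column are
excluded — primers cannot span indels. Degenerate reference bases count as
a match only when the consensus base is inside their IUPAC set (the
conservative call).

`enumerate_candidates` pairs windows whose between-window core is, per
template, non-empty and shorter than `max_core_len` (default 200 bp —
applied to the inter-primer core, not the full fragment, which is what the
length of a sequenced amplicon insert actually is) and whose minimum
pairwise core difference count reaches `min_core_diffs`. The default of 5
encodes "every pair of target species differs at five or more sites", the
empirical floor for species-level assignment with a two-substitution
identity tolerance. Core differences are counted with pairwise deletion
(columns gapped in either sequence are skipped).

### Primer thermodynamics

G/C content is fractional over IUPAC codes (S → 1, R/Y/K/M → ½, N → ½,
B/V → ⅔, D/H → ⅓).

Melting temperature uses the nearest-neighbor model
`Tm = ΔH / (ΔS + R ln(Ct/4)) − 273.15 + 16.6·log10[Na+]` with SantaLucia
1998 unified stacking parameters and terminal initiation. The remaining
free quantities — a duplex-initiation term (ΔH₀ = −0.6 kcal/mol,
ΔS₀ = +9.0 cal/mol/K), 50 mM monovalent salt and 100 nM total strand
concentration — were calibrated once against the OligoCalc-style web
calculator convention used when the reference eel ATP6 pair was designed
(reported 55.7 °C and 55.9 °C for the 22-mer/26-mer pair; the frozen
default reproduces both within 0.1 °C) and are not meant to be tuned per
run. Breslauer 1986 stacking is available as an alternative table but
cannot reproduce that calibration pair under any initiation/salt variant we
tried (it spreads the two primers by ≈ 5 °C), which is why it is not the
default. `nn_tm` is exactly symmetric under reverse complement, as a duplex
quantity must be.

### Binding sites and mismatch classes

A forward primer anneals to the minus strand, so its bases pair with the
complement of the plus-strand base; a reverse primer anneals to the plus
strand and pairs with it directly. Each mismatch is classified by the
unordered duplex pair the primer base forms with the template base on the
annealed strand: T·G (the thermodynamically mild wobble), A·C (the next
mildest), or other. This matters for PCR-bias reasoning: templates whose
only mismatch is a wobble amplify nearly as well as perfect matches.

In-silico PCR (`extract_amplicons`) requires exactly one compatible
forward/reverse site pair per template with a core under `max_core_len`;
zero or multiple products are reported per template, never raised.

## Taxonomic resolution

Pairwise distances support complete deletion (drop every column gapped in
*any* sequence — the convention for the K2P/NJ analysis) and pairwise
deletion. K2P is `−½ ln(1−2P−Q) − ¼ ln(1−2Q)`; saturation (non-positive
logarithm argument) raises a `SaturationError` rather than being clamped,
because a silently clamped distance would poison a tree.

Neighbor joining is the classical Saitou–Nei algorithm, deterministic:
Q-criterion ties are broken by the lexicographically smallest label pair
(internal nodes inherit the smallest leaf label beneath them), and negative
branch lengths are clamped to zero with the deficit moved to the sister
branch so path lengths through the join are preserved. On additive
matrices NJ is provably consistent; the test suite checks exact topology
recovery against an independent bipartition oracle on random trees
(n ≤ 12) and cross-checks real matrices against scikit-bio's independent
implementation.

Bootstrap support resamples alignment columns with replacement
(seed-controlled), rebuilds the NJ tree per replicate, and annotates each
internal edge of the full-data tree with the percentage of replicates
containing the same bipartition (branch lengths ignored). The conventional
depth for this marker's reference analysis is 300 replicates; tests use
smaller depths (30–100) purely as a size choice, since the statistic is a
percentage whose properties do not change.

The ambiguity report flags sequence pairs whose nucleotide-difference count
is at or below the assignment tolerance (default 2, matching the 98.5 %
identity threshold over a 167 bp amplicon). This is the quantitative form
of the subspecies problem: subspecies pairs separated by only 1–3 sites sit
at or near the tolerance, so reads from one can be attributed to the other
and such calls should be treated as unresolved.

## The read pipeline

Per sample, in order, with all thresholds living in one `PipelineConfig`:

1. **Tail truncation** at the first base with Phred < 20, then **merging**
   over the best ungapped overlap of R1 with the reverse-complemented R2
   (offset maximizing matches; ties to the longer overlap). Rejected when
   the overlap is < 16 bp or disagrees at > 5 positions. Agreeing overlap
   positions take quality `max(Q1, Q2)`; conflicts take the higher-quality
   base with quality `|Q1 − Q2|` (forward base on an exact tie). The
   merger assumes the insert is at least as long as each read, which holds
   for this marker (215 bp fragment, 2 × 150 bp reads, ≈ 85 bp overlap).
2. **Primer stripping** from both ends, each primer within 2 mismatches by
   default — sequencing errors in the primer region should not discard a
   read, and the in-silico panel shows up to one genuine primer–template
   mismatch is expected.
3. **Expected-error filtering.** The criterion is a maximum expected-error
   *rate*: EE = Σ 10^(−Q/10) over the core, kept iff EE/length ≤ 1 % and
   length ≥ 120 bp. The boundary stays on the accept side (an all-Q20 read
   has rate exactly 1 % and is kept); a small epsilon guards the floating
   comparison.
4. **Dereplication** into exact-sequence uniques, sorted by descending
   abundance then lexicographically; abundances ≤ 3 (singletons through
   tripletons) are removed, the standard guard against error inflation.
5. **Denoising** with the UNOISE abundance-skew rule: visiting uniques in
   descending abundance, a unique merges into the closest centroid whose
   skew `abund(u)/abund(c)` is at most `1/2^(αd+1)` (α = 2, the command's
   documented default; d = Levenshtein distance, computed with edlib under
   a derived distance bound). The skew test uses the centroid's own
   pre-pooling abundance; pooled abundances are reported. Chimera
   detection is deliberately out of scope (a hook exists for a future
   bimera test).
6. **Assignment** at ≥ 98.5 % global identity, where identity is
   matches / alignment columns with terminal gap runs excluded and internal
   gaps included — this reproduces the "two substitutions over 167 bp ⇒
   98.80 % ≥ 98.5, three ⇒ 98.20 % < 98.5" arithmetic while still
   penalizing indels. Ties at the top score are assigned only when all
   tied references share one taxon; otherwise the centroid is counted
   unassigned-ambiguous rather than split — forcing a choice between
   subspecies the marker cannot separate would manufacture certainty.

Per-stage read tallies are kept for every sample (kept + rejected always
reconciles with input), and any read surviving to the final table in a
declared blank marks the whole run contaminated (`assign` CLI exit code 2).

## Synthetic data: what it shows and what it does not

`plant_marker_alignment` builds alignments in which the planted flanks are
provably the only maximal conserved windows (rotating-base background,
hyper-variable guard columns at the core edges, adjacent "killer" column
pairs every ≤ 10 core columns, and ≥ 7 single-mismatch templates per flank
pinning the boundaries — with a perfectly conserved flank, one-column
extensions can never exceed a 1-mismatch budget, so exact boundary recovery
would be ill-posed). The core's minimum pairwise difference count equals
`min_core_diffs` exactly, realized by the designated "subspecies" pair;
every other template carries two extra private sites. Defaults mirror the
reference marker's architecture: 19 templates, 25 bp flanks, a 167 bp
core, minimum difference 5, and a forward flank with 12 single-mismatch
templates split 10 T·G / 2 A·C. The reverse flank plants 7 synthetic
wobbles — a deliberate departure from the reference assay's mismatch-free
reverse primer, required for exact boundary recovery; mismatch-free
primers are exercised separately in the primer-evaluation tests.

`simulate_mock_reads` draws 2 × 150 bp pairs from the amplicon fragment
with per-base qualities from a clipped normal (mean Q35, sd 3, clipped to
[2, 40] — typical of a 2 × 150 bp benchtop run) and substitution errors at
the Phred-implied probability. `error_free=True` suppresses substitutions
and floors qualities at Q30, so qualities remain consistent with the
absence of errors and quality-gated stages cannot stochastically drop
reads the error model promised to keep. PCR bias is one per-mismatch
efficiency multiplier applied to read counts before rounding — a
qualitative stand-in for template competition, not a cycle-resolved model.
The simulator is substitution-only (no indels, no chimeras, no
index-hopping, no trained instrument error profiles); passing tests
therefore demonstrate the pipeline's arithmetic and thresholds, not its
behavior on real flowcell artifacts.

## Problem sizes and determinism

Fixtures use the default 19-template panel; property checks run across 20
generator seeds, merge-versus-oracle comparisons on 150–1000 random pairs,
NJ recovery on 12–15 random additive trees up to 12 taxa, and mock
communities of 3–5 taxa at 20–250 reads each — sizes chosen to make every
check exact or near-exact while keeping the suite fast. All generators and
the bootstrap are pure functions of their seed; CLI outputs embed the tool
version, config hash and seed, and identical inputs reproduce outputs
byte-for-byte.

## Known limitations

* The merger does not handle inserts shorter than the read length
  (read-through into adapters); this marker's fragment makes that case
  unreachable, but other assays may need pre-trimming.
* Identity uses edlib's unit-cost alignment, so a 1 bp indel costs one
  column — indel-rich markers may want affine costs.
* The K2P/NJ stack is for quick resolution screening, not phylogenetics;
  no rate heterogeneity, no likelihood models.
* Taxonomic assignment is purely identity-based against a curated amplicon
  reference; it inherits every gap in that reference.
* The planted-alignment exactness argument assumes the scanner's default
  window range (20–30) and a 1-mismatch budget; other settings fall back
  to ordinary (non-exact) recovery behavior.
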