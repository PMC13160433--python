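# Methods

This note documents the models, algorithms, parameters and design choices
behind the package, what the synthetic data does and does not emulate, and
the known limitations.

## Variant ingestion and consequence calling

Coordinates are 1-based throughout: VCF positions, closed CDS intervals, and
protein residue numbers (matching `C282Y`-style mutation nomenclature).
A transcript model carries its CDS intervals in transcription (5'→3') order
— ascending genomic coordinates on the plus strand, descending on minus —
plus the spliced coding sequence (stop codon included) and its translation.

A genomic SNV is located inside the CDS by interval walking; minus-strand
alleles are complemented; the containing codon is re-translated with the
standard genetic code and the class read off the amino-acid pair: missense,
synonymous, nonsense (stop gained), stop-lost, or non-coding for anything
outside the CDS (UTRs, introns and intergenic positions are deliberately not
distinguished — full consequence calling is the job of a dedicated
annotator, and an import path for pre-annotated tables is provided instead).
A disagreement between the VCF reference allele and the CDS base is a hard
error carrying both bases: silent reference drift is the classic failure
mode of coordinate pipelines.

Only missense calls proceed to structural analysis; nonsense and stop-lost
variants change protein length and are out of scope for the per-residue
calculations downstream.

The independent check for this stage is a brute-force oracle that shares no
code with the caller: it rebuilds the entire mutated CDS string, translates
the original and mutant sequences end to end, and diffs the peptides.

### Case file dialect

The pipeline-ready case file is a comma-delimited table with fixed column
order `gene, transcript_id, protein_id, aa_change, inheritance, provenance`.
The final column records whether a variant arrived as genomic (VCF) or
proteomic (CSV) input and makes the write→parse round trip exact; parsers
accept files without it. Amino-acid changes are accepted compact (`C282Y`)
or split across `ref_aa`/`position`/`alt_aa` columns. Malformed rows are
excluded and reported with their row number; they never abort the case.

## Cross-reference reconciliation and isoforms

Transcript and curated protein sequences drift apart between database
releases, so every transcript↔protein pair is classified by a total,
four-way rule: no curated sequence → `NO_XREF`; identical → `PERFECT`;
equal length with any mismatch → `LEN_MATCH_SEQ_MISMATCH`; otherwise
`LEN_MISMATCH`. Only `PERFECT` transcripts proceed;
`LEN_MATCH_SEQ_MISMATCH` transcripts are rejected outright even when the
mismatch is far from the variant — a conservative choice, since a
mismatched record gives no guarantee about which database side the
structure catalogs were aligned to.

Any rejection produces a machine-readable halt report grouped by reason,
and the run stops (non-zero exit) so the user can rework coordinates or
patch the case file by hand; `--force` proceeds with the retained subset.
Stopping is the default because silently dropping a clinical candidate
variant is worse than a failed run.

Retained variants are expanded across the protein's curated splice
isoforms. The canonical isoform is the unsuffixed identifier ("-1" is
treated as its synonym — a curation convention, recorded here as an
assumption). Position mapping uses a gap-free prefix check first (identical
peptides through the variant position map identity), then global pairwise
alignment (match +1, mismatch −1, gap open −5, gap extend −0.5: splice
isoforms differ by exon-sized blocks, so expensive opens with cheap
extensions recover indels as single gaps). A position maps only if its
alignment column pairs the reference residue with an identical residue;
isoforms where the residue is absent are skipped with a logged reason, and
a variant mapping to no isoform feeds the halt protocol. Every expanded
variant is finally re-validated against the target peptide
(`peptide[pos] == ref_aa`) before any downstream work.

## Structure selection

Candidates come from a catalog table (source, experimental method,
resolution or 0–100 model confidence, oligomeric state, coordinate file)
plus an alignment catalog of explicit gap-free segments mapping transcript
positions to (chain, residue number) — residue numbering in coordinate
files is never trusted as a sequence coordinate. AlphaFold-style models
cover canonical sequences only and are attached only to canonical-isoform
queries. Missing coordinate files drop the candidate with a warning rather
than failing the case.

Each candidate's marginal utility with respect to the already-selected set
is

    u(c | S) = w_cov·[c covers the variant and S does not yet]
             + w_div·[c's method not yet in S]
             + w_qual·q(c)
             + w_mult·[oligomeric state > 1]
             − w_red·J(c, S)

with defaults w_cov = 4, w_div = 1, w_qual = 1, w_mult = 1, w_red = 2
(config-exposed). Quality q maps resolution ≤ 2 Å → 1 linearly down to
≥ 4 Å → 0 for experimental structures, and confidence/100 for models.
J(c, S) is the Jaccard overlap between c's covered positions and the union
covered by S. Two deliberate refinements:

- the **coverage term is marginal** (paid only while the selection does not
  yet cover the variant), so an exact duplicate of a selected structure
  scores ≤ 0 and is never added;
- the **redundancy penalty is Jaccard**, not the fraction of the
  candidate's own positions; the symmetric form makes the summed utility of
  a set nearly independent of addition order (a small structure nested in a
  large one is penalised equally whichever came first), which is what lets
  a greedy selector track the exhaustive optimum.

Selection is greedy: repeatedly add the highest positive-marginal candidate
(ties: better quality, then source preference PDB > AlphaFold > SwissModel
> ModBase, then structure id) until `max_structures` (default 6, chosen to
keep reports readable) or nothing positive remains. If any candidate covers
the variant the final set is guaranteed to contain a covering structure:
when the greedy loop never picked one, the best covering candidate is
forced in, replacing the weakest pick if the budget is full. The
self-validation harness scores the greedy set and every enumerable subset
(≤ 8 candidates, k ≤ 3) by the identical best-order total and checks the
classical (1 − 1/e) factor; across thousands of random instances the worst
observed ratio is ≈ 0.84.

Apo/holo distinction and multi-conformation handling are explicitly not
modeled.

## Spatial clustering statistic

For a query residue q on one chain, with pathogenic site set P and benign
set B (Cα coordinates, duplicates collapsed, the query's own residue
excluded from both — leave-one-out):

    score(q) = (1/|P|) Σ_{s∈P} K(d(q,s)) − (1/|B|) Σ_{s∈B} K(d(q,s))

K(d) = 1/(1+d) by default (d in Å); an exponential kernel exp(−d/scale) is
available in config. The reciprocal kernel was fixed so that the worked
examples are exact rational numbers; it is bounded on (0, 1], monotone
decreasing, and heavy-tailed enough that distant sites still contribute.
The score is antisymmetric under label swap and invariant under rigid
motion by construction; both are asserted to machine precision.

Significance uses a permutation null: both site sets are relocated onto
residues drawn uniformly **without replacement** from the mapped residues
of the chain, the score recomputed per draw, and

    p = (1 + #{score_null ≥ score_obs}) / (1 + n_perm)

(+1 convention, so p is never 0; n_perm default 199, minimum 99). The
query's own residue is removed from the relocation pool as well as from the
observed sets, so observed and null scores are exchangeable with identical
site counts — under a uniform null p is then exactly uniform on its grid,
which the calibration harness confirms (2,000 simulated cases: type-I error
at α = 0.05 inside the exact binomial 99% interval; KS statistic below the
1% critical value). Uniform relocation (not a sequence shuffle) is the
chosen null because the question is "does the variant sit in this spatial
constellation better than a randomly placed site set would".

Degenerate inputs are handled explicitly: a missing label class yields a
one-sided result with the p-value suppressed; too few eligible residues
(≤ |P| + |B|) skips the test with the reason recorded. On multimers the
query is evaluated per protomer chain (labeled sites are replicated across
copies by the catalog layer) and the minimum-p chain is reported with
per-chain detail retained; no multiple-testing correction is applied across
structures — reports show every per-structure p with its n_perm, leaving
reliability judgment to the reader.

A per-residue score track (every mapped residue as query, leave-one-out) is
emitted as CSV for backbone colouring; when excluding a residue would empty
a label class (it carries the only site of that label), that residue is
scored without the exclusion so the track stays total.

Power behaviour: with planted clusters, the median p of cluster-member
queries falls as the benign set moves away, saturating at the permutation
floor 1/(n_perm + 1) once the separation clearly exceeds the cluster
radius; the test grid (separations 0, 8, 30 Å at radius 8 Å) therefore
asserts a monotone non-increasing curve with a strict overall drop.

## Planning, execution and status protocol

One case run lives under `VUStruct/<case>_<GUID>/` (GUID per run, so
concurrent cases never collide), with per-job directories
`transcript / structure-and-variant / calculation / {work,status}`; path
components are sanitized to `[A-Za-z0-9._+-]` with collisions detected,
never silently merged. The workplan is a flat CSV (one row per job:
identity, variant, structure, JSON parameters, relative paths) containing
no scheduler- or host-specific fields — planning is architecture-
independent by construction, and a thin executor contract replaces cluster
submission: an executor receives (row, workdir, context) and writes a
`result.csv` of `metric,value,qualifier` rows.

Job state is communicated through append-only, timestamped transition files
(`planned → submitted → running → complete | failed`), one JSON file per
transition; backward transitions are rejected at write time and torn files
are skipped at read time, so a monitor can always reconstruct the latest
state and full history from a directory listing. An executor exception
fails only its own job, with the message captured in the status detail. For
byte-reproducible runs a logical clock (monotone counter timestamps) can be
injected; the wall clock is the default.

The two-part stability protocol's expensive "relax" half is cached in a
keyed repository — (structure, chain, protocol tag, parameter hash) — with
completion markers; corrupt entries are recomputed and overwritten with a
warning.

Stub executors for the licensed / ML calculators emit pseudo-scores derived
from a SHA-256 hash of the job identity and the run seed, mapped into
documented ranges (ΔΔG-like −1…7; interface / PTM / digenic probabilities
0…1). They are not predictions — they exist so that end-to-end runs are
deterministic and exercise the full result-aggregation plumbing. Digenic
jobs pair genes (one job per unordered pair of distinct case genes), not
individual variants.

## Precomputed scores

Substitution-level tables key on (protein, position, alt residue);
constraint tables on (protein, position). Lookup is exact: absent keys come
back absent, never imputed, and there is no canonical-isoform fallback by
default (transcriptome-wide precomputations cover canonical sequences
only); an explicit flag enables the fallback with provenance marked.
Duplicate keys are load-time errors naming the key.

## Reporting

Because several structures — and, for genomic input, several isoforms —
contribute per variant, every metric is presented as a [min, max] range
with the count of contributing results and the count of missing ones
(failed or silent jobs are counted, never coerced to zero; per-chain
p-value details and cache bookkeeping rows are excluded from summary
ranges). Summary rows group by the originating case variant (the canonical
variant's identity is carried through isoform expansion), with child rows
ordered canonical first, then "-N" numerically. Rendering is a pure
function of the files on disk: partial states show "pending" cells,
schemas never change between refreshes, and re-rendering unchanged results
is byte-identical (SVG output uses a fixed hash salt and no date metadata).
The interactive 3D-viewer layer is out of scope; its data contract — the
per-residue score track CSV and a static domain-track SVG with the variant
marked — is emitted instead.

Case-summary flags use config thresholds (defaults: ΔΔG ≥ 2.0,
clustering p ≤ 0.05, interface/PTM/digenic scores ≥ 0.5); the
recommendation column is intentionally blank for the analyst.

## Synthetic data: what it does and does not emulate

The fixture module generates, from a seed (byte-identical for identical
spec + seed):

- **toy transcriptomes** — default 6 genes, peptides 60–120 aa, single- or
  two-exon CDS on both strands in non-overlapping 50-kb windows; the four
  cross-reference classes planted by exact largest-remainder apportionment
  of the configured mix (default 70/10/10/10% — perfect cross-references
  dominate real curation censuses, with each discrepancy class present);
  per gene, a canonical isoform plus "-N" variants built by internal
  deletion, C-terminal truncation or extension;
- **structures** — ideal α-helix Cα traces (rise 1.5 Å, 100°/residue,
  radius 2.3 Å; protomer copies translated 40 Å apart), 2–4 per protein,
  sources mixed (40% experimental / 60% models), resolutions 1.2–4.2 Å,
  confidences 40–95, ~30% homodimers, partial coverage with residue
  numbering shifted by a small per-structure offset so maps are exercised;
- **planted site sets** — default 8 pathogenic within 8 Å of a random
  centre, 8 benign at ≥ 20 Å, with a ground-truth sidecar; separation 0 is
  the null geometry used for calibration;
- **cases** — VCF SNVs sampled until 5 missense hits (plus non-missense
  records and one indel to exercise skip paths), with the expected case
  file computed by the brute-force oracle, independent of the ingest code;
  score tables planted for every expected variant.

These sizes are the study conditions for the whole test-suite. What the
synthetic world does **not** emulate: real protein folds (helix traces only
support distance, coverage and multimer arithmetic), realistic allele
frequencies or variant spectra, database-scale censuses, and real
calculator outputs (stubs are hashes). Passing tests therefore demonstrate
the correctness of the pipeline's logic — coordinate arithmetic, filtering,
selection optimality, statistical calibration, conservation and
reproducibility — not the clinical accuracy of any score on real proteins.

## Numerical and engineering choices

- Permutation draws are vectorized (argsort of i.i.d. uniforms → one
  without-replacement sample per row); kernels between the query and all
  eligible residues are computed once per test.
- All randomness flows through seeded `numpy` generators; derived seeds
  stay below 2³¹.
- Validation problem sizes (1,000 oracle SNVs; 200 selection instances with
  ≤ 8 candidates and k ≤ 3; 2,000 calibration cases at n_perm = 199;
  10-variant reproducibility cases) were chosen so each harness gives
  statistically meaningful answers while the whole suite runs in seconds.
- Ties in the null (`≥` comparison) make p conservative; exact ties are
  measure-zero except when the same index set is redrawn.
- VCF parsing goes through htslib (cyvcf2); parse errors therefore name the
  record index rather than a raw line number.

## Known limitations

- The clustering kernel and null are this package's own fixed, documented
  choices; other spatial-proximity formulations (nearest-neighbour
  aggregation, distance-rank statistics) would need their own calibration.
- `LEN_MATCH_SEQ_MISMATCH` transcripts are never rescued, even when the
  mismatch is distal to the variant.
- Isoform position mapping trusts a single optimal global alignment;
  ambiguous alignments (repeats) are not flagged.
- The report layer presents per-structure statistics without multiplicity
  correction, by design.
- Real schedulers are out of scope; the executor contract is the seam where
  a cluster adapter would attach.
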