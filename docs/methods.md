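# Methods

## Inputs and data model

The pipeline consumes three files:

* **CD-Search Features table** — tab-delimited, seven fields per row:
  query, domain type (specific/superfamily), title, the coordinate list of
  functional sites (letter + 1-based position, `P9, V10, …`), complete size
  (expected number of sites), mapped size (observed sites), and the source
  domain's PSSM id. Lines starting with `#` and blank lines are skipped, so
  the raw download and a preamble-stripped file parse identically. Rows are
  validated at construction: mapped size must equal the parsed site count
  and not exceed the complete size, and positions must be strictly
  increasing. The `Q#N - >` query-prefix dialect is stripped; the query id
  is the first whitespace token, matching FASTA headers.
* **Protein FASTA** — read with Biopython; wrapped lines concatenated.
* **Genome metadata** — TSV/CSV with genome id, organism, genus, sequencing
  status (`draft` / `finished` / `permanent draft`, normalized
  case-insensitively), the *hgcAB* mercury-methylation flag, and an
  optional total gene count. Unknown columns are preserved verbatim.
  Duplicate sequencing projects for one strain remain distinct records.

The USP domain model is identified by PSSM id **23812** by default.
Because PSSM ids drift across CDD releases, every entry point accepts an
override (a set of ids is allowed, e.g. to include the sensor-kinase USP
region model).

## Pattern extraction

For each USP feature row, two signatures are derived from the coordinate
list: the amino-acid pattern (residues concatenated in position order) and
the position pattern (all positions joined with `_`). Every coordinate
contributes exactly one field to each signature, so the two always have
equal length — the invariant the whole downstream accounting relies on.
Patterns are per domain instance: a tandem sequence contributes two.
Unsorted site lists are rejected, never silently re-sorted, to surface
upstream parsing bugs. A USP row with an empty coordinate field yields an
UNCLASSIFIED placeholder (CD-Search reports no functional sites for some
queries).

## ATP-binding motif

The motif G–X₂–G–X₉–G–(S/T) is read with **exact** gaps: anchors at offsets
0, +3, +13, +14 from the first glycine, a 15-residue span. Both canonical
ATP-binding contact layouts (`PVDCMGRGGSVT` with anchors G109/G112/G122/
S123, and `AVDVMGHGGSVA` with G113/G116/G126/S127) fit these offsets
exactly; a variable-gap reading would make the two-way pattern counts
ill-defined. Classification is a total function on valid site lists:

* **contact route** (primary): ATP-binding iff all four anchors are
  themselves contact sites with allowed residues; intervening positions are
  unconstrained and need not be contacts. Empty site list → UNCLASSIFIED;
  otherwise NON_ATP. With several valid anchors the smallest is reported
  (reporting only; the binary call is unaffected).
* **sequence route** (verification): a direct scan of the full sequence for
  the same 15-residue signature, independent of the annotation.

Anchors are matched against uppercase canonical residues only; ambiguity
codes (B, Z, X) never satisfy an anchor. The motif is configurable through
a small grammar (`"G,2,G,9,G,ST"`: residue sets alternate with gap
lengths).

## Architecture categories

Per sequence: 1 USP domain → SINGLE_ATP / SINGLE_NON_ATP; 2 USP domains →
TANDEM_Y / TANDEM_N / TANDEM_STAR (both / neither / exactly one
ATP-binding); USP domains present but none with sites → NO_SITES; no USP
domain → NO_USP; more than two USP domains → MULTI (tallied separately; not
observed in the family studied). A tandem with exactly one sited domain is
categorized by that domain and flagged `partial`, and excluded from the
Y/N/\* tallies — this keeps the three-way tandem split a clean partition of
fully-annotated tandems, and explains how a cohort can have one more
two-domain sequence than the sum of its Y/N/\* categories. Domains are
ordered by first contact position. Query-to-genome assignment uses the
longest genome-id prefix of the locus tag unless an explicit mapping is
supplied.

## Aggregation

Per-genome summaries count sequences with ≥1 USP domain (NO_SITES included,
NO_USP tallied separately); zero-count genomes stay visible. Pattern
frequencies are reported per domain instance **and** per gene, since the
two countings coincide only for single-domain patterns. The category ×
*hgcAB* stratification is a complete contingency table whose marginals
reconcile with the category tally and per-flag totals by construction (and
by test). All tables sort descending by count with lexicographic
tie-breaks, so output files are byte-deterministic.

## Synthetic cohorts

The generator emulates the study conditions: 93 genomes, 1–16 USP genes per
genome (uniform), sequencing statuses drawn 23:69:1
finished:permanent-draft:draft, tandem fraction 163/651, single-domain ATP
fraction 340/488, tandem mix 3:138:21 (Y:N:\*), no-site fraction 3/719,
decoy-only fraction 67/719 (queries whose conserved-domain hits are all
non-USP families), and a 5 % chance of a fusion partner domain on a
single-USP sequence. Methylator fraction defaults to 0.5 — the study family
contains both methylators and non-methylators and the stratification logic
is what is under test, not their ratio.

Contact layouts use the canonical 12-slot offsets
(0,1,2,30,102,103,105,106,116,117,118,119 from the first contact; anchors
at slots 5/7/8/9) with a configurable start jitter (default ±3) to exercise
position independence. Non-anchor slots draw a consensus residue (from the
most frequent family pattern `AVDVMGHGGSVA`) with probability 0.7,
otherwise a uniform residue — homologous domains therefore share recurring
patterns, as in real families. ATP domains get intact anchors; non-ATP
domains have one or two anchors broken. Rejection sampling redraws any
sequence until the full-sequence motif scan finds exactly the planted
anchors (and none in non-ATP or background-only sequences), so the contact
route and the sequence route agree by construction; typical acceptance is
>99 % of draws. Contact residues are read back from the emitted sequence,
so FASTA and Features are always mutually consistent. One seeded NumPy
generator drives all draws; identical config + seed gives byte-identical
files.

**What the generator does not emulate:** real homology structure (phylogeny,
per-genus pattern sharing), CD-Search E-values, superfamily hierarchies and
alignment details, domain-boundary variation beyond start jitter, and any
correlation between *hgcAB* status and USP content (none is modelled, so
stratified counts differ between flags only by sampling noise). Passing
tests therefore demonstrate that the bookkeeping — parsing, motif calls,
category partitions, marginal conservation — is exact, not that any
biological signal is recovered.

## Numerical and design choices

* Positions are 1-based throughout, matching CD-Search residue labels.
* Problem sizes: the default test suite and the acceptance script run the
  93-genome cohort (~800 sequences, < 2 s end to end), 100 randomized
  small cohorts for recovery checks, and 1000 fresh cases for the two-route
  classifier equivalence — comfortable desk-scale sizes for this pipeline,
  which is linear in the number of feature rows.
* Degenerate inputs: empty Features file → empty outputs; metadata-only
  genomes → zero-count rows; a sequence with no hits → NO_USP.
* The exact published tallies (651 USP sequences; 488/163 single/tandem;
  340/148; 3/138/21; 353 patterns over 247 layouts, 117 ATP / 236 non-ATP;
  top pattern at 54) are asserted by a dedicated test that runs the
  pipeline on the deposited cohort inputs when placed under
  `data/deposited/`; the deposit is not redistributed with this package.

## Known limitations

* The motif criterion is purely sequence/contact-based; no structural or
  energetic assessment of ATP binding.
* Domain boundaries derive solely from contact positions; overlapping USP
  layouts (not produced by CD-Search Features rows) trigger no special
  handling beyond ordering by first contact.
* Gene-level vs instance-level pattern counting can legitimately differ for
  tandem sequences; both columns are emitted rather than choosing one.
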