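# Methods

## Census model

The census post-processes homology-search output; it never runs the search
tools themselves. Inputs are the standard text dialects: HMMER per-domain
tables (domtblout), 12-column BLAST tabular output, protein/nucleotide
FASTA, and a Newick species tree whose leaves carry group labels
(Aspergilli vs outgroup). All coordinates are 1-based inclusive throughout,
matching both dialects; minus-strand nucleotide subjects are normalized to
(min, max) plus a strand flag at parse time.

### Filtering and merging

* **Domain hits** are retained iff they cover ≥ 50 % of the profile model
  *or* of the hit protein (`hmm_cov_min`, default 0.5, inclusive). The
  hit-side fraction is measured against the protein's full length, not the
  envelope. Filtering uses the per-domain independent e-value column; the
  full-sequence e-value is parsed and kept available.
* **HSP merging** unions the query spans and, separately, the subject spans
  of all HSPs of one (query, subject) pair. Overlap handling is purely
  set-theoretic: only the non-redundant region counts toward coverage. The
  merged match is represented by the numerically largest (worst)
  constituent e-value — the conservative reading of "highest e-value" — with
  a config switch (`evalue_rule="best"`) exposing the alternative.
* **Retention** keeps merged matches with e-value strictly below 1e-5 and
  strictly more than 50 % coverage of query or subject. All retention
  inequalities in the package are strict ("lower than", "more than",
  "higher than"), including the identification filters in the MS half; the
  two inclusive boundaries are the domain-hit coverage cutoff ("a cutoff
  calculated by 50 % length coverage") and alignment-column trimming
  (remove only when the gap fraction *exceeds* 0.9).
* **Escalation** to an iterative profile search is flagged when fewer than
  ten retained matches fall in Aspergilli, counting matches (subject
  proteins), not species. The next query is the best Aspergilli hit —
  smallest e-value, ties broken by larger query coverage then lexicographic
  subject id, so the decision is deterministic across platforms — or the
  original query when no Aspergilli match survived. The escalated search
  itself (5 iterations) is an upstream tool; its filtered output joins the
  primary set keyed by subject id, keeping the smaller e-value on
  collision.
* **Genomic rescue** expands translated-search hits with e-value < 1e-5 by
  4500 nt on both sides, clamps to the contig, and merges overlapping
  windows per (contig, strand, query). The bundled gene-finder is a
  deliberately simple single-exon fallback: it reports ATG-initiated,
  stop-terminated ORFs of ≥ 50 codons in the six frames of the window
  (standard genetic code), longest first. A spliced aligner producing
  candidate proteins for a window can be plugged in through the same
  contract; introns are the main thing the fallback misses.

### Architecture classification and presence calls

Families are defined by required/forbidden Pfam-domain sets with explicit
priorities; rules with larger required sets outrank their subsets, so SET2
(SET + AWS + SRI) is never shadowed by Ash1 (SET + AWS, SRI forbidden) and
Elp3 outranks a bare GNAT domain. Unmatched architectures are labelled by
their catalytic superfamily ("SET-unclassified", …) or UNCLASSIFIED;
classification is total and deterministic. Presence calls take the best
available evidence tier (domain scan > pairwise search > iterative search >
genomic rescue); adding evidence can only raise the tier, never flip a call
to absent.

### Presence/absence categorization

The subunit × species matrix stores three cell states (present / absent /
present-by-rescue); rescue counts as presence for categorization, since the
rescue stage corrects false absences, but stays distinct for rendering. Row
categories are assigned with this precedence: conserved-in-all →
single-species → absent-in-all-Aspergilli-with-patchy-outgroup →
all-Aspergilli-with-patchy-outgroup → all-outgroup-with-patchy-Aspergilli →
patchy-in-both → other. The precedence resolves the overlap between
"single-species" and "patchy in both" in favor of single-species. Rows
absent everywhere, or uniform-in-both-groups-but-different (all outgroup /
no Aspergilli), land in the catch-all class. The categorizer is exhaustively
checked against a brute-force enumeration over all boolean rows for panels
of up to 12 species. A species-exclusion list is honored at categorization
time (the panel analysis drops two taxa), configured, not hard-coded.

## Histone MS model

Digestion is strict Arg-C: cleavage C-terminal of every arginine, no
proline exception (exposed in config), up to 2 missed cleavages, minimum
peptide length 4. Propionylation is modeled on lysine side chains only;
peptide N-termini carry fixed PIC (the protein N-terminal α-amine is
treated like any peptide N-terminus by default — its exact chemistry is not
observable in the quantified tail peptides). The five lysine states and
their elemental deltas are: pr C3H4O (+56.02621 Da), me1 C4H6O (+70.04186;
monomethyl lysines are still propionylated), me2 C2H4, me3 C3H6 (no
propionyl — the side chain is blocked), ac C2H2O (acetyl blocks
propionylation). Masses are monoisotopic sums over residue compositions
plus water plus PIC plus per-lysine deltas; proton mass 1.00727646 Da; m/z
is computed at charge 2 (the quantified precursors). The test suite checks
the implementation against an independently hand-built elemental-
composition oracle on a 20-peptide fixture (agreement < 1e-3 Da; the
reference peptide TKQTAR+K4pr weighs 878.4610 Da, m/z 440.2378).

%RA divides each form's XIC area by the summed areas of all observed forms
of that peptide span. Denominators are computed after identification
filtering (score > 50, localization probability > 0.75, strict); whether
sub-threshold observations should contribute to denominators is genuinely
ambiguous, and filtered-first was chosen as the defensible reading. Spans
whose areas are all zero carry no defined %RA and are omitted. Upstream
concerns — FDR control, fragment matching, peak picking, XIC integration —
stay upstream; the package consumes score/probability columns.

PTM status queries distinguish three outcomes: a mark is *detected* when
any quantified form of a covering peptide carries it with %RA > 0; *not
detected* when covering peptides were quantified but never with that mark
(the informative negative — e.g. a K27-covering peptide seen only in
methylation-free forms); *span not observed* when no form of any covering
peptide was quantified at all (a technical absence, as for a missing
K20-containing peptide). The "me" class matches any methyl state.

Default histone sequences: canonical fungal H3 (135 aa) and mature H4
(initiator methionine removed). Histone tails are invariant across
Ascomycota at every position quantified here, so the defaults are safe for
tail-peptide coordinates; pass explicit sequences for anything else.

## Synthetic data

The census generator realizes gene content per (species, family) with
Bernoulli losses and duplications, builds proteins as fixed 60-residue
domain-motif blocks (one arbitrary block per Pfam accession, derived from
the accession and independent of the run seed) joined by linkers, and
emits search output exercising each filter: genuine domain rows are
fragmented into up to 3 *overlapping* pieces that each clear the per-row
coverage cutoff while their union reconstructs the true span; pairwise
HSPs are fragmented into contiguous non-overlapping pieces, since those are
merged before filtering; decoys carry weak e-values or ≤ 30 % coverage
(strong-e-value decoys always report the same query segment so merging
several never crosses the coverage threshold). Withheld (species, family)
pairs are dropped from the annotated proteome and the search tables, and
instead planted as intact single-exon genes (one codon per residue,
stop-padded to suppress run-through ORFs) in random contigs with matching
translated-search rows — recoverable only through the rescue stage. A
ladder species tree provides ordering and grouping. Defaults mirror the
study design (94 + 15 species); recovery tests use a 20-species, 12-family
panel with loss 0.2, duplication 0.1 — sizes chosen so the full pipeline
runs in seconds.

The MS generator draws AUC(form) = span_total × true_proportion ×
lognormal(cv) with span_total 1e6 and cv 0.05 by default, gives true forms
super-threshold scores and optionally plants sub-threshold false forms. The
default design observes the H3 K4, K9/K14 (all 25 forms) and K18/K23
peptides.

What the generators do **not** emulate: sequence evolution (substitutions,
indels — proteins of a family are identical across species), realistic
e-value distributions, introns, isotope envelopes or retention-time
structure. Passing recovery tests therefore demonstrate the correctness of
the filtering/merging/rescue logic and the quantification arithmetic, not
robustness to diverged sequences or noisy spectra — those live upstream in
the real search tools.

The synthetic subunit panel (`synthetic_subunit_panel`) is a labelled
stand-in for the published complex catalog: 15 complexes, 83 uniquely named
subunits, 107 species (93 Aspergilli + 14 outgroup), each row drawn to
realize its planted conservation category (44 conserved / 10 patchy-both /
9 single-species, all *S. cerevisiae* / 8 + 9 outgroup-patchy / 3
Aspergilli-patchy), with occasional rescue-marked cells. The categorizer
recomputes the counts from the matrix; nothing is read off the design.

## Numerical and design notes

* Interval unions join adjacent intervals (end + 1 = next start): coverage
  is defined by the set of covered positions.
* Merged-match coverage equals a per-position boolean-array oracle
  (property-tested on 10,000 random instances with coordinates ≤ 1000).
* Joined search strategies are deduplicated by subject with best-e-value
  wins; ties prefer larger coverage.
* The rescue ORF scanner requires an explicit stop codon; ORFs running off
  the window edge are not reported.
* ppm matching is inclusive at the tolerance (|Δ|/theoretical × 1e6 ≤ tol).
* Determinism: one seeded generator per simulated run; every emitted file
  records its seed; pipeline runs write a manifest with config hash and
  input checksums, and reruns are byte-identical.

## Known limitations

Single-exon rescue misses spliced genes; the architecture rule table covers
the well-characterized families and labels the rest by superfamily; the
categorizer's catch-all class absorbs patterns the five named categories
exclude; the MS model quantifies at the form level and does not model
co-eluting isobaric forms (e.g. me3 vs ac separated by 0.036 Da are distinct
in mass but real XICs may interfere at wide tolerances).
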