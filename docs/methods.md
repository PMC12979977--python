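# Methods

## Model

`pedkit` treats a pedigree as a directed acyclic graph of
parent→offspring edges over individually identified animals. Each
record carries an id, a sex (male / female / unknown), optional sire
and dam links, and — for founders only — an optional known inbreeding
coefficient. The genetic model is the classical identity-by-descent
calculus on pedigrees:

* kinship (coancestry) φ(a, b): the probability that one allele drawn
  at random from each of a and b is identical by descent;
* inbreeding F of an individual: φ of its parents;
* self-kinship: φ(x, x) = ½(1 + F_x).

Assumptions: autosomal inheritance, no selection or mutation within the
recorded pedigree, and founders drawn unrelated from the base
population. A missing parent is treated as an unrelated, non-inbred
founder, so its leg contributes φ = 0; consequently incomplete records
can only *underestimate* F, never overstate it. Founders default to
F = 0, but a known founder F may be recorded and is honored everywhere
(self-kinship, recursion, path counting).

## Two computation routes

**Production path — memoized recursion (tabular method).** For a not an
ancestor of b, φ(a, b) = ½[φ(sire_a, b) + φ(dam_a, b)]. We expand the
individual with the greater longest-path depth; because an ancestor is
always strictly shallower than its descendant under longest-path depth,
the expanded individual is never an ancestor of the other, which is the
condition the recurrence needs. Results are cached per unordered pair,
so a full kinship matrix over n animals costs O(n²) cached entries.

**Verification path — generalized Wright path counting.** Every
common-ancestor loop — a sire-side and a dam-side parent-ward path,
each internally simple, meeting at ancestor X and sharing no other
individual — contributes (½)^(n₁+n₂+1)(1 + F_X). The textbook form of
this formula omits (1 + F_X) because it assumes non-inbred common
ancestors; the generalized factor is required as soon as a common
ancestor is itself inbred (e.g. a chain in which a daughter with
F = 0.375 is mated to her own descendants — the recursion gives 0.5 and
the simplified path sum does not). F_X is itself computed by path
counting, so the route never leans on the recursion it is meant to
check. Enumeration is exponential in pedigree depth; it is guarded by a
configurable member-count limit (default 64) and reserved for
small-pedigree verification, which is exactly its role in the test
suite and the acceptance script.

All arithmetic uses `fractions.Fraction`. Every pedigree-derived F is a
dyadic rational, so exactness is free and the dual-route contract can
be asserted with equality rather than a tolerance. Decimal rendering
(4 places, half-even) happens only at the presentation layer; the JSON
CLI format emits numerator/denominator pairs for lossless scripting.

## Risk bands

F = 0 → None; 0 < F < 0.0625 → Low; 0.0625 ≤ F < 0.125 → Moderate
(first cousin to half sib); 0.125 ≤ F < 0.25 → High (half sib to full
sib); F ≥ 0.25 → Very High (full sib / parent–offspring). Intervals
are closed on the left: the named relationship equivalences (0.0625,
0.125, 0.25) anchor the *lower* edge of their band — a full-sib-
equivalent mating at exactly 0.25 is Very High.

## Validation rules and conventions

Mutations are atomic: every check (duplicate id, self-parentage,
sire = dam, sex-role conflict, cycle) runs before any state changes, so
a rejected call leaves the pedigree exactly as it was, and cycle
detection runs on every mutation, not only at import. Batch
`validate()` reports all violations as data instead of raising.

Conventions adopted where a convention had to be chosen:

* Ids are case-sensitive, whitespace-trimmed strings (trimming prevents
  spreadsheet-import near-duplicates).
* A named-but-unregistered parent is auto-created as an unknown-sex
  founder; it represents an unidentified animal and its sex stays
  unknown. A *registered* unknown-sex animal named as sire or dam has
  its sex fixed by the role (sire → male, dam → female), and the
  inference is written to the audit trail. Interactive edits therefore
  infer; bulk imports do not (`infer_sex=False`), because an imported
  file's recorded sexes are authoritative and the export→import→export
  round trip must be a fixed point.
* An unknown-sex animal cannot serve as sire of one litter and dam of
  another: the first role fixes its sex, and the second is then a
  sex-role violation.
* `founder_f` is reset to 0 the moment an animal gains a parent; a
  non-founder with founder_f set is a validation violation.

## Virtual breeding

A session overlays ordered provisional offspring on a permanent
pedigree. Proposals never mutate the store; their F is computed over
the combined view, so provisional animals can parent further proposals
(required for multi-generation planning chains). Commit cascades over
provisional ancestors in topological order by default (disable with
`cascade=False` to demand explicit ordering); each committed record's F
is recomputed against the permanent pedigree. Discard cascades over
provisional *descendants* and leaves the permanent audit log untouched
— the permanent trail records only what became permanent.

## Persistence

The store contract is an append-only audit log plus a snapshot. Entries
carry an ISO-8601 UTC timestamp and a monotonic sequence number (the
tie-breaker that makes replay ordering reproducible), an action
(`add`, `update`, `delete`, `commit_virtual`, `import`,
`sex_inferred`), and full before/after record snapshots, so replay is
primitive and deterministic by construction; `replay(log, since=seq)`
applies deltas over a snapshot. The snapshot is a single JSON file.
CSV exchange uses the header `id,sex,sire,dam,f,label` with sex coded
1/2/0 (words accepted on import). The `f` column is output-only: on
import it is validated against recomputation and disagreements are
warnings (the recomputed value wins), with one exception — on a founder
row it is the declaration channel for a known-inbred founder. Extra
columns round-trip verbatim but are never interpreted. Exports are
written in lexicographic id order with exact finite decimals for F, so
export→import→export is byte-identical. DOT export encodes sex as node
shape (box/ellipse/diamond), F in the label (4 decimals), and the risk
band as fill color.

## Synthetic pedigrees

The generator emulates the structure of real breeding records: discrete
generations, male × female matings only, unknown-sex placeholder
founders, optional missing parent links (mid-pedigree founders, as
incomplete documentation produces), and a close-kin bias. With bias p,
each mating deliberately prefers a dam within grandparental kinship of
the sire with probability p; otherwise it avoids such kin (skipping the
mating if only kin are available), so p = 0 keeps founder lines
distinct and F ≡ 0, while p = 1 drives F into the 0.0625–0.5 range
within three generations — the moderate-to-high band reported for real
cattery datasets. Defaults (8 founders, 3 generations, 4 matings × 2
offspring) give pedigrees of a few dozen animals, which is the scale at
which path enumeration stays trivially fast. The generator is fully
deterministic per seed.

What it does **not** emulate: overlapping generations, litter-size
variation, mate choice driven by phenotype or availability, and
recording errors (wrong parentage rather than missing parentage).
Passing tests on synthetic pedigrees therefore demonstrates
computational correctness on valid records, not robustness to
biologically erroneous ones — pedigree-based F is only as good as the
recorded genealogy.

## Test and verification sizes

The dual-route (recursion vs path counting) equivalence is asserted
exactly on 200 generated pedigrees of ≤ 25 members spanning bias and
missing-parent settings; closed-form checks cover repeated full-sib
mating (F_t = ¼(1 + 2F_{t−1} + F_{t−2}), six generations) and repeated
backcrossing to one parent (F_t = ¼(1 + 2F_{t−1})); the doubled kinship
matrix (numerator relationship matrix) is checked symmetric positive
semidefinite; generator validity is checked across 1000 seeds. These
sizes keep the whole suite around a second while exercising every
branch of the path enumeration (inbred common ancestors, mid-pedigree
founders, multiple loops per ancestor).

## Known limitations

* Pedigree-based F ignores genomic realities: no marker-based
  homozygosity, no Mendelian sampling variance, no X-linkage.
* Mean kinship, effective population size, and gene-dropping summaries
  are out of scope in this version.
* Path enumeration (not the recursion) is exponential and deliberately
  capped; the recursion handles arbitrarily large pedigrees.
* The store is single-user and file-based; no concurrency control.
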