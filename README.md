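# pedkit

Pedigree management and inbreeding analysis for companion-animal
breeding programs (written with catteries in mind, but species-agnostic).
It is aimed at breeders and breeding advisors who keep pedigree records
and want to quantify — before a mating happens — how inbred the
resulting offspring would be.

`pedkit` provides:

* a validated pedigree record model (duplicate ids, self-parentage,
  sire = dam conflicts, sex-role mismatches, and circular parentage are
  all rejected or reported; unknown parents become founders),
* **exact** inbreeding coefficients *F* and kinship coefficients φ,
  computed as rationals over the full recorded pedigree depth,
* *virtual breeding*: propose a sire × dam pairing, see the prospective
  offspring's *F* and risk band instantly, chain further proposals on
  top of uncommitted ones, and commit or discard at will,
* a five-level risk classification of *F*,
* a durable store with a time-stamped, replayable audit trail, CSV
  template import/export, and Graphviz DOT pedigree graphs,
* a seedable synthetic-pedigree generator for testing and teaching,
* a scriptable CLI (`pedkit`).

## The statistic at the core

The inbreeding coefficient *F* of an individual is the probability that
its two alleles at a locus are identical by descent. It equals the
kinship of its parents, φ(s, d), computed by the recursive coancestry
(tabular) method:

    φ(x, x) = ½ (1 + F_x)
    φ(a, b) = ½ [φ(sire_a, b) + φ(dam_a, b)]   (a not an ancestor of b;
                                                a missing parent contributes 0)

Founders are assumed non-inbred (*F* = 0) unless a known founder *F* is
supplied. Equivalently, by Wright's path-counting formula, summing over
every common-ancestor loop (a sire-side and a dam-side path meeting at
ancestor *X* and sharing no other individual):

    F = Σ_loops (½)^(n₁ + n₂ + 1) (1 + F_X)

`pedkit` implements **both**: the memoized recursion is the production
path, and path enumeration is an independent cross-check (they must
agree exactly — all values are dyadic rationals and are computed with
exact arithmetic). Risk bands follow the standard relationship
equivalences: *F* < 0.0625 Low, 0.0625–0.125 Moderate (first cousin to
half sib), 0.125–0.25 High (half sib to full sib), ≥ 0.25 Very High
(full sib / parent–offspring); boundaries belong to the higher band.

## Worked example

A founder dam `Cora`, her son `Bandit` (sire unknown), and a chain of
four virtual breedings, each committed before the next:

```sh
pedkit --store cattery.json register Cora --sex f
pedkit --store cattery.json register Bandit --sex m --sire "?" --dam Cora
pedkit --store cattery.json breed Bandit Cora --id Jochen --commit
pedkit --store cattery.json breed Jochen Cora --id Merle  --commit
pedkit --store cattery.json breed Bandit Merle --id Carl  --commit
pedkit --store cattery.json breed Carl Merle --id Luise   --commit
pedkit --store cattery.json report
```

prints (abridged):

```
Jochen (committed): Bandit x Cora -> F=0.2500 band=Very High
  common ancestor Cora: n1=1 n2=0 F_X=0.0000 contribution=0.2500
Merle (committed): Jochen x Cora -> F=0.3750 band=Very High
Carl (committed): Bandit x Merle -> F=0.3125 band=Very High
Luise (committed): Carl x Merle -> F=0.5000 band=Very High
  common ancestor Merle: n1=1 n2=0 F_X=0.3750 contribution=0.3438
...
# 7 animals | males=3 females=2 unknown=2 | F>0: 4 (min=0.2500, max=0.5000)
```

The first line is the mother–son mating: the only common ancestor is
Cora herself, with path legs of length 1 and 0, so
F = (½)² = 0.25 — a Very High-risk pairing. Each later breeding stacks
new loops; note Luise's largest contribution comes through Merle, who
is herself inbred (F_X = 0.375), which is why the (1 + F_X) factor in
the path formula matters. The same chain is available programmatically
via `pedkit.BreedingSession`, and `pedkit.wright_paths` /
`pedkit.kinship` expose the two computation routes directly.

`pedkit --store cattery.json export out.csv` writes the template
spreadsheet (`id,sex,sire,dam,f,label`; sex coded 1/2/0), `graph`
writes a DOT pedigree with sex-shaped, risk-colored nodes, and `audit`
exports the time-stamped transaction log.

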