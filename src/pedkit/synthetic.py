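"""Deterministic synthetic pedigrees for testing and demonstration.

:func:`generate` builds random multi-generation pedigrees that are
valid by construction (acyclic, sexes consistent with roles) and fully
reproducible from a seed.  A close-kin bias dial forces consanguineous
matings — mates sharing at least one grandparent are preferred — so
generated populations can exhibit the moderate-to-high inbreeding
range seen in real cattery records (F up to roughly 0.375), and a
missing-parent rate blanks links to create mid-pedigree founders the
way incomplete documentation does.

:func:`make_example_pedigrees` returns the three small worked scenarios
used throughout the documentation and tests: a mother-son back-mating,
a first-cousin mating, and a four-generation chain of increasingly
inbred virtual offspring.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .core import Individual, Pedigree, Sex
from .errors import DomainError

__all__ = ["GenParams", "generate", "make_example_pedigrees"]


@dataclass(frozen=True)
class GenParams:
    """Knobs for the random generator.

    ``close_kin_bias`` is the probability that a mating deliberately
    picks related mates (sharing a parent or grandparent) when any are
    available; otherwise near kin are actively avoided (the mating is
    skipped if only kin are on offer), so a bias of 0 keeps founder
    lines distinct.  ``missing_parent_rate`` independently blanks each
    parent link of a new offspring.
    """

    n_founders: int = 8
    n_generations: int = 3
    matings_per_generation: int = 4
    offspring_per_mating: int = 2
    close_kin_bias: float = 0.0
    missing_parent_rate: float = 0.0
    seed: int = 0

    def check(self) -> None:
        for name in ("n_founders", "n_generations",
                     "matings_per_generation", "offspring_per_mating"):
            if int(getattr(self, name)) < 1:
                raise DomainError(f"{name} must be a positive integer")
        for name in ("close_kin_bias", "missing_parent_rate"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise DomainError(f"{name} must be a probability in [0, 1]")


def _near_kin(ped: Pedigree, a: str, b: str) -> bool:
    """Share an individual within grandparental depth (or one is the
    other's parent/grandparent)?"""

    def close_set(ident: str) -> set[str]:
        rec = ped[ident]
        out = {ident}
        for p in rec.parent_ids:
            if p in ped:
                out.add(p)
                out.update(gp for gp in ped[p].parent_ids if gp in ped)
        return out

    return bool(close_set(a) & close_set(b))


def generate(params: GenParams) -> Pedigree:
    """Build a random valid pedigree; identical seeds give identical
    pedigrees (and therefore identical edge lists)."""
    params.check()
    rng = random.Random(params.seed)
    ped = Pedigree()

    founders: list[str] = []
    for i in range(params.n_founders):
        # alternate sexes so every cohort can breed
        sex = Sex.MALE if i % 2 == 0 else Sex.FEMALE
        ident = f"F{i:03d}"
        ped.add_individual(Individual(id=ident, sex=sex))
        founders.append(ident)

    cohort = list(founders)
    serial = 0
    for gen in range(1, params.n_generations + 1):
        males = [i for i in cohort if ped[i].sex is Sex.MALE]
        females = [i for i in cohort if ped[i].sex is Sex.FEMALE]
        # discrete generations; fall back to founders if a sex died out
        if not males:
            males = [i for i in founders if ped[i].sex is Sex.MALE]
        if not females:
            females = [i for i in founders if ped[i].sex is Sex.FEMALE]
        next_cohort: list[str] = []
        for _ in range(params.matings_per_generation):
            sire = rng.choice(sorted(males))
            dams = sorted(d for d in females if d != sire)
            if not dams:
                continue
            if rng.random() < params.close_kin_bias:
                kin = [d for d in dams if _near_kin(ped, sire, d)]
                dam = rng.choice(kin) if kin else rng.choice(dams)
            else:
                # deliberate avoidance: only mate outside grandparental
                # kinship; skip the mating if no such dam exists
                nonkin = [d for d in dams if not _near_kin(ped, sire, d)]
                if not nonkin:
                    continue
                dam = rng.choice(nonkin)
            for j in range(params.offspring_per_mating):
                sex = Sex.MALE if (serial + j) % 2 == 0 else Sex.FEMALE
                child = f"G{gen}_{serial + j:03d}"
                keep_sire = rng.random() >= params.missing_parent_rate
                keep_dam = rng.random() >= params.missing_parent_rate
                ped.add_individual(Individual(
                    id=child, sex=sex,
                    sire_id=sire if keep_sire else None,
                    dam_id=dam if keep_dam else None,
                ))
                next_cohort.append(child)
            serial += params.offspring_per_mating
        cohort = next_cohort or cohort
    return ped


def make_example_pedigrees() -> dict[str, Pedigree]:
    """The three worked pedigree scenarios, keyed ``mother_son``, ``first_cousins``,
    ``inbred_chain``.

    * ``mother_son`` — mother-son mating: founder dam Cora, her son Bandit
      (sire an unknown founder ``?``), and their offspring Jochen
      (F = 0.25).
    * ``first_cousins`` — first-cousin mating: founder grandparents Gm x Gf
      produce siblings P1 and P2; each mates an unrelated founder
      (S1, S2); the cousins C1 x C2 produce O3 (F = 0.0625).
    * ``inbred_chain`` — the mother_son chain extended by successive close
      matings: Merle (Jochen x Cora, F = 0.375), Carl (Bandit x Merle,
      F = 0.3125), Luise (Carl x Merle, F = 0.5).
    """
    mother_son = Pedigree([
        Individual(id="Cora", sex=Sex.FEMALE),
        Individual(id="Bandit", sex=Sex.MALE, sire_id="?", dam_id="Cora"),
        Individual(id="Jochen", sex=Sex.MALE, sire_id="Bandit", dam_id="Cora"),
    ])

    first_cousins = Pedigree([
        Individual(id="Gm", sex=Sex.MALE),
        Individual(id="Gf", sex=Sex.FEMALE),
        Individual(id="P1", sex=Sex.MALE, sire_id="Gm", dam_id="Gf"),
        Individual(id="P2", sex=Sex.FEMALE, sire_id="Gm", dam_id="Gf"),
        Individual(id="S1", sex=Sex.FEMALE),
        Individual(id="S2", sex=Sex.MALE),
        Individual(id="C1", sex=Sex.MALE, sire_id="P1", dam_id="S1"),
        Individual(id="C2", sex=Sex.FEMALE, sire_id="S2", dam_id="P2"),
        Individual(id="O3", sex=Sex.UNKNOWN, sire_id="C1", dam_id="C2"),
    ])

    inbred_chain = Pedigree([
        Individual(id="Cora", sex=Sex.FEMALE),
        Individual(id="Bandit", sex=Sex.MALE, sire_id="?", dam_id="Cora"),
        Individual(id="Jochen", sex=Sex.MALE, sire_id="Bandit", dam_id="Cora"),
        Individual(id="Merle", sex=Sex.FEMALE, sire_id="Jochen", dam_id="Cora"),
        Individual(id="Carl", sex=Sex.MALE, sire_id="Bandit", dam_id="Merle"),
        Individual(id="Luise", sex=Sex.UNKNOWN, sire_id="Carl", dam_id="Merle"),
    ])

    return {"mother_son": mother_son, "first_cousins": first_cousins, "inbred_chain": inbred_chain}
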