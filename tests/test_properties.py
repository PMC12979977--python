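"""Cross-route and closed-form invariants of the relatedness machinery.

The central contract: the recursive coancestry method (production
path) and generalized Wright path counting (independent enumeration)
must agree exactly — as rationals — on every acyclic pedigree.
"""

import io
import random
from fractions import Fraction

import numpy as np
from hypothesis import given, settings
from hypothesis import strategies as st

from pedkit import (
    GenParams,
    Individual,
    KinshipCalculator,
    Pedigree,
    PedigreeStore,
    RiskBand,
    Sex,
    classify_f,
    export_table,
    generate,
    import_table,
    inbreeding,
    kinship_matrix,
    replay,
    wright_f,
)
from pedkit.errors import PedkitError

_BAND_ORDER = [RiskBand.NONE, RiskBand.LOW, RiskBand.MODERATE,
               RiskBand.HIGH, RiskBand.VERY_HIGH]


def _random_pedigrees(count):
    """Deterministic stream of small, structurally varied pedigrees."""
    for seed in range(count):
        yield generate(GenParams(
            n_founders=4,
            n_generations=1 + seed % 3,
            matings_per_generation=2,
            offspring_per_mating=2,
            close_kin_bias=[0.0, 0.5, 1.0][seed % 3],
            missing_parent_rate=[0.0, 0.2][seed % 2],
            seed=seed,
        ))


def test_wright_path_counting_equals_kinship_recursion_everywhere():
    """Exact rational agreement on 200 random pedigrees (<= 25 members)."""
    rng = random.Random(2024)
    checked_pairs = 0
    for ped in _random_pedigrees(200):
        assert len(ped) <= 25
        calc = KinshipCalculator(ped)
        for rec in ped:
            if rec.sire_id and rec.dam_id:
                assert wright_f(ped, rec.sire_id, rec.dam_id) == calc.f(rec.id)
                checked_pairs += 1
        ids = ped.ids()
        a, b = rng.sample(ids, 2)
        assert wright_f(ped, a, b) == calc.phi(a, b)
        checked_pairs += 1
    assert checked_pairs >= 200


def test_full_sib_line_matches_closed_form_recurrence():
    """Repeated full-sib mating: F_t = 1/4 (1 + 2 F_{t-1} + F_{t-2})."""
    # independent oracle: iterate the recurrence on plain rationals
    expected, f_prev2, f_prev1 = [], Fraction(0), Fraction(0)
    for _ in range(6):
        f_t = Fraction(1, 4) * (1 + 2 * f_prev1 + f_prev2)
        expected.append(f_t)
        f_prev2, f_prev1 = f_prev1, f_t
    assert expected[:4] == [Fraction(1, 4), Fraction(3, 8),
                            Fraction(1, 2), Fraction(19, 32)]

    ped = Pedigree([Individual(id="m0", sex=Sex.MALE),
                    Individual(id="f0", sex=Sex.FEMALE)])
    for t in range(1, 7):
        ped.add_individual(Individual(
            id=f"m{t}", sex=Sex.MALE, sire_id=f"m{t-1}", dam_id=f"f{t-1}"))
        ped.add_individual(Individual(
            id=f"f{t}", sex=Sex.FEMALE, sire_id=f"m{t-1}", dam_id=f"f{t-1}"))
    # the F of generation-(t+1) offspring is the sib kinship phi(m_t, f_t)
    calc = KinshipCalculator(ped)
    observed = [calc.phi(f"m{t}", f"f{t}") for t in range(1, 7)]
    assert observed == expected


def test_backcross_line_matches_closed_form_recurrence():
    """Offspring repeatedly backcrossed to one non-inbred parent:
    F_t = 1/4 (1 + 2 F_{t-1}); first two steps are 1/4 then 3/8."""
    ped = Pedigree([Individual(id="P", sex=Sex.FEMALE),
                    Individual(id="x0", sex=Sex.MALE)])
    f_prev = Fraction(0)
    for t in range(1, 7):
        ped.add_individual(Individual(
            id=f"x{t}", sex=Sex.MALE, sire_id=f"x{t-1}", dam_id="P"))
        f_t = inbreeding(ped, f"x{t}").f
        assert f_t == Fraction(1, 4) * (1 + 2 * f_prev) if t > 1 else f_t == 0
        f_prev = f_t
    assert inbreeding(ped, "x2").f == Fraction(1, 4)
    assert inbreeding(ped, "x3").f == Fraction(3, 8)


def test_doubled_kinship_matrix_is_psd_on_random_pedigrees():
    for seed in (0, 7, 23):
        ped = generate(GenParams(n_founders=6, n_generations=3,
                                 matings_per_generation=3,
                                 close_kin_bias=0.7, seed=seed))
        a_matrix = 2.0 * kinship_matrix(ped).to_numpy()
        assert np.allclose(a_matrix, a_matrix.T)
        assert np.linalg.eigvalsh(a_matrix).min() > -1e-9


def test_all_f_and_phi_values_lie_in_unit_interval():
    for ped in _random_pedigrees(30):
        calc = KinshipCalculator(ped)
        ids = ped.ids()
        for i in ids:
            assert 0 <= calc.f(i) < 1
            for j in ids:
                assert 0 <= calc.phi(i, j) <= 1


def test_csv_round_trip_is_fixed_point_on_random_pedigrees():
    for seed in (1, 5, 9):
        ped = generate(GenParams(n_founders=6, n_generations=2,
                                 close_kin_bias=0.8,
                                 missing_parent_rate=0.2, seed=seed))
        buf1 = io.StringIO()
        export_table(ped, buf1)
        ped2, report = import_table(io.StringIO(buf1.getvalue()))
        assert report.is_valid
        assert ped2 == ped
        buf2 = io.StringIO()
        export_table(ped2, buf2)
        assert buf2.getvalue() == buf1.getvalue()


def test_audit_replay_reproduces_random_mutation_sequences():
    for seed in range(10):
        rng = random.Random(seed)
        store = PedigreeStore()
        for step in range(40):
            ids = store.pedigree.ids()
            op = rng.random()
            try:
                if op < 0.55 or len(ids) < 3:
                    sire = rng.choice(ids) if ids and rng.random() < 0.7 else None
                    dam = rng.choice(ids) if ids and rng.random() < 0.7 else None
                    store.add_individual(Individual(
                        id=f"a{seed}_{step}",
                        sex=rng.choice(list(Sex)),
                        sire_id=sire, dam_id=dam))
                elif op < 0.8:
                    store.set_parents(rng.choice(ids),
                                      rng.choice(ids), rng.choice(ids))
                else:
                    store.remove_individual(rng.choice(ids))
            except PedkitError:
                pass  # rejected mutations must leave no partial state
        assert store.pedigree.validate().is_valid
        assert replay(store.log) == store.pedigree


@settings(max_examples=80, derandomize=True)
@given(st.fractions(min_value=0, max_value=Fraction(999, 1000)),
       st.fractions(min_value=0, max_value=Fraction(999, 1000)))
def test_risk_band_is_monotone_in_f(f1, f2):
    if f1 > f2:
        f1, f2 = f2, f1
    assert _BAND_ORDER.index(classify_f(f1)) <= _BAND_ORDER.index(classify_f(f2))


@settings(max_examples=30, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_generator_determinism_for_arbitrary_seeds(seed):
    params = GenParams(n_founders=4, n_generations=2,
                       close_kin_bias=0.5, missing_parent_rate=0.1, seed=seed)
    assert generate(params).edge_list() == generate(params).edge_list()
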