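"""Shared fixtures: reference sequences and pinned synthetic landscapes."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ribofit as rf

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

#: A fixed 69-nt reference used throughout the suite. The real ribozyme's
#: sequence is not public in machine-readable form; any 69-nt sequence
#: exercises the same code paths (synthetic, labeled as such).
REF69 = "GCAUCGGAUCCGGAAACGGUUAAGGGCUAUGGACUCAUAAGGUCCAGGCAAUGCCUCGAUCCAAGGCAU"


@pytest.fixture(scope="session")
def ref69():
    return rf.ReferenceSequence(REF69)


@pytest.fixture(scope="session")
def ref20():
    rng = np.random.default_rng(11)
    return rf.ReferenceSequence("".join(rng.choice(list("ACGU"), 20)))


def make_recovery_fixture():
    """L=20 additive landscape: train on WT+singles+doubles, test 200 triples.

    Effect sizes are moderate (about one latent logistic unit) so that
    order-3 latents stay inside the link's responsive range — the landscape
    is genuinely learnable from pairwise data, which is what this fixture is
    meant to certify.
    """
    rng = np.random.default_rng(11)
    ref = rf.ReferenceSequence("".join(rng.choice(list("ACGU"), 20)))
    model = rf.sample_landscape_model(
        ref,
        n_compensatory_pairs=0,
        epistasis_scale=0.0,
        seed=5,
        deleterious_mean=-1.0,
        deleterious_sd=0.5,
    )
    gens = (
        [rf.Genotype.wildtype()]
        + rf.enumerate_single_mutants(ref)
        + rf.enumerate_double_mutants(ref)
    )
    table = rf.true_activity_table(model, gens)
    data = rf.encode_dataset(table)
    singles = rf.enumerate_single_mutants(ref)
    triples, seen = [], set()
    while len(triples) < 200:
        idx = rng.choice(len(singles), 3, replace=False)
        muts = tuple(singles[i].mutations[0] for i in idx)
        if len({m.position for m in muts}) != 3:
            continue
        g = rf.Genotype(muts)
        if str(g) in seen:
            continue
        seen.add(str(g))
        triples.append(g)
    truth = np.array([rf.true_activity(model, g) for g in triples])
    return {"ref": ref, "model": model, "table": table, "data": data,
            "triples": triples, "truth": truth}


@pytest.fixture(scope="session")
def recovery_fixture():
    return make_recovery_fixture()


def make_trend_fixture():
    """Combinatorial landscape with planted three-way structure.

    Twelve biallelic variable positions on a 25-nt reference give a 2^12
    genotype cube; thirty strong three-way latent terms among the scheme's
    mutations are invisible in single- and double-mutant data by
    construction, so a model trained only on orders <= 2 cannot learn them.
    """
    rng = np.random.default_rng(21)
    ref = rf.ReferenceSequence("".join(rng.choice(list("ACGU"), 25)))
    positions = sorted(rng.choice(np.arange(1, 26), 12, replace=False))
    entries, pool = [], []
    for pos in positions:
        r = ref.base_at(int(pos))
        alt = str(rng.choice([a for a in "ACGU" if a != r]))
        entries.append((int(pos), (alt,)))
        pool.append(rf.Mutation(int(pos), r, alt))
    scheme = rf.VariablePositionScheme(tuple(entries))
    model = rf.sample_landscape_model(
        ref,
        n_compensatory_pairs=0,
        epistasis_scale=0.5,
        seed=9,
        deleterious_mean=-1.0,
        deleterious_sd=0.5,
        background_pair_fraction=0.02,
        n_threeway_terms=30,
        threeway_scale=2.0,
        mutation_pool=pool,
    )
    gens = rf.enumerate_combinatorial_variants(ref, scheme)
    table = rf.true_activity_table(model, gens)
    return {"ref": ref, "scheme": scheme, "model": model, "table": table}


@pytest.fixture(scope="session")
def trend_fixture():
    return make_trend_fixture()
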