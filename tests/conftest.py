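"""Shared fixtures: preset scenarios and (expensive) pipeline runs.

Simulation/alignment-heavy results are session-scoped so unit tests and
the acceptance suite can share one computation.
"""

from __future__ import annotations

import pytest

import subtelomap as st
from subtelomap.scenarios import CEPH_TRIO


@pytest.fixture(scope="session")
def worked_scenario():
    return st.load_preset("worked_example")


@pytest.fixture(scope="session")
def insertion_diploid():
    """Diploid with a ~50 kb telomere-adjacent insertion on one allele."""
    sc = st.load_preset("three_haplotypes_15q")
    params = sc.sim_params.model_copy(update={"seed": 7, "coverage": 30.0})
    molecules = st.simulate_molecules(sc.diploid("h1", "h3"), params)
    result = st.run_pipeline(
        sc.reference, molecules, one_copy_interval=sc.one_copy_interval
    )
    return sc, molecules, result


@pytest.fixture(scope="session")
def missing_site_diploid():
    """Diploid where one allele lacks a single nick site."""
    sc = st.load_preset("three_haplotypes_15q")
    params = sc.sim_params.model_copy(update={"seed": 7, "coverage": 30.0})
    molecules = st.simulate_molecules(sc.diploid("h2", "h3"), params)
    result = st.run_pipeline(
        sc.reference, molecules, one_copy_interval=sc.one_copy_interval
    )
    return sc, molecules, result


@pytest.fixture(scope="session")
def d4z4_run():
    """q-arm diploid with 12- vs 19-copy macrosatellite array alleles."""
    sc = st.load_preset("d4z4_array")
    params = sc.sim_params.model_copy(update={"seed": 5, "coverage": 30.0})
    molecules = st.simulate_molecules(sc.haplotypes, params)
    result = st.run_pipeline(
        sc.reference, molecules, one_copy_interval=sc.one_copy_interval
    )
    return sc, molecules, result


@pytest.fixture(scope="session")
def telo_run():
    """Diploid telomere-length contrast (16.6 kb vs 4.8 kb tracts), aligned."""
    sc = st.load_preset("telo_diploid")
    params = sc.sim_params.model_copy(update={"seed": 5, "coverage": 30.0})
    molecules = st.simulate_molecules(sc.haplotypes, params)
    alignments = [st.align_molecule(m, sc.reference) for m in molecules]
    return sc, molecules, alignments


@pytest.fixture(scope="session")
def trio_groups():
    """Haplotype groups per trio member for the 15q scenario."""
    sc = st.load_preset("three_haplotypes_15q")
    out = {}
    for k, (indiv, (a, b)) in enumerate(CEPH_TRIO.items()):
        params = sc.sim_params.model_copy(update={"seed": 100 + k, "coverage": 30.0})
        molecules = st.simulate_molecules(sc.diploid(a, b), params, id_prefix=indiv)
        result = st.run_pipeline(
            sc.reference, molecules, one_copy_interval=sc.one_copy_interval
        )
        out[indiv] = (result.cluster.groups, molecules)
    return out


def truth_confusion(molecules, groups):
    """(true haplotype, assigned group) counts for assigned molecules."""
    by_id = {m.id: m for m in molecules}
    counts: dict[tuple[str, str], int] = {}
    for g in groups:
        for mid in g.member_ids:
            key = (by_id[mid].truth.haplotype, g.haplotype_id)
            counts[key] = counts.get(key, 0) + 1
    return counts


def assignment_accuracy(molecules, groups):
    """Fraction of assigned molecules whose group maps to their true allele.

    The group->allele mapping is the majority vote per group.
    """
    counts = truth_confusion(molecules, groups)
    best: dict[str, tuple[str, int]] = {}
    for (true_h, grp), n in counts.items():
        if grp not in best or n > best[grp][1]:
            best[grp] = (true_h, n)
    mapping = {grp: th for grp, (th, _) in best.items()}
    good = sum(n for (th, grp), n in counts.items() if mapping[grp] == th)
    total = sum(counts.values())
    return good / total if total else 0.0
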