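"""Nick-pattern alignment: DP optimality, orientation, anchoring, outliers."""

import numpy as np
import pytest

import subtelomap as st
from _oracles import oracle_both_orientations

FAST = st.ScoringParams(n_decoys=0)  # skip decoy DP where confidence is irrelevant


def random_instance(rng):
    n_labels = int(rng.integers(2, 9))
    n_sites = int(rng.integers(3, 13))
    length = float(rng.uniform(60_000, 150_000))
    labels = np.sort(rng.uniform(1_000, length - 1_000, n_labels))
    while np.any(np.diff(labels) < 100):
        labels = np.sort(rng.uniform(1_000, length - 1_000, n_labels))
    sites = np.sort(rng.choice(np.arange(1_000, 140_000, 250), n_sites, replace=False))
    mol = st.Molecule(id="r", length=length, labels=labels)
    ref = st.ReferenceMap(id="r", length=150_000, sites=[int(s) for s in sites])
    return mol, ref


def test_dp_matches_exhaustive_enumeration():
    """The DP optimum equals brute-force chain enumeration, both orientations."""
    rng = np.random.default_rng(2026)
    checked = 0
    for _ in range(220):
        mol, ref = random_instance(rng)
        aln = st.align_molecule(mol, ref, FAST)
        want = oracle_both_orientations(mol, [float(s) for s in ref.sites], FAST, float(ref.length))
        if aln is None:
            assert want is None
            continue
        checked += 1
        assert aln.score == pytest.approx(want, abs=1e-9)
    assert checked >= 200


# --- worked example ---------------------------------------------------------


def test_worked_example_forward_pairs(worked_scenario):
    mol = worked_scenario.extra_molecules[0]
    aln = st.align_molecule(mol, worked_scenario.reference)
    assert aln.orientation == "forward"
    assert aln.pairs == [(0, 0), (1, 1), (2, 2)]
    assert aln.matched_sites(worked_scenario.reference) == [12_000, 37_000, 162_000]


def test_worked_example_reverse_pairs(worked_scenario):
    mol = worked_scenario.extra_molecules[1]
    aln = st.align_molecule(mol, worked_scenario.reference)
    assert aln.orientation == "reverse"
    assert aln.pairs == [(0, 0), (1, 1), (2, 2)]
    # in the original molecule frame labels 30/155/180 kb match 162/37/12 kb
    oriented = aln.oriented_labels(mol)
    assert np.allclose(oriented, [25_000, 50_000, 175_000])


# --- properties -------------------------------------------------------------


def test_orientation_involution(telo_run):
    """Reversing a molecule flips the orientation but not placement or score."""
    sc, molecules, alignments = telo_run
    n_checked = 0
    for mol, aln in zip(molecules, alignments):
        if aln is None or n_checked >= 12:
            continue
        n_checked += 1
        rev = mol.reversed_copy(mol.id + "_rev")
        aln_r = st.align_molecule(rev, sc.reference)
        assert aln_r is not None
        assert aln_r.orientation != aln.orientation
        assert aln_r.score == pytest.approx(aln.score, abs=1e-6)
        assert [j for _, j in aln_r.pairs] == [j for _, j in aln.pairs]
    assert n_checked >= 10


def test_noise_free_recovery_of_origin_and_orientation():
    """Noise-free molecules with >= 5 labels all map to their true origin."""
    sc = st.load_preset("telo_diploid")
    params = st.SimParams(
        seed=21, coverage=20.0, fn_rate=0.0, fp_rate=0.0,
        sizing_rel_sd=0.0, sizing_abs_sd=0.0, inp_break_probability=0.0,
    )
    molecules = st.simulate_molecules(sc.haplotypes, params)
    eligible = [m for m in molecules if m.n_labels >= 5]
    assert len(eligible) >= 40
    ok = 0
    for m in eligible:
        aln = st.align_molecule(m, sc.reference, FAST)
        if aln is None:
            continue
        hap = sc.haplotypes[m.truth.haplotype]
        expected_offset = m.truth.start - hap.ref_shift
        if aln.orientation == ("reverse" if m.truth.reversed else "forward"):
            if abs(aln.offset - expected_offset) < 2_000:
                ok += 1
    assert ok / len(eligible) >= 0.99


def test_noise_never_raises_expected_true_alignment_score():
    sc = st.load_preset("telo_diploid")
    clean_params = st.SimParams(
        seed=22, coverage=6.0, fn_rate=0.0, fp_rate=0.0,
        sizing_rel_sd=0.0, sizing_abs_sd=0.0, inp_break_probability=0.0,
    )
    molecules = st.simulate_molecules(sc.haplotypes, clean_params)[:15]
    rng = np.random.default_rng(23)
    clean_scores, noisy_scores = [], []
    for m in molecules:
        aln = st.align_molecule(m, sc.reference, FAST)
        if aln is None:
            continue
        clean_scores.append(aln.score)
        bounds = np.concatenate([[0.0], m.labels, [m.length]])
        d = np.diff(bounds)
        d = np.maximum(d + rng.normal(0, 1, d.size) * np.maximum(0.03 * d, 250.0), 1.0)
        pos = np.cumsum(np.concatenate([[0.0], d]))
        noisy = st.Molecule(id=m.id + "n", length=float(pos[-1]), labels=pos[1:-1])
        aln_n = st.align_molecule(noisy, sc.reference, FAST)
        noisy_scores.append(aln_n.score if aln_n else 0.0)
    assert np.mean(noisy_scores) <= np.mean(clean_scores)


def test_sparse_molecules_are_unalignable():
    ref = st.ReferenceMap(id="t", length=100_000, sites=[10_000, 40_000, 80_000])
    no_labels = st.Molecule(id="a", length=50_000, labels=np.array([]))
    one_label = st.Molecule(id="b", length=50_000, labels=np.array([20_000.0]))
    assert st.align_molecule(no_labels, ref) is None
    assert st.align_molecule(one_label, ref) is None


# --- anchoring --------------------------------------------------------------


def _alignment(pairs, ref_id="t"):
    return st.Alignment(
        molecule_id="m", ref_id=ref_id, orientation="forward",
        pairs=pairs, offset=0.0, score=10.0, confidence=30.0,
    )


def test_anchor_fails_when_matches_stay_in_sre_region():
    ref = st.ReferenceMap(id="t", length=200_000, sites=[10_000, 50_000, 100_000, 150_000])
    aln = _alignment([(0, 0), (1, 1), (2, 2)])  # sites <= 100 kb only
    assert not st.anchor_check(aln, ref, (140_000, 200_000))


def test_anchor_passes_when_reaching_one_copy_dna():
    ref = st.ReferenceMap(id="t", length=200_000, sites=[10_000, 50_000, 100_000, 150_000])
    aln = _alignment([(0, 0), (1, 1), (2, 3)])
    assert st.anchor_check(aln, ref, (140_000, 200_000))


def test_anchor_boundary_is_half_open():
    ref = st.ReferenceMap(id="t", length=200_000, sites=[10_000, 140_000])
    aln = _alignment([(0, 0), (1, 1)])
    assert st.anchor_check(aln, ref, (140_000, 200_000))
    assert not st.anchor_check(aln, ref, (140_001, 200_000))


# --- outlier intervals ------------------------------------------------------


def _noise_free_molecules(scenario, pair, seed, coverage=4.0, min_length=150_000.0):
    params = st.SimParams(
        seed=seed, coverage=coverage, fn_rate=0.0, fp_rate=0.0,
        sizing_rel_sd=0.0, sizing_abs_sd=0.0, inp_break_probability=0.0,
        min_molecule_length=min_length,
    )
    return st.simulate_molecules(
        {k: scenario.haplotypes[k] for k in pair}, params
    )


def test_insertion_appears_as_positive_outlier():
    sc = st.load_preset("three_haplotypes_15q")
    mols = _noise_free_molecules(sc, ("h1",), seed=31)
    found = False
    for m in mols:
        if not (m.truth.start < 45_000 and m.truth.end > 120_000):
            continue
        aln = st.align_molecule(m, sc.reference, FAST)
        outs = st.detect_outliers(aln, sc.reference, m, min_size=20_000)
        assert len(outs) == 1
        assert outs[0].size_delta == pytest.approx(50_000, abs=500)
        found = True
    assert found


def test_concordant_molecule_has_no_outliers():
    sc = st.load_preset("three_haplotypes_15q")
    mols = _noise_free_molecules(sc, ("h3",), seed=32)
    checked = 0
    for m in mols[:10]:
        aln = st.align_molecule(m, sc.reference, FAST)
        if aln is None:
            continue
        checked += 1
        assert st.detect_outliers(aln, sc.reference, m, min_size=5_000) == []
    assert checked >= 5


def test_deletion_appears_as_negative_outlier():
    spec = st.SubtelomereSpec(
        id="del_toy",
        tract_lengths={"h1": 8_000},
        blocks=[("toyblockA", 40_000)],
        one_copy_length=120_000,
        edits={"h1": [st.Edit(kind="deletion", position=60_000, size=35_000)]},
    )
    sc = st.build_scenario(spec)
    # the deleted haplotype is only ~133 kb long, so relax the length cut
    mols = _noise_free_molecules(sc, ("h1",), seed=33, coverage=6.0, min_length=100_000.0)
    found = False
    for m in mols:
        if not (m.truth.start < 50_000 and m.truth.end > 120_000):
            continue
        aln = st.align_molecule(m, sc.reference, FAST)
        outs = st.detect_outliers(aln, sc.reference, m, min_size=20_000)
        deltas = [o.size_delta for o in outs]
        assert any(abs(d + 35_000) < 1_000 for d in deltas)
        found = True
    assert found
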