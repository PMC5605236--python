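"""Diploid construction and the molecule error model."""

import numpy as np
import pytest

import subtelomap as st
from subtelomap.simulate import Edit


def small_spec(**kw):
    base = dict(
        id=kw.pop("id", "toy"),
        tract_lengths={"h1": 8_000, "h2": 8_000},
        blocks=[("toyblockA", 40_000)],
        one_copy_length=120_000,
    )
    base.update(kw)
    return st.SubtelomereSpec(**base)


def noise_free(seed=0, **kw):
    params = dict(
        seed=seed, fn_rate=0.0, fp_rate=0.0, sizing_rel_sd=0.0,
        sizing_abs_sd=0.0, inp_break_probability=0.0,
    )
    params.update(kw)
    return st.SimParams(**params)


def test_no_edits_yields_identical_haplotypes():
    haps = st.build_diploid_subtelomere(small_spec())
    assert haps["h1"].sequence == haps["h2"].sequence
    assert haps["h1"].map.sites == haps["h2"].map.sites


def test_insertion_adds_length_and_sites_confined_to_it():
    spec = small_spec(
        edits={"h1": [Edit(kind="insertion", position=5_000, size=50_000)], "h2": []}
    )
    haps = st.build_diploid_subtelomere(spec)
    h1, h2 = haps["h1"], haps["h2"]
    assert h1.length == h2.length + 50_000
    # sites distal of the insertion unchanged; proximal ones shifted by 50 kb
    edit_at = h1.tract_length + 5_000
    distal1 = [s for s in h1.map.sites if s < edit_at]
    distal2 = [s for s in h2.map.sites if s < edit_at]
    assert distal1 == distal2
    prox1 = [s for s in h1.map.sites if s >= edit_at + 50_000]
    prox2 = [s + 50_000 for s in h2.map.sites if s >= edit_at]
    assert prox1 == prox2


def test_tandem_array_copy_number_difference():
    """12 vs 19 copies of a 3.3 kb unit differ by exactly 23.1 kb."""
    spec = small_spec(
        edits={
            "h1": [Edit(kind="tandem_array", position=10_000, copies=12, label="u")],
            "h2": [Edit(kind="tandem_array", position=10_000, copies=19, label="u")],
        }
    )
    haps = st.build_diploid_subtelomere(spec)
    assert haps["h2"].length - haps["h1"].length == 7 * 3_300
    # the array unit is motif-free, so site patterns differ only by the
    # +23.1 kb shift of everything proximal of the array
    edit_at = haps["h1"].tract_length + 10_000
    distal1 = [s for s in haps["h1"].map.sites if s < edit_at]
    distal2 = [s for s in haps["h2"].map.sites if s < edit_at]
    assert distal1 == distal2


def test_nick_site_loss_removes_exactly_one_site():
    spec = small_spec(edits={"h1": [Edit(kind="nick_site_loss", position=30_000)], "h2": []})
    haps = st.build_diploid_subtelomere(spec)
    s1, s2 = set(haps["h1"].map.sites), set(haps["h2"].map.sites)
    assert len(s2 - s1) == 1 and s1 < s2
    (lost,) = s2 - s1
    assert abs(lost - (haps["h1"].tract_length + 30_000)) < 30_000


def test_edit_outside_bounds_rejected():
    spec = small_spec(
        edits={"h1": [Edit(kind="deletion", position=159_000, size=5_000)], "h2": []}
    )
    with pytest.raises(ValueError):
        st.build_diploid_subtelomere(spec)


def test_shared_block_ids_reproduce_sequence_across_specs():
    """Paralogy: the same SRE block id yields the same DNA in any subtelomere."""
    a = st.build_diploid_subtelomere(small_spec(id="left"))["h1"]
    b = st.build_diploid_subtelomere(small_spec(id="right"))["h1"]
    t = a.tract_length
    assert a.sequence[t : t + 40_000] == b.sequence[t : t + 40_000]
    assert a.sequence[t + 40_000 :] != b.sequence[t + 40_000 :]  # 1-copy differs


# --- molecule simulation ----------------------------------------------------


def test_noise_free_labels_equal_true_sites():
    haps = st.build_diploid_subtelomere(small_spec())
    mols = st.simulate_molecules(haps, noise_free(seed=3, coverage=5.0))
    assert mols
    for m in mols:
        truth = m.truth
        sites = np.asarray(haps[truth.haplotype].map.sites, dtype=float)
        spanned = sites[(sites >= truth.start) & (sites < truth.end)]
        expected = spanned - truth.start
        if truth.reversed:
            expected = (m.length - expected)[::-1]
        assert np.allclose(m.labels, expected)


def test_false_negative_rate_recovered():
    haps = st.build_diploid_subtelomere(small_spec())
    params = noise_free(seed=4, coverage=40.0, fn_rate=0.10)
    mols = st.simulate_molecules(haps, params)
    spanned = sum(m.truth.n_true_spanned for m in mols)
    labeled = sum(m.truth.n_true_labeled for m in mols)
    assert spanned > 1_200
    frac_missing = 1 - labeled / spanned
    tol = 3 * np.sqrt(0.1 * 0.9 / spanned)
    assert abs(frac_missing - 0.10) < tol


def test_terminal_molecule_has_no_labels_in_the_tract():
    """With no false positives the telomere overhang is label-free."""
    spec = small_spec()
    spec = spec.model_copy(update={"tract_lengths": {"h1": 13_000, "h2": 13_000}})
    haps = st.build_diploid_subtelomere(spec)
    mols = st.simulate_molecules(haps, noise_free(seed=5, coverage=10.0))
    terminal = [m for m in mols if m.truth.start == 0 and not m.truth.reversed]
    assert terminal
    first_site = min(haps["h1"].map.sites)
    for m in terminal:
        assert not np.any(m.labels < first_site - 1)


def test_coverage_conservation():
    haps = st.build_diploid_subtelomere(small_spec())
    genome = sum(h.length for h in haps.values())
    mols = st.simulate_molecules(haps, noise_free(seed=6, coverage=25.0))
    total = sum(m.truth.end - m.truth.start for m in mols)
    assert abs(total / genome - 25.0) / 25.0 < 0.05


def test_orientation_balance():
    haps = st.build_diploid_subtelomere(small_spec())
    mols = st.simulate_molecules(haps, noise_free(seed=7, coverage=40.0))
    rev = np.array([m.truth.reversed for m in mols])
    n = len(rev)
    assert abs(rev.mean() - 0.5) < 3 * np.sqrt(0.25 / n)


def test_minimum_molecule_length_enforced():
    haps = st.build_diploid_subtelomere(small_spec())
    mols = st.simulate_molecules(haps, st.SimParams(seed=8, coverage=10.0))
    assert all(m.truth.end - m.truth.start >= 150_000 for m in mols)


def test_same_seed_reproduces_bit_exact_molecules():
    haps = st.build_diploid_subtelomere(small_spec())
    params = st.SimParams(seed=9, coverage=10.0)
    a = st.simulate_molecules(haps, params)
    b = st.simulate_molecules(haps, params)
    c = st.simulate_molecules(haps, st.SimParams(seed=10, coverage=10.0))
    assert len(a) == len(b)
    for ma, mb in zip(a, b):
        assert ma.id == mb.id and ma.length == mb.length
        assert np.array_equal(ma.labels, mb.labels)
    assert any(
        ma.length != mc.length or not np.array_equal(ma.labels, mc.labels)
        for ma, mc in zip(a, c)
    )


def test_inp_breakage_fragments_spanning_molecules():
    """With certain breakage no kept molecule spans an inverted nick pair."""
    spec = small_spec(id="inp_toy")
    haps = st.build_diploid_subtelomere(spec)
    # plant an INP: motif on top strand and reverse-complement 400 bp later
    h = haps["h1"]
    seq = list(h.sequence)
    p = 90_000
    seq[p : p + 7] = st.NT_BSPQI_MOTIF
    seq[p + 400 : p + 407] = st.revcomp(st.NT_BSPQI_MOTIF)
    seq = "".join(seq)
    truth = st.build_reference_map("inp:h1", seq, distal_offset=0)
    from subtelomap.simulate import HaplotypeTruth
    from subtelomap.refmaps import in_silico_nick

    hap = HaplotypeTruth(
        name="h1", sequence=seq, map=truth, tract_length=h.tract_length,
        ref_shift=h.ref_shift, stranded_sites=in_silico_nick(seq),
    )
    # short min length so both fragments of a broken molecule remain visible
    params = noise_free(
        seed=11, coverage=20.0, inp_break_probability=1.0, min_molecule_length=50_000
    )
    mols = st.simulate_molecules({"h1": hap}, params)
    mid = p + 200
    assert mols
    assert not any(m.truth.start < mid - 300 and m.truth.end > mid + 300 for m in mols)


def test_zero_coverage_draws_nothing():
    haps = st.build_diploid_subtelomere(small_spec())
    assert st.simulate_molecules(haps, st.SimParams(seed=1, coverage=0.0)) == []
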