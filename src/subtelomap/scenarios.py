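"""Preset simulation scenarios.

Each preset bundles a subtelomere architecture, the haplotype structure to
simulate, and molecule-generation parameters into a :class:`Scenario`.  The
presets mirror the canonical situations a subtelomere mapping study meets:

``worked_example``
    A schematic 192 kb reference with sites at exactly 12, 37 and 162 kb
    and a 13 kb telomere tract; its canonical 205 kb three-label molecule
    (labels 25/50/175 kb, or 30/155/180 kb when imaged the other way
    round) is attached as a deterministic fixture.
``three_haplotypes_15q``
    A 15q-like subtelomere with three alleles: h1 carries a ~50 kb
    telomere-adjacent insertion, h2 lacks one nick site, h3 matches the
    backbone.  Supports trio construction (grandmother h1/h2, grandfather
    h3/h3, child h1/h3).
``gap_region_6p``
    A 6p-like subtelomere whose reference begins distal of a 60 kb
    unsequenced gap region; two alleles differ inside the gap region.
``d4z4_array``
    A q-arm subtelomere with a D4Z4-like 3.3 kb macrosatellite array of 12
    vs 19 copies (about 40 vs 62 kb of array DNA).
``telo_diploid``
    Telomere-length contrast: tracts of 16.6 kb vs 4.8 kb on an otherwise
    identical diploid pair.
``telo_gap_offset``
    A homozygous telomere behind 10 kb of unsequenced telomere-adjacent
    DNA (unknown distal offset), demonstrating the gap-haplotype
    overestimation of telomere length.
``gap_fill_130kb``
    130 kb of mappable telomere-adjacent DNA absent from the reference,
    delineated by consensus end extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .refmaps import NT_BSPQI_MOTIF, ReferenceMap
from .simulate import (
    Edit,
    HaplotypeTruth,
    Molecule,
    SimParams,
    SubtelomereSpec,
    build_diploid_subtelomere,
    build_reference,
    one_copy_interval,
)


@dataclass
class Scenario:
    """A fully realized simulation setting with ground truth."""

    spec: SubtelomereSpec
    sim_params: SimParams
    reference_sequence: str
    reference: ReferenceMap
    haplotypes: dict[str, HaplotypeTruth]
    one_copy_interval: tuple[int, int]
    extra_molecules: list[Molecule] = field(default_factory=list)

    def diploid(self, hap_a: str, hap_b: str) -> dict[str, HaplotypeTruth]:
        """The two-allele subset an individual carries."""
        return {hap_a: self.haplotypes[hap_a], hap_b: self.haplotypes[hap_b]}


def build_scenario(
    spec: SubtelomereSpec,
    sim_params: SimParams | None = None,
    motif: str = NT_BSPQI_MOTIF,
) -> Scenario:
    ref_seq, ref = build_reference(spec, motif)
    haps = build_diploid_subtelomere(spec, motif)
    return Scenario(
        spec=spec,
        sim_params=sim_params or SimParams(),
        reference_sequence=ref_seq,
        reference=ref,
        haplotypes=haps,
        one_copy_interval=one_copy_interval(spec, ref),
    )


def _canonical_worked_molecules() -> list[Molecule]:
    # 205 kb molecule, telomere end first: labels 25/50/175 kb match sites
    # 12/37/162 kb (13 kb telomere); same molecule imaged the other way:
    # labels 30/155/180 kb match sites 162/37/12 kb.
    fwd = Molecule(id="worked_forward", length=205_000.0, labels=np.array([25_000.0, 50_000.0, 175_000.0]))
    rev = fwd.reversed_copy("worked_reverse")
    return [fwd, rev]


def worked_example(sim_params: SimParams | None = None) -> Scenario:
    spec = SubtelomereSpec(
        id="worked",
        arm="p",
        tract_lengths={"h1": 13_000},
        one_copy_length=192_000,
        planted_sites=[12_000, 37_000, 162_000],
    )
    params = sim_params or SimParams(coverage=30.0, length_median=220_000.0)
    scenario = build_scenario(spec, params)
    scenario.one_copy_interval = (100_000, scenario.reference.length)
    scenario.extra_molecules = _canonical_worked_molecules()
    return scenario


def three_haplotypes_15q(sim_params: SimParams | None = None) -> Scenario:
    spec = SubtelomereSpec(
        id="15q",
        arm="p",
        tract_lengths={"h1": 12_000, "h2": 9_000, "h3": 7_000},
        blocks=[("dup1", 30_000), ("dup2", 25_000), ("dup3", 20_000),
                ("dup4", 25_000), ("dup5", 20_000)],
        one_copy_length=150_000,
        edits={
            # telomere-adjacent ~50 kb of extra DNA relative to the backbone
            "h1": [Edit(kind="insertion", position=40_000, size=50_000, label="15q_ins")],
            # allele missing one nicking site in duplicon DNA
            "h2": [Edit(kind="nick_site_loss", position=60_000)],
            "h3": [],
        },
    )
    return build_scenario(spec, sim_params or SimParams())


#: trio structure for the 15q scenario: (child, parent1, parent2) allele pairs
CEPH_TRIO = {
    "NA12878": ("h1", "h3"),  # child
    "NA12892": ("h1", "h2"),  # transmitting parent of h1
    "NA12891": ("h3", "h3"),  # transmitting parent of h3 (homozygous)
}


def gap_region_6p(sim_params: SimParams | None = None) -> Scenario:
    spec = SubtelomereSpec(
        id="6p",
        arm="p",
        tract_lengths={"h1": 10_000, "h2": 10_000},
        blocks=[("dup3", 20_000), ("dup4", 25_000), ("dup5", 20_000), ("dup8", 25_000)],
        one_copy_length=150_000,
        distal_extra_length=60_000,  # the unsequenced gap region
        edits={
            "h1": [],
            # gap-region structural difference between the two alleles
            "h2": [Edit(kind="insertion", position=20_000, size=25_000, label="6p_gapvar")],
        },
    )
    return build_scenario(spec, sim_params or SimParams())


def d4z4_array(sim_params: SimParams | None = None) -> Scenario:
    spec = SubtelomereSpec(
        id="10q",
        arm="q",
        tract_lengths={"h1": 6_000, "h2": 6_000},
        blocks=[("d4z4_flank", 60_000)],
        one_copy_length=150_000,
        edits={
            "h1": [Edit(kind="tandem_array", position=30_000, copies=12,
                        unit_length=3_300, label="d4z4_unit")],
            "h2": [Edit(kind="tandem_array", position=30_000, copies=19,
                        unit_length=3_300, label="d4z4_unit")],
        },
        reference_edits=[Edit(kind="tandem_array", position=30_000, copies=12,
                              unit_length=3_300, label="d4z4_unit")],
    )
    return build_scenario(spec, sim_params or SimParams())


def telo_diploid(sim_params: SimParams | None = None) -> Scenario:
    spec = SubtelomereSpec(
        id="teloAB",
        arm="p",
        tract_lengths={"h1": 16_600, "h2": 4_800},
        blocks=[("telA", 40_000), ("telB", 40_000)],
        one_copy_length=150_000,
    )
    return build_scenario(spec, sim_params or SimParams(coverage=30.0))


def telo_gap_offset(sim_params: SimParams | None = None) -> Scenario:
    spec = SubtelomereSpec(
        id="teloGap",
        arm="p",
        tract_lengths={"h1": 9_000},
        blocks=[("telC", 40_000), ("telD", 40_000)],
        one_copy_length=150_000,
        distal_extra_length=10_000,  # unsequenced (TTAGGG)n-adjacent placeholder
        distal_extra_motif_free=True,
    )
    return build_scenario(spec, sim_params or SimParams())


def gap_fill_130kb(sim_params: SimParams | None = None) -> Scenario:
    spec = SubtelomereSpec(
        id="3q_like",
        arm="p",
        tract_lengths={"h1": 8_000},
        blocks=[("gapblockA", 40_000)],
        one_copy_length=150_000,
        distal_extra_length=130_000,
    )
    return build_scenario(spec, sim_params or SimParams())


PRESETS = {
    "worked_example": worked_example,
    "three_haplotypes_15q": three_haplotypes_15q,
    "gap_region_6p": gap_region_6p,
    "d4z4_array": d4z4_array,
    "telo_diploid": telo_diploid,
    "telo_gap_offset": telo_gap_offset,
    "gap_fill_130kb": gap_fill_130kb,
}


def load_preset(name: str, sim_params: SimParams | None = None) -> Scenario:
    try:
        builder = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}") from None
    return builder(sim_params)
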