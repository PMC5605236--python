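"""Synthetic subtelomeres and nick-labeled single molecules.

The generator emulates what a nanochannel mapping run sees at one
subtelomere: a diploid pair of long-range haplotype structures, each ending
in a terminal (TTAGGG)n tract that contains no nicking motif, preceded by
subtelomeric repeat element (SRE) blocks and chromosome-specific 1-copy
DNA.  Haplotypes differ by large edits (insertions/deletions >= 20 kb,
loss of a single nick site, tandem-array copy-number differences).
Molecules are drawn to a target fold-coverage with the error model of the
imaging chemistry: 10% of true sites unlabeled (false negatives), spurious
labels at 10% of the true-site rate (false positives), per-interval sizing
noise, random channel-entry orientation, a minimum molecule length cut, and
fragmentation at inverted-nick-pair (INP) loci.

Every molecule carries hidden truth (haplotype, genomic origin,
orientation) so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .refmaps import (
    NT_BSPQI_MOTIF,
    TELOMERE_UNIT,
    INPLocus,
    NickSite,
    ReferenceMap,
    build_reference_map,
    detect_inp,
    in_silico_nick,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _seed_from(tag: str) -> int:
    """Stable 31-bit seed from a string tag (shared-paralogy block identity)."""
    return zlib.crc32(tag.encode()) & 0x7FFFFFFF


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return rng.choice(_BASES, size=n).tobytes().decode()


#: genome-average strand-collapsed motif spacing the simulator emulates
MOTIF_SPACING_BP = 9300


def _genomic_seq(rng: np.random.Generator, n: int, motif: str = NT_BSPQI_MOTIF) -> str:
    """Random DNA with at least ~70% of the genome-average motif density.

    Uniform-random sequence already carries close to one motif per ~8 kb on
    average, but an individual seeded region can come out pathologically
    sparse; mappable genomic DNA does not, so under-dense draws get motif
    copies planted at random positions until the floor is met.
    """
    seq = _random_seq(rng, n)
    if n < 2 * MOTIF_SPACING_BP:
        return seq
    target = int(0.7 * n / MOTIF_SPACING_BP)
    sites = in_silico_nick(seq, motif)
    guard = 0
    while len(sites) < target and guard < 200:
        guard += 1
        pos = int(rng.integers(0, n - len(motif)))
        if any(abs(pos - s.position) < 2000 for s in sites):
            continue
        seq = seq[:pos] + motif + seq[pos + len(motif):]
        sites = in_silico_nick(seq, motif)
    return seq


def _scrub_motif(seq: str, motif: str = NT_BSPQI_MOTIF) -> str:
    """Mutate bases until neither the motif nor its reverse complement occurs."""
    targets = (motif, revcomp(motif))
    buf = list(seq)
    for _ in range(200):
        text = "".join(buf)
        hit = -1
        for t in targets:
            idx = text.find(t)
            if idx >= 0:
                hit = idx
                break
        if hit < 0:
            return text
        mid = hit + len(motif) // 2
        buf[mid] = {"A": "C", "C": "A", "G": "T", "T": "G"}[buf[mid]]
    raise RuntimeError("failed to scrub motif occurrences")  # pragma: no cover


def _plant_sites(seq: str, positions: Sequence[int], motif: str = NT_BSPQI_MOTIF) -> str:
    """Overwrite ``seq`` with ``motif`` at each position (top strand)."""
    buf = list(seq)
    for p in positions:
        buf[p : p + len(motif)] = motif
    return "".join(buf)


def telomere_tract(length: int) -> str:
    """A literal (TTAGGG)n tract of ``length`` bp (guaranteed motif-free)."""
    reps = length // len(TELOMERE_UNIT) + 1
    return (TELOMERE_UNIT * reps)[:length]


class Edit(BaseModel):
    """One large structural difference carried by a haplotype.

    ``position`` is measured on the assembled pre-tract sequence (distal
    extra DNA + SRE blocks + 1-copy region), 0 at its telomeric edge.
    ``label`` salts the random content so edits shared between haplotypes
    (e.g. the same tandem-array unit) reuse identical sequence.
    """

    kind: Literal["insertion", "deletion", "nick_site_loss", "tandem_array"]
    position: int = Field(ge=0)
    size: int = 0
    copies: int = 0
    unit_length: int = 3300
    label: str = ""

    @model_validator(mode="after")
    def _check(self) -> "Edit":
        if self.kind in ("insertion", "deletion") and self.size <= 0:
            raise ValueError(f"{self.kind} requires size > 0")
        if self.kind == "tandem_array" and (self.copies <= 0 or self.unit_length <= 0):
            raise ValueError("tandem_array requires copies > 0 and unit_length > 0")
        return self

    def span(self) -> tuple[int, int]:
        """Footprint on the pre-edit sequence, for overlap checks."""
        if self.kind == "deletion":
            return (self.position, self.position + self.size)
        return (self.position, self.position + 1)


class SubtelomereSpec(BaseModel):
    """Architecture of one synthetic subtelomere and its haplotypes.

    SRE blocks are seeded by block id alone, so reusing a block id across
    different specs reproduces the paralogy sharing seen between real
    subtelomeres (the same duplicon appearing at several telomeres).
    """

    id: str
    arm: Literal["p", "q"] = "p"
    tract_lengths: dict[str, int]  # haplotype name -> (TTAGGG)n length, bp
    blocks: list[tuple[str, int]] = Field(default_factory=list)  # (block id, bp)
    one_copy_length: int = 150_000
    distal_extra_length: int = 0  # telomere-adjacent DNA absent from the reference
    distal_extra_motif_free: bool = False
    edits: dict[str, list[Edit]] = Field(default_factory=dict)
    reference_edits: list[Edit] = Field(default_factory=list)
    #: schematic mode: motif-scrubbed backbone of ``one_copy_length`` bp with
    #: the motif planted exactly at these positions (blocks must be empty)
    planted_sites: list[int] | None = None

    @model_validator(mode="after")
    def _check(self) -> "SubtelomereSpec":
        if not self.tract_lengths:
            raise ValueError("at least one haplotype is required")
        if self.planted_sites is not None and self.blocks:
            raise ValueError("planted_sites replaces the block backbone")
        for hap, t in self.tract_lengths.items():
            if t < 0:
                raise ValueError(f"tract length for {hap} must be >= 0")
        for hap, edits in self.edits.items():
            if hap not in self.tract_lengths:
                raise ValueError(f"edits given for unknown haplotype {hap!r}")
            spans = sorted(e.span() for e in edits)
            for (_, b0), (a1, _) in zip(spans, spans[1:]):
                if a1 < b0:
                    raise ValueError(f"overlapping edits for haplotype {hap!r}")
        return self

    @property
    def haplotype_names(self) -> list[str]:
        return list(self.tract_lengths)


class SimParams(BaseModel):
    """Molecule-generation parameters mirroring the imaging error model."""

    coverage: float = Field(default=30.0, ge=0)  # 0 = draw nothing
    min_molecule_length: float = Field(default=150_000.0, ge=0)
    length_median: float = Field(default=250_000.0, gt=0)
    length_sigma: float = Field(default=0.35, ge=0)  # log-normal shape
    fn_rate: float = Field(default=0.10, ge=0, le=1)
    fp_rate: float = Field(default=0.10, ge=0)
    fp_mode: Literal["per_true_site", "per_kb"] = "per_true_site"
    sizing_rel_sd: float = Field(default=0.03, ge=0)
    sizing_abs_sd: float = Field(default=250.0, ge=0)
    inp_break_probability: float = Field(default=0.5, ge=0, le=1)
    inp_max_gap: int = Field(default=1000, gt=0)
    seed: int = 0
    max_molecules: int = 200_000


@dataclass
class MoleculeTruth:
    """Hidden ground truth recorded before noise was applied."""

    haplotype: str
    start: float  # genomic origin interval on the haplotype sequence
    end: float
    reversed: bool
    n_true_spanned: int = 0  # true sites inside [start, end)
    n_true_labeled: int = 0  # of those, how many survived the FN draw


@dataclass
class Molecule:
    """One imaged DNA fragment: total length plus ordered label positions."""

    id: str
    length: float
    labels: np.ndarray  # strictly increasing, in molecule bp
    truth: MoleculeTruth | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if self.labels.size and not np.all(np.diff(self.labels) > 0):
            raise ValueError("labels must be strictly increasing")
        if self.labels.size and (self.labels[0] < 0 or self.labels[-1] >= self.length):
            raise ValueError("labels must lie in [0, length)")

    @property
    def n_labels(self) -> int:
        return int(self.labels.size)

    def reversed_copy(self, new_id: str | None = None) -> "Molecule":
        """The same fragment imaged in the opposite channel orientation."""
        truth = None
        if self.truth is not None:
            truth = MoleculeTruth(
                self.truth.haplotype,
                self.truth.start,
                self.truth.end,
                not self.truth.reversed,
                self.truth.n_true_spanned,
                self.truth.n_true_labeled,
            )
        return Molecule(
            id=new_id or self.id,
            length=self.length,
            labels=(self.length - self.labels)[::-1].copy(),
            truth=truth,
        )


@dataclass
class HaplotypeTruth:
    """One haplotype's full source sequence and its exact nick map."""

    name: str
    sequence: str
    map: ReferenceMap  # truth map of the whole haplotype molecule source
    tract_length: int
    ref_shift: int  # haplotype coordinate of the reference origin (edit-free part)
    stranded_sites: list[NickSite] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def inp_loci(self, max_gap: int) -> list[INPLocus]:
        return detect_inp(self.stranded_sites, max_gap)


def _block_sequence(block_id: str, length: int) -> str:
    rng = np.random.default_rng(_seed_from(f"sre-block:{block_id}"))
    return _genomic_seq(rng, length)


def _assemble_backbone(spec: SubtelomereSpec) -> str:
    """SRE blocks + 1-copy region (or the planted-site schematic backbone)."""
    if spec.planted_sites is not None:
        rng = np.random.default_rng(_seed_from(f"planted:{spec.id}"))
        seq = _scrub_motif(_random_seq(rng, spec.one_copy_length))
        return _plant_sites(seq, spec.planted_sites)
    parts = [_block_sequence(bid, blen) for bid, blen in spec.blocks]
    rng_u = np.random.default_rng(_seed_from(f"one-copy:{spec.id}"))
    parts.append(_genomic_seq(rng_u, spec.one_copy_length))
    return "".join(parts)


def _assemble_pretract(spec: SubtelomereSpec) -> str:
    """distal extra DNA + backbone, telomere edge at coordinate 0."""
    rng_d = np.random.default_rng(_seed_from(f"distal:{spec.id}"))
    distal = _genomic_seq(rng_d, spec.distal_extra_length)
    if spec.distal_extra_motif_free and distal:
        distal = _scrub_motif(distal)
    return distal + _assemble_backbone(spec)


def _apply_edits(seq: str, edits: Sequence[Edit], spec_id: str, motif: str) -> str:
    for edit in sorted(edits, key=lambda e: e.position, reverse=True):
        if edit.span()[1] > len(seq):
            raise ValueError(f"edit at {edit.position} outside sequence bounds")
        if edit.kind == "insertion":
            rng = np.random.default_rng(
                _seed_from(f"ins:{spec_id}:{edit.label or edit.position}")
            )
            ins = _genomic_seq(rng, edit.size)
            seq = seq[: edit.position] + ins + seq[edit.position :]
        elif edit.kind == "deletion":
            seq = seq[: edit.position] + seq[edit.position + edit.size :]
        elif edit.kind == "tandem_array":
            rng = np.random.default_rng(
                _seed_from(f"unit:{edit.label or spec_id}:{edit.unit_length}")
            )
            unit = _scrub_motif(_random_seq(rng, edit.unit_length), motif)
            # motif at both array flanks so the array length is readable as
            # the inter-site interval between the flanking labels
            ins = motif + unit * edit.copies + motif
            seq = seq[: edit.position] + ins + seq[edit.position :]
        elif edit.kind == "nick_site_loss":
            seq = _lose_nearest_site(seq, edit.position, motif)
    return seq


def _lose_nearest_site(seq: str, position: int, motif: str) -> str:
    sites = in_silico_nick(seq, motif)
    if not sites:
        raise ValueError("nick_site_loss: sequence has no sites")
    target = min(sites, key=lambda s: abs(s.position - position))
    p = target.position
    window = seq[p : p + len(motif)]
    if window not in (motif, revcomp(motif)):  # pragma: no cover - defensive
        raise RuntimeError("site bookkeeping mismatch")
    mid = p + len(motif) // 2
    swapped = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[mid]]
    return seq[:mid] + swapped + seq[mid + 1 :]


def build_diploid_subtelomere(
    spec: SubtelomereSpec, motif: str = NT_BSPQI_MOTIF
) -> dict[str, HaplotypeTruth]:
    """Realize every haplotype of ``spec`` as sequence plus exact nick map.

    Haplotypes share the spec's backbone; each edit is applied to the
    pre-tract sequence, then the (TTAGGG)n tract (motif-free by
    construction) is prepended (p-arm) or the whole sequence is
    reverse-complemented (q-arm) so the telomere sits at the correct edge.
    """
    backbone = _assemble_pretract(spec)
    out: dict[str, HaplotypeTruth] = {}
    for hap, tract_len in spec.tract_lengths.items():
        pretract = _apply_edits(backbone, spec.edits.get(hap, ()), spec.id, motif)
        seq = telomere_tract(tract_len) + pretract
        ref_shift = tract_len + spec.distal_extra_length
        if spec.arm == "q":
            seq = revcomp(seq)
            ref_shift = 0
        stranded = in_silico_nick(seq, motif)
        truth_map = build_reference_map(
            f"{spec.id}:{hap}", seq, arm=spec.arm, distal_offset=0, motif=motif
        )
        out[hap] = HaplotypeTruth(
            name=hap,
            sequence=seq,
            map=truth_map,
            tract_length=tract_len,
            ref_shift=ref_shift,
            stranded_sites=stranded,
        )
    return out


def build_reference(
    spec: SubtelomereSpec, motif: str = NT_BSPQI_MOTIF
) -> tuple[str, ReferenceMap]:
    """The reference assembly for ``spec``: backbone plus reference edits.

    The reference excludes the (TTAGGG)n tract (real assemblies lack
    significant telomere repeat) and excludes any ``distal_extra`` DNA
    (modelling unsequenced gap regions); when distal extra DNA exists the
    reference's ``distal_offset`` is unknown, so telomere length estimates
    against it are flagged as overestimates.
    """
    seq = _apply_edits(_assemble_backbone(spec), spec.reference_edits, spec.id, motif)
    if spec.arm == "q":
        seq = revcomp(seq)
    offset: int | None = 0 if spec.distal_extra_length == 0 else None
    ref = build_reference_map(spec.id, seq, arm=spec.arm, distal_offset=offset, motif=motif)
    return seq, ref


def one_copy_interval(spec: SubtelomereSpec, ref: ReferenceMap) -> tuple[int, int]:
    """Reference interval of chromosome-specific 1-copy DNA."""
    if spec.arm == "p":
        return (ref.length - spec.one_copy_length, ref.length)
    return (0, spec.one_copy_length)


def simulate_molecules(
    haplotypes: dict[str, HaplotypeTruth],
    params: SimParams,
    id_prefix: str = "mol",
) -> list[Molecule]:
    """Draw nick-labeled molecules from a set of haplotypes.

    Molecules are drawn until the total genomic footprint reaches
    ``coverage`` x total haplotype length.  Each draw picks a haplotype
    uniformly, a log-normal length truncated at ``min_molecule_length`` and
    clipped at the chromosome ends (so terminal molecules retain the full
    telomere tract distal of their start), keeps each spanned true site
    with probability ``1 - fn_rate``, adds Poisson spurious labels, rescales
    every inter-label interval with independent Gaussian sizing noise
    (SD = max(rel_sd * interval, abs_sd)), reverses the molecule with
    probability 1/2, and fragments it at spanned INP loci with
    ``inp_break_probability``.  Truth is recorded before noise.
    """
    rng = np.random.default_rng(params.seed)
    names = list(haplotypes)
    haps = [haplotypes[n] for n in names]
    inp_positions = [
        np.array([l.midpoint for l in h.inp_loci(params.inp_max_gap)]) for h in haps
    ]
    site_arrays = [np.asarray(h.map.sites, dtype=float) for h in haps]
    genome_length = sum(h.length for h in haps)
    target = params.coverage * genome_length

    molecules: list[Molecule] = []
    total = 0.0
    counter = 0
    attempts = 0
    while total < target and counter < params.max_molecules:
        attempts += 1
        if attempts > 100 * params.max_molecules:  # pragma: no cover
            raise RuntimeError("molecule sampling failed to reach target coverage")
        k = int(rng.integers(len(names)))
        hap = haps[k]
        mol_len = params.length_median * float(np.exp(params.length_sigma * rng.standard_normal()))
        start = float(rng.uniform(-mol_len, hap.length))
        s0, e0 = max(0.0, start), min(float(hap.length), start + mol_len)
        if e0 - s0 < params.min_molecule_length:
            continue
        # double-strand breaks at spanned inverted nick pairs
        pieces = [(s0, e0)]
        for pos in inp_positions[k]:
            if s0 < pos < e0 and rng.random() < params.inp_break_probability:
                new_pieces = []
                for a, b in pieces:
                    if a < pos < b:
                        new_pieces += [(a, pos), (pos, b)]
                    else:
                        new_pieces.append((a, b))
                pieces = new_pieces
        for a, b in pieces:
            if b - a < params.min_molecule_length:
                continue
            mol = _make_molecule(
                f"{id_prefix}{counter:06d}", names[k], site_arrays[k], a, b, params, rng
            )
            molecules.append(mol)
            total += b - a
            counter += 1
    return molecules


def _make_molecule(
    mol_id: str,
    hap_name: str,
    sites: np.ndarray,
    start: float,
    end: float,
    params: SimParams,
    rng: np.random.Generator,
) -> Molecule:
    frag_len = end - start
    spanned = sites[(sites >= start) & (sites < end)]
    keep = rng.random(spanned.size) >= params.fn_rate
    labels = spanned[keep] - start
    if params.fp_mode == "per_true_site":
        lam = params.fp_rate * spanned.size
    else:
        lam = params.fp_rate * frag_len / 1000.0
    n_fp = int(rng.poisson(lam)) if lam > 0 else 0
    if n_fp:
        labels = np.concatenate([labels, rng.uniform(0.0, frag_len, n_fp)])
    labels = np.unique(labels)

    if params.sizing_rel_sd > 0 or params.sizing_abs_sd > 0:
        bounds = np.concatenate([[0.0], labels, [frag_len]])
        d = np.diff(bounds)
        sd = np.maximum(params.sizing_rel_sd * d, params.sizing_abs_sd)
        d_noisy = np.maximum(d + rng.normal(0.0, 1.0, d.size) * sd, 1.0)
        positions = np.cumsum(np.concatenate([[0.0], d_noisy]))
        length = float(positions[-1])
        labels = positions[1:-1]
    else:
        length = frag_len

    rev = bool(rng.random() < 0.5)
    if rev and labels.size:
        labels = (length - labels)[::-1].copy()
    truth = MoleculeTruth(
        haplotype=hap_name,
        start=float(start),
        end=float(end),
        reversed=rev,
        n_true_spanned=int(spanned.size),
        n_true_labeled=int(keep.sum()),
    )
    return Molecule(id=mol_id, length=length, labels=labels, truth=truth)
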