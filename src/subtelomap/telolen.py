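"""Single-molecule telomere length estimation.

Reference subtelomere assemblies begin (p-arm) or end (q-arm) at the
subtelomeric sequence and carry essentially no (TTAGGG)n repeat, and the
repeat tract itself contains no nicking motif.  A molecule that aligns to
the reference and runs past its telomeric edge therefore overhangs by an
unlabeled stretch whose length is the telomere repeat tract.  The estimate
is the molecule length beyond the telomere-proximal *matched* label (using
the matched pair rather than the raw first label guards against false
positive labels in the tract), minus the matched site's distance from the
reference edge, minus any known distal offset between the reference edge
and the true tract start.  When that offset is unknown (gap haplotypes)
the estimate systematically overestimates the tract by up to the local
inter-site spacing and is flagged accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .align import Alignment, anchor_check
from .refmaps import ReferenceMap
from .simulate import Molecule

#: one unmatched label tolerated per this many bp of overhang before the
#: overhang is flagged as suspiciously labeled (false positives expected)
FP_ALLOWANCE_BP = 10_000.0


@dataclass
class TelomereEstimate:
    """Per-molecule telomere (TTAGGG)n tract length with filter flags."""

    molecule_id: str
    telomere_id: str
    length: float  # bp, >= 0
    orientation: str
    haplotype_id: str | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("length must be non-negative")


@dataclass
class TelomereSummary:
    """Per-telomere / per-haplotype aggregate: mean ± SD over n molecules."""

    telomere_id: str
    haplotype_id: str | None
    mean: float  # bp
    sd: float | None  # bp; undefined for n < 2
    n: int
    gap_flag: bool = False  # any member estimated against an unknown distal offset

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n >= 2 and self.sd is None:
            raise ValueError("sd must be defined for n >= 2")
        if self.n == 1 and self.sd is not None:
            raise ValueError("sd is undefined for n == 1")


def estimate_telomere_length(
    molecule: Molecule,
    alignment: Alignment,
    ref: ReferenceMap,
    *,
    min_confidence: float | None = None,
    one_copy_interval: tuple[float, float] | None = None,
    haplotype_id: str | None = None,
) -> TelomereEstimate | None:
    """Estimate one molecule's telomere tract length from its alignment.

    Returns ``None`` (estimate refused, not an error) when the alignment's
    confidence is below ``min_confidence`` or, if ``one_copy_interval`` is
    given, when no matched site anchors in 1-copy DNA.  Both filters are
    opt-in: pipeline callers pass their configured thresholds, while the
    worked-example/unit path may evaluate the bare arithmetic.

    In the oriented-molecule frame the telomere-proximal matched pair is
    the first pair (p-arm) or last pair (q-arm); the raw overhang is the
    molecule length distal of that label minus the matched site's distance
    from the reference's telomeric edge.  Negative raw values (possible
    under sizing noise) clamp to 0 with a ``negative_clamped`` flag.
    """
    if min_confidence is not None and alignment.confidence < min_confidence:
        return None
    if one_copy_interval is not None and not anchor_check(alignment, ref, one_copy_interval):
        return None

    labels = alignment.oriented_labels(molecule)
    if ref.arm == "p":
        i_star, j_star = alignment.pairs[0]
        overhang = float(labels[i_star])
        site_to_edge = float(ref.sites[j_star])
        n_overhang_labels = int(i_star)
    else:
        i_star, j_star = alignment.pairs[-1]
        overhang = float(molecule.length - labels[i_star])
        site_to_edge = float(ref.length - ref.sites[j_star])
        n_overhang_labels = int(len(labels) - 1 - i_star)

    raw = overhang - site_to_edge
    flags: set[str] = set()
    if ref.distal_offset is None:
        flags.add("gap_haplotype_overestimate")
    else:
        raw -= ref.distal_offset
    if raw < 0:
        raw = 0.0
        flags.add("negative_clamped")
    if n_overhang_labels > max(raw, 0.0) / FP_ALLOWANCE_BP:
        flags.add("overhang_labels_present")
    return TelomereEstimate(
        molecule_id=molecule.id,
        telomere_id=ref.id,
        length=raw,
        orientation=alignment.orientation,
        haplotype_id=haplotype_id,
        flags=flags,
    )


def aggregate_lengths(
    estimates: Iterable[TelomereEstimate],
    by_haplotype: bool = True,
) -> list[TelomereSummary]:
    """Group estimates per telomere (and haplotype) into mean ± SD, n.

    Sample SD uses the n-1 denominator and is undefined (None) for single
    molecule groups.  Empty groups are simply absent.  A group inherits the
    gap flag if any member was estimated against an unknown distal offset.
    """
    groups: dict[tuple[str, str | None], list[TelomereEstimate]] = {}
    for est in estimates:
        key = (est.telomere_id, est.haplotype_id if by_haplotype else None)
        groups.setdefault(key, []).append(est)
    summaries = []
    for (tel, hap), members in sorted(groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
        values = np.array([m.length for m in members], dtype=float)
        n = values.size
        summaries.append(
            TelomereSummary(
                telomere_id=tel,
                haplotype_id=hap,
                mean=float(values.mean()),
                sd=float(values.std(ddof=1)) if n >= 2 else None,
                n=int(n),
                gap_flag=any("gap_haplotype_overestimate" in m.flags for m in members),
            )
        )
    return summaries


def estimate_all(
    molecules: Sequence[Molecule],
    alignments: Sequence[Alignment | None],
    ref: ReferenceMap,
    *,
    min_confidence: float | None = None,
    one_copy_interval: tuple[float, float] | None = None,
    haplotype_of: dict[str, str] | None = None,
) -> list[TelomereEstimate]:
    """Vector form of :func:`estimate_telomere_length` over a molecule set."""
    out = []
    for mol, aln in zip(molecules, alignments):
        if aln is None:
            continue
        est = estimate_telomere_length(
            mol,
            aln,
            ref,
            min_confidence=min_confidence,
            one_copy_interval=one_copy_interval,
            haplotype_id=(haplotype_of or {}).get(mol.id),
        )
        if est is not None:
            out.append(est)
    return out
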