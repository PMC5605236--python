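"""In-silico nick maps of reference sequences.

A nicking endonuclease (Nt.BspQI by default) cuts one strand of the double
helix wherever its recognition motif occurs.  Labelling those nicks turns a
long DNA molecule into an ordered pattern of fluorescent marks; the same
pattern can be computed for a reference sequence by scanning for the motif
on both strands.  This module performs that electronic digest, collapses it
to the strand-less coordinate list the imaging system actually observes,
annotates assembly gaps (which carry no sequence, hence no sites), and flags
inverted nick pairs (INPs) -- two close opposite-strand sites whose
simultaneous nicking breaks the double helix and fragments molecules.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: Canonical Nt.BspQI recognition sequence.  The enzyme nicks one base
#: downstream of the motif; at map scale (kb) the offset is immaterial, so
#: the motif start is used as the site coordinate by default.
NT_BSPQI_MOTIF = "GCTCTTC"

TELOMERE_UNIT = "TTAGGG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_SEQ_ALPHABET = frozenset("ACGTN")
_MOTIF_ALPHABET = frozenset("ACGT")


def revcomp(sequence: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class NickSite:
    """A single motif occurrence: base-pair offset plus the nicked strand."""

    position: int
    strand: str  # "top" | "bottom"

    def __post_init__(self) -> None:
        if self.strand not in ("top", "bottom"):
            raise ValueError(f"strand must be 'top' or 'bottom', got {self.strand!r}")
        if self.position < 0:
            raise ValueError("position must be non-negative")


@dataclass(frozen=True)
class INPLocus:
    """Inverted nick pair: adjacent opposite-strand sites within ``gap`` bp.

    Both strands nicked close together amounts to a double-strand break, so
    molecules spanning an INP locus tend to fragment there.
    """

    left_site: NickSite
    right_site: NickSite
    gap: int

    def __post_init__(self) -> None:
        if self.left_site.strand == self.right_site.strand:
            raise ValueError("INP sites must lie on opposite strands")
        if self.gap != self.right_site.position - self.left_site.position:
            raise ValueError("gap must equal the distance between the two sites")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.left_site.position + self.right_site.position)


@dataclass
class ReferenceMap:
    """Strand-collapsed nick map of one subtelomere reference.

    Parameters
    ----------
    id:
        Telomere identifier, e.g. ``"15q"``.
    length:
        Reference length in bp.
    sites:
        Strictly increasing strand-collapsed site positions (bp).  The
        imaging system cannot tell strands apart, so only positions are kept
        here; strand information lives in :class:`NickSite` for INP work.
    arm:
        ``"p"`` places the telomere at the map origin (coordinate 0),
        ``"q"`` at the map terminus (coordinate ``length``).
    gaps:
        ``[start, end)`` intervals with no sequence content (e.g. NNN runs);
        they can contain no sites.
    distal_offset:
        bp between the map's telomeric edge and the true start of the
        (TTAGGG)n tract, or ``None`` when unknown (gap haplotypes).  Unknown
        offsets make downstream telomere-length estimates overestimates.
    """

    id: str
    length: int
    sites: list[int]
    arm: str = "p"
    gaps: list[tuple[int, int]] = field(default_factory=list)
    distal_offset: int | None = 0

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValueError("arm must be 'p' or 'q'")
        if self.length < 0:
            raise ValueError("length must be non-negative")
        self.sites = [int(s) for s in self.sites]
        if any(b <= a for a, b in zip(self.sites, self.sites[1:])):
            raise ValueError("sites must be strictly increasing")
        if self.sites and not (0 <= self.sites[0] and self.sites[-1] < self.length):
            raise ValueError("sites must lie within [0, length)")
        self.gaps = [(int(a), int(b)) for a, b in self.gaps]
        _check_gaps(self.gaps, self.length)
        for a, b in self.gaps:
            if any(a <= s < b for s in self.sites):
                raise ValueError("no site may lie inside a gap interval")
        if self.distal_offset is not None and not (0 <= self.distal_offset <= self.length):
            raise ValueError("distal_offset must lie in [0, length] when known")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def telomeric_edge(self) -> int:
        """Reference coordinate of the telomere-proximal map edge."""
        return 0 if self.arm == "p" else self.length


def _check_gaps(gaps: Sequence[tuple[int, int]], length: int) -> None:
    ordered = sorted(gaps)
    for a, b in ordered:
        if not (0 <= a < b <= length):
            raise ValueError(f"gap interval [{a}, {b}) outside [0, {length})")
    for (_, b0), (a1, _) in zip(ordered, ordered[1:]):
        if a1 < b0:
            raise ValueError("gap intervals must not overlap")


def _validate_motif(motif: str) -> str:
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 bp")
    bad = set(motif) - _MOTIF_ALPHABET
    if bad:
        raise ValueError(f"motif contains characters outside {{A,C,G,T}}: {sorted(bad)}")
    return motif


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = 0
    while True:
        idx = haystack.find(needle, start)
        if idx < 0:
            return
        yield idx
        start = idx + 1  # overlapping occurrences count


def in_silico_nick(
    sequence: str,
    motif: str = NT_BSPQI_MOTIF,
    nick_offset: int = 0,
) -> list[NickSite]:
    """Electronically digest ``sequence`` with a nicking enzyme motif.

    One :class:`NickSite` is produced per occurrence of ``motif`` on the top
    strand and per occurrence of its reverse complement (a bottom-strand
    occurrence).  Any window containing ``N`` matches nothing, so assembly
    gaps are label-free.  The site coordinate is the motif occurrence start
    (in top-strand coordinates) shifted by ``nick_offset`` towards the
    enzyme's actual nick position: ``+nick_offset`` for top-strand sites,
    ``-nick_offset`` for bottom-strand sites, clamped to the sequence.

    Returns sites sorted by position (then strand).
    """
    motif = _validate_motif(motif)
    sequence = sequence.upper()
    bad = set(sequence) - _SEQ_ALPHABET
    if bad:
        raise ValueError(f"sequence contains characters outside {{A,C,G,T,N}}: {sorted(bad)}")
    length = len(sequence)
    rc_motif = revcomp(motif)
    sites: list[NickSite] = []
    for pos in _find_all(sequence, motif):
        p = min(max(pos + nick_offset, 0), length - 1)
        sites.append(NickSite(p, "top"))
    for pos in _find_all(sequence, rc_motif):
        p = min(max(pos - nick_offset, 0), length - 1)
        sites.append(NickSite(p, "bottom"))
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def detect_inp(sites: Sequence[NickSite], max_gap: int) -> list[INPLocus]:
    """Report adjacent opposite-strand site pairs separated by ≤ ``max_gap`` bp.

    ``sites`` must be sorted by position.  Each qualifying adjacent pair is
    reported exactly once.
    """
    if max_gap <= 0:
        raise ValueError("max_gap must be positive")
    positions = [s.position for s in sites]
    if positions != sorted(positions):
        raise ValueError("sites must be sorted by position")
    loci: list[INPLocus] = []
    for left, right in zip(sites, sites[1:]):
        if left.strand != right.strand and right.position - left.position <= max_gap:
            loci.append(INPLocus(left, right, right.position - left.position))
    return loci


def build_reference_map(
    id: str,
    sequence_or_sites: str | Sequence[int] | Sequence[NickSite],
    arm: str = "p",
    gaps: Sequence[tuple[int, int]] = (),
    distal_offset: int | None = 0,
    *,
    length: int | None = None,
    motif: str = NT_BSPQI_MOTIF,
) -> ReferenceMap:
    """Assemble a strand-collapsed :class:`ReferenceMap`.

    ``sequence_or_sites`` may be a nucleotide string (digested in silico
    with ``motif``), a list of :class:`NickSite`, or bare integer positions.
    Sites are strand-collapsed and deduplicated, and sites falling inside
    ``gaps`` are removed (gap sequence is unknown, so its electronic digest
    is void).  ``length`` is required unless a sequence is given.
    """
    if isinstance(sequence_or_sites, str):
        raw = in_silico_nick(sequence_or_sites, motif)
        positions = [s.position for s in raw]
        length = len(sequence_or_sites)
    else:
        positions = [
            s.position if isinstance(s, NickSite) else int(s) for s in sequence_or_sites
        ]
        if length is None:
            raise ValueError("length is required when passing a site list")
    _check_gaps(list(gaps), length)
    collapsed = sorted(set(positions))
    kept = [p for p in collapsed if not any(a <= p < b for a, b in gaps)]
    return ReferenceMap(
        id=id,
        length=length,
        sites=kept,
        arm=arm,
        gaps=list(gaps),
        distal_offset=distal_offset,
    )
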