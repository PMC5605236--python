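"""Nick-pattern alignment of single molecules to reference maps.

A molecule is an ordered list of label positions; a reference map is an
ordered list of site positions.  Alignment finds the maximum-score monotone
pairing of labels to sites over both channel orientations.  Each matched
pair earns a fixed information credit; each matched inter-label interval is
scored as a log-likelihood ratio of the sizing model (SD =
max(rel_sd * interval, abs_sd)) against a flat null at genomic label
density, capped at ``outlier_penalty`` so that large indels cross the
alignment as bounded-cost outlier intervals instead of breaking it;
skipped sites and labels pay per-event penalties except inside a declared
outlier interval, whose content is explained by the indel itself.
Alignment is semi-global in the molecule: unmatched labels beyond the
chain ends are charged when they would project inside the reference, and
free when they project beyond it (telomere-tract overhangs, gap
extensions, molecules running off the map).

Confidence is the log10 margin between the best alignment and its
strongest competitor: the best placement at a distinctly different offset
(either orientation) or the best alignment to interval-shuffled decoy maps.
The scale is this package's own; the conventional threshold of 20 used by
commercial mapping pipelines refers to an unpublished proprietary score,
and the default here is calibrated so that essentially no random molecule
passes while typical well-anchored molecules (15+ labels) do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .refmaps import ReferenceMap
from .simulate import Molecule

LN10 = math.log(10.0)


@dataclass
class ScoringParams:
    """Alignment scoring knobs; sizing terms should match the data's noise."""

    rel_sd: float = 0.03  # relative sizing SD per interval
    abs_sd: float = 250.0  # absolute sizing SD floor, bp
    match_bonus: float = 5.0  # credit (nats) per matched label/site pair
    miss_penalty: float = 2.3  # per unmatched reference site spanned (~ -ln 0.1)
    extra_penalty: float = 2.3  # per unmatched molecule label spanned (~ -ln 0.1)
    outlier_penalty: float = 12.0  # cap on one interval's sizing cost (nats)
    site_density_bp: float = 9_300.0  # genome-average motif spacing; scales the
    # information reward a tightly matched interval earns over a random one
    max_skips: int = 8  # max consecutive skipped sites or labels (a 50 kb
    # insertion at ~9 kb label spacing needs ~6 skips to bridge)
    min_confidence: float = 12.0  # log10 margin required of a placement;
    # calibrated so that no molecule out of 1200 random label patterns
    # (uniform labels at genomic density vs. four preset references) passes
    min_matched_pairs: int = 2
    n_decoys: int = 3
    decoy_seed: int = 1729
    offset_tol: float = 30_000.0  # offsets closer than this are one placement

    def __post_init__(self) -> None:
        if min(self.miss_penalty, self.extra_penalty, self.outlier_penalty) < 0:
            raise ValueError("penalties must be non-negative")
        if self.min_confidence < 0:
            raise ValueError("min_confidence must be non-negative")
        if self.max_skips < 0:
            raise ValueError("max_skips must be non-negative")
        if self.min_matched_pairs < 2:
            raise ValueError("min_matched_pairs must be at least 2")

    def interval_sd(self, dr: float) -> float:
        return max(self.rel_sd * dr, self.abs_sd, 1e-9)

    def interval_score(self, dm: float, dr: float) -> float:
        """Log-likelihood-ratio of a matched interval vs a random placement.

        Gaussian sizing likelihood against a flat null at the genome's
        label density; the sizing term is capped so a large indel crosses
        as one bounded-cost outlier interval.
        """
        sd = self.interval_sd(dr)
        z = (dm - dr) / sd
        reward = max(0.0, math.log(self.site_density_bp / (sd * 2.5066282746310002)))
        return reward - min(0.5 * z * z, self.outlier_penalty)

    def transition_score(self, dm: float, dr: float, n_extra: int, n_miss: int) -> float:
        """Score of one chain transition (matched interval plus its skips).

        When the sizing cost hits the outlier cap the interval is treated
        as an indel: the labels/sites inside it belong to DNA present in
        only one of molecule and reference, so they are explained by the
        indel itself rather than charged as noise.
        """
        sd = self.interval_sd(dr)
        z = (dm - dr) / sd
        half_z2 = 0.5 * z * z
        reward = max(0.0, math.log(self.site_density_bp / (sd * 2.5066282746310002)))
        if half_z2 >= self.outlier_penalty:
            return reward - self.outlier_penalty
        return reward - half_z2 - n_extra * self.extra_penalty - n_miss * self.miss_penalty


@dataclass
class Alignment:
    """Best-scoring placement of one molecule on one reference map.

    ``pairs`` are (label index, site index) matches, strictly increasing in
    both coordinates; label indices refer to the *oriented* molecule (for a
    reverse alignment, label k is the k-th label after mirroring the
    molecule).  ``offset`` is the reference coordinate of oriented-molecule
    coordinate 0.  ``residuals`` hold, per matched interval, molecule length
    minus reference length in bp (positive = molecule longer).
    """

    molecule_id: str
    ref_id: str
    orientation: str  # "forward" | "reverse"
    pairs: list[tuple[int, int]]
    offset: float
    score: float
    confidence: float
    residuals: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError("orientation must be 'forward' or 'reverse'")
        for (i0, j0), (i1, j1) in zip(self.pairs, self.pairs[1:]):
            if i1 <= i0 or j1 <= j0:
                raise ValueError("pairs must be strictly increasing in both indices")
        if self.confidence < 0:
            raise ValueError("confidence must be non-negative")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def matched_sites(self, ref: ReferenceMap) -> list[int]:
        return [ref.sites[j] for _, j in self.pairs]

    def oriented_labels(self, molecule: Molecule) -> np.ndarray:
        return orient_labels(molecule, self.orientation)


@dataclass(frozen=True)
class OutlierInterval:
    """A matched interval whose sizing residual indicates an indel."""

    start: float  # reference bp
    end: float
    size_delta: float  # signed bp; positive = insertion in the molecule
    molecule_id: str


def orient_labels(molecule: Molecule, orientation: str) -> np.ndarray:
    if orientation == "forward":
        return molecule.labels
    return (molecule.length - molecule.labels)[::-1].copy()


class _DPTables:
    """Two-layer chain DP over (label i, site j) cells.

    ``s1`` is the best score of any chain ending at a cell; ``s2`` the best
    with at least two matched pairs (its prefix is a best ``s1`` chain,
    which keeps the layer exact when the connecting link scores below
    zero).  ``start2`` flattens the chain's first pair for offset
    bookkeeping; ``parent2``/``parent1`` support traceback.

    Alignment is semi-global in the molecule: unmatched labels beyond the
    chain ends are charged ``extra_penalty`` when they would project
    *inside* the reference (a chain must explain the part of the molecule
    the reference covers), and are free when they project beyond it
    (telomere-tract overhangs, gap extensions, molecules running off the
    map).  The start-side charge depends only on the chain's first pair and
    the end-side charge only on its last, so applying them at chain
    initiation and at selection keeps the DP exact.
    """

    __slots__ = (
        "n", "m", "s1", "s2", "parent1", "parent2",
        "start1", "start2", "npairs1", "npairs2", "end_pen",
    )

    def __init__(
        self,
        labels: np.ndarray,
        sites: Sequence[float],
        params: ScoringParams,
        ref_length: float,
    ):
        n, m = len(labels), len(sites)
        self.n, self.m = n, m
        NEG = -math.inf
        lab = np.asarray(labels, dtype=float)
        site_arr = np.asarray(sites, dtype=float)
        # start_pen[i][j]: labels before i that project at or after the
        # reference origin when (i, j) is the first pair
        # end_pen[i][j]:   labels after i that project at or before the
        # reference end when (i, j) is the last pair
        start_pen = np.empty((n, m))
        end_pen = np.empty((n, m))
        for i in range(n):
            lo = lab[i] - site_arr  # label position projecting to ref coord 0
            hi = lab[i] + (ref_length - site_arr)
            start_pen[i] = (i - np.searchsorted(lab[:i], lo, side="left")) * params.extra_penalty
            end_pen[i] = (
                np.searchsorted(lab[i + 1 :], hi, side="right")
            ) * params.extra_penalty
        self.end_pen = end_pen

        s1 = [[0.0] * m for _ in range(n)]
        s2 = [[NEG] * m for _ in range(n)]
        parent1 = [[-1] * m for _ in range(n)]
        parent2 = [[-1] * m for _ in range(n)]
        start1 = [[0] * m for _ in range(n)]
        start2 = [[0] * m for _ in range(n)]
        npairs1 = [[1] * m for _ in range(n)]
        npairs2 = [[0] * m for _ in range(n)]
        k = params.max_skips
        mb = params.match_bonus
        tscore = params.transition_score
        for i in range(n):
            li = float(lab[i])
            row1, row2 = s1[i], s2[i]
            sp_row = start_pen[i]
            for j in range(m):
                sj = sites[j]
                best_ext = NEG
                best_parent = -1
                for pi in range(max(0, i - 1 - k), i):
                    dm = li - float(lab[pi])
                    n_extra = i - pi - 1
                    ps1 = s1[pi]
                    for pj in range(max(0, j - 1 - k), j):
                        cand = ps1[pj] + tscore(dm, sj - sites[pj], n_extra, j - pj - 1)
                        if cand > best_ext:
                            best_ext = cand
                            best_parent = pi * m + pj
                fresh = -float(sp_row[j])
                if best_parent >= 0:
                    row2[j] = best_ext + mb
                    parent2[i][j] = best_parent
                    pi, pj = divmod(best_parent, m)
                    start2[i][j] = start1[pi][pj]
                    npairs2[i][j] = npairs1[pi][pj] + 1
                if best_ext > fresh:
                    row1[j] = best_ext + mb
                    parent1[i][j] = best_parent
                    pi, pj = divmod(best_parent, m)
                    start1[i][j] = start1[pi][pj]
                    npairs1[i][j] = npairs1[pi][pj] + 1
                else:
                    row1[j] = fresh + mb
                    start1[i][j] = i * m + j
        self.s1, self.s2 = s1, s2
        self.parent1, self.parent2 = parent1, parent2
        self.start1, self.start2 = start1, start2
        self.npairs1, self.npairs2 = npairs1, npairs2

    def final_score(self, i: int, j: int) -> float:
        return self.s2[i][j] - float(self.end_pen[i][j])

    def best(self, min_pairs: int) -> tuple[float, int, int] | None:
        """Best (score, end_i, end_j) among chains with >= min_pairs pairs."""
        best_score = -math.inf
        best_cell = None
        for i in range(self.n):
            row, nprow, ep = self.s2[i], self.npairs2[i], self.end_pen[i]
            for j in range(self.m):
                if nprow[j] < min_pairs:
                    continue
                score = row[j] - float(ep[j])
                if score > best_score:
                    best_score = score
                    best_cell = (i, j)
        if best_cell is None:
            return None
        return best_score, best_cell[0], best_cell[1]

    def traceback(self, end_i: int, end_j: int) -> list[tuple[int, int]]:
        pairs = [(end_i, end_j)]
        cur = self.parent2[end_i][end_j]
        while cur >= 0:
            i, j = divmod(cur, self.m)
            pairs.append((i, j))
            cur = self.parent1[i][j]
        return pairs[::-1]


_DECOY_CACHE: dict[tuple, list[list[float]]] = {}


def decoy_maps(ref: ReferenceMap, params: ScoringParams) -> list[list[float]]:
    """Interval-shuffled versions of ``ref`` used as confidence competitors."""
    key = (ref.id, ref.length, tuple(ref.sites), params.n_decoys, params.decoy_seed)
    cached = _DECOY_CACHE.get(key)
    if cached is not None:
        return cached
    sites = np.asarray(ref.sites, dtype=float)
    decoys: list[list[float]] = []
    if sites.size >= 3:
        rng = np.random.default_rng(params.decoy_seed)
        intervals = np.diff(sites)
        for _ in range(params.n_decoys):
            # an identity-order shuffle would be the true map, and a mirrored
            # one is the true map read backwards (the same physical
            # placement under molecule reversal) -- neither is a decoy
            for _attempt in range(20):
                shuffled = rng.permutation(intervals)
                if not np.array_equal(shuffled, intervals) and not np.array_equal(
                    shuffled, intervals[::-1]
                ):
                    break
            else:
                continue
            decoys.append(list(sites[0] + np.concatenate([[0.0], np.cumsum(shuffled)])))
    _DECOY_CACHE[key] = decoys
    return decoys


def align_molecule(
    molecule: Molecule,
    ref: ReferenceMap,
    params: ScoringParams | None = None,
) -> Alignment | None:
    """Best alignment of ``molecule`` to ``ref`` over both orientations.

    Returns ``None`` ("unalignable") when the molecule has fewer than two
    labels or no chain with ``min_matched_pairs`` matches exists.  The
    returned alignment's confidence is always computed; callers decide
    whether to filter on ``params.min_confidence``.

    Ties are broken by (higher score, more matched pairs, smaller absolute
    total residual, forward orientation).
    """
    params = params or ScoringParams()
    if molecule.n_labels < 2 or ref.n_sites < 2:
        return None
    sites = [float(s) for s in ref.sites]

    tables: dict[str, tuple[_DPTables, np.ndarray]] = {}
    candidates = []
    for orientation in ("forward", "reverse"):
        labels = orient_labels(molecule, orientation)
        dp = _DPTables(labels, sites, params, float(ref.length))
        tables[orientation] = (dp, labels)
        top = dp.best(params.min_matched_pairs)
        if top is None:
            continue
        score, ei, ej = top
        pairs = dp.traceback(ei, ej)
        residual = sum(
            abs((labels[i1] - labels[i0]) - (sites[j1] - sites[j0]))
            for (i0, j0), (i1, j1) in zip(pairs, pairs[1:])
        )
        npairs = len(pairs)
        candidates.append((score, npairs, residual, orientation, pairs))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2], 0 if c[3] == "forward" else 1))
    score, _, _, orientation, pairs = candidates[0]
    dp, labels = tables[orientation]
    i0, j0 = pairs[0]
    best_offset = sites[j0] - float(labels[i0])

    # a rival explanation must account for a comparable share of the
    # molecule: tiny sub-patterns (e.g. a coincidentally palindromic run of
    # a few intervals) do not make the placement of a 15-label molecule
    # ambiguous
    min_pairs_comp = max(params.min_matched_pairs, (len(pairs) + 1) // 2)
    competitor = _competitor_score(
        tables, sites, best_offset, orientation, set(pairs), min_pairs_comp, params
    )
    for decoy in decoy_maps(ref, params):
        for o in ("forward", "reverse"):
            dtop = _DPTables(tables[o][1], decoy, params, float(ref.length)).best(min_pairs_comp)
            if dtop is not None:
                competitor = max(competitor, dtop[0])
    confidence = max(0.0, (score - competitor) / LN10)

    residuals = [
        float((labels[i1] - labels[i0]) - (sites[j1] - sites[j0]))
        for (i0, j0), (i1, j1) in zip(pairs, pairs[1:])
    ]
    return Alignment(
        molecule_id=molecule.id,
        ref_id=ref.id,
        orientation=orientation,
        pairs=pairs,
        offset=float(best_offset),
        score=float(score),
        confidence=float(confidence),
        residuals=residuals,
    )


def _competitor_score(
    tables: dict[str, tuple[_DPTables, np.ndarray]],
    sites: Sequence[float],
    best_offset: float,
    best_orientation: str,
    best_pairs: set[tuple[int, int]],
    min_pairs: int,
    params: ScoringParams,
) -> float:
    """Best chain score at a placement genuinely distinct from the winner's.

    Chains at a nearby offset are the same placement under noise, and
    chains whose start or end pair belongs to the winning chain are
    sub-placements of it (e.g. the non-SV block of a molecule carrying a
    large indel, re-anchored at a shifted offset) -- neither measures
    ambiguity, so both are excluded.
    """
    competitor = 0.0
    for orientation, (dp, labels) in tables.items():
        same = orientation == best_orientation
        for i in range(dp.n):
            srow, nprow, strow = dp.s2[i], dp.npairs2[i], dp.start2[i]
            ep = dp.end_pen[i]
            for j in range(dp.m):
                if nprow[j] < min_pairs:
                    continue
                score = srow[j] - float(ep[j])
                if score <= competitor:
                    continue
                si, sj = divmod(strow[j], dp.m)
                off = sites[sj] - float(labels[si])
                if same and abs(off - best_offset) <= params.offset_tol:
                    continue
                if same and ((si, sj) in best_pairs or (i, j) in best_pairs):
                    continue
                competitor = score
    return competitor


def anchor_check(
    alignment: Alignment, ref: ReferenceMap, one_copy_interval: tuple[float, float]
) -> bool:
    """True iff at least one matched reference site lies in the 1-copy region.

    Anchoring in chromosome-specific 1-copy DNA is what guarantees the
    molecule belongs to this subtelomere rather than to a paralogous one.
    """
    a, b = one_copy_interval
    return any(a <= ref.sites[j] < b for _, j in alignment.pairs)


def detect_outliers(
    alignment: Alignment,
    ref: ReferenceMap,
    molecule: Molecule,
    min_size: float = 5000.0,
) -> list[OutlierInterval]:
    """Matched intervals whose sizing residual exceeds ``min_size`` in bp.

    Positive ``size_delta`` means the molecule carries more DNA than the
    reference across that interval (insertion); negative means less
    (deletion).  Runs of skipped reference sites fold into the enclosing
    matched interval's residual.
    """
    labels = alignment.oriented_labels(molecule)
    out: list[OutlierInterval] = []
    for (i0, j0), (i1, j1) in zip(alignment.pairs, alignment.pairs[1:]):
        dr = float(ref.sites[j1] - ref.sites[j0])
        dm = float(labels[i1] - labels[i0])
        delta = dm - dr
        if abs(delta) > min_size:
            out.append(
                OutlierInterval(
                    start=float(ref.sites[j0]),
                    end=float(ref.sites[j1]),
                    size_delta=delta,
                    molecule_id=alignment.molecule_id,
                )
            )
    return out
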