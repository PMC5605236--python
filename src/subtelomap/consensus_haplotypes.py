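"""Reference-anchored consensus maps, haplotype partitioning, SV calls, trios.

Aligned molecules are projected into reference coordinates and their labels
clustered into consensus sites; consensus inter-site intervals are
re-estimated from the molecule-measured label distances (not from the
reference), so insertions and deletions carried by the sample survive into
the consensus geometry.  Consensus maps may extend beyond the reference's
telomeric edge (gap delineation / distal extension).

Haplotype partitioning proposes discriminant features from bimodality --
a consensus site supported by an intermediate fraction of spanning
molecules (site presence/absence) or an inter-site interval whose
molecule-level lengths split into two well-separated modes (large indel or
tandem-array copy-number difference) -- and assigns each molecule to the
haplotype group agreeing with most of its observed features.  Structural
variant calls compare consensus geometry with the reference and are coded
``g`` (gap fill / distal extension), ``sv`` (large insertion/deletion) and
``h`` (call differs between haplotype groups), mirroring the gap /
haplotype / SV vocabulary used for subtelomere surveys.

This is deliberately *reference-anchored* consensus building, not de novo
overlap-layout-consensus assembly: every subtelomere-scale question here
(gap fills, haplotypes, large SVs) is expressed relative to a reference
map, for which anchored consensus with end extension suffices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import Alignment, ScoringParams, align_molecule, detect_outliers, orient_labels
from .refmaps import ReferenceMap
from .simulate import Molecule


@dataclass
class ConsensusParams:
    """Consensus building, haplotype clustering and SV calling knobs."""

    min_molecules: int = 5  # below this: no-consensus
    min_site_support_abs: int = 3
    min_site_support_frac: float = 0.30  # of spanning molecules; tolerant of 10% FN
    #: consensus sites with no reference match need slightly stronger support:
    #: chance runs of false-positive labels reach ~1/3 of spanning molecules
    min_segment_support_frac: float = 0.35
    cluster_gap: float = 1500.0  # 1-D gap threshold for unmatched-label clustering, bp
    #: a true heterozygous site is carried by ~45% of spanning molecules
    #: (half the molecules, less the 10% false-negative rate); homozygous
    #: sites sit at 70-90% once aligner slop is added, so the acceptance
    #: window is asymmetric around one-half
    het_low: float = 0.30
    het_high: float = 0.65
    min_group_members: int = 5
    min_mode_separation: float = 10_000.0  # interval bimodality threshold, bp
    sv_min_size: float = 20_000.0  # large-SV size floor
    site_match_tol: float = 3_000.0  # consensus-vs-consensus site matching, bp
    snap_tol: float = 5_000.0  # absorb sizing drift onto reference site positions


@dataclass
class ConsensusMap:
    """Ordered consensus label positions in reference coordinates.

    Sites may be negative (distal of a p-arm reference origin) or beyond
    the reference length: that is the map's end extension.
    """

    telomere_id: str
    haplotype_id: str | None
    sites: list[float]
    support: list[int]
    extension_length: float = 0.0
    n_molecules: int = 0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.sites, self.sites[1:])):
            raise ValueError("consensus sites must be strictly increasing")
        if len(self.support) != len(self.sites):
            raise ValueError("one support count per site required")


@dataclass(frozen=True)
class Feature:
    """A discriminant observable separating haplotypes."""

    kind: str  # "site_presence" | "interval_length"
    position: float  # ref coordinate: the site, or the interval start
    interval: tuple[float, float] | None = None
    modes: tuple[float, float] | None = None  # (lo, hi) for interval_length

    @property
    def fid(self) -> str:
        return f"{self.kind}@{self.position:.0f}"


@dataclass
class HaplotypeGroup:
    """One allelic long-range structure and the molecules supporting it."""

    haplotype_id: str
    features: dict[str, object]  # feature id -> expected observation
    member_ids: list[str]
    consensus: ConsensusMap | None = None
    warning: bool = False


@dataclass
class ClusterResult:
    groups: list[HaplotypeGroup]
    features: list[Feature]
    unassigned_ids: list[str]

    @property
    def zygosity(self) -> str:
        return {1: "homozygous", 2: "heterozygous"}.get(len(self.groups), "complex")


@dataclass
class SVCall:
    """One structural call relative to the reference map."""

    telomere_id: str
    type: str  # insertion | deletion | gap_fill | distal_extension
    position: float  # reference bp
    size: float  # bp
    haplotype_id: str | None
    support: int
    codes: tuple[str, ...]  # subset of ("g", "h", "sv")

    def __post_init__(self) -> None:
        if self.type not in ("insertion", "deletion", "gap_fill", "distal_extension"):
            raise ValueError(f"unknown SV type {self.type!r}")
        if any(c not in ("g", "h", "sv") for c in self.codes):
            raise ValueError("codes must be among g/h/sv")


# ---------------------------------------------------------------------------
# label projection and clustering


@dataclass
class _MoleculeTrack:
    mol: Molecule
    aln: Alignment
    labels: np.ndarray  # oriented
    proj: np.ndarray  # nearest-anchor projection to ref coords
    matched: dict[int, int]  # oriented label index -> ref site index
    span: tuple[float, float]  # projected molecule extent in ref coords
    matched_range: tuple[float, float] = (0.0, 0.0)  # first..last matched ref bp


def _project(molecule: Molecule, alignment: Alignment, ref: ReferenceMap) -> _MoleculeTrack:
    labels = orient_labels(molecule, alignment.orientation)
    anchors_m = np.array([labels[i] for i, _ in alignment.pairs])
    anchors_r = np.array([float(ref.sites[j]) for _, j in alignment.pairs])

    def proj_of(x: np.ndarray) -> np.ndarray:
        idx = np.clip(
            np.searchsorted(anchors_m, x), 1, len(anchors_m) - 1
        ) if len(anchors_m) > 1 else np.zeros(len(x), dtype=int)
        left = idx - 1
        use_right = (anchors_m[idx] - x) < (x - anchors_m[left])
        nearest = np.where(use_right, idx, left)
        return anchors_r[nearest] + (x - anchors_m[nearest])

    proj = proj_of(labels) if labels.size else np.empty(0)
    ends = proj_of(np.array([0.0, molecule.length]))
    return _MoleculeTrack(
        mol=molecule,
        aln=alignment,
        labels=labels,
        proj=proj,
        matched=dict(alignment.pairs),
        span=(float(ends[0]), float(ends[1])),
        matched_range=(float(anchors_r[0]), float(anchors_r[-1])),
    )


@dataclass
class _Cluster:
    """One consensus site candidate.

    Reference-matched clusters collect the labels the aligner paired with
    one reference site.  Unmatched labels are clustered *per segment*: the
    stretch of each molecule between two consecutive matched anchors (or
    beyond the outermost anchor), located by the measured offset from the
    segment's anchor label.  Segment clustering keeps inserted, gap-fill
    and extension content geometrically consistent across molecules, which
    a plain projection onto reference coordinates cannot (an insertion
    carries more DNA than the reference has room for).
    """

    ref_site: int | None  # matched reference site index, or None
    seg: tuple[int | None, int | None] | None  # enclosing anchor site indices
    members: dict[str, float]  # molecule id -> oriented label position
    offsets: dict[str, float] | None = None  # molecule id -> offset from anchor
    support: int = 0
    spanning: int = 0
    position: float = 0.0  # consensus coordinate, filled by the chain step

    @property
    def frac(self) -> float:
        return self.support / self.spanning if self.spanning else 0.0

    @property
    def mean_offset(self) -> float:
        # median: robust to the minority of molecules whose aligner chained
        # a few indel-content labels onto reference sites
        return float(np.median(list(self.offsets.values()))) if self.offsets else 0.0


def _cluster_labels(
    tracks: Sequence[_MoleculeTrack], ref: ReferenceMap, params: ConsensusParams
) -> list[_Cluster]:
    matched: dict[int, _Cluster] = {}
    loose: dict[tuple[int | None, int | None], list[tuple[float, str, float]]] = {}
    for t in tracks:
        pair_is = [i for i, _ in t.aln.pairs]
        for i in range(len(t.labels)):
            j = t.matched.get(i)
            x = float(t.labels[i])
            if j is not None:
                c = matched.setdefault(j, _Cluster(ref_site=j, seg=None, members={}))
                c.members.setdefault(t.mol.id, x)
                continue
            prev = max((pi for pi in pair_is if pi < i), default=None)
            nxt = min((pi for pi in pair_is if pi > i), default=None)
            j0 = t.matched[prev] if prev is not None else None
            j1 = t.matched[nxt] if nxt is not None else None
            if j0 is not None:
                off = x - float(t.labels[prev])
            elif j1 is not None:
                off = x - float(t.labels[nxt])  # negative: distal overhang
            else:  # pragma: no cover - alignment guarantees >= 2 anchors
                continue
            loose.setdefault((j0, j1), []).append((off, t.mol.id, x))

    clusters = list(matched.values())

    def emit(seg, run):
        # a genuine site's offsets scatter only by sizing noise; random
        # false-positive labels chain into broad runs at this density, so
        # recursively split any run whose spread exceeds the noise bound
        offs = [o for o, _, _ in run]
        mean = float(np.mean(offs))
        bound = 2.0 * max(250.0, 0.03 * abs(mean))
        if len(run) >= 3 and float(np.std(offs)) > bound:
            gaps = np.diff(offs)
            cut = int(np.argmax(gaps))
            emit(seg, run[: cut + 1])
            emit(seg, run[cut + 1 :])
            return
        members: dict[str, float] = {}
        offsets: dict[str, float] = {}
        for off, mid, lab in run:
            if mid not in members:
                members[mid] = lab
                offsets[mid] = off
        clusters.append(_Cluster(ref_site=None, seg=seg, members=members, offsets=offsets))

    for seg, items in loose.items():
        items.sort()
        run: list[tuple[float, str, float]] = []
        for item in items + [(math.inf, "", 0.0)]:
            if run and item[0] - run[-1][0] > params.cluster_gap:
                emit(seg, run)
                run = []
            if math.isfinite(item[0]):
                run.append(item)

    for c in clusters:
        c.support = len(c.members)
    return clusters


def _chain_positions(
    clusters: list[_Cluster],
    tracks: Sequence[_MoleculeTrack],
    ref: ReferenceMap,
    params: ConsensusParams,
) -> list[_Cluster]:
    """Fill consensus coordinates; return clusters sorted by position.

    Reference-matched clusters are chained by the mean molecule-measured
    spacing, snapping onto the reference position where the walk lands
    within ``snap_tol`` (absorbing sizing drift) and keeping measured
    geometry where it does not (an indel carried by the sample).  Segment
    clusters are placed at their mean measured offset from the anchoring
    matched cluster, so inserted/extension content sits inside the
    stretched interval it belongs to.
    """
    site_clusters = sorted(
        (c for c in clusters if c.ref_site is not None), key=lambda c: c.ref_site
    )

    def delta(a: _Cluster, b: _Cluster) -> float:
        shared = [b.members[mid] - a.members[mid] for mid in a.members.keys() & b.members.keys()]
        d = float(np.median(shared)) if shared else float(
            ref.sites[b.ref_site] - ref.sites[a.ref_site]
        )
        return max(d, 1.0)

    pos_of: dict[int, float] = {}
    if site_clusters:
        site_clusters[0].position = float(ref.sites[site_clusters[0].ref_site])
        pos_of[site_clusters[0].ref_site] = site_clusters[0].position
        for prev, cur in zip(site_clusters, site_clusters[1:]):
            cand = prev.position + delta(prev, cur)
            if abs(cand - ref.sites[cur.ref_site]) <= params.snap_tol:
                cand = float(ref.sites[cur.ref_site])
            cur.position = max(cand, prev.position + 1.0)
            pos_of[cur.ref_site] = cur.position

    for c in clusters:
        if c.ref_site is not None:
            continue
        j0, j1 = c.seg
        if j0 is not None and j0 in pos_of:
            c.position = pos_of[j0] + c.mean_offset
        elif j1 is not None and j1 in pos_of:
            c.position = pos_of[j1] + c.mean_offset
        else:
            c.position = c.mean_offset

    ordered = sorted(clusters, key=lambda c: c.position)

    # the same physical site reaches this point under several segment keys
    # when a flank label was missed in some molecules; re-merge unmatched
    # clusters that land at the same consensus position
    merged: list[_Cluster] = []
    for c in ordered:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and c.ref_site is None
            and prev.ref_site is None
            and c.position - prev.position <= params.cluster_gap
        ):
            n_p, n_c = len(prev.members), len(c.members)
            prev.position = (prev.position * n_p + c.position * n_c) / (n_p + n_c)
            for mid, lab in c.members.items():
                prev.members.setdefault(mid, lab)
            prev.support = len(prev.members)
            continue
        merged.append(c)
    ordered = merged

    for prev, cur in zip(ordered, ordered[1:]):  # strict monotonicity
        if cur.position <= prev.position:
            cur.position = prev.position + 1.0

    # a molecule spans an interior position only between its matched sites
    # (unmatched overhangs may be sample-specific DNA the reference lacks,
    # so their projected reach is unreliable there); beyond the reference's
    # outermost sites -- the genuine end-extension region -- the projected
    # molecule extent is the only available span
    lo_ref = float(ref.sites[0]) if ref.sites else 0.0
    hi_ref = float(ref.sites[-1]) if ref.sites else 0.0
    for c in ordered:
        p = c.position
        n = 0
        for t in tracks:
            if t.matched_range[0] <= p <= t.matched_range[1]:
                n += 1
            elif (p < lo_ref or p > hi_ref) and t.span[0] <= p <= t.span[1]:
                n += 1
        c.spanning = n
    return ordered


def build_consensus(
    molecules: Sequence[Molecule],
    alignments: Sequence[Alignment | None],
    ref: ReferenceMap,
    params: ConsensusParams | None = None,
    haplotype_id: str | None = None,
) -> ConsensusMap | None:
    """Cluster aligned molecules' labels into a consensus map.

    Labels are projected to reference coordinates through each molecule's
    alignment (unmatched and overhanging labels included), clustered, and
    clusters with support below ``max(min_site_support_abs,
    min_site_support_frac x spanning molecules)`` dropped.  Consensus
    inter-site intervals are the mean molecule-measured label spacing, so
    sample-specific indels are preserved; positions are anchored by least
    offset to the matched reference sites.  ``extension_length`` is the
    overshoot of the most distal consensus site beyond the reference's
    telomeric edge.  Returns None if fewer than ``min_molecules`` molecules
    align.
    """
    params = params or ConsensusParams()
    tracks = [
        _project(m, a, ref) for m, a in zip(molecules, alignments) if a is not None
    ]
    if len(tracks) < params.min_molecules:
        return None
    ordered = _chain_positions(_cluster_labels(tracks, ref, params), tracks, ref, params)
    kept = [
        c
        for c in ordered
        if c.support
        >= max(
            params.min_site_support_abs,
            (
                params.min_site_support_frac
                if c.ref_site is not None
                else params.min_segment_support_frac
            )
            * c.spanning,
        )
    ]
    if not kept:
        return None
    # re-chain after the support filter: a handful of mis-matched labels can
    # otherwise anchor the walk onto reference sites the sample lacks (e.g.
    # inside a deletion), snapping the chain past the very indel it carries
    kept = _chain_positions(kept, tracks, ref, params)
    positions = [c.position for c in kept]
    # end extension = consensus content beyond the outermost reference-
    # matched site, less the reference DNA remaining past that site; raw
    # coordinates alone would misread an interior insertion's shift as
    # telomere-ward extension
    matched_idx = [k for k, c in enumerate(kept) if c.ref_site is not None]
    extension = 0.0
    if matched_idx:
        if ref.arm == "p":
            k0 = matched_idx[0]
            r0 = float(ref.sites[kept[k0].ref_site])
            extension = max(0.0, (positions[k0] - positions[0]) - r0)
        else:
            k1 = matched_idx[-1]
            r1 = float(ref.sites[kept[k1].ref_site])
            extension = max(0.0, (positions[-1] - positions[k1]) - (ref.length - r1))
    return ConsensusMap(
        telomere_id=ref.id,
        haplotype_id=haplotype_id,
        sites=positions,
        support=[c.support for c in kept],
        extension_length=float(extension),
        n_molecules=len(tracks),
    )


# ---------------------------------------------------------------------------
# haplotype clustering


def _spans(track: _MoleculeTrack, p: float, lo_ref: float, hi_ref: float) -> bool:
    if track.matched_range[0] <= p <= track.matched_range[1]:
        return True
    return (p < lo_ref or p > hi_ref) and track.span[0] <= p <= track.span[1]


def _propose_features(
    tracks: Sequence[_MoleculeTrack],
    clusters: Sequence[_Cluster],
    ref: ReferenceMap,
    params: ConsensusParams,
) -> tuple[list[Feature], dict[str, dict[str, object]]]:
    """Candidate discriminants plus per-molecule observations (None = unseen)."""
    features: list[Feature] = []
    obs: dict[str, dict[str, object]] = {t.mol.id: {} for t in tracks}
    lo_ref = float(ref.sites[0]) if ref.sites else 0.0
    hi_ref = float(ref.sites[-1]) if ref.sites else 0.0

    # Site presence/absence candidates: interior reference sites only, with
    # no close reference neighbour (labels there are not attributable to one
    # site), judged against molecules whose alignment matches sites on BOTH
    # flanks -- that excludes molecules that merely end nearby (INP breakage,
    # short pieces) from the denominator.
    for c in clusters:
        j = c.ref_site
        if j is None or j == 0 or j == len(ref.sites) - 1:
            continue
        if min(ref.sites[j] - ref.sites[j - 1], ref.sites[j + 1] - ref.sites[j]) < params.cluster_gap:
            continue
        through = [
            t
            for t in tracks
            if any(jj < j for jj in t.matched.values())
            and any(jj > j for jj in t.matched.values())
        ]
        if len(through) < 2 * params.min_group_members:
            continue
        present = sum(1 for t in through if t.mol.id in c.members)
        frac = present / len(through)
        if not (params.het_low <= frac <= params.het_high):
            continue
        if min(present, len(through) - present) < params.min_group_members:
            continue
        f = Feature(kind="site_presence", position=c.position)
        features.append(f)
        for t in through:
            obs[t.mol.id][f.fid] = t.mol.id in c.members

    # Beyond the reference's outermost sites (the gap / end-extension
    # region) there are no reference-matched clusters; allele-specific gap
    # content shows up as segment clusters with intermediate support.
    for c in clusters:
        if c.ref_site is not None or (lo_ref <= c.position <= hi_ref):
            continue
        if c.spanning < 2 * params.min_group_members:
            continue
        if c.support < params.min_site_support_abs:
            continue
        if not (max(params.het_low, 0.35) <= c.frac <= params.het_high):
            continue
        if min(c.support, c.spanning - c.support) < params.min_group_members:
            continue
        f = Feature(kind="site_presence", position=c.position)
        features.append(f)
        for t in tracks:
            if _spans(t, c.position, lo_ref, hi_ref):
                obs[t.mol.id][f.fid] = t.mol.id in c.members

    core = sorted(
        (c for c in clusters if c.ref_site is not None
         and c.frac > params.het_high and c.spanning >= 2),
        key=lambda c: c.ref_site,
    )
    for c0, c1 in zip(core, core[1:]):
        values: dict[str, float] = {}
        for mid in c0.members.keys() & c1.members.keys():
            values[mid] = c1.members[mid] - c0.members[mid]
        if len(values) < 2 * params.min_group_members:
            continue
        ordered = np.sort(np.array(list(values.values())))
        gaps = np.diff(ordered)
        cut = int(np.argmax(gaps))
        lo, hi = ordered[: cut + 1], ordered[cut + 1 :]
        if min(len(lo), len(hi)) < params.min_group_members:
            continue
        sep = float(hi.mean() - lo.mean())
        if sep < params.min_mode_separation or gaps[cut] < 0.6 * sep:
            continue
        f = Feature(
            kind="interval_length",
            position=c0.position,
            interval=(c0.position, c1.position),
            modes=(float(lo.mean()), float(hi.mean())),
        )
        features.append(f)
        mid_cut = 0.5 * (lo.mean() + hi.mean())
        for mid_id, v in values.items():
            obs[mid_id][f.fid] = "hi" if v > mid_cut else "lo"
    return features, obs


def cluster_haplotypes(
    molecules: Sequence[Molecule],
    alignments: Sequence[Alignment | None],
    ref: ReferenceMap,
    params: ConsensusParams | None = None,
) -> ClusterResult:
    """Partition aligned molecules into haplotype groups.

    Discriminant features are proposed from bimodality (intermediate-
    support sites; bimodal inter-site intervals), haplotype signatures are
    the distinct complete feature vectors carried by enough molecules, and
    each molecule joins the group agreeing with the majority of its
    observed features (ties and orphan signatures stay unassigned).  With
    no discriminant feature the result is a single homozygous group.
    """
    params = params or ConsensusParams()
    pairs = [(m, a) for m, a in zip(molecules, alignments) if a is not None]
    tracks = [_project(m, a, ref) for m, a in pairs]
    clusters = _chain_positions(
        _cluster_labels(tracks, ref, params), tracks, ref, params
    )
    features, obs = _propose_features(tracks, clusters, ref, params)

    if not features:
        members = [t.mol.id for t in tracks]
        group = HaplotypeGroup(haplotype_id="h1", features={}, member_ids=members)
        group.consensus = build_consensus(
            [m for m, _ in pairs], [a for _, a in pairs], ref, params, haplotype_id="h1"
        )
        return ClusterResult(groups=[group], features=[], unassigned_ids=[])

    fids = [f.fid for f in features]
    signature_counts: dict[tuple, int] = {}
    for t in tracks:
        o = obs[t.mol.id]
        if all(fid in o for fid in fids):
            sig = tuple(o[fid] for fid in fids)
            signature_counts[sig] = signature_counts.get(sig, 0) + 1
    signatures = [
        sig
        for sig, n in sorted(signature_counts.items(), key=lambda kv: -kv[1])
        if n >= params.min_group_members
    ][:2]
    if not signatures:
        signatures = [max(signature_counts, key=signature_counts.get)] if signature_counts else []
    if not signatures:
        return ClusterResult(groups=[], features=features, unassigned_ids=[t.mol.id for t in tracks])

    assignment: dict[str, int] = {}
    unassigned: list[str] = []
    for t in tracks:
        o = obs[t.mol.id]
        observed = [fid for fid in fids if fid in o]
        if not observed:
            unassigned.append(t.mol.id)
            continue
        scores = [
            sum(1 for fid, want in zip(fids, sig) if fid in o and o[fid] == want)
            for sig in signatures
        ]
        best = max(scores)
        if scores.count(best) > 1 or best < math.ceil(len(observed) / 2 + 0.001):
            unassigned.append(t.mol.id)
            continue
        assignment[t.mol.id] = scores.index(best)

    groups: list[HaplotypeGroup] = []
    for k, sig in enumerate(signatures):
        member_ids = [mid for mid, g in assignment.items() if g == k]
        if len(member_ids) < params.min_group_members:
            continue
        sel = [(m, a) for m, a in pairs if m.id in set(member_ids)]
        hap_id = f"h{len(groups) + 1}"
        group = HaplotypeGroup(
            haplotype_id=hap_id,
            features=dict(zip(fids, sig)),
            member_ids=member_ids,
            warning=len(unassigned) > 0.2 * len(tracks),
        )
        group.consensus = build_consensus(
            [m for m, _ in sel], [a for _, a in sel], ref, params, haplotype_id=hap_id
        )
        groups.append(group)
    return ClusterResult(groups=groups, features=features, unassigned_ids=unassigned)


# ---------------------------------------------------------------------------
# SV calling


def _consensus_pseudo_molecule(consensus: ConsensusMap) -> tuple[Molecule, float]:
    """Express a consensus map as a noiseless molecule for map-to-map alignment."""
    sites = np.asarray(consensus.sites, dtype=float)
    margin = 1000.0
    labels = sites - sites[0] + margin
    length = float(labels[-1] + margin)
    mol = Molecule(id=f"consensus:{consensus.telomere_id}", length=length, labels=labels)
    return mol, float(sites[0] - margin)


def _molecule_indel_calls(
    molecules: Sequence[Molecule],
    alignments: Sequence[Alignment | None],
    ref: ReferenceMap,
    min_size: float,
    params: ConsensusParams,
    telomere_id: str,
    haplotype_id: str | None,
) -> list[SVCall]:
    """Indel calls from clustered per-molecule outlier intervals.

    Each molecule that bridges an indel cleanly reports its full size as a
    single outlier residual; molecules whose aligner partially absorbed the
    indel content smear their residual below threshold and drop out of the
    supporting set instead of biasing the size, so the median residual over
    supporters is a robust size estimate.
    """
    raw: list[OutlierInterval] = []
    for mol, aln in zip(molecules, alignments):
        if aln is None:
            continue
        raw.extend(detect_outliers(aln, ref, mol, min_size=min_size))
    calls: list[SVCall] = []
    for sign in (1, -1):
        group = sorted(
            (o for o in raw if (o.size_delta > 0) == (sign > 0)), key=lambda o: o.start
        )
        run: list[OutlierInterval] = []
        for o in group + [None]:
            if run and (o is None or o.start > run[-1].end + 2 * params.site_match_tol):
                support = len({x.molecule_id for x in run})
                if support >= params.min_site_support_abs:
                    size = float(np.median([abs(x.size_delta) for x in run]))
                    calls.append(
                        SVCall(
                            telomere_id=telomere_id,
                            type="insertion" if sign > 0 else "deletion",
                            position=float(np.median([x.start for x in run])),
                            size=size,
                            haplotype_id=haplotype_id,
                            support=support,
                            codes=("sv",),
                        )
                    )
                run = []
            if o is not None:
                run.append(o)
    return calls


def call_svs(
    consensus: ConsensusMap,
    ref: ReferenceMap,
    min_size: float | None = None,
    params: ConsensusParams | None = None,
    scoring: ScoringParams | None = None,
    molecules: Sequence[Molecule] | None = None,
    alignments: Sequence[Alignment | None] | None = None,
) -> list[SVCall]:
    """Call large SVs, gap fills and distal extension from one consensus map.

    Insertions/deletions (code ``sv``): when the supporting ``molecules``
    and ``alignments`` are given, indels are called from clustered
    per-molecule outlier residuals (robust to aligner absorption of indel
    content); otherwise the consensus map itself is aligned to the
    reference (map-to-map, the same DP as molecules) and interval-length
    discrepancies of at least ``min_size`` are reported.  Consensus sites
    inside reference gap intervals become a ``gap_fill`` call delineating
    the gap content; positive end extension becomes ``distal_extension``
    (both code ``g``).  Heterozygosity codes (``h``) are added by
    :func:`call_svs_for_groups` when calls differ between groups.
    """
    params = params or ConsensusParams()
    if min_size is None:
        min_size = params.sv_min_size
    scoring = scoring or ScoringParams()
    calls: list[SVCall] = []

    if molecules is not None and alignments is not None:
        calls.extend(
            _molecule_indel_calls(
                molecules, alignments, ref, min_size, params,
                consensus.telomere_id, consensus.haplotype_id,
            )
        )
    else:
        pseudo, _ = _consensus_pseudo_molecule(consensus)
        aln = align_molecule(pseudo, ref, scoring) if pseudo.n_labels >= 2 else None
        if aln is not None:
            for out in detect_outliers(aln, ref, pseudo, min_size=min_size):
                calls.append(
                    SVCall(
                        telomere_id=consensus.telomere_id,
                        type="insertion" if out.size_delta > 0 else "deletion",
                        position=out.start,
                        size=abs(out.size_delta),
                        haplotype_id=consensus.haplotype_id,
                        support=consensus.n_molecules,
                        codes=("sv",),
                    )
                )

    for a, b in ref.gaps:
        inside = [
            (s, sup) for s, sup in zip(consensus.sites, consensus.support) if a <= s < b
        ]
        if inside:
            lo = min(s for s, _ in inside)
            hi = max(s for s, _ in inside)
            calls.append(
                SVCall(
                    telomere_id=consensus.telomere_id,
                    type="gap_fill",
                    position=float(a),
                    size=float(max(hi - lo, 1.0)),
                    haplotype_id=consensus.haplotype_id,
                    support=min(sup for _, sup in inside),
                    codes=("g",),
                )
            )

    if consensus.extension_length > 0:
        calls.append(
            SVCall(
                telomere_id=consensus.telomere_id,
                type="distal_extension",
                position=float(ref.telomeric_edge()),
                size=float(consensus.extension_length),
                haplotype_id=consensus.haplotype_id,
                support=consensus.support[0 if ref.arm == "p" else -1],
                codes=("g",),
            )
        )
    calls.sort(key=lambda c: c.position)
    return calls


def call_svs_for_groups(
    groups: Sequence[HaplotypeGroup],
    ref: ReferenceMap,
    min_size: float | None = None,
    params: ConsensusParams | None = None,
    molecules: Sequence[Molecule] | None = None,
    alignments: Sequence[Alignment | None] | None = None,
) -> list[SVCall]:
    """Per-group SV calls with ``h`` added to calls not shared by all groups."""
    params = params or ConsensusParams()
    by_id = {}
    if molecules is not None and alignments is not None:
        by_id = {m.id: (m, a) for m, a in zip(molecules, alignments) if a is not None}

    def group_calls(g: HaplotypeGroup) -> list[SVCall]:
        if g.consensus is None:
            return []
        if by_id:
            sel = [by_id[mid] for mid in g.member_ids if mid in by_id]
            return call_svs(
                g.consensus, ref, min_size, params,
                molecules=[m for m, _ in sel], alignments=[a for _, a in sel],
            )
        return call_svs(g.consensus, ref, min_size, params)

    per_group = [group_calls(g) for g in groups]
    if len(groups) < 2:
        return per_group[0] if per_group else []
    tol = params.site_match_tol

    def shared(call: SVCall, others: list[list[SVCall]]) -> bool:
        return all(
            any(
                c.type == call.type
                and abs(c.position - call.position) <= 2 * tol
                and abs(c.size - call.size) <= max(2 * tol, 0.2 * max(c.size, call.size))
                for c in other
            )
            for other in others
        )

    out: list[SVCall] = []
    for k, calls in enumerate(per_group):
        others = per_group[:k] + per_group[k + 1 :]
        for call in calls:
            codes = call.codes if shared(call, others) else tuple(sorted(set(call.codes) | {"h"}))
            out.append(
                SVCall(
                    telomere_id=call.telomere_id,
                    type=call.type,
                    position=call.position,
                    size=call.size,
                    haplotype_id=call.haplotype_id,
                    support=call.support,
                    codes=codes,
                )
            )
    out.sort(key=lambda c: (c.position, c.haplotype_id or ""))
    return out


# ---------------------------------------------------------------------------
# trio inheritance


@dataclass
class TrioAssignment:
    child_haplotype: str
    parent: str  # "parent1" | "parent2"
    parent_haplotype: str
    distance: float


@dataclass
class TrioResult:
    assignments: list[TrioAssignment]
    consistent: bool
    ambiguous: bool


def map_distance(a: ConsensusMap, b: ConsensusMap, tolerance: float = 1500.0) -> float:
    """1 - fraction of sites co-matched between two consensus maps.

    The maps are compared by nick-pattern alignment (the same DP used for
    molecules), which absorbs the slow positional drift that cumulated
    measured intervals acquire away from reference-snapped anchors and
    crosses allele-specific indels; ``tolerance`` sets the sizing slack.
    0 means every site of each map is matched by the other.
    """
    sa, sb = list(a.sites), list(b.sites)
    total = len(sa) + len(sb)
    if total == 0:
        return 0.0
    if len(sa) < 2 or len(sb) < 2:
        return 1.0
    shift = min(sb)
    ref_sites: list[int] = []
    for s in sb:
        v = int(round(s - shift)) + 1000
        if not ref_sites or v > ref_sites[-1]:
            ref_sites.append(v)
    ref_b = ReferenceMap(
        id="map-b", length=ref_sites[-1] + 1000, sites=ref_sites, arm="p"
    )
    mol_a, _ = _consensus_pseudo_molecule(a)
    scoring = ScoringParams(abs_sd=max(250.0, tolerance / 3.0), n_decoys=0)
    aln = align_molecule(mol_a, ref_b, scoring)
    matched = aln.n_pairs if aln is not None else 0
    return 1.0 - 2.0 * matched / total


def trio_consistency(
    child: Sequence[HaplotypeGroup],
    parent1: Sequence[HaplotypeGroup],
    parent2: Sequence[HaplotypeGroup],
    tolerance: float = 1500.0,
    max_distance: float = 0.10,
) -> TrioResult:
    """Match child haplotypes to parental haplotypes by consensus-map distance.

    Each child haplotype must come from a different parent; both pairings
    (child A from parent 1 / child B from parent 2, and the swap) are
    scored by total consensus-map distance to the closest allele of the
    assigned parent.  Mendelian consistency requires both distances within
    ``max_distance``; the assignment is declared ambiguous when the two
    pairings are equally good (e.g. parents homozygous for the same
    allele).
    """

    def best_allele(group: HaplotypeGroup, parent: Sequence[HaplotypeGroup]):
        scored = [
            (map_distance(group.consensus, p.consensus, tolerance), p.haplotype_id)
            for p in parent
            if p.consensus is not None and group.consensus is not None
        ]
        if not scored:
            return (math.inf, "?")
        return min(scored)

    kids = list(child)
    if len(kids) == 1:
        kids = kids * 2  # homozygous child: one allele from each parent
    pairings = []
    for order in ((parent1, parent2), (parent2, parent1)):
        names = ("parent1", "parent2") if order[0] is parent1 else ("parent2", "parent1")
        d0, h0 = best_allele(kids[0], order[0])
        d1, h1 = best_allele(kids[1], order[1])
        pairings.append(
            (
                d0 + d1,
                [
                    TrioAssignment(kids[0].haplotype_id, names[0], h0, d0),
                    TrioAssignment(kids[1].haplotype_id, names[1], h1, d1),
                ],
            )
        )
    pairings.sort(key=lambda p: p[0])
    best, second = pairings[0], pairings[1]
    consistent = all(a.distance <= max_distance for a in best[1])
    ambiguous = abs(best[0] - second[0]) < 1e-9
    return TrioResult(assignments=best[1], consistent=consistent, ambiguous=ambiguous)
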