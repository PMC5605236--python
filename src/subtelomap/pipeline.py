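"""End-to-end orchestration: simulate/align/cluster/call/estimate.

Glue used by the command-line interface, the bundled examples and the test
suite; all scientific content lives in the per-step modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .align import Alignment, ScoringParams, align_molecule, anchor_check
from .consensus_haplotypes import (
    ClusterResult,
    ConsensusParams,
    SVCall,
    build_consensus,
    call_svs,
    call_svs_for_groups,
    cluster_haplotypes,
)
from .refmaps import ReferenceMap
from .simulate import Molecule
from .telolen import TelomereEstimate, TelomereSummary, aggregate_lengths, estimate_all


@dataclass
class PipelineResult:
    reference: ReferenceMap
    molecules: list[Molecule]
    alignments: list[Alignment | None]
    passed: list[bool]  # confidence + 1-copy anchoring filter per molecule
    cluster: ClusterResult | None
    sv_calls: list[SVCall]
    estimates: list[TelomereEstimate]
    summaries: list[TelomereSummary]
    stats: dict = field(default_factory=dict)

    def passing(self) -> list[tuple[Molecule, Alignment]]:
        return [
            (m, a)
            for m, a, ok in zip(self.molecules, self.alignments, self.passed)
            if ok and a is not None
        ]


def run_pipeline(
    reference: ReferenceMap,
    molecules: Sequence[Molecule],
    *,
    one_copy_interval: tuple[float, float] | None = None,
    scoring: ScoringParams | None = None,
    consensus_params: ConsensusParams | None = None,
    do_haplotypes: bool = True,
    do_telomeres: bool = True,
) -> PipelineResult:
    """Align all molecules, partition haplotypes, call SVs, estimate telomeres.

    Molecules enter consensus/haplotype/telomere work only if their
    alignment confidence reaches ``scoring.min_confidence`` and (when a
    1-copy interval is given) at least one matched site anchors there.
    """
    scoring = scoring or ScoringParams()
    cparams = consensus_params or ConsensusParams()

    alignments = [align_molecule(m, reference, scoring) for m in molecules]
    passed = []
    for aln in alignments:
        ok = aln is not None and aln.confidence >= scoring.min_confidence
        if ok and one_copy_interval is not None:
            ok = anchor_check(aln, reference, one_copy_interval)
        passed.append(bool(ok))

    kept_m = [m for m, ok in zip(molecules, passed) if ok]
    kept_a = [a for a, ok in zip(alignments, passed) if ok]

    cluster = None
    sv_calls: list[SVCall] = []
    hap_of: dict[str, str] = {}
    if do_haplotypes and kept_m:
        cluster = cluster_haplotypes(kept_m, kept_a, reference, cparams)
        for g in cluster.groups:
            for mid in g.member_ids:
                hap_of[mid] = g.haplotype_id
        if cluster.groups:
            sv_calls = call_svs_for_groups(
                cluster.groups, reference, params=cparams,
                molecules=kept_m, alignments=kept_a,
            )
        else:
            consensus = build_consensus(kept_m, kept_a, reference, cparams)
            if consensus is not None:
                sv_calls = call_svs(
                    consensus, reference, params=cparams,
                    molecules=kept_m, alignments=kept_a,
                )

    estimates: list[TelomereEstimate] = []
    summaries: list[TelomereSummary] = []
    if do_telomeres and kept_m:
        estimates = estimate_all(
            kept_m, kept_a, reference, haplotype_of=hap_of or None
        )
        if estimates:
            summaries = aggregate_lengths(estimates)

    n_aligned = sum(a is not None for a in alignments)
    stats = {
        "telomere": reference.id,
        "molecules_in": len(molecules),
        "aligned": n_aligned,
        "passed_filters": sum(passed),
        "haplotype_groups": len(cluster.groups) if cluster else 0,
        "sv_calls": len(sv_calls),
        "telomere_estimates": len(estimates),
    }
    return PipelineResult(
        reference=reference,
        molecules=list(molecules),
        alignments=alignments,
        passed=passed,
        cluster=cluster,
        sv_calls=sv_calls,
        estimates=estimates,
        summaries=summaries,
        stats=stats,
    )
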