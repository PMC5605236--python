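"""File formats: FASTA in, CMAP/BNX/XMAP-style TSV dialects, BED, YAML config.

The tabular formats are named after the optical-mapping ecosystem's CMAP
(reference/consensus maps), BNX (molecules) and XMAP (alignments) files,
but the dialects here are this package's own pinned column sets: plain
tab-separated text, ``#``-prefixed comment/metadata lines, one row per
site/molecule/alignment.  Write-then-read is lossless for every field.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from Bio import SeqIO
from pydantic import BaseModel, Field

from .align import Alignment
from .consensus_haplotypes import ConsensusMap, SVCall
from .refmaps import ReferenceMap
from .simulate import Molecule, MoleculeTruth, SimParams, SubtelomereSpec
from .telolen import TelomereEstimate, TelomereSummary


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(record id, uppercase sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_rows(
    path: str | Path,
    header: Sequence[str],
    rows: Iterable[Sequence],
    meta: dict | None = None,
) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        fh.write("#" + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _read_rows(path: str | Path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    return rows


# -- CMAP-style maps ---------------------------------------------------------

_CMAP_HEADER = ("map_id", "map_length", "n_sites", "site_id", "position")


def write_cmap(path: str | Path, maps: Sequence[ReferenceMap], meta: dict | None = None) -> None:
    """One row per site: map id, map length, site count, 1-based index, bp."""
    rows = []
    for m in maps:
        for k, pos in enumerate(m.sites, start=1):
            rows.append((m.id, m.length, len(m.sites), k, pos))
        if not m.sites:  # keep empty maps representable
            rows.append((m.id, m.length, 0, 0, ""))
    _write_rows(path, _CMAP_HEADER, rows, meta)


def write_map_sidecar(path: str | Path, maps: Sequence[ReferenceMap]) -> None:
    """YAML sidecar for the fields a bare site table cannot carry."""
    payload = {
        m.id: {
            "arm": m.arm,
            "gaps": [list(g) for g in m.gaps],
            "distal_offset": "unknown" if m.distal_offset is None else int(m.distal_offset),
        }
        for m in maps
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_reference_maps(cmap_path: str | Path, sidecar_path: str | Path | None = None) -> list[ReferenceMap]:
    side = {}
    if sidecar_path is not None and Path(sidecar_path).exists():
        side = yaml.safe_load(Path(sidecar_path).read_text()) or {}
    by_id: dict[str, dict] = {}
    for row in _read_rows(cmap_path):
        mid, mlen, _, site_id, pos = row[0], int(row[1]), row[2], int(row[3]), row[4]
        entry = by_id.setdefault(mid, {"length": mlen, "sites": []})
        if site_id > 0 and pos != "":
            entry["sites"].append(int(float(pos)))
    maps = []
    for mid, entry in by_id.items():
        extra = side.get(mid, {})
        off = extra.get("distal_offset", 0)
        maps.append(
            ReferenceMap(
                id=mid,
                length=entry["length"],
                sites=sorted(entry["sites"]),
                arm=extra.get("arm", "p"),
                gaps=[tuple(g) for g in extra.get("gaps", [])],
                distal_offset=None if off == "unknown" else int(off),
            )
        )
    return maps


_CONSENSUS_HEADER = ("telomere_id", "haplotype_id", "site_id", "position", "support",
                     "extension_length", "n_molecules")


def write_consensus_cmap(path: str | Path, maps: Sequence[ConsensusMap], meta: dict | None = None) -> None:
    rows = []
    for m in maps:
        for k, (pos, sup) in enumerate(zip(m.sites, m.support), start=1):
            rows.append((m.telomere_id, m.haplotype_id or "", k, repr(float(pos)), sup,
                         repr(float(m.extension_length)), m.n_molecules))
    _write_rows(path, _CONSENSUS_HEADER, rows, meta)


def read_consensus_cmaps(path: str | Path) -> list[ConsensusMap]:
    grouped: dict[tuple[str, str], dict] = {}
    for row in _read_rows(path):
        key = (row[0], row[1])
        entry = grouped.setdefault(
            key, {"sites": [], "support": [], "ext": float(row[5]), "n": int(row[6])}
        )
        entry["sites"].append(float(row[3]))
        entry["support"].append(int(row[4]))
    return [
        ConsensusMap(
            telomere_id=tel,
            haplotype_id=hap or None,
            sites=e["sites"],
            support=e["support"],
            extension_length=e["ext"],
            n_molecules=e["n"],
        )
        for (tel, hap), e in grouped.items()
    ]


# -- BNX-style molecules -----------------------------------------------------

_BNX_HEADER = ("molecule_id", "length", "labels")
_TRUTH_HEADER = ("molecule_id", "haplotype", "origin_start", "origin_end",
                 "reversed", "n_true_spanned", "n_true_labeled")


def write_molecules(path: str | Path, molecules: Sequence[Molecule], meta: dict | None = None) -> None:
    rows = [
        (m.id, repr(float(m.length)), ",".join(repr(float(x)) for x in m.labels))
        for m in molecules
    ]
    _write_rows(path, _BNX_HEADER, rows, meta)


def read_molecules(path: str | Path, truth_path: str | Path | None = None) -> list[Molecule]:
    truth: dict[str, MoleculeTruth] = {}
    if truth_path is not None and Path(truth_path).exists():
        for row in _read_rows(truth_path):
            truth[row[0]] = MoleculeTruth(
                haplotype=row[1],
                start=float(row[2]),
                end=float(row[3]),
                reversed=row[4] == "1",
                n_true_spanned=int(row[5]),
                n_true_labeled=int(row[6]),
            )
    out = []
    for row in _read_rows(path):
        labels = np.array([float(x) for x in row[2].split(",") if x], dtype=float)
        out.append(
            Molecule(id=row[0], length=float(row[1]), labels=labels, truth=truth.get(row[0]))
        )
    return out


def write_truth(path: str | Path, molecules: Sequence[Molecule], meta: dict | None = None) -> None:
    rows = [
        (m.id, t.haplotype, repr(float(t.start)), repr(float(t.end)), int(t.reversed),
         t.n_true_spanned, t.n_true_labeled)
        for m in molecules
        if (t := m.truth) is not None
    ]
    _write_rows(path, _TRUTH_HEADER, rows, meta)


# -- XMAP-style alignments ---------------------------------------------------

_XMAP_HEADER = ("molecule_id", "ref_id", "orientation", "offset", "score",
                "confidence", "pairs", "residuals")


def write_alignments(path: str | Path, alignments: Sequence[Alignment | None], meta: dict | None = None) -> None:
    rows = []
    for a in alignments:
        if a is None:
            continue
        rows.append(
            (
                a.molecule_id,
                a.ref_id,
                "+" if a.orientation == "forward" else "-",
                repr(float(a.offset)),
                repr(float(a.score)),
                repr(float(a.confidence)),
                ";".join(f"{i}:{j}" for i, j in a.pairs),
                ";".join(repr(float(r)) for r in a.residuals),
            )
        )
    _write_rows(path, _XMAP_HEADER, rows, meta)


def read_alignments(path: str | Path) -> list[Alignment]:
    out = []
    for row in _read_rows(path):
        pairs = [tuple(int(x) for x in p.split(":")) for p in row[6].split(";") if p]
        residuals = [float(x) for x in row[7].split(";") if x]
        out.append(
            Alignment(
                molecule_id=row[0],
                ref_id=row[1],
                orientation="forward" if row[2] == "+" else "reverse",
                pairs=pairs,
                offset=float(row[3]),
                score=float(row[4]),
                confidence=float(row[5]),
                residuals=residuals,
            )
        )
    return out


# -- SV BED, haplotype table, telomere tables --------------------------------


def write_sv_bed(path: str | Path, calls: Sequence[SVCall], meta: dict | None = None) -> None:
    """BED: chrom = telomere id, name = type:codes[:haplotype], score = support."""
    rows = []
    for c in calls:
        start = int(max(0, c.position))
        end = int(max(start + 1, c.position + c.size))
        name = f"{c.type}:{'+'.join(c.codes)}" + (f":{c.haplotype_id}" if c.haplotype_id else "")
        rows.append((c.telomere_id, start, end, name, c.support))
    _write_rows(path, ("chrom", "start", "end", "name", "score"), rows, meta)


def write_haplotype_table(path: str | Path, groups, unassigned: Sequence[str] = (),
                          meta: dict | None = None) -> None:
    rows = [(mid, g.haplotype_id) for g in groups for mid in g.member_ids]
    rows += [(mid, "unassigned") for mid in unassigned]
    _write_rows(path, ("molecule_id", "haplotype_id"), rows, meta)


def write_estimates(path: str | Path, estimates: Sequence[TelomereEstimate], meta: dict | None = None) -> None:
    rows = [
        (
            e.molecule_id,
            e.telomere_id,
            e.haplotype_id or "",
            repr(float(e.length)),
            f"{e.length / 1000:.1f}",
            e.orientation,
            ",".join(sorted(e.flags)),
        )
        for e in estimates
    ]
    _write_rows(
        path,
        ("molecule_id", "telomere_id", "haplotype_id", "length_bp", "length_kb",
         "orientation", "flags"),
        rows,
        meta,
    )


def write_summary(path: str | Path, summaries: Sequence[TelomereSummary], meta: dict | None = None) -> None:
    """Mean ± SD (kb, 1 decimal), molecule count, gap asterisk per group."""
    rows = [
        (
            s.telomere_id,
            s.haplotype_id or "",
            f"{s.mean / 1000:.1f}",
            "" if s.sd is None else f"{s.sd / 1000:.1f}",
            s.n,
            "*" if s.gap_flag else "",
        )
        for s in summaries
    ]
    _write_rows(path, ("telomere_id", "haplotype_id", "mean_kb", "sd_kb", "n", "gap"), rows, meta)


# -- run configuration and manifest ------------------------------------------


class ScenarioConfig(BaseModel):
    """YAML-loadable scenario: subtelomere architecture + simulation params."""

    spec: SubtelomereSpec
    sim: SimParams = Field(default_factory=SimParams)


def load_scenario_config(path: str | Path) -> ScenarioConfig:
    return ScenarioConfig.model_validate(yaml.safe_load(Path(path).read_text()))


def save_scenario_config(path: str | Path, config: ScenarioConfig) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True))


class RunConfig(BaseModel):
    """End-to-end run: where inputs come from and where outputs go."""

    out_dir: str
    seed: int = 0
    scenario: str | None = None  # preset name
    scenario_file: str | None = None  # ScenarioConfig YAML
    molecules: str | None = None  # BNX-style input instead of simulating
    reference_cmap: str | None = None
    reference_sidecar: str | None = None
    diploid: tuple[str, str] | None = None  # haplotype pair to simulate
    scoring: dict = Field(default_factory=dict)
    consensus: dict = Field(default_factory=dict)
    sim: dict = Field(default_factory=dict)


def config_hash(config: BaseModel) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str | Path, config: BaseModel, outputs: Sequence[str]) -> None:
    payload = {
        "config_hash": config_hash(config),
        "seed": getattr(config, "seed", None),
        "outputs": sorted(str(o) for o in outputs),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
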