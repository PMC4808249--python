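"""Assemble all per-position tracks into one profile set and serialize it.

The profile set is keyed to the reference sequence: every track has exactly
one value (possibly null) per reference position.  Nulls serialize as "NA"
in TSV and as native null in JSON.  User annotation tracks (domains,
phosphosites, catalytic sites, disorder propensity, ...) are ingested from a
position-interval TSV rather than fetched from external databases.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

from .binding_profile import associate_names, binding_site_profile
from .ccp import CCPConfig, compute_ccp, global_rmsd
from .pairing import PairCandidate
from .profile import Profile, new_profile
from .refmap import ReferenceSequence, ResidueMap, build_residue_map
from .secstruct import loop_fraction, overlay_disorder
from .seq_profiles import MSA, conservation_profile, hydropathy_profile
from .superpose import superpose


def structure_pair_id(before_id: str, before_chain: str,
                      after_id: str, after_chain: str) -> str:
    """11-character pair id: 4-char PDB id + chain for each state, '_' joined."""
    for pdb_id in (before_id, after_id):
        if len(pdb_id) != 4:
            raise ValueError(f"PDB id must be 4 characters: {pdb_id!r}")
    for chain in (before_chain, after_chain):
        if len(chain) != 1:
            raise ValueError(f"chain id must be 1 character: {chain!r}")
    return f"{before_id}{before_chain}_{after_id}{after_chain}"


@dataclass
class IntervalTrack:
    """Labeled closed intervals on reference positions."""

    name: str
    intervals: list[tuple[int, int, str]] = field(default_factory=list)

    def clipped(self, L: int) -> "IntervalTrack":
        out = []
        for lo, hi, label in self.intervals:
            lo, hi = max(1, lo), min(L, hi)
            if lo <= hi:
                out.append((lo, hi, label))
        return IntervalTrack(self.name, out)

    def to_profile(self, ref_id: str, L: int) -> Profile:
        prof = new_profile(ref_id, L, kind="names", name=self.name)
        for i in range(L):
            prof.values[i] = []
        for lo, hi, label in self.clipped(L).intervals:
            for i in range(lo, hi + 1):
                prof.values[i - 1].append(label)
        for i in range(L):
            prof.values[i] = sorted(set(prof.values[i]))
        return prof


def read_annotation_tsv(path: str | Path) -> list[IntervalTrack]:
    """Read interval annotations: track <TAB> start <TAB> end <TAB> label."""
    tracks: dict[str, IntervalTrack] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: need track/start/end[/label] columns")
        name, start, end = parts[0], int(parts[1]), int(parts[2])
        label = parts[3] if len(parts) > 3 else name
        if start < 1 or end < start:
            raise ValueError(f"{path}:{lineno}: bad interval [{start}, {end}]")
        tracks.setdefault(name, IntervalTrack(name)).intervals.append((start, end, label))
    return list(tracks.values())


@dataclass
class ProfileSet:
    ref: ReferenceSequence
    tracks: dict[str, Profile]
    metadata: dict[str, Any]

    @property
    def length(self) -> int:
        return len(self.ref)


def assemble(
    pair: PairCandidate,
    ref: ReferenceSequence,
    msa: Optional[MSA] = None,
    annotations: Sequence[IntervalTrack] = (),
    config: Optional[CCPConfig] = None,
    site_cutoff: float = 5.0,
    name_cutoff: float = 3.0,
    log=None,
) -> ProfileSet:
    """Compute every available track for a structure pair.

    Absent inputs (no MSA, no annotations) simply yield absent tracks.
    Module errors propagate with the stage name attached.
    """
    config = config or CCPConfig()
    L = len(ref)
    tracks: dict[str, Profile] = {}
    stage = "mapping"
    t0 = time.perf_counter()

    def tick(name: str) -> None:
        nonlocal stage, t0
        if log is not None:
            log(f"stage {stage}: {time.perf_counter() - t0:.3f}s")
        stage, t0 = name, time.perf_counter()

    try:
        rmap = build_residue_map(pair.before, pair.after, ref)
        tick("ccp")
        tracks["ccp"] = compute_ccp(rmap, config)
        grmsd = global_rmsd(rmap, config)
        tick("binding")
        tracks["binding_flag"] = binding_site_profile(
            rmap, pair.after, pair.targets, cutoff=site_cutoff
        )
        tracks["binding_names"] = associate_names(
            rmap, pair.after, pair.targets, cutoff=name_cutoff
        )
        tick("secstruct")
        tracks["ss_before"] = overlay_disorder(rmap, 1)
        tracks["ss_after"] = overlay_disorder(rmap, 2)
        tick("sequence profiles")
        if msa is not None:
            tracks["conservation"] = conservation_profile(msa, ref)
        tracks["hydropathy"] = hydropathy_profile(ref)
        tick("annotations")
        for track in annotations:
            tracks[track.name] = track.to_profile(ref.id, L)
        tick("done")
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    metadata = {
        "pair_id": structure_pair_id(
            pair.before_file.id, pair.before.chain_id,
            pair.after_file.id, pair.after.chain_id,
        ),
        "reference": ref.id,
        "before": f"{pair.before_file.id}{pair.before.chain_id}",
        "after": f"{pair.after_file.id}{pair.after.chain_id}",
        "global_rmsd": grmsd,
        "worse_resolution": pair.worse_resolution,
        "ph": pair.after_file.ph,
        "temperature": pair.after_file.temperature,
        "loop_fraction_before": loop_fraction(tracks["ss_before"]),
        "loop_fraction_after": loop_fraction(tracks["ss_after"]),
        "binding_targets": [
            {"category": t.category, "name": t.name} for t in pair.targets
        ],
    }
    return ProfileSet(ref=ref, tracks=tracks, metadata=metadata)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_TRACK_ORDER = [
    "ccp", "binding_flag", "binding_names", "ss_before", "ss_after",
    "conservation", "hydropathy",
]

_DECIMALS = {"ccp": 4, "hydropathy": 4, "conservation": 3}


def _format_value(name: str, value: Any) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, list):
        return ";".join(value) if value else "NA"
    if isinstance(value, float):
        return f"{value:.{_DECIMALS.get(name, 4)}f}"
    return str(value)


def _ordered_tracks(ps: ProfileSet) -> list[str]:
    extra = [n for n in ps.tracks if n not in _TRACK_ORDER]
    return [n for n in _TRACK_ORDER if n in ps.tracks] + sorted(extra)


def write_tsv(ps: ProfileSet, path: str | Path) -> None:
    names = _ordered_tracks(ps)
    lines = ["\t".join(["position", "ref_aa"] + names)]
    for i in range(1, ps.length + 1):
        row = [str(i), ps.ref.sequence[i - 1]]
        row += [_format_value(n, ps.tracks[n][i]) for n in names]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(ps: ProfileSet, path: str | Path) -> None:
    payload = {
        "reference": {"id": ps.ref.id, "sequence": ps.ref.sequence},
        "metadata": ps.metadata,
        "tracks": {
            name: {
                "kind": prof.kind,
                "units": prof.units,
                "values": prof.values,
            }
            for name, prof in ps.tracks.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_json(path: str | Path) -> ProfileSet:
    payload = json.loads(Path(path).read_text())
    ref = ReferenceSequence(payload["reference"]["id"], payload["reference"]["sequence"])
    tracks = {
        name: Profile(ref.id, spec["values"], spec["kind"], spec["units"], name)
        for name, spec in payload["tracks"].items()
    }
    return ProfileSet(ref=ref, tracks=tracks, metadata=payload["metadata"])


def write_meta(ps: ProfileSet, path: str | Path) -> None:
    lines = []
    for key, value in ps.metadata.items():
        if key == "binding_targets":
            value = ";".join(f"{t['name']}({t['category']})" for t in value) or "none"
        elif isinstance(value, float):
            value = f"{value:.4f}"
        lines.append(f"{key}\t{value if value is not None else 'NA'}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pair_report(pairs, rmap_global, path: str | Path) -> None:
    """TSV pair report: ids, chains, global RMSD, worse resolution, targets."""
    header = [
        "before_id", "before_chain", "after_id", "after_chain",
        "global_rmsd", "worse_resolution", "binding_targets",
    ]
    lines = ["\t".join(header)]
    for pair, grmsd in zip(pairs, rmap_global):
        targets = ";".join(f"{t.name}({t.category})" for t in pair.targets) or "NA"
        res = pair.worse_resolution
        lines.append("\t".join([
            pair.before_file.id, pair.before.chain_id,
            pair.after_file.id, pair.after.chain_id,
            "NA" if grmsd is None else f"{grmsd:.4f}",
            "NA" if res is None else f"{res:.2f}",
            targets,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_superposed_pair(pair: PairCandidate, ref: ReferenceSequence,
                          path: str | Path, config: Optional[CCPConfig] = None) -> None:
    """Two-state PDB: MODEL 1 = before, MODEL 2 = after in before's frame."""
    import numpy as np

    from .structure_io import transform_structure, write_pdb

    config = config or CCPConfig()
    rmap = build_residue_map(pair.before, pair.after, ref)
    X, Y = [], []
    for i in rmap.doubly_observed():
        r1, r2 = rmap.residue(1, i), rmap.residue(2, i)
        a1, a2 = r1.atom("CA"), r2.atom("CA")
        if a1 is not None and a2 is not None:
            X.append(a2.coords)  # after -> before frame
            Y.append(a1.coords)
    result = superpose(np.asarray(X), np.asarray(Y), estimator=config.estimator)
    moved = transform_structure(pair.after, result.rotation, result.translation)
    write_pdb([pair.before, moved], path,
              remarks=[f"superposed pair, rmsd {result.rmsd:.4f} A"])
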