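"""Readers and writers for the pipeline's TSV/CSV dialects.

All tables are plain text.  The count-table dialect has one row per marker
per strand:

    sample_id  skeleton_id  marker  strand  A  C  G  T  INS  DEL

with strand ``+`` or ``-``.  Downstream outputs (calls, consensus, drop-out
report, input codes, loss report) round-trip through the same module.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .calling import GenotypeCall, SampleLibrary, StrandBaseCounts
from .consensus import ConsensusEntry, DropoutEvent
from .panel import ALL_TOKENS
from .simulate import TruthSet

COUNT_COLUMNS = ["sample_id", "skeleton_id", "marker", "strand", *ALL_TOKENS]


def write_count_table(libraries: Iterable[SampleLibrary], path: str | Path) -> None:
    rows = []
    for lib in libraries:
        for marker, counts in lib.counts.items():
            for strand, side in (("+", counts.plus), ("-", counts.minus)):
                row = {
                    "sample_id": lib.sample_id,
                    "skeleton_id": lib.skeleton_id,
                    "marker": marker,
                    "strand": strand,
                }
                for token in ALL_TOKENS:
                    row[token] = int(side.get(token, 0))
                rows.append(row)
    pd.DataFrame(rows, columns=COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_count_table(
    path: str | Path, negative_control_ids: Sequence[str] = ("NTC", "ENC")
) -> list[SampleLibrary]:
    """Parse a count table into libraries (one per sample_id, input order)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "skeleton_id": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: count table missing columns {sorted(missing)}")
    libraries = []
    for sample_id, group in df.groupby("sample_id", sort=False):
        skeleton_id = str(group["skeleton_id"].iloc[0])
        counts: dict[str, StrandBaseCounts] = {}
        for marker, mgroup in group.groupby("marker", sort=False):
            sides = {"+": {}, "-": {}}
            for row in mgroup.itertuples(index=False):
                if row.strand not in sides:
                    raise ValueError(f"{path}: bad strand {row.strand!r} at {marker}")
                sides[row.strand] = {t: int(getattr(row, t)) for t in ALL_TOKENS}
            counts[str(marker)] = StrandBaseCounts(str(marker), sides["+"], sides["-"])
        is_nc = str(sample_id) in negative_control_ids or skeleton_id in negative_control_ids
        libraries.append(SampleLibrary(str(sample_id), skeleton_id, counts, is_nc))
    return libraries


def write_calls(
    calls_by_sample: Mapping[str, Mapping[str, GenotypeCall]], path: str | Path
) -> None:
    rows = []
    for sample_id, calls in calls_by_sample.items():
        for marker, call in calls.items():
            rows.append(
                {
                    "sample_id": sample_id,
                    "marker": marker,
                    "genotype": call.genotype_str,
                    "flags": ";".join(sorted(call.flags)),
                    "coverages": ";".join(
                        f"{a}:{n}" for a, n in sorted(call.allele_coverages.items())
                    ),
                    "dropins": ";".join(
                        f"{d.nucleotide}:{d.coverage}:{d.pct}" for d in call.dropins
                    ),
                }
            )
    pd.DataFrame(
        rows, columns=["sample_id", "marker", "genotype", "flags", "coverages", "dropins"]
    ).to_csv(path, sep="\t", index=False)


def write_consensus(
    profiles: Mapping[str, Mapping[str, ConsensusEntry]], path: str | Path
) -> None:
    rows = []
    for skeleton_id, profile in profiles.items():
        for marker, entry in profile.items():
            rows.append(
                {
                    "skeleton_id": skeleton_id,
                    "marker": marker,
                    "consensus": entry.genotype_str,
                    "rule": entry.rule,
                    "n_support": len(entry.supporting),
                    "single_source": entry.single_source,
                }
            )
    pd.DataFrame(
        rows,
        columns=["skeleton_id", "marker", "consensus", "rule", "n_support", "single_source"],
    ).to_csv(path, sep="\t", index=False)


def write_dropouts(
    events_by_skeleton: Mapping[str, Sequence[DropoutEvent]], path: str | Path
) -> None:
    rows = []
    for skeleton_id, events in events_by_skeleton.items():
        for ev in events:
            rows.append(
                {
                    "skeleton_id": skeleton_id,
                    "marker": ev.marker,
                    "sample_id": ev.sample_id,
                    "missing_allele": ev.missing_allele,
                    "surviving_allele": ev.surviving_allele,
                    "surviving_coverage": ev.surviving_coverage,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "skeleton_id",
            "marker",
            "sample_id",
            "missing_allele",
            "surviving_allele",
            "surviving_coverage",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_codes(
    codes_by_individual: Mapping[str, Mapping[str, Optional[int]]],
    path: str | Path,
) -> None:
    """Webtool-style upload CSV: one row per individual, marker-named
    columns, NA left blank."""
    markers: list[str] = []
    for codes in codes_by_individual.values():
        for rsid in codes:
            if rsid not in markers:
                markers.append(rsid)
    rows = []
    for individual, codes in codes_by_individual.items():
        row: dict[str, object] = {"individual": individual}
        for rsid in markers:
            code = codes.get(rsid)
            row[rsid] = "" if code is None else int(code)
        rows.append(row)
    pd.DataFrame(rows, columns=["individual", *markers]).to_csv(path, index=False)


def read_codes(path: str | Path) -> dict[str, dict[str, Optional[int]]]:
    df = pd.read_csv(path, dtype={"individual": str})
    out: dict[str, dict[str, Optional[int]]] = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        individual = d.pop("individual")
        out[individual] = {
            rsid: (None if pd.isna(v) else int(v)) for rsid, v in d.items()
        }
    return out


def write_loss_report(
    rows: Iterable[Mapping[str, object]], path: str | Path
) -> None:
    """Loss report TSV: individual, trait, loss, gate."""
    pd.DataFrame(list(rows), columns=["individual", "trait", "loss", "gate"]).to_csv(
        path, sep="\t", index=False
    )


def write_truth(truth: TruthSet, genotype_path: str | Path, event_path: str | Path) -> None:
    rows = [
        {"skeleton_id": sk, "marker": marker, "genotype": "/".join(g)}
        for sk, per_marker in truth.genotypes.items()
        for marker, g in per_marker.items()
    ]
    pd.DataFrame(rows, columns=["skeleton_id", "marker", "genotype"]).to_csv(
        genotype_path, sep="\t", index=False
    )
    ev_rows = [
        {
            "event": "dropout",
            "sample_id": ev.sample_id,
            "marker": ev.marker,
            "allele": ev.dropped_allele,
            "reads": "",
        }
        for ev in truth.dropouts
    ] + [
        {
            "event": "dropin",
            "sample_id": ev.sample_id,
            "marker": ev.marker,
            "allele": ev.nucleotide,
            "reads": ev.reads,
        }
        for ev in truth.dropins
    ]
    pd.DataFrame(
        ev_rows, columns=["event", "sample_id", "marker", "allele", "reads"]
    ).to_csv(event_path, sep="\t", index=False)


def read_truth_genotypes(path: str | Path) -> dict[str, dict[str, tuple[str, str]]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, dict[str, tuple[str, str]]] = {}
    for row in df.itertuples(index=False):
        a, b = row.genotype.split("/")
        out.setdefault(row.skeleton_id, {})[row.marker] = (a, b)
    return out
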