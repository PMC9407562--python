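"""End-to-end orchestration: counts -> calls -> consensus -> codes -> losses.

Two strategies are supported. In ``replicate`` mode, the libraries of each
skeleton are reconciled into a consensus profile before phenotype coding,
and allelic drop-outs are enumerated against that consensus. In
``single_test`` mode each library is coded on its own, with
imbalance-flagged markers conservatively masked to NA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .calling import (
    GenotypeCall,
    SampleLibrary,
    call_library,
    flag_summary,
)
from .consensus import (
    ConsensusEntry,
    DropoutEvent,
    bin_surviving_coverage,
    build_consensus_profile,
    enumerate_dropouts,
)
from .panel import Panel, Thresholds
from .phenotype import (
    REPLICATE,
    SINGLE_TEST,
    AUCLossTable,
    CodingTable,
    compute_auc_loss,
    conservative_na_mask,
    prediction_gate,
    to_input_codes,
)

logger = logging.getLogger("mpspheno")


@dataclass
class PipelineResult:
    calls_by_sample: dict[str, dict[str, GenotypeCall]]
    profiles: dict[str, dict[str, ConsensusEntry]] = field(default_factory=dict)
    dropouts: dict[str, list[DropoutEvent]] = field(default_factory=dict)
    codes: dict[str, dict[str, Optional[int]]] = field(default_factory=dict)
    losses: dict[str, dict[str, float]] = field(default_factory=dict)
    gates: dict[str, dict[str, str]] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def has_usable_markers(calls: Mapping[str, GenotypeCall]) -> bool:
    return any(not c.is_nn for c in calls.values())


def run_pipeline(
    libraries: Sequence[SampleLibrary],
    panel: Panel,
    thresholds: Thresholds,
    mode: str = REPLICATE,
    coding: Optional[CodingTable] = None,
    losses: Optional[AUCLossTable] = None,
) -> PipelineResult:
    """Run calling, consensus (replicate mode), coding and loss accounting.

    Libraries with no marker above the coverage thresholds are discarded
    before consensus, as are negative controls.  The summary aggregates the
    flag statistics, drop-in statistics, NA fraction, drop-out count and
    the surviving-coverage histogram.
    """
    if mode not in (REPLICATE, SINGLE_TEST):
        raise ValueError(f"unknown mode {mode!r}")
    if coding is None:
        coding = CodingTable.variant_counted(panel)
    coding.validate(panel)

    calls_by_sample: dict[str, dict[str, GenotypeCall]] = {}
    for lib in libraries:
        calls = call_library(lib, panel, thresholds)
        calls_by_sample[lib.sample_id] = calls
        if lib.is_negative_control and has_usable_markers(calls):
            logger.warning("negative control %s produced calls", lib.sample_id)

    result = PipelineResult(calls_by_sample=calls_by_sample)

    analysable = [lib for lib in libraries if not lib.is_negative_control]
    discarded = [
        lib.sample_id
        for lib in analysable
        if not has_usable_markers(calls_by_sample[lib.sample_id])
    ]
    for sample_id in discarded:
        logger.info("library %s discarded: no marker above thresholds", sample_id)

    if mode == REPLICATE:
        by_skeleton: dict[str, dict[str, dict[str, GenotypeCall]]] = {}
        for lib in analysable:
            if lib.sample_id in discarded:
                continue
            by_skeleton.setdefault(lib.skeleton_id, {})[lib.sample_id] = (
                calls_by_sample[lib.sample_id]
            )
        for skeleton_id, sample_calls in by_skeleton.items():
            profile = build_consensus_profile(sample_calls, panel)
            result.profiles[skeleton_id] = profile
            result.dropouts[skeleton_id] = enumerate_dropouts(profile, sample_calls)
            for marker, entry in profile.items():
                if entry.is_na:
                    logger.info(
                        "skeleton %s marker %s: NA (%s)", skeleton_id, marker, entry.rule
                    )
            result.codes[skeleton_id] = to_input_codes(profile, coding, panel)
    else:
        for lib in analysable:
            if lib.sample_id in discarded:
                continue
            calls = calls_by_sample[lib.sample_id]
            masked = {
                marker: conservative_na_mask(call, SINGLE_TEST)
                for marker, call in calls.items()
            }
            for marker, genotype in masked.items():
                if genotype is None and not calls[marker].is_nn:
                    logger.info(
                        "sample %s marker %s: masked to NA (imbalance)",
                        lib.sample_id,
                        marker,
                    )
            result.codes[lib.sample_id] = to_input_codes(masked, coding, panel)

    for individual, codes in result.codes.items():
        result.gates[individual] = prediction_gate(codes)
        if losses is not None:
            result.losses[individual] = compute_auc_loss(codes, losses)

    attempted = [
        call
        for lib in analysable
        if lib.sample_id not in discarded
        for call in calls_by_sample[lib.sample_id].values()
    ]
    all_events = [ev for evs in result.dropouts.values() for ev in evs]
    n_codes = sum(len(c) for c in result.codes.values())
    n_na = sum(1 for c in result.codes.values() for v in c.values() if v is None)
    result.summary = {
        "n_libraries": len(analysable),
        "n_discarded_libraries": len(discarded),
        "flags": flag_summary(attempted) if attempted else {},
        "na_fraction": (n_na / n_codes) if n_codes else 0.0,
        "n_dropout_events": len(all_events),
        "dropout_coverage_bins": bin_surviving_coverage(all_events),
    }
    return result
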