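"""Reference analyses and simulation experiments.

Bundles the computations the analysis drivers and validation checks share:
re-analysis of the reference tri-allelic drop-in events, drop-out-rate
recovery from simulated replicate cohorts, deamination-rate recovery from
detected drop-in fractions, and the noiseless end-to-end identity check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calling import StrandBaseCounts, call_library, detect_drop_in, flag_summary
from .consensus import build_consensus_profile, enumerate_dropouts
from .panel import Marker, Panel, Thresholds, default_panel
from .phenotype import CodingTable, to_input_codes
from .pipeline import run_pipeline
from .simulate import SimulationParams, simulate_library, simulate_skeleton_set

# Reference set of eight tri-allelic drop-in events observed in aged
# skeletal samples: marker, combined base counts, and the expert-called
# heterozygous genotype. In every event the dropped-in nucleotide is a T,
# consistent with cytosine-deamination damage.
TRIALLELIC_REFERENCE = [
    ("rs683", {"A": 2576, "C": 3930, "T": 707}, ("A", "C")),
    ("rs1042602", {"A": 16538, "C": 23040, "T": 1079}, ("A", "C")),
    ("rs12896399", {"G": 7075, "T": 5543, "A": 982}, ("G", "T")),
    ("rs12896399", {"G": 12904, "T": 6626, "A": 432}, ("G", "T")),
    ("rs16891982", {"C": 4217, "G": 1943, "T": 199}, ("C", "G")),
    ("rs4959270", {"A": 1824, "C": 5200, "T": 236}, ("A", "C")),
    ("rs683", {"A": 15494, "C": 13807, "T": 1455}, ("A", "C")),
    ("rs1042602", {"C": 2943, "A": 296, "T": 707}, ("C", "A")),
]


def split_balanced(combined: dict[str, int]) -> StrandBaseCounts:
    """Spread combined counts evenly over the two strands."""
    plus = {t: n // 2 for t, n in combined.items()}
    minus = {t: n - n // 2 for t, n in combined.items()}
    return StrandBaseCounts("", plus, minus)


def triallelic_reanalysis(thresholds: Thresholds | None = None) -> dict:
    """Score the reference tri-allelic events through detect_drop_in.

    Returns the per-event drop-in percentages (one decimal) and their
    mean/min/max, the mean taken over the unrounded coverage fractions and
    then rounded to one decimal.
    """
    thresholds = thresholds or Thresholds()
    pcts: list[float] = []
    raw: list[float] = []
    for marker, combined, genotype in TRIALLELIC_REFERENCE:
        counts = split_balanced(combined)
        counts.marker = marker
        records = detect_drop_in(counts, genotype, thresholds)
        assert len(records) == 1, f"{marker}: expected exactly one drop-in"
        pcts.append(records[0].pct)
        raw.append(100.0 * records[0].coverage / counts.total)
    from .calling import round_half_away

    return {
        "pcts": pcts,
        "mean": round_half_away(sum(raw) / len(raw), 1),
        "min": min(pcts),
        "max": max(pcts),
    }


@dataclass
class DropoutRecovery:
    """Outcome of the drop-out-rate recovery experiment."""

    p_true: float
    p_hat: float
    se: float
    n_events: int
    n_opportunities: int

    @property
    def within(self) -> float:
        """Absolute estimation error in units of the standard error."""
        return abs(self.p_hat - self.p_true) / self.se if self.se else math.inf


def dropout_recovery(
    seed: int,
    p_dropout: float = 0.10,
    n_skeletons: int = 15,
    n_libraries: int = 4,
) -> DropoutRecovery:
    """Estimate the per-allele drop-out probability from consensus output.

    All truth genotypes are heterozygous, so every library-marker is an
    opportunity for drop-out.  At markers with a heterozygous consensus, a
    usable library called homozygous is one detected drop-out event.  A
    usable call is homozygous when exactly one of its two alleles dropped,
    so, conditional on usability, events occur with probability
    2p(1-p)/(1-p^2) = 2p/(1+p); the observed event fraction f therefore
    gives the method-of-moments estimate p_hat = f/(2-f).  The standard
    error follows from the binomial variance of f by the delta method.
    Replication (>= 3 libraries) keeps the consensus heterozygous in nearly
    all cases, so the selection bias of the few unresolved markers stays
    well inside the standard error at these sizes.
    """
    panel = default_panel()
    truth = {
        f"sk_{i + 1}": {m.rsid: tuple(sorted(m.alleles)) for m in panel}
        for i in range(n_skeletons)
    }
    params = SimulationParams(
        n_skeletons=n_skeletons,
        n_libraries=n_libraries,
        p_dropout=p_dropout,
        deam_rate=0.0,
        imbalance_sd=0.03,
        base_depth=8000.0,
        lambda_decay=0.002,
        dispersion=5.0,
        seed=seed,
        truth_genotypes=truth,
    )
    libraries, _ = simulate_skeleton_set(panel, params)
    thresholds = Thresholds()

    n_events = 0
    n_opportunities = 0
    by_skeleton: dict[str, dict] = {}
    for lib in libraries:
        if lib.is_negative_control:
            continue
        by_skeleton.setdefault(lib.skeleton_id, {})[lib.sample_id] = call_library(
            lib, panel, thresholds
        )
    for skeleton_id, calls_by_sample in by_skeleton.items():
        profile = build_consensus_profile(calls_by_sample, panel)
        events = enumerate_dropouts(profile, calls_by_sample)
        n_events += len(events)
        for rsid, entry in profile.items():
            if entry.result is None or entry.result[0] == entry.result[1]:
                continue
            n_opportunities += sum(
                1
                for calls in calls_by_sample.values()
                if rsid in calls and not calls[rsid].is_nn
            )
    f = n_events / n_opportunities
    p_hat = f / (2.0 - f)
    var_f = f * (1.0 - f) / n_opportunities
    se = 2.0 / (2.0 - f) ** 2 * math.sqrt(var_f)
    return DropoutRecovery(p_dropout, p_hat, se, n_events, n_opportunities)


@dataclass
class DeaminationRecovery:
    """Outcome of the deamination drop-in recovery experiment."""

    expected_pct: float
    observed_mean_pct: float
    se: float
    n_libraries: int


def deamination_recovery(
    seed: int,
    deam_rate: float = 0.05,
    depth: float = 10_000.0,
    n_libraries: int = 200,
) -> DeaminationRecovery:
    """Mean detected drop-in percentage at a C-carrying heterozygote.

    For a het(A, C) marker, each C read flips to T with the deamination
    rate d; with the heterozygous fraction centred on one half the
    analytic expectation of the T share of marker coverage is 100 * d / 2.
    """
    marker = Marker("rs1042602", "C", "A", 133)
    panel = Panel([marker])
    params = SimulationParams(
        base_depth=depth,
        lambda_decay=0.0,
        dispersion=50.0,
        p_dropout=0.0,
        deam_rate=deam_rate,
        imbalance_sd=0.05,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    thresholds = Thresholds()
    truth = {marker.rsid: ("A", "C")}
    pcts = []
    for i in range(n_libraries):
        lib, _, _ = simulate_library(truth, panel, params, rng, sample_id=f"lib_{i}")
        counts = lib.counts[marker.rsid]
        records = detect_drop_in(counts, ("A", "C"), thresholds)
        t_rec = [r for r in records if r.nucleotide == "T"]
        pcts.append(t_rec[0].pct if t_rec else 0.0)
    mean = float(np.mean(pcts))
    se = float(np.std(pcts, ddof=1) / math.sqrt(len(pcts)))
    return DeaminationRecovery(100.0 * deam_rate / 2.0, mean, se, n_libraries)


def noiseless_roundtrip(seed: int, n_skeletons: int = 11, n_libraries: int = 4) -> dict:
    """Simulate with all noise off and push the cohort through the full
    pipeline; report code mismatches against truth and the NA count."""
    panel = default_panel()
    params = SimulationParams(
        n_skeletons=n_skeletons,
        n_libraries=n_libraries,
        p_dropout=0.0,
        deam_rate=0.0,
        imbalance_sd=0.0,
        base_depth=5000.0,
        seed=seed,
    )
    libraries, truth = simulate_skeleton_set(panel, params)
    coding = CodingTable.variant_counted(panel)
    result = run_pipeline(libraries, panel, Thresholds(), mode="replicate", coding=coding)
    n_na = 0
    n_mismatch = 0
    n_codes = 0
    for sk, genotypes in truth.genotypes.items():
        expected = to_input_codes(genotypes, coding, panel)
        got = result.codes[sk]
        for rsid, code in expected.items():
            n_codes += 1
            if got[rsid] is None:
                n_na += 1
            elif got[rsid] != code:
                n_mismatch += 1
    return {"n_codes": n_codes, "n_na": n_na, "n_mismatch": n_mismatch}
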