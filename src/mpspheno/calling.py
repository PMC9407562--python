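"""Threshold-based genotype calling from stranded base counts.

Implements the Converge-style locus rules used for degraded-DNA PCR-MPS
genotyping: a coverage gate (NN below 20x total or without more than 10x on
each strand), a minor-allele percentage rule separating heterozygotes from
homozygotes, the MAF allelic-imbalance flag, the homozygote second-allele
alert, and the recording of dropped-in third nucleotides (in aged samples
typically C→T transitions from cytosine deamination).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .panel import ALL_TOKENS, Marker, Panel, Thresholds

# flag identifiers
LOW_COVERAGE = "LOW_COVERAGE"
STRAND_FAIL = "STRAND_FAIL"
MAF_IMBALANCE = "MAF_IMBALANCE"
HOM_SECOND_ALLELE_ALERT = "HOM_SECOND_ALLELE_ALERT"


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (2.25 -> 2.3, -2.25 -> -2.3)."""
    factor = 10.0**ndigits
    scaled = x * factor
    if scaled >= 0:
        return math.floor(scaled + 0.5) / factor
    return -math.floor(-scaled + 0.5) / factor


@dataclass
class StrandBaseCounts:
    """Per-strand read counts over the allele tokens at one marker."""

    marker: str
    plus: Mapping[str, int]
    minus: Mapping[str, int]

    def __post_init__(self) -> None:
        for strand in (self.plus, self.minus):
            for token, n in strand.items():
                if token not in ALL_TOKENS:
                    raise ValueError(f"{self.marker}: unknown allele token {token!r}")
                if n < 0 or int(n) != n:
                    raise ValueError(f"{self.marker}: counts must be non-negative integers")

    def combined(self) -> dict[str, int]:
        out = {t: 0 for t in ALL_TOKENS}
        for strand in (self.plus, self.minus):
            for token, n in strand.items():
                out[token] += int(n)
        return out

    @property
    def plus_total(self) -> int:
        return int(sum(self.plus.values()))

    @property
    def minus_total(self) -> int:
        return int(sum(self.minus.values()))

    @property
    def total(self) -> int:
        return self.plus_total + self.minus_total


@dataclass(frozen=True)
class DropInRecord:
    """A nucleotide outside the called genotype, with its share of coverage.

    ``pct`` is the percentage of the marker's total coverage (all tokens,
    both strands), rounded half away from zero to one decimal.
    """

    nucleotide: str
    coverage: int
    pct: float


@dataclass
class GenotypeCall:
    """Called genotype plus artifact flags for one marker in one library."""

    marker: str
    alleles: Optional[tuple[str, ...]]  # None encodes NN
    flags: frozenset[str] = frozenset()
    allele_coverages: dict[str, int] = field(default_factory=dict)
    dropins: tuple[DropInRecord, ...] = ()

    @property
    def is_nn(self) -> bool:
        return self.alleles is None

    @property
    def is_het(self) -> bool:
        return self.alleles is not None and self.alleles[0] != self.alleles[1]

    @property
    def is_hom(self) -> bool:
        return self.alleles is not None and self.alleles[0] == self.alleles[1]

    @property
    def genotype_str(self) -> str:
        if self.alleles is None:
            return "NN"
        return "/".join(self.alleles)


@dataclass
class SampleLibrary:
    """All marker count tables of one sequencing library."""

    sample_id: str
    skeleton_id: str
    counts: dict[str, StrandBaseCounts]
    is_negative_control: bool = False


def detect_drop_in(
    counts: StrandBaseCounts,
    called_alleles: Sequence[str],
    thresholds: Thresholds,
) -> tuple[DropInRecord, ...]:
    """Record every uncalled nucleotide above the drop-in floors.

    The percentage is computed against the marker's entire coverage (all
    allele tokens, both strands) and rounded half away from zero to one
    decimal.  Records are ordered by decreasing coverage.
    """
    combined = counts.combined()
    total = counts.total
    if total == 0:
        return ()
    called = set(called_alleles)
    records = []
    for token, n in combined.items():
        if token in called or n == 0:
            continue
        pct = 100.0 * n / total
        if n >= thresholds.dropin_min_reads and pct >= thresholds.dropin_min_pct:
            records.append(DropInRecord(token, n, round_half_away(pct, 1)))
    records.sort(key=lambda r: (-r.coverage, r.nucleotide))
    return tuple(records)


def call_genotype(
    counts: StrandBaseCounts,
    thresholds: Thresholds,
    marker: Optional[Marker] = None,
) -> GenotypeCall:
    """Call one marker from stranded base counts.

    Coverage gates: below ``min_total_cov`` total reads the marker is NN
    with LOW_COVERAGE; with any strand at or below ``min_strand_cov`` it is
    NN with STRAND_FAIL.  Otherwise alleles are ranked by combined-strand
    coverage: a second allele above ``het_min_minor_pct`` percent of total
    coverage makes a heterozygote of the top two; within
    ``hom_alert_range`` it leaves a homozygote of the top allele carrying
    HOM_SECOND_ALLELE_ALERT; otherwise a clean homozygote.

    For heterozygotes the variant-allele fraction of the two called alleles'
    reads is tested against the closed imbalance ranges and MAF_IMBALANCE
    attached when inside either.  ``marker`` supplies the designated
    (variant) allele; without it the minor called allele is used.  Ties in
    coverage rank break alphabetically on the token.
    """
    total = counts.total
    if total < thresholds.min_total_cov:
        return GenotypeCall(counts.marker, None, frozenset({LOW_COVERAGE}))
    if (
        counts.plus_total <= thresholds.min_strand_cov
        or counts.minus_total <= thresholds.min_strand_cov
    ):
        return GenotypeCall(counts.marker, None, frozenset({STRAND_FAIL}))

    combined = counts.combined()
    ranked = sorted(combined.items(), key=lambda kv: (-kv[1], kv[0]))
    top, top_n = ranked[0]
    second, second_n = ranked[1]
    second_pct = 100.0 * second_n / total

    flags: set[str] = set()
    if second_pct > thresholds.het_min_minor_pct:
        alleles = tuple(sorted((top, second)))
        pair_total = top_n + second_n
        if marker is not None and marker.var_allele in alleles:
            designated = marker.var_allele
        else:
            designated = second  # minor called allele
        frac = 100.0 * combined[designated] / pair_total
        lo_rng, hi_rng = thresholds.imbalance_ranges
        if lo_rng[0] <= frac <= lo_rng[1] or hi_rng[0] <= frac <= hi_rng[1]:
            flags.add(MAF_IMBALANCE)
        coverages = {alleles[0]: combined[alleles[0]], alleles[1]: combined[alleles[1]]}
    else:
        alleles = (top, top)
        lo, hi = thresholds.hom_alert_range
        if second_n > 0 and lo <= second_pct <= hi:
            flags.add(HOM_SECOND_ALLELE_ALERT)
        coverages = {top: top_n}

    dropins = detect_drop_in(counts, alleles, thresholds)
    return GenotypeCall(counts.marker, alleles, frozenset(flags), coverages, dropins)


def call_library(
    library: SampleLibrary, panel: Panel, thresholds: Thresholds
) -> dict[str, GenotypeCall]:
    """Call every panel marker of one library; markers resolve via the panel."""
    calls = {}
    for rsid in panel.rsids:
        counts = library.counts.get(rsid)
        if counts is None:
            counts = StrandBaseCounts(rsid, {}, {})
        calls[rsid] = call_genotype(counts, thresholds, panel[rsid])
    return calls


def compute_rdoc(library: SampleLibrary) -> dict[str, float]:
    """Relative depth of coverage: each marker's share of the library's
    on-panel base coverage. Entries sum to one."""
    totals = {rsid: c.total for rsid, c in library.counts.items()}
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError(
            f"library {library.sample_id}: rDoC undefined, zero total coverage"
        )
    return {rsid: t / grand for rsid, t in totals.items()}


def flag_summary(calls: Iterable[GenotypeCall]) -> dict:
    """Dataset-level flag statistics over a collection of genotype calls.

    Reports the percentage of markers typed NN, of heterozygotes carrying
    the MAF imbalance flag, of homozygotes carrying the second-allele alert,
    and count / mean / min / max of drop-in percentages. Percentages are
    rounded half away from zero to one decimal.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("flag_summary requires a non-empty collection of calls")
    n = len(calls)
    n_nn = sum(c.is_nn for c in calls)
    hets = [c for c in calls if c.is_het]
    homs = [c for c in calls if c.is_hom]
    n_het_imb = sum(MAF_IMBALANCE in c.flags for c in hets)
    n_hom_alert = sum(HOM_SECOND_ALLELE_ALERT in c.flags for c in homs)
    dropin_pcts = [d.pct for c in calls for d in c.dropins]
    summary = {
        "n_markers": n,
        "n_nn": n_nn,
        "pct_nn": round_half_away(100.0 * n_nn / n, 1),
        "n_het": len(hets),
        "n_het_imbalanced": n_het_imb,
        "pct_het_imbalanced": (
            round_half_away(100.0 * n_het_imb / len(hets), 1) if hets else 0.0
        ),
        "n_hom": len(homs),
        "n_hom_alerted": n_hom_alert,
        "pct_hom_alerted": (
            round_half_away(100.0 * n_hom_alert / len(homs), 1) if homs else 0.0
        ),
        "n_dropins": len(dropin_pcts),
        "dropin_pct_mean": (
            round_half_away(sum(dropin_pcts) / len(dropin_pcts), 1)
            if dropin_pcts
            else None
        ),
        "dropin_pct_min": min(dropin_pcts) if dropin_pcts else None,
        "dropin_pct_max": max(dropin_pcts) if dropin_pcts else None,
    }
    return summary
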