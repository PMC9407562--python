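"""Multi-sample consensus genotyping across replicate libraries.

Skeletal remains are typed from several skeletal elements of the same
individual; the per-library genotypes are reconciled marker by marker under
fixed clauses.  Homozygosity requires unanimity.  Heterozygosity is assigned
for replicated heterozygotes, for one heterozygote supported by homozygotes
for *different* alleles (allelic drop-out in the homozygous libraries), or
for two-plus homozygotes for different alleles alone.  One heterozygote
against two-plus *identical* homozygotes is unresolvable (NA), as are two
discordant calls when only two libraries are usable.

Enumerating the markers where a heterozygous consensus coexists with a
homozygous library call yields the allelic drop-out events and the coverage
of each surviving sister allele.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .calling import GenotypeCall
from .panel import Panel

# consensus rule identifiers
ALL_HOM_SAME = "ALL_HOM_SAME"
HET_REPLICATED = "HET_REPLICATED"
HET_WITH_DISCORDANT_HOMS = "HET_WITH_DISCORDANT_HOMS"
TWO_HOMS_DIFFERENT = "TWO_HOMS_DIFFERENT"
NA_ONE_HET_VS_IDENTICAL_HOMS = "NA_ONE_HET_VS_IDENTICAL_HOMS"
NA_TWO_SAMPLES_DISCORDANT = "NA_TWO_SAMPLES_DISCORDANT"
SINGLE_SOURCE = "SINGLE_SOURCE"
# outcomes outside the clause set
DATA_INTEGRITY = "DATA_INTEGRITY"
NO_USABLE_CALLS = "NO_USABLE_CALLS"

Genotype = tuple[str, str]


@dataclass
class ConsensusEntry:
    """Consensus result at one marker, with the clause that produced it."""

    marker: str
    result: Optional[Genotype]  # None encodes NA
    rule: str
    supporting: tuple[tuple[str, Genotype], ...] = ()
    single_source: bool = False

    @property
    def is_na(self) -> bool:
        return self.result is None

    @property
    def genotype_str(self) -> str:
        return "NA" if self.result is None else "/".join(self.result)


@dataclass(frozen=True)
class DropoutEvent:
    """A homozygous library call at a heterozygous-consensus marker."""

    marker: str
    sample_id: str
    missing_allele: str
    surviving_allele: str
    surviving_coverage: int


def _norm(genotype: Sequence[str]) -> Genotype:
    if len(genotype) != 2:
        raise ValueError(f"genotype must have two alleles, got {genotype!r}")
    a, b = sorted(genotype)
    return (a, b)


def consensus_marker(
    calls: Sequence[Sequence[str]], marker: str = ""
) -> ConsensusEntry:
    """Reconcile the usable (non-NN) genotype calls at one marker.

    Clauses, in precedence order:

    1. a single usable call is adopted as-is (SINGLE_SOURCE);
    2. exactly two usable calls that disagree -> NA;
    3. all calls identical homozygous -> that homozygote;
    4. two or more identical heterozygotes -> that heterozygote;
    5. a heterozygote plus two or more homozygotes for different alleles ->
       the heterozygote (the homozygotes are read as drop-outs);
    6. no heterozygote, homozygotes for two different alleles -> the implied
       heterozygote;
    7. one heterozygote against two or more identical homozygotes -> NA.

    The order of ``calls`` is irrelevant. More than two distinct alleles at
    a bi-allelic marker is a data-integrity problem: a warning is issued and
    NA returned.
    """
    if not calls:
        raise ValueError("consensus_marker requires at least one usable call")
    genotypes = [_norm(g) for g in calls]

    if len(genotypes) == 1:
        return ConsensusEntry(marker, genotypes[0], SINGLE_SOURCE, single_source=True)
    if len(genotypes) == 2 and genotypes[0] != genotypes[1]:
        return ConsensusEntry(marker, None, NA_TWO_SAMPLES_DISCORDANT)

    alleles = set(a for g in genotypes for a in g)
    if len(alleles) > 2:
        warnings.warn(
            f"marker {marker or '<unnamed>'}: more than two distinct alleles "
            f"across replicate calls ({sorted(alleles)}); assigning NA",
            stacklevel=2,
        )
        return ConsensusEntry(marker, None, DATA_INTEGRITY)

    hets = [g for g in genotypes if g[0] != g[1]]
    homs = [g for g in genotypes if g[0] == g[1]]
    hom_alleles = set(g[0] for g in homs)

    if not hets and len(hom_alleles) == 1:
        return ConsensusEntry(marker, homs[0], ALL_HOM_SAME)
    het_counts = Counter(hets)
    if het_counts and max(het_counts.values()) >= 2:
        replicated = max(het_counts, key=lambda g: (het_counts[g], g))
        return ConsensusEntry(marker, replicated, HET_REPLICATED)
    if hets and len(homs) >= 2 and len(hom_alleles) >= 2:
        return ConsensusEntry(marker, hets[0], HET_WITH_DISCORDANT_HOMS)
    if not hets and len(hom_alleles) == 2:
        a, b = sorted(hom_alleles)
        return ConsensusEntry(marker, (a, b), TWO_HOMS_DIFFERENT)
    if len(hets) == 1 and len(homs) >= 2 and len(hom_alleles) == 1:
        return ConsensusEntry(marker, None, NA_ONE_HET_VS_IDENTICAL_HOMS)

    # bi-allelic inputs cannot reach this point; guard anyway
    warnings.warn(
        f"marker {marker or '<unnamed>'}: call pattern matched no clause; NA",
        stacklevel=2,
    )
    return ConsensusEntry(marker, None, DATA_INTEGRITY)


def build_consensus_profile(
    calls_by_sample: Mapping[str, Mapping[str, GenotypeCall]],
    panel: Panel,
) -> dict[str, ConsensusEntry]:
    """Marker-wise consensus over the libraries of one skeleton.

    NN calls are excluded before clause evaluation; a marker with no usable
    call at all becomes NA with empty support.
    """
    if not calls_by_sample:
        raise ValueError("skeleton has no libraries")
    if not any(
        not call.is_nn for calls in calls_by_sample.values() for call in calls.values()
    ):
        raise ValueError("skeleton has no usable (non-NN) calls in any library")

    profile: dict[str, ConsensusEntry] = {}
    for rsid in panel.rsids:
        support = [
            (sample_id, calls[rsid].alleles)
            for sample_id, calls in calls_by_sample.items()
            if rsid in calls and not calls[rsid].is_nn
        ]
        if not support:
            profile[rsid] = ConsensusEntry(rsid, None, NO_USABLE_CALLS)
            continue
        entry = consensus_marker([g for _, g in support], marker=rsid)
        entry.supporting = tuple((s, _norm(g)) for s, g in support)
        profile[rsid] = entry
    return profile


def enumerate_dropouts(
    profile: Mapping[str, ConsensusEntry],
    calls_by_sample: Mapping[str, Mapping[str, GenotypeCall]],
) -> list[DropoutEvent]:
    """List allelic drop-out events implied by a consensus profile.

    At each marker whose consensus is heterozygous(X, Y), every library
    called homozygous for X or Y contributes one event; the surviving
    coverage is that library's read count for its called allele.
    """
    events: list[DropoutEvent] = []
    for rsid, entry in profile.items():
        if entry.result is None or entry.result[0] == entry.result[1]:
            continue
        x, y = entry.result
        for sample_id, calls in calls_by_sample.items():
            call = calls.get(rsid)
            if call is None or not call.is_hom:
                continue
            allele = call.alleles[0]
            if allele not in (x, y):
                continue
            missing = y if allele == x else x
            coverage = call.allele_coverages.get(allele, 0)
            events.append(DropoutEvent(rsid, sample_id, missing, allele, coverage))
    return events


def bin_surviving_coverage(
    events: Iterable[DropoutEvent | int],
    edges: Sequence[int] = (1000, 5000, 10000),
) -> tuple[int, ...]:
    """Histogram of surviving-allele coverages over half-open ranges.

    With edges (e1, e2, e3) the bins are [0, e1), [e1, e2), [e2, e3) and
    [e3, inf).
    """
    edges = tuple(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    bins = [0] * (len(edges) + 1)
    for ev in events:
        cov = ev.surviving_coverage if isinstance(ev, DropoutEvent) else int(ev)
        i = sum(cov >= e for e in edges)
        bins[i] += 1
    return tuple(bins)
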