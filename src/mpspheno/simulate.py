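"""Synthetic degraded-DNA count tables with known truth.

Generates per-library stranded base-count tables carrying the statistical
structure the genotyping workflow assumes: negative-binomial marker depth
whose mean decays exponentially with amplicon length (degraded templates
amplify short targets preferentially), per-allele PCR drop-out, heterozygous
allele imbalance, cytosine-deamination drop-ins (reads of a C allele
misread as T, of a G allele as A), a configurable strand split, and one
clean all-zero negative control per run.  Every injected drop-out and
drop-in is logged so downstream detection can be scored against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .calling import SampleLibrary, StrandBaseCounts
from .panel import ALL_TOKENS, Marker, Panel

#: deamination substitutions: reads of the key allele misread as the value
DEAMINATION_FLIPS = {"C": "T", "G": "A"}

Genotype = tuple[str, str]


@dataclass
class SimulationParams:
    """Knobs of the degraded-DNA generator.

    * ``n_skeletons`` / ``n_libraries`` — cohort shape; defaults mirror a
      multi-element study design (11 skeletons, 4 skeletal elements each).
    * ``base_depth`` — mean reads a zero-length amplicon would draw.
    * ``lambda_decay`` — per-bp exponential depth decay from degradation.
    * ``dispersion`` — negative-binomial shape; smaller is noisier.
    * ``p_dropout`` — per-allele, per-library amplification failure.
    * ``deam_rate`` — probability a read of a C (or G) allele is misread as
      T (or A), the cytosine-deamination artifact of aged DNA.
    * ``imbalance_sd`` — s.d. of the heterozygous allele fraction around 0.5.
    * ``strand_bias`` — expected plus-strand share of reads.
    """

    n_skeletons: int = 11
    n_libraries: int = 4
    base_depth: float = 8000.0
    lambda_decay: float = 0.004
    dispersion: float = 3.0
    p_dropout: float = 0.05
    deam_rate: float = 0.08
    imbalance_sd: float = 0.06
    strand_bias: float = 0.5
    seed: int = 0
    truth_genotypes: Optional[dict[str, dict[str, Genotype]]] = None

    def __post_init__(self) -> None:
        for name in ("p_dropout", "deam_rate", "strand_bias"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.base_depth <= 0:
            raise ValueError("base_depth must be positive")
        if self.lambda_decay < 0:
            raise ValueError("lambda_decay must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.imbalance_sd < 0:
            raise ValueError("imbalance_sd must be >= 0")


@dataclass(frozen=True)
class InjectedDropout:
    sample_id: str
    marker: str
    dropped_allele: str


@dataclass(frozen=True)
class InjectedDropin:
    sample_id: str
    marker: str
    nucleotide: str
    reads: int


@dataclass
class TruthSet:
    """Ground truth of one simulated cohort."""

    genotypes: dict[str, dict[str, Genotype]]  # skeleton -> marker -> genotype
    dropouts: list[InjectedDropout] = field(default_factory=list)
    dropins: list[InjectedDropin] = field(default_factory=list)


def expected_depth(marker: Marker, params: SimulationParams) -> float:
    """Mean read depth for a marker: base depth decayed exponentially with
    amplicon length."""
    return params.base_depth * math.exp(-params.lambda_decay * marker.amplicon_len)


def draw_truth_genotypes(
    panel: Panel, params: SimulationParams, rng: np.random.Generator
) -> dict[str, dict[str, Genotype]]:
    """Truth genotypes per skeleton under Hardy-Weinberg at allele
    frequency one half (hom-ref 1/4, het 1/2, hom-var 1/4)."""
    truth: dict[str, dict[str, Genotype]] = {}
    for i in range(params.n_skeletons):
        sk = f"sk_{i + 1}"
        per_marker: dict[str, Genotype] = {}
        for m in panel:
            n_var = int(rng.binomial(2, 0.5))
            alleles = [m.ref_allele] * (2 - n_var) + [m.var_allele] * n_var
            per_marker[m.rsid] = tuple(sorted(alleles))
        truth[sk] = per_marker
    return truth


def simulate_library(
    truth: Mapping[str, Genotype],
    panel: Panel,
    params: SimulationParams,
    rng: np.random.Generator,
    sample_id: str = "lib_1",
    skeleton_id: str = "sk_1",
) -> tuple[SampleLibrary, list[InjectedDropout], list[InjectedDropin]]:
    """Simulate the stranded count table of one library.

    Per marker: draw total depth (negative binomial, mean from
    ``expected_depth``); drop each allele of the genotype with
    ``p_dropout`` (a dropped heterozygote allele yields zero reads, the
    sister allele taking the full depth; a fully dropped genotype yields an
    empty marker); split heterozygote reads by a fraction drawn around 0.5
    with ``imbalance_sd``; misread C-allele reads as T (G as A) with
    ``deam_rate``; split every token binomially between strands.
    """
    counts: dict[str, StrandBaseCounts] = {}
    dropouts: list[InjectedDropout] = []
    dropins: list[InjectedDropin] = []
    for m in panel:
        genotype = truth.get(m.rsid)
        if genotype is None:
            raise ValueError(f"no truth genotype for marker {m.rsid}")
        bad = set(genotype) - set(m.alleles)
        if bad:
            raise ValueError(
                f"{m.rsid}: truth allele(s) {sorted(bad)} outside the marker's tokens"
            )
        mean = expected_depth(m, params)
        k = params.dispersion
        depth = int(rng.negative_binomial(k, k / (k + mean)))

        distinct = sorted(set(genotype))
        surviving = [a for a in distinct if rng.random() >= params.p_dropout]
        for a in distinct:
            if a not in surviving:
                dropouts.append(InjectedDropout(sample_id, m.rsid, a))

        reads: dict[str, int] = {t: 0 for t in ALL_TOKENS}
        if depth > 0 and surviving:
            if len(surviving) == 2:
                f = float(np.clip(rng.normal(0.5, params.imbalance_sd), 0.02, 0.98))
                n_first = int(rng.binomial(depth, f))
                reads[surviving[0]] += n_first
                reads[surviving[1]] += depth - n_first
            else:
                reads[surviving[0]] += depth

        if params.deam_rate > 0 and m.kind == "SNP":
            for allele, product in DEAMINATION_FLIPS.items():
                n = reads.get(allele, 0)
                if n == 0 or allele not in surviving:
                    continue
                flipped = int(rng.binomial(n, params.deam_rate))
                if flipped:
                    reads[allele] -= flipped
                    reads[product] += flipped
                    dropins.append(InjectedDropin(sample_id, m.rsid, product, flipped))

        plus = {}
        minus = {}
        for token, n in reads.items():
            if n == 0:
                continue
            p = int(rng.binomial(n, params.strand_bias))
            if p:
                plus[token] = p
            if n - p:
                minus[token] = n - p
        counts[m.rsid] = StrandBaseCounts(m.rsid, plus, minus)

    library = SampleLibrary(sample_id, skeleton_id, counts)
    return library, dropouts, dropins


def negative_control(panel: Panel, sample_id: str = "NTC") -> SampleLibrary:
    """An all-zero library, as clean extraction/template controls must be."""
    counts = {m.rsid: StrandBaseCounts(m.rsid, {}, {}) for m in panel}
    return SampleLibrary(sample_id, sample_id, counts, is_negative_control=True)


def simulate_skeleton_set(
    panel: Panel, params: SimulationParams
) -> tuple[list[SampleLibrary], TruthSet]:
    """Simulate a full cohort: ``n_libraries`` libraries per skeleton plus
    one negative control, with the complete truth log.

    All randomness flows from ``params.seed``; identical params reproduce
    identical cohorts.
    """
    rng = np.random.default_rng(params.seed)
    truth_genotypes = params.truth_genotypes
    if truth_genotypes is None:
        truth_genotypes = draw_truth_genotypes(panel, params, rng)
    truth = TruthSet(genotypes={k: dict(v) for k, v in truth_genotypes.items()})

    libraries: list[SampleLibrary] = []
    lib_no = 0
    for sk, genotypes in truth.genotypes.items():
        for _ in range(params.n_libraries):
            lib_no += 1
            lib, dropouts, dropins = simulate_library(
                genotypes, panel, params, rng, sample_id=f"lib_{lib_no}", skeleton_id=sk
            )
            libraries.append(lib)
            truth.dropouts.extend(dropouts)
            truth.dropins.extend(dropins)
    libraries.append(negative_control(panel))
    return libraries, truth
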