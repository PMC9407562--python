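"""Phenotype-model input coding, conservative NA masking and AUC-loss bookkeeping.

The eye/hair-colour prediction model itself is an external webtool; this
module prepares its inputs.  Each marker's genotype becomes the count of a
designated *counted* allele (0, 1 or 2), NA propagating.  Under the
conservative single-test policy, heterozygotes flagged for allelic
imbalance are demoted to NA before coding.  Missing inputs degrade the
external model's discrimination; the loss of AUC (area under the ROC curve)
per missing marker and trait category is supplied as a user-configured
table and summed over the NA markers of a profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .calling import MAF_IMBALANCE, GenotypeCall
from .consensus import ConsensusEntry, Genotype
from .panel import EYE_GATE_MARKER, Panel

REPLICATE = "replicate"
SINGLE_TEST = "single_test"

PREDICTABLE = "predictable"
UNDETERMINED = "undetermined"


class CodingError(ValueError):
    """Profile allele inconsistent with the coding table or panel."""


@dataclass
class CodingTable:
    """Which allele's copies are counted per marker (webtool convention).

    The counted allele must be one of the marker's two alleles; the exact
    convention lives in the external webtool's conversion script, so the
    table is mandatory configuration.  ``variant_counted`` builds the
    common convention of counting the variant allele.
    """

    counted: dict[str, str]

    @classmethod
    def variant_counted(cls, panel: Panel) -> "CodingTable":
        return cls({m.rsid: m.var_allele for m in panel})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodingTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"marker", "counted_allele"} <= set(df.columns):
            raise CodingError("coding table needs columns: marker, counted_allele")
        return cls(dict(zip(df["marker"], df["counted_allele"])))

    def validate(self, panel: Panel) -> None:
        for rsid, allele in self.counted.items():
            if rsid in panel and allele not in panel[rsid].alleles:
                raise CodingError(
                    f"{rsid}: counted allele {allele!r} is neither ref nor var"
                )


@dataclass
class AUCLossTable:
    """Per-trait-category, per-marker AUC loss contributions (user config).

    ``losses[trait][marker]`` is the non-negative AUC loss the external
    prediction model suffers when that marker is NA; absent entries read as
    zero.  Losses are taken as additive over NA markers.
    """

    losses: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for trait, per_marker in self.losses.items():
            for rsid, loss in per_marker.items():
                if loss < 0:
                    raise CodingError(f"{trait}/{rsid}: AUC loss must be >= 0")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AUCLossTable":
        df = pd.read_csv(path, sep="\t")
        if not {"trait", "marker", "loss"} <= set(df.columns):
            raise CodingError("loss table needs columns: trait, marker, loss")
        losses: dict[str, dict[str, float]] = {}
        for row in df.itertuples(index=False):
            losses.setdefault(row.trait, {})[row.marker] = float(row.loss)
        return cls(losses)

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(self.losses)


def _genotype_of(entry) -> Optional[Genotype]:
    if entry is None:
        return None
    if isinstance(entry, ConsensusEntry):
        return entry.result
    if isinstance(entry, GenotypeCall):
        return entry.alleles
    return tuple(entry)  # bare genotype tuple


def to_input_codes(
    profile: Mapping[str, object],
    coding: CodingTable,
    panel: Panel,
) -> dict[str, Optional[int]]:
    """Convert a genotype profile into webtool input codes.

    Per marker the code is the number of copies of the counted allele in
    the genotype (0, 1 or 2); NA genotypes yield None.  Values accepted per
    marker: a ConsensusEntry, a GenotypeCall, a bare allele pair, or None.
    """
    codes: dict[str, Optional[int]] = {}
    for rsid, entry in profile.items():
        if rsid not in coding.counted:
            raise CodingError(f"{rsid}: no counted allele configured")
        genotype = _genotype_of(entry)
        if genotype is None:
            codes[rsid] = None
            continue
        allowed = set(panel[rsid].alleles)
        bad = set(genotype) - allowed
        if bad:
            raise CodingError(
                f"{rsid}: genotype allele(s) {sorted(bad)} outside ref/var {sorted(allowed)}"
            )
        codes[rsid] = sum(a == coding.counted[rsid] for a in genotype)
    return codes


def conservative_na_mask(call: GenotypeCall, mode: str) -> Optional[Genotype]:
    """Apply the conservative single-test NA policy to one call.

    In ``single_test`` mode a call flagged for allelic imbalance is masked
    to NA; in ``replicate`` mode (where replicate libraries adjudicate
    imbalance) calls pass through.  NN is NA in both modes.
    """
    if mode not in (REPLICATE, SINGLE_TEST):
        raise ValueError(f"mode must be {REPLICATE!r} or {SINGLE_TEST!r}, got {mode!r}")
    if call.is_nn:
        return None
    if mode == SINGLE_TEST and MAF_IMBALANCE in call.flags:
        return None
    return call.alleles


def prediction_gate(
    codes: Mapping[str, Optional[int]],
    eye_gate_marker: str = EYE_GATE_MARKER,
) -> dict[str, str]:
    """Per-trait predictability of the external model given the codes.

    Eye colour hinges on the HERC2 marker rs12913832: with that marker NA
    the eye-colour prediction is undetermined.  Hair colour carries no
    single gating marker and stays predictable (possibly with AUC loss).
    """
    eye = UNDETERMINED if codes.get(eye_gate_marker) is None else PREDICTABLE
    return {"eye": eye, "hair": PREDICTABLE}


def compute_auc_loss(
    codes: Mapping[str, Optional[int]],
    losses: AUCLossTable,
) -> dict[str, float]:
    """Total AUC loss per trait category: sum of the configured
    contributions over the profile's NA markers (zero with no NA)."""
    na_markers = [rsid for rsid, code in codes.items() if code is None]
    return {
        trait: sum(losses.losses[trait].get(rsid, 0.0) for rsid in na_markers)
        for trait in losses.traits
    }
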