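"""Marker panel, analysis thresholds and protocol helper rules.

The default panel is the 24-marker HIrisPlex eye/hair-colour panel as typed
by multiplex PCR followed by massively parallel sequencing (PCR-MPS):
23 bi-allelic SNPs plus one InDel (rs796296176, also known as rs312262906,
the MC1R N29insA insertion), distributed over 17 short amplicons so that
several MC1R markers share an amplicon.  Amplicon lengths are carried as
panel metadata; they matter only to the synthetic-data depth model, where
longer amplicons lose coverage faster as template degradation increases.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

#: allele tokens a stranded count table may carry
NUCLEOTIDES = ("A", "C", "G", "T")
INDEL_TOKENS = ("INS", "DEL")
ALL_TOKENS = NUCLEOTIDES + INDEL_TOKENS

SNP = "SNP"
INDEL = "InDel"

#: rsid of the marker gating eye-colour prediction (HERC2)
EYE_GATE_MARKER = "rs12913832"


class PanelConfigError(ValueError):
    """Malformed panel or threshold configuration."""


@dataclass(frozen=True)
class Marker:
    """One panel marker: a bi-allelic SNP or the single InDel.

    ``amplicon_len`` is the length in bp of the sequenced PCR target the
    marker sits on.
    """

    rsid: str
    ref_allele: str
    var_allele: str
    amplicon_len: int
    kind: str = SNP

    def __post_init__(self) -> None:
        valid = ALL_TOKENS
        if self.ref_allele not in valid or self.var_allele not in valid:
            raise PanelConfigError(
                f"{self.rsid}: allele tokens must be in {valid}, got "
                f"{self.ref_allele!r}/{self.var_allele!r}"
            )
        if self.ref_allele == self.var_allele:
            raise PanelConfigError(f"{self.rsid}: ref and var allele identical")
        if self.amplicon_len <= 0:
            raise PanelConfigError(f"{self.rsid}: amplicon_len must be positive")
        if self.kind not in (SNP, INDEL):
            raise PanelConfigError(f"{self.rsid}: kind must be SNP or InDel")

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.ref_allele, self.var_allele)


class Panel:
    """Ordered collection of markers with unique rsids."""

    def __init__(self, markers: Iterable[Marker]):
        self.markers: tuple[Marker, ...] = tuple(markers)
        seen: set[str] = set()
        for m in self.markers:
            if m.rsid in seen:
                raise PanelConfigError(f"duplicate marker rsid {m.rsid}")
            seen.add(m.rsid)
        self._by_rsid = {m.rsid: m for m in self.markers}

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._by_rsid

    def __eq__(self, other) -> bool:
        return isinstance(other, Panel) and self.markers == other.markers

    def __getitem__(self, rsid: str) -> Marker:
        try:
            return self._by_rsid[rsid]
        except KeyError:
            raise KeyError(f"marker {rsid!r} not in panel") from None

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(m.rsid for m in self.markers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(m) for m in self.markers])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# Default panel. MC1R markers share amplicons (the panel's 24 markers sit on
# 17 amplicons); lengths are representative of the short-amplicon design used
# for degraded templates.
_DEFAULT_PANEL_ROWS = [
    # rsid, ref, var, amplicon_len, kind
    ("rs796296176", "DEL", "INS", 82, INDEL),  # MC1R N29insA
    ("rs1805005", "G", "T", 82, SNP),
    ("rs1805006", "C", "A", 82, SNP),
    ("rs11547464", "G", "A", 90, SNP),
    ("rs885479", "G", "A", 90, SNP),
    ("rs2228479", "G", "A", 90, SNP),
    ("rs1805007", "C", "T", 95, SNP),
    ("rs1805008", "C", "T", 95, SNP),
    ("rs1110400", "T", "C", 95, SNP),
    ("rs1805009", "G", "C", 100, SNP),
    ("rs201326893", "C", "A", 100, SNP),  # Y152OCH
    ("rs12203592", "C", "T", 87, SNP),
    ("rs2402130", "A", "G", 106, SNP),
    ("rs12821256", "T", "C", 109, SNP),
    ("rs2378249", "A", "G", 115, SNP),
    ("rs28777", "C", "A", 117, SNP),
    ("rs1800407", "G", "A", 124, SNP),
    ("rs4959270", "C", "A", 125, SNP),
    ("rs16891982", "C", "G", 128, SNP),
    ("rs1393350", "G", "A", 131, SNP),
    ("rs1042602", "C", "A", 133, SNP),
    ("rs12913832", "A", "G", 140, SNP),
    ("rs683", "A", "C", 148, SNP),
    ("rs12896399", "G", "T", 159, SNP),
]


def default_panel() -> Panel:
    """The built-in 24-marker HIrisPlex panel (23 SNPs + 1 InDel)."""
    return Panel(Marker(*row) for row in _DEFAULT_PANEL_ROWS)


def load_panel(config_path: Optional[str | Path] = None) -> Panel:
    """Load a panel from a TSV config, or return the default 24-marker panel.

    The TSV must carry the header
    ``rsid  ref_allele  var_allele  amplicon_len  kind``; row order is
    preserved.
    """
    if config_path is None:
        return default_panel()
    df = pd.read_csv(config_path, sep="\t", dtype=str)
    required = {"rsid", "ref_allele", "var_allele", "amplicon_len", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise PanelConfigError(f"panel config missing columns: {sorted(missing)}")
    markers = []
    for row in df.itertuples(index=False):
        try:
            length = int(row.amplicon_len)
        except (TypeError, ValueError):
            raise PanelConfigError(
                f"{row.rsid}: amplicon_len {row.amplicon_len!r} is not an integer"
            ) from None
        markers.append(Marker(row.rsid, row.ref_allele, row.var_allele, length, row.kind))
    return Panel(markers)


@dataclass
class Thresholds:
    """Locus thresholds of the Converge-style genotyping workflow.

    Percent quantities are fractions of the marker's total coverage (all
    allele tokens, both strands) unless noted.

    * ``min_total_cov`` — minimum marker coverage for typing (inclusive).
    * ``min_strand_cov`` — each strand must exceed this (strict: > 10 means
      at least 11 reads per strand).
    * ``het_min_minor_pct`` — a second allele above this percent (strict)
      makes the call heterozygous.
    * ``imbalance_ranges`` — closed percent intervals on the variant-allele
      fraction of a heterozygote's two allele reads; inside either interval
      the MAF (major allele frequency) flag is raised.
    * ``hom_alert_range`` — closed percent interval: a second allele in this
      band under a homozygous call raises an alert.
    * ``dropin_min_pct`` / ``dropin_min_reads`` — floor for recording a
      dropped-in (uncalled) nucleotide.
    """

    min_total_cov: int = 20
    min_strand_cov: int = 10
    het_min_minor_pct: float = 10.0
    imbalance_ranges: tuple[tuple[float, float], tuple[float, float]] = (
        (10.1, 35.0),
        (65.0, 89.1),
    )
    hom_alert_range: tuple[float, float] = (1.0, 10.0)
    dropin_min_pct: float = 1.0
    dropin_min_reads: int = 10

    def __post_init__(self) -> None:
        if self.min_total_cov < 1:
            raise PanelConfigError("min_total_cov must be >= 1")
        bounds = [
            self.het_min_minor_pct,
            *self.imbalance_ranges[0],
            *self.imbalance_ranges[1],
            *self.hom_alert_range,
            self.dropin_min_pct,
        ]
        if any(not (0.0 <= b <= 100.0) for b in bounds):
            raise PanelConfigError("all percent bounds must lie in [0, 100]")
        lo_rng, hi_rng = self.imbalance_ranges
        if lo_rng[1] >= hi_rng[0]:
            raise PanelConfigError("imbalance ranges must not overlap")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Thresholds":
        raw = json.loads(Path(path).read_text())
        if "imbalance_ranges" in raw:
            raw["imbalance_ranges"] = tuple(tuple(r) for r in raw["imbalance_ranges"])
        if "hom_alert_range" in raw:
            raw["hom_alert_range"] = tuple(raw["hom_alert_range"])
        return cls(**raw)


def recommended_pcr_cycles(template_ng: float) -> int:
    """Cycle-number rule for the multiplex PCR, by template amount.

    25 cycles from 0.3 ng up, 27 cycles from 0.1 to 0.3 ng, 28 cycles below
    0.1 ng.  The published ranges touch at their boundaries; boundary values
    get the lower cycle count, the conservative PCR choice.
    """
    if not (template_ng > 0) or math.isnan(template_ng):
        raise ValueError(f"template amount must be positive, got {template_ng}")
    if template_ng >= 0.3:
        return 25
    if template_ng >= 0.1:
        return 27
    return 28
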