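#!/usr/bin/env python
"""Convert consensus profiles to phenotype-model input codes, apply the
eye-colour gate, and account AUC loss from an illustrative loss table.

The loss table shipped here is synthetic (clearly labelled so): the real
per-marker AUC-loss contributions belong to the external prediction model
and are user configuration.  Writes results/phenotype/{input_codes.csv,
loss_report.tsv}.
"""

import argparse
from pathlib import Path

from mpspheno import io
from mpspheno.panel import EYE_GATE_MARKER, Thresholds, default_panel
from mpspheno.phenotype import AUCLossTable
from mpspheno.pipeline import run_pipeline

# synthetic, illustrative AUC-loss table: not the external model's values
SYNTHETIC_LOSSES = AUCLossTable(
    {
        "blue_eye": {EYE_GATE_MARKER: 0.062, "rs1800407": 0.010},
        "brown_eye": {EYE_GATE_MARKER: 0.063, "rs1800407": 0.012},
        "intermediate_eye": {EYE_GATE_MARKER: 0.040},
        "blond_hair": {"rs12821256": 0.020, "rs12203592": 0.015},
        "brown_hair": {"rs683": 0.010, "rs2402130": 0.008},
        "red_hair": {"rs1805007": 0.050, "rs1805008": 0.045},
        "black_hair": {"rs16891982": 0.012},
    }
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--counts", type=Path, default=Path("results/sim/counts.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results/phenotype"))
    ap.add_argument("--mode", choices=("replicate", "single_test"), default="replicate")
    args = ap.parse_args()

    panel = default_panel()
    libraries = io.read_count_table(args.counts)
    result = run_pipeline(
        libraries, panel, Thresholds(), mode=args.mode, losses=SYNTHETIC_LOSSES
    )

    args.out.mkdir(parents=True, exist_ok=True)
    io.write_codes(result.codes, args.out / "input_codes.csv")
    rows = [
        {
            "individual": ind,
            "trait": trait,
            "loss": round(result.losses[ind][trait], 4),
            "gate": result.gates[ind]["eye" if "eye" in trait else "hair"],
        }
        for ind in result.codes
        for trait in SYNTHETIC_LOSSES.traits
    ]
    io.write_loss_report(rows, args.out / "loss_report.tsv")

    n_full = sum(
        all(v is not None for v in codes.values()) for codes in result.codes.values()
    )
    n_eye_blocked = sum(g["eye"] == "undetermined" for g in result.gates.values())
    print(f"coded {len(result.codes)} individuals; full profiles: {n_full}")
    print(f"eye colour undetermined (gate marker NA): {n_eye_blocked}")
    print(f"NA fraction of codes: {result.summary['na_fraction']:.3f}")


if __name__ == "__main__":
    main()
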