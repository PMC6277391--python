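#!/usr/bin/env python
"""Generate the synthetic datasets every later analysis step consumes.

Writes the raw inputs (CPMG decays, feeding/composition tables, peptide
evidence + FASTA, melt curves) under scratch/data/ -- these can be large and
are regenerated deterministically from the seed, so they are scratch, not
results.  Run from the repository root:

    python analysis/01_simulate_datasets.py [--seed 1]
"""

import argparse
from pathlib import Path

from limnodigest import io as lio
from limnodigest import synth
from limnodigest.config import stage_seed

import pandas as pd


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("scratch/data"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    # feeding experiments: willow (headline 22% loss) and Scots pine
    for name, scenario in (("willow", synth.willow_scenario()),
                           ("pine", synth.pine_scenario())):
        records, wood, feces = synth.gen_feeding_experiment(
            scenario, n_batches=10, seed=stage_seed(args.seed, "feeding"),
            n_wood_samples=10, n_feces_samples=8,
        )
        lio.write_feeding(records, out / f"{name}_feeding.csv")
        lio.write_composition(wood, out / f"{name}_wood_composition.csv")
        lio.write_composition(feces, out / f"{name}_feces_composition.csv")
        print(f"{name}: 10 feeding batches, {len(wood)} wood / {len(feces)} "
              f"fecal composition samples (true loss {100*scenario.mass_loss:.0f}%)")

    # CPMG decays: control and hemocyanin-treated pore-population presets
    for name in ("control", "treated"):
        acq = synth.acquisition_preset(name, seed=stage_seed(args.seed, "relaxometry"))
        decay = synth.gen_cpmg_decay(synth.pore_population_preset(name), acq)
        lio.write_decay(decay, out / f"cpmg_{name}.csv")
        print(f"cpmg_{name}: {len(decay)} echoes at 70 us, SNR preset {acq.snr:.0f}")

    # digestive proteome evidence
    preset = synth.digestome_preset(seed=stage_seed(args.seed, "proteome"))
    evidence, sequences = synth.gen_proteome_evidence(preset)
    lio.write_evidence(evidence, out / "evidence.tsv")
    lio.write_fasta(sequences, out / "proteins.fasta")
    pd.Series(synth.annotations_of(preset), name="family").rename_axis(
        "protein_id"
    ).to_csv(out / "annotations.csv")
    print(f"proteome: {len(evidence)} peptide matches over "
          f"{evidence['protein_id'].nunique()} proteins, 3 compartments x 3 replicates")

    # thermofluor melt curves
    for i, name in enumerate(("native", "buffer", "seawater", "chelator")):
        curve = synth.gen_melt_curve(
            synth.melt_preset(name, seed=stage_seed(args.seed, "melt", i))
        )
        lio.write_melt(curve, out / f"melt_{name}.csv")
    print("melt curves: native/buffer (70 C), seawater (65 C), chelator (53 C)")


if __name__ == "__main__":
    main()
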