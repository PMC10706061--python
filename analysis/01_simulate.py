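"""Generate the synthetic grape dataset the rest of the analysis consumes.

Draws 200 samples of stage-labelled chemistry (stage counts 32/34/55/49/30)
and 10 replicate reflectance spectra each on the 1507-channel 400-1029 nm
grid, then writes the chemistry table, the per-stage chemistry summary and
the per-stage mean spectra under results/.  The full replicate tensor is
regenerated on demand from the config (seed 0) rather than stored.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from graperipe import synthio
from graperipe.containers import INDICATOR_COLUMNS, stage_name

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

config = synthio.SynthConfig(seed=0)
chem, labels = synthio.generate_chemistry(config)
reps = synthio.generate_spectra(chem, labels, config)

synthio.write_chemistry_csv(chem, OUT / "chemistry.csv")
config.to_yaml(OUT / "synth_config.yaml")

summary = (
    chem.assign(stage=[stage_name(s) for s in labels])
    .groupby("stage")[list(INDICATOR_COLUMNS) + ["ssc_ta_ratio"]]
    .agg(["mean", "std"])
    .round(2)
)
summary.to_csv(OUT / "chemistry_stage_summary.csv")

# per-stage mean spectra, thinned to every 4th channel for a compact table
thin = slice(None, None, 4)
mean_spectra = pd.DataFrame(
    {
        stage_name(s): np.round(reps.values[labels == s].mean(axis=(0, 1))[thin], 5)
        for s in range(5)
    },
    index=np.round(config.wavelengths[thin], 4),
)
mean_spectra.index.name = "wavelength_nm"
mean_spectra.to_csv(OUT / "stage_mean_spectra.csv")

print(f"samples: {len(chem)}  stage counts: {np.bincount(labels).tolist()}")
print(f"replicates per sample: {reps.n_replicates}  channels: {reps.values.shape[2]}")
print(f"wrote chemistry.csv, chemistry_stage_summary.csv, stage_mean_spectra.csv -> {OUT}")
print("\nper-stage chemistry (mean):")
print(summary.xs("mean", axis=1, level=1).to_string())
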