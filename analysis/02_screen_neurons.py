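#!/usr/bin/env python
"""Screen neurons for face responsiveness.

Per image: two-sided paired signed-rank of post- (0-500 ms) vs pre-stimulus
(-500-0 ms) firing rate; responsive = at least one image with p < 0.05 and
an increase.  Output: results/screening.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from amygdecode import screening
from amygdecode.data_model import read_spike_dataset

ap = argparse.ArgumentParser()
ap.add_argument("--dataset", type=Path, default=Path("results/dataset.csv"))
ap.add_argument("--out-dir", type=Path, default=Path("results"))
args = ap.parse_args()

ds = read_spike_dataset(args.dataset)
results = screening.screen_dataset(ds)
df = pd.DataFrame(
    {
        "neuron_id": [r.neuron_id for r in results],
        "responsive": [r.responsive for r in results],
        "excluded": [r.excluded for r in results],
        "min_p": [min(r.per_image_p.values()) if r.per_image_p else float("nan") for r in results],
    }
)
df.to_csv(args.out_dir / "screening.csv", index=False)
n_resp = int(df["responsive"].sum())
print(f"{n_resp}/{len(df)} neurons face-responsive (signed-rank p<0.05 with an increase)")
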