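#!/usr/bin/env python
"""Population decoding of facial expression over sliding windows.

One-vs-rest linear C-SVC (cost 0.125) on max-normalized spike counts,
repeated random 80/20 train/test splits, label-shuffled chance, pairwise
AUC profiles at the detected peaks, and peak/trough localization.
Outputs: results/decoding.csv, results/auc_profile.csv, results/peaks.csv,
and per-rep open-mouth weights at the early reference window
(results/weights_raw.csv) for the weight analysis.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from amygdecode import decoding, pipeline
from amygdecode.data_model import EXPRESSIONS, WindowSpec, read_spike_dataset

ap = argparse.ArgumentParser()
ap.add_argument("--dataset", type=Path, default=Path("results/dataset.csv"))
ap.add_argument("--out-dir", type=Path, default=Path("results"))
ap.add_argument("--step", type=float, default=6.0)
ap.add_argument("--n-reps", type=int, default=48)
ap.add_argument("--reference-center", type=float, default=55.0)
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

ds = read_spike_dataset(args.dataset)
spec = WindowSpec(step=args.step, center_min=-60, center_max=400)
tc = decoding.decode_timecourse(
    ds, spec, n_reps=args.n_reps, seed=args.seed,
    store_weights_at=args.reference_center,
)
per_class = tc.mean_per_class
pd.DataFrame(
    {
        "center": tc.centers,
        "accuracy": tc.mean_accuracy,
        **{f"accuracy_{e}": per_class[:, k] for k, e in enumerate(EXPRESSIONS)},
        "chance": tc.mean_chance,
    }
).to_csv(args.out_dir / "decoding.csv", index=False)

pk = pipeline.find_peaks_and_trough(tc.centers, tc.mean_accuracy, min_prominence=0.05)
pd.DataFrame([vars(pk)]).to_csv(args.out_dir / "peaks.csv", index=False)

rows = []
for name, center in (("early_peak", pk.early_peak), ("trough", pk.trough),
                     ("global_peak", pk.global_peak)):
    if center is None:
        continue
    for (a, b), v in decoding.pairwise_auc_profile(tc, center).items():
        rows.append({"window": name, "center": center, "pair": f"{a}_vs_{b}", "auc": v})
pd.DataFrame(rows).to_csv(args.out_dir / "auc_profile.csv", index=False)

ref = tc.result_at(args.reference_center)
w = ref.weights_open_mouth
pd.DataFrame(w, columns=[f"n{int(i)}" for i in ref.neuron_ids]).to_csv(
    args.out_dir / "weights_raw.csv", index=False
)

print(f"peaks: early {pk.early_peak} ms, trough {pk.trough} ms, global {pk.global_peak} ms "
      f"(delay {pk.delay} ms)")
if pk.early_peak is not None:
    ie = int(np.argmin(np.abs(tc.centers - pk.early_peak)))
    ig = int(np.argmin(np.abs(tc.centers - pk.global_peak)))
    print(f"best classifier at early peak: {EXPRESSIONS[np.argmax(per_class[ie])]}; "
          f"at global peak: {EXPRESSIONS[np.argmax(per_class[ig])]}")
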