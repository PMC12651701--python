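# eegnetkit

Low- and high-order functional network analysis of resting-state EEG, for
studies that compare two recording conditions (for example before and after
a neurofeedback or other cognitive intervention) in a paired cohort design.

Scalp EEG is recorded on 16 channels of the international 10–20 montage,
resampled to 128 Hz, notch-filtered, and split into delta (1–4 Hz), theta
(4–8), alpha (8–13) and beta (13–30) bands with a Daubechies-4 wavelet
decomposition (or exact-edge FIR filters). Per band, the toolkit builds:

- **LOFC** — the low-order network: `w_ij = |Pearson(env_i, env_j)|` between
  Hilbert amplitude envelopes of channels i and j;
- **HOFC** — the high-order network: for each node pair, the absolute
  Pearson correlation of their Fisher-z-transformed connectivity *profiles*
  (LOFC columns with rows {i, j} removed), measuring similarity of
  connection patterns rather than of signals;
- **graph metrics** on either network, with edge lengths `1/w_ij`:
  nodal efficiency `NE_i = (1/(N−1)) Σ_{j≠i} 1/d_ij`, global efficiency
  `GE = (1/N) Σ NE_i`, the Zhang–Horvath weighted clustering coefficient
  `NCC_i = Σ_{j≠k} w_ij w_jk w_ki / ((Σ w_ij)² − Σ w_ij²)` and its network
  average `Cave`, plus frontal/temporal/parietal/occipital lobe means;
- **dynamic networks** over non-overlapping windows (seven lengths per band:
  1/f_min and 1, 2, 4, 6, 8, 10 s), each window classified integrated (1)
  or segregated (0) by a median split on its GE, and the normalized state
  entropy of the four consecutive-pair transition patterns 00/01/10/11,
  `NSE = −(1/log 4) Σ p_i log p_i`;
- **paired statistics**: two-sided paired-samples t-tests pre vs post for
  every metric, star coding (`*` p<0.05, `**` p<0.01, `***` p<0.001),
  optional Benjamini–Hochberg adjustment, and an improved/stable/declined
  summary for integer cognitive scores.

A synthetic-cohort generator produces 16-channel recordings with known
band-specific envelope coupling, known integrated/segregated epoch dynamics
and a JSON ground-truth ledger, so every stage can be validated against
planted structure. See `docs/methods.md` for the models and the design
choices.

## Worked example

```python
import numpy as np
from eegnetkit import (
    CohortSpec, generate_cohort, wavelet_band_decompose,
    band_connectivity, compute_hofc, mean_connectivity,
    compute_graph_metrics, dynamic_entropy,
)

cohort = generate_cohort(CohortSpec(n_subjects=4, duration_s=120,
                                    sampling_rate=128, seed=42))

for cond in ("pre", "post"):
    vals = [
        mean_connectivity(band_connectivity(
            wavelet_band_decompose(cohort.recordings[sid][cond])["delta"], "low"))
        for sid in cohort.subject_ids
    ]
    print(cond, round(float(np.mean(vals)), 4))

bands = wavelet_band_decompose(cohort.recordings["s00"]["post"])
lofc = band_connectivity(bands["delta"], "low")
gm = compute_graph_metrics(lofc)
print("GE", round(gm.global_efficiency, 4), "Cave", round(gm.average_clustering, 4))
nse, dist, states = dynamic_entropy(bands["delta"], 2.0, order="low")
print("NSE", round(nse, 4), "windows", len(states))
```

prints

```
pre 0.2453
post 0.5239
GE 0.5103 Cave 0.5217
NSE 0.9872 windows 60
```

The cohort's default preset raises delta-band coupling in the post
condition and lowers theta/alpha/beta, so the mean delta LOFC roughly
doubles from pre (0.2453) to post (0.5239). For subject `s00` post, global
efficiency and average clustering of the delta LOFC network are ≈ 0.51–0.52,
and the 2-second-window state sequence is close to maximally irregular
(NSE ≈ 0.99; 1.0 would mean all four transition patterns equally likely).

The same pipeline runs from the shell:

```bash
eegnetkit simulate --subjects 4 --duration 120 --rate 128 --seed 42 --out cohort/
eegnetkit run --in cohort/ --rate 128 --out results/   # or omit --in to simulate
```

writing tidy `metrics.csv`, `dynamics.csv`, `stats.csv`, per-matrix CSVs,
fixed-scale (0–0.6) connectivity heatmaps and a manifest carrying the
configuration hash.

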