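# gazetherm

Thermodynamic analysis of collective gaze behaviour.

When a group of people watches the same video, their eye movements are
partially synchronised. `gazetherm` quantifies that collective behaviour
with tools from statistical mechanics: it turns multi-viewer gaze
trajectories into inter-subject correlations, infers the pairwise
"interactions" between viewers with a maximum-entropy model, asks how close
the audience is to a critical point between random and lock-step viewing,
and measures the community structure of the resulting viewer network. It is
aimed at researchers studying audience responses to dynamic stimuli
(eye-tracking panels, media testing, collective-attention studies).

## The model

Each viewer `i` contributes a unit eye-movement direction vector
`σ_i(t) = v_i(t)/|v_i(t)|`, with velocity from central differences of the
gaze position. The pairwise connected correlation and its all-pair average
(the susceptibility χ) are

    C_ij = ⟨σ_i·σ_j⟩_t − μ_i·μ_j,        C_σ = 1/(N(N−1)) Σ_{i≠j} C_ij .

The least-structured distribution matching the observed means μ_i and
correlations C_ij is the Boltzmann distribution of a fully connected XY
model,

    P_T(σ) ∝ exp(−E(σ)/T),    E = −Σ_i h_i·σ_i − Σ_{i<j} J_ij σ_i·σ_j ,

at operating temperature T_o = 1. The couplings J_ij ("interactions") are
inferred by Monte-Carlo Boltzmann learning until the model reproduces the
observed correlations. Sweeping the temperature of the fitted model and
locating the peak of the heat capacity C_V(T) = Var(E)/T² gives the
critical temperature T_c: audiences with T_c close to 1 are near the
critical balance between disorder and lock-step at which distinct groups of
viewing behaviour emerge. Those groups are quantified by thresholding J at
the percolation point J_o and maximising network modularity Q. Preference
ratings enter through the homophily statistic
`O = 1/(N(N−1)) Σ_{i≠j} (1 − |p_i − p_j|/p_max)`.

Because eye-tracking panels are rarely shareable, the package ships a
first-class synthetic-data generator: the forward model of the same XY
distribution with planted community couplings, integrated into on-screen
pixel trajectories with bursty tracker dropout and group-structured
ratings. Every stage of the pipeline is tested against it.

## Worked example

Four synthetic 30-s "videos" (250 Hz panels of 12 viewers, two planted
viewer groups) with the planted coupling scale increasing across videos:

```python
import pandas as pd
from gazetherm import (SyntheticConfig, simulate_gaze_video, simulate_ratings,
                       RatingsTable, RunConfig, FitOptions, run_study)

cfg = SyntheticConfig(n_subjects=12)
manifest, frames = {}, []
for k, scale in enumerate((0.7, 1.2, 1.7, 2.2)):
    vid = f"v{k:02d}"
    panel, model = simulate_gaze_video(cfg, seed=100 + k, coupling_scale=scale)
    manifest[vid] = panel
    frames.append(simulate_ratings(cfg, seed=200 + k, video=vid,
                                   group_labels=model.group_labels).ratings)
ratings = RatingsTable(pd.concat(frames))
run_cfg = RunConfig(seed=7, scan_samples=2000)
run_cfg.fit = FitOptions(fidelity_target=0.95, max_iterations=250,
                         n_samples_max=6000, n_validation=15000)
summary, report = run_study(manifest, run_cfg, ratings)
```

The per-video summary it prints:

```text
video  C_sigma  J_avg    T_c  T_c_eigen    J_o      Q  homophily
  v00   0.0297 0.0468 0.1700     0.2916 0.0981 0.4107     0.7976
  v01   0.0443 0.0635 0.1700     0.3739 0.1548 0.4012     0.8410
  v02   0.0795 0.0952 0.3445     0.5406 0.1898 0.5350     0.8374
  v03   0.1217 0.1260 0.4622     0.7041 0.1927 0.4452     0.7827
```

Reading the rows: as the planted coupling scale grows, the measured
susceptibility `C_sigma`, the mean inferred coupling `J_avg` and the
critical temperature `T_c` all rise together — the more strongly coupled
audiences sit closer to criticality (`T_c → T_o = 1`). `T_c_eigen` is the
fast mean-field proxy λ_max(J)/2, which tracks the Monte-Carlo `T_c`
without equalling it (here r = 0.98 across the four videos, reported by the
accompanying correlation table). `J_o` is the percolation threshold at
which the giant component of the viewer network emerges and `Q` the
modularity of the detected viewer communities; `homophily` near 0.8 says
the 12 raters largely agree.

A command-line interface mirrors the library
(`gazetherm simulate | preprocess | isc | fit | thermo | network |
null-check | run-all`); see `gazetherm --help`.

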