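# cyclesig

Single-cell analysis of growth-signaling activity across the budding-yeast
cell cycle. The package quantifies the nuclear-to-cytosolic (N/C) ratio of
fluorescently tagged transcription factors (e.g. Sfp1, Tod6 — readouts of
TORC1/PKA activity) from time-lapse microscopy, aligns and averages
single-cell traces anchored at cell-cycle events, recovers
maturation-corrected ribosomal-protein synthesis rates, and statistically
compares two groups of single-cell time series with a non-stationary
Gaussian-process population model. A synthetic-data module generates
images, traces, GP population draws and maturation-model trajectories with
known ground truth, so the whole pipeline is testable end to end without
microscope data.

## Who this is for

Groups doing quantitative time-lapse microscopy of dividing cells who need
to (a) turn segmented two-channel images into localization readouts,
(b) compare readout dynamics between strains or conditions without the
pseudo-replication of pointwise t-tests, and (c) convert fluorescent-fusion
abundance curves into synthesis rates corrected for fluorophore maturation.

## The core methods

**N/C ratio.** With the nucleus segmented by an Otsu-style threshold in the
RFP channel, the readout is the mean GFP inside a small disk (radius
0.48 µm) at the nucleus centroid divided by the mean GFP over the cell mask
minus a large disk (radius 1.44 µm).

**Cycle alignment.** Each cycle is anchored at karyokinesis (K), budding
(B) and the next karyokinesis; G1 = [K, B), S/G2/M = [B, K']. Both phases
are linearly resampled onto equidistant points — 80 per cycle in total,
allocated in proportion to the population-mean phase durations (40/60 min
means give a 32/48 split) — and averaged on a relative-time axis with
95% confidence bands (1.96·SEM).

**Synthesis rate.** The tagged protein is produced into an immature pool
P<sub>i</sub> at rate K<sub>p</sub>(t) and matures at constant rate
K<sub>m</sub> = ln2 / t<sub>½</sub> (0.116 min⁻¹ for sfGFP's 6-min
half-time):

    dPi/dt = Kp(t) − Km·Pi,     dPm/dt = Km·Pi
    ⇒  Kp(t) = Pm''(t)/Km + Pm'(t)

Derivatives of the measured abundance P<sub>m</sub> = mean GFP × total
volume come from a GCV-selected cubic smoothing spline, refit once for the
second derivative.

**Group comparison.** Each cell trace is modeled as x(t) = B′(t)α + d(t),
with B a Gaussian-kernel basis (J = 10) and d a zero-mean GP with
non-stationary Matérn-5/2 covariance whose σ(t) and ℓ(t) are log-linear in
a coarser basis (L = 5), plus i.i.d. noise τ². Hyperparameters are
estimated by MAP under N(0, 10²)/Γ priors; the posterior of the population
mean m(s) on a sparse J-point grid is Gaussian by conjugacy, and the two
groups are compared through

    T = (μx − μy)′ (Σx + Σy)⁺ (μx − μy)  ~  χ²(ν),

with ν the number of positive eigenvalues, tail probability ε, and a
whitened effect profile E (T = ΣE²) that localizes the difference in time.

## Worked example

```python
import numpy as np
from cyclesig import synthdata as sd, cyclealign as ca, gptools as gp

# two populations of 60 cells on a 40-point grid; the second has its mean
# shifted by 2 pooled sd over the last quarter of the window
times = np.linspace(0, 117, 40)
spec = dict(time_grid=times, alpha=np.array([5,6,5,4,5,6,5,4,5,6], float),
            beta=np.full(5, .2), gamma=np.full(5, 1.5), tau=.3, n_cells=60)
X = ca.traces_to_matrix(sd.simulate_population(sd.PopulationSpec(seed=0, **spec)))
Y = ca.traces_to_matrix(sd.simulate_population(sd.PopulationSpec(seed=1, **spec)))
sig, _ = gp.eval_sigma_ell(gp.GPHyperparams(np.full(5,.2), np.full(5,1.5), .3),
                           gp.gaussian_basis(times, 5), times)
Y[:, -10:] += 2 * np.sqrt(sig[-10:]**2 + .3**2)

res, post_x, post_y = gp.compare_trace_groups(X, Y, times, seed=0)
print(f"T={res.T:.1f}  nu={res.nu}  epsilon={res.epsilon:.3g}")
```

prints

```
T=580.1  nu=10  epsilon=3.17e-118
```

i.e. the difference statistic T = 580.1 on ν = 10 degrees of freedom: the
1−ε credible region of the mean difference excludes zero except at an
astronomically small tail level, so the two populations clearly differ;
`res.effect` shows the deviation is concentrated in the late grid points.
Running the same comparison with the shift removed gives T = 9.0 and
ε = 0.54 — no evidence of a difference.

The same analysis is available from the shell:

```bash
cyclesig simulate --out runs/sim
cyclesig align --out runs/aln \
    --traces runs/sim/traces_<hash>.csv --events runs/sim/events_<hash>.csv
cyclesig compare --out runs/cmp --group-x g1.csv --group-y g2.csv
```

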