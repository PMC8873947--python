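# dblsim

A reduced conductance-based simulator of mouse hippocampal CA1 pyramidal
neurons built around one question: what keeps these cells firing
full-amplitude action potentials while their interspike membrane potential —
the *depolarization baseline* (DBL), the mean of the minimum voltage between
successive spikes — climbs tens of millivolts during a strong sustained
input?  A conventional Hodgkin–Huxley model cannot do this: once the baseline
rises above the Na⁺ inactivation range, the channel pool cannot recover
between spikes and the model falls into depolarization block.

`dblsim` implements an activity-dependent mechanism in which the recent
somatic depolarization, tracked by an exponential moving average

    EMA[n] = a·x[n] + (1 − a)·EMA[n−1],   x = v − v_rest,   a = F/(cnt + 1),

with `F = 2` and `cnt` capped at `t_step = 1000` integration steps, drives a
saturating Hill function per ion species i ∈ {Na, K, Ca},

    f_vrun,i = B_i·C_i·EMA / (C_i + EMA),

which dynamically offsets the Na⁺ and K⁺ reversal potentials
(E_Na ↓ by α_ENa·f_vrun,Na, E_K ↑ by α_EK·f_vrun,K — both gradients shrink, as
expected when ions accumulate on the side they flow toward) and translates
every channel's activation/inactivation curves along the voltage axis by
sh_i = α_i·f_vrun,i.  Two published per-cell coefficient sets
(`CELL_203030003_R`, `CELL_170518_4E`) are built in.  Setting every `B_i = 0`
switches the mechanism off identically.

The package is for computational neuroscientists who want to reproduce,
probe, or reuse this mechanism without a full morphological simulation: the
cell is reduced to three compartments (soma, proximal and distal dendrite)
with a compact surrogate channel set, a Crank–Nicolson/exponential-Euler
integrator (numba-compiled), current-step and in-vivo-like synaptic
protocols, spike/DBL/threshold/block feature extraction, spectral analysis,
and Nernst-based inversion of predicted reversal shifts into local ion
concentration changes.

## Worked example

```python
import dblsim as ds
from dblsim.analysis import extract_features

cell = ds.default_cell()
res = ds.run(cell, t_total=550.0, inj={"soma": 0.3}, t_on=50.0, t_off=450.0,
             mechanism=ds.CELL_203030003_R)
f = extract_features(res.soma_trace())
print(f"spikes: {f.n_spikes}")
print(f"DBL: {f.dbl:.1f} mV")
print(f"max K+ reversal shift: +{res.shifts['dE_K'].max():.1f} mV")
```

prints

```
spikes: 12
DBL: -61.0 mV
max K+ reversal shift: +43.6 mV
```

i.e. during a 0.3 nA, 400 ms somatic step the fitted model fires a regular
12-spike train whose interspike baseline sits at −61 mV — some 9 mV above the
resting potential — while E_K is transiently driven up by ~44 mV.  The same
run with the mechanism disabled (`mechanism=None`) fires 4 slow spikes with a
deep −90.6 mV baseline, and at 0.4 nA the reduced conventional reference cell
(`ds.conventional_cell()`) enters depolarization block outright.  Inverting
the +44 mV K⁺ reversal shift with `dblsim.nernst.invert_shift` translates it
into a roughly ten-fold rise of the local external K⁺ concentration.

A command-line interface mirrors the library:

```
dblsim sweep --cell default --dbl 203030003_R --protocol lab1 --out runs/sweep
dblsim nernst --ion K --cin 135 --cout 2.5 --temp 308.15
dblsim features my_recording.csv --stim 50 450
```

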