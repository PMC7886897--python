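# stellate

Conductance-based models of cerebellar stellate cells and the
molecular-layer microcircuit they control.

Stellate cells (SCs) are the inhibitory interneurons of the outer
cerebellar molecular layer. They fire spontaneously (~24 Hz), respond
to hyperpolarization with an HCN-mediated sag and T-type-driven rebound
bursts, and receive strongly facilitating parallel-fiber (PF) synapses
(release probability 0.15), which makes them respond to PF *bursts*
with a delay and only at high input frequency — a delay-high-pass
filter. Wired in feed-forward inhibition onto Purkinje cells (PCs),
whose own PF synapses saturate an order of magnitude lower in
frequency, they convert the PF→PC pathway into a low-pass (or, with
SC→SC inhibition, band-pass) filter. This package implements that whole
chain as reproducible simulations:

* **morphology** — SWC I/O, a statistical SC-morphology generator
  matched to published morphometrics, and the five-class electrotonic
  reduction (soma / proximal / distal dendrite / AIS / axon, split at
  the 0.6-µm dendritic diameter cut-off);
* **channels** — fourteen voltage- and calcium-gated mechanisms
  (Nav1.1/1.6, Kv3.4, Kv4.3, Kv1.1, Kir2.3, Kv7, BK, SK, Cav2.1,
  Cav3.2/3.3, HCN1, leak) in a uniform Hodgkin–Huxley parameterization
  with Q10 = 3 temperature scaling and per-compartment calcium pools;
* **solver** — implicit fixed-step (0.025 ms) cable integration on the
  compartment tree (Crank–Nicolson/backward Euler, Hines elimination,
  numba-compiled), with current steps, ideal voltage clamp and
  event-driven synapses;
* **synapses** — Tsodyks–Markram short-term plasticity
  (``u ← u·e^{−Δt/τ_F}; u ← u + p(1−u); release = u·R; R ← R − release``)
  driving AMPA / NMDA / GABA_A conductances with the recorded parameter
  sets;
* **optimize** — IBEA multi-objective evolution of the 36 maximum
  conductance densities against SEM-normalized experimental feature
  targets;
* **features / protocols** — spike threshold (second-derivative), half
  width, AHP, f–I curves, sag/rebound, PSTHs, burst/pause statistics,
  and the standard stimulation batteries;
* **circuit** — the PF→SC→PC microcircuit (100 PF→PC, 3 PF→SC,
  25–300 SC→PC, optional 32 SC→SC synapses) with a reduced,
  explicitly-documented PC stand-in.

See `docs/methods.md` for model assumptions and calibration decisions.

## Worked example

```python
from stellate.models import build_sc_cell, run_step, run_train
from stellate.features import train_stats, sag_rebound, burst_rate_change
from stellate.protocols import TrainProtocol

cell = build_sc_cell()                      # reference optimized SC

ts = run_step(cell, 0.0, duration_ms=2000)  # spontaneous activity
print(train_stats(ts.spikes["soma"], (1000, 3000)).frequency_hz)

ts = run_step(cell, -16.0, duration_ms=2000)
sr = sag_rebound(ts.t, ts.v["soma"], (1000, 3000), ts.spikes["soma"])
print(sr.sag_mV, sr.first_spike_delay_ms)

train = TrainProtocol(10, 100.0, n_synapses=3, onset_ms=2000)
ts = run_train(cell, train, duration_ms=3000)
print(burst_rate_change(ts.spikes["soma"], 2000.0, train.span_ms + 10))
```

This prints the spontaneous rate (`25.0` Hz — the experimental
pacemaking rate is 24.2 ± 2.1 Hz), the sag amplitude and rebound
first-spike delay for the −16 pA step (`10.5` mV and `16.5` ms against
10.3 ± 2.0 mV and 17.2 ± 2.3 ms), and the (baseline, burst, % increase)
triple for a 10-pulse 100-Hz PF burst through 3 synapses
(`(25.0, 80.0, 220.0)` — the model's burst responsiveness runs above
the recorded 154.5 ± 40.5 %; see `docs/methods.md` for why the reduced
model's per-synapse efficacy is high).

The command line mirrors the library:

```bash
stellate morph --seed 1 --out cell.swc        # generate a morphology
stellate simulate -c config.yaml              # run configured protocols
stellate gain --target sc                     # EPSC gain curve + half-frequency
stellate circuit --sc-synapses 100            # PC filtering report
stellate optimize --preset desk --out fits/   # conductance optimization
stellate example-config                       # annotated config template
```

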