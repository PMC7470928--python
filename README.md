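# vtanic

Conductance-based simulator of the ventral tegmental area (VTA)
dopamine–GABA microcircuit under cholinergic and nicotinic modulation.

## The problem

Dopamine (DA) neurons of the VTA fire in two modes — regular low-frequency
pacemaking and bursting — and the burst mode carries reward and salience
signals. Knocking out beta2-containing nicotinic acetylcholine receptors
(beta2-nAChRs) abolishes DA-neuron bursting even though the glutamatergic
afferents that drive bursts stay intact; re-expressing the receptors only on
DA neurons does not restore bursting, while re-expressing them on
neighboring GABA interneurons does. Nicotine, acting on the very same
receptors, produces the *opposite* modulation to endogenous ACh in several
of these conditions. `vtanic` implements a biophysical circuit model that
reproduces this effect matrix mechanistically: a DA pacemaker neuron
receiving balanced NMDA excitation and GABA-population inhibition, with
four-state nAChR pools (activation x desensitization) driven either by
pulsatile ACh release or by a slow nicotine concentration profile.

The package is for computational neuroscientists who want to run, perturb,
or extend the circuit: every biological parameter is an explicit, documented
config field, all randomness is seeded, and each run is bit-reproducible.

## The model in brief

* **DA neuron** — single compartment, membrane equation
  `C dV/dt = I_Ca + I_KCa + I_K + I_DR + I_Na + I_sNa + I_leak + I_h + I_NMDA + I_AMPA + I_GABA + I_ACh`,
  with spike-gated Ca entry and an SK feedback loop that paces the cell at
  1–5 Hz; NMDA input carries the Mg-block nonlinearity
  `B(V) = 1/(1 + [Mg]/3.57 e^{-0.062V})` that makes bursting
  voltage-dependent.
* **GABA population** — N tonically active fast-spiking interneurons
  (Wang–Buzsaki kinetics, heterogeneous leak), all projecting to the DA
  neuron through a fast pooled gate.
* **nAChR pools** — mean-field activated fraction `a` and desensitized
  fraction `d`; conductance `g = g_max a (1-d)`;
  `a_inf = 1/(1 + (EC50/(c_ACh + w c_nic))^{1.05})`,
  `d_inf = 1/(1 + (IC50/c_nic))^{0.5}`, activation tau 5 ms, desensitization
  tau 500 ms–600 s depending on nicotine.
* **Conditions** — the knockout/re-expression matrix is encoded purely in
  the two maximal conductances (mS/cm², DA pool / GABA pool): KO (0, 0),
  re-expression on DA (5, 0), on GABA (0, 4), on both and wild-type
  (10, 1.5).
* **Metrics** — bursts are detected with the classic interval criterion
  (onset at ISI < 80 ms, termination at ISI > 160 ms); reported statistics
  are firing rate, %SWB (percent spikes within bursts), mean burst length,
  ISI CV, and a surrogate-normalized GABA-population synchrony index.

See `docs/methods.md` for the full model description, parameter tables and
numerical scheme.

## Worked example

Simulate 100 s of the GABA-re-expression condition under endogenous ACh and
compare it with the knockout:

```python
from vtanic import CircuitConfig, run_simulation

for cond in ("KO", "REEXP_GABA"):
    res = run_simulation(CircuitConfig(condition=cond, master_seed=1,
                                       duration=100_000.0))
    m = res.da_metrics()
    print(f"{cond:12s} rate={m.rate:.2f} Hz  %SWB={m.pct_swb:.1f}  "
          f"ISI CV={m.isi_cv:.2f}")
```

```
KO           rate=5.17 Hz  %SWB=0.6  ISI CV=0.43
REEXP_GABA   rate=5.73 Hz  %SWB=21.3  ISI CV=0.46
```

Restoring nicotinic receptors on the GABA interneurons alone raises both the
DA firing rate and, most prominently, its bursting: the common cholinergic
pulses synchronize the GABA population, and the pulsatile inhibition
transiently relieves the DA neuron's SK current so it escapes with
short-ISI doublets — the circuit's disinhibition-burst mechanism.

The same experiments are available from the shell:

```sh
vtanic experiment run --preset fig5 --seeds 10 --out results/fig5
vtanic experiment run --preset fig6 --seeds 10 --out results/fig6
vtanic experiment report --in results/fig5
```

`fig5` tabulates the four re-expression conditions under ACh (rate, %SWB,
burst length as mean ± SEM across seeds); `fig6` runs the
baseline-then-nicotine protocol for all five conditions and tabulates
pre/post differences. Single runs (`vtanic simulate --config run.yaml --out
DIR`) write `da_spikes.csv`, `gaba_spikes.csv`, `metrics.json`,
`concentrations.csv` and a config echo sufficient for exact replay.

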