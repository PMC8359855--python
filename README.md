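# paleocarb

Carbon cycle inverse modeling of the history of fractional organic carbon
burial over Earth history.

## The problem

The burial of organic carbon is the long-term source of atmospheric oxygen,
and its magnitude relative to total (organic + carbonate) carbon burial —
the fractional organic burial, f_org — is conventionally read off the
sedimentary carbon isotope record through the mass balance

    f_org = (δ¹³C_carb_buried − δ¹³C_inputs) / (δ¹³C_carb_buried − δ¹³C_org_buried)

with the input value δ¹³C_inputs pinned at the modern mantle composition of
−5.5‰.  Because the record shows no large secular trend, this reading
implies a nearly constant oxygen source flux through time, which forces
explanations of the Great Oxidation Event (~2.4 Ga) to rely on declining
oxygen sinks.  But δ¹³C_inputs is not a constant of nature: it is the
flux-weighted mean of mantle outgassing, metamorphic/arc recycling, and the
weathering of crustal carbonates and organics.  O₂-dependent oxidative
weathering of ¹³C-depleted organic matter, and the preferential subduction
of organics into the mantle, can both move it — decoupling the isotope
record from the true organic burial history.

`paleocarb` quantifies how much decoupling is allowed.  It implements a
self-consistent five-reservoir model of mantle–crust–ocean carbon cycling
(atmosphere–ocean carbon and alkalinity, crustal organic and carbonate
carbon, mantle carbon) with full ¹³C bookkeeping, integrated from 4.1 Ga to
the present, and inverts it with an affine-invariant ensemble MCMC against
the binned isotope record plus geologic proxy constraints (Archean mantle
outgassing from Xe isotopes, modern reservoir inventories, modern climate
and ocean state, mantle δ¹³C, and an Archean anoxia condition expressed
through the oxygenation parameter K_oxy).  The target of inference is the
f_org history — epoch values j1, j1·j2, j1·j2·j3 for the Archean,
Proterozoic and Phanerozoic, or a linear trend — and the headline derived
quantity is the fold change in f_org over Earth history (j2·j3).

It is written for researchers in geobiology / Earth-system science who want
a tested, reusable, fully synthetic-data-capable version of this style of
analysis: every input the pipeline needs can be generated by the package
itself.

## Worked example

Invert a stylized isotope record (flat carbonates near 0‰, organics offset
by 28‰ — the gross structure of the real archive) under the nominal model:

```python
import paleocarb as pc

record = pc.stylized_record(seed=7)
chain = pc.run_inference(record, pc.Scenario(name="nominal"),
                         n_walkers=48, n_steps=250, burn_in=100,
                         seed=11, init="ball")
summary = pc.summarize(chain, n_envelope=100)
fc = summary.fold_change_summary()
print(f"fold change in f_org: {fc['q50']:.2f} "
      f"(1σ {fc['q16']:.2f}–{fc['q84']:.2f})")
print(f"modern f_org: {summary.derived['modern_forg']['q50']:.2f}")
print(f"fraction of draws with anoxic Archean (K_oxy < 1): "
      f"{summary.frac_archean_koxy_lt1:.2f}")
```

which prints

```
fold change in f_org: 2.62 (1σ 1.75–3.91)
modern f_org: 0.28
fraction of draws with anoxic Archean (K_oxy < 1): 0.70
```

Read: even though the synthetic record is flat, the posterior admits a
~2.5-fold increase in fractional organic burial since the Archean, because
the O₂ dependence of organic weathering and evolving subduction
efficiencies let δ¹³C_inputs drift; the modern fractional organic burial
comes out near 0.3; and about two-thirds of posterior draws satisfy the
Archean anoxia condition.  Switching those two mechanisms off
(`Scenario` flags `oxidative_weathering=False`,
`subduction_evolution=False`) collapses the inferred fold change toward
the conventional near-constant reading.

The same pipeline is scriptable from the shell:

```bash
paleocarb synth --seed 7 --out record.csv
paleocarb fit --record record.csv --scenario-name nominal \
          --walkers 48 --steps 250 --burn 100 --seed 11 --out fit/
paleocarb scenarios --record record.csv --out suite/
```

`fit` writes the chain, a posterior summary JSON, credible-envelope CSVs
and figures, and a reproducibility manifest.

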