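# chondrosim

Kinetic modelling of cytokine-induced cartilage breakdown.

In rheumatoid arthritis and osteoarthritis, chondrocytes stimulated with
interleukin-1 (IL-1) and oncostatin M (OSM) up-regulate matrix
metalloproteinases (MMP-1, MMP-3, MMP-13) and the aggrecanase ADAMTS-4,
which together destroy the cartilage matrix: ADAMTS-4 strips aggrecan from
the aggrecan–collagen complex, exposing collagen to irreversible cleavage
by the collagenases.  `chondrosim` implements an integrated mass-action
model of this system for researchers studying joint degradation and virtual
therapeutic intervention screening.

## The model

Three coupled submodels, every reaction pure mass action
(rate = *k* · Π reactant amounts · Π modifier amounts, molecule counts,
unit-volume compartments):

* **IL-1 arm** — IL-1·IL-1R → IRAK-2 → TRAF6 → JNK & p38; pJNK
  phosphorylates c-Jun (*k*<sub>phoscJun</sub> = 1×10⁻⁴ molecules⁻¹s⁻¹);
  phospho-c-Jun homodimers weakly transcribe eight target genes.  Negative
  feedback through induced MKP-1 (pJNK/p-p38 dephosphorylation) and PP-4
  (TRAF6 sequestration).
* **OSM arm** — OSM·OSMR → JAK-1 → STAT-3
  (*k*<sub>phosSTAT3</sub> = 5×10⁻³); nuclear pSTAT-3 transcribes c-Fos,
  PTPRT, SOCS-3 (and TIMP-1); p-p38 phosphorylates c-Fos
  (*k*<sub>phoscFos</sub> = 5×10⁻⁷); pc-Fos + pc-Jun ⇌ AP-1, the strong
  transcription factor for twelve target genes, with Sp-1 repressing the
  TIMP-1 promoter and SOCS-3 silencing the receptor.
* **ECM arm** — proMMP activation by a generic MMP activator and by active
  MMP-3; 30-hour half-life of active MMP pools; ADAMTS-4 cleavage of the
  aggrecan–collagen complex; collagenolysis by MMP-1/MMP-13 (MMP-13 the
  more active, MMP-1 ten-fold more transcribed); TIMP-1/TIMP-3 inhibition
  with the classical selectivity (TIMP-1 → MMPs, TIMP-3 → ADAMTS-4).

Two engines share the model: a stiff ODE integrator (LSODA, rtol 1e-8) and
an exact Gillespie direct-method simulator (numba-compiled, seed-exact).
The endpoint readout is percent release,
100 · fragments / initial matrix pool, for aggrecan and collagen.

## Worked example

```python
from chondrosim import (build_integrated_model, make_treatment, simulate_ode,
                        percent_release, peak_metrics, apply_kinase_inhibition)
from chondrosim.ode import GRID_14D

model = build_integrated_model()

# 48-hour cytokine response
tc = simulate_ode(model, make_treatment(model, il1=True, osm=True, activator=False))
t_peak, peak, fold, _ = peak_metrics(tc, "mRNA_MMP1")
print(f"MMP-1 mRNA peak: {peak:.0f} molecules at {t_peak:.2f} h")

# 14 days with the MMP-activator bolus
sc = make_treatment(model, True, True, True, horizon_h=336.0)
tc14 = simulate_ode(model, sc, horizon_h=336.0, grid_h=GRID_14D)
print(f"day-14 collagen released: {percent_release(tc14, 'CollFrag', 10000)[-1]:.2f} %")
print(f"day-14 aggrecan released: {percent_release(tc14, 'AggFrag', 10000)[-1]:.2f} %")

# virtual 50% JNK inhibition
jnk = apply_kinase_inhibition(model, "JNK", 0.5)
tc_jnk = simulate_ode(jnk, sc, horizon_h=336.0, grid_h=GRID_14D)
print(f"day-14 collagen with 50% JNK inhibition: "
      f"{percent_release(tc_jnk, 'CollFrag', 10000)[-1]:.2f} %")
```

prints

```
MMP-1 mRNA peak: 14782 molecules at 8.00 h
day-14 collagen released: 9.78 %
day-14 aggrecan released: 88.72 %
day-14 collagen with 50% JNK inhibition: 7.47 %
```

The combined cytokines drive a synergistic MMP-1 transcription pulse
peaking around 8 hours (IL-1 alone peaks around 12 hours at roughly
one-twentieth the level); with an activating protease present about 10% of
the collagen pool is cleaved by day 14 while ADAMTS-4 releases ~87–89% of
the aggrecan, and inhibiting JNK halfway reduces collagen loss by roughly a
quarter.

A command-line interface wraps the same functions:

```bash
chondrosim simulate --scenario il1_osm_activator --engine ode --horizon 336 --out run/
chondrosim scan --preset fig6b_timp3 --out scans/ --plot
chondrosim calibrate --seed 1 --out fit.yaml
chondrosim export-sbml --out model.sbml.xml
chondrosim make-synthetic --seed 0 --out data/
```

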