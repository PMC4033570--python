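# Methods

## Model scope and structure

`chondrosim` models a single chondrocyte-and-matrix compartment responding
to a one-time addition of IL-1 (interleukin-1), OSM (oncostatin M) and,
optionally, an MMP-activating protease.  The network is assembled from
three fragments (IL-1/JNK signalling, OSM/JAK-1/STAT-3 signalling, and
proMMP activation with matrix degradation) that share interface species
(TRAF6, phospho-p38, phospho-c-Jun, the induced phosphatases, the
MMP/TIMP/ADAMTS transcripts and proteins, AP-1).  The composed model has 71
species and 139 reactions.  Everything is elementary mass action — no
Hill functions, no delays, no spatial structure.  Amounts are molecule
counts in unit-volume compartments (cytoplasm, nucleus, matrix); time is
seconds internally and hours at the reporting layer.

Counts are deliberately small — basal expression in the 0–200 range,
cytokine-induced levels in the ~500–30,000 range — so that exact
stochastic simulation of the full system stays cheap enough for ensembles.

## Key mechanisms

**Transcriptional logic.**  Phospho-c-Jun homodimers are a weak
transcription factor for eight genes (c-Jun, MMP-1, MMP-3, MMP-13,
ADAMTS-4, PP-4, DUSP-16, MKP-1).  AP-1 (phospho-c-Fos bound to
phospho-c-Jun) is the strong factor for twelve genes (those eight plus
c-Fos, Sp-1, TIMP-1, TIMP-3).  c-Jun, TIMP-1 and TIMP-3 also have basal,
factor-independent transcription.  c-Fos is regulated transcriptionally
(induced by nuclear pSTAT-3, very short mRNA half-life ~20 min), c-Jun
post-translationally (phosphorylation by pJNK).  Because c-Fos is absent
without OSM, IL-1 alone yields only the weak homodimer response — the
origin of the IL-1/OSM synergy.  MMP-1 transcription is fixed at ten times
MMP-13's in both factor contexts with one shared mRNA decay constant, so
the MMP-1:MMP-13 mRNA ratio is exactly 10 throughout any cytokine
time course.

**TIMP-1 regulation.**  Nuclear pSTAT-3 drives TIMP-1 transcription in
addition to its stated targets (c-Fos, PTPRT, SOCS-3).  This link is
required for the early (2–4 h) TIMP-1 transient under OSM alone, which is
unreachable from AP-1 (absent without IL-1); it simultaneously explains why
TIMP-1 induction is *lower* under IL-1+OSM: AP-1 then induces Sp-1, which
occludes the TIMP-1 promoter (modelled as reversible binding of Sp-1 to a
two-copy promoter species that gates all TIMP-1 transcription).

**Signal termination.**  The IL-1 arm adapts partially: induced MKP-1
dephosphorylates pJNK/p-p38 and induced PP-4 sequesters TRAF6, so the
homodimer signal decays from its ~5 h peak to a sustained low plateau
(which carries the slow 14-day "tail" of transcription).  The OSM arm
shuts off completely: SOCS-3 (long-lived) outcompetes OSM for the
receptor and the SOCS-3-bound receptor is internalized and degraded —
the canonical SOCS mechanism — so STAT-3 signalling is a single pulse.

**STAT-3 pulse design.**  STAT-3 activation is built as a saturated,
single-pass bolus: JAK-1 phosphorylation of STAT-3 is very fast relative
to nuclear import (the bottleneck, ~1.4 h), nuclear dephosphorylation is
moderate, nuclear export is slow (~14 h), and the free cytoplasmic pool
turns over slowly.  Consequences that match the intended intervention
phenotypes: partial JAK-1 inhibition (even 98%) barely changes the
nuclear STAT-3 exposure, because the whole pool still transits once;
complete inhibition abolishes it; and an OSMR antagonist must reach an
enormous (~10⁷) excess before the trickle of receptor signalling fails to
deliver the pool within the 14-day window.

**Matrix economy.**  Aggrecan is bound to collagen as a complex
(10,000 units; chosen so percent-release readouts resolve 0.01%).
ADAMTS-4 cleaves the complex into exposed collagen plus aggrecan
fragments; only exposed collagen can be cut by MMP-1/MMP-13 (MMP-13 ten
times more active).  This "aggrecan protects collagen" coupling is what
makes TIMP-3 (which neutralizes ADAMTS-4 and delays exposure) more
protective than TIMP-1 (which inhibits the collagenases directly) at
equal overexpression.  TIMP inhibition is reversible 1:1 binding with
selectivity in the on-rates; the TIMP-1–MMP complex has a moderate
effective affinity (Kd ~100 molecules) — the free-fraction equilibrium
this produces makes the low-activator collagen readout a smooth function
of the basal activator level rather than a stoichiometric-titration knife
edge.  Active MMP pools (free and TIMP-bound) are removed with a 30-hour
half-life.  ProMMP-1 and proMMP-3 are activated by the generic activator;
active MMP-3 additionally activates proMMP-1 and proMMP-13.  The
activator itself is synthesized at a very low AP-1-driven rate (so that
IL-1+OSM without an exogenous bolus releases only ~0.03% of collagen by
day 14) and is added as a 10,000-molecule bolus in "activator" scenarios.

## Parameters

The three literature rate constants are fixed: *k*<sub>phoscJun</sub> =
1×10⁻⁴ and *k*<sub>phoscFos</sub> = 5×10⁻⁷ molecules⁻¹s⁻¹, and
*k*<sub>phosSTAT3</sub> = 5×10⁻³ (units taken as molecules⁻¹s⁻¹).  Their
very different magnitudes shape the design: pJNK is kept at a few
molecules (so c-Jun phosphorylation is partially saturated and JNK
inhibition acts gradually), while p-p38 sits at ~200 (so the slow c-Fos
phosphorylation is appreciable and p38 inhibition acts linearly — making
p38 inhibition slightly the more effective intervention, as the
phosphorylation saturation differs).  mRNA half-life is 3 h (c-Fos
~20 min); protein half-lives range from ~5 h (c-Fos) to ~30 h (MMPs,
long-lived phosphatases).  Treatment doses (IL-1 1,000; OSM 2,000;
activator 10,000 molecules) are calibration-level choices standing in for
1 ng/ml IL-1 and 10 ng/ml OSM.  Antagonists bind their receptor with the
cognate ligand's on-rate and no signalling; their off-rates are free
parameters.

Seven rate constants are treated as free in calibration (c-Jun and c-Fos
turnover, the strong MMP-1 transcription rate, nuclear STAT-3
dephosphorylation, the aggrecanolysis and collagenolysis constants, and
basal activator synthesis), each searched in a ×3 box around the shipped
values with two structural ties re-imposed after every proposal (MMP-13
transcription = MMP-1/10; MMP-13 collagenolysis = 10 × MMP-1).  The
objective is a weighted sum of squared relative residuals over seven
behavioural anchors (MMP-1 peak times under IL-1 and IL-1+OSM, ~20-fold
synergy, the OSM-alone TIMP-1 peak window, and the day-14 release
percentages with and without activator), minimized by Nelder–Mead on
log10 parameters from Latin-hypercube multi-starts (default: the shipped
values plus one sampled start, ≤80 evaluations each, short-circuiting
when the objective falls below 5×10⁻³).  Intervention outcomes — the
JAK-1 inhibition profile, the antagonist ladder thresholds, the
TIMP-1/TIMP-3 contrast — are never fitted; they are held-out structural
predictions checked by the test suite.

## Numerical choices

* ODE: LSODA with analytic Jacobian, rtol 1e-8, atol 1e-10.  Output
  grids: 15-minute spacing for 48-h runs, 1-hour for 14-day runs (3-minute
  grids where peak times are measured).  "Day 14" means t = 336 h exactly.
  Amounts below −10⁻⁹ (relative to the largest pool) abort the run;
  smaller negative excursions are clipped to zero for reporting.
* SSA: Gillespie direct method, combinatorial propensities (n(n−1)/2 for
  a homodimerization), exponential waiting times and categorical reaction
  choice by inverse transform from one seeded generator per run (numba's
  NumPy-compatible Mersenne Twister), piecewise-constant recording on the
  deterministic grids.  Ensemble run *i* uses seed base_seed + *i*; runs
  are mutually independent.
* Matrix-pool conservation (aggrecan–collagen complex + exposed collagen
  + fragments) holds exactly in the stoichiometry and is verified along
  trajectories to <10⁻⁶ relative drift (exactly, in integer arithmetic,
  for the SSA).

## What the synthetic-data generator emulates

`generate_timecourse_data` mimics the chondrocyte stimulation study
design: treat at t = 0, harvest at 4, 8, 12, 24, 48 and 72 h, measure
transcript levels with multiplicative log-normal noise (σ = 0.2 by
default) per replicate — the right shape for positive, right-skewed
qPCR-style measurements.  It does not emulate between-donor variability,
batch effects, normalization-gene error, or limits of detection, so
passing recovery tests demonstrates identifiability of the model given
its own noise model, not robustness to real experimental artefacts.

## Known limitations

* The network is reconstructed from prose-level descriptions; three
  substrate assignments are classical-but-assumed (MKP-1 → pJNK/p-p38,
  PTPRT → nuclear pSTAT-3, a constant generic phosphatase → pc-Fos), and
  the STAT-3 single-pass/receptor-degradation kinetics are this package's
  design for the stated intervention phenotypes, not a documented
  mechanism inventory.
* The OSMR-antagonist dose–response shows a +0.4% relative bump in
  day-14 collagen at intermediate ratios (a slightly delayed cytokine
  pulse overlaps marginally better with the growing exposed-collagen
  pool); monotonicity therefore holds to a 0.5% band, not strictly.
* TIMP-1 overexpression at the highest dose reduces day-14 collagen more
  strongly (~3.5% vs ~10%) than a pure delay; the delay-dominated
  behaviour holds at the lower doses of the ladder.
* Single-bolus dosing only; no pharmacokinetics, no repeated-media-change
  schedules, no additional cytokines, no microRNA layer.
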