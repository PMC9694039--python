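# Methods

## Scope

`hemosim` simulates the two global hemostasis assays used to phenotype
plasma coagulation — the thrombin generation assay (TGA) and spatial
clot growth from an immobilized tissue-factor surface — on top of a
detailed plasma-coagulation reaction network, and couples them to a
personalized pharmacokinetic (PK) model of subcutaneous low-molecular-
weight heparin (LMWH) and an APTT/PT-based estimator of individual
factor levels. The intended use is in-silico prediction of a patient's
global-assay readouts from routine labs and the dosing schedule.

## The coagulation network

The chemistry is a fresh reconstruction, not a transcription of any
single published constant table: the extrinsic/common-pathway core
follows the standard empirical kinetics of the TF-initiated cascade
(the Hockin–Mann lineage of constants), and the remaining structure —
three competing lipid surfaces, contact pathway, fibrin formation,
fluorogenic reporter, α2-macroglobulin, heparin action — was assembled
from standard literature mechanisms. Free constants were then
calibrated, once, against the verification outputs that the model
family is known to reproduce (normal-plasma TGA and clot-growth
parameters, and a panel of single-factor-deficient plasmas). The
packaged `plasma.yaml` is the complete, diffable definition: 59 volume
species, 19 activator-surface species (78 states well-mixed), ~150
reactions, three lipid pools.

Key structural choices, each forced by the deficiency panel the model
must reproduce:

* **Cofactor activation is Xa-driven.** Factors V and VIII are
  activated by factor Xa (an established reaction, here carrying the
  whole load with lumped effective constants), not by thrombin. In a
  thrombin-feedback model, reducing prothrombin to 2% would slow every
  readout; in the reference behavior the timing of both assays is
  unchanged and only the thrombin amplitude scales with prothrombin.
  Thrombin in this network is a pure readout species: it cleaves
  fibrinogen and the reporter substrate and is consumed by inhibitors,
  but feeds nothing back upstream.
* **Propagation is carried by an Xa–VIIIa–tenase wave.** Intrinsic
  tenase (IXa:VIIIa) assembled on lipid converts X; the produced Xa
  activates fresh VIII ahead of the front. Factor IXa is supplied from
  the activator surface (extrinsic tenase) near the wall and, in the
  far field, by slow contact activation of factor XII with direct
  XIIa-mediated IX activation. Thrombin-mediated XI feedback is set to
  zero: clot-front velocity is then insensitive to factor XI (as
  observed) while remaining steeply dependent on VIII, IX and X.
* **Lipid-surface competition.** Each membrane-bound species occupies
  a fixed phospholipid footprint (60 head groups); binding rates scale
  with the remaining free-site density of its pool. Three pools exist:
  endogenous VLDL-equivalent surface (200 µM at normal lipids,
  personalized via LDL), artificial vesicles (assay reagent, 2–4 µM),
  and the TF-reagent lipid (5000 phospholipids per TF molecule).
  Extrinsic tenase exists only on the TF pool.
* **Membrane-bound enzymes are attacked by antithrombin at reduced
  rates.** Without this, the activator surface becomes an inexhaustible
  thrombin source and an unphysical antithrombin-depletion burning
  front propagates regardless of factor levels.
* **The reporter.** The fluorogenic substrate is cleaved by thrombin
  and, with 0.6-fold efficiency, by the thrombin–α2M complex; the TGA
  thrombin signal is therefore `IIa + 0.6·IIa:α2M`. The spatial wave
  amplitude A is read on free thrombin: the α2M complex is formed
  irreversibly and accumulates behind the front, so it carries no
  propagating peak (in the source data, too, free thrombin and the α2M
  complex are plotted as separate profiles).

Constants that had to move away from their textbook values to
reproduce the verification set (notably the effective Xa-mediated
cofactor activation rates, the fibrinogen turnover number, the TFPI
quaternary-complex capture rate, and the contact-pathway rates) are
calibration results and are flagged as such in the YAML comments. They
should be read as effective constants of this network, not as
measurements.

## Assay engines

*Well-mixed (TGA).* All 78 species are bulk concentrations; plasma
species are diluted 2:1 with the reagent mix, which contributes 5 pM
TF (with its vesicle lipid), 2 µM artificial phospholipid and 400 µM
substrate at final concentrations. Integration uses BDF with relative
tolerance 5·10⁻³ and a scaled absolute tolerance (factor 0.05 of each
species' initial scale, floored so that trace species remain
resolved).

*Spatial.* Method-of-lines on an equidistant 1-D grid (4 mm domain,
activator at x = 0, zero-flux far end). Surface species evolve as
densities (nmol/m²) at x = 0 only; boundary reactions convert volume
species through the first grid cell. Bimolecular constants are shared
between modes because the capture rate per surface molecule, k·C, is
geometry-independent; compilation enforces that every boundary
reaction carries exactly one surface-unit factor. Integration uses BDF
(rtol 10⁻², scaled atol factor 10⁻⁶) with an exact analytic Jacobian
assembled from the reaction graph (validated against finite
differences); concentrations are clipped to [0, 10 mM] inside the rate
evaluation and Michaelis denominators are guarded, which keeps Newton
iterations stable across the steep clot front. The well-mixed engine
uses the same analytic Jacobian in dense form.

The packaged default grid is 200 nodes (20 µm spacing). On the
normal-plasma run the front metrics at 200 vs 400 nodes are
Tlag 0.7/0.7 min, Vst 29.2/29.0 µm/min (0.8%), A 46.3/46.1 nM (0.5%),
so the default is grid-converged well below the assay's reproducibility;
400 nodes roughly double the runtime.

## Readouts

Clot size CS(t) is the outermost coordinate where fibrin exceeds 50%
of initial fibrinogen (linear interpolation between nodes). Tlag is
the first time CS exceeds half a grid spacing; Vi and Vst are
least-squares slopes over Tlag+2…6 min and Tlag+15…25 min. If the
horizon truncates the Vst window, the slope over the available tail
(≥5 min) is reported with a truncation flag. The wave amplitude A is
the time-median of the interior local-maximum height of free thrombin
(first 100 µm and the pre-lag transient excluded); the median is used
because the pulse height is nearly constant and a median is robust to
the early boundary transient. TGA metrics: Amax and Tmax from the
thrombin observable, T1/2 as the time fibrin reaches half its plateau;
a run converting <10% of fibrinogen reports NC, a thrombin curve that
never exceeds 1 nM reports NP.

## Pharmacokinetics

Three linear states: interstitial amount, free and lipid-bound blood
concentration. Subcutaneous dosing is an impulse into the interstitial
compartment; exchange (Kin, Kout), lipid association/dissociation
(Ka, Kd) and first-order renal elimination of the free form (Kelim)
follow the compartment scheme. Personalization: Vb = 1.4·W·c·(1−HC)
with c = 0.065 (female) / 0.075 (male); Vint = W/80·6 L;
Ka = Chol·0.15·10⁻⁵ s⁻¹; Kelim = (1+33/Creat)·3.85·10⁻⁵ s⁻¹. The
non-personalized constants are fixed at Kin = 1.7·10⁻⁴ s⁻¹,
Kout = 5·10⁻⁶ s⁻¹, Kd = 10⁻⁵ s⁻¹, chosen so a typical patient's blood
half-life falls in the 4.5–5 h band reported for LMWH and the level
peaks 2–3 h post-dose. The system is solved exactly with matrix
exponentials, so dose linearity and superposition hold to machine
precision. Anti-Xa IU/mL converts to molarity via enoxaparin's nominal
100 IU/mg and 4500 Da mean molecular weight (1 IU/mL ≈ 2222 nM),
configurable. Measured anti-Xa activity is mapped to total (free +
bound) blood LMWH by default.

## Personalization

Intrinsic-pathway factors (Fg, VIII, IX, XI) scale as F0·31.43/APTT;
extrinsic/common factors (II, V, VII, X) as F0·12.09/PT, where 31.43 s
and 12.09 s are the normal means of the reference test system.
Measured antithrombin and fibrinogen override inference. The VLDL pool
scales as 200 µM·LDL/3.0 mmol L⁻¹ (reference LDL configurable).
Inferred levels are clipped to 1–400% of normal with a warning,
because a heparin-prolonged APTT would otherwise read as a deep factor
deficiency; whether clotting times should be heparin-corrected before
inference is an open question of the method itself. Normal means
(prothrombin 1400 nM, AT 2400 nM, fibrinogen 8800 nM, etc.) live in
the network file with the rest of the chemistry.

## Synthetic cohort

The generator draws patients uniformly from ranges spanning the
reference group's spread (weight 46–96 kg, hematocrit 19.8–56.3%,
creatinine 32–111 µmol/L, cholesterol 3.12–6.87 mmol/L, LDL 1.32–4.62
mmol/L) plus clotting-time and antithrombin ranges around normal
(APTT 25–45 s, PT 10–16 s, AT 70–120%), one top-level seed, one
substream per patient. It emulates the marginal spreads only — no
covariance between labs, no longitudinal drift, no measurement error —
so passing pipeline tests demonstrate plumbing and determinism, not
clinical realism.

## Numerical and design notes

* Determinism: both engines are deterministic; the only randomness in
  the package is the cohort generator (seeded `numpy` Generator).
* Degenerate inputs: zero TF in both bulk and boundary produces no
  clotting within the 60 min horizon (the contact pathway alone is too
  slow by construction).
* Problem sizes: the well-mixed system is 78 ODEs (sub-second); a
  60-minute spatial run at 200 nodes is ≈11,800 ODEs and takes a few
  minutes on one core. Verification and acceptance runs use these
  sizes.
* Known limitations: no platelet or endothelial biology, no flow, no
  2-D/3-D geometry, no optical-instrument model (metrics are computed
  on concentration observables), no population-PK estimation, and the
  renal model is a single creatinine-dependent rate. The α2M level is
  fixed at its network normal.
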