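# pulserad

Analysis toolkit for pulse-radiolysis studies of HO•-induced oxidation of
thioether model peptides — dipeptide models of methionine
(CH₃C(O)NHCH(CH₂CH₂SCH₃)C(O)NHCH₃, "compound 1") and S-methyl-cysteine
(one CH₂ shorter, "compound 2").  It is written for radiation chemists who
quantify short-lived sulfur radicals from transient absorption spectra and
account for the stable radical-coupling products seen by LC–MS.

## What it computes

**Yields and dosimetry.** Water radiolysis yields e⁻(aq), HO• and H• with
G = 0.28, 0.28 and 0.06 µmol J⁻¹; N₂O saturation converts e⁻(aq) to HO•,
so G(HO•) = 0.56 µmol J⁻¹ (90% HO• / 10% H•).  The scavenging-capacity
dependence follows the Schuler formula

```
G(S•) = g0 + g1·√(a[S]) / (1 + √(a[S]))      g0 = 0.539, g1 = 0.307 µmol J⁻¹, a = 19.6 M⁻¹
```

with thiocyanate dosimetry (ε₄₇₂ = 7580 M⁻¹ cm⁻¹, G = 0.635 µmol J⁻¹)
to convert observed absorbance into absorbed dose.

**Spectral resolution.** Each time slice OD(λ) is transformed to Gε(λ)
using dose and path, then unmixed on a reference-spectrum basis by
non-negative least squares:

```
Gε(λᵢ) = Σⱼ εⱼ(λᵢ)·Gⱼ
```

The regression coefficients Gⱼ are the radiation-chemical yields of the
transients: the hydroxysulfuranyl adduct HOS•, carbon radicals αC(1)•
and αC(2)•, the α-(alkylthio)alkyl radical αS•, and the three-electron
bonded species SS•⁺, SN• and SO•⁺.  Reference spectra are Gaussian bands
anchored at the literature (λmax, ε) pairs, or user-supplied tabulated
curves.

**Kinetics.** The mechanistic schemes (HO• addition vs abstraction, HOS•
decay at k_d = 5.6×10⁵ s⁻¹ to S•⁺, then SS/SN/SO cyclisation and
α-deprotonation; H• desulfurisation releasing CH₃S•) are encoded as
mass-action networks and integrated with a stiff ODE solver, producing
simulated G(t) profiles directly comparable to the resolved ones.

**Product accounting.** All radical–radical coupling dimers of one parent
are isobaric (MH⁺ 407.1781 for compound 1, 379.1468 for compound 2);
CH₃S-adduct intensities act as a footprint of relative radical
concentrations; diastereoisomer counts follow from the fixed (S) parent
stereocentres and the new R/S centres created on coupling.

A synthetic-data generator (`pulserad.synth`) reproduces the whole
forward model — scheme → yields → Beer–Lambert OD with seeded Gaussian
noise — so the entire inverse pipeline is testable end to end.

## Worked example

```
$ pulserad yields schuler --conc 0.0002
0.557
$ pulserad yields n2o
G(HO.) = 0.56 umol/J  (HO. 90% / H. 10%)
```

0.557 µmol J⁻¹ is the total scavengeable radical yield at the working
substrate concentration of 0.2 mM — the expected material balance that
the resolved per-species yields should sum to once all HO• has reacted.

```
$ pulserad products enumerate --compound 2 --adducts
    pair      formula         mh  n_diastereomers  homodimer   kind
 aS2-aS2 C14H26N4O4S2 379.146823                3       True  dimer
 aS2-aS1 C14H26N4O4S2 379.146823                2      False  dimer
 aS2-aC2 C14H26N4O4S2 379.146823                2      False  dimer
 aS1-aS1 C14H26N4O4S2 379.146823                1       True  dimer
 aS1-aC2 C14H26N4O4S2 379.146823                1      False  dimer
 aC2-aC2 C14H26N4O4S2 379.146823                1       True  dimer
aS2-CH3S  C8H16N2O2S2 237.072596                2      False adduct
aS1-CH3S  C8H16N2O2S2 237.072596                1      False adduct
aC2-CH3S  C8H16N2O2S2 237.072596                1      False adduct
```

Every dimer of the S-methyl-cysteine derivative sits at m/z 379.1468 —
they are constitutional isomers of one formula — and the aS2–aS2
homodimer is expected as 3 diastereoisomers (SSSS, SRSS, SRRS: two fixed
S centres plus two new centres, with the half-swap identification).

A full synthetic experiment, resolved back to yields:

```
$ pulserad synth pulse --compound 1 --seed 42 --out data/
$ pulserad resolve --series data/series.csv --meta data/series.json \
    --species HOS,aC1,aC2,aS,SS,SN --out profile.csv
```

`profile.csv` then holds G_j(t) for the six transients; comparing with
`data/true_profile.csv` shows recovery to within ~0.01 µmol J⁻¹ at the
default noise level.

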