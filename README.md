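# metadia

Metabolite annotation and co-elution scoring for **multiplexed
data-independent-acquisition (DIA) LC-HRMS runs**.

Modern q-TOF and q-Orbitrap instruments can merge several full-scan
experiments at stepped collision energies into one injection (e.g. CID 0,
5, 10, 20 eV, or HCD 0/30 %).  The 0-energy scans carry intact-molecule
MS¹ information; the other channels are all-ion-fragmentation (AIF) MS/MS
spectra in which every precursor fragments at once, so fragments must be
re-associated with their precursor computationally.  `metadia` implements
that workflow end to end:

1. **Collision-energy demultiplexing** — an mzML/mzXML run is split into
   per-energy scan channels.
2. **Targeted MS¹ annotation** — extracted ion chromatograms (EICs) for
   every (library metabolite × adduct × isotopologue) within 5 ppm /
   0.005 Da, peak detection, grouping per metabolite.
3. **AIF MS/MS annotation** — each library precursor is anchored on the
   MS¹ channel and its fragments are searched on one collision-energy
   channel; a match needs both the mass tolerance and apex-to-apex
   retention-time agreement (0.08 min default), with a configurable
   minimum-fragment constraint (≥ 1 … all).
4. **Quality scoring** — five statistics per annotation/pair:

   | statistic | definition | rule |
   |---|---|---|
   | asymmetry factor *f* | (t<sub>Rf</sub> − t<sub>Rmax</sub>)/(t<sub>Rmax</sub> − t<sub>Ri</sub>) over the peak span; 0 if < 3 scans or apex on an edge | 1 = symmetric |
   | IPIR | I<sub>k</sub>/I<sub>k+1</sub>, monoisotopic over +1-isotopologue apex intensity | > 1 absent S/Br |
   | PPC | Pearson *r* of two smoothed EIC peaks over shared scans (+ two-sided *p*) | ≥ 0.7 |
   | PPS | *f*₁/*f*₂ shape ratio of a peak pair | 0.3 – 3 inclusive |
   | F/P ion ratio | I<sub>max,F</sub>/I<sub>max,P</sub>, fragment over MS¹ precursor EIC maxima | reported |

   A precursor–fragment association is accepted iff PPC ≥ 0.7 **and** PPS
   ∈ [0.3, 3].

Libraries are plain CSV: a neutral-mass MS¹ library (name, formula or
monoisotopic mass, polarity, optional RT) and an AIF MS/MS library (name,
adduct, precursor m/z, fragment m/z list, optional CE).  A built-in
simulator generates multiplexed runs with known ground truth, so the whole
pipeline is testable without instrument files.

## Worked example

```bash
metadia simulate --out demo.mzML --seed 11 --write-libraries
metadia annotate-ms1 demo.mzML --library demo_ms1_library.csv --out ms1.csv
metadia annotate-aif demo.mzML --library demo_msms_library.csv --out dia.csv
```

The simulated run interleaves four channels (CID 0/5/10/20 eV, four
spectra/s) with three spiked metabolites.  `ms1.csv` contains (abridged):

```
   metabolite adduct  isotopologue  theoretical_mz  observed_mz  ppm_error  rt_apex_min      f  IPIR    PPC    PPS verdict
    glutamine [M+H]+             0      147.076418   147.076133     -1.938       0.1500 1.3333   8.0 0.9988 1.0909  accept
    glutamine [M+H]+             1      148.079773   148.079777      0.029       0.1500 1.2222   8.0 0.9988 1.0909  accept
phenylalanine [M+H]+             0      166.086255   166.086079     -1.059       0.3667 1.0000   8.0 0.9990 1.0000  accept
```

Glutamine [M+H]⁺ is found at its theoretical 147.0764 m/z within 2 ppm
(the simulator jitters centroids by up to 2 ppm); its +1 isotopologue
co-elutes and the isotope ratio IPIR = 8.0 (> 1, as required for a CHNO
formula), the smoothed mono/+1 traces correlate at PPC = 0.999, and the
shape ratio PPS = 1.09 sits well inside the 0.3–3 band, so the annotation
is accepted.  The DIA report (`dia.csv`, CE 10 eV rows) shows both
glutamine fragments (84.0444, 130.0499 m/z) co-eluting with the precursor
within 0.01 min, PPC ≈ 0.98, and a fragment/precursor ion ratio of 0.49 —
the simulator's ground truth is 0.5:

```
   metabolite  fragment_mz  ppm_error  dRT_min    PPC    PPS  FP_ratio verdict
    glutamine    84.044390     -0.421  -0.0083 0.9819 1.1250    0.4893  accept
    glutamine   130.049870     -1.711  -0.0083 0.9819 1.1250    0.4893  accept
```

`metadia plot` draws the EIC QC plot (trace + per-scan m/z deviation) or
the precursor/fragment co-elution overlay; `metadia batch` processes many
runs from one YAML config with per-run failure isolation; `metadia
split-ce` writes one mzML per collision-energy channel.

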