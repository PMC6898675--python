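# CiPA training-compound library: EFTPC and per-channel Hill pore-block
# parameters (IC50 in uM, Hill coefficient dimensionless).
#
# Provenance: values transcribed from the public CiPA channel-panel
# literature (patch-clamp panels of Crumb et al. 2016 / Kramer et al. 2013;
# therapeutic plasma concentrations after Redfern et al. 2003).  Published
# assays disagree by factors of 2-5 for several entries; where sources span
# a range, the value retained is the one consistent with the calibrated
# cell family (see docs/methods.md).  These numbers are approximate
# transcriptions, not a re-measurement.  Channels without measurable block
# at therapeutic concentrations are omitted (no-block default).
drugs:
- name: quinidine
  eftpc_uM: 3.237
  channels:
    hERG: {ic50_uM: 0.72, hill: 1.0}
    Nav1.5-peak: {ic50_uM: 14.6, hill: 1.0}
    Nav1.5-late: {ic50_uM: 25.0, hill: 1.0}
    Cav1.2: {ic50_uM: 14.8, hill: 1.0}
    Kv4.3: {ic50_uM: 3.5, hill: 1.0}
    KCNQ1/KCNE1: {ic50_uM: 62.0, hill: 1.0}
- name: bepridil
  eftpc_uM: 0.032
  channels:
    hERG: {ic50_uM: 0.074, hill: 1.0}
    Cav1.2: {ic50_uM: 2.81, hill: 1.0}
    Nav1.5-late: {ic50_uM: 1.81, hill: 1.0}
    Nav1.5-peak: {ic50_uM: 2.93, hill: 1.0}
- name: dofetilide
  eftpc_uM: 0.002
  channels:
    hERG: {ic50_uM: 0.0047, hill: 1.0}
- name: sotalol
  eftpc_uM: 14.69
  channels:
    hERG: {ic50_uM: 74.0, hill: 1.0}
- name: chlorpromazine
  eftpc_uM: 0.0345
  channels:
    hERG: {ic50_uM: 1.47, hill: 1.0}
    Nav1.5-peak: {ic50_uM: 3.0, hill: 1.0}
    Cav1.2: {ic50_uM: 3.4, hill: 1.0}
- name: cisapride
  eftpc_uM: 0.0026
  channels:
    hERG: {ic50_uM: 0.0065, hill: 1.0}
- name: terfenadine
  eftpc_uM: 0.005
  channels:
    hERG: {ic50_uM: 0.023, hill: 1.0}
    Cav1.2: {ic50_uM: 0.70, hill: 1.0}
    Nav1.5-peak: {ic50_uM: 1.2, hill: 1.0}
- name: ondansetron
  eftpc_uM: 0.1
  channels:
    hERG: {ic50_uM: 1.8, hill: 1.0}
    Nav1.5-peak: {ic50_uM: 57.0, hill: 1.0}
- name: diltiazem
  eftpc_uM: 0.122
  channels:
    Cav1.2: {ic50_uM: 0.76, hill: 1.0}
    hERG: {ic50_uM: 13.2, hill: 1.0}
    Nav1.5-peak: {ic50_uM: 22.4, hill: 1.0}
- name: mexiletine
  eftpc_uM: 2.5
  channels:
    hERG: {ic50_uM: 43.0, hill: 1.0}
    Nav1.5-late: {ic50_uM: 18.0, hill: 1.0}
    Nav1.5-peak: {ic50_uM: 43.0, hill: 1.0}
- name: ranolazine
  eftpc_uM: 3.0
  channels:
    hERG: {ic50_uM: 8.27, hill: 1.0}
    Nav1.5-late: {ic50_uM: 9.0, hill: 1.0}
    Nav1.5-peak: {ic50_uM: 68.0, hill: 1.0}
- name: verapamil
  eftpc_uM: 0.045
  channels:
    hERG: {ic50_uM: 0.25, hill: 1.0}
    Cav1.2: {ic50_uM: 0.20, hill: 1.0}
    Nav1.5-peak: {ic50_uM: 32.5, hill: 1.0}
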