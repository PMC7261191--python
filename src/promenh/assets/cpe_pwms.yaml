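# Core promoter element position weight matrices.
# Frequency matrices derived from published IUPAC consensus sequences;
# bases allowed by the consensus share the column mass evenly, disallowed
# bases keep a floor of 0.02. Weights are log2 odds against the uniform
# background with the pseudocount below; cutoffs are inclusive score
# thresholds, given as a fraction of the maximum achievable score.
# Edit or replace freely: the loader accepts any matrix of per-column
# [A, C, G, T] frequencies and numeric or fractional cutoffs.
background: [0.25, 0.25, 0.25, 0.25]
pseudocount: 0.01
pwms:
- name: BREu
  consensus: SSRCGCC
  expected_position: -38
  cutoff: {fraction: 0.8}
  matrix:
  - [0.020000, 0.480000, 0.480000, 0.020000]
  - [0.020000, 0.480000, 0.480000, 0.020000]
  - [0.480000, 0.020000, 0.480000, 0.020000]
  - [0.020000, 0.940000, 0.020000, 0.020000]
  - [0.020000, 0.020000, 0.940000, 0.020000]
  - [0.020000, 0.940000, 0.020000, 0.020000]
  - [0.020000, 0.940000, 0.020000, 0.020000]
- name: TATA
  consensus: TATAWAAR
  expected_position: -31
  cutoff: {fraction: 0.8}
  matrix:
  - [0.020000, 0.020000, 0.020000, 0.940000]
  - [0.940000, 0.020000, 0.020000, 0.020000]
  - [0.020000, 0.020000, 0.020000, 0.940000]
  - [0.940000, 0.020000, 0.020000, 0.020000]
  - [0.480000, 0.020000, 0.020000, 0.480000]
  - [0.940000, 0.020000, 0.020000, 0.020000]
  - [0.940000, 0.020000, 0.020000, 0.020000]
  - [0.480000, 0.020000, 0.480000, 0.020000]
- name: BREd
  consensus: RTDKKKK
  expected_position: -23
  cutoff: {fraction: 0.8}
  matrix:
  - [0.480000, 0.020000, 0.480000, 0.020000]
  - [0.020000, 0.020000, 0.020000, 0.940000]
  - [0.326667, 0.020000, 0.326667, 0.326667]
  - [0.020000, 0.020000, 0.480000, 0.480000]
  - [0.020000, 0.020000, 0.480000, 0.480000]
  - [0.020000, 0.020000, 0.480000, 0.480000]
  - [0.020000, 0.020000, 0.480000, 0.480000]
- name: XCPE1
  consensus: DSGYGGRASM
  expected_position: -8
  cutoff: {fraction: 0.8}
  matrix:
  - [0.326667, 0.020000, 0.326667, 0.326667]
  - [0.020000, 0.480000, 0.480000, 0.020000]
  - [0.020000, 0.020000, 0.940000, 0.020000]
  - [0.020000, 0.480000, 0.020000, 0.480000]
  - [0.020000, 0.020000, 0.940000, 0.020000]
  - [0.020000, 0.020000, 0.940000, 0.020000]
  - [0.480000, 0.020000, 0.480000, 0.020000]
  - [0.940000, 0.020000, 0.020000, 0.020000]
  - [0.020000, 0.480000, 0.480000, 0.020000]
  - [0.480000, 0.480000, 0.020000, 0.020000]
- name: Inr
  consensus: YYANWYY
  expected_position: -2
  cutoff: {fraction: 0.8}
  matrix:
  - [0.020000, 0.480000, 0.020000, 0.480000]
  - [0.020000, 0.480000, 0.020000, 0.480000]
  - [0.940000, 0.020000, 0.020000, 0.020000]
  - [0.250000, 0.250000, 0.250000, 0.250000]
  - [0.480000, 0.020000, 0.020000, 0.480000]
  - [0.020000, 0.480000, 0.020000, 0.480000]
  - [0.020000, 0.480000, 0.020000, 0.480000]
- name: TCT
  consensus: YYCTTTYY
  expected_position: -2
  cutoff: {fraction: 0.8}
  matrix:
  - [0.020000, 0.480000, 0.020000, 0.480000]
  - [0.020000, 0.480000, 0.020000, 0.480000]
  - [0.020000, 0.940000, 0.020000, 0.020000]
  - [0.020000, 0.020000, 0.020000, 0.940000]
  - [0.020000, 0.020000, 0.020000, 0.940000]
  - [0.020000, 0.020000, 0.020000, 0.940000]
  - [0.020000, 0.480000, 0.020000, 0.480000]
  - [0.020000, 0.480000, 0.020000, 0.480000]
- name: DCE_I
  consensus: CTTC
  expected_position: 6
  cutoff: {fraction: 0.8}
  matrix:
  - [0.020000, 0.940000, 0.020000, 0.020000]
  - [0.020000, 0.020000, 0.020000, 0.940000]
  - [0.020000, 0.020000, 0.020000, 0.940000]
  - [0.020000, 0.940000, 0.020000, 0.020000]
- name: DCE_II
  consensus: CTGT
  expected_position: 16
  cutoff: {fraction: 0.8}
  matrix:
  - [0.020000, 0.940000, 0.020000, 0.020000]
  - [0.020000, 0.020000, 0.020000, 0.940000]
  - [0.020000, 0.020000, 0.940000, 0.020000]
  - [0.020000, 0.020000, 0.020000, 0.940000]
- name: MTE
  consensus: CSARCSSAACGS
  expected_position: 18
  cutoff: {fraction: 0.8}
  matrix:
  - [0.020000, 0.940000, 0.020000, 0.020000]
  - [0.020000, 0.480000, 0.480000, 0.020000]
  - [0.940000, 0.020000, 0.020000, 0.020000]
  - [0.480000, 0.020000, 0.480000, 0.020000]
  - [0.020000, 0.940000, 0.020000, 0.020000]
  - [0.020000, 0.480000, 0.480000, 0.020000]
  - [0.020000, 0.480000, 0.480000, 0.020000]
  - [0.940000, 0.020000, 0.020000, 0.020000]
  - [0.940000, 0.020000, 0.020000, 0.020000]
  - [0.020000, 0.940000, 0.020000, 0.020000]
  - [0.020000, 0.020000, 0.940000, 0.020000]
  - [0.020000, 0.480000, 0.480000, 0.020000]
- name: PB
  consensus: KCGRWCG
  expected_position: 25
  cutoff: {fraction: 0.8}
  matrix:
  - [0.020000, 0.020000, 0.480000, 0.480000]
  - [0.020000, 0.940000, 0.020000, 0.020000]
  - [0.020000, 0.020000, 0.940000, 0.020000]
  - [0.480000, 0.020000, 0.480000, 0.020000]
  - [0.480000, 0.020000, 0.020000, 0.480000]
  - [0.020000, 0.940000, 0.020000, 0.020000]
  - [0.020000, 0.020000, 0.940000, 0.020000]
- name: DPE
  consensus: RGWYVT
  expected_position: 28
  cutoff: {fraction: 0.8}
  requires: Inr
  matrix:
  - [0.480000, 0.020000, 0.480000, 0.020000]
  - [0.020000, 0.020000, 0.940000, 0.020000]
  - [0.480000, 0.020000, 0.020000, 0.480000]
  - [0.020000, 0.480000, 0.020000, 0.480000]
  - [0.326667, 0.326667, 0.326667, 0.020000]
  - [0.020000, 0.020000, 0.020000, 0.940000]
- name: DCE_III
  consensus: AGC
  expected_position: 30
  cutoff: {fraction: 0.8}
  matrix:
  - [0.940000, 0.020000, 0.020000, 0.020000]
  - [0.020000, 0.020000, 0.940000, 0.020000]
  - [0.020000, 0.940000, 0.020000, 0.020000]
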