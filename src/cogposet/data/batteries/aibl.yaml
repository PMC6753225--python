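name: AIBL
tests:
  - name: CVLT delayed recall
    requires: [ATT, EM1, EM2, EM3]
  - name: CVLT word recognition
    requires: [ATT, EM1]
  - name: CVLT lists 1-5
    requires: [ATT, EM1, EM2]
  - name: CVLT list B
    requires: [ATT, EM1, EM2]
  - name: Boston naming
    requires: [ATT, VF]
  - name: Category fluency
    requires: [ATT, VF, CF]
  - name: Category switching
    requires: [ATT, VF, CF]
  - name: Stroop words
    requires: [ATT]
    orientation: lower-is-better
    response_kind: continuous-timed
  - name: Stroop colors
    requires: [ATT, CF]
    orientation: lower-is-better
    response_kind: continuous-timed
  - name: CogState detection
    requires: [ATT, PS]
    orientation: lower-is-better
  - name: CogState identification
    requires: [ATT, PS]
    orientation: lower-is-better
  - name: CogState one back
    requires: [ATT, EM1]
  - name: CogState one card learning
    requires: [ATT, EM1, EM2, PS]
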