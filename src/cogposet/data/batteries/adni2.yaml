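name: ADNI2
tests:
  - name: ADAS delayed recall
    requires: [ATT, EM1, EM2, EM3]
    orientation: lower-is-better
  - name: ADAS word recognition
    requires: [ATT, EM1]
    orientation: lower-is-better
  - name: AVLT list 6
    requires: [ATT, EM1, EM2, EM3]
  - name: AVLT list B
    requires: [ATT, EM1, EM2]
  - name: Boston naming
    requires: [ATT, VF]
  - name: Category fluency
    requires: [ATT, VF, CF]
  - name: ADAS number cancellation
    requires: [ATT]
    orientation: lower-is-better
  - name: Trails A
    requires: [ATT, PS]
    orientation: lower-is-better
    response_kind: continuous-timed
  - name: Trails B
    requires: [ATT, CF, PS]
    orientation: lower-is-better
    response_kind: continuous-timed
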