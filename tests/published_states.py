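"""Frozen published state tables for the two bundled batteries.

Each entry is the high-function label of one state, in state-index
order (1-based).  "CF*" marks cognitive flexibility undetermined by
confounding; the bottom state is the empty label.  One typographical
duplicate in the available rendering of the 9-test panel's table (its
row 13 repeating row 17) is corrected to the unique intermediate label
ATT EM1 EM2 PS.
"""

ADNI2_STATE_LABELS = [
    "ATT EM1 EM2 EM3 VF CF PS",
    "ATT EM1 EM2 EM3 VF CF",
    "ATT EM1 EM2 EM3 VF PS",
    "ATT EM1 EM2 EM3 VF",
    "ATT EM1 EM2 EM3 CF PS",
    "ATT EM1 EM2 EM3 PS",
    "ATT EM1 EM2 EM3 CF*",
    "ATT EM1 EM2 VF CF PS",
    "ATT EM1 EM2 VF CF",
    "ATT EM1 EM2 VF PS",
    "ATT EM1 EM2 VF",
    "ATT EM1 EM2 CF PS",
    "ATT EM1 EM2 PS",
    "ATT EM1 EM2 CF*",
    "ATT EM1 VF CF PS",
    "ATT EM1 VF CF",
    "ATT EM1 VF PS",
    "ATT EM1 VF",
    "ATT EM1 CF PS",
    "ATT EM1 PS",
    "ATT EM1 CF*",
    "ATT VF CF PS",
    "ATT VF CF",
    "ATT VF PS",
    "ATT VF",
    "ATT CF PS",
    "ATT PS",
    "ATT CF*",
    "",
]

AIBL_STATE_LABELS = [
    "ATT EM1 EM2 EM3 VF CF PS",
    "ATT EM1 EM2 EM3 VF CF",
    "ATT EM1 EM2 EM3 VF PS",
    "ATT EM1 EM2 EM3 VF",
    "ATT EM1 EM2 EM3 CF PS",
    "ATT EM1 EM2 EM3 CF",
    "ATT EM1 EM2 EM3 PS",
    "ATT EM1 EM2 EM3",
    "ATT EM1 EM2 VF CF PS",
    "ATT EM1 EM2 VF CF",
    "ATT EM1 EM2 VF PS",
    "ATT EM1 EM2 VF",
    "ATT EM1 EM2 CF PS",
    "ATT EM1 EM2 CF",
    "ATT EM1 EM2 PS",
    "ATT EM1 EM2",
    "ATT EM1 VF CF PS",
    "ATT EM1 VF CF",
    "ATT EM1 VF PS",
    "ATT EM1 VF",
    "ATT EM1 CF PS",
    "ATT EM1 CF",
    "ATT EM1 PS",
    "ATT EM1",
    "ATT VF CF PS",
    "ATT VF CF",
    "ATT VF PS",
    "ATT VF",
    "ATT CF PS",
    "ATT CF",
    "ATT PS",
    "ATT",
    "",
]
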