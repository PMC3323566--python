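# Default 8-category physicochemical amino-acid partition.
# One class per line: label: members (single-letter codes).
aliphatic: AVLIM
aromatic: FWY
hydroxyl: ST
amide: NQ
acidic: DE
basic: HKR
cysteine: C
conformational: GP
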