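# Shared polarity cues for tri-state findings.
# negate_before cues must fall within `negation_window` tokens before the
# feature head on the same line; affirm/negate_after apply after the head.
negation_window: 5
affirm:
  - '\bpresent\b'
  - '\bidentified\b'
  - '\bseen\b'
  - '\bpositive\b'
  - '\binvolv(?:ed|ing)\b'
negate_after:
  - '\babsent\b'
  - 'not\s+identified'
  - 'not\s+seen'
  - '\bnegative\b'
  - 'none\s+(?:identified|seen)'
  - 'no\s+evidence'
negate_before:
  - '\bno\b'
  - '\bwithout\b'
  - 'negative\s+for'
  - 'absence\s+of'
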