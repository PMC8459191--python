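# TIL grade: surface forms normalized into the Clark three-tier system.
# Value groups are tried in order; the first group with a match on the
# mention line wins ("nonbrisk" precedes "brisk" so that hyphenated
# "non-brisk" is never swallowed by the bare "brisk" pattern).
feature: til_grade
heads:
  - 'tumou?r[\s-]*infiltrating\s+lymphocytes(?:\s*\(tils?\))?'
  - '\btils?\b'
  - 'lymphocytic\s+host\s+response'
values:
  - target: nonbrisk
    patterns:
      - 'present\s*[\(\[]\s*non[\s-]?brisk\s*[\)\]]'
      - 'present,?\s+non[\s-]?brisk'
      - '\bnon[\s-]?brisk\b'
  - target: brisk
    patterns:
      - 'present,?\s+at\s+least\s+brisk'
      - 'present\s*[\(\[]\s*brisk\s*[\)\]]'
      - 'present,?\s+brisk'
      - '\bbrisk\b'
  - target: absent
    patterns:
      - '\babsent\b'
      - 'not\s+identified'
      - 'none\s+(?:identified|seen)'
      - '\bnone\b'
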