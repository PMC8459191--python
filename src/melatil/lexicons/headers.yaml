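# Recognized section headers, matched case-insensitively at line starts.
# Order is the display order only; matching is by regex alternation.
headers:
  - label: SPECIMENS
    pattern: 'specimen(?:\(s\)|s)?'
  - label: CLINICAL
    pattern: 'clinical\s+(?:history|data|information)'
  - label: GROSS
    pattern: 'gross\s+description'
  - label: MICROSCOPIC
    pattern: 'microscopic\s+description'
  - label: RESULTS
    pattern: 'results?'
  - label: DIAGNOSIS
    pattern: '(?:final\s+)?diagnosis'
  - label: SYNOPTIC
    pattern: 'synoptic\s+report'
  - label: COMMENT
    pattern: 'comment'
  - label: ADDENDUM
    pattern: 'addendum'
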