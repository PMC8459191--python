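# Mitotic rate per mm^2. Zero phrasings ("no mitotic figures identified",
# "<1/mm2") normalize to 0; a number without a per-area unit is unparseable.
feature: mitotic_rate
heads:
  - 'mitotic\s+(?:rate|index|activity|count|figures)'
  - '\bmitoses\b'
value_pattern: '(\d+(?:\.\d+)?)\s*(?:/|per\s+)\s*(?:mm2|mm²|mm\^?2|square\s+millimeter)'
zero_patterns:
  - 'no\s+mito(?:ses|tic\s+figures)\s+(?:identified|seen)'
  - '<\s*1\s*(?:/|per\s+)\s*(?:mm2|mm²|mm\^?2)'
  - 'less\s+than\s+1\s*(?:/|per\s+)\s*(?:mm2|mm²|mm\^?2)'
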