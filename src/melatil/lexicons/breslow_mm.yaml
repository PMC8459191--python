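# Breslow thickness in millimetres. The numeric group captures the value;
# "at least X mm" floors are reported as X.
feature: breslow_mm
heads:
  - 'breslow(?:\s+(?:thickness|depth))?'
  - 'depth\s+of\s+invasion'
  - '\bthickness\b'
value_pattern: '(?:at\s+least\s+|greater\s+than\s+|>\s*|≥\s*)?(\d+(?:\.\d+)?)\s*mm\b'
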