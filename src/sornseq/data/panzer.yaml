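# Canonical 20-element arm-movement sequences (lever task).
# Positions 1-4 are lead-in context elements (A1-A4 vs B1-B4); the remaining
# 16 elements encode target position and movement direction jointly
# (e.g. "2" = upward move into position 2, "3p" = downward move from 3,
# written 3' in the original notation).
alphabet: [A1, A2, A3, A4, B1, B2, B3, B4, "1p", "2", "2p", "3", "3p", "4"]
sequences:
  S1: [A1, A2, A3, A4, "2", "3", "4", "3p", "2p", "3", "2p", "1p", "2", "3", "2p", "3", "4", "3p", "2p", "1p"]
  S2: [B1, B2, B3, B4, "2", "3", "4", "3p", "2p", "1p", "2", "3", "2p", "3", "2p", "3", "4", "3p", "2p", "1p"]
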