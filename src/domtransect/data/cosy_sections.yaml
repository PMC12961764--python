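description: Approximate COSY section rectangles (f2_low, f2_high, f1_low, f1_high
  in ppm) for the 19 structural-motif sections a-s used in DOM analysis. Boundaries
  are editable; they follow common 1H shift ranges for the listed motifs.
sections:
  a:
  - - 0.0
    - 0.6
    - 0.0
    - 0.6
  - - 0.0
    - 0.6
    - 0.6
    - 1.05
  - - 0.6
    - 1.05
    - 0.0
    - 0.6
  - - 0.0
    - 0.6
    - 1.05
    - 1.9
  - - 1.05
    - 1.9
    - 0.0
    - 0.6
  b:
  - - 0.6
    - 1.05
    - 0.6
    - 1.05
  c:
  - - 0.6
    - 1.05
    - 1.05
    - 1.9
  - - 1.05
    - 1.9
    - 0.6
    - 1.05
  - - 1.05
    - 1.9
    - 1.05
    - 1.9
  d:
  - - 1.05
    - 1.9
    - 1.9
    - 2.3
  - - 1.9
    - 2.3
    - 1.05
    - 1.9
  - - 1.05
    - 1.9
    - 2.3
    - 3.0
  - - 2.3
    - 3.0
    - 1.05
    - 1.9
  e:
  - - 0.6
    - 1.05
    - 1.9
    - 2.3
  - - 1.9
    - 2.3
    - 0.6
    - 1.05
  - - 0.6
    - 1.05
    - 2.3
    - 3.0
  - - 2.3
    - 3.0
    - 0.6
    - 1.05
  f:
  - - 0.6
    - 1.05
    - 3.0
    - 4.3
  - - 3.0
    - 4.3
    - 0.6
    - 1.05
  g:
  - - 1.05
    - 1.9
    - 3.0
    - 4.3
  - - 3.0
    - 4.3
    - 1.05
    - 1.9
  h:
  - - 3.0
    - 4.3
    - 3.0
    - 4.3
  i:
  - - 1.05
    - 1.9
    - 4.3
    - 5.3
  - - 4.3
    - 5.3
    - 1.05
    - 1.9
  - - 1.9
    - 2.3
    - 4.3
    - 5.3
  - - 4.3
    - 5.3
    - 1.9
    - 2.3
  j:
  - - 3.0
    - 4.3
    - 4.3
    - 5.3
  - - 4.3
    - 5.3
    - 3.0
    - 4.3
  k:
  - - 4.3
    - 5.3
    - 4.3
    - 5.3
  l:
  - - 5.3
    - 6.5
    - 5.3
    - 6.5
  m:
  - - 0.6
    - 1.05
    - 5.3
    - 6.5
  - - 5.3
    - 6.5
    - 0.6
    - 1.05
  - - 1.05
    - 1.9
    - 5.3
    - 6.5
  - - 5.3
    - 6.5
    - 1.05
    - 1.9
  n:
  - - 5.3
    - 6.5
    - 6.5
    - 7.3
  - - 6.5
    - 7.3
    - 5.3
    - 6.5
  - - 5.3
    - 6.5
    - 7.3
    - 8.4
  - - 7.3
    - 8.4
    - 5.3
    - 6.5
  o:
  - - 6.5
    - 7.3
    - 6.5
    - 7.3
  p:
  - - 6.5
    - 7.3
    - 7.3
    - 8.4
  - - 7.3
    - 8.4
    - 6.5
    - 7.3
  - - 7.3
    - 8.4
    - 7.3
    - 8.4
  q:
  - - 7.3
    - 8.4
    - 8.4
    - 10.0
  - - 8.4
    - 10.0
    - 7.3
    - 8.4
  - - 8.4
    - 10.0
    - 8.4
    - 10.0
  r:
  - - 6.5
    - 7.3
    - 8.4
    - 10.0
  - - 8.4
    - 10.0
    - 6.5
    - 7.3
  s:
  - - 1.9
    - 2.3
    - 6.5
    - 7.3
  - - 6.5
    - 7.3
    - 1.9
    - 2.3
  - - 2.3
    - 3.0
    - 6.5
    - 7.3
  - - 6.5
    - 7.3
    - 2.3
    - 3.0
  - - 2.3
    - 3.0
    - 7.3
    - 8.4
  - - 7.3
    - 8.4
    - 2.3
    - 3.0
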