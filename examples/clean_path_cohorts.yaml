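# Recorded cohorts of the published no-DLT escalation path
cohorts:
- m:
  - 31
  - 47
  - 86
  b:
  - 10
  - 10
  - 10
  dlt:
  - 0
  - 0
  - 0
- m:
  - 66
  - 29
  - 44
  b:
  - 30
  - 30
  - 30
  dlt:
  - 0
  - 0
  - 0
- m:
  - 28
  - 56
  - 66
  b:
  - 60
  - 60
  - 60
  dlt:
  - 0
  - 0
  - 0
- m:
  - 18
  - 84
  - 83
  b:
  - 90
  - 90
  - 90
  dlt:
  - 0
  - 0
  - 0
- m:
  - 74
  - 30
  - 75
  b:
  - 90
  - 90
  - 90
  dlt:
  - 0
  - 0
  - 0
- m:
  - 82
  - 90
  - 10
  b:
  - 90
  - 90
  - 90
  dlt:
  - 0
  - 0
  - 0
- m:
  - 64
  - 60
  - 91
  b:
  - 90
  - 90
  - 90
  dlt:
  - 0
  - 0
  - 0
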