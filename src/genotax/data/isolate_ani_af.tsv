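# Pairwise comparison of the seven Lower Volga isolates.
# Lower triangle: OrthoANI (%). Upper triangle: alignment fraction AF (%).
strain	I-1	I-2	I-4	I-5	II-2	III-1	III-2
I-1	-	71.6	68.8	68.7	67.7	63.1	65.6
I-2	99.97	-	66.6	89.8	66.1	62.4	64.5
I-4	99.93	99.94	-	67.1	64.4	63.4	63.4
I-5	99.96	99.98	99.93	-	65.1	62.4	64.7
II-2	99.78	99.80	99.77	99.81	-	65.0	66.9
III-1	99.72	99.73	99.77	99.74	99.74	-	64.8
III-2	99.79	99.70	99.77	99.74	99.70	99.80	-
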