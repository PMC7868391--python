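label	x_mm	y_mm	z_mm
F3	-2.0	5.0	5.0
F4	2.0	5.0	5.0
C3	-3.2	2.2	5.0
C4	3.2	2.2	5.0
P3	-2.5	-3.8	5.0
P4	2.5	-3.8	5.0
P5	-4.5	-4.5	5.0
P6	4.5	-4.5	5.0
T3	-7.2	-3.6	5.0
T4	7.2	-3.6	5.0
T5	-5.8	-8.3	5.0
T6	5.8	-8.3	5.0
Ref	0.0	7.5	5.0
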