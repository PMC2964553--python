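stratum	Caucasian
.	11	13	33
11	0	0	1
13	0	9	36
33	2	29	201

stratum	Female/African-American
.	11	13	33
11	1	11	8
13	8	26	40
33	4	34	24

stratum	Male/African-American
.	11	13	33
11	1	2	5
13	1	14	17
33	1	11	11
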