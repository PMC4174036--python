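condition	label	x	y	z	radius
rest	PCC	-6	-60	28	6
rest	lIPC	-42	-66	44	6
rest	MPFC	1	50	24	6
rest	rIPC	48	-57	36	6
rest	rITC	63	-27	-20	6
rest	lITC	-59	-21	-20	6
rest	lHC	-24	-12	-28	6
rest	rHC	24	-30	-16	6
task	PCC	-1	-63	24	6
task	lIPC	-45	-69	39	6
task	MPFC	-6	54	28	6
task	rIPC	52	-66	28	6
task	rITC	54	6	-36	6
task	lITC	-51	-9	-28	6
task	lHC	-24	-12	-28	6
task	rHC	24	-30	-16	6
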