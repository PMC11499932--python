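inversion	sample	proximal	distal	consensus_proximal	consensus_distal	shift_proximal	shift_distal
Chr6	CS2	22282765	25427801	22282765	24868582	-	559219
Chr6	CS4	22282765	24869682	22282765	24868582	-	1100
Chr6	CS7	22282765	24869682	22282765	24868582	-	1100
Chr6	CS10	22282765	24869682	22282765	24868582	-	1100
Chr12	BS1	17826318	25603093	17826318	25603093	-	-
Chr12	BS2	17826318	25603093	17826318	25603093	-	-
Chr12	BS3	17826318	25603093	17826318	25603093	-	-
Chr12	BS4	17826318	25603093	17826318	25603093	-	-
Chr12	BS5	17826318	25603093	17826318	25603093	-	-
Chr12	BS6	17826318	25603093	17826318	25603093	-	-
Chr17	CS2	25802209	27568510	25802209	27568510	-	-
Chr17	CS4	25802209	27568510	25802209	27568510	-	-
Chr17	CS5	25802212	27568510	25802209	27568510	3	-
Chr17	CS7	25802212	27568510	25802209	27568510	3	-
Chr17	CS8	25802209	27568510	25802209	27568510	-	-
Chr17	CS10	25802209	27568510	25802209	27568510	-	-
Chr23	BS1	16225343	17604279	16225343	17604279	-	-
Chr23	BS2	16216922	17604291	16225343	17604279	8421	12
Chr23	BS3	16225343	17604291	16225343	17604279	-	12
Chr23	BS4	16225343	17604279	16225343	17604279	-	-
Chr23	BS5	16225343	17604277	16225343	17604279	-	2
Chr23	BS6	16226443	17603173	16225343	17604279	1100	1106
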