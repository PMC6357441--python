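pup_id	sex	H2Afb3	Gm14920	H2Afb2
L74-1	female	XX (wt)	XX (wt)	XX (wt)
L74-2	female	XX (wt)	XX (wt)	XX (wt)
L74-3	female	XX (wt)	XX (wt)	XX (wt)
L74-4	male	XY (wt)	XY (wt)	XY (wt)
L74-5	male	X^∆5+286 Y	X^∆15 Y	X^∆17 Y
L79-1	female	X^Δ10 X^Δ10	X^Δ12 X^Δ12 Chimera of b/Δ/c	X^Δ15 X^Δ15 Chimera of c/Δ/b
L89-1	female	X^Δ22 X^Δ160	X^Δ5 X^Δ17 Chimera c/Δ/b)	X^Δ5 X^Δ5
L89-2	male	X^Δ65 Y	X^C/T,A/G Y	X^Δ42 Y Chimera b/Δ/c)
L89-3	male	X^Δ26 Y Chimera c/Δ/a)	X^Δ10 Y Chimera b/Δ/c)	X^Δ10 Y Chimera b/Δ/c)
L90-1	female	XX (wt)	XX (wt)	XX (wt)
L90-2	female	XX (wt)	XX (wt)	XX (wt)
L90-3	female	X^Δ28 X^Δ5	X^Δ10 X^Δ10	X^Δ64 X^Δ64
L90-4	female	X^Δ15 X^Δ10	No successful PCR amplification	No successful PCR amplification.
L90-5	female	XX (wt)	XX (wt)	XX (wt)
L90-6	female	X^Δ17 X^Δ17 Chimera of c/Δ/a	X^Δ5 X^Δ5 Chimera of b/Δ/c	X^Δ5 X^Δ5 Chimera of c/b/Δ/c
L90-7	female	XX (wt)	XX (wt)	XX (wt)
L90-8	male	X^Δ16 Y	X^Δ17 Y Chimera of c/Δ/c/b	No successful PCR amplification.
L90-9	male	XY (wt)	XY (wt)	XY (wt)
L90-10	male	XY (wt)	XY (wt)	XY (wt)
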