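name	targets	composition	delta_mass	role
la	K	C3H4O2	72.021129	target
ac	K	C2H2O	42.010565	background
cr	K	C4H4O	68.026215	target
hib	K	C4H6O2	86.036779	target
bz	K	C7H4O	104.026215	target
me1	K	CH2	14.015650	background
me2	K	C2H4	28.031300	background
me3	K	C3H6	42.046950	background
rme1	R	CH2	14.015650	background
rme2	R	C2H4	28.031300	background
cam	C	C2H3NO	57.021464	background
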