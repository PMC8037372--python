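# Published reference bond-critical-point properties for the two short HBs in
# the dark-state PYP active site (DFT-quality electron density, atomic units;
# BCP-to-atom distances in Å). These are inputs to the energy-density and
# classification stages; the package never regenerates them.
# bcp	pair	side	connects	rho_au	lap_au	d_bcp_o_A	d_bcp_h_A
b1	E46	donor	OE46-H1	1.70e-1	-2.83e-1	0.91	0.31
b2	E46	acceptor	OpCA-H1	1.44e-1	-1.06e-1	0.94	0.34
b3	Y42	acceptor	OpCA-H2	6.71e-2	1.51e-1	1.05	0.49
b4	Y42	donor	OY42-H2	3.42e-1	-2.72	0.77	0.21
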