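# pure water absorption, literature-shaped compilation (NIR window, 970 nm peak)
# columns: wavelength_nm	mu_a_per_cm
650	0.0034
660	0.004
670	0.0045
680	0.005
690	0.0055
700	0.006
710	0.0105
720	0.016
730	0.0215
740	0.0261
750	0.026
760	0.027
770	0.024
780	0.0233
790	0.0227
800	0.0224
810	0.0265
820	0.0307
830	0.0336
840	0.0385
850	0.0433
860	0.0466
870	0.051
880	0.0557
890	0.0605
900	0.0679
910	0.0849
920	0.112
930	0.148
940	0.2236
950	0.3072
960	0.388
970	0.4497
980	0.462
990	0.454
1000	0.442
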