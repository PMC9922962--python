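# pure lipid (fat) absorption, literature-shaped compilation with the 930 nm NIR peak
# columns: wavelength_nm	mu_a_per_cm
650	0.032
660	0.03
670	0.029
680	0.029
690	0.03
700	0.032
710	0.036
720	0.042
730	0.05
740	0.055
750	0.058
760	0.065
770	0.072
780	0.08
790	0.09
800	0.1
810	0.115
820	0.135
830	0.17
840	0.2
850	0.23
860	0.26
870	0.3
880	0.37
890	0.48
900	0.64
910	0.85
920	1.04
930	1.12
940	0.93
950	0.6
960	0.43
970	0.35
980	0.32
990	0.32
1000	0.34
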