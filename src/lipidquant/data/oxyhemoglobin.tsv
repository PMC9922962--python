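# oxyhemoglobin absorption of whole blood (150 g Hb/L), from compiled molar extinction coefficients
# columns: wavelength_nm	mu_a_per_cm
650	1.97094
660	1.71172
670	1.57461
680	1.48677
690	1.4782
700	1.55319
710	1.68173
720	1.86382
730	2.08877
740	2.38869
750	2.77431
760	3.13851
770	3.48128
780	3.80263
790	4.1454
800	4.37034
810	4.62742
820	4.90593
830	5.21656
840	5.47364
850	5.66645
860	5.84855
870	6.04136
880	6.18061
890	6.30915
900	6.41627
910	6.48053
920	6.52338
930	6.5448
940	6.55552
950	6.53409
960	6.50196
970	6.4484
980	6.37342
990	6.27701
1000	6.15919
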