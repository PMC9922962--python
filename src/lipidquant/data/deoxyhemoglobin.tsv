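# deoxyhemoglobin absorption of whole blood (150 g Hb/L), from compiled molar extinction coefficients
# columns: wavelength_nm	mu_a_per_cm
650	20.0843
660	17.2832
670	14.9695
680	12.8914
690	10.9848
700	9.60833
710	8.68713
720	7.65881
730	6.98934
740	7.16608
750	7.76593
760	8.2908
770	7.44458
780	6.32522
790	5.08802
800	4.07577
810	3.84547
820	3.71158
830	3.64195
840	3.65267
850	3.70087
860	3.7812
870	3.85619
880	3.92046
890	3.98473
900	4.03828
910	4.08113
920	4.12398
930	4.16682
940	4.20967
950	4.23109
960	4.23109
970	4.20967
980	4.16682
990	4.10255
1000	4.01686
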