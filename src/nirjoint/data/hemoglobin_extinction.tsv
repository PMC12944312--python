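# Molar extinction coefficients of human hemoglobin, abridged NIR compilation
# (Prahl tabulation family, as distributed at omlc.org/spectra)
# columns: wavelength_nm  eps_hbo2_cm^-1_M^-1  eps_hb_cm^-1_M^-1
650	368.0	3750.12
660	319.6	3226.56
680	277.6	2407.92
690	276.0	2051.96
700	290.0	1794.28
710	314.0	1540.48
720	348.0	1325.88
730	390.0	1102.20
740	446.0	1115.88
750	518.0	1405.24
760	586.0	1548.52
770	650.0	1311.88
780	710.0	1075.44
790	756.0	890.80
800	816.0	761.72
810	864.0	717.08
820	916.0	693.76
830	974.0	693.04
840	1022.0	692.36
850	1058.0	691.32
860	1092.0	692.12
880	1154.0	726.44
900	1198.0	761.84
920	1234.0	797.04
940	1214.0	800.92
950	1204.0	785.96
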