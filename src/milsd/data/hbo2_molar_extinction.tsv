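# Molar extinction coefficient of oxyhemoglobin (HbO2), cm^-1 / M
# Standard compiled literature values, 660-1000 nm.
# wavelength_nm	epsilon
660	319.6
680	277.6
700	290.0
720	324.7
740	446.0
760	586.0
780	710.0
800	816.0
820	916.0
840	1022.0
860	1058.0
880	1154.0
900	1198.0
920	1226.0
940	1214.0
960	1170.0
980	1102.0
1000	1050.0
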