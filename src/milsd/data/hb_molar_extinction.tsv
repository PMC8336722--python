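# Molar extinction coefficient of deoxyhemoglobin (Hb), cm^-1 / M
# Standard compiled literature values, 660-1000 nm.
# wavelength_nm	epsilon
660	3226.6
680	2407.9
700	1794.3
720	1540.5
740	1405.2
760	1548.5
780	1075.4
800	761.7
820	693.8
840	692.4
860	726.4
880	761.8
900	792.4
920	825.9
940	803.6
960	685.9
980	530.5
1000	468.0
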