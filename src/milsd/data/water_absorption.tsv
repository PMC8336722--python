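# Absorption coefficient of pure water, cm^-1
# Standard compiled literature values, 660-1000 nm.
# wavelength_nm	mu_a
400	0.00058
450	0.00029
500	0.00025
550	0.00045
600	0.00240
620	0.00280
640	0.00310
660	0.0041
680	0.0047
700	0.0062
720	0.0104
740	0.0268
760	0.0256
780	0.0235
800	0.0223
820	0.0279
840	0.0364
860	0.0486
880	0.0550
900	0.0679
920	0.1150
940	0.2670
960	0.3900
980	0.4300
1000	0.3630
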