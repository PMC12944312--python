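# Pure-water absorption coefficient, abridged NIR compilation
# (Hale & Querry 1973 / Segelstein 1981 family, as distributed at omlc.org/spectra)
# columns: wavelength_nm  mua_cm^-1
650	0.00340
675	0.00450
700	0.00624
725	0.01489
750	0.02620
775	0.02410
800	0.02070
825	0.02820
850	0.04300
875	0.05580
900	0.06790
925	0.14400
950	0.27800
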