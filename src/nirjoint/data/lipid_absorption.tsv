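# Purified-lipid absorption coefficient, NIR digitization
# (van Veen purified-oil family; published digitizations of this spectrum scatter
#  by ~10% in the 800-880 nm trough, which bounds the accuracy of lipid-rich mixes)
# columns: wavelength_nm  mua_cm^-1
650	0.00950
680	0.00720
700	0.00640
720	0.00620
740	0.00740
760	0.00900
780	0.00760
800	0.00690
820	0.00660
840	0.00645
850	0.00640
860	0.00645
880	0.00760
900	0.01600
910	0.02900
920	0.06200
930	0.11000
940	0.08800
950	0.05200
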