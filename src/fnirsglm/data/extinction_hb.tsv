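# Molar extinction coefficients of hemoglobin in 1/(mM*cm),
# interpolated from the standard compiled in-vitro spectra.
wavelength_nm	hbo	hbr
690	0.2764	2.0515
730	0.3900	1.1022
740	0.4383	1.3386
760	0.5862	1.5485
769	0.6398	1.3269
780	0.7360	1.1050
808	0.8440	0.7861
830	0.9740	0.6931
850	1.0580	0.6913
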