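# Chromophore optical data at the eight measurement wavelengths, version 1.
# SYNTHETIC STAND-IN: values compiled/rounded from standard visible/NIR
# literature magnitudes (hemoglobin molar extinction, pure water and pure
# lipid absorption) and cross-checked against the dermis transport mean
# free paths (0.21 mm @ 526 nm, 0.46 mm @ 851 nm) and the dermal
# scattering-to-absorption ratio span (~17 to ~400) this model assumes.
# Units: eps_* in cm^-1 M^-1, mua_* in cm^-1.
wavelength_nm,eps_hbo2_cm_M,eps_hb_cm_M,mua_water_cm,mua_lipid_cm,source
471,32500,16000,0.00012,0.010,compiled-vis-nir-v1-synthetic
526,23500,25000,0.00045,0.006,compiled-vis-nir-v1-synthetic
591,11500,25000,0.0015,0.004,compiled-vis-nir-v1-synthetic
621,1100,9200,0.0028,0.003,compiled-vis-nir-v1-synthetic
691,277,2050,0.0050,0.002,compiled-vis-nir-v1-synthetic
731,390,1100,0.0191,0.003,compiled-vis-nir-v1-synthetic
811,864,717,0.0209,0.006,compiled-vis-nir-v1-synthetic
851,1058,691,0.0430,0.008,compiled-vis-nir-v1-synthetic
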