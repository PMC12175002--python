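# Subcutaneous (adipose) reduced scattering at the eight measurement
# wavelengths, version 1.  SYNTHETIC STAND-IN: Mie-type power law
# musp = 122 * lambda_nm^-0.685 (mm^-1), anchored so that subcutis
# musp stays below dermal musp across 471-851 nm, consistent with
# published adipose-tissue magnitudes.  Override via configuration to
# use a different compilation.
wavelength_nm,musp_mm,source
471,1.797,powerlaw-adipose-v1-synthetic
526,1.669,powerlaw-adipose-v1-synthetic
591,1.542,powerlaw-adipose-v1-synthetic
621,1.490,powerlaw-adipose-v1-synthetic
691,1.385,powerlaw-adipose-v1-synthetic
731,1.333,powerlaw-adipose-v1-synthetic
811,1.241,powerlaw-adipose-v1-synthetic
851,1.201,powerlaw-adipose-v1-synthetic
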