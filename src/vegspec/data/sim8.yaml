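# Simulated 8-band set: nominal published Landsat 8 OLI band centres and FWHM
# in nm, excluding the panchromatic band.  Nominal sensor specifications.
name: sim8
bands:
  - {name: B1_coastal, centre_nm: 443.0, fwhm_nm: 16.0}
  - {name: B2_blue, centre_nm: 482.0, fwhm_nm: 60.0}
  - {name: B3_green, centre_nm: 561.5, fwhm_nm: 57.0}
  - {name: B4_red, centre_nm: 654.5, fwhm_nm: 37.0}
  - {name: B5_nir, centre_nm: 865.0, fwhm_nm: 28.0}
  - {name: B9_cirrus, centre_nm: 1373.5, fwhm_nm: 20.0}
  - {name: B6_swir1, centre_nm: 1608.5, fwhm_nm: 85.0}
  - {name: B7_swir2, centre_nm: 2200.5, fwhm_nm: 187.0}
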